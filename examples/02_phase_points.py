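"""The four stationary regimes of the gradient cylinder.

Measures the normalized mean payoff at one representative (b, w) point
per regime on the 50x50 gradient cylinder (desk-scale protocol):

  near-full cooperation   payoff ~ 1    high b, weak selection
  near-full defection     payoff ~ 0    low b, moderate selection
  majority-favouring      payoff ~ 3/4  high b, strong selection
  minority-favouring      payoff ~ 1/4  low b, strong selection

plus one point (b = 3.5, w = 1) in the crossover band between the
discriminating regimes, where the stationary state is a stable mixture
of the two one-sided strategies and the payoff sits between 1/4 and 3/4.
"""

from labelgame import (
    ModelParams,
    ScanProtocol,
    assign_labels_gradient,
    build_cylinder,
    run_point,
)

POINTS = [
    ("near-full cooperation", 6.0, 0.02),
    ("near-full defection  ", 2.0, 0.02),
    ("majority-favouring   ", 8.0, 1.0),
    ("minority-favouring   ", 2.5, 1.0),
    ("crossover mixture    ", 3.5, 1.0),
]

protocol = ScanProtocol(transient_steps=10_000_000, n_samples=20, sample_window=10_000_000)
graph = build_cylinder(50, 50)

print(f"{'regime':<22} {'b':>4} {'w':>5}  payoff  discrimination")
for name, b, w in POINTS:
    labels = assign_labels_gradient(graph, seed=7)
    pt = run_point(ModelParams(b=b, w=w, mu=0.001), graph, labels, protocol, seed=7)
    print(f"{name:<22} {b:>4} {w:>5}  {pt.mean_payoff_norm:.3f}   {pt.discrimination_index:.3f}")
print()
print("payoff = realized donations / all directed neighbour pairs;")
print("discrimination = population share of the two one-sided strategies.")
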