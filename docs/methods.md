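# Methods

## The model

Agents occupy the nodes of an undirected graph. Each agent *i* carries an
immutable binary label λ_i ∈ {blue, green} — an observable tag with no
intrinsic payoff consequence — and a mutable strategy, one of four
label-conditional action rules: cooperate with all, cooperate only with
green, cooperate only with blue, defect all. Writing S_i(λ) ∈ {0, 1} for
whether agent *i*'s strategy donates to a partner wearing label λ, the
game is a donation game: a cooperator pays one unit and the recipient
gains b > 1 units. Payoff is a function of the current configuration
only (it never accumulates):

    p_i = Σ_{j∈N_i} [ b · S_j(λ_i) − S_i(λ_j) ].

Payoff maps to fitness exponentially, f_i = exp(w · p_i), with selection
pressure w ≥ 0. The exponential keeps fitness positive at any w, so the
deterministic copy-the-best limit (w = ∞) is well defined.

Dynamics are asynchronous. One event: a uniformly random focal agent
either mutates (probability μ, resampling its strategy uniformly from
all four, so the effective change probability is 3μ/4) or copies the
strategy of a neighbour drawn with probability proportional to fitness.
The focal agent itself is never a copy candidate; copying an identical
strategy is a legal no-op. "Time" counts single events, not sweeps. At
w = 0 the imitation dynamics reduce to a four-opinion voter model.

Parameters, units, defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| b | cooperation benefit (dimensionless) | per experiment | must exceed 1 |
| w | selection pressure (per payoff unit) | per experiment | 0 = neutral drift, ∞ = copy-the-best |
| μ | mutation probability per event | 0.001 | keeps strategies from going extinct while adding little noise |

## Topologies and label fields

The reference topology is a width-W, height-H square-lattice *cylinder*:
periodic in the width direction, open in the height direction, with von
Neumann 4-neighbourhoods (degree 3 on the two open rows, no ghost
cells). The open axis carries the label gradient: an agent in row r is
green with probability r/(H−1), independently. Row 0 is therefore all
blue and row H−1 all green; the expected overall green fraction is 1/2
and the expected local-majority fraction within each half is 3/4. This
field is what the generators emulate: a population with a smooth spatial
composition gradient, giving each half a clear regional majority. It
deliberately omits features of real social systems — correlated label
clusters, degree heterogeneity, community structure, label-strategy
correlations at initialization — so simulation results here demonstrate
the mechanism (imitation-driven hierarchical discrimination), not a
calibrated prediction for any empirical network.

Also provided: torus, ring, open line, Erdős–Rényi G(n, p) (isolated
nodes permitted but flagged; their update events are wasted), uniform
Bernoulli label fields, and the 1D fields of the wall analysis (a single
green agent mid-line; short patterns tiled along the line).

## Measurement protocol

Each (b, w) point starts from the all-defector state, discards a
transient, then averages the normalized mean payoff — realized donations
divided by directed neighbour pairs, equal to Σp / (E(b−1)) — and the
four strategy shares over evenly spaced samples. Phase scans draw a
fresh label field per grid cell (per-cell seeds from a SeedSequence), so
no result hinges on one particular label layout. Per-sample dispersion
is reported so stochastic tolerances can be set from the measured SEM.

Problem sizes were chosen so the full test suite and the acceptance
script each run in minutes on one core: the desk-scale protocol uses a
50×50 cylinder with a 5×10⁶-event transient and 20 samples over 10⁷
events (≈ 6 000 sweeps of burn-in). The package supports the full-scale
protocol (100×100, 2×10⁷ + 10⁸ events) through configuration, and spot
checks at that scale reproduce the desk-scale phase structure.

## Stationary regimes of the gradient cylinder

Four regimes appear in the (b, w) plane (payoff = normalized mean payoff):

* **near-full cooperation** (payoff ≈ 0.93–0.94 at 50×50): b above the
  lattice connectivity (~4) and weak-but-nonzero selection, w ≈ 0.02–0.03;
* **near-full defection** (payoff ≈ 0.02–0.05): b ≈ 2, w ≳ 0.02;
* **majority-favouring discrimination** (payoff ≈ 3/4): b ≳ 4 at strong
  selection — each half cooperates only with its regional majority label,
  producing a hierarchy in which minority agents donate to the majority
  without reciprocation;
* **minority-favouring discrimination** (payoff ≈ 1/4): b ≈ 2–3 at strong
  selection — the one-sided strategies survive but each half's donations
  flow to its regional minority.

Two caveats matter when comparing specific coordinates against these
regimes, both measured by the examples and acceptance tests rather than
assumed. First, at very low selection pressure (w ≲ 0.01) mutation noise
and voter-like mixing keep the stationary state a patchy mixture of all
four strategies: measured payoffs sit at intermediate values (≈ 0.15–0.45
depending on b) and move *away* from the pure-phase values as the
transient is extended. In particular, at b = 3.5 the payoff never falls
below ≈ 0.15 at any w ∈ [0.003, 0.3] at this system size, so a
"departure from zero payoff" threshold does not exist on that cut; the
near-zero regime requires lower b. Second, the band between the two
discriminating regimes is wide: at b = 3.5, w = 1 the stationary state
is a stable mixture of the two one-sided strategies (payoff ≈ 0.55–0.65
at both 50×50 and 100×100), not the minority-favouring state; that state
is robust at b ≤ 3.

## 1D domain-wall theory

With mutation off, end strategies pinned (full cooperation on the left,
cooperate-with-blue on the right), nearest-neighbour copying on a line
preserves the two-domain structure exactly, so the state reduces to the
wall position k (agents 0..k cooperate with all; the rest cooperate with
blue). The wall is a birth–death chain: it moves right only when focal
agent k+1 copies leftwards across it, left only when focal agent k
copies rightwards, with two-candidate fitness-proportional probabilities
computed from the explicit configuration's payoffs. Stationary weights
follow from detailed balance, π_{k+1}/π_k = P_right(k)/P_left(k+1),
accumulated in the log domain to avoid overflow at large w·b.

For the single-green line the bias is confined to the four wall
positions within three steps of the green agent, and the product of the
four biased ratios telescopes to exp(−2w)·(tanh(wb)+1): the stationary
odds of finding the wall on the discriminating side (the side where the
green agent is covered by cooperate-with-blue) approach

    R(w, b) = exp(2w) / (tanh(wb) + 1)

in the long-line limit. The implementation reproduces this to machine
precision from the stepping probabilities alone. R > 1 — one-sided
cooperation beats full cooperation — requires w above a critical value;
as b → ∞, R → exp(2w)/2 and the threshold tends to log(2)/2 ≈ 0.3466.

Two aggregation conventions are exposed, because they answer different
questions. `sides="finite"` sums stationary weights over wall positions
on each side of the green agent for the given finite line; this is
exactly what the Monte-Carlo oracle measures on the same line, so the
chain-versus-simulation comparison is apples to apples (the default
41-agent line keeps pinned-end corrections visible but small).
`sides="infinite"` takes the ratio of the two far-field plateau weights
(probes at least two positions clear of the pinned ends and of the
biased window), which is the limit of the mass ratio as both sides grow
and equals the closed form exactly. Wall positions are classified by
which strategy the green agent itself holds, which pins the side cut
unambiguously.

For a label pattern of period P tiled along the line, the same machinery
compares stationary weights one period apart (a phase-aligned product of
P consecutive detailed-balance ratios taken in the translation-invariant
bulk) and locates the benefit b* where the ratio crosses 1 by Brent
root-finding on b ∈ [1+10⁻⁶, 64] to |Δb| ≤ 10⁻⁶. A pattern with no
green agent makes the two strategies behave identically — the ratio is
identically 1 and a no-crossing sentinel (NaN) is returned, distinct
from a numerical failure (raised). The perfectly alternating pattern
crosses at b* = 2 independent of w; so does the all-green pattern, whose
one-period ratio is exp(w(b−2)). Not every pattern has a crossing in the
search bracket.

## Monte-Carlo oracle

`monte_carlo_boundary` simulates the actual pinned-end 1D dynamics
(compiled event loop; ends excluded from focal selection) and samples
which side of the green agent the wall occupies every n events. Samples
along the walk are strongly autocorrelated — the wall's relaxation time
is of order n³ events — so the standard error uses batch means over 16
long blocks of the post-burn-in samples (first 10% discarded), delta-
method-propagated to the odds. With runs much longer than the relaxation
time this estimate is calibrated to within a few tens of percent, which
the 3-standard-error agreement tests absorb. The sampler also counts
states whose two-domain structure is broken; with a two-domain start
this count is provably zero and is asserted to be so.

## Numerical choices

* Selection probabilities are computed as exp(w·(p − max p)) normalized —
  invariant to common payoff offsets and immune to overflow; w = ∞ takes
  an argmax with uniform tie-breaking over exactly co-maximal payoffs.
* The event loops are numba-compiled; each call seeds the kernel RNG from
  the state's generator, so runs are pure functions of the initial seed.
  A pure-Python `step` implements the identical update law through the
  library's public payoff/selection functions and is cross-checked
  against the kernel statistically.
* Detailed-balance weights are accumulated as log-sums; side masses use
  `logsumexp`. In the deterministic limit some stepping probabilities
  vanish and parts of the chain become unreachable; this raises a
  dedicated error naming the position rather than returning weights.
* Phase-scan cells that fail are recorded (NaN row + error entry) and the
  scan continues.

## Known limitations

* The boundary theory assumes the two-domain structure; on lattices of
  dimension ≥ 2 no analogous reduction exists and the package makes no
  analytic claims there.
* Batch-means errors modestly under-report for runs shorter than ~50
  relaxation times; use longer runs when an accurate error bar matters.
* Low-selection-pressure observables at desk scale are mixing-limited:
  they equilibrate to noisy mixtures, and pushing the transient longer
  moves them toward those mixtures, not toward the pure phases.
* The phase boundaries quoted above are for the 50×50 gradient cylinder
  with μ = 0.001; they shift with system size, mutation rate, and label
  field.
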