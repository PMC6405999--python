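"""Measurement protocol and phase scans.

The central observable is the *normalized mean payoff*: the number of
realized donations divided by the number of directed neighbour pairs.
It is 1 under full cooperation, 0 under full defection, and — because
every realized donation contributes ``b - 1`` to the payoff sum — equals
``sum_i p_i / (E * (b - 1))`` for E directed pairs.

A measurement point starts from the all-defector state, discards a
transient, then averages the observables over evenly spaced samples.
On the gradient cylinder four regimes appear in the (b, w) plane:

* near-full cooperation (payoff ~ 1) at high b, low w;
* near-full defection (payoff ~ 0) at low b, low w;
* majority-favouring discrimination (payoff ~ 3/4) at high b, high w;
* minority-favouring discrimination (payoff ~ 1/4) at moderate b, high w.

The desk-scale default (50x50 lattice, 5e6-event transient, 20 samples
over 1e7 events) resolves these regimes in minutes; the original
full-scale protocol (100x100, 2e7 + 1e8 events) is available by
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import ModelParams, SimState, Strategy, ACTION, run_events
from .populations import PopulationGraph, build_cylinder, assign_labels_gradient

__all__ = [
    "ScanProtocol",
    "PointResult",
    "ScanResult",
    "normalized_mean_payoff",
    "strategy_shares",
    "discrimination_index",
    "regional_strategy_shares",
    "run_point",
    "phase_scan",
]


@dataclass(frozen=True)
class ScanProtocol:
    """Sampling protocol for one phase-scan.

    ``transient_steps`` events are discarded after the all-defector
    initialization; observables are then averaged over ``n_samples``
    states spaced evenly across ``sample_window`` further events.
    """

    b_grid: tuple = (2.0, 3.5, 5.0, 6.5, 8.0)
    w_grid: tuple = (0.003, 0.01, 0.03, 0.1, 0.3, 1.0)
    width: int = 50
    height: int = 50
    transient_steps: int = 5_000_000
    n_samples: int = 20
    sample_window: int = 10_000_000
    mu: float = 0.001
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.b_grid) == 0 or len(self.w_grid) == 0:
            raise ValueError("parameter grids must be non-empty")


@dataclass
class PointResult:
    """Observables measured at one (b, w) grid cell."""

    b: float
    w: float
    seed: int
    mean_payoff_norm: float
    sem_payoff_norm: float
    shares: np.ndarray  # mean share per StrategyCode, ordered by code
    discrimination_index: float
    payoff_samples: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ScanResult:
    """Phase-scan output: one table row per grid cell plus metadata."""

    table: pd.DataFrame
    protocol: ScanProtocol
    errors: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.9g")


def normalized_mean_payoff(state: SimState, b: float | None = None) -> float:
    """Fraction of realized donations among all directed neighbour pairs.

    Independent of *b* (the argument is accepted for signature symmetry
    with the payoff-based identity ``sum p / (E * (b - 1))``).  Raises on
    an empty edge set.
    """
    g = state.graph
    if g.n_directed_edges == 0:
        raise ValueError("normalized mean payoff undefined on an edgeless graph")
    src = np.repeat(np.arange(g.n_agents), np.diff(g.indptr))
    donations = int(ACTION[state.strategies[src], state.labels[g.indices]].sum())
    return donations / g.n_directed_edges


def strategy_shares(state: SimState) -> np.ndarray:
    """Fractions of agents holding each strategy, ordered by Strategy code."""
    return np.bincount(state.strategies, minlength=4) / state.n_agents


def discrimination_index(state: SimState) -> float:
    """Combined population share of the two discriminating strategies."""
    s = strategy_shares(state)
    return float(s[Strategy.COOP_GREEN] + s[Strategy.COOP_BLUE])


def regional_strategy_shares(state: SimState) -> dict:
    """Strategy shares within the two halves along the gradient axis.

    The regional hierarchies of the discriminating phases live in the
    blue-majority and green-majority halves separately, so per-half
    shares are the natural diagnostic.  Cylinder topologies only.
    """
    height = state.graph.gradient_axis_length
    width = state.graph.dims[0]
    half = (height // 2) * width
    lower = np.bincount(state.strategies[:half], minlength=4) / half
    upper = np.bincount(state.strategies[half:], minlength=4) / (state.n_agents - half)
    return {"blue_majority_half": lower, "green_majority_half": upper}


def run_point(
    params: ModelParams,
    graph: PopulationGraph,
    labels: np.ndarray,
    protocol: ScanProtocol,
    seed: int,
) -> PointResult:
    """Measure one parameter point: all-defector init, transient, sampling."""
    state = SimState(
        graph=graph,
        labels=labels,
        strategies=np.full(graph.n_agents, Strategy.DEFECT_ALL, dtype=np.uint8),
        rng=np.random.default_rng(seed),
    )
    run_events(state, params, protocol.transient_steps)
    spacing = max(protocol.sample_window // protocol.n_samples, 1)
    payoffs = np.empty(protocol.n_samples)
    shares = np.empty((protocol.n_samples, 4))
    for s in range(protocol.n_samples):
        run_events(state, params, spacing)
        payoffs[s] = normalized_mean_payoff(state)
        shares[s] = strategy_shares(state)
    mean_shares = shares.mean(axis=0)
    sem = float(payoffs.std(ddof=1) / np.sqrt(len(payoffs))) if len(payoffs) > 1 else 0.0
    return PointResult(
        b=params.b,
        w=params.w,
        seed=seed,
        mean_payoff_norm=float(payoffs.mean()),
        sem_payoff_norm=sem,
        shares=mean_shares,
        discrimination_index=float(mean_shares[Strategy.COOP_GREEN] + mean_shares[Strategy.COOP_BLUE]),
        payoff_samples=payoffs,
        meta={"n_agents": graph.n_agents, "topology": graph.topology, "dims": graph.dims},
    )


def _default_builder(protocol: ScanProtocol, cell_seed: np.random.SeedSequence):
    """Fresh gradient cylinder + label field for one grid cell."""
    graph = build_cylinder(protocol.width, protocol.height)
    label_seed, sim_seed = cell_seed.spawn(2)
    labels = assign_labels_gradient(graph, np.random.default_rng(label_seed))
    return graph, labels, int(sim_seed.generate_state(1)[0] % 2**31)


def phase_scan(
    protocol: ScanProtocol,
    builder: Callable | None = None,
    progress: bool = False,
) -> ScanResult:
    """Run :func:`run_point` over the full (b, w) grid.

    Every cell gets its own seed and a freshly drawn label field, so no
    result can be an artefact of one particular random label layout.
    Per-cell failures are recorded and the scan continues.
    """
    builder = builder or _default_builder
    rows, errors = [], []
    cells = [(b, w) for b in protocol.b_grid for w in protocol.w_grid]
    iterator = enumerate(cells)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = enumerate(tqdm(cells, desc="phase scan"))
    for idx, (b, w) in iterator:
        cell_seed = np.random.SeedSequence([int(protocol.base_seed), idx])
        try:
            graph, labels, sim_seed = builder(protocol, cell_seed)
            params = ModelParams(b=b, w=w, mu=protocol.mu)
            pt = run_point(params, graph, labels, protocol, sim_seed)
            rows.append(
                {
                    "b": b,
                    "w": w,
                    "seed": pt.seed,
                    "mean_payoff_norm": pt.mean_payoff_norm,
                    "sem_payoff_norm": pt.sem_payoff_norm,
                    "share_coop_all": pt.shares[0],
                    "share_coop_green": pt.shares[1],
                    "share_coop_blue": pt.shares[2],
                    "share_defect_all": pt.shares[3],
                    "discrimination_index": pt.discrimination_index,
                }
            )
        except Exception as exc:  # cell failure must not kill the scan
            errors.append({"b": b, "w": w, "error": repr(exc)})
            rows.append(
                {
                    "b": b,
                    "w": w,
                    "seed": -1,
                    "mean_payoff_norm": np.nan,
                    "sem_payoff_norm": np.nan,
                    "share_coop_all": np.nan,
                    "share_coop_green": np.nan,
                    "share_coop_blue": np.nan,
                    "share_defect_all": np.nan,
                    "discrimination_index": np.nan,
                }
            )
    return ScanResult(table=pd.DataFrame(rows), protocol=protocol, errors=errors)
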