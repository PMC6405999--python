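"""Core dynamics of the label-conditional donation game.

Agents live on a graph, carry an immutable binary label (green or blue),
and hold one of four strategies that condition the decision to cooperate
on the *partner's* label.  Cooperation means donating one unit, which the
recipient receives multiplied by the benefit ``b > 1``.  An agent's payoff
is recomputed from the current configuration (it never accumulates):

    p_i = sum_{j in N_i} [ b * S_j(lam_i) - S_i(lam_j) ]

where ``S_i(lam)`` is 1 if agent i's strategy cooperates with label
``lam``.  Payoff maps to fitness through ``f = exp(w * p)`` with selection
pressure ``w >= 0``; ``w = 0`` is neutral drift (a four-opinion voter
model) and ``w = inf`` is deterministic copy-the-best.

The dynamics are asynchronous: one event picks a uniformly random focal
agent which, with probability ``mu``, resamples its strategy uniformly
from all four, and otherwise copies the strategy of a neighbour drawn
with probability proportional to fitness.  Labels never change.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from . import _kernels

if TYPE_CHECKING:  # pragma: no cover
    from .populations import PopulationGraph

__all__ = [
    "Label",
    "Strategy",
    "ACTION",
    "ModelParams",
    "SimState",
    "IsolatedAgentError",
    "payoff",
    "all_payoffs",
    "fitness",
    "selection_probabilities",
    "choose_imitation_target",
    "step",
    "run_events",
    "swap_labels",
]


class Label(enum.IntEnum):
    """Observable, immutable binary tag carried by every agent."""

    BLUE = 0
    GREEN = 1


class Strategy(enum.IntEnum):
    """The four label-conditional action rules.

    ``COOP_GREEN`` donates only to green-labelled partners, ``COOP_BLUE``
    only to blue ones; the two unconditional rules ignore the label.
    """

    COOP_ALL = 0
    COOP_GREEN = 1
    COOP_BLUE = 2
    DEFECT_ALL = 3

    def action(self, label: int) -> int:
        """Return 1 if this strategy donates to a partner wearing *label*."""
        return int(ACTION[self, label])


# ACTION[s, lam] = 1 iff strategy s cooperates with a partner of label lam.
# Rows follow Strategy codes, columns follow Label codes (BLUE=0, GREEN=1).
ACTION = np.array(
    [
        [1, 1],  # COOP_ALL
        [0, 1],  # COOP_GREEN
        [1, 0],  # COOP_BLUE
        [0, 0],  # DEFECT_ALL
    ],
    dtype=np.uint8,
)


class IsolatedAgentError(ValueError):
    """Raised when imitation is requested for an agent with no neighbours."""


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.

    Parameters
    ----------
    b
        Cooperation benefit (dimensionless multiplier on the donated unit),
        must exceed 1 so the game is a social dilemma.
    w
        Selection pressure, the exponent scaling payoff into fitness.
        ``w = 0`` gives fitness-blind (voter-model) imitation; ``math.inf``
        selects the payoff-maximal neighbour deterministically.
    mu
        Mutation probability per update event.  Mutation resamples
        uniformly over all four strategies (including the current one), so
        the effective change probability is ``3 * mu / 4``.
    """

    b: float
    w: float
    mu: float = 0.001

    def __post_init__(self) -> None:
        if not self.b > 1:
            raise ValueError(f"cooperation benefit must exceed 1, got b={self.b}")
        if not (self.w >= 0):
            raise ValueError(f"selection pressure must be >= 0, got w={self.w}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mutation rate must lie in [0, 1], got mu={self.mu}")


@dataclass
class SimState:
    """Mutable state of one simulation: labels, strategies and a clock.

    All stochastic decisions draw from ``rng`` so that a run is a pure
    function of (initial state, parameters, seed).  Within :func:`step`
    the draws occur in a fixed order: focal agent, mutation coin, then
    either the uniform strategy draw or the single uniform used for the
    fitness-proportional neighbour choice.
    """

    graph: "PopulationGraph"
    labels: np.ndarray
    strategies: np.ndarray
    t: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        self.strategies = np.ascontiguousarray(self.strategies, dtype=np.uint8)
        n = self.graph.n_agents
        if len(self.labels) != n or len(self.strategies) != n:
            raise ValueError(
                "labels and strategies must both have one entry per agent "
                f"(n={n}, got {len(self.labels)} labels, "
                f"{len(self.strategies)} strategies)"
            )

    @property
    def n_agents(self) -> int:
        return self.graph.n_agents

    def copy(self) -> "SimState":
        """Deep copy sharing the (immutable) graph but not the RNG stream."""
        import copy as _copy

        return SimState(
            graph=self.graph,
            labels=self.labels.copy(),
            strategies=self.strategies.copy(),
            t=self.t,
            rng=_copy.deepcopy(self.rng),
        )


def payoff(state: SimState, i: int, b: float) -> float:
    """Payoff of agent *i* under benefit *b* in the current configuration.

    Returns ``sum_j [b * S_j(lam_i) - S_i(lam_j)]`` over the neighbours j
    of i.  An isolated agent (possible only in random graphs) has payoff 0.
    """
    if not 0 <= i < state.n_agents:
        raise IndexError(f"agent index {i} out of range for n={state.n_agents}")
    neigh = state.graph.neighbors(i)
    if len(neigh) == 0:
        return 0.0
    received = int(ACTION[state.strategies[neigh], state.labels[i]].sum())
    given = int(ACTION[state.strategies[i], state.labels[neigh]].sum())
    return float(b) * received - given


def all_payoffs(state: SimState, b: float) -> np.ndarray:
    """Vector of payoffs for every agent (vectorised over the edge list)."""
    g = state.graph
    src = np.repeat(np.arange(g.n_agents), np.diff(g.indptr))
    dst = g.indices
    received = np.zeros(g.n_agents)
    given = np.zeros(g.n_agents)
    # donation on directed edge (i -> j) exists iff ACTION[s_i, lam_j]
    donates = ACTION[state.strategies[src], state.labels[dst]].astype(np.float64)
    np.add.at(given, src, donates)
    np.add.at(received, dst, donates)
    return b * received - given


def fitness(p, w: float):
    """Exponential fitness ``exp(w * p)``; strictly positive for finite input.

    Raw exponentials can overflow for large ``w * p``; selection
    probabilities must therefore be computed through
    :func:`selection_probabilities`, which is invariant to a common payoff
    offset (softmax shift invariance) and never overflows.
    """
    return np.exp(w * np.asarray(p, dtype=np.float64))


def selection_probabilities(payoffs: np.ndarray, w: float) -> np.ndarray:
    """Fitness-proportional selection probabilities, computed shift-safely.

    Uses ``exp(w * (p - max p))`` so that the result is well defined for
    arbitrarily large ``w * p``.  For ``w = inf`` returns the uniform
    distribution over payoff-maximal entries.
    """
    p = np.asarray(payoffs, dtype=np.float64)
    if p.size == 0:
        raise ValueError("selection over an empty candidate set")
    if math.isinf(w):
        best = p == p.max()
        return best / best.sum()
    shifted = np.exp(w * (p - p.max()))
    return shifted / shifted.sum()


def choose_imitation_target(state: SimState, i: int, params: ModelParams) -> int:
    """Draw a neighbour of *i* with probability proportional to its fitness.

    The focal agent itself is never a candidate.  Raises
    :class:`IsolatedAgentError` when *i* has no neighbours, for which
    imitation is undefined.
    """
    neigh = state.graph.neighbors(i)
    if len(neigh) == 0:
        raise IsolatedAgentError(f"agent {i} has no neighbours to imitate")
    probs = selection_probabilities(
        [payoff(state, int(j), params.b) for j in neigh], params.w
    )
    u = state.rng.random()
    k = int(np.searchsorted(np.cumsum(probs), u, side="right"))
    return int(neigh[min(k, len(neigh) - 1)])


def step(state: SimState, params: ModelParams) -> SimState:
    """Advance the state by one asynchronous update event (in place).

    A uniformly random focal agent either mutates (probability ``mu``,
    uniform over all four strategies) or copies a fitness-proportionally
    chosen neighbour.  Copying a neighbour with the same strategy is a
    legal no-op.  Labels are immutable; only one strategy entry can change.
    """
    rng = state.rng
    i = int(rng.integers(state.n_agents))
    coin = rng.random()
    if coin < params.mu:
        state.strategies[i] = rng.integers(4)
    else:
        j = choose_imitation_target(state, i, params)
        state.strategies[i] = state.strategies[j]
    state.t += 1
    return state


def run_events(state: SimState, params: ModelParams, n_events: int) -> SimState:
    """Advance the state by *n_events* update events using the JIT kernel.

    Semantically equivalent to ``n_events`` calls of :func:`step` (same
    update law, same marginal distributions) but runs through a compiled
    loop with its own seeded stream, derived once from ``state.rng``; a
    run therefore remains a pure function of the initial seed.  Isolated
    agents (random graphs only) simply waste their event.
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    if n_events == 0:
        return state
    seed = int(state.rng.integers(2**31))
    g = state.graph
    _kernels.run_events_kernel(
        g.indptr,
        g.indices,
        state.labels,
        state.strategies,
        ACTION,
        n_events,
        float(params.b),
        0.0 if math.isinf(params.w) else float(params.w),
        float(params.mu),
        seed,
        math.isinf(params.w),
    )
    state.t += n_events
    return state


def swap_labels(state: SimState) -> SimState:
    """Return the mirror state: GREEN <-> BLUE and COOP_GREEN <-> COOP_BLUE.

    The model treats the two labels symmetrically, so stepping the mirror
    state with an identical decision stream yields the mirror of stepping
    the original.
    """
    out = state.copy()
    out.labels = (1 - state.labels.astype(np.int8)).astype(np.uint8)
    swapped = state.strategies.copy()
    swapped[state.strategies == Strategy.COOP_GREEN] = Strategy.COOP_BLUE
    swapped[state.strategies == Strategy.COOP_BLUE] = Strategy.COOP_GREEN
    out.strategies = swapped
    return out
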