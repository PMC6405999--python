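"""1D domain-boundary theory: the wall between two strategy domains as a
birth-death chain.

Setup: agents on an open line, mutation off, the left end agent pinned to
full cooperation (COOP_ALL) and the right end agent pinned to the
discriminating strategy COOP_BLUE.  Nearest-neighbour copying preserves
the two-domain structure, so the whole state is one integer: the position
``k`` of the wall, meaning agents ``0..k`` hold COOP_ALL and agents
``k+1..n-1`` hold COOP_BLUE.

One update event moves the wall right iff the focal agent is ``k+1`` and
it copies its left neighbour, and left iff the focal agent is ``k`` and
copies its right neighbour; the copy probabilities follow from the
exponential fitnesses of the two candidate neighbours, with payoffs
computed from the explicit 1D configuration.  Where every agent in sight
is blue the two strategies act identically and the wall walks without
bias; label structure near the wall biases it.  For a single green agent
on an otherwise blue line the bias is confined to the four wall positions
within three steps of the green agent, and the stationary odds of finding
the wall on the discriminating side versus the cooperating side converge
(in the long-line limit) to the closed form

    ratio(w, b) = exp(2 w) / (tanh(w b) + 1),

which exceeds 1 — discrimination beats full cooperation — above a
critical selection pressure; as b -> inf that threshold tends to
log(2)/2.  For periodically repeated label patterns the same machinery
compares stationary weights one period apart and locates the benefit
``b*`` at which the odds cross 1; for the perfectly alternating pattern
the crossing sits at b* = 2 independent of w.

A Monte-Carlo oracle (:func:`monte_carlo_boundary`) simulates the actual
1D imitation dynamics with pinned ends and measures the side occupancy
directly, arbitrating the chain calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .core import Label, ModelParams, SimState, Strategy, payoff
from .populations import build_line

__all__ = [
    "BoundaryChain",
    "MCBoundaryResult",
    "UnreachableStateError",
    "stepping_probabilities",
    "stationary_log_weights",
    "stationary_ratio",
    "closed_form_ratio",
    "critical_selection_pressure",
    "transition_line",
    "monte_carlo_boundary",
    "NO_CROSSING",
]

#: Sentinel returned by :func:`transition_line` when the stationary odds
#: never cross 1 inside the search bracket (distinct from a numerical
#: failure, which raises).
NO_CROSSING = float("nan")


class UnreachableStateError(ValueError):
    """A zero step probability makes part of the chain unreachable."""

    def __init__(self, position: int):
        self.position = position
        super().__init__(f"zero step probability at boundary position {position}")


def _wall_state(labels: np.ndarray, k: int) -> SimState:
    """Explicit 1D configuration with the wall at position k."""
    n = len(labels)
    strategies = np.full(n, Strategy.COOP_BLUE, dtype=np.uint8)
    strategies[: k + 1] = Strategy.COOP_ALL
    return SimState(
        graph=build_line(n),
        labels=labels,
        strategies=strategies,
        rng=np.random.default_rng(0),
    )


def _copy_prob(p_target: float, p_other: float, w: float) -> float:
    """P(copy the target neighbour) among two candidates, shift-safe."""
    if math.isinf(w):
        if p_target > p_other:
            return 1.0
        if p_target < p_other:
            return 0.0
        return 0.5
    d = w * (p_other - p_target)
    if d > 700.0:
        return 0.0
    if d < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(d))


def stepping_probabilities(
    labels: np.ndarray, position: int, b: float, w: float
) -> tuple[float, float, float]:
    """Per-event move probabilities (P_left, P_right, P_stay) of the wall.

    Derived from the core update rule with the two end agents pinned
    (excluded from focal selection): the wall at ``position`` moves right
    when focal agent ``position + 1`` copies across the wall, left when
    focal agent ``position`` does.  Payoffs come from
    :func:`labelgame.core.payoff` on the explicit configuration.
    """
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    n = len(labels)
    if n < 4:
        raise ValueError("line too short for a pinned-end wall chain")
    if not 0 <= position <= n - 2:
        raise IndexError(f"wall position {position} outside [0, {n - 2}]")
    n_free = n - 2
    state = _wall_state(labels, position)
    p_right = 0.0
    if position + 1 <= n - 2:  # focal agent k+1 must be free
        f_left = payoff(state, position, b)
        f_right = payoff(state, position + 2, b)
        p_right = _copy_prob(f_left, f_right, w) / n_free
    p_left = 0.0
    if position >= 1:  # focal agent k must be free
        f_left = payoff(state, position - 1, b)
        f_right = payoff(state, position + 1, b)
        p_left = _copy_prob(f_right, f_left, w) / n_free
    return p_left, p_right, 1.0 - p_left - p_right


@dataclass
class BoundaryChain:
    """Birth-death chain of wall positions for a fixed 1D label field."""

    labels: np.ndarray
    b: float
    w: float
    positions: np.ndarray = field(init=False)
    p_left: np.ndarray = field(init=False)
    p_right: np.ndarray = field(init=False)
    p_stay: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        n = len(self.labels)
        self.positions = np.arange(n - 1)
        pl, pr, ps = [], [], []
        for k in self.positions:
            a, c, s = stepping_probabilities(self.labels, int(k), self.b, self.w)
            pl.append(a)
            pr.append(c)
            ps.append(s)
        self.p_left = np.array(pl)
        self.p_right = np.array(pr)
        self.p_stay = np.array(ps)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def green_index(self) -> int:
        greens = np.flatnonzero(self.labels == Label.GREEN)
        if len(greens) != 1:
            raise ValueError(
                f"need exactly one green agent to define the focal region, found {len(greens)}"
            )
        return int(greens[0])


def stationary_log_weights(chain: BoundaryChain) -> np.ndarray:
    """Log stationary weights by detailed balance, accumulated in log domain.

    ``log pi[k+1] = log pi[k] + log P_right(k) - log P_left(k+1)``; the
    reflecting ends need no special casing because only interior ratios
    enter.  Raises :class:`UnreachableStateError` if an interior step
    probability vanishes (possible only in the deterministic ``w = inf``
    limit).
    """
    m = chain.n_positions
    logpi = np.zeros(m)
    for k in range(m - 1):
        if chain.p_right[k] <= 0.0:
            raise UnreachableStateError(int(k))
        if chain.p_left[k + 1] <= 0.0:
            raise UnreachableStateError(int(k + 1))
        logpi[k + 1] = logpi[k] + math.log(chain.p_right[k]) - math.log(chain.p_left[k + 1])
    return logpi


def stationary_ratio(
    chain: BoundaryChain,
    green_index: int | None = None,
    sides: str = "finite",
) -> float:
    """Stationary odds of discrimination dominating over full cooperation.

    The wall at position ``k`` leaves the green agent covered by the
    discriminating strategy iff ``k <= green_index - 1``; those positions
    form the discrimination side, the rest the cooperation side (the
    green agent's own strategy decides the focal window, which is exactly
    this cut).

    ``sides="finite"`` sums the stationary weights of the given finite
    chain on each side — the quantity the Monte-Carlo oracle measures on
    the same line.  ``sides="infinite"`` returns the limit of that mass
    ratio for equally long sides growing without bound, i.e. the ratio of
    the two far-field plateau weights; on the single-green line this is
    the closed form ``exp(2w) / (tanh(wb) + 1)`` exactly.
    """
    m = green_index if green_index is not None else chain.green_index()
    if not 0 < m < len(chain.labels) - 1:
        raise ValueError("green agent must be interior to the line")
    logpi = stationary_log_weights(chain)
    if sides == "finite":
        return float(np.exp(logsumexp(logpi[:m]) - logsumexp(logpi[m:])))
    if sides == "infinite":
        # plateau probes: clear of the pinned ends (2 positions) and of the
        # biased window around the green agent (wall positions m-3 .. m)
        kl, kr = 2, chain.n_positions - 2
        if not (kl <= m - 4 + 1 and m + 1 <= kr):
            raise ValueError(
                "line too short to expose unbiased plateaus on both sides"
            )
        return float(np.exp(logpi[kl] - logpi[kr]))
    raise ValueError(f"unknown sides mode {sides!r}")


def closed_form_ratio(w: float, b: float) -> float:
    """Closed-form stationary odds for the single-green line.

    ``exp(2w) / (tanh(wb) + 1)``: equals 1 at w = 0, and tends to
    ``exp(2w)/2`` as b -> inf, which crosses 1 at w = log(2)/2.
    """
    if w < 0:
        raise ValueError("selection pressure must be >= 0")
    if b <= 1:
        raise ValueError("cooperation benefit must exceed 1")
    return math.exp(2.0 * w) / (math.tanh(w * b) + 1.0)


def critical_selection_pressure(b: float, w_hi: float = 2.0) -> float:
    """Selection pressure at which the closed-form odds cross 1 at fixed b."""
    f = lambda w: math.log(closed_form_ratio(w, b))
    lo = 1e-9
    if f(lo) * f(w_hi) > 0:
        return NO_CROSSING
    return float(brentq(f, lo, w_hi, xtol=1e-12))


def _period_log_ratio(labels: np.ndarray, k0: int, period: int, b: float, w: float) -> float:
    """log of the stationary-weight ratio across one pattern period,
    ``log(pi[k0 + period] / pi[k0])``, from the bulk stepping probabilities."""
    total = 0.0
    for k in range(k0, k0 + period):
        _, pr, _ = stepping_probabilities(labels, k, b, w)
        pl_next, _, _ = stepping_probabilities(labels, k + 1, b, w)
        if pr <= 0.0:
            raise UnreachableStateError(k)
        if pl_next <= 0.0:
            raise UnreachableStateError(k + 1)
        total += math.log(pr) - math.log(pl_next)
    return total


def transition_line(
    pattern,
    w: float,
    b_lo: float = 1.0 + 1e-6,
    b_hi: float = 64.0,
    xtol: float = 1e-6,
) -> float:
    """Critical benefit ``b*`` for a periodically repeated label pattern.

    Tiles *pattern* along a line long enough that one full period of wall
    positions sits in the translation-invariant bulk, computes the
    stationary-weight ratio across that period, and bisects on ``b`` for
    the crossing of 1 (`brentq` to ``|db| <= xtol``).  Returns
    :data:`NO_CROSSING` (NaN) when the ratio never crosses 1 inside
    ``[b_lo, b_hi]`` — e.g. for an all-blue pattern, where the two
    strategies act identically and the wall is globally unbiased.
    """
    pat = [int(x) for x in pattern]
    if not 1 <= len(pat) <= 6:
        raise ValueError("pattern length must be between 1 and 6")
    if w <= 0:
        raise ValueError("transition line needs w > 0")
    period = len(pat)
    if Label.GREEN not in pat:
        return NO_CROSSING
    # long enough that payoffs within the probed period never feel the ends
    reps = max(10, (30 + 2 * period) // period)
    labels = np.tile(np.asarray(pat, dtype=np.uint8), reps)
    n = len(labels)
    k0 = period * ((n // 2) // period)  # phase-aligned bulk start

    def g(b: float) -> float:
        return _period_log_ratio(labels, k0, period, b, w)

    g_lo, g_hi = g(b_lo), g(b_hi)
    if g_lo == 0.0:
        return float(b_lo)
    if g_hi == 0.0:
        return float(b_hi)
    if g_lo * g_hi > 0:
        return NO_CROSSING
    return float(brentq(g, b_lo, b_hi, xtol=xtol))


@dataclass
class MCBoundaryResult:
    """Side-occupancy measurement from the 1D Monte-Carlo oracle."""

    ratio: float
    se: float
    p_disc: float
    n_samples: int
    n_mixed: int
    n_events: int


def monte_carlo_boundary(
    labels: np.ndarray,
    params: ModelParams,
    n_events: int,
    seed: int,
    thin: int | None = None,
    burn_in_fraction: float = 0.1,
    n_batches: int = 16,
) -> MCBoundaryResult:
    """Direct simulation oracle for the stationary side-occupancy odds.

    Runs the full 1D imitation dynamics (mutation off, end strategies
    pinned to COOP_ALL / COOP_BLUE, ends excluded from focal selection)
    from a wall at the green agent, samples every ``thin`` events which
    side of the green agent the wall occupies, and returns the occupancy
    odds with a standard error.  Samples along the walk are correlated,
    so the error is estimated by batch means over ``n_batches`` blocks of
    the post-burn-in samples and propagated to the odds by the delta
    method; batches must be long compared to the wall's relaxation time
    (of order n^3 events) for the estimate to be well calibrated, which
    favours few long batches.  States without a clean two-domain structure (impossible for
    a two-domain start, but checked) are tallied separately as mixed.
    """
    from . import _kernels
    from .core import ACTION

    if params.mu != 0.0:
        raise ValueError("the wall chain is defined for mu = 0 only")
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    n = len(labels)
    greens = np.flatnonzero(labels == Label.GREEN)
    if len(greens) != 1:
        raise ValueError("oracle needs exactly one green agent")
    m = int(greens[0])
    if thin is None:
        thin = n
    strategies = np.full(n, Strategy.COOP_BLUE, dtype=np.uint8)
    strategies[: m + 1] = Strategy.COOP_ALL  # wall starts at the green agent
    samples = _kernels.run_line_pinned_kernel(
        labels,
        strategies,
        ACTION,
        int(n_events),
        float(params.b),
        0.0 if math.isinf(params.w) else float(params.w),
        int(seed) % 2**31,
        m,
        int(thin),
        math.isinf(params.w),
    )
    burn = int(len(samples) * burn_in_fraction)
    kept = samples[burn:]
    n_mixed = int((kept == -1).sum())
    clean = kept[kept >= 0]
    if len(clean) < n_batches * 2:
        raise ValueError("too few samples for a batch-means error estimate")
    p_disc = float(clean.mean())
    usable = len(clean) - len(clean) % n_batches
    batches = clean[:usable].reshape(n_batches, -1).mean(axis=1)
    se_p = float(batches.std(ddof=1) / np.sqrt(n_batches))
    if p_disc in (0.0, 1.0):
        raise ValueError("degenerate occupancy; increase n_events")
    ratio = p_disc / (1.0 - p_disc)
    se_ratio = se_p / (1.0 - p_disc) ** 2
    return MCBoundaryResult(
        ratio=ratio,
        se=se_ratio,
        p_disc=p_disc,
        n_samples=len(clean),
        n_mixed=n_mixed,
        n_events=int(n_events),
    )
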