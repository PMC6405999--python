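"""Graph topologies and label fields.

The reference topology is a square-lattice *cylinder*: periodic in the
width direction, open in the height direction, so that a label-density
gradient can run along the open axis without joining its two ends.  The
gradient field makes an agent in row ``r`` green with probability
``r / (H - 1)``, i.e. the bottom row is all blue and the top row all
green, with a regional blue majority in one half and a green majority in
the other.

Also provided: torus / ring / line lattices, Erdos-Renyi random graphs
(via networkx), uniform Bernoulli label fields, and the patterned 1D
label fields used by the domain-boundary analysis (a single green agent
in the middle of a blue line, or a short pattern tiled along the line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .core import Label

__all__ = [
    "PopulationGraph",
    "build_cylinder",
    "build_torus",
    "build_ring",
    "build_line",
    "build_erdos_renyi",
    "assign_labels_gradient",
    "assign_labels_uniform",
    "assign_labels_line",
]


@dataclass(frozen=True)
class PopulationGraph:
    """Undirected agent adjacency in CSR form.

    ``indices[indptr[i]:indptr[i+1]]`` are the neighbours of agent *i*.
    Symmetry (j in N_i iff i in N_j) and absence of self-loops are
    invariants of every builder.
    """

    indptr: np.ndarray
    indices: np.ndarray
    topology: str
    dims: tuple | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_agents(self) -> int:
        return len(self.indptr) - 1

    @property
    def n_directed_edges(self) -> int:
        return len(self.indices)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def gradient_axis_length(self) -> int:
        """Number of rows along the open (gradient) axis; cylinders only."""
        if self.topology != "cylinder" or self.dims is None:
            raise ValueError(
                f"topology {self.topology!r} has no gradient axis"
            )
        return self.dims[1]


def _from_neighbor_lists(
    lists: Sequence[Sequence[int]], topology: str, dims=None, meta=None
) -> PopulationGraph:
    indptr = np.zeros(len(lists) + 1, dtype=np.int64)
    for i, nb in enumerate(lists):
        indptr[i + 1] = indptr[i] + len(nb)
    indices = np.empty(indptr[-1], dtype=np.int64)
    for i, nb in enumerate(lists):
        indices[indptr[i] : indptr[i + 1]] = sorted(nb)
    return PopulationGraph(indptr, indices, topology, dims, meta or {})


def build_cylinder(width: int, height: int) -> PopulationGraph:
    """Square lattice, periodic in width, open in height (a cylinder).

    Agent ``r * width + c`` sits in row *r* (the gradient axis runs over
    rows) and column *c*.  Von Neumann 4-neighbourhood; agents in the two
    open rows have degree 3, all others degree 4.
    """
    if width < 3 or height < 2:
        raise ValueError(f"cylinder needs width >= 3 and height >= 2, got {width}x{height}")
    lists = []
    for r in range(height):
        for c in range(width):
            nb = [r * width + (c - 1) % width, r * width + (c + 1) % width]
            if r > 0:
                nb.append((r - 1) * width + c)
            if r < height - 1:
                nb.append((r + 1) * width + c)
            lists.append(nb)
    return _from_neighbor_lists(lists, "cylinder", (width, height))


def build_torus(width: int, height: int) -> PopulationGraph:
    """Square lattice with periodic boundaries in both directions."""
    if width < 3 or height < 3:
        raise ValueError(f"torus needs width >= 3 and height >= 3, got {width}x{height}")
    lists = []
    for r in range(height):
        for c in range(width):
            lists.append(
                [
                    r * width + (c - 1) % width,
                    r * width + (c + 1) % width,
                    ((r - 1) % height) * width + c,
                    ((r + 1) % height) * width + c,
                ]
            )
    return _from_neighbor_lists(lists, "torus", (width, height))


def build_ring(n: int) -> PopulationGraph:
    """Cycle graph: every agent has exactly two neighbours."""
    if n < 3:
        raise ValueError(f"ring needs n >= 3, got {n}")
    lists = [[(i - 1) % n, (i + 1) % n] for i in range(n)]
    return _from_neighbor_lists(lists, "ring", (n,))


def build_line(n: int) -> PopulationGraph:
    """Path graph: open 1D line, end agents have degree 1."""
    if n < 2:
        raise ValueError(f"line needs n >= 2, got {n}")
    lists = [
        [j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)
    ]
    return _from_neighbor_lists(lists, "line", (n,))


def build_erdos_renyi(n: int, p: float, seed: int) -> PopulationGraph:
    """G(n, p) random graph; reproducible for a fixed seed.

    Disconnected results are permitted but flagged in ``meta`` (isolated
    agents waste their update events).
    """
    if n < 2 or not 0.0 <= p <= 1.0:
        raise ValueError(f"need n >= 2 and p in [0, 1], got n={n}, p={p}")
    g = nx.gnp_random_graph(n, p, seed=int(seed))
    lists = [list(g.neighbors(i)) for i in range(n)]
    meta = {"edge_probability": p, "seed": int(seed), "connected": nx.is_connected(g) if n > 0 else True}
    return _from_neighbor_lists(lists, "erdos_renyi", (n,), meta)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def assign_labels_gradient(graph: PopulationGraph, seed) -> np.ndarray:
    """Gradient label field on a cylinder: row r is green w.p. r/(H-1).

    Row 0 is deterministically all blue and row H-1 all green; draws are
    independent Bernoulli given the seed.  The expected overall green
    fraction is 1/2, and the expected local-majority fraction within each
    half of the lattice is 3/4.
    """
    height = graph.gradient_axis_length  # raises for non-cylinder topologies
    width = graph.dims[0]
    rng = _as_rng(seed)
    rows = np.repeat(np.arange(height), width)
    p_green = rows / (height - 1)
    return (rng.random(graph.n_agents) < p_green).astype(np.uint8)


def assign_labels_uniform(n: int, p_green: float, seed) -> np.ndarray:
    """I.i.d. Bernoulli(p_green) label field."""
    if not 0.0 <= p_green <= 1.0:
        raise ValueError(f"p_green must lie in [0, 1], got {p_green}")
    rng = _as_rng(seed)
    return (rng.random(n) < p_green).astype(np.uint8)


def assign_labels_line(n: int, kind: str, pattern: Sequence[int] | None = None) -> np.ndarray:
    """1D label fields for the domain-boundary analysis.

    ``kind="single_minority"``: all blue except one green agent at the
    middle index ``n // 2`` (requires ``n >= 7`` so the biased window of
    +-3 boundary positions around the green agent fits inside the line).
    ``kind="repeated_pattern"``: *pattern* (a sequence over Label codes)
    tiled along the line.
    """
    if kind == "single_minority":
        if n < 7:
            raise ValueError(f"single_minority needs n >= 7, got {n}")
        labels = np.full(n, Label.BLUE, dtype=np.uint8)
        labels[n // 2] = Label.GREEN
        return labels
    if kind == "repeated_pattern":
        if pattern is None or len(pattern) == 0:
            raise ValueError("repeated_pattern needs a non-empty pattern")
        pat = np.asarray([int(x) for x in pattern], dtype=np.uint8)
        if not np.all((pat == 0) | (pat == 1)):
            raise ValueError("pattern entries must be Label codes (0=BLUE, 1=GREEN)")
        reps = -(-n // len(pat))
        return np.tile(pat, reps)[:n].copy()
    raise ValueError(f"unknown 1D label kind {kind!r}")
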