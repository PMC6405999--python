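"""Configuration, serialization, and snapshot rendering.

Configs are flat YAML key-value files that round-trip losslessly; every
stochastic output is a pure function of (config, seed).  Tables are CSV
with a header row and 9-significant-digit floats; states are JSON
(labels, strategies, topology spec); snapshots are PNG with the fixed
strategy colour code (yellow: cooperate with all, green: cooperate with
green, blue: cooperate with blue, purple: defect all).
"""

from __future__ import annotations

import json
import time
import uuid
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import SimState, Strategy
from .populations import (
    PopulationGraph,
    assign_labels_gradient,
    assign_labels_line,
    assign_labels_uniform,
    build_cylinder,
    build_erdos_renyi,
    build_line,
    build_ring,
    build_torus,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "build_from_config",
    "state_to_json",
    "state_from_json",
    "write_table",
    "snapshot_png",
    "STRATEGY_COLORS",
    "new_run_id",
]

#: Snapshot colour code, ordered by Strategy code.
STRATEGY_COLORS = ("gold", "forestgreen", "royalblue", "purple")

FLOAT_FORMAT = "%.9g"


@dataclass
class RunConfig:
    """Flat, file-round-trippable description of one run or scan."""

    b: float = 5.0
    w: float = 0.1
    mu: float = 0.001
    topology: str = "cylinder"
    width: int = 50
    height: int = 50
    n: int = 100  # 1D / random-graph sizes
    edge_probability: float = 0.1
    label_kind: str = "gradient"  # gradient | uniform | single_minority | repeated_pattern
    p_green: float = 0.5
    pattern: str = "GB"
    seed: int = 0
    transient_steps: int = 5_000_000
    n_samples: int = 20
    sample_window: int = 10_000_000
    b_grid: list = field(default_factory=list)
    w_grid: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _parse_pattern(text: str):
    mapping = {"G": 1, "B": 0, "1": 1, "0": 0}
    try:
        return [mapping[ch] for ch in text.strip().upper()]
    except KeyError as exc:
        raise ValueError(f"pattern characters must be G/B, got {text!r}") from exc


def build_from_config(cfg: RunConfig):
    """Materialize (graph, labels) from a config, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.topology == "cylinder":
        graph = build_cylinder(cfg.width, cfg.height)
    elif cfg.topology == "torus":
        graph = build_torus(cfg.width, cfg.height)
    elif cfg.topology == "ring":
        graph = build_ring(cfg.n)
    elif cfg.topology == "line":
        graph = build_line(cfg.n)
    elif cfg.topology == "erdos_renyi":
        graph = build_erdos_renyi(cfg.n, cfg.edge_probability, cfg.seed)
    else:
        raise ValueError(f"unknown topology {cfg.topology!r}")
    if cfg.label_kind == "gradient":
        labels = assign_labels_gradient(graph, rng)
    elif cfg.label_kind == "uniform":
        labels = assign_labels_uniform(graph.n_agents, cfg.p_green, rng)
    elif cfg.label_kind in ("single_minority", "repeated_pattern"):
        labels = assign_labels_line(
            graph.n_agents,
            cfg.label_kind,
            _parse_pattern(cfg.pattern) if cfg.label_kind == "repeated_pattern" else None,
        )
    else:
        raise ValueError(f"unknown label kind {cfg.label_kind!r}")
    return graph, labels


def state_to_json(state: SimState, path) -> None:
    g = state.graph
    payload = {
        "t": int(state.t),
        "topology": g.topology,
        "dims": list(g.dims) if g.dims else None,
        "labels": state.labels.tolist(),
        "strategies": state.strategies.tolist(),
        "indptr": g.indptr.tolist(),
        "indices": g.indices.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def state_from_json(path) -> SimState:
    payload = json.loads(Path(path).read_text())
    graph = PopulationGraph(
        indptr=np.asarray(payload["indptr"], dtype=np.int64),
        indices=np.asarray(payload["indices"], dtype=np.int64),
        topology=payload["topology"],
        dims=tuple(payload["dims"]) if payload["dims"] else None,
    )
    return SimState(
        graph=graph,
        labels=np.asarray(payload["labels"], dtype=np.uint8),
        strategies=np.asarray(payload["strategies"], dtype=np.uint8),
        t=payload["t"],
        rng=np.random.default_rng(0),
    )


def write_table(df, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def snapshot_png(state: SimState, path, show_labels: bool = False) -> None:
    """Render a lattice state as a PNG using the fixed strategy colours."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if state.graph.dims is None or len(state.graph.dims) != 2:
        raise ValueError("snapshots are defined for 2D lattices only")
    width, height = state.graph.dims
    field_ = (state.labels if show_labels else state.strategies).reshape(height, width)
    cmap = (
        ListedColormap(["royalblue", "forestgreen"])
        if show_labels
        else ListedColormap(list(STRATEGY_COLORS))
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(field_, cmap=cmap, vmin=0, vmax=1 if show_labels else 3, origin="lower")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def new_run_id() -> str:
    """Short run identifier for log lines (informational only)."""
    return f"{time.strftime('%Y%m%d-%H%M%S')}-{uuid.uuid4().hex[:8]}"
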