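"""K-core filtration, module detection, and force-directed layout of the
chemical similarity graph.

K-core filtration iteratively removes the nodes with the fewest neighbors
until every remaining node has at least k neighbors, concentrating the map
on its cohesive center. Modules (communities of densely inter-similar
chemicals) are found by the Louvain greedy modularity algorithm on
the similarity-weighted graph. Chemicals dropped by the filtration are kept
in a special "Undefined" module so downstream tables still account for them.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io_model import ChemicalRecord, SENSITIZER, NON_SENSITIZER

#: module id assigned to chemicals outside the retained (filtered) graph
UNDEFINED_MODULE = -1


@dataclass
class ModuleTally:
    count: int = 0
    n_sensitizers: int = 0
    n_non_sensitizers: int = 0
    n_unknown: int = 0


@dataclass
class ModulePartition:
    """Assignment of chemicals to modules plus per-module label tallies.

    ``assignment`` maps chemical id -> integer module id; chemicals that
    were filtered out of the graph carry :data:`UNDEFINED_MODULE`.
    """

    assignment: dict[str, int] = field(default_factory=dict)
    tallies: dict[int, ModuleTally] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        """Defined module ids (Undefined excluded), sorted."""
        return sorted(m for m in self.tallies if m != UNDEFINED_MODULE)

    def members(self, module_id: int) -> list[str]:
        return [cid for cid, m in self.assignment.items() if m == module_id]

    def add_undefined(self, ids: Sequence[str],
                      labels: Mapping[str, str] | None = None) -> None:
        """Assign chemicals absent from the partition to the Undefined module."""
        for cid in ids:
            if cid not in self.assignment:
                self.assignment[cid] = UNDEFINED_MODULE
                self._tally(UNDEFINED_MODULE,
                            labels.get(cid) if labels else None)

    def _tally(self, module_id: int, label: str | None) -> None:
        tally = self.tallies.setdefault(module_id, ModuleTally())
        tally.count += 1
        if label == SENSITIZER:
            tally.n_sensitizers += 1
        elif label == NON_SENSITIZER:
            tally.n_non_sensitizers += 1
        else:
            tally.n_unknown += 1

    @classmethod
    def from_communities(cls, communities: Sequence[set[str]],
                         labels: Mapping[str, str] | None = None
                         ) -> "ModulePartition":
        """Number communities by decreasing size (ties by smallest member id,
        so numbering is stable under label switching of the algorithm)."""
        part = cls()
        ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
        for mid, community in enumerate(ordered):
            for cid in sorted(community):
                part.assignment[cid] = mid
                part._tally(mid, labels.get(cid) if labels else None)
        return part


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph in which every node has at least k neighbors.

    The empty graph is a legitimate result (e.g. k above the maximum
    degree). k = 0 returns the graph unchanged.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    core = nx.k_core(graph, k)
    result = graph.subgraph(core.nodes).copy()
    result.graph.update(graph.graph)
    return result


def detect_modules(graph: nx.Graph, seed: int = 0, *,
                   resolution: float = 1.0, weighted: bool = True,
                   labels: Mapping[str, str] | None = None) -> ModulePartition:
    """Louvain module detection on the similarity graph.

    Greedy modularity optimization with community aggregation; edge
    similarities serve as modularity weights by default. Deterministic for
    a given seed (the seed shuffles the node visit order, making the
    algorithm's stochasticity explicit).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect modules on an empty graph")
    if labels is None:
        labels = {n: d.get("label", "unknown") for n, d in graph.nodes(data=True)}
    communities = nx.community.louvain_communities(
        graph, weight="weight" if weighted else None,
        resolution=resolution, seed=seed)
    return ModulePartition.from_communities(
        [set(c) for c in communities], labels)


def modularity(graph: nx.Graph, partition: ModulePartition, *,
               weighted: bool = True) -> float:
    """Newman modularity of a partition restricted to the graph's nodes."""
    groups: dict[int, set[str]] = {}
    for node in graph.nodes:
        groups.setdefault(partition.assignment[node], set()).add(node)
    return nx.community.modularity(graph, groups.values(),
                                   weight="weight" if weighted else None)


def write_partition_csv(partition: ModulePartition, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "module"])
        for cid in sorted(partition.assignment):
            mid = partition.assignment[cid]
            writer.writerow([cid, "Undefined" if mid == UNDEFINED_MODULE else mid])


# ---------------------------------------------------------------------------
# force-directed layout

@dataclass
class LayoutConfig:
    """Parameters of the force simulation used for map layout.

    Nodes are charged particles repelling each other; edges are springs
    attracting their endpoints; a weak gravity pulls everything toward the
    origin so disconnected parts do not drift apart. Defaults follow the
    force-atlas parameterization commonly used for chemical similarity maps.
    Coordinates feed GEXF export and visual QC only — no downstream
    computation depends on them.
    """

    inertia: float = 0.1
    repulsion: float = 200.0
    attraction: float = 10.0
    max_displacement: float = 10.0
    autostabilize: bool = True
    autostabilize_strength: float = 80.0
    autostabilize_sensibility: float = 0.2
    gravity: float = 9000.0
    attraction_distribution: bool = False
    adjust_by_sizes: bool = True
    speed: float = 10.0
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iteration count must be >= 0")
        for name in ("inertia", "repulsion", "attraction", "max_displacement",
                     "gravity", "speed"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"layout parameter {name} must be finite")


_GRAVITY_SCALE = 1e-4  # gravity constant is conventionally quoted x10^4
_TIME_STEP = 1e-2


def force_layout(graph: nx.Graph,
                 config: LayoutConfig | None = None) -> dict[str, tuple[float, float]]:
    """Deterministic 2-D force simulation of the similarity graph.

    Returns a map node -> (x, y). Same graph and same seed give identical
    coordinates. Repulsion decays as 1/distance, spring attraction grows
    linearly with distance (scaled by edge weight), and displacement per
    step is capped at ``max_displacement`` and blended with the previous
    step's displacement by ``inertia``.
    """
    config = config or LayoutConfig()
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    rng = np.random.default_rng(config.seed)
    pos = rng.uniform(-50.0, 50.0, size=(n, 2))
    prev_disp = np.zeros_like(pos)
    index = {node: i for i, node in enumerate(nodes)}
    if graph.number_of_edges():
        edges = np.array([(index[u], index[v]) for u, v in graph.edges])
        weights = np.array([graph[u][v].get("weight", 1.0) for u, v in graph.edges])
    else:
        edges = np.empty((0, 2), dtype=int)
        weights = np.empty(0)
    degrees = np.array([graph.degree(node) for node in nodes], dtype=float)
    sizes = 1.0 + degrees / max(degrees.max(), 1.0) if config.adjust_by_sizes else np.ones(n)
    speed = config.speed

    for _ in range(config.iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        # repulsion ~ k_r / d along the separation direction
        rep = config.repulsion * sizes[None, :, None] * delta / (dist ** 2)[..., None]
        force = rep.sum(axis=1)
        # spring attraction ~ k_a * d * weight
        if len(edges):
            evec = pos[edges[:, 1]] - pos[edges[:, 0]]
            k_att = config.attraction * weights
            if config.attraction_distribution:
                k_att = k_att / np.maximum(degrees[edges[:, 0]], 1.0)
            pull = k_att[:, None] * evec
            np.add.at(force, edges[:, 0], pull)
            np.add.at(force, edges[:, 1], -pull)
        force -= _GRAVITY_SCALE * config.gravity * pos
        disp = config.inertia * prev_disp + speed * _TIME_STEP * force
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        cap = config.max_displacement
        disp = np.where(norms > cap, disp * cap / norms, disp)
        pos = pos + disp
        if config.autostabilize:
            # damp the step size when displacements stay large relative
            # to the stabilization sensibility
            mean_disp = float(np.linalg.norm(disp, axis=1).mean())
            if mean_disp > config.autostabilize_sensibility:
                speed = max(speed * (1.0 - config.autostabilize_strength / 1e3),
                            1e-3)
        prev_disp = disp

    return {node: (float(pos[i, 0]), float(pos[i, 1])) for i, node in enumerate(nodes)}


def annotate_graph(graph: nx.Graph, partition: ModulePartition | None = None,
                   layout: Mapping[str, tuple[float, float]] | None = None) -> nx.Graph:
    """Attach module ids and viz positions as node attributes (for GEXF)."""
    out = graph.copy()
    for node, data in out.nodes(data=True):
        if partition is not None:
            mid = partition.assignment.get(node, UNDEFINED_MODULE)
            data["module"] = "Undefined" if mid == UNDEFINED_MODULE else int(mid)
        if layout is not None and node in layout:
            x, y = layout[node]
            data["viz"] = {"position": {"x": x, "y": y, "z": 0.0}}
    return out
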