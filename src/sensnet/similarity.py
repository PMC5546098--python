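"""Tanimoto similarity on binary substructure fingerprints and the
similarity graph.

Fingerprints are sets of substructure-bit indices. Tanimoto similarity is
the number of shared substructures divided by the total number of
substructures in both chemicals, |A∩B| / |A∪B|, ranging from 0 (disjoint)
to 1 (identical). The similarity graph connects chemicals whose similarity
reaches a threshold (0.65 by default for map construction); edge weights
carry the full-precision similarity.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .io_model import ChemicalRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.65


def tanimoto(fp_a: frozenset[int] | set[int], fp_b: frozenset[int] | set[int]) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| between two bit-index sets.

    Both sets empty is a degenerate input: the similarity is defined as 0
    and a warning is emitted.
    """
    if not fp_a and not fp_b:
        warnings.warn("tanimoto of two empty fingerprints is degenerate; "
                      "returning 0", stacklevel=2)
        return 0.0
    inter = len(fp_a & fp_b)
    union = len(fp_a) + len(fp_b) - inter
    return inter / union


def _fingerprint_matrix(chems: Sequence[ChemicalRecord]) -> np.ndarray:
    missing = [c.id for c in chems if c.fingerprint is None]
    if missing:
        raise ValueError(
            f"chemicals without fingerprints cannot enter similarity "
            f"analysis: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    all_bits = sorted(set().union(*(c.fingerprint for c in chems))) if chems else []
    index = {b: j for j, b in enumerate(all_bits)}
    mat = np.zeros((len(chems), len(all_bits)), dtype=np.uint8)
    for i, c in enumerate(chems):
        for b in c.fingerprint:
            mat[i, index[b]] = 1
    return mat


def pairwise_tanimoto(chems: Sequence[ChemicalRecord]) -> np.ndarray:
    """Dense n×n Tanimoto matrix via bit-vector algebra (diagonal = 1)."""
    mat = _fingerprint_matrix(chems).astype(np.float64)
    inter = mat @ mat.T
    card = mat.sum(axis=1)
    union = card[:, None] + card[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def build_similarity_graph(chems: Sequence[ChemicalRecord],
                           threshold: float = DEFAULT_THRESHOLD) -> nx.Graph:
    """Build the similarity graph: one node per chemical, an edge (i, j)
    for every pair with Tanimoto similarity >= ``threshold``.

    Every chemical needs a fingerprint. All pairs are compared (O(n²) in
    the pair count, vectorized). The threshold is stored on the graph as
    ``G.graph['threshold']``.
    """
    graph = nx.Graph(threshold=float(threshold))
    for c in chems:
        graph.add_node(c.id, label=c.label)
    if len(chems) >= 2:
        sim = pairwise_tanimoto(chems)
        ii, jj = np.nonzero(np.triu(sim >= threshold, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            graph.add_edge(chems[i].id, chems[j].id, weight=float(sim[i, j]))
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Export as edge-list CSV: id_a, id_b, similarity."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "similarity"])
        for u, v, w in sorted(graph.edges(data="weight")):
            writer.writerow([u, v, repr(w)])


def read_edge_list(path: str | Path, threshold: float | None = None) -> nx.Graph:
    graph = nx.Graph(threshold=threshold)
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            graph.add_edge(row["id_a"], row["id_b"],
                           weight=float(row["similarity"]))
    return graph


def write_gexf(graph: nx.Graph, path: str | Path) -> None:
    """GEXF export for Gephi interchange (None attributes dropped)."""
    export = graph.copy()
    export.graph.pop("threshold", None)
    for _, data in export.nodes(data=True):
        for key in [k for k, v in data.items() if v is None]:
            del data[key]
    nx.write_gexf(export, str(path))
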