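"""Residue contact graph and distance binning.

Residues become nodes; an edge joins every unordered pair whose CA-CA
distance is strictly below a threshold (7 A by default), weighted by the
inverse square of that distance.  Pairwise distances are discretised
into T uniform bins over [d_min, d_max) for the distance-classification
task, with out-of-range distances clamped into the boundary bins.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import DihedralTable, ProteinStructure, backbone_dihedrals, ca_distance_matrix


class DuplicateCoordinateError(ValueError):
    """Two distinct residues share a CA position (1/d^2 undefined)."""


@dataclass(frozen=True)
class DistanceBinning:
    """Uniform discretisation of CA-CA distances into T classes."""

    T: int = 30
    d_min: float = 2.0
    d_max: float = 20.0

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("need at least 2 bins")
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be below d_max")

    @property
    def width(self) -> float:
        return (self.d_max - self.d_min) / self.T


def bin_distance(d, binning: DistanceBinning = DistanceBinning()):
    """Class index of a distance: floor((d - d_min)/width), clamped to [0, T)."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    idx = np.floor((d - binning.d_min) / binning.width).astype(np.int64)
    idx = np.clip(idx, 0, binning.T - 1)
    return idx if idx.ndim else int(idx)


@dataclass
class ResidueGraph:
    """Contact-graph view of one protein, ready for the GNN."""

    sequence: str
    distance_matrix: np.ndarray
    edges: set  # unordered pairs as (i, j) tuples with i < j
    edge_weight: dict  # (i, j) -> 1/d_ij^2
    dihedrals: DihedralTable
    threshold: float
    chain_break_after: frozenset = field(default_factory=frozenset)
    id: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.sequence)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weight matrix W with W_ij = 1/d_ij^2 on edges."""
        W = np.zeros_like(self.distance_matrix)
        for (i, j), w in self.edge_weight.items():
            W[i, j] = W[j, i] = w
        return W


def build_residue_graph(s: ProteinStructure, threshold: float = 7.0) -> ResidueGraph:
    """Contact graph with strict d_ij < threshold edges and 1/d^2 weights."""
    D = ca_distance_matrix(s)
    L = len(s)
    off = ~np.eye(L, dtype=bool)
    if np.any(D[off] == 0.0):
        raise DuplicateCoordinateError("distinct residues with identical CA coordinates")
    ii, jj = np.where((D < threshold) & off)
    edges = set()
    weights = {}
    for i, j in zip(ii, jj):
        if i < j:
            edges.add((int(i), int(j)))
            weights[(int(i), int(j))] = 1.0 / D[i, j] ** 2
    return ResidueGraph(
        sequence=s.sequence,
        distance_matrix=D,
        edges=edges,
        edge_weight=weights,
        dihedrals=backbone_dihedrals(s),
        threshold=threshold,
        chain_break_after=s.chain_break_after,
        id=s.id,
    )


def export_edges_tsv(g: ResidueGraph, path) -> None:
    """Debug dump of the edge list: i, j, d_ij, weight."""
    rows = [
        (i, j, g.distance_matrix[i, j], w) for (i, j), w in sorted(g.edge_weight.items())
    ]
    pd.DataFrame(rows, columns=["i", "j", "d_ij", "weight"]).to_csv(
        path, sep="\t", index=False
    )
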