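"""Node featurisation, the edge-weighted GNN and the sequence encoder.

Node features concatenate a per-residue sequence embedding with radial
basis function (RBF) expansions of the normalised phi and psi torsions
plus a mask-flag channel.  The GNN aggregates neighbour messages with
the sum function weighted by 1/d^2 edge features, combines them with a
per-layer linear map applied to h^(k-1) + a^(k), and reads the graph
vector out as the mean over nodes.  Sequence and structure streams are
fused additively per residue.

The sequence encoder is pluggable: the built-in stand-in is a trainable
per-amino-acid embedding table followed by a fixed symmetric 5-residue
sliding-window average, and externally precomputed per-residue
embeddings can be supplied instead.  Either way a trainable linear
projection lifts the embedding to the GNN hidden width; the table and
the projection together form the sequence-side parameter group (theta).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import ResidueGraph
from .nn import init_linear, linear
from .structure import AA_WITH_UNKNOWN


@dataclass(frozen=True)
class RBFSpec:
    """Radial basis expansion of a scalar in [-1, 1].

    Component j is exp(-gamma * (x - u_j)^2) with centers u_j evenly
    spaced from -1 to +1; gamma sets the kernel width.
    """

    n_centers: int = 16
    gamma: float = 10.0

    def __post_init__(self):
        if self.n_centers < 2:
            raise ValueError("need at least 2 centers to span [-1, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.n_centers)


def rbf_expand(x: float, spec: RBFSpec = RBFSpec()) -> np.ndarray:
    """exp(-gamma (x - u_j)^2) for every center u_j."""
    return np.exp(-spec.gamma * (np.asarray(x)[..., None] - spec.centers) ** 2)


def normalize_angle(angle):
    """Map an angle in (-pi, pi] onto (-1, 1] by dividing by pi."""
    angle = np.asarray(angle, dtype=np.float64)
    if np.any(angle <= -np.pi) or np.any(angle > np.pi):
        raise ValueError("angle must lie in (-pi, pi]")
    out = angle / np.pi
    return out if out.ndim else float(out)


def angle_feature_block(
    g: ResidueGraph, masked_indices=(), rbf: RBFSpec = RBFSpec()
) -> np.ndarray:
    """Per-residue [RBF(phi) | RBF(psi) | mask_flag] block, shape (L, 2n+1).

    Invalid terminal/break angles give an all-zero RBF sub-block with
    flag 0; masked residues have both RBF sub-blocks zeroed and flag 1,
    so "undefined" and "masked" stay distinguishable.
    """
    L = g.n_nodes
    n = rbf.n_centers
    block = np.zeros((L, 2 * n + 1))
    d = g.dihedrals
    for i in range(L):
        if d.phi_valid[i]:
            block[i, :n] = rbf_expand(normalize_angle(d.phi[i]), rbf)
        if d.psi_valid[i]:
            block[i, n : 2 * n] = rbf_expand(normalize_angle(d.psi[i]), rbf)
    for i in masked_indices:
        block[i, : 2 * n] = 0.0
        block[i, 2 * n] = 1.0
    return block


# ---------------------------------------------------------------------
# sequence encoder (pluggable; theta parameter group)
# ---------------------------------------------------------------------

_AA_INDEX = {c: i for i, c in enumerate(AA_WITH_UNKNOWN)}
_WINDOW = 5


def init_seq_encoder(rng: np.random.Generator, emb_dim: int, hidden_dim: int) -> dict:
    """Stand-in sequence-encoder parameters: embedding table + projection."""
    a = np.sqrt(3.0 / emb_dim)
    return {
        "table": Tensor(
            rng.uniform(-a, a, size=(len(AA_WITH_UNKNOWN), emb_dim)), requires_grad=True
        ),
        "proj": init_linear(rng, emb_dim, hidden_dim),
    }


def sequence_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in sequence], dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"illegal residue code {e.args[0]!r}") from None


def window_matrix(L: int, window: int = _WINDOW) -> np.ndarray:
    """Row-normalised symmetric sliding-window averaging matrix."""
    half = window // 2
    A = np.zeros((L, L))
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        A[i, lo:hi] = 1.0 / (hi - lo)
    return A


def seq_encode(sequence: str, theta: dict) -> Tensor:
    """Per-residue embedding h^s (pre-projection) from the stand-in encoder."""
    idx = sequence_indices(sequence)
    emb = ad.take_rows(theta["table"], idx)
    return Tensor(window_matrix(len(sequence))) @ emb


def seq_project(theta: dict, emb: Tensor) -> Tensor:
    """Lift sequence embeddings to the GNN hidden width."""
    return linear(theta["proj"], emb)


def load_external_embeddings(path) -> dict:
    """Load per-protein residue embeddings from an .npz keyed by protein id."""
    with np.load(path) as f:
        return {k: np.asarray(f[k], dtype=np.float64) for k in f.files}


def external_embedding(embeddings: dict, protein_id: str, L: int) -> Tensor:
    emb = embeddings.get(protein_id)
    if emb is None:
        raise KeyError(f"no embedding for protein {protein_id!r}")
    if emb.shape[0] != L:
        raise ValueError(
            f"embedding for {protein_id!r} has {emb.shape[0]} rows, expected {L}"
        )
    return Tensor(emb)


# ---------------------------------------------------------------------
# node features and GNN
# ---------------------------------------------------------------------


def init_node_features(
    g: ResidueGraph, seq_emb: Tensor, masked_indices=(), rbf: RBFSpec = RBFSpec()
) -> Tensor:
    """X_v = [seq_embedding | RBF(phi) | RBF(psi) | mask_flag] per residue."""
    if seq_emb.shape[0] != g.n_nodes:
        raise ValueError(
            f"sequence embedding has {seq_emb.shape[0]} rows for {g.n_nodes} nodes"
        )
    block = angle_feature_block(g, masked_indices, rbf)
    return ad.concat([seq_emb, Tensor(block)], axis=1)


def init_gnn_params(
    rng: np.random.Generator, in_dim: int, hidden_dim: int = 1280, n_layers: int = 2
) -> dict:
    """Per-layer linear maps (omega).  Layer 1 maps in_dim -> hidden."""
    if n_layers < 1 or hidden_dim < 1:
        raise ValueError("need n_layers >= 1 and hidden_dim >= 1")
    params = {}
    for k in range(n_layers):
        params[f"layer{k}"] = init_linear(
            rng, in_dim if k == 0 else hidden_dim, hidden_dim
        )
    return params


def gnn_forward(g: ResidueGraph, X: Tensor, omega: dict, adjacency: np.ndarray | None = None):
    """Edge-weighted message passing.

    Per layer: a_i = sum_{v in N(i)} e_iv h_v, then h_i = Linear(h_i + a_i);
    the graph vector h_G is the mean of the final node representations.
    Returns (H, h_G) with H of shape (L, hidden) and h_G of shape (1, hidden).
    """
    if X.shape[0] != g.n_nodes:
        raise ValueError("feature rows must match node count")
    W = Tensor(g.adjacency() if adjacency is None else adjacency)
    h = X
    for k in range(len(omega)):
        a = W @ h
        h = linear(omega[f"layer{k}"], h + a)
    hG = ad.tmean(h, axis=0, keepdims=True)
    return h, hG


def fuse(h_seq: Tensor, h_struct: Tensor) -> Tensor:
    """Additive per-residue fusion of the two streams."""
    if h_seq.shape != h_struct.shape:
        raise ValueError(f"shape mismatch: {h_seq.shape} vs {h_struct.shape}")
    return h_seq + h_struct
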