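"""The two self-supervised tasks and their joint loss.

Distance task: a two-layer head on the difference of two residue
representations predicts which of T uniform bins their CA-CA distance
falls in; the loss is the mean cross-entropy over all ordered pairs
i != j.  With an untrained (all-zero) head the prediction is uniform and
the loss equals ln T exactly, a closed form the tests pin down.

Angle task: 15% of residues (those with both torsions defined) have
their angle features masked; a second two-layer head reconstructs the
normalised (phi, psi) from the masked residue's representation, scored
by a summed squared error over the masked set.

Both losses share one masked forward pass per protein and add up to the
joint pretraining objective.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import RBFSpec, fuse, gnn_forward, init_node_features, normalize_angle
from .graph import DistanceBinning, ResidueGraph, bin_distance
from .nn import init_mlp2, mlp2


class SkipProtein(Exception):
    """No residue has both torsions defined; the angle task cannot run."""


@dataclass(frozen=True)
class MaskSpec:
    """The set M of angle-masked residues for one protein."""

    masked_indices: tuple
    fraction: float = 0.15

    def __len__(self) -> int:
        return len(self.masked_indices)


def maskable_residues(g: ResidueGraph) -> np.ndarray:
    """Residues with both phi and psi valid (the only maskable ones)."""
    d = g.dihedrals
    return np.flatnonzero(d.phi_valid & d.psi_valid)


def mask_size(L: int, fraction: float = 0.15) -> int:
    """max(1, round(fraction * L)) with half-up rounding."""
    return max(1, int(np.floor(fraction * L + 0.5)))


def sample_mask(
    g: ResidueGraph, fraction: float = 0.15, rng: np.random.Generator | None = None
) -> MaskSpec:
    """Uniform sample (without replacement) of maskable residues."""
    rng = rng or np.random.default_rng(0)
    valid = maskable_residues(g)
    if valid.size == 0:
        raise SkipProtein("no residue with both torsions defined")
    k = min(mask_size(g.n_nodes, fraction), valid.size)
    chosen = rng.choice(valid, size=k, replace=False)
    return MaskSpec(masked_indices=tuple(int(i) for i in sorted(chosen)), fraction=fraction)


# ---------------------------------------------------------------------
# prediction heads (alpha parameter group)
# ---------------------------------------------------------------------


def init_heads(
    rng: np.random.Generator,
    hidden_dim: int,
    T: int = 30,
    head_hidden: int | None = None,
    zero: bool = False,
) -> dict:
    """Distance head (hidden -> T logits) and angle head (hidden -> 2).

    ``zero=True`` zeroes every weight, giving the uniform-prediction /
    zero-output closed forms.
    """
    hh = hidden_dim if head_hidden is None else head_hidden
    heads = {
        "dist": init_mlp2(rng, hidden_dim, hh, T),
        "angle": init_mlp2(rng, hidden_dim, hh, 2),
        "dist_reg": init_mlp2(rng, hidden_dim, hh, 1),
    }
    if zero:
        for tree in heads.values():
            for layer in tree.values():
                for t in layer.values():
                    t.data = np.zeros_like(t.data)
    return heads


def ordered_pairs(L: int) -> tuple[np.ndarray, np.ndarray]:
    """All ordered pairs (i, j) with i != j."""
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    off = ii != jj
    return ii[off], jj[off]


def distance_logits(h_i: Tensor, h_j: Tensor, heads: dict) -> Tensor:
    """Softmax distribution over T distance bins for one residue pair."""
    diff = ad.reshape(h_i - h_j, (1, -1))
    return ad.reshape(ad.softmax(mlp2(heads["dist"], diff), axis=1), (-1,))


def distance_loss(
    h: Tensor,
    D: np.ndarray,
    binning: DistanceBinning = DistanceBinning(),
    heads: dict | None = None,
    pair_idx: tuple | None = None,
    labels: np.ndarray | None = None,
) -> Tensor:
    """Mean cross-entropy over ordered pairs i != j.

    ``pair_idx``/``labels`` allow precomputed pairs and bin labels to be
    reused across epochs.
    """
    L = h.shape[0]
    if L < 2:
        raise ValueError("need at least 2 residues")
    ii, jj = ordered_pairs(L) if pair_idx is None else pair_idx
    if labels is None:
        labels = bin_distance(D[ii, jj], binning)
    diff = h[ii] - h[jj]
    logits = mlp2(heads["dist"], diff)
    logp = ad.log_softmax(logits, axis=1)
    onehot = np.zeros((len(labels), binning.T))
    onehot[np.arange(len(labels)), labels] = 1.0
    return -ad.tmean(ad.tsum(logp * Tensor(onehot), axis=1))


def distance_loss_regression(
    h: Tensor,
    D: np.ndarray,
    heads: dict,
    pair_idx: tuple | None = None,
) -> Tensor:
    """Ablation variant: regress the raw distance, mean squared error."""
    L = h.shape[0]
    ii, jj = ordered_pairs(L) if pair_idx is None else pair_idx
    pred = mlp2(heads["dist_reg"], h[ii] - h[jj])
    target = Tensor(D[ii, jj][:, None])
    return ad.tmean(ad.power(pred - target, 2.0))


def angle_prediction(h_masked: Tensor, heads: dict) -> Tensor:
    """(phi_bar, psi_bar) on the normalised scale for masked residues."""
    if h_masked.ndim == 1:
        h_masked = ad.reshape(h_masked, (1, -1))
    return mlp2(heads["angle"], h_masked)


def angle_loss(pred: Tensor, truth: np.ndarray) -> Tensor:
    """Sum over masked residues of squared phi and psi errors."""
    truth = np.asarray(truth, dtype=np.float64)
    if truth.size == 0:
        raise ValueError("need at least one masked residue")
    return ad.tsum(ad.power(pred - Tensor(truth), 2.0))


def normalized_truth(g: ResidueGraph, masked_indices) -> np.ndarray:
    """Ground-truth (phi, psi)/pi rows for the masked residues."""
    d = g.dihedrals
    idx = np.asarray(masked_indices, dtype=np.intp)
    return np.column_stack(
        [normalize_angle(d.phi[idx]), normalize_angle(d.psi[idx])]
    )


# ---------------------------------------------------------------------
# joint loss
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class AblationFlags:
    no_angle: bool = False
    no_distance: bool = False
    distance_regression: bool = False


def protein_ssl_terms(
    g: ResidueGraph,
    seq_emb: Tensor,
    theta: dict,
    omega: dict,
    heads: dict,
    mask: MaskSpec,
    binning: DistanceBinning = DistanceBinning(),
    rbf: RBFSpec = RBFSpec(),
    ablate: AblationFlags = AblationFlags(),
    cache: dict | None = None,
):
    """One masked forward pass feeding both losses for one protein.

    ``seq_emb`` is the raw (pre-projection) sequence embedding; the
    projected stream is fused with the GNN output and both heads consume
    the fused representation.  Returns (l_dis, l_angle) as scalar
    tensors (zero-constant where ablated).
    """
    from .encoders import seq_project

    cache = cache or {}
    X = init_node_features(g, seq_emb, mask.masked_indices, rbf)
    H, _ = gnn_forward(g, X, omega, adjacency=cache.get("adjacency"))
    h = fuse(seq_project(theta, seq_emb), H)

    if ablate.no_distance:
        l_dis = Tensor(0.0)
    elif ablate.distance_regression:
        l_dis = distance_loss_regression(
            h, g.distance_matrix, heads, pair_idx=cache.get("pair_idx")
        )
    else:
        l_dis = distance_loss(
            h,
            g.distance_matrix,
            binning,
            heads,
            pair_idx=cache.get("pair_idx"),
            labels=cache.get("labels"),
        )

    if ablate.no_angle or len(mask) == 0:
        l_angle = Tensor(0.0)
    else:
        idx = np.asarray(mask.masked_indices, dtype=np.intp)
        pred = angle_prediction(h[idx], heads)
        l_angle = angle_loss(pred, normalized_truth(g, mask.masked_indices))
    return l_dis, l_angle


def ssl_loss(
    proteins: list,
    theta: dict,
    omega: dict,
    heads: dict,
    masks: list,
    seq_embs: list,
    binning: DistanceBinning = DistanceBinning(),
    rbf: RBFSpec = RBFSpec(),
    ablate: AblationFlags = AblationFlags(),
    caches: list | None = None,
):
    """Batch-mean joint loss: total = mean(l_dis) + mean(l_angle)."""
    if not proteins:
        raise ValueError("empty batch")
    caches = caches or [None] * len(proteins)
    dis_terms, angle_terms = [], []
    for g, mask, emb, cache in zip(proteins, masks, seq_embs, caches):
        l_dis, l_angle = protein_ssl_terms(
            g, emb, theta, omega, heads, mask, binning, rbf, ablate, cache
        )
        dis_terms.append(l_dis)
        angle_terms.append(l_angle)
    n = float(len(proteins))
    l_dis = ad.tsum(ad.concat([ad.reshape(t, (1,)) for t in dis_terms])) / n
    l_angle = ad.tsum(ad.concat([ad.reshape(t, (1,)) for t in angle_terms])) / n
    return l_dis, l_angle, l_dis + l_angle
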