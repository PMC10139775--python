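"""Jensen-Shannon mutual information and the pseudo bi-level scheme.

The discriminator scores a (sequence-vector, structure-vector) pair; the
JS bound averages -softplus(-score) over matched pairs and subtracts the
average softplus(score) over mismatched pairs (a seeded within-batch
derangement).  With a zero discriminator the bound is exactly -2 ln 2.

The bi-level scheme perturbs the sequence-encoder parameters theta by
one gradient-ascent step on the MI bound, evaluates the self-supervised
loss at the perturbed theta(omega), and differentiates the result with
respect to the GNN parameters *through* the inner step (second-order
mode).  The perturbed theta is used only inside the step: the persistent
theta is never modified, which is the "pseudo" contract.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import RBFSpec, gnn_forward, init_node_features, seq_project
from .graph import DistanceBinning
from .nn import init_linear, linear, tree_leaves, tree_tensors
from .objectives import AblationFlags, ssl_loss


class NonFiniteGradientError(RuntimeError):
    """An outer step produced a non-finite gradient; the step is aborted."""


@dataclass(frozen=True)
class BilevelConfig:
    """Learning rates and mode of the pseudo bi-level optimiser.

    mode "second_order" differentiates through the inner ascent step,
    "first_order" treats the perturbed theta as a constant, and "off"
    reduces to plain self-supervised training.
    """

    inner_lr: float = 5e-5
    outer_lr: float = 1e-3
    mode: str = "second_order"
    mi_enabled: bool = True

    def __post_init__(self):
        if self.inner_lr < 0:
            raise ValueError("inner_lr must be >= 0")
        if self.mode not in ("second_order", "first_order", "off"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------
# discriminator (beta parameter group)
# ---------------------------------------------------------------------


def init_discriminator(rng: np.random.Generator, dim: int) -> dict:
    """Three equal-width FC layers; skip connections keep the width."""
    return {f"fc{k}": init_linear(rng, dim, dim) for k in range(3)}


def discriminator_embed(beta: dict, v: Tensor) -> Tensor:
    """Shared tower applied to either side before the dot product."""
    y1 = ad.relu(linear(beta["fc0"], v))
    y2 = ad.relu(linear(beta["fc1"], y1) + y1)
    return linear(beta["fc2"], y2) + y2


def discriminator_score(beta: dict, s: Tensor, g: Tensor) -> Tensor:
    """Scalar score T_beta(s, g): dot product of the two tower outputs."""
    return ad.tsum(discriminator_embed(beta, s) * discriminator_embed(beta, g))


# ---------------------------------------------------------------------
# protein-level representations and the JS bound
# ---------------------------------------------------------------------


def protein_level_reps(
    graphs: list,
    seq_embs: list,
    theta: dict,
    omega: dict,
    rbf: RBFSpec = RBFSpec(),
    caches: list | None = None,
):
    """(s_x, g_x) per protein: mean projected sequence embedding and the
    GNN graph readout, both computed on unmasked features."""
    caches = caches or [None] * len(graphs)
    reps = []
    for g, emb, cache in zip(graphs, seq_embs, caches):
        s_x = ad.tmean(seq_project(theta, emb), axis=0, keepdims=True)
        X = init_node_features(g, emb, (), rbf)
        _, g_x = gnn_forward(g, X, omega, adjacency=(cache or {}).get("adjacency"))
        reps.append((s_x, g_x))
    return reps


def derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A permutation of range(n) with no fixed point (needs n >= 2)."""
    if n < 2:
        raise ValueError("negatives need at least two proteins in the batch")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def mi_estimate(reps: list, beta: dict, neg_idx: np.ndarray) -> Tensor:
    """JS bound: E_pos[-sp(-T)] - E_neg[sp(T)] with sp(z) = log(1+e^z)."""
    n = len(reps)
    if n < 2:
        raise ValueError("mutual information needs a batch of at least 2")
    pos_terms = []
    neg_terms = []
    for x in range(n):
        s_x, g_x = reps[x]
        pos_terms.append(ad.reshape(-ad.softplus(-discriminator_score(beta, s_x, g_x)), (1,)))
        g_neg = reps[int(neg_idx[x])][1]
        neg_terms.append(ad.reshape(ad.softplus(discriminator_score(beta, s_x, g_neg)), (1,)))
    return ad.tmean(ad.concat(pos_terms)) - ad.tmean(ad.concat(neg_terms))


# ---------------------------------------------------------------------
# bi-level steps
# ---------------------------------------------------------------------


def inner_step(theta: dict, mi_value: Tensor, eta: float, mode: str = "second_order") -> dict:
    """theta(omega) = theta + eta * dI/dtheta, without touching theta.

    In second-order mode the returned tensors keep the graph linking
    them to omega (and beta), so the outer gradient can flow through the
    inner ascent step; in first-order mode they are detached constants.
    """
    paths_leaves = list(tree_leaves(theta))
    leaves = [t for _, t in paths_leaves]
    grads = ad.grad(mi_value, leaves, create_graph=(mode == "second_order"))
    perturbed = {}
    for (path, leaf), g in zip(paths_leaves, grads):
        if mode == "second_order":
            perturbed[path] = leaf + Tensor(eta) * g
        else:
            perturbed[path] = Tensor(leaf.data + eta * g.data)
    return _unflatten(theta, perturbed)


def _unflatten(template, flat: dict, prefix: str = ""):
    if isinstance(template, Tensor):
        return flat[prefix]
    return {
        k: _unflatten(v, flat, f"{prefix}/{k}" if prefix else k)
        for k, v in template.items()
    }


def outer_step(
    params: dict,
    graphs: list,
    masks: list,
    seq_embs: list,
    cfg: BilevelConfig,
    rng: np.random.Generator,
    optimizer=None,
    beta_optimizer=None,
    lr: float | None = None,
    binning: DistanceBinning = DistanceBinning(),
    rbf: RBFSpec = RBFSpec(),
    ablate: AblationFlags = AblationFlags(),
    caches: list | None = None,
) -> dict:
    """One outer update of (omega, alpha, beta); theta is left untouched.

    Returns the step's metrics (l_dis, l_angle, total, I).  When
    ``optimizer`` is None the gradients are returned under "grads"
    instead of being applied (used by tests to compare against oracles).
    """
    theta, omega, alpha, beta = (
        params["theta"],
        params["omega"],
        params["alpha"],
        params["beta"],
    )
    metrics: dict = {}
    theta_eff = theta
    mi_value = None
    if cfg.mi_enabled and len(graphs) >= 2:
        reps = protein_level_reps(graphs, seq_embs, theta, omega, rbf, caches)
        neg = derangement(len(graphs), rng)
        mi_value = mi_estimate(reps, beta, neg)
        metrics["I"] = mi_value.item()
        if cfg.mode != "off" and cfg.inner_lr > 0:
            theta_eff = inner_step(theta, mi_value, cfg.inner_lr, cfg.mode)

    l_dis, l_angle, total = ssl_loss(
        graphs, theta_eff, omega, alpha, masks, seq_embs, binning, rbf, ablate, caches
    )
    metrics.update(l_dis=l_dis.item(), l_angle=l_angle.item(), total=total.item())

    targets = tree_tensors(omega) + tree_tensors(alpha)
    grads = ad.grad(total, targets)
    if not all(np.all(np.isfinite(g.data)) for g in grads):
        raise NonFiniteGradientError("non-finite outer gradient; step aborted")

    beta_grads = None
    if mi_value is not None:
        beta_grads = ad.grad(mi_value, tree_tensors(beta))
        if not all(np.all(np.isfinite(g.data)) for g in beta_grads):
            raise NonFiniteGradientError("non-finite discriminator gradient")

    if optimizer is None:
        metrics["grads"] = grads
        metrics["beta_grads"] = beta_grads
        return metrics
    optimizer.step(grads, lr=lr)
    if beta_grads is not None and beta_optimizer is not None:
        beta_optimizer.step(beta_grads, lr=lr)
    return metrics
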