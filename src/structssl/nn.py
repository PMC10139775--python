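"""Parameter containers, layers and optimisation utilities.

Parameters live in nested dicts of :class:`~structssl.autodiff.Tensor`
leaves (requires_grad=True).  Forward functions are purely functional:
they take a parameter tree and inputs, which is what allows the bi-level
scheme to evaluate a network at perturbed, graph-carrying parameters
without mutating anything.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor, relu

# ---------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------


def init_linear(rng: np.random.Generator, n_in: int, n_out: int) -> dict:
    """Glorot-uniform weight, zero bias."""
    a = np.sqrt(6.0 / (n_in + n_out))
    return {
        "W": Tensor(rng.uniform(-a, a, size=(n_in, n_out)), requires_grad=True),
        "b": Tensor(np.zeros(n_out), requires_grad=True),
    }


def linear(p: dict, x: Tensor) -> Tensor:
    return x @ p["W"] + p["b"]


def init_mlp2(rng: np.random.Generator, n_in: int, n_hidden: int, n_out: int) -> dict:
    """Two fully connected layers with a ReLU in the middle."""
    return {"fc1": init_linear(rng, n_in, n_hidden), "fc2": init_linear(rng, n_hidden, n_out)}


def mlp2(p: dict, x: Tensor) -> Tensor:
    return linear(p["fc2"], relu(linear(p["fc1"], x)))


# ---------------------------------------------------------------------
# parameter trees
# ---------------------------------------------------------------------


def tree_leaves(tree, prefix: str = ""):
    """Yield (path, Tensor) pairs in a deterministic order."""
    if isinstance(tree, Tensor):
        yield prefix, tree
        return
    for key in sorted(tree):
        yield from tree_leaves(tree[key], f"{prefix}/{key}" if prefix else key)


def tree_tensors(tree) -> list[Tensor]:
    return [t for _, t in tree_leaves(tree)]


def tree_map(tree, fn):
    """Apply ``fn`` to every leaf tensor, preserving structure."""
    if isinstance(tree, Tensor):
        return fn(tree)
    return {k: tree_map(v, fn) for k, v in tree.items()}


def tree_to_arrays(tree) -> dict:
    return {path: t.data.copy() for path, t in tree_leaves(tree)}


def tree_from_arrays(tree, arrays: dict):
    """Rebuild a tree with the given leaf arrays (requires_grad leaves)."""
    if isinstance(tree, Tensor):
        raise TypeError("pass the dict tree, not a leaf")
    out = {}
    for k, v in tree.items():
        if isinstance(v, Tensor):
            out[k] = None  # filled below
        else:
            out[k] = v
    return _rebuild(tree, arrays, "")


def _rebuild(tree, arrays, prefix):
    if isinstance(tree, Tensor):
        return Tensor(arrays[prefix], requires_grad=True)
    return {
        k: _rebuild(v, arrays, f"{prefix}/{k}" if prefix else k) for k, v in tree.items()
    }


def tree_bytes(tree) -> bytes:
    """A canonical byte string of all leaves, for exact-identity checks."""
    return b"".join(t.data.tobytes() for _, t in tree_leaves(tree))


# ---------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------


class Adam:
    """Adam over a list of leaf tensors; updates ``.data`` in place.

    ``maximize=True`` performs gradient ascent (used for the MI
    discriminator).
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 maximize: bool = False):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.maximize = maximize
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            g = g.data if isinstance(g, Tensor) else np.asarray(g)
            if self.maximize:
                g = -g
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(step: int, total: int, lr0: float) -> float:
    """Cosine decay from lr0 at step 0 to exactly 0 at step == total."""
    if total <= 0:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * min(step, total) / total))
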