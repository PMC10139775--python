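"""Pretraining loop, checkpointing and the finetuning harness.

Pretraining minimises the joint self-supervised loss over a corpus of
backbones with Adam under a cosine learning-rate decay, optionally
coupling the sequence encoder through the pseudo bi-level MI scheme.
The persistent parameter groups are omega (GNN), alpha (task heads) and
beta (MI discriminator); theta (sequence encoder) is initialised once
and never updated, matching the frozen-language-model contract.

Finetuning attaches a purely linear head to the mean-pooled fused
residue representations; "full" mode trains the GNN and the head,
"head_only" freezes the GNN.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import (
    RBFSpec,
    external_embedding,
    fuse,
    gnn_forward,
    init_gnn_params,
    init_node_features,
    init_seq_encoder,
    load_external_embeddings,
    seq_encode,
    seq_project,
)
from .graph import DistanceBinning, ResidueGraph, bin_distance, build_residue_graph
from .mi import BilevelConfig, NonFiniteGradientError, init_discriminator, outer_step
from .nn import Adam, cosine_lr, init_linear, linear, tree_from_arrays, tree_tensors, tree_to_arrays
from .objectives import AblationFlags, MaskSpec, SkipProtein, init_heads, ordered_pairs, sample_mask
from .structure import ProteinStructure


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters."""

    hidden_dim: int = 1280
    n_layers: int = 2
    emb_dim: int = 32
    rbf_centers: int = 16
    rbf_gamma: float = 10.0
    threshold: float = 7.0
    T: int = 30
    d_min: float = 2.0
    d_max: float = 20.0
    mask_fraction: float = 0.15
    seq_encoder: str = "standin"  # "standin" or "external"
    embeddings_path: str | None = None

    @property
    def rbf(self) -> RBFSpec:
        return RBFSpec(self.rbf_centers, self.rbf_gamma)

    @property
    def binning(self) -> DistanceBinning:
        return DistanceBinning(self.T, self.d_min, self.d_max)

    @property
    def input_dim(self) -> int:
        return self.emb_dim + 2 * self.rbf_centers + 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (Adam, cosine decay)."""

    epochs_pretrain: int = 10
    epochs_finetune: int = 5
    lr_gnn: float = 1e-3
    lr_inner: float = 5e-5
    lr_finetune: float = 1e-4
    batch_size: int = 8
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    bilevel_mode: str = "second_order"
    mi_enabled: bool = True
    no_angle: bool = False
    no_distance: bool = False
    distance_regression: bool = False

    def __post_init__(self):
        for name in ("lr_gnn", "lr_finetune"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs_pretrain < 1 or self.epochs_finetune < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def bilevel(self) -> BilevelConfig:
        return BilevelConfig(
            inner_lr=self.lr_inner,
            outer_lr=self.lr_gnn,
            mode=self.bilevel_mode,
            mi_enabled=self.mi_enabled,
        )

    @property
    def ablations(self) -> AblationFlags:
        return AblationFlags(self.no_angle, self.no_distance, self.distance_regression)


def load_config(path) -> tuple[ModelConfig, TrainConfig]:
    """Read the nested YAML config into the two config dataclasses."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    rbf = raw.get("rbf", {})
    bilevel = raw.get("bilevel", {})
    mi = raw.get("mi", {})
    ablations = raw.get("ablations", {})
    se = raw.get("seq_encoder", "standin")
    if isinstance(se, str):
        se = {"mode": se}
    model = ModelConfig(
        hidden_dim=raw.get("hidden_dim", 1280),
        n_layers=raw.get("layers", 2),
        emb_dim=raw.get("emb_dim", 32),
        rbf_centers=rbf.get("n_centers", 16),
        rbf_gamma=rbf.get("gamma", 10.0),
        threshold=raw.get("threshold", 7.0),
        T=raw.get("T", 30),
        mask_fraction=raw.get("mask_fraction", 0.15),
        seq_encoder=se.get("mode", "standin"),
        embeddings_path=se.get("embeddings"),
    )
    train = TrainConfig(
        epochs_pretrain=raw.get("epochs_pretrain", 10),
        epochs_finetune=raw.get("epochs_finetune", 5),
        lr_gnn=bilevel.get("outer_lr", raw.get("lr_gnn", 1e-3)),
        lr_inner=bilevel.get("inner_lr", 5e-5),
        lr_finetune=raw.get("lr_finetune", 1e-4),
        batch_size=raw.get("batch_size", 8),
        seed=raw.get("seed", 0),
        bilevel_mode=bilevel.get("mode", "second_order"),
        mi_enabled=mi.get("enabled", True),
        no_angle=ablations.get("no_angle", False),
        no_distance=ablations.get("no_distance", False),
        distance_regression=ablations.get("distance_regression", False),
    )
    return model, train


# ---------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------


def init_model(model_cfg: ModelConfig, seed: int = 0) -> dict:
    """The four parameter groups: theta, omega, alpha, beta."""
    rng = np.random.default_rng(seed)
    return {
        "theta": init_seq_encoder(rng, model_cfg.emb_dim, model_cfg.hidden_dim),
        "omega": init_gnn_params(
            rng, model_cfg.input_dim, model_cfg.hidden_dim, model_cfg.n_layers
        ),
        "alpha": init_heads(rng, model_cfg.hidden_dim, model_cfg.T),
        "beta": init_discriminator(rng, model_cfg.hidden_dim),
    }


def make_embedder(model_cfg: ModelConfig, theta: dict):
    """Per-protein sequence-embedding function.

    "standin" runs the trainable table+window encoder on the sequence;
    "external" serves precomputed rows keyed by protein id from the
    configured .npz file.
    """
    if model_cfg.seq_encoder == "external":
        if not model_cfg.embeddings_path:
            raise ValueError("external sequence encoder requires embeddings_path")
        store = load_external_embeddings(model_cfg.embeddings_path)

        def external(g):
            emb = external_embedding(store, g.id, g.n_nodes)
            if emb.shape[1] != model_cfg.emb_dim:
                raise ValueError(
                    f"embedding width {emb.shape[1]} != configured emb_dim "
                    f"{model_cfg.emb_dim}"
                )
            return emb

        return external
    if model_cfg.seq_encoder != "standin":
        raise ValueError(f"unknown seq_encoder {model_cfg.seq_encoder!r}")
    return lambda g: seq_encode(g.sequence, theta)


@dataclass
class PreparedProtein:
    """A residue graph plus cached static arrays reused every epoch."""

    graph: ResidueGraph
    cache: dict

    @property
    def id(self) -> str:
        return self.graph.id


def prepare_proteins(structures: list, model_cfg: ModelConfig) -> list:
    out = []
    for s in structures:
        g = build_residue_graph(s, model_cfg.threshold)
        ii, jj = ordered_pairs(g.n_nodes)
        out.append(
            PreparedProtein(
                graph=g,
                cache={
                    "adjacency": g.adjacency(),
                    "pair_idx": (ii, jj),
                    "labels": bin_distance(g.distance_matrix[ii, jj], model_cfg.binning),
                },
            )
        )
    return out


@dataclass
class Checkpoint:
    """Frozen copy of all parameter groups plus configs and loss history."""

    params: dict  # group -> {path -> ndarray}
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    epoch: int
    history: list = field(default_factory=list)
    aborted: bool = False

    def save(self, path) -> None:
        arrays = {
            f"{group}:{p}": arr
            for group, tree in self.params.items()
            for p, arr in tree.items()
        }
        meta = json.dumps(
            {
                "model_cfg": asdict(self.model_cfg),
                "train_cfg": asdict(self.train_cfg),
                "epoch": self.epoch,
                "history": self.history,
                "aborted": self.aborted,
            }
        )
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as f:
            meta = json.loads(str(f["__meta__"]))
            params: dict = {}
            for key in f.files:
                if key == "__meta__":
                    continue
                group, p = key.split(":", 1)
                params.setdefault(group, {})[p] = f[key]
        return cls(
            params=params,
            model_cfg=ModelConfig(**meta["model_cfg"]),
            train_cfg=TrainConfig(**meta["train_cfg"]),
            epoch=meta["epoch"],
            history=meta["history"],
            aborted=meta["aborted"],
        )

    def materialize(self, seed: int = 0) -> dict:
        """Rebuild live parameter trees from the stored arrays."""
        template = init_model(self.model_cfg, seed)
        return {
            group: tree_from_arrays(template[group], self.params[group])
            for group in template
        }


def snapshot_params(params: dict) -> dict:
    return {group: tree_to_arrays(tree) for group, tree in params.items()}


# ---------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------


def pretrain(
    structures: list,
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    log_path=None,
) -> Checkpoint:
    """Self-supervised pretraining over a corpus of backbones."""
    if not structures:
        raise ValueError("empty pretraining dataset")
    prepared = prepare_proteins(structures, model_cfg)
    params = init_model(model_cfg, train_cfg.seed)
    embedder = make_embedder(model_cfg, params["theta"])
    rng = np.random.default_rng(train_cfg.seed + 1)
    opt = Adam(
        tree_tensors(params["omega"]) + tree_tensors(params["alpha"]),
        lr=train_cfg.lr_gnn,
        betas=(train_cfg.adam_beta1, train_cfg.adam_beta2),
    )
    beta_opt = Adam(
        tree_tensors(params["beta"]),
        lr=train_cfg.lr_gnn,
        betas=(train_cfg.adam_beta1, train_cfg.adam_beta2),
        maximize=True,
    )
    history: list = []
    last_good = snapshot_params(params)
    log_f = open(log_path, "w") if log_path else None
    try:
        for epoch in range(train_cfg.epochs_pretrain):
            lr = cosine_lr(epoch, train_cfg.epochs_pretrain, train_cfg.lr_gnn)
            order = rng.permutation(len(prepared))
            for start in range(0, len(order), train_cfg.batch_size):
                batch = [prepared[i] for i in order[start : start + train_cfg.batch_size]]
                graphs = [p.graph for p in batch]
                caches = [p.cache for p in batch]
                masks = []
                for g in graphs:
                    try:
                        masks.append(sample_mask(g, model_cfg.mask_fraction, rng))
                    except SkipProtein:
                        masks.append(MaskSpec((), model_cfg.mask_fraction))
                seq_embs = [embedder(g) for g in graphs]
                try:
                    metrics = outer_step(
                        params,
                        graphs,
                        masks,
                        seq_embs,
                        train_cfg.bilevel,
                        rng,
                        optimizer=opt,
                        beta_optimizer=beta_opt,
                        lr=lr,
                        binning=model_cfg.binning,
                        rbf=model_cfg.rbf,
                        ablate=train_cfg.ablations,
                        caches=caches,
                    )
                except NonFiniteGradientError:
                    return Checkpoint(
                        params=last_good,
                        model_cfg=model_cfg,
                        train_cfg=train_cfg,
                        epoch=epoch,
                        history=history,
                        aborted=True,
                    )
                record = {
                    "epoch": epoch,
                    "step": start // train_cfg.batch_size,
                    "lr": lr,
                    "l_dis": metrics["l_dis"],
                    "l_angle": metrics["l_angle"],
                    "total": metrics["total"],
                    "I": metrics.get("I"),
                    "seed": train_cfg.seed,
                }
                history.append(record)
                if log_f:
                    log_f.write(json.dumps(record) + "\n")
            last_good = snapshot_params(params)
    finally:
        if log_f:
            log_f.close()
    return Checkpoint(
        params=snapshot_params(params),
        model_cfg=model_cfg,
        train_cfg=train_cfg,
        epoch=train_cfg.epochs_pretrain,
        history=history,
    )


# ---------------------------------------------------------------------
# finetuning and evaluation
# ---------------------------------------------------------------------


def fused_protein_vector(
    p: PreparedProtein, theta: dict, omega: dict, rbf: RBFSpec, embedder=None
) -> Tensor:
    """Mean over residues of the fused representation (1 x hidden)."""
    emb = embedder(p.graph) if embedder is not None else seq_encode(p.graph.sequence, theta)
    X = init_node_features(p.graph, emb, (), rbf)
    H, _ = gnn_forward(p.graph, X, omega, adjacency=p.cache.get("adjacency"))
    h = fuse(seq_project(theta, emb), H)
    return ad.tmean(h, axis=0, keepdims=True)


@dataclass
class Classifier:
    """A linear head over mean-pooled fused residue representations.

    The pooled vectors are standardised with per-dimension statistics
    frozen from the training set before the head is applied; the whole
    map stays affine, so this is still a purely linear head.
    """

    params: dict  # theta / omega trees
    head: dict
    model_cfg: ModelConfig
    classes: int
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def _standardize(self, row: Tensor) -> Tensor:
        if self.feature_mean is None:
            return row
        return (row - Tensor(self.feature_mean[None, :])) / Tensor(
            self.feature_scale[None, :]
        )

    def logits(self, structures: list) -> np.ndarray:
        prepared = prepare_proteins(structures, self.model_cfg)
        embedder = make_embedder(self.model_cfg, self.params["theta"])
        rows = [
            linear(
                self.head,
                self._standardize(
                    fused_protein_vector(
                        p,
                        self.params["theta"],
                        self.params["omega"],
                        self.model_cfg.rbf,
                        embedder,
                    )
                ),
            ).data[0]
            for p in prepared
        ]
        return np.array(rows)

    def predict(self, structures: list) -> np.ndarray:
        return np.argmax(self.logits(structures), axis=1)


def finetune(
    ckpt: Checkpoint,
    structures: list,
    labels,
    mode: str = "full",
    train_cfg: TrainConfig | None = None,
    n_classes: int | None = None,
) -> Classifier:
    """Train a linear classification head; "head_only" freezes the GNN.

    The head starts from zero weights; pooled features are standardised
    with statistics taken once from the training set at the pretrained
    parameters.
    """
    if mode not in ("full", "head_only"):
        raise ValueError(f"unknown finetune mode {mode!r}")
    labels = np.asarray(labels, dtype=np.int64)
    if n_classes is None:
        n_classes = int(labels.max()) + 1 if labels.size else 1
    if np.any(labels < 0) or np.any(labels >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cfg = train_cfg or ckpt.train_cfg
    model_cfg = ckpt.model_cfg
    params = ckpt.materialize(cfg.seed)
    rng = np.random.default_rng(cfg.seed + 2)
    head = init_linear(rng, model_cfg.hidden_dim, n_classes)
    for t in tree_tensors(head):
        t.data = np.zeros_like(t.data)
    trainable = tree_tensors(head)
    if mode == "full":
        trainable = trainable + tree_tensors(params["omega"])
    opt = Adam(trainable, lr=cfg.lr_finetune, betas=(cfg.adam_beta1, cfg.adam_beta2))
    prepared = prepare_proteins(structures, model_cfg)
    embedder = make_embedder(model_cfg, params["theta"])
    with ad.no_grad():
        feats = np.concatenate(
            [
                fused_protein_vector(
                    p, params["theta"], params["omega"], model_cfg.rbf, embedder
                ).data
                for p in prepared
            ]
        )
    feature_mean = feats.mean(axis=0)
    feature_scale = feats.std(axis=0)
    feature_scale[feature_scale < 1e-8] = 1.0
    mean_t, scale_t = Tensor(feature_mean[None, :]), Tensor(feature_scale[None, :])
    for epoch in range(cfg.epochs_finetune):
        lr = cosine_lr(epoch, cfg.epochs_finetune, cfg.lr_finetune)
        order = rng.permutation(len(prepared))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            rows = [
                fused_protein_vector(
                    prepared[i], params["theta"], params["omega"], model_cfg.rbf, embedder
                )
                for i in idx
            ]
            feats_b = (ad.concat(rows, axis=0) - mean_t) / scale_t
            logits = linear(head, feats_b)
            logp = ad.log_softmax(logits, axis=1)
            onehot = np.zeros((len(idx), n_classes))
            onehot[np.arange(len(idx)), labels[idx]] = 1.0
            loss = -ad.tmean(ad.tsum(logp * Tensor(onehot), axis=1))
            grads = ad.grad(loss, trainable)
            opt.step(grads, lr=lr)
    return Classifier(
        params={"theta": params["theta"], "omega": params["omega"]},
        head=head,
        model_cfg=model_cfg,
        classes=n_classes,
        feature_mean=feature_mean,
        feature_scale=feature_scale,
    )


def ssl_eval_metrics(
    params: dict,
    structures: list,
    model_cfg: ModelConfig,
    seed: int = 0,
) -> dict:
    """Held-out probes of the two pretraining tasks.

    Runs the same masked forward pass as training and reports the
    argmax accuracy of the distance-bin classifier over all ordered
    residue pairs, and the per-angle mean squared error of the masked
    torsion reconstruction (normalised scale).
    """
    from .objectives import angle_prediction, normalized_truth
    from .nn import mlp2

    rng = np.random.default_rng(seed)
    prepared = prepare_proteins(structures, model_cfg)
    embedder = make_embedder(model_cfg, params["theta"])
    correct = 0
    total = 0
    sq_err = 0.0
    n_angles = 0
    with ad.no_grad():
        for p in prepared:
            g = p.graph
            try:
                mask = sample_mask(g, model_cfg.mask_fraction, rng)
            except SkipProtein:
                mask = MaskSpec((), model_cfg.mask_fraction)
            emb = embedder(g)
            X = init_node_features(g, emb, mask.masked_indices, model_cfg.rbf)
            H, _ = gnn_forward(g, X, params["omega"], adjacency=p.cache["adjacency"])
            h = fuse(seq_project(params["theta"], emb), H)
            ii, jj = p.cache["pair_idx"]
            logits = mlp2(params["alpha"]["dist"], h[ii] - h[jj])
            pred = np.argmax(logits.data, axis=1)
            correct += int(np.sum(pred == p.cache["labels"]))
            total += len(pred)
            if len(mask):
                idx = np.asarray(mask.masked_indices, dtype=np.intp)
                ang = angle_prediction(h[idx], params["alpha"]).data
                truth = normalized_truth(g, mask.masked_indices)
                sq_err += float(np.sum((ang - truth) ** 2))
                n_angles += 2 * len(idx)
    return {
        "distance_bin_accuracy": correct / total if total else float("nan"),
        "masked_angle_mse": sq_err / n_angles if n_angles else float("nan"),
    }


def evaluate(classifier: Classifier, structures: list, labels) -> float:
    """Mean accuracy of argmax predictions."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(structures) == 0:
        raise ValueError("empty evaluation set")
    pred = classifier.predict(structures)
    return float(np.mean(pred == labels))
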