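"""Model assembly, training loop and evaluation harness.

The full model runs both encoder branches per protein — per-residue MLP for
the sequence representation X, GCN over the normalized contact adjacency for
the structure representation G — pools each branch with its own grouped
self-attention head, concatenates the pooled vectors and applies a fully
connected head.  Training uses Adam with a fixed learning rate for a fixed
number of epochs (default 10); after every epoch each split is evaluated and
the best-performing epoch on the selection split is kept.

Reproducibility: a single integer seed drives parameter initialisation,
epoch shuffling and contrastive sampling through per-purpose
``numpy.random.default_rng`` streams, so two runs with the same seed produce
bit-identical loss trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import aggregation, contrastive, encoders
from .autodiff import Tensor
from . import autodiff as ad
from .aggregation import LossConfig
from .contrastive import ContrastiveConfig
from .data import load_dataset_container, make_batch
from .metrics import (
    MetricReport,
    auc,
    confusion_counts,
    macro_roc_auc,
    pearson,
    precision,
    r_squared,
    rmse,
    spearman,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainResult",
    "Model",
    "train_model",
    "evaluate_model",
    "select_best_epoch",
    "predict_records",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    task: str = "classification"
    n_classes: int = 2
    F: int = 32
    D: int = 128
    mlp_depth: int = 2
    gcn_depth: int = 2
    attention_groups: int = 4
    adjacency_c: float = 1e-6
    zscore_targets: bool = False  # regression only: train on standardized t_m

    @property
    def out_dim(self) -> int:
        return self.n_classes if self.task == "classification" else 1


@dataclasses.dataclass
class TrainConfig:
    """Optimisation protocol: Adam, fixed learning rate, fixed epoch count."""

    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 4
    seed: int = 0
    selection_metric: str = "accuracy"  # accuracy | pearson
    selection_split: str = "valid"  # "test" reproduces the test-selection protocol

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclasses.dataclass
class TrainResult:
    """Per-epoch losses and metrics, plus the selected epoch and checkpoint."""

    history: list  # per epoch: {"losses": {...}, "batch_losses": [...], "metrics": {split: {...}}}
    best_epoch: int
    checkpoint_path: str | None
    config: dict
    model: object = None  # the trained Model (best-epoch parameters restored)


#: The §preset learning-rate/batch-size pairs exposed to the CLI.
PROTOCOL_PRESETS = {
    "small-binary": {"learning_rate": 8e-5, "batch_size": 4},
    "small-multiclass": {"learning_rate": 8e-4, "batch_size": 4},
    "large": {"learning_rate": 1e-4, "batch_size": 512},
    "melting-temperature": {"learning_rate": 1e-4, "batch_size": 8},
}


class Model:
    """Parameter container plus forward pass for the full predictor."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng([int(seed), 0])
        mlp = encoders.init_mlp(cfg.F, cfg.D, rng, depth=cfg.mlp_depth)
        gcn = encoders.init_gcn(cfg.D, rng, depth=cfg.gcn_depth)
        attn_struct = aggregation.init_attention(cfg.D, rng, n_groups=cfg.attention_groups)
        attn_seq = aggregation.init_attention(cfg.D, rng, n_groups=cfg.attention_groups)
        head = aggregation.init_head(cfg.D, cfg.out_dim, rng)
        self.params: dict[str, np.ndarray] = {}
        for k, (w, b) in enumerate(mlp.layers):
            self.params[f"mlp.{k}.W"] = w
            self.params[f"mlp.{k}.b"] = b
        for k, w in enumerate(gcn.layers):
            self.params[f"gcn.{k}.W"] = w
        self.params["attn_struct.W1"] = attn_struct.W1
        self.params["attn_struct.W2"] = attn_struct.W2
        self.params["attn_seq.W1"] = attn_seq.W1
        self.params["attn_seq.W2"] = attn_seq.W2
        self.params["head.W"] = head.weight
        self.params["head.b"] = head.bias
        # regression target standardisation (identity until fitted)
        self.target_mean = 0.0
        self.target_sd = 1.0

    # -- parameter views ------------------------------------------------------
    def tensors(self) -> dict[str, Tensor]:
        """Fresh trainable Tensor views over the current parameter arrays."""
        return {k: Tensor(v, requires_grad=True) for k, v in self.params.items()}

    def _structured(self, t):
        cfg = self.cfg
        mlp = encoders.MlpParams(
            [(t[f"mlp.{k}.W"], t[f"mlp.{k}.b"]) for k in range(cfg.mlp_depth)]
        )
        gcn = encoders.GcnParams([t[f"gcn.{k}.W"] for k in range(cfg.gcn_depth)])
        attn_struct = aggregation.AttentionParams(t["attn_struct.W1"], t["attn_struct.W2"])
        attn_seq = aggregation.AttentionParams(t["attn_seq.W1"], t["attn_seq.W2"])
        head = aggregation.HeadParams(t["head.W"], t["head.b"])
        return mlp, gcn, attn_struct, attn_seq, head

    # -- forward --------------------------------------------------------------
    def forward_protein(self, embedding, a_hat, t=None, mask=None):
        """Run one protein through both branches.

        ``t`` is a tensor view from :meth:`tensors` (training) or None for a
        detached numpy-parameter pass (inference).  Returns a dict with the
        residue representations X and G, pooled vectors and the output.
        """
        t = self.tensors() if t is None else t
        mlp, gcn, attn_struct, attn_seq, head = self._structured(t)
        P = embedding if isinstance(embedding, Tensor) else Tensor(np.asarray(embedding))
        X = encoders.mlp_forward(P, mlp)
        G = encoders.gcn_forward(X, a_hat, gcn)
        a_seq = aggregation.attention_weights(X, attn_seq, mask)
        a_struct = aggregation.attention_weights(G, attn_struct, mask)
        x_tilde = aggregation.pool(X, a_seq)
        g_tilde = aggregation.pool(G, a_struct)
        out = aggregation.fuse_and_predict(g_tilde, x_tilde, head)
        return {"X": X, "G": G, "x_tilde": x_tilde, "g_tilde": g_tilde, "out": out}

    def predict_scores(self, triples):
        """Detached per-protein outputs: (n, C) logits or (n,) t_m estimates."""
        outs = []
        for rec, emb, cmap in triples:
            a_hat = encoders.normalize_adjacency(cmap, self.cfg.adjacency_c)
            out = self.forward_protein(emb.values, a_hat)["out"].data
            outs.append(out)
        outs = np.asarray(outs)
        if self.cfg.task == "regression":
            outs = outs[:, 0] * self.target_sd + self.target_mean
        return outs


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] = params[k] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _batch_losses(model, batch_triples, t, cont_cfg, loss_cfg, rng):
    """Forward one batch; returns (pred_loss, cont_loss, total_loss) Tensors."""
    outs, conts = [], []
    targets = []
    for rec, emb, cmap in batch_triples:
        a_hat = encoders.normalize_adjacency(cmap, model.cfg.adjacency_c)
        fwd = model.forward_protein(emb.values, a_hat, t=t)
        outs.append(fwd["out"])
        targets.append(
            rec.class_label
            if model.cfg.task == "classification"
            else (rec.tm - model.target_mean) / model.target_sd
        )
        if cont_cfg.enabled and loss_cfg.alpha > 0:
            conts.append(
                contrastive.contrastive_loss(
                    fwd["X"], fwd["G"], rec.residue_labels, cont_cfg, rng
                )
            )
    stacked = ad.stack(outs) if model.cfg.task == "classification" else ad.concatenate(outs)
    pred = aggregation.prediction_loss(stacked, np.asarray(targets), model.cfg.task)
    if conts:
        cont = conts[0]
        for c in conts[1:]:
            cont = cont + c
        cont = cont * (1.0 / len(conts))
    else:
        cont = Tensor(0.0)
    total = aggregation.total_loss(pred, cont, loss_cfg)
    return pred, cont, total


def train_model(
    container_path,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    cont_cfg: ContrastiveConfig | None = None,
    loss_cfg: LossConfig | None = None,
    checkpoint_path=None,
) -> TrainResult:
    """Train on the container's train split; evaluate every epoch on all splits.

    Fully reproducible from ``train_cfg.seed``.  The parameters of the best
    epoch (by ``selection_metric`` on ``selection_split``) are restored into
    the returned model state and, if requested, written to ``checkpoint_path``.
    """
    triples, task, n_classes = load_dataset_container(container_path)
    if task != model_cfg.task:
        raise ValueError(f"container task {task!r} != model task {model_cfg.task!r}")
    if task == "classification" and n_classes != model_cfg.n_classes:
        raise ValueError(
            f"container has {n_classes} classes, model expects {model_cfg.n_classes}"
        )
    f_dim = triples[0][1].F
    if f_dim != model_cfg.F:
        raise ValueError(f"container feature dim {f_dim} != model F {model_cfg.F}")
    cont_cfg = cont_cfg or ContrastiveConfig()
    loss_cfg = loss_cfg or LossConfig(task=task)
    if loss_cfg.task != task:
        raise ValueError("loss config task does not match container task")

    train = [tr for tr in triples if tr[0].split == "train"]
    if not train:
        raise ValueError("container has no train split")
    model = Model(model_cfg, seed=train_cfg.seed)
    if task == "regression" and model_cfg.zscore_targets:
        tms = np.array([rec.tm for rec, _, _ in train])
        model.target_mean = float(tms.mean())
        model.target_sd = float(tms.std()) or 1.0

    optimizer = _Adam(model.params, train_cfg.learning_rate)
    history = []
    best_params = None
    best_state = None
    metric_name = train_cfg.selection_metric
    for epoch in range(train_cfg.epochs):
        epoch_rng = np.random.default_rng([int(train_cfg.seed), 1, epoch])
        order = epoch_rng.permutation(len(train))
        shuffled = [train[i] for i in order]
        batch_records = []
        for start in range(0, len(shuffled), train_cfg.batch_size):
            chunk = shuffled[start : start + train_cfg.batch_size]
            t = model.tensors()
            pred, cont, total = _batch_losses(
                model, chunk, t, cont_cfg, loss_cfg, epoch_rng
            )
            total.backward()
            if train_cfg.learning_rate > 0:
                optimizer.step(model.params, {k: v.grad for k, v in t.items()})
            batch_records.append(
                {"pred": pred.item(), "cont": cont.item(), "total": total.item()}
            )
        split_metrics = {
            split: evaluate_model(model, triples=triples, split=split).metrics
            for split in ("train", "valid", "test")
            if any(tr[0].split == split for tr in triples)
        }
        history.append(
            {
                "epoch": epoch,
                "losses": {
                    key: float(np.mean([b[key] for b in batch_records]))
                    for key in ("pred", "cont", "total")
                },
                "batch_losses": batch_records,
                "metrics": split_metrics,
            }
        )
        score = split_metrics[train_cfg.selection_split][metric_name]
        if best_state is None or score > best_state[1]:
            best_state = (epoch, score)
            best_params = {k: v.copy() for k, v in model.params.items()}

    model.params = best_params
    result = TrainResult(
        history=history,
        best_epoch=best_state[0],
        checkpoint_path=None,
        config={
            "model": dataclasses.asdict(model_cfg),
            "train": dataclasses.asdict(train_cfg),
            "contrastive": dataclasses.asdict(cont_cfg),
            "loss": dataclasses.asdict(loss_cfg),
            "target_mean": model.target_mean,
            "target_sd": model.target_sd,
        },
    )
    if checkpoint_path is not None:
        result.checkpoint_path = str(save_checkpoint(checkpoint_path, model))
    result.model = model  # convenience handle for in-process use
    return result


def select_best_epoch(result: TrainResult, metric: str, split: str = "valid") -> int:
    """Argmax of the metric over epochs; earliest epoch wins ties."""
    scores = [h["metrics"][split][metric] for h in result.history]
    return int(np.argmax(scores))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _softmax_rows(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def evaluate_model(model, container_path=None, triples=None, split="test") -> MetricReport:
    """Deterministic evaluation of one split (no contrastive sampling).

    Classification: accuracy, per-class precision, macro one-vs-rest ROC/AUC
    (plus binary AUC and hot-class precision when C = 2).  Regression:
    Pearson, Spearman, R-squared and RMSE in degrees C.
    """
    if triples is None:
        triples, task, _ = load_dataset_container(container_path)
    subset = [tr for tr in triples if tr[0].split == split]
    if not subset:
        raise ValueError(f"split {split!r} absent from container")
    scores = model.predict_scores(subset)
    if model.cfg.task == "classification":
        truth = np.array([rec.class_label for rec, _, _ in subset])
        probs = _softmax_rows(scores)
        preds = probs.argmax(axis=1)
        metrics = {"accuracy": float(np.mean(preds == truth))}
        for c in range(model.cfg.n_classes):
            metrics[f"precision_class_{c}"] = precision(
                confusion_counts((preds == c).astype(int), (truth == c).astype(int))
            )
        roc_payload = None
        if np.unique(truth).size == model.cfg.n_classes:
            per_class, macro, macro_curve = macro_roc_auc(probs, truth)
            metrics["macro_auc"] = macro
            for c, a in enumerate(per_class):
                metrics[f"auc_class_{c}"] = float(a)
            roc_payload = {
                "macro": {"fpr": macro_curve.fpr.tolist(), "tpr": macro_curve.tpr.tolist()}
            }
            if model.cfg.n_classes == 2:
                # binary view: positive class is "hot" (index 1)
                metrics["auc"] = auc(probs[:, 1], (truth == 1).astype(int))
                metrics["precision"] = metrics["precision_class_1"]
        return MetricReport(task="classification", metrics=metrics, roc=roc_payload)
    truth = np.array([rec.tm for rec, _, _ in subset])
    metrics = {
        "pearson": pearson(truth, scores),
        "spearman": spearman(truth, scores),
        "r_squared": r_squared(truth, scores),
        "rmse": rmse(truth, scores),
    }
    return MetricReport(task="regression", metrics=metrics)


def predict_records(model, triples):
    """Per-protein predictions: (ids, probs (n, C)) or (ids, t_m (n,))."""
    ids = [rec.id for rec, _, _ in triples]
    scores = model.predict_scores(triples)
    if model.cfg.task == "classification":
        return ids, _softmax_rows(scores)
    return ids, scores


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: Model) -> None:
    """Single npz archive: named parameter tensors + config snapshot."""
    path = Path(path)
    if path.suffix != ".npz":  # np.savez would silently append the suffix
        path = path.with_suffix(path.suffix + ".npz")
    meta = {
        "model_cfg": dataclasses.asdict(model.cfg),
        "target_mean": model.target_mean,
        "target_sd": model.target_sd,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.params)
    return path


def load_checkpoint(path) -> Model:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint {path} does not exist")
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        params = {k: archive[k].copy() for k in archive.files if k != "__meta__"}
    model = Model(ModelConfig(**meta["model_cfg"]))
    model.params = params
    model.target_mean = meta["target_mean"]
    model.target_sd = meta["target_sd"]
    return model
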