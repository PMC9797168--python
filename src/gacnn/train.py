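"""Semi-supervised training with pseudo labels.

The train set is split into a labeled part S (a stratified fraction given
by the labeling rate) and an unlabeled part U whose ground truth is hidden
from the loss. After a short warm-up the model's own argmax predictions on
U become one-hot pseudo labels, refreshed every epoch (optionally every
step), and the total objective is

    L = L_label + lambda * L_unl

where both terms are the binary cross-entropy summed over the K classes
and over the samples of S (with true one-hot labels P) and of U (with
pseudo labels P-hat) respectively:

    L_label = - sum_K sum_{S_i in S} [ P_i log Z_i + (1 - P_i) log(1 - Z_i) ].

Optimisation is SGD with momentum 0.9 and weight decay 1e-4; the learning
rate is divided by 10 every 20 epochs. Defaults follow the full-scale
recipe (lr 1e-4, 60 epochs, batch 32, lambda 0.1); the scaled-down desk
profile raises the base rate because a small model trained from scratch on
a desk-sized synthetic set needs it to move at all (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .autodiff import SGD, Adam, softmax
from . import autodiff as ad
from .graphbuild import GraphBuildConfig, ImageGraph, build_graph
from .network import BackboneConfig, FusionConfig, GACNN, GCNConfig
from .synthetic import LabeledImageSet
from . import evaluate as ev

__all__ = ["TrainConfig", "split_by_labeling_rate", "generate_pseudo_labels",
           "supervised_loss", "unsupervised_loss", "total_loss",
           "learning_rate_at_epoch", "fit", "cross_validate", "FitResult"]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    lambda_unl: float = 0.1
    optimizer: str = "sgd"            # "sgd" (momentum) or "adam"
    lr: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20          # epochs
    epochs: int = 60
    batch_size: int = 32
    labeling_rate: float = 1.0
    folds: int = 10
    seed: int = 0
    pseudo_label_warmup: int = 5      # epochs before L_unl activates
    pseudo_refresh: str = "epoch"     # "epoch" or "step"
    clip_norm: float | None = None    # global gradient-norm bound
    warmup_epochs: int = 0            # linear lr ramp over the first epochs
    eval_every: int = 1               # epochs between metric evaluations
    n_classes: int = 5

    def __post_init__(self):
        if not (0.0 < self.labeling_rate <= 1.0):
            raise ValueError("labeling_rate must be in (0, 1]")
        if self.lambda_unl < 0:
            raise ValueError("lambda must be nonnegative")

    @staticmethod
    def desk_scale(**overrides) -> "TrainConfig":
        """The scaled-down CPU profile used throughout the test suite."""
        base = dict(optimizer="adam", lr=1e-3, epochs=30, pseudo_label_warmup=5)
        base.update(overrides)
        return TrainConfig(**base)


def learning_rate_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Effective lr for a 1-based epoch: divided by 10 every 20 epochs,
    after an optional linear warm-up ramp."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    if epoch <= cfg.warmup_epochs:
        return cfg.lr * epoch / (cfg.warmup_epochs + 1)
    steps = (epoch - 1) // cfg.lr_decay_every
    return cfg.lr * (cfg.lr_decay_factor ** steps)


# ---------------------------------------------------------------------------
# labeled / unlabeled split
# ---------------------------------------------------------------------------

def split_by_labeling_rate(labels, rate: float, seed: int = 0,
                           n_classes: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split into (labeled S, unlabeled U).

    |S| is the per-class rounded share of ``rate``; every class keeps at
    least one labeled sample (with a warning when rounding would drop a
    class entirely). rate = 1 gives U empty (fully supervised).
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must be in (0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x51)))
    labeled, unlabeled = [], []
    for c in range(n_classes):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 0:
            continue
        idx = idx[rng.permutation(len(idx))]
        n_lab = int(round(rate * len(idx)))
        if n_lab == 0 and rate > 0:
            warnings.warn(f"labeling rate {rate} leaves class {c} without "
                          "labels; keeping one labeled sample")
            n_lab = 1
        labeled.append(idx[:n_lab])
        unlabeled.append(idx[n_lab:])
    S = np.sort(np.concatenate(labeled))
    U = np.sort(np.concatenate(unlabeled)) if any(len(u) for u in unlabeled) \
        else np.array([], dtype=int)
    return S, U


# ---------------------------------------------------------------------------
# losses (the printed binary-CE-over-classes form)
# ---------------------------------------------------------------------------

def _binary_ce_sum(Z: np.ndarray, P: np.ndarray) -> float:
    Z = np.clip(np.asarray(Z, dtype=np.float64), _EPS, 1.0 - _EPS)
    P = np.asarray(P, dtype=np.float64)
    if Z.size == 0:
        return 0.0
    return float(-(P * np.log(Z) + (1.0 - P) * np.log(1.0 - Z)).sum())


def supervised_loss(Z_S: np.ndarray, P: np.ndarray) -> float:
    """L_label: binary CE summed over classes and labeled samples."""
    return _binary_ce_sum(Z_S, P)


def unsupervised_loss(Z_U: np.ndarray, P_hat: np.ndarray) -> float:
    """L_unl: same functional form with pseudo labels; empty U gives 0."""
    return _binary_ce_sum(Z_U, P_hat)


def total_loss(L_label: float, L_unl: float, lambda_unl: float) -> float:
    """L = L_label + lambda * L_unl."""
    if lambda_unl < 0:
        raise ValueError("lambda must be nonnegative")
    return float(L_label) + float(lambda_unl) * float(L_unl)


def generate_pseudo_labels(model: GACNN, images: np.ndarray,
                           graphs: list[ImageGraph],
                           n_classes: int = 5) -> np.ndarray:
    """One-hot argmax predictions on unlabeled samples (ties -> lowest class)."""
    if len(graphs) == 0:
        return np.zeros((0, n_classes))
    probs = model.predict_proba(images, graphs)
    idx = np.argmax(probs, axis=-1)     # first max wins ties
    return np.eye(n_classes)[idx]


def one_hot(labels, n_classes: int = 5) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(labels, dtype=int)]


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: GACNN
    history: pd.DataFrame          # per-epoch loss/accuracy/kappa curves
    labeled_idx: np.ndarray
    unlabeled_idx: np.ndarray


def _prepare(dataset: LabeledImageSet, graph_cfg: GraphBuildConfig,
             graphs: list[ImageGraph] | None):
    images = np.stack(dataset.images).astype(np.float64)
    if graphs is None:
        graphs = [build_graph(img, graph_cfg) for img in dataset.images]
    return images, graphs


def fit(dataset: LabeledImageSet, cfg: TrainConfig = TrainConfig(),
        backbone_cfg: BackboneConfig = BackboneConfig(),
        gcn_cfg: GCNConfig = GCNConfig(),
        fusion_cfg: FusionConfig = FusionConfig(),
        graph_cfg: GraphBuildConfig = GraphBuildConfig(),
        graphs: list[ImageGraph] | None = None,
        test_set: LabeledImageSet | None = None,
        test_graphs: list[ImageGraph] | None = None,
        model: GACNN | None = None) -> FitResult:
    """Train a GACNN on a labeled/unlabeled split of ``dataset``.

    Per epoch: shuffle, iterate mini-batches mixing S and (post-warm-up) U,
    minimise L = L_label + lambda L_unl by momentum SGD with the staircase
    lr schedule, then refresh pseudo labels. Fully deterministic for a
    fixed (dataset, cfg, seed).
    """
    images, graphs = _prepare(dataset, graph_cfg, graphs)
    labels = np.asarray(dataset.labels)
    S, U = split_by_labeling_rate(labels, cfg.labeling_rate, seed=cfg.seed,
                                  n_classes=cfg.n_classes)
    P = one_hot(labels, cfg.n_classes)
    if model is None:
        model = GACNN(backbone_cfg, gcn_cfg, fusion_cfg, seed=cfg.seed)
        model.calibrate([graphs[i] for i in range(len(dataset))])
    if cfg.optimizer == "adam":
        opt = Adam(model.parameters().values(), lr=cfg.lr,
                   weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    elif cfg.optimizer == "sgd":
        opt = SGD(model.parameters().values(), lr=cfg.lr,
                  momentum=cfg.momentum, weight_decay=cfg.weight_decay,
                  clip_norm=cfg.clip_norm)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0xEC)))
    is_labeled = np.zeros(len(dataset), dtype=bool)
    is_labeled[S] = True
    pseudo = np.zeros((len(dataset), cfg.n_classes))
    records = []

    if test_set is not None and test_graphs is None:
        test_graphs = [build_graph(img, graph_cfg) for img in test_set.images]

    for epoch in range(1, cfg.epochs + 1):
        opt.lr = learning_rate_at_epoch(cfg, epoch)
        use_unlabeled = (len(U) > 0 and cfg.lambda_unl > 0
                         and epoch > cfg.pseudo_label_warmup)
        if use_unlabeled and (epoch == cfg.pseudo_label_warmup + 1
                              or cfg.pseudo_refresh == "epoch"):
            pseudo[U] = generate_pseudo_labels(
                model, images[U], [graphs[i] for i in U], cfg.n_classes)
        pool = np.concatenate([S, U]) if use_unlabeled else S
        order = pool[rng.permutation(len(pool))]
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            if cfg.pseudo_refresh == "step" and use_unlabeled:
                ub = batch[~is_labeled[batch]]
                if len(ub):
                    pseudo[ub] = generate_pseudo_labels(
                        model, images[ub], [graphs[i] for i in ub],
                        cfg.n_classes)
            logits = model.forward(images[batch], [graphs[i] for i in batch])
            lab_mask = is_labeled[batch]
            targets = np.where(lab_mask[:, None], P[batch], pseudo[batch])
            weights = np.where(lab_mask, 1.0, cfg.lambda_unl)
            # per-sample weighted binary CE, scaled by 1/|batch| for the
            # step; probabilities are kept off 0/1 by affine smoothing
            # (p' = eps + (1-2 eps) p) so the log gradients never vanish
            probs = ad.add(_EPS, ad.mul(1.0 - 2.0 * _EPS,
                                        softmax(logits, axis=-1)))
            pos = ad.mul(targets, ad.log(probs))
            neg = ad.mul(1.0 - targets,
                         ad.log(ad.add(1.0, ad.mul(-1.0, probs))))
            per_sample = ad.mul(-1.0, ad.sum_(ad.add(pos, neg), axis=1))
            loss = ad.mul(1.0 / len(batch),
                          ad.sum_(ad.mul(per_sample, weights)))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        a = model.attention_weights()
        assert np.all(a >= 0) and abs(a.sum() - 1.0) < 1e-9, \
            "attention weights left the simplex"
        rec = {"epoch": epoch, "lr": opt.lr,
               "train_loss": epoch_loss / len(order)}
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
            preds = _predict_in_batches(model, images[S],
                                        [graphs[i] for i in S], cfg.batch_size)
            rep = ev.report(labels[S], preds, cfg.n_classes)
            rec.update(train_accuracy=rep.accuracy, train_kappa=rep.kappa)
            if test_set is not None:
                tpred = _predict_in_batches(model, np.stack(test_set.images),
                                            test_graphs, cfg.batch_size)
                trep = ev.report(np.asarray(test_set.labels), tpred,
                                 cfg.n_classes)
                rec.update(test_accuracy=trep.accuracy, test_kappa=trep.kappa)
        records.append(rec)
    return FitResult(model=model, history=pd.DataFrame(records),
                     labeled_idx=S, unlabeled_idx=U)


def _predict_in_batches(model: GACNN, images, graphs, batch_size: int) -> np.ndarray:
    preds = []
    for start in range(0, len(graphs), batch_size):
        preds.append(model.predict(images[start:start + batch_size],
                                   graphs[start:start + batch_size]))
    return np.concatenate(preds) if preds else np.array([], dtype=int)


def stratified_folds(labels, n_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified K-fold assignment; returns test-index lists."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF0)))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(dataset: LabeledImageSet, cfg: TrainConfig = TrainConfig(),
                   **fit_kwargs) -> pd.DataFrame:
    """K-fold CV: per-fold test metrics plus the mean +/- sd aggregate row.

    The labeled/unlabeled split is drawn inside each fold's train portion.
    """
    labels = np.asarray(dataset.labels)
    graph_cfg = fit_kwargs.pop("graph_cfg", GraphBuildConfig())
    graphs = fit_kwargs.pop("graphs", None)
    images, graphs = _prepare(dataset, graph_cfg, graphs)
    rows = []
    for fold, test_idx in enumerate(stratified_folds(labels, cfg.folds, cfg.seed)):
        train_idx = np.setdiff1d(np.arange(len(dataset)), test_idx)
        train_set = LabeledImageSet([dataset.images[i] for i in train_idx],
                                    [dataset.labels[i] for i in train_idx],
                                    [dataset.ids[i] for i in train_idx])
        test_set = LabeledImageSet([dataset.images[i] for i in test_idx],
                                   [dataset.labels[i] for i in test_idx],
                                   [dataset.ids[i] for i in test_idx])
        res = fit(train_set, replace(cfg, seed=cfg.seed + fold),
                  graph_cfg=graph_cfg, graphs=[graphs[i] for i in train_idx],
                  test_set=test_set,
                  test_graphs=[graphs[i] for i in test_idx], **fit_kwargs)
        last = res.history.iloc[-1]
        rows.append({"fold": fold, "accuracy": last["test_accuracy"],
                     "kappa": last["test_kappa"]})
    df = pd.DataFrame(rows)
    agg = {"fold": "mean+/-sd", "accuracy": df["accuracy"].mean(),
           "kappa": df["kappa"].mean(),
           "accuracy_sd": df["accuracy"].std(ddof=1),
           "kappa_sd": df["kappa"].std(ddof=1)}
    return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
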