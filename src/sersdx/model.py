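"""Hybrid spectral classifier: 1D CNN + stacked MLP refiner, grouped CV.

The CNN (64 filters, kernel 3, stride 1; dropout; max-pool 2/2; fully
connected head; softmax) classifies individual spectra. Its class
probabilities are then refined by a small MLP (two hidden layers of 64,
ReLU, softmax) trained by stacked generalization: the refiner only ever
sees out-of-fold CNN probabilities, so no spectrum is refined by a model
that saw it during training.

Cross-validation is grouped at the sample level — all spectra of one
serum sample share a fold — because spectrum-level splits would leak
sample identity between train and validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .dataset import CohortDataset
from .nn import (Adam, Conv1D, Dense, Flatten, LeakyReLU, MaxPool1D,
                 Network, ReduceLROnPlateau, ReLU, ReLUDropout,
                 softmax_cross_entropy)

__all__ = ["ModelConfig", "build_cnn", "build_refiner_mlp", "make_folds",
           "train_cnn", "train_refiner", "cross_validate", "CrossValResult",
           "LeakageError"]

log = logging.getLogger(__name__)
F32 = np.float32


class LeakageError(RuntimeError):
    """Raised when stacked-refiner training data is not out-of-fold."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training schedule of the CNN + MLP stack.

    Convolution/pooling sizes and the training schedule follow the
    printed architecture (64 filters, kernel 3, stride 1; pool 2/2;
    refiner hidden layers 64/64; 50 epochs; batch 64; scheduler patience
    5). Unprinted pieces are package defaults: one FC hidden layer of 64
    (matching the refiner width), dropout 0.25, Adam at 1e-3 with
    reduce-on-plateau factor 0.5, and early stopping once the internal
    grouped monitor split's accuracy stops improving.
    """

    n_classes: int = 2
    conv_filters: int = 64
    conv_kernel: int = 3
    conv_stride: int = 1
    dropout_rate: float = 0.25
    pool_size: int = 2
    pool_stride: int = 2
    fc_sizes: tuple[int, ...] = (64,)
    mlp_hidden: tuple[int, ...] = (64, 64)
    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-3
    scheduler_patience: int = 5
    scheduler_factor: float = 0.5
    early_stop_patience: int = 4
    min_epochs: int = 5
    monitor_fraction: float = 0.15
    grad_clip: float | None = 1.0  # global gradient-norm ceiling
    refiner_epochs: int = 150
    class_weight: str | None = None  # None or "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


# -------------------------------------------------------------- networks

def build_cnn(cfg: ModelConfig, input_length: int,
              rng: np.random.Generator | None = None
              ) -> tuple[Network, list[str]]:
    """Build the spectrum CNN; returns (network, per-layer shape report).

    Valid (unpadded) convolution: conv output length L - kernel + 1,
    pooled length floor(conv/2), flatten size filters * pooled.
    """
    if input_length <= cfg.conv_kernel:
        raise ValueError(
            f"input length {input_length} too short for kernel "
            f"{cfg.conv_kernel}")
    rng = rng or np.random.default_rng(cfg.seed)
    conv_len = input_length - cfg.conv_kernel + 1
    pool_len = conv_len // cfg.pool_size
    flat = cfg.conv_filters * pool_len

    layers = [
        Conv1D(cfg.conv_filters, cfg.conv_kernel, rng),
        ReLUDropout(cfg.dropout_rate, rng),
        MaxPool1D(cfg.pool_size, cfg.pool_stride),
        Flatten(),
    ]
    report = [
        f"input: ({input_length},)",
        f"conv1d(filters={cfg.conv_filters}, kernel={cfg.conv_kernel}, "
        f"stride={cfg.conv_stride}, padding=valid): "
        f"({conv_len}, {cfg.conv_filters})",
        f"dropout(rate={cfg.dropout_rate})",
        f"maxpool(size={cfg.pool_size}, stride={cfg.pool_stride}): "
        f"({pool_len}, {cfg.conv_filters})",
        f"flatten: ({flat},)",
    ]
    n_in = flat
    for width in cfg.fc_sizes:
        # leaky activation: a hard ReLU after this wide dense layer can
        # die for every input at once and never recover
        layers += [Dense(n_in, width, rng), LeakyReLU(0.01)]
        report.append(f"dense({width}) + leaky_relu")
        n_in = width
    layers.append(Dense(n_in, cfg.n_classes, rng))
    report.append(f"dense({cfg.n_classes}) + softmax")
    return Network(layers), report


def build_refiner_mlp(cfg: ModelConfig, rng: np.random.Generator,
                      identity_gain: float = 8.0) -> Network:
    """MLP refiner: n_classes -> 64 -> 64 -> n_classes, ReLU hidden.

    Initialized to pass the input probabilities through (first
    ``n_classes`` hidden units copy them; the output layer scales them by
    ``identity_gain``), so before training the refiner reproduces the
    CNN's argmax and gradient descent departs from that map only where it
    reduces the stacking loss. Remaining units start at small random
    weights to break symmetry.
    """
    layers: list = []
    n_in = cfg.n_classes
    dense: list[Dense] = []
    for width in cfg.mlp_hidden:
        d = Dense(n_in, width, rng)
        dense.append(d)
        layers += [d, ReLU()]
        n_in = width
    out = Dense(n_in, cfg.n_classes, rng)
    dense.append(out)
    layers.append(out)

    k = cfg.n_classes
    for d in dense:
        d.W *= 0.05
    for d in dense[:-1]:
        if d.W.shape[0] >= k and d.W.shape[1] >= k:
            d.W[:k, :k] += np.eye(k, dtype=d.W.dtype)
    if out.W.shape[0] >= k:
        out.W[:k, :] += identity_gain * np.eye(k, dtype=out.W.dtype)
    return Network(layers)


# ------------------------------------------------------------------ folds

def make_folds(dataset: CohortDataset, k: int = 5,
               seed: int = 0) -> pd.Series:
    """Stratified sample-level fold assignment (all spectra of a sample
    share its fold). Returns a Series mapping sample_id -> fold index."""
    st = dataset.sample_table()
    counts = st["class_label"].value_counts()
    small = counts[counts < k]
    if not small.empty:
        raise ValueError(
            f"classes with fewer than k={k} samples: "
            f"{small.index.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = pd.Series(index=st["sample_id"].to_numpy(), dtype=int,
                     name="fold")
    for f, (_, vidx) in enumerate(
            skf.split(st["sample_id"], st["class_label"])):
        fold.iloc[vidx] = f
    return fold


# --------------------------------------------------------------- training

def _epoch_batches(n: int, batch_size: int,
                   rng: np.random.Generator):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i:i + batch_size]


def _class_weights(y: np.ndarray, n_classes: int,
                   mode: str | None) -> np.ndarray | None:
    if mode is None:
        return None
    if mode != "balanced":
        raise ValueError(f"unknown class_weight {mode!r}")
    counts = np.bincount(y, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    return y.size / (n_classes * counts)


def _fit(net: Network, X: np.ndarray, y: np.ndarray, cfg: ModelConfig,
         rng: np.random.Generator, X_mon: np.ndarray | None = None,
         y_mon: np.ndarray | None = None, epochs: int | None = None,
         early_stop: bool = True) -> pd.DataFrame:
    """Mini-batch Adam training with plateau scheduler and early stopping.

    The monitored loss drives both the scheduler and early stopping; when
    no monitor set is supplied the (running) training loss is used.
    """
    epochs = epochs or cfg.epochs
    opt = Adam(net.params, lr=cfg.lr)
    sched = ReduceLROnPlateau(opt, cfg.scheduler_patience,
                              cfg.scheduler_factor)
    weights = _class_weights(y, cfg.n_classes, cfg.class_weight)
    rows = []
    best_acc, stale = -np.inf, 0
    # majority-class rate of the monitored split: a model still at this
    # baseline has not started learning, so stopping is premature no
    # matter how long accuracy has been flat
    y_base = y_mon if y_mon is not None else y
    baseline_acc = np.bincount(y_base).max() / y_base.size
    # require clearing the baseline by more than monitor-set noise before
    # the scheduler or early stopping may act
    margin = max(0.05, 2.0 * np.sqrt(baseline_acc * (1 - baseline_acc)
                                     / y_base.size))
    learning_started = False
    best_loss_at_best = np.inf
    snapshot: list[np.ndarray] | None = None
    if X_mon is not None and X_mon.shape[0] > 0:
        # the untrained state is a restoration candidate too: a refiner
        # initialized as the identity map must not be returned in a
        # worse-than-initial state just because every epoch underperformed
        logits0 = net.forward(X_mon, train=False)
        loss0, _ = softmax_cross_entropy(logits0, y_mon, weights)
        best_acc = float((logits0.argmax(axis=1) == y_mon).mean())
        best_loss_at_best = loss0
        snapshot = [p.copy() for p in net.params]
    for epoch in range(epochs):
        losses, hits, seen = [], 0, 0
        for idx in _epoch_batches(X.shape[0], cfg.batch_size, rng):
            logits = net.forward(X[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx], weights)
            net.backward(dlogits)
            if cfg.grad_clip is not None:
                gsq = sum(float((g.astype(np.float64) ** 2).sum())
                          for g in net.grads)
                gnorm = np.sqrt(gsq)
                if gnorm > cfg.grad_clip:
                    scale = F32(cfg.grad_clip / gnorm)
                    for g in net.grads:
                        g *= scale
            opt.step(net.grads)
            losses.append(loss * idx.size)
            hits += int((logits.argmax(axis=1) == y[idx]).sum())
            seen += idx.size
        train_loss = float(np.sum(losses) / seen)
        train_acc = hits / seen
        if X_mon is not None and X_mon.shape[0] > 0:
            logits = net.forward(X_mon, train=False)
            mon_loss, _ = softmax_cross_entropy(logits, y_mon, weights)
            mon_acc = float((logits.argmax(axis=1) == y_mon).mean())
        else:
            mon_loss, mon_acc = train_loss, train_acc
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "train_acc": train_acc, "val_loss": mon_loss,
                     "val_acc": mon_acc, "lr": opt.lr})
        if mon_acc > best_acc + 1e-9:
            best_acc, stale = mon_acc, 0
            best_loss_at_best = mon_loss
            snapshot = [p.copy() for p in net.params]
        else:
            if (mon_acc >= best_acc - 1e-9
                    and mon_loss < best_loss_at_best):
                best_loss_at_best = mon_loss
                snapshot = [p.copy() for p in net.params]
            stale += 1
        learning_started = learning_started or \
            best_acc > baseline_acc + margin
        # the scheduler must not decay the lr during warmup — on small
        # cohorts that spirals into a dead model stuck at chance
        if learning_started:
            sched.step(mon_loss)
            # converged once monitor accuracy stops reaching new bests;
            # loss creep toward zero on a solved task must not postpone
            # the stop
            if (early_stop and epoch + 1 >= cfg.min_epochs
                    and stale >= cfg.early_stop_patience):
                break
    # hand back the best-monitored weights, not whatever the last epoch
    # left behind — on few-batch cohorts the final epochs oscillate
    if snapshot is not None and X_mon is not None:
        for p, s in zip(net.params, snapshot):
            p[...] = s
    return pd.DataFrame(rows)


def train_cnn(X: np.ndarray, y: np.ndarray, sample_ids: np.ndarray,
              cfg: ModelConfig,
              seed: int | np.random.SeedSequence | None = None
              ) -> tuple[Network, pd.DataFrame]:
    """Train the spectrum CNN on one training split.

    A grouped monitor split (``cfg.monitor_fraction`` of training
    samples, stratified by class) is carved out to drive the scheduler
    and early stopping; the remaining spectra are fitted.
    """
    X = np.ascontiguousarray(X, dtype=F32)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training split contains a single class")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    net, _ = build_cnn(cfg, X.shape[1], rng)

    mon_mask = np.zeros(X.shape[0], dtype=bool)
    if cfg.monitor_fraction > 0:
        samples = pd.DataFrame({"sample_id": sample_ids, "y": y})
        st = samples.drop_duplicates("sample_id")
        for cls, grp in st.groupby("y"):
            ids = grp["sample_id"].to_numpy()
            n_mon = max(1, int(round(cfg.monitor_fraction * ids.size)))
            if n_mon >= ids.size:  # too few samples to spare
                continue
            chosen = rng.choice(ids, size=n_mon, replace=False)
            mon_mask |= np.isin(sample_ids, chosen)
        if np.unique(y[~mon_mask]).size < 2:
            mon_mask[:] = False

    if mon_mask.any():
        X_mon, y_mon = X[mon_mask], y[mon_mask]
        if X_mon.shape[0] > 512:  # cap monitor cost; keeps class mix
            step = X_mon.shape[0] // 512 + 1
            X_mon, y_mon = X_mon[::step], y_mon[::step]
    else:
        X_mon = y_mon = None
    hist = _fit(net, X[~mon_mask], y[~mon_mask], cfg, rng,
                X_mon=X_mon, y_mon=y_mon)
    return net, hist


def train_refiner(oof_probs: np.ndarray, labels: np.ndarray,
                  cfg: ModelConfig,
                  producer_folds: np.ndarray | None = None,
                  heldout_fold: int | None = None,
                  seed: int | np.random.SeedSequence | None = None
                  ) -> Network:
    """Train the stacked MLP refiner on out-of-fold CNN probabilities.

    ``producer_folds[i]`` is the CV fold of example ``i`` — i.e. the fold
    whose CNN produced its probability vector out-of-fold. When
    ``heldout_fold`` is given, any training example produced by that
    fold's CNN run means the refiner would indirectly see the held-out
    spectra; this raises :class:`LeakageError`.
    """
    oof_probs = np.ascontiguousarray(oof_probs, dtype=F32)
    if producer_folds is not None and heldout_fold is not None:
        if np.any(np.asarray(producer_folds) == heldout_fold):
            raise LeakageError(
                f"refiner training set contains fold-{heldout_fold} "
                "spectra; stacked refinement requires out-of-fold inputs")
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    net = build_refiner_mlp(cfg, rng)
    labels = np.asarray(labels)
    # hold out 20% of the stacking examples to stop once refinement no
    # longer generalizes (the identity init makes "no change" the floor)
    n = oof_probs.shape[0]
    val = np.zeros(n, dtype=bool)
    if n >= 25:
        val[rng.choice(n, size=n // 5, replace=False)] = True
    if np.unique(labels[~val]).size < np.unique(labels).size:
        val[:] = False
    _fit(net, oof_probs[~val], labels[~val], cfg, rng,
         X_mon=oof_probs[val] if val.any() else None,
         y_mon=labels[val] if val.any() else None,
         epochs=cfg.refiner_epochs, early_stop=val.any())
    return net


# ------------------------------------------------------------------- CV

@dataclass
class CrossValResult:
    """Out-of-fold spectrum predictions plus per-fold training histories."""

    predictions: pd.DataFrame  # spectrum_id, sample_id, class_label, fold,
    #                            cnn_p_<cls>..., ref_p_<cls>...
    histories: list[pd.DataFrame]
    folds: pd.Series
    classes: list[str]

    def prob_matrix(self, kind: str = "refined") -> np.ndarray:
        prefix = {"cnn": "cnn_p_", "refined": "ref_p_"}[kind]
        cols = [prefix + c for c in self.classes]
        return self.predictions[cols].to_numpy()

    def to_csv(self, path) -> None:
        self.predictions.to_csv(path, index=False)


def cross_validate(dataset: CohortDataset, cfg: ModelConfig | None = None,
                   k: int = 5) -> CrossValResult:
    """Grouped, stratified k-fold CV of the full CNN + refiner stack.

    Every spectrum receives exactly one out-of-fold CNN prediction and
    one refined prediction (from a refiner that never trained on its
    fold's probabilities).
    """
    classes = dataset.classes
    if cfg is None:
        cfg = ModelConfig(n_classes=len(classes))
    if cfg.n_classes != len(classes):
        cfg = replace(cfg, n_classes=len(classes))
    if not dataset.attrs.get("preprocessed", False):
        log.warning("cross_validate called on a dataset not marked "
                    "preprocessed")

    y = dataset.meta["class_label"].map(
        {c: i for i, c in enumerate(classes)}).to_numpy()
    sample_ids = dataset.meta["sample_id"].to_numpy()
    folds = make_folds(dataset, k=k, seed=cfg.seed)
    spec_fold = dataset.meta["sample_id"].map(folds).to_numpy()
    X = np.ascontiguousarray(dataset.intensities, dtype=F32)

    ss = np.random.SeedSequence(cfg.seed)
    cnn_seeds = ss.spawn(k)
    ref_seeds = ss.spawn(k)

    n = X.shape[0]
    cnn_probs = np.zeros((n, len(classes)))
    histories = []
    for f in range(k):
        tr = spec_fold != f
        va = ~tr
        overlap = set(sample_ids[tr]) & set(sample_ids[va])
        if overlap:  # cannot happen with sample-level folds; belt & braces
            raise LeakageError(f"fold {f}: samples in both splits {overlap}")
        try:
            net, hist = train_cnn(X[tr], y[tr], sample_ids[tr], cfg,
                                  seed=cnn_seeds[f])
        except ValueError as e:
            raise ValueError(f"fold {f}: {e}") from e
        cnn_probs[va] = net.predict_proba(X[va])
        histories.append(hist)
        log.info("fold %d: CNN trained %d epochs, final val_acc=%.3f",
                 f, len(hist), hist["val_acc"].iloc[-1])

    refined = np.zeros_like(cnn_probs)
    for f in range(k):
        tr = spec_fold != f
        va = ~tr
        refiner = train_refiner(cnn_probs[tr], y[tr], cfg,
                                producer_folds=spec_fold[tr],
                                heldout_fold=f, seed=ref_seeds[f])
        refined[va] = refiner.predict_proba(cnn_probs[va].astype(F32))

    pred = dataset.meta[["spectrum_id", "sample_id", "class_label"]].copy()
    pred["fold"] = spec_fold
    for j, c in enumerate(classes):
        pred[f"cnn_p_{c}"] = cnn_probs[:, j]
    for j, c in enumerate(classes):
        pred[f"ref_p_{c}"] = refined[:, j]
    return CrossValResult(pred, histories, folds, list(classes))
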