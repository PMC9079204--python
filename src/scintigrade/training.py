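"""Imbalance-aware training machinery: stratified folds, randomized
augmentation, inverse-frequency class weights, task relabeling, and the
Adam/plateau training loop.

The clinical problem is heavily imbalanced (positive cardiac uptake in only
a few percent of bone scans), so minority grades are up-weighted in the
loss with ``w_c = n / (n_classes * n_c)``, which makes every class
contribute equally in expectation while keeping the total effective sample
count unchanged (sum_c w_c * n_c = n).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from sklearn.model_selection import StratifiedKFold, train_test_split

from .models import NetworkHandle
from .nn import Adam, ReduceLROnPlateau, weighted_sparse_ce
from .preprocess import PreprocessedImage

logger = logging.getLogger(__name__)

TASKS = ("four_class", "pos_vs_neg", "grade3_vs_rest")

__all__ = [
    "TASKS",
    "FoldSplit",
    "AugmentationConfig",
    "TrainConfig",
    "ClassWeights",
    "make_stratified_folds",
    "augment_image",
    "augment_training_set",
    "compute_class_weights",
    "relabel_for_task",
    "train_model",
]


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: np.ndarray
    test_ids: np.ndarray


@dataclass
class AugmentationConfig:
    """Randomized shift / rotation / zoom augmentation.

    Ranges follow the training recipe: shifts up to ±10% of the image size
    in both axes, rotations up to ±20 degrees, zoom up to ±20%; each
    augmented image draws all three independently and uniformly.
    """

    shift_range: float = 0.10
    rotation_range: float = 20.0
    zoom_range: float = 0.20
    multiplier: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.shift_range, self.rotation_range, self.zoom_range) < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the training recipe:
    50 epochs, batch 128, Adam at 1e-4 with plateau reduction to 1e-7,
    10% of the training data held out for validation)."""

    epochs: int = 50
    batch_size: int = 128
    initial_lr: float = 1e-4
    min_lr: float = 1e-7
    lr_patience: int = 2
    lr_factor: float = 0.1
    validation_fraction: float = 0.10
    class_weighting: str = "inverse_frequency"
    seed: int = 0
    # optional conditioning for small-step-budget runs (off by default, so
    # the plain recipe above is what runs unless explicitly requested):
    # scaled_init rescales initial weights to unit activation variance;
    # head_init_steps pre-fits the softmax head on the frozen random
    # convolutional features before joint training
    scaled_init: bool = False
    head_init_steps: int = 0
    head_init_lr: float = 1e-2
    # tail weight averaging (Polyak): average the weights visited during the
    # last fraction of epochs and use the average as the final model; free
    # variance reduction for short noisy runs, 0 disables
    average_tail_fraction: float = 0.0
    # snapshot ensembling: keep the weights at the end of the last m epochs
    # (plus the tail average, if enabled) and average predicted class
    # probabilities over them at inference; 0 disables
    snapshot_ensemble: int = 0

    def __post_init__(self):
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr must be <= initial_lr")
        if self.class_weighting not in ("inverse_frequency", "none"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass
class ClassWeights:
    """Per-class loss weights; index with the integer class label."""

    weights: np.ndarray

    def __getitem__(self, c):
        return self.weights[c]

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        return self.weights[np.asarray(labels, dtype=int)]


def make_stratified_folds(labels, k: int = 5, seed: int = 0,
                          ids=None) -> list[FoldSplit]:
    """Seeded stratified k-fold assignment.

    Per-class fold counts are seed-independent (only membership shuffles),
    and each fold's class proportions match the global ones within ±1
    study. A class with fewer members than ``k`` degrades to covering as
    many folds as possible, with a logged warning.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.arange(len(labels)) if ids is None else np.asarray(ids)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        logger.warning(
            "least populated class has %d members < k=%d; some folds will "
            "lack it", counts.min(), k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        splits = list(skf.split(np.zeros(len(labels)), labels))
    return [FoldSplit(i, ids[tr], ids[te]) for i, (tr, te) in enumerate(splits)]


def augment_image(image: np.ndarray, rng: np.random.Generator,
                  cfg: AugmentationConfig) -> np.ndarray:
    """One random shift/rotate/zoom of a 2-D image (bilinear, zero fill)."""
    h, w = image.shape
    theta = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    zy = 1.0 + rng.uniform(-cfg.zoom_range, cfg.zoom_range)
    zx = 1.0 + rng.uniform(-cfg.zoom_range, cfg.zoom_range)
    ty = rng.uniform(-cfg.shift_range, cfg.shift_range) * h
    tx = rng.uniform(-cfg.shift_range, cfg.shift_range) * w
    # forward map: p -> R(theta) @ diag(zy, zx) @ (p - c) + c + t;
    # affine_transform needs the inverse (output -> input) mapping
    cos, sin = np.cos(theta), np.sin(theta)
    fwd = np.array([[cos * zy, -sin * zx], [sin * zy, cos * zx]])
    inv = np.linalg.inv(fwd)
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = c - inv @ (c + np.array([ty, tx]))
    return affine_transform(image, inv, offset=offset, order=1, mode="constant",
                            cval=0.0)


def augment_training_set(images, cfg: AugmentationConfig) -> list:
    """Generate ``multiplier x n`` randomized variants of the training set.

    Each output draws a source image uniformly at random and applies an
    independent random transform; labels are inherited. Originals are kept
    by the caller alongside the returned augmented images.
    """
    images = list(images)
    if not images:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    n_out = cfg.multiplier * len(images)
    out = []
    for i in range(n_out):
        src = images[rng.integers(len(images))]
        if isinstance(src, PreprocessedImage):
            aug = augment_image(src.pixels, rng, cfg)
            out.append(PreprocessedImage(
                pixels=np.maximum(aug, 0.0),
                source_id=f"{src.source_id}_aug{i}",
                grade=src.grade,
                has_metastases=src.has_metastases,
            ))
        else:
            out.append(augment_image(np.asarray(src, dtype=np.float64), rng, cfg))
    return out


def compute_class_weights(labels, n_classes: int | None = None) -> ClassWeights:
    """Inverse-frequency weights ``w_c = n / (n_classes * n_c)``."""
    labels = np.asarray(labels, dtype=int)
    k = int(n_classes if n_classes is not None else labels.max() + 1)
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise ValueError(f"empty class among declared {k} classes: counts={counts}")
    return ClassWeights(len(labels) / (k * counts.astype(np.float64)))


def relabel_for_task(labels, task: str) -> np.ndarray:
    """Map Perugini grades to task labels.

    ``four_class`` is the identity; ``pos_vs_neg`` marks grade >= 2 positive
    (the clinical positivity threshold); ``grade3_vs_rest`` marks grade 3.
    """
    labels = np.asarray(labels, dtype=int)
    if ((labels < 0) | (labels > 3)).any():
        raise ValueError("grades must be in 0..3")
    if task == "four_class":
        return labels.copy()
    if task == "pos_vs_neg":
        return (labels >= 2).astype(int)
    if task == "grade3_vs_rest":
        return (labels == 3).astype(int)
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _fit_head(handle, x, y, sample_w, cfg: TrainConfig) -> None:
    """Pre-fit the softmax head on the frozen initial convolutional features.

    A long plain convolutional stack started from random weights can settle
    into emitting the class prior for every input before its features align
    with the signal; fitting the head first (a weighted multinomial
    regression on the random features) gives joint training a descent
    direction out of that saddle. Convolutional weights are not touched.
    """
    flat_node = handle.registry["flatten"]
    # a subset of the training images suffices to seed the head
    if len(x) > 96:
        keep = np.linspace(0, len(x) - 1, 96).astype(int)
        x, y = x[keep], y[keep]
        sample_w = None if sample_w is None else np.asarray(sample_w)[keep]
    feats = []
    for i in range(0, len(x), 48):
        _, cap = handle.net.forward(x[i : i + 48], capture=[flat_node])
        feats.append(cap[flat_node])
    f = np.concatenate(feats).astype(np.float64)
    head = handle.net.layer(handle.registry["head"])
    W = head.W.astype(np.float64)
    b = head.b.astype(np.float64)
    k = W.shape[1]
    onehot = np.eye(k)[y]
    w = np.ones(len(y)) if sample_w is None else np.asarray(sample_w, dtype=np.float64)
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    lr, b1, b2, eps = cfg.head_init_lr, 0.9, 0.999, 1e-7
    for t in range(1, cfg.head_init_steps + 1):
        p = _softmax(f @ W + b)
        g = (p - onehot) * w[:, None] / len(y)
        gW, gb = f.T @ g, g.sum(axis=0)
        for par, gr, m, v in ((W, gW, mW, vW), (b, gb, mb, vb)):
            m *= b1; m += (1 - b1) * gr
            v *= b2; v += (1 - b2) * gr * gr
            par -= lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
    head.W[...] = W.astype(head.W.dtype)
    head.b[...] = b.astype(head.b.dtype)


def _stratified_val_split(n, labels, frac, seed):
    labels = np.asarray(labels)
    idx = np.arange(n)
    _, counts = np.unique(labels, return_counts=True)
    n_val = max(1, int(np.ceil(frac * n)))
    # stratify only when every class can contribute to both partitions
    strat = (labels if counts.min() >= 2 and 1 < len(counts) <= n_val
             else None)
    tr, va = train_test_split(idx, test_size=n_val, random_state=seed,
                              stratify=strat, shuffle=True)
    return tr, va


def train_model(handle: NetworkHandle, train_images, train_labels,
                weights: ClassWeights | None, cfg: TrainConfig,
                verbose: bool = False):
    """Train a network with class-weighted cross-entropy and Adam.

    10% of the training data (stratified when possible) is held out as a
    validation set that only steers the learning-rate schedule: the LR is
    multiplied by ``lr_factor`` whenever the validation loss has not
    improved on its running best for ``lr_patience`` consecutive epochs,
    floored at ``min_lr``. Returns ``(handle, history)`` where history
    records per-epoch training loss, validation loss, and LR.
    """
    x = np.asarray(train_images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(train_labels, dtype=int)
    if len(x) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    handle.net.reseed_dropout(int(rng.integers(2**31 - 1)))

    tr, va = _stratified_val_split(len(x), y, cfg.validation_fraction, cfg.seed)
    xt, yt, xv, yv = x[tr], y[tr], x[va], y[va]
    wt = weights.per_sample(yt).astype(np.float32) if weights is not None else None

    if cfg.scaled_init:
        from .models import scale_init

        scale_init(handle, xt[: min(4, len(xt))], max_iter=2)
    if cfg.head_init_steps > 0:
        _fit_head(handle, xt, yt, wt, cfg)

    opt = Adam(handle.net, lr=cfg.initial_lr)
    sched = ReduceLROnPlateau(cfg.lr_factor, cfg.lr_patience, cfg.min_lr)
    history = {"loss": [], "val_loss": [], "lr": []}
    avg_start = (cfg.epochs - max(1, round(cfg.average_tail_fraction * cfg.epochs))
                 if cfg.average_tail_fraction > 0 else cfg.epochs)
    avg_w, avg_n = None, 0
    snapshots: list = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xt))
        losses, sizes = [], []
        for i in range(0, len(xt), cfg.batch_size):
            b = order[i : i + cfg.batch_size]
            probs = handle.net.forward(xt[b], training=True)
            loss, dp = weighted_sparse_ce(probs, yt[b],
                                          None if wt is None else wt[b])
            handle.net.backward(dp)
            opt.step()
            losses.append(loss)
            sizes.append(len(b))
            if epoch >= avg_start:
                ws = handle.net.get_weights()
                if avg_w is None:
                    avg_w = ws
                else:
                    for a, w_new in zip(avg_w, ws):
                        a += w_new
                avg_n += 1
        pv = handle.net.forward(xv, training=False)
        val_loss, _ = weighted_sparse_ce(pv, yv)
        epoch_loss = float(np.average(losses, weights=sizes))
        history["loss"].append(epoch_loss)
        history["val_loss"].append(float(val_loss))
        history["lr"].append(opt.lr)
        opt.lr = sched.update(val_loss, opt.lr)
        if verbose:
            logger.info("epoch %d: loss=%.4f val_loss=%.4f lr=%.2e",
                        epoch, epoch_loss, val_loss, opt.lr)
        if cfg.snapshot_ensemble > 0 and epoch >= cfg.epochs - cfg.snapshot_ensemble:
            snapshots.append(handle.net.get_weights())
    if avg_w is not None and avg_n > 0:
        handle.net.set_weights([w / avg_n for w in avg_w])
        if cfg.snapshot_ensemble > 0:
            snapshots.append(handle.net.get_weights())
    if cfg.snapshot_ensemble > 0:
        handle.snapshots = snapshots
    return handle, history
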