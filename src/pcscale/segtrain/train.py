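"""Training protocol for the desk-scale structure segmenter.

The protocol mirrors routine practice for SegNet-family models: per-pixel
cross-entropy over the 10 classes, Adam (initial learning rate 0.001, L2
weight decay 1e-4, minibatch 4), online augmentation (random crop, or random
±10% scaling processed back to the crop size), learning-rate division by 10
when the tuning loss plateaus, and early stopping by keeping the checkpoint
with the lowest tuning loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ..evalstats import iou
from ..volumetry import STRUCTURES
from .nn import Adam, SegModelSpec, SegNet2D, class_weights, softmax_cross_entropy


@dataclass
class TrainConfig:
    """Optimization and augmentation hyperparameters."""

    batch_size: int = 4
    lr: float = 1e-3
    lr_decay: float = 10.0
    weight_decay: float = 1e-4
    patience: int = 8
    max_epochs: int = 60
    crop: int = 480
    scale_amplitude: float = 0.10
    min_delta: float = 1e-4
    class_balance: bool = True  # median-frequency class weighting in the loss
    balance_fraction: float = 0.6  # fraction of epochs trained with class weights
    window_level: float = 35.0
    window_width: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.lr_decay <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def normalize(image: np.ndarray, level: float = 35.0, width: float = 80.0) -> np.ndarray:
    """Brain-window clamp then linear map to [0, 1].

    Intensities are clipped to [level - width/2, level + width/2]; the window
    center maps to 0.5, the edges to exactly 0 and 1.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite intensities")
    lo = level - width / 2.0
    return (np.clip(image, lo, lo + width) - lo) / width


def augment(image: np.ndarray, labels: np.ndarray, config: TrainConfig, seed=None):
    """One online augmentation draw: random crop, or random scaling processed
    back to the crop size.

    The identical spatial transform is applied to image (linear resampling)
    and labels (nearest neighbor).  With ``scale_amplitude == 0`` and
    ``crop`` equal to the input size this is the identity.  Deterministic
    under a fixed seed.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.shape != labels.shape or image.ndim != 2:
        raise ValueError("image and labels must be aligned 2D arrays")
    crop = int(config.crop)
    if crop > min(image.shape):
        raise ValueError(f"crop {crop} larger than image {image.shape}")
    rng = np.random.default_rng(seed)

    do_scale = config.scale_amplitude > 0 and rng.random() < 0.5
    if do_scale:
        s = 1.0 + rng.uniform(-config.scale_amplitude, config.scale_amplitude)
        image = ndimage.zoom(image, s, order=1)
        labels = ndimage.zoom(labels, s, order=0)
        if min(image.shape) < crop:  # scaled below the crop size: pad with background
            ph = max(0, crop - image.shape[0])
            pw = max(0, crop - image.shape[1])
            pads = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
            image = np.pad(image, pads, constant_values=image.min())
            labels = np.pad(labels, pads, constant_values=0)
    r0 = rng.integers(0, image.shape[0] - crop + 1)
    c0 = rng.integers(0, image.shape[1] - crop + 1)
    return image[r0 : r0 + crop, c0 : c0 + crop], labels[r0 : r0 + crop, c0 : c0 + crop]


def with_coords(images: np.ndarray, z=None, freqs=(1, 2, 4, 8)) -> np.ndarray:
    """Stack coordinate channels onto (N, H, W) images: intensity, the raw
    normalized coordinates (slice position z, row, col), and sin/cos Fourier
    encodings of each coordinate at the given frequencies.

    ``z`` gives each slice's through-plane position in [0, 1] (default 0.5
    for standalone slices).  Coordinate input breaks the convolutional
    translation equivariance on purpose: on a stylized phantom, different
    slices put different structures at the same in-plane position with
    near-identical attenuation, so the per-pixel task is ill-posed from
    intensity alone; the Fourier encoding makes position-dependent decision
    boundaries easy for a shallow network to carve.
    """
    n, h, w = images.shape
    z = np.full(n, 0.5) if z is None else np.asarray(z, dtype=float)
    zz = np.broadcast_to(z[:, None, None], (n, h, w))
    rr = np.broadcast_to(np.linspace(0, 1, h)[:, None], (n, h, w))
    cc = np.broadcast_to(np.linspace(0, 1, w)[None, :], (n, h, w))
    chans = [images, zz, rr, cc]
    for k in freqs:
        for c in (zz, rr, cc):
            chans.append(np.sin(2 * np.pi * k * c))
            chans.append(np.cos(2 * np.pi * k * c))
    return np.stack(chans, axis=1).astype(np.float32)


def _tuning_loss(model: SegNet2D, images: np.ndarray, labels: np.ndarray,
                 batch: int = 4, weights=None, z=None) -> float:
    total, count = 0.0, 0
    z = np.full(len(images), 0.5) if z is None else np.asarray(z, dtype=float)
    for i in range(0, len(images), batch):
        x = with_coords(images[i : i + batch], z[i : i + batch])
        logits = model.forward(x)
        loss, _ = softmax_cross_entropy(logits, labels[i : i + batch], weights)
        total += loss * x.shape[0]
        count += x.shape[0]
    return total / count


def train_segmenter(
    train_images,
    train_labels,
    config: TrainConfig | None = None,
    spec: SegModelSpec | None = None,
    tune_images=None,
    tune_labels=None,
    train_z=None,
    tune_z=None,
):
    """Train the segmenter; returns (model, history DataFrame).

    ``train_images``/``train_labels`` are (N, H, W) stacks of raw-intensity
    slices and integer label maps; ``train_z``/``tune_z`` optionally give each
    slice's normalized through-plane position (see :func:`with_coords`).  The tuning set drives the learning-rate
    schedule and early stopping: after every epoch the tuning loss is
    evaluated, the parameters are checkpointed whenever it improves, and the
    learning rate is divided by ``lr_decay`` when it fails to improve by more
    than ``min_delta`` for ``patience`` consecutive epochs.  The returned
    model carries the checkpoint with the lowest tuning loss.

    History columns: epoch, train_loss, tune_loss, lr.
    """
    config = config or TrainConfig()
    spec = spec or SegModelSpec()
    train_images = np.asarray(train_images, dtype=float)
    train_labels = np.asarray(train_labels)
    if tune_images is None or len(tune_images) == 0:
        raise ValueError("tuning set must not be empty")
    tune_images = normalize(np.asarray(tune_images, dtype=float),
                            config.window_level, config.window_width)
    tune_labels = np.asarray(tune_labels)
    train_z = np.full(len(train_images), 0.5) if train_z is None else np.asarray(train_z, float)
    tune_z = np.full(len(tune_images), 0.5) if tune_z is None else np.asarray(tune_z, float)

    rng = np.random.default_rng(config.seed)
    model = SegNet2D(spec, seed=int(rng.integers(2**31)))
    if config.max_epochs <= 0:
        warnings.warn("max_epochs <= 0: returning an untrained model")
        return model, pd.DataFrame(columns=["epoch", "train_loss", "tune_loss", "lr"])

    # class-weighted gradient for the warmup phase, plain cross-entropy after
    # (weighting finds the small structures, the unweighted phase sharpens
    # their boundaries); the plateau monitor always tracks the objective
    # currently optimized, and its state resets when the objective switches
    weights = class_weights(train_labels, spec.n_classes) if config.class_balance else None
    balance_until = int(np.ceil(config.balance_fraction * config.max_epochs))
    opt = Adam(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    best_loss = np.inf
    best_state = model.get_state()
    stall = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        w_now = weights if epoch <= balance_until else None
        if epoch == balance_until + 1:  # objective switch: restart the monitor
            best_loss, stall = np.inf, 0
            best_state = model.get_state()
        order = rng.permutation(len(train_images))
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            imgs, labs = [], []
            for j in sel:
                im, lb = augment(train_images[j], train_labels[j], config,
                                 seed=rng.integers(2**31))
                imgs.append(normalize(im, config.window_level, config.window_width))
                labs.append(lb)
            x = with_coords(np.stack(imgs), train_z[sel])
            y = np.stack(labs).astype(np.int64)
            logits = model.forward(x)
            loss, dlogits = softmax_cross_entropy(logits, y, w_now)
            model.backward(dlogits)
            opt.step()
            ep_loss += loss
            nb += 1
        tune_loss = _tuning_loss(model, tune_images, tune_labels, config.batch_size,
                                 w_now, tune_z)
        history.append(
            {"epoch": epoch, "train_loss": ep_loss / max(nb, 1),
             "tune_loss": tune_loss, "lr": opt.lr}
        )
        if tune_loss < best_loss - config.min_delta:
            best_loss = tune_loss
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                opt.lr /= config.lr_decay
                stall = 0
                if opt.lr < 1e-7:  # schedule exhausted
                    break
    model.set_state(best_state)
    return model, pd.DataFrame(history)


def predict_slices(model: SegNet2D, images, config: TrainConfig | None = None,
                   z=None) -> np.ndarray:
    """Predicted label maps for a stack of raw-intensity slices."""
    config = config or TrainConfig()
    images = normalize(np.asarray(images, dtype=float),
                       config.window_level, config.window_width)
    z = np.full(len(images), 0.5) if z is None else np.asarray(z, dtype=float)
    out = []
    for i in range(0, len(images), 8):
        out.append(model.predict(with_coords(images[i : i + 8], z[i : i + 8])))
    return np.concatenate(out)


def _stack_z(image_stack) -> np.ndarray:
    s = len(image_stack)
    return (np.arange(s) + 0.5) / s


def structure_iou_report(pred_cases, true_cases) -> pd.Series:
    """Per-structure IoU averaged over cases; each case pooled over its
    slices (voxel union)."""
    per_struct = np.zeros(9)
    for s_idx in range(9):
        vals = [
            iou(pred == s_idx + 1, true == s_idx + 1)
            for pred, true in zip(pred_cases, true_cases)
        ]
        per_struct[s_idx] = float(np.mean(vals))
    return pd.Series(per_struct, index=list(STRUCTURES))


def evaluate_folds(
    cases,
    k: int = 5,
    seed: int = 0,
    config: TrainConfig | None = None,
    spec: SegModelSpec | None = None,
    predictor=None,
) -> pd.DataFrame:
    """k-fold cross-validated per-structure IoU report.

    ``cases`` is a list of (image_stack, label_stack) pairs, one per visit;
    each image stack is (S, H, W) and its slices get normalized through-plane
    positions (i + 0.5)/S.  Cases are partitioned into k folds by a
    seeded shuffle; for each fold a model is trained on the other folds'
    slices (one training case is held out as the tuning set) and evaluated on
    the fold's cases, so no case is ever predicted by a model that saw it.
    IoU is computed per structure on the voxel union of each case's slices and
    averaged over the fold's cases.

    ``predictor`` (image_stack -> label_stack) bypasses training; used to
    audit the bookkeeping with an oracle.

    Returns a 9-row DataFrame (structures) with columns fold_1..fold_k and
    mean (arithmetic mean of the fold columns).
    """
    config = config or TrainConfig()
    spec = spec or SegModelSpec()
    if len(cases) < k:
        raise ValueError(f"{len(cases)} cases cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    folds = [sorted(order[i::k].tolist()) for i in range(k)]

    tested = []
    cols = {}
    for f, test_idx in enumerate(folds, start=1):
        train_idx = [i for i in range(len(cases)) if i not in test_idx]
        assert not set(train_idx) & set(test_idx)
        tested.extend(test_idx)
        if predictor is None:
            tune_case = train_idx[-1]
            fit_idx = train_idx[:-1] or train_idx
            imgs = np.concatenate([cases[i][0] for i in fit_idx])
            labs = np.concatenate([cases[i][1] for i in fit_idx])
            zs = np.concatenate([_stack_z(cases[i][0]) for i in fit_idx])
            model, _ = train_segmenter(
                imgs, labs, config, spec,
                tune_images=cases[tune_case][0], tune_labels=cases[tune_case][1],
                train_z=zs, tune_z=_stack_z(cases[tune_case][0]),
            )
            predict = lambda im: predict_slices(model, im, config, z=_stack_z(im))  # noqa: E731
        else:
            predict = predictor
        preds = [predict(np.asarray(cases[i][0], dtype=float)) for i in test_idx]
        trues = [np.asarray(cases[i][1]) for i in test_idx]
        cols[f"fold_{f}"] = structure_iou_report(preds, trues)
    assert sorted(tested) == list(range(len(cases))), "folds must partition the cases"
    report = pd.DataFrame(cols)
    report["mean"] = report.mean(axis=1)
    return report
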