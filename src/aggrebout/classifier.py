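"""Frame-level aggression classifier: training, inference, evaluation.

The classifier is a small convolutional network reading the
difference-channel stack of each frame and emitting an attack
probability.  Because attack frames are rare (~1% of a session),
training balances the classes by subsampling negative frames per video
and weighting the positive class in the loss.  Validation follows a
leave-one-video-out scheme: each labeled video is held out once, the
model is trained on the rest, and frame-level ROC AUC is measured on the
held-out video.  The operating threshold is then chosen
specificity-first, trading sensitivity for a hard floor on the
false-positive rate — with 99% of frames negative, false positives
otherwise dominate the scored attack duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata

from .frames import build_difference_stack, to_grayscale
from .nn import Adam, SmallConvNet, weighted_bce_with_logits
from .video import VideoSession

__all__ = [
    "TrainingConfig",
    "ClassifierModel",
    "ProbabilityTrace",
    "train_frame_classifier",
    "predict_probabilities",
    "roc_auc",
    "select_specificity_threshold",
    "ThresholdResult",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the frame classifier.

    ``neg_pos_ratio`` controls the negative-frame subsample per video
    (relative to that video's positive count); the remaining imbalance
    in the assembled set is absorbed by ``pos_weight`` ("auto" weighs
    positives by negatives/positives).  ``lags`` are the frame lags of
    the difference channels; with the default (1, 2) the input has three
    channels, taking the slot of the replaced RGB layout.
    """

    epochs: int = 12
    batch_size: int = 32
    learning_rate: float = 3e-3
    neg_pos_ratio: float = 8.0
    pos_weight: float | str = "auto"
    lags: tuple[int, ...] = (1, 2)
    conv_filters: tuple[int, ...] = (8, 16, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(self.lags) == 0 or min(self.lags) < 1:
            raise ValueError("need at least one lag >= 1")
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg_pos_ratio must be > 0")


@dataclass
class ClassifierModel:
    """A trained network plus everything needed to reproduce inference:
    the difference-channel lags, expected frame geometry, and the
    per-channel normalization scales estimated on the training set."""

    net: SmallConvNet
    lags: tuple[int, ...]
    input_shape: tuple[int, int]
    norm_scales: np.ndarray
    config: TrainingConfig = field(default_factory=TrainingConfig)


@dataclass
class ProbabilityTrace:
    """Per-frame attack probabilities for one video."""

    probs: np.ndarray
    fps: float
    video_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise ValueError("probs must be 1-D")
        if len(self.probs) and (
            self.probs.min() < 0.0 or self.probs.max() > 1.0
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probs)


def _gray_video(video: VideoSession) -> np.ndarray:
    if video.frames.ndim == 4:
        return np.stack([to_grayscale(f) for f in video.frames])
    return video.frames


def _features_at(
    gray: np.ndarray, idx: np.ndarray, lags: tuple[int, ...]
) -> np.ndarray:
    """Difference-channel features for selected frames only (avoids
    materializing the full stack for long videos)."""
    g = gray.astype(np.float32)
    t = len(g)
    out = np.zeros((len(idx), 1 + len(lags)) + g.shape[1:], dtype=np.float32)
    out[:, 0] = g[idx]
    for c, lag in enumerate(lags, start=1):
        ok = idx >= lag
        out[ok, c] = g[idx[ok]] - g[idx[ok] - lag]
    return out


def _assemble_training_set(
    videos: list[VideoSession],
    config: TrainingConfig,
    rng: np.random.Generator,
    fold_name: str,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for v in videos:
        if v.labels is None:
            raise ValueError(f"video {v.video_id!r} has no labels")
        gray = _gray_video(v)
        pos = np.flatnonzero(v.labels == 1)
        neg = np.flatnonzero(v.labels == 0)
        if len(pos):
            n_neg = min(len(neg), int(np.ceil(config.neg_pos_ratio * len(pos))))
        else:
            n_neg = min(len(neg), 120)
        neg_sel = rng.choice(neg, size=n_neg, replace=False) if n_neg else neg[:0]
        sel = np.concatenate([pos, neg_sel])
        xs.append(_features_at(gray, sel, config.lags))
        ys.append(v.labels[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(np.float64)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"training fold {fold_name!r} contains a single class "
            f"({n_pos} positive / {n_neg} negative frames)"
        )
    return x, y


def _fit(
    x: np.ndarray, y: np.ndarray, config: TrainingConfig, seed: int
) -> tuple[SmallConvNet, np.ndarray]:
    rng = np.random.default_rng(seed)
    scales = np.maximum(
        np.abs(x).max(axis=(0, 2, 3)), 1e-6
    )  # per-channel max-abs -> inputs in [-1, 1]
    xn = x / scales[None, :, None, None]
    net = SmallConvNet(xn.shape[1], config.conv_filters, rng=rng)
    if config.pos_weight == "auto":
        pw = max((len(y) - y.sum()) / max(y.sum(), 1.0), 1.0)
    else:
        pw = float(config.pos_weight)
    opt = Adam(net.params, lr=config.learning_rate)
    n = len(xn)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for s in range(0, n, config.batch_size):
            b = order[s : s + config.batch_size]
            logits, cache = net.forward(xn[b], need_cache=True)
            _, dlogits = weighted_bce_with_logits(logits, y[b], pw)
            grads = net.backward(dlogits, cache)
            opt.step(net.params, grads)
    return net, scales


def train_frame_classifier(
    videos: list[VideoSession], config: TrainingConfig | None = None
) -> tuple[ClassifierModel, list[dict]]:
    """Leave-one-video-out training of the frame classifier.

    Each video is held out once; a model trained on the remaining videos
    is evaluated on every frame of the held-out video (frame-level ROC
    AUC).  The returned model is retrained on all videos.  The per-fold
    metrics list has one entry per video with the held-out AUC.
    """
    config = config or TrainingConfig()
    if len(videos) < 2:
        raise ValueError("leave-one-video-out needs at least 2 videos")
    shapes = {v.frame_shape for v in videos}
    if len(shapes) > 1:
        raise ValueError(f"videos have mixed frame shapes: {shapes}")
    metrics: list[dict] = []
    for k, held in enumerate(videos):
        rng = np.random.default_rng(config.seed + 1000 + k)
        train_videos = [v for i, v in enumerate(videos) if i != k]
        x, y = _assemble_training_set(
            train_videos, config, rng, fold_name=held.video_id or f"fold{k}"
        )
        net, scales = _fit(x, y, config, seed=config.seed + 2000 + k)
        model = ClassifierModel(
            net=net, lags=config.lags, input_shape=held.frame_shape,
            norm_scales=scales, config=config,
        )
        trace = predict_probabilities(model, held)
        lab = np.asarray(held.labels)
        # frame-level AUC needs both classes in the held-out video; at ~1%
        # prevalence short sessions may contain no bout at all
        auc = roc_auc(trace.probs, lab) if 0 < lab.sum() < len(lab) else None
        metrics.append(
            {
                "fold": k,
                "held_out_video": held.video_id or f"fold{k}",
                "auc": auc,
                "n_train_frames": len(y),
                "n_train_pos": int(y.sum()),
            }
        )
    rng = np.random.default_rng(config.seed + 999)
    x, y = _assemble_training_set(videos, config, rng, fold_name="final")
    net, scales = _fit(x, y, config, seed=config.seed + 2999)
    final = ClassifierModel(
        net=net, lags=config.lags, input_shape=videos[0].frame_shape,
        norm_scales=scales, config=config,
    )
    return final, metrics


def predict_probabilities(
    model: ClassifierModel, video: VideoSession
) -> ProbabilityTrace:
    """One attack probability per frame; deterministic given the model."""
    if video.frame_shape != tuple(model.input_shape):
        raise ValueError(
            f"video frame shape {video.frame_shape} does not match the "
            f"model's training geometry {tuple(model.input_shape)}"
        )
    gray = _gray_video(video)
    x = build_difference_stack(gray, model.lags)
    xn = x / np.asarray(model.norm_scales)[None, :, None, None]
    probs = model.net.predict_proba(xn)
    return ProbabilityTrace(probs=probs, fps=video.fps, video_id=video.video_id)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney formulation.

    Equals the probability that a random positive outscores a random
    negative, counting ties 1/2; invariant to any strictly monotone
    transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(s)  # midranks: ties counted 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


class ThresholdResult(NamedTuple):
    threshold: float
    specificity: float
    sensitivity: float


def select_specificity_threshold(
    scores: np.ndarray, labels: np.ndarray, min_specificity: float
) -> ThresholdResult:
    """Smallest threshold whose specificity meets the floor.

    Frames scoring strictly above the threshold are called positive.
    Among thresholds achieving specificity >= ``min_specificity`` the
    smallest is returned, which maximizes sensitivity subject to the
    specificity floor (specificity is monotone in the threshold).  With
    ``min_specificity = 0`` a threshold below the minimum score is
    returned and every frame is called positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not 0.0 <= min_specificity <= 1.0:
        raise ValueError("min_specificity must be in [0, 1]")
    neg = s[y == 0]
    pos = s[y == 1]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both classes must be present")
    candidates = np.concatenate([[s.min() - 1.0], np.unique(s)])
    for th in candidates:
        spec = float(np.mean(neg <= th))
        if spec >= min_specificity:
            return ThresholdResult(
                threshold=float(th),
                specificity=spec,
                sensitivity=float(np.mean(pos > th)),
            )
    raise ValueError(f"specificity {min_specificity} unattainable")


# --------------------------------------------------------------------------
# persistence: metadata JSON + weights npz in a directory


def save_model(model: ClassifierModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "lags": list(model.lags),
        "input_shape": list(model.input_shape),
        "norm_scales": np.asarray(model.norm_scales).tolist(),
        "conv_filters": list(model.config.conv_filters),
        "config": {
            "epochs": model.config.epochs,
            "batch_size": model.config.batch_size,
            "learning_rate": model.config.learning_rate,
            "neg_pos_ratio": model.config.neg_pos_ratio,
            "pos_weight": model.config.pos_weight,
            "lags": list(model.config.lags),
            "conv_filters": list(model.config.conv_filters),
            "seed": model.config.seed,
        },
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", **model.net.state_dict())


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    cfg = meta["config"]
    config = TrainingConfig(
        epochs=cfg["epochs"],
        batch_size=cfg["batch_size"],
        learning_rate=cfg["learning_rate"],
        neg_pos_ratio=cfg["neg_pos_ratio"],
        pos_weight=cfg["pos_weight"],
        lags=tuple(cfg["lags"]),
        conv_filters=tuple(cfg["conv_filters"]),
        seed=cfg["seed"],
    )
    net = SmallConvNet(1 + len(meta["lags"]), tuple(meta["conv_filters"]))
    with np.load(path / "weights.npz") as z:
        net.load_state_dict({k: z[k] for k in z.files})
    return ClassifierModel(
        net=net,
        lags=tuple(meta["lags"]),
        input_shape=tuple(meta["input_shape"]),
        norm_scales=np.asarray(meta["norm_scales"]),
        config=config,
    )
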