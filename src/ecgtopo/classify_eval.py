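"""Binary quality classification of rendered persistence images.

Positive class is "acceptable". Metrics follow the usual screening-test
definitions, reported as percentages:

    Se  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    F1  = TP / (TP + 0.5 (FP + FN))
    Acc = (TP + TN) / total
    mAcc = (Se + Sp) / 2        (balanced accuracy, the headline metric)

Three interchangeable backends share one fit/predict contract:
``linear_pixels`` (logistic regression on downsampled grayscale pixels),
``baseline_cnn`` (fixed seeded random convolution features + logistic
head — CPU-trainable in seconds) and ``googlenet_transfer`` (optional,
requires torch/torchvision with pretrained weights).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ecgtopo.rendering import RasterImage

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "confusion_matrix",
    "compute_metrics",
    "balanced_accuracy",
    "kfold_split",
    "train_classifier",
    "cross_validate",
    "BACKENDS",
]

METRIC_NAMES = ("se", "sp", "f1", "acc", "macc")
BACKENDS = ("baseline_cnn", "linear_pixels", "googlenet_transfer")
_FEATURE_SIDE = 64  # backends downsample to 64x64 internally


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with "acceptable" as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five derived scores, as percentages; NaN marks an undefined one."""

    se: float
    sp: float
    f1: float
    acc: float
    macc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class CVResult:
    folds: list[MetricsReport]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds and not self.mean:
            stacked = {
                name: np.array([f.as_dict()[name] for f in self.folds])
                for name in METRIC_NAMES
            }
            self.mean = {k: float(np.nanmean(v)) for k, v in stacked.items()}
            self.std = {k: float(np.nanstd(v)) for k, v in stacked.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "k": len(self.folds),
                    "mean": self.mean,
                    "std": self.std,
                    "folds": [f.as_dict() for f in self.folds],
                },
                indent=1,
                allow_nan=True,
            )
        )


def _coerce_binary(values: Sequence) -> np.ndarray:
    mapping = {"acceptable": 1, "unacceptable": 0}
    out = np.array([mapping.get(v, v) for v in values])
    try:
        out = out.astype(int)
    except (TypeError, ValueError):
        raise ValueError(f"labels must be binary or acceptable/unacceptable")
    if not set(np.unique(out)) <= {0, 1}:
        raise ValueError(f"labels must be binary, got values {sorted(set(out))}")
    return out


def confusion_matrix(labels: Sequence, predictions: Sequence) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with acceptable (1) as the positive class."""
    y = _coerce_binary(labels)
    p = _coerce_binary(predictions)
    if y.shape != p.shape:
        raise ValueError(f"{y.size} labels vs {p.size} predictions")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def balanced_accuracy(se: float, sp: float) -> float:
    """mAcc = (Se + Sp) / 2, on whatever scale Se and Sp share."""
    return (se + sp) / 2.0


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive Se, Sp, F1, Acc and mAcc (percentages) from counts.

    A metric whose denominator vanishes is reported as NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    se = ratio(cm.tp, cm.tp + cm.fn)
    sp = ratio(cm.tn, cm.tn + cm.fp)
    f1 = ratio(cm.tp, cm.tp + 0.5 * (cm.fp + cm.fn))
    acc = ratio(cm.tp + cm.tn, cm.total)
    return MetricsReport(se=se, sp=sp, f1=f1, acc=acc, macc=balanced_accuracy(se, sp))


def kfold_split(
    n: int,
    k: int,
    labels: Optional[Sequence] = None,
    stratified: bool = True,
    seed: int = 0,
) -> list[np.ndarray]:
    """Partition 0..n-1 into k folds (sizes differing by <= 1), shuffled
    deterministically by ``seed``; stratified splits keep the class ratio
    within one record per fold and require ``labels``.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified:
        if labels is None:
            raise ValueError("stratified split requires labels")
        y = _coerce_binary(labels)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), y)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


# ---------------------------------------------------------------------------
# Classifier backends
# ---------------------------------------------------------------------------


def _to_pixel_stack(images: Sequence) -> np.ndarray:
    arrays = [im.pixels if isinstance(im, RasterImage) else np.asarray(im) for im in images]
    sides = {a.shape for a in arrays}
    if len(sides) != 1:
        raise ValueError(f"images disagree in shape: {sorted(sides)}")
    shape = arrays[0].shape
    if len(shape) != 3 or shape[2] != 3 or shape[0] != shape[1]:
        raise ValueError(f"expected square (s, s, 3) images, got {shape}")
    return np.stack(arrays)


def _grayscale_64(stack: np.ndarray) -> np.ndarray:
    """Grayscale + bilinear downsample to 64x64, scaled to [0, 1]."""
    gray = stack.mean(axis=3).astype(np.uint8)
    if gray.shape[1] == _FEATURE_SIDE:
        return gray.astype(float) / 255.0
    out = np.empty((gray.shape[0], _FEATURE_SIDE, _FEATURE_SIDE))
    for i, g in enumerate(gray):
        out[i] = np.asarray(
            Image.fromarray(g).resize((_FEATURE_SIDE, _FEATURE_SIDE), Image.BILINEAR)
        )
    return out / 255.0


class _SklearnHeadModel:
    """Feature extractor + scaler + logistic-regression head."""

    def __init__(self, seed: int):
        self.seed = seed
        self.scaler = StandardScaler()
        self.head = LogisticRegression(max_iter=500, random_state=seed)

    def features(self, stack: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fit(self, images: Sequence, labels: Sequence) -> "_SklearnHeadModel":
        y = _coerce_binary(labels)
        if len(set(y.tolist())) < 2:
            raise ValueError("training data must contain both classes")
        feats = self.features(_grayscale_64(_to_pixel_stack(images)))
        self.head.fit(self.scaler.fit_transform(feats), y)
        return self

    def predict(self, images: Sequence) -> np.ndarray:
        feats = self.features(_grayscale_64(_to_pixel_stack(images)))
        return self.head.predict(self.scaler.transform(feats))


class LinearPixelsModel(_SklearnHeadModel):
    """Logistic regression on raw downsampled pixels."""

    def features(self, stack: np.ndarray) -> np.ndarray:
        return stack.reshape(stack.shape[0], -1)


class BaselineCNNModel(_SklearnHeadModel):
    """Random-kitchen-sinks CNN: fixed seeded 5x5 convolution filters,
    ReLU, 4x4 average pooling, then a trained logistic head. Deterministic
    for a given seed and trainable on one CPU in seconds."""

    n_filters = 8
    kernel = 5
    pool = 4

    def __init__(self, seed: int):
        super().__init__(seed)
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((self.n_filters, self.kernel, self.kernel))
        self.filters = f - f.mean(axis=(1, 2), keepdims=True)

    def features(self, stack: np.ndarray) -> np.ndarray:
        windows = np.lib.stride_tricks.sliding_window_view(
            stack, (self.kernel, self.kernel), axis=(1, 2)
        )  # (n, H', W', k, k)
        fmap = np.maximum(np.einsum("nhwij,fij->nfhw", windows, self.filters), 0.0)
        n, nf, h, w = fmap.shape
        hp, wp = h // self.pool, w // self.pool
        fmap = fmap[:, :, : hp * self.pool, : wp * self.pool]
        pooled = fmap.reshape(n, nf, hp, self.pool, wp, self.pool).mean(axis=(3, 5))
        return pooled.reshape(n, -1)


class GooglenetTransferModel:
    """Adapter around torchvision's pretrained GoogLeNet (optional extra).

    Excluded from the default test/acceptance paths: it needs torch,
    torchvision and downloadable pretrained weights.
    """

    def __init__(self, seed: int):
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the googlenet_transfer backend requires torch and torchvision "
                "with pretrained weights; install them or use baseline_cnn"
            ) from exc
        self.seed = seed

    def fit(self, images, labels):  # pragma: no cover - optional heavy path
        import torch
        from torchvision.models import googlenet

        torch.manual_seed(self.seed)
        y = _coerce_binary(labels)
        if len(set(y.tolist())) < 2:
            raise ValueError("training data must contain both classes")
        net = googlenet(weights="DEFAULT")
        net.fc = torch.nn.Linear(net.fc.in_features, 2)
        self.net = net
        x = torch.tensor(
            _to_pixel_stack(images).transpose(0, 3, 1, 2) / 255.0, dtype=torch.float32
        )
        t = torch.tensor(y, dtype=torch.long)
        opt = torch.optim.Adam(net.fc.parameters(), lr=1e-3)
        net.train()
        for _ in range(5):
            opt.zero_grad()
            loss = torch.nn.functional.cross_entropy(net(x).logits, t)
            loss.backward()
            opt.step()
        return self

    def predict(self, images):  # pragma: no cover - optional heavy path
        import torch

        self.net.eval()
        x = torch.tensor(
            _to_pixel_stack(images).transpose(0, 3, 1, 2) / 255.0, dtype=torch.float32
        )
        with torch.no_grad():
            return self.net(x).argmax(dim=1).numpy()


def train_classifier(
    images: Sequence, labels: Sequence, backend: str = "baseline_cnn", seed: int = 0
):
    """Fit the named backend; all backends share the fit/predict contract."""
    if backend == "baseline_cnn":
        return BaselineCNNModel(seed).fit(images, labels)
    if backend == "linear_pixels":
        return LinearPixelsModel(seed).fit(images, labels)
    if backend == "googlenet_transfer":
        return GooglenetTransferModel(seed).fit(images, labels)
    raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")


def cross_validate(
    images: Sequence,
    labels: Sequence,
    k: int = 10,
    backend: str = "baseline_cnn",
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """k-fold cross-validation: fit on k-1 folds, score the held-out fold."""
    y = _coerce_binary(labels)
    stack = _to_pixel_stack(images)
    folds = kfold_split(len(y), k, labels=y, stratified=stratified, seed=seed)
    reports = []
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        model = train_classifier(stack[mask], y[mask], backend=backend, seed=seed)
        preds = model.predict(stack[test_idx])
        reports.append(compute_metrics(confusion_matrix(y[test_idx], preds)))
    return CVResult(folds=reports)
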