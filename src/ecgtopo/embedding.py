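"""Sliding-window delay embedding of ECG segments into point clouds.

A length-n series is folded into a d x t matrix (row i holds samples
``x[(i-1)t+1 .. it]``); its t columns are the points of the cloud in R^d,
i.e. point j = (x_j, x_{j+t}, ..., x_{j+(d-1)t}). Trailing samples beyond
d*t are discarded, as is any segment shorter than one window. Multi-lead
records embed per lead and concatenate coordinates point-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EmbeddingParams",
    "PointCloud",
    "SegmentTooShortError",
    "sliding_window_embed",
    "embedding_dimension",
    "stack_leads",
]


class SegmentTooShortError(ValueError):
    """The series cannot fill a single sliding window and is discarded."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Window length and sampling rate; t and d are derived.

    t = round(window_seconds * fs) is the window length in samples and the
    number of points; d = floor(n / t) is the per-lead ambient dimension.
    """

    window_seconds: float
    fs: float

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.fs <= 0:
            raise ValueError("window_seconds and fs must be positive")
        if self.window_samples < 1:
            raise ValueError("window shorter than one sample")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds * self.fs))

    def dimension(self, n_samples: int) -> int:
        d = n_samples // self.window_samples
        if d < 1:
            raise SegmentTooShortError(
                f"series of {n_samples} samples cannot fill a "
                f"{self.window_samples}-sample window"
            )
        return d


@dataclass
class PointCloud:
    """t points in R^d with Euclidean metric and embedding provenance."""

    points: np.ndarray  # shape (t, d)
    params: EmbeddingParams | None = None
    record_id: str = ""
    metric: str = field(default="euclidean")

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D (t, d) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]


def sliding_window_embed(
    series: Sequence[float] | np.ndarray,
    params: EmbeddingParams,
    record_id: str = "",
) -> PointCloud:
    """Embed a scalar series into R^d via non-overlapping window stacking.

    Raises :class:`SegmentTooShortError` when the series is shorter than one
    window (such segments are discarded upstream).
    """
    x = np.asarray(series, dtype=float).ravel()
    t = params.window_samples
    d = params.dimension(x.size)  # raises if n < t
    points = x[: d * t].reshape(d, t).T  # column j -> point j
    return PointCloud(points=points, params=params, record_id=record_id)


def embedding_dimension(
    duration_s: float, fs: float, window_seconds: float, n_leads: int = 1
) -> int:
    """Ambient dimension of the stacked cloud for a given window choice.

    Equals ``n_leads * floor(duration_s*fs / round(window_seconds*fs))``;
    e.g. 10-s, 500-Hz records give 100/50/33/25/20 per lead for 0.1-0.5 s
    windows, and 120/60/36/24/24 for 12 leads with 1-5 s windows.
    """
    if n_leads < 1:
        raise ValueError("n_leads must be >= 1")
    params = EmbeddingParams(window_seconds=window_seconds, fs=fs)
    n = int(round(duration_s * fs))
    return n_leads * params.dimension(n)


def stack_leads(per_lead_clouds: Sequence[PointCloud]) -> PointCloud:
    """Concatenate per-lead clouds coordinate-wise into one cloud.

    Point j of the output is the concatenation of point j of every input;
    the dimension is the sum of per-lead dimensions. All inputs must share
    one point count.
    """
    if not per_lead_clouds:
        raise ValueError("need at least one cloud")
    counts = {c.n_points for c in per_lead_clouds}
    if len(counts) != 1:
        raise ValueError(f"mismatched point counts across leads: {sorted(counts)}")
    if len(per_lead_clouds) == 1:
        return per_lead_clouds[0]
    first = per_lead_clouds[0]
    return PointCloud(
        points=np.hstack([c.points for c in per_lead_clouds]),
        params=first.params,
        record_id=first.record_id.rsplit("_", 1)[0] if first.record_id else "",
    )
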