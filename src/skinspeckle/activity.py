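"""Biospeckle activity via the THSP-based inertia-moment method.

The time history of the speckle pattern (THSP) tracks one spatial column of
the stack through time: column ``k`` of frame ``t`` becomes column ``t`` of
an ``H x T`` matrix.  Consecutive-in-time gray-level pairs ``(i, j)`` from
every row are accumulated into a co-occurrence matrix ``N_ij``, each row of
which is normalized by its occupancy to ``M_ij``.  The inertia moment

    IM = sum_ij M_ij (i - j)^2

measures the spread of transitions away from the diagonal: a static surface
puts all counts on the diagonal (IM = 0), while an active tissue spreads
them out.  Biospeckle activity (BA) is identified with IM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SpeckleSequence

__all__ = [
    "THSPMatrix",
    "COMatrix",
    "BAResult",
    "BiospeckleActivity",
    "extract_thsp",
    "build_com",
    "inertia_moment",
    "biospeckle_activity",
    "ba_over_windows",
    "window_correlation",
]

DEFAULT_WINDOWS_SECONDS: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)


@dataclass(frozen=True)
class THSPMatrix:
    """H x T time history of the speckle pattern."""

    values: np.ndarray  # (H, T) integer gray levels
    column_index: int
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class COMatrix:
    """Gray-level transition counts ``N_ij`` and row-normalized ``M_ij``."""

    counts: np.ndarray  # (G, G) non-negative integers
    normalized: np.ndarray  # (G, G) rows sum to 1 or 0

    @property
    def gray_levels(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class BAResult:
    """Scalar biospeckle activity for one stack and one time window."""

    ba: float
    window_seconds: float
    n_frames_used: int
    column_index: int


def _as_frames(seq: SpeckleSequence | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(seq, SpeckleSequence):
        return seq.frames, seq.frame_rate
    frames = np.asarray(seq)
    if frames.ndim != 3:
        raise ValueError("expected a SpeckleSequence or a (T, H, W) array")
    return frames, float("nan")


def extract_thsp(
    seq: SpeckleSequence | np.ndarray, column_index: int | None = None
) -> THSPMatrix:
    """Form the THSP from one tracked column of the stack.

    ``column_index`` is 0-based; ``None`` selects the middle column, which
    for a 512-pixel-wide region is index 255 — the "256th column" in 1-based
    counting.
    """
    frames, frame_rate = _as_frames(seq)
    n_frames, _, width = frames.shape
    if n_frames < 2:
        raise ValueError("THSP needs at least 2 frames")
    if column_index is None:
        column_index = (width - 1) // 2
    if not 0 <= column_index < width:
        raise IndexError(
            f"column_index {column_index} out of range for width-{width} frames"
        )
    # column of frame t -> column t of the THSP
    thsp = frames[:, :, column_index].T.copy()
    return THSPMatrix(values=thsp, column_index=column_index, frame_rate=frame_rate)


def build_com(thsp: THSPMatrix | np.ndarray, gray_levels: int = 256) -> COMatrix:
    """Accumulate consecutive-in-time transition counts over all THSP rows.

    Each of the H rows contributes its T-1 temporal transitions, so
    ``counts.sum() == H * (T - 1)``.  Rows of ``normalized`` belonging to
    unvisited gray levels are left all-zero (row normalization is undefined
    there and zeros preserve the IM semantics).
    """
    values = thsp.values if isinstance(thsp, THSPMatrix) else np.asarray(thsp)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("THSP must be a 2-D matrix with at least 2 columns")
    vmax = int(values.max())
    if gray_levels < vmax + 1:
        raise ValueError(
            f"gray_levels={gray_levels} smaller than observed maximum {vmax}"
        )
    i = values[:, :-1].ravel().astype(np.int64)
    j = values[:, 1:].ravel().astype(np.int64)
    flat = np.bincount(i * gray_levels + j, minlength=gray_levels * gray_levels)
    counts = flat.reshape(gray_levels, gray_levels)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, 0.0)
    return COMatrix(counts=counts, normalized=normalized)


def inertia_moment(com: COMatrix | np.ndarray) -> float:
    """Second moment of the normalized COM about its principal diagonal."""
    m = com.normalized if isinstance(com, COMatrix) else np.asarray(com, dtype=float)
    g = m.shape[0]
    idx = np.arange(g)
    weights = (idx[:, None] - idx[None, :]) ** 2
    return float((m * weights).sum())


def biospeckle_activity(
    seq: SpeckleSequence | np.ndarray,
    column_index: int | None = None,
    gray_levels: int = 256,
    n_frames: int | None = None,
    window_seconds: float | None = None,
) -> BAResult:
    """Compute BA = IM for one stack, optionally on a prefix of frames."""
    frames, frame_rate = _as_frames(seq)
    total = frames.shape[0]
    if n_frames is None:
        n_frames = total
    if not 2 <= n_frames <= total:
        raise ValueError(f"n_frames must lie in [2, {total}], got {n_frames}")
    thsp = extract_thsp(frames[:n_frames], column_index)
    ba = inertia_moment(build_com(thsp, gray_levels))
    if window_seconds is None:
        window_seconds = n_frames / frame_rate if frame_rate == frame_rate else float("nan")
    return BAResult(
        ba=ba,
        window_seconds=window_seconds,
        n_frames_used=n_frames,
        column_index=thsp.column_index,
    )


def ba_over_windows(
    seq: SpeckleSequence,
    windows_seconds: Sequence[float | str] = DEFAULT_WINDOWS_SECONDS,
    column_index: int | None = None,
    gray_levels: int = 256,
) -> list[BAResult]:
    """BA on prefix windows of the recording.

    A window of ``w`` seconds uses the first ``floor(w * frame_rate)``
    frames.  The string ``"all"`` uses every recorded frame, which resolves
    the mismatch between a 40 s window at 12.5 Hz (500 frames) and a
    512-frame recording.
    """
    results = []
    for w in windows_seconds:
        if isinstance(w, str):
            if w != "all":
                raise ValueError(f"unknown window spec {w!r}")
            n = seq.n_frames
            w_sec = seq.n_frames / seq.frame_rate
        else:
            n = int(np.floor(w * seq.frame_rate))
            w_sec = float(w)
            if n > seq.n_frames:
                raise ValueError(
                    f"window of {w} s needs {n} frames but the recording has "
                    f"only {seq.n_frames}"
                )
            if n < 2:
                raise ValueError(f"window of {w} s yields fewer than 2 frames")
        results.append(
            biospeckle_activity(
                seq,
                column_index=column_index,
                gray_levels=gray_levels,
                n_frames=n,
                window_seconds=w_sec,
            )
        )
    return results


def window_correlation(
    ba_table: np.ndarray, reference_window: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each window's BA against a reference window.

    ``ba_table`` is a samples x windows matrix.  Returns ``(r, p)`` vectors,
    one entry per window; the reference correlates with itself at exactly 1.
    """
    from scipy import stats as sps

    table = np.asarray(ba_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 3:
        raise ValueError("ba_table must be 2-D with at least 3 samples")
    ref = table[:, reference_window]
    if np.ptp(ref) == 0:
        raise ValueError("reference window has zero variance; correlation undefined")
    r = np.empty(table.shape[1])
    p = np.empty(table.shape[1])
    for k in range(table.shape[1]):
        if k == reference_window:
            r[k], p[k] = 1.0, 0.0
            continue
        col = table[:, k]
        if np.ptp(col) == 0:
            raise ValueError(f"window column {k} has zero variance; correlation undefined")
        r[k], p[k] = sps.pearsonr(ref, col)
    return r, p


class BiospeckleActivity(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping speckle stacks to BA features.

    Parameters
    ----------
    column_index : int or None
        0-based tracked column; ``None`` means the middle column.
    gray_levels : int
        Size of the co-occurrence matrix (8-bit cameras: 256).
    windows_seconds : sequence of float/"all" or None
        If ``None``, one BA per stack over all frames; otherwise one BA per
        window, producing a ``(n_samples, n_windows)`` feature matrix.
    """

    def __init__(
        self,
        column_index: int | None = None,
        gray_levels: int = 256,
        windows_seconds: Sequence[float | str] | None = None,
    ):
        self.column_index = column_index
        self.gray_levels = gray_levels
        self.windows_seconds = windows_seconds

    def fit(self, X: Iterable[SpeckleSequence], y=None) -> "BiospeckleActivity":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[SpeckleSequence]) -> np.ndarray:
        rows = []
        for seq in X:
            if self.windows_seconds is None:
                res = biospeckle_activity(
                    seq, column_index=self.column_index, gray_levels=self.gray_levels
                )
                rows.append([res.ba])
            else:
                results = ba_over_windows(
                    seq,
                    windows_seconds=self.windows_seconds,
                    column_index=self.column_index,
                    gray_levels=self.gray_levels,
                )
                rows.append([r.ba for r in results])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if self.windows_seconds is None:
            return np.asarray(["ba"], dtype=object)
        return np.asarray(
            [f"ba_{w}s" if not isinstance(w, str) else "ba_all" for w in self.windows_seconds],
            dtype=object,
        )
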