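"""Multi-feature dynamic-time-warping dissimilarity between whistle contours.

Each contour is resampled to a uniform time grid and described per point by
four parameters: elapsed time, fundamental frequency, fundamental-frequency
change (local slope) and vibrato amplitude (the amplitude of fast periodic
modulation, the "buzz").  Parameters are scaled to unit variance across the
dataset, multiplied by the analysis weights, and compared by classic DTW
with steps {(1,0),(0,1),(1,1)}.  The local cost is the weighted Euclidean
distance between point vectors; the score is the accumulated cost along the
optimal path divided by the path length, so contours with similar modulation
patterns but different durations remain comparable.

The default weights (time 10.0 ms, fundamental frequency 3.513, frequency
change 2.413, vibrato amplitude 1.973) follow the standard Luscinia analysis
configuration for delphinid whistles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .contours import WhistleContour

VIBRATO_WINDOW_MS = 50.0


@dataclass(frozen=True)
class DtwWeights:
    """Relative weights of the four DTW comparison parameters."""

    time_weight: float = 10.0
    f0_weight: float = 3.513
    f0_change_weight: float = 2.413
    vibrato_weight: float = 1.973

    def __post_init__(self) -> None:
        if min(self.time_weight, self.f0_weight, self.f0_change_weight, self.vibrato_weight) <= 0:
            raise ValueError("all DTW weights must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.time_weight, self.f0_weight, self.f0_change_weight, self.vibrato_weight]
        )


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with the whistle ids in row order."""

    ids: list[str]
    D: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("non-finite dissimilarity")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("non-zero diagonal")

    def __len__(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.D, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))


def contour_features_for_dtw(c: WhistleContour) -> np.ndarray:
    """Per-point raw parameter matrix (n_points x 4), un-normalized.

    Columns: elapsed time (ms from contour start), f0 (kHz), f0 slope
    (kHz/ms, central differences), vibrato amplitude (kHz, half the local
    peak-to-trough excursion of the residual after removing a 50 ms
    moving-average trend).
    """
    if len(c) < 2:
        raise ValueError(f"{c.whistle_id}: need >= 2 points")
    t = c.times - c.times[0]
    f = c.freqs / 1000.0
    if len(c) >= 3:
        slope = np.gradient(f, t)
    else:
        slope = np.full_like(f, (f[1] - f[0]) / (t[1] - t[0]))
    step = float(np.median(np.diff(t)))
    win = max(3, int(round(VIBRATO_WINDOW_MS / step)))
    win = min(win, len(f)) if len(f) >= 3 else len(f)
    trend = uniform_filter1d(f, size=win, mode="nearest")
    resid = f - trend
    vib = 0.5 * (
        maximum_filter1d(resid, size=win, mode="nearest")
        - minimum_filter1d(resid, size=win, mode="nearest")
    )
    return np.column_stack([t, f, slope, vib])


def dataset_scales(feature_tracks: Sequence[np.ndarray]) -> np.ndarray:
    """Pooled per-parameter standard deviations used to normalize features.

    Zero SDs (a parameter constant across the whole dataset) are replaced by
    1 so the parameter simply does not discriminate.
    """
    stacked = np.vstack(feature_tracks)
    sd = stacked.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return sd


@njit(cache=True)
def _dtw_core(a: np.ndarray, b: np.ndarray) -> float:
    """DTW score between two weighted feature tracks.

    Accumulated weighted-Euclidean cost minimized over monotone paths with
    steps {(1,0),(0,1),(1,1)}; ties in cost resolved toward shorter paths.
    Returns total cost / number of cells on the optimal path.
    """
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    cost = np.empty((n, m))
    steps = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            d = 0.0
            for k in range(a.shape[1]):
                diff = a[i, k] - b[j, k]
                d += diff * diff
            d = np.sqrt(d)
            if i == 0 and j == 0:
                cost[i, j] = d
                steps[i, j] = 1.0
                continue
            best_c = big
            best_s = big
            if i > 0 and j > 0:
                if cost[i - 1, j - 1] < best_c or (
                    cost[i - 1, j - 1] == best_c and steps[i - 1, j - 1] < best_s
                ):
                    best_c = cost[i - 1, j - 1]
                    best_s = steps[i - 1, j - 1]
            if i > 0:
                if cost[i - 1, j] < best_c or (
                    cost[i - 1, j] == best_c and steps[i - 1, j] < best_s
                ):
                    best_c = cost[i - 1, j]
                    best_s = steps[i - 1, j]
            if j > 0:
                if cost[i, j - 1] < best_c or (cost[i, j - 1] == best_c and steps[i, j - 1] < best_s):
                    best_c = cost[i, j - 1]
                    best_s = steps[i, j - 1]
            cost[i, j] = best_c + d
            steps[i, j] = best_s + 1.0
    return cost[n - 1, m - 1] / steps[n - 1, m - 1]


def dtw_distance(
    a: np.ndarray,
    b: np.ndarray,
    w: DtwWeights = DtwWeights(),
    scales: np.ndarray | None = None,
) -> float:
    """DTW dissimilarity between two raw feature tracks (n x 4 arrays).

    ``scales`` are the pooled dataset SDs; when omitted the pair's own pooled
    SDs are used (adequate for two-contour comparisons only).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty feature track")
    if scales is None:
        scales = dataset_scales([a, b])
    wv = w.as_array() / scales
    return float(_dtw_core(a * wv, b * wv))


def build_dissimilarity_matrix(
    contours: Sequence[WhistleContour],
    w: DtwWeights = DtwWeights(),
    resample_ms: float = 1.0,
) -> DissimilarityMatrix:
    """All pairwise DTW dissimilarities on a common ``resample_ms`` grid."""
    if len(contours) < 2:
        raise ValueError("need >= 2 contours")
    tracks = []
    for c in contours:
        try:
            tracks.append(contour_features_for_dtw(c.resampled(resample_ms)))
        except ValueError as exc:
            raise ValueError(f"invalid contour {c.whistle_id!r}: {exc}") from exc
    scales = dataset_scales(tracks)
    wv = w.as_array() / scales
    weighted = [t * wv for t in tracks]
    n = len(contours)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _dtw_core(weighted[i], weighted[j])
    meta = {
        "local_cost": "weighted Euclidean over z-scaled (time, f0, f0_change, vibrato)",
        "normalization": "accumulated cost / path length",
        "weights": list(w.as_array()),
        "resample_ms": resample_ms,
    }
    return DissimilarityMatrix([c.whistle_id for c in contours], D, meta)


def dtw_brute_force(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive-path DTW oracle for tiny tracks (already weighted).

    Enumerates every monotone warping path, scores each by total local cost,
    and returns total/length for the lexicographically minimal (total,
    length) path — the same convention as the dynamic program.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = len(a), len(b)
    local = np.array([[np.linalg.norm(a[i] - b[j]) for j in range(m)] for i in range(n)])
    best: list[tuple[float, int]] = [(np.inf, 0)]

    def walk(i: int, j: int, total: float, length: int) -> None:
        total += local[i, j]
        length += 1
        if i == n - 1 and j == m - 1:
            if (total, length) < best[0]:
                best[0] = (total, length)
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, total, length)
        if i + 1 < n:
            walk(i + 1, j, total, length)
        if j + 1 < m:
            walk(i, j + 1, total, length)

    walk(0, 0, 0.0, 0)
    total, length = best[0]
    return total / length
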