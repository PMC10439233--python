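"""Whistle contour data types, I/O, selection filters and acoustic features.

The unit of analysis is the *whistle contour*: the trajectory of a whistle's
fundamental frequency over time, traced from a spectrogram.  Times are stored
in milliseconds, frequencies in Hz; the seven standard acoustic parameters
(duration, minimum/maximum/start/end/delta/peak frequency) are reported in
seconds and kHz, matching the conventions of the bioacoustics literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_NAMES = (
    "duration",
    "min_freq",
    "max_freq",
    "start_freq",
    "end_freq",
    "delta_freq",
    "peak_freq",
)

ECOTYPES = ("coastal", "offshore")


class ContourError(ValueError):
    """Raised for malformed or invariant-violating contour data."""


@dataclass
class WhistleContour:
    """A sampled fundamental-frequency trace with metadata.

    Parameters
    ----------
    whistle_id : str
        Unique identifier within a dataset.
    times : ndarray
        Sample times in ms, strictly increasing, length >= 2.
    freqs : ndarray
        Fundamental frequency in Hz at each time, all > 0.
    amps : ndarray or None
        Optional relative amplitude per point (dB); used for peak frequency.
    meta : dict
        Free-form metadata; recognised keys: ``ecotype`` (coastal / offshore /
        unknown), ``group_id``, ``recording_id``, ``sample_rate``,
        ``shape_class``.
    """

    whistle_id: str
    times: np.ndarray
    freqs: np.ndarray
    amps: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.amps is not None:
            self.amps = np.asarray(self.amps, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.times.ndim != 1 or self.freqs.ndim != 1:
            raise ContourError(f"{self.whistle_id}: times/freqs must be 1-D")
        if len(self.times) != len(self.freqs):
            raise ContourError(f"{self.whistle_id}: times and freqs lengths differ")
        if len(self.times) < 2:
            raise ContourError(f"{self.whistle_id}: contour needs >= 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ContourError(f"{self.whistle_id}: times not strictly increasing")
        if not np.all(self.freqs > 0):
            raise ContourError(f"{self.whistle_id}: non-positive frequency")
        if self.amps is not None and len(self.amps) != len(self.times):
            raise ContourError(f"{self.whistle_id}: amps length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_ms(self) -> float:
        return float(self.times[-1] - self.times[0])

    def shifted(self, offset_ms: float) -> "WhistleContour":
        """Copy with a uniform time offset (features are invariant to this)."""
        return replace(self, times=self.times + offset_ms)

    def resampled(self, step_ms: float = 1.0) -> "WhistleContour":
        """Linear interpolation onto a uniform grid with spacing ``step_ms``."""
        n = max(int(round(self.duration_ms / step_ms)) + 1, 2)
        grid = self.times[0] + np.arange(n) * step_ms
        grid = np.clip(grid, self.times[0], self.times[-1])
        # clipping can duplicate the final point; force strict monotonicity
        grid = self.times[0] + np.linspace(0.0, self.duration_ms, n)
        freqs = np.interp(grid, self.times, self.freqs)
        amps = np.interp(grid, self.times, self.amps) if self.amps is not None else None
        return WhistleContour(self.whistle_id, grid, freqs, amps, dict(self.meta))


@dataclass(frozen=True)
class WhistleFeatures:
    """The seven standard acoustic parameters of a whistle.

    duration in s; all frequencies in kHz.  ``delta_freq`` is the frequency
    excursion (max - min); ``peak_freq`` is the frequency at maximum amplitude.
    """

    duration: float
    min_freq: float
    max_freq: float
    start_freq: float
    end_freq: float
    delta_freq: float
    peak_freq: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


@dataclass(frozen=True)
class SelectionRules:
    """Whistle selection thresholds applied before analysis.

    min_snr : dB — whistles at or below this signal-to-noise ratio are dropped.
    min_gap : ms — a whistle starting closer than this to the previous kept
        whistle's end (same recording) is not counted as an individual whistle.
    max_fundamental : kHz — contours reaching this frequency are excluded so
        recordings made at different sampling rates remain comparable.
    """

    min_snr: float = 4.0
    min_gap: float = 200.0
    max_fundamental: float = 22.05

    def __post_init__(self) -> None:
        if min(self.min_snr, self.min_gap, self.max_fundamental) <= 0:
            raise ValueError("all selection thresholds must be > 0")


def extract_features(c: WhistleContour) -> WhistleFeatures:
    """Extract the seven standard acoustic parameters from a contour.

    Peak frequency is read at the sample of maximum amplitude when an
    amplitude track is present; otherwise the median frequency of the trace
    is used (the trace carries no energy information without amplitudes).
    """
    c.validate()
    f_khz = c.freqs / 1000.0
    mf = float(f_khz.min())
    mxf = float(f_khz.max())
    if c.amps is not None:
        pf = float(f_khz[int(np.argmax(c.amps))])
    else:
        pf = float(np.median(f_khz))
    return WhistleFeatures(
        duration=c.duration_ms / 1000.0,
        min_freq=mf,
        max_freq=mxf,
        start_freq=float(f_khz[0]),
        end_freq=float(f_khz[-1]),
        delta_freq=mxf - mf,
        peak_freq=pf,
    )


def features_table(contours: Sequence[WhistleContour]) -> pd.DataFrame:
    """Feature table: one row per whistle, seven parameters + metadata."""
    rows = []
    for c in contours:
        row = {"whistle_id": c.whistle_id}
        row.update(extract_features(c).as_dict())
        for key in ("ecotype", "group_id", "recording_id", "shape_class"):
            if key in c.meta:
                row[key] = c.meta[key]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: long-format contour CSV and Raven selection tables
# ---------------------------------------------------------------------------

RAVEN_COLUMNS = ["Selection", "Begin Time (s)", "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)"]


def read_contours(path: str | Path, format: str = "long_csv") -> list[WhistleContour]:
    """Read whistle contours from a table file.

    ``long_csv``: columns whistle_id,time_ms,freq_hz[,amp_db] plus optional
    metadata columns (ecotype, group_id, recording_id), one row per sample.
    ``raven_selection``: tab-separated Raven selection table; only selection
    bounds are available, so each selection becomes a two-point contour
    spanning (Begin, Low Freq) -> (End, High Freq).
    """
    path = Path(path)
    if format == "long_csv":
        return _read_long_csv(path)
    if format == "raven_selection":
        return _read_raven(path)
    raise ValueError(f"unknown contour format: {format!r}")


def _read_long_csv(path: Path) -> list[WhistleContour]:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ContourError(f"{path}: malformed CSV ({exc})") from exc
    required = {"whistle_id", "time_ms", "freq_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ContourError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_ms", "freq_hz"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ContourError(f"{path}: malformed value in column {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    meta_cols = [c for c in ("ecotype", "group_id", "recording_id", "shape_class") if c in df.columns]
    contours = []
    for wid, sub in df.groupby("whistle_id", sort=False):
        sub = sub.sort_values("time_ms")
        times = sub["time_ms"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise ContourError(f"whistle {wid!r}: non-monotone or duplicated time stamps")
        amps = sub["amp_db"].to_numpy(float) if "amp_db" in sub.columns else None
        meta = {k: sub[k].iloc[0] for k in meta_cols}
        contours.append(WhistleContour(str(wid), times, sub["freq_hz"].to_numpy(float), amps, meta))
    return contours


def _read_raven(path: Path) -> list[WhistleContour]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RAVEN_COLUMNS if c not in df.columns]
    if missing:
        raise ContourError(f"{path}: Raven table missing columns {missing}")
    contours = []
    for _, row in df.iterrows():
        t0 = float(row["Begin Time (s)"]) * 1000.0
        t1 = float(row["End Time (s)"]) * 1000.0
        if t1 <= t0:
            raise ContourError(f"selection {row['Selection']}: End Time <= Begin Time")
        contours.append(
            WhistleContour(
                str(row["Selection"]),
                np.array([t0, t1]),
                np.array([float(row["Low Freq (Hz)"]), float(row["High Freq (Hz)"])]),
                meta={"source": "raven_selection"},
            )
        )
    return contours


def write_contours(contours: Iterable[WhistleContour], path: str | Path) -> None:
    """Write contours in the long CSV dialect (inverse of read_contours)."""
    rows = []
    for c in contours:
        for i in range(len(c)):
            row = {"whistle_id": c.whistle_id, "time_ms": c.times[i], "freq_hz": c.freqs[i]}
            if c.amps is not None:
                row["amp_db"] = c.amps[i]
            for key in ("ecotype", "group_id", "recording_id", "shape_class"):
                if key in c.meta:
                    row[key] = c.meta[key]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------


def apply_selection_rules(
    contours: Sequence[WhistleContour],
    rules: SelectionRules,
    snr: dict[str, float],
    onsets: dict[str, float] | None = None,
) -> tuple[list[WhistleContour], list[tuple[WhistleContour, str]]]:
    """Filter whistles by SNR, fundamental-frequency cap and inter-whistle gap.

    Returns (kept, rejected) where rejected entries carry a reason string:
    ``low_snr``, ``above_fmax`` or ``min_gap``.  The gap rule is applied per
    recording in onset order: a whistle beginning less than ``min_gap`` ms
    after the previous *kept* whistle's end is rejected.  ``onsets`` defaults
    to each contour's first time stamp.
    """
    kept: list[WhistleContour] = []
    rejected: list[tuple[WhistleContour, str]] = []
    last_end: dict[str, float] = {}

    def onset(c: WhistleContour) -> float:
        if onsets is not None and c.whistle_id in onsets:
            return onsets[c.whistle_id]
        return float(c.times[0])

    order = sorted(contours, key=lambda c: (str(c.meta.get("recording_id", "")), onset(c)))
    for c in order:
        rec = str(c.meta.get("recording_id", ""))
        if snr.get(c.whistle_id, math.inf) <= rules.min_snr:
            rejected.append((c, "low_snr"))
            continue
        if np.any(c.freqs >= rules.max_fundamental * 1000.0):
            rejected.append((c, "above_fmax"))
            continue
        start = onset(c)
        if rec in last_end and start - last_end[rec] < rules.min_gap:
            rejected.append((c, "min_gap"))
            continue
        kept.append(c)
        last_end[rec] = start + c.duration_ms
    return kept, rejected


# ---------------------------------------------------------------------------
# Ecotype comparison of acoustic parameters
# ---------------------------------------------------------------------------


def mann_whitney_by_ecotype(
    features: pd.DataFrame,
    params: Sequence[str] = FEATURE_NAMES,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    group_col: str = "ecotype",
) -> pd.DataFrame:
    """Mann–Whitney U test per acoustic parameter between the two ecotypes.

    Uses mid-ranks with tie correction (normal approximation); the exact null
    distribution is used when both groups have n <= 8 and no ties.  The
    Bonferroni adjustment multiplies each raw p by the number of parameters.
    Returns a DataFrame indexed by parameter with columns W, p_raw,
    p_adjusted, significant.
    """
    groups = sorted(features[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    a = features[features[group_col] == groups[0]]
    b = features[features[group_col] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    rows = {}
    for p in params:
        x, y = a[p].to_numpy(float), b[p].to_numpy(float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        p_adj = min(1.0, len(params) * float(res.pvalue))
        rows[p] = {
            "W": float(res.statistic),
            "p_raw": float(res.pvalue),
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    return pd.DataFrame(rows).T
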