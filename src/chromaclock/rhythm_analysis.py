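"""Actogram quantification: periodogram, phase markers, IS/IV, waveforms.

Implements the standard rhythm-analysis toolbox for binned activity count
series: the Sokolove-Bushell chi-square periodogram for period estimation,
activity-bout duration (alpha), activity onset/offset/midpoint phase markers
with jet-lag normalization, smoothed mean waveforms, the nonparametric
interdaily-stability (IS) and intradaily-variability (IV) statistics,
night-activity percentages, pairwise day-day correlations, and the exact
2x2 test used for paired categorical comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivityRecord",
    "DailyMatrix",
    "PeriodogramResult",
    "PhaseMarkerSeries",
    "RhythmMetrics",
    "chi_square_periodogram",
    "estimate_alpha",
    "detect_onset_offset",
    "phase_midpoint",
    "phase_marker_series",
    "normalize_phase_series",
    "mean_waveform",
    "smoothed_crossing_markers",
    "interdaily_stability",
    "intradaily_variability",
    "pct_activity_outside_night",
    "day_day_correlation",
    "fisher_exact_2x2",
    "analyze_paradigm",
]


@dataclass(frozen=True)
class ActivityRecord:
    """Uniformly binned activity counts.

    Attributes
    ----------
    start : pandas.Timestamp
        Timestamp of the first bin's left edge.
    bin_seconds : int
        Bin width in seconds (60 for wheel revolutions, 600 for PIR).
    counts : ndarray of int
        Non-negative counts per bin; gaps must be explicit (zero or masked),
        never missing rows.
    """

    start: pd.Timestamp
    bin_seconds: int
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_seconds <= 0:
            raise ValueError("bin width must be positive")
        object.__setattr__(self, "counts", c.astype(np.int64))
        object.__setattr__(self, "start", pd.Timestamp(self.start))

    @property
    def bins_per_day(self) -> int:
        bpd = 86400 / self.bin_seconds
        if bpd != int(bpd):
            raise ValueError("bin width must divide 24 h")
        return int(bpd)

    @property
    def duration_hours(self) -> float:
        return len(self.counts) * self.bin_seconds / 3600.0

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self.counts)) * self.bin_seconds, unit="s"
        )


@dataclass(frozen=True)
class DailyMatrix:
    """Day x bin matrix of activity counts (values X_i in the IS/IV formulas).

    Rows are consecutive days (D of them), columns the P bins per day.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("need a 2-D day x bin matrix")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_record(cls, record: ActivityRecord, offset_bins: int = 0) -> "DailyMatrix":
        """Fold a record into complete days, dropping the trailing remainder."""
        p = record.bins_per_day
        x = record.counts[offset_bins:]
        d = len(x) // p
        if d < 1:
            raise ValueError("record shorter than one day")
        return cls(x[: d * p].reshape(d, p))

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def bins_per_day(self) -> int:
        return self.values.shape[1]

    @property
    def column_means(self) -> np.ndarray:
        """Across-day mean per time-of-day bin (the X-bar_h series)."""
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())


# ---------------------------------------------------------------------------
# Periodogram and alpha
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    threshold: np.ndarray
    best_period_h: float | None
    significance_level: float

    @property
    def significant(self) -> np.ndarray:
        return self.qp > self.threshold


def _sokolove_bushell_qp(x: np.ndarray, period_bins: int) -> float:
    """Chi-square periodogram statistic at one candidate period.

    Folds the series into K complete cycles of ``period_bins`` columns and
    returns Qp = K * sum_h (Xbar_h - Xbar)^2 / (sum_i (X_i - Xbar)^2 / n),
    which is chi-square distributed with period_bins - 1 degrees of freedom
    for white noise and grows with the number of samples for a true rhythm.
    """
    k = len(x) // period_bins
    xs = x[: k * period_bins]
    folded = xs.reshape(k, period_bins)
    col = folded.mean(axis=0)
    grand = xs.mean()
    denom = np.sum((xs - grand) ** 2) / xs.size
    if denom == 0:
        raise ValueError("record has zero variance; periodogram undefined")
    return float(k * np.sum((col - grand) ** 2) / denom)


def chi_square_periodogram(
    record: ActivityRecord,
    period_range_h: tuple[float, float] = (20.0, 28.0),
    significance: float = 0.001,
) -> PeriodogramResult:
    """Chi-square periodogram over a grid of candidate periods.

    Candidate periods step by one data bin across ``period_range_h``. The
    best period is the candidate maximizing Qp among those exceeding the
    chi-square(bins-1) quantile at ``significance``; ties are broken toward
    the candidate whose Qp neighborhood mean is larger. Returns
    ``best_period_h=None`` when no candidate is significant.
    """
    x = record.counts.astype(float)
    bin_h = record.bin_seconds / 3600.0
    lo, hi = period_range_h
    if record.duration_hours < 2 * hi:
        raise ValueError(
            f"record ({record.duration_hours:.1f} h) shorter than two cycles "
            f"of the longest candidate period ({hi} h)"
        )
    if x.std() == 0:
        raise ValueError("record has zero variance; periodogram undefined")
    pb_lo = int(np.ceil(lo / bin_h))
    pb_hi = int(np.floor(hi / bin_h))
    period_bins = np.arange(pb_lo, pb_hi + 1)
    qp = np.array([_sokolove_bushell_qp(x, int(p)) for p in period_bins])
    thr = stats.chi2.ppf(1.0 - significance, period_bins - 1)
    periods_h = period_bins * bin_h

    best = None
    sig = qp > thr
    if sig.any():
        top = np.flatnonzero(sig & np.isclose(qp, qp[sig].max()))
        if len(top) > 1:
            # neighborhood-mean tie-break
            def hood(i):
                sl = slice(max(0, i - 2), min(len(qp), i + 3))
                return qp[sl].mean()
            top = sorted(top, key=hood, reverse=True)
        best = float(periods_h[top[0]])
    return PeriodogramResult(periods_h, qp, thr, best, significance)


def estimate_alpha(record: ActivityRecord, period_h: float) -> float:
    """Activity bout duration as a fraction of the circadian cycle.

    Folds the record at ``period_h`` and returns the fraction of
    folded-cycle bins whose mean activity exceeds the folded-cycle mean.
    """
    bin_h = record.bin_seconds / 3600.0
    pb = int(round(period_h / bin_h))
    if pb < 2:
        raise ValueError("period too short for the bin width")
    x = record.counts.astype(float)
    k = len(x) // pb
    if k < 1:
        raise ValueError("record shorter than one cycle")
    profile = x[: k * pb].reshape(k, pb).mean(axis=0)
    return float(np.mean(profile > profile.mean()))


# ---------------------------------------------------------------------------
# Phase markers
# ---------------------------------------------------------------------------


def detect_onset_offset(
    day_counts: np.ndarray,
    context_counts: np.ndarray,
    bin_seconds: int,
    onset_window_min: float = 30.0,
    offset_window_min: float = 90.0,
) -> tuple[float | None, float | None]:
    """Onset/offset of activity for one day by the 30/90-min window rule.

    Onset is the start of the first ``onset_window_min`` epoch in which
    every bin is strictly above the daily mean, scanning forward from the
    day's reference time (index 0); offset is the start of the first
    ``offset_window_min`` epoch after onset in which every bin is strictly
    below the daily mean. Windows may run into ``context_counts`` (the bins
    immediately following the day). Missing markers are returned as None,
    never fabricated.

    Returns (onset_hours, offset_hours) relative to the day's start.
    """
    day = np.asarray(day_counts, dtype=float)
    ext = np.concatenate([day, np.asarray(context_counts, dtype=float)])
    mean = day.mean()
    w_on = int(round(onset_window_min * 60 / bin_seconds))
    w_off = int(round(offset_window_min * 60 / bin_seconds))
    if w_on < 1 or w_off < 1:
        raise ValueError("window shorter than one bin")
    p = len(day)
    above = ext > mean
    below = ext < mean

    onset_idx = None
    for i in range(p):
        if i + w_on <= len(ext) and above[i : i + w_on].all():
            onset_idx = i
            break
    if onset_idx is None:
        return None, None
    offset_idx = None
    for j in range(onset_idx + 1, p + onset_idx + 1):
        if j + w_off <= len(ext) and below[j : j + w_off].all():
            offset_idx = j
            break
    to_h = bin_seconds / 3600.0
    return (
        onset_idx * to_h,
        None if offset_idx is None else offset_idx * to_h,
    )


def phase_midpoint(onset_h: float, offset_h: float) -> float:
    """Circular midpoint of onset and offset on a 24-h clock.

    Wraps correctly when the offset falls on the next day, e.g.
    midpoint(18, 6) = 0 (midnight).
    """
    span = (offset_h - onset_h) % 24.0
    return float((onset_h + span / 2.0) % 24.0)


@dataclass
class PhaseMarkerSeries:
    """Per-day phase markers, hours since each day's reference time.

    NaN encodes a day whose marker could not be determined.
    """

    onset_h: np.ndarray
    offset_h: np.ndarray
    midpoint_h: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.onset_h)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.midpoint_h).sum())


def phase_marker_series(
    record: ActivityRecord,
    offset_bins: int = 0,
    onset_window_min: float = 30.0,
    offset_window_min: float = 90.0,
) -> PhaseMarkerSeries:
    """Apply the 30/90-min onset/offset rule to every complete day.

    ``offset_bins`` shifts the day boundary (e.g. to anchor days at
    lights-off). The wrap-around context for each day is the following day's
    bins (empty for the final day).
    """
    p = record.bins_per_day
    x = record.counts[offset_bins:]
    d = len(x) // p
    on = np.full(d, np.nan)
    off = np.full(d, np.nan)
    mid = np.full(d, np.nan)
    for i in range(d):
        day = x[i * p : (i + 1) * p]
        ctx = x[(i + 1) * p : (i + 2) * p]
        o, f = detect_onset_offset(day, ctx, record.bin_seconds,
                                   onset_window_min, offset_window_min)
        if o is not None:
            on[i] = o
        if f is not None:
            off[i] = f
        if o is not None and f is not None:
            mid[i] = phase_midpoint(o % 24.0, f % 24.0)
    return PhaseMarkerSeries(on, off, mid)


def _unwrap_daily(marker_h: np.ndarray) -> np.ndarray:
    """Unwrap a circular (24-h) daily marker series into a continuous one."""
    out = marker_h.astype(float).copy()
    last = None
    for i in range(len(out)):
        if np.isnan(out[i]):
            continue
        if last is not None:
            k = np.round((last - out[i]) / 24.0)
            out[i] += 24.0 * k
            # keep successive steps within half a cycle
            while out[i] - last > 12.0:
                out[i] -= 24.0
            while out[i] - last < -12.0:
                out[i] += 24.0
        last = out[i]
    return out


def normalize_phase_series(
    marker_h: np.ndarray, shift_day: int, pre_days: int = 5
) -> np.ndarray:
    """Phase-shift curve: markers minus their mean over the 5 pre-shift days.

    ``shift_day`` indexes the first day after the schedule shift; the
    baseline is the mean of days ``shift_day - pre_days .. shift_day - 1``
    (missing days excluded). The marker series is unwrapped on the 24-h
    circle first, so a shift past midnight does not alias.
    """
    if shift_day < pre_days:
        raise ValueError("not enough pre-shift days to form a baseline")
    unwrapped = _unwrap_daily(np.asarray(marker_h, dtype=float))
    base = np.nanmean(unwrapped[shift_day - pre_days : shift_day])
    return unwrapped - base


# ---------------------------------------------------------------------------
# Waveforms and nonparametric statistics
# ---------------------------------------------------------------------------


def _circular_running_mean(x: np.ndarray, window_bins: int) -> np.ndarray:
    kernel = np.ones(window_bins) / window_bins
    n = len(x)
    ext = np.concatenate([x[-window_bins:], x, x[:window_bins]])
    sm = np.convolve(ext, kernel, mode="same")
    return sm[window_bins : window_bins + n]


def mean_waveform(
    matrix: DailyMatrix, bin_seconds: int, smooth_h: float = 2.0
) -> np.ndarray:
    """Normalized mean daily activity waveform.

    Each day is smoothed by a centered circular running mean of width
    ``smooth_h``; days are averaged, the daily mean subtracted, and the
    result divided by its maximum, so the returned waveform peaks at exactly
    1. A zero-variance (flat) mean profile has no defined normalization and
    raises ``ValueError``.
    """
    w = int(round(smooth_h * 3600 / bin_seconds))
    sm = np.array([_circular_running_mean(row, w) for row in matrix.values])
    avg = sm.mean(axis=0)
    centered = avg - avg.mean()
    peak = centered.max()
    if peak <= 0:
        raise ValueError("flat mean waveform; normalization undefined")
    return centered / peak


def smoothed_crossing_markers(waveform: np.ndarray, bin_seconds: int
                              ) -> tuple[float | None, float | None]:
    """Onset/offset as mean crossings of a smoothed daily waveform.

    The waveform is expected mean-centered (as from :func:`mean_waveform`);
    onset is the first upward zero crossing, offset the first downward
    crossing after it, both in hours. Crossings are located at the first bin
    on the new side of the mean. Returns None for markers that do not exist
    (e.g. a waveform that never crosses its mean).
    """
    x = np.asarray(waveform, dtype=float)
    n = len(x)
    up = [i for i in range(n) if x[i - 1] <= 0 < x[i]]
    if not up:
        return None, None
    onset = up[0]
    down = [i for i in range(n) if x[i - 1] > 0 >= x[i]]
    to_h = bin_seconds / 3600.0
    after = [i for i in down if i > onset]
    offset = after[0] if after else (down[0] if down else None)
    return onset * to_h, None if offset is None else offset * to_h


def interdaily_stability(matrix: DailyMatrix) -> float:
    """Interdaily stability (IS).

    IS = [n * sum_h (Xbar_h - Xbar)^2] / [p * sum_i (X_i - Xbar)^2], with n
    the total number of samples and p the bins per day. IS is the fraction
    of variance explained by the mean 24-h profile: 1 for perfectly
    repeating (non-constant) days, ~1/D for white noise over D days.
    """
    x = matrix.values
    n = x.size
    p = matrix.bins_per_day
    grand = x.mean()
    ss_tot = np.sum((x - grand) ** 2)
    if ss_tot == 0:
        raise ValueError("zero total variance; IS undefined")
    ss_pattern = np.sum((matrix.column_means - grand) ** 2)
    return float(n * ss_pattern / (p * ss_tot))


def intradaily_variability(series: np.ndarray) -> float:
    """Intradaily variability (IV): normalized mean-square successive difference.

    IV = [n * sum_{i=2..n} (X_i - X_{i-1})^2] / [(n-1) * sum_i (X_i - Xbar)^2].
    IV is ~2 for white noise, 4 for a strictly alternating series, and near 0
    for a slow smooth rhythm sampled finely. Invariant under affine
    transforms of the series.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    ss_tot = np.sum((x - x.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero variance; IV undefined")
    ss_diff = np.sum(np.diff(x) ** 2)
    return float(n * ss_diff / ((n - 1) * ss_tot))


def pct_activity_outside_night(
    matrix: DailyMatrix, night_start_bin: int, night_bins: int
) -> float:
    """Percent of total activity falling outside the night window.

    The night window is ``night_bins`` bins starting at ``night_start_bin``
    (time-of-day index, wrapping past midnight). For an 8-h night this is
    the rhythm-amplitude measure: 0% when all activity is nocturnal and
    100 * 16/24 = 66.7% for activity uniform in time.
    """
    p = matrix.bins_per_day
    idx = (night_start_bin + np.arange(night_bins)) % p
    night_mask = np.zeros(p, dtype=bool)
    night_mask[idx] = True
    total = matrix.values.sum()
    if total == 0:
        raise ValueError("no activity; percentage undefined")
    outside = matrix.values[:, ~night_mask].sum()
    return float(100.0 * outside / total)


def day_day_correlation(matrix: DailyMatrix) -> tuple[float, int, int]:
    """Mean Pearson r over every unordered pair of days.

    Pairs involving a zero-variance day are excluded (their r is undefined)
    and counted. Returns (mean_r, n_pairs_used, n_pairs_excluded).
    """
    x = matrix.values
    d = x.shape[0]
    if d < 2:
        raise ValueError("need at least two days")
    stds = x.std(axis=1)
    rs = []
    excluded = 0
    for i in range(d):
        for j in range(i + 1, d):
            if stds[i] == 0 or stds[j] == 0:
                excluded += 1
                continue
            rs.append(np.corrcoef(x[i], x[j])[0, 1])
    if not rs:
        raise ValueError("all day pairs degenerate")
    return float(np.mean(rs)), len(rs), excluded


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The two-sided p is the sum of probabilities of all tables (with the
    observed margins) whose point hypergeometric probability does not exceed
    the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Paradigm-level analysis
# ---------------------------------------------------------------------------


@dataclass
class RhythmMetrics:
    """The metric set quantifying rhythm robustness and stability."""

    interdaily_stability: float
    intradaily_variability: float
    pct_outside_night: float
    mean_day_day_r: float
    n_pairs: int
    alpha: float | None = None
    period_h: float | None = None

    def as_dict(self) -> dict:
        return {
            "IS": self.interdaily_stability,
            "IV": self.intradaily_variability,
            "pct_outside_night": self.pct_outside_night,
            "mean_day_day_r": self.mean_day_day_r,
            "n_pairs": self.n_pairs,
            "alpha": self.alpha,
            "period_h": self.period_h,
        }


def _select_label_days(record: ActivityRecord, timeline, prefix: str,
                       last_hours: float | None) -> np.ndarray:
    """Stack analysis days (rows) for every timeline block matching prefix.

    ``last_hours`` keeps only that trailing portion of each block (e.g. the
    last 48 h of each 3-day block); None keeps the whole block.
    """
    p = record.bins_per_day
    step = timeline.step_min
    bins_per_tl_sample = record.bin_seconds / 60.0 / step
    labels = timeline.labels
    days = []
    i = 0
    n = len(labels)
    while i < n:
        lab = labels[i]
        j = i
        while j < n and labels[j] == lab:
            j += 1
        if str(lab).startswith(prefix):
            t_start = timeline.time_min[i]
            t_end = timeline.time_min[j - 1] + step
            if last_hours is not None:
                t_start = max(t_start, t_end - last_hours * 60.0)
            b0 = int(round(t_start * 60.0 / record.bin_seconds))
            b1 = int(round(t_end * 60.0 / record.bin_seconds))
            nbins = b1 - b0
            ndays = nbins // p
            for d in range(ndays):
                seg = record.counts[b0 + d * p : b0 + (d + 1) * p]
                if len(seg) == p:
                    days.append(seg)
        i = j
    if not days:
        raise ValueError(f"no complete days labelled {prefix!r}*")
    return np.asarray(days, dtype=float)


def analyze_paradigm(
    record: ActivityRecord,
    timeline,
    conditions: dict[str, dict] | None = None,
    night_start_hour: float = 20.0,
    night_hours: float = 8.0,
) -> dict[str, RhythmMetrics]:
    """Per-condition rhythm metrics for the natural-entrainment paradigm.

    For each condition a set of analysis days is selected from the schedule
    labels: by default the last 48 h of every ``natural``/``intensity_only``
    block (diurnal days) and the full 24-h ``dim`` constant-routine epochs
    that follow each block (circadian days). The full metric set is computed
    on the stacked day x bin matrix of each condition.

    ``night_start_hour``/``night_hours`` place the (projected) night window
    used for the percent-outside-night measure, in schedule time-of-day.
    """
    if record.bin_seconds % int(timeline.step_min * 60) and \
            int(timeline.step_min * 60) % record.bin_seconds:
        raise ValueError("record bins and schedule grid are incommensurate")
    if conditions is None:
        conditions = {
            "natural": {"prefix": "natural_", "last_hours": 48.0},
            "natural_cr": {"prefix": "dim_natural_", "last_hours": None},
            "intensity_only": {"prefix": "intensity_only_", "last_hours": 48.0},
            "intensity_only_cr": {"prefix": "dim_intensity_only_",
                                  "last_hours": None},
        }
    p = record.bins_per_day
    night_start_bin = int(round(night_start_hour * 3600 / record.bin_seconds)) % p
    night_bins = int(round(night_hours * 3600 / record.bin_seconds))
    out = {}
    for name, sel in conditions.items():
        days = _select_label_days(record, timeline, sel["prefix"],
                                  sel["last_hours"])
        m = DailyMatrix(days)
        mean_r, n_pairs, _ = day_day_correlation(m)
        out[name] = RhythmMetrics(
            interdaily_stability=interdaily_stability(m),
            intradaily_variability=intradaily_variability(m.values.ravel()),
            pct_outside_night=pct_activity_outside_night(
                m, night_start_bin, night_bins),
            mean_day_day_r=mean_r,
            n_pairs=n_pairs,
        )
    return out
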