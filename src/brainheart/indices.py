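"""Derivation of the five neuromonitoring indices at 1-min resolution.

* ICP / mean ABP — 60-s waveform time integration (see ``signal_io``).
* CPP — mean ABP minus ICP, minute-wise.
* PRx — pressure reactivity index: moving Pearson correlation between 10-s
  averages of ABP and ICP over 5-min windows updated every 10 s; positive
  values indicate impaired cerebrovascular reactivity.
* BRS — baroreflex sensitivity by the sequential cross-correlation (xBRS)
  method: 10-s segments of 1-s-resampled systolic pressure and interbeat
  interval, correlated at candidate delays 0-5 s; the regression slope
  (ms/mmHg) at the best positive, significant delay is recorded.
* LF/HF — ratio of low-frequency (0.04-0.15 Hz) to high-frequency
  (0.15-0.40 Hz) heart-rate-variability power from the Lomb-Scargle
  periodogram of the unevenly sampled interbeat-interval series.

Beats are taken from ABP pulse peaks; pulse-interval variability stands in
for ECG R-R variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats

from .types import MinuteSeries, WaveformSignal

__all__ = [
    "BeatSeries",
    "detect_systolic_peaks",
    "compute_cpp",
    "compute_prx",
    "compute_brs",
    "compute_lfhf",
    "ten_second_means",
]

#: Plausibility band for interbeat intervals (ms); out-of-band beats flagged.
IBI_BAND_MS = (250.0, 2000.0)

#: Floor on integrated HF power below which the LF/HF ratio is unstable.
HF_POWER_FLOOR = 1e-12


@dataclass
class BeatSeries:
    """Beat-wise systolic peaks: times (s), SBP (mmHg) and IBI (ms)."""

    peak_times: np.ndarray
    sbp: np.ndarray
    ibi: np.ndarray        # ibi[i] = interval ending at peak i+1 (ms); len = n-1
    valid: np.ndarray      # per-interval plausibility flag

    def __post_init__(self) -> None:
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")


def detect_systolic_peaks(abp: WaveformSignal) -> BeatSeries:
    """Locate one systolic peak per cardiac cycle on the ABP waveform.

    Local maxima exceeding an adaptive (percentile-spread) prominence
    threshold, with a 250-ms refractory period. Intervals outside the
    plausibility band are flagged, not dropped.
    """
    if abp.fs < 50:
        raise ValueError("fs must be >= 50 Hz for beat detection")
    x = abp.samples
    finite = np.isfinite(x)
    xw = np.where(finite, x, np.nanmedian(x[finite]) if finite.any() else 0.0)
    lo, hi = np.percentile(xw, [5, 95])
    spread = hi - lo
    if spread <= 1e-6:
        raise ValueError("fewer than 2 peaks detected (flat signal)")
    peaks, _ = sps.find_peaks(
        xw, distance=max(1, int(round(0.25 * abp.fs))), prominence=0.3 * spread
    )
    peaks = peaks[finite[peaks]]
    if peaks.size < 2:
        raise ValueError("fewer than 2 peaks detected")
    times = abp.t0 + peaks / abp.fs
    sbp = x[peaks]
    ibi = np.diff(times) * 1000.0
    valid = (ibi >= IBI_BAND_MS[0]) & (ibi <= IBI_BAND_MS[1])
    valid &= np.isfinite(sbp[:-1]) & np.isfinite(sbp[1:])
    return BeatSeries(times, sbp, ibi, valid)


def compute_cpp(abp_min: MinuteSeries, icp_min: MinuteSeries) -> MinuteSeries:
    """CPP[m] = mean ABP[m] - ICP[m]; missing where either input is."""
    if len(abp_min) != len(icp_min) or abp_min.start_min != icp_min.start_min:
        raise ValueError("ABP and ICP minute series must be aligned")
    values = abp_min.values - icp_min.values
    missing = abp_min.missing | icp_min.missing
    return MinuteSeries(values, start_min=abp_min.start_min, missing=missing)


def ten_second_means(signal: WaveformSignal, invalid_frac: float = 0.25):
    """10-s averages isolating the slow waves; returns (values, missing)."""
    x = signal.samples
    spb = int(round(signal.fs * 10))
    if spb < 1:
        raise ValueError("fs too low for 10-s averaging")
    n_bins = x.size // spb
    seg = x[: n_bins * spb].reshape(n_bins, spb)
    finite = np.isfinite(seg)
    n_valid = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vals = np.where(n_valid > 0, np.nansum(np.where(finite, seg, 0.0), axis=1), np.nan)
        vals = vals / np.where(n_valid > 0, n_valid, 1)
    missing = (spb - n_valid) > invalid_frac * spb
    vals[missing] = np.nan
    return vals, missing


def prx_updates(
    abp: WaveformSignal,
    icp: WaveformSignal,
    window_s: int = 300,
    update_s: int = 10,
    min_pair_frac: float = 0.5,
) -> np.ndarray:
    """Per-update PRx: Pearson correlation of the 30 most recent 10-s
    ABP/ICP mean pairs (a 5-min window), one value per 10-s step.

    Entry ``i`` is the correlation of the window ending at bin ``i``; the
    first ``window_s/update_s - 1`` entries and windows with too few valid
    pairs or zero variance in either channel are NaN (undefined, never 0).
    """
    if abp.samples.size / abp.fs < window_s or icp.samples.size / icp.fs < window_s:
        raise ValueError("need at least 5 min of overlapping ABP and ICP")
    a, a_miss = ten_second_means(abp)
    b, b_miss = ten_second_means(icp)
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    pair_valid = ~(a_miss[:n] | b_miss[:n])
    w = window_s // update_s  # 30 pairs per window
    per_update = np.full(n, np.nan)
    for end in range(w - 1, n):
        sl = slice(end - w + 1, end + 1)
        v = pair_valid[sl]
        if v.sum() < min_pair_frac * w:
            continue
        x, y = a[sl][v], b[sl][v]
        sx, sy = x.std(), y.std()
        if sx <= 1e-12 or sy <= 1e-12:
            continue
        per_update[end] = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return per_update


def compute_prx(
    abp: WaveformSignal,
    icp: WaveformSignal,
    window_s: int = 300,
    update_s: int = 10,
    min_pair_frac: float = 0.5,
) -> MinuteSeries:
    """Pressure reactivity index at 1-min resolution.

    The minute value averages the six 10-s-updated window correlations
    ending inside that minute (see :func:`prx_updates`); missing when none
    of them is defined.
    """
    per_update = prx_updates(abp, icp, window_s, update_s, min_pair_frac)
    updates_per_min = 60 // update_s
    n_min = per_update.size // updates_per_min
    vals = np.full(n_min, np.nan)
    for m in range(n_min):
        seg = per_update[m * updates_per_min:(m + 1) * updates_per_min]
        if np.isfinite(seg).any():
            vals[m] = np.nanmean(seg)
    start_min = int(min(abp.t0, icp.t0) // 60)
    return MinuteSeries(vals, start_min=start_min)


def _nearest(grid: np.ndarray, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(t, grid), 1, t.size - 1)
    left = idx - 1
    take_left = (grid - t[left]) < (t[idx] - grid)
    return v[np.where(take_left, left, idx)]


def _resample_1s(beats: BeatSeries) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beat-wise SBP and IBI sampled onto a 1-s grid (nearest beat).

    Nearest-beat sampling (rather than interpolation) keeps grid samples
    statistically independent when beats are independent, so the segment
    significance test stays calibrated.
    """
    # IBI i is attributed to the time of the closing peak i+1
    t_ibi = beats.peak_times[1:]
    ok = beats.valid
    if ok.sum() < 3:
        raise ValueError("too few plausible beats")
    grid = np.arange(np.ceil(beats.peak_times[0]), np.floor(beats.peak_times[-1]) + 1)
    sbp = _nearest(grid, beats.peak_times, beats.sbp)
    ibi = _nearest(grid, t_ibi[ok], beats.ibi[ok])
    return grid, sbp, ibi


def xbrs_segments(
    beats: BeatSeries,
    delays_s: Tuple[int, ...] = (0, 1, 2, 3, 4, 5),
    segment_s: int = 10,
    alpha: float = 0.01,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment xBRS estimates.

    Returns ``(seg_start_s, best_delay_s, slope_ms_per_mmHg, accepted)`` for
    the consecutive 10-s segments of the 1-s-resampled SBP/IBI series. Per
    segment, the candidate delay with the highest correlation wins; it is
    accepted only when the correlation is positive and significant. The
    per-delay threshold is Sidak-adjusted so that the family-wise acceptance
    rate across the delay candidates equals ``alpha`` under an
    independence null.
    """
    if beats.peak_times[-1] - beats.peak_times[0] < segment_s:
        raise ValueError("need at least 10 s of beats")
    grid, sbp, ibi = _resample_1s(beats)
    n = segment_s
    dof = n - 2
    alpha_per = 1.0 - (1.0 - alpha) ** (1.0 / len(delays_s))
    t_crit = stats.t.ppf(1.0 - alpha_per, dof)  # one-sided, positive slopes only
    r_crit = t_crit / np.sqrt(dof + t_crit**2)

    max_delay = max(delays_s)
    n_seg = (grid.size - max_delay) // segment_s
    seg_start = grid[np.arange(n_seg) * segment_s]
    seg_delay = np.full(n_seg, np.nan)
    seg_slope = np.full(n_seg, np.nan)
    accepted = np.zeros(n_seg, dtype=bool)
    for s in range(n_seg):
        lo = s * segment_s
        x = sbp[lo:lo + n]
        if x.std() <= 1e-9:
            continue
        best_r, best_d = -np.inf, None
        for d in delays_s:
            y = ibi[lo + d:lo + d + n]
            sy = y.std()
            if sy <= 1e-12:
                continue
            r = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * sy)
            if r > best_r:
                best_r, best_d = r, d
        if best_d is None or best_r <= r_crit:
            continue
        y = ibi[lo + best_d:lo + best_d + n]
        seg_delay[s] = best_d
        seg_slope[s] = best_r * y.std() / x.std()  # ms/mmHg, positive by construction
        accepted[s] = True
    return seg_start, seg_delay, seg_slope, accepted


def compute_brs(
    beats: BeatSeries,
    delays_s: Tuple[int, ...] = (0, 1, 2, 3, 4, 5),
    segment_s: int = 10,
    alpha: float = 0.01,
) -> MinuteSeries:
    """Baroreflex sensitivity (ms/mmHg) by sequential cross-correlation.

    Minute value = mean of the accepted 10-s segment slopes starting in
    that minute (see :func:`xbrs_segments`); missing when none accepted.
    The physiological gain is reported as a positive slope: higher systolic
    pressure lengthening the interbeat interval.
    """
    seg_start, _, seg_slope, accepted = xbrs_segments(
        beats, delays_s=delays_s, segment_s=segment_s, alpha=alpha
    )
    seg_minute = (seg_start // 60).astype(int)
    n_min = int(seg_minute.max()) + 1 if seg_minute.size else 0
    vals = np.full(n_min, np.nan)
    for m in range(n_min):
        sel = (seg_minute == m) & accepted
        if sel.any():
            vals[m] = seg_slope[sel].mean()
    return MinuteSeries(vals, start_min=0)


def lomb_scargle_band_power(
    t: np.ndarray, y: np.ndarray, band: Tuple[float, float],
    df: float = 0.002,
) -> float:
    """Integrated Lomb-Scargle power over a frequency band (Hz)."""
    freqs = np.arange(band[0], band[1] + df / 2, df)
    pgram = sps.lombscargle(t, y - y.mean(), 2 * np.pi * freqs)
    return float(np.trapezoid(pgram, freqs))


def compute_lfhf(
    beats: BeatSeries,
    window_min: int = 5,
    step_min: int = 1,
    lf_band: Tuple[float, float] = (0.04, 0.15),
    hf_band: Tuple[float, float] = (0.15, 0.40),
    min_beat_frac: float = 0.5,
) -> MinuteSeries:
    """LF/HF heart-rate-variability ratio on a 1-min grid.

    Windows are right-aligned (causal): the value for minute ``m`` uses the
    ``window_min`` minutes ending at the close of minute ``m``. Per window
    the Lomb-Scargle periodogram of the unevenly sampled IBI series is
    integrated over the LF and HF bands. Windows with fewer than
    ``min_beat_frac`` of the expected beats, or with HF power below the
    stability floor, are missing.
    """
    if window_min < 2:
        raise ValueError("window must be >= 2 min")
    t_ibi = beats.peak_times[1:][beats.valid]
    ibi = beats.ibi[beats.valid]
    if ibi.size < 4:
        raise ValueError("too few plausible beats")
    med_ibi_s = np.median(ibi) / 1000.0
    expected = window_min * 60.0 / med_ibi_s

    n_min = int(beats.peak_times[-1] // 60) + 1
    vals = np.full(n_min, np.nan)
    for m in range(window_min - 1, n_min, step_min):
        t_hi = (m + 1) * 60.0
        t_lo = t_hi - window_min * 60.0
        sel = (t_ibi >= t_lo) & (t_ibi < t_hi)
        if sel.sum() < min_beat_frac * expected:
            continue
        tt, yy = t_ibi[sel], ibi[sel]
        lf = lomb_scargle_band_power(tt, yy, lf_band)
        hf = lomb_scargle_band_power(tt, yy, hf_band)
        if hf <= HF_POWER_FLOOR:
            continue
        vals[m] = lf / hf
    return MinuteSeries(vals, start_min=0)
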