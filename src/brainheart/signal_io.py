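"""Waveform/panel I/O and the 60-s waveform time integration.

Minute values are trapezoidal time integrals over half-open minute bins
[m, m+1), divided by the covered time span, which makes the value exact for
constant signals and second-order accurate (O(1/fs^2)) for band-limited ones
regardless of the recorder's sampling rate. Missingness is an explicit
boolean mask throughout.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping, Tuple

import h5py
import numpy as np
import pandas as pd

from .types import MAX_MINUTES, MinutePanel, MinuteSeries, PANEL_INDICES, PatientRecord, WaveformSignal

__all__ = [
    "integrate_60s",
    "crop_align",
    "write_waveforms_h5",
    "read_waveforms_h5",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_panel_csv",
    "read_panel_csv",
    "write_metadata_csv",
    "read_metadata_csv",
]


def integrate_60s(signal: WaveformSignal, invalid_frac: float = 0.25) -> MinuteSeries:
    """Waveform time integration over 60-s intervals.

    For minute ``m`` the value is the trapezoidal integral of the waveform
    over [m, m+1) min divided by the integrated span. The sample at the next
    minute boundary, when present, closes the integral so that a full minute
    spans exactly 60 s. A minute whose fraction of invalid (non-finite)
    samples exceeds ``invalid_frac`` is flagged missing. An all-invalid
    signal yields an all-missing series (not an error).
    """
    x = signal.samples
    if x.size == 0:
        raise ValueError("empty signal")
    fs = signal.fs
    spm = fs * 60.0  # samples per minute
    if spm < 1:
        raise ValueError("fs too low: less than one sample per minute")
    n_min = int(np.ceil(x.size / spm))
    values = np.full(n_min, np.nan)
    missing = np.ones(n_min, dtype=bool)
    finite = np.isfinite(x)
    t = np.arange(x.size) / fs
    for m in range(n_min):
        lo = int(round(m * spm))
        hi = min(int(round((m + 1) * spm)), x.size - 1)  # inclusive right edge
        if hi <= lo:
            continue
        seg = slice(lo, hi + 1)
        f = finite[seg]
        n_interior = hi - lo  # boundary sample belongs to the next minute
        if (~finite[lo:hi]).sum() > invalid_frac * n_interior:
            continue
        xs, ts = x[seg][f], t[seg][f]
        if xs.size < 2:
            continue
        span = ts[-1] - ts[0]
        if span <= 0:
            continue
        values[m] = np.trapezoid(xs, ts) / span
        missing[m] = False
    start_min = int(signal.t0 // 60)
    return MinuteSeries(values, start_min=start_min, missing=missing)


def crop_align(
    series: Mapping[str, MinuteSeries],
    patient_id: str = "",
    length: int = MAX_MINUTES,
) -> MinutePanel:
    """Trim/pad named minute series to a common [0, length) grid from onset.

    Series starting late are padded with missing minutes; samples beyond the
    window are discarded. A series with zero overlap with the window is an
    error naming the offending series.
    """
    aligned: Dict[str, MinuteSeries] = {}
    bad = [
        name for name, s in series.items()
        if s.start_min >= length or s.start_min + len(s) <= 0
    ]
    if bad:
        raise ValueError(
            f"series with no overlap with the first {length} min: {sorted(bad)}"
        )
    for name, s in series.items():
        values = np.full(length, np.nan)
        missing = np.ones(length, dtype=bool)
        src_lo = max(0, -s.start_min)
        dst_lo = max(0, s.start_min)
        n = min(len(s) - src_lo, length - dst_lo)
        values[dst_lo:dst_lo + n] = s.values[src_lo:src_lo + n]
        missing[dst_lo:dst_lo + n] = s.missing[src_lo:src_lo + n]
        aligned[name] = MinuteSeries(values, start_min=0, missing=missing)
    return MinutePanel(patient_id=patient_id, series=aligned)


# ----------------------------------------------------------------------------
# HDF5 waveform layout: datasets /abp and /icp, attributes fs and t0
# ----------------------------------------------------------------------------

def write_waveforms_h5(path, abp: WaveformSignal, icp: WaveformSignal) -> None:
    with h5py.File(path, "w") as f:
        for name, sig in (("abp", abp), ("icp", icp)):
            d = f.create_dataset(name, data=sig.samples)
            d.attrs["fs"] = sig.fs
            d.attrs["t0"] = sig.t0


def read_waveforms_h5(path) -> Tuple[WaveformSignal, WaveformSignal]:
    out = []
    with h5py.File(path, "r") as f:
        for name, label in (("abp", "ABP"), ("icp", "ICP")):
            if name not in f:
                raise ValueError(f"missing dataset '/{name}' in {path}")
            d = f[name]
            if "fs" not in d.attrs:
                raise ValueError(f"dataset '/{name}' lacks required attribute 'fs'")
            out.append(
                WaveformSignal(
                    d[()], fs=float(d.attrs["fs"]),
                    t0=float(d.attrs.get("t0", 0.0)), label=label,
                )
            )
    return out[0], out[1]


def write_waveform_csv(path, sig: WaveformSignal) -> None:
    df = pd.DataFrame({"time_s": sig.times(), "value": sig.samples})
    df.to_csv(path, index=False)


def read_waveform_csv(path, label: str = "") -> WaveformSignal:
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError("waveform CSV needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("waveform CSV must be uniformly sampled")
    return WaveformSignal(df["value"].to_numpy(float), fs=1.0 / dt[0], t0=t[0], label=label)


# ----------------------------------------------------------------------------
# minute-panel CSV layout: time_min, icp, cpp, prx, brs, lfhf
# ----------------------------------------------------------------------------

def write_panel_csv(path, panel: MinutePanel) -> None:
    panel.to_frame().to_csv(path, index=False)


def read_panel_csv(path, patient_id: str = "") -> MinutePanel:
    df = pd.read_csv(path)
    required = ("time_min",) + PANEL_INDICES
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    start = int(df["time_min"].iloc[0])
    series = {
        name: MinuteSeries(df[name].to_numpy(float), start_min=start)
        for name in PANEL_INDICES
    }
    return MinutePanel(patient_id=patient_id, series=series)


# ----------------------------------------------------------------------------
# metadata CSV layout
# ----------------------------------------------------------------------------

_META_COLS = (
    "patient_id", "age", "gcs", "pupils", "extracranial",
    "outcome_short", "outcome_long",
)


def write_metadata_csv(path, records: Iterable[PatientRecord]) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "age": r.age,
            "gcs": r.gcs,
            "pupils": r.pupils,
            "extracranial": None if r.extracranial_injury is None else int(r.extracranial_injury),
            "outcome_short": r.outcome_short,
            "outcome_long": r.outcome_long,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, index=False)


def read_metadata_csv(path) -> list:
    # keep the outcome sentinel "NA" as a string; only empty cells are missing
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age=None if pd.isna(row["age"]) else float(row["age"]),
                gcs=None if pd.isna(row["gcs"]) else int(row["gcs"]),
                pupils=None if pd.isna(row["pupils"]) else str(row["pupils"]),
                extracranial_injury=(
                    None if pd.isna(row["extracranial"]) else bool(int(row["extracranial"]))
                ),
                outcome_short=str(row["outcome_short"]),
                outcome_long=str(row["outcome_long"]),
            )
        )
    return records
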