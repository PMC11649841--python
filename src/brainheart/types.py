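"""Core data containers shared across the pipeline.

All physiological series live in one of two representations:

* :class:`WaveformSignal` — a uniformly sampled pressure waveform (mmHg) at
  50 Hz or more, used for beat detection and 10-s slow-wave averaging.
* :class:`MinuteSeries` / :class:`MinutePanel` — 1-min-resolution index series
  with an explicit boolean missingness mask (never NaN sentinels in the mask
  path; downstream correlation windows need exact missing counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

#: Length of the monitoring episode analysed per patient: the first 72 h.
MAX_MINUTES = 72 * 60

PANEL_INDICES = ("icp", "cpp", "prx", "brs", "lfhf")

OUTCOME_FAV = "fav"
OUTCOME_UNFAV = "unfav"
OUTCOME_NA = "NA"

PUPIL_CATEGORIES = ("bilateral", "unilateral", "nonreactive")


@dataclass
class WaveformSignal:
    """Uniformly sampled pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Pressure in mmHg. Non-finite samples mark artefacts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Start time in seconds from monitoring onset.
    label : str
        Channel name, conventionally ``"ABP"`` or ``"ICP"``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from monitoring onset."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class MinuteSeries:
    """A 1-min-resolution index series with explicit missingness."""

    values: np.ndarray
    start_min: int = 0
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask shape mismatch")
            self.missing = self.missing | ~np.isfinite(self.values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_valid(self) -> int:
        return int((~self.missing).sum())

    def masked(self) -> np.ndarray:
        """Values with missing entries replaced by NaN."""
        out = self.values.copy()
        out[self.missing] = np.nan
        return out


@dataclass
class MinutePanel:
    """Aligned 1-min panel of the five neuromonitoring indices (<= 72 h)."""

    patient_id: str
    series: Dict[str, MinuteSeries]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.series.values()}
        starts = {s.start_min for s in self.series.values()}
        if len(lengths) > 1 or len(starts) > 1:
            raise ValueError("panel series must share start and length")
        if self.length > MAX_MINUTES:
            raise ValueError(f"panel longer than {MAX_MINUTES} min")

    @property
    def length(self) -> int:
        return len(next(iter(self.series.values())))

    def __getitem__(self, name: str) -> MinuteSeries:
        return self.series[name]

    def to_frame(self):
        """Panel as a pandas DataFrame (missing -> NaN), column ``time_min``."""
        import pandas as pd

        start = next(iter(self.series.values())).start_min
        data = {"time_min": start + np.arange(self.length)}
        for name, s in self.series.items():
            data[name] = s.masked()
        return pd.DataFrame(data)


@dataclass
class PatientRecord:
    """Clinical metadata plus dichotomized outcome labels.

    The four covariates mirror the CRASH prognostic model: age, GCS,
    pupil reactivity and major extracranial injury. ``None`` marks a
    missing covariate (such patients are dropped by the tabular stage).
    """

    patient_id: str
    age: Optional[float] = None
    gcs: Optional[int] = None
    pupils: Optional[str] = None
    extracranial_injury: Optional[bool] = None
    outcome_short: str = OUTCOME_NA
    outcome_long: str = OUTCOME_NA

    def __post_init__(self) -> None:
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise ValueError("GCS must be in [3, 15]")
        if self.pupils is not None and self.pupils not in PUPIL_CATEGORIES:
            raise ValueError(f"pupils must be one of {PUPIL_CATEGORIES}")
        for attr in ("outcome_short", "outcome_long"):
            v = getattr(self, attr)
            if v not in (OUTCOME_FAV, OUTCOME_UNFAV, OUTCOME_NA):
                raise ValueError(f"{attr} must be fav/unfav/NA, got {v!r}")
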