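"""Synthetic coupled brain-heart signal generator.

Emulates the acute-phase monitoring setting: an arterial blood pressure (ABP)
beat train whose interbeat intervals respond to systolic pressure through a
baroreflex with known gain, an intracranial pressure (ICP) signal carrying
slow (B-wave band) oscillations with a controllable pressure-reactivity
polarity, and a planted ICP -> autonomic coupling in which the low-frequency
heart-rate-variability envelope follows the ICP slow trend at a known lag.

Every generated quantity has a ground truth stored in
:class:`SimPatientParams`, so the derived indices (PRx, BRS, LF/HF), the
windowed lagged-correlation stage and the end-to-end classifier all have a
parameter-recovery oracle.

Two fidelity levels exist:

* ``waveform`` — full pressure waveforms at >= 50 Hz; used to validate beat
  detection and index derivation on short (<= 2 h) snippets.
* ``minute``  — 1-min index panels emitted directly with the same statistical
  structure the waveform path yields after derivation; used for cohort-scale
  experiments where 72 h at 200 Hz would be prohibitive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Tuple, Union

import numpy as np

from .types import (
    MinutePanel,
    MinuteSeries,
    OUTCOME_FAV,
    OUTCOME_UNFAV,
    PatientRecord,
    WaveformSignal,
)

__all__ = [
    "SimPatientParams",
    "SimCohortSpec",
    "simulate_waveforms",
    "simulate_beat_series",
    "simulate_minute_panel",
    "simulate_cohort",
]

#: Hard cap on samples per simulated channel (72 h at 200 Hz is ~5.2e7).
DEFAULT_SAMPLE_BUDGET = 60_000_000

_MINUTE_BAND_CPM = (0.3, 0.5)   # representable sub-band on a 1-min grid
_WAVEFORM_BAND_CPM = (0.3, 3.0)  # full B-wave band


@dataclass
class SimPatientParams:
    """Ground-truth physiology of one synthetic patient.

    Units follow monitoring conventions: pressures in mmHg, intervals in ms,
    baroreflex gain in ms/mmHg, powers in ms^2, lags in minutes.
    """

    hr_base: float = 75.0          # beats/min
    ibi_sd: float = 10.0           # ms, unexplained beat-to-beat noise
    lf_power: float = 400.0        # ms^2, IBI modulation power near 0.1 Hz
    hf_power: float = 400.0        # ms^2, IBI modulation power near 0.25 Hz
    baro_gain: float = 6.0         # ms/mmHg
    baro_delay: float = 1.0        # s
    sbp_base: float = 120.0        # mmHg
    map_base: float = 90.0         # mmHg
    icp_base: float = 12.0         # mmHg
    icp_slow_amp: float = 3.0      # mmHg, slow-wave (B-wave band) amplitude
    prx_target_sign: int = 0       # {+1, -1, 0} slow ABP->ICP coupling polarity
    coupling_lag: float = 0.0      # min, ICP slow trend leads LF/HF modulation
    coupling_strength: float = 0.0  # [0, 1]
    outcome_label: str = OUTCOME_FAV
    # secondary knobs (defaults are realistic; rarely need touching)
    sbp_osc_lf: float = 4.0        # mmHg, Mayer-wave systolic oscillation
    sbp_osc_hf: float = 2.0        # mmHg, respiratory systolic oscillation
    abp_slow_amp: float = 4.0      # mmHg, slow ABP mean wandering
    prx_coupling: float = 0.9      # |corr| of ICP and ABP slow components
    panel_noise: float = 0.05      # relative noise for minute-fidelity series

    def __post_init__(self) -> None:
        if not 40 <= self.hr_base <= 140:
            raise ValueError("hr_base must be in [40, 140] beats/min")
        for name in ("sbp_base", "map_base", "icp_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baro_gain < 0:
            raise ValueError("baro_gain must be >= 0")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must be in [0, 1]")
        if abs(self.coupling_lag) > 120:
            raise ValueError("|coupling_lag| must be <= 120 min")
        if self.prx_target_sign not in (-1, 0, 1):
            raise ValueError("prx_target_sign must be -1, 0 or +1")
        if self.outcome_label not in (OUTCOME_FAV, OUTCOME_UNFAV):
            raise ValueError("outcome_label must be 'fav' or 'unfav'")


@dataclass
class SimCohortSpec:
    """Cohort-level generation recipe: class templates plus jitter."""

    n_patients: int
    class_params: Dict[str, SimPatientParams]
    param_jitter: float = 0.1
    duration_h: float = 72.0
    fidelity: Literal["waveform", "minute"] = "minute"
    seed: int = 0
    fs: float = 100.0  # only used at waveform fidelity

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.duration_h > 72:
            raise ValueError("duration_h must be <= 72")
        labels = {p.outcome_label for p in self.class_params.values()}
        if len(self.class_params) < 2 or len(labels) < 2:
            raise ValueError("both outcome classes must be represented")


class _SlowWave:
    """Sum of random-phase sinusoids in a cycles/min band, unit variance.

    Chosen over filtered noise for analytic controllability: the wave can be
    evaluated at any (possibly lagged) time without edge effects.
    """

    def __init__(self, rng: np.random.Generator, band_cpm: Tuple[float, float],
                 n_components: int = 4):
        lo, hi = band_cpm
        # stratified draw: one component per equal log-frequency stratum, so
        # every realisation actually covers the band (an unconstrained draw
        # occasionally collapses to a near-monochromatic wave whose
        # quasi-periodic autocorrelation makes lags ambiguous modulo the
        # period)
        edges = np.logspace(np.log10(lo), np.log10(hi), n_components + 1)
        self.freqs_cpm = np.exp(
            rng.uniform(np.log(edges[:-1]), np.log(edges[1:]))
        )
        amps = rng.uniform(0.5, 1.0, n_components)
        # normalize so that the variance sum(a_i^2)/2 equals 1
        amps = amps / np.sqrt(np.sum(amps**2) / 2.0)
        self.amps = amps
        self.phases = rng.uniform(0, 2 * np.pi, n_components)

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)[..., None]
        return np.sum(
            self.amps * np.sin(2 * np.pi * self.freqs_cpm * t + self.phases),
            axis=-1,
        )


def _icp_slow_wave(params: SimPatientParams, rng: np.random.Generator,
                   band_cpm: Tuple[float, float]) -> Tuple[_SlowWave, "_MixedWave"]:
    """Return (shared ABP slow wave u, ICP slow wave s).

    s is correlated with u at polarity ``prx_target_sign`` and magnitude
    ``prx_coupling``; with sign 0 it is independent of u.
    """
    u = _SlowWave(rng, band_cpm)
    v = _SlowWave(rng, band_cpm)
    if params.prx_target_sign == 0:
        return u, _MixedWave(v, v, 0.0, 1.0)
    rho = params.prx_target_sign * params.prx_coupling
    return u, _MixedWave(u, v, rho, np.sqrt(1 - params.prx_coupling**2))


class _MixedWave:
    """a*u + b*v of two unit-variance slow waves (still unit variance)."""

    def __init__(self, u, v, a: float, b: float):
        self.u, self.v, self.a, self.b = u, v, a, b

    def __call__(self, t_min):
        return self.a * self.u(t_min) + self.b * self.v(t_min)


# ----------------------------------------------------------------------------
# waveform fidelity
# ----------------------------------------------------------------------------

# Raised-cosine systolic upstroke over a FIXED rise time followed by an
# exponential decay with a fixed time constant. The systolic peak sits a
# constant 0.12 s after beat onset (as in real arterial pulses); a peak at a
# fixed *fraction* of the interval would high-pass filter the detected IBI
# sequence and bias pulse-derived HRV.
_PULSE_RISE_S = 0.12
_PULSE_TAU_S = 0.25


def _pulse_shape(tau_s: np.ndarray) -> np.ndarray:
    """Template value at time tau_s (s) after beat onset; peak value 1."""
    tau = np.asarray(tau_s, dtype=float)
    rising = tau < _PULSE_RISE_S
    out = np.empty_like(tau)
    out[rising] = 0.5 * (1 - np.cos(np.pi * tau[rising] / _PULSE_RISE_S))
    out[~rising] = np.exp(-(tau[~rising] - _PULSE_RISE_S) / _PULSE_TAU_S)
    return out


def _pulse_mean(ibi_s: np.ndarray) -> np.ndarray:
    """Time average of the template over a beat of length ibi_s (closed form)."""
    T = np.asarray(ibi_s, dtype=float)
    rise_area = 0.5 * _PULSE_RISE_S
    decay_area = _PULSE_TAU_S * (1.0 - np.exp(-(T - _PULSE_RISE_S) / _PULSE_TAU_S))
    return (rise_area + decay_area) / T


def simulate_beat_series(
    params: SimPatientParams, duration_h: float, seed: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, "_BeatContext"]:
    """Generate the beat-level ground truth underlying the ABP waveform.

    Returns ``(beat_times_s, sbp_mmHg, ibi_ms, context)`` where ``context``
    carries the slow-wave generators (needed to evaluate the ICP channel).
    The IBI recursion realises the baroreflex: a rise in delayed systolic
    pressure lengthens the interval by ``baro_gain`` ms/mmHg, on top of
    intrinsic LF (~0.1 Hz) and HF (~0.25 Hz) modulation and white noise.
    """
    rng = np.random.default_rng(seed)
    u, s_icp = _icp_slow_wave(params, rng, _WAVEFORM_BAND_CPM)
    phi_lf, phi_hf, phi_sbp_lf, phi_sbp_hf = rng.uniform(0, 2 * np.pi, 4)

    ibi0 = 60_000.0 / params.hr_base  # ms
    duration_s = duration_h * 3600.0
    n_est = int(duration_s / (ibi0 / 1000.0)) + 16
    noise = rng.normal(0.0, params.ibi_sd, n_est) if params.ibi_sd > 0 else np.zeros(n_est)

    delay_beats = max(0, int(round(params.baro_delay / (ibi0 / 1000.0))))
    a_hf = np.sqrt(2 * params.hf_power)
    a_lf0 = np.sqrt(2 * params.lf_power)

    times: List[float] = []
    sbps: List[float] = []
    ibis: List[float] = []
    t = 0.0
    n = 0
    while t < duration_s and n < n_est:
        sbp = (
            params.sbp_base
            + params.abp_slow_amp * u(t / 60.0)
            + params.sbp_osc_lf * np.sin(2 * np.pi * 0.10 * t + phi_sbp_lf)
            + params.sbp_osc_hf * np.sin(2 * np.pi * 0.25 * t + phi_sbp_hf)
        )
        # LF envelope follows the ICP slow trend at the planted lag
        env = 1.0
        if params.coupling_strength > 0:
            lagged = s_icp((t / 60.0) - params.coupling_lag)
            env = max(0.0, 1.0 + params.coupling_strength * 0.5 * lagged)
        lf_term = a_lf0 * env * np.sin(2 * np.pi * 0.10 * t + phi_lf)
        hf_term = a_hf * np.sin(2 * np.pi * 0.25 * t + phi_hf)

        sbps.append(float(sbp))
        sbp_drive = sbps[n - delay_beats] if n >= delay_beats else params.sbp_base
        ibi = (
            ibi0
            + params.baro_gain * (sbp_drive - params.sbp_base)
            + lf_term
            + hf_term
            + noise[n]
        )
        ibi = float(np.clip(ibi, 300.0, 2000.0))
        times.append(t)
        ibis.append(ibi)
        t += ibi / 1000.0
        n += 1

    ctx = _BeatContext(u=u, s_icp=s_icp)
    return np.array(times), np.array(sbps), np.array(ibis), ctx


@dataclass
class _BeatContext:
    u: object      # shared ABP slow wave
    s_icp: object  # ICP slow wave


def simulate_waveforms(
    params: SimPatientParams,
    duration_h: float,
    fs: float,
    seed: int,
    sample_budget: int = DEFAULT_SAMPLE_BUDGET,
) -> Tuple[WaveformSignal, WaveformSignal]:
    """Synthesize coupled ABP and ICP pressure waveforms.

    The ABP channel is a beat train: each beat a stereotyped pulse scaled to
    the beat's systolic pressure on a slowly varying mean. The ICP channel is
    ``icp_base`` plus B-wave-band slow oscillations (polarity-coupled to the
    slow ABP mean per ``prx_target_sign``) plus a small cardiac pulse.
    Deterministic given ``seed``.
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz (beat morphology unresolvable below)")
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    n_samples = int(round(duration_h * 3600 * fs))
    if n_samples > sample_budget:
        raise ValueError(
            f"requested {n_samples} samples exceeds the sample budget of "
            f"{sample_budget}; lower duration or fs, or raise sample_budget"
        )

    beat_t, sbp, ibi, ctx = simulate_beat_series(params, duration_h, seed)
    t = np.arange(n_samples) / fs
    idx = np.clip(np.searchsorted(beat_t, t, side="right") - 1, 0, beat_t.size - 1)
    tau = np.clip(t - beat_t[idx], 0.0, None)
    pulse = _pulse_shape(tau)
    m_p = _pulse_mean(ibi[idx] / 1000.0)

    t_min = t / 60.0
    mean_abp = params.map_base + params.abp_slow_amp * ctx.u(t_min)
    sbp_beat = sbp[idx]
    # baseline chosen so that each beat's time average equals the slow mean
    base = (mean_abp - sbp_beat * m_p) / (1.0 - m_p)
    abp = base + (sbp_beat - base) * pulse

    icp = (
        params.icp_base
        + params.icp_slow_amp * ctx.s_icp(t_min)
        + 1.5 * (pulse - m_p)
    )
    icp = np.clip(icp, 0.0, None)

    return (
        WaveformSignal(abp, fs=fs, label="ABP"),
        WaveformSignal(icp, fs=fs, label="ICP"),
    )


# ----------------------------------------------------------------------------
# minute fidelity
# ----------------------------------------------------------------------------

def simulate_minute_panel(
    params: SimPatientParams, duration_h: float, seed: int
) -> MinutePanel:
    """Directly emit the 1-min index panel the waveform path would yield.

    ICP carries unit-variance slow waves scaled by ``icp_slow_amp``; the
    LF/HF series is ``lf_power/hf_power`` modulated multiplicatively by the
    ICP slow component evaluated ``coupling_lag`` minutes earlier and scaled
    by ``coupling_strength``; BRS fluctuates around ``baro_gain``; PRx around
    ``prx_target_sign * prx_coupling``; CPP = mean ABP - ICP, where the mean
    ABP wanders slowly around ``map_base`` (amplitude ``abp_slow_amp``).
    """
    if duration_h <= 0 or duration_h > 72:
        raise ValueError("duration_h must be in (0, 72]")
    rng = np.random.default_rng(seed)
    n_min = int(round(duration_h * 60))
    t_min = np.arange(n_min, dtype=float)

    u, s_icp = _icp_slow_wave(params, rng, _MINUTE_BAND_CPM)
    s_now = s_icp(t_min)
    icp = np.clip(params.icp_base + params.icp_slow_amp * s_now, 0.0, None)
    map_series = params.map_base + params.abp_slow_amp * u(t_min)
    cpp = map_series - icp

    ratio0 = params.lf_power / max(params.hf_power, 1e-12)
    # linear modulation: band-limited like s itself, so the planted lag is
    # the unique sharp ridge of the lagged cross-correlation (the squared
    # envelope->power relation of the waveform path would add harmonic
    # content above the minute-grid Nyquist)
    mod = np.clip(
        1.0 + params.coupling_strength * 0.5 * s_icp(t_min - params.coupling_lag),
        0.05,
        None,
    )
    lfhf = ratio0 * mod
    if params.panel_noise > 0:
        lfhf = lfhf * np.exp(rng.normal(0.0, params.panel_noise, n_min))

    brs = params.baro_gain * (1.0 + params.panel_noise * rng.standard_normal(n_min))
    brs = np.clip(brs, 0.0, None)

    prx = params.prx_target_sign * params.prx_coupling + (
        2.0 * params.panel_noise * rng.standard_normal(n_min)
    )
    prx = np.clip(prx, -0.99, 0.99)

    series = {
        "icp": icp,
        "cpp": cpp,
        "prx": prx,
        "brs": brs,
        "lfhf": lfhf,
    }
    return MinutePanel(
        patient_id="sim",
        series={k: MinuteSeries(v) for k, v in series.items()},
    )


# ----------------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------------

_JITTER_FIELDS = (
    "hr_base", "ibi_sd", "lf_power", "hf_power", "baro_gain", "sbp_base",
    "map_base", "icp_base", "icp_slow_amp", "abp_slow_amp", "sbp_osc_lf",
    "sbp_osc_hf",
)


def _jitter_params(
    template: SimPatientParams, jitter: float, rng: np.random.Generator
) -> SimPatientParams:
    """Per-patient params: relative jitter on continuous physiology fields.

    Fields carrying the designed class signal (coupling_lag, coupling_strength,
    prx_target_sign, baro_delay) are copied exactly.
    """
    kwargs = dataclasses.asdict(template)
    for name in _JITTER_FIELDS:
        kwargs[name] = kwargs[name] * (1.0 + jitter * rng.uniform(-1, 1))
    kwargs["hr_base"] = float(np.clip(kwargs["hr_base"], 40, 140))
    return SimPatientParams(**kwargs)


def _sample_metadata(
    patient_id: str, outcome: str, rng: np.random.Generator
) -> PatientRecord:
    """CRASH-style covariates from severe-TBI-like marginals; no class signal."""
    age = float(np.clip(round(rng.normal(45, 16)), 18, 85))
    gcs = int(rng.integers(3, 13))  # moderate-to-severe presentation
    pupils = str(rng.choice(
        ["bilateral", "unilateral", "nonreactive"], p=[0.76, 0.14, 0.10]
    ))
    extracranial = bool(rng.random() < 0.45)
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        gcs=gcs,
        pupils=pupils,
        extracranial_injury=extracranial,
        outcome_short=outcome,
        outcome_long=outcome,
    )


def simulate_cohort(
    spec: SimCohortSpec,
) -> List[Tuple[PatientRecord, Union[MinutePanel, Tuple[WaveformSignal, WaveformSignal]]]]:
    """Generate a labelled synthetic cohort, reproducible given ``spec.seed``.

    Patients are allocated to outcome classes as evenly as possible (every
    class gets at least one patient); per-patient physiology is the class
    template with relative jitter; metadata is sampled independently of class.
    """
    classes = list(spec.class_params.items())
    n_per = [spec.n_patients // len(classes)] * len(classes)
    for i in range(spec.n_patients % len(classes)):
        n_per[i] += 1
    if min(n_per) == 0:
        raise ValueError("every requested class needs at least one patient")

    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_patients)]

    out = []
    pidx = 0
    for (class_name, template), n_class in zip(classes, n_per):
        for _ in range(n_class):
            seed = child_seeds[pidx]
            rng = np.random.default_rng(seed)
            params = _jitter_params(template, spec.param_jitter, rng)
            pid = f"P{pidx:03d}"
            record = _sample_metadata(pid, template.outcome_label, rng)
            data_seed = int(rng.integers(0, 2**31))
            if spec.fidelity == "minute":
                panel = simulate_minute_panel(params, spec.duration_h, data_seed)
                panel.patient_id = pid
                out.append((record, panel))
            else:
                abp, icp = simulate_waveforms(
                    params, spec.duration_h, spec.fs, data_seed
                )
                out.append((record, (abp, icp)))
            pidx += 1
    return out
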