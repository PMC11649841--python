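"""Shared fixtures: all data is generated programmatically at test time.

Expensive artefacts (waveform snippets, the end-to-end cohort experiment)
are session-scoped so independent tests can assert different properties of
one computation.
"""

import numpy as np
import pytest

from brainheart import cnn, pipeline, synth, wtlcc


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free physiology with a known baroreflex gain of 6 ms/mmHg."""
    return synth.SimPatientParams(
        baro_gain=6.0, ibi_sd=0.0, lf_power=0.0, hf_power=0.0,
        baro_delay=0.0, coupling_strength=0.0,
    )


@pytest.fixture(scope="session")
def short_waveforms(quiet_params):
    """30-min ABP/ICP snippet at 125 Hz from the quiet patient."""
    return synth.simulate_waveforms(quiet_params, duration_h=0.5, fs=125, seed=2)


def make_lag_cohort(lag_fav=0, lag_unfav=60, n_patients=40, seed=5,
                    jitter=0.1, abp_slow_amp=4.0, strength=0.9):
    """Two-class minute-fidelity cohort differing only in coupling lag."""
    fav = synth.SimPatientParams(
        coupling_lag=lag_fav, coupling_strength=strength,
        outcome_label="fav", abp_slow_amp=abp_slow_amp,
    )
    unf = synth.SimPatientParams(
        coupling_lag=lag_unfav, coupling_strength=strength,
        outcome_label="unfav", abp_slow_amp=abp_slow_amp,
    )
    spec = synth.SimCohortSpec(
        n_patients=n_patients, class_params={"fav": fav, "unfav": unf},
        param_jitter=jitter, seed=seed,
    )
    return pipeline.simulate_minute_cohort(spec)


SMALL_WTLCC = wtlcc.WTLCCParams(N=360, S=120, K=15)
SMALL_CNN = cnn.CNNConfig(
    conv_blocks=((8, 3, 2), (16, 3, 2)), dense_width=32, epochs=6, seed=0
)


@pytest.fixture(scope="session")
def lag_cohort():
    return make_lag_cohort()


@pytest.fixture(scope="session")
def lag_experiment(lag_cohort):
    """End-to-end result on the lag cohort: scorer + CNN/tabular reports."""
    return pipeline.run_single_cohort_experiment(
        lag_cohort, ("icp", "lfhf"), SMALL_WTLCC, SMALL_CNN, seed=0
    )
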