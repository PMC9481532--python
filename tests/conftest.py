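import numpy as np
import pytest

import arousalseq as aq


@pytest.fixture(scope="session")
def small_session():
    """A compact 9-nucleus session with physio contamination and EEG."""
    cfg = aq.SessionConfig(
        duration=600.0, seed=11, n_thalamic=9, n_cortical=2, n_arousals=10,
        cardiac_amp=0.1, respiratory_amp=0.1, with_eeg=True, noise_std=0.1,
    )
    return aq.make_session(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free locked ensembles with lags spanning 1.5 s across 3 ROIs."""
    specs = (
        aq.ROISpec(name="early", lag=-0.6),
        aq.ROISpec(name="mid", lag=0.0),
        aq.ROISpec(name="late", lag=0.9),
    )
    ens, truth = aq.make_locked_cohort(
        n_subjects=2, events_per_subject=10, roi_specs=specs, noise_std=0.0, seed=5)
    return ens, truth


def assert_series_close(a: np.ndarray, b: np.ndarray, **kw):
    np.testing.assert_allclose(np.asarray(a), np.asarray(b), **kw)
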