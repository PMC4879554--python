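import numpy as np
import pytest

import ramanclass as rc


def lorentzian(axis, center, hwhm, amp):
    return amp * hwhm**2 / ((axis - center) ** 2 + hwhm**2)


@pytest.fixture
def simple_axis():
    return np.arange(700.0, 1801.0)


@pytest.fixture
def make_spectrum():
    def _make(axis, intensities, **meta):
        meta.setdefault("group", "G")
        meta.setdefault("spectrum_id", "s0")
        return rc.Spectrum(axis, intensities, meta=meta)

    return _make


@pytest.fixture(scope="session")
def two_class_processed():
    """Default controlled two-class study (seed 1), preprocessed for PCA."""
    sset, _ = rc.simulate_two_class_study(rc.SimConfig(seed=1))
    return rc.classification_pipeline(sset, rc.PreprocessConfig())


@pytest.fixture(scope="session")
def toy_processed():
    """Tiny well-separated 2-class set (n=10) for oracle-equivalence checks."""
    cfg = rc.SimConfig(seed=7, n_spectra_per_group=5)
    sset, _ = rc.simulate_two_class_study(cfg, delta_in_noise_units=12.0)
    return rc.classification_pipeline(sset, rc.PreprocessConfig())
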