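import numpy as np
import pytest

from sf12risk import synth


@pytest.fixture(scope="session")
def calibrated_config():
    """Default synthetic config calibrated to the target prevalence.

    Session-scoped: calibration simulates a few hundred thousand patients
    and is shared by every test that needs a calibrated cohort.
    """
    return synth.calibrate_prevalence(synth.default_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_spectrum_data(seed: int, n: int = 50, p: int = 6) -> np.ndarray:
    """Random data with a well-separated population spectrum (centered).

    Used by the PCA/GPCA oracle-equivalence checks: a randomly rotated
    Gaussian with population eigenvalues (6, 4, 2.5, 1.5, 0.8, 0.4), so the
    sample eigengaps stay bounded away from zero and per-axis angular
    comparisons are well-posed.
    """
    r = np.random.default_rng(seed)
    spectrum = np.array([6.0, 4.0, 2.5, 1.5, 0.8, 0.4])[:p]
    q, _ = np.linalg.qr(r.normal(size=(p, p)))
    X = r.normal(size=(n, p)) * np.sqrt(spectrum) @ q.T
    return X - X.mean(axis=0)
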