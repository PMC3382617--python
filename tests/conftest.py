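import numpy as np
import pytest

from swale.basis import make_polynomial_basis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_basis():
    """64-sample, 8-function basis on a 2 ms grid."""
    return make_polynomial_basis(64, 8, np.arange(64) * 2.0)


@pytest.fixture(scope="session")
def default_basis():
    """Default-geometry basis: 300 samples at 500 Hz, q=20."""
    return make_polynomial_basis(300, 20, np.arange(300) * 2.0)


def make_model_data(seed, n_trials=100, n_samples=300, q=20, latency_sd_ms=20.0,
                    snr=1.0, noise_kind="ar", sfreq=500.0):
    """Correct-model data; returns (TrialMatrix, basis, coeffs, amplitude, rho)."""
    from swale.experiments import simulate_from_model

    md = simulate_from_model(
        seed,
        n_trials=n_trials,
        n_samples=n_samples,
        n_basis=q,
        latency_sd_ms=latency_sd_ms,
        snr=snr,
        noise_kind=noise_kind,
        sfreq=sfreq,
    )
    return md.data, md.basis, md.coeffs, md.amplitude, md.rho
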