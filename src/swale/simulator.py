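"""Synthetic multi-trial EEG/MEG datasets with ground truth.

Each trial holds one or more Gaussian-shaped peaks whose amplitude is drawn
from a truncated lognormal distribution and whose latency shift is drawn
from a zero-mean normal, embedded in white or AR(p) noise rescaled to a
target signal-to-noise ratio. In the ``fixed`` condition a single
amplitude/latency draw per trial is shared by every peak (one underlying
signal); in the ``free`` condition each peak draws independently (separate
signals, the worst case for methods assuming one waveform).

Peaks are shifted *continuously* — the bump is evaluated analytically at the
shifted times, never rolled by whole samples — because the latency model is
about continuous shifts. SNR is defined as the RMS amplitude ratio
RMS(clean)/RMS(noise) over the whole trial matrix; the noise realization is
rescaled so the realized ratio matches the target exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import lfilter

from swale.errors import InvalidInputError
from swale.model import NoiseSpec, TrialMatrix

__all__ = ["PeakSpec", "SimConfig", "SimDataset", "simulate", "ar_noise", "realized_snr"]

#: AR(5) coefficients emulating temporally correlated EEG background activity.
DEFAULT_AR5 = (0.35, 0.20, 0.10, 0.05, 0.02)


class PeakSpec(NamedTuple):
    """One simulated component: a Gaussian bump.

    ``width_ms`` is the Gaussian standard deviation; ``polarity`` is +1 for
    a positive deflection, -1 for a negative one.
    """

    center_ms: float
    width_ms: float
    polarity: int = 1
    base_amplitude: float = 1.0


def _default_peaks() -> list[PeakSpec]:
    return [PeakSpec(250.0, 40.0, 1, 1.0), PeakSpec(400.0, 40.0, 1, 1.0)]


@dataclass
class SimConfig:
    """Simulation settings; defaults define the package's study conditions.

    600 ms epochs (300 samples at 500 Hz) with two positive peaks at 250 and
    400 ms (sd 40 ms), 100 trials, trial amplitudes lognormal(0, 0.25)
    truncated to [0.5, 2], latency shifts N(0, latency_sd_ms), AR(5) noise
    at SNR 1.
    """

    n_trials: int = 100
    n_samples: int = 300
    sfreq: float = 500.0
    peaks: list = field(default_factory=_default_peaks)
    amp_log_mean: float = 0.0
    amp_log_sd: float = 0.25
    amp_trunc: tuple = (0.5, 2.0)
    latency_sd_ms: float = 20.0
    condition: str = "fixed"
    snr: float = 1.0
    noise: NoiseSpec = field(
        default_factory=lambda: NoiseSpec(kind="ar", ar_coeffs=np.array(DEFAULT_AR5), sigma=1.0)
    )
    seed: int = 0
    tmin_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_samples < 2:
            raise InvalidInputError("need n_trials >= 1 and n_samples >= 2")
        if self.condition not in ("fixed", "free"):
            raise InvalidInputError(f"condition must be 'fixed' or 'free', got {self.condition!r}")
        lo, hi = self.amp_trunc
        if not 0 < lo < hi:
            raise InvalidInputError(f"amplitude truncation needs 0 < lo < hi, got {self.amp_trunc}")
        if self.snr <= 0 and not np.isinf(self.snr):
            raise InvalidInputError("snr must be positive (or inf for noise-free)")
        if self.latency_sd_ms < 0:
            raise InvalidInputError("latency_sd_ms must be nonnegative")
        self.peaks = [PeakSpec(*p) for p in self.peaks]
        t = self.time_axis
        for p in self.peaks:
            if not t[0] <= p.center_ms <= t[-1]:
                raise InvalidInputError(
                    f"peak center {p.center_ms} ms outside epoch [{t[0]}, {t[-1]}] ms"
                )

    @property
    def time_axis(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq


@dataclass
class SimDataset:
    """Simulated trials plus the ground truth that generated them.

    ``truth_amplitude`` and ``truth_latency_shift`` have one row per peak
    and one column per trial; in the fixed condition the rows are identical.
    """

    data: TrialMatrix
    clean: np.ndarray
    truth_amplitude: np.ndarray
    truth_latency_shift: np.ndarray
    config_echo: SimConfig

    @property
    def noise(self) -> np.ndarray:
        return self.data.data - self.clean


def _truncated_lognormal(
    rng: np.random.Generator, log_mean: float, log_sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection sampling from a lognormal restricted to [lo, hi]."""
    out = np.empty(size)
    have = 0
    for _ in range(1000):
        need = size - have
        draw = rng.lognormal(log_mean, log_sd, size=max(4 * need, 16))
        ok = draw[(draw >= lo) & (draw <= hi)][:need]
        out[have : have + ok.size] = ok
        have += ok.size
        if have == size:
            return out
    raise InvalidInputError(
        f"truncation bounds [{lo}, {hi}] reject >99% of lognormal({log_mean}, {log_sd}) draws"
    )


def ar_noise(
    n_trials: int,
    n_samples: int,
    coeffs: Sequence[float],
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
    burn_in: int = 500,
) -> np.ndarray:
    """Independent AR(p) realizations per trial (Gaussian innovations).

    Empty ``coeffs`` gives white Gaussian noise. A burn-in of at least 500
    samples is generated and discarded so each realization is effectively
    stationary.
    """
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    if coeffs.size:
        NoiseSpec(kind="ar", ar_coeffs=coeffs, sigma=max(sigma, 0.0))  # stationarity check
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burn = max(int(burn_in), 500) if coeffs.size else 0
    e = rng.normal(0.0, sigma, size=(n_trials, n_samples + burn))
    if not coeffs.size:
        return e
    x = lfilter([1.0], np.concatenate(([1.0], -coeffs)), e, axis=1)
    return x[:, burn:]


def realized_snr(clean: np.ndarray, noise: np.ndarray) -> float:
    """RMS(clean) / RMS(noise) over all elements (amplitude-ratio definition)."""
    clean = np.asarray(clean, float)
    noise = np.asarray(noise, float)
    if clean.shape != noise.shape:
        raise InvalidInputError(f"shape mismatch: {clean.shape} vs {noise.shape}")
    rms_n = np.sqrt(np.mean(noise**2))
    if rms_n == 0:
        warnings.warn("noise is identically zero; SNR is infinite", RuntimeWarning, stacklevel=2)
        return np.inf
    return float(np.sqrt(np.mean(clean**2)) / rms_n)


def simulate(config: SimConfig) -> SimDataset:
    """Generate one dataset under the configured study conditions.

    Per trial, amplitude scale(s) are drawn from the truncated lognormal and
    latency shifts from N(0, latency_sd); the fixed condition shares one
    draw across peaks, the free condition draws per peak. Noise (white or
    AR) is rescaled so RMS(clean)/RMS(noise) equals the target SNR exactly.
    """
    rng = np.random.default_rng(config.seed)
    n, t_ax = config.n_trials, config.time_axis
    npk = len(config.peaks)
    lo, hi = config.amp_trunc

    if config.condition == "fixed":
        amp = np.tile(
            _truncated_lognormal(rng, config.amp_log_mean, config.amp_log_sd, lo, hi, n), (npk, 1)
        )
        lat = np.tile(rng.normal(0.0, config.latency_sd_ms, size=n), (npk, 1))
    else:
        amp = _truncated_lognormal(
            rng, config.amp_log_mean, config.amp_log_sd, lo, hi, npk * n
        ).reshape(npk, n)
        lat = rng.normal(0.0, config.latency_sd_ms, size=(npk, n))

    clean = np.zeros((n, t_ax.size))
    for k, pk in enumerate(config.peaks):
        # analytic evaluation at shifted times: positive shift = peak later
        arg = (t_ax[None, :] - pk.center_ms - lat[k][:, None]) / pk.width_ms
        clean += (amp[k][:, None] * pk.polarity * pk.base_amplitude) * np.exp(-0.5 * arg**2)

    if np.isinf(config.snr) or config.noise.sigma == 0:
        noise = np.zeros_like(clean)
    else:
        raw = ar_noise(
            n, t_ax.size, config.noise.ar_coeffs, sigma=max(config.noise.sigma, 1e-300), seed=rng
        )
        rms_c = np.sqrt(np.mean(clean**2))
        rms_r = np.sqrt(np.mean(raw**2))
        noise = raw * (rms_c / (config.snr * rms_r))

    data = TrialMatrix(data=clean + noise, sfreq=config.sfreq, time_axis=t_ax)
    return SimDataset(
        data=data,
        clean=clean,
        truth_amplitude=amp,
        truth_latency_shift=lat,
        config_echo=config,
    )
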