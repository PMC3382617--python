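"""The SWALE generative model.

Each trial i is modeled as an amplitude-scaled common waveform plus a scaled
copy of the waveform's first temporal derivative::

    y_i = a_i * (B @ b) + rho_i * (D @ b) + noise,   rho_i = a_i * tau_i

where ``B @ b`` is the waveform on the sample grid and ``D @ b`` its exact
derivative. The derivative term is the first-order Taylor expansion of a
small latency shift: since W(t - d) ~= W(t) - d * W'(t), a trial whose peak
occurs *later* by ``d`` ms corresponds to ``rho_i = -a_i * d``. The reported
latency shift is therefore ``lambda_i = -rho_i / a_i`` so that positive
lambda means "peak occurs later".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from swale.basis import BasisSet
from swale.errors import InvalidInputError

__all__ = [
    "TrialMatrix",
    "Waveform",
    "TrialParams",
    "NoiseSpec",
    "predict_trial",
    "predict_all",
    "rss",
]

#: Trials whose |a_i| falls below this fraction of median(|a|) get an
#: undefined latency (lambda = -rho/a explodes as a -> 0).
DEFAULT_AMP_FLOOR = 0.05


@dataclass
class TrialMatrix:
    """Epoched single-channel data: N trials by T samples.

    Attributes
    ----------
    data : (N, T) ndarray
        Baseline-corrected trials (uV or fT), one row per trial.
    sfreq : float
        Sampling frequency in Hz.
    time_axis : (T,) ndarray
        Sample times in ms (stimulus onset at 0 unless the epoch starts
        earlier).
    """

    data: np.ndarray
    sfreq: float
    time_axis: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        n, t = self.data.shape
        if n < 1 or t < 2:
            raise InvalidInputError(f"need N >= 1 trials and T >= 2 samples, got {n}x{t}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise InvalidInputError(
                f"non-finite value at trial {bad[0]}, sample {bad[1]}"
            )
        if self.time_axis.size != t:
            raise InvalidInputError(
                f"time_axis length {self.time_axis.size} != number of samples {t}"
            )
        if self.sfreq <= 0:
            raise InvalidInputError(f"sfreq must be positive, got {self.sfreq}")
        step = 1000.0 / self.sfreq
        if t > 1 and np.max(np.abs(np.diff(self.time_axis) - step)) > 1e-6:
            raise InvalidInputError(
                "time_axis spacing inconsistent with sampling frequency "
                f"({self.sfreq} Hz implies {step} ms steps)"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_array(cls, data, sfreq: float, tmin: float = 0.0) -> "TrialMatrix":
        """Build a TrialMatrix with a time axis derived from sfreq and tmin (ms)."""
        data = np.atleast_2d(np.asarray(data, dtype=float))
        t = tmin + np.arange(data.shape[1]) * 1000.0 / sfreq
        return cls(data=data, sfreq=sfreq, time_axis=t)


@dataclass
class Waveform:
    """A waveform as basis coefficients plus an optional support mask.

    The evaluated waveform is ``(B @ coeffs) * support_mask``; split
    waveforms (multiple-signal models) differ only in their masks.
    """

    coeffs: np.ndarray
    support_mask: np.ndarray
    basis_id: str = ""

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        self.support_mask = np.asarray(self.support_mask, dtype=bool).ravel()

    def values(self, basis: BasisSet) -> np.ndarray:
        """Evaluated waveform on the sample grid (zero outside support)."""
        self._check(basis)
        return (basis.B @ self.coeffs) * self.support_mask

    def derivative(self, basis: BasisSet) -> np.ndarray:
        """Evaluated waveform derivative (per ms) under the same mask."""
        self._check(basis)
        return (basis.D @ self.coeffs) * self.support_mask

    def _check(self, basis: BasisSet) -> None:
        if self.coeffs.size != basis.n_basis:
            raise InvalidInputError(
                f"waveform has {self.coeffs.size} coefficients but basis has "
                f"{basis.n_basis} functions"
            )
        if self.support_mask.size != basis.n_samples:
            raise InvalidInputError(
                f"support mask length {self.support_mask.size} != "
                f"{basis.n_samples} samples"
            )


@dataclass
class TrialParams:
    """Per-trial amplitude a_i and derivative coefficient rho_i = a_i * tau_i.

    ``latency_shift`` (ms) is derived as lambda_i = -rho_i / a_i; trials with
    |a_i| below ``amp_floor * median(|a|)`` are flagged and their latency
    reported as NaN.
    """

    amplitude: np.ndarray
    rho: np.ndarray
    amp_floor: float = DEFAULT_AMP_FLOOR

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float).ravel()
        self.rho = np.asarray(self.rho, dtype=float).ravel()
        if self.amplitude.size != self.rho.size:
            raise InvalidInputError("amplitude and rho must have equal length")

    @property
    def n_trials(self) -> int:
        return self.amplitude.size

    @property
    def latency_undefined(self) -> np.ndarray:
        floor = self.amp_floor * np.median(np.abs(self.amplitude))
        return np.abs(self.amplitude) < max(floor, np.finfo(float).tiny)

    @property
    def latency_shift(self) -> np.ndarray:
        """Latency shifts in ms; NaN where the amplitude is below the floor."""
        bad = self.latency_undefined
        lam = np.full(self.n_trials, np.nan)
        np.divide(-self.rho, self.amplitude, out=lam, where=~bad)
        return lam


@dataclass
class NoiseSpec:
    """Additive Gaussian noise: white, or an AR(p) process.

    ``ar_coeffs`` are the autoregressive coefficients c_1..c_p of
    x_t = sum_k c_k x_{t-k} + e_t; empty means white noise. Stationarity
    (all characteristic roots inside the unit circle) is checked at
    construction.
    """

    kind: str = "white"
    ar_coeffs: np.ndarray = field(default_factory=lambda: np.array([]))
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "ar"):
            raise InvalidInputError(f"noise kind must be 'white' or 'ar', got {self.kind!r}")
        self.ar_coeffs = np.asarray(self.ar_coeffs, dtype=float).ravel()
        if self.kind == "white" and self.ar_coeffs.size:
            raise InvalidInputError("white noise takes no AR coefficients")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be nonnegative")
        if self.ar_coeffs.size:
            # roots of z^p - c1 z^(p-1) - ... - cp must lie inside the unit circle
            roots = np.roots(np.concatenate(([1.0], -self.ar_coeffs)))
            if np.any(np.abs(roots) >= 1.0 - 1e-10):
                raise InvalidInputError(
                    f"AR coefficients {self.ar_coeffs.tolist()} are not stationary"
                )


def predict_trial(
    waveform: Waveform, basis: BasisSet, amplitude: float, rho: float
) -> np.ndarray:
    """Model prediction for one trial: a*(B@b) + rho*(D@b), masked."""
    return amplitude * waveform.values(basis) + rho * waveform.derivative(basis)


def predict_all(
    waveforms: Sequence[Waveform],
    basis: BasisSet,
    params: Sequence[TrialParams],
) -> np.ndarray:
    """Model predictions for all trials, summed over waveforms.

    Row i is the sum over waveforms w of
    ``a_i^(w) * (B @ b_w) + rho_i^(w) * (D @ b_w)`` (masked). This is the
    row-wise equivalent of the vectorized Kronecker-product formulation.
    """
    if len(waveforms) != len(params):
        raise InvalidInputError("need exactly one TrialParams per waveform")
    if not waveforms:
        raise InvalidInputError("need at least one waveform")
    ns = {p.n_trials for p in params}
    if len(ns) != 1:
        raise InvalidInputError(f"inconsistent trial counts across waveforms: {sorted(ns)}")
    n = ns.pop()
    out = np.zeros((n, basis.n_samples))
    for w, p in zip(waveforms, params):
        out += np.outer(p.amplitude, w.values(basis)) + np.outer(p.rho, w.derivative(basis))
    return out


def rss(observed, predicted) -> float:
    """Residual sum of squares over all N*T points."""
    obs = observed.data if isinstance(observed, TrialMatrix) else np.asarray(observed, float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InvalidInputError(f"shape mismatch: observed {obs.shape} vs predicted {pred.shape}")
    r = obs - pred
    return float(np.dot(r.ravel(), r.ravel()))
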