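"""Single-trial peak extraction and the peak-picking baseline.

After a model is fitted, the analyst specifies a time range containing the
peak of interest in the average model. For every trial the fitted model's
contribution of the selected waveform is evaluated and the extremum inside
the range gives that trial's latency (its time point) and amplitude (its
value). The classical comparator, peak-picking, smooths each *raw* trial
with a Gaussian kernel and takes the windowed extremum directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from swale.basis import BasisSet
from swale.errors import InvalidInputError
from swale.model import TrialMatrix

__all__ = ["PeakRange", "SingleTrialPeaks", "extract_peaks", "peak_pick"]

_POLARITIES = ("max", "min", "absolute")


@dataclass(frozen=True)
class PeakRange:
    """Closed time interval [t_lo, t_hi] in ms and the extremum polarity."""

    t_lo: float
    t_hi: float
    polarity: str = "max"

    def __post_init__(self) -> None:
        if not self.t_lo < self.t_hi:
            raise InvalidInputError(f"need t_lo < t_hi, got [{self.t_lo}, {self.t_hi}]")
        if self.polarity not in _POLARITIES:
            raise InvalidInputError(
                f"polarity must be one of {_POLARITIES}, got {self.polarity!r}"
            )

    def indices(self, time_axis: np.ndarray) -> np.ndarray:
        """Boolean mask of samples inside the range; errors if outside the epoch."""
        t = np.asarray(time_axis, float)
        if self.t_lo < t[0] - 1e-9 or self.t_hi > t[-1] + 1e-9:
            raise InvalidInputError(
                f"range [{self.t_lo}, {self.t_hi}] ms outside epoch "
                f"[{t[0]}, {t[-1]}] ms"
            )
        return (t >= self.t_lo - 1e-9) & (t <= self.t_hi + 1e-9)


@dataclass
class SingleTrialPeaks:
    """Per-trial latency (ms), amplitude (signal units), and boundary flags.

    ``undefined`` marks trials for which no sample of the searched waveform's
    support falls inside the range (latency and amplitude are NaN there).
    """

    latency: np.ndarray
    amplitude: np.ndarray
    at_boundary: np.ndarray
    undefined: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.latency.size


def _windowed_extrema(
    trials: np.ndarray, times: np.ndarray, polarity: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extremum per row on the sample grid; ties broken by earliest sample."""
    if polarity == "max":
        idx = np.argmax(trials, axis=1)
    elif polarity == "min":
        idx = np.argmin(trials, axis=1)
    else:
        idx = np.argmax(np.abs(trials), axis=1)
    lat = times[idx]
    amp = trials[np.arange(trials.shape[0]), idx]
    at_boundary = (idx == 0) | (idx == trials.shape[1] - 1)
    return lat, amp, at_boundary


def extract_peaks(
    fit, basis: BasisSet, peak_range: PeakRange, waveform_index: int = 0
) -> SingleTrialPeaks:
    """Single-trial amplitude and latency of one waveform's modeled peak.

    For each trial the selected waveform's modeled contribution
    ``a_i*(B@b) + rho_i*(D@b)`` is evaluated on the sample grid restricted
    to the range (and the waveform's support); the argextremum time and its
    value are returned. With multiple waveforms the extraction is performed
    per waveform via ``waveform_index``.
    """
    if not 0 <= waveform_index < fit.n_waveforms:
        raise InvalidInputError(
            f"waveform_index {waveform_index} out of range for a "
            f"{fit.n_waveforms}-waveform model"
        )
    w = fit.waveforms[waveform_index]
    p = fit.params[waveform_index]
    in_range = peak_range.indices(basis.time_axis)
    sel = in_range & w.support_mask
    n = p.n_trials
    if not sel.any():
        nanv = np.full(n, np.nan)
        return SingleTrialPeaks(
            latency=nanv.copy(),
            amplitude=nanv.copy(),
            at_boundary=np.zeros(n, bool),
            undefined=np.ones(n, bool),
        )
    wv = (basis.B @ w.coeffs)[sel]
    dv = (basis.D @ w.coeffs)[sel]
    modeled = np.outer(p.amplitude, wv) + np.outer(p.rho, dv)
    lat, amp, bnd = _windowed_extrema(modeled, basis.time_axis[sel], peak_range.polarity)
    return SingleTrialPeaks(
        latency=lat, amplitude=amp, at_boundary=bnd, undefined=np.zeros(n, bool)
    )


def peak_pick(
    data: TrialMatrix,
    kernel_width_ms: float,
    window: PeakRange,
    width_is_fwhm: bool = False,
) -> SingleTrialPeaks:
    """Gaussian-smoothing peak-picking on the raw trials.

    Each trial is convolved with a normalized Gaussian kernel (standard
    deviation ``kernel_width_ms``, or full width at half maximum when
    ``width_is_fwhm``; truncated at +/-4 sd, reflect-padded edges), then the
    windowed extremum gives latency and amplitude.
    """
    if kernel_width_ms <= 0:
        raise InvalidInputError("kernel width must be positive")
    sd_ms = kernel_width_ms / 2.3548200450309493 if width_is_fwhm else kernel_width_ms
    sd_samples = sd_ms * data.sfreq / 1000.0
    t = data.n_samples
    if 2 * int(4.0 * sd_samples + 0.5) + 1 > t:
        raise InvalidInputError(
            f"kernel (sd {sd_ms} ms, +/-4 sd support) is wider than the epoch"
        )
    smoothed = gaussian_filter1d(data.data, sigma=sd_samples, axis=1, mode="reflect", truncate=4.0)
    sel = window.indices(data.time_axis)
    lat, amp, bnd = _windowed_extrema(smoothed[:, sel], data.time_axis[sel], window.polarity)
    n = data.n_trials
    return SingleTrialPeaks(
        latency=lat, amplitude=amp, at_boundary=bnd, undefined=np.zeros(n, bool)
    )
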