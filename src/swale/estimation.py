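"""Alternating least-squares estimation of waveform and trial parameters.

The algorithm starts from the grand average of the data projected onto the
basis, then alternates two exact linear solves until the residual sum of
squares (RSS) stops decreasing:

1. *Trial step* — given the waveform(s), each trial's (a_i, rho_i) is the
   ordinary least-squares solution of a regression on the evaluated
   waveform and its derivative (2 regressors per waveform, solved jointly
   across waveforms). The design matrix is shared by all trials, so all N
   regressions are one matrix solve.
2. *Waveform step* — given all (a_i, rho_i), the basis coefficients b are
   the global least-squares solution of the stacked system whose per-trial
   design is a_i*B + rho_i*D (masked per waveform), solved via accumulated
   normal equations.

Because each half-step is an exact least-squares solve, the RSS trace is
non-increasing. The model has a scale indeterminacy (b -> c*b, a -> a/c,
rho -> rho/c); after each waveform step the fit is re-gauged so that
mean(a) = 1 per waveform, making a_i interpretable as relative amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from swale.basis import BasisSet, make_polynomial_basis
from swale.errors import InvalidInputError, NumericalError
from swale.model import (
    DEFAULT_AMP_FLOOR,
    TrialMatrix,
    TrialParams,
    Waveform,
    predict_all,
    rss,
)

__all__ = ["FitConfig", "SwaleFit", "fit", "fit_trial_params", "fit_waveform"]

_COLLINEAR_RTOL = 1e-10  # singular-value ratio below which rho is dropped


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    Attributes
    ----------
    n_basis : int
        Number of polynomial basis functions (default 20).
    max_iter : int
        Maximum number of full alternating iterations.
    rel_tol : float
        Stop when the relative RSS decrease over one full iteration falls
        below this ("negligible" decrease).
    amp_floor : float
        Relative amplitude floor below which a trial's latency is flagged
        undefined (see TrialParams).
    normalize_each_iter : bool
        Apply the mean(a) = 1 gauge after every waveform step.
    """

    n_basis: int = 20
    max_iter: int = 200
    rel_tol: float = 1e-8
    amp_floor: float = DEFAULT_AMP_FLOOR
    normalize_each_iter: bool = True

    def __post_init__(self) -> None:
        if self.n_basis < 1:
            raise InvalidInputError("n_basis must be >= 1")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise InvalidInputError("rel_tol must be positive")


@dataclass
class SwaleFit:
    """A fitted model: waveform(s), per-trial parameters, diagnostics."""

    waveforms: list
    params: list
    rss_trace: np.ndarray
    n_iter: int
    converged: bool
    aic: float
    n_params_k: int
    n_points_n: int
    config: FitConfig
    basis: BasisSet
    collinearity_fallback: bool = False

    @property
    def n_waveforms(self) -> int:
        return len(self.waveforms)

    @property
    def rss(self) -> float:
        return float(self.rss_trace[-1])

    def predict(self) -> np.ndarray:
        """Modeled N x T data under the fitted parameters."""
        return predict_all(self.waveforms, self.basis, self.params)


def _design_columns(waveforms: Sequence[Waveform], basis: BasisSet) -> np.ndarray:
    """T x 2W matrix of regressors [W1, W1', W2, W2', ...] (masked)."""
    cols = []
    for w in waveforms:
        cols.append(w.values(basis))
        cols.append(w.derivative(basis))
    return np.column_stack(cols)


def _solve_trial_params(
    Y: np.ndarray, waveforms: Sequence[Waveform], basis: BasisSet, amp_floor: float
) -> tuple[list, bool]:
    """Joint per-trial OLS for all trials at once (shared design matrix).

    Returns one TrialParams per waveform plus a flag indicating that the
    derivative regressors were dropped because of collinearity.
    """
    X = _design_columns(waveforms, basis)
    nw = len(waveforms)
    s = np.linalg.svd(X, compute_uv=False)
    fallback = s[-1] <= s[0] * _COLLINEAR_RTOL
    if fallback:
        # degenerate waveform: D@b parallel to B@b (or zero); amplitude-only fit
        Xa = X[:, 0::2]
        sa = np.linalg.svd(Xa, compute_uv=False)
        if sa[-1] <= sa[0] * _COLLINEAR_RTOL:
            raise NumericalError("waveform regressors are rank deficient even without rho")
        beta_a, *_ = np.linalg.lstsq(Xa, Y.T, rcond=None)
        beta = np.zeros((2 * nw, Y.shape[0]))
        beta[0::2] = beta_a
    else:
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    out = [
        TrialParams(amplitude=beta[2 * w], rho=beta[2 * w + 1], amp_floor=amp_floor)
        for w in range(nw)
    ]
    return out, fallback


def fit_trial_params(
    trial: np.ndarray, waveform: Waveform, basis: BasisSet
) -> tuple[float, float]:
    """Least-squares (a, rho) for one trial given a fixed waveform.

    Solves ``trial ~= a*(B@b) + rho*(D@b)`` over the supported samples. If
    the two regressors are numerically collinear the fit falls back to an
    amplitude-only regression with rho = 0 and emits a warning.
    """
    trial = np.asarray(trial, dtype=float).ravel()
    if trial.size != basis.n_samples:
        raise InvalidInputError(
            f"trial length {trial.size} != basis n_samples {basis.n_samples}"
        )
    params, fallback = _solve_trial_params(
        trial[None, :], [waveform], basis, DEFAULT_AMP_FLOOR
    )
    if fallback:
        warnings.warn(
            "waveform and its derivative are collinear; rho set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(params[0].amplitude[0]), float(params[0].rho[0])


def fit_waveform(
    data: TrialMatrix,
    basis: BasisSet,
    params: Sequence[TrialParams],
    masks: Sequence[np.ndarray] | None = None,
) -> list:
    """Least-squares waveform coefficients given fixed trial parameters.

    All waveforms share one coefficient vector b — a split model is the one
    underlying waveform cut into masked pieces that move independently per
    trial. Trial i's design contribution is therefore
    ``sum_w a_i^(w)*(M_w B) + rho_i^(w)*(M_w D)`` (M_w the support masks),
    and b is the global least-squares solution of the stacked (N*T) x q
    system, computed via accumulated normal equations. Returns one Waveform
    per mask, all holding the shared coefficients.
    """
    Y = data.data
    n, t = Y.shape
    if masks is None:
        masks = [np.ones(t, dtype=bool)] * len(params)
    if len(masks) != len(params):
        raise InvalidInputError("need one support mask per TrialParams")
    if any(p.n_trials != n for p in params):
        raise InvalidInputError("TrialParams length must equal the number of trials")
    if all(np.allclose(p.amplitude, 0) and np.allclose(p.rho, 0) for p in params):
        raise InvalidInputError("all trial parameters are zero; waveform unidentifiable")

    q = basis.n_basis
    nw = len(params)
    masks = [np.asarray(m, bool).ravel() for m in masks]
    Bm = [basis.B * m[:, None] for m in masks]
    Dm = [basis.D * m[:, None] for m in masks]

    # X_i = sum_w a_iw Bm_w + rho_iw Dm_w; accumulate A = sum_i X_i'X_i and
    # rhs = sum_i X_i'y_i from the cross-Gram matrices of the masked bases.
    A = np.zeros((q, q))
    rhs = np.zeros(q)
    for w in range(nw):
        aw, rw = params[w].amplitude, params[w].rho
        rhs += Bm[w].T @ (Y.T @ aw) + Dm[w].T @ (Y.T @ rw)
        for v in range(nw):
            av, rv = params[v].amplitude, params[v].rho
            A += (
                float(aw @ av) * (Bm[w].T @ Bm[v])
                + float(aw @ rv) * (Bm[w].T @ Dm[v])
                + float(rw @ av) * (Dm[w].T @ Bm[v])
                + float(rw @ rv) * (Dm[w].T @ Dm[v])
            )
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(
            f"stacked normal matrix is singular or near-singular (cond={cond:.3g}); "
            "check for all-zero amplitudes or empty support masks"
        )
    b = np.linalg.solve(A, rhs)
    return [Waveform(coeffs=b.copy(), support_mask=m, basis_id=basis.basis_id) for m in masks]


def _apply_gauge(waveforms: list, params: list) -> tuple[list, list]:
    """Rescale so the grand mean amplitude is 1; predictions are unchanged.

    The coefficients are shared across waveforms, so a single scale factor
    (the mean of all amplitude vectors) is absorbed into b; for a
    one-waveform model this is exactly mean(a) = 1.
    """
    m = float(np.mean([p.amplitude for p in params]))
    if abs(m) < 1e-12:
        return waveforms, params
    new_w = [replace(w, coeffs=w.coeffs * m) for w in waveforms]
    new_p = [
        TrialParams(p.amplitude / m, p.rho / m, amp_floor=p.amp_floor) for p in params
    ]
    return new_w, new_p


def fit(
    data: TrialMatrix,
    config: FitConfig | None = None,
    waveform_masks: Sequence[np.ndarray] | None = None,
    basis: BasisSet | None = None,
) -> SwaleFit:
    """Fit the SWALE model by alternating least squares.

    Starts from the grand average projected onto the basis (masked per
    waveform when ``waveform_masks`` is given), alternates trial-parameter
    and waveform solves, and stops when the relative RSS decrease over a
    full iteration drops below ``config.rel_tol`` or ``config.max_iter`` is
    reached.
    """
    if config is None:
        config = FitConfig()
    Y = data.data
    n, t = Y.shape
    if basis is None:
        basis = make_polynomial_basis(t, config.n_basis, data.time_axis)
    if waveform_masks is None:
        masks = [np.ones(t, dtype=bool)]
    else:
        masks = [np.asarray(m, bool).ravel() for m in waveform_masks]
        for m in masks:
            if m.size != t:
                raise InvalidInputError("support masks must have one entry per sample")
        stacked = np.sum(masks, axis=0)
        if np.any(stacked > 1):
            raise InvalidInputError("support masks must be disjoint")
    nw = len(masks)

    # init: project the grand average onto the basis (shared coefficients,
    # fitted over the union of the supports)
    for m in masks:
        if not m.any():
            raise InvalidInputError("empty support mask")
    union = np.any(masks, axis=0)
    grand = Y.mean(axis=0)
    coef, *_ = np.linalg.lstsq(basis.B[union], grand[union], rcond=None)
    waveforms = [
        Waveform(coeffs=coef.copy(), support_mask=m, basis_id=basis.basis_id) for m in masks
    ]

    trace: list[float] = []
    params: list = []
    converged = False
    fallback_any = False
    rss_prev = np.inf
    # below this, RSS is numerically zero (perfect fit) and its roundoff-level
    # fluctuations no longer carry convergence information
    rss_floor = 1e-20 * max(float(np.sum(Y * Y)), np.finfo(float).tiny)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        params, fb = _solve_trial_params(Y, waveforms, basis, config.amp_floor)
        fallback_any |= fb
        r = rss(Y, predict_all(waveforms, basis, params))
        if not np.isfinite(r):
            raise NumericalError(f"non-finite RSS at iteration {n_iter}")
        trace.append(r)
        if r <= rss_floor or (
            np.isfinite(rss_prev)
            and rss_prev - r <= config.rel_tol * max(rss_prev, np.finfo(float).tiny)
        ):
            converged = True
            break
        waveforms = fit_waveform(data, basis, params, masks)
        if config.normalize_each_iter:
            waveforms, params = _apply_gauge(waveforms, params)
        r = rss(Y, predict_all(waveforms, basis, params))
        if not np.isfinite(r):
            raise NumericalError(f"non-finite RSS at iteration {n_iter}")
        trace.append(r)
        rss_prev = r

    if config.normalize_each_iter:
        # final half-step re-estimates a, so re-gauge once more (predictions,
        # and hence the trace, are unchanged)
        waveforms, params = _apply_gauge(waveforms, params)

    k = config.n_basis + 2 * nw * n
    npts = n * t
    final = trace[-1]
    if final > 0 and npts > k:
        from swale.selection import aic as _aic

        aic_val = _aic(final, k, npts)
    else:
        aic_val = -np.inf  # perfect (or over-saturated) fit; AIC degenerate
    return SwaleFit(
        waveforms=waveforms,
        params=params,
        rss_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        aic=aic_val,
        n_params_k=k,
        n_points_n=npts,
        config=config,
        basis=basis,
        collinearity_fallback=fallback_any,
    )
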