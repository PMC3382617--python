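"""Multi-waveform split search and AIC model selection.

A one-waveform model forces every signal in the epoch to share one amplitude
and one latency per trial. To test for multiple signals, the fitted waveform
is split into two masked waveforms at every candidate time point between two
adjacent peaks of the average model; for each candidate the per-trial
parameters are re-estimated (with the waveform coefficients frozen) and the
split with the lowest RSS wins, after which the full alternating fit is
re-run with the winning masks. Models with different numbers of waveforms
(and different numbers of basis functions) are compared with the Gaussian
least-squares AIC

    AIC = n * ln(RSS / n) + 2k,

with n the number of data points (N*T) and k the number of estimated
parameters, counted as q waveform coefficients plus an amplitude and a
derivative coefficient per trial per waveform: k = q + 2*W*N. The model with
the smallest AIC is taken as the best model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from swale.basis import BasisSet
from swale.errors import InvalidInputError, NumericalError
from swale.estimation import FitConfig, SwaleFit, _solve_trial_params, fit
from swale.model import TrialMatrix, Waveform, predict_all, rss
from swale.peaks import PeakRange

__all__ = [
    "ModelScore",
    "SplitCandidate",
    "aic",
    "find_split_candidates",
    "best_split",
    "select_model",
    "select_n_basis",
]


@dataclass(frozen=True)
class ModelScore:
    """Fit/complexity summary of one model: RSS, parameter count k, n, AIC."""

    rss: float
    k: int
    n: int

    @property
    def aic(self) -> float:
        return aic(self.rss, self.k, self.n)


@dataclass
class SplitCandidate:
    """One evaluated split: sample index, the two masks, RSS and AIC."""

    split_sample: int
    masks: tuple
    rss: float
    aic: float


def aic(rss_value: float, k: int, n: int) -> float:
    """Gaussian least-squares Akaike Information Criterion.

    ``n * ln(rss/n) + 2k``; smaller is better. ``rss`` must be positive
    (a perfect fit is a degenerate case handled by the caller).
    """
    if rss_value <= 0:
        raise InvalidInputError(f"AIC needs rss > 0, got {rss_value}")
    if not n > k >= 0:
        raise InvalidInputError(f"AIC needs n > k >= 0, got k={k}, n={n}")
    return n * math.log(rss_value / n) + 2 * k


def _local_extrema(values: np.ndarray) -> np.ndarray:
    """Indices of strict local extrema; plateaus count once, at their leftmost sample.

    Runs of equal values are compressed to their first sample, then an
    interior run is an extremum when strictly above (or below) both
    neighboring runs.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        return np.array([], dtype=int)
    keep = np.concatenate(([True], np.diff(v) != 0))
    starts = np.flatnonzero(keep)
    rv = v[starts]
    if rv.size < 3:
        return np.array([], dtype=int)
    mid = rv[1:-1]
    is_ext = ((mid > rv[:-2]) & (mid > rv[2:])) | ((mid < rv[:-2]) & (mid < rv[2:]))
    return starts[1:-1][is_ext]


def find_split_candidates(
    waveform: Waveform, basis: BasisSet, peak_range: PeakRange
) -> list[int]:
    """All sample indices strictly between adjacent peaks of the waveform.

    Local extrema of the evaluated (masked) average waveform inside the
    range are located on the sample grid; every sample strictly between two
    adjacent extrema is a candidate split point. Empty when the range holds
    fewer than two extrema ("no split possible").
    """
    sel = peak_range.indices(basis.time_axis) & waveform.support_mask
    idx = np.flatnonzero(sel)
    if idx.size < 3:
        return []
    values = (basis.B @ waveform.coeffs)[idx]
    ext_local = _local_extrema(values)
    if ext_local.size < 2:
        return []
    ext = idx[ext_local]
    out: list[int] = []
    for e1, e2 in zip(ext[:-1], ext[1:]):
        out.extend(range(int(e1) + 1, int(e2)))
    return out


def _score_splits(
    data: TrialMatrix,
    parent: SwaleFit,
    basis: BasisSet,
    candidates: Sequence[int],
    component: int,
) -> list[SplitCandidate]:
    """Score every candidate split of one component with frozen coefficients.

    The parent fit's coefficient vectors stay fixed; only the per-trial
    (a, rho) are re-estimated, jointly across the (W+1) masked waveforms.
    """
    Y = data.data
    n, t = Y.shape
    w0 = parent.waveforms[component]
    others = [w for i, w in enumerate(parent.waveforms) if i != component]
    scored: list[SplitCandidate] = []
    sample_index = np.arange(t)
    n_fail = 0
    for s in candidates:
        left = w0.support_mask & (sample_index < s)
        right = w0.support_mask & (sample_index >= s)
        if not left.any() or not right.any():
            continue
        split_wfs = (
            others
            + [
                Waveform(w0.coeffs.copy(), left, basis_id=w0.basis_id),
                Waveform(w0.coeffs.copy(), right, basis_id=w0.basis_id),
            ]
        )
        try:
            params, _ = _solve_trial_params(Y, split_wfs, basis, parent.config.amp_floor)
        except NumericalError:
            n_fail += 1
            continue
        r = rss(Y, predict_all(split_wfs, basis, params))
        nw = len(split_wfs)
        k = parent.config.n_basis + 2 * nw * n
        a = aic(r, k, n * t) if r > 0 and n * t > k else -np.inf
        scored.append(SplitCandidate(split_sample=int(s), masks=(left, right), rss=r, aic=a))
    if not scored and n_fail:
        raise NumericalError("all candidate split regressions were rank deficient")
    return scored


def best_split(
    data: TrialMatrix,
    fit1: SwaleFit,
    basis: BasisSet,
    peak_range: PeakRange,
    refit: bool = True,
) -> tuple[SplitCandidate, SwaleFit]:
    """Best two-waveform split of a one-waveform fit.

    Scans every candidate split point (waveform coefficients frozen,
    per-trial parameters re-estimated jointly), selects the minimum-RSS
    split, and — unless ``refit`` is False — re-runs the full alternating
    fit with the winning masks.
    """
    if fit1.n_waveforms != 1:
        raise InvalidInputError("best_split expects a one-waveform fit")
    candidates = find_split_candidates(fit1.waveforms[0], basis, peak_range)
    if not candidates:
        raise InvalidInputError(
            "no split possible: fewer than two peaks of the average model "
            "inside the range"
        )
    scored = _score_splits(data, fit1, basis, candidates, component=0)
    if not scored:
        raise InvalidInputError("no valid split candidate (degenerate masks)")
    winner = min(scored, key=lambda c: c.rss)
    if refit:
        fit2 = fit(data, fit1.config, waveform_masks=list(winner.masks), basis=basis)
    else:
        # frozen-coefficients variant: report the scan-time model as a fit
        wfs = [
            Waveform(fit1.waveforms[0].coeffs.copy(), m, basis_id=basis.basis_id)
            for m in winner.masks
        ]
        params, fb = _solve_trial_params(data.data, wfs, basis, fit1.config.amp_floor)
        n, t = data.data.shape
        k = fit1.config.n_basis + 2 * len(wfs) * n
        fit2 = SwaleFit(
            waveforms=wfs,
            params=params,
            rss_trace=np.array([winner.rss]),
            n_iter=0,
            converged=True,
            aic=winner.aic,
            n_params_k=k,
            n_points_n=n * t,
            config=fit1.config,
            basis=basis,
            collinearity_fallback=fb,
        )
    return winner, fit2


def select_model(
    data: TrialMatrix,
    config: FitConfig | None = None,
    peak_range: PeakRange | None = None,
    max_waveforms: int = 2,
    audit: list | None = None,
) -> SwaleFit:
    """AIC-guided greedy search over the number of waveforms.

    Fits the one-waveform model, then repeatedly tries splitting each
    current component (frozen-coefficient scan, full refit of the best
    candidate) and accepts the refit model while its AIC strictly decreases
    and the waveform count stays within ``max_waveforms``. When ``audit``
    is a list, every scored candidate split is appended to it as a dict
    (waveform count, component, split sample, RSS, AIC) for auditability.
    """
    if max_waveforms < 1:
        raise InvalidInputError("max_waveforms must be >= 1")
    if config is None:
        config = FitConfig()
    best = fit(data, config)
    if max_waveforms == 1 or peak_range is None:
        return best
    basis = best.basis
    while best.n_waveforms < max_waveforms:
        scored_all: list[tuple[SplitCandidate, int]] = []
        for comp in range(best.n_waveforms):
            cands = find_split_candidates(best.waveforms[comp], basis, peak_range)
            if not cands:
                continue
            scored = _score_splits(data, best, basis, cands, component=comp)
            if audit is not None:
                audit.extend(
                    {
                        "n_waveforms_before": best.n_waveforms,
                        "component": comp,
                        "split_sample": c.split_sample,
                        "rss": c.rss,
                        "aic": c.aic,
                    }
                    for c in scored
                )
            if scored:
                scored_all.append((min(scored, key=lambda c: c.aic), comp))
        if not scored_all:
            break
        winner, comp = min(scored_all, key=lambda wc: wc[0].aic)
        masks = [m for i, w in enumerate(best.waveforms) if i != comp for m in [w.support_mask]]
        masks += list(winner.masks)
        refit = fit(data, config, waveform_masks=masks, basis=basis)
        if refit.aic < best.aic:
            best = refit
        else:
            break
    return best


def select_n_basis(
    data: TrialMatrix,
    candidate_qs: Sequence[int],
    config: FitConfig | None = None,
) -> int:
    """AIC-optimal number of basis functions among the candidates.

    Fits the one-waveform model once per q (k = q + 2N) and returns the q
    with the smallest AIC.
    """
    if not candidate_qs:
        raise InvalidInputError("candidate_qs must be nonempty")
    if config is None:
        config = FitConfig()
    best_q, best_aic = None, np.inf
    for q in candidate_qs:
        if q > data.n_samples:
            raise InvalidInputError(f"q={q} exceeds T={data.n_samples}")
        f = fit(data, FitConfig(
            n_basis=q,
            max_iter=config.max_iter,
            rel_tol=config.rel_tol,
            amp_floor=config.amp_floor,
            normalize_each_iter=config.normalize_each_iter,
        ))
        if f.aic < best_aic:
            best_q, best_aic = q, f.aic
    return int(best_q)
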