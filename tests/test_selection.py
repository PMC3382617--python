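import math

import numpy as np
import pytest

from conftest import make_model_data
from swale.basis import make_polynomial_basis
from swale.errors import InvalidInputError
from swale.estimation import FitConfig, fit
from swale.model import TrialMatrix, Waveform
from swale.peaks import PeakRange
from swale.selection import (
    aic,
    best_split,
    find_split_candidates,
    select_model,
    select_n_basis,
)
from swale.simulator import SimConfig, simulate
from swale.model import NoiseSpec

SEARCH_RANGE = PeakRange(150, 500)


class TestAic:
    def test_closed_form_anchors(self):
        assert aic(100.0, 0, 100) == 0.0
        base = aic(50.0, 3, 200)
        assert aic(100.0, 3, 200) - base == pytest.approx(200 * math.log(2))

    def test_ordering_matches_independent_formula(self, rng):
        for _ in range(20):
            r1, r2 = rng.uniform(10, 1000, 2)
            k1, k2 = rng.integers(1, 50, 2)
            n = 5000
            ref = lambda r, k: n * np.log(r / n) + 2 * k
            assert (aic(r1, int(k1), n) < aic(r2, int(k2), n)) == (
                ref(r1, k1) < ref(r2, k2)
            )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            aic(0.0, 1, 10)
        with pytest.raises(InvalidInputError):
            aic(1.0, 10, 10)


class TestSplitCandidates:
    def _waveform_from_signal(self, signal):
        t = signal.size
        basis = make_polynomial_basis(t, t)  # full basis: exact representation
        return Waveform(basis.B.T @ signal, np.ones(t, bool)), basis

    def test_definition_on_known_extrema(self):
        """Extrema at samples 30 and 60 yield candidates {31..59}."""
        i = np.arange(100, dtype=float)
        signal = np.cos(2 * np.pi * (i - 30) / 60)  # max at 30, min at 60
        w, basis = self._waveform_from_signal(signal)
        got = find_split_candidates(w, basis, PeakRange(0, 70))
        assert got == list(range(31, 60))

    def test_monotone_waveform_has_no_candidates(self):
        w, basis = self._waveform_from_signal(np.linspace(-1, 1, 80) ** 3)
        assert find_split_candidates(w, basis, PeakRange(0, 79)) == []

    def test_matches_brute_force_extrema_scan(self):
        i = np.arange(120, dtype=float)
        signal = (
            np.exp(-0.5 * ((i - 30) / 8) ** 2)
            - 0.7 * np.exp(-0.5 * ((i - 60) / 9) ** 2)
            + np.exp(-0.5 * ((i - 95) / 7) ** 2)
        )
        w, basis = self._waveform_from_signal(signal)
        got = find_split_candidates(w, basis, PeakRange(0, 119))
        ext = [
            j
            for j in range(1, 119)
            if (signal[j] > signal[j - 1] and signal[j] > signal[j + 1])
            or (signal[j] < signal[j - 1] and signal[j] < signal[j + 1])
        ]
        expect = []
        for e1, e2 in zip(ext[:-1], ext[1:]):
            expect.extend(range(e1 + 1, e2))
        assert got == expect


class TestBestSplit:
    def test_matches_exhaustive_oracle(self):
        """The chosen split minimizes per-candidate RSS computed independently."""
        ds = simulate(SimConfig(seed=77, condition="free", latency_sd_ms=30.0, n_trials=20))
        f1 = fit(ds.data)
        basis = f1.basis
        winner, _ = best_split(ds.data, f1, basis, SEARCH_RANGE, refit=False)
        cands = find_split_candidates(f1.waveforms[0], basis, SEARCH_RANGE)
        b = f1.waveforms[0].coeffs
        wv, dv = basis.B @ b, basis.D @ b
        best_rss, best_s = np.inf, None
        for s in cands:
            m = np.arange(300) < s
            X = np.column_stack([wv * m, dv * m, wv * ~m, dv * ~m])
            beta, *_ = np.linalg.lstsq(X, ds.data.data.T, rcond=None)
            r = float(np.sum((ds.data.data.T - X @ beta) ** 2))
            if r < best_rss:
                best_rss, best_s = r, s
        assert winner.split_sample == best_s
        assert winner.rss == pytest.approx(best_rss, rel=1e-9)

    def test_masks_partition_support(self):
        ds = simulate(SimConfig(seed=78, condition="free", latency_sd_ms=30.0, n_trials=15))
        f1 = fit(ds.data)
        winner, f2 = best_split(ds.data, f1, f1.basis, SEARCH_RANGE)
        left, right = winner.masks
        assert np.array_equal(left ^ right, f1.waveforms[0].support_mask)
        assert f2.n_waveforms == 2

    def test_nesting_two_waveforms_never_fit_worse(self):
        ds = simulate(SimConfig(seed=79, condition="free", latency_sd_ms=30.0, n_trials=15))
        f1 = fit(ds.data)
        _, f2 = best_split(ds.data, f1, f1.basis, SEARCH_RANGE)
        assert f2.rss <= f1.rss * (1 + 1e-9)

    def test_shared_signal_split_gains_at_most_representation_error(self):
        """Noiseless fixed-condition data: the split can only nibble at the
        basis truncation residue, not explain real structure."""
        ds = simulate(
            SimConfig(
                seed=80,
                latency_sd_ms=0.0,
                snr=np.inf,
                noise=NoiseSpec(kind="white", sigma=0.0),
            )
        )
        f1 = fit(ds.data)
        _, f2 = best_split(ds.data, f1, f1.basis, SEARCH_RANGE)
        proj = f1.basis.B @ (f1.basis.B.T @ ds.clean.T)
        rep_energy = float(np.sum((ds.clean.T - proj) ** 2))
        assert f1.rss - f2.rss <= rep_energy + 1e-9
        assert f1.rss <= rep_energy + 1e-9

    def test_no_candidates_is_an_error(self):
        t = np.arange(128) * 2.0
        ramp = np.tile(t / 100.0, (6, 1))
        data = TrialMatrix.from_array(ramp + 0.01 * np.random.default_rng(0).normal(size=(6, 128)), 500.0)
        f1 = fit(data, FitConfig(n_basis=3))
        with pytest.raises(InvalidInputError, match="no split possible"):
            best_split(data, f1, f1.basis, PeakRange(50, 200))


class TestSelectModel:
    def test_max_one_waveform_is_plain_fit(self):
        ds = simulate(SimConfig(seed=81, n_trials=20))
        m = select_model(ds.data, None, SEARCH_RANGE, max_waveforms=1)
        f = fit(ds.data)
        assert m.n_waveforms == 1
        assert m.aic == pytest.approx(f.aic)
        assert np.allclose(m.waveforms[0].coeffs, f.waveforms[0].coeffs)

    def test_free_condition_selects_two_waveforms(self):
        ds = simulate(SimConfig(seed=82, condition="free", latency_sd_ms=30.0))
        m = select_model(ds.data, None, SEARCH_RANGE, max_waveforms=2)
        assert m.n_waveforms == 2

    def test_fixed_model_generated_white_noise_selects_one(self):
        data, *_ = make_model_data(seed=83, noise_kind="white")
        m = select_model(data, None, SEARCH_RANGE, max_waveforms=2)
        assert m.n_waveforms == 1

    def test_aic_is_consistent_with_stored_rss(self):
        ds = simulate(SimConfig(seed=84, n_trials=20))
        m = select_model(ds.data, None, SEARCH_RANGE, max_waveforms=2)
        assert m.aic == aic(m.rss, m.n_params_k, m.n_points_n)

    def test_audit_records_candidates(self):
        ds = simulate(SimConfig(seed=85, condition="free", latency_sd_ms=30.0, n_trials=30))
        audit = []
        select_model(ds.data, None, SEARCH_RANGE, max_waveforms=2, audit=audit)
        assert audit and {"split_sample", "rss", "aic"} <= set(audit[0])


class TestSelectNBasis:
    def test_single_candidate_returned(self):
        ds = simulate(SimConfig(seed=86, n_trials=10))
        assert select_n_basis(ds.data, [12]) == 12

    def test_low_order_signal_selects_small_q(self):
        """Data whose waveform is a degree-5 polynomial need few basis functions."""
        rng = np.random.default_rng(87)
        t = np.arange(200) * 2.0
        basis6 = make_polynomial_basis(200, 6, t)
        shape = basis6.B @ rng.normal(size=6)
        a = 1 + 0.2 * rng.normal(size=40)
        clean = np.outer(a, shape)
        noisy = clean + 0.02 * np.std(shape) * rng.normal(size=clean.shape)
        data = TrialMatrix.from_array(noisy, sfreq=500.0)
        qs = [4, 6, 8, 10, 14, 20]
        q_star = select_n_basis(data, qs)
        assert q_star <= 10
        rss_at = {}
        for q in (q_star, 20):
            rss_at[q] = fit(data, FitConfig(n_basis=q)).rss
        assert rss_at[q_star] <= 1.05 * rss_at[20]

    def test_pure_noise_rss_gain_per_basis_function_exceeds_nominal(self):
        """On pure noise the alternating fit removes several noise-variance
        units of RSS per added basis function — more than the one unit a
        linear model with k = q + 2N parameters would: the bilinear model's
        effective dof exceeds its nominal parameter count, so the AIC is
        biased toward complexity (the same bias behind over-selection under
        correlated noise)."""
        qs = [5, 10, 15, 20]
        curves = []
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            data = TrialMatrix.from_array(rng.normal(size=(30, 150)), sfreq=500.0)
            curves.append([fit(data, FitConfig(n_basis=q)).rss for q in qs])
        mean_rss = np.mean(curves, axis=0)
        # sigma^2 = 1: nominal expectation is ~1 unit of RSS per extra q
        gain_per_q = (mean_rss[0] - mean_rss[-1]) / (qs[-1] - qs[0])
        assert gain_per_q > 1.0
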