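import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdsee.data_io import Cohort, EEProfile
from fdsee.smoothing import (
    DomainError,
    SmoothingError,
    evaluate_basis,
    evaluate_curves,
    fit_curves,
    make_bspline_basis,
    mean_curve,
    penalty_matrix,
    select_K_myopic,
)
from fdsee.synthetic import SimulationConfig, simulate_blank_room, simulate_cohort


def _cohort_from_matrix(Y, time=None):
    time = np.arange(1, Y.shape[1] + 1) if time is None else time
    return Cohort(
        [
            EEProfile(
                subject_id=f"s{i}",
                group="obese",
                weight=50.0,
                height=150.0,
                age=12.0,
                sex=0,
                time=time,
                see=row,
            )
            for i, row in enumerate(Y)
        ]
    )


class TestBasis:
    def test_bernstein_gram_closed_form(self):
        # K = order = 4 on [0,1] is the degree-3 Bernstein basis;
        # int B0^2 = int (1-t)^6 dt = 1/7
        basis = make_bspline_basis((0, 1), K=4)
        assert basis.gram[0, 0] == pytest.approx(1 / 7, abs=1e-12)
        # and int B0 B1 = int (1-t)^3 * 3t(1-t)^2 dt = 3/2 * B(2,6) = 3/42
        assert basis.gram[0, 1] == pytest.approx(3 / 42, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=405.0))
    def test_partition_of_unity(self, t):
        basis = make_bspline_basis((1, 405), K=17)
        assert evaluate_basis(basis, [t]).sum() == pytest.approx(1.0, abs=1e-10)

    def test_study_default_basis_shape(self):
        basis = make_bspline_basis((1, 405), K=40)
        assert basis.knots.size == 40 + 4
        interior = basis.knots[4:-4]
        assert interior.size == 36
        evals = np.linalg.eigvalsh(basis.gram)
        assert evals.min() > 0
        assert np.isfinite(evals.max() / evals.min())

    def test_K_below_order_rejected(self):
        with pytest.raises(ValueError):
            make_bspline_basis((0, 1), K=3)

    def test_gram_symmetric_positive_definite(self):
        basis = make_bspline_basis((1, 100), K=12)
        np.testing.assert_allclose(basis.gram, basis.gram.T, atol=1e-14)
        assert np.linalg.eigvalsh(basis.gram).min() > 0


class TestFit:
    def test_constant_series_reproduced_for_any_K_and_lambda(self):
        cohort = _cohort_from_matrix(np.full((1, 60), 0.7))
        for K, lam in [(6, 0.0), (12, 0.0), (12, 5.0)]:
            basis = make_bspline_basis((1, 60), K)
            curves = fit_curves(cohort, basis, lam=lam)
            vals = evaluate_curves(curves, np.linspace(1, 60, 200))
            np.testing.assert_allclose(vals, 0.7, atol=1e-8)
            assert curves.rss[0] == pytest.approx(0.0, abs=1e-16)

    def test_saturated_fit_interpolates(self):
        rng = np.random.default_rng(4)
        T = 25
        Y = 1.0 + 0.1 * rng.random((3, T))
        cohort = _cohort_from_matrix(Y)
        basis = make_bspline_basis((1, T), K=T)
        curves = fit_curves(cohort, basis, lam=0.0)
        np.testing.assert_allclose(curves.rss, 0.0, atol=1e-14)
        np.testing.assert_allclose(
            evaluate_curves(curves, np.arange(1, T + 1)), Y, atol=1e-6
        )

    def test_polynomials_up_to_degree_three_exact(self):
        t = np.arange(1, 81, dtype=float)
        Y = np.vstack([1 + 0.01 * t, 2 + 0.001 * t**2, 3 + 1e-5 * t**3])
        cohort = _cohort_from_matrix(Y)
        basis = make_bspline_basis((1, 80), K=10)
        curves = fit_curves(cohort, basis, lam=0.0)
        np.testing.assert_allclose(curves.rss, 0.0, atol=1e-12)

    def test_too_few_points_for_unpenalized_fit(self):
        cohort = _cohort_from_matrix(np.full((1, 10), 1.0))
        basis = make_bspline_basis((1, 10), K=12)
        with pytest.raises(SmoothingError):
            fit_curves(cohort, basis, lam=0.0)

    def test_smoothing_beats_raw_series_in_mise(self):
        cfg = SimulationConfig(n_per_group=(50, 50), T=200)
        cohort, truth = simulate_cohort(cfg, seed=21)
        basis = make_bspline_basis((1, 200), K=20)
        curves = fit_curves(cohort, basis)
        fitted = evaluate_curves(curves, truth.time)
        signal = truth.weights[:, None] ** 0.5 * truth.signals
        mise_smooth = ((fitted - signal) ** 2).mean()
        mise_raw = ((cohort.see_matrix() - signal) ** 2).mean()
        assert mise_smooth < mise_raw

    def test_affine_time_reparameterization_invariance(self):
        rng = np.random.default_rng(8)
        T = 90
        Y = 1.0 + 0.1 * rng.random((4, T))
        t = np.arange(1, T + 1)
        cohort_a = _cohort_from_matrix(Y, time=t)
        basis_a = make_bspline_basis((1, T), K=14)
        vals_a = evaluate_curves(fit_curves(cohort_a, basis_a), t)
        # same data, time mapped onto [0, 1]; note profiles need integer
        # minutes so fit directly via the basis least squares
        s = (t - 1) / (T - 1)
        basis_b = make_bspline_basis((0, 1), K=14)
        Phi = evaluate_basis(basis_b, s)
        coef = np.linalg.lstsq(Phi, Y.T, rcond=None)[0].T
        vals_b = coef @ Phi.T
        np.testing.assert_allclose(vals_a, vals_b, rtol=1e-7, atol=1e-9)


class TestMyopicSelection:
    def test_noise_free_cubic_selects_smallest_candidate(self):
        t = np.arange(1, 101, dtype=float)
        Y = np.vstack([5 + 1e-6 * (t - 50) ** 3, 4 + 1e-4 * t**2])
        cohort = _cohort_from_matrix(Y)
        K, trace = select_K_myopic(cohort, candidates=(10, 20, 40))
        assert K == 10

    def test_oversized_candidates_skipped_with_warning(self):
        cohort = _cohort_from_matrix(np.full((2, 50), 1.0))
        with pytest.warns(UserWarning, match="skipped"):
            K, _ = select_K_myopic(cohort, candidates=(10, 20, 80))
        assert K in (10, 20)

    def test_selection_stable_under_reseeding(self):
        # six true modes of variation; the selected K should not jitter
        modes = (
            lambda s: np.ones_like(s),
            lambda s: np.cos(np.pi * s),
            lambda s: np.sin(2 * np.pi * s),
            lambda s: np.cos(2 * np.pi * s),
            lambda s: np.sin(3 * np.pi * s),
            lambda s: np.cos(3 * np.pi * s),
        )
        cfg = SimulationConfig(
            n_per_group=(15, 15),
            T=200,
            eigenfunctions=modes,
            eigenvalues=(0.04, 0.017, 0.008, 0.004, 0.002, 0.001),
        )
        picks = []
        for seed in range(20):
            cohort, _ = simulate_cohort(cfg, seed=seed)
            K, _ = select_K_myopic(cohort, candidates=(10, 20, 40, 80))
            picks.append(K)
        values, counts = np.unique(picks, return_counts=True)
        assert counts.max() / len(picks) >= 0.9


class TestEvaluateAndMean:
    def test_mean_of_coefficients_equals_pointwise_mean(self, small_curves):
        curves, _ = small_curves
        grid = np.linspace(1, 120, 333)
        via_coef = mean_curve(curves) @ evaluate_basis(curves.basis, grid).T
        pointwise = evaluate_curves(curves, grid).mean(axis=0)
        np.testing.assert_allclose(via_coef, pointwise, atol=1e-12)

    def test_single_subject_mean_is_that_subject(self, small_curves):
        curves, _ = small_curves
        np.testing.assert_array_equal(mean_curve(curves, [0]), curves.coef[0])

    def test_outside_domain_raises(self, small_curves):
        curves, _ = small_curves
        with pytest.raises(DomainError):
            evaluate_curves(curves, [500.0])


class TestBlankRoom:
    def test_noise_suppressed_without_artifacts(self):
        cohort = simulate_blank_room(T=540, sigma=0.05, n_runs=5, level=1.0, seed=3)
        basis = make_bspline_basis((1, 540), K=40)
        curves = fit_curves(cohort, basis)
        fitted = evaluate_curves(curves, np.arange(1, 541))
        raw = cohort.see_matrix()
        sup_fit = np.abs(fitted - 1.0).max(axis=1)
        sup_raw = np.abs(raw - 1.0).max(axis=1)
        assert (sup_fit < sup_raw).all()
        # the fitted noise process has pointwise SD ~ sigma*sqrt(K/T) = 0.27 sigma,
        # so its supremum stays well below the raw traces' ~3.3 sigma excursions
        assert (sup_fit < 1.5 * 0.05).all()
        # noise passes to residuals: residual SD tracks the input noise SD
        resid_sd = np.sqrt(curves.rss / 540)
        np.testing.assert_allclose(resid_sd, 0.05, rtol=0.15)

    def test_zero_noise_reproduces_constant_exactly(self):
        cohort = simulate_blank_room(T=200, sigma=1e-12, n_runs=2, level=0.8, seed=1)
        basis = make_bspline_basis((1, 200), K=20)
        fitted = evaluate_curves(fit_curves(cohort, basis), np.arange(1, 201))
        np.testing.assert_allclose(fitted, 0.8, atol=1e-7)

    def test_penalty_matrix_annihilates_lines(self):
        basis = make_bspline_basis((1, 50), K=10)
        P = penalty_matrix(basis, m=2)
        # a straight line has zero curvature penalty
        c_line = np.linalg.lstsq(
            evaluate_basis(basis, np.linspace(1, 50, 60)),
            np.linspace(1, 50, 60),
            rcond=None,
        )[0]
        assert c_line @ P @ c_line == pytest.approx(0.0, abs=1e-8)
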