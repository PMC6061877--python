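"""Error propagation: derivatives, covariances and the Monte-Carlo oracle."""

import numpy as np
import pytest

from lpmadc import (dq_dh, fit_quantities, quantity_covariance,
                    total_treatment_error)
from lpmadc.uncertainty import QuantityCovariance

from .conftest import make_histogram, model_from_components, random_components


class TestDqDh:
    def test_single_component_unit_derivative(self, rng):
        """K = 1: Q = sum(H), so dQ/dH = 1 everywhere."""
        comps = random_components(rng, 1, 0)
        model = model_from_components(comps)
        h = make_histogram(rng.poisson(40, (8, 2)), model.binning)
        fit = fit_quantities(model, h)
        for method in ("analytic", "finite_difference"):
            D = dq_dh(model, h, fit, method=method)
            assert np.allclose(D, 1.0, atol=5e-3 if method != "analytic"
                               else 1e-9)

    def test_disjoint_support_indicator_derivatives(self, small_binning,
                                                    disjoint_components, rng):
        model = model_from_components(disjoint_components)
        h = make_histogram(rng.poisson(25, (8, 2)), small_binning)
        fit = fit_quantities(model, h)
        D = dq_dh(model, h, fit, method="analytic")
        D = D.reshape(2, 8, 2)
        assert np.allclose(D[0, :4, :], 1.0, atol=1e-8)
        assert np.allclose(D[0, 4:, :], 0.0, atol=1e-8)
        assert np.allclose(D[1, 4:, :], 1.0, atol=1e-8)

    def test_analytic_matches_finite_difference(self, rng):
        """Three overlapping components: implicit vs numerical derivatives."""
        comps = random_components(rng, 3, 0)
        model = model_from_components(comps)
        # large counts keep the finite-difference step small relative to
        # the cell contents, so truncation error stays below the tolerance
        q_true = np.array([5e4, 8e4, 4e4])
        M = (q_true @ comps.flat).reshape(8, 2)
        h = make_histogram(rng.poisson(M), model.binning)
        fit = fit_quantities(model, h)
        Da = dq_dh(model, h, fit, method="analytic")
        Df = dq_dh(model, h, fit, method="finite_difference")
        mask = np.abs(Da) > 1e-6
        # agreement is limited by the 1% finite-difference step itself
        assert np.allclose(Da[mask], Df[mask], rtol=1e-2, atol=1e-3)


class TestQuantityCovariance:
    def test_single_component_poisson_counting_error(self, rng):
        """K = 1 with chi2 <= 1: variance is the total count itself."""
        comps = random_components(rng, 1, 0)
        model = model_from_components(comps)
        h = make_histogram(rng.poisson(60, (8, 2)), model.binning)
        fit = fit_quantities(model, h)
        cov = quantity_covariance(model, h, fit, 0.5)
        assert cov.chi2_scale == 1.0  # clamped at unity
        assert cov.cov[0, 0] == pytest.approx(h.total, rel=1e-6)

    def test_disjoint_support_diagonal(self, small_binning,
                                       disjoint_components, rng):
        model = model_from_components(disjoint_components)
        counts = rng.poisson(30, (8, 2))
        h = make_histogram(counts, small_binning)
        fit = fit_quantities(model, h)
        cov = quantity_covariance(model, h, fit, 1.0)
        assert cov.cov[0, 0] == pytest.approx(counts[:4].sum(), rel=1e-6)
        assert cov.cov[1, 1] == pytest.approx(counts[4:].sum(), rel=1e-6)
        assert abs(cov.cov[0, 1]) < 1e-6 * counts.sum()

    def test_chi2_scale_boosts_errors(self, rng):
        comps = random_components(rng, 1, 0)
        model = model_from_components(comps)
        h = make_histogram(rng.poisson(50, (8, 2)), model.binning)
        fit = fit_quantities(model, h)
        c1 = quantity_covariance(model, h, fit, 1.0)
        c3 = quantity_covariance(model, h, fit, 3.0)
        assert c3.cov[0, 0] == pytest.approx(3.0 * c1.cov[0, 0])

    def test_count_scaling_linearity(self, rng):
        """Multiplying all counts by alpha scales the K=1 variance by alpha."""
        comps = random_components(rng, 1, 0)
        model = model_from_components(comps)
        base = rng.poisson(20, (8, 2)) + 1
        h1 = make_histogram(base, model.binning)
        h4 = make_histogram(4 * base, model.binning)
        v1 = quantity_covariance(model, h1, fit_quantities(model, h1), 1.0)
        v4 = quantity_covariance(model, h4, fit_quantities(model, h4), 1.0)
        assert v4.cov[0, 0] == pytest.approx(4.0 * v1.cov[0, 0], rel=1e-6)

    def test_psd_and_symmetry_over_random_models(self, rng):
        for _ in range(25):
            K = int(rng.integers(1, 4))
            comps = random_components(rng, K, 0)
            model = model_from_components(comps)
            q = rng.uniform(100, 800, K)
            M = (q @ comps.flat).reshape(8, 2)
            h = make_histogram(rng.poisson(M), model.binning)
            fit = fit_quantities(model, h)
            cov = quantity_covariance(model, h, fit, 1.0)
            assert np.allclose(cov.cov, cov.cov.T, atol=1e-10)
            eig = np.linalg.eigvalsh(cov.cov)
            assert eig.min() >= -1e-8 * np.trace(cov.cov)

    def test_monte_carlo_oracle_three_components(self, rng):
        """Propagated diagonal matches refit scatter under Poisson resampling."""
        comps = random_components(rng, 3, 0)
        model = model_from_components(comps)
        q_true = np.array([400.0, 700.0, 300.0])
        M = (q_true @ comps.flat).reshape(8, 2)
        h = make_histogram(np.rint(M).astype(int), model.binning)
        fit = fit_quantities(model, h)
        cov = quantity_covariance(model, h, fit, 1.0)
        qs = [fit_quantities(model,
                             make_histogram(rng.poisson(M), model.binning)
                             ).quantities
              for _ in range(200)]
        emp = np.cov(np.array(qs).T)
        rel = np.abs(np.diag(cov.cov) - np.diag(emp)) / np.diag(emp)
        assert np.all(rel < 0.25)


class TestTotalTreatmentError:
    def _cov(self, mat):
        return QuantityCovariance(np.asarray(mat, dtype=float), 1.0,
                                  "analytic")

    def test_single_component(self):
        cov = self._cov([[4.0, 0.0], [0.0, 9.0]])
        assert total_treatment_error(cov, [1]) == 3.0

    def test_independent_pythagorean_sum(self):
        cov = self._cov([[9.0, 0.0], [0.0, 16.0]])
        assert total_treatment_error(cov, [0, 1]) == 5.0

    def test_anticorrelated_cancellation(self):
        cov = self._cov([[4.0, -4.0], [-4.0, 4.0]])
        assert total_treatment_error(cov, [0, 1]) == 0.0

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            total_treatment_error(self._cov([[1.0]]), [3])


def test_full_training_propagation_exceeds_frozen_error(rng):
    """Propagating training-cohort noise can only widen per-fit errors."""
    from lpmadc import em_fit_control, extend_with_treatment
    from lpmadc.synthetic import make_components, simulate_cohort
    comps = make_components(2, 1, n_bins=32, seed=8)
    ctl, trt, _ = simulate_cohort(comps, 5, 5, voxels_per_tumor=3000,
                                  responding_fraction=0.4, seed=8)
    m = em_fit_control(ctl, 2, seed=8, restarts=3)
    mf = extend_with_treatment(m, trt, 1, seed=8, restarts=3)
    h = trt[0]
    fit = fit_quantities(mf, h)
    froz = quantity_covariance(mf, h, fit, 1.0, method="analytic")
    full = quantity_covariance(mf, h, fit, 1.0,
                               method="full_training_propagation",
                               control_histos=ctl, treated_histos=trt)
    t_idx = mf.components.treatment_indices
    assert total_treatment_error(full, t_idx) >= \
        0.8 * total_treatment_error(froz, t_idx)
    assert full.method == "full_training_propagation"
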