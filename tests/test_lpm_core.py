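"""Extended-likelihood EM: closed forms, invariants and oracle comparisons."""

import numpy as np
import pytest
from scipy.optimize import minimize

from lpmadc import (BinningScheme, PairedHistogram, em_fit_control,
                    extend_with_treatment, fit_quantities, log_likelihood)
from lpmadc.lpm_core import (CONTROL, TREATMENT, ComponentSet, _em_run,
                             sqrt_residual_chi2)
from .conftest import make_histogram, model_from_components, random_components


def _random_cohort(rng, components, n_tumors, total=2000):
    P = components.flat
    K = P.shape[0]
    histos = []
    for i in range(n_tumors):
        q = rng.dirichlet(np.ones(K)) * total
        counts = rng.poisson((q @ P).reshape(components.pmfs.shape[1], 2))
        histos.append(PairedHistogram(counts, f"t{i}",
                                      BinningScheme.uniform(components.pmfs.shape[1])))
    return histos


class TestLogLikelihood:
    def test_saturated_single_component_closed_form(self, small_binning, rng):
        counts = rng.poisson(30.0, size=(8, 2))
        h = make_histogram(counts, small_binning)
        pmf = counts / counts.sum()
        comps = ComponentSet(pmf[None], (CONTROL,))
        ll = log_likelihood([h], comps, [np.array([counts.sum()])])
        H = counts.astype(float)
        mask = H > 0
        expected = float((H[mask] * np.log(H[mask])).sum() - H.sum())
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_total_quantity_optimum_at_observed_total(self, small_binning, rng):
        """Any rescaling of the extended-ML quantities lowers the likelihood."""
        counts = rng.poisson(25.0, size=(8, 2))
        h = make_histogram(counts, small_binning)
        pmf = counts / counts.sum()
        comps = ComponentSet(pmf[None], (CONTROL,))
        q_opt = float(counts.sum())
        ll_opt = log_likelihood([h], comps, [np.array([q_opt])])
        for alpha in [0.5, 0.8, 0.95, 1.05, 1.3, 2.0]:
            ll = log_likelihood([h], comps, [np.array([alpha * q_opt])])
            assert ll < ll_opt

    def test_treatment_terms_enter_subtracted_total(self, rng):
        comps = random_components(rng, 1, 1)
        model = model_from_components(comps)
        h = make_histogram(rng.poisson(10, (8, 2)), model.binning)
        q = np.array([50.0, 30.0])
        ll = log_likelihood([h], comps, [q])
        P = comps.flat
        H = h.counts.astype(float).ravel()
        M = q @ P
        mask = H > 0
        assert ll == pytest.approx(float(H[mask] @ np.log(M[mask]) - q.sum()))

    def test_negative_quantity_rejected(self, rng):
        comps = random_components(rng, 1, 0)
        h = make_histogram(np.ones((8, 2), dtype=int),
                           BinningScheme.uniform(8))
        with pytest.raises(ValueError):
            log_likelihood([h], comps, [np.array([-1.0])])


class TestEmFitControl:
    def test_single_component_closed_form(self, small_binning, rng):
        """N_C = 1: pooled normalized histogram and q_i = total, to 1e-10."""
        histos = [make_histogram(rng.poisson(20, (8, 2)), small_binning, f"t{i}")
                  for i in range(4)]
        model = em_fit_control(histos, 1, seed=0, restarts=2)
        pooled = sum(h.counts for h in histos).astype(float)
        pooled /= pooled.sum()
        assert np.allclose(model.components.pmfs[0], pooled, atol=1e-10)
        for h in histos:
            assert model.quantities[h.tumor_id][0] == pytest.approx(
                h.total, rel=1e-10)

    def test_disjoint_support_exact_recovery(self, small_binning,
                                             disjoint_components, rng):
        """Noiseless two-component mixture recovered up to permutation."""
        P = disjoint_components.flat
        histos = []
        for i in range(3):
            # multiples of 16 make every expected cell an exact integer
            q = np.array([416.0 + 96 * i, 896.0 - 96 * i])
            counts = np.rint((q @ P)).astype(int).reshape(8, 2)
            assert np.allclose(counts.ravel(), q @ P)
            histos.append(make_histogram(counts, small_binning, f"t{i}"))
        model = em_fit_control(histos, 2, seed=1, restarts=4,
                               tol=1e-14, max_iter=50000)
        got = model.components.flat
        want = disjoint_components.flat
        err = min(np.abs(got[list(p)] - want).max()
                  for p in [(0, 1), (1, 0)])
        # EM is an iterative method: recovery is exact up to its
        # convergence limit, a few orders above float resolution
        assert err < 1e-5

    def test_loglik_monotone_over_seeds(self, small_binning, rng):
        """EM never decreases the extended log-likelihood, any seed."""
        comps = random_components(rng, 3, 0)
        histos = _random_cohort(rng, comps, 4)
        H = np.stack([h.counts.astype(float).ravel() for h in histos])
        for seed in range(20):
            r = np.random.default_rng(seed)
            P0 = r.dirichlet(np.ones(16), size=3)
            Q0 = np.tile((H.sum(axis=1) / 3)[:, None], (1, 3))
            _, _, _, trace, _, _ = _em_run(H, P0, Q0, 0, 1e-10, 200)
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-7 * (np.abs(trace[:-1]) + 1))

    def test_mass_conservation_and_pmf_normalization(self, small_binning, rng):
        comps = random_components(rng, 2, 0)
        histos = _random_cohort(rng, comps, 5)
        model = em_fit_control(histos, 2, seed=3, restarts=2)
        for h in histos:
            assert model.quantities[h.tumor_id].sum() == pytest.approx(
                h.total, rel=1e-6)
        sums = model.components.flat.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_too_many_components_rejected(self, small_binning):
        h = make_histogram(np.eye(8, 2, dtype=int), small_binning)
        with pytest.raises(ValueError, match="non-empty"):
            em_fit_control([h], 10)


class TestExtendWithTreatment:
    def test_control_pmfs_frozen_bit_identical(self, small_binning, rng):
        comps = random_components(rng, 2, 1)
        ctl = _random_cohort(rng, ComponentSet(comps.pmfs[:2],
                                               (CONTROL,) * 2), 4)
        trt = _random_cohort(rng, comps, 4)
        base = em_fit_control(ctl, 2, seed=0, restarts=2)
        before = base.components.pmfs.copy()
        full = extend_with_treatment(base, trt, 1, seed=0, restarts=2)
        assert np.array_equal(full.components.pmfs[:2], before)
        assert full.components.labels == (CONTROL, CONTROL, TREATMENT)

    def test_rejects_double_extension(self, small_binning, rng):
        comps = random_components(rng, 1, 0)
        ctl = _random_cohort(rng, comps, 3)
        base = em_fit_control(ctl, 1, seed=0, restarts=1)
        full = extend_with_treatment(base, ctl, 1, seed=0, restarts=1)
        with pytest.raises(ValueError):
            extend_with_treatment(full, ctl, 1)


class TestFitQuantities:
    def test_pure_component_input(self, rng):
        comps = random_components(rng, 2, 0)
        model = model_from_components(comps)
        counts = np.rint(200.0 * comps.pmfs[0]).astype(int)
        h = make_histogram(counts, model.binning)
        fit = fit_quantities(model, h)
        assert fit.quantities[0] == pytest.approx(counts.sum(), rel=0.05)
        assert fit.quantities[1] < 0.05 * counts.sum()

    def test_disjoint_support_decouples(self, small_binning,
                                        disjoint_components, rng):
        model = model_from_components(disjoint_components)
        counts = rng.poisson(15, (8, 2))
        h = make_histogram(counts, small_binning)
        fit = fit_quantities(model, h)
        assert fit.quantities[0] == pytest.approx(counts[:4].sum(), rel=1e-9)
        assert fit.quantities[1] == pytest.approx(counts[4:].sum(), rel=1e-9)

    def test_agrees_with_independent_optimizer(self, rng):
        """EM quantities match Nelder-Mead on the same objective, K = 3."""
        comps = random_components(rng, 3, 0)
        model = model_from_components(comps)
        P = comps.flat
        q_true = np.array([300.0, 500.0, 200.0])
        counts = rng.poisson((q_true @ P).reshape(8, 2))
        h = make_histogram(counts, model.binning)
        fit = fit_quantities(model, h)

        H = h.counts.astype(float).ravel()

        def neg_ll(log_q):
            q = np.exp(log_q)
            M = q @ P
            mask = H > 0
            return -(H[mask] @ np.log(M[mask]) - q.sum())

        res = minimize(neg_ll, np.log(fit.quantities + 1.0),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        q_oracle = np.exp(res.x)
        assert np.allclose(fit.quantities, q_oracle, rtol=1e-4, atol=1e-3)

    def test_model_hist_consistency(self, rng):
        comps = random_components(rng, 2, 1)
        model = model_from_components(comps)
        h = make_histogram(rng.poisson(20, (8, 2)), model.binning)
        fit = fit_quantities(model, h)
        assert fit.model_hist.min() >= 0
        assert fit.model_hist.sum() == pytest.approx(fit.quantities.sum(),
                                                     rel=1e-9)

    def test_empty_histogram_rejected(self, rng):
        comps = random_components(rng, 1, 0)
        model = model_from_components(comps)
        h = make_histogram(np.zeros((8, 2), dtype=int), model.binning)
        with pytest.raises(ValueError, match="empty"):
            fit_quantities(model, h)


class TestInvariants:
    def test_label_permutation_leaves_likelihood_unchanged(self, rng):
        comps = random_components(rng, 3, 0)
        h = make_histogram(rng.poisson(12, (8, 2)), BinningScheme.uniform(8))
        q = np.array([100.0, 200.0, 50.0])
        ll1 = log_likelihood([h], comps, [q])
        perm = [2, 0, 1]
        comps2 = ComponentSet(comps.pmfs[perm], (CONTROL,) * 3)
        ll2 = log_likelihood([h], comps2, [q[perm]])
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_chi2_quadratic_in_residual(self):
        H = np.array([100.0, 50.0])
        M1 = (np.sqrt(H) - 0.5) ** 2  # residual 0.5 on sqrt scale
        M2 = (np.sqrt(H) - 1.0) ** 2  # doubled residual
        c1, _, _, _ = sqrt_residual_chi2([H], [M1], 0)
        c2, _, _, _ = sqrt_residual_chi2([H], [M2], 0)
        assert c2 == pytest.approx(4.0 * c1)


def test_model_roundtrip_serialization(tmp_path, rng):
    from lpmadc import io as lio
    comps = random_components(rng, 2, 1)
    model = model_from_components(comps)
    model.quantities = {"t0": np.array([1.0, 2.0, 3.0])}
    model.training_meta = {"seed": 1, "loglik": -12.5}
    lio.save_model(model, tmp_path / "m")
    back = lio.load_model(tmp_path / "m")
    assert back.components.labels == model.components.labels
    assert back.training_meta == model.training_meta
    assert np.allclose(back.components.pmfs, model.components.pmfs,
                       atol=1e-15)
    assert np.array_equal(back.quantities["t0"], model.quantities["t0"])
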