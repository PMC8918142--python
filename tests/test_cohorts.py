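"""Tests for the transformation-model cohort simulator."""

import math

import numpy as np
import pytest

import survscreen as sv
from survscreen.cohorts import apply_link


class TestTransform:
    def test_known_value(self):
        # log(0.5 (e^2 - 1)) evaluated independently
        assert sv.transform_H(1.0) == pytest.approx(math.log(0.5 * (math.e**2 - 1)), abs=1e-12)

    def test_inverse_round_trip(self, rng):
        u = rng.uniform(-20, 20, size=200)
        assert np.allclose(sv.transform_H(sv.transform_H_inv(u)), u, atol=1e-10)
        assert sv.transform_H(sv.transform_H_inv(0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_closed_form(self):
        assert sv.transform_H_inv(0.0) == pytest.approx(0.5 * math.log(3), abs=1e-12)
        # for large u, t ~ u/2 + log(2)/2 asymptotically dominated by u/2
        assert sv.transform_H_inv(50.0) == pytest.approx(25.0 + 0.5 * math.log(2), abs=1e-6)

    def test_strictly_increasing(self, rng):
        t = np.sort(rng.uniform(0.001, 10, size=200))
        h = sv.transform_H(t)
        assert np.all(np.diff(h) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sv.transform_H(0.0)
        with pytest.raises(ValueError):
            sv.transform_H(-1.0)


class TestEffectVectors:
    def test_sim1_structure(self):
        spec = sv.build_beta("sim1")
        assert len(spec.beta) == 2000
        assert len(spec.support) == 14
        assert spec.beta[spec.support].sum() == pytest.approx(-4.8)

    def test_sim3_has_15_nonzeros(self):
        spec = sv.build_beta("sim3")
        assert len(spec.support) == 15
        assert set(np.abs(spec.beta[spec.support])) == {1.5}

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            sv.build_beta("sim9")

    def test_sim2_links(self):
        spec = sv.build_links()
        # feature 4 (1-based): g(x) = beta * x^2 with beta = 0.8
        assert apply_link(spec.links[3], spec.beta[3], np.array([2.0]))[0] == pytest.approx(3.2)
        # feature 5: indicator of x > 0
        assert apply_link(spec.links[4], spec.beta[4], np.array([-1.0]))[0] == 0.0
        # feature 3 stays linear: 0.5 * 2
        assert apply_link(spec.links[2], spec.beta[2], np.array([2.0]))[0] == pytest.approx(1.0)


class TestLinearPredictor:
    def test_all_linear_matches_matmul(self, rng):
        X = rng.standard_normal((20, 8))
        beta = rng.standard_normal(8)
        eta = sv.linear_predictor(X, sv.EffectSpec(beta=beta))
        assert np.allclose(eta, X @ beta)

    def test_sim2_abs_link(self):
        spec = sv.build_links(p=30)
        X = np.zeros((1, 30))
        X[0, 0] = -2.0  # beta_1 = -1, link |x|
        assert sv.linear_predictor(X, spec)[0] == pytest.approx(-1.0 * 2.0)
        assert sv.linear_predictor(np.zeros((1, 30)), spec)[0] == 0.0

    def test_shape_error(self):
        with pytest.raises(ValueError):
            sv.linear_predictor(np.zeros((3, 4)), sv.EffectSpec(beta=np.ones(5)))


class TestNetworkCovariance:
    def test_ar1_exact(self):
        cov, edges = sv.generate_network_covariance(sv.NetworkSpec("ar1", p=3, rho=0.5))
        assert np.allclose(cov, [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        assert edges == [(0, 1), (1, 2)]

    def test_band_chain_edges(self):
        _, edges = sv.generate_network_covariance(sv.NetworkSpec("band", p=10, bandwidth=1))
        assert len(edges) == 9

    def test_hub_edge_count(self):
        _, edges = sv.generate_network_covariance(
            sv.NetworkSpec("hub", p=100, group_size=20), seed=0
        )
        assert len(edges) == 5 * 19

    @pytest.mark.parametrize("structure", ["band", "hub", "cluster", "scale_free"])
    def test_unit_diagonal_positive_definite(self, structure):
        cov, edges = sv.generate_network_covariance(
            sv.NetworkSpec(structure, p=60, group_size=15), seed=3
        )
        assert np.allclose(np.diag(cov), 1.0)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        assert np.allclose(cov, cov.T)
        # precision sparsity pattern equals adjacency plus diagonal
        prec = np.linalg.inv(cov)
        prec[np.abs(prec) < 1e-8] = 0.0
        A = np.zeros((60, 60))
        for j, k in edges:
            A[j, k] = A[k, j] = 1
        offdiag = (prec != 0) & ~np.eye(60, dtype=bool)
        assert np.array_equal(offdiag, A.astype(bool))

    def test_draw_covariates_moments(self):
        cov, _ = sv.generate_network_covariance(sv.NetworkSpec("ar1", p=3, rho=0.5))
        X = sv.draw_covariates(50_000, cov, seed=5)
        corr = np.corrcoef(X.T)
        assert corr[0, 1] == pytest.approx(0.5, abs=0.02)
        assert corr[0, 2] == pytest.approx(0.25, abs=0.02)
        assert np.allclose(X.var(axis=0), 1.0, atol=0.03)

    def test_draw_covariates_reproducible(self):
        cov, _ = sv.generate_network_covariance(sv.NetworkSpec("ar1", p=4))
        assert np.array_equal(sv.draw_covariates(10, cov, seed=1), sv.draw_covariates(10, cov, seed=1))


class TestContamination:
    def test_prob_zero_identity(self, rng):
        X = rng.standard_normal((30, 10))
        Xc, mask = sv.contaminate(X, sv.ContaminationSpec(prob=0.0), seed=0)
        assert np.array_equal(Xc, X)
        assert not mask.any()

    def test_prob_one_heavy_tails(self, rng):
        from scipy import stats

        X = rng.standard_normal((2000, 20))
        Xc, mask = sv.contaminate(X, sv.ContaminationSpec(prob=1.0), seed=1)
        assert mask.all()
        # t(2) has no finite kurtosis; sample excess kurtosis far above Gaussian
        assert stats.kurtosis(Xc.ravel()) > 10

    def test_mask_frequency(self, rng):
        X = rng.standard_normal((500, 200))
        _, mask = sv.contaminate(X, sv.ContaminationSpec(prob=0.1), seed=2)
        n_entries = mask.size
        sigma = np.sqrt(0.1 * 0.9 / n_entries)
        assert abs(mask.mean() - 0.1) < 4 * sigma

    def test_per_subject_mode(self, rng):
        X = rng.standard_normal((200, 10))
        _, mask = sv.contaminate(X, sv.ContaminationSpec(prob=0.3, per_subject=True), seed=3)
        # a contaminated subject has its whole row flagged
        rows = mask.any(axis=1)
        assert np.array_equal(mask, np.repeat(rows[:, None], 10, axis=1))


class TestSurvivalDraws:
    def test_ph_median(self):
        T = sv.draw_survival(np.zeros(200_000), sv.ErrorModel("extreme_value_ph"), seed=1)
        # solve 0.5 (e^{2t} - 1) = log 2
        expected = 0.5 * math.log(1 + 2 * math.log(2))
        assert np.median(T) == pytest.approx(expected, abs=0.005)

    def test_po_median(self):
        T = sv.draw_survival(np.zeros(200_000), sv.ErrorModel("logistic_po"), seed=2)
        expected = 0.5 * math.log(3)  # solve 0.5 (e^{2t} - 1) = 1
        assert np.median(T) == pytest.approx(expected, abs=0.005)

    def test_ph_survivor_function_deciles(self):
        n = 100_000
        T = sv.draw_survival(np.zeros(n), sv.ErrorModel("extreme_value_ph"), seed=3)
        for q in np.arange(0.1, 1.0, 0.1):
            t_q = np.quantile(T, q)
            s_model = math.exp(-0.5 * (math.exp(2 * t_q) - 1))
            assert abs(s_model - (1 - q)) < 3 / math.sqrt(n)

    def test_location_shift(self):
        # shifting eta by +c shifts the H(T) distribution by -c
        eta0 = np.zeros(100_000)
        T0 = sv.draw_survival(eta0, sv.ErrorModel("extreme_value_ph"), seed=4)
        T1 = sv.draw_survival(eta0 + 1.0, sv.ErrorModel("extreme_value_ph"), seed=4)
        m0 = np.median(sv.transform_H(T0))
        m1 = np.median(sv.transform_H(T1))
        assert m0 - m1 == pytest.approx(1.0, abs=0.02)


class TestCensoringCalibration:
    @pytest.mark.parametrize("target", [0.3, 0.5])
    def test_reaches_target(self, target):
        cfg = sv.scenario_config("sim1", p=2000)
        T, C, V, delta, cens = sv.draw_outcomes(
            sv.ScenarioConfig(
                n=100_000,
                network=cfg.network,
                effects=cfg.effects,
                censoring_rate=target,
                contamination=None,
            ),
            100_000,
            seed=11,
        )
        assert 1 - delta.mean() == pytest.approx(target, abs=0.01)
        assert cens.a == 0.0 and np.isfinite(cens.b)

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            sv.calibrate_censoring(0.0, lambda n, rng: rng.exponential(size=n))


class TestSimulate:
    def test_cohort_contracts(self):
        cohort = sv.simulate(sv.scenario_config("sim1", n=100, p=80), seed=7)
        assert cohort.X.shape == (100, 80)
        assert len(cohort.truth) == 14
        assert np.allclose(cohort.V, np.minimum(cohort.T_true, cohort.C_true))
        assert np.array_equal(cohort.delta, (cohort.T_true <= cohort.C_true).astype(int))
        assert np.all(cohort.V > 0)

    def test_no_censoring_flag(self):
        cfg = sv.ScenarioConfig(
            n=50,
            network=sv.NetworkSpec("ar1", p=40),
            effects=sv.build_beta("sim1", p=40),
            censoring_rate=None,
            contamination=None,
        )
        cohort = sv.simulate(cfg, seed=8)
        assert cohort.delta.sum() == 50

    def test_determinism(self):
        cfg = sv.scenario_config("sim3", n=60, p=50, structure="hub")
        a = sv.simulate(cfg, seed=9)
        b = sv.simulate(cfg, seed=9)
        # allclose rather than bitwise: threaded BLAS matmul reduction order
        # can perturb the last float bit between calls
        assert np.allclose(a.X, b.X, rtol=0, atol=1e-10)
        assert np.allclose(a.V, b.V, rtol=0, atol=1e-10)
        assert np.array_equal(a.delta, b.delta)
        assert np.array_equal(a.contaminated_mask, b.contaminated_mask)

    def test_eta_uses_clean_covariates_by_default(self):
        cfg = sv.scenario_config("sim1", n=80, p=60)
        cohort = sv.simulate(cfg, seed=10)
        # contamination must have touched X but not the latent times:
        # re-simulating without contamination from the same seed gives identical V
        from dataclasses import replace

        clean = sv.simulate(replace(cfg, contamination=None), seed=10)
        assert not np.array_equal(cohort.X, clean.X)
        assert np.array_equal(cohort.V, clean.V)
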