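"""Growth-model primitives against independent oracles.

The hypergeometric/Poisson factors are checked against scipy's
distributions and hand-enumerated draws; the Newton-Raphson fit against
dense grid search; the posterior against its two algebraic routes.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gbmgrowth.growth import (TumorGrowthModel, detection_pmf, eventual_volume,
                              fit_lambda_star, fit_mle, joint_step_pmf,
                              log_likelihood, posterior, prob_no_undetected,
                              proliferation_pmf, weighted_prior,
                              _log_likelihood_raw, _profiled_lambda)
from gbmgrowth.simulate import simulate_trajectory
from gbmgrowth.trajectory import CellTrajectory, GrowthParameters


class TestDetectionPmf:
    def test_no_malignant_cells_remaining(self):
        assert detection_pmf(0, 2, 5, 0) == pytest.approx(1.0)

    def test_enumeration_oracle_value(self):
        # C(2,1)*C(3,1)/C(5,2) = 6/10 over the 10 unordered draws
        assert detection_pmf(1, 2, 5, 2) == pytest.approx(0.6, abs=1e-12)

    @pytest.mark.parametrize("m,N,K", [(3, 8, 3), (0, 4, 2), (5, 5, 5)])
    def test_normalization(self, m, N, K):
        total = sum(detection_pmf(k, m, N, K) for k in range(m + 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_hypergeom(self, rng):
        for _ in range(50):
            N = int(rng.integers(1, 30))
            K = int(rng.integers(0, N + 1))
            m = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, m + 1))
            assert detection_pmf(k, m, N, K) == pytest.approx(
                stats.hypergeom.pmf(k, N, K, m), abs=1e-12)

    @pytest.mark.parametrize("args", [(-1, 2, 5, 2), (1, 6, 5, 2),
                                      (3, 2, 5, 2), (1, 2, 5, 6)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            detection_pmf(*args)


class TestProliferationPmf:
    def test_poisson_at_zero(self):
        p = GrowthParameters(nu=10, nu_star=5, lam=0.2)
        assert proliferation_pmf(0, p, mode="literal") == pytest.approx(
            math.exp(-2.0), abs=1e-12)

    def test_closed_form_value(self):
        p = GrowthParameters(nu=10, nu_star=5, lam=0.2)
        assert proliferation_pmf(2, p, mode="literal") == pytest.approx(
            4 * math.exp(-2.0) / 2, abs=1e-12)

    def test_depleted_equals_literal_before_any_detection(self):
        p = GrowthParameters(nu=10, nu_star=5, lam=0.2)
        assert proliferation_pmf(3, p, M_prev=0, mode="depleted") == \
            pytest.approx(proliferation_pmf(3, p, M_prev=0, mode="literal"))

    def test_nonpositive_mean_rejected(self):
        p = GrowthParameters(nu=10, nu_star=5, lam=0.2)
        with pytest.raises(ValueError, match="mean"):
            proliferation_pmf(1, p, M_prev=10, mode="depleted")


class TestJointStepPmf:
    def test_factorization_against_oracle_factors(self):
        p = GrowthParameters(nu=5, nu_star=2, lam=0.4)
        expect = 0.6 * stats.poisson.pmf(2, 2.0)
        assert joint_step_pmf(2, 1, p, mode="literal") == pytest.approx(
            expect, abs=1e-12)

    def test_detection_factor_one_reduces_to_poisson(self):
        p = GrowthParameters(nu=8, nu_star=0, lam=0.3)
        assert joint_step_pmf(3, 0, p, mode="literal") == pytest.approx(
            proliferation_pmf(3, p, mode="literal"), abs=1e-14)

    @pytest.mark.parametrize("nu,nu_star,lam", [(12, 5, 0.2), (20, 8, 0.1)])
    def test_truncated_normalization_brute_force(self, nu, nu_star, lam):
        """Sum over all (m <= nu, m* <= m), with the Poisson truncated to
        the population and renormalized, is exactly 1."""
        p = GrowthParameters(nu=nu, nu_star=nu_star, lam=lam)
        pois_norm = sum(proliferation_pmf(m, p, mode="literal")
                        for m in range(nu + 1))
        total = 0.0
        for m in range(nu + 1):
            pois = proliferation_pmf(m, p, mode="literal") / pois_norm
            for k in range(m + 1):
                total += detection_pmf(k, m, nu, nu_star) * pois
        assert total == pytest.approx(1.0, abs=1e-10)


class TestLogLikelihood:
    def test_single_step_reduction(self, small_params):
        traj = CellTrajectory(m=[4], m_star=[2], delta_voxels=[10])
        expect = math.log(joint_step_pmf(4, 2, small_params, mode="literal"))
        assert log_likelihood(traj, small_params, mode="literal") == \
            pytest.approx(expect, abs=1e-12)

    def test_sum_decomposition(self, small_trajectory, small_params):
        total = 0.0
        M_prev = Ms_prev = 0
        for m, k in zip(small_trajectory.m, small_trajectory.m_star):
            total += math.log(joint_step_pmf(int(m), int(k), small_params,
                                             M_prev, Ms_prev, mode="literal"))
            M_prev += int(m)
            Ms_prev += int(k)
        assert log_likelihood(small_trajectory, small_params,
                              mode="literal") == pytest.approx(total, abs=1e-10)

    def test_infeasible_returns_neg_inf_not_exception(self, small_trajectory):
        tight = GrowthParameters(nu=10.0, nu_star=5.0, lam=0.1)
        assert log_likelihood(small_trajectory, tight) == -np.inf

    def test_appending_empty_step_multiplies_by_poisson_zero(self, small_params):
        traj = CellTrajectory(m=[4, 3], m_star=[2, 1], delta_voxels=[10, 10])
        extended = CellTrajectory(m=[4, 3, 0], m_star=[2, 1, 0],
                                  delta_voxels=[10, 10, 10])
        base = log_likelihood(traj, small_params, mode="literal")
        ext = log_likelihood(extended, small_params, mode="literal")
        assert ext - base == pytest.approx(
            -small_params.nu * small_params.lam, abs=1e-10)


class TestFitMle:
    def test_newton_matches_dense_grid_oracle(self):
        true = GrowthParameters(nu=150, nu_star=60, lam=0.1, lam_star=2.0)
        traj = simulate_trajectory(true, 5, seed=3, mode="depleted")
        fit, report = fit_mle(traj, mode="depleted")
        M_T, Ms_T = float(traj.M[-1]), float(traj.M_star[-1])
        best = -np.inf
        for nu in np.linspace(M_T + 0.5, 3 * M_T, 120):
            lam = _profiled_lambda(traj.m, nu, "depleted")
            for nus in np.linspace(Ms_T, min(nu - (M_T - Ms_T), nu), 120):
                ll = _log_likelihood_raw(traj.m, traj.m_star, nu, nus, lam,
                                         "depleted")
                best = max(best, ll)
        assert log_likelihood(traj, fit, mode="depleted") >= best - 1e-3

    def test_mle_beats_generating_parameters(self):
        true = GrowthParameters(nu=500, nu_star=200, lam=0.05)
        for seed in (1, 2, 3):
            traj = simulate_trajectory(true, 10, seed=seed, mode="depleted")
            fit, _ = fit_mle(traj, mode="depleted")
            assert log_likelihood(traj, fit, mode="depleted") >= \
                log_likelihood(traj, true, mode="depleted") - 1e-6

    def test_estimates_feasible(self):
        true = GrowthParameters(nu=300, nu_star=100, lam=0.08)
        traj = simulate_trajectory(true, 8, seed=11, mode="depleted")
        fit, report = fit_mle(traj, mode="depleted")
        assert fit.nu_star <= fit.nu
        assert fit.nu >= traj.M[-1]
        assert fit.nu_star >= traj.M_star[-1]
        assert report.n_iter >= 1 and np.isfinite(report.grad_norm)

    def test_literal_mode_collapses_to_boundary(self):
        """Documented pathology: under the literal Poisson mean the MLE
        sits at nu = M_T with lam = 1/T exactly."""
        true = GrowthParameters(nu=400, nu_star=150, lam=0.06)
        traj = simulate_trajectory(true, 10, seed=5, mode="literal")
        fit, _ = fit_mle(traj, mode="literal")
        assert fit.nu == pytest.approx(traj.M[-1], rel=1e-3)
        assert fit.lam == pytest.approx(1.0 / traj.T, rel=1e-3)


class TestFitLambdaStar:
    def test_newton_matches_closed_form(self, small_trajectory):
        nu_star = 40.0
        est, report = fit_lambda_star(small_trajectory, nu_star)
        Ms_prev = np.concatenate([[0.0], small_trajectory.M_star[:-1]])
        closed = small_trajectory.m_star.sum() / np.sum(nu_star - Ms_prev)
        if closed > 1:
            assert est == pytest.approx(closed, rel=1e-8)
        assert report.converged

    def test_scale_equivariance_at_fixed_exposures(self):
        traj = CellTrajectory(m=[5, 5, 5], m_star=[2, 2, 2],
                              delta_voxels=[5, 5, 5])
        nu_star = 10.0  # exposures 10, 8, 6
        est1, _ = fit_lambda_star(traj, nu_star, counts=np.array([30, 25, 20]))
        est2, _ = fit_lambda_star(traj, nu_star, counts=np.array([60, 50, 40]))
        assert est1 == pytest.approx(75 / 24, rel=1e-6)
        assert est2 == pytest.approx(2 * est1, rel=1e-6)

    def test_all_zero_counts_flagged_boundary(self):
        traj = CellTrajectory(m=[5, 5], m_star=[0, 0], delta_voxels=[1, 1])
        est, report = fit_lambda_star(traj, 10.0)
        assert report.boundary
        assert est == pytest.approx(1.0, abs=1e-5)


class TestWeightedPrior:
    def test_closed_form_cv_half(self):
        # mean (nu* - M*) lam* = 4 gives c.v. = 0.5
        p = GrowthParameters(nu=10, nu_star=2, lam=0.1, lam_star=2.0)
        for k in range(6):
            assert weighted_prior(k, p, 0) == pytest.approx(
                stats.poisson.pmf(k, 4.0) * 0.5, abs=1e-12)

    def test_total_mass_equals_cv(self):
        p = GrowthParameters(nu=10, nu_star=3, lam=0.1, lam_star=3.0)
        mean = 9.0
        total = sum(weighted_prior(k, p, 0) for k in range(200))
        assert total == pytest.approx(mean ** -0.5, abs=1e-10)
        assert total < 1.0

    def test_cv_decreasing_in_remaining_pool(self):
        cvs = [((10 - ms) * 2.0) ** -0.5 for ms in (0, 2, 4)]
        assert cvs == sorted(cvs)

    def test_constraint_violation_names_condition(self):
        p = GrowthParameters(nu=10, nu_star=1, lam=0.1, lam_star=1.01)
        with pytest.raises(ValueError, match="<= 1"):
            weighted_prior(0, p, 1)


class TestPosterior:
    def test_single_step_degenerate(self):
        traj = CellTrajectory(m=[4], m_star=[3], delta_voxels=[10])
        p = GrowthParameters(nu=20, nu_star=10, lam=0.1, lam_star=2.0)
        weights, mean = posterior(traj, p)
        assert weights == pytest.approx([1.0])
        assert mean == pytest.approx(3.0)

    def test_two_route_equality(self, small_trajectory):
        p = GrowthParameters(nu=60, nu_star=25, lam=0.08, lam_star=2.0)
        w1, m1 = posterior(small_trajectory, p, include_likelihood_factor=False)
        w2, m2 = posterior(small_trajectory, p, include_likelihood_factor=True)
        np.testing.assert_allclose(w1, w2, atol=1e-10)
        assert m1 == pytest.approx(m2, abs=1e-10)

    def test_weights_proportional_to_prior(self, small_trajectory):
        p = GrowthParameters(nu=60, nu_star=25, lam=0.08, lam_star=2.0)
        weights, _ = posterior(small_trajectory, p)
        g = []
        Ms_prev = 0
        for k in small_trajectory.m_star:
            g.append(weighted_prior(int(k), p, Ms_prev))
            Ms_prev += int(k)
        np.testing.assert_allclose(weights, np.array(g) / np.sum(g),
                                   atol=1e-12)

    def test_missing_lam_star_rejected(self, small_trajectory):
        with pytest.raises(ValueError, match="lam_star"):
            posterior(small_trajectory,
                      GrowthParameters(nu=60, nu_star=25, lam=0.08))


class TestEventualVolume:
    @pytest.mark.parametrize("h,v,expect", [(1.0, 100.0, 100.0),
                                            (0.0, 55.0, 0.0),
                                            (2.5, 40.0, 100.0)])
    def test_proportionality(self, h, v, expect):
        assert eventual_volume(h, v) == pytest.approx(expect)

    def test_linearity_in_initial_volume(self):
        assert eventual_volume(3.0, 200.0) == 2 * eventual_volume(3.0, 100.0)

    def test_discrete_mode_rounds(self):
        assert eventual_volume(1.26, 10.0, discrete=True) == 13.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            eventual_volume(-1.0, 10.0)


class TestProbNoUndetected:
    def test_zero_detections_no_evidence(self):
        assert prob_no_undetected([0])[0] == 0.0

    def test_ratio_of_squares_values(self):
        assert prob_no_undetected([3])[0] == pytest.approx(0.5625, abs=1e-12)
        assert prob_no_undetected([5])[0] == pytest.approx(25 / 36, abs=1e-12)

    def test_monotone_in_count(self):
        p = prob_no_undetected([0, 1, 3, 10, 100])
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p < 1))

    def test_matches_geometric_survival_function(self):
        for k in (1, 3, 7):
            geom_sf = stats.geom.sf(2, 1.0 / (k + 1))
            assert prob_no_undetected([k], r=2)[0] == pytest.approx(
                geom_sf, abs=1e-12)


@st.composite
def trajectories(draw):
    T = draw(st.integers(1, 6))
    m = draw(st.lists(st.integers(0, 8), min_size=T, max_size=T))
    m_star = [draw(st.integers(0, mi)) for mi in m]
    if sum(m) == 0:
        m = [mi + 1 for mi in m]
    return CellTrajectory(m=m, m_star=m_star, delta_voxels=[1] * T)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(traj=trajectories())
def test_posterior_contract_property(traj):
    """Weights sum to one and the posterior mean is a convex combination
    of per-step malignant counts, for arbitrary feasible trajectories."""
    nu_star = float(traj.M_star[-1] + 5)
    p = GrowthParameters(nu=float(traj.M[-1] + 10), nu_star=nu_star,
                         lam=0.1, lam_star=2.0)
    weights, mean = posterior(traj, p)
    assert abs(weights.sum() - 1.0) < 1e-10
    assert traj.m_star.min() - 1e-9 <= mean <= traj.m_star.max() + 1e-9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(m=st.integers(0, 12), N=st.integers(0, 30), data=st.data())
def test_detection_pmf_normalization_property(m, N, data):
    m = min(m, N)
    K = data.draw(st.integers(0, N))
    total = sum(detection_pmf(k, m, N, K) for k in range(m + 1))
    assert abs(total - 1.0) < 1e-10


def test_results_independent_of_region_sizes_and_labels(small_params):
    """The time labels and incremental region sizes attached to steps do
    not enter the model: only the count sequence matters."""
    a = CellTrajectory(m=[4, 3, 5], m_star=[2, 1, 3], delta_voxels=[1, 1, 1])
    b = CellTrajectory(m=[4, 3, 5], m_star=[2, 1, 3],
                       delta_voxels=[999, 5, 123])
    assert log_likelihood(a, small_params) == log_likelihood(b, small_params)
    wa, ma = posterior(a, small_params)
    wb, mb = posterior(b, small_params)
    np.testing.assert_array_equal(wa, wb)
    assert ma == mb


class TestTumorGrowthModel:
    def test_sklearn_style_params(self):
        model = TumorGrowthModel()
        params = model.get_params()
        assert params["mode"] == "depleted" and params["c"] == 1.0
        model.set_params(r=3, discrete_volumes=True)
        assert model.r == 3 and model.discrete_volumes
        with pytest.raises(ValueError):
            model.set_params(nonsense=1)

    def test_fit_predict_summarize(self):
        true = GrowthParameters(nu=400, nu_star=180, lam=0.07, lam_star=2.0)
        traj = simulate_trajectory(true, 8, seed=21)
        model = TumorGrowthModel().fit(traj)
        summary = model.summarize(v_initial=1000.0)
        assert summary.v_new == pytest.approx(
            summary.posterior_mean * 1000.0)
        assert 0.0 <= summary.p_subject < 1.0
        assert len(summary.step_weights) == traj.T
        assert model.predict(2000.0) == pytest.approx(2 * model.predict(1000.0))

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            TumorGrowthModel().predict(10.0)
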