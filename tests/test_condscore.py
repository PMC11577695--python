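"""Conditional-score estimator: trajectory fits, pooled variance, score
oracles, root solving, subgroup combination."""

import numpy as np
import pytest
from scipy.optimize import brentq

from enrichjm.condscore import (
    ConditionalScoreModel,
    combine_subgroups,
    ols_trajectory,
    pooled_sigma2,
)
from enrichjm.cox import CoxTimeVaryingModel
from enrichjm.exceptions import InsufficientMeasurements, NoResidualDf
from enrichjm.params import JointModelParams
from enrichjm.simulate import (
    TrialSnapshot,
    simulate_trial,
    snapshot_at_event_count,
)


class TestOlsTrajectory:
    def test_two_point_line(self):
        fit = ols_trajectory([0.0, 1.0], [1.0, 3.0], t=1.0)
        assert fit.bhat0 == pytest.approx(1.0)
        assert fit.bhat1 == pytest.approx(2.0)
        assert fit.xhat(1.0) == pytest.approx(3.0)
        # leverage at the second of two points: 1/2 + 1/2
        assert fit.leverage(1.0) == pytest.approx(1.0)

    def test_flat_data_and_center_leverage(self):
        fit = ols_trajectory([0.0, 1.0, 2.0], [5.0, 5.0, 5.0], t=2.0)
        assert fit.bhat1 == pytest.approx(0.0)
        assert fit.xhat(1.7) == pytest.approx(5.0)
        assert fit.leverage(1.0) == pytest.approx(1.0 / 3.0)

    def test_leverage_minimised_at_mean_time(self):
        rng = np.random.default_rng(0)
        v = np.sort(rng.uniform(0, 3, 7))
        d = rng.normal(size=7)
        fit = ols_trajectory(v, d, t=3.0)
        assert fit.leverage(fit.vbar) == pytest.approx(1.0 / 7.0)
        for t in (0.0, 1.0, 2.9):
            assert fit.leverage(t) >= 1.0 / 7.0 - 1e-12

    def test_prefix_restriction_and_errors(self):
        with pytest.raises(InsufficientMeasurements):
            ols_trajectory([0.0, 1.0], [1.0, 2.0], t=0.5)
        with pytest.raises(np.linalg.LinAlgError):
            ols_trajectory([1.0, 1.0], [1.0, 2.0], t=2.0)


def _one_subject_snapshot(times, values):
    return TrialSnapshot(
        analysis_index=1,
        calendar_time=10.0,
        subject_id=np.array([0]),
        subgroup=np.array([1]),
        psi=np.array([0]),
        recruit=np.array([0.0]),
        tobs=np.array([max(times) + 1.0]),
        delta=np.array([0]),
        meas_times=[np.asarray(times, dtype=float)],
        meas_values=[np.asarray(values, dtype=float)],
    )


class TestPooledSigma2:
    def test_collinear_gives_zero(self):
        snap = _one_subject_snapshot([0, 1, 2], [0, 1, 2])
        assert pooled_sigma2(snap, 1) == pytest.approx(0.0)

    def test_hand_computed_residual(self):
        # points (0,0),(1,1),(2,0): OLS slope 0, mean 1/3, RSS = 2/3, df 1
        snap = _one_subject_snapshot([0, 1, 2], [0, 1, 0])
        assert pooled_sigma2(snap, 1) == pytest.approx(2.0 / 3.0)

    def test_two_measurements_contribute_nothing(self):
        snap = _one_subject_snapshot([0, 1], [0, 1])
        with pytest.raises(NoResidualDf):
            pooled_sigma2(snap, 1)

    def test_simulated_variance_recovery(self, base_params, alt_snapshot):
        est = pooled_sigma2(alt_snapshot, 1)
        assert abs(est - base_params.sigma2) < 0.05 * base_params.sigma2


def _restricted_cox_score(snapshot, subgroup, theta):
    """Independent oracle: treatment-only partial score on risk sets
    restricted to subjects with two measurements by t (direct loops)."""
    idx = np.flatnonzero(snapshot.subgroup_mask(subgroup))
    tobs = snapshot.tobs[idx]
    delta = snapshot.delta[idx]
    psi = snapshot.psi[idx]
    v2 = np.array(
        [
            snapshot.meas_times[i][1] if len(snapshot.meas_times[i]) > 1 else np.inf
            for i in idx
        ]
    )
    score = 0.0
    for k in np.flatnonzero((delta == 1) & (v2 <= tobs)):
        t = tobs[k]
        risk = (tobs >= t) & (v2 <= t)
        w = np.exp(theta * psi[risk])
        score += psi[k] - (w * psi[risk]).sum() / w.sum()
    return score


class TestScoreOracles:
    def test_gamma0_theta_component_is_restricted_cox_score(self, alt_snapshot):
        model = ConditionalScoreModel(alt_snapshot, 1)
        for theta in (-0.4, 0.0, 0.3):
            u = model.score(0.0, theta)
            oracle = _restricted_cox_score(alt_snapshot, 1, theta)
            assert u[1] == pytest.approx(oracle, abs=1e-8)

    def test_gamma0_fixed_solve_matches_restricted_cox_root(self, alt_snapshot):
        res = ConditionalScoreModel(alt_snapshot, 1).fit(fix_gamma=0.0)
        root = brentq(
            lambda th: _restricted_cox_score(alt_snapshot, 1, th), -2, 2,
            xtol=1e-12,
        )
        assert res.theta_hat == pytest.approx(root, abs=1e-4)

    def test_sigma0_solve_matches_tvc_cox_with_ols_covariate(self, base_params):
        # with no measurement error the sufficient statistic is the OLS
        # prediction itself, so the score is the partial score of a Cox
        # model with the fitted trajectory as time-varying covariate
        p = base_params.replace(sigma2=0.0)
        rng = np.random.default_rng(21)
        data = simulate_trial(p, 900, theta_overrides=(-0.5, 0.0), rng=rng)
        snap = snapshot_at_event_count(data, 1, 120, 1)
        cs = ConditionalScoreModel(snap, 1).fit(sigma2=0.0)
        tvc = CoxTimeVaryingModel(snap, 1, covariate="ols").fit()
        assert cs.theta_hat == pytest.approx(tvc.theta_hat, abs=1e-4)
        assert cs.gamma_hat == pytest.approx(tvc.gamma_hat, abs=1e-4)

    def test_score_mean_zero_at_truth(self, base_params):
        rng = np.random.default_rng(23)
        us = []
        for _ in range(150):
            data = simulate_trial(
                base_params, 400, theta_overrides=(-0.5, 0.0), rng=rng
            )
            snap = snapshot_at_event_count(data, 1, 60, 1)
            m = ConditionalScoreModel(snap, 1)
            us.append(m.score(0.8, -0.5, base_params.sigma2))
        us = np.array(us)
        se = us.std(axis=0, ddof=1) / np.sqrt(len(us))
        assert np.all(np.abs(us.mean(axis=0)) < 3 * se)


class TestSolve:
    def test_parameter_recovery(self, alt_snapshot):
        res = ConditionalScoreModel(alt_snapshot, 1).fit()
        # single large snapshot: estimates near truth, convergent root
        assert abs(res.gamma_hat - 0.8) < 0.2
        assert abs(res.theta_hat + 0.5) < 0.35
        u = ConditionalScoreModel(alt_snapshot, 1).score(
            res.gamma_hat, res.theta_hat, res.sigma2_hat
        )
        assert np.abs(u).max() < 1e-8 * res.d

    def test_mean_theta_recovery_over_replicates(self, base_params):
        rng = np.random.default_rng(29)
        ths = []
        for _ in range(60):
            data = simulate_trial(
                base_params, 700, theta_overrides=(-0.5, 0.0), rng=rng
            )
            snap = snapshot_at_event_count(data, 1, 100, 1)
            ths.append(ConditionalScoreModel(snap, 1).fit().theta_hat)
        se = np.std(ths, ddof=1) / np.sqrt(len(ths))
        assert abs(np.mean(ths) + 0.5) < 3 * se + 0.02

    def test_zero_theta_gives_zero_z(self, alt_snapshot):
        res = ConditionalScoreModel(alt_snapshot, 1).fit()
        assert res.z == pytest.approx(-res.theta_hat * np.sqrt(res.info))

    def test_info_invariant_to_per_patient_normalisation(self, alt_snapshot):
        # info = [A_tot^{-1} B_tot A_tot^{-T}]_{22}^{-1}: the per-patient
        # scaling of A and B cancels
        res = ConditionalScoreModel(alt_snapshot, 1).fit()
        A, B, n = res.A, res.B, res.n
        for c in (1.0, 2.5, n):
            Ainv = np.linalg.inv(A * c)
            var = (Ainv @ (B * c) @ Ainv.T)[1, 1] * c / n
            assert 1.0 / var == pytest.approx(res.info, rel=1e-10)

    def test_summary_mentions_key_quantities(self, alt_snapshot):
        res = ConditionalScoreModel(alt_snapshot, 1).fit()
        s = res.summary()
        for token in ("gamma_hat", "theta_hat", "information", "events"):
            assert token in s


class TestCombineSubgroups:
    def test_equal_effects_pass_through(self, alt_snapshot):
        f1 = ConditionalScoreModel(alt_snapshot, 1).fit()
        f2 = ConditionalScoreModel(alt_snapshot, 2).fit()
        comb = combine_subgroups(f1, f1, 0.4)
        assert comb.theta_hat == pytest.approx(f1.theta_hat)
        lam = 2 / 3
        comb = combine_subgroups(f1, f2, lam)
        assert comb.theta_hat == pytest.approx(
            lam * f1.theta_hat + (1 - lam) * f2.theta_hat
        )
        assert comb.info == pytest.approx(
            1.0 / (lam**2 / f1.info + (1 - lam) ** 2 / f2.info)
        )

    def test_equal_information_closed_form(self):
        class F:
            def __init__(self, th, i):
                self.theta_hat, self.info = th, i

        comb = combine_subgroups(F(-0.5, 9.0), F(0.0, 9.0), 2 / 3)
        assert comb.info == pytest.approx(9.0 * 9 / 5)

    def test_boundary_limit_and_domain(self):
        class F:
            def __init__(self, th, i):
                self.theta_hat, self.info = th, i

        a, b = F(-0.4, 12.0), F(0.1, 5.0)
        comb = combine_subgroups(a, b, 1 - 1e-9)
        assert comb.theta_hat == pytest.approx(a.theta_hat, abs=1e-6)
        assert comb.info == pytest.approx(a.info, rel=1e-6)
        with pytest.raises(ValueError):
            combine_subgroups(a, b, 1.5)
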