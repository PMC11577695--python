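"""Design layer: threshold solve, selection densities, spending, boundary
equations and the Imax planner, validated against quadrature and
Monte-Carlo oracles at the Z-process level."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest, norm

from enrichjm.design import (
    Boundaries,
    _boundaries_at,
    _f_weights,
    _plan_infos,
    joint_density_zw,
    predict_information,
    selection_probabilities,
    simulate_z_process,
    solve_imax,
    solve_stage1_boundaries,
    solve_stage2_boundaries,
    solve_threshold_and_info,
    spend,
    stage2_conditional_density,
)
from enrichjm.params import DesignConfig

ZETA, I1 = solve_threshold_and_info(0.5, 0.6, 0.2)
LAM = 2.0 / 3.0


class TestThresholdSolve:
    def test_worked_design_example(self):
        assert ZETA == pytest.approx(0.674, abs=1e-3)
        assert I1 == pytest.approx(9.19, abs=0.01)

    def test_closed_form_is_exact_quantile(self):
        assert ZETA == pytest.approx(norm.ppf(0.75), abs=1e-12)

    def test_numeric_solve_agrees(self):
        zn, i1n = solve_threshold_and_info(0.5, 0.6, 0.2, method="numeric")
        assert zn == pytest.approx(ZETA, abs=1e-8)
        assert i1n == pytest.approx(I1, rel=1e-8)

    def test_equal_targets_give_zero_threshold(self):
        z, _ = solve_threshold_and_info(0.5, 0.3, 0.3)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            solve_threshold_and_info(0.5, 0.7, 0.4)
        with pytest.raises(ValueError):
            solve_threshold_and_info(-0.1, 0.6, 0.2)


class TestSelectionProbabilities:
    def test_solved_design_hits_targets(self):
        p = selection_probabilities(0.5, 0.0, ZETA, I1, 0.5 * I1)
        assert p[1] == pytest.approx(0.6, abs=1e-9)
        assert p["F"] == pytest.approx(0.2, abs=1e-9)

    def test_global_null_quartile_threshold(self):
        # zeta = Phi^{-1}(3/4): P(empty) = (3/4)^2, P(F) = (1/4)^2
        p = selection_probabilities(0.0, 0.0, norm.ppf(0.75), 9.0, 5.0)
        assert p["empty"] == pytest.approx(0.5625, abs=1e-12)
        assert p["F"] == pytest.approx(0.0625, abs=1e-12)

    @pytest.mark.parametrize("e1,e2", [(0.0, 0.0), (0.5, 0.0), (-0.3, 0.6)])
    def test_partition_sums_to_one(self, e1, e2):
        p = selection_probabilities(e1, e2, ZETA, I1, 4.0)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
        pc = selection_probabilities(e1, e2, ZETA, I1, 4.0, "conventional")
        assert set(pc) == {1, "F", "empty"}
        assert sum(pc.values()) == pytest.approx(1.0, abs=1e-12)
        assert pc[1] == pytest.approx(p[1])
        assert pc["F"] == pytest.approx(p["F"])


class TestJointDensities:
    EFF = (0.5, 0.0)
    I2 = 4.8

    @pytest.mark.parametrize("w", [1, 2, "F"])
    def test_normalisation_matches_selection_probability(self, w):
        probs = selection_probabilities(*self.EFF, ZETA, I1, self.I2)
        val, err = quad(
            lambda z: float(
                joint_density_zw(z, w, self.EFF, ZETA, I1, self.I2, LAM)
            ),
            -12,
            14,
            limit=300,
        )
        assert val == pytest.approx(probs[w], abs=1e-6)

    def test_w_density_vanishes_below_threshold(self):
        z = np.linspace(-3, ZETA, 50)
        assert np.all(
            joint_density_zw(z, 1, self.EFF, ZETA, I1, self.I2, LAM) == 0.0
        )

    def test_futility_index_has_no_density(self):
        with pytest.raises(ValueError):
            joint_density_zw(0.0, "empty", self.EFF, ZETA, I1, self.I2, LAM)

    def test_f_density_matches_monte_carlo(self):
        # draw (Z1, Z2), retain both-above-threshold, compare Z_F sample
        # with the analytic conditional density by KS
        rng = np.random.default_rng(99)
        n = 400_000
        mu1 = self.EFF[0] * math.sqrt(I1)
        z1 = rng.normal(mu1, 1.0, n)
        z2 = rng.normal(0.0, 1.0, n)
        keep = (z1 > ZETA) & (z2 > ZETA)
        c1, c2, _ = _f_weights(LAM, I1, self.I2)
        zf = c1 * z1[keep] + c2 * z2[keep]
        pF = selection_probabilities(*self.EFF, ZETA, I1, self.I2)["F"]

        grid = np.linspace(zf.min() - 1, zf.max() + 1, 4000)
        pdf = joint_density_zw(grid, "F", self.EFF, ZETA, I1, self.I2, LAM) / pF
        cdf_grid = np.cumsum(pdf) * (grid[1] - grid[0])
        cdf_grid /= cdf_grid[-1]

        res = kstest(zf, lambda x: np.interp(x, grid, cdf_grid))
        assert res.pvalue > 0.01


class TestStage2Conditional:
    def test_zero_drift_mean_and_variance(self):
        d = stage2_conditional_density(0.0, 0.0, 0.0, 4.0, 16.0)
        sd = math.sqrt(1 - 4.0 / 16.0)
        assert d == pytest.approx(norm.pdf(0.0) / sd)

    def test_independence_limit(self):
        d = stage2_conditional_density(1.3, -5.0, 0.7, 1e-9, 1.0)
        assert d == pytest.approx(norm.pdf(1.3 - 0.7), rel=1e-3)

    def test_integrates_to_one(self):
        val, _ = quad(
            lambda z2: float(stage2_conditional_density(z2, 1.1, 2.0, 9.0, 30.0)),
            -10,
            14,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            stage2_conditional_density(0.0, 0.0, 0.0, 5.0, 5.0)


class TestSpending:
    def test_quadratic_values(self):
        a1, a2, b1, b2 = spend(0.025, 0.1, 5.0, 10.0, 10.0)
        assert a1 == pytest.approx(0.025 * 0.25)
        assert a1 + a2 == pytest.approx(0.025)
        assert b1 == pytest.approx(0.1 * 0.25)
        assert b1 + b2 == pytest.approx(0.1)

    def test_cap_and_degenerate(self):
        a1, a2, *_ = spend(0.025, 0.1, 8.0, 15.0, 10.0)
        assert a1 + a2 == pytest.approx(0.025)  # beyond Imax: fully spent
        a1, a2, *_ = spend(0.025, 0.1, 6.0, 6.0, 10.0)
        assert a2 == pytest.approx(0.0)


def _plan_fixture():
    cfg = DesignConfig()
    m = (5.11, 5.11, 5.11)  # physical events-per-information constants
    d1 = math.ceil(m[0] * I1)
    imax, d_total = solve_imax(cfg, m, d1)
    infos1, infos2 = _plan_infos(cfg, m, d1, imax)
    bd = _boundaries_at(cfg, ZETA, infos1, infos2, imax, "full")
    return cfg, m, d1, imax, d_total, infos1, infos2, bd


class TestBoundaries:
    def setup_method(self):
        (self.cfg, self.m, self.d1, self.imax, self.d_total, self.infos1,
         self.infos2, self.bd) = _plan_fixture()

    def test_final_boundaries_meet(self):
        assert abs(self.bd.a2 - self.bd.b2) < 1e-4

    def test_stage1_self_consistency(self):
        # recomputed tail mass at b1 equals the spent alpha1
        from enrichjm.design import _integrate

        tot = 0.0
        for w in (1, 2, "F"):
            lo = max(self.bd.b1, ZETA if w != "F" else -8.0)
            tot += _integrate(
                lambda z: joint_density_zw(
                    z, w, (0.0, 0.0), ZETA, self.infos1[1], self.infos1[2], LAM
                ),
                lo,
                10.0,
            )
        assert tot == pytest.approx(self.bd.alpha1, abs=1e-8)

    def test_boundary_ordering_and_spend_totals(self):
        assert self.bd.a1 < self.bd.b1
        assert self.bd.alpha1 + self.bd.alpha2 == pytest.approx(self.cfg.alpha)
        assert self.bd.beta1 + self.bd.beta2 == pytest.approx(self.cfg.beta)

    def test_tiny_alpha1_caps_boundary(self):
        with pytest.warns(UserWarning):
            _, b1 = solve_stage1_boundaries(
                0.0, 0.01, ZETA, (0.5, 0.0),
                (self.infos1[1], self.infos1[2]), LAM,
            )
        assert b1 == 8.0

    def test_fwer_by_z_process_monte_carlo(self):
        # 10^5 replications of the two-stage statistic process under the
        # global null: total rejection probability = alpha within 3 MC SE
        rng = np.random.default_rng(123)
        out = simulate_z_process(
            (0.0, 0.0), ZETA, self.infos1, self.infos2, self.bd, LAM,
            200_000, rng,
        )
        fwer = out["reject"].mean()
        se = math.sqrt(0.025 * 0.975 / 200_000)
        assert abs(fwer - self.cfg.alpha) < 3 * se

    def test_power_by_z_process_monte_carlo(self):
        rng = np.random.default_rng(124)
        out = simulate_z_process(
            (0.5, 0.0), ZETA, self.infos1, self.infos2, self.bd, LAM,
            200_000, rng,
        )
        sel1 = out["w"] == "1"
        power = out["reject"][sel1].mean()
        se = math.sqrt(0.9 * 0.1 / sel1.sum())
        assert abs(power - 0.9) < 3 * se
        # selection frequencies match the analytic targets
        assert abs(sel1.mean() - 0.6) < 0.005
        assert abs((out["w"] == "F").mean() - 0.2) < 0.005

    def test_stage1_futility_spends_beta1_conditionally(self):
        # P(Z1 < a1 | W=1 ; Theta_A) equals beta1 normalised by P(W=1)
        rng = np.random.default_rng(125)
        mu1 = 0.5 * math.sqrt(self.infos1[1])
        z1 = rng.normal(mu1, 1.0, 400_000)
        z2 = rng.normal(0.0, 1.0, 400_000)
        w1 = (z1 > ZETA) & (z2 <= ZETA)
        frac = (z1[w1] < self.bd.a1).mean()
        p1 = selection_probabilities(0.5, 0.0, ZETA, *[self.infos1[1], self.infos1[2]])[1]
        target = self.bd.beta1  # conditional scale
        se = math.sqrt(target * (1 - target) / w1.sum())
        assert abs(frac - target) < 3 * se + 1e-3

    def test_theorem_strong_control_at_null_boundary(self):
        # drift configurations with theta_F = 0 must not exceed alpha
        rng = np.random.default_rng(126)
        for e1, e2 in [(0.6, -1.2), (0.3, -0.6), (-0.5, 1.0)]:
            eff = (e1, e2)
            assert LAM * e1 + (1 - LAM) * e2 == pytest.approx(0.0)
            out = simulate_z_process(
                eff, ZETA, self.infos1, self.infos2, self.bd, LAM,
                200_000, rng,
            )
            # true nulls: any hypothesis with non-positive benefit
            nulls = {"F"} | ({"1"} if e1 <= 0 else set()) | (
                {"2"} if e2 <= 0 else set()
            )
            false_rej = out["reject"] & np.isin(out["w"], list(nulls))
            se = math.sqrt(0.025 * 0.975 / 200_000)
            assert false_rej.mean() <= self.cfg.alpha + 3 * se

    def test_imax_monotone_in_beta(self):
        # demanding less power must lower the total event count
        cfg = DesignConfig()
        d_prev = None
        for beta in (0.05, 0.1, 0.2, 0.3):
            c = DesignConfig(beta=beta)
            _, d_tot = solve_imax(c, self.m, self.d1)
            if d_prev is not None:
                assert d_tot < d_prev
            d_prev = d_tot

    def test_final_information_is_imax_by_construction(self):
        assert self.infos2["F"] == pytest.approx(self.imax)
        assert self.d_total == math.ceil(self.m[2] * self.imax)

    def test_conventional_variant_solves_and_controls(self):
        # folding the biomarker-negative selection into futility leaves the
        # w = 1, F densities unchanged and the design still meets a2 = b2
        cfg = DesignConfig(omega_variant="conventional")
        imax, d_tot = solve_imax(cfg, self.m, self.d1)
        infos1, infos2 = _plan_infos(cfg, self.m, self.d1, imax)
        bd = _boundaries_at(cfg, ZETA, infos1, infos2, imax, "conventional")
        assert abs(bd.a2 - bd.b2) < 1e-4
        rng = np.random.default_rng(321)
        out = simulate_z_process(
            (0.0, 0.0), ZETA, infos1, infos2, bd, LAM, 200_000, rng,
            variant="conventional",
        )
        assert "2" not in set(out["w"])
        se = math.sqrt(0.025 * 0.975 / 200_000)
        assert abs(out["reject"].mean() - cfg.alpha) < 3 * se


class TestPredictInformation:
    def test_scaling(self):
        assert predict_information(9.0, 45, 45) == pytest.approx(9.0)
        assert predict_information(9.0, 45, 90) == pytest.approx(18.0)
        with pytest.raises(ValueError):
            predict_information(9.0, 0, 90)
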