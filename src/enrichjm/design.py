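"""Pre-trial and at-analysis design computation for the enrichment trial.

The interim uses the threshold rule: each subgroup with Z_j(1) > zeta is
selected (both -> continue in the full population F, neither -> stop for
futility).  Everything is driven by the joint law of the selection index W
and the selected statistic Z_W(1): under independence of Z_1(1), Z_2(1) the
w = 1, 2 densities are truncated normals, and the w = F density is the
convolution of the two scaled components of Z_F restricted to both
exceeding zeta (evaluated here in closed form through the conditional
normal law of one component given Z_F).

Error is spent as f(t) = min(alpha t^2, alpha), g(t) = min(beta t^2, beta)
of the full-population information fraction t = I_F/Imax; stage boundaries
(a1, b1, a2, b2) solve the spent-error equations, with the stage-2 tail
integrated against the stage-1 joint density and the canonical-joint-
distribution increment law.  Sample-size planning exploits the empirical
proportionality I = d/m between information and event count: the constants
m_j are calibrated by progressively censoring one simulated dataset, and
Imax is found by bisection so that the final boundaries meet (a2 = b2).

Drifts throughout are on the hazard-reduction scale: a beneficial effect
of magnitude e shifts Z by +e*sqrt(I).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .condscore import MIN_EVENTS_GUIDELINE, ConditionalScoreModel
from .cox import CoxModel, CoxTimeVaryingModel
from .exceptions import InfeasibleSpend, NoResidualDf, RootNotFound
from .params import DesignConfig, JointModelParams
from .simulate import simulate_trial, snapshot_at_calendar_time

__all__ = [
    "solve_threshold_and_info",
    "selection_probabilities",
    "joint_density_zw",
    "stage2_conditional_density",
    "spend",
    "solve_stage1_boundaries",
    "solve_stage2_boundaries",
    "calibrate_information_rate",
    "predict_information",
    "solve_imax",
    "plan_design",
    "DesignPlan",
    "Boundaries",
    "fit_method",
    "simulate_z_process",
]

_TAIL = 8.0  # standard-normal tails are truncated here


def _spend_error(side: str, msg: str) -> InfeasibleSpend:
    exc = InfeasibleSpend(msg)
    exc.side = side
    return exc
_GL_NODES = 160


def _gl(n=_GL_NODES):
    return np.polynomial.legendre.leggauss(n)


_GL_X, _GL_W = _gl()


def _integrate(f, a, b):
    """Fixed-order Gauss-Legendre integral of a vectorised integrand."""
    if b <= a:
        return 0.0
    x = 0.5 * (b - a) * _GL_X + 0.5 * (a + b)
    return 0.5 * (b - a) * float(np.sum(_GL_W * f(x)))


# ---------------------------------------------------------------------------
# Threshold rule
# ---------------------------------------------------------------------------

def solve_threshold_and_info(
    delta: float, p_select_1: float, p_select_F: float, method: str = "closed_form"
) -> tuple[float, float]:
    """Threshold zeta and interim information I1 meeting the selection
    targets under the design alternative (drift delta*sqrt(I1) in subgroup
    1, zero drift in subgroup 2, independent interim statistics).

    Closed form: with p1 + pF = P(Z1 > zeta) and p1/(p1+pF) = P(Z2 <= zeta),
    zeta = Phi^{-1}(p1/(p1+pF)) and
    I1 = ((zeta + Phi^{-1}(p1+pF)) / delta)^2.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    p1, pF = p_select_1, p_select_F
    if min(p1, pF) <= 0 or p1 + pF >= 1:
        raise ValueError("need p_select_1, p_select_F > 0 with sum < 1")
    zeta = norm.ppf(p1 / (p1 + pF))
    i1 = ((zeta + norm.ppf(p1 + pF)) / delta) ** 2
    if method == "closed_form":
        return float(zeta), float(i1)
    if method == "numeric":
        from scipy.optimize import fsolve

        def eqs(x):
            z, mu = x  # mu = delta*sqrt(I1)
            return [
                norm.sf(z - mu) * norm.cdf(z) - p1,
                norm.sf(z - mu) * norm.sf(z) - pF,
            ]

        sol = fsolve(eqs, [zeta, delta * math.sqrt(i1)], full_output=False)
        return float(sol[0]), float((sol[1] / delta) ** 2)
    raise ValueError("method must be 'closed_form' or 'numeric'")


def selection_probabilities(
    effect_1: float,
    effect_2: float,
    zeta: float,
    I1: float,
    I2: float,
    variant: str = "full",
) -> dict:
    """P(W = w) over the selection space for independent interim statistics
    with means effect_j*sqrt(I_j).  ``variant="conventional"`` folds the
    biomarker-negative selection into futility."""
    if min(I1, I2) <= 0:
        raise ValueError("informations must be positive")
    mu1 = effect_1 * math.sqrt(I1)
    mu2 = effect_2 * math.sqrt(I2)
    q1 = norm.sf(zeta - mu1)  # P(Z1 > zeta)
    q2 = norm.sf(zeta - mu2)
    probs = {
        1: q1 * (1 - q2),
        2: (1 - q1) * q2,
        "F": q1 * q2,
        "empty": (1 - q1) * (1 - q2),
    }
    if variant == "conventional":
        probs["empty"] += probs.pop(2)
    return probs


def _f_weights(lam, I1, I2):
    """Coefficients of Z_F = c1*Z1 + c2*Z2 (c1^2 + c2^2 = 1) and I_F."""
    i_f = 1.0 / (lam**2 / I1 + (1 - lam) ** 2 / I2)
    c1 = lam * math.sqrt(i_f / I1)
    c2 = (1 - lam) * math.sqrt(i_f / I2)
    return c1, c2, i_f


def joint_density_zw(
    z,
    w,
    effects: tuple[float, float],
    zeta: float,
    I1: float,
    I2: float,
    lam: float,
):
    """Joint density f(z, w) of the selected statistic and selection index.

    w in {1, 2}: truncated-normal form, zero at or below zeta.  w = "F":
    the restricted convolution of the two components of Z_F, evaluated via
    the conditional normal law of c1*Z1 given Z_F = z (both components must
    clear zeta).  w = "empty" carries the constant mass P(W = empty) and
    must never be passed to a z-integral (contract error).
    """
    e1, e2 = effects
    mu1 = e1 * math.sqrt(I1)
    mu2 = e2 * math.sqrt(I2)
    z = np.asarray(z, dtype=float)
    if w == 1:
        return np.where(z > zeta, norm.cdf(zeta - mu2) * norm.pdf(z - mu1), 0.0)
    if w == 2:
        return np.where(z > zeta, norm.cdf(zeta - mu1) * norm.pdf(z - mu2), 0.0)
    if w in ("F", "f"):
        c1, c2, _ = _f_weights(lam, I1, I2)
        m = c1 * mu1 + c2 * mu2
        # U = c1*Z1 ~ N(c1*mu1, c1^2); U | Z_F = z ~ N(mu_u, (c1*c2)^2)
        mu_u = c1 * mu1 + c1**2 * (z - m)
        s_u = c1 * c2
        hi = (z - c2 * zeta - mu_u) / s_u
        lo = (c1 * zeta - mu_u) / s_u
        return norm.pdf(z - m) * np.clip(norm.cdf(hi) - norm.cdf(lo), 0.0, None)
    if w in ("empty", None):
        raise ValueError(
            "the futility index has no z-density; its mass is "
            "selection_probabilities()['empty']"
        )
    raise ValueError(f"unknown selection index {w!r}")


def stage2_conditional_density(z2, z1, drift2: float, I_1: float, I_2: float):
    """Increment law of the canonical joint distribution: Z(2) | Z(1)=z1 is
    normal with mean drift2 + sqrt(I1/I2)*(z1 - drift1) and variance
    1 - I1/I2, where drift1 = drift2*sqrt(I1/I2)."""
    if not (0.0 < I_1 < I_2):
        raise ValueError("require 0 < I_1 < I_2")
    rho = math.sqrt(I_1 / I_2)
    mean = drift2 + rho * (np.asarray(z1, dtype=float) - drift2 * rho)
    sd = math.sqrt(1.0 - I_1 / I_2)
    return norm.pdf((np.asarray(z2, dtype=float) - mean) / sd) / sd


def _stage2_tail(z1, b2, drift2, I_1, I_2, lower=False):
    """P(Z(2) > b2 | Z(1) = z1) under the CJD (or <= if lower)."""
    rho = math.sqrt(I_1 / I_2)
    mean = drift2 + rho * (np.asarray(z1, dtype=float) - drift2 * rho)
    sd = math.sqrt(1.0 - I_1 / I_2)
    arg = (b2 - mean) / sd
    return norm.cdf(arg) if lower else norm.sf(arg)


# ---------------------------------------------------------------------------
# Error spending
# ---------------------------------------------------------------------------

def spend(alpha: float, beta: float, IF1: float, IF2: float, Imax: float):
    """Quadratic error spending over the full-population information
    fraction; returns (alpha1, alpha2, beta1, beta2)."""
    if not (0.0 < IF1 <= IF2):
        raise ValueError("require 0 < IF1 <= IF2")

    def f(t, total):
        return min(total * t**2, total)

    a1 = f(IF1 / Imax, alpha)
    a2 = f(IF2 / Imax, alpha) - a1
    b1 = f(IF1 / Imax, beta)
    b2 = f(IF2 / Imax, beta) - b1
    return a1, a2, b1, b2


def _omega(variant):
    return (1, 2, "F") if variant == "full" else (1, "F")


def solve_stage1_boundaries(
    alpha1: float,
    beta1: float,
    zeta: float,
    effects_alt: tuple[float, float],
    infos1: tuple[float, float],
    lam: float,
    variant: str = "full",
) -> tuple[float, float]:
    """Stage-1 futility/efficacy pair (a1, b1).

    b1 spends alpha1 as the global-null upper-tail mass summed over the
    selectable indices (a futility-stopped trial rejects nothing); a1
    spends beta1 as the lower-tail mass of the w=1 density under the
    design alternative.
    """
    I1, I2 = infos1
    null = (0.0, 0.0)

    def upper_mass(b):
        tot = 0.0
        for w in _omega(variant):
            lo = max(b, zeta if w != "F" else -_TAIL)
            tot += _integrate(
                lambda z: joint_density_zw(z, w, null, zeta, I1, I2, lam),
                lo,
                _TAIL + 2.0,
            )
        return tot

    if alpha1 <= 0:
        b1 = _TAIL
        warnings.warn("alpha1 ~ 0: efficacy boundary capped at +8", stacklevel=2)
    else:
        lo_b = min(zeta, -2.0)
        if upper_mass(lo_b) < alpha1:
            raise _spend_error("alpha", "alpha1 exceeds attainable rejection mass")
        if upper_mass(_TAIL) > alpha1:
            b1 = _TAIL
            warnings.warn("efficacy boundary capped at +8", stacklevel=2)
        else:
            b1 = brentq(lambda b: upper_mass(b) - alpha1, lo_b, _TAIL, xtol=1e-10)

    e1, e2 = effects_alt
    mu1 = e1 * math.sqrt(I1)
    mu2 = e2 * math.sqrt(I2)
    mass1 = norm.cdf(zeta - mu2)  # weight of the w=1 truncated normal

    def lower_mass(a):
        return mass1 * max(norm.cdf(a - mu1) - norm.cdf(zeta - mu1), 0.0)

    if beta1 <= 0:
        a1 = zeta
    else:
        if lower_mass(b1) < beta1:
            raise _spend_error("beta", "beta1 exceeds attainable futility mass below b1")
        a1 = brentq(lambda a: lower_mass(a) - beta1, zeta, b1, xtol=1e-10)
    return float(a1), float(b1)


def solve_stage2_boundaries(
    alpha2: float,
    beta2: float,
    a1: float,
    b1: float,
    zeta: float,
    effects_alt: tuple[float, float],
    infos_stage1: dict,
    infos_stage2: dict,
    lam: float,
    variant: str = "full",
) -> tuple[float, float]:
    """Stage-2 pair (a2, b2).

    b2 solves sum_w int_{a1}^{b1} f(z1, w; null) P(Z(2) > b2 | z1) dz1 =
    alpha2 (the conditional tail weighted by the stage-1 joint density);
    a2 solves the analogous lower-tail equation under the alternative,
    restricted to w = 1.  ``infos_stage1``/``infos_stage2`` map each w in
    {1, 2, "F"} to its information at the two analyses.
    """
    I1, I2 = infos_stage1[1], infos_stage1[2]
    for w_ in (1, 2, "F"):
        if infos_stage2[w_] <= infos_stage1[w_]:
            raise ValueError(f"stage-2 information must exceed stage-1 for w={w_}")

    # cache stage-1 density values on fixed nodes per w; infinite stage-1
    # boundaries are clamped to the working tails
    hi1 = min(b1, _TAIL + 4.0)
    node_cache = []
    for w in _omega(variant):
        lo = max(a1, zeta if w != "F" else -_TAIL, -_TAIL)
        if hi1 <= lo:
            continue
        x = 0.5 * (hi1 - lo) * _GL_X + 0.5 * (lo + hi1)
        wt = 0.5 * (hi1 - lo) * _GL_W
        fz = joint_density_zw(x, w, (0.0, 0.0), zeta, I1, I2, lam)
        node_cache.append((w, x, wt * fz))

    def alpha_mass(b2):
        tot = 0.0
        for w, x, wf in node_cache:
            tot += float(
                np.sum(wf * _stage2_tail(x, b2, 0.0, infos_stage1[w], infos_stage2[w]))
            )
        return tot

    if alpha2 <= 0:
        b2 = _TAIL
        warnings.warn("alpha2 ~ 0: final boundary capped at +8", stacklevel=2)
    elif alpha_mass(-_TAIL) < alpha2:
        raise _spend_error("alpha", "alpha2 exceeds attainable rejection mass")
    elif alpha_mass(_TAIL) > alpha2:
        b2 = _TAIL
        warnings.warn("final efficacy boundary capped at +8", stacklevel=2)
    else:
        b2 = brentq(lambda b: alpha_mass(b) - alpha2, -_TAIL, _TAIL, xtol=1e-10)

    # beta equation: w = 1 under the alternative
    e1, e2 = effects_alt
    mu1_1 = e1 * math.sqrt(infos_stage1[1])
    drift2 = e1 * math.sqrt(infos_stage2[1])
    lo = max(a1, zeta, -_TAIL)
    x = 0.5 * (hi1 - lo) * _GL_X + 0.5 * (lo + hi1)
    wt = 0.5 * (hi1 - lo) * _GL_W
    fz = norm.cdf(zeta - e2 * math.sqrt(infos_stage1[2])) * norm.pdf(x - mu1_1)

    def beta_mass(a2):
        return float(
            np.sum(
                wt
                * fz
                * _stage2_tail(
                    x, a2, drift2, infos_stage1[1], infos_stage2[1], lower=True
                )
            )
        )

    if beta2 <= 0:
        a2 = -_TAIL
    elif beta_mass(_TAIL) < beta2:
        raise _spend_error("beta", "beta2 exceeds attainable acceptance mass")
    else:
        a2 = brentq(lambda a: beta_mass(a) - beta2, -_TAIL, _TAIL, xtol=1e-10)
    return float(a2), float(b2)


# ---------------------------------------------------------------------------
# Events-information calibration
# ---------------------------------------------------------------------------

def fit_method(snapshot, subgroup, method: str = "condscore", **kwargs):
    """Dispatch a per-subgroup fit by method name."""
    if method == "condscore":
        return ConditionalScoreModel(snapshot, subgroup).fit(**kwargs)
    if method == "cox":
        return CoxModel(snapshot, subgroup).fit()
    if method == "cox_tvc":
        return CoxTimeVaryingModel(snapshot, subgroup).fit(**kwargs)
    raise ValueError(f"unknown method {method!r}")


def calibrate_information_rate(
    params: JointModelParams,
    method: str = "condscore",
    n_patients: int = 5000,
    grid_size: int = 30,
    rng: np.random.Generator | None = None,
    d_max: int = 300,
    effects: tuple[float, float] | None = None,
    n_datasets: int = 8,
):
    """Estimate the events-per-information constants (m1, m2, mF).

    Each replicate simulates a dataset under the design alternative,
    progressively right-censors it at a grid of calendar times (quantiles
    of the event times up to the ``d_max``-th subgroup-1 event), fits the
    analysis method at each cut and regresses information on event count
    without intercept; 1/slope gives m per subgroup, with mF from the
    combined full-population information against total events.  The
    constants are averaged over ``n_datasets`` replicates to tame the
    variance of the per-cut information estimates.
    """
    if rng is None:
        rng = np.random.default_rng()
    if effects is None:
        effects = (-0.5, 0.0)
    out = np.zeros(3)
    for _ in range(n_datasets):
        out += np.asarray(
            _calibrate_once(
                params, method, n_patients, grid_size, rng, d_max, effects
            )
        )
    out /= n_datasets
    return float(out[0]), float(out[1]), float(out[2])


def _calibrate_once(params, method, n_patients, grid_size, rng, d_max, effects):
    data = simulate_trial(params, n_patients, theta_overrides=effects, rng=rng)

    obs = (data.latent < data.ltfu) & np.isfinite(data.latent)
    cal1 = np.sort(data.recruit[obs & (data.subgroup == 1)] + data.latent[obs & (data.subgroup == 1)])
    if cal1.size < grid_size:
        raise InfeasibleSpend(
            f"only {cal1.size} subgroup-1 events; increase n_patients"
        )
    t_end = cal1[min(d_max, cal1.size) - 1]
    cal_all = np.sort(data.recruit[obs] + data.latent[obs])
    cal_all = cal_all[cal_all <= t_end]
    probs = np.linspace(1.0 / grid_size, 1.0, grid_size)
    cutoffs = np.quantile(cal_all, probs)

    snap_max = snapshot_at_calendar_time(data, float(t_end) + 1e-9, 0)

    records = {1: [], 2: []}
    n_fail = 0
    if method == "condscore":
        from .condscore import _CondScoreCore, _pooled_sigma2_from_stats

        for j in (1, 2):
            idx = np.flatnonzero(snap_max.subgroup_mask(j))
            core = _CondScoreCore(
                [snap_max.meas_times[i] for i in idx],
                [snap_max.meas_values[i] for i in idx],
                snap_max.psi[idx],
                snap_max.tobs[idx],
                snap_max.delta[idx],
            )
            recruit = snap_max.recruit[idx]
            warm = (0.0, 0.0)
            for ci, c in enumerate(cutoffs):
                admin = c - recruit
                tobs_c = np.minimum(core.tobs, np.maximum(admin, 0.0))
                delta_c = (core.delta == 1) & (core.tobs <= admin)
                ev_on = delta_c[core.ev_subj] & (core.te <= admin[core.ev_subj])
                if int(ev_on.sum()) < MIN_EVENTS_GUIDELINE:
                    continue  # immature cut: asymptotics (and roots) unreliable
                counts_c = core.cum.counts_at(tobs_c)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sigma2_c = _pooled_sigma2_from_stats(core.cum, counts_c)
                        # fresh jackknife partitions per cut decorrelate the
                        # variance-estimator noise across the grid
                        sol = core.solve(
                            sigma2_c, ev_on=ev_on, tobs=tobs_c, start=warm,
                            jk_splits=20,
                            jk_seed=7000 + 31 * ci + int(rng.integers(1 << 20)),
                        )
                    warm = (sol["gamma_hat"], sol["theta_hat"])
                    # event counts on the trigger scale (all observed events,
                    # not only measurement-eligible ones): analyses are timed
                    # by total events, so m must relate I to that count
                    d_all = int(delta_c.sum())
                    records[j].append((c, d_all, sol["info"], sol["theta_hat"]))
                except (RootNotFound, NoResidualDf):
                    warm = (0.0, 0.0)  # do not propagate a bad basin
                    n_fail += 1
    else:
        for c in cutoffs:
            snap = snapshot_at_calendar_time(data, float(c), 0)
            for j in (1, 2):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = fit_method(snap, j, method)
                    records[j].append((c, res.d, res.info, res.theta_hat))
                except (RootNotFound, NoResidualDf):
                    n_fail += 1

    if n_fail > grid_size:  # more than half of the 2*grid fits
        raise RootNotFound(
            f"{n_fail} of {2 * grid_size} calibration fits failed"
        )
    if n_fail:
        warnings.warn(
            f"{n_fail} calibration fits dropped (too few events)", stacklevel=2
        )

    def slope_m(dd, ii):
        """No-intercept LS slope of I on d, as 1/slope = m.

        Points with fewer than 20 events (unreliable asymptotics) or with a
        grossly outlying per-point ratio (failed variance estimate) are
        excluded before the fit.
        """
        dd = np.asarray(dd, dtype=float)
        ii = np.asarray(ii, dtype=float)
        keep = (dd >= MIN_EVENTS_GUIDELINE) & (ii > 0) & np.isfinite(ii)
        if keep.sum() < 3:
            raise RootNotFound("too few usable calibration points")
        ratio = dd[keep] / ii[keep]
        med = np.median(ratio)
        ok = (ratio < 3 * med) & (ratio > med / 3)
        dd, ii = dd[keep][ok], ii[keep][ok]
        if dd.size < 3:
            raise RootNotFound("too few usable calibration points")
        return float(np.sum(dd * dd) / np.sum(dd * ii))

    m = {}
    for j in (1, 2):
        if len(records[j]) < 3:
            raise RootNotFound(f"too few calibration points for subgroup {j}")
        _, dd, ii, _ = zip(*records[j])
        m[j] = slope_m(dd, ii)

    # combined information at common cutoffs
    c1 = {c: (d, i) for c, d, i, _ in records[1]}
    c2 = {c: (d, i) for c, d, i, _ in records[2]}
    common = sorted(set(c1) & set(c2))
    dF, iF = [], []
    lam = params.lam
    for c in common:
        d1, i1 = c1[c]
        d2, i2 = c2[c]
        dF.append(d1 + d2)
        iF.append(1.0 / (lam**2 / i1 + (1 - lam) ** 2 / i2))
    mF = slope_m(dF, iF)
    return m[1], m[2], mF


def predict_information(I_interim: float, d_interim: int, d_target: int) -> float:
    """Forward-predict information from event counts: I2 = d2 * I1 / d1."""
    if d_interim < 1:
        raise ValueError("d_interim must be >= 1")
    return float(d_target) * I_interim / float(d_interim)


# ---------------------------------------------------------------------------
# Planner
# ---------------------------------------------------------------------------

@dataclass
class Boundaries:
    """Z-scale stopping boundaries with their spent errors."""

    a1: float
    b1: float
    a2: float
    b2: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DesignPlan:
    """Pre-trial plan: threshold, calibrated m-constants, event counts and
    maximum information."""

    zeta: float
    I1_interim: float
    m1: float
    m2: float
    mF: float
    d1_interim: int
    d_total: int
    Imax: float
    d2_interim_pred: float
    dF_interim_pred: float
    config: DesignConfig = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("config", None)
        return d


def _plan_infos(config, m, d1_interim, Imax):
    lam = config.lam
    m1, m2, mF = m
    d_int = {1: float(d1_interim), 2: (1 - lam) * d1_interim / lam,
             "F": d1_interim / lam}
    mm = {1: m1, 2: m2, "F": mF}
    infos1 = {w: d_int[w] / mm[w] for w in d_int}
    infos2 = {w: mF * Imax / mm[w] for w in d_int}
    return infos1, infos2


def _boundaries_at(config, zeta, infos1, infos2, Imax, variant):
    """Solve all four boundaries for a given information sequence.

    Power is defined conditionally on selecting subgroup 1, so the type-2
    spent errors are rescaled by P(W=1; Theta_A) before being matched
    against the (unconditional) joint density in the beta equations.
    """
    alpha1, alpha2, beta1, beta2 = spend(
        config.alpha, config.beta, infos1["F"], infos2["F"], Imax
    )
    effects_alt = (config.delta, 0.0)
    p1_alt = selection_probabilities(
        config.delta, 0.0, zeta, infos1[1], infos1[2], variant
    )[1]
    a1, b1 = solve_stage1_boundaries(
        alpha1, beta1 * p1_alt, zeta, effects_alt, (infos1[1], infos1[2]),
        config.lam, variant,
    )
    a2, b2 = solve_stage2_boundaries(
        alpha2, beta2 * p1_alt, a1, b1, zeta, effects_alt, infos1, infos2,
        config.lam, variant,
    )
    return Boundaries(a1, b1, a2, b2, alpha1, alpha2, beta1, beta2)


def solve_imax(
    config: DesignConfig,
    m_constants: tuple[float, float, float],
    d1_interim: int,
    zeta: float | None = None,
    tol: float = 1e-4,
):
    """Maximum full-population information such that the final boundaries
    meet (a2 = b2), by bisection; d_total = ceil(mF * Imax)."""
    config.validate()
    if zeta is None:
        zeta, _ = solve_threshold_and_info(
            config.delta, config.p_select_1, config.p_select_F
        )
    m1, m2, mF = m_constants
    if1 = (d1_interim / config.lam) / mF

    def gap(imax):
        infos1, infos2 = _plan_infos(config, m_constants, d1_interim, imax)
        try:
            bd = _boundaries_at(
                config, zeta, infos1, infos2, imax, config.omega_variant
            )
        except InfeasibleSpend as exc:
            # under-informed designs can fail to spend beta (continuation
            # region too small): treat as "futility boundary above efficacy"
            if getattr(exc, "side", "beta") == "beta":
                return -2.0 * _TAIL
            return 2.0 * _TAIL
        return bd.a2 - bd.b2

    lo = if1 * 1.02
    hi = 2.0 * config.lam * ((norm.ppf(1 - config.alpha) + norm.ppf(1 - config.beta))
                             / config.delta) ** 2
    hi = max(hi, lo * 2)
    g_lo, g_hi = gap(lo), gap(hi)
    tries = 0
    while g_lo * g_hi > 0 and tries < 4:
        hi *= 2.5
        if hi > 10 * max(if1, 1.0) * 20:
            break
        g_hi = gap(hi)
        tries += 1
    if g_lo * g_hi > 0:
        raise InfeasibleSpend("no bracketing interval for Imax")
    imax = brentq(gap, lo, hi, xtol=tol)
    d_total = int(math.ceil(mF * imax))
    return float(imax), d_total


def plan_design(
    config: DesignConfig,
    params: JointModelParams,
    rng: np.random.Generator | None = None,
    method: str = "condscore",
    n_calib: int = 5000,
    grid_size: int = 30,
) -> tuple[DesignPlan, Boundaries]:
    """Full pre-trial pipeline: threshold solve -> events-information
    calibration -> interim event count -> Imax search -> boundaries."""
    config.validate()
    params.validate()
    if rng is None:
        rng = np.random.default_rng()
    zeta, i1 = solve_threshold_and_info(
        config.delta, config.p_select_1, config.p_select_F
    )
    m1, m2, mF = calibrate_information_rate(
        params,
        method=method,
        n_patients=n_calib,
        grid_size=grid_size,
        rng=rng,
        effects=(-config.delta, 0.0),
    )
    d1 = int(math.ceil(m1 * i1))
    imax, d_total = solve_imax(config, (m1, m2, mF), d1, zeta=zeta)
    infos1, infos2 = _plan_infos(config, (m1, m2, mF), d1, imax)
    boundaries = _boundaries_at(
        config, zeta, infos1, infos2, imax, config.omega_variant
    )
    lam = config.lam
    plan = DesignPlan(
        zeta=zeta,
        I1_interim=i1,
        m1=m1,
        m2=m2,
        mF=mF,
        d1_interim=d1,
        d_total=d_total,
        Imax=imax,
        d2_interim_pred=(1 - lam) * d1 / lam,
        dF_interim_pred=d1 / lam,
        config=config,
    )
    return plan, boundaries


# ---------------------------------------------------------------------------
# Analytic-level Z process (validation tool)
# ---------------------------------------------------------------------------

def simulate_z_process(
    effects: tuple[float, float],
    zeta: float,
    infos1: dict,
    infos2: dict,
    boundaries: Boundaries,
    lam: float,
    n_reps: int,
    rng: np.random.Generator,
    variant: str = "full",
):
    """Monte-Carlo replication of the two-stage procedure directly on the
    canonical joint distribution (no data simulation): returns per-replicate
    selection index, stage stopped and rejection flag.  Used to validate
    boundaries and error spending against their defining integrals."""
    e1, e2 = effects
    z1 = rng.normal(e1 * math.sqrt(infos1[1]), 1.0, n_reps)
    z2 = rng.normal(e2 * math.sqrt(infos1[2]), 1.0, n_reps)
    sel1 = z1 > zeta
    sel2 = z2 > zeta
    if variant == "conventional":
        sel2 = sel2 & sel1
    w = np.where(sel1 & sel2, 2, np.where(sel1, 1, np.where(sel2 & (variant == "full"), 3, 0)))
    # codes: 0 empty, 1 -> subgroup1, 2 -> F(both), 3 -> subgroup2
    c1, c2, _ = _f_weights(lam, infos1[1], infos1[2])
    zf = c1 * z1 + c2 * z2
    zw1 = np.where(w == 1, z1, np.where(w == 3, z2, zf))
    reject = np.zeros(n_reps, dtype=bool)
    stage = np.ones(n_reps, dtype=int)
    cont = (w != 0) & (zw1 <= boundaries.b1) & (zw1 >= boundaries.a1)
    reject |= (w != 0) & (zw1 > boundaries.b1)
    idx = np.flatnonzero(cont)
    stage[idx] = 2
    for code, wkey, eff in ((1, 1, e1), (3, 2, e2), (2, "F", None)):
        sub = idx[w[idx] == code]
        if sub.size == 0:
            continue
        i1w, i2w = infos1[wkey], infos2[wkey]
        if wkey == "F":
            drift2 = (lam * e1 + (1 - lam) * e2) * math.sqrt(i2w)
        else:
            drift2 = eff * math.sqrt(i2w)
        rho = math.sqrt(i1w / i2w)
        mean = drift2 + rho * (zw1[sub] - drift2 * rho)
        zw2 = rng.normal(mean, math.sqrt(1 - i1w / i2w))
        reject[sub] = zw2 > boundaries.b2
    w_label = np.array(["empty", "1", "F", "2"], dtype=object)[w]
    return {"w": w_label, "stage": stage, "reject": reject}
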