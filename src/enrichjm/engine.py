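"""Whole-trial execution and operating characteristics.

A trial runs as: simulate subjects -> interim snapshot at the planned
number of subgroup-1 events -> per-subgroup fits -> threshold selection
(both statistics above zeta: continue in the full population; exactly one:
enrich that subgroup; neither: stop for futility) -> early stopping against
the planned stage-1 boundaries -> if continuing, predict the stage-2
information from realized interim information and event counts, re-spend
the error at the realized information fractions, re-solve the final
boundary, take the final snapshot at the planned total event count in the
selected population, and reject iff the final statistic clears it.

Operating characteristics replicate this over many trials with
per-replicate child seeds (common random numbers across analysis methods),
reporting the familywise error rate, conditional power given selection,
selection frequencies and Monte-Carlo standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .condscore import combine_subgroups
from .design import (
    Boundaries,
    DesignPlan,
    fit_method,
    predict_information,
    selection_probabilities,
    solve_stage2_boundaries,
    spend,
)
from .exceptions import EnrichjmError, InfeasibleSpend
from .params import DesignConfig, JointModelParams
from .simulate import simulate_trial, snapshot_at_event_count

__all__ = [
    "run_trial",
    "operating_characteristics",
    "mc_standard_error",
    "TrialResult",
    "OperatingCharacteristics",
]


def mc_standard_error(p: float, N: int) -> float:
    """Binomial Monte-Carlo standard error sqrt(p(1-p)/N)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0,1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    return math.sqrt(p * (1.0 - p) / N)


@dataclass
class TrialResult:
    """Outcome of one simulated enrichment trial."""

    w: object  # 1, 2, "F" or "empty"
    stage_stopped: int
    rejected: object  # None or the selected hypothesis label ("H0,1", ...)
    z_interim: dict
    z_final: float | None
    events_interim: dict
    info_interim: dict
    events_final: int | None
    info_final: float | None
    b2_realized: float | None = None
    failed: bool = False
    fail_reason: str = ""


def _fit_population(snapshot, w, method, lam):
    if w in (1, 2):
        return fit_method(snapshot, w, method)
    f1 = fit_method(snapshot, 1, method)
    f2 = fit_method(snapshot, 2, method)
    return combine_subgroups(f1, f2, lam)


def run_trial(
    params: JointModelParams,
    plan: DesignPlan,
    boundaries: Boundaries,
    method: str = "condscore",
    n_patients: int = 1000,
    theta: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    config: DesignConfig | None = None,
) -> TrialResult:
    """Execute one trial under effects ``theta`` (model scale, negative =
    benefit) against a pre-computed plan and stage-1 boundaries."""
    if rng is None:
        rng = np.random.default_rng()
    if config is None:
        config = plan.config if plan.config is not None else DesignConfig()
    lam = config.lam
    variant = config.omega_variant

    data = simulate_trial(params, n_patients, theta_overrides=theta, rng=rng)

    def _failed(reason):
        return TrialResult(
            w=None, stage_stopped=0, rejected=None, z_interim={}, z_final=None,
            events_interim={}, info_interim={}, events_final=None,
            info_final=None, failed=True, fail_reason=reason,
        )

    try:
        snap1 = snapshot_at_event_count(data, 1, plan.d1_interim, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit1 = fit_method(snap1, 1, method)
            fit2 = fit_method(snap1, 2, method)
    except EnrichjmError as exc:
        return _failed(f"interim: {exc}")
    comb = combine_subgroups(fit1, fit2, lam)
    z_int = {1: fit1.z, 2: fit2.z, "F": comb.z}
    # trigger-scale event counts (all observed events) for information
    # prediction; the fits' own eligible-event counts sit slightly lower
    d_int = {1: snap1.n_events(1), 2: snap1.n_events(2)}
    d_int["F"] = d_int[1] + d_int[2]
    i_int = {1: fit1.info, 2: fit2.info, "F": comb.info}

    sel1 = fit1.z > plan.zeta
    sel2 = fit2.z > plan.zeta
    if variant == "conventional":
        sel2 = sel2 and sel1
    if sel1 and sel2:
        w = "F"
    elif sel1:
        w = 1
    elif sel2:
        w = 2
    else:
        return TrialResult(
            w="empty", stage_stopped=1, rejected=None, z_interim=z_int,
            z_final=None, events_interim=d_int, info_interim=i_int,
            events_final=None, info_final=None,
        )

    zw1 = z_int[w]
    label = f"H0,{w}"
    if zw1 > boundaries.b1:
        return TrialResult(
            w=w, stage_stopped=1, rejected=label, z_interim=z_int,
            z_final=None, events_interim=d_int, info_interim=i_int,
            events_final=None, info_final=None,
        )
    if zw1 < boundaries.a1:
        return TrialResult(
            w=w, stage_stopped=1, rejected=None, z_interim=z_int,
            z_final=None, events_interim=d_int, info_interim=i_int,
            events_final=None, info_final=None,
        )

    # stage 2: realized interim informations drive the spend and the final
    # boundary; stage-2 informations are forward-predicted from event counts
    infos1 = dict(i_int)
    infos2 = {
        j: predict_information(infos1[j], d_int[j], plan.d_total)
        for j in (1, 2, "F")
    }
    try:
        alpha1, _, beta1, _ = spend(
            config.alpha, config.beta, infos1["F"], infos2["F"], plan.Imax
        )
        # the second analysis is terminal, so all remaining error is spent
        # there (the information fraction only shapes the interim spend);
        # otherwise a conservative interim information estimate would leave
        # type-1/2 error unspent and the final boundary needlessly high
        alpha2 = config.alpha - alpha1
        beta2 = config.beta - beta1
        p1_alt = selection_probabilities(
            config.delta, 0.0, plan.zeta, infos1[1], infos1[2], variant
        )[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, b2 = solve_stage2_boundaries(
                alpha2, beta2 * p1_alt, boundaries.a1, boundaries.b1,
                plan.zeta, (config.delta, 0.0), infos1, infos2, lam, variant,
            )
    except (InfeasibleSpend, ValueError) as exc:
        return _failed(f"stage-2 boundary: {exc}")

    try:
        snap2 = snapshot_at_event_count(data, w, plan.d_total, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitw2 = _fit_population(snap2, w, method, lam)
    except EnrichjmError as exc:
        return _failed(f"final: {exc}")

    rejected = label if fitw2.z > b2 else None
    return TrialResult(
        w=w, stage_stopped=2, rejected=rejected, z_interim=z_int,
        z_final=fitw2.z, events_interim=d_int, info_interim=i_int,
        events_final=fitw2.d, info_final=fitw2.info, b2_realized=b2,
    )


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the two-stage design."""

    n_reps: int
    n_failed: int
    fwer: float
    fwer_se: float
    power_conditional: float | None
    power_se: float | None
    n_selected_1: int
    selection_freq: dict
    reject_freq: dict
    mean_events_interim: dict
    mean_events_final: float | None
    results: list = field(default_factory=list, repr=False)

    def summary(self) -> str:
        lines = [
            "operating characteristics",
            "=" * 44,
            f"replicates (failed)   {self.n_reps} ({self.n_failed})",
            f"FWER / any-rejection  {self.fwer:.4f}  (MC se {self.fwer_se:.4f})",
        ]
        if self.power_conditional is not None:
            lines.append(
                f"power | select S1     {self.power_conditional:.4f}  "
                f"(MC se {self.power_se:.4f}, n={self.n_selected_1})"
            )
        sel = ", ".join(f"{k}: {v:.3f}" for k, v in self.selection_freq.items())
        lines.append(f"selection frequencies {sel}")
        return "\n".join(lines)


def _true_nulls(theta: tuple[float, float], lam: float) -> set:
    """Hypotheses that are true nulls (no benefit) under the model-scale
    effects: H0,j true iff theta_j >= 0 (benefit is negative)."""
    t1, t2 = theta
    tf = lam * t1 + (1 - lam) * t2
    out = set()
    if t1 >= 0:
        out.add("H0,1")
    if t2 >= 0:
        out.add("H0,2")
    if tf >= 0:
        out.add("H0,F")
    return out


def operating_characteristics(
    params: JointModelParams,
    plan: DesignPlan,
    boundaries: Boundaries,
    method: str = "condscore",
    n_reps: int = 500,
    theta: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | int | None = None,
    n_patients: int = 1000,
    config: DesignConfig | None = None,
    max_fail_frac: float = 0.05,
    keep_results: bool = False,
) -> OperatingCharacteristics:
    """Replicate :func:`run_trial` and summarise error rates.

    Each replicate derives its own child seed from the root, so different
    methods analysed at the same root seed see the same simulated trials
    (common random numbers).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for meaningful estimates")
    if isinstance(rng, np.random.Generator):
        root = rng.integers(1 << 31)
    else:
        root = rng if rng is not None else 0
    seeds = np.random.SeedSequence(root).spawn(n_reps)

    true_nulls = _true_nulls(theta, config.lam if config else plan.config.lam)
    results = []
    n_failed = 0
    for r in range(n_reps):
        res = run_trial(
            params, plan, boundaries, method=method, n_patients=n_patients,
            theta=theta, rng=np.random.default_rng(seeds[r]), config=config,
        )
        if res.failed:
            n_failed += 1
        results.append(res)
    if n_failed > max_fail_frac * n_reps:
        raise EnrichjmError(
            f"{n_failed}/{n_reps} replicates failed to fit; "
            "increase n_patients or event targets"
        )

    ok = [r for r in results if not r.failed]
    n_ok = len(ok)
    false_rej = [r.rejected in true_nulls for r in ok]
    fwer = float(np.mean(false_rej)) if n_ok else float("nan")
    sel1 = [r for r in ok if r.w == 1]
    if sel1:
        pwr = float(np.mean([r.rejected == "H0,1" for r in sel1]))
        pwr_se = mc_standard_error(pwr, len(sel1))
    else:
        pwr, pwr_se = None, None
    sel_freq = {
        k: float(np.mean([r.w == k for r in ok])) for k in (1, 2, "F", "empty")
    }
    rej_freq = {
        k: float(np.mean([r.rejected == f"H0,{k}" for r in ok]))
        for k in (1, 2, "F")
    }
    mean_d_int = {
        k: float(np.mean([r.events_interim.get(k, np.nan) for r in ok]))
        for k in (1, 2, "F")
    }
    finals = [r.events_final for r in ok if r.events_final is not None]
    return OperatingCharacteristics(
        n_reps=n_reps,
        n_failed=n_failed,
        fwer=fwer,
        fwer_se=mc_standard_error(fwer, n_ok) if n_ok else float("nan"),
        power_conditional=pwr,
        power_se=pwr_se,
        n_selected_1=len(sel1),
        selection_freq=sel_freq,
        reject_freq=rej_freq,
        mean_events_interim=mean_d_int,
        mean_events_final=float(np.mean(finals)) if finals else None,
        results=results if keep_results else [],
    )
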