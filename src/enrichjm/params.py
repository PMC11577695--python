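"""Parameter containers for the working joint model and the trial design.

The working model couples a linear longitudinal biomarker trajectory
``X(v) = b0 + b1 v`` (bivariate-normal random effects, Gaussian measurement
error) with a proportional-hazards survival submodel

    h_ji(t) = h0_j(t) * exp{gamma_j * X_ji(t) + theta_j * psi_ji}

where ``psi`` is the treatment indicator and the baseline hazard is
piecewise constant with a single knot at t = 1 year.  Default values are
the metastatic-breast-cancer calibration used throughout the package:
ctDNA-like trajectories, two subgroups (HER2-defined) with prevalence
``lam`` of subgroup 1 in the full population.

All times are in years; a week is 7/365.25 years and a scheduling "month"
is four weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

WEEK = 7.0 / 365.25

#: Loss-to-follow-up hazard (per year) calibrated so that roughly 10% of
#: subjects are lost before min(event, 3 years) under the null parameter
#: set.  See :func:`enrichjm.simulate.calibrate_censor_rate`.
DEFAULT_CENSOR_RATE = 0.0832


@dataclass
class VisitSchedule:
    """Biomarker sampling rule: a visit at entry, then every
    ``early_interval_wk`` weeks for ``early_span_wk`` weeks, then every
    ``late_interval_wk`` weeks indefinitely."""

    early_interval_wk: float = 2.0
    early_span_wk: float = 12.0
    late_interval_wk: float = 4.0


@dataclass
class JointModelParams:
    """Parameters of the working joint model used for data generation.

    Hazard constants ``c_jp`` are events/year for subgroup ``j`` in piece
    ``p`` (piece 1: t <= 1 year, piece 2: t > 1).  ``theta_j`` are
    log-hazard treatment effects (negative = benefit).
    """

    gamma_1: float = 0.8
    gamma_2: float = 0.8
    theta_1: float = 0.0
    theta_2: float = 0.0
    sigma2: float = 0.25
    c_11: float = 0.0085
    c_12: float = 0.0142
    c_21: float = 0.0085
    c_22: float = 0.0142
    mu0_1: float = 4.23
    mu1_1: float = 1.81
    mu0_2: float = 4.23
    mu1_2: float = 1.81
    phi1_1: float = 2.5
    phi12_1: float = 1.7
    phi2_1: float = 5.0
    phi1_2: float = 2.5
    phi12_2: float = 1.7
    phi2_2: float = 5.0
    lam: float = 2.0 / 3.0
    recruit_rate: float = 2.0  # patients per week, deterministic
    censor_rate: float = DEFAULT_CENSOR_RATE  # LTFU hazard per year
    schedule: VisitSchedule = field(default_factory=VisitSchedule)

    def validate(self) -> None:
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"lam must be in (0,1), got {self.lam}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        for name in ("c_11", "c_12", "c_21", "c_22"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recruit_rate <= 0:
            raise ValueError("recruit_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        for j in (1, 2):
            cov = self.random_effects_cov(j)
            if np.linalg.eigvalsh(cov).min() < -1e-12:
                raise ValueError(
                    f"random-effect covariance for subgroup {j} is not PSD"
                )

    def random_effects_mean(self, subgroup: int) -> np.ndarray:
        return np.array(
            [getattr(self, f"mu0_{subgroup}"), getattr(self, f"mu1_{subgroup}")]
        )

    def random_effects_cov(self, subgroup: int) -> np.ndarray:
        p1 = getattr(self, f"phi1_{subgroup}")
        p12 = getattr(self, f"phi12_{subgroup}")
        p2 = getattr(self, f"phi2_{subgroup}")
        return np.array([[p1, p12], [p12, p2]])

    def gamma(self, subgroup: int) -> float:
        return getattr(self, f"gamma_{subgroup}")

    def theta(self, subgroup: int) -> float:
        return getattr(self, f"theta_{subgroup}")

    def hazard_pieces(self, subgroup: int) -> tuple[float, float]:
        return (getattr(self, f"c_{subgroup}1"), getattr(self, f"c_{subgroup}2"))

    def replace(self, **kwargs) -> "JointModelParams":
        d = asdict(self)
        sched = d.pop("schedule")
        d.update(kwargs)
        if "schedule" not in kwargs:
            d["schedule"] = VisitSchedule(**sched)
        p = JointModelParams(**d)
        p.validate()
        return p

    # -- config file round trip -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "JointModelParams":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        sched = d.pop("schedule", None)
        p = cls(**d)
        if sched is not None:
            p.schedule = VisitSchedule(**sched)
        p.validate()
        return p


@dataclass
class DesignConfig:
    """Pre-trial design requirements.

    ``delta`` is the design effect magnitude on the hazard-reduction scale
    (a beneficial log-hazard effect of -delta), ``p_select_1`` and
    ``p_select_F`` the target interim probabilities of enriching subgroup 1
    and of continuing in the full population under the design alternative.
    ``omega_variant`` chooses between the full selection space {1,2,F,empty}
    and the conventional one {1,F,empty} in which the biomarker-negative
    subgroup is never enriched.  Error is spent with the quadratic rules
    f(t) = min(alpha t^2, alpha), g(t) = min(beta t^2, beta).
    """

    alpha: float = 0.025
    beta: float = 0.10
    delta: float = 0.5
    lam: float = 2.0 / 3.0
    p_select_1: float = 0.6
    p_select_F: float = 0.2
    omega_variant: str = "full"

    def validate(self) -> None:
        import warnings

        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie in (0,1)")
        if self.delta <= 0:
            raise ValueError("delta must be a positive effect magnitude")
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lam must be in (0,1)")
        if min(self.p_select_1, self.p_select_F) <= 0:
            raise ValueError("selection targets must be positive")
        if self.p_select_1 + self.p_select_F >= 1.0:
            raise ValueError("p_select_1 + p_select_F must be < 1")
        if self.omega_variant not in ("full", "conventional"):
            raise ValueError("omega_variant must be 'full' or 'conventional'")
        if self.p_select_1 < 0.5:
            warnings.warn(
                "p_select_1 < 0.5: asymptotic behaviour of the selected-"
                "subgroup estimator may be poor",
                stacklevel=2,
            )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        c = cls(**d)
        c.validate()
        return c
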