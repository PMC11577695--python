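"""Trial data generation from the working joint model.

Subjects enter at a deterministic rate (``recruit_rate`` per week), are
assigned a subgroup by a Bernoulli(lam) draw and an arm by 1:1 alternation
within subgroup.  Each subject carries latent random effects (b0, b1), a
latent event time drawn by inverting the cumulative hazard of

    h(t) = h0(t) * exp{gamma * (b0 + b1 t) + theta * psi},

an independent exponential loss-to-follow-up time, and noisy biomarker
measurements on the visit schedule.  Analyses view the trial through
:class:`TrialSnapshot` objects: administrative censoring at the calendar
time at which a pre-specified event count is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientEvents
from .params import WEEK, JointModelParams, VisitSchedule

__all__ = [
    "measurement_schedule",
    "sample_event_time",
    "simulate_trial",
    "snapshot_at_event_count",
    "calibrate_censor_rate",
    "SubjectRecord",
    "TrialData",
    "TrialSnapshot",
    "write_trial_csv",
    "read_trial_csv",
]


def measurement_schedule(
    horizon: float, schedule: VisitSchedule | None = None
) -> np.ndarray:
    """Visit offsets (years from entry) up to and including ``horizon``.

    Default rule: entry visit at 0, every 2 weeks through week 12, then
    every 4 weeks.  A "month" is four weeks by convention.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if schedule is None:
        schedule = VisitSchedule()
    horizon_wk = horizon / WEEK + 1e-9  # tolerate float representation of weeks
    early = np.arange(
        0.0, min(schedule.early_span_wk, horizon_wk) + 1e-9, schedule.early_interval_wk
    )
    visits = [early]
    if horizon_wk > schedule.early_span_wk:
        late = np.arange(
            schedule.early_span_wk + schedule.late_interval_wk,
            horizon_wk + 1e-9,
            schedule.late_interval_wk,
        )
        visits.append(late)
    return np.concatenate(visits) * WEEK


_KAPPA_TOL = 1e-12


def _g(t, kappa):
    """Integral of exp(kappa*s) over (0, t): (e^{kappa t}-1)/kappa.

    Vectorised in both arguments; linear limit at kappa ~ 0.
    """
    t = np.asarray(t, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    safe = np.where(np.abs(kappa) < _KAPPA_TOL, 1.0, kappa)
    return np.where(np.abs(kappa) < _KAPPA_TOL, t, np.expm1(safe * t) / safe)


def _ginv(y, kappa):
    """Inverse of :func:`_g`; +inf where y exceeds the range (kappa<0)."""
    y = np.asarray(y, dtype=float)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), y.shape)
    lin = np.abs(kappa) < _KAPPA_TOL
    arg = 1.0 + kappa * y
    out = np.full(y.shape, np.inf)
    ok = lin | (arg > 0)
    safe_kappa = np.where(lin, 1.0, kappa)
    with np.errstate(invalid="ignore"):
        vals = np.where(lin, y, np.log1p(np.where(ok, kappa * y, 0.0)) / safe_kappa)
    out[ok] = vals[ok]
    return out


def _invert_cumhaz(e_draw, a_fac, c1, c2, kappa):
    """Solve H(t) = e_draw for t given H(t) = a_fac*[c1 g(min(t,1)) +
    c2 (g(t)-g(1)) 1{t>1}].  All arguments broadcastable arrays."""
    e_draw = np.asarray(e_draw, dtype=float)
    a_fac, kappa = np.broadcast_arrays(
        np.asarray(a_fac, dtype=float), np.asarray(kappa, dtype=float)
    )
    a_fac = np.broadcast_to(a_fac, e_draw.shape)
    kappa = np.broadcast_to(kappa, e_draw.shape)
    g1 = _g(1.0, kappa)
    h1 = a_fac * c1 * g1
    first = e_draw <= h1
    y = np.where(first, e_draw / (a_fac * c1), g1 + (e_draw - h1) / (a_fac * c2))
    return _ginv(y, kappa)


def sample_event_time(b0, b1, psi, subgroup, params, rng):
    """Draw one latent event time (years from entry); may be +inf when the
    total cumulative hazard is bounded (a 'cure' draw)."""
    params.validate()
    gamma = params.gamma(subgroup)
    theta = params.theta(subgroup)
    c1, c2 = params.hazard_pieces(subgroup)
    a_fac = math.exp(gamma * b0 + theta * psi)
    e_draw = rng.exponential(1.0)
    return float(_invert_cumhaz(np.array([e_draw]), a_fac, c1, c2, gamma * b1)[0])


@dataclass
class SubjectRecord:
    """One patient's complete latent and observed history."""

    subject_id: int
    subgroup: int
    psi: int
    recruit_time: float
    b0: float
    b1: float
    meas_times: np.ndarray
    meas_values: np.ndarray
    latent_event_time: float
    ltfu_time: float


@dataclass
class TrialData:
    """Vectorised container for a simulated trial (column arrays plus
    ragged per-subject measurement arrays)."""

    subject_id: np.ndarray
    subgroup: np.ndarray
    psi: np.ndarray
    recruit: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    latent: np.ndarray
    ltfu: np.ndarray
    meas_times: list = field(repr=False)
    meas_values: list = field(repr=False)

    @property
    def n(self) -> int:
        return self.subject_id.size

    def subject(self, i: int) -> SubjectRecord:
        return SubjectRecord(
            subject_id=int(self.subject_id[i]),
            subgroup=int(self.subgroup[i]),
            psi=int(self.psi[i]),
            recruit_time=float(self.recruit[i]),
            b0=float(self.b0[i]),
            b1=float(self.b1[i]),
            meas_times=self.meas_times[i],
            meas_values=self.meas_values[i],
            latent_event_time=float(self.latent[i]),
            ltfu_time=float(self.ltfu[i]),
        )


def simulate_trial(
    params: JointModelParams,
    n_patients: int,
    theta_overrides: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> TrialData:
    """Simulate ``n_patients`` subjects from the working joint model.

    ``theta_overrides`` replaces (theta_1, theta_2) for scenario runs
    without mutating ``params``.  Measurements are generated on the visit
    schedule up to min(latent event, loss to follow-up); later visits can
    never be observed in any snapshot.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if theta_overrides is not None:
        params = params.replace(theta_1=theta_overrides[0], theta_2=theta_overrides[1])
    params.validate()

    n = int(n_patients)
    recruit = np.arange(n) * (WEEK / params.recruit_rate)
    subgroup = np.where(rng.random(n) < params.lam, 1, 2)
    # 1:1 allocation by alternation within subgroup, in recruitment order
    psi = np.zeros(n, dtype=int)
    for j in (1, 2):
        idx = np.flatnonzero(subgroup == j)
        psi[idx] = np.arange(idx.size) % 2

    b0 = np.empty(n)
    b1 = np.empty(n)
    latent = np.empty(n)
    e_draw = rng.exponential(1.0, size=n)
    for j in (1, 2):
        idx = np.flatnonzero(subgroup == j)
        b = rng.multivariate_normal(
            params.random_effects_mean(j), params.random_effects_cov(j), size=idx.size
        )
        b0[idx], b1[idx] = b[:, 0], b[:, 1]
        gamma = params.gamma(j)
        theta = params.theta(j)
        c1, c2 = params.hazard_pieces(j)
        a_fac = np.exp(gamma * b0[idx] + theta * psi[idx])
        latent[idx] = _invert_cumhaz(e_draw[idx], a_fac, c1, c2, gamma * b1[idx])

    if params.censor_rate > 0:
        ltfu = rng.exponential(1.0 / params.censor_rate, size=n)
    else:
        ltfu = np.full(n, np.inf)

    # Measurements exist only up to min(event, LTFU); a single master
    # schedule is sliced per subject to avoid per-subject schedule builds.
    horizon = np.minimum(latent, ltfu)
    horizon = np.where(np.isfinite(horizon), horizon, 0.0)
    master = measurement_schedule(float(horizon.max()), params.schedule)
    counts = np.searchsorted(master, horizon, side="right")
    sigma = math.sqrt(params.sigma2)
    total = int(counts.sum())
    eps_flat = rng.normal(0.0, sigma, size=total) if sigma > 0 else np.zeros(total)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    meas_times: list = []
    meas_values: list = []
    for i in range(n):
        v = master[: counts[i]].copy()
        eps = eps_flat[offsets[i] : offsets[i + 1]]
        meas_times.append(v)
        meas_values.append(b0[i] + b1[i] * v + eps)

    return TrialData(
        subject_id=np.arange(n),
        subgroup=subgroup,
        psi=psi,
        recruit=recruit,
        b0=b0,
        b1=b1,
        latent=latent,
        ltfu=ltfu,
        meas_times=meas_times,
        meas_values=meas_values,
    )


@dataclass
class TrialSnapshot:
    """Administratively censored view of a trial at one analysis.

    ``tobs`` is years from entry, ``delta`` 1 only when the latent event
    was attained before both loss to follow-up and the analysis cut;
    retained measurements never post-date ``tobs``.
    """

    analysis_index: int
    calendar_time: float
    subject_id: np.ndarray
    subgroup: np.ndarray
    psi: np.ndarray
    recruit: np.ndarray
    tobs: np.ndarray
    delta: np.ndarray
    meas_times: list = field(repr=False)
    meas_values: list = field(repr=False)

    @property
    def tau(self) -> float:
        """Maximum follow-up time at this analysis."""
        return float(self.tobs.max()) if self.tobs.size else 0.0

    @property
    def n(self) -> int:
        return self.subject_id.size

    def subgroup_mask(self, subgroup) -> np.ndarray:
        if subgroup in ("F", "f", 0, None):
            return np.ones(self.n, dtype=bool)
        return self.subgroup == int(subgroup)

    def n_events(self, subgroup="F") -> int:
        return int(self.delta[self.subgroup_mask(subgroup)].sum())


def _event_calendar_times(data: TrialData, mask: np.ndarray) -> np.ndarray:
    observed = mask & (data.latent < data.ltfu) & np.isfinite(data.latent)
    return np.sort(data.recruit[observed] + data.latent[observed])


def snapshot_at_event_count(
    data: TrialData, trigger_subgroup, d: int, analysis_index: int = 1
) -> TrialSnapshot:
    """Snapshot at the calendar time of the d-th event in ``trigger_subgroup``
    (1, 2 or "F").  Raises :class:`InsufficientEvents` if fewer than ``d``
    events ever occur there."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if trigger_subgroup in ("F", "f", 0, None):
        mask = np.ones(data.n, dtype=bool)
    else:
        mask = data.subgroup == int(trigger_subgroup)
    cal = _event_calendar_times(data, mask)
    if cal.size < d:
        raise InsufficientEvents(
            f"only {cal.size} events ever occur in subgroup {trigger_subgroup}, "
            f"requested {d}; increase n_patients"
        )
    return snapshot_at_calendar_time(data, float(cal[d - 1]), analysis_index)


def snapshot_at_calendar_time(
    data: TrialData, calendar_time: float, analysis_index: int = 1
) -> TrialSnapshot:
    """Administratively censor every subject at ``calendar_time``."""
    entered = data.recruit < calendar_time
    idx = np.flatnonzero(entered)
    admin = calendar_time - data.recruit[idx]
    tobs = np.minimum(np.minimum(data.latent[idx], data.ltfu[idx]), admin)
    delta = (
        (data.latent[idx] <= data.ltfu[idx]) & (data.latent[idx] <= admin)
    ).astype(int)
    meas_t, meas_v = [], []
    for pos, i in enumerate(idx):
        v = data.meas_times[i]
        keep = v <= tobs[pos]
        meas_t.append(v[keep])
        meas_v.append(data.meas_values[i][keep])
    return TrialSnapshot(
        analysis_index=analysis_index,
        calendar_time=float(calendar_time),
        subject_id=data.subject_id[idx].copy(),
        subgroup=data.subgroup[idx].copy(),
        psi=data.psi[idx].copy(),
        recruit=data.recruit[idx].copy(),
        tobs=tobs,
        delta=delta,
        meas_times=meas_t,
        meas_values=meas_v,
    )


# ---------------------------------------------------------------------------
# CSV interface: long-format longitudinal table + survival table
# ---------------------------------------------------------------------------

def snapshot_to_frames(snap: TrialSnapshot) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for i in range(snap.n):
        for v, dv in zip(snap.meas_times[i], snap.meas_values[i]):
            rows.append((int(snap.subject_id[i]), int(snap.subgroup[i]),
                         int(snap.psi[i]), float(v), float(dv)))
    longi = pd.DataFrame(
        rows, columns=["subject_id", "subgroup", "arm", "time_years", "biomarker"]
    )
    surv = pd.DataFrame(
        {
            "subject_id": snap.subject_id,
            "subgroup": snap.subgroup,
            "arm": snap.psi,
            "recruit_years": snap.recruit,
            "time_years": snap.tobs,
            "event": snap.delta,
        }
    )
    return longi, surv


def snapshot_from_frames(
    longi: pd.DataFrame, surv: pd.DataFrame, analysis_index: int = 1
) -> TrialSnapshot:
    surv = surv.sort_values("subject_id").reset_index(drop=True)
    groups = {
        int(sid): g.sort_values("time_years")
        for sid, g in longi.groupby("subject_id")
    }
    meas_t, meas_v = [], []
    for sid in surv["subject_id"]:
        g = groups.get(int(sid))
        if g is None:
            meas_t.append(np.empty(0))
            meas_v.append(np.empty(0))
        else:
            meas_t.append(g["time_years"].to_numpy(dtype=float))
            meas_v.append(g["biomarker"].to_numpy(dtype=float))
    calendar = float((surv["recruit_years"] + surv["time_years"]).max())
    return TrialSnapshot(
        analysis_index=analysis_index,
        calendar_time=calendar,
        subject_id=surv["subject_id"].to_numpy(),
        subgroup=surv["subgroup"].to_numpy(),
        psi=surv["arm"].to_numpy(),
        recruit=surv["recruit_years"].to_numpy(dtype=float),
        tobs=surv["time_years"].to_numpy(dtype=float),
        delta=surv["event"].to_numpy(dtype=int),
        meas_times=meas_t,
        meas_values=meas_v,
    )


def write_trial_csv(snap: TrialSnapshot, longitudinal_path, survival_path) -> None:
    longi, surv = snapshot_to_frames(snap)
    longi.to_csv(longitudinal_path, index=False)
    surv.to_csv(survival_path, index=False)


def read_trial_csv(longitudinal_path, survival_path, analysis_index=1) -> TrialSnapshot:
    longi = pd.read_csv(longitudinal_path)
    surv = pd.read_csv(survival_path)
    return snapshot_from_frames(longi, surv, analysis_index)


# ---------------------------------------------------------------------------
# Censoring-rate calibration
# ---------------------------------------------------------------------------

def calibrate_censor_rate(
    params: JointModelParams | None = None,
    target: float = 0.10,
    horizon: float = 3.0,
    n: int = 40000,
    seed: int = 0,
) -> float:
    """Loss-to-follow-up hazard such that a fraction ``target`` of subjects
    drop out before min(event, ``horizon``) under ``params``.

    The working model has a cure fraction (bounded cumulative hazard when
    gamma*b1 < 0), so dropout-before-event is anchored to a finite
    observation horizon.  P(LTFU first) = 1 - E[exp(-r*min(T, horizon))] is
    smooth and increasing in r, so a deterministic bisection on one set of
    latent event draws suffices.
    """
    if params is None:
        params = JointModelParams()
    rng = np.random.default_rng(seed)
    data = simulate_trial(params.replace(censor_rate=0.0, sigma2=0.0), n, rng=rng)
    t_cap = np.minimum(data.latent, horizon)

    def frac(rate):
        return 1.0 - np.exp(-rate * t_cap).mean()

    lo, hi = 1e-6, 5.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
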