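"""Comparator survival analyses for the enrichment design.

Two deliberately simpler analyses of the same snapshots:

* :class:`CoxModel` -- plain proportional-hazards fit of treatment only,
  ignoring the biomarker entirely (misspecified when gamma != 0; its
  estimand is the attenuated marginal log-hazard ratio).
* :class:`CoxTimeVaryingModel` -- partial-likelihood fit of (gamma, theta)
  treating the observed biomarker as an error-free time-varying covariate,
  evaluated by last-observation-carried-forward (optionally linear
  interpolation, or the prefix-OLS prediction).

Both return results compatible with the conditional-score surface
(theta_hat, info, z) so any method can drive the trial engine.  Ties are
handled by the Breslow convention; simulated event times are continuous so
ties only arise from file-based input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .condscore import ConditionalScoreResults, _CumStats
from .exceptions import RootNotFound
from .simulate import TrialSnapshot

__all__ = ["CoxModel", "CoxTimeVaryingModel"]

_THETA_CAP = 10.0  # monotone-likelihood guard


@dataclass
class _SnapshotSubset:
    psi: np.ndarray
    tobs: np.ndarray
    delta: np.ndarray
    meas_times: list
    meas_values: list


def _subset(snapshot: TrialSnapshot, subgroup) -> _SnapshotSubset:
    idx = np.flatnonzero(snapshot.subgroup_mask(subgroup))
    if idx.size == 0:
        raise ValueError(f"no subjects in subgroup {subgroup}")
    return _SnapshotSubset(
        psi=snapshot.psi[idx].astype(float),
        tobs=snapshot.tobs[idx],
        delta=snapshot.delta[idx],
        meas_times=[snapshot.meas_times[i] for i in idx],
        meas_values=[snapshot.meas_values[i] for i in idx],
    )


class CoxModel:
    """Treatment-only Cox proportional-hazards model for one subgroup.

    All subjects are eligible (no minimum-measurement criterion); the
    information reported is the observed partial-likelihood information at
    the root and z = -theta_hat*sqrt(I).
    """

    def __init__(self, snapshot: TrialSnapshot, subgroup):
        self.subgroup = subgroup
        sub = _subset(snapshot, subgroup)
        self.psi, self.tobs, self.delta = sub.psi, sub.tobs, sub.delta
        ev = np.flatnonzero(self.delta == 1)
        order = np.argsort(self.tobs[ev], kind="stable")
        self.ev_subj = ev[order]
        self.te = self.tobs[self.ev_subj]
        # risk-set treated/control counts at each event time (Breslow)
        risk = self.tobs[None, :] >= self.te[:, None]
        self.n_treat = (risk * (self.psi == 1)[None, :]).sum(axis=1).astype(float)
        self.n_ctrl = (risk * (self.psi == 0)[None, :]).sum(axis=1).astype(float)
        self.ev_psi = self.psi[self.ev_subj]

    @property
    def n_events(self) -> int:
        return self.te.size

    def score_info(self, theta: float) -> tuple[float, float]:
        w1 = self.n_treat * np.exp(theta)
        p = w1 / (w1 + self.n_ctrl)
        return float((self.ev_psi - p).sum()), float((p * (1.0 - p)).sum())

    def fit(self) -> ConditionalScoreResults:
        if self.n_events == 0:
            raise RootNotFound("no events observed")
        theta = 0.0
        for _ in range(50):
            u, i_obs = self.score_info(theta)
            if i_obs <= 1e-12:
                break
            step = u / i_obs
            theta += np.clip(step, -2.0, 2.0)
            if abs(theta) > _THETA_CAP:
                warnings.warn(
                    "monotone partial likelihood: estimate capped", stacklevel=2
                )
                theta = np.clip(theta, -_THETA_CAP, _THETA_CAP)
                break
            if abs(u) < 1e-10 * max(1, self.n_events):
                break
        u, info = self.score_info(theta)
        if info <= 0:
            raise RootNotFound("degenerate partial-likelihood information")
        return ConditionalScoreResults(
            gamma_hat=0.0,
            theta_hat=float(theta),
            sigma2_hat=float("nan"),
            A=np.array([[0.0, 0.0], [0.0, -info]]),
            B=np.array([[0.0, 0.0], [0.0, info]]),
            info=float(info),
            z=float(-theta * np.sqrt(info)),
            d=self.n_events,
            n=self.psi.size,
            subgroup=self.subgroup,
            method="cox",
        )


class CoxTimeVaryingModel:
    """Cox model with the observed biomarker as a time-varying covariate.

    ``covariate`` selects the evaluation rule at risk-set times:
    ``"locf"`` (default) carries the last observed value forward,
    ``"linear"`` interpolates between visits (flat beyond the last), and
    ``"ols"`` uses the prefix least-squares prediction (at least two
    measurements required -- the noiseless limit of the conditional score).
    Subjects with no usable covariate value at an event time are excluded
    from that risk set (with a logged warning for subjects never eligible).
    """

    def __init__(self, snapshot: TrialSnapshot, subgroup, covariate: str = "locf"):
        if covariate not in ("locf", "linear", "ols"):
            raise ValueError("covariate must be 'locf', 'linear' or 'ols'")
        self.subgroup = subgroup
        self.covariate = covariate
        sub = _subset(snapshot, subgroup)
        self.psi, self.tobs, self.delta = sub.psi, sub.tobs, sub.delta
        ns = self.psi.size

        if covariate == "ols":
            cum = _CumStats(sub.meas_times, sub.meas_values)
            counts = cum.counts_at(self.tobs)
            subj_ok = counts >= 2
        else:
            subj_ok = np.array([len(v) >= 1 for v in sub.meas_times])
        n_bad = int((~subj_ok).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} subjects excluded: no usable biomarker value",
                stacklevel=2,
            )

        ev = np.flatnonzero((self.delta == 1) & subj_ok)
        order = np.argsort(self.tobs[ev], kind="stable")
        self.ev_subj = ev[order]
        self.te = self.tobs[self.ev_subj]
        ne = self.te.size

        if covariate == "ols":
            _, xhat, _, valid = cum.prefix_ols(self.te)
            self.Zc = np.where(valid, xhat, 0.0)
            cov_ok = valid
        else:
            self.Zc = np.zeros((ne, ns))
            cov_ok = np.zeros((ne, ns), dtype=bool)
            for l in range(ns):
                v, dv = sub.meas_times[l], sub.meas_values[l]
                if len(v) == 0:
                    continue
                if covariate == "locf":
                    pos = np.searchsorted(v, self.te, side="right")
                    ok = pos > 0
                    self.Zc[ok, l] = dv[np.maximum(pos[ok] - 1, 0)]
                else:  # linear, flat extrapolation
                    ok = self.te >= v[0]
                    self.Zc[ok, l] = np.interp(self.te[ok], v, dv)
                cov_ok[:, l] = ok
        self.risk = (self.tobs[None, :] >= self.te[:, None]) & cov_ok
        self.ev_z = self.Zc[np.arange(ne), self.ev_subj]
        self.ev_psi = self.psi[self.ev_subj]

    @property
    def n_events(self) -> int:
        return self.te.size

    def score_hess(self, gamma: float, theta: float):
        logw = gamma * self.Zc + theta * self.psi[None, :]
        logw = np.where(self.risk, logw, -np.inf)
        mx = logw.max(axis=1, keepdims=True)
        w = np.exp(logw - mx)
        w[~np.isfinite(mx[:, 0])] = 0.0
        W = w.sum(axis=1)
        Wsafe = np.where(W > 0, W, 1.0)
        mz = (w * self.Zc).sum(axis=1) / Wsafe
        mp = (w * self.psi[None, :]).sum(axis=1) / Wsafe
        vzz = (w * self.Zc**2).sum(axis=1) / Wsafe - mz**2
        vpp = (w * self.psi[None, :] ** 2).sum(axis=1) / Wsafe - mp**2
        vzp = (w * self.Zc * self.psi[None, :]).sum(axis=1) / Wsafe - mz * mp
        U = np.array([(self.ev_z - mz).sum(), (self.ev_psi - mp).sum()])
        H = np.array([[vzz.sum(), vzp.sum()], [vzp.sum(), vpp.sum()]])
        return U, H

    def fit(self, fix_gamma: float | None = None) -> ConditionalScoreResults:
        if self.n_events == 0:
            raise RootNotFound("no events observed")
        x = np.zeros(2)
        if fix_gamma is not None:
            x[0] = fix_gamma
        for _ in range(80):
            U, H = self.score_hess(x[0], x[1])
            if fix_gamma is not None:
                U = U[1:]
                Hs = H[1:, 1:]
            else:
                Hs = H
            try:
                step = np.linalg.solve(Hs, U)
            except np.linalg.LinAlgError as exc:
                raise RootNotFound("singular time-varying Cox information") from exc
            step = np.clip(step, -2.0, 2.0)
            if fix_gamma is None:
                x += step
            else:
                x[1] += step[0]
            if np.abs(x).max() > _THETA_CAP:
                warnings.warn("monotone partial likelihood: estimate capped",
                              stacklevel=2)
                x = np.clip(x, -_THETA_CAP, _THETA_CAP)
                break
            if np.abs(U).max() < 1e-10 * max(1, self.n_events):
                break
        U, H = self.score_hess(x[0], x[1])
        Hinv = np.linalg.inv(H)
        info = 1.0 / Hinv[1, 1]
        if info <= 0:
            raise RootNotFound("degenerate information")
        return ConditionalScoreResults(
            gamma_hat=float(x[0]),
            theta_hat=float(x[1]),
            sigma2_hat=0.0,
            A=-H / self.psi.size,
            B=H / self.psi.size,
            info=float(info),
            z=float(-x[1] * np.sqrt(info)),
            d=self.n_events,
            n=self.psi.size,
            subgroup=self.subgroup,
            method="cox_tvc",
        )
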