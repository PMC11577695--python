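"""Conditional-score estimation for the joint longitudinal-survival model.

The treatment effect theta and biomarker association gamma are estimated
without distributional assumptions on the random effects: each subject's
true biomarker value at time t is replaced by the prefix ordinary-least-
squares prediction Xhat(t) from measurements taken at or before t, and the
measurement error is conditioned out through the sufficient statistic

    S_i(t) = Xhat_i(t) + gamma * sigma^2 * lev_i(t) * dN_i(t),

where sigma^2 * lev_i(t) is the prediction variance of Xhat_i(t) (lev is
the OLS leverage of the point t).  The estimating equation sums, over
observed event times, the difference between the event subject's (S, psi)
and the E0-weighted risk-set average, with E0 = exp{gamma*S -
gamma^2*sigma^2*lev/2 + theta*psi}.  Only subjects whose second measurement
precedes t enter risk sets or event sums.

The root gives (gamma_hat, theta_hat); a sandwich estimator built from the
numerically differenced Jacobian (A) and the per-subject score outer
products (B) yields the information I = 1/Var(theta_hat) and the
standardised statistic z = -theta_hat * sqrt(I), so that hazard reduction
(benefit) maps to large positive z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientMeasurements, NoResidualDf, RootNotFound
from .simulate import TrialSnapshot

__all__ = [
    "OLSFit",
    "ols_trajectory",
    "pooled_sigma2",
    "ConditionalScoreModel",
    "ConditionalScoreResults",
    "CombinedResults",
    "combine_subgroups",
]

MIN_EVENTS_GUIDELINE = 20  # below this, asymptotics are unreliable


# ---------------------------------------------------------------------------
# Per-subject trajectory fits
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    """Prefix least-squares trajectory fit for one subject.

    ``leverage(t)`` = 1/s + (t - vbar)^2 / Sxx, so that the prediction
    variance of ``xhat(t)`` is sigma^2 * leverage(t).
    """

    bhat0: float
    bhat1: float
    s: int
    vbar: float
    sxx: float

    def xhat(self, t: float) -> float:
        return self.bhat0 + self.bhat1 * t

    def leverage(self, t: float) -> float:
        return 1.0 / self.s + (t - self.vbar) ** 2 / self.sxx


def ols_trajectory(meas_times, meas_values, t: float) -> OLSFit:
    """OLS line through the measurements taken at or before ``t``."""
    v = np.asarray(meas_times, dtype=float)
    d = np.asarray(meas_values, dtype=float)
    use = v <= t
    v, d = v[use], d[use]
    s = v.size
    if s < 2:
        raise InsufficientMeasurements(
            f"need at least two measurements at or before t={t}, have {s}"
        )
    vbar = v.mean()
    sxx = float(((v - vbar) ** 2).sum())
    if sxx <= 0:
        raise np.linalg.LinAlgError("singular design: identical measurement times")
    b1 = float(((d - d.mean()) * (v - vbar)).sum() / sxx)
    b0 = float(d.mean() - b1 * vbar)
    return OLSFit(bhat0=b0, bhat1=b1, s=s, vbar=vbar, sxx=sxx)


# ---------------------------------------------------------------------------
# Padded cumulative measurement statistics (vectorised prefix OLS)
# ---------------------------------------------------------------------------

class _CumStats:
    """Padded per-subject cumulative sums enabling O(1) prefix-OLS lookups."""

    def __init__(self, meas_times: list, meas_values: list):
        ns = len(meas_times)
        m = max((len(v) for v in meas_times), default=1)
        m = max(m, 1)
        V = np.full((ns, m), np.inf)
        D = np.zeros((ns, m))
        for i, (v, d) in enumerate(zip(meas_times, meas_values)):
            V[i, : len(v)] = v
            D[i, : len(v)] = d
        mask = np.isfinite(V)
        Vz = np.where(mask, V, 0.0)
        self.V = V
        self.ns, self.m = ns, m
        self.Cv = np.cumsum(Vz, axis=1)
        self.Cv2 = np.cumsum(Vz**2, axis=1)
        self.Cd = np.cumsum(D, axis=1)
        self.Cd2 = np.cumsum(D**2, axis=1)
        self.Cvd = np.cumsum(Vz * D, axis=1)
        self.counts_total = mask.sum(axis=1)

    def counts_at(self, t) -> np.ndarray:
        """Number of measurements at or before each subject's time t[i]."""
        t = np.asarray(t, dtype=float)
        if t.ndim != 1 or t.shape[0] != self.ns:
            raise ValueError("counts_at expects per-subject times")
        out = np.empty(self.ns, dtype=np.int64)
        for i in range(self.ns):
            out[i] = np.searchsorted(self.V[i], t[i], side="right")
        return out

    def _gather(self, arr, idx):
        flat = arr.ravel()
        cols = np.clip(idx, 0, self.m - 1)
        rows = np.arange(self.ns)[None, :]
        return flat[rows * self.m + cols]

    def prefix_ols(self, te: np.ndarray):
        """Vectorised prefix OLS of every subject at every time in ``te``.

        Returns (counts, xhat, lev, valid) with shape (ne, ns); ``valid``
        marks s >= 2 with non-degenerate spread.
        """
        ne, ns = te.size, self.ns
        cnt = np.empty((ne, ns), dtype=np.int64)
        for i in range(ns):  # per-subject searchsorted beats a dense tensor
            cnt[:, i] = np.searchsorted(self.V[i], te, side="right")
        idx = cnt - 1
        s = cnt.astype(float)
        Sv = self._gather(self.Cv, idx)
        Sv2 = self._gather(self.Cv2, idx)
        Sd = self._gather(self.Cd, idx)
        Svd = self._gather(self.Cvd, idx)
        with np.errstate(divide="ignore", invalid="ignore"):
            sxx = Sv2 - Sv**2 / s
            b1 = (Svd - Sv * Sd / s) / sxx
            b0 = (Sd - b1 * Sv) / s
            xh = b0 + b1 * te[:, None]
            lv = 1.0 / s + (te[:, None] - Sv / s) ** 2 / sxx
        ok = (cnt >= 2) & (sxx > 1e-12)
        xhat = np.where(ok, xh, 0.0)
        lev = np.where(ok, lv, 0.0)
        return cnt, xhat, lev, ok

    def rss_at_counts(self, counts: np.ndarray):
        """Residual sum of squares of each subject's OLS fit to its first
        ``counts`` measurements (nan where count < 3)."""
        idx = counts - 1
        cols = np.clip(idx, 0, self.m - 1)
        rows = np.arange(self.ns)
        s = counts.astype(float)
        Sv = self.Cv[rows, cols]
        Sv2 = self.Cv2[rows, cols]
        Sd = self.Cd[rows, cols]
        Sd2 = self.Cd2[rows, cols]
        Svd = self.Cvd[rows, cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            sxx = Sv2 - Sv**2 / s
            syy = Sd2 - Sd**2 / s
            sxy = Svd - Sv * Sd / s
            rss = syy - sxy**2 / sxx
        rss = np.where((counts >= 3) & (sxx > 1e-12), np.maximum(rss, 0.0), np.nan)
        return rss


def _pooled_sigma2_from_stats(cum: _CumStats, counts: np.ndarray) -> float:
    rss = cum.rss_at_counts(counts)
    use = counts > 2
    if not np.any(use):
        raise NoResidualDf("no subject has more than two retained measurements")
    df = (counts[use] - 2).sum()
    return float(np.nansum(rss[use]) / df)


def pooled_sigma2(snapshot: TrialSnapshot, subgroup) -> float:
    """Pooled measurement-error variance: per-subject full-prefix OLS
    residual sums of squares with m-2 degrees of freedom, over subjects
    with more than two retained measurements."""
    mask = snapshot.subgroup_mask(subgroup)
    idx = np.flatnonzero(mask)
    cum = _CumStats(
        [snapshot.meas_times[i] for i in idx],
        [snapshot.meas_values[i] for i in idx],
    )
    return _pooled_sigma2_from_stats(cum, cum.counts_total)


# ---------------------------------------------------------------------------
# Score core: dense per-event design quantities, re-censorable
# ---------------------------------------------------------------------------

class _CondScoreCore:
    """Precomputed prefix-OLS design quantities at a fixed set of candidate
    event times; supports evaluating the score under any administrative
    re-censoring that only removes events / shortens follow-up."""

    def __init__(self, meas_times, meas_values, psi, tobs, delta):
        self.psi = np.asarray(psi, dtype=float)
        self.tobs = np.asarray(tobs, dtype=float)
        self.delta = np.asarray(delta, dtype=int)
        self.ns = self.psi.size
        self.cum = _CumStats(meas_times, meas_values)
        self.counts_obs = self.cum.counts_at(self.tobs)
        self.elig_subject = self.counts_obs >= 2
        # candidate events: observed events among measurement-eligible subjects
        ev = np.flatnonzero((self.delta == 1) & self.elig_subject)
        order = np.argsort(self.tobs[ev], kind="stable")
        self.ev_subj = ev[order]
        self.te = self.tobs[self.ev_subj]
        self.ne = self.te.size
        if self.ne:
            cnt, xhat, lev, valid = self.cum.prefix_ols(self.te)
            self.xhat, self.lev, self.valid = xhat, lev, valid
        else:
            self.xhat = self.lev = np.zeros((0, self.ns))
            self.valid = np.zeros((0, self.ns), dtype=bool)
        self.n_empty_risk = 0

    def risk_mask(self, tobs=None) -> np.ndarray:
        t = self.tobs if tobs is None else tobs
        return (t[None, :] >= self.te[:, None]) & self.valid

    def score(
        self,
        gamma: float,
        theta: float,
        sigma2: float,
        ev_on: np.ndarray | None = None,
        risk: np.ndarray | None = None,
        per_subject: bool = False,
        subject_weights: np.ndarray | None = None,
    ):
        """Conditional score U (2-vector); optionally per-subject summands.

        ``subject_weights`` multiplies each subject's event terms and risk
        contributions (used by the jackknife variance estimator).
        """
        if risk is None:
            risk = self.risk_mask()
        if ev_on is None:
            ev_on = np.ones(self.ne, dtype=bool)
        rows = np.flatnonzero(ev_on)
        if rows.size == 0:
            raise RootNotFound("no events to score")
        e_idx = self.ev_subj[rows]
        S = self.xhat[rows]
        lev = self.lev[rows]
        r = risk[rows]
        ar = np.arange(rows.size)
        # sufficient-statistic increment for the event subject (dN = 1)
        S_event = S[ar, e_idx] + gamma * sigma2 * lev[ar, e_idx]
        S = S.copy()
        S[ar, e_idx] = S_event
        logw = gamma * S - 0.5 * gamma**2 * sigma2 * lev + theta * self.psi[None, :]
        logw = np.where(r, logw, -np.inf)
        mx = logw.max(axis=1, keepdims=True)
        nonempty = np.isfinite(mx[:, 0])
        self.n_empty_risk = int((~nonempty).sum())
        if self.n_empty_risk:
            warnings.warn(
                f"{self.n_empty_risk} event times had an empty risk set and "
                "were excluded",
                stacklevel=2,
            )
        w = np.exp(logw - np.where(nonempty, mx[:, 0], 0.0)[:, None])
        w[~nonempty] = 0.0
        gmult = None
        if subject_weights is not None:
            gmult = np.asarray(subject_weights, dtype=float)
            w = w * gmult[None, :]
        W = w.sum(axis=1)
        empty = W <= 0
        Wsafe = np.where(empty, 1.0, W)
        ES = (w * S).sum(axis=1) / Wsafe
        Epsi = (w * self.psi[None, :]).sum(axis=1) / Wsafe
        keep = nonempty & ~empty
        u1 = np.where(keep, S_event - ES, 0.0)
        u2 = np.where(keep, self.psi[e_idx] - Epsi, 0.0)
        if gmult is not None:
            ge = gmult[e_idx]
            u1 = u1 * ge
            u2 = u2 * ge
        U = np.array([u1.sum(), u2.sum()])
        if not per_subject:
            return U
        # Per-subject influence contributions: each subject's own event term
        # minus its share of every risk-set average it enters (the score-
        # residual decomposition).
        p = w / Wsafe[:, None]
        comp1 = (p * S).sum(axis=0) - p.T @ ES
        comp2 = self.psi * p.sum(axis=0) - p.T @ Epsi
        xi = np.zeros((self.ns, 2))
        np.add.at(xi, e_idx, np.column_stack([u1, u2]))
        xi[:, 0] -= comp1
        xi[:, 1] -= comp2
        return U, xi

    def var_score_jackknife(
        self,
        gamma: float,
        theta: float,
        sigma2: float,
        ev_on: np.ndarray | None = None,
        risk: np.ndarray | None = None,
        n_groups: int = 40,
        n_splits: int = 1,
        seed: int = 1234,
    ) -> np.ndarray:
        """Estimate Var(U) by a delete-one-group jackknife.

        Subjects are split into ``n_groups`` blocks; the full nonlinear
        score is re-evaluated with each block removed, and Var(U) ~
        G/(G-1) * sum_g (U_(g) - Ubar)^2, averaged over ``n_splits``
        independent random partitions (deterministic seed).  Unlike the
        first-order influence decomposition this retains the contribution
        of the heavy-tailed risk-set weights, which otherwise leads to an
        overstated information when the measurement error is large.
        """
        G = min(n_groups, self.ns)
        if risk is None:
            risk = self.risk_mask()
        if ev_on is None:
            ev_on = np.ones(self.ne, dtype=bool)
        rows = np.flatnonzero(ev_on)
        e_idx = self.ev_subj[rows]
        S = self.xhat[rows]
        lev = self.lev[rows]
        ar = np.arange(rows.size)
        S_event = S[ar, e_idx] + gamma * sigma2 * lev[ar, e_idx]
        S = S.copy()
        S[ar, e_idx] = S_event
        logw = gamma * S - 0.5 * gamma**2 * sigma2 * lev + theta * self.psi[None, :]
        logw = np.where(risk[rows], logw, -np.inf)
        mx = logw.max(axis=1, keepdims=True)
        nonempty = np.isfinite(mx[:, 0])
        w = np.exp(logw - np.where(nonempty, mx[:, 0], 0.0)[:, None])
        w[~nonempty] = 0.0
        W = w.sum(axis=1)
        wS = w * S
        wP = w * self.psi[None, :]
        numS = wS.sum(axis=1)
        numP = wP.sum(axis=1)
        ev_psi = self.psi[e_idx]

        # The weights are fixed across deletions, so every group-deleted
        # score follows from group-wise sums: two matrix products give all
        # G replicates of one partition at once.
        out = np.zeros((2, 2))
        rng = np.random.default_rng(seed)
        for _ in range(n_splits):
            grp = rng.permutation(self.ns) % G
            Gmat = np.zeros((self.ns, G))
            Gmat[np.arange(self.ns), grp] = 1.0
            sub_w = w @ Gmat          # (ne, G)
            sub_wS = wS @ Gmat
            sub_wP = wP @ Gmat
            W_del = W[:, None] - sub_w
            ok = nonempty[:, None] & (W_del > 1e-300)
            with np.errstate(divide="ignore", invalid="ignore"):
                ES_del = (numS[:, None] - sub_wS) / W_del
                EP_del = (numP[:, None] - sub_wP) / W_del
            keep = ok & (grp[e_idx][:, None] != np.arange(G)[None, :])
            u1 = np.where(keep, S_event[:, None] - ES_del, 0.0).sum(axis=0)
            u2 = np.where(keep, ev_psi[:, None] - EP_del, 0.0).sum(axis=0)
            Ug = np.column_stack([u1, u2])
            dev = Ug - Ug.mean(axis=0)
            out += G / (G - 1) * dev.T @ dev
        return out / n_splits

    def solve(
        self,
        sigma2: float,
        ev_on: np.ndarray | None = None,
        tobs: np.ndarray | None = None,
        start: tuple[float, float] = (0.0, 0.0),
        fix_gamma: float | None = None,
        tol_scale: float = 1e-8,
        max_iter: int = 60,
        b_method: str = "jackknife",
        jk_groups: int = 40,
        jk_splits: int = 10,
        jk_seed: int = 1234,
    ):
        """Damped-Newton root of the score; returns the full sandwich.

        Convergence: ||U||_inf < tol_scale * d.  Restarts from theta =
        +/-0.5 before giving up (roots can fail when sigma2 is large and
        events are few).
        """
        risk = self.risk_mask(tobs)
        if ev_on is None:
            ev_on = np.ones(self.ne, dtype=bool)
        d = int(ev_on.sum())
        if d < 1:
            raise RootNotFound("no events available")
        if d < MIN_EVENTS_GUIDELINE:
            warnings.warn(
                f"only {d} events; at least {MIN_EVENTS_GUIDELINE} per subgroup "
                "are recommended for reliable asymptotics",
                stacklevel=2,
            )
        tol = tol_scale * d

        if fix_gamma is None:
            def fun(x):
                return self.score(x[0], x[1], sigma2, ev_on, risk)
        else:
            def fun(x):
                return np.atleast_1d(
                    self.score(fix_gamma, x[0], sigma2, ev_on, risk)[1]
                )

        starts = [np.asarray(start, dtype=float)]
        for alt in (0.5, -0.5):
            base = np.asarray(start, dtype=float).copy()
            base[-1] = alt
            starts.append(base)
        if fix_gamma is not None:
            starts = [s[-1:] for s in starts]

        x, U = None, None
        for x0 in starts:
            x, U, ok = _damped_newton(fun, x0, tol, max_iter)
            if ok and np.abs(x).max() <= 8.0:  # reject spurious distant roots
                break
        else:
            raise RootNotFound(
                f"conditional score root not found (d={d}, |U|={np.abs(U).max():.3g})"
            )

        if fix_gamma is None:
            gamma_hat, theta_hat = float(x[0]), float(x[1])
        else:
            gamma_hat, theta_hat = float(fix_gamma), float(x[0])
        # the score has spurious roots at extreme parameter values where the
        # risk-set weights degenerate; reject them as non-roots
        if max(abs(gamma_hat), abs(theta_hat)) > 8.0:
            raise RootNotFound(
                f"divergent root (gamma={gamma_hat:.2f}, theta={theta_hat:.2f})"
            )

        J = _num_jac(
            lambda y: self.score(y[0], y[1], sigma2, ev_on, risk),
            np.array([gamma_hat, theta_hat]),
        )
        n = self.ns
        A = J / n
        if b_method == "jackknife":
            B = self.var_score_jackknife(
                gamma_hat, theta_hat, sigma2, ev_on, risk,
                n_groups=jk_groups, n_splits=jk_splits, seed=jk_seed,
            ) / n
        elif b_method == "influence":
            _, xi = self.score(
                gamma_hat, theta_hat, sigma2, ev_on, risk, per_subject=True
            )
            B = (xi.T @ xi) / n
        else:
            raise ValueError("b_method must be 'jackknife' or 'influence'")
        try:
            if fix_gamma is None:
                Ainv = np.linalg.inv(A)
                var_theta = (Ainv @ B @ Ainv.T)[1, 1] / n
            else:  # one-parameter sandwich for theta alone
                var_theta = B[1, 1] / (A[1, 1] ** 2) / n
        except np.linalg.LinAlgError as exc:
            raise RootNotFound("singular derivative matrix at the root") from exc
        if not np.isfinite(var_theta) or var_theta <= 0:
            raise RootNotFound("non-positive variance estimate at the root")
        info = 1.0 / var_theta
        return {
            "gamma_hat": gamma_hat,
            "theta_hat": theta_hat,
            "sigma2_hat": sigma2,
            "A": A,
            "B": B,
            "info": float(info),
            "z": float(-theta_hat * np.sqrt(info)),
            "d": d,
            "n": n,
        }


def _num_jac(fun, x, rel_step=1e-5):
    """Central-difference Jacobian with step rel_step*max(1,|x_i|)."""
    x = np.asarray(x, dtype=float)
    p = x.size
    f0 = np.atleast_1d(fun(x))
    J = np.empty((f0.size, p))
    for i in range(p):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.atleast_1d(fun(xp)) - np.atleast_1d(fun(xm))) / (2 * h)
    return J


def _damped_newton(fun, x0, tol, max_iter):
    x = np.asarray(x0, dtype=float).copy()
    U = np.atleast_1d(fun(x))
    for _ in range(max_iter):
        if np.abs(U).max() < tol:
            return x, U, True
        J = _num_jac(fun, x)
        try:
            step = np.linalg.solve(np.atleast_2d(J), U)
        except np.linalg.LinAlgError:
            return x, U, False
        # backtrack until the score norm decreases
        lam, accepted = 1.0, False
        for _ in range(12):
            xn = x - lam * step
            Un = np.atleast_1d(fun(xn))
            if not np.all(np.isfinite(Un)):
                lam *= 0.5
                continue
            if np.abs(Un).max() < np.abs(U).max() or lam == 1.0 and np.abs(
                Un
            ).max() < tol:
                x, U, accepted = xn, Un, True
                break
            lam *= 0.5
        if not accepted:
            x = x - lam * step
            U = np.atleast_1d(fun(x))
            if not np.all(np.isfinite(U)):
                return x, U, False
    return x, U, bool(np.abs(U).max() < tol)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

@dataclass
class ConditionalScoreResults:
    """Per-subgroup conditional-score fit at one analysis."""

    gamma_hat: float
    theta_hat: float
    sigma2_hat: float
    A: np.ndarray
    B: np.ndarray
    info: float
    z: float
    d: int
    n: int
    subgroup: object = None
    method: str = "condscore"

    def to_dict(self) -> dict:
        return {
            "gamma_hat": self.gamma_hat,
            "theta_hat": self.theta_hat,
            "sigma2_hat": self.sigma2_hat,
            "info": self.info,
            "z": self.z,
            "d": self.d,
            "n": self.n,
        }

    def summary(self) -> str:
        se = 1.0 / np.sqrt(self.info)
        lines = [
            f"{self.method} fit  (subgroup {self.subgroup})",
            "=" * 44,
            f"subjects            {self.n:>10d}",
            f"events              {self.d:>10d}",
            f"gamma_hat           {self.gamma_hat:>10.4f}",
            f"theta_hat           {self.theta_hat:>10.4f}  (se {se:.4f})",
            f"sigma2_hat          {self.sigma2_hat:>10.4f}",
            f"information I       {self.info:>10.4f}",
            f"z (-theta*sqrt(I))  {self.z:>10.4f}",
        ]
        return "\n".join(lines)


class ConditionalScoreModel:
    """Conditional-score model for one subgroup of a trial snapshot.

    Parameters
    ----------
    snapshot : TrialSnapshot
    subgroup : {1, 2}
        Subgroup to fit.  The full population is handled by combining the
        two subgroup fits with :func:`combine_subgroups`.
    """

    def __init__(self, snapshot: TrialSnapshot, subgroup):
        self.subgroup = subgroup
        mask = snapshot.subgroup_mask(subgroup)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no subjects in subgroup {subgroup}")
        self._core = _CondScoreCore(
            [snapshot.meas_times[i] for i in idx],
            [snapshot.meas_values[i] for i in idx],
            snapshot.psi[idx],
            snapshot.tobs[idx],
            snapshot.delta[idx],
        )
        self.sigma2_hat = _pooled_sigma2_from_stats(
            self._core.cum, self._core.counts_obs
        )

    @property
    def n_events(self) -> int:
        return int(self._core.ne)

    def score(self, gamma, theta, sigma2=None) -> np.ndarray:
        """Evaluate the estimating function U(gamma, theta, sigma2)."""
        if sigma2 is None:
            sigma2 = self.sigma2_hat
        return self._core.score(gamma, theta, sigma2)

    def fit(
        self,
        start=(0.0, 0.0),
        fix_gamma: float | None = None,
        sigma2: float | None = None,
        b_method: str = "jackknife",
    ) -> ConditionalScoreResults:
        if sigma2 is None:
            sigma2 = self.sigma2_hat
        sol = self._core.solve(
            sigma2, start=start, fix_gamma=fix_gamma, b_method=b_method
        )
        sol["sigma2_hat"] = sigma2
        return ConditionalScoreResults(subgroup=self.subgroup, **sol)


# ---------------------------------------------------------------------------
# Full-population combination
# ---------------------------------------------------------------------------

@dataclass
class CombinedResults:
    """Prevalence-weighted full-population estimate."""

    theta_hat: float
    info: float
    z: float
    lam: float
    d: int = 0
    n: int = 0

    def to_dict(self) -> dict:
        return {"theta_hat": self.theta_hat, "info": self.info, "z": self.z,
                "d": self.d, "n": self.n}


def combine_subgroups(fit1, fit2, lam: float) -> CombinedResults:
    """theta_F = lam*theta_1 + (1-lam)*theta_2 with information
    I_F = (lam^2/I_1 + (1-lam)^2/I_2)^{-1}."""
    if not (0.0 < lam < 1.0):
        raise ValueError("lam must lie in (0,1)")
    if fit1.info <= 0 or fit2.info <= 0:
        raise ValueError("both informations must be positive")
    theta = lam * fit1.theta_hat + (1.0 - lam) * fit2.theta_hat
    info = 1.0 / (lam**2 / fit1.info + (1.0 - lam) ** 2 / fit2.info)
    return CombinedResults(
        theta_hat=float(theta),
        info=float(info),
        z=float(-theta * np.sqrt(info)),
        lam=lam,
        d=getattr(fit1, "d", 0) + getattr(fit2, "d", 0),
        n=getattr(fit1, "n", 0) + getattr(fit2, "n", 0),
    )
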