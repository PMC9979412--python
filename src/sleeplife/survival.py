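"""Proportional-hazards estimation on counting-process data.

Implements the partial-likelihood machinery directly (Newton-Raphson with
step-halving, Efron or Breslow tie handling, left truncation via delayed
entry) because every downstream quantity — Breslow baselines, profile
predictions, Fine-Gray subdistribution fits — reuses the same risk-set
bookkeeping.  Risk set at time t: rows with entry < t <= exit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "StepFunction",
    "TransitionFit",
    "FineGrayFit",
    "NoEventsError",
    "fit_cox",
    "breslow_baseline",
    "predict_cumhaz",
    "fit_finegray",
]

MAX_ITER = 50
LOGLIK_RTOL = 1e-9


class NoEventsError(ValueError):
    """No event on the requested transition."""


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous non-decreasing step function (cumulative hazard)."""

    times: np.ndarray  # strictly increasing jump locations
    increments: np.ndarray  # jump sizes, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        dz = np.asarray(self.increments, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "increments", dz)
        if t.shape != dz.shape:
            raise ValueError("times and increments differ in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(dz < 0):
            raise ValueError("negative increments")

    def __call__(self, t) -> np.ndarray:
        """Cumulative value at t (right-continuous)."""
        csum = np.concatenate([[0.0], np.cumsum(self.increments)])
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return csum[idx]

    def scaled(self, factor: float) -> "StepFunction":
        return StepFunction(self.times, self.increments * factor)


@dataclass
class TransitionFit:
    """One fitted transition-specific Cox model."""

    transition: int | None
    names: tuple[str, ...]
    beta: np.ndarray
    covariance: np.ndarray
    baseline: StepFunction  # cumulative hazard at the reference profile
    reference: np.ndarray  # covariate value the fit is centered at
    ties: str
    loglik: float
    converged: bool
    n_iter: int
    n_events: int
    n_rows: int
    message: str = ""

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def hazard_ratios(self, z: float = 1.959963984540054) -> dict[str, tuple[float, float, float]]:
        """name -> (HR, lower, upper) Wald intervals."""
        se = self.se()
        return {
            name: (float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s)))
            for name, b, s in zip(self.names, self.beta, se)
        }

    def to_dict(self) -> dict:
        return {
            "transition": self.transition,
            "names": list(self.names),
            "beta": self.beta.tolist(),
            "covariance": self.covariance.tolist(),
            "baseline_times": self.baseline.times.tolist(),
            "baseline_increments": self.baseline.increments.tolist(),
            "reference": self.reference.tolist(),
            "ties": self.ties,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_events": self.n_events,
            "n_rows": self.n_rows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionFit":
        return cls(
            transition=d["transition"],
            names=tuple(d["names"]),
            beta=np.asarray(d["beta"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            baseline=StepFunction(
                np.asarray(d["baseline_times"], dtype=float),
                np.asarray(d["baseline_increments"], dtype=float),
            ),
            reference=np.asarray(d["reference"], dtype=float),
            ties=d["ties"],
            loglik=d["loglik"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            n_events=d["n_events"],
            n_rows=d["n_rows"],
        )


@dataclass
class FineGrayFit:
    names: tuple[str, ...]
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_events: int
    n_competing: int
    hr: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


# ---------------------------------------------------------------------------
# risk-set bookkeeping
# ---------------------------------------------------------------------------


class _RiskSets:
    """Precomputed sort orders and event-group structure.

    Suffix-sum identity: because entry < exit row-wise, the at-risk sum at
    time t over {entry < t <= exit} equals (sum over exit >= t) minus
    (sum over entry >= t).
    """

    def __init__(self, entry: np.ndarray, exit_: np.ndarray, status: np.ndarray, X: np.ndarray):
        self.n, self.p = X.shape
        self.entry, self.exit, self.status, self.X = entry, exit_, status, X
        self.order_exit = np.argsort(exit_, kind="stable")
        self.order_entry = np.argsort(entry, kind="stable")
        self.exit_sorted = exit_[self.order_exit]
        self.entry_sorted = entry[self.order_entry]

        deaths = np.flatnonzero(status == 1)
        deaths = deaths[np.argsort(exit_[deaths], kind="stable")]
        self.deaths = deaths
        times, starts, counts = np.unique(exit_[deaths], return_index=True, return_counts=True)
        self.event_times = times  # (m,)
        self.group_starts = starts
        self.d = counts.astype(float)  # tie multiplicities
        self.sx = np.add.reduceat(X[deaths], starts, axis=0) if deaths.size else np.zeros((0, self.p))
        # positions of event times in the sorted exit/entry arrays
        self.ie = np.searchsorted(self.exit_sorted, times, side="left")
        self.je = np.searchsorted(self.entry_sorted, times, side="left")

    def risk_sums(self, w: np.ndarray):
        """S0 (m,), S1 (m,p), S2 (m,p,p) over the risk set at each event time."""
        X = self.X
        wx = w[:, None] * X
        wxx = wx[:, :, None] * X[:, None, :]

        def _suffix(arr, order, idx):
            s = arr[order][::-1].cumsum(axis=0)[::-1]
            pad = np.zeros((1,) + arr.shape[1:])
            s = np.concatenate([s, pad], axis=0)
            return s[idx]

        S0 = _suffix(w[:, None], self.order_exit, self.ie)[:, 0] - _suffix(
            w[:, None], self.order_entry, self.je
        )[:, 0]
        S1 = _suffix(wx, self.order_exit, self.ie) - _suffix(wx, self.order_entry, self.je)
        S2 = _suffix(wxx, self.order_exit, self.ie) - _suffix(wxx, self.order_entry, self.je)
        return S0, S1, S2

    def death_sums(self, w: np.ndarray):
        """Same moments restricted to the tied deaths at each event time."""
        idx = self.deaths
        wd = w[idx]
        Xd = self.X[idx]
        D0 = np.add.reduceat(wd, self.group_starts)
        D1 = np.add.reduceat(wd[:, None] * Xd, self.group_starts, axis=0)
        D2 = np.add.reduceat(
            (wd[:, None] * Xd)[:, :, None] * Xd[:, None, :], self.group_starts, axis=0
        )
        return D0, D1, D2


def _efron_quantities(rs: _RiskSets, beta: np.ndarray, ties: str):
    """(loglik, gradient, information) at beta."""
    w = np.exp(rs.X @ beta)
    S0, S1, S2 = rs.risk_sums(w)
    lp_deaths = (rs.X @ beta)[rs.deaths]
    ll = float(np.add.reduceat(lp_deaths, rs.group_starts).sum()) if rs.deaths.size else 0.0
    p = rs.p
    grad = rs.sx.sum(axis=0)
    info = np.zeros((p, p))

    if ties == "breslow":
        ll -= float((rs.d * np.log(S0)).sum())
        Ebar = S1 / S0[:, None]
        grad -= (rs.d[:, None] * Ebar).sum(axis=0)
        info += (
            rs.d[:, None, None]
            * (S2 / S0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :])
        ).sum(axis=0)
        return ll, grad, info

    D0, D1, D2 = rs.death_sums(w)
    dmax = int(rs.d.max()) if rs.d.size else 0
    for l in range(dmax):
        mask = rs.d > l
        frac = (l / rs.d[mask])[:, None]
        R0 = S0[mask] - frac[:, 0] * D0[mask]
        R1 = S1[mask] - frac * D1[mask]
        R2 = S2[mask] - frac[:, :, None] * D2[mask]
        ll -= float(np.log(R0).sum())
        Ebar = R1 / R0[:, None]
        grad -= Ebar.sum(axis=0)
        info += (R2 / R0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :]).sum(axis=0)
    return ll, grad, info


def fit_cox(
    entry,
    exit_,
    status,
    X=None,
    names: Sequence[str] = (),
    ties: str = "efron",
    transition: int | None = None,
    reference: np.ndarray | None = None,
    tol: float = LOGLIK_RTOL,
    max_iter: int = MAX_ITER,
) -> TransitionFit:
    """Cox proportional hazards on left-truncated counting-process rows.

    The fit is centered at ``reference`` (default: covariate column means),
    which is also where the Breslow baseline is evaluated; recenter via
    :func:`predict_cumhaz`.  Perfect separation (monotone likelihood) is
    flagged as non-convergence, never silently returned.
    """
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    status = np.asarray(status, dtype=int)
    n = entry.size
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    names = tuple(names) if names else tuple(f"x{i}" for i in range(p))
    if len(names) != p:
        raise ValueError("names length does not match covariate count")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if np.any(entry >= exit_):
        raise ValueError("entry must be strictly before exit for every row")
    if status.sum() == 0:
        raise NoEventsError(f"no events on transition {transition}")
    if p and np.any(X.std(axis=0) == 0):
        const = [names[j] for j in range(p) if X[:, j].std() == 0]
        raise ValueError(f"constant covariates {const} cannot enter the partial likelihood")

    if reference is None:
        reference = X.mean(axis=0) if p else np.zeros(0)
    reference = np.asarray(reference, dtype=float)
    Xc = X - reference

    rs = _RiskSets(entry, exit_, status, Xc)
    beta = np.zeros(p)
    ll, grad, info = _efron_quantities(rs, beta, ties)
    converged = False
    n_iter = 0
    message = ""
    if p == 0:
        converged = True
    for n_iter in range(1, max_iter + 1):
        if p == 0:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step halving
        new_beta, new_ll = beta, ll
        for half in range(40):
            cand = beta + step / (2**half)
            cand_ll, cand_grad, cand_info = _efron_quantities(rs, cand, ties)
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                new_beta, new_ll, grad, info = cand, cand_ll, cand_grad, cand_info
                break
        else:
            message = "step halving failed to improve the likelihood"
            break
        rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, ll = new_beta, new_ll
        if rel < tol:
            converged = True
            break
    if p and not converged and not message:
        message = "maximum iterations reached"
    if p and np.any(np.abs(beta) > 20):
        converged = False
        message = "diverging coefficients: possible monotone likelihood / perfect separation"
        log.warning("fit_cox transition %s: %s", transition, message)

    if p:
        try:
            covariance = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            covariance = np.full((p, p), np.nan)
            converged = False
            message = message or "singular information at optimum"
    else:
        covariance = np.zeros((0, 0))

    baseline = breslow_baseline(rs, beta)
    return TransitionFit(
        transition=transition,
        names=names,
        beta=beta,
        covariance=covariance,
        baseline=baseline,
        reference=reference,
        ties=ties,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        n_events=int(status.sum()),
        n_rows=n,
        message=message,
    )


def breslow_baseline(rs: _RiskSets, beta: np.ndarray) -> StepFunction:
    """Breslow-form baseline cumulative hazard at the centering profile.

    Increment at event time t: d(t) / sum over the risk set of exp(beta'x).
    With beta = 0 and no ties this is the Nelson-Aalen estimator.
    """
    w = np.exp(rs.X @ beta)
    S0, _, _ = rs.risk_sums(w)
    if np.any(S0 <= 0):
        raise RuntimeError("empty risk set at an event time")
    return StepFunction(rs.event_times, rs.d / S0)


def predict_cumhaz(fit: TransitionFit, profile: Mapping[str, float]) -> StepFunction:
    """Cumulative hazard at a covariate profile: A0(t) * exp(beta'(x - ref))."""
    missing = [nm for nm in fit.names if nm not in profile]
    if missing:
        raise KeyError(f"profile is missing covariates {missing}")
    x = np.array([float(profile[nm]) for nm in fit.names])
    factor = float(np.exp(fit.beta @ (x - fit.reference)))
    return fit.baseline.scaled(factor)


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution hazards
# ---------------------------------------------------------------------------


def _censoring_km(time: np.ndarray, is_censored: np.ndarray):
    """Kaplan-Meier of the censoring distribution G(t).

    Returns (times, G_after) where G_after[i] is G evaluated just after
    times[i]; G is 1 before the first censoring time.  Risk set at t is
    {T_i >= t} (events at t are still at risk for censoring at t).
    """
    ct = np.unique(time[is_censored])
    sorted_all = np.sort(time)
    n = time.size
    at_risk = n - np.searchsorted(sorted_all, ct, side="left")
    dc = np.array([np.sum((time == t) & is_censored) for t in ct], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.cumprod(1.0 - dc / at_risk)
    return ct, G


def _G_left(ct: np.ndarray, G: np.ndarray, t) -> np.ndarray:
    """G(t-): left-continuous evaluation of the censoring survival."""
    idx = np.searchsorted(ct, np.asarray(t, dtype=float), side="left")
    Gpad = np.concatenate([[1.0], G])
    return Gpad[idx]


def fit_finegray(
    time,
    event,
    X,
    names: Sequence[str] = (),
    tol: float = LOGLIK_RTOL,
    max_iter: int = MAX_ITER,
) -> FineGrayFit:
    """Fine-Gray subdistribution-hazards model for cause 1.

    ``event``: 0 = censored, 1 = event of interest, 2 = competing event.
    Subjects with a competing event stay in the subdistribution risk set
    after it, down-weighted by the inverse-probability-of-censoring ratio
    G(t-)/G(T_i-) from the Kaplan-Meier of the censoring distribution.
    Breslow tie handling; covariance is the inverse weighted information
    (a model-based approximation, not a sandwich).  With no competing
    events the fit reduces exactly to a right-censored Cox model.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    names = tuple(names) if names else tuple(f"x{i}" for i in range(p))
    if (event == 1).sum() == 0:
        raise NoEventsError("no events of interest")
    ref = X.mean(axis=0)
    Xc = X - ref

    ct, G = _censoring_km(time, event == 0)

    # event-of-interest groups
    d_idx = np.flatnonzero(event == 1)
    d_idx = d_idx[np.argsort(time[d_idx], kind="stable")]
    etimes, starts, counts = np.unique(time[d_idx], return_index=True, return_counts=True)
    d = counts.astype(float)
    sx = np.add.reduceat(Xc[d_idx], starts, axis=0)
    m = etimes.size

    # sort orders for the two cumulative pieces
    order_t = np.argsort(time, kind="stable")
    t_sorted = time[order_t]
    ie = np.searchsorted(t_sorted, etimes, side="left")  # suffix over T_i >= t

    comp = np.flatnonzero(event == 2)
    comp = comp[np.argsort(time[comp], kind="stable")]
    comp_t = time[comp]
    jc = np.searchsorted(comp_t, etimes, side="left")  # prefix over T_i < t
    G_at_comp = _G_left(ct, G, comp_t)
    inv_G_comp = np.where(G_at_comp > 0, 1.0 / G_at_comp, 0.0)
    G_at_e = _G_left(ct, G, etimes)

    def quantities(beta):
        w = np.exp(Xc @ beta)
        wx = w[:, None] * Xc
        wxx = wx[:, :, None] * Xc[:, None, :]

        def _suffix(arr):
            s = arr[order_t][::-1].cumsum(axis=0)[::-1]
            s = np.concatenate([s, np.zeros((1,) + arr.shape[1:])], axis=0)
            return s[ie]

        def _prefix(arr):
            a = arr[comp] * inv_G_comp.reshape((-1,) + (1,) * (arr.ndim - 1))
            s = np.concatenate([np.zeros((1,) + arr.shape[1:]), a.cumsum(axis=0)], axis=0)
            return s[jc]

        S0 = _suffix(w[:, None])[:, 0] + G_at_e * _prefix(w[:, None])[:, 0]
        S1 = _suffix(wx) + G_at_e[:, None] * _prefix(wx)
        S2 = _suffix(wxx) + G_at_e[:, None, None] * _prefix(wxx)
        ll = float((Xc[d_idx] @ beta).sum()) - float((d * np.log(S0)).sum())
        Ebar = S1 / S0[:, None]
        grad = sx.sum(axis=0) - (d[:, None] * Ebar).sum(axis=0)
        info = (
            d[:, None, None]
            * (S2 / S0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :])
        ).sum(axis=0)
        return ll, grad, info

    beta = np.zeros(p)
    ll, grad, info = quantities(beta)
    converged = p == 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if p == 0:
            break
        step = np.linalg.solve(info, grad)
        new_beta, new_ll = beta, ll
        for half in range(40):
            cand = beta + step / (2**half)
            cand_ll, cand_grad, cand_info = quantities(cand)
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                new_beta, new_ll, grad, info = cand, cand_ll, cand_grad, cand_info
                break
        rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, ll = new_beta, new_ll
        if rel < tol:
            converged = True
            break

    covariance = np.linalg.inv(info) if p else np.zeros((0, 0))
    fit = FineGrayFit(
        names=names,
        beta=beta,
        covariance=covariance,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        n_events=int((event == 1).sum()),
        n_competing=int((event == 2).sum()),
    )
    z = 1.959963984540054
    se = fit.se()
    fit.hr = {
        nm: (float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s)))
        for nm, b, s in zip(names, beta, se)
    }
    return fit
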