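"""From fitted transition hazards to restricted life expectancies.

The three cumulative transition hazards, evaluated at a covariate profile,
are combined by the Aalen-Johansen product integral into state-occupation
probabilities P(age0, t) for the illness-death structure (1 = CVD-free,
2 = alive with CVD, 3 = dead).  Integrating the occupation probabilities
over [age0, tau] gives restricted state-specific life expectancies, whose
between-group differences are years of life lost.  Uncertainty comes from
person-level nonparametric bootstrap percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import Covariate
from .survival import StepFunction

log = logging.getLogger(__name__)

__all__ = [
    "OccupationCurve",
    "LifeExpectancySummary",
    "ConvergenceError",
    "covariate_profile",
    "aalen_johansen",
    "restricted_expectancies",
    "years_of_life_lost",
    "bootstrap_ci",
]


class ConvergenceError(RuntimeError):
    """A model fit inside the pipeline failed to converge."""


@dataclass
class OccupationCurve:
    """State-transition probability matrices P(age0, t) on a jump grid.

    ``ages`` starts at age0 (identity matrix) and ends at tau; rows of
    every matrix sum to one, state 3 is absorbing.  Between grid ages the
    matrices are right-continuous step functions.
    """

    ages: np.ndarray  # (m,)
    p11: np.ndarray
    p12: np.ndarray
    p13: np.ndarray
    p22: np.ndarray
    p23: np.ndarray

    def matrix(self, i: int) -> np.ndarray:
        return np.array(
            [
                [self.p11[i], self.p12[i], self.p13[i]],
                [0.0, self.p22[i], self.p23[i]],
                [0.0, 0.0, 1.0],
            ]
        )

    def check(self, atol: float = 1e-10) -> None:
        """Raise if the row-stochastic / monotonicity invariants fail."""
        for arr in (self.p11, self.p12, self.p13, self.p22, self.p23):
            if np.any(arr < -atol) or np.any(arr > 1 + atol):
                raise ValueError("occupation probability outside [0, 1]")
        if not np.allclose(self.p11 + self.p12 + self.p13, 1.0, atol=atol):
            raise ValueError("row 1 does not sum to one")
        if not np.allclose(self.p22 + self.p23, 1.0, atol=atol):
            raise ValueError("row 2 does not sum to one")
        if np.any(np.diff(self.p11) > atol):
            raise ValueError("P11 must be non-increasing")
        if np.any(np.diff(self.p13) < -atol):
            raise ValueError("P13 must be non-decreasing")


@dataclass
class LifeExpectancySummary:
    """Restricted expectancies for one exposure group in one sex stratum."""

    sex: str
    exposure: str
    e_free: float
    e_with: float
    e_total: float
    reference: str | None = None
    yll_free: float | None = None
    yll_total: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        if abs(self.e_free + self.e_with - self.e_total) > 1e-8:
            raise ValueError("e_free + e_with must equal e_total")


def covariate_profile(
    df: pd.DataFrame, covariates: Sequence[Covariate]
) -> dict[str, object]:
    """Reference covariate setting for life-expectancy prediction.

    Continuous covariates at the stratum mean, ordered categoricals at the
    median category (by cumulative counts), nominal categoricals at the
    modal category.
    """
    if len(df) == 0:
        raise ValueError("empty stratum")
    profile: dict[str, object] = {}
    for cov in covariates:
        col = df[cov.name].dropna()
        if len(col) == 0:
            raise ValueError(f"covariate {cov.name!r} is all-missing in the stratum")
        if cov.kind == "continuous":
            profile[cov.name] = float(col.mean())
        elif cov.kind == "ordered":
            codes = pd.Categorical(col, categories=list(cov.levels)).codes
            median_code = int(np.median(codes))
            profile[cov.name] = cov.levels[median_code]
        else:
            profile[cov.name] = col.mode().iloc[0]
    return profile


def aalen_johansen(
    cumhaz: Mapping[int, StepFunction],
    age0: float = 40.0,
    tau: float = 81.0,
) -> OccupationCurve:
    """Product-integral occupation probabilities from three cumulative hazards.

    ``cumhaz`` maps transition k (1: 1->2, 2: 1->3, 3: 2->3) to its step
    function at the chosen profile.  At each jump u the matrix I + dA(u) is
    applied; any row whose off-diagonal increments sum beyond one is
    proportionally truncated so the diagonal stays non-negative (logged).
    """
    if not age0 < tau:
        raise ValueError("tau must exceed age0")
    for k in (1, 2, 3):
        if k not in cumhaz:
            raise ValueError(f"missing cumulative hazard for transition {k}")

    def _clip(sf: StepFunction) -> StepFunction:
        keep = (sf.times > age0) & (sf.times <= tau)
        return StepFunction(sf.times[keep], sf.increments[keep])

    sfs = {k: _clip(cumhaz[k]) for k in (1, 2, 3)}
    grid = np.unique(np.concatenate([sfs[k].times for k in (1, 2, 3)]))
    m = grid.size

    def _on_grid(sf: StepFunction) -> np.ndarray:
        out = np.zeros(m)
        idx = np.searchsorted(grid, sf.times)
        out[idx] = sf.increments
        return out

    dA12, dA13, dA23 = (_on_grid(sfs[k]) for k in (1, 2, 3))

    row1 = dA12 + dA13
    over = row1 > 1.0
    if over.any():
        log.warning("truncating %d jumps with row-1 increment sum > 1", int(over.sum()))
        scale = np.where(over, 1.0 / np.maximum(row1, 1.0), 1.0)
        dA12, dA13 = dA12 * scale, dA13 * scale
    cap = 1.0 - 1e-12  # keep state 2 sub-stochastic so P22 ratios stay defined
    over2 = dA23 > cap
    if over2.any():
        log.warning("truncating %d jumps with row-2 increment > 1", int(over2.sum()))
        dA23 = np.minimum(dA23, cap)

    # closed-form illness-death product integral, all cumulative operations
    p11 = np.cumprod(1.0 - dA12 - dA13)
    q = np.cumprod(1.0 - dA23)  # P22(age0, t)
    p11_minus = np.concatenate([[1.0], p11[:-1]])
    # P12(t) = sum_{u <= t} P11(u-) dA12(u) P22(u, t), with P22(u, t) = q(t)/q(u);
    # once q underflows to zero, state 2 is empty and P12 is zero anyway
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        contrib = np.where(q > 1e-250, p11_minus * dA12 / np.maximum(q, 1e-250), 0.0)
    p12 = q * np.cumsum(contrib)
    p13 = 1.0 - p11 - p12

    ages = np.concatenate([[age0], grid])
    one = np.ones(1)
    zero = np.zeros(1)
    curve_args = dict(
        p11=np.concatenate([one, p11]),
        p12=np.concatenate([zero, p12]),
        p13=np.concatenate([zero, p13]),
        p22=np.concatenate([one, q]),
        p23=np.concatenate([zero, 1.0 - q]),
    )
    if ages[-1] < tau:
        ages = np.concatenate([ages, [tau]])
        curve_args = {k: np.concatenate([v, v[-1:]]) for k, v in curve_args.items()}
    curve = OccupationCurve(ages=ages, **curve_args)
    # numerical guard: cumulative products can drift a hair below zero
    np.clip(curve.p13, 0.0, 1.0, out=curve.p13)
    curve.check(atol=1e-9)
    return curve


def restricted_expectancies(curve: OccupationCurve) -> tuple[float, float, float]:
    """(e_free, e_with, e_total): exact integrals of the step-wise curve.

    P(age0, .) is right-continuous and piecewise constant, so each integral
    is a sum of interval widths times the occupation probability holding on
    the interval.
    """
    widths = np.diff(curve.ages)
    e_free = float((widths * curve.p11[:-1]).sum())
    e_with = float((widths * curve.p12[:-1]).sum())
    return e_free, e_with, e_free + e_with


def years_of_life_lost(
    exposed: LifeExpectancySummary, reference: LifeExpectancySummary
) -> tuple[float, float]:
    """(YLL_free, YLL_total) = reference minus exposed expectancy.

    Positive values are years lost by the exposed group.
    """
    if exposed.sex != reference.sex:
        raise ValueError(
            f"mismatched strata: {exposed.sex!r} vs {reference.sex!r}"
        )
    return (
        reference.e_free - exposed.e_free,
        reference.e_total - exposed.e_total,
    )


def bootstrap_ci(
    closure: Callable[[pd.DataFrame], Mapping[str, float]],
    cohort: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    strata: str = "sex",
    drop_warn_fraction: float = 0.05,
) -> dict:
    """Percentile bootstrap of every quantity the closure reports.

    Persons are the resampling unit (all of a person's transition rows move
    together because the closure rebuilds them from the participant table);
    resampling is stratified within ``strata``.  Iterations where the
    closure raises :class:`ConvergenceError` are dropped and logged; the
    result is flagged when more than ``drop_warn_fraction`` dropped.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    groups = {key: grp.index.to_numpy() for key, grp in cohort.groupby(strata)}
    draws: list[Mapping[str, float]] = []
    dropped = 0
    for _ in range(B):
        idx = np.concatenate(
            [rng.choice(members, size=members.size, replace=True) for members in groups.values()]
        )
        sample = cohort.loc[idx].reset_index(drop=True)
        try:
            draws.append(dict(closure(sample)))
        except ConvergenceError as err:
            dropped += 1
            log.info("bootstrap iteration dropped: %s", err)
    if not draws:
        raise ConvergenceError("all bootstrap iterations failed")
    flagged = dropped > drop_warn_fraction * B
    if flagged:
        log.warning("bootstrap dropped %d of %d iterations", dropped, B)
    keys = draws[0].keys()
    table = {k: np.array([d[k] for d in draws]) for k in keys}
    cis = {
        k: tuple(np.percentile(v, [2.5, 97.5], method="linear")) for k, v in table.items()
    }
    return {
        "ci": cis,
        "n_effective": len(draws),
        "n_dropped": dropped,
        "flagged": flagged,
        "samples": table,
    }
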