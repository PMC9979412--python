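"""Cohort construction: exclusion cascade, follow-up truncation and the
counting-process multistate expansion.

States: 1 = CVD-free, 2 = alive with CVD, 3 = dead.  Transitions:
1 (healthy->CVD), 2 (healthy->death), 3 (CVD->death).  Age is the model
timescale, so every person enters the risk set at their enrollment age
(left truncation) and exits at min(death, administrative censoring, tau).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import Covariate

log = logging.getLogger(__name__)

__all__ = [
    "ExclusionReport",
    "DEFAULT_TAU",
    "DEFAULT_LANDMARK",
    "SAME_AGE_EPSILON",
    "apply_exclusions",
    "build_followup",
    "to_multistate",
    "person_years",
    "validate_multistate",
]

DEFAULT_TAU = 81.0
DEFAULT_LANDMARK = 2.0
SAME_AGE_EPSILON = 1.0 / 365.25  # one day, for same-age CVD+death records

EXCLUSION_STAGES = (
    "missing_sleep_responses",
    "prevalent_cvd",
    "missing_covariates",
    "event_within_landmark",
)


@dataclass
class ExclusionReport:
    """Counts removed/remaining per sequential exclusion stage."""

    stages: tuple[str, ...]
    removed: tuple[int, ...]
    remaining: tuple[int, ...]
    initial: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stages, "removed": self.removed, "remaining": self.remaining}
        )

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.removed):
            raise ValueError("negative removal count")
        seq = (self.initial,) + tuple(self.remaining)
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError("remaining counts must be non-increasing")


def apply_exclusions(
    df: pd.DataFrame,
    covariates: Sequence[Covariate] = (),
    landmark: float = DEFAULT_LANDMARK,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Sequential exclusion cascade.

    Stage order is fixed: (1) unscorable sleep profile, (2) prevalent CVD,
    (3) missing covariates, (4) incident CVD or death within the first
    ``landmark`` years of follow-up.  ``df`` must already carry the
    ``sleep_category`` column from phenotyping.
    """
    if "sleep_category" not in df.columns:
        raise KeyError("run phenotyping first: no sleep_category column")
    kept = df
    removed, remaining = [], []

    masks = {
        "missing_sleep_responses": lambda d: d["sleep_category"] == "unscorable",
        "prevalent_cvd": lambda d: d["prevalent_cvd"].fillna(False).astype(bool),
        "missing_covariates": lambda d: (
            d[[c.name for c in covariates]].isna().any(axis=1)
            if covariates
            else pd.Series(False, index=d.index)
        ),
        "event_within_landmark": lambda d: (
            ((d["cvd_age"] - d["enroll_age"]) < landmark)
            | ((d["death_age"] - d["enroll_age"]) < landmark)
        ).fillna(False),
    }
    for stage in EXCLUSION_STAGES:
        drop = masks[stage](kept)
        removed.append(int(drop.sum()))
        kept = kept[~drop]
        remaining.append(len(kept))
        log.info("exclusion stage %s: removed %d, remaining %d", stage, removed[-1], remaining[-1])
    report = ExclusionReport(EXCLUSION_STAGES, tuple(removed), tuple(remaining), len(df))
    return kept.copy(), report


def build_followup(
    df: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    epsilon: float = SAME_AGE_EPSILON,
) -> pd.DataFrame:
    """Resolve each person's follow-up against the tau restriction.

    Effective exit = min(death age, administrative censoring age, tau).
    Death at exactly tau counts as an event; later deaths are censored at
    tau.  CVD events after the effective exit are discarded; a CVD age
    coinciding with the exit age is nudged ``epsilon`` years earlier so the
    post-CVD interval is non-empty.  Adds columns cvd_age_eff, cvd_status,
    exit_age, death_status; persons whose follow-up is empty after
    truncation are dropped with a logged reason.
    """
    out = df.copy()
    death = out["death_age"].to_numpy(dtype=float)
    censor = out["censor_age"].to_numpy(dtype=float)
    cvd = out["cvd_age"].to_numpy(dtype=float)
    enroll = out["enroll_age"].to_numpy(dtype=float)

    exit_age = np.fmin(np.where(np.isnan(death), np.inf, death), np.fmin(censor, tau))
    death_status = (~np.isnan(death) & (death <= np.fmin(censor, tau))).astype(int)

    cvd_eff = np.where(~np.isnan(cvd) & (cvd <= exit_age), cvd, np.nan)
    cvd_status = (~np.isnan(cvd_eff)).astype(int)
    clash = cvd_status.astype(bool) & (cvd_eff >= exit_age)
    if clash.any():
        log.info("nudging %d same-age CVD events %g years earlier", clash.sum(), epsilon)
        cvd_eff = np.where(clash, exit_age - epsilon, cvd_eff)

    out["cvd_age_eff"] = cvd_eff
    out["cvd_status"] = cvd_status
    out["exit_age"] = exit_age
    out["death_status"] = death_status

    empty = exit_age <= enroll
    if empty.any():
        log.warning(
            "dropping %d persons with empty follow-up after tau truncation: %s",
            empty.sum(),
            out.loc[empty, "person_id"].tolist()[:20],
        )
        out = out[~empty]
    bad_cvd = out["cvd_status"].astype(bool) & (out["cvd_age_eff"] <= out["enroll_age"])
    if bad_cvd.any():
        raise ValueError(
            f"CVD at or before enrollment for persons {out.loc[bad_cvd, 'person_id'].tolist()[:20]}"
        )
    return out


def to_multistate(df: pd.DataFrame, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Counting-process rows per transition.

    Every person contributes one transition-1 and one transition-2 row over
    (enrollment age, first-exit age]; persons with a transition-1 event
    additionally contribute a transition-3 row over (CVD age, exit age].
    Columns: person_id, transition, entry, exit, status, sex + any
    ``extra_columns`` carried through.
    """
    required = ("person_id", "sex", "enroll_age", "exit_age", "cvd_age_eff", "cvd_status", "death_status")
    for col in required:
        if col not in df.columns:
            raise KeyError(f"build_followup first: no {col!r} column")
    carried = ["person_id", "sex", *extra_columns]

    cvd = df["cvd_status"].astype(bool).to_numpy()
    first_exit = np.where(cvd, df["cvd_age_eff"].to_numpy(dtype=float), df["exit_age"].to_numpy(dtype=float))

    k1 = df[carried].copy()
    k1["transition"] = 1
    k1["entry"] = df["enroll_age"].to_numpy()
    k1["exit"] = first_exit
    k1["status"] = cvd.astype(int)

    k2 = df[carried].copy()
    k2["transition"] = 2
    k2["entry"] = df["enroll_age"].to_numpy()
    k2["exit"] = first_exit
    # death without prior CVD
    k2["status"] = (~cvd & df["death_status"].astype(bool).to_numpy()).astype(int)

    sub = df[cvd]
    k3 = sub[carried].copy()
    k3["transition"] = 3
    k3["entry"] = sub["cvd_age_eff"].to_numpy()
    k3["exit"] = sub["exit_age"].to_numpy()
    k3["status"] = sub["death_status"].astype(int).to_numpy()

    ms = pd.concat([k1, k2, k3], ignore_index=True)
    validate_multistate(ms)
    return ms


def validate_multistate(ms: pd.DataFrame, tau: float = DEFAULT_TAU) -> None:
    """Raise with offending person ids if counting-process invariants fail."""
    bad = ms[ms["entry"] >= ms["exit"]]
    if len(bad):
        raise ValueError(
            f"entry >= exit for persons {sorted(set(bad['person_id']))[:20]}"
        )
    if (ms["exit"] > tau + 1e-9).any():
        over = ms[ms["exit"] > tau + 1e-9]
        raise ValueError(f"exit beyond tau for persons {sorted(set(over['person_id']))[:20]}")
    n1 = (ms["transition"] == 1).sum()
    n2 = (ms["transition"] == 2).sum()
    if n1 != n2:
        raise ValueError(f"{n1} transition-1 rows but {n2} transition-2 rows")
    n3 = (ms["transition"] == 3).sum()
    e1 = int(ms.loc[ms["transition"] == 1, "status"].sum())
    if n3 != e1:
        raise ValueError(f"{n3} transition-3 rows but {e1} transition-1 events")


def person_years(followup: pd.DataFrame) -> float:
    """Total years at risk of death: sum of (effective exit - enrollment)."""
    return float((followup["exit_age"] - followup["enroll_age"]).sum())
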