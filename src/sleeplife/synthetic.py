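"""Synthetic cohort generator with known ground truth.

Event histories follow a three-state illness-death process
(1 = CVD-free, 2 = alive with CVD, 3 = dead) with Gompertz baseline
intensities on the age scale,

    lambda_k(age) = a_k * exp(b_k * (age - 40)) * exp(eta_k),

where eta_k collects multiplicative sleep-category and covariate effects
for transition k in {1: healthy->CVD, 2: healthy->death, 3: CVD->death}.
The 2->3 hazard is evaluated at current age (clock-forward Markov).  A
numerical oracle integrates the same intensities into restricted
state-specific life expectancies, so pipeline estimates can be checked
against the truth that generated the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import integrate

from .covariates import DEFAULT_COVARIATES, Covariate
from .phenotyping import (
    DEFAULT_CODELIST,
    HEALTHY_RESPONSES,
    RESPONSE_SETS,
    CodeList,
)

__all__ = [
    "GompertzIntensity",
    "SimulationTruth",
    "DEFAULT_TRUTH",
    "generate_cohort",
    "true_life_expectancy",
    "simulate_subdistribution",
    "write_cohort",
    "read_participants",
    "read_events",
]

SLEEP_CATEGORIES = ("healthy", "intermediate", "poor")
TRANSITIONS = (1, 2, 3)
NA_TOKEN = "NA"


@dataclass(frozen=True)
class GompertzIntensity:
    """Baseline intensity a*exp(b*(age-40)); reduces to exponential at b=0."""

    rate: float  # a >= 0, per year, at age 40
    shape: float = 0.0  # b >= 0, per year

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.shape < 0:
            raise ValueError("shape must be non-negative")

    def value(self, age: float) -> float:
        return self.rate * np.exp(self.shape * (age - 40.0))

    def cumulative(self, age0, age1, multiplier: float = 1.0):
        """Integral of the intensity (times ``multiplier``) over [age0, age1]."""
        a = self.rate * multiplier
        if self.shape == 0.0:
            return a * (np.asarray(age1) - np.asarray(age0))
        b = self.shape
        return (a / b) * (np.exp(b * (np.asarray(age1) - 40.0)) - np.exp(b * (np.asarray(age0) - 40.0)))

    def sample_first_passage(self, age0: np.ndarray, multiplier: np.ndarray, rng) -> np.ndarray:
        """Ages at which unit-exponential thresholds are crossed, entering at age0.

        Inversion of the cumulative hazard; infinite when the intensity is
        zero or the threshold is never reached.
        """
        age0 = np.asarray(age0, dtype=float)
        exceed = rng.exponential(size=age0.shape)
        a = self.rate * np.asarray(multiplier, dtype=float)
        out = np.full(age0.shape, np.inf)
        pos = a > 0
        if self.shape == 0.0:
            out[pos] = age0[pos] + exceed[pos] / a[pos]
            return out
        b = self.shape
        arg = b * exceed[pos] / a[pos] + np.exp(b * (age0[pos] - 40.0))
        out[pos] = 40.0 + np.log(arg) / b
        return out


def _default_sleep_log_hr() -> dict[int, dict[str, float]]:
    # Effect sizes sized so the poor-vs-healthy CVD-free contrast at age 40
    # lands in the one-to-seven-year range.
    return {
        1: {"healthy": 0.0, "intermediate": 0.15, "poor": 0.55},
        2: {"healthy": 0.0, "intermediate": 0.08, "poor": 0.30},
        3: {"healthy": 0.0, "intermediate": 0.05, "poor": 0.20},
    }


def _default_covariate_log_hr() -> dict[int, dict[str, float]]:
    # Nonzero effects on a small subset of encoded covariate columns.
    return {
        1: {"mental_health": 0.15, "screen_time": 0.02, "smoking": 0.10},
        2: {"mental_health": 0.10, "screen_time": 0.01, "smoking": 0.20},
        3: {"smoking": 0.10},
    }


def _default_prevalence() -> dict[str, dict[str, float]]:
    return {
        "female": {"healthy": 0.62, "intermediate": 0.36, "poor": 0.02},
        "male": {"healthy": 0.57, "intermediate": 0.41, "poor": 0.02},
    }


def _default_missing_rates() -> dict[str, float]:
    rates = {c: 0.035 for c in ("chronotype", "sleep_duration", "insomnia", "snoring", "sleepiness")}
    rates.update({c.name: 0.012 for c in DEFAULT_COVARIATES})
    return rates


def _default_disorder_rates() -> dict[str, float]:
    return {"insomnia": 0.009, "srbd": 0.017, "other": 0.030, "prescription": 0.020}


@dataclass
class SimulationTruth:
    """Everything needed to generate a cohort and to know its truth."""

    baseline: dict[int, GompertzIntensity] = field(
        default_factory=lambda: {
            1: GompertzIntensity(0.004, 0.075),
            2: GompertzIntensity(0.0012, 0.095),
            3: GompertzIntensity(0.020, 0.070),
        }
    )
    sleep_log_hr: dict[int, dict[str, float]] = field(default_factory=_default_sleep_log_hr)
    covariate_log_hr: dict[int, dict[str, float]] = field(default_factory=_default_covariate_log_hr)
    sleep_prevalence: dict[str, dict[str, float]] = field(default_factory=_default_prevalence)
    covariates: tuple[Covariate, ...] = DEFAULT_COVARIATES
    enrollment_age_range: tuple[float, float] = (40.0, 69.0)
    followup_range: tuple[float, float] = (10.0, 14.0)
    female_fraction: float = 0.56
    prevalent_cvd_rate: float = 0.10
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    disorder_rates: dict[str, float] = field(default_factory=_default_disorder_rates)
    event_window: tuple[float, float] = (-3.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for k in TRANSITIONS:
            if k not in self.baseline:
                raise ValueError(f"missing baseline intensity for transition {k}")
        for sex, prev in self.sleep_prevalence.items():
            total = sum(prev.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"sleep prevalences for {sex!r} sum to {total}, not 1")
            if any(p < 0 for p in prev.values()):
                raise ValueError("negative prevalence")
        lo, hi = self.enrollment_age_range
        if not (lo < hi):
            raise ValueError("empty enrollment age range")

    # -- linear predictors ------------------------------------------------

    def eta(self, transition: int, sleep_category: str, encoded: Mapping[str, float]) -> float:
        """Log hazard-ratio for one profile on one transition."""
        out = self.sleep_log_hr[transition].get(sleep_category)
        if out is None:
            raise ValueError(f"unknown sleep category {sleep_category!r}")
        for name, beta in self.covariate_log_hr.get(transition, {}).items():
            out += beta * float(encoded.get(name, 0.0))
        return out

    # -- (de)serialization ------------------------------------------------

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["baseline"] = {
            k: {"rate": v.rate, "shape": v.shape} for k, v in self.baseline.items()
        }
        raw["covariates"] = [
            {"name": c.name, "kind": c.kind, "levels": list(c.levels) if c.levels else None}
            for c in self.covariates
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["baseline"] = {
            int(k): GompertzIntensity(**v) for k, v in raw["baseline"].items()
        }
        raw["covariates"] = tuple(
            Covariate(c["name"], c["kind"], tuple(c["levels"]) if c["levels"] else None)
            for c in raw["covariates"]
        )
        for key in ("sleep_log_hr", "covariate_log_hr"):
            raw[key] = {int(k): dict(v) for k, v in raw[key].items()}
        for key in ("enrollment_age_range", "followup_range", "event_window"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


DEFAULT_TRUTH = SimulationTruth()


# ---------------------------------------------------------------------------
# covariate marginals for generation (roughly cohort-like, configurable by
# replacing this table)
# ---------------------------------------------------------------------------

_COVARIATE_MARGINALS: dict[str, tuple[float, ...]] = {
    "ses": (0.22, 0.25, 0.26, 0.27),
    "mental_health": (0.67, 0.33),
    "perceived_health": (0.19, 0.61, 0.17, 0.03),
    "bmi_class": (0.78, 0.20, 0.02),
    "economic_activity": (0.37, 0.53, 0.05, 0.05),
    "smoking": (0.57, 0.33, 0.10),
    "alcohol": (0.04, 0.03, 0.56, 0.22, 0.15),
    "diet": (0.06, 0.62, 0.32),
    "physical_activity": (0.15, 0.10, 0.15, 0.60),
}
_SCREEN_TIME_MEAN, _SCREEN_TIME_SD = 3.8, 2.0

_UNHEALTHY_RESPONSES = {
    name: tuple(r for r in RESPONSE_SETS[name] if r not in HEALTHY_RESPONSES[name])
    for name in RESPONSE_SETS
}


def _draw_sleep_responses(score: np.ndarray, rng) -> pd.DataFrame:
    """Five responses consistent with the given composite scores."""
    n = score.size
    # choose which traits are healthy, uniformly among subsets of that size:
    # trait j is healthy iff its random rank falls below the score
    ranks = np.argsort(np.argsort(rng.random((n, 5)), axis=1), axis=1)
    healthy_mask = ranks < score[:, None]

    def _pick(name: str, healthy: np.ndarray) -> np.ndarray:
        h = np.asarray(HEALTHY_RESPONSES[name], dtype=object)
        u = np.asarray(_UNHEALTHY_RESPONSES[name], dtype=object)
        out = np.where(
            healthy,
            h[rng.integers(0, len(h), size=n)],
            u[rng.integers(0, len(u), size=n)],
        )
        return out

    duration = np.where(
        healthy_mask[:, 1],
        rng.integers(7, 9, size=n),
        np.where(rng.random(n) < 0.7, rng.integers(4, 7, size=n), rng.integers(9, 12, size=n)),
    )
    return pd.DataFrame(
        {
            "chronotype": _pick("chronotype", healthy_mask[:, 0]),
            "sleep_duration": duration.astype(float),
            "insomnia": _pick("insomnia", healthy_mask[:, 2]),
            "snoring": _pick("snoring", healthy_mask[:, 3]),
            "sleepiness": _pick("sleepiness", healthy_mask[:, 4]),
        }
    )


def generate_cohort(
    truth: SimulationTruth, n: int, codelist: CodeList = DEFAULT_CODELIST
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``n`` participants and their coded sleep-disorder events.

    Returns (participants, events).  The participant table carries the raw
    questionnaire responses plus latent ``true_sleep_category``; the event
    table has one row per planted coded event with both an ISO date and an
    ``age_offset`` in years relative to enrollment (negative = before).
    Fixing ``truth.seed`` makes the output reproducible byte for byte.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(truth.seed)

    sex = np.where(rng.random(n) < truth.female_fraction, "female", "male")
    lo, hi = truth.enrollment_age_range
    enroll_age = rng.uniform(lo, hi, size=n)
    enroll_date = pd.to_datetime("2006-01-01") + pd.to_timedelta(
        rng.integers(0, 5 * 365, size=n), unit="D"
    )

    category = np.empty(n, dtype=object)
    for s in ("female", "male"):
        mask = sex == s
        prev = truth.sleep_prevalence[s]
        cats = list(prev)
        probs = np.array([prev[c] for c in cats])
        category[mask] = rng.choice(cats, size=mask.sum(), p=probs / probs.sum())
    score_lookup = {"poor": (0, 1), "intermediate": (2, 3), "healthy": (4, 5)}
    lo_s = np.array([score_lookup[c][0] for c in category])
    hi_s = np.array([score_lookup[c][1] for c in category])
    score = rng.integers(lo_s, hi_s + 1)

    sleep = _draw_sleep_responses(score, rng)

    cov_cols: dict[str, np.ndarray] = {}
    for cov in truth.covariates:
        if cov.kind == "continuous":
            cov_cols[cov.name] = np.clip(
                rng.normal(_SCREEN_TIME_MEAN, _SCREEN_TIME_SD, size=n), 0.0, None
            ).round(1)
        else:
            probs = np.asarray(_COVARIATE_MARGINALS[cov.name])
            levels = np.asarray(cov.levels, dtype=object)
            cov_cols[cov.name] = levels[
                rng.choice(len(levels), size=n, p=probs / probs.sum())
            ]

    # encoded covariate values for the hazard linear predictor
    encoded: dict[str, np.ndarray] = {}
    for cov in truth.covariates:
        if cov.kind == "continuous":
            encoded[cov.name] = cov_cols[cov.name].astype(float)
        elif cov.kind == "ordered":
            lut = {lvl: i for i, lvl in enumerate(cov.levels)}
            encoded[cov.name] = np.vectorize(lut.get)(cov_cols[cov.name]).astype(float)
        else:
            for lvl in cov.levels[1:]:
                encoded[f"{cov.name}__{lvl}"] = (cov_cols[cov.name] == lvl).astype(float)

    def _multiplier(transition: int) -> np.ndarray:
        lhr = np.array([truth.sleep_log_hr[transition][c] for c in category])
        for name, beta in truth.covariate_log_hr.get(transition, {}).items():
            lhr = lhr + beta * encoded.get(name, 0.0)
        return np.exp(lhr)

    t_cvd = truth.baseline[1].sample_first_passage(enroll_age, _multiplier(1), rng)
    t_death_healthy = truth.baseline[2].sample_first_passage(enroll_age, _multiplier(2), rng)
    censor_age = enroll_age + rng.uniform(*truth.followup_range, size=n)

    first_exit = np.minimum(t_cvd, t_death_healthy)
    has_cvd = (t_cvd < t_death_healthy) & (t_cvd <= censor_age)
    m3 = _multiplier(3)
    t_death_after = truth.baseline[3].sample_first_passage(
        np.where(has_cvd, t_cvd, enroll_age), m3, rng
    )

    cvd_age = np.where(has_cvd, t_cvd, np.nan)
    death_age = np.where(
        has_cvd,
        t_death_after,
        np.where(t_death_healthy <= first_exit, t_death_healthy, np.inf),
    )
    death_age = np.where(death_age <= censor_age, death_age, np.nan)

    participants = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": sex,
            "enroll_age": enroll_age,
            "enroll_date": enroll_date.strftime("%Y-%m-%d"),
            **sleep,
            **cov_cols,
            "prevalent_cvd": rng.random(n) < truth.prevalent_cvd_rate,
            "cvd_age": cvd_age,
            "death_age": death_age,
            "censor_age": censor_age,
            "true_sleep_category": category,
        }
    )

    # missingness, completely at random per field
    for col, rate in truth.missing_rates.items():
        if rate <= 0 or col not in participants.columns:
            continue
        mask = rng.random(n) < rate
        if participants[col].dtype == object:
            participants.loc[mask, col] = None
        else:
            participants.loc[mask, col] = np.nan

    # coded sleep-disorder events in a window around enrollment
    ev_person, ev_offset, ev_vocab, ev_code = [], [], [], []
    w_lo, w_hi = truth.event_window
    for disorder, rate in truth.disorder_rates.items():
        entries = codelist.entries.get(disorder, ())
        if not entries or rate <= 0:
            continue
        hit = np.flatnonzero(rng.random(n) < rate)
        offsets = rng.uniform(w_lo, w_hi, size=hit.size)
        picks = rng.integers(0, len(entries), size=hit.size)
        for pid, off, j in zip(hit, offsets, picks):
            ev_person.append(int(pid))
            ev_offset.append(float(off))
            ev_vocab.append(entries[j].vocabulary)
            ev_code.append(entries[j].code)
    events = pd.DataFrame(
        {
            "person_id": ev_person,
            "age_offset": ev_offset,
            "vocabulary": ev_vocab,
            "code": ev_code,
        }
    ).sort_values(["person_id", "age_offset"], kind="stable").reset_index(drop=True)
    if len(events):
        base = pd.Series(
            pd.to_datetime(participants["enroll_date"].iloc[events["person_id"]].to_numpy())
        )
        offset = pd.to_timedelta(
            (events["age_offset"] * 365.25).round().astype(int), unit="D"
        )
        events["date"] = (base + offset).dt.strftime("%Y-%m-%d")
    else:
        events["date"] = pd.Series(dtype=str)
    return participants, events


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def true_life_expectancy(
    truth: SimulationTruth,
    sleep_category: str = "healthy",
    encoded_covariates: Mapping[str, float] | None = None,
    age0: float = 40.0,
    tau: float = 81.0,
) -> tuple[float, float, float]:
    """Restricted (e_free, e_with, e_total) at ``age0`` under the truth.

    e_free integrates CVD-free survival; e_with integrates expected
    restricted residence in the CVD state over (CVD age, death age); both
    by adaptive quadrature to relative tolerance 1e-8.
    """
    if not age0 < tau:
        raise ValueError("tau must exceed age0")
    enc = dict(encoded_covariates or {})
    mult = {k: float(np.exp(truth.eta(k, sleep_category, enc))) for k in TRANSITIONS}
    b1, b2, b3 = (truth.baseline[k] for k in TRANSITIONS)

    def surv_free(u):
        return np.exp(-(b1.cumulative(age0, u, mult[1]) + b2.cumulative(age0, u, mult[2])))

    e_free, _ = integrate.quad(surv_free, age0, tau, epsabs=1e-11, epsrel=1e-8, limit=200)

    if b1.rate * mult[1] == 0.0:
        return e_free, 0.0, e_free

    def residual_with(s):
        # expected restricted time in state 2 entering it at age s
        val, _ = integrate.quad(
            lambda u: np.exp(-b3.cumulative(s, u, mult[3])),
            s,
            tau,
            epsabs=1e-11,
            epsrel=1e-8,
            limit=200,
        )
        return val

    def integrand(s):
        dens = surv_free(s) * b1.value(s) * mult[1]
        return dens * residual_with(s)

    e_with, _ = integrate.quad(integrand, age0, tau, epsabs=1e-11, epsrel=1e-8, limit=200)
    return e_free, e_with, e_free + e_with


# ---------------------------------------------------------------------------
# direct simulation with a known subdistribution hazard ratio
# ---------------------------------------------------------------------------


def simulate_subdistribution(
    n: int,
    log_shr: float,
    p_event: float = 0.4,
    censor_horizon: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-cause data whose cause-1 subdistribution obeys a proportional model.

    Cause-1 cumulative incidence given binary x:
    F1(t|x) = 1 - (1 - p_event*(1 - exp(-t)))**exp(log_shr * x), the direct
    construction for which the subdistribution hazard ratio of x is exactly
    exp(log_shr).  Cause-2 times are unit exponentials; censoring is
    uniform on (0, censor_horizon).  Columns: time, event (0/1/2), x.
    """
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    ehr = np.exp(log_shr * x)
    p_cause1 = 1.0 - (1.0 - p_event) ** ehr
    is1 = rng.random(n) < p_cause1
    u = rng.random(n)
    # inverse of F1(t|x)/F1(inf|x)
    inner = 1.0 - (1.0 - u * p_cause1) ** (1.0 / ehr)
    t1 = -np.log1p(-np.clip(inner / p_event, 0.0, 1.0 - 1e-12))
    t2 = rng.exponential(size=n)
    time = np.where(is1, t1, t2)
    cause = np.where(is1, 1, 2)
    cens = rng.uniform(0, censor_horizon, size=n)
    event = np.where(time <= cens, cause, 0)
    return pd.DataFrame({"time": np.minimum(time, cens), "event": event, "x": x})


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------


def write_cohort(participants: pd.DataFrame, events: pd.DataFrame, outdir, truth=None) -> None:
    """Write participant and event tables as CSV with an explicit NA token."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants.to_csv(outdir / "participants.csv", index=False, na_rep=NA_TOKEN)
    events.to_csv(outdir / "events.csv", index=False, na_rep=NA_TOKEN)
    if truth is not None:
        truth.to_yaml(outdir / "truth.yaml")


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True)
    required = {"person_id", "sex", "enroll_age", "censor_age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participant table lacks columns {sorted(missing)}")
    return df


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True)
    required = {"person_id", "vocabulary", "code"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table lacks columns {sorted(missing)}")
    return df
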