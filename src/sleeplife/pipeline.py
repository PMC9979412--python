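"""End-to-end orchestration: phenotype, exclude, fit, integrate, report.

Everything is sex-stratified: separate transition fits, profiles and
bootstrap resampling per sex, never a sex covariate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import phenotyping, synthetic
from .covariates import DEFAULT_COVARIATES, Covariate, encode_frame, encode_profile
from .lifetime import (
    ConvergenceError,
    LifeExpectancySummary,
    aalen_johansen,
    bootstrap_ci,
    covariate_profile,
    restricted_expectancies,
    years_of_life_lost,
)
from .survival import TransitionFit, fit_cox, fit_finegray, predict_cumhaz

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ExposureSpec",
    "CATEGORY_EXPOSURE",
    "estimate_expectancies",
    "finegray_comparison",
    "hazard_ratio_table",
    "run_pipeline",
    "category_share",
]

SEXES = ("female", "male")


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure contrast: column, ordered levels, reference level."""

    column: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError("reference must be one of the levels")

    @property
    def dummy_columns(self) -> tuple[str, ...]:
        return tuple(
            f"{self.column}[{lvl}]" for lvl in self.levels if lvl != self.reference
        )

    def encode(self, values: pd.Series) -> pd.DataFrame:
        out = {}
        for lvl in self.levels:
            if lvl == self.reference:
                continue
            out[f"{self.column}[{lvl}]"] = (values == lvl).to_numpy(dtype=float)
        return pd.DataFrame(out, index=values.index)

    def profile_values(self, level: str) -> dict[str, float]:
        return {
            f"{self.column}[{lvl}]": float(lvl == level)
            for lvl in self.levels
            if lvl != self.reference
        }


CATEGORY_EXPOSURE = ExposureSpec(
    "sleep_category", ("healthy", "intermediate", "poor"), "healthy"
)


@dataclass
class RunConfig:
    """Knobs of a full pipeline run."""

    mode: str = "simulate"  # "simulate" | "files"
    participants_path: str | None = None
    events_path: str | None = None
    codelist_path: str | None = None
    n: int = 2000
    seed: int = 0
    tau: float = 81.0
    age0: float = 40.0
    landmark: float = 2.0
    lookback: float = 2.0
    bootstrap: int = 0
    timescale: str = "age"  # "age" | "followup" (switch for the multistate fits)
    covariates: tuple[str, ...] = tuple(c.name for c in DEFAULT_COVARIATES)
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not self.age0 < self.tau:
            raise ValueError("age0 must be below tau")
        if self.bootstrap < 0:
            raise ValueError("bootstrap count must be >= 0")
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.timescale not in ("age", "followup"):
            raise ValueError(f"unknown timescale {self.timescale!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def covariate_specs(self) -> tuple[Covariate, ...]:
        by_name = {c.name: c for c in DEFAULT_COVARIATES}
        return tuple(by_name[name] for name in self.covariates)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _design(
    ms: pd.DataFrame,
    exposure: ExposureSpec | None,
    covariates: Sequence[Covariate],
) -> tuple[np.ndarray, tuple[str, ...]]:
    parts = []
    if exposure is not None:
        parts.append(exposure.encode(ms[exposure.column]))
    if covariates:
        parts.append(encode_frame(ms, covariates))
    if not parts:
        return np.empty((len(ms), 0)), ()
    design = pd.concat(parts, axis=1)
    return design.to_numpy(dtype=float), tuple(design.columns)


def fit_transitions(
    ms: pd.DataFrame,
    exposure: ExposureSpec | None,
    covariates: Sequence[Covariate],
    ties: str = "efron",
    timescale: str = "age",
) -> dict[int, TransitionFit]:
    """One Cox fit per transition on a (single-sex) multistate dataset."""
    fits: dict[int, TransitionFit] = {}
    for k in (1, 2, 3):
        rows = ms[ms["transition"] == k]
        X, names = _design(rows, exposure, covariates)
        if timescale == "age":
            entry, exit_ = rows["entry"].to_numpy(), rows["exit"].to_numpy()
        else:
            # follow-up clock: time since enrollment (transition 3 stays
            # left-truncated at the CVD time), baseline age as a covariate
            if "enroll_age" not in rows.columns:
                raise KeyError("followup timescale needs enroll_age carried through")
            enroll = rows["enroll_age"].to_numpy()
            entry = rows["entry"].to_numpy() - enroll
            exit_ = rows["exit"].to_numpy() - enroll
            age_col = enroll[:, None]
            X = np.column_stack([X, age_col]) if X.size else age_col
            names = names + ("entry_age",)
        fits[k] = fit_cox(
            entry,
            exit_,
            rows["status"].to_numpy(),
            X,
            names=names,
            ties=ties,
            transition=k,
        )
        if not fits[k].converged:
            raise ConvergenceError(
                f"transition {k} fit did not converge: {fits[k].message}"
            )
    return fits


def expectancies_from_fits(
    fits: Mapping[int, TransitionFit],
    exposure: ExposureSpec,
    base_profile: Mapping[str, float],
    sex: str,
    age0: float,
    tau: float,
    timescale: str = "age",
) -> list[LifeExpectancySummary]:
    """Profile-conditional expectancies per exposure level plus YLL.

    On the follow-up clock the product integral runs over time-on-study
    (0 to tau - age0) with entry age fixed at ``age0`` in the profile.
    """
    summaries: dict[str, LifeExpectancySummary] = {}
    lo, hi = (age0, tau) if timescale == "age" else (0.0, tau - age0)
    for level in exposure.levels:
        profile = dict(base_profile) | exposure.profile_values(level)
        if timescale == "followup":
            profile["entry_age"] = age0
        cumhaz = {k: predict_cumhaz(fits[k], profile) for k in (1, 2, 3)}
        curve = aalen_johansen(cumhaz, age0=lo, tau=hi)
        e_free, e_with, e_total = restricted_expectancies(curve)
        summaries[level] = LifeExpectancySummary(
            sex=sex, exposure=level, e_free=e_free, e_with=e_with, e_total=e_total
        )
    ref = summaries[exposure.reference]
    for level, summ in summaries.items():
        if level == exposure.reference:
            continue
        summ.reference = exposure.reference
        summ.yll_free, summ.yll_total = years_of_life_lost(summ, ref)
    return [summaries[lvl] for lvl in exposure.levels]


def estimate_expectancies(
    followup: pd.DataFrame,
    exposure: ExposureSpec = CATEGORY_EXPOSURE,
    covariates: Sequence[Covariate] = (),
    age0: float = 40.0,
    tau: float = 81.0,
    ties: str = "efron",
    sexes: Sequence[str] = SEXES,
    timescale: str = "age",
) -> tuple[list[LifeExpectancySummary], dict[str, dict[int, TransitionFit]]]:
    """Sex-stratified expectancy estimates on a follow-up-resolved cohort.

    ``followup`` is the participant table after exclusions and
    :func:`sleeplife.cohort.build_followup`.  ``timescale`` selects the
    model clock: "age" (left truncation at enrollment, the default) or
    "followup" (time-on-study with entry age as a covariate).
    """
    all_summaries: list[LifeExpectancySummary] = []
    all_fits: dict[str, dict[int, TransitionFit]] = {}
    extra = [exposure.column, "enroll_age", *(c.name for c in covariates)]
    for sex in sexes:
        stratum = followup[followup["sex"] == sex]
        if len(stratum) == 0:
            raise ValueError(f"empty stratum {sex!r}")
        ms = cohort_mod.to_multistate(stratum, extra_columns=extra)
        fits = fit_transitions(ms, exposure, covariates, ties=ties, timescale=timescale)
        raw_profile = covariate_profile(stratum, covariates) if covariates else {}
        base = encode_profile(raw_profile, covariates) if covariates else {}
        all_summaries.extend(
            expectancies_from_fits(fits, exposure, base, sex, age0, tau, timescale)
        )
        all_fits[sex] = fits
    return all_summaries, all_fits


def summaries_frame(summaries: Sequence[LifeExpectancySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "sex": s.sex,
            "exposure": s.exposure,
            "e_free": s.e_free,
            "e_with": s.e_with,
            "e_total": s.e_total,
            "reference": s.reference,
            "yll_free": s.yll_free,
            "yll_total": s.yll_total,
            "n_bootstrap": s.n_bootstrap,
        }
        for quantity, (lo, hi) in s.ci.items():
            row[f"{quantity}_lo"], row[f"{quantity}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def _expectancy_closure(exposure, covariates, age0, tau, sexes):
    def closure(sample: pd.DataFrame) -> dict[str, float]:
        out: dict[str, float] = {}
        summaries, _ = estimate_expectancies(
            sample, exposure, covariates, age0=age0, tau=tau, sexes=sexes
        )
        for s in summaries:
            out[f"{s.sex}:{s.exposure}:e_free"] = s.e_free
            out[f"{s.sex}:{s.exposure}:e_total"] = s.e_total
            if s.yll_free is not None:
                out[f"{s.sex}:{s.exposure}:yll_free"] = s.yll_free
                out[f"{s.sex}:{s.exposure}:yll_total"] = s.yll_total
        return out

    return closure


def bootstrap_expectancies(
    followup: pd.DataFrame,
    summaries: Sequence[LifeExpectancySummary],
    exposure: ExposureSpec = CATEGORY_EXPOSURE,
    covariates: Sequence[Covariate] = (),
    B: int = 1000,
    seed: int = 0,
    age0: float = 40.0,
    tau: float = 81.0,
    sexes: Sequence[str] = SEXES,
) -> dict:
    """Attach percentile bootstrap CIs to expectancy summaries in place."""
    closure = _expectancy_closure(exposure, covariates, age0, tau, sexes)
    result = bootstrap_ci(closure, followup, B=B, seed=seed, strata="sex")
    for s in summaries:
        for quantity in ("e_free", "e_total", "yll_free", "yll_total"):
            key = f"{s.sex}:{s.exposure}:{quantity}"
            if key in result["ci"]:
                s.ci[quantity] = result["ci"][key]
        s.n_bootstrap = result["n_effective"]
    return result


# ---------------------------------------------------------------------------
# Fine-Gray comparability analysis
# ---------------------------------------------------------------------------


def finegray_comparison(
    followup: pd.DataFrame,
    exposure: ExposureSpec = CATEGORY_EXPOSURE,
    covariates: Sequence[Covariate] = (),
    sexes: Sequence[str] = SEXES,
) -> dict[str, object]:
    """Subdistribution-hazard fits for incident CVD, per sex.

    Runs on the follow-up clock with baseline age among the covariates;
    non-CVD death is the competing risk.
    """
    fits = {}
    for sex in sexes:
        stratum = followup[followup["sex"] == sex]
        time = (stratum["exit_age"] - stratum["enroll_age"]).to_numpy()
        cvd = stratum["cvd_status"].to_numpy(dtype=bool)
        death = stratum["death_status"].to_numpy(dtype=bool)
        event = np.where(cvd, 1, np.where(death, 2, 0))
        X, names = _design(stratum, exposure, covariates)
        X = np.column_stack([X, stratum["enroll_age"].to_numpy()]) if X.size else stratum[["enroll_age"]].to_numpy()
        names = names + ("enroll_age",)
        fits[sex] = fit_finegray(time, event, X, names=names)
    return fits


def category_share(counts: pd.DataFrame, category: str, total: int | None = None) -> float:
    """Pooled share of persons in ``category`` from per-sex count columns.

    ``counts`` is indexed by category with one column per stratum; the
    denominator defaults to the grand total of the table.
    """
    numerator = float(counts.loc[category].sum())
    denominator = float(total) if total is not None else float(counts.to_numpy().sum())
    if denominator <= 0:
        raise ValueError("non-positive denominator")
    return numerator / denominator


def hazard_ratio_table(fits: Mapping[str, object]) -> pd.DataFrame:
    """HR [95% CI] per coefficient per sex, formatted to two decimals."""
    rows = []
    for sex, fit in fits.items():
        for name, (hr, lo, hi) in fit.hr.items():
            rows.append(
                {
                    "sex": sex,
                    "term": name,
                    "hr": hr,
                    "ci_low": lo,
                    "ci_high": hi,
                    "formatted": f"{hr:.2f} [{lo:.2f}–{hi:.2f}]",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute every stage and write tables, logs and the run manifest."""
    outdir = pathlib.Path(config.outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("config")
        current = json.loads(json.dumps(dataclasses.asdict(config)))
        if previous != current:
            raise ValueError(
                f"{outdir} holds results from a different configuration; "
                "refusing to overwrite (choose another output directory)"
            )
    outdir.mkdir(parents=True, exist_ok=True)
    covs = config.covariate_specs()
    codelist = (
        phenotyping.CodeList.from_yaml(config.codelist_path)
        if config.codelist_path
        else phenotyping.DEFAULT_CODELIST
    )

    if config.mode == "simulate":
        truth = synthetic.SimulationTruth(seed=config.seed)
        participants, events = synthetic.generate_cohort(truth, config.n, codelist)
        truth.to_yaml(outdir / "truth.yaml")
    else:
        participants = synthetic.read_participants(config.participants_path)
        events = (
            synthetic.read_events(config.events_path)
            if config.events_path
            else pd.DataFrame(columns=["person_id", "age_offset", "vocabulary", "code"])
        )

    scored = phenotyping.score_frame(participants)
    scored = phenotyping.extract_disorders_frame(
        scored, events, codelist, lookback=config.lookback
    )
    kept, report = cohort_mod.apply_exclusions(scored, covs, landmark=config.landmark)
    followup = cohort_mod.build_followup(kept, tau=config.tau)
    followup.to_csv(outdir / "followup.csv", index=False, na_rep=synthetic.NA_TOKEN)
    report.to_frame().to_csv(outdir / "exclusions.csv", index=False)

    ms = cohort_mod.to_multistate(
        followup,
        extra_columns=["sleep_category", *(c.name for c in covs)],
    )
    ms.to_csv(outdir / "multistate.csv", index=False, na_rep=synthetic.NA_TOKEN)

    summaries, fits = estimate_expectancies(
        followup,
        CATEGORY_EXPOSURE,
        covs,
        age0=config.age0,
        tau=config.tau,
        timescale=config.timescale,
    )
    if config.bootstrap:
        bootstrap_expectancies(
            followup,
            summaries,
            CATEGORY_EXPOSURE,
            covs,
            B=config.bootstrap,
            seed=config.seed,
        )
    est = summaries_frame(summaries)
    est.to_csv(outdir / "estimates.csv", index=False, na_rep=synthetic.NA_TOKEN)

    fg = finegray_comparison(followup, CATEGORY_EXPOSURE, covs)
    hr_table = hazard_ratio_table(fg)
    hr_table.to_csv(outdir / "hazard_ratios.csv", index=False)

    for sex, tfits in fits.items():
        payload = {str(k): f.to_dict() for k, f in tfits.items()}
        (outdir / f"fits_{sex}.json").write_text(json.dumps(payload))

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": _versions(),
        "counts": {
            "input": report.initial,
            "analyzed": int(report.remaining[-1]),
            "incident_cvd": int(followup["cvd_status"].sum()),
            "deaths": int(followup["death_status"].sum()),
            "person_years": cohort_mod.person_years(followup),
        },
        "exclusions": report.to_frame().to_dict(orient="records"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "exclusions": report,
        "followup": followup,
        "summaries": summaries,
        "estimates": est,
        "finegray": fg,
        "hazard_ratios": hr_table,
        "manifest": manifest,
    }


def _versions() -> dict[str, str]:
    from importlib.metadata import version

    import scipy

    return {
        "sleeplife": "0.1.0",
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "click": version("click"),
        "pyyaml": version("pyyaml"),
    }
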