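"""Sleep exposure derivation.

Two routes into the analysis:

* the composite sleep score — five self-reported characteristics, each
  mapped to a healthy/unhealthy phenotype, summed to a 0-5 score and
  collapsed to poor (<=1) / intermediate (2-3) / healthy (>=4); and
* clinical sleep-disorder flags — vocabulary-aware code-list matching of
  coded clinical events and prescriptions inside a pre-enrollment
  lookback window.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "SleepProfile",
    "DisorderFlags",
    "CodeList",
    "CodedEvent",
    "UnknownVocabularyError",
    "RESPONSE_SETS",
    "HEALTHY_RESPONSES",
    "DEFAULT_CODELIST",
    "VOCABULARIES",
    "score_sleep",
    "score_frame",
    "extract_disorders",
    "extract_disorders_frame",
    "confusion_matrix",
]

VOCABULARIES = ("ICD9", "ICD10", "ReadV2", "CTV3", "BNF")
DISORDERS = ("insomnia", "srbd", "other")

#: Allowed questionnaire responses per characteristic.  Duration is an
#: integer number of hours per day rather than an enumerated set.
RESPONSE_SETS: dict[str, tuple[str, ...]] = {
    "chronotype": (
        "definitely_morning",
        "more_morning",
        "more_evening",
        "definitely_evening",
    ),
    "insomnia": ("never_rarely", "sometimes", "usually"),
    "snoring": ("no", "yes"),
    "sleepiness": ("never_rarely", "sometimes", "often", "always"),
}

#: Responses counted as the healthy phenotype.  Config-overridable: the
#: exact response-level cutoffs come from the score's source instrument.
HEALTHY_RESPONSES: dict[str, tuple[str, ...]] = {
    "chronotype": ("definitely_morning", "more_morning"),
    "insomnia": ("never_rarely",),
    "snoring": ("no",),
    "sleepiness": ("never_rarely", "sometimes"),
}

SLEEP_RESPONSE_COLUMNS = ("chronotype", "sleep_duration", "insomnia", "snoring", "sleepiness")


class UnknownVocabularyError(ValueError):
    """A coded event carries a vocabulary outside the supported set."""


@dataclass(frozen=True)
class CodedEvent:
    """One dated clinical or prescription code."""

    person_id: int
    date: object  # datetime.date or float age-offset in years from enrollment
    vocabulary: str
    code: str

    def __post_init__(self) -> None:
        if self.vocabulary not in VOCABULARIES:
            raise UnknownVocabularyError(
                f"vocabulary {self.vocabulary!r} not one of {VOCABULARIES}"
            )
        if not self.code:
            raise ValueError("empty code")


@dataclass(frozen=True)
class SleepProfile:
    """Composite sleep score for one participant.

    ``scorable`` is False when any of the five responses is missing; the
    exclusion cascade consumes that marker — missing responses are never
    imputed.
    """

    early_chronotype: bool | None
    adequate_duration: bool | None
    no_insomnia: bool | None
    no_snoring: bool | None
    no_sleepiness: bool | None
    score: int | None
    category: str  # poor | intermediate | healthy | unscorable

    @property
    def scorable(self) -> bool:
        return self.score is not None


@dataclass
class DisorderFlags:
    insomnia: bool = False
    srbd: bool = False
    other: bool = False
    evidence: dict[str, list[CodedEvent]] = field(
        default_factory=lambda: {d: [] for d in DISORDERS}
    )

    @property
    def any(self) -> bool:
        return self.insomnia or self.srbd or self.other


@dataclass(frozen=True)
class CodeEntry:
    vocabulary: str
    code: str
    match: str = "prefix"  # "prefix" | "exact"

    def matches(self, vocabulary: str, code: str) -> bool:
        if vocabulary != self.vocabulary:
            return False
        if self.match == "exact":
            return code == self.code
        return code.startswith(self.code)


class CodeList:
    """Disorder -> code-entry mapping with per-entry match mode.

    No code entry may be assigned to two disorders within the same
    vocabulary.
    """

    def __init__(self, entries: Mapping[str, Sequence[CodeEntry]]):
        seen: dict[tuple[str, str], str] = {}
        for disorder, items in entries.items():
            for entry in items:
                key = (entry.vocabulary, entry.code)
                if key in seen and seen[key] != disorder:
                    raise ValueError(
                        f"code {entry.code!r} ({entry.vocabulary}) assigned to both "
                        f"{seen[key]!r} and {disorder!r}"
                    )
                seen[key] = disorder
        self.entries: dict[str, tuple[CodeEntry, ...]] = {
            d: tuple(items) for d, items in entries.items()
        }

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def classify(self, vocabulary: str, code: str) -> str | None:
        """Disorder matched by (vocabulary, code), or None."""
        if vocabulary not in VOCABULARIES:
            raise UnknownVocabularyError(
                f"vocabulary {vocabulary!r} not one of {VOCABULARIES}"
            )
        for disorder, items in self.entries.items():
            if any(e.matches(vocabulary, code) for e in items):
                return disorder
        return None

    @classmethod
    def from_yaml(cls, path) -> "CodeList":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = {
            disorder: [
                CodeEntry(e["vocabulary"], str(e["code"]), e.get("match", "prefix"))
                for e in items
            ]
            for disorder, items in raw.items()
        }
        return cls(entries)

    def to_yaml(self, path) -> None:
        raw = {
            d: [
                {"vocabulary": e.vocabulary, "code": e.code, "match": e.match}
                for e in items
            ]
            for d, items in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


#: Illustrative default code list: one or two representative codes per
#: disorder per vocabulary.  Real deployments plug in their full lists.
DEFAULT_CODELIST = CodeList(
    {
        "insomnia": [
            CodeEntry("ICD10", "G47.0"),
            CodeEntry("ICD10", "F51.0"),
            CodeEntry("ICD9", "780.52"),
            CodeEntry("ReadV2", "Fy00."),
            CodeEntry("CTV3", "Xa0A1"),
        ],
        "srbd": [
            CodeEntry("ICD10", "G47.3"),
            CodeEntry("ICD9", "327.23"),
            CodeEntry("ReadV2", "Fy03."),
            CodeEntry("CTV3", "Xa0A3"),
        ],
        "other": [
            CodeEntry("ICD10", "G47.1"),
            CodeEntry("ICD10", "G47.2"),
            CodeEntry("ICD10", "G47.8"),
            CodeEntry("ICD9", "327.8"),
            CodeEntry("ReadV2", "Fy08."),
            CodeEntry("CTV3", "Xa0A8"),
        ],
        # BNF chapter 4 section 1 (hypnotics and anxiolytics); exact match.
        "prescription": [CodeEntry("BNF", "0401", match="exact")],
    }
)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


def score_sleep(
    chronotype,
    sleep_duration,
    insomnia,
    snoring,
    sleepiness,
    *,
    healthy_responses: Mapping[str, tuple[str, ...]] = HEALTHY_RESPONSES,
) -> SleepProfile:
    """Composite sleep score from the five questionnaire responses.

    Healthy phenotypes: morning chronotype, 7 to <9 h/day duration, no
    usual insomnia complaints, no snoring, no frequent daytime sleepiness.
    Score = count of healthy phenotypes; category poor <=1, intermediate
    2-3, healthy >=4.  Any missing response yields an unscorable profile.
    """
    responses = {
        "chronotype": chronotype,
        "insomnia": insomnia,
        "snoring": snoring,
        "sleepiness": sleepiness,
    }
    if any(_is_missing(v) for v in responses.values()) or _is_missing(sleep_duration):
        return SleepProfile(None, None, None, None, None, None, "unscorable")
    for name, value in responses.items():
        if value not in RESPONSE_SETS[name]:
            raise ValueError(f"{value!r} is not an allowed {name} response")

    traits = {
        "early_chronotype": chronotype in healthy_responses["chronotype"],
        "adequate_duration": 7 <= float(sleep_duration) < 9,
        "no_insomnia": insomnia in healthy_responses["insomnia"],
        "no_snoring": snoring in healthy_responses["snoring"],
        "no_sleepiness": sleepiness in healthy_responses["sleepiness"],
    }
    score = sum(traits.values())
    category = "poor" if score <= 1 else ("intermediate" if score <= 3 else "healthy")
    return SleepProfile(**traits, score=score, category=category)


def score_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`score_sleep` over a participant table.

    Returns a copy of ``df`` with ``sleep_score`` (nullable integer) and
    ``sleep_category`` columns appended.
    """
    for col in SLEEP_RESPONSE_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"participant table lacks column {col!r}")
    out = df.copy()
    healthy = pd.DataFrame(
        {
            "early_chronotype": df["chronotype"].isin(HEALTHY_RESPONSES["chronotype"]),
            "adequate_duration": (df["sleep_duration"] >= 7) & (df["sleep_duration"] < 9),
            "no_insomnia": df["insomnia"].isin(HEALTHY_RESPONSES["insomnia"]),
            "no_snoring": df["snoring"].isin(HEALTHY_RESPONSES["snoring"]),
            "no_sleepiness": df["sleepiness"].isin(HEALTHY_RESPONSES["sleepiness"]),
        }
    )
    missing = df[list(SLEEP_RESPONSE_COLUMNS)].isna().any(axis=1)
    score = healthy.sum(axis=1).astype("Int64")
    score[missing] = pd.NA
    category = pd.Series("intermediate", index=df.index)
    category[score <= 1] = "poor"
    category[score >= 4] = "healthy"
    category[missing] = "unscorable"
    out["sleep_score"] = score
    out["sleep_category"] = category
    return out


def _within_window(event_date, enrollment, lookback_years: float) -> bool:
    """Closed-interval membership in [enrollment - lookback, enrollment]."""
    if isinstance(event_date, (_dt.date, _dt.datetime)):
        delta = (pd.Timestamp(enrollment) - pd.Timestamp(event_date)).days / 365.25
    else:  # age offset in years relative to enrollment (negative = before)
        delta = -float(event_date)
    return 0.0 <= delta <= lookback_years


def extract_disorders(
    events: Iterable[CodedEvent],
    enrollment,
    codelist: CodeList = DEFAULT_CODELIST,
    lookback: float = 2.0,
) -> DisorderFlags:
    """Clinical sleep-disorder flags from coded events.

    An event counts iff its date lies in the closed window
    [enrollment - lookback, enrollment].  Clinical codes map to insomnia /
    sleep-related breathing disorder / other per the code list; a BNF
    hypnotic/anxiolytic prescription with no clinical sleep code in the
    window maps to "other", while one co-occurring with any clinical code
    contributes nothing extra.
    """
    if lookback <= 0:
        raise ValueError("lookback must be positive")
    if len(codelist) == 0:
        warnings.warn("empty code list: no disorder can be flagged", stacklevel=2)
    flags = DisorderFlags()
    prescriptions: list[CodedEvent] = []
    any_clinical = False
    for ev in events:
        if ev.vocabulary not in VOCABULARIES:
            raise UnknownVocabularyError(
                f"vocabulary {ev.vocabulary!r} not one of {VOCABULARIES}"
            )
        if not _within_window(ev.date, enrollment, lookback):
            continue
        disorder = codelist.classify(ev.vocabulary, ev.code)
        if disorder is None:
            continue
        if disorder == "prescription":
            prescriptions.append(ev)
            continue
        any_clinical = True
        setattr(flags, disorder, True)
        flags.evidence[disorder].append(ev)
    if prescriptions and not any_clinical:
        flags.other = True
        flags.evidence["other"].extend(prescriptions)
    return flags


def extract_disorders_frame(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    codelist: CodeList = DEFAULT_CODELIST,
    lookback: float = 2.0,
) -> pd.DataFrame:
    """Per-person disorder flags over a coded-event table.

    ``events`` has columns person_id, age_offset (years relative to
    enrollment, negative = before), vocabulary, code.  Returns
    ``participants`` with boolean columns dx_insomnia, dx_srbd, dx_other,
    dx_any appended (False for persons without any matching event).
    """
    if lookback <= 0:
        raise ValueError("lookback must be positive")
    if len(codelist) == 0:
        warnings.warn("empty code list: no disorder can be flagged", stacklevel=2)
    bad = set(events["vocabulary"]) - set(VOCABULARIES)
    if bad:
        raise UnknownVocabularyError(f"unknown vocabularies {sorted(bad)}")

    out = participants.copy()
    for d in DISORDERS:
        out[f"dx_{d}"] = False
    in_window = (events["age_offset"] >= -lookback) & (events["age_offset"] <= 0)
    windowed = events[in_window]
    clinical_ids: set = set()
    flagged: dict[str, set] = {d: set() for d in DISORDERS}
    prescription_ids: set = set()
    for _, ev in windowed.iterrows():
        disorder = codelist.classify(ev["vocabulary"], str(ev["code"]))
        if disorder is None:
            continue
        if disorder == "prescription":
            prescription_ids.add(ev["person_id"])
        else:
            clinical_ids.add(ev["person_id"])
            flagged[disorder].add(ev["person_id"])
    flagged["other"] |= prescription_ids - clinical_ids
    for d in DISORDERS:
        out[f"dx_{d}"] = out["person_id"].isin(flagged[d]).to_numpy()
    out["dx_any"] = out[[f"dx_{d}" for d in DISORDERS]].any(axis=1)
    return out


def confusion_matrix(self_flag: pd.Series, dx_flag: pd.Series) -> dict[str, float]:
    """2x2 agreement of a self-reported flag with a diagnosed flag.

    Both series must be boolean and indexed by the same person ids.
    Metrics with a zero denominator come back as NaN, never as zero.
    """
    if not self_flag.index.sort_values().equals(dx_flag.index.sort_values()):
        raise ValueError("self_flag and dx_flag are defined on different id sets")
    dx = dx_flag.reindex(self_flag.index).astype(bool)
    sf = self_flag.astype(bool)
    tp = int((sf & dx).sum())
    fp = int((sf & ~dx).sum())
    fn = int((~sf & dx).sum())
    tn = int((~sf & ~dx).sum())

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "n": tp + fp + fn + tn,
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }
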