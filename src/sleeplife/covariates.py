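"""Covariate metadata shared by the simulator, the model matrix builder and
the covariate-profile rule.

A covariate is either continuous (entered as-is), ordered categorical
(entered as its integer level code) or nominal categorical (entered as
dummy columns against the first level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Covariate",
    "DEFAULT_COVARIATES",
    "encoded_columns",
    "encode_frame",
    "encode_profile",
]


@dataclass(frozen=True)
class Covariate:
    """Description of one adjustment variable."""

    name: str
    kind: str  # "continuous" | "ordered" | "nominal"
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordered", "nominal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind != "continuous" and not self.levels:
            raise ValueError(f"categorical covariate {self.name!r} needs levels")

    def level_code(self, value: str) -> int:
        assert self.levels is not None
        try:
            return self.levels.index(value)
        except ValueError:
            raise ValueError(
                f"{value!r} is not a level of covariate {self.name!r}"
            ) from None


#: Default adjustment set: socioeconomic status, mental health, perceived
#: health, BMI class, economic activity/shift work, smoking, alcohol, diet
#: quality, discretionary screen time, physical activity.
DEFAULT_COVARIATES: tuple[Covariate, ...] = (
    Covariate("ses", "ordered", ("highest_deprivation", "second", "third", "least_deprivation")),
    Covariate("mental_health", "ordered", ("no", "yes")),
    Covariate("perceived_health", "ordered", ("excellent", "good", "fair", "poor")),
    Covariate("bmi_class", "ordered", ("lt30", "30to40", "ge40")),
    Covariate("economic_activity", "nominal", ("retired", "employed_no_shift", "night_shift", "day_shift")),
    Covariate("smoking", "ordered", ("never", "cessation", "current")),
    Covariate("alcohol", "ordered", ("never", "quit", "lt14", "14to28", "ge28")),
    Covariate("diet", "ordered", ("poor", "intermediate", "healthy")),
    Covariate("screen_time", "continuous"),
    Covariate("physical_activity", "ordered", ("none", "lt10", "10to20", "ge20")),
)


def encoded_columns(covariates: Sequence[Covariate]) -> list[str]:
    """Names of the numeric model-matrix columns for ``covariates``."""
    cols: list[str] = []
    for cov in covariates:
        if cov.kind == "nominal":
            assert cov.levels is not None
            cols.extend(f"{cov.name}__{lvl}" for lvl in cov.levels[1:])
        else:
            cols.append(cov.name)
    return cols


def encode_frame(df: pd.DataFrame, covariates: Sequence[Covariate]) -> pd.DataFrame:
    """Numeric model matrix for the covariate columns of ``df``.

    Ordered categoricals become integer level codes, nominal categoricals
    become 0/1 dummies against their first level, continuous columns pass
    through as floats.
    """
    out: dict[str, np.ndarray] = {}
    for cov in covariates:
        col = df[cov.name]
        if cov.kind == "continuous":
            out[cov.name] = col.to_numpy(dtype=float)
        elif cov.kind == "ordered":
            assert cov.levels is not None
            codes = pd.Categorical(col, categories=list(cov.levels)).codes
            if (codes < 0).any():
                bad = sorted(set(col[codes < 0].dropna()))
                raise ValueError(f"unknown levels {bad} in covariate {cov.name!r}")
            out[cov.name] = codes.astype(float)
        else:
            assert cov.levels is not None
            for lvl in cov.levels[1:]:
                out[f"{cov.name}__{lvl}"] = (col == lvl).to_numpy(dtype=float)
    return pd.DataFrame(out, index=df.index)


def encode_profile(
    profile: dict[str, object], covariates: Sequence[Covariate]
) -> dict[str, float]:
    """Encode a covariate profile (name -> raw value) onto model columns."""
    out: dict[str, float] = {}
    for cov in covariates:
        if cov.name not in profile:
            raise KeyError(f"profile is missing covariate {cov.name!r}")
        value = profile[cov.name]
        if cov.kind == "continuous":
            out[cov.name] = float(value)  # type: ignore[arg-type]
        elif cov.kind == "ordered":
            out[cov.name] = float(
                cov.level_code(value) if isinstance(value, str) else value
            )
        else:
            assert cov.levels is not None
            for lvl in cov.levels[1:]:
                out[f"{cov.name}__{lvl}"] = float(value == lvl)
    return out
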