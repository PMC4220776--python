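"""Ready-made FACT-G -> EQ-5D / SF-6D crosswalks from published coefficients.

The package ships the regression coefficients of the published mapping study
(three estimators x three predictor sets x two utility targets) as a plain
data file, so new FACT-G cohorts can be assigned utilities without refitting.
Three predictor sets exist: spec 1 uses the rescaled global score, spec 2 the
rescaled PWB/FWB/EWB domain scores, spec 3 adds tumour-site and disease-stage
dummies.  The published spec-3 rows omit the age and sex coefficients that
were part of the estimated model, so those crosswalks are flagged incomplete
and refuse to run without an explicit acknowledgement.

The recommended defaults follow the source study: CLAD coefficients for the
EQ-5D and GLM coefficients for the SF-6D.

Because the original analysis is ambiguous about whether the coefficients
were estimated on 0-100 rescaled scores or on raw scores, every prediction
call must name its ``convention`` ("rescaled" or "raw") explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .scoring import DOMAIN_MAX, DomainScores

__all__ = [
    "CrosswalkCoefficients",
    "RECOMMENDED_METHOD",
    "load_published_coefficients",
    "published_table",
    "crosswalk_predict",
]

_TARGETS = ("EQ5D", "SF6D")
_METHODS = ("OLS", "GLM", "CLAD")
_SPECS = (1, 2, 3)

#: The source study's recommendation per target instrument.
RECOMMENDED_METHOD = {"EQ5D": "CLAD", "SF6D": "GLM"}

_SPEC_TERMS = {
    1: ("FACT-G",),
    2: ("PWB", "FWB", "EWB"),
    3: ("PWB", "FWB", "EWB", "Colorectal", "Lung", "Stage-2", "Stage-3", "Stage-4"),
}

_CONVENTIONS = ("rescaled", "raw")


class IncompleteCrosswalkError(ValueError):
    """Raised when a spec-3 crosswalk is used without acknowledgement."""


@dataclass(frozen=True)
class CrosswalkCoefficients:
    """One published coefficient set, kept verbatim (strings preserved)."""

    target: str
    method: str
    spec: int
    constant: float
    coefficients: Mapping[str, float]
    raw_values: Mapping[str, str]  # term -> value exactly as printed
    stars: Mapping[str, str]
    complete: bool
    provenance: str = (
        "Published FACT-G to EQ-5D/SF-6D mapping study, development-sample "
        "regression table"
    )


def published_table() -> pd.DataFrame:
    """The full packaged coefficient table (one row per term)."""
    with resources.files("utilmap.data").joinpath(
        "published_coefficients.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"value": str}, keep_default_na=False)


def load_published_coefficients(
    target: str, method: str, spec: int
) -> CrosswalkCoefficients:
    """Load one packaged coefficient set by (target, method, spec) key.

    Spec-3 sets are incomplete — the published table omits the age and sex
    coefficients of the estimated model — and loading one emits a warning;
    predicting with one additionally requires ``allow_incomplete=True``.
    """
    target = target.upper().replace("-", "")
    method = method.upper()
    if target not in _TARGETS or method not in _METHODS or spec not in _SPECS:
        raise KeyError(
            f"unknown crosswalk key ({target!r}, {method!r}, {spec!r}); valid "
            f"keys are targets {_TARGETS}, methods {_METHODS}, specs {_SPECS}"
        )
    table = published_table()
    rows = table[
        (table.target == target) & (table.method == method) & (table.spec == spec)
    ]
    coefficients = {
        r.term: float(r.value) for r in rows.itertuples() if r.term != "Constant"
    }
    expected = set(_SPEC_TERMS[spec])
    if set(coefficients) != expected:
        raise RuntimeError(
            f"packaged table corrupt for ({target}, {method}, {spec}): terms "
            f"{sorted(coefficients)} != {sorted(expected)}"
        )
    constant = float(rows.loc[rows.term == "Constant", "value"].iloc[0])
    complete = spec != 3
    if not complete:
        warnings.warn(
            f"spec-3 crosswalk ({target}, {method}): the published table omits "
            "the estimated age and sex coefficients; predictions are based on "
            "an incomplete linear predictor",
            stacklevel=2,
        )
    return CrosswalkCoefficients(
        target=target,
        method=method,
        spec=spec,
        constant=constant,
        coefficients=coefficients,
        raw_values={r.term: r.value for r in rows.itertuples()},
        stars={r.term: r.stars for r in rows.itertuples()},
        complete=complete,
    )


def _predictor_frame(
    scores: Union[DomainScores, pd.DataFrame], convention: str
) -> pd.DataFrame:
    if isinstance(scores, DomainScores):
        scores = pd.DataFrame(
            [{
                "pwb": scores.pwb, "swb": scores.swb, "ewb": scores.ewb,
                "fwb": scores.fwb, "factg": scores.global_score,
            }]
        )
    df = scores.copy()
    if convention == "rescaled":
        mapping = {"pwb": "pwb", "ewb": "ewb", "fwb": "fwb", "factg": "global"}
        for col, key in mapping.items():
            if col in df:
                df[col] = df[col] * 100.0 / DOMAIN_MAX[key]
    return df


def crosswalk_predict(
    scores: Union[DomainScores, pd.DataFrame],
    coeffs: CrosswalkCoefficients,
    convention: str,
    allow_incomplete: bool = False,
    clamp_ceiling: float = 1.0,
) -> pd.DataFrame:
    """Predict utilities for new patients from published coefficients.

    ``scores`` is a DataFrame with raw FACT-G columns (``factg`` for spec 1;
    ``pwb``, ``fwb``, ``ewb`` for specs 2-3; plus ``site`` and ``stage`` for
    spec 3), or a single :class:`DomainScores`.  ``convention`` must be
    ``"rescaled"`` (scores divided by their maxima onto 0-100, the published
    analysis's stated scale) or ``"raw"``.

    The linear predictor follows the estimator that produced the
    coefficients: identity for OLS, ``exp`` for GLM, ceiling at 1 for CLAD;
    a final ceiling clamp at 1 applies to every method.  Rows with missing
    predictors yield NaN with a per-row flag instead of aborting.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    if not coeffs.complete and not allow_incomplete:
        raise IncompleteCrosswalkError(
            "this spec-3 crosswalk omits the unpublished age/sex coefficients; "
            "pass allow_incomplete=True to acknowledge and proceed"
        )
    df = _predictor_frame(scores, convention)
    n = len(df)
    linpred = np.full(n, coeffs.constant)
    missing = np.zeros(n, dtype=bool)

    def col(name: str) -> np.ndarray:
        if name not in df:
            raise KeyError(
                f"crosswalk requires column {name!r}; available: {list(df.columns)}"
            )
        values = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        return values

    for term, value in coeffs.coefficients.items():
        if term == "FACT-G":
            x = col("factg")
        elif term in ("PWB", "FWB", "EWB"):
            x = col(term.lower())
        elif term in ("Colorectal", "Lung"):
            if "site" not in df:
                raise KeyError("spec-3 crosswalk requires a 'site' column")
            x = (df["site"].astype(str).str.lower() == term.lower()).to_numpy(float)
        elif term.startswith("Stage-"):
            if "stage" not in df:
                raise KeyError("spec-3 crosswalk requires a 'stage' column")
            level = int(term.split("-")[1])
            stage = pd.to_numeric(df["stage"], errors="coerce").to_numpy(float)
            missing |= np.isnan(stage)
            x = (stage == level).astype(float)
        else:  # pragma: no cover - guarded by loader invariants
            raise KeyError(f"unknown coefficient term {term!r}")
        missing |= np.isnan(x)
        x = np.where(np.isnan(x), 0.0, x)
        linpred = linpred + value * x

    if coeffs.method == "GLM":
        utility = np.exp(linpred)
    elif coeffs.method == "CLAD":
        utility = np.minimum(linpred, 1.0)
    else:
        utility = linpred
    utility = np.minimum(utility, clamp_ceiling)
    utility[missing] = np.nan
    return pd.DataFrame({"utility": utility, "missing_predictor": missing},
                        index=df.index)
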