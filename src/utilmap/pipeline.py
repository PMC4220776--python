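"""Study orchestration: design matrices, sample splitting, and the full
method x model x target comparison.

Three nested predictor sets are used to map FACT-G scores onto each utility
index:

* **Model 1** — rescaled FACT-G global score;
* **Model 2** — rescaled PWB, FWB and EWB domain scores (SWB is never
  included: its association with either utility is negligible);
* **Model 3** — Model 2 plus age, sex (female = 1), tumour-site dummies
  (colorectal, lung; breast reference) and stage dummies (2-4; stage 1
  reference).  Optional interaction terms (PWB x FWB, PWB x EWB, age squared,
  age x sex) are available but off by default.

The cohort is split once into development and validation halves; every
estimator (OLS, GLM, CLAD) is fitted on the development half of every model
and target, and validated on the held-out half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import (
    CladConfig,
    FittedModel,
    RegressionData,
    fit_clad,
    fit_glm_log,
    fit_ols,
    predict_utility,
)
from .metrics import PredictionPairs, ValidationReport, validate_predictions
from .scoring import DOMAIN_MAX

__all__ = [
    "ModelSpec",
    "SplitAssignment",
    "StudyResult",
    "build_design",
    "split_sample",
    "compare_samples",
    "run_mapping_study",
    "significance_stars",
]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Three-symbol significance scheme: * p<0.05, ** p<0.01, *** p<0.001."""
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass(frozen=True)
class ModelSpec:
    """One of the three published predictor sets for one target utility."""

    target: str  # "eq5d" | "sf6d"
    spec_id: int  # 1 | 2 | 3
    include_interactions: bool = False

    def __post_init__(self) -> None:
        if self.target not in ("eq5d", "sf6d"):
            raise ValueError("target must be 'eq5d' or 'sf6d'")
        if self.spec_id not in (1, 2, 3):
            raise ValueError("spec_id must be 1, 2 or 3")
        if self.include_interactions and self.spec_id != 3:
            raise ValueError("interaction terms only apply to Model 3")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.spec_id == 1:
            cols: list[str] = ["Constant", "FACT-G"]
        else:
            cols = ["Constant", "PWB", "FWB", "EWB"]
        if self.spec_id == 3:
            cols += ["Age", "Female", "Colorectal", "Lung",
                     "Stage-2", "Stage-3", "Stage-4"]
            if self.include_interactions:
                cols += ["PWBxFWB", "PWBxEWB", "Age2", "AgexFemale"]
        return tuple(cols)


_REQUIRED_COLUMNS = {
    1: ("factg",),
    2: ("pwb", "fwb", "ewb"),
    3: ("pwb", "fwb", "ewb", "age", "sex", "site", "stage"),
}


def build_design(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    convention: str = "rescaled",
) -> tuple[RegressionData, dict]:
    """Design matrix for one model spec with listwise deletion.

    Returns the regression data (constant column first) and an info dict with
    the listwise-deletion count — the reason the effective N shrinks for
    Model 3, where stage is often missing in registry data.
    """
    if convention not in ("rescaled", "raw"):
        raise ValueError("convention must be 'rescaled' or 'raw'")
    required = _REQUIRED_COLUMNS[spec.spec_id] + (spec.target,)
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks required columns: {missing_cols}")
    work = cohort.loc[:, list(required)].copy()
    for col in work.columns:
        if col not in ("sex", "site"):
            work[col] = pd.to_numeric(work[col], errors="coerce")
    complete = work.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    work = work[complete]
    if work.empty:
        raise ValueError("no complete rows after listwise deletion")

    def rescale(col: str, key: str) -> np.ndarray:
        values = work[col].to_numpy(dtype=float)
        if convention == "rescaled":
            values = values * 100.0 / DOMAIN_MAX[key]
        return values

    columns: dict[str, np.ndarray] = {"Constant": np.ones(len(work))}
    if spec.spec_id == 1:
        columns["FACT-G"] = rescale("factg", "global")
    else:
        columns["PWB"] = rescale("pwb", "pwb")
        columns["FWB"] = rescale("fwb", "fwb")
        columns["EWB"] = rescale("ewb", "ewb")
    if spec.spec_id == 3:
        age = work["age"].to_numpy(dtype=float)
        female = (work["sex"].astype(str).str.lower() == "female").to_numpy(float)
        site = work["site"].astype(str).str.lower()
        stage = work["stage"].to_numpy(dtype=float)
        columns["Age"] = age
        columns["Female"] = female
        columns["Colorectal"] = (site == "colorectal").to_numpy(float)
        columns["Lung"] = (site == "lung").to_numpy(float)
        for level in (2, 3, 4):
            dummy = (stage == level).astype(float)
            if dummy.sum() == 0:
                import warnings

                warnings.warn(f"stage-{level} dummy has zero rows", stacklevel=2)
            columns[f"Stage-{level}"] = dummy
        if spec.include_interactions:
            columns["PWBxFWB"] = columns["PWB"] * columns["FWB"]
            columns["PWBxEWB"] = columns["PWB"] * columns["EWB"]
            columns["Age2"] = age**2
            columns["AgexFemale"] = age * female
    X = np.column_stack([columns[label] for label in spec.labels])
    ids = (
        work.index.to_numpy()
        if "patient_id" not in cohort.columns
        else cohort.loc[work.index, "patient_id"].to_numpy()
    )
    data = RegressionData(
        y=work[spec.target].to_numpy(dtype=float),
        X=X,
        labels=spec.labels,
        ids=ids,
    )
    info = {"n_dropped": n_dropped, "n_used": data.n,
            "used_index": work.index,
            "dropped_index": cohort.index[~complete]}
    return data, info


@dataclass(frozen=True)
class SplitAssignment:
    """Development/validation partition, reproducible from its seed."""

    labels: np.ndarray  # "development" | "validation" per row
    seed: Optional[int]
    proportion: float

    @property
    def development(self) -> np.ndarray:
        return np.asarray(self.labels) == "development"

    @property
    def validation(self) -> np.ndarray:
        return np.asarray(self.labels) == "validation"


def split_sample(
    n: int, proportion: float = 0.5, seed: Optional[int] = None
) -> SplitAssignment:
    """Simple random split into development (ceil(n*p)) and validation rows."""
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_dev = math.ceil(n * proportion)
    labels = np.full(n, "validation", dtype=object)
    labels[perm[:n_dev]] = "development"
    return SplitAssignment(labels=labels, seed=seed, proportion=proportion)


def compare_samples(
    cohort: pd.DataFrame,
    split: SplitAssignment,
    continuous: Sequence[str] = ("age", "factg", "eq5d", "sf6d"),
    categorical: Sequence[str] = ("sex", "site", "stage", "ecog"),
) -> pd.DataFrame:
    """Balance tests between the halves: Welch t (continuous), Pearson
    chi-square (categorical).  Categories empty in both halves are dropped
    with a warning."""
    import warnings

    if len(split.labels) != len(cohort):
        raise ValueError("split does not cover the cohort")
    dev = cohort[split.development]
    val = cohort[split.validation]
    rows = []
    for var in continuous:
        if var not in cohort:
            continue
        a = pd.to_numeric(dev[var], errors="coerce").dropna()
        b = pd.to_numeric(val[var], errors="coerce").dropna()
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": var, "test": "welch_t", "statistic": float(stat),
                     "df": np.nan, "p": float(p)})
    for var in categorical:
        if var not in cohort:
            continue
        table = pd.crosstab(cohort[var], split.labels)
        empty = table.sum(axis=1) == 0
        if empty.any():
            warnings.warn(
                f"{var}: categories {list(table.index[empty])} empty in both "
                "halves; dropped",
                stacklevel=2,
            )
            table = table[~empty]
        stat, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"variable": var, "test": "chi2", "statistic": float(stat),
                     "df": float(df), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Output of one full mapping study run."""

    comparison: pd.DataFrame
    reports: dict[tuple[str, str, int], ValidationReport]
    models: dict[tuple[str, str, int], FittedModel]
    split: SplitAssignment
    balance: pd.DataFrame
    failures: dict[tuple[str, str, int], str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _fit_one(
    method: str, data: RegressionData, clad_config: CladConfig
) -> FittedModel:
    if method == "OLS":
        return fit_ols(data)
    if method == "GLM":
        return fit_glm_log(data)
    if method == "CLAD":
        return fit_clad(data, clad_config)
    raise ValueError(f"unknown method {method!r}")


def run_mapping_study(
    cohort: pd.DataFrame,
    methods: Sequence[str] = ("OLS", "GLM", "CLAD"),
    spec_ids: Sequence[int] = (1, 2, 3),
    targets: Sequence[str] = ("eq5d", "sf6d"),
    proportion: float = 0.5,
    seed: Optional[int] = None,
    convention: str = "rescaled",
    clad_config: Optional[CladConfig] = None,
) -> StudyResult:
    """Fit every method x model x target combination and validate each.

    The cohort is split once (seeded); each combination is fitted on the
    development half (listwise deletion within the half) and evaluated on the
    validation half.  Individual fit failures are recorded per cell without
    aborting the rest; only a completely failed run raises.

    The comparison table has one row per combination: coefficients with
    significance stars from robust (OLS), model-based (GLM) or bootstrap
    (CLAD) standard errors, the constant, adjusted R-squared (OLS),
    log-likelihood (OLS/GLM), development and validation RMSE/MAE, and N.
    """
    ss = np.random.SeedSequence(seed)
    split_seed, clad_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if clad_config is None:
        clad_config = CladConfig(bootstrap_reps=200, seed=clad_seed)
    elif clad_config.seed is None:
        clad_config = CladConfig(
            ceiling=clad_config.ceiling, max_iter=clad_config.max_iter,
            tol=clad_config.tol, bootstrap_reps=clad_config.bootstrap_reps,
            seed=clad_seed,
        )
    split = split_sample(len(cohort), proportion, seed=split_seed)
    balance = compare_samples(cohort, split)
    dev = cohort[split.development].reset_index(drop=True)
    val = cohort[split.validation].reset_index(drop=True)

    rows = []
    reports: dict[tuple[str, str, int], ValidationReport] = {}
    models: dict[tuple[str, str, int], FittedModel] = {}
    failures: dict[tuple[str, str, int], str] = {}
    log: list[str] = [f"split seed {split_seed}: {int(split.development.sum())} "
                      f"development / {int(split.validation.sum())} validation"]
    for target in targets:
        for spec_id in spec_ids:
            spec = ModelSpec(target=target, spec_id=spec_id)
            for method in methods:
                key = (target, method, spec_id)
                try:
                    data, info = build_design(dev, spec, convention)
                    log.append(
                        f"{key}: {info['n_used']} rows used, "
                        f"{info['n_dropped']} dropped listwise"
                    )
                    model = _fit_one(method, data, clad_config)
                    vdata, vinfo = build_design(val, spec, convention)
                    vpred = predict_utility(model, vdata.X)
                except Exception as err:  # record, keep going
                    failures[key] = f"{type(err).__name__}: {err}"
                    continue
                pairs_kwargs = {}
                vrows = val.loc[vinfo["used_index"]]
                for name in ("stage", "ecog"):
                    if name in vrows:
                        labels_ = pd.to_numeric(vrows[name],
                                                errors="coerce").to_numpy()
                        if not np.isnan(labels_).any():
                            pairs_kwargs[name] = labels_.astype(int)
                pairs = PredictionPairs(
                    observed=vdata.y, predicted=vpred, **pairs_kwargs
                )
                report = validate_predictions(pairs, n_predictors=data.k - 1)
                reports[key] = report
                models[key] = model
                row: dict[str, object] = {
                    "target": target, "method": method, "spec": spec_id,
                }
                pvals = model.pvalues
                for i, label in enumerate(model.labels):
                    coef = model.params[i]
                    stars = significance_stars(float(pvals[i])) if np.isfinite(
                        pvals[i]
                    ) else ""
                    row[label] = coef
                    row[f"{label}_stars"] = stars
                row.update(
                    adj_r2=model.stats.get("adj_r2"),
                    ll=model.stats.get("ll"),
                    rmse_dev=model.stats["rmse"],
                    mae_dev=model.stats["mae"],
                    rmse_val=report.rmse,
                    mae_val=report.mae,
                    n=model.stats["n"],
                )
                rows.append(row)
    if not rows:
        raise RuntimeError(f"every fit failed: {failures}")
    comparison = pd.DataFrame(rows)
    return StudyResult(
        comparison=comparison,
        reports=reports,
        models=models,
        split=split,
        balance=balance,
        failures=failures,
        log=log,
    )
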