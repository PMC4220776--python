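"""Prediction-accuracy metrics for observed-vs-predicted utility comparisons.

MAE/RMSE, adjusted R-squared, Spearman rank correlation, the Wilcoxon
matched-pairs signed-rank test (exact null distribution for small samples,
tie-corrected normal approximation otherwise), percentile summaries and
subgroup (stage / ECOG) summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PredictionPairs",
    "ValidationReport",
    "prediction_errors",
    "adjusted_r2",
    "wilcoxon_signed_rank",
    "spearman",
    "percentile_summary",
    "subgroup_summary",
    "validate_predictions",
]

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class PredictionPairs:
    """Aligned observed/predicted utilities with optional severity labels."""

    observed: np.ndarray
    predicted: np.ndarray
    stage: Optional[np.ndarray] = None  # 1..4
    ecog: Optional[np.ndarray] = None   # 0..3

    def __post_init__(self) -> None:
        o = np.asarray(self.observed, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if o.shape != p.shape or o.ndim != 1:
            raise ValueError("observed and predicted must be aligned 1-D vectors")
        object.__setattr__(self, "observed", o)
        object.__setattr__(self, "predicted", p)
        for name, values, lo, hi in (("stage", self.stage, 1, 4),
                                     ("ecog", self.ecog, 0, 3)):
            if values is None:
                continue
            v = np.asarray(values)
            if v.shape != o.shape:
                raise ValueError(f"{name} labels must align with the pairs")
            if not np.isin(v, np.arange(lo, hi + 1)).all():
                raise ValueError(f"{name} labels must lie in {lo}..{hi}")
            object.__setattr__(self, name, v)


def prediction_errors(observed, predicted) -> dict[str, float]:
    """Mean absolute error and root mean squared error of predictions."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size == 0:
        raise ValueError("no prediction pairs")
    e = o - p
    return {
        "mae": float(np.mean(np.abs(e))),
        "rmse": float(np.sqrt(np.mean(e**2))),
    }


def adjusted_r2(observed, fitted, n_predictors: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - k - 1) with k slope predictors."""
    o = np.asarray(observed, dtype=float)
    f = np.asarray(fitted, dtype=float)
    n = o.size
    if n <= n_predictors + 1:
        raise ValueError("need n > n_predictors + 1 observations")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance")
    r2 = 1.0 - float(np.sum((o - f) ** 2)) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = sps.rankdata(np.abs(d), method="average")
    return ranks, d > 0


def _exact_wilcoxon_cdf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) by dynamic programming over sign patterns.

    Average ranks may be half-integers, so ranks are doubled to integers and
    the distribution of 2*W+ is convolved exactly; each of the 2^n sign
    patterns is equiprobable under the null.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2.0 * w))
    cdf = float(pmf[: w2 + 1].sum())
    sf = float(pmf[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(
    observed,
    predicted,
    zero_method: str = "wilcox",
    mode: str = "auto",
) -> dict[str, float]:
    """Wilcoxon matched-pairs signed-rank test of observed vs predicted.

    Differences of exactly zero are dropped (Wilcoxon's convention; the Pratt
    variant, which ranks zeros before discarding them, is selectable); tied
    absolute differences receive average ranks.  The statistic reported is
    ``W+``, the sum of ranks of positive differences.  For 25 or fewer
    nonzero pairs the two-sided p-value comes from the exact null
    distribution (all sign patterns enumerated by convolution); beyond that a
    tie-corrected normal approximation with continuity correction is used.
    When every difference is zero the result is ``p = 1`` with
    ``all_zero = True``.
    """
    d = np.asarray(observed, dtype=float) - np.asarray(predicted, dtype=float)
    if d.size == 0:
        raise ValueError("no pairs")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    nonzero = d != 0
    if not nonzero.any():
        return {"statistic": 0.0, "p": 1.0, "n_used": 0, "all_zero": True}

    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks, positive = _signed_ranks(d_used)
    else:  # pratt: rank |d| including zeros, then drop the zeros' ranks
        ranks_all = sps.rankdata(np.abs(d), method="average")
        ranks = ranks_all[nonzero]
        positive = d[nonzero] > 0
    n = int(nonzero.sum())
    w_plus = float(ranks[positive].sum())

    use_exact = (mode == "exact") or (
        mode == "auto" and n <= _EXACT_WILCOXON_MAX_N and zero_method == "wilcox"
    )
    if use_exact:
        cdf, sf = _exact_wilcoxon_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        if zero_method == "pratt":
            # Pratt correction: zeros occupy the lowest ranks.
            n_zero = int(d.size - n)
            mean = (d.size * (d.size + 1) - n_zero * (n_zero + 1)) / 4.0
            var = (
                d.size * (d.size + 1) * (2 * d.size + 1)
                - n_zero * (n_zero + 1) * (2 * n_zero + 1)
            ) / 24.0
        else:
            mean = n * (n + 1) / 4.0
            var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
        if var <= 0:
            return {"statistic": w_plus, "p": 1.0, "n_used": n, "all_zero": False}
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    return {
        "statistic": w_plus,
        "p": float(min(p, 1.0)),
        "n_used": n,
        "all_zero": False,
        "method": method,
    }


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def percentile_summary(values) -> dict[str, float]:
    """Mean, SD, min, 10th/50th/90th percentiles and max of one source.

    Percentiles use linear interpolation between closest ranks (the
    ``numpy`` 'linear' convention).  Fewer than 10 values triggers a warning
    — the tail percentiles are then barely meaningful.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no values to summarise")
    if arr.size < 10:
        warnings.warn(
            f"percentile summary of only {arr.size} values; 10th/90th "
            "percentiles are unstable",
            stacklevel=2,
        )
    p10, p50, p90 = np.percentile(arr, [10, 50, 90], method="linear")
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "p10": float(p10),
        "p50": float(p50),
        "p90": float(p90),
        "max": float(arr.max()),
    }


def subgroup_summary(pairs: PredictionPairs) -> pd.DataFrame:
    """Mean observed vs mean predicted utility by cancer stage and ECOG.

    One row per (grouping, level): n, mean observed, mean predicted, mean
    error (observed - predicted).  Groups with no members are omitted;
    single-member groups are flagged degenerate.
    """
    frames = []
    for name, labels in (("stage", pairs.stage), ("ecog", pairs.ecog)):
        if labels is None:
            continue
        df = pd.DataFrame(
            {"group": labels, "observed": pairs.observed,
             "predicted": pairs.predicted}
        )
        g = df.groupby("group", sort=True).agg(
            n=("observed", "size"),
            mean_observed=("observed", "mean"),
            mean_predicted=("predicted", "mean"),
        )
        g["mean_error"] = g["mean_observed"] - g["mean_predicted"]
        g["degenerate"] = g["n"] < 2
        g = g.reset_index()
        g.insert(0, "grouping", name)
        frames.append(g)
    if not frames:
        return pd.DataFrame(
            columns=["grouping", "group", "n", "mean_observed",
                     "mean_predicted", "mean_error", "degenerate"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class ValidationReport:
    """Accuracy battery for one model's predictions on held-out patients."""

    mae: float
    rmse: float
    adj_r2: Optional[float]
    spearman_rho: float
    wilcoxon: dict
    observed_summary: dict
    predicted_summary: dict
    subgroups: pd.DataFrame = field(default_factory=pd.DataFrame)
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row summary (subgroup table serialised separately)."""
        row = {
            "n": self.n,
            "mae": self.mae,
            "rmse": self.rmse,
            "adj_r2": self.adj_r2,
            "spearman_rho": self.spearman_rho,
            "wilcoxon_statistic": self.wilcoxon["statistic"],
            "wilcoxon_p": self.wilcoxon["p"],
        }
        for src, summ in (("observed", self.observed_summary),
                          ("predicted", self.predicted_summary)):
            for key, val in summ.items():
                row[f"{src}_{key}"] = val
        return pd.DataFrame([row])


def validate_predictions(
    pairs: PredictionPairs, n_predictors: Optional[int] = None
) -> ValidationReport:
    """Run the full accuracy battery on one set of prediction pairs."""
    errors = prediction_errors(pairs.observed, pairs.predicted)
    adj = None
    if n_predictors is not None and pairs.observed.size > n_predictors + 1:
        try:
            adj = adjusted_r2(pairs.observed, pairs.predicted, n_predictors)
        except ValueError:
            adj = None
    try:
        rho = spearman(pairs.observed, pairs.predicted)
    except ValueError:
        rho = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs_summary = percentile_summary(pairs.observed)
        pred_summary = percentile_summary(pairs.predicted)
    return ValidationReport(
        mae=errors["mae"],
        rmse=errors["rmse"],
        adj_r2=adj,
        spearman_rho=rho,
        wilcoxon=wilcoxon_signed_rank(pairs.observed, pairs.predicted),
        observed_summary=obs_summary,
        predicted_summary=pred_summary,
        subgroups=subgroup_summary(pairs),
        n=int(pairs.observed.size),
    )
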