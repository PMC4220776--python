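"""Regression estimators for utility mapping: OLS, log-link GLM, LAD and CLAD.

Utility indices are bounded above at 1 (full health) and frequently pile up
there; ordinary least squares is then inconsistent for the latent
relationship.  Three estimators are provided:

* :func:`fit_ols` — least squares with heteroscedasticity-robust (HC1 by
  default) standard errors;
* :func:`fit_glm_log` — log-link GLM (Gaussian or Gamma family) so the
  conditional mean is ``exp(x'b)``;
* :func:`fit_clad` — censored least absolute deviations, the median-regression
  analogue of the Tobit: it minimises ``sum |y_i - min(x_i'b, c)|`` for a
  known ceiling ``c`` and stays consistent under heteroscedasticity,
  non-normality and ceiling censoring.  It is solved by the iterative
  linear-programming algorithm: fit LAD on the full sample, drop observations
  whose prediction reaches the ceiling, refit on the retained set, and repeat
  until the retained set stabilises; inference is by nonparametric case
  bootstrap.

LAD subproblems are solved exactly as a linear program (HiGHS).  With an even
split of residual signs the LAD argmin can be a segment; the LP's
deterministic pivoting under a fixed row order picks one canonical vertex, so
the *objective* (not the argmin) is the reproducible contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import linprog

__all__ = [
    "RegressionData",
    "FittedModel",
    "CladConfig",
    "BootstrapResult",
    "ConvergenceError",
    "fit_ols",
    "fit_glm_log",
    "fit_lad",
    "fit_clad",
    "bootstrap_vcov",
    "predict_utility",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge; carries its trace."""

    def __init__(self, message: str, trace: Optional[list] = None) -> None:
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class RegressionData:
    """Response vector and design matrix (leading constant column).

    Rows with missing cells must be removed upstream (listwise deletion);
    construction fails on NaN.
    """

    y: np.ndarray
    X: np.ndarray
    labels: tuple[str, ...]
    ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("y must be 1-D and X 2-D with matching rows")
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("missing cells in regression data; delete listwise first")
        if X.shape[0] < X.shape[1]:
            raise ValueError(f"fewer rows ({X.shape[0]}) than columns ({X.shape[1]})")
        if len(self.labels) != X.shape[1]:
            raise ValueError("label count must match design columns")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def subset(self, index: np.ndarray) -> "RegressionData":
        ids = self.ids[index] if self.ids is not None else None
        return RegressionData(self.y[index], self.X[index], self.labels, ids)


def _check_full_rank(data: RegressionData) -> None:
    """Raise naming (nearly) collinear columns when the design is rank deficient."""
    X = data.X
    rank = np.linalg.matrix_rank(X)
    if rank < data.k:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [data.labels[i] for i in np.where(diag <= tol)[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {data.k}); "
            f"collinear columns: {bad or 'undetermined'}"
        )


@dataclass
class BootstrapResult:
    vcov: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_reps: int
    n_failed: int
    draws: Optional[np.ndarray] = None


@dataclass
class FittedModel:
    """Output of one estimator: coefficients, vcov and fit statistics.

    ``stats`` always carries in-sample ``rmse``, ``mae`` and ``n``; OLS adds
    ``r2``/``adj_r2``; OLS and GLM add the log-likelihood ``ll``; CLAD adds
    ``objective``, ``n_iter`` and ``n_retained``.
    """

    method: str
    labels: tuple[str, ...]
    params: np.ndarray
    vcov: Optional[np.ndarray]
    stats: dict
    link: Optional[str] = None
    ceiling: Optional[float] = None
    bootstrap: Optional[BootstrapResult] = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if len(self.labels) != self.params.size:
            raise ValueError("coefficient count must match labels")
        if self.vcov is not None:
            self.vcov = np.asarray(self.vcov, dtype=float)
            if self.vcov.shape != (self.params.size, self.params.size):
                raise ValueError("vcov dimension must match coefficients")

    @property
    def se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.params.size, np.nan)
        return np.sqrt(np.diag(self.vcov))

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.se
        return 2.0 * norm.sf(np.abs(z))

    def predict(
        self, X: np.ndarray, clamp: Optional[tuple[float, float]] = None
    ) -> np.ndarray:
        return predict_utility(self, X, clamp=clamp)

    # -- serialization (reload and predict bit-identically) ------------------
    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "labels": list(self.labels),
            "params": self.params.tolist(),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "stats": {k: v for k, v in self.stats.items()},
            "link": self.link,
            "ceiling": self.ceiling,
            "config": self.config,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            method=d["method"],
            labels=tuple(d["labels"]),
            params=np.asarray(d["params"], dtype=float),
            vcov=None if d["vcov"] is None else np.asarray(d["vcov"], dtype=float),
            stats=d["stats"],
            link=d.get("link"),
            ceiling=d.get("ceiling"),
            config=d.get("config", {}),
        )


def _error_stats(y: np.ndarray, fitted: np.ndarray) -> dict:
    e = y - fitted
    return {
        "rmse": float(np.sqrt(np.mean(e**2))),
        "mae": float(np.mean(np.abs(e))),
        "n": int(y.size),
    }


def fit_ols(data: RegressionData, cov_type: str = "HC1") -> FittedModel:
    """Least squares with a heteroscedasticity-robust sandwich vcov.

    HC1 (the small-sample degrees-of-freedom corrected sandwich, the default
    "robust" of most econometric software) is the default; HC0/HC2/HC3 are
    selectable.
    """
    _check_full_rank(data)
    if data.n == data.k:
        cov_type = "HC0"  # saturated exact fit; HC1's n/(n-k) is undefined
    res = sm.OLS(data.y, data.X).fit(cov_type=cov_type)
    stats = _error_stats(data.y, res.fittedvalues)
    stats.update(
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        ll=float(res.llf),
    )
    return FittedModel(
        method="OLS",
        labels=data.labels,
        params=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        stats=stats,
        config={"cov_type": cov_type},
    )


def fit_glm_log(
    data: RegressionData,
    family: str = "gaussian",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> FittedModel:
    """Log-link GLM so that the fitted mean is ``exp(x'b)``.

    The Gaussian family (default) keeps the additive-error assumption while
    letting the mean be multiplicative in the predictors — consistent with a
    negative constant plus positive slopes for a response bounded near 1.
    The Gamma family (strictly positive responses) is selectable.
    """
    _check_full_rank(data)
    if family == "gaussian":
        fam = sm.families.Gaussian(sm.families.links.Log())
    elif family == "gamma":
        if np.any(data.y <= 0):
            raise ValueError("gamma family requires strictly positive responses")
        fam = sm.families.Gamma(sm.families.links.Log())
    else:
        raise ValueError(f"unknown family {family!r}; use 'gaussian' or 'gamma'")
    # OLS on log(y) gives well-behaved IRLS starting values for bounded utilities.
    y_floor = np.clip(data.y, 1e-3, None)
    start = np.linalg.lstsq(data.X, np.log(y_floor), rcond=None)[0]
    model = sm.GLM(data.y, data.X, family=fam)
    res = model.fit(start_params=start, maxiter=maxiter, tol=tol, scale="x2")
    if not res.converged:
        raise ConvergenceError(
            f"log-link GLM ({family}) did not converge in {maxiter} iterations",
            trace=list(getattr(res, "fit_history", {}).get("deviance", [])),
        )
    fitted = np.asarray(res.fittedvalues)
    stats = _error_stats(data.y, fitted)
    stats["ll"] = float(res.llf)
    stats["deviance"] = float(res.deviance)
    return FittedModel(
        method="GLM",
        labels=data.labels,
        params=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        stats=stats,
        link="log",
        config={"family": family, "maxiter": maxiter, "tol": tol},
    )


def fit_lad(data: RegressionData, tol: float = 1e-8) -> np.ndarray:
    """Median (least absolute deviations) regression via an exact LP.

    Minimises ``sum |y - Xb|`` with free coefficients and split residuals
    ``u+ - u-``; HiGHS under a fixed row order yields a deterministic vertex
    when the argmin is not unique.
    """
    from scipy import sparse

    _check_full_rank(data)
    n, k = data.n, data.k
    c = np.concatenate([np.zeros(k), np.ones(2 * n)])
    A_eq = sparse.hstack(
        [sparse.csr_matrix(data.X), sparse.eye(n), -sparse.eye(n)],
        format="csr",
    )
    bounds = [(None, None)] * k + [(0, None)] * (2 * n)
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=data.y,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": tol,
                 "dual_feasibility_tolerance": tol},
    )
    if res.status != 0:
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    return np.asarray(res.x[:k], dtype=float)


@dataclass(frozen=True)
class CladConfig:
    """Settings for the CLAD iterative-trimming fit and its bootstrap."""

    ceiling: float = 1.0
    max_iter: int = 50
    tol: float = 1e-8
    bootstrap_reps: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.ceiling):
            raise ValueError("ceiling must be finite")
        if self.bootstrap_reps and self.bootstrap_reps < 2:
            raise ValueError("bootstrap needs at least 2 replicates")


def _clad_objective(data: RegressionData, beta: np.ndarray, c: float) -> float:
    pred = np.minimum(data.X @ beta, c)
    return float(np.sum(np.abs(data.y - pred)))


#: Exact vertex enumeration is used instead of iterative trimming when the
#: problem is this small (and has at most two coefficients).
_CLAD_EXACT_MAX_N = 40


def _clad_exact_small(
    data: RegressionData, c: float
) -> Optional[tuple[np.ndarray, float]]:
    """Global CLAD minimiser for k <= 2 by enumerating arrangement vertices.

    ``S(b) = sum |y_i - min(x_i'b, c)|`` is piecewise linear; its minimum is
    attained where k hyperplanes from {y_i = x_i'b} and {x_i'b = c}
    intersect, so enumerating all such intersections is an exact solve.
    """
    n, k = data.n, data.k
    if k > 2 or n > _CLAD_EXACT_MAX_N:
        return None
    X, y = data.X, data.y
    candidates: list[np.ndarray] = []
    if k == 1:
        x = X[:, 0]
        ok = x != 0
        for rhs in (y[ok], np.full(ok.sum(), c)):
            candidates.extend(np.atleast_2d(rhs / x[ok]).T)
    else:
        rhs_choices = (y, np.full(n, c))
        for i in range(n - 1):
            for j in range(i + 1, n):
                A = X[[i, j]]
                det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
                if abs(det) < 1e-12:
                    continue
                inv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
                for bi in (rhs_choices[0][i], rhs_choices[1][i]):
                    for bj in (rhs_choices[0][j], rhs_choices[1][j]):
                        candidates.append(inv @ np.array([bi, bj]))
    if not candidates:
        return None
    B = np.vstack(candidates)  # m x k
    preds = np.minimum(X @ B.T, c)  # n x m
    objectives = np.abs(y[:, None] - preds).sum(axis=0)
    best = int(np.argmin(objectives))
    return B[best], float(objectives[best])


def _clad_point(data: RegressionData, config: CladConfig) -> tuple[np.ndarray, dict]:
    """One CLAD fit by iterative trimming; returns (beta, diagnostics)."""
    c = config.ceiling
    if np.any(data.y > c + 1e-9):
        raise ValueError("responses above the ceiling; check the censoring value")
    exact = _clad_exact_small(data, c)
    if exact is not None:
        beta, obj = exact
        pred = data.X @ beta
        if not (pred < c).any():
            raise RuntimeError("all predictions at the ceiling; CLAD undefined")
        if int((pred < c).sum()) < data.k:
            raise RuntimeError(
                "retained set smaller than the number of coefficients; "
                "censoring too severe for CLAD"
            )
        return beta, {
            "objective": obj,
            "n_iter": 1,
            "n_retained": int((pred < c).sum()),
            "oscillated": False,
            "solver": "exact",
        }
    keep = np.ones(data.n, dtype=bool)
    seen: list[bytes] = []
    best_beta: Optional[np.ndarray] = None
    best_obj = np.inf
    best_keep = int(data.n)
    n_iter = 0
    oscillated = False
    for n_iter in range(1, config.max_iter + 1):
        if keep.sum() < data.k:
            raise RuntimeError(
                f"retained set ({int(keep.sum())}) smaller than the number of "
                f"coefficients ({data.k}); censoring too severe for CLAD"
            )
        beta = fit_lad(data.subset(np.where(keep)[0]), tol=config.tol)
        obj = _clad_objective(data, beta, c)
        if obj < best_obj - 1e-15:
            best_beta, best_obj, best_keep = beta, obj, int(keep.sum())
        pred = data.X @ beta
        new_keep = pred < c
        if not new_keep.any():
            raise RuntimeError("all predictions at the ceiling; CLAD undefined")
        if new_keep.tobytes() == keep.tobytes():
            break
        if new_keep.tobytes() in seen:  # cycle: keep the best-objective iterate
            oscillated = True
            break
        seen.append(keep.tobytes())
        keep = new_keep
    assert best_beta is not None
    diag = {
        "objective": best_obj,
        "n_iter": n_iter,
        "n_retained": best_keep,
        "oscillated": oscillated,
        "solver": "ilpa",
    }
    return best_beta, diag


def fit_clad(
    data: RegressionData,
    config: CladConfig = CladConfig(),
    compute_se: bool = True,
) -> FittedModel:
    """Censored LAD by iterative trimming with bootstrap standard errors.

    Algorithm: LAD on the full sample; retain observations with ``x'b < c``;
    refit LAD on the retained set; iterate until the retained set is stable.
    If the retained sets cycle, the iterate with the smallest censored
    objective ``S(b) = sum |y - min(x'b, c)|`` is returned.  Because the
    trimming iteration can stall in a local optimum of the piecewise-linear
    objective when the sample is tiny and censoring heavy, problems with at
    most two coefficients and up to 40 observations are instead solved
    exactly by enumerating the arrangement vertices of the objective
    (``stats["solver"]`` records which path ran).  The vcov is the
    nonparametric case bootstrap (patients resampled with replacement, the
    whole fit re-run per replicate).
    """
    beta, diag = _clad_point(data, config)
    fitted = np.minimum(data.X @ beta, config.ceiling)
    stats = _error_stats(data.y, fitted)
    stats.update(diag)
    boot: Optional[BootstrapResult] = None
    vcov: Optional[np.ndarray] = None
    if compute_se and config.bootstrap_reps >= 2:
        boot = bootstrap_vcov(
            data,
            lambda d: _clad_point(d, config)[0],
            n_reps=config.bootstrap_reps,
            seed=config.seed,
        )
        vcov = boot.vcov
    return FittedModel(
        method="CLAD",
        labels=data.labels,
        params=beta,
        vcov=vcov,
        stats=stats,
        ceiling=config.ceiling,
        bootstrap=boot,
        config={
            "ceiling": config.ceiling,
            "max_iter": config.max_iter,
            "tol": config.tol,
            "bootstrap_reps": config.bootstrap_reps if compute_se else 0,
            "seed": config.seed,
        },
    )


def bootstrap_vcov(
    data: RegressionData,
    fit: Callable[[RegressionData], np.ndarray],
    n_reps: int,
    seed: Optional[int] = None,
    keep_draws: bool = True,
) -> BootstrapResult:
    """Nonparametric case bootstrap of a coefficient-returning fit procedure.

    Patients are resampled with replacement; replicates where the fit raises
    are dropped and counted, and more than 50% failures aborts.  SEs are the
    (ddof=1) SDs of the replicate coefficients; 95% intervals are percentile.
    """
    if n_reps < 2:
        raise ValueError("bootstrap needs at least 2 replicates")
    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, data.n, size=data.n)
        try:
            draws.append(np.asarray(fit(data.subset(idx)), dtype=float))
        except Exception:
            n_failed += 1
    if n_failed > n_reps / 2:
        raise RuntimeError(
            f"bootstrap failed in {n_failed}/{n_reps} replicates; "
            "estimates unreliable"
        )
    arr = np.vstack(draws)
    vcov = np.atleast_2d(np.cov(arr, rowvar=False, ddof=1))
    return BootstrapResult(
        vcov=vcov,
        se=np.std(arr, axis=0, ddof=1),
        ci_lower=np.percentile(arr, 2.5, axis=0),
        ci_upper=np.percentile(arr, 97.5, axis=0),
        n_reps=n_reps,
        n_failed=n_failed,
        draws=arr if keep_draws else None,
    )


def predict_utility(
    model: FittedModel,
    X: np.ndarray | Sequence[Sequence[float]],
    clamp: Optional[tuple[float, float]] = None,
    labels: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Predict utilities from a fitted model on new design rows.

    OLS predicts ``x'b``; GLM ``exp(x'b)``; CLAD ``min(x'b, c)``.  Optional
    ``clamp=(lo, hi)`` is applied last (off by default; the CLAD ceiling is
    always applied).  ``labels``, when given, must match the model's.
    """
    if labels is not None and tuple(labels) != tuple(model.labels):
        raise ValueError(
            f"design labels {tuple(labels)} do not match model labels "
            f"{tuple(model.labels)}"
        )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.params.size:
        raise ValueError(
            f"design has {X.shape[1]} columns, model has {model.params.size} "
            "coefficients"
        )
    eta = X @ model.params
    if model.method == "GLM":
        pred = np.exp(eta)
    elif model.method == "CLAD":
        pred = np.minimum(eta, model.ceiling if model.ceiling is not None else 1.0)
    else:
        pred = eta
    if clamp is not None:
        pred = np.clip(pred, clamp[0], clamp[1])
    return pred
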