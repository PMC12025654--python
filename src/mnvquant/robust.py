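"""Percentile-fence outlier downweighting and weighted regression.

Far outliers are downweighted rather than removed.  For each numeric
variable the 10th and 90th sample percentiles (linear interpolation
between order statistics, the default convention of mainstream
statistical software) define fences

    t_low  = p10 - 1.5 * (p90 - p10)
    t_high = p90 + 1.5 * (p90 - p10)

and each observation receives the Gaussian-kernel weight

    w(x) = exp(-0.5 * (max(0, t_low - x, x - t_high) / (0.5 * (t_high - t_low)))**2)

i.e. w = 1 on the closed fence interval, continuous and strictly
decreasing in the distance outside it, symmetric about the interval.
The half-range normalizer makes an excursion of half the fence range
cost exactly one kernel standard deviation (w = exp(-0.5)).  A model's
per-observation weight is the geometric mean of the weights of the
numeric variables entering that model.

Fits are weighted least squares (coefficient t-tests on n - p residual
degrees of freedom) and weighted logistic maximum likelihood via
iteratively reweighted least squares (Wald tests), both delegated to
statsmodels behind this module's interface.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError, SeparationError, SingularDesignError

LOGISTIC_TOL = 1e-8
LOGISTIC_MAXITER = 100


@dataclasses.dataclass(frozen=True)
class FenceThresholds:
    """Percentile fences of one variable's sample."""

    p10: float
    p90: float
    t_low: float
    t_high: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class WeightedFitResult:
    """Coefficients, inference and per-observation weights of one fit."""

    kind: str  # "linear" | "logistic"
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    weights: np.ndarray
    nobs: int
    df_resid: float
    _sm_result: object = dataclasses.field(default=None, repr=False)

    def joint_pvalue(self, terms: list[str]) -> float:
        """Joint test that the named coefficients are simultaneously zero
        (F test for linear fits, Wald chi-square for logistic)."""
        constraint = ", ".join(f"{t} = 0" for t in terms)
        if self.kind == "linear":
            return float(self._sm_result.f_test(constraint).pvalue)
        return float(self._sm_result.wald_test(constraint, scalar=True).pvalue)


def fence_thresholds(values) -> FenceThresholds:
    """Compute the percentile fences of a numeric sample (>= 2 finite values)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ParameterError("fence_thresholds needs at least 2 finite values")
    p10, p90 = np.percentile(arr, [10.0, 90.0])  # linear interpolation
    spread = p90 - p10
    return FenceThresholds(
        p10=float(p10),
        p90=float(p90),
        t_low=float(p10 - 1.5 * spread),
        t_high=float(p90 + 1.5 * spread),
        degenerate=bool(spread == 0.0),
    )


def outlier_weight(x, fences: FenceThresholds):
    """Gaussian-kernel weight(s) in (0, 1] for value(s) ``x``.

    Degenerate fences (p10 = p90) carry no spread information; every
    observation then receives weight 1, with a warning.
    """
    x = np.asarray(x, dtype=float)
    if fences.degenerate:
        warnings.warn(
            "outlier_weight: degenerate fences (p10 == p90); returning unit weights",
            stacklevel=2,
        )
        out = np.ones_like(x)
        return float(out) if out.ndim == 0 else out
    excess = np.maximum(0.0, np.maximum(fences.t_low - x, x - fences.t_high))
    half_range = 0.5 * (fences.t_high - fences.t_low)
    w = np.exp(-0.5 * (excess / half_range) ** 2)
    return float(w) if w.ndim == 0 else w


def combine_weights(per_variable_weights) -> np.ndarray:
    """Geometric mean across variables of a (k, n) stack of weights.

    With no involved variables every observation gets weight 1.
    """
    stack = np.atleast_2d(np.asarray(per_variable_weights, dtype=float))
    if stack.size == 0:
        return np.ones(stack.shape[-1] if stack.ndim > 1 else 1)
    if np.any(stack <= 0) or np.any(stack > 1):
        raise ParameterError("combine_weights expects weights in (0, 1]")
    return np.exp(np.mean(np.log(stack), axis=0))


def _as_design(ivs, confounder, names) -> pd.DataFrame:
    if isinstance(ivs, pd.DataFrame):
        X = ivs.copy()
    else:
        arr = np.atleast_2d(np.asarray(ivs, dtype=float))
        if arr.shape[0] == 1 and arr.shape[1] > 1 and names and len(names) == 1:
            arr = arr.T
        elif arr.shape[0] < arr.shape[1] and arr.shape[0] == (len(names) if names else 1):
            arr = arr.T
        X = pd.DataFrame(arr, columns=names or [f"x{i}" for i in range(arr.shape[1])])
    if confounder is not None:
        conf = confounder if isinstance(confounder, pd.DataFrame) else pd.DataFrame(
            np.atleast_2d(np.asarray(confounder, dtype=float)).reshape(len(X), -1),
            columns=None,
        )
        if not isinstance(confounder, pd.DataFrame):
            conf.columns = [f"confounder{i}" for i in range(conf.shape[1])]
        X = pd.concat([X.reset_index(drop=True), conf.reset_index(drop=True)], axis=1)
    return X


def _check_rank(design: pd.DataFrame, weights: np.ndarray) -> None:
    mat = design.to_numpy(dtype=float) * np.sqrt(weights)[:, None]
    rank = np.linalg.matrix_rank(mat)
    if rank < design.shape[1]:
        collinear = []
        for col in design.columns:
            reduced = design.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(reduced * np.sqrt(weights)[:, None]) == rank:
                collinear.append(str(col))
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {collinear or list(map(str, design.columns))}",
            columns=collinear,
        )


def weighted_linear_fit(
    dv,
    ivs,
    confounder=None,
    weights=None,
    names: list[str] | None = None,
) -> WeightedFitResult:
    """Weighted least squares with intercept.

    Solves the weighted normal equations; coefficient p-values come from
    the t distribution on (n - p) residual degrees of freedom with the
    weighted residual variance.  An integer weight k on a row is
    equivalent (for the coefficients) to replicating that row k times.
    """
    y = np.asarray(dv, dtype=float)
    X = _as_design(ivs, confounder, names)
    n = len(y)
    if len(X) != n:
        raise ParameterError("dv and ivs disagree in length")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ParameterError("weights must be non-negative")
    p = X.shape[1] + 1
    if int((w > 0).sum()) < p + 2:
        raise ParameterError(
            f"need at least {p + 2} positive-weight observations for {p} parameters"
        )
    design = sm.add_constant(X, has_constant="add")
    _check_rank(design, w)
    result = sm.WLS(y, design, weights=w).fit()
    return WeightedFitResult(
        kind="linear",
        params=result.params,
        bse=result.bse,
        pvalues=result.pvalues,
        weights=w,
        nobs=int(result.nobs),
        df_resid=float(result.df_resid),
        _sm_result=result,
    )


def weighted_logistic_fit(
    dv,
    ivs,
    confounder=None,
    weights=None,
    names: list[str] | None = None,
) -> WeightedFitResult:
    """Weighted logistic regression via IRLS (tolerance 1e-8, <= 100
    iterations) with Wald p-values.

    Weights enter the score equations multiplicatively, so rescaling all
    weights by a constant leaves the coefficient estimates unchanged.
    Complete separation raises :class:`SeparationError` with guidance.
    """
    y = np.asarray(dv, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ParameterError("logistic dv must be binary 0/1")
    X = _as_design(ivs, confounder, names)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    positive = w > 0
    classes = np.unique(y[positive])
    if classes.size < 2:
        raise ParameterError(
            "both outcome classes must be present among positive-weight observations"
        )
    design = sm.add_constant(X, has_constant="add")
    _check_rank(design, w)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*[Ss]eparation.*")
        try:
            model = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=w)
            result = model.fit(maxiter=LOGISTIC_MAXITER, tol=LOGISTIC_TOL)
        except PerfectSeparationError as exc:
            raise SeparationError(
                "logistic likelihood diverged: the classes are completely separated; "
                "remove the separating covariate or use penalized estimation"
            ) from exc
    fitted = np.asarray(result.fittedvalues)
    perfectly_fitted = np.max(np.abs(fitted[positive] - y[positive])) < 1e-6
    if not getattr(result, "converged", True) or perfectly_fitted:
        raise SeparationError(
            "logistic likelihood diverged: the outcome classes are (quasi-)separated; "
            "remove the separating covariate or use penalized estimation"
        )
    return WeightedFitResult(
        kind="logistic",
        params=result.params,
        bse=result.bse,
        pvalues=result.pvalues,
        weights=w,
        nobs=int(result.nobs),
        df_resid=float(result.df_resid),
        _sm_result=result,
    )
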