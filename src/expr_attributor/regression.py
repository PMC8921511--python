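"""Sign-constrained multiple linear regression of target-gene expression.

The model is the ordinary linear form

    y_i = beta_0 + beta_1 x_i1 + ... + beta_n x_in + eps_i

fitted under box constraints on the coefficients: TF-activity predictors
are bounded below by zero (a TF may only activate the target), except for
designated repressor candidates (BRD4) and the intercept, which are free.
The bounded fit is solved with a bounded-variable least-squares (BVLS)
solver; coefficients driven to the zero bound are removed, and statistical
inference (t-test p-values, R^2, overall F-test) is then obtained from an
ordinary least-squares refit on the surviving variables.  Backward
elimination at a significance threshold yields the final model.

Reported alongside the fit are per-patient relative contributions
(beta_j x_ij / sum_k beta_k x_ik * 100, intercept excluded from the
denominator) and variance-inflation-factor collinearity diagnostics
(VIF_i = 1 / (1 - R_i^2) from auxiliary regressions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import lsq_linear

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "FitResult",
    "ContributionTable",
    "CollinearityReport",
    "fit_bounded",
    "infer_ols",
    "select_model",
    "predict",
    "contributions",
    "vif",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix does not have full column rank."""


@dataclass
class DesignSpec:
    """Per-variable box bounds for the coefficient vector.

    The intercept is always unbounded and handled internally; bounds here
    cover only the named predictors.
    """

    variable_names: List[str]
    lower_bounds: Dict[str, float]
    upper_bounds: Dict[str, float]

    def __post_init__(self) -> None:
        for v in self.variable_names:
            lo = self.lower_bounds.get(v, -np.inf)
            hi = self.upper_bounds.get(v, np.inf)
            if lo > hi:
                raise ValueError(f"lower bound exceeds upper bound for {v!r}")

    @classmethod
    def nonnegative(
        cls, variable_names: Sequence[str], free: Sequence[str] = ("BRD4",)
    ) -> "DesignSpec":
        """Lower bound 0 for every variable except those in ``free``."""
        names = list(variable_names)
        lower = {v: (-np.inf if v in set(free) else 0.0) for v in names}
        return cls(names, lower, {v: np.inf for v in names})

    @classmethod
    def unbounded(cls, variable_names: Sequence[str]) -> "DesignSpec":
        names = list(variable_names)
        return cls(names, {v: -np.inf for v in names}, {v: np.inf for v in names})

    def subset(self, names: Sequence[str]) -> "DesignSpec":
        return DesignSpec(
            list(names),
            {v: self.lower_bounds.get(v, -np.inf) for v in names},
            {v: self.upper_bounds.get(v, np.inf) for v in names},
        )

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.lower_bounds.get(v, -np.inf) for v in self.variable_names])
        hi = np.array([self.upper_bounds.get(v, np.inf) for v in self.variable_names])
        return lo, hi


@dataclass
class FitResult:
    """A fitted (possibly intercept-only) linear model."""

    beta0: float
    betas: pd.Series  # coefficient per selected variable
    pvalues: pd.Series
    r2: float
    fit_pvalue: float  # overall F-test p
    residuals: pd.Series  # per patient, observed - fitted
    selected: List[str]
    alpha: float
    intercept_only: bool = False

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "betas": self.betas.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "r2": self.r2,
            "fit_pvalue": self.fit_pvalue,
            "selected": list(self.selected),
            "alpha": self.alpha,
            "intercept_only": self.intercept_only,
        }


@dataclass
class ContributionTable:
    """Per-patient percent contributions of the selected variables."""

    per_patient: pd.DataFrame  # samples x variables, percent
    mean: pd.Series
    sd: pd.Series
    undefined_samples: List[str] = field(default_factory=list)


@dataclass
class CollinearityReport:
    """VIF and auxiliary R^2 per variable, with the conventional flags."""

    table: pd.DataFrame  # columns: variable, aux_r2, vif, flag_vif_gt4, flag_vif_gt10


def _as_design(X: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [v for v in names if v not in X.columns]
    if missing:
        raise ValueError(f"design matrix missing variables: {missing}")
    return X.loc[:, list(names)].to_numpy(dtype=float)


def _check_rank(design: np.ndarray, context: str) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficientError(
            f"{context}: design matrix is rank deficient "
            f"(rank < {design.shape[1]} columns); remove collinear variables"
        )


def fit_bounded(
    y: pd.Series, X: pd.DataFrame, spec: DesignSpec
) -> Tuple[float, pd.Series]:
    """Box-constrained least squares via the BVLS algorithm.

    Returns ``(intercept, coefficients)``.  Coefficients pinned at an
    active bound come back exactly at the bound value.
    """
    names = spec.variable_names
    A = _as_design(X, names)
    yv = np.asarray(y, dtype=float)
    if A.shape[0] != yv.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    if A.shape[0] <= A.shape[1]:
        raise ValueError("need more observations than predictors")
    design = np.column_stack([np.ones(A.shape[0]), A])
    _check_rank(design, "fit_bounded")
    lo, hi = spec.bounds_arrays()
    res = lsq_linear(
        design,
        yv,
        bounds=(np.concatenate([[-np.inf], lo]), np.concatenate([[np.inf], hi])),
        method="bvls",
        tol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"BVLS failed to converge: {res.message}")
    coefs = pd.Series(res.x[1:], index=names)
    return float(res.x[0]), coefs


def infer_ols(y: pd.Series, X_selected: pd.DataFrame):
    """Ordinary least squares with standard t/F inference.

    Returns the fitted statsmodels results object; the design is augmented
    with an intercept column named ``const``.
    """
    A = X_selected.to_numpy(dtype=float)
    design = np.column_stack([np.ones(A.shape[0]), A])
    _check_rank(design, "infer_ols")
    exog = pd.DataFrame(
        design, columns=["const"] + list(X_selected.columns), index=X_selected.index
    )
    return sm.OLS(np.asarray(y, dtype=float), exog).fit()


def _at_zero_bound(value: float, lo: float, hi: float, atol: float = 1e-10) -> bool:
    return (lo == 0.0 and abs(value) <= atol) or (hi == 0.0 and abs(value) <= atol)


def select_model(
    y: pd.Series, X_full: pd.DataFrame, spec: DesignSpec, alpha: float = 0.001
) -> FitResult:
    """Significance-driven variable selection under sign constraints.

    Iterates: BVLS on the current candidate set; discard variables pinned
    at a zero bound; OLS refit on the survivors; if the worst p-value is at
    or above ``alpha`` drop that single variable (ties broken by name) and
    start over.  The final result reports the OLS-refit coefficients,
    p-values, R^2 and overall F p of the surviving set.
    """
    current = list(spec.variable_names)
    sample_index = X_full.index

    def _intercept_only() -> FitResult:
        yv = np.asarray(y, dtype=float)
        beta0 = float(np.mean(yv))
        resid = pd.Series(yv - beta0, index=sample_index)
        logger.warning("select_model: no variable survived; intercept-only model")
        return FitResult(
            beta0=beta0,
            betas=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float),
            r2=0.0,
            fit_pvalue=np.nan,
            residuals=resid,
            selected=[],
            alpha=alpha,
            intercept_only=True,
        )

    while True:
        if not current:
            return _intercept_only()
        sub = spec.subset(current)
        _, coefs = fit_bounded(y, X_full, sub)
        keep = [
            v
            for v in current
            if not _at_zero_bound(
                coefs[v], sub.lower_bounds.get(v, -np.inf), sub.upper_bounds.get(v, np.inf)
            )
        ]
        if not keep:
            return _intercept_only()
        ols = infer_ols(y, X_full.loc[:, keep])
        pvals = ols.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p >= alpha:
            # deterministic: among ties on p, drop the lexicographically first
            worst = sorted(pvals.index[pvals == worst_p])[0]
            current = [v for v in keep if v != worst]
            continue
        if keep != current:
            current = keep
            continue
        # survivors are significant; verify OLS signs respect the bounds
        infeasible = [
            v
            for v in keep
            if not (
                sub.lower_bounds.get(v, -np.inf) - 1e-10
                <= ols.params[v]
                <= sub.upper_bounds.get(v, np.inf) + 1e-10
            )
        ]
        if infeasible:
            current = [v for v in keep if v not in infeasible]
            continue
        fitted = ols.fittedvalues.to_numpy()
        return FitResult(
            beta0=float(ols.params["const"]),
            betas=ols.params.drop("const"),
            pvalues=pvals,
            r2=float(ols.rsquared),
            fit_pvalue=float(ols.f_pvalue),
            residuals=pd.Series(np.asarray(y, dtype=float) - fitted, index=sample_index),
            selected=list(keep),
            alpha=alpha,
        )


def predict(fit: FitResult, X: pd.DataFrame) -> pd.Series:
    """yhat = beta_0 + sum_j beta_j x_j over the selected variables."""
    if fit.intercept_only:
        return pd.Series(fit.beta0, index=X.index)
    A = _as_design(X, fit.selected)
    return pd.Series(
        fit.beta0 + A @ fit.betas.loc[fit.selected].to_numpy(), index=X.index
    )


def contributions(
    fit: FitResult, X: pd.DataFrame, y: Optional[pd.Series] = None
) -> ContributionTable:
    """Per-patient percent contribution of each selected variable.

    C_ij = beta_j x_ij / sum_k beta_k x_ik * 100.  The denominator excludes
    the intercept and keeps negative terms (a repressor contributes
    negatively, the rest compensate above 100%).  Patients whose denominator
    is numerically zero are flagged and excluded from the mean/SD summary.
    """
    if not fit.selected:
        raise ValueError("contributions undefined for an intercept-only model")
    A = _as_design(X, fit.selected)
    terms = A * fit.betas.loc[fit.selected].to_numpy()
    denom = terms.sum(axis=1)
    scale = float(np.std(y)) if y is not None else float(np.std(denom))
    tol = 1e-9 * (scale if scale > 0 else 1.0)
    bad = np.abs(denom) < tol
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = terms / denom[:, None] * 100.0
    pct[bad] = np.nan
    per_patient = pd.DataFrame(pct, index=X.index, columns=fit.selected)
    ok = per_patient.loc[~bad]
    undefined = list(X.index[bad])
    if undefined:
        logger.warning("contributions: %d patients with near-zero denominator", len(undefined))
    return ContributionTable(
        per_patient=per_patient,
        mean=ok.mean(axis=0),
        sd=ok.std(axis=0, ddof=1),
        undefined_samples=undefined,
    )


def vif(X_selected: pd.DataFrame) -> CollinearityReport:
    """Variance inflation factors from auxiliary regressions.

    For each variable x_i, regress it (with intercept) on the remaining
    variables; VIF_i = 1 / (1 - R_i^2).  Perfectly collinear variables get
    VIF = inf.
    """
    cols = list(X_selected.columns)
    if len(cols) < 2:
        raise ValueError("VIF requires at least two variables")
    rows = []
    for v in cols:
        others = [c for c in cols if c != v]
        aux = infer_ols(X_selected[v], X_selected.loc[:, others])
        r2 = float(aux.rsquared)
        vif_i = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append((v, r2, vif_i, vif_i > 4, vif_i > 10))
    table = pd.DataFrame(
        rows, columns=["variable", "aux_r2", "vif", "flag_vif_gt4", "flag_vif_gt10"]
    )
    return CollinearityReport(table=table)
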