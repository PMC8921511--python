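"""miRNA-based explanation of unexplained high expression.

miRNAs significantly *negatively* correlated with target-gene expression
(two-sided Pearson test, r < 0, p < 0.01) are called critical: they are
candidate post-transcriptional repressors.  Patients are then binned into
quartiles of the average critical-miRNA abundance — named low,
lower-midrange, upper-midrange and high — and low abundance of these
repressors serves as an explanation for unexpectedly high target
expression.  As with mutations, discovery runs first on the accurately
predicted patients and is then reiterated on the whole population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix
from .regression import FitResult, infer_ols

logger = logging.getLogger(__name__)

__all__ = [
    "CriticalMiRNASet",
    "QuantileAssignment",
    "discover_critical_mirnas",
    "average_critical_expression",
    "assign_quantiles",
    "fit_mirna_model",
]

QUARTILE_NAMES = ("low", "lower-midrange", "upper-midrange", "high")


@dataclass
class CriticalMiRNASet:
    """miRNAs negatively and significantly correlated with the target."""

    table: pd.DataFrame  # columns: mirna, pearson_r, p_value
    basis: str  # "accurate_only" | "all_patients"
    p_max: float

    @property
    def mirna_ids(self) -> list:
        return self.table["mirna"].tolist()


@dataclass
class QuantileAssignment:
    """Quantile bin per patient based on average critical-miRNA level."""

    averages: pd.Series
    labels: pd.Series  # bin name per patient
    cut_points: np.ndarray  # the k-1 interior empirical quantiles
    bin_names: List[str]
    degenerate: bool = False

    def fraction_in(self, bin_name: str, samples: Sequence[str]) -> float:
        if not len(samples):
            raise ValueError("empty sample list")
        return float((self.labels.loc[list(samples)] == bin_name).mean())


def discover_critical_mirnas(
    target_expr: pd.Series,
    mirna: ExpressionMatrix,
    subset: Optional[Sequence[str]] = None,
    p_max: float = 0.01,
    basis: str = "all_patients",
) -> CriticalMiRNASet:
    """Pearson screen for negative regulators of the target gene."""
    samples = list(subset) if subset is not None else mirna.sample_ids
    if len(samples) < 3:
        raise ValueError("need at least 3 patients for a correlation test")
    expr = target_expr.loc[samples].to_numpy(dtype=float)
    mat = mirna.values.loc[:, samples]
    rows = []
    for mid in mirna.feature_ids:
        v = mat.loc[mid].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(expr) == 0:
            logger.info("discover_critical_mirnas: %s skipped (zero variance)", mid)
            continue
        r, p = stats.pearsonr(v, expr)
        if r < 0 and p < p_max:
            rows.append((mid, r, p))
    table = (
        pd.DataFrame(rows, columns=["mirna", "pearson_r", "p_value"])
        .sort_values(["p_value", "mirna"], kind="mergesort")
        .reset_index(drop=True)
    )
    return CriticalMiRNASet(table=table, basis=basis, p_max=p_max)


def average_critical_expression(
    mirna: ExpressionMatrix, critical: CriticalMiRNASet
) -> pd.Series:
    """Unweighted mean of the critical miRNA rows, per patient."""
    ids = critical.mirna_ids
    if not ids:
        raise ValueError("no critical miRNAs: average undefined")
    missing = [m for m in ids if m not in mirna.values.index]
    if missing:
        raise ValueError(f"critical miRNAs absent from matrix: {missing}")
    return mirna.values.loc[ids].mean(axis=0)


def assign_quantiles(averages: pd.Series, k: int = 4) -> QuantileAssignment:
    """Bin patients at the empirical (1/k .. (k-1)/k) quantiles.

    A value equal to a cut point falls in the upper bin, matching the
    "low: < q1 ... high: >= q3" convention.  Bins left empty by massive
    ties are reported as-is with the ``degenerate`` flag set.
    """
    if len(averages) < k:
        raise ValueError(f"need at least k={k} patients")
    names = list(QUARTILE_NAMES) if k == 4 else [f"q{i + 1}" for i in range(k)]
    cuts = np.quantile(averages.to_numpy(dtype=float), np.arange(1, k) / k)
    idx = np.searchsorted(cuts, averages.to_numpy(dtype=float), side="right")
    labels = pd.Series([names[i] for i in idx], index=averages.index)
    degenerate = len(labels.unique()) < k
    if degenerate:
        logger.warning("assign_quantiles: %d of %d bins occupied (heavy ties)",
                       len(labels.unique()), k)
    return QuantileAssignment(
        averages=averages,
        labels=labels,
        cut_points=cuts,
        bin_names=names,
        degenerate=degenerate,
    )


def fit_mirna_model(target_expr: pd.Series, averages: pd.Series) -> FitResult:
    """Single-predictor regression of the target on the miRNA average.

    The slope is unbounded; for genuine repressors it comes out negative.
    """
    X = pd.DataFrame({"mirna_average": averages.loc[target_expr.index]})
    ols = infer_ols(target_expr, X)
    return FitResult(
        beta0=float(ols.params["const"]),
        betas=ols.params.drop("const"),
        pvalues=ols.pvalues.drop("const"),
        r2=float(ols.rsquared),
        fit_pvalue=float(ols.f_pvalue),
        residuals=pd.Series(
            np.asarray(target_expr, dtype=float) - ols.fittedvalues.to_numpy(),
            index=target_expr.index,
        ),
        selected=["mirna_average"],
        alpha=np.nan,
    )
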