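"""Mutation-based explanation of unexplained high expression.

Genes whose mutated carriers show elevated target-gene expression are
called *critical*: a gene qualifies when its carrier prevalence in the
analysis subset exceeds 1%, the fold change of target expression between
mutated and wild-type patients exceeds 1.5, and a two-sided Mann-Whitney U
test gives p < 0.01.  No multiple-testing correction is applied by
default; the raw-p + fold-change double filter is the selection rule, with
an optional Benjamini-Hochberg flag for users who want it.

The analysis is run twice: first on the accurately predicted patients only
(so the discovered associations are not driven by the unexplained group
itself) and then on the whole population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import mann_whitney
from .classify import PredictionClassification
from .cohort_io import MutationEventTable

logger = logging.getLogger(__name__)

__all__ = [
    "CriticalGeneSet",
    "discover_critical_genes",
    "count_critical",
    "compare_group_burden",
]


@dataclass
class CriticalGeneSet:
    """Genes passing the prevalence / fold-change / Mann-Whitney filters."""

    table: pd.DataFrame  # columns: gene, p_value, fold_change, prevalence
    basis: str  # "accurate_only" | "all_patients"
    thresholds: dict

    @property
    def genes(self) -> list:
        return self.table["gene"].tolist()


def discover_critical_genes(
    target_expr: pd.Series,
    events: MutationEventTable,
    subset: Optional[Sequence[str]] = None,
    p_max: float = 0.01,
    fc_min: float = 1.5,
    prevalence_min: float = 0.01,
    basis: str = "all_patients",
    fc_scale: str = "log2geometric",
    fdr: bool = False,
) -> CriticalGeneSet:
    """Screen every mutated gene for association with high target expression.

    Per gene with carrier prevalence above ``prevalence_min`` in the subset:
    compare target expression of mutated vs wild-type patients (two-sided
    Mann-Whitney U) and compute the fold change.  With the default
    ``log2geometric`` scale, FC = 2**(mean log2 mutated - mean log2
    wild-type), i.e. a ratio of geometric means; ``fc_scale="linear"``
    back-transforms through 2**v - 1 first and uses arithmetic means.
    Genes passing all three filters are returned sorted by p.
    """
    samples = list(subset) if subset is not None else events.sample_ids
    missing = [s for s in samples if s not in set(events.sample_ids)]
    if missing:
        raise ValueError(f"subset samples absent from event table: {missing[:5]}")
    expr = target_expr.loc[samples].to_numpy(dtype=float)
    ev = events.events.loc[:, samples].to_numpy()
    n = len(samples)

    rows, skipped = [], 0
    for gi, gene in enumerate(events.gene_ids):
        carriers = ev[gi].astype(bool)
        n_mut = int(carriers.sum())
        prevalence = n_mut / n
        if prevalence <= prevalence_min:
            continue
        if n_mut < 2 or n - n_mut < 2:
            skipped += 1
            logger.info("discover_critical_genes: %s skipped (arm < 2)", gene)
            continue
        mut_expr, wt_expr = expr[carriers], expr[~carriers]
        if fc_scale == "log2geometric":
            fc = 2.0 ** (mut_expr.mean() - wt_expr.mean())
        elif fc_scale == "linear":
            lin_mut = np.mean(2.0 ** mut_expr - 1.0)
            lin_wt = np.mean(2.0 ** wt_expr - 1.0)
            fc = np.inf if lin_wt == 0 else lin_mut / lin_wt
        else:
            raise ValueError(f"unknown fc_scale {fc_scale!r}")
        _, p = mann_whitney(mut_expr, wt_expr)
        rows.append((gene, p, fc, prevalence))

    table = pd.DataFrame(rows, columns=["gene", "p_value", "fold_change", "prevalence"])
    if fdr and len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        keep_p = table["q_value"] < p_max
    else:
        keep_p = table["p_value"] < p_max
    table = (
        table[keep_p & (table["fold_change"] > fc_min)]
        .sort_values(["p_value", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )
    return CriticalGeneSet(
        table=table,
        basis=basis,
        thresholds={"p_max": p_max, "fc_min": fc_min, "prevalence_min": prevalence_min},
    )


def count_critical(events: MutationEventTable, critical: CriticalGeneSet) -> pd.Series:
    """Per-patient number of critical genes carrying an event."""
    genes = critical.genes
    missing = [g for g in genes if g not in set(events.gene_ids)]
    if missing:
        raise ValueError(f"critical genes absent from event table: {missing}")
    if not genes:
        return pd.Series(0, index=events.events.columns, dtype=int)
    return events.events.loc[genes].sum(axis=0).astype(int)


def compare_group_burden(
    counts: pd.Series, classification: PredictionClassification
) -> Tuple[float, float, float, float]:
    """Critical-mutation burden, underpredicted vs accurate patients.

    Returns (mean burden underpredicted, mean burden accurate, U, two-sided
    Mann-Whitney p).
    """
    under = classification.samples_with("underpredicted")
    accurate = classification.samples_with("accurate")
    if not under or not accurate:
        raise ValueError("group comparison undefined: an arm is empty")
    u_counts = counts.loc[under].to_numpy(dtype=float)
    a_counts = counts.loc[accurate].to_numpy(dtype=float)
    u_stat, p = mann_whitney(u_counts, a_counts)
    return float(u_counts.mean()), float(a_counts.mean()), u_stat, p
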