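"""Regulon-based TF-activity proxies.

A TF's per-patient activity is estimated as the mean log2(x + 1) expression
of its regulon's target genes, restricted to the highest-confidence targets
that are unique among the TFs under consideration and excluding the
dependent gene itself.  This deliberately simple proxy (no enrichment
scoring) is the quantity the downstream regression consumes.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix, RegulonTable

logger = logging.getLogger(__name__)

__all__ = ["select_unique_targets", "compute_activity", "activity_mrna_correlation"]

_GRADE_ORDER = "ABCDE"


def select_unique_targets(
    regulons: RegulonTable,
    tfs: Sequence[str],
    confidence: str = "A",
    exclude: Sequence[str] = (),
    expressed: Optional[Sequence[str]] = None,
) -> Dict[str, List[str]]:
    """Per-TF unique target sets at a confidence grade.

    Filtering order: keep records graded at or above ``confidence`` (A is
    best, so "at or above" means lexicographically <=); drop targets claimed
    by more than one of the considered TFs; drop explicitly excluded genes
    (the dependent gene, typically); intersect with ``expressed`` when given.
    A TF whose set ends up empty has no defined activity, which is an error.
    """
    if confidence not in _GRADE_ORDER:
        raise ValueError(f"confidence grade must be one of A-E, got {confidence!r}")
    missing_tfs = [tf for tf in tfs if tf not in set(regulons.records["tf"])]
    if missing_tfs:
        raise ValueError(f"TFs absent from regulon table: {missing_tfs}")

    rec = regulons.records
    kept = rec[rec["tf"].isin(list(tfs)) & (rec["confidence"] <= confidence)]

    counts = Counter(kept["target"])
    shared = {g for g, c in counts.items() if c > 1}
    excluded = set(exclude)
    expressed_set = set(expressed) if expressed is not None else None

    sets: Dict[str, List[str]] = {}
    for tf in tfs:
        targets = kept.loc[kept["tf"] == tf, "target"]
        chosen = [g for g in targets if g not in shared and g not in excluded]
        if expressed_set is not None:
            n_before = len(chosen)
            chosen = [g for g in chosen if g in expressed_set]
            if n_before - len(chosen):
                logger.info(
                    "select_unique_targets: %s dropped %d targets absent from "
                    "expression matrix", tf, n_before - len(chosen),
                )
        if not chosen:
            raise ValueError(
                f"TF {tf!r} has no usable target genes after filtering; "
                "its activity is undefined"
            )
        sets[tf] = sorted(chosen)
    return sets


def compute_activity(
    expr: ExpressionMatrix, sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Mean target-gene expression per TF and patient (tf x sample)."""
    missing = {
        tf: [g for g in genes if g not in expr.values.index]
        for tf, genes in sets.items()
    }
    missing = {tf: gs for tf, gs in missing.items() if gs}
    if missing:
        raise ValueError(f"target genes absent from expression matrix: {missing}")
    rows = {
        tf: expr.values.loc[list(genes)].mean(axis=0) for tf, genes in sets.items()
    }
    return pd.DataFrame(rows).T.loc[list(sets)]


def activity_mrna_correlation(
    expr: ExpressionMatrix,
    activity: pd.DataFrame,
    tf_gene_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Pearson correlation between each TF's activity and its own mRNA.

    ``tf_gene_map`` maps TF names to mRNA row ids; by default the TF name is
    assumed to be its gene symbol.  Zero-variance vectors yield NaN r/p.
    """
    out = []
    for tf in activity.index:
        gene = (tf_gene_map or {}).get(tf, tf)
        if gene not in expr.values.index:
            raise ValueError(f"mRNA row {gene!r} for TF {tf!r} not in expression matrix")
        a = activity.loc[tf].to_numpy(dtype=float)
        m = expr.values.loc[gene, activity.columns].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(m) == 0:
            out.append((tf, gene, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(a, m)
        out.append((tf, gene, r, p))
    return pd.DataFrame(out, columns=["tf", "gene", "pearson_r", "p_value"])
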