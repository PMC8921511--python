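"""End-to-end attribution pipeline and generalization experiments.

Stages: TF activities from regulons -> sign-constrained TF regression ->
residual-based patient classification -> critical-mutation and
critical-miRNA discovery (accurate-only pass, then whole-population pass)
-> combined TF + mutation-burden + miRNA-average model -> per-patient
explanation attribution.

Attribution rule for an underpredicted patient: *mutation* if they carry at
least one critical mutation, *miRNA* if their average critical-miRNA level
falls in the lowest quantile, *mutation+miRNA* if both, *unexplained* if
neither.  Accurately predicted patients are attributed to TF activity;
overpredicted patients are kept as their own category (the analysis of why
a model overshoots is out of scope).  The critical sets used for
attribution are the whole-population ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .classify import PredictionClassification, classify_patients, group_fractions
from .cohort_io import CohortBundle, RegulonTable
from .mirnas import (
    CriticalMiRNASet,
    QuantileAssignment,
    assign_quantiles,
    average_critical_expression,
    discover_critical_mirnas,
    fit_mirna_model,
)
from .mutations import (
    CriticalGeneSet,
    compare_group_burden,
    count_critical,
    discover_critical_genes,
)
from .regression import (
    DesignSpec,
    FitResult,
    contributions,
    predict,
    select_model,
    vif,
)
from .synthetic import SimulationConfig, simulate_cohort
from .tf_activity import compute_activity, select_unique_targets

logger = logging.getLogger(__name__)

__all__ = [
    "EXPLANATIONS",
    "AttributionSummary",
    "GeneralizationResult",
    "PipelineConfig",
    "PipelineResult",
    "fit_combined",
    "attribute_patients",
    "split_train_test",
    "fit_generalized",
    "run_pipeline",
]

EXPLANATIONS = ("TF", "mutation", "miRNA", "mutation+miRNA", "unexplained", "overpredicted")


@dataclass
class AttributionSummary:
    """Explanation-category fractions, each summing to 1 per population."""

    underpredicted_fractions: Dict[str, float]
    cohort_fractions: Dict[str, float]
    n_underpredicted: int
    n_total: int


@dataclass
class GeneralizationResult:
    """Pooled-cohort train/test fits and two-fold-band test accuracy."""

    repeats: List[dict]  # per repeat: seed, train/test ids, fit, band fractions
    coefficient_table: pd.DataFrame  # repeat x variable coefficients


def fit_combined(
    target_expr: pd.Series,
    tf_activity: pd.DataFrame,
    mutation_counts: pd.Series,
    mirna_average: pd.Series,
    alpha: float = 0.01,
    free_tfs: Sequence[str] = ("BRD4",),
) -> FitResult:
    """Joint model: TF activities + critical-mutation count + miRNA average.

    TF coefficients are bounded below by 0 (except designated repressors),
    the mutation count likewise (mutations only push expression up), and
    the miRNA-average coefficient is bounded above by 0 (miRNAs are modeled
    strictly as repressors).  Selection runs at ``alpha`` (default 0.01).
    """
    samples = target_expr.index
    X = tf_activity.T.loc[samples].copy()
    if float(mutation_counts.loc[samples].std()) == 0.0:
        logger.warning("fit_combined: mutation counts have zero variance; term dropped")
    else:
        X["mutation_count"] = mutation_counts.loc[samples]
    X["mirna_average"] = mirna_average.loc[samples]

    names = list(X.columns)
    lower = {v: (-np.inf if v in set(free_tfs) else 0.0) for v in names}
    upper = {v: np.inf for v in names}
    lower["mirna_average"], upper["mirna_average"] = -np.inf, 0.0
    spec = DesignSpec(names, lower, upper)
    return select_model(target_expr, X, spec, alpha=alpha)


def attribute_patients(
    classification: PredictionClassification,
    mutation_counts: pd.Series,
    quantiles: QuantileAssignment,
) -> Tuple[pd.DataFrame, AttributionSummary]:
    """Assign each patient an explanation category (see module docstring)."""
    samples = classification.frame.index
    for name, s in (("mutation counts", mutation_counts), ("quantiles", quantiles.labels)):
        missing = samples.difference(s.index)
        if len(missing):
            raise ValueError(f"{name} missing for patients: {list(missing[:5])}")
    low_bin = quantiles.bin_names[0]

    records = []
    for sid in samples:
        label = classification.frame.at[sid, "label"]
        count = int(mutation_counts.loc[sid])
        qbin = quantiles.labels.loc[sid]
        if label == "accurate":
            explanation = "TF"
        elif label == "overpredicted":
            explanation = "overpredicted"
        else:
            has_mut = count >= 1
            low_mirna = qbin == low_bin
            if has_mut and low_mirna:
                explanation = "mutation+miRNA"
            elif has_mut:
                explanation = "mutation"
            elif low_mirna:
                explanation = "miRNA"
            else:
                explanation = "unexplained"
        records.append((sid, label, count, qbin, explanation))
    frame = pd.DataFrame(
        records,
        columns=["patient", "label", "critical_mutation_count", "mirna_quantile", "explanation"],
    ).set_index("patient")

    under = frame[frame["label"] == "underpredicted"]
    n_under, n_total = len(under), len(frame)
    under_fracs = {
        e: (float((under["explanation"] == e).mean()) if n_under else 0.0)
        for e in ("mutation", "miRNA", "mutation+miRNA", "unexplained")
    }
    cohort_fracs = {e: float((frame["explanation"] == e).mean()) for e in EXPLANATIONS}
    return frame, AttributionSummary(
        underpredicted_fractions=under_fracs,
        cohort_fractions=cohort_fracs,
        n_underpredicted=n_under,
        n_total=n_total,
    )


def split_train_test(
    sample_ids: Sequence[str], train_frac: float = 0.8, seed: int = 0
) -> Tuple[List[str], List[str]]:
    """Random disjoint, exhaustive train/test split; same seed, same split."""
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(round(n * train_frac))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def _twofold_band_fraction(
    fit: FitResult, target_expr: pd.Series, X: pd.DataFrame, fold: float
) -> float:
    cls = classify_patients(target_expr, predict(fit, X), fold=fold)
    return group_fractions(cls)["accurate"]


def _tf_design(bundle: CohortBundle, regulons: RegulonTable, tfs, confidence) -> pd.DataFrame:
    sets = select_unique_targets(
        regulons,
        tfs,
        confidence=confidence,
        exclude=[bundle.target_gene_id],
        expressed=bundle.mrna.feature_ids,
    )
    return compute_activity(bundle.mrna, sets)


def fit_generalized(
    cohorts: Sequence[CohortBundle],
    regulons: RegulonTable,
    tfs: Sequence[str],
    seed: int = 0,
    n_repeats: int = 1,
    train_frac: float = 0.8,
    external_cohorts: Sequence[CohortBundle] = (),
    confidence: str = "A",
    alpha: float = 0.001,
    fold: float = 2.0,
    free_tfs: Sequence[str] = ("BRD4",),
) -> GeneralizationResult:
    """Pool cohorts, fit on a random training split, evaluate elsewhere.

    Per repeat (seeds spawned deterministically from ``seed``): split the
    pooled patients train/test, run constrained selection on the training
    pool, and report the fraction of test and external-cohort patients
    predicted within the two-fold band.  Coefficient dispersion across
    repeats indicates model stability.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    designs = [_tf_design(b, regulons, tfs, confidence) for b in cohorts]
    tf_sets = {tuple(d.index) for d in designs}
    if len(tf_sets) != 1:
        raise ValueError("TF sets inconsistent across cohorts")
    pooled_X = pd.concat([d.T for d in designs], axis=0)
    pooled_y = pd.concat([b.target_expression for b in cohorts])
    if pooled_X.index.duplicated().any():
        raise ValueError("cohorts share sample ids; cannot pool")

    spec = DesignSpec.nonnegative(list(pooled_X.columns), free=free_tfs)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(seed).spawn(n_repeats)]
    repeats = []
    coef_rows = []
    for rep_seed in seeds:
        train, test = split_train_test(list(pooled_X.index), train_frac, rep_seed)
        fit = select_model(pooled_y.loc[train], pooled_X.loc[train], spec, alpha=alpha)
        band = {
            "test": _twofold_band_fraction(fit, pooled_y.loc[test], pooled_X.loc[test], fold)
        }
        for i, ext in enumerate(external_cohorts):
            ext_X = _tf_design(ext, regulons, tfs, confidence).T
            band[f"external_{i}"] = _twofold_band_fraction(
                fit, ext.target_expression, ext_X, fold
            )
        repeats.append(
            {"seed": rep_seed, "train_ids": train, "test_ids": test, "fit": fit,
             "band_fractions": band}
        )
        row = {"seed": rep_seed, "beta0": fit.beta0}
        row.update(fit.betas.to_dict())
        coef_rows.append(row)
    return GeneralizationResult(
        repeats=repeats, coefficient_table=pd.DataFrame(coef_rows).fillna(0.0)
    )


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``simulation`` is given (a synthetic cohort is generated) or the
    caller passes a prebuilt bundle + regulons to :func:`run_pipeline`.
    """

    simulation: Optional[SimulationConfig] = None
    tfs: Optional[List[str]] = None  # default: all TFs in the regulon table
    confidence: str = "A"
    free_tfs: Tuple[str, ...] = ("BRD4",)
    alpha_tf: float = 0.001
    alpha_combined: float = 0.01
    fold: float = 2.0
    mutation_p_max: float = 0.01
    mutation_fc_min: float = 1.5
    mutation_prevalence_min: float = 0.01
    mirna_p_max: float = 0.01
    n_quantiles: int = 4
    outdir: Optional[str] = None


@dataclass
class PipelineResult:
    """Everything one pipeline run computed."""

    config: PipelineConfig
    activity: pd.DataFrame
    tf_fit: FitResult
    tf_vif: Optional[pd.DataFrame]
    classification: PredictionClassification
    fractions: Dict[str, float]
    critical_genes: Dict[str, CriticalGeneSet]  # keyed by basis
    critical_mirnas: Dict[str, CriticalMiRNASet]
    mutation_counts: Optional[pd.Series]
    burden_comparison: Optional[tuple]
    mirna_average: Optional[pd.Series]
    quantiles: Optional[QuantileAssignment]
    mirna_fit: Optional[FitResult]
    combined_fit: Optional[FitResult]
    attribution: Optional[pd.DataFrame]
    summary: Optional[AttributionSummary]
    contributions_mean: Optional[pd.Series]

    def summary_dict(self) -> dict:
        out = {
            "tf_model": self.tf_fit.to_dict(),
            "group_fractions": self.fractions,
            "n_critical_genes": {b: len(s.genes) for b, s in self.critical_genes.items()},
            "n_critical_mirnas": {
                b: len(s.mirna_ids) for b, s in self.critical_mirnas.items()
            },
        }
        if self.summary is not None:
            out["attribution"] = {
                "underpredicted_fractions": self.summary.underpredicted_fractions,
                "cohort_fractions": self.summary.cohort_fractions,
                "n_underpredicted": self.summary.n_underpredicted,
                "n_total": self.summary.n_total,
            }
        if self.combined_fit is not None:
            out["combined_model"] = self.combined_fit.to_dict()
        if self.mirna_fit is not None:
            out["mirna_model"] = self.mirna_fit.to_dict()
        return out


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run_pipeline(
    config: PipelineConfig,
    bundle: Optional[CohortBundle] = None,
    regulons: Optional[RegulonTable] = None,
) -> PipelineResult:
    """Execute every stage on one cohort and optionally write artifacts.

    Outputs under ``config.outdir`` (when set): activity matrix, fit JSONs,
    per-patient predictions/labels, critical gene/miRNA tables, attribution
    records, attribution summary, and a run log with thresholds and seeds.
    Reruns with the same config and seed produce identical bytes.
    """

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(f"stage {name!r}: {exc}") from exc
                return False

        return _Ctx()

    truth = None
    if bundle is None:
        with stage("simulate"):
            if config.simulation is None:
                raise ValueError("no bundle given and no simulation configured")
            bundle, truth = simulate_cohort(config.simulation)
            regulons = truth.regulons
    if regulons is None:
        raise ValueError("regulon table required when passing a prebuilt bundle")

    tfs = config.tfs if config.tfs is not None else regulons.tf_names
    y = bundle.target_expression

    with stage("activity"):
        activity = _tf_design(bundle, regulons, tfs, config.confidence)

    with stage("fit"):
        spec = DesignSpec.nonnegative(list(activity.index), free=config.free_tfs)
        tf_fit = select_model(y, activity.T, spec, alpha=config.alpha_tf)
        tf_vif = (
            vif(activity.T.loc[:, tf_fit.selected]).table
            if len(tf_fit.selected) >= 2
            else None
        )
        contrib_mean = (
            contributions(tf_fit, activity.T, y=y).mean if tf_fit.selected else None
        )

    with stage("classify"):
        classification = classify_patients(y, predict(tf_fit, activity.T), config.fold)
        fractions = group_fractions(classification)
        accurate = classification.samples_with("accurate")

    critical_genes: Dict[str, CriticalGeneSet] = {}
    mutation_counts = burden = None
    if bundle.mutations is not None:
        with stage("mutations"):
            for basis, subset in (("accurate_only", accurate), ("all_patients", None)):
                critical_genes[basis] = discover_critical_genes(
                    y,
                    bundle.mutations,
                    subset=subset,
                    p_max=config.mutation_p_max,
                    fc_min=config.mutation_fc_min,
                    prevalence_min=config.mutation_prevalence_min,
                    basis=basis,
                )
            mutation_counts = count_critical(bundle.mutations, critical_genes["all_patients"])
            if classification.samples_with("underpredicted") and accurate:
                burden = compare_group_burden(mutation_counts, classification)

    critical_mirnas: Dict[str, CriticalMiRNASet] = {}
    mirna_average = quantiles = mirna_fit = None
    if bundle.mirna is not None:
        with stage("mirnas"):
            for basis, subset in (("accurate_only", accurate), ("all_patients", None)):
                critical_mirnas[basis] = discover_critical_mirnas(
                    y,
                    bundle.mirna,
                    subset=subset,
                    p_max=config.mirna_p_max,
                    basis=basis,
                )
            population_set = critical_mirnas["all_patients"]
            if population_set.mirna_ids:
                mirna_average = average_critical_expression(bundle.mirna, population_set)
                quantiles = assign_quantiles(mirna_average, k=config.n_quantiles)
                mirna_fit = fit_mirna_model(y, mirna_average)

    combined_fit = None
    if mutation_counts is not None and mirna_average is not None:
        with stage("combined"):
            combined_fit = fit_combined(
                y,
                activity,
                mutation_counts,
                mirna_average,
                alpha=config.alpha_combined,
                free_tfs=config.free_tfs,
            )

    attribution = summary = None
    if mutation_counts is not None and quantiles is not None:
        with stage("attribute"):
            attribution, summary = attribute_patients(
                classification, mutation_counts, quantiles
            )

    result = PipelineResult(
        config=config,
        activity=activity,
        tf_fit=tf_fit,
        tf_vif=tf_vif,
        classification=classification,
        fractions=fractions,
        critical_genes=critical_genes,
        critical_mirnas=critical_mirnas,
        mutation_counts=mutation_counts,
        burden_comparison=burden,
        mirna_average=mirna_average,
        quantiles=quantiles,
        mirna_fit=mirna_fit,
        combined_fit=combined_fit,
        attribution=attribution,
        summary=summary,
        contributions_mean=contrib_mean,
    )
    if config.outdir is not None:
        with stage("write"):
            _write_outputs(result, bundle, truth, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, bundle, truth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.activity.to_csv(outdir / "tf_activity.tsv", sep="\t")
    result.classification.frame.to_csv(outdir / "prediction_labels.tsv", sep="\t")
    for basis, cset in result.critical_genes.items():
        cset.table.to_csv(outdir / f"critical_genes_{basis}.tsv", sep="\t", index=False)
    for basis, mset in result.critical_mirnas.items():
        mset.table.to_csv(outdir / f"critical_mirnas_{basis}.tsv", sep="\t", index=False)
    if result.mutation_counts is not None:
        result.mutation_counts.rename("critical_mutation_count").to_csv(
            outdir / "mutation_burden.tsv", sep="\t"
        )
    if result.quantiles is not None:
        pd.DataFrame(
            {"average": result.quantiles.averages, "quantile": result.quantiles.labels}
        ).to_csv(outdir / "mirna_quantiles.tsv", sep="\t")
    if result.attribution is not None:
        result.attribution.to_csv(outdir / "attribution.tsv", sep="\t")
    if result.tf_vif is not None:
        result.tf_vif.to_csv(outdir / "vif.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary_dict(), fh, indent=2, sort_keys=True, default=float)
    log = {
        "package_version": __version__,
        "thresholds": {
            k: v
            for k, v in dataclasses.asdict(result.config).items()
            if k not in ("simulation", "outdir")
        },
        "seed": result.config.simulation.seed if result.config.simulation else None,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json())
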