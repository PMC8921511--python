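"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: latent per-patient TF activities drive disjoint blocks of target
genes; the dependent gene (named ``CD274``) is a linear combination of a
subset of those activities, plus additive shifts for carriers of a few
"effect" mutations, plus negative contributions from a few repressive
miRNAs, plus Gaussian noise on the log2 scale.  Everything is generated
directly in log2(x + 1) units (unit_tag ``"synthetic"``); no round trip
through FPKM/RPM is attempted.

miRNA effects act on the deviation of a miRNA's level from its population
mean, so the overall expression level of the dependent gene does not depend
on how many repressors are modeled — only patients with atypically low or
high repressor abundance are shifted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort_io import (
    CohortBundle,
    CohortValidationError,
    ExpressionMatrix,
    MutationEventTable,
    RegulonTable,
)

__all__ = ["SimulationConfig", "SyntheticGroundTruth", "simulate_cohort", "null_cohort", "DEFAULT_TF_NAMES"]

#: the ten PD-L1-associated TFs used as default regulators
DEFAULT_TF_NAMES = (
    "MYC", "HIF1A", "HIF2A", "JUN", "IRF1",
    "STAT1", "STAT3", "NFKB", "NRF2", "BRD4",
)

TARGET_GENE = "CD274"


def _default_beta() -> Dict[str, float]:
    return {"IRF1": 0.6, "STAT1": 0.5, "NFKB": 0.8}


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic cohort.

    Defaults describe the reference study conditions: 1000 patients, ten
    candidate TFs of which IRF1/STAT1/NFKB truly drive the dependent gene,
    latent activities ~ Normal(4, 1) log2 units, per-target measurement
    noise 0.5, response noise sigma = 1.0, mutations at 3% prevalence
    adding +1.5 log2 units each, and five repressive miRNAs at -0.3 per
    log2 unit of (centered) abundance.
    """

    n_patients: int = 1000
    tf_names: Tuple[str, ...] = DEFAULT_TF_NAMES
    targets_per_tf: int = 20
    true_beta: Dict[str, float] = field(default_factory=_default_beta)
    intercept: float = -4.0
    noise_sigma: float = 1.0
    activity_mean: float = 4.0
    activity_sd: float = 1.0
    target_noise_sd: float = 0.5
    n_effect_genes: int = 10
    mutation_prevalence: float = 0.03
    mutation_effect: float = 1.5
    n_background_genes: int = 200
    n_effect_mirnas: int = 5
    n_background_mirnas: int = 200
    mirna_effect: float = -0.3
    mirna_mean: float = 4.0
    mirna_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "targets_per_tf": self.targets_per_tf,
            "n_effect_genes": self.n_effect_genes,
            "n_background_genes": self.n_background_genes,
            "n_effect_mirnas": self.n_effect_mirnas,
            "n_background_mirnas": self.n_background_mirnas,
        }
        for name, value in counts.items():
            if value < 0:
                raise CohortValidationError(f"{name} must be >= 0, got {value}")
        if self.n_patients < 1:
            raise CohortValidationError("n_patients must be >= 1")
        if self.noise_sigma <= 0:
            raise CohortValidationError("noise_sigma must be > 0")
        if not 0 < self.mutation_prevalence < 1:
            raise CohortValidationError("mutation_prevalence must be in (0, 1)")
        for tf, beta in self.true_beta.items():
            if tf not in self.tf_names:
                raise CohortValidationError(f"true_beta refers to unknown TF {tf!r}")
            if beta < 0 and tf != "BRD4":
                raise CohortValidationError(
                    f"negative true_beta only allowed for BRD4, got {tf}={beta}"
                )
        if self.mirna_effect > 0:
            raise CohortValidationError("mirna_effect must be <= 0 (repressors)")


@dataclass
class SyntheticGroundTruth:
    """Generating parameters plus the realized latent state of a cohort."""

    config: SimulationConfig
    activities: pd.DataFrame  # tf x patient latent activities
    effect_genes: List[str]
    effect_mirnas: List[str]
    mutation_effect: float
    mirna_effect: float
    regulons: RegulonTable

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "effect_genes": self.effect_genes,
            "effect_mirnas": self.effect_mirnas,
            "mutation_effect": self.mutation_effect,
            "mirna_effect": self.mirna_effect,
        }
        payload["config"]["tf_names"] = list(self.config.tf_names)
        return json.dumps(payload, indent=2, sort_keys=True)


def _target_name(tf: str, k: int) -> str:
    return f"{tf}_T{k:02d}"


def simulate_cohort(config: SimulationConfig) -> Tuple[CohortBundle, SyntheticGroundTruth]:
    """Draw one cohort; the same seed reproduces it bit-for-bit.

    All randomness flows through a single ``numpy.random.default_rng``
    stream seeded with ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    samples = [f"P{i:05d}" for i in range(n)]
    tfs = list(config.tf_names)

    # latent activities, one row per TF
    activities = pd.DataFrame(
        rng.normal(config.activity_mean, config.activity_sd, size=(len(tfs), n)),
        index=tfs,
        columns=samples,
    )

    # disjoint target blocks: each target = its TF's activity + noise
    target_rows, target_names, regulon_records = [], [], []
    for tf in tfs:
        for k in range(config.targets_per_tf):
            name = _target_name(tf, k)
            target_names.append(name)
            regulon_records.append((tf, name, "A"))
            target_rows.append(
                activities.loc[tf].to_numpy()
                + rng.normal(0.0, config.target_noise_sd, size=n)
            )
    regulons = RegulonTable(
        pd.DataFrame(regulon_records, columns=["tf", "target", "confidence"])
    )

    # TF's own mRNA, a noisy readout of its activity (for correlation checks)
    tf_mrna = {
        tf: activities.loc[tf].to_numpy() + rng.normal(0.0, config.target_noise_sd, size=n)
        for tf in tfs
    }

    # mutations: sparse Bernoulli events; first n_effect_genes carry an effect
    gene_names = [f"MUTG_E{k:03d}" for k in range(config.n_effect_genes)] + [
        f"MUTG_B{k:03d}" for k in range(config.n_background_genes)
    ]
    mutations = None
    events = np.zeros((len(gene_names), n), dtype=np.int8)
    if gene_names:
        events = (
            rng.random(size=(len(gene_names), n)) < config.mutation_prevalence
        ).astype(np.int8)
        mutations = MutationEventTable(
            pd.DataFrame(events, index=gene_names, columns=samples)
        )
    effect_genes = gene_names[: config.n_effect_genes]

    # miRNAs: Normal levels floored at 0; first n_effect_mirnas repress CD274
    mirna_names = [f"miR-E{k:03d}" for k in range(config.n_effect_mirnas)] + [
        f"miR-B{k:03d}" for k in range(config.n_background_mirnas)
    ]
    mirna = None
    mirna_values = np.zeros((len(mirna_names), n))
    if mirna_names:
        mirna_values = np.maximum(
            rng.normal(config.mirna_mean, config.mirna_sd, size=(len(mirna_names), n)),
            0.0,
        )
        mirna = ExpressionMatrix(
            pd.DataFrame(mirna_values, index=mirna_names, columns=samples),
            "synthetic",
            log_transformed=True,
        )
    effect_mirnas = mirna_names[: config.n_effect_mirnas]

    # dependent gene
    y = np.full(n, config.intercept, dtype=float)
    for tf, beta in config.true_beta.items():
        y += beta * activities.loc[tf].to_numpy()
    if effect_genes:
        y += config.mutation_effect * events[: config.n_effect_genes].sum(axis=0)
    if effect_mirnas:
        centered = mirna_values[: config.n_effect_mirnas] - config.mirna_mean
        y += config.mirna_effect * centered.sum(axis=0)
    y += rng.normal(0.0, config.noise_sigma, size=n)

    mrna_values = np.vstack(
        [np.maximum(np.asarray(target_rows), 0.0)]
        + [np.maximum(np.asarray([tf_mrna[tf] for tf in tfs]), 0.0)]
        + [np.maximum(y, 0.0)[None, :]]
    )
    mrna = ExpressionMatrix(
        pd.DataFrame(
            mrna_values, index=target_names + tfs + [TARGET_GENE], columns=samples
        ),
        "synthetic",
        log_transformed=True,
    )

    bundle = CohortBundle(
        mrna=mrna, target_gene_id=TARGET_GENE, mirna=mirna, mutations=mutations
    )
    truth = SyntheticGroundTruth(
        config=config,
        activities=activities,
        effect_genes=effect_genes,
        effect_mirnas=effect_mirnas,
        mutation_effect=config.mutation_effect,
        mirna_effect=config.mirna_effect,
        regulons=regulons,
    )
    return bundle, truth


def null_cohort(config: SimulationConfig) -> Tuple[CohortBundle, SyntheticGroundTruth]:
    """A cohort where neither mutations nor miRNAs affect the dependent gene.

    All would-be effect genes/miRNAs are regenerated as background features,
    so discovery stages can be checked for type-I-error control.
    """
    null_config = dataclasses.replace(
        config,
        n_effect_genes=0,
        n_background_genes=config.n_background_genes + config.n_effect_genes,
        n_effect_mirnas=0,
        n_background_mirnas=config.n_background_mirnas + config.n_effect_mirnas,
    )
    return simulate_cohort(null_config)
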