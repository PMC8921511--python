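"""Reading, normalizing and aligning the cohort inputs.

A cohort consists of up to four components: an mRNA expression matrix
(FPKM-normalized), an optional miRNA expression matrix (RPM-normalized), an
optional table of somatic mutation events derived from a MAF file, and the
identifier of the dependent gene whose expression the downstream models try
to explain (CD274/PD-L1 in the motivating application).

All expression values are analyzed on the log2(x + 1) scale; matrices are
oriented features x samples throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GRADES = frozenset("ABCDE")

__all__ = [
    "ExpressionMatrix",
    "MutationEventTable",
    "RegulonTable",
    "CohortBundle",
    "log2p1_transform",
    "read_expression_table",
    "read_maf_events",
    "read_regulon_table",
    "align_cohort",
]


class CohortValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise CohortValidationError(f"duplicate {what}: {dups}")


def _check_nonneg_finite(values: pd.DataFrame, what: str) -> None:
    arr = values.to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CohortValidationError(
            f"non-finite value in {what} at feature "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )
    neg = arr < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise CohortValidationError(
            f"negative value {arr[i, j]!r} in {what} at feature "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )


@dataclass
class ExpressionMatrix:
    """A features x samples abundance matrix.

    ``values`` rows are feature ids (genes or miRNAs), columns are sample
    ids.  ``unit_tag`` records the pre-transform normalization (``"FPKM"``
    for mRNA, ``"RPM"`` for miRNA, ``"synthetic"`` for simulated data) and
    ``log_transformed`` whether :func:`log2p1_transform` has been applied.
    Values must be finite and non-negative in either state, since raw
    abundances are non-negative and log2(x + 1) maps them to [0, inf).
    """

    values: pd.DataFrame
    unit_tag: str
    log_transformed: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        _check_nonneg_finite(self.values, f"{self.unit_tag} expression matrix")

    @property
    def feature_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)], self.unit_tag, self.log_transformed
        )


@dataclass
class MutationEventTable:
    """Binary gene x sample matrix of somatic mutation events.

    An entry of 1 means the patient carries at least one somatic mutation in
    the gene; multiple MAF records for the same (patient, gene) pair collapse
    to a single event, and mutation type/position are deliberately ignored.
    """

    events: pd.DataFrame  # genes x samples, entries in {0, 1}

    def __post_init__(self) -> None:
        _check_unique(self.events.index, "gene ids")
        _check_unique(self.events.columns, "sample ids")
        arr = self.events.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise CohortValidationError("mutation events must be binary 0/1")

    @property
    def gene_ids(self) -> list:
        return self.events.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.events.columns.tolist()

    def subset_samples(self, samples: Sequence[str]) -> "MutationEventTable":
        return MutationEventTable(self.events.loc[:, list(samples)])


@dataclass
class RegulonTable:
    """(tf, target, confidence) records mapping TFs to their target genes."""

    records: pd.DataFrame  # columns: tf, target, confidence

    def __post_init__(self) -> None:
        required = {"tf", "target", "confidence"}
        missing = required - set(self.records.columns)
        if missing:
            raise CohortValidationError(f"regulon table missing columns: {sorted(missing)}")
        bad = set(self.records["confidence"]) - VALID_GRADES
        if bad:
            raise CohortValidationError(
                f"invalid confidence grades {sorted(bad)}; allowed: A-E"
            )
        if self.records.duplicated(["tf", "target"]).any():
            dup = self.records[self.records.duplicated(["tf", "target"])]
            raise CohortValidationError(
                f"duplicate (tf, target) pairs, e.g. {dup.iloc[0][['tf', 'target']].tolist()}"
            )

    @property
    def tf_names(self) -> list:
        return sorted(self.records["tf"].unique())


@dataclass
class CohortBundle:
    """All cohort components restricted to a common, identically ordered
    set of samples."""

    mrna: ExpressionMatrix
    target_gene_id: str
    mirna: Optional[ExpressionMatrix] = None
    mutations: Optional[MutationEventTable] = None
    n_dropped: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list:
        return self.mrna.sample_ids

    @property
    def target_expression(self) -> pd.Series:
        """log2(x+1) expression of the dependent gene across samples."""
        return self.mrna.values.loc[self.target_gene_id]


def log2p1_transform(
    raw: Union[pd.DataFrame, ExpressionMatrix], unit_tag: Optional[str] = None
) -> ExpressionMatrix:
    """Apply the log2(x + 1) transform to a raw abundance matrix.

    The pseudo-count of 1 retains zeros: log2(0 + 1) = 0.  The transform is
    strictly monotone and invertible (inverse: 2**v - 1).
    """
    if isinstance(raw, ExpressionMatrix):
        if raw.log_transformed:
            raise CohortValidationError("matrix is already log2(x+1)-transformed")
        values, unit_tag = raw.values, raw.unit_tag
    else:
        values = raw
        if unit_tag is None:
            raise CohortValidationError("unit_tag required for a bare DataFrame")
    _check_nonneg_finite(values, f"raw {unit_tag} matrix")
    return ExpressionMatrix(np.log2(values + 1.0), unit_tag, log_transformed=True)


def read_expression_table(path: Union[str, Path], unit_tag: str) -> ExpressionMatrix:
    """Read a features x samples TSV (header = sample ids, first column =
    feature ids) into an untransformed :class:`ExpressionMatrix`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(f"{path}: no features (empty file)") from None
    except pd.errors.ParserError as exc:  # pandas messages include line numbers
        raise CohortValidationError(f"{path}: {exc}") from None
    if frame.shape[0] == 0:
        raise CohortValidationError(f"{path}: no features")
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            row = bad[0] if len(bad) else frame.index[frame[col].isna()][0]
            # +2: one for the header line, one for 1-based numbering
            line = frame.index.get_loc(row) + 2
            raise CohortValidationError(
                f"{path}: non-numeric value in column {col!r}, feature {row!r} (line {line})"
            )
    return ExpressionMatrix(frame, unit_tag, log_transformed=False)


MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode")


def read_maf_events(path: Union[str, Path]) -> MutationEventTable:
    """Collapse a MAF file to a binary gene x patient event matrix.

    Only ``Hugo_Symbol`` and ``Tumor_Sample_Barcode`` are used; mutation
    type and position are ignored, and any number of records for the same
    (patient, gene) pair counts as one mutational event.
    """
    path = Path(path)
    try:
        maf = pd.read_csv(path, sep="\t", comment="#", low_memory=False)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(f"{path}: no records (empty MAF)") from None
    missing = [c for c in MAF_REQUIRED if c not in maf.columns]
    if missing:
        raise CohortValidationError(f"{path}: MAF missing mandatory columns {missing}")
    if maf.shape[0] == 0:
        raise CohortValidationError(f"{path}: no records")
    pairs = maf[list(MAF_REQUIRED)].astype(str).apply(lambda s: s.str.strip())
    events = (
        pd.crosstab(pairs["Hugo_Symbol"], pairs["Tumor_Sample_Barcode"])
        .clip(upper=1)
        .astype(np.int8)
    )
    events.index.name = None
    events.columns.name = None
    return MutationEventTable(events)


def read_regulon_table(path: Union[str, Path]) -> RegulonTable:
    """Read a TSV with columns ``tf``, ``target``, ``confidence``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in frame.columns:
        frame[col] = frame[col].str.strip()
    return RegulonTable(frame)


def align_cohort(
    mrna: ExpressionMatrix,
    target_gene_id: str,
    mirna: Optional[ExpressionMatrix] = None,
    mutations: Optional[MutationEventTable] = None,
) -> CohortBundle:
    """Restrict all components to the samples they share.

    Sample order of the bundle follows the mRNA matrix.  Only patients with
    every provided data kind are retained, mirroring the requirement that
    both mutation spectrum and RNA-seq data be available per patient.
    """
    if target_gene_id not in mrna.values.index:
        raise CohortValidationError(
            f"target gene {target_gene_id!r} absent from mRNA matrix"
        )
    common = set(mrna.sample_ids)
    for comp in (mirna, mutations):
        if comp is not None:
            common &= set(comp.sample_ids)
    if not common:
        raise CohortValidationError("no samples shared by all cohort components")
    order = [s for s in mrna.sample_ids if s in common]

    n_dropped = {"mrna": len(mrna.sample_ids) - len(order)}
    bundle_mirna = bundle_mut = None
    if mirna is not None:
        n_dropped["mirna"] = len(mirna.sample_ids) - len(order)
        bundle_mirna = mirna.subset_samples(order)
    if mutations is not None:
        n_dropped["mutations"] = len(mutations.sample_ids) - len(order)
        bundle_mut = mutations.subset_samples(order)
    for name, n in n_dropped.items():
        if n:
            logger.info("align_cohort: dropped %d samples from %s", n, name)
    return CohortBundle(
        mrna=mrna.subset_samples(order),
        target_gene_id=target_gene_id,
        mirna=bundle_mirna,
        mutations=bundle_mut,
        n_dropped=n_dropped,
    )
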