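"""Residual-based patient stratification.

Patients are partitioned by how far observed expression deviates from the
model prediction.  "Two-fold" is interpreted on the expression scale, which
on stored log2(x + 1) values is a gap of log2(fold) = 1 log2 unit: a
patient whose observed value exceeds the prediction by more than that gap
is *underpredicted* (the model cannot account for their high expression),
the mirror case is *overpredicted*, everyone else is *accurate*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

__all__ = ["PredictionClassification", "classify_patients", "group_fractions", "LABELS"]

LABELS = ("accurate", "underpredicted", "overpredicted")


@dataclass
class PredictionClassification:
    """Per-patient observed/predicted values, their gap, and the label."""

    frame: pd.DataFrame  # columns: observed, predicted, delta, label
    fold: float

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def samples_with(self, label: str) -> list:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return list(self.frame.index[self.frame["label"] == label])


def classify_patients(
    observed: pd.Series, predicted: pd.Series, fold: float = 2.0
) -> PredictionClassification:
    """Label each patient by the observed-minus-predicted gap.

    underpredicted: observed - predicted > log2(fold)
    overpredicted:  predicted - observed > log2(fold)
    accurate otherwise.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if not observed.index.equals(predicted.index):
        predicted = predicted.reindex(observed.index)
    obs = observed.to_numpy(dtype=float)
    pred = predicted.to_numpy(dtype=float)
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("observed/predicted values must be finite")
    delta = obs - pred
    gap = np.log2(fold)
    label = np.where(
        delta > gap, "underpredicted", np.where(-delta > gap, "overpredicted", "accurate")
    )
    frame = pd.DataFrame(
        {"observed": obs, "predicted": pred, "delta": delta, "label": label},
        index=observed.index,
    )
    return PredictionClassification(frame=frame, fold=fold)


def group_fractions(classification: PredictionClassification) -> Dict[str, float]:
    """Fraction of patients per label; fractions sum to 1."""
    n = len(classification.frame)
    if n == 0:
        raise ValueError("empty classification")
    counts = classification.frame["label"].value_counts()
    return {label: counts.get(label, 0) / n for label in LABELS}
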