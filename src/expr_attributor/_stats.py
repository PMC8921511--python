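"""Shared statistical helpers."""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import stats

__all__ = ["mann_whitney"]

EXACT_MAX_ARM = 8


def mann_whitney(x, y) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test, (U, p).

    Small untied samples (both arms <= 8) use exact enumeration so toy
    examples are reproducible; otherwise the normal approximation with tie
    correction and continuity correction is used (exact enumeration is not
    valid under ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    small = max(len(x), len(y)) <= EXACT_MAX_ARM
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
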