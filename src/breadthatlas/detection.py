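"""Expression detection against a negative-control quantile and breadth classes.

A gene is called expressed in a tissue when its (replicate-averaged,
probe-collapsed) normalized intensity is strictly greater than the 99%
quantile of all valid negative-control spot intensities pooled across all
arrays. The number of tissues where a gene is called expressed is its
*breadth*; breadth 0 is silent, breadth 1 tissue-specific, breadth T (all
tissues) housekeeping, anything between is intermediate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .microarray import NegativeControls

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_SILENT",
    "CLASS_TISSUE_SPECIFIC",
    "CLASS_INTERMEDIATE",
    "CLASS_HOUSEKEEPING",
    "DetectionResult",
    "detection_threshold",
    "call_expressed",
    "classify_breadth",
    "detect",
]

CLASS_SILENT = "silent"
CLASS_TISSUE_SPECIFIC = "tissue-specific"
CLASS_INTERMEDIATE = "intermediate"
CLASS_HOUSEKEEPING = "housekeeping"


@dataclass
class DetectionResult:
    """Detection threshold with per-gene calls, breadth and class labels."""

    threshold: float
    calls: pd.DataFrame          # gene x tissue booleans
    breadth: pd.Series           # gene -> int in 0..T
    labels: pd.Series            # gene -> breadth class
    histogram: pd.Series         # breadth value (0..T) -> gene count

    @property
    def n_tissues(self) -> int:
        return self.calls.shape[1]

    @property
    def n_expressed(self) -> int:
        """Genes expressed in at least one tissue."""
        return int((self.breadth > 0).sum())

    def class_counts(self) -> pd.Series:
        order = [CLASS_SILENT, CLASS_TISSUE_SPECIFIC, CLASS_INTERMEDIATE,
                 CLASS_HOUSEKEEPING]
        return self.labels.value_counts().reindex(order, fill_value=0)


def detection_threshold(controls: NegativeControls, q: float = 0.99) -> float:
    """q-quantile of pooled valid negative-control intensities.

    Linear interpolation between order statistics (the type-7 convention,
    h = (n-1)q + 1), the default in both major stats ecosystems.
    """
    if not 0.0 < q < 1.0:
        raise InputError(f"quantile q must lie in (0, 1), got {q!r}")
    values = controls.valid_values()
    if values.size == 0:
        raise InputError("no valid negative-control values")
    if values.size < 100:
        warnings.warn(
            f"only {values.size} valid control spots; quantile estimate is noisy",
            stacklevel=2,
        )
    return float(np.quantile(values, q, method="linear"))


def call_expressed(gene_tissue: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Boolean calls: strictly greater than the threshold ("higher than").

    Missing values (all contributing spots invalid) call False; the count is
    logged since silent-by-missingness differs from silent-by-intensity.
    """
    n_missing = int(gene_tissue.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%d missing gene x tissue cells call not-expressed", n_missing)
    return gene_tissue.gt(threshold).fillna(False).astype(bool)


def classify_breadth(calls: pd.DataFrame, n_tissues: int | None = None):
    """Per-gene breadth, class labels, and the breadth histogram over 0..T."""
    T = int(n_tissues) if n_tissues is not None else calls.shape[1]
    if calls.shape[1] != T:
        raise InputError(f"calls have {calls.shape[1]} tissues, expected {T}")
    breadth = calls.sum(axis=1).astype(int)
    labels = pd.Series(CLASS_INTERMEDIATE, index=calls.index, name="label")
    labels[breadth == 0] = CLASS_SILENT
    labels[breadth == 1] = CLASS_TISSUE_SPECIFIC
    labels[breadth == T] = CLASS_HOUSEKEEPING
    histogram = (
        breadth.value_counts().reindex(range(T + 1), fill_value=0).rename("n_genes")
    )
    histogram.index.name = "breadth"
    return breadth.rename("breadth"), labels, histogram


def detect(
    gene_tissue: pd.DataFrame, controls: NegativeControls, q: float = 0.99
) -> DetectionResult:
    """Threshold, call, and classify in one step."""
    threshold = detection_threshold(controls, q=q)
    calls = call_expressed(gene_tissue, threshold)
    breadth, labels, histogram = classify_breadth(calls)
    return DetectionResult(threshold, calls, breadth, labels, histogram)
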