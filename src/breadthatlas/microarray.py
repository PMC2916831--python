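"""Microarray intensity I/O: spot-flag weighting, replicate and probe averaging.

The processing contract follows common two-colour array practice: any spot
flagged bad by the scanner software (GenePix FLAG < -50) gets weight 0.01 and
is treated as missing downstream; expression is first averaged over biological
replicates within each tissue, then probes targeting the same gene are
averaged. Averages are arithmetic means over the valid (weight-1) cells only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "BAD_FLAG_THRESHOLD",
    "LOW_WEIGHT",
    "FULL_WEIGHT",
    "ExpressionMatrix",
    "NegativeControls",
    "apply_flag_weights",
    "average_replicates",
    "collapse_probes",
    "read_matrix_tsv",
    "read_sample_meta",
    "read_probe_map",
    "read_negative_controls",
]

#: spots with FLAG strictly below this are "bad" and effectively excluded
BAD_FLAG_THRESHOLD = -50
LOW_WEIGHT = 0.01
FULL_WEIGHT = 1.0


def apply_flag_weights(raw_flags: pd.DataFrame) -> pd.DataFrame:
    """Map integer spot flags to validity weights.

    FLAG < -50 (flagged "bad spot") -> 0.01, anything else -> 1. Cells with
    weight 0.01 are removed from all further analysis (treated as missing).
    """
    if raw_flags is None or raw_flags.size == 0:
        raise FormatError("flag table is empty or missing")
    flags = raw_flags.to_numpy()
    if not np.all(np.isfinite(flags)):
        raise FormatError("flags must be finite integers")
    weights = np.where(flags < BAD_FLAG_THRESHOLD, LOW_WEIGHT, FULL_WEIGHT)
    return pd.DataFrame(weights, index=raw_flags.index, columns=raw_flags.columns)


@dataclass
class ExpressionMatrix:
    """Normalized intensities (probes-or-genes x samples) with metadata.

    ``sample_meta`` is indexed by sample ID with columns ``tissue`` and
    ``replicate``; ``weights`` has the same shape as ``values`` with entries
    in {0.01, 1}.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = pd.DataFrame(
                FULL_WEIGHT, index=self.values.index, columns=self.values.columns
            )
        if self.values.shape != self.weights.shape:
            raise InputError(
                f"values {self.values.shape} and weights {self.weights.shape} "
                "dimensions disagree"
            )
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise InputError(f"samples without tissue metadata: {sorted(missing)[:5]}")
        if "tissue" not in self.sample_meta.columns:
            raise FormatError("sample metadata requires a 'tissue' column")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise InputError("intensities must be finite")

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_meta.loc[s, "tissue"], None)
        return list(seen)

    def masked_values(self) -> pd.DataFrame:
        """Values with low-weight cells replaced by NaN."""
        return self.values.where(self.weights.to_numpy() >= FULL_WEIGHT)


@dataclass
class NegativeControls:
    """Negative-control spot intensities pooled across all arrays."""

    intensities: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.weights is None:
            self.weights = np.full(self.intensities.shape, FULL_WEIGHT)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.intensities.shape != self.weights.shape:
            raise InputError("control intensities and weights differ in length")
        if self.valid_values().size == 0:
            raise InputError("no valid negative-control measurements after weighting")

    def valid_values(self) -> np.ndarray:
        return self.intensities[self.weights >= FULL_WEIGHT]


def average_replicates(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Average valid replicate measurements within each tissue.

    Returns a probe-or-gene x tissue frame; a cell is NaN only if *all* of its
    replicate measurements were invalid.
    """
    masked = matrix.masked_values()
    tissue_of = matrix.sample_meta["tissue"]
    grouped = masked.T.groupby(tissue_of.loc[masked.columns]).mean()
    out = grouped.T
    # preserve first-appearance tissue order rather than alphabetical
    out = out[[t for t in matrix.tissues]]
    n_dead = int(out.isna().all(axis=1).sum())
    if n_dead:
        logger.warning(
            "%d probes have no valid measurement in any tissue", n_dead
        )
    return out


def collapse_probes(tissue_matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Average tissue-level probe values over probes targeting the same gene.

    ``probe_map`` maps probe ID -> gene ID (many-to-one allowed). Probes absent
    from the map are dropped with a warning; NaNs are ignored in the mean.
    """
    if probe_map.index.has_duplicates:
        dupes = probe_map.index[probe_map.index.duplicated()].unique()
        raise InputError(f"probes mapped to more than one gene: {list(dupes[:5])}")
    mapped = tissue_matrix.index.intersection(probe_map.index)
    if len(mapped) == 0:
        raise InputError("no probe in the matrix appears in the probe map")
    n_dropped = tissue_matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.warning("dropping %d unmapped probes", n_dropped)
    sub = tissue_matrix.loc[mapped]
    gene_ids = probe_map.loc[mapped]
    collapsed = sub.groupby(gene_ids.to_numpy()).mean()
    collapsed.index.name = "gene_id"
    return collapsed


# --- readers ---------------------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a probe x sample intensity (or flag) table with a header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    return df


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "tissue", "replicate"}
    if not required <= set(meta.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return meta.set_index("sample")


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns ['probe_id', 'gene_id']")
    return df.set_index("probe_id")["gene_id"]


def read_negative_controls(path) -> NegativeControls:
    """Read long-format control spots (control_id, sample, intensity, flag)."""
    df = pd.read_csv(path, sep="\t")
    if "intensity" not in df.columns:
        raise FormatError(f"{path}: expected an 'intensity' column")
    if "flag" in df.columns:
        w = np.where(df["flag"].to_numpy() < BAD_FLAG_THRESHOLD, LOW_WEIGHT, FULL_WEIGHT)
    else:
        w = None
    return NegativeControls(df["intensity"].to_numpy(), w)
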