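"""Cross-species expression conservation via relative mRNA abundance (RA).

Expression measured on different species-specific platforms is not directly
comparable; dividing each gene's expression in a tissue by the sum of its
expression over a shared tissue panel yields relative abundances that are.
An ortholog pair is called *conserved* when the correlation of its two RA
vectors exceeds the 95% quantile of correlations of random (non-orthologous)
cross-species gene pairs. Tissue-level similarity is the Spearman rank
correlation between species-tissue RA columns, with average-linkage
hierarchical clustering on 1 - rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import squareform

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "to_relative_abundance",
    "ConservationResult",
    "pair_conservation",
    "TissueSimilarity",
    "tissue_similarity",
    "nearest_cross_species_neighbors",
    "read_ortholog_table",
]


def to_relative_abundance(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a gene x tissue table to relative abundances.

    Each row is divided by its row sum so entries are >= 0 and sum to 1.
    Negative entries (normalized-scale artifacts) are clipped to 0 with a
    warning; rows whose sum is <= 0 are dropped with a logged count.
    """
    values = expr.to_numpy(dtype=float)
    n_negative = int((values < 0).sum())
    if n_negative:
        logger.warning("clipping %d negative expression entries to 0", n_negative)
        values = np.clip(values, 0.0, None)
    totals = values.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d genes with non-positive total expression", n_dropped)
    ra = values[keep] / totals[keep, None]
    return pd.DataFrame(ra, index=expr.index[keep], columns=expr.columns)


def _row_correlations(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Correlation between corresponding rows of two equal-shape arrays.

    Rows with zero variance on either side yield NaN.
    """
    if method == "spearman":
        a = stats.rankdata(a, axis=1)  # average ranks for ties
        b = stats.rankdata(b, axis=1)
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return r


@dataclass
class ConservationResult:
    """Per-ortholog-pair RA correlations against a random-pair null."""

    pairs: pd.DataFrame        # id_a, id_b, r, conserved
    null_correlations: np.ndarray
    null_quantile: float       # r0: the 95% quantile of the null
    conserved_fraction: float
    n_excluded: int            # pairs dropped for undefined correlation
    method: str

    @property
    def n_conserved(self) -> int:
        return int(self.pairs["conserved"].sum())


def pair_conservation(
    ra_a: pd.DataFrame,
    ra_b: pd.DataFrame,
    orthologs: pd.DataFrame,
    n_random_pairs: int = 10_000,
    seed: int = 0,
    method: str = "pearson",
    null_q: float = 0.95,
) -> ConservationResult:
    """Call conserved expression for ortholog pairs of two species.

    ``orthologs`` must have two columns: the species-A and species-B gene IDs.
    The null is built from ``n_random_pairs`` uniformly sampled cross-species
    gene pairs, excluding the true orthologous pairings; a pair is conserved
    when its RA correlation is strictly greater than the null's ``null_q``
    (default 95%) linear-interpolation quantile.
    """
    if ra_a.shape[1] < 2:
        raise InputError("need at least two common tissues")
    if list(ra_a.columns) != list(ra_b.columns):
        raise InputError("tissue panels differ between the two RA tables")
    orth = orthologs.iloc[:, :2].copy()
    orth.columns = ["id_a", "id_b"]
    present = orth["id_a"].isin(ra_a.index) & orth["id_b"].isin(ra_b.index)
    n_absent = int((~present).sum())
    if n_absent:
        logger.info("dropping %d ortholog pairs absent from the RA tables", n_absent)
    orth = orth[present].reset_index(drop=True)
    if orth.empty:
        raise InputError("no ortholog pair present in both RA tables")

    A = ra_a.loc[orth["id_a"]].to_numpy()
    B = ra_b.loc[orth["id_b"]].to_numpy()
    r = _row_correlations(A, B, method)
    defined = ~np.isnan(r)
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.warning("%d pairs with undefined correlation excluded", n_excluded)

    # random-pair null: uniform over cross-species index pairs (i, j), i != j,
    # which excludes the true orthologous pairings of this comparison
    rng = np.random.default_rng(seed)
    n = len(orth)
    idx_a = rng.integers(0, n, size=n_random_pairs)
    idx_b = rng.integers(0, n, size=n_random_pairs)
    clash = idx_a == idx_b
    while clash.any():
        idx_b[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = idx_a == idx_b
    null = _row_correlations(A[idx_a], B[idx_b], method)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise InputError("random-pair null is empty (all correlations undefined)")
    r0 = float(np.quantile(null, null_q, method="linear"))

    pairs = orth.assign(r=r, conserved=(r > r0) & defined)[defined].reset_index(
        drop=True
    )
    return ConservationResult(
        pairs=pairs,
        null_correlations=null,
        null_quantile=r0,
        conserved_fraction=float(pairs["conserved"].mean()),
        n_excluded=n_excluded,
        method=method,
    )


@dataclass
class TissueSimilarity:
    """Spearman similarity between species-tissue columns with clustering."""

    rho: pd.DataFrame          # (species:tissue) x (species:tissue)
    linkage_matrix: np.ndarray  # scipy average-linkage on 1 - rho
    leaf_order: list[str]


def tissue_similarity(ra_tables: dict[str, pd.DataFrame]) -> TissueSimilarity:
    """Tissue x tissue Spearman matrix across species, plus clustering.

    ``ra_tables`` maps species name to an RA table over the *same ortholog
    rows in the same order* (one row per ortholog group) and the same tissue
    panel. Columns are labelled ``species:tissue``.
    """
    species = list(ra_tables)
    n_rows = {sp: len(df) for sp, df in ra_tables.items()}
    if len(set(n_rows.values())) != 1:
        raise InputError(f"RA tables differ in row counts: {n_rows}")
    if min(n_rows.values()) < 3:
        raise InputError("need at least 3 shared ortholog rows")
    blocks = []
    labels = []
    for sp in species:
        df = ra_tables[sp]
        blocks.append(df.to_numpy())
        labels.extend(f"{sp}:{t}" for t in df.columns)
    stacked = np.hstack(blocks)
    rho_values = stats.spearmanr(stacked, axis=0).statistic
    rho = pd.DataFrame(np.atleast_2d(rho_values), index=labels, columns=labels)
    dist = squareform(np.clip(1.0 - rho.to_numpy(), 0.0, None), checks=False)
    Z = linkage(dist, method="average")
    order = [labels[i] for i in leaves_list(Z)]
    return TissueSimilarity(rho=rho, linkage_matrix=Z, leaf_order=order)


def nearest_cross_species_neighbors(rho: pd.DataFrame) -> pd.Series:
    """For each species:tissue column, its most-correlated other-species column.

    Useful to check that homologous tissues are each other's nearest
    cross-species neighbours.
    """
    out = {}
    for col in rho.columns:
        sp = col.split(":", 1)[0]
        others = [c for c in rho.columns if c.split(":", 1)[0] != sp]
        out[col] = rho.loc[col, others].idxmax()
    return pd.Series(out, name="nearest")


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a 1:1:1 ortholog table (one ID column per species).

    Any ID appearing in more than one row violates the 1:1 constraint.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"{path}: need at least two species ID columns")
    for col in df.columns:
        if col == "conserved":
            continue
        if df[col].duplicated().any():
            raise InputError(f"{path}: duplicate IDs in column {col}; not 1:1")
    return df
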