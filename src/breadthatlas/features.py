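"""Structural genomic features per gene and rank-based class comparisons.

Features computed per gene: gene length (span), coding-sequence length,
average exon length, average intron length (undefined for single-exon genes)
and intergenic length (mean of the gaps to the nearest flanking genes on the
same chromosome; single flank at chromosome ends). Distributions between
breadth classes are compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney U) test, with no multiple-testing correction.

Coordinates follow the GFF3 convention throughout this module: 1-based,
closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnnotationError, FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "FEATURE_COLUMNS",
    "compute_features",
    "RankSumResult",
    "rank_sum_test",
    "compare_classes",
    "write_gff3",
]

FEATURE_COLUMNS = (
    "gene_length",
    "cds_length",
    "mean_exon_length",
    "mean_intron_length",
    "intergenic_length",
)


@dataclass
class GeneAnnotation:
    """Gene models: spans plus per-gene exon and CDS intervals.

    ``genes`` is indexed by gene ID with columns ``chrom``, ``strand``,
    ``start``, ``end`` (1-based, closed). ``exons``/``cds`` map gene ID to
    sorted, non-overlapping interval lists.
    """

    genes: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]]
    cds: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        required = {"chrom", "strand", "start", "end"}
        if not required <= set(self.genes.columns):
            raise AnnotationError(f"gene table requires columns {sorted(required)}")
        bad = self.genes[self.genes["start"] > self.genes["end"]]
        if len(bad):
            raise AnnotationError(f"start > end for genes {list(bad.index[:5])}")
        for gid, ivs in self.exons.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise AnnotationError(f"overlapping exons in gene {gid}")
            span = self.genes.loc[gid]
            if ivs and (ivs[0][0] < span["start"] or ivs[-1][1] > span["end"]):
                raise AnnotationError(f"exons outside gene span for {gid}")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        """Read gene/mRNA/exon/CDS features; the first mRNA per gene is used."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=False,
            merge_strategy="error",
        )
        rows, exons, cds = [], {}, {}
        for gene in db.features_of_type("gene"):
            gid = gene.attributes.get("gene_id", [gene.id.split(":")[-1]])[0]
            rows.append((gid, gene.seqid, gene.strand, gene.start, gene.end))
            mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
            parent = mrnas[0] if mrnas else gene
            exons[gid] = [
                (f.start, f.end)
                for f in db.children(parent, featuretype="exon", order_by="start")
            ]
            cds[gid] = [
                (f.start, f.end)
                for f in db.children(parent, featuretype="CDS", order_by="start")
            ]
        if not rows:
            raise FormatError(f"{path}: no gene features found")
        genes = pd.DataFrame(
            rows, columns=["gene_id", "chrom", "strand", "start", "end"]
        ).set_index("gene_id")
        return cls(genes, exons, cds)


def write_gff3(annotation: GeneAnnotation, path) -> None:
    """Write gene/mRNA/exon/CDS features (1-based closed coordinates)."""
    order = annotation.genes.sort_values(["chrom", "start"]).index
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in order:
            g = annotation.genes.loc[gid]
            base = f"{g['chrom']}\tbreadthatlas\t"
            tail = f"\t.\t{g['strand']}\t"
            fh.write(
                f"{base}gene\t{g['start']}\t{g['end']}{tail}.\t"
                f"ID=gene:{gid};gene_id={gid}\n"
            )
            fh.write(
                f"{base}mRNA\t{g['start']}\t{g['end']}{tail}.\t"
                f"ID=mrna:{gid};Parent=gene:{gid}\n"
            )
            for i, (s, e) in enumerate(annotation.exons.get(gid, []), 1):
                fh.write(
                    f"{base}exon\t{s}\t{e}{tail}.\t"
                    f"ID=exon:{gid}.{i};Parent=mrna:{gid}\n"
                )
            for i, (s, e) in enumerate(annotation.cds.get(gid, []), 1):
                fh.write(
                    f"{base}CDS\t{s}\t{e}{tail}0\t"
                    f"ID=cds:{gid}.{i};Parent=mrna:{gid}\n"
                )


def _interval_total(ivs: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in ivs)


def compute_features(
    annotation: GeneAnnotation, intergenic: str = "mean"
) -> pd.DataFrame:
    """Per-gene structural feature table.

    ``intergenic`` selects how the two flanking gaps combine: ``"mean"``
    (default), ``"min"``, or ``"upstream"`` (strand-aware upstream gap).
    Genes alone on their chromosome get a missing intergenic length; lengths
    are strand-independent apart from the ``"upstream"`` option.
    """
    if intergenic not in {"mean", "min", "upstream"}:
        raise InputError(f"unknown intergenic mode {intergenic!r}")
    genes = annotation.genes
    out = pd.DataFrame(index=genes.index, columns=list(FEATURE_COLUMNS), dtype=float)
    out["gene_length"] = (genes["end"] - genes["start"] + 1).astype(float)
    for gid in genes.index:
        exons = annotation.exons.get(gid, [])
        out.at[gid, "cds_length"] = float(_interval_total(annotation.cds.get(gid, [])))
        if exons:
            out.at[gid, "mean_exon_length"] = _interval_total(exons) / len(exons)
            if len(exons) > 1:
                introns = [
                    (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])
                ]
                out.at[gid, "mean_intron_length"] = _interval_total(introns) / len(introns)

    # intergenic gaps from the sorted gene layout per chromosome
    for _, chrom_genes in genes.groupby("chrom", sort=False):
        ordered = chrom_genes.sort_values("start")
        starts = ordered["start"].to_numpy()
        ends = ordered["end"].to_numpy()
        n = len(ordered)
        if n < 2:
            continue  # single gene on chromosome: intergenic stays missing
        gaps = starts[1:] - ends[:-1] - 1  # bp strictly between adjacent spans
        if np.any(gaps < 0):
            logger.warning(
                "overlapping gene spans on %s; clipping negative gaps to 0",
                ordered["chrom"].iloc[0],
            )
            gaps = np.clip(gaps, 0, None)
        left = np.concatenate([[np.nan], gaps])   # gap to the previous gene
        right = np.concatenate([gaps, [np.nan]])  # gap to the next gene
        if intergenic == "mean":
            vals = np.nanmean(np.vstack([left, right]), axis=0)
        elif intergenic == "min":
            vals = np.nanmin(np.vstack([left, right]), axis=0)
        else:  # upstream, strand-aware
            minus = (ordered["strand"] == "-").to_numpy()
            vals = np.where(minus, right, left)
        out.loc[ordered.index, "intergenic_length"] = vals
    return out


@dataclass
class RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test result.

    ``statistic`` is the U statistic for the first sample; ``method`` records
    whether the p-value is exact or a tie/continuity-corrected normal
    approximation.
    """

    statistic: float
    pvalue: float
    n1: int
    n2: int
    method: str


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided rank-sum test of two independent samples.

    Exact null enumeration when n1 + n2 <= 20 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise InputError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return RankSumResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n1=int(x.size),
        n2=int(y.size),
        method=method,
    )


def compare_classes(
    features: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "housekeeping",
    group_b: str = "tissue-specific",
) -> pd.DataFrame:
    """Rank-sum comparison of every feature between two breadth classes.

    Returns one row per feature with class medians, sample sizes, U and the
    two-sided p-value. Features with no finite value in one class are skipped
    with a warning. No multiple-testing correction is applied.
    """
    idx_a = labels.index[labels == group_a]
    idx_b = labels.index[labels == group_b]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise InputError(f"empty class: {group_a}={len(idx_a)}, {group_b}={len(idx_b)}")
    rows = []
    for feat in features.columns:
        a = features.loc[features.index.intersection(idx_a), feat].dropna()
        b = features.loc[features.index.intersection(idx_b), feat].dropna()
        if a.empty or b.empty:
            logger.warning("feature %s missing entirely in one class; skipped", feat)
            continue
        res = rank_sum_test(a, b)
        rows.append(
            {
                "feature": feat,
                f"median_{group_a}": float(a.median()),
                f"median_{group_b}": float(b.median()),
                "n1": res.n1,
                "n2": res.n2,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
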