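"""Synthetic expression-atlas generator with planted ground truth.

Every pipeline input can be generated here with known truth: breadth classes
(housekeeping / tissue-specific / intermediate / silent) drive which gene x
tissue cells are "on"; structural compactness differences between classes are
planted multiplicatively; RIDGE intervals are contiguous blocks holding a
housekeeping-enriched gene subset; and a fraction of 1:1:1 ortholog triplets
share a tissue-profile template across species.

Intensities are drawn directly on the normalized (glog) scale as Gaussians —
the variance-stabilizing transform itself is not simulated. Each logical
output has its own RNG stream spawned from the master seed, so regenerating
one file never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .detection import (
    CLASS_HOUSEKEEPING,
    CLASS_INTERMEDIATE,
    CLASS_SILENT,
    CLASS_TISSUE_SPECIFIC,
)
from .enrichment import TermDAG
from .errors import SizingError
from .features import GeneAnnotation, write_gff3
from .microarray import ExpressionMatrix, NegativeControls, apply_flag_weights
from .ridges import RidgeSet, write_bed

__all__ = [
    "TISSUES8",
    "COMMON5",
    "SPECIES3",
    "GroundTruth",
    "ExpressionBundle",
    "SimulatedDataset",
    "tissue_names",
    "common_tissue_names",
    "species_names",
    "generate_expression",
    "generate_annotation",
    "generate_ortholog_expression",
    "generate_term_dag",
    "simulate_dataset",
    "write_dataset",
]

#: the eight adult tissues of the default design
TISSUES8 = (
    "brain", "bursa", "kidney", "liver", "lung", "intestine", "spleen", "thymus",
)
#: the five-tissue panel shared across species
COMMON5 = ("brain", "kidney", "liver", "lung", "intestine")
SPECIES3 = ("chicken", "mouse", "frog")

# RNG stream indices (one per logical output)
_STREAM_EXPRESSION = 0
_STREAM_ANNOTATION = 1
_STREAM_ORTHOLOGS = 2
_STREAM_DAG = 3


def _stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def tissue_names(n_tissues: int) -> list[str]:
    if n_tissues == len(TISSUES8):
        return list(TISSUES8)
    return [f"tissue{i + 1:02d}" for i in range(n_tissues)]


def common_tissue_names(config: SimConfig) -> list[str]:
    names = tissue_names(config.n_tissues)
    if names == list(TISSUES8) and config.n_common_tissues <= len(COMMON5):
        return list(COMMON5[: config.n_common_tissues])
    return names[: config.n_common_tissues]


def species_names(n_species: int) -> list[str]:
    if n_species == len(SPECIES3):
        return list(SPECIES3)
    return [f"species{i + 1}" for i in range(n_species)]


@dataclass
class GroundTruth:
    """Planted truth: per-gene class (plus in-RIDGE flag once the annotation
    exists) and per-ortholog-triplet conserved flags."""

    genes: pd.DataFrame
    orthologs: pd.DataFrame | None = None

    def class_counts(self) -> pd.Series:
        return self.genes["label"].value_counts()


@dataclass
class ExpressionBundle:
    """Probe-level expression with everything needed to re-read it from disk."""

    matrix: ExpressionMatrix
    flags: pd.DataFrame
    probe_map: pd.Series
    controls: NegativeControls
    control_table: pd.DataFrame


def _plant_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_genes
    n_hk = round(config.frac_housekeeping * n)
    n_ts = round(config.frac_tissue_specific * n)
    n_silent = round(config.frac_silent * n)
    n_int = n - n_hk - n_ts - n_silent
    if n_int < 0:  # rounding overshoot by at most a couple of genes
        n_silent += n_int
        n_int = 0
    labels = np.array(
        [CLASS_HOUSEKEEPING] * n_hk
        + [CLASS_TISSUE_SPECIFIC] * n_ts
        + [CLASS_SILENT] * n_silent
        + [CLASS_INTERMEDIATE] * n_int
    )
    return rng.permutation(labels)


def generate_expression(
    config: SimConfig,
) -> tuple[ExpressionBundle, GroundTruth]:
    """Simulate the probe x sample intensity matrix plus negative controls.

    Housekeeping genes are "on" in every tissue, tissue-specific genes in one
    uniformly chosen tissue, intermediate genes in a uniform 2..T-1 subset and
    silent genes nowhere; "off" cells and negative controls share the
    background distribution N(background_mean, background_sd), replicate noise
    has the same sd.
    """
    rng = _stream(config.seed, _STREAM_EXPRESSION)
    n, T, R = config.n_genes, config.n_tissues, config.n_replicates
    tissues = tissue_names(T)
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    labels = _plant_labels(config, rng)

    on = np.zeros((n, T), dtype=bool)
    specific = np.full(n, "", dtype=object)
    on[labels == CLASS_HOUSEKEEPING, :] = True
    ts_rows = np.flatnonzero(labels == CLASS_TISSUE_SPECIFIC)
    ts_tissue = rng.integers(0, T, size=ts_rows.size)
    on[ts_rows, ts_tissue] = True
    specific[ts_rows] = [tissues[t] for t in ts_tissue]
    for i in np.flatnonzero(labels == CLASS_INTERMEDIATE):
        b = int(rng.integers(2, T))  # breadth 2 .. T-1
        on[i, rng.choice(T, size=b, replace=False)] = True

    level = np.full((n, T), config.background_mean)
    mid = 0.5 * (config.expr_mean_hk + config.expr_mean_ts)
    per_class = {
        CLASS_HOUSEKEEPING: config.expr_mean_hk,
        CLASS_TISSUE_SPECIFIC: config.expr_mean_ts,
        CLASS_INTERMEDIATE: mid,
    }
    for cls, mean in per_class.items():
        rows = labels == cls
        level[rows] = np.where(on[rows], mean, config.background_mean)

    # probes: most genes have one probe, a planted fraction two
    n_two = round(config.frac_two_probe * n)
    two_probe = np.zeros(n, dtype=bool)
    two_probe[rng.choice(n, size=n_two, replace=False)] = True
    gene_of_probe = np.repeat(np.arange(n), np.where(two_probe, 2, 1))
    probe_ids = np.array([f"P{j:06d}" for j in range(gene_of_probe.size)])

    sample_ids = [f"{t}_r{r + 1}" for t in tissues for r in range(R)]
    tissue_of_sample = np.repeat(np.arange(T), R)
    meta = pd.DataFrame(
        {
            "tissue": [tissues[t] for t in tissue_of_sample],
            "replicate": list(np.tile(np.arange(1, R + 1), T)),
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    means = level[gene_of_probe][:, tissue_of_sample]
    values = means + rng.normal(0.0, config.background_sd, size=means.shape)
    values_df = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )
    flags = pd.DataFrame(
        np.where(rng.random(values.shape) < config.frac_flagged, -100, 0),
        index=values_df.index,
        columns=values_df.columns,
    )

    # negative controls: n_negative_controls spots on each array
    n_ctl = config.n_negative_controls
    ctl_values = rng.normal(
        config.background_mean, config.background_sd, size=(n_ctl, len(sample_ids))
    )
    ctl_flags = np.where(rng.random(ctl_values.shape) < config.frac_flagged, -100, 0)
    control_table = pd.DataFrame(
        {
            "control_id": np.repeat([f"C{i:04d}" for i in range(n_ctl)],
                                    len(sample_ids)),
            "sample": np.tile(sample_ids, n_ctl),
            "intensity": ctl_values.ravel(),
            "flag": ctl_flags.ravel(),
        }
    )
    controls = NegativeControls(
        ctl_values.ravel(),
        np.where(ctl_flags.ravel() < -50, 0.01, 1.0),
    )

    matrix = ExpressionMatrix(values_df, meta, apply_flag_weights(flags))
    probe_map = pd.Series(
        gene_ids[gene_of_probe], index=values_df.index, name="gene_id"
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "label": labels,
                "specific_tissue": specific,
                "breadth_true": on.sum(axis=1),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    bundle = ExpressionBundle(matrix, flags, probe_map, controls, control_table)
    return bundle, truth


def _gene_structure(config: SimConfig, rng: np.random.Generator, is_ts: np.ndarray):
    """Draw exon counts and exon/intron lengths; TS genes get more exons and
    longer introns (hence longer genes and CDS, same mean exon length)."""
    n = is_ts.size
    effect = np.where(is_ts, config.compactness_effect, 1.0)
    counts = np.maximum(
        1,
        np.rint(
            effect
            * rng.lognormal(config.exon_count_log_mean, config.exon_count_log_sd, n)
        ).astype(int),
    )
    # one exon-length scale per gene, shared by all its exons: the per-gene
    # mean exon length is then distribution-identical across classes even
    # though exon counts differ, keeping that feature exactly null
    gene_exon_length = np.maximum(
        10,
        np.rint(
            rng.lognormal(config.exon_length_log_mean,
                          config.exon_length_log_sd, n)
        ).astype(int),
    )
    exon_lengths, intron_lengths = [], []
    for i in range(n):
        k = counts[i]
        ex = np.full(k, gene_exon_length[i])
        if k > 1:
            intr = np.maximum(
                30,
                np.rint(
                    effect[i]
                    * rng.lognormal(config.intron_length_log_mean,
                                    config.intron_length_log_sd, k - 1)
                ).astype(int),
            )
        else:
            intr = np.empty(0, dtype=int)
        exon_lengths.append(ex)
        intron_lengths.append(intr)
    return counts, exon_lengths, intron_lengths


def _cds_from_exons(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """A simple single-ORF coding region: trim half of the first and last exon."""
    if len(exons) == 1:
        s, e = exons[0]
        L = e - s + 1
        cs, ce = s + L // 4, e - L // 4
        return [(cs, ce)] if cs <= ce else [(s, e)]
    out = []
    for i, (s, e) in enumerate(exons):
        if i == 0:
            s = s + (e - s + 1) // 2
        elif i == len(exons) - 1:
            e = e - (e - s + 1) // 2
        if s <= e:
            out.append((s, e))
    return out


def generate_annotation(
    config: SimConfig, truth: GroundTruth
) -> tuple[GeneAnnotation, RidgeSet]:
    """Lay genes out on toy chromosomes and carve RIDGE blocks.

    Genes are placed sequentially with exponential intergenic gaps (gaps
    flanking tissue-specific genes are stretched by sqrt(compactness_effect)
    on each side). A fixed count round(ridge_genome_frac * n_genes) of genes
    is drawn into RIDGEs without replacement, with housekeeping genes' odds
    multiplied by ridge_hk_enrichment; each chromosome's RIDGE genes sit in
    one contiguous block whose interval boundaries cut the flanking gaps at
    their midpoint. Adds the realized ``in_ridge`` column to ``truth.genes``.
    """
    rng = _stream(config.seed, _STREAM_ANNOTATION)
    genes = truth.genes
    n = len(genes)
    labels = genes["label"].to_numpy()
    is_ts = labels == CLASS_TISSUE_SPECIFIC
    is_hk = labels == CLASS_HOUSEKEEPING

    counts, exon_lengths, intron_lengths = _gene_structure(config, rng, is_ts)
    span_lengths = np.array(
        [ex.sum() + intr.sum() for ex, intr in zip(exon_lengths, intron_lengths)]
    )
    if span_lengths.sum() > 2**40:
        raise SizingError(
            "total gene length exceeds the supported toy-genome size; "
            "reduce n_genes or the length scales"
        )

    # RIDGE membership: fixed total count, HK odds boosted
    m = round(config.ridge_genome_frac * n)
    weights = np.where(is_hk, config.ridge_hk_enrichment, 1.0)
    in_ridge = np.zeros(n, dtype=bool)
    if m > 0:
        chosen = rng.choice(n, size=m, replace=False, p=weights / weights.sum())
        in_ridge[chosen] = True

    # chromosome assignment: random chunks; ridge genes contiguous per chrom
    order = rng.permutation(n)
    chunks = np.array_split(order, config.n_chromosomes)
    strands = rng.choice(["+", "-"], size=n)
    gap_scale = np.where(is_ts, math.sqrt(config.compactness_effect), 1.0)

    rows = []
    exon_map: dict[str, list[tuple[int, int]]] = {}
    cds_map: dict[str, list[tuple[int, int]]] = {}
    ridge_intervals: dict[str, list[tuple[int, int]]] = {}
    gene_ids = genes.index.to_numpy()

    for c, chunk in enumerate(chunks):
        if chunk.size == 0:
            continue
        chrom = f"chr{c + 1}"
        ridge_part = [g for g in chunk if in_ridge[g]]
        plain_part = [g for g in chunk if not in_ridge[g]]
        insert_at = int(rng.integers(0, len(plain_part) + 1))
        ordered = plain_part[:insert_at] + ridge_part + plain_part[insert_at:]

        pos = 1  # next free 1-based coordinate
        starts, ends = {}, {}
        prev_idx = None
        for g in ordered:
            scale = config.intergenic_mean * gap_scale[g]
            if prev_idx is not None:
                scale = config.intergenic_mean * math.sqrt(
                    gap_scale[g] * gap_scale[prev_idx]
                )
            gap = max(2, int(round(rng.exponential(scale))))
            start = pos + gap
            ex, intr = exon_lengths[g], intron_lengths[g]
            cursor = start
            gid = gene_ids[g]
            exon_map[gid] = []
            for j, L in enumerate(ex):
                exon_map[gid].append((cursor, cursor + int(L) - 1))
                cursor += int(L)
                if j < len(intr):
                    cursor += int(intr[j])
            end = cursor - 1
            cds_map[gid] = _cds_from_exons(exon_map[gid])
            starts[g], ends[g] = start, end
            rows.append((gid, chrom, strands[g], start, end))
            pos = end
            prev_idx = g

        if ridge_part:
            first, last = ridge_part[0], ridge_part[-1]
            i0 = ordered.index(first)
            i1 = ordered.index(last)
            prev_end0 = ends[ordered[i0 - 1]] if i0 > 0 else 0
            bed_start = prev_end0 + (starts[first] - 1 - prev_end0) // 2
            if i1 + 1 < len(ordered):
                next_start0 = starts[ordered[i1 + 1]] - 1
            else:
                next_start0 = ends[last] + max(
                    2, int(round(rng.exponential(config.intergenic_mean)))
                )
            bed_end = ends[last] + (next_start0 - ends[last]) // 2
            bed_end = max(bed_end, ends[last])  # never cut into the last gene
            ridge_intervals[chrom] = [(bed_start, bed_end)]

    gene_table = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end"]
    ).set_index("gene_id").loc[gene_ids]
    annotation = GeneAnnotation(gene_table, exon_map, cds_map)
    ridges = RidgeSet.from_intervals(ridge_intervals)
    truth.genes["in_ridge"] = pd.Series(in_ridge, index=genes.index)
    return annotation, ridges


def generate_ortholog_expression(
    config: SimConfig, truth: GroundTruth
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-species expression over the common tissue panel plus the 1:1:1 table.

    Conserved triplets share a standard-normal log-profile template with
    independent N(0, ortholog_noise_sd) noise per species; non-conserved
    triplets get fully independent profiles. Expression is exp(log-profile),
    so tables are positive and relative-abundance-ready. Fills
    ``truth.orthologs``.
    """
    if config.n_species < 2:
        raise SizingError("cross-species comparison needs n_species >= 2")
    rng = _stream(config.seed, _STREAM_ORTHOLOGS)
    n, T = config.n_ortholog_triplets, config.n_common_tissues
    panel = common_tissue_names(config)
    species = species_names(config.n_species)

    n_cons = round(config.frac_conserved_orthologs * n)
    conserved = np.zeros(n, dtype=bool)
    conserved[:n_cons] = True
    conserved = rng.permutation(conserved)

    template = rng.standard_normal((n, T))
    tables: dict[str, pd.DataFrame] = {}
    id_columns: dict[str, np.ndarray] = {}
    for sp in species:
        ids = np.array([f"{sp}_G{i:05d}" for i in range(n)])
        noise = rng.normal(0.0, config.ortholog_noise_sd, size=(n, T))
        independent = rng.standard_normal((n, T))
        z = np.where(conserved[:, None], template + noise, independent)
        tables[sp] = pd.DataFrame(
            np.exp(z), index=pd.Index(ids, name="gene_id"), columns=panel
        )
        id_columns[sp] = ids

    orthologs = pd.DataFrame(id_columns)
    truth.orthologs = orthologs.assign(conserved=conserved)
    return tables, orthologs


def generate_term_dag(
    config: SimConfig, truth: GroundTruth
) -> tuple[TermDAG, list[tuple[str, str]], list[tuple[str, str]], str]:
    """A toy three-level term DAG with one housekeeping-enriched leaf term.

    Every gene is annotated to 1-3 uniformly chosen leaf terms; the designated
    term additionally receives ``enriched_term_size`` genes sampled with odds
    ``enriched_term_hk_weight`` for housekeeping genes. Returns the DAG, its
    (child, parent) edges, the (gene, term) annotations, and the enriched
    term's ID.
    """
    rng = _stream(config.seed, _STREAM_DAG)
    genes = truth.genes.index.to_numpy()
    labels = truth.genes["label"].to_numpy()
    parents = [f"P{p + 1:02d}" for p in range(config.n_term_parents)]
    edges = [(p, "ROOT") for p in parents]
    leaves: list[str] = []
    for p in parents:
        for c in range(config.n_term_children_per_parent):
            leaf = f"{p}.L{c + 1:02d}"
            leaves.append(leaf)
            edges.append((leaf, p))

    gene_terms: list[tuple[str, str]] = []
    n_terms_per_gene = rng.integers(1, 4, size=genes.size)
    for gene, k in zip(genes, n_terms_per_gene):
        for leaf in rng.choice(leaves, size=k, replace=False):
            gene_terms.append((gene, leaf))

    enriched = leaves[0]
    size = min(config.enriched_term_size, genes.size)
    w = np.where(labels == CLASS_HOUSEKEEPING, config.enriched_term_hk_weight, 1.0)
    planted = rng.choice(genes.size, size=size, replace=False, p=w / w.sum())
    existing = {g for g, t in gene_terms if t == enriched}
    for i in planted:
        if genes[i] not in existing:
            gene_terms.append((genes[i], enriched))
    dag = TermDAG.from_edges(edges, gene_terms)
    return dag, edges, gene_terms, enriched


@dataclass
class SimulatedDataset:
    """Everything one run of the generator produces, in memory."""

    config: SimConfig
    truth: GroundTruth
    expression: ExpressionBundle
    annotation: GeneAnnotation
    ridges: RidgeSet
    species_expression: dict[str, pd.DataFrame]
    orthologs: pd.DataFrame
    dag: TermDAG
    dag_edges: list[tuple[str, str]] = field(default_factory=list)
    gene_terms: list[tuple[str, str]] = field(default_factory=list)
    enriched_term: str = ""


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate every pipeline input for one configuration."""
    bundle, truth = generate_expression(config)
    annotation, ridges = generate_annotation(config, truth)
    tables, orthologs = generate_ortholog_expression(config, truth)
    dag, edges, gene_terms, enriched = generate_term_dag(config, truth)
    return SimulatedDataset(
        config=config,
        truth=truth,
        expression=bundle,
        annotation=annotation,
        ridges=ridges,
        species_expression=tables,
        orthologs=orthologs,
        dag=dag,
        dag_edges=edges,
        gene_terms=gene_terms,
        enriched_term=enriched,
    )


_FLOAT_FMT = "%.6f"


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write every input file of the pipeline; returns {logical name: path}.

    Formats: TSV matrices (probes x `tissue_rep` sample IDs), long-format
    negative controls, GFF3 annotation (1-based closed), BED RIDGEs (0-based
    half-open), per-species expression TSVs, ortholog and truth tables, and
    the term DAG as two TSVs.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name, fname, writer):
        path = out / fname
        writer(path)
        paths[name] = str(path)

    expr = ds.expression
    _save("matrix", "matrix.tsv",
          lambda p: expr.matrix.values.to_csv(p, sep="\t", float_format=_FLOAT_FMT))
    _save("flags", "flags.tsv", lambda p: expr.flags.to_csv(p, sep="\t"))
    _save("samples", "samples.tsv", lambda p: expr.matrix.sample_meta.to_csv(p, sep="\t"))
    _save("probe_map", "probe_map.tsv",
          lambda p: expr.probe_map.rename_axis("probe_id").to_csv(p, sep="\t"))
    _save("controls", "negative_controls.tsv",
          lambda p: expr.control_table.to_csv(p, sep="\t", index=False,
                                              float_format=_FLOAT_FMT))
    _save("truth_genes", "truth_genes.tsv", lambda p: ds.truth.genes.to_csv(p, sep="\t"))
    _save("gff3", "annotation.gff3", lambda p: write_gff3(ds.annotation, p))
    _save("ridges", "ridges.bed", lambda p: write_bed(ds.ridges, p))
    _save("orthologs", "orthologs.tsv",
          lambda p: ds.orthologs.to_csv(p, sep="\t", index=False))
    if ds.truth.orthologs is not None:
        _save("truth_orthologs", "truth_orthologs.tsv",
              lambda p: ds.truth.orthologs.to_csv(p, sep="\t", index=False))
    for sp, table in ds.species_expression.items():
        _save(f"expr_{sp}", f"expr_{sp}.tsv",
              lambda p, t=table: t.to_csv(p, sep="\t", float_format=_FLOAT_FMT))
    _save("term_edges", "term_edges.tsv",
          lambda p: pd.DataFrame(ds.dag_edges, columns=["child", "parent"])
          .to_csv(p, sep="\t", index=False))
    _save("gene_terms", "gene_terms.tsv",
          lambda p: pd.DataFrame(ds.gene_terms, columns=["gene", "term"])
          .to_csv(p, sep="\t", index=False))
    _save("config", "config.yaml", lambda p: ds.config.to_yaml(p))
    return paths
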