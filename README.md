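# breadthatlas

Analysis toolkit for multi-tissue expression atlases measured on two-colour
microarrays: which genes are expressed where, how widely, and what that
breadth correlates with — gene compactness, chromosomal clustering, and
cross-species conservation of expression profiles.

## What it does

Given a normalized probe × sample intensity matrix with spot flags, negative
controls, a probe→gene map, a GFF3 gene annotation, a BED set of RIDGE
intervals (Regions of Increased Gene Expression), per-species expression
tables with a 1:1:1 ortholog table, and a term DAG, the pipeline:

1. **Detection & breadth.** Weights flagged spots (FLAG < −50 → 0.01),
   averages replicates within tissue and probes within gene, and calls a gene
   expressed in a tissue when its value exceeds the 99% quantile of all
   pooled negative-control spots:
   expressed(g, t) ⇔ x̄₍g,t₎ > Q₀.₉₉(controls).
   Breadth B(g) = Σₜ expressed(g, t); B = 1 defines *tissue-specific*,
   B = T *housekeeping* genes.
2. **Compactness.** Computes gene length, CDS length, mean exon/intron
   length and intergenic length per gene, and compares housekeeping vs
   tissue-specific distributions with the two-sided Wilcoxon rank-sum test.
3. **RIDGE enrichment.** Assigns genes to RIDGEs by span midpoint and tests
   over-representation of a query set with a permutation null: 1000 draws of
   |query| genes without replacement, p = (1 + #{null ≥ obs}) / (n_perm + 1).
4. **Conservation.** Transforms expression to relative mRNA abundance,
   RAᵢ = xᵢ / Σⱼ xⱼ over a shared tissue panel, and calls an ortholog pair
   conserved when corr(RA_A, RA_B) exceeds the 95% quantile of random
   cross-species gene pairs; clusters species-tissue columns by Spearman ρ
   (average linkage on 1 − ρ) to ask whether homologous tissues group.
5. **Term enrichment.** Conditional hypergeometric test on a term DAG with
   true-path propagation: a parent term is tested after removing genes of its
   already-significant children, P(X ≥ k) with X ~ Hypergeom(N, K, n).

A synthetic-data generator (`breadthatlas.simulate`) produces every input
with planted ground truth — breadth classes, compactness ratios, RIDGE odds,
conserved ortholog fractions — so the whole stack is testable offline. Its
defaults emulate an 8,908-gene chicken-style atlas: 8 tissues × 5 replicates,
~28% housekeeping, ~8% tissue-specific, RIDGEs covering 10% of the genome,
and 3,892 ortholog triplets across three species over 5 common tissues.

## Worked example

```python
from breadthatlas import (
    SimConfig, simulate_dataset, detect,
    average_replicates, collapse_probes,
    compute_features, compare_classes,
    assign_in_ridge, permutation_enrichment,
)

ds = simulate_dataset(SimConfig(seed=0))          # default full-scale atlas
gene_tissue = collapse_probes(
    average_replicates(ds.expression.matrix), ds.expression.probe_map
)
result = detect(gene_tissue, ds.expression.controls)
print(f"threshold={result.threshold:.3f}  expressed={result.n_expressed}")
print(result.class_counts().to_dict())

table = compare_classes(compute_features(ds.annotation), result.labels)
print(f"intron p = {table.loc['mean_intron_length', 'pvalue']:.3g}")

in_ridge = assign_in_ridge(ds.annotation, ds.ridges)
hk = result.labels.index[result.labels == "housekeeping"]
perm = permutation_enrichment(hk, ds.annotation.genes.index, in_ridge,
                              n_perm=1000, seed=0)
print(f"HK in RIDGEs: {perm.observed_fraction:.1%} "
      f"(null {perm.null_mean:.1%} ± {perm.null_sd:.1%}, p={perm.empirical_p:.4g})")
```

prints

```
threshold=7.139  expressed=5078
{'silent': 3830, 'tissue-specific': 722, 'intermediate': 1880, 'housekeeping': 2476}
intron p = 5.83e-225
HK in RIDGEs: 18.5% (null 10.0% ± 0.5%, p=0.000999)
```

i.e. the detection threshold lands ~2.3 control-sd above background, 57% of
genes are expressed somewhere, the planted class mix is recovered almost
exactly, housekeeping introns are overwhelmingly shorter, and housekeeping
genes sit in RIDGEs at nearly twice the random rate — the permutation p-value
is at its floor of 1/(n_perm + 1).

The same analyses are available from the shell:

```bash
breadthatlas simulate --outdir data/ --seed 0
breadthatlas run --config run.yaml          # full pipeline + report.json
breadthatlas detect --matrix g.tsv --controls c.tsv --out classes.tsv
breadthatlas ridge --gff data/annotation.gff3 --ridges data/ridges.bed \
    --query hk.txt --nperm 1000 --seed 7
```

## Layout

| module | contents |
|---|---|
| `breadthatlas.simulate` | synthetic atlas generator + file writers |
| `breadthatlas.microarray` | flag weighting, replicate/probe averaging, readers |
| `breadthatlas.detection` | control-quantile threshold, calls, breadth classes |
| `breadthatlas.features` | GFF3 I/O, structural features, rank-sum comparisons |
| `breadthatlas.ridges` | BED I/O, midpoint assignment, permutation test |
| `breadthatlas.conservation` | RA transform, conservation calls, tissue clustering |
| `breadthatlas.enrichment` | term DAG, (conditional) hypergeometric tests |
| `breadthatlas.pipeline` | end-to-end orchestration + run report |
| `breadthatlas.cli` | `breadthatlas` command group |

See `docs/methods.md` for the model details, generator assumptions and
numerical conventions.
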