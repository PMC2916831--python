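# Methods

## The analysis

`breadthatlas` implements a multi-tissue expression-atlas analysis for
two-colour microarray data, together with a synthetic-data generator that
plants every effect the analysis is designed to detect.

### Detection and breadth

Spots flagged bad by the scanner (GenePix FLAG < −50) receive weight 0.01 and
are treated as missing everywhere downstream; all other spots receive weight 1.
Normalized (variance-stabilized, "glog"-scale) intensities are averaged
arithmetically — first over the biological replicates of each tissue, then
over probes targeting the same gene. A gene×tissue cell is missing only when
*all* contributing measurements are invalid.

The detection threshold is the q-quantile (default q = 0.99) of all valid
negative-control spot intensities pooled across all arrays, computed by linear
interpolation between order statistics (type-7, h = (n−1)q + 1). A gene is
*expressed* in a tissue when its averaged value is **strictly** greater than
the threshold. Breadth is the number of tissues with a positive call; breadth
0 is *silent*, 1 *tissue-specific*, T (all tissues) *housekeeping*, otherwise
*intermediate*.

Two conventions were genuinely open and are config-exposed:

* **Quantile rule.** Type-7 interpolation, the default of both major stats
  ecosystems.
* **Averaging before thresholding.** The threshold is applied to
  tissue-averaged, probe-collapsed values. Note the consequence: the 1%
  false-positive rate of a 99% cutoff holds for *single spots*; after
  averaging R replicates the null exceedance rate drops to roughly
  Φ(−z₀.₉₉·√R), far below 1%. `call_expressed` accepts any matrix, so
  per-array (unaveraged) calling is available for sensitivity analysis.

### Structural compactness

Per gene: gene length = span end − start + 1; CDS length = Σ CDS intervals;
mean exon length = Σ exon / k; mean intron length = Σ intron / (k−1), missing
for single-exon genes (which are therefore excluded from intron comparisons);
intergenic length = mean of the gaps to the nearest flanking genes on the same
chromosome (single flank at chromosome ends; `min` and strand-aware `upstream`
variants are options; genes alone on a chromosome get a missing value). Gaps
are measured between gene spans, not TSSs. GFF3 coordinates are 1-based
closed; BED 0-based half-open.

Classes are compared feature-by-feature with the two-sided Wilcoxon rank-sum
test: exact null enumeration when n₁+n₂ ≤ 20 and tie-free, otherwise the
normal approximation with tie and continuity corrections. No multiple-testing
correction is applied across the five features.

### RIDGE enrichment

A gene is inside a RIDGE (Region of Increased Gene Expression) when its span
midpoint, as a continuous 0-based coordinate, lies inside a half-open BED
interval; a midpoint exactly at an interval end is outside ("any overlap" is
an option). Enrichment of a query set is tested by drawing |query| genes
without replacement from the universe n_perm times (default 1000) and scoring
the in-RIDGE fraction of each draw. The empirical p-value is
(1 + #{null ≥ observed}) / (n_perm + 1), so it can never be 0; its floor at
n_perm = 1000 is ≈ 0.000999. The null mean estimates the hypergeometric
expectation K/N.

### Cross-species conservation

Relative mRNA abundance (RA): each gene's expression in a tissue divided by
the sum of its expression over the shared tissue panel. RA is invariant to
per-gene scale, which is what makes profiles from different platforms
comparable. Negative inputs are clipped to 0 with a warning; rows with
non-positive totals are dropped.

An ortholog pair is *conserved* when the Pearson correlation (Spearman is an
option) of its two RA vectors exceeds the 95% linear-interpolation quantile of
a null of 10,000 random non-orthologous cross-species pairs, sampled
uniformly with one shared null per species-pair comparison. Pairs with a
zero-variance RA vector have undefined correlation and are excluded with a
count. By construction the null calibrates the call rate to 5% when orthology
carries no signal.

Tissue-level similarity is the Spearman rank correlation (average ranks for
ties) between every pair of species-tissue RA columns over the shared
ortholog rows, followed by average-linkage hierarchical clustering on 1 − ρ.

### Conditional term enrichment

The base test is the upper-tail hypergeometric P(X ≥ k) for k query genes in
a K-gene term within an n-gene query and N-gene universe, computed through
the log-space survival function. Annotations obey the true-path rule (a gene
annotated to a term is annotated to all its ancestors). The conditional
variant processes terms leaves-to-root: when testing a term, genes annotated
to its already-significant **direct** children (descendant semantics are an
option) are removed from both the term's gene set and the universe, so a
parent is only significant given evidence beyond its children. The
significance cutoff used during the walk and for reporting is raw p < 0.01;
no multiple-testing correction.

The universe adjustment in the conditional step (remove child genes from the
universe as well as from the term) is one of two conventions in circulation;
`adjust_universe=False` gives the other.

## The synthetic atlas

The generator's defaults are the study conditions the pipeline is shaped
around, and are not tuned per-test:

| parameter | default | meaning |
|---|---|---|
| n_genes | 8,908 | genes on the array |
| n_tissues × n_replicates | 8 × 5 | adult tissue panel, biological replicates |
| frac_housekeeping / ts / silent | 0.278 / 0.081 / 0.430 | planted class mix (57% expressed) |
| background_mean ± sd | 6.0 ± 0.5 | glog-scale background and replicate noise |
| expr_mean_hk / expr_mean_ts | 10.0 / 9.0 | "on"-cell means (housekeeping higher) |
| compactness_effect | 2.0 | TS/HK ratio on intron length, exon count, gaps |
| ridge_genome_frac | 0.10 | genome fraction covered by RIDGEs |
| ridge_hk_enrichment | 3.0 | odds multiplier for HK genes inside RIDGEs |
| n_ortholog_triplets | 3,892 | 1:1:1 triplets over a 5-tissue panel |
| frac_conserved_orthologs | 0.10 | triplets sharing a profile template |
| ortholog_noise_sd | 0.5 | per-species noise around the template |

Mechanics and deliberate simplifications:

* Intensities are Gaussians drawn directly on the normalized scale; dye bias,
  print-tip effects and the normalization step itself are not simulated.
  Intermediate genes' "on" cells sit halfway between the HK and TS means and
  their breadth is uniform on 2..T−1.
* Tissue-specific genes get their single tissue uniformly at random; ~10% of
  genes carry two probes; ~1% of spots are flagged bad.
* Genes are laid out sequentially per chromosome with exponential intergenic
  gaps; gaps flanking TS genes are stretched by √compactness_effect per side.
  All exons of a gene share one log-normally drawn length, so the per-gene
  *mean* exon length is distribution-identical between classes (an exactly
  null feature) even though TS genes have compactness_effect-times more
  exons — which is what lengthens their CDS and span. With iid exon lengths
  this feature would *not* be null: the mean of more draws from a skewed
  distribution is stochastically shifted, and at n ≈ 9,000 genes the rank-sum
  test detects that reliably.
* A fixed count round(ridge_genome_frac·n_genes) of genes is drawn into
  RIDGEs by weighted sampling without replacement (HK weight =
  ridge_hk_enrichment), then each chromosome's RIDGE genes are made
  contiguous and the interval boundaries cut the flanking gaps at their
  midpoints. Coverage therefore tracks the target fraction by *gene count*;
  by base pairs it wobbles with the class mix of the sampled genes.
* Ortholog log-profiles: conserved triplets share a standard-normal template
  plus N(0, noise_sd) per species; others are independent. Expression is
  exp(log-profile). Real cross-platform data has heavier tails, probe biases
  and partially conserved modules; passing tests here show the *procedure* is
  calibrated and recovers planted structure, not that any particular
  biological dataset would yield a given conserved fraction.
* A toy 3-level term DAG (root, 5 parents, 25 leaves) annotates every gene
  with 1–3 leaves; one leaf is planted housekeeping-enriched. This generator
  exists so the enrichment stage runs end-to-end; it is not part of the
  planted-truth contracts above.
* One RNG stream per logical output, spawned from the master seed, so
  regenerating one file leaves the others bit-identical.

## Numerical choices and degenerate inputs

* Strict `>` at the detection threshold; missing cells call not-expressed and
  are counted in the log.
* Probes missing from the probe map are dropped with a warning; an empty
  matrix∩map intersection is an error; a probe mapped to two genes is an
  error.
* Wilcoxon p is clipped to ≤ 1; identical samples give p = 1.
* Enrichment terms with K = 0 or n = 0 after child-removal report p = 1.
* Permutation and conservation nulls are reproducible from their seed
  arguments alone.
* Constant (zero-variance) RA vectors are excluded from correlation, not
  imputed.

## Problem sizes used by the test suite

The bundled tests run the full default scale (8,908 genes, 3,892 triplets)
once for the end-to-end checks and scaled-down configurations (300–2,000
genes) for calibration loops over 10–60 seeds; the whole suite completes in
well under a minute of compute plus ~20 s for the full-scale fixture.

## Known limitations

* The generator plants breadth classes directly rather than via a biological
  covariance structure; correlations between expression level, breadth and
  compactness exist in real genomes beyond what is planted here.
* Intergenic stretching couples neighbouring genes (each gap is shared by two
  genes), so the planted intergenic effect is diluted relative to
  compactness_effect; it is the weakest of the planted signals, mirroring its
  relatively weaker significance in real data.
* RIDGE discovery itself (sliding-window expression mapping) is out of scope;
  RIDGEs are consumed as a given interval set.
* The conditional enrichment walk is deterministic leaves-to-root on the
  supplied DAG; very deep DAGs with diamond topologies can make the
  child-removal order matter, as it does in the reference semantics.
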