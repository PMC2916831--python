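"""Simulation and run configuration objects.

``SimConfig`` holds every knob of the synthetic-data generator. The defaults
reproduce the shape of the study the pipeline was designed around: an
8,908-gene two-colour microarray measured in 8 adult tissues with 5 biological
replicates each, class fractions matching the observed breadth distribution
(about 28% housekeeping, 8% tissue-specific, 43% silent), RIDGE intervals
covering 10% of the genome, and a 3-species ortholog panel of 3,892 1:1:1
triplets over 5 common tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

import yaml

from .errors import ConfigError

__all__ = ["SimConfig"]


@dataclass
class SimConfig:
    """Parameters of the synthetic expression atlas.

    Intensities are generated directly on the normalized (glog) scale as
    Gaussians; the variance-stabilizing step itself is not simulated because
    the analysis consumes normalized values.
    """

    # --- expression matrix shape ---
    n_genes: int = 8908
    n_tissues: int = 8
    n_replicates: int = 5
    #: negative-control spots per array; controls are pooled across all arrays
    n_negative_controls: int = 100

    # --- planted breadth classes ---
    frac_housekeeping: float = 0.278
    frac_tissue_specific: float = 0.081
    frac_silent: float = 0.430

    # --- intensity model (normalized/glog scale) ---
    expr_mean_hk: float = 10.0
    expr_mean_ts: float = 9.0
    background_mean: float = 6.0
    background_sd: float = 0.5

    # --- structural compactness ---
    #: multiplicative TS/HK ratio applied to intron lengths, exon counts
    #: (hence CDS and gene length) and intergenic gaps; 1.0 = no effect
    compactness_effect: float = 2.0
    exon_count_log_mean: float = math.log(4.0)
    exon_count_log_sd: float = 0.5
    exon_length_log_mean: float = math.log(150.0)
    exon_length_log_sd: float = 0.6
    intron_length_log_mean: float = math.log(800.0)
    intron_length_log_sd: float = 0.8
    intergenic_mean: float = 2000.0
    n_chromosomes: int = 10

    # --- RIDGEs ---
    ridge_genome_frac: float = 0.10
    #: odds multiplier for a housekeeping gene to be placed inside a RIDGE
    ridge_hk_enrichment: float = 3.0

    # --- cross-species panel ---
    n_species: int = 3
    n_ortholog_triplets: int = 3892
    frac_conserved_orthologs: float = 0.10
    #: sd of the per-species Gaussian noise around a conserved triplet's
    #: shared log-profile template (template entries are standard normal)
    ortholog_noise_sd: float = 0.5
    n_common_tissues: int = 5

    # --- nuisance structure ---
    #: probability that any one spot is flagged "bad" (weight 0.01)
    frac_flagged: float = 0.01
    #: fraction of genes represented by two probes instead of one
    frac_two_probe: float = 0.10

    # --- term DAG (set-enrichment inputs) ---
    n_term_parents: int = 5
    n_term_children_per_parent: int = 5
    enriched_term_size: int = 150
    enriched_term_hk_weight: float = 10.0

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "n_replicates": self.n_replicates,
            "n_negative_controls": self.n_negative_controls,
            "n_chromosomes": self.n_chromosomes,
            "n_species": self.n_species,
            "n_ortholog_triplets": self.n_ortholog_triplets,
            "n_common_tissues": self.n_common_tissues,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        props = {
            "frac_housekeeping": self.frac_housekeeping,
            "frac_tissue_specific": self.frac_tissue_specific,
            "frac_silent": self.frac_silent,
            "ridge_genome_frac": self.ridge_genome_frac,
            "frac_conserved_orthologs": self.frac_conserved_orthologs,
            "frac_flagged": self.frac_flagged,
            "frac_two_probe": self.frac_two_probe,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        total = self.frac_housekeeping + self.frac_tissue_specific + self.frac_silent
        if total > 1.0 + 1e-12:
            raise ConfigError(
                "frac_housekeeping + frac_tissue_specific + frac_silent must be <= 1, "
                f"got {total:.4f}"
            )
        scales = {
            "background_sd": self.background_sd,
            "compactness_effect": self.compactness_effect,
            "ridge_hk_enrichment": self.ridge_hk_enrichment,
            "ortholog_noise_sd": self.ortholog_noise_sd,
            "intergenic_mean": self.intergenic_mean,
            "expr_mean_hk": self.expr_mean_hk,
            "expr_mean_ts": self.expr_mean_ts,
            "background_mean": self.background_mean,
        }
        for name, value in scales.items():
            if not value > 0:
                raise ConfigError(f"{name} must be > 0, got {value!r}")
        if self.frac_intermediate > 1e-9 and self.n_tissues < 3:
            raise ConfigError(
                "intermediate-breadth genes require n_tissues >= 3; "
                "set frac_housekeeping + frac_tissue_specific + frac_silent = 1"
            )
        if self.n_common_tissues > self.n_tissues:
            raise ConfigError("n_common_tissues cannot exceed n_tissues")

    @property
    def frac_intermediate(self) -> float:
        return 1.0 - (
            self.frac_housekeeping + self.frac_tissue_specific + self.frac_silent
        )

    @property
    def n_samples(self) -> int:
        return self.n_tissues * self.n_replicates

    # --- (de)serialization -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
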