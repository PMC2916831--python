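"""Ground-truth plumbing of the synthetic atlas generator."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from breadthatlas.config import SimConfig
from breadthatlas.detection import detection_threshold
from breadthatlas.errors import ConfigError
from breadthatlas.ridges import assign_in_ridge, permutation_enrichment
from breadthatlas.simulate import (
    generate_annotation,
    generate_expression,
    generate_ortholog_expression,
    simulate_dataset,
    write_dataset,
)


def _cfg(**kw):
    base = dict(
        n_genes=300, n_negative_controls=50, n_ortholog_triplets=200,
        n_chromosomes=4, seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ConfigError):
            _cfg(frac_housekeeping=0.6, frac_tissue_specific=0.3, frac_silent=0.3)

    def test_fraction_range_checked(self):
        with pytest.raises(ConfigError):
            _cfg(frac_silent=1.2)

    def test_counts_checked(self):
        with pytest.raises(ConfigError):
            _cfg(n_tissues=0)

    def test_scales_positive(self):
        with pytest.raises(ConfigError):
            _cfg(background_sd=0.0)


class TestExpressionGenerator:
    def test_matrix_shape_and_metadata(self):
        cfg = _cfg()
        bundle, truth = generate_expression(cfg)
        assert bundle.matrix.values.shape[1] == cfg.n_samples
        assert bundle.probe_map.nunique() == cfg.n_genes
        assert set(bundle.matrix.sample_meta["tissue"]) == set(
            bundle.matrix.tissues
        )
        assert len(bundle.matrix.tissues) == cfg.n_tissues

    def test_class_proportions_within_rounding(self):
        cfg = _cfg(n_genes=1000)
        _, truth = generate_expression(cfg)
        counts = truth.class_counts()
        assert counts["housekeeping"] == round(cfg.frac_housekeeping * 1000)
        assert counts["tissue-specific"] == round(cfg.frac_tissue_specific * 1000)
        assert counts["silent"] == round(cfg.frac_silent * 1000)
        assert counts.sum() == 1000

    def test_every_gene_appears_exactly_once(self):
        _, truth = generate_expression(_cfg())
        assert truth.genes.index.is_unique

    def test_all_silent_config_calls_about_one_percent_per_spot(self):
        """With every gene at background, per-spot calls above the 99%
        control quantile occur at the cutoff's false-positive rate."""
        cfg = _cfg(
            n_genes=2000, frac_housekeeping=0, frac_tissue_specific=0,
            frac_silent=1, frac_flagged=0, seed=21,
        )
        bundle, _ = generate_expression(cfg)
        thr = detection_threshold(bundle.controls, 0.99)
        rate = (bundle.matrix.values.to_numpy() > thr).mean()
        assert 0.005 < rate < 0.02

    def test_same_seed_same_matrices(self):
        a, _ = generate_expression(_cfg())
        b, _ = generate_expression(_cfg())
        pd.testing.assert_frame_equal(a.matrix.values, b.matrix.values)
        np.testing.assert_array_equal(a.controls.intensities, b.controls.intensities)

    def test_different_seed_differs(self):
        a, _ = generate_expression(_cfg(seed=1))
        b, _ = generate_expression(_cfg(seed=2))
        assert not a.matrix.values.equals(b.matrix.values)


class TestAnnotationGenerator:
    def test_genes_do_not_overlap(self):
        cfg = _cfg()
        _, truth = generate_expression(cfg)
        ann, _ = generate_annotation(cfg, truth)
        for _, chrom_genes in ann.genes.groupby("chrom"):
            ordered = chrom_genes.sort_values("start")
            assert (ordered["start"].to_numpy()[1:]
                    > ordered["end"].to_numpy()[:-1]).all()

    def test_ridge_coverage_near_target(self):
        cfg = _cfg(n_genes=2000, n_chromosomes=8, seed=3)
        _, truth = generate_expression(cfg)
        ann, ridges = generate_annotation(cfg, truth)
        genome = int(
            ann.genes.groupby("chrom")["end"].max().sum()
        )
        frac = ridges.total_length() / genome
        assert 0.04 < frac < 0.2  # contiguous-block layout, ~10% by gene count

    def test_no_enrichment_keeps_hk_at_background(self):
        cfg = _cfg(n_genes=1500, ridge_hk_enrichment=1.0, seed=17)
        _, truth = generate_expression(cfg)
        ann, ridges = generate_annotation(cfg, truth)
        in_ridge = assign_in_ridge(ann, ridges)
        hk = truth.genes.index[truth.genes["label"] == "housekeeping"]
        res = permutation_enrichment(hk, ann.genes.index, in_ridge,
                                     n_perm=1000, seed=8)
        z = (res.observed_fraction - res.null_mean) / res.null_sd
        assert abs(z) <= 3

    def test_compactness_off_gives_calibrated_wilcoxon(self):
        """With no planted effect, the intron comparison is significant at
        alpha=0.01 in about 1% of generator draws."""
        from breadthatlas.features import compare_classes, compute_features

        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = _cfg(n_genes=300, compactness_effect=1.0, seed=seed)
            _, truth = generate_expression(cfg)
            ann, _ = generate_annotation(cfg, truth)
            feats = compute_features(ann)
            table = compare_classes(feats, truth.genes["label"])
            hits += table.loc["mean_intron_length", "pvalue"] < 0.01
        # Binomial(60, 0.01): P(X >= 5) ~ 3e-4
        assert hits <= 4


class TestOrthologGenerator:
    def test_fully_conserved_zero_noise_all_called(self):
        from breadthatlas.conservation import pair_conservation, to_relative_abundance

        cfg = _cfg(frac_conserved_orthologs=1.0, ortholog_noise_sd=1e-9,
                   n_ortholog_triplets=200)
        _, truth = generate_expression(cfg)
        tables, orth = generate_ortholog_expression(cfg, truth)
        species = list(tables)
        ra_a = to_relative_abundance(tables[species[0]])
        ra_b = to_relative_abundance(tables[species[1]])
        res = pair_conservation(ra_a, ra_b, orth[[species[0], species[1]]],
                                n_random_pairs=1000, seed=0)
        assert res.conserved_fraction == 1.0

    def test_no_conserved_calls_near_five_percent(self):
        from breadthatlas.conservation import pair_conservation, to_relative_abundance

        cfg = _cfg(frac_conserved_orthologs=0.0, n_ortholog_triplets=3000)
        _, truth = generate_expression(cfg)
        tables, orth = generate_ortholog_expression(cfg, truth)
        species = list(tables)
        ra_a = to_relative_abundance(tables[species[0]])
        ra_b = to_relative_abundance(tables[species[1]])
        res = pair_conservation(ra_a, ra_b, orth[[species[0], species[1]]],
                                n_random_pairs=5000, seed=0)
        assert 0.03 < res.conserved_fraction < 0.07

    def test_truth_table_matches_config(self):
        cfg = _cfg(frac_conserved_orthologs=0.25, n_ortholog_triplets=400)
        _, truth = generate_expression(cfg)
        generate_ortholog_expression(cfg, truth)
        assert truth.orthologs["conserved"].sum() == 100
        for col in truth.orthologs.columns:
            if col != "conserved":
                assert truth.orthologs[col].is_unique


class TestFileDeterminism:
    def test_same_config_same_files_byte_for_byte(self, tmp_path):
        cfg = _cfg()
        p1 = write_dataset(simulate_dataset(cfg), tmp_path / "run1")
        p2 = write_dataset(simulate_dataset(cfg), tmp_path / "run2")
        assert p1.keys() == p2.keys()
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name
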