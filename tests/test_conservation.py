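"""Relative-abundance transform, ortholog conservation calls, tissue similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from breadthatlas.conservation import (
    nearest_cross_species_neighbors,
    pair_conservation,
    tissue_similarity,
    to_relative_abundance,
)
from breadthatlas.errors import InputError


def _df(rows, index=None, columns=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    index = index or [f"g{i}" for i in range(rows.shape[0])]
    columns = columns or [f"t{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=index, columns=columns)


class TestRelativeAbundance:
    def test_uniform_vector(self):
        ra = to_relative_abundance(_df([[2, 2, 2, 2, 2]]))
        assert ra.iloc[0].tolist() == [0.2] * 5

    def test_proportional_vector(self):
        ra = to_relative_abundance(_df([[1, 2, 3, 4]]))
        np.testing.assert_allclose(ra.iloc[0], [0.1, 0.2, 0.3, 0.4])

    def test_zero_row_dropped(self):
        ra = to_relative_abundance(_df([[0, 0, 0], [1, 1, 2]]))
        assert list(ra.index) == ["g1"]

    def test_negative_entries_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ra = to_relative_abundance(_df([[-1, 2, 2]]))
        assert "clipping" in caplog.text
        np.testing.assert_allclose(ra.iloc[0], [0.0, 0.5, 0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
        st.floats(1e-6, 1e6),
    )
    def test_scale_invariance_and_row_sum(self, values, c):
        base = to_relative_abundance(_df([values]))
        scaled = to_relative_abundance(_df([[v * c for v in values]]))
        assert base.iloc[0].sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(base, scaled, atol=1e-9)


def _orth(n, prefix_a="a", prefix_b="b"):
    return pd.DataFrame(
        {
            "id_a": [f"{prefix_a}{i}" for i in range(n)],
            "id_b": [f"{prefix_b}{i}" for i in range(n)],
        }
    )


class TestPairConservation:
    def test_identical_profiles_called_conserved(self, rng):
        values = rng.uniform(0.1, 10, size=(50, 5))
        ra_a = to_relative_abundance(_df(values, index=[f"a{i}" for i in range(50)]))
        ra_b = to_relative_abundance(_df(values, index=[f"b{i}" for i in range(50)]))
        res = pair_conservation(ra_a, ra_b, _orth(50), n_random_pairs=500, seed=0)
        assert res.conserved_fraction == 1.0
        np.testing.assert_allclose(res.pairs["r"], 1.0)

    def test_correlation_symmetry(self, rng):
        va = rng.uniform(0.1, 10, size=(40, 5))
        vb = rng.uniform(0.1, 10, size=(40, 5))
        ra_a = to_relative_abundance(_df(va, index=[f"a{i}" for i in range(40)]))
        ra_b = to_relative_abundance(_df(vb, index=[f"b{i}" for i in range(40)]))
        fwd = pair_conservation(ra_a, ra_b, _orth(40), n_random_pairs=200, seed=1)
        rev = pair_conservation(
            ra_b, ra_a, _orth(40, "b", "a"), n_random_pairs=200, seed=1
        )
        np.testing.assert_allclose(fwd.pairs["r"], rev.pairs["r"])

    def test_null_quantile_matches_brute_force(self, rng):
        va = rng.uniform(0.1, 10, size=(60, 5))
        vb = rng.uniform(0.1, 10, size=(60, 5))
        ra_a = to_relative_abundance(_df(va, index=[f"a{i}" for i in range(60)]))
        ra_b = to_relative_abundance(_df(vb, index=[f"b{i}" for i in range(60)]))
        res = pair_conservation(ra_a, ra_b, _orth(60), n_random_pairs=1000, seed=2)
        xs = sorted(res.null_correlations)
        h = (len(xs) - 1) * 0.95
        lo = int(np.floor(h))
        oracle = xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])
        assert res.null_quantile == pytest.approx(oracle, abs=1e-12)

    def test_constant_profile_excluded(self, rng, caplog):
        va = rng.uniform(0.1, 10, size=(30, 5))
        va[0] = 3.0  # uniform RA -> zero variance -> undefined correlation
        vb = rng.uniform(0.1, 10, size=(30, 5))
        ra_a = to_relative_abundance(_df(va, index=[f"a{i}" for i in range(30)]))
        ra_b = to_relative_abundance(_df(vb, index=[f"b{i}" for i in range(30)]))
        with caplog.at_level("WARNING"):
            res = pair_conservation(ra_a, ra_b, _orth(30), n_random_pairs=200, seed=3)
        assert res.n_excluded == 1
        assert len(res.pairs) == 29

    def test_mismatched_panels_rejected(self):
        ra_a = _df([[0.5, 0.5]], columns=["x", "y"])
        ra_b = _df([[0.5, 0.5]], columns=["y", "x"])
        with pytest.raises(InputError):
            pair_conservation(ra_a, ra_b, _orth(1))

    def test_spearman_option(self, rng):
        va = rng.uniform(0.1, 10, size=(30, 5))
        ra_a = to_relative_abundance(_df(va, index=[f"a{i}" for i in range(30)]))
        ra_b = to_relative_abundance(_df(va, index=[f"b{i}" for i in range(30)]))
        res = pair_conservation(
            ra_a, ra_b, _orth(30), n_random_pairs=200, seed=4, method="spearman"
        )
        np.testing.assert_allclose(res.pairs["r"], 1.0)


class TestTissueSimilarity:
    def test_self_correlation_is_one(self, rng):
        ra = to_relative_abundance(_df(rng.uniform(0.1, 10, size=(20, 3))))
        sim = tissue_similarity({"s1": ra, "s2": ra})
        assert np.allclose(np.diag(sim.rho), 1.0)
        # identical tables: cross-species same-tissue correlation is exactly 1
        assert sim.rho.loc["s1:t0", "s2:t0"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        # gene profiles chosen so v's columns reverse u's gene ordering
        a = _df([[1, 10, 100], [2, 20, 200], [3, 30, 300]])
        b = _df([[3, 30, 300], [2, 20, 200], [1, 10, 100]])
        sim = tissue_similarity({"u": a, "v": b})
        assert sim.rho.loc["u:t0", "u:t1"] == pytest.approx(1.0)
        assert sim.rho.loc["u:t0", "v:t0"] == pytest.approx(-1.0)

    def test_too_few_rows_rejected(self):
        ra = _df([[1, 2], [2, 1]])
        with pytest.raises(InputError):
            tissue_similarity({"s1": ra, "s2": ra})

    def test_homologous_tissues_cluster_on_synthetic_atlas(self):
        # needs ortholog counts of the study's order: the homolog-vs-
        # non-homolog rho margin scales like 1/sqrt(n_triplets)
        from breadthatlas.config import SimConfig
        from breadthatlas.simulate import (
            generate_expression, generate_ortholog_expression,
        )

        cfg = SimConfig(n_genes=50, n_negative_controls=50,
                        n_ortholog_triplets=3000, seed=4)
        _, truth = generate_expression(cfg)
        tables, _ = generate_ortholog_expression(cfg, truth)
        ra = {sp: to_relative_abundance(t) for sp, t in tables.items()}
        sim = tissue_similarity(ra)
        nn = nearest_cross_species_neighbors(sim.rho)
        same_tissue = [
            col.split(":", 1)[1] == match.split(":", 1)[1]
            for col, match in nn.items()
        ]
        assert np.mean(same_tissue) == 1.0


class TestNullCalibration:
    def test_shuffled_orthology_calls_about_five_percent(self, rng):
        """With orthology destroyed, the 95%-quantile rule calls ~5%."""
        n = 2000
        va = rng.uniform(0.1, 10, size=(n, 5))
        vb = rng.uniform(0.1, 10, size=(n, 5))
        ra_a = to_relative_abundance(_df(va, index=[f"a{i}" for i in range(n)]))
        ra_b = to_relative_abundance(_df(vb, index=[f"b{i}" for i in range(n)]))
        res = pair_conservation(ra_a, ra_b, _orth(n), n_random_pairs=5000, seed=6)
        assert 0.03 < res.conserved_fraction < 0.07
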