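"""Diversity metrics, COG renormalisation, PCoA and PERMANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from strainmatch import (
    bray_curtis,
    cog_renormalise,
    dissimilarity_matrix,
    jaccard_binary,
    pb_ratio,
    pcoa,
    permanova,
    shannon_index,
)


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4))

    def test_single_species_is_zero(self):
        assert shannon_index([1.0]) == 0.0

    def test_hand_value(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=5e-5)

    def test_renormalises_away_unknown_fraction(self):
        # same composition scaled by (1 - unknown) must give the same H
        assert shannon_index([0.4, 0.2, 0.2]) == pytest.approx(
            shannon_index([0.5, 0.25, 0.25])
        )

    def test_include_unknown_flag(self):
        with_unknown = shannon_index(
            [0.25, 0.25], include_unknown=True, unknown_fraction=0.5
        )
        assert with_unknown > shannon_index([0.25, 0.25])

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = rng.dirichlet(np.ones(6))
            assert shannon_index(q) <= math.log(6) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])


class TestDissimilarities:
    def test_bray_curtis_cases(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0
        assert bray_curtis([0.5, 0.5, 0], [0, 0.5, 0.5]) == pytest.approx(0.5)

    def test_jaccard_cases(self):
        assert jaccard_binary([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)
        assert jaccard_binary([1, 1], [2, 3]) == 0.0
        assert jaccard_binary([1, 0], [0, 1]) == 1.0

    def test_flat_profile_bray_curtis_vs_jaccard(self):
        """On {0,c} profiles Bray-Curtis reduces to the Sorensen form
        symdiff/(|A|+|B|): never above Jaccard, equal exactly when the
        supports are identical or disjoint."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = rng.integers(0, 2, size=8).astype(float) * 0.3
            b = rng.integers(0, 2, size=8).astype(float) * 0.3
            if a.sum() == 0 or b.sum() == 0:
                continue
            bc, jc = bray_curtis(a, b), jaccard_binary(a, b)
            assert bc <= jc + 1e-12
            sa, sb = set(np.nonzero(a)[0]), set(np.nonzero(b)[0])
            if sa == sb or not (sa & sb):
                assert bc == pytest.approx(jc)
            elif sa != sb:
                assert bc < jc

    def test_matrix_properties(self, default_cohort):
        d = dissimilarity_matrix(default_cohort.abundance, "bray-curtis")
        x = d.to_numpy()
        assert np.allclose(x, x.T)
        assert np.allclose(np.diag(x), 0.0)
        assert (x >= -1e-12).all() and (x <= 1 + 1e-12).all()


class TestPBRatio:
    def test_simple_ratio(self):
        prof = pd.Series({"Prevotella_a": 0.2, "Bacteroides_b": 0.1})
        assert pb_ratio(prof) == pytest.approx(2.0)

    def test_zero_numerator(self):
        prof = pd.Series({"Prevotella_a": 0.0, "Bacteroides_b": 0.1})
        assert pb_ratio(prof) == 0.0

    def test_infinite_when_no_bacteroides(self):
        prof = pd.Series({"Prevotella_a": 0.2, "Bacteroides_b": 0.0})
        assert math.isinf(pb_ratio(prof))

    def test_undefined_is_nan(self):
        prof = pd.Series({"Prevotella_a": 0.0, "Bacteroides_b": 0.0})
        assert math.isnan(pb_ratio(prof))

    def test_explicit_taxa_override(self):
        prof = pd.Series({"x": 0.3, "y": 0.1})
        assert pb_ratio(prof, ["x"], ["y"]) == pytest.approx(3.0)


class TestCogRenormalise:
    def test_worked_multi_annotation_example(self):
        # 10 genes: 8 single-category, 1 with two categories, 1 unannotated.
        rows = [("s1", f"g{i}", "C") for i in range(8)]
        rows += [("s1", "g8", "E"), ("s1", "g8", "F"), ("s1", "g9", "NA")]
        prof = cog_renormalise(
            pd.DataFrame(rows, columns=["sample_id", "gene_id", "category"])
        )
        # raw weights: C 8/10, E 1/10, F 1/10, NA 1/10 -> sum 11/10
        assert prof.loc["s1"].sum() == pytest.approx(1.0)
        assert prof.loc["s1", "C"] == pytest.approx(8 / 11)
        assert prof.loc["s1", "NA"] == pytest.approx(1 / 11)

    def test_single_category_genes_identity(self):
        rows = [("s1", "g1", "C"), ("s1", "g2", "E")]
        prof = cog_renormalise(
            pd.DataFrame(rows, columns=["sample_id", "gene_id", "category"])
        )
        assert prof.loc["s1", "C"] == pytest.approx(0.5)

    def test_all_unannotated(self):
        rows = [("s1", "g1", "NA"), ("s1", "g2", "NA")]
        prof = cog_renormalise(
            pd.DataFrame(rows, columns=["sample_id", "gene_id", "category"])
        )
        assert prof.loc["s1", "NA"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, default_cohort):
        prof = cog_renormalise(default_cohort.cog)
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-9)


class TestPcoa:
    def test_collinear_points_recovered_in_one_dimension(self):
        # points at 0, 1, 3 on a line: Euclidean distances are exact
        d = pd.DataFrame(
            [[0, 1, 3], [1, 0, 2], [3, 2, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        res = pcoa(d, k=1)
        x = res.coordinates["PC1"].to_numpy()
        for i in range(3):
            for j in range(3):
                assert abs(x[i] - x[j]) == pytest.approx(d.iloc[i, j], abs=1e-8)

    def test_identical_samples_coincide(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        res = pcoa(d, k=1)
        assert np.allclose(res.coordinates.to_numpy(), 0.0, atol=1e-8)

    def test_two_blocks_separate_on_pc1(self):
        n = 6
        d = np.ones((n, n))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        frame = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        res = pcoa(frame, k=2)
        pc1 = res.coordinates["PC1"].to_numpy()
        assert (pc1[:3] > 0).all() != (pc1[3:] > 0).all()  # opposite signs


class TestPermanova:
    def _two_group_data(self, shift, n=10, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 4))
        x[n // 2 :] += shift
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=ids, columns=ids), labels

    def test_pseudo_f_matches_skbio(self):
        d, labels = self._two_group_data(shift=1.0, n=12, seed=3)
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(
            DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=list(labels),
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_strong_effect_hits_resolution_floor(self):
        # Only a permutation reproducing the 10/10 split can match the
        # observed F; the sampled permutations contain at most a couple of
        # those by chance, so p sits at (or within one hit of) the
        # 1/(n_permutations+1) resolution floor.
        d, labels = self._two_group_data(shift=50.0, n=20, seed=1)
        res = permanova(d, labels, n_permutations=999, seed=0)
        assert res.p_value <= 2 / 1000

    def test_exhaustive_enumeration_agrees_with_sampling(self):
        d, labels = self._two_group_data(shift=1.5, n=5, seed=2)
        exact = permanova(d, labels, exhaustive=True)
        sampled = permanova(d, labels, n_permutations=999, seed=4)
        assert abs(exact.p_value - sampled.p_value) < 0.05
        assert exact.n_permutations == 120

    def test_r_squared_is_permutation_invariant(self):
        d, labels = self._two_group_data(shift=1.0, n=10, seed=5)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(labels))
        permuted = d.iloc[idx, idx]
        a = permanova(d, labels, n_permutations=9, seed=0)
        b = permanova(permuted, labels[idx], n_permutations=9, seed=0)
        assert a.r_squared == pytest.approx(b.r_squared)
        assert a.pseudo_f == pytest.approx(b.pseudo_f)

    def test_continuous_predictor(self):
        rng = np.random.default_rng(6)
        covariate = rng.normal(size=12)
        x = np.outer(covariate, np.ones(3)) + rng.normal(size=(12, 3), scale=0.1)
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        res = permanova(
            pd.DataFrame(d, index=ids, columns=ids),
            covariate,
            n_permutations=999,
            seed=0,
        )
        assert res.p_value == pytest.approx(0.001)
        assert res.r_squared > 0.8

    def test_degenerate_predictors_rejected(self):
        d, labels = self._two_group_data(shift=0.0, n=6)
        with pytest.raises(ValueError):
            permanova(d, np.array(["a"] * 6), n_permutations=9)
        with pytest.raises(ValueError):
            permanova(d, np.ones(6), n_permutations=9)

    def test_seed_reproducible(self):
        d, labels = self._two_group_data(shift=0.5, n=10, seed=7)
        a = permanova(d, labels, n_permutations=99, seed=42)
        b = permanova(d, labels, n_permutations=99, seed=42)
        assert a.p_value == b.p_value
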