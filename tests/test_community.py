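"""Dissimilarities, ordination, clustering, rarefaction, differential taxa."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from stormtrace.community import (
    DissimilarityMatrix,
    bray_curtis,
    differential_taxa,
    hcluster,
    nmds,
    rarefy,
    spearman_dissim,
)


def _df(cols):
    return pd.DataFrame(cols)


class TestBrayCurtis:
    def test_identical_columns_are_zero(self):
        d = bray_curtis(_df({"a": [5, 3, 2], "b": [5, 3, 2]}))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_are_one(self):
        d = bray_curtis(_df({"a": [5, 0, 2, 0], "b": [0, 3, 0, 1]}))
        assert d.values[0, 1] == 1.0

    def test_hand_evaluated_example(self):
        # x=(6,0,2), y=(0,4,2): 1 - 2*2/14 = 0.714
        d = bray_curtis(_df({"x": [6, 0, 2], "y": [0, 4, 2]}))
        assert d.values[0, 1] == pytest.approx(1 - 4 / 14)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis(_df({"a": [1, 2], "b": [0, 0]}))

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 50, (20, 6)))
        d = bray_curtis(df)
        assert np.all(d.values >= 0) and np.all(d.values <= 1)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


class TestSpearmanDissim:
    def test_identical_vectors_zero(self):
        d = spearman_dissim(_df({"a": [1, 5, 3, 2], "b": [1, 5, 3, 2]}))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_reversed_ranks_one(self):
        d = spearman_dissim(_df({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]}))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        """(1 - rho)/2 equals mid-ranking followed by Pearson, to 1e-12."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.integers(0, 30, 25).astype(float)
            y = rng.integers(0, 30, 25).astype(float)
            d = spearman_dissim(_df({"a": x, "b": y}))
            rho = stats.pearsonr(
                stats.rankdata(x), stats.rankdata(y)
            ).statistic
            assert d.values[0, 1] == pytest.approx((1 - rho) / 2, abs=1e-12)

    def test_constant_vector_error_names_sample(self):
        with pytest.raises(ValueError, match="flat"):
            spearman_dissim(_df({"flat": [2, 2, 2], "b": [1, 2, 3]}))


class TestNMDS:
    def test_planar_configuration_has_low_stress(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 1.8], [2, 0.5]])
        d = squareform(pdist(pts))
        dm = DissimilarityMatrix(tuple("abcdef"), d / d.max(), "bray_curtis")
        coords, stress = nmds(dm, seed=0)
        assert stress < 0.01
        assert np.allclose(coords.mean(axis=0), 0, atol=1e-8)

    def test_recovers_configuration_up_to_procrustes(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        dm = DissimilarityMatrix(tuple(f"s{i}" for i in range(12)), d / d.max(),
                                 "bray_curtis")
        coords, _ = nmds(dm, n_starts=8, seed=3)
        _, _, disparity = procrustes(pts, coords.to_numpy())
        assert disparity < 0.05

    def test_k_must_be_less_than_n(self):
        d = DissimilarityMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]]), "bray_curtis")
        with pytest.raises(ValueError):
            nmds(d, k=2)


class TestHCluster:
    def test_close_pair_merges_first(self):
        vals = squareform([1.0, 10.0, 10.0])  # a-b close, c far
        d = DissimilarityMatrix(("a", "b", "c"), vals / 10, "bray_curtis")
        dendro = hcluster(d)
        cut = dendro.cut(2)
        assert cut["a"] == cut["b"] != cut["c"]
        assert np.all(np.diff(dendro.heights()) >= -1e-12)

    def test_ultrametric_input_reproduced_exactly(self):
        """Cophenetic distances of an ultrametric input equal the input."""
        # two pairs at height .2, joined at height .8
        vals = np.array(
            [
                [0, 0.2, 0.8, 0.8],
                [0.2, 0, 0.8, 0.8],
                [0.8, 0.8, 0, 0.2],
                [0.8, 0.8, 0.2, 0],
            ]
        )
        d = DissimilarityMatrix(("a", "b", "c", "d"), vals, "bray_curtis")
        dendro = hcluster(d)
        assert np.allclose(dendro.cophenetic(), vals)

    def test_two_contamination_groups_recovered(self, two_group_table):
        """Contaminated vs clean samples split at the two-cluster cut."""
        table, groups = two_group_table
        dendro = hcluster(bray_curtis(table))
        cut = dendro.cut(2)
        labels_c = {cut[s] for s in groups["contaminated"]}
        labels_u = {cut[s] for s in groups["clean"]}
        assert len(labels_c) == 1 and len(labels_u) == 1
        assert labels_c != labels_u

    def test_newick_roundtrip_has_all_leaves(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.integers(1, 50, (10, 5)),
                          columns=[f"s{i}" for i in range(5)])
        nwk = hcluster(bray_curtis(df)).to_newick()
        assert nwk.endswith(";")
        for i in range(5):
            assert f"s{i}:" in nwk


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        df = _df({"a": [5, 3, 2]})
        out = rarefy(df, 10, seed=1)
        assert (out["a"] == df["a"]).all()

    def test_column_sums_equal_depth(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.integers(0, 200, (30, 4)))
        out = rarefy(df, 100, seed=2)
        assert (out.sum(axis=0) == 100).all()
        assert (out <= df).all().all()

    def test_shallow_samples_dropped_with_warning(self):
        df = _df({"deep": [80, 40], "shallow": [3, 2]})
        with pytest.warns(UserWarning, match="shallow"):
            out = rarefy(df, 50, seed=3)
        assert list(out.columns) == ["deep"]

    def test_expected_counts_hypergeometric(self):
        """Mean rarefied count over 100 seeds matches depth * proportion."""
        df = _df({"a": [60, 30, 10]})
        depth = 50
        draws = np.array(
            [rarefy(df, depth, seed=s)["a"].to_numpy() for s in range(100)]
        )
        total = 100
        p = df["a"] / total
        expect = depth * p
        # hypergeometric variance with finite-population correction
        var = depth * p * (1 - p) * (total - depth) / (total - 1)
        se = np.sqrt(var / 100)
        assert np.all(np.abs(draws.mean(axis=0) - expect) <= 4 * se + 1e-9)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(_df({"a": [5]}), 0, seed=1)


class TestDifferentialTaxa:
    def test_identical_groups_nothing_significant(self, two_group_table):
        table, _ = two_group_table
        ids = table.sample_ids[:4]
        res = differential_taxa(
            table, {"g1": ids, "g2": ids}, rank="genus"
        )
        assert all(r.p_adj > 0.05 for r in res)

    def test_planted_contrast_directions(self, two_group_table):
        """Gut genera flag '+' in the contaminated group, background
        genera '-', at the genus floor of 1e-2."""
        table, groups = two_group_table
        res = differential_taxa(table, groups, rank="genus")
        sig = {r.taxon: r for r in res if r.p_adj < 0.05}
        assert sig, "no significant taxa on a planted contrast"
        from stormtrace.synthetic import ENV_GENERA, GUT_GENERA

        for taxon, r in sig.items():
            if taxon in GUT_GENERA:
                assert r.direction == "+"
            elif taxon in ENV_GENERA:
                assert r.direction == "-"
        assert any(t in GUT_GENERA for t in sig)
        assert any(t in ENV_GENERA for t in sig)
        for r in res:
            assert r.p_adj >= r.p_raw - 1e-15

    def test_abundance_floor_limits_tested_taxa(self, two_group_table):
        table, groups = two_group_table
        few = differential_taxa(table, groups, rank="genus", abundance_floor=0.2)
        many = differential_taxa(table, groups, rank="genus", abundance_floor=1e-6)
        assert len(few) < len(many)

    def test_small_group_rejected(self, two_group_table):
        table, groups = two_group_table
        with pytest.raises(ValueError, match=">= 2"):
            differential_taxa(
                table, {"g1": groups["clean"][:1], "g2": groups["contaminated"]}
            )
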