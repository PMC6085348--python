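"""FIO set construction, contamination index, correlations, sensitivity math."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stormtrace import synthetic as syn
from stormtrace.amplicon import (
    ContaminationIndex,
    build_fio_set_by_identity,
    build_fio_set_by_taxon,
    contamination_index,
    correlate_index_mpn,
    default_fio_list,
    genome_equivalents,
    reads_needed,
)
from stormtrace.matcher import percent_identity
from stormtrace.mpn import MPNEstimate


@pytest.fixture(scope="module")
def small_table(ref10):
    profs = [
        syn.compose_community(ref10, f, 40 + i, sample_id=f"S{i + 1}")
        for i, f in enumerate([0.0, 0.1, 0.3])
    ]
    return syn.simulate_amplicon_table(profs, ref10, depth=8_000, seed=41)


class TestTaxonSets:
    def test_single_genus_matches_labelled_rows(self, small_table):
        fio = build_fio_set_by_taxon(small_table, ["Escherichia/Shigella"])
        expected = {
            rid
            for rid, tax in small_table.taxa.items()
            if tax.endswith("Escherichia/Shigella")
        }
        assert fio.member_ids == expected
        assert fio.definition == "taxon_single"

    def test_absent_names_give_empty_set(self, small_table):
        fio = build_fio_set_by_taxon(small_table, ["Vibrio", "Salmonella"])
        assert fio.member_ids == frozenset()

    def test_list_is_union_of_singletons(self, small_table):
        names = ["Escherichia/Shigella", "Bacteroides", "Blautia", "Pseudomonas"]
        union = frozenset().union(
            *(build_fio_set_by_taxon(small_table, [n]).member_ids for n in names)
        )
        fio = build_fio_set_by_taxon(small_table, names)
        assert fio.member_ids == union
        assert fio.definition == "taxon_list"

    def test_matching_is_case_insensitive(self, small_table):
        a = build_fio_set_by_taxon(small_table, ["bacteroides"])
        b = build_fio_set_by_taxon(small_table, ["Bacteroides"])
        assert a.member_ids == b.member_ids != frozenset()

    def test_empty_name_list_rejected(self, small_table):
        with pytest.raises(ValueError):
            build_fio_set_by_taxon(small_table, [])

    def test_default_list_has_20_entries(self):
        assert len(default_fio_list()) == 20


class TestIdentitySet:
    def test_clean_table_recovers_gut_rows_exactly(self, ref10, small_table):
        fio = build_fio_set_by_identity(small_table, ref10.marker_catalog("gut"))
        gut_rows = {r.id for r in ref10.markers("gut")}
        assert fio.member_ids == gut_rows

    def test_stricter_threshold_gives_subset(self, ref10):
        prof = syn.compose_community(ref10, 0.3, seed=50)
        table = syn.simulate_amplicon_table(
            [prof], ref10, depth=2_000, seed=51, mutation_rate=0.004
        )
        gut = ref10.marker_catalog("gut")
        at99 = build_fio_set_by_identity(table, gut, threshold=99.0)
        at100 = build_fio_set_by_identity(table, gut, threshold=100.0)
        assert at100.member_ids <= at99.member_ids

    def test_membership_matches_all_pairs_identity(self, ref10, small_table):
        """Exhaustive oracle: for every row, max identity over all gut
        markers decides membership (quadratic, no prefilter, no best-hit)."""
        gut = ref10.marker_catalog("gut")
        min_len = int(0.9 * 400)
        expected = set()
        for rid in small_table.row_ids:
            seq = small_table.sequences[rid]
            for g in gut.values():
                ident, aln_len = percent_identity(seq, g)
                if ident >= 99.0 and aln_len >= min_len:
                    expected.add(rid)
                    break
        fio = build_fio_set_by_identity(small_table, gut)
        assert fio.member_ids == frozenset(expected)


class TestContaminationIndex:
    def test_arithmetic_and_zero_flag(self, ref10, small_table):
        fio = build_fio_set_by_identity(small_table, ref10.marker_catalog("gut"))
        rows = contamination_index(small_table, fio)
        for ci in rows:
            assert ci.index == pytest.approx(ci.raw_fraction * ci.dna_yield)
            assert 0.0 <= ci.raw_fraction <= 1.0
        byid = {ci.sample_id: ci for ci in rows}
        assert byid["S1"].raw_fraction == 0.0 and byid["S1"].zero_fio
        assert byid["S3"].raw_fraction == pytest.approx(0.3, abs=0.03)

    def test_fractions_partition_to_one(self, ref10, small_table):
        gut = build_fio_set_by_identity(small_table, ref10.marker_catalog("gut"))
        env_rows = frozenset(small_table.row_ids) - gut.member_ids
        from stormtrace.amplicon import FIOSet

        env = FIOSet(env_rows, "taxon_list", ("complement",))
        a = contamination_index(small_table, gut)
        b = contamination_index(small_table, env)
        for x, y in zip(a, b):
            assert x.raw_fraction + y.raw_fraction == pytest.approx(1.0)

    def test_index_increases_with_spiked_f(self, ref10):
        """At fixed DNA yield the index is strictly increasing in f."""
        fs = [0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
        profs = [
            syn.compose_community(ref10, f, 60 + i, sample_id=f"G{i}")
            for i, f in enumerate(fs)
        ]
        table = syn.simulate_amplicon_table(profs, ref10, depth=20_000, seed=61)
        table.sample_meta["dna_yield"] = 2.0
        fio = build_fio_set_by_identity(table, ref10.marker_catalog("gut"))
        idx = [ci.index for ci in contamination_index(table, fio)]
        assert all(b > a for a, b in zip(idx, idx[1:]))

    def test_missing_yield_rejected(self, ref10, small_table):
        from stormtrace.amplicon import FIOSet

        table = syn.simulate_amplicon_table(
            [syn.compose_community(ref10, 0.1, 1)], ref10, 100, 2
        )
        table.sample_meta = table.sample_meta.drop(columns=["dna_yield"])
        with pytest.raises(ValueError, match="dna_yield"):
            contamination_index(table, FIOSet(frozenset(), "taxon_list", ("x",)))


def _fake_indices(values):
    return [
        ContaminationIndex(f"S{i}", 0.1, 1.0, v, zero_fio=v == 0)
        for i, v in enumerate(values)
    ]


def _fake_mpns(values):
    return [MPNEstimate(v, "point") for v in values]


class TestCorrelation:
    def test_exact_loglinear_gives_r_one(self):
        idx = _fake_indices([0.01, 0.1, 1.0, 10.0])
        mpns = _fake_mpns([10.0, 100.0, 1000.0, 10000.0])
        res = correlate_index_mpn(idx, mpns)
        assert res.r == pytest.approx(1.0)
        assert res.n_used == 4

    def test_scale_invariance_under_log(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(0, 1, 20)
        mpns = _fake_mpns(list(rng.lognormal(5, 1, 20)))
        r1 = correlate_index_mpn(_fake_indices(vals), mpns).r
        r2 = correlate_index_mpn(_fake_indices(vals * 37.0), mpns).r
        assert r1 == pytest.approx(r2)

    def test_permuted_pairs_decorrelate(self):
        """Permutation oracle: mean r over 1,000 shuffles is ~0."""
        rng = np.random.default_rng(4)
        vals = list(rng.lognormal(0, 1, 30))
        mpn_vals = np.exp(np.log(vals) * 2 + rng.normal(0, 0.1, 30) + 5)
        rs = []
        for _ in range(1_000):
            perm = rng.permutation(30)
            rs.append(
                correlate_index_mpn(
                    _fake_indices(vals), _fake_mpns(list(mpn_vals[perm]))
                ).r
            )
        assert abs(float(np.mean(rs))) < 0.1

    def test_censored_substituted_at_limits(self):
        idx = _fake_indices([0.01, 0.1, 1.0, 10.0])
        mpns = [
            MPNEstimate(0.0, "below_lod"),
            MPNEstimate(500.0, "point"),
            MPNEstimate(5_000.0, "point"),
            MPNEstimate(math.inf, "above_uod"),
        ]
        res = correlate_index_mpn(idx, mpns)
        assert res.n_used == 4 and res.n_censored == 2
        # dropping both censored samples leaves too few pairs
        with pytest.raises(ValueError, match="usable pairs"):
            correlate_index_mpn(idx, mpns, censored_policy="drop")

    def test_zero_indices_dropped_under_log(self):
        idx = _fake_indices([0.0, 0.1, 1.0, 10.0])
        mpns = _fake_mpns([10.0, 100.0, 1000.0, 10000.0])
        res = correlate_index_mpn(idx, mpns)
        assert res.n_used == 3


class TestSensitivityArithmetic:
    def test_genome_equivalents_worked_example(self):
        # 1.15 ng DNA/ml with 3 Mbp genomes -> ~3.6e5 genomes/ml
        assert genome_equivalents(1.15) == pytest.approx(355_693, rel=2e-3)

    def test_linearity(self):
        assert genome_equivalents(2.3) == pytest.approx(
            2 * genome_equivalents(1.15)
        )

    def test_genome_mass_constant(self):
        # 3 Mbp * 649 g/mol / N_A = 3.233 fg per genome
        mass_fg = 1e-9 / genome_equivalents(1.0) * 1e15
        assert mass_fg == pytest.approx(3e6 * 649 / 6.022e23 * 1e15, rel=1e-4)

    def test_reads_needed(self):
        assert reads_needed(355_693, 1.0) == pytest.approx(3.6e5, rel=0.02)
        assert reads_needed(100.0, 100.0) == 1.0
        assert reads_needed(100.0, 0.5) == 2 * reads_needed(100.0, 1.0)
        with pytest.raises(ValueError):
            reads_needed(100.0, 0.0)


def test_indicator_definitions_order_by_breadth(ref10):
    """Across replicates, correlation with true f is weakest for the
    single-genus set, intermediate for the multi-genus list and strongest
    for the identity-matched set (which recovers every gut read)."""
    single, listed, matched = [], [], []
    gut = ref10.marker_catalog("gut")
    fio_names = default_fio_list()
    for rep in range(20):
        fs = np.geomspace(0.02, 0.5, 12)
        profs = [
            syn.compose_community(ref10, f, 7000 + 37 * rep + i, sample_id=f"S{i}")
            for i, f in enumerate(fs)
        ]
        table = syn.simulate_amplicon_table(profs, ref10, depth=4_000, seed=900 + rep)
        sets = {
            "single": build_fio_set_by_taxon(table, ["Escherichia/Shigella"]),
            "list": build_fio_set_by_taxon(table, fio_names),
            "match": build_fio_set_by_identity(table, gut),
        }
        logf = np.log10(fs)
        rs = {}
        for key, fio in sets.items():
            fracs = np.array(
                [ci.raw_fraction for ci in contamination_index(table, fio)]
            )
            mask = fracs > 0
            rs[key] = (
                stats.pearsonr(logf[mask], np.log10(fracs[mask])).statistic
                if mask.sum() >= 3
                else 0.0
            )
        single.append(rs["single"])
        listed.append(rs["list"])
        matched.append(rs["match"])
    assert np.mean(single) < np.mean(listed) < np.mean(matched)
    assert np.mean(matched) > 0.95
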