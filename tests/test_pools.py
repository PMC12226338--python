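"""Pool classification, footprint mapping, composition and registers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tripletrep.pools import (
    PoolRecord,
    RibozymeReference,
    SequencePool,
    class_proportions,
    classify,
    classify_pool,
    composition_stats,
    longest_match,
    map_sites,
    register_class,
    uniqueness_fraction,
)
from tripletrep.seqtools import AlphabetError, reverse_complement

rna = st.text(alphabet="ACGU", min_size=1, max_size=25)


def oracle_longest_match(seq, ref):
    """Quadratic common-suffix DP in plain Python (independent oracle)."""
    best, positions = 0, []
    prev = [0] * (len(ref) + 1)
    for i, qc in enumerate(seq):
        cur = [0] * (len(ref) + 1)
        for j, rc in enumerate(ref):
            if qc == rc:
                cur[j + 1] = prev[j] + 1
                if cur[j + 1] > best:
                    best = cur[j + 1]
                    positions = [(i - best + 1, j - best + 2 - 1)]
                elif cur[j + 1] == best > 0:
                    positions.append((i - best + 1, j + 1 - best))
        prev = cur
    return best, positions


class TestLongestMatch:
    def test_containment(self, toy_ref):
        ref = toy_ref.subunits["S1"]
        window = ref[40:55]
        length, pos = longest_match(window, ref)
        assert length == 15
        assert (0, 40) in pos

    def test_disjoint_alphabets(self):
        length, pos = longest_match("AAAA", "GGGGGG")
        assert length == 0 and pos == []

    def test_alphabet_violation(self):
        with pytest.raises(AlphabetError):
            longest_match("ACGT", "ACGU")

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGU"))
        ref = "".join(bases[rng.integers(0, 4, 200)])
        for _ in range(200):
            q = "".join(bases[rng.integers(0, 4, 20)])
            got = longest_match(q, ref)
            exp = oracle_longest_match(q, ref)
            assert got[0] == exp[0]
            assert sorted(got[1]) == sorted(exp[1])

    @given(seq=rna, ref=rna)
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_oracle_equivalence_property(self, seq, ref):
        got = longest_match(seq, ref)
        exp = oracle_longest_match(seq, ref)
        assert got[0] == exp[0]
        assert sorted(got[1]) == sorted(exp[1])


class TestClassify:
    def test_minus_homologous_construction(self, toy_ref):
        window = toy_ref.subunits["S1"][30:50]
        cls = classify(reverse_complement(window), toy_ref, min_match=12)
        assert cls.label == "minus_homologous"
        assert cls.best_match_len >= 20

    def test_plus_homologous_construction(self, toy_ref):
        window = toy_ref.subunits["S1"][30:50]
        cls = classify(window, toy_ref, min_match=12)
        assert cls.label == "plus_homologous"

    def test_minus_interval_in_plus_coordinates(self):
        ref = RibozymeReference({"R": "AAAAAAAAAACCCGGGUUUCCCAAAAAAAAAA"})
        window = ref.subunits["R"][10:25]
        cls = classify(reverse_complement(window), ref, min_match=12)
        assert cls.label == "minus_homologous"
        assert ("R", "-", 10, 25) in cls.match_intervals

    def test_reverse_complement_symmetry(self, toy_ref):
        # reverse-complementing the query swaps plus/minus roles
        rng = np.random.default_rng(3)
        for _ in range(20):
            start = int(rng.integers(0, 150))
            window = toy_ref.subunits["S1"][start : start + 18]
            fwd = classify(window, toy_ref, min_match=12)
            rev = classify(reverse_complement(window), toy_ref, min_match=12)
            assert fwd.label == "plus_homologous"
            assert rev.label == "minus_homologous"
            assert fwd.best_match_len == rev.best_match_len

    def test_random_query_specificity(self, toy_ref):
        # analytic bound on random 15-mers matching >= 12 nt by chance
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGU"))
        n_draws = 10_000
        hits = 0
        for _ in range(n_draws):
            q = "".join(bases[rng.integers(0, 4, 15)])
            if classify(q, toy_ref, min_match=12).label != "no_homology":
                hits += 1
        ref_nt = sum(len(s) for s in toy_ref.subunits.values())
        # 4 query offsets x reference positions x 2 strands, each 4^-12
        bound = 4 * (2 * ref_nt) * 4.0**-12
        assert hits / n_draws <= max(5 * bound, 10 / n_draws)

    def test_min_match_floor(self, toy_ref):
        with pytest.raises(ValueError):
            classify("ACGUACGUACGU", toy_ref, min_match=5)


class TestMapSites:
    def test_single_interval_histogram(self):
        ref = RibozymeReference({"R": "A" * 10 + "CCCGGGUUUCCCGGG" + "A" * 10})
        frag = ref.subunits["R"][10:25]
        pool = SequencePool([PoolRecord(id="x", sequence=frag, weight=2.0,
                                        lane_intensity=3.0)])
        hist = map_sites(pool, ref, min_match=12, seed=0)
        arr = hist[("R", "+")]
        assert np.all(arr[10:25] == 6.0)
        assert arr.sum() == pytest.approx(6.0 * 15)

    def test_lane_intensity_linearity(self, toy_ref):
        frag = toy_ref.subunits["S1"][60:80]
        p1 = SequencePool([PoolRecord(id="x", sequence=frag, lane_intensity=1.0)])
        p2 = SequencePool([PoolRecord(id="x", sequence=frag, lane_intensity=2.0)])
        h1 = map_sites(p1, toy_ref, seed=4)
        h2 = map_sites(p2, toy_ref, seed=4)
        for key in h1:
            assert np.allclose(2.0 * h1[key], h2[key])

    def test_multimapper_assignment_frequencies(self):
        # query matching two disjoint sites is assigned ~uniformly
        seg = "CCCGGGUUUCCC"
        ref = RibozymeReference({"R": seg + "A" * 12 + seg})
        pool = SequencePool([PoolRecord(id="x", sequence=seg)])
        first = 0
        n = 10_000
        for seed in range(n):
            hist = map_sites(pool, ref, min_match=12, seed=seed)
            if hist[("R", "+")][0] > 0:
                first += 1
        assert abs(first / n - 0.5) <= 0.02

    def test_mass_conserved_across_seeds(self, toy_ref):
        frag = toy_ref.subunits["S2"][12:30]
        pool = SequencePool([PoolRecord(id="x", sequence=frag, weight=1.5)])
        masses = set()
        for seed in range(5):
            hist = map_sites(pool, toy_ref, seed=seed)
            masses.add(round(sum(arr.sum() for arr in hist.values()), 9))
        assert len(masses) == 1


class TestProportionsAndComposition:
    def test_pure_minus_pool(self, toy_ref):
        rng = np.random.default_rng(9)
        recs = []
        for i in range(40):
            start = 3 * int(rng.integers(0, 50))
            frag = toy_ref.subunits["S1"][start : start + 15]
            recs.append(PoolRecord(id=f"m{i}", sequence=reverse_complement(frag),
                                   cycle=5))
        table = class_proportions(SequencePool(recs), toy_ref, min_match=12)
        assert table.loc[5, "minus_homologous"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, toy_ref):
        from tripletrep.simulate import PoolGenSpec, gen_emergent_pool

        spec = PoolGenSpec(seed=2, n_sequences=200,
                           class_weights=(0.3, 0.3, 0.2, 0.2),
                           length_range_nt=(12, 27))
        pool = gen_emergent_pool(toy_ref, spec)
        table = class_proportions(pool, toy_ref, min_match=12)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_length_band(self, tiny_pool, toy_ref):
        table = class_proportions(tiny_pool, toy_ref, length_band=(30, 27))
        assert table.empty

    def test_composition_counting(self):
        pool = SequencePool([PoolRecord(id="a", sequence="GCGC")])
        stats = composition_stats(pool)
        assert stats.gc_fraction == 1.0
        assert stats.g_to_c_ratio == pytest.approx(1.0)
        assert math.isnan(stats.a_to_u_ratio)

    def test_composition_zero_denominator(self):
        pool = SequencePool([PoolRecord(id="a", sequence="GGGG")])
        assert math.isnan(composition_stats(pool).g_to_c_ratio)

    def test_composition_split_invariance(self, tiny_pool):
        whole = composition_stats(tiny_pool)
        split_records = []
        for rec in tiny_pool:
            for half in "xy":
                split_records.append(
                    PoolRecord(id=rec.id + half, sequence=rec.sequence,
                               weight=rec.weight / 2, cycle=rec.cycle)
                )
        split = composition_stats(SequencePool(split_records[::-1]))
        assert split.gc_fraction == pytest.approx(whole.gc_fraction)
        assert split.g_to_c_ratio == pytest.approx(whole.g_to_c_ratio)

    def test_composition_label_filter(self, toy_ref):
        pool = SequencePool(
            [
                PoolRecord(id="a", sequence="GCGCGCGCG", label="no_homology"),
                PoolRecord(id="b", sequence="AUAUAUAUA", label="minus_homologous"),
            ]
        )
        stats = composition_stats(pool, labels={"no_homology"})
        assert stats.gc_fraction == pytest.approx(1.0)


class TestUniquenessAndRegister:
    def test_uniqueness(self):
        distinct = SequencePool(
            [PoolRecord(id=str(i), sequence="ACG" * (i + 3)) for i in range(5)]
        )
        assert uniqueness_fraction(distinct) == 1.0
        repeated = SequencePool(
            [PoolRecord(id=str(i), sequence="ACGACGACG") for i in range(5)]
        )
        assert uniqueness_fraction(repeated) == 0.0

    def test_uniqueness_mixture(self):
        # 90 singletons + 5 doubletons = 100 records, 90% unique
        records = []
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGU"))
        seqs = {"".join(bases[rng.integers(0, 4, 15)]) for _ in range(200)}
        seqs = sorted(seqs)[:95]
        for i, s in enumerate(seqs[:90]):
            records.append(PoolRecord(id=f"u{i}", sequence=s))
        for i, s in enumerate(seqs[90:95]):
            records.append(PoolRecord(id=f"d{i}a", sequence=s))
            records.append(PoolRecord(id=f"d{i}b", sequence=s))
        assert uniqueness_fraction(SequencePool(records)) == pytest.approx(0.90)

    def test_register_labels(self):
        assert register_class(14, {0, 5}) == "(3)n+5"
        assert register_class(18, {0, 5}) == "(3)n"
        assert register_class(1, {0, 5}) is None

    def test_register_ambiguous_offsets(self):
        with pytest.raises(ValueError, match="congruent"):
            register_class(12, {0, 3})

    def test_register_shorter_than_offset(self):
        assert register_class(2, {0, 5}) is None
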