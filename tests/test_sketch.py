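"""kmer_sketch unit + property tests (string-level oracles throughout)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guideasm.sketch import (
    KmerSet,
    Sketch,
    ani_from_jaccard,
    bottom_sketch,
    build_kmer_set,
    canonical_kmer_codes,
    canonical_kmers,
    containment,
    estimate_ani,
    kmer_intersection_size,
    merge_sketches,
    mix64,
    read_sketch,
    revcomp,
    sketch_jaccard,
    write_sketch,
)
from tests.conftest import mutate_subs, random_dna

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=200)


class TestCanonicalKmers:
    def test_acgt_k3(self):
        assert canonical_kmers("ACGT", 3) == {"ACG": 2}

    def test_homopolymer(self):
        assert canonical_kmers("AAAA", 2) == {"AA": 3}

    def test_all_windows_contain_n(self):
        assert canonical_kmers("ACNGT", 3) == {}

    def test_k_longer_than_sequence(self):
        assert canonical_kmers("ACG", 5) == {}

    def test_case_insensitive(self):
        assert canonical_kmers("acgt", 3) == canonical_kmers("ACGT", 3)

    @given(dna_n, st.integers(1, 8))
    @settings(max_examples=100, deadline=None)
    def test_codes_agree_with_strings(self, seq, k):
        oracle = canonical_kmers(seq, k)
        codes = canonical_kmer_codes(seq, k)
        assert len(codes) == sum(oracle.values())
        assert len(np.unique(codes)) == len(oracle)

    @given(dna, st.integers(1, 8))
    @settings(max_examples=100, deadline=None)
    def test_strand_invariance(self, seq, k):
        assert canonical_kmers(seq, k) == canonical_kmers(revcomp(seq), k)


class TestBuildKmerSet:
    def test_duplicate_sequence_is_noop(self):
        one = build_kmer_set(["ACGTACGTAAGG"], 4)
        two = build_kmer_set(["ACGTACGTAAGG"] * 2, 4)
        assert np.array_equal(one.hashes, two.hashes)

    def test_revcomp_gives_identical_set(self):
        s = "ACGTTGCACCA"
        a = build_kmer_set([s], 3)
        b = build_kmer_set([revcomp(s)], 3)
        assert np.array_equal(a.hashes, b.hashes)

    def test_size_matches_bruteforce_k28(self, rng):
        seq = random_dna(rng, 1000)
        ks = build_kmer_set([seq], 28)
        assert len(ks) == len(canonical_kmers(seq, 28))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_set([], 5)

    def test_hash_is_injective_on_codes(self, rng):
        codes = np.unique(rng.integers(0, 2**56, 5000).astype(np.uint64))
        assert len(np.unique(mix64(codes))) == len(codes)


class TestBottomSketch:
    def test_saturation(self):
        ks = build_kmer_set(["ACGTACGTA"], 4)
        sk = bottom_sketch(ks, 1000)
        assert np.array_equal(sk.hashes, ks.hashes)

    def test_singleton_is_global_min(self, rng):
        ks = build_kmer_set([random_dna(rng, 500)], 7)
        sk = bottom_sketch(ks, 1)
        assert sk.hashes[0] == ks.hashes.min()

    def test_sketch_subset_of_full_set(self, rng):
        ks = build_kmer_set([random_dna(rng, 2000)], 11)
        sk = bottom_sketch(ks, 50)
        assert np.isin(sk.hashes, ks.hashes).all()

    def test_sketch_containment_close_to_exact(self, rng):
        base = random_dna(rng, 10_000)
        other = mutate_subs(base, 0.01, rng)
        k = 21
        ks_a, ks_b = build_kmer_set([base], k), build_kmer_set([other], k)
        sk = bottom_sketch(ks_a, 400)
        exact = np.isin(ks_a.hashes, ks_b.hashes).sum() / len(ks_a)
        assert abs(containment(sk, ks_b) - exact) <= 0.1

    def test_mergeability(self, rng):
        a, b = random_dna(rng, 3000), random_dna(rng, 3000)
        k, s = 15, 100
        sk_cat = bottom_sketch(build_kmer_set([a, b], k), s)
        merged = merge_sketches(
            bottom_sketch(build_kmer_set([a], k), s),
            bottom_sketch(build_kmer_set([b], k), s),
        )
        assert np.array_equal(sk_cat.hashes, merged.hashes)


class TestContainment:
    def test_self_containment_is_one(self, rng):
        ks = build_kmer_set([random_dna(rng, 5000)], 21)
        assert containment(bottom_sketch(ks, 200), ks) == 1.0

    def test_reads_from_reference_full_containment(self, rng):
        genome = random_dna(rng, 5000)
        reads = [genome[i : i + 100] for i in range(0, 4901, 20)]
        k = 21
        ref = bottom_sketch(build_kmer_set([genome], k), 500)
        assert containment(ref, build_kmer_set(reads, k)) == 1.0

    def test_unrelated_genome_near_zero(self, rng):
        a, b = random_dna(rng, 20_000), random_dna(rng, 20_000)
        k = 28
        sk = bottom_sketch(build_kmer_set([a], k), 500)
        reads_b = build_kmer_set([b[i : i + 100] for i in range(0, 19_901, 10)], k)
        assert containment(sk, reads_b) < 0.01

    def test_empty_sketch_rejected(self):
        empty = Sketch(k=5, s=10, hashes=np.empty(0, dtype=np.uint64))
        ks = build_kmer_set(["ACGTACGT"], 5)
        with pytest.raises(ValueError):
            containment(empty, ks)

    def test_monotone_in_mutation_rate(self, rng):
        from scipy.stats import spearmanr

        genome = random_dna(rng, 20_000)
        k = 21
        ref = bottom_sketch(build_kmer_set([genome], k), 500)
        rates = np.linspace(0.0, 0.09, 10)
        values = []
        for rate in rates:
            cs = []
            for rep in range(3):
                mut = mutate_subs(genome, rate, np.random.default_rng([rep, int(rate * 1e6)]))
                reads = [mut[i : i + 100] for i in range(0, len(mut) - 100, 25)]
                cs.append(containment(ref, build_kmer_set(reads, k)))
            values.append(np.mean(cs))
        rho, _ = spearmanr(rates, values)
        assert rho < -0.95
        assert all(x >= y - 0.02 for x, y in zip(values, values[1:]))


class TestIntersectionSize:
    def test_disjoint(self, rng):
        a = KmerSet(5, np.array([1, 2, 3], dtype=np.uint64))
        b = KmerSet(5, np.array([4, 5], dtype=np.uint64))
        assert kmer_intersection_size(a, b) == 0

    def test_identical(self, rng):
        ks = build_kmer_set([random_dna(rng, 1000)], 9)
        assert kmer_intersection_size(ks, ks) == len(ks)

    def test_string_level_oracle(self, rng):
        cluster = [random_dna(rng, 4000), random_dna(rng, 3000)]
        base = cluster[0]
        reads = [base[i : i + 80] for i in range(0, 3900, 40)] + [random_dna(rng, 80) for _ in range(20)]
        k = 28
        got = kmer_intersection_size(build_kmer_set(cluster, k), build_kmer_set(reads, k))
        cluster_strings = set().union(*(canonical_kmers(s, k) for s in cluster))
        read_strings = set().union(*(canonical_kmers(r, k) for r in reads))
        assert got == len(cluster_strings & read_strings)

    def test_k_mismatch_rejected(self):
        a = KmerSet(5, np.array([1], dtype=np.uint64))
        b = KmerSet(7, np.array([1], dtype=np.uint64))
        with pytest.raises(ValueError):
            kmer_intersection_size(a, b)


class TestEstimateAni:
    def test_self_is_100(self, rng):
        sk = bottom_sketch(build_kmer_set([random_dna(rng, 50_000)], 21), 1000)
        assert estimate_ani(sk, sk) == 100.0

    def test_unrelated_undetected_or_low(self, rng):
        k = 21
        a = bottom_sketch(build_kmer_set([random_dna(rng, 100_000)], k), 1000)
        b = bottom_sketch(build_kmer_set([random_dna(rng, 100_000)], k), 1000)
        ani = estimate_ani(a, b)
        assert ani is None or ani < 80

    @pytest.mark.parametrize("rep", range(10))
    def test_three_percent_strain(self, rep):
        rng = np.random.default_rng([42, rep])
        genome = random_dna(rng, 200_000)
        strain = mutate_subs(genome, 0.03, rng)
        k = 21
        a = bottom_sketch(build_kmer_set([genome], k), 1000)
        b = bottom_sketch(build_kmer_set([strain], k), 1000)
        ani = estimate_ani(a, b)
        assert ani is not None and 95.5 <= ani <= 98.5

    def test_symmetry(self, rng):
        a = bottom_sketch(build_kmer_set([random_dna(rng, 30_000)], 21), 500)
        bseq = mutate_subs(random_dna(rng, 30_000), 0.0, rng)
        b = bottom_sketch(build_kmer_set([bseq], 21), 500)
        assert estimate_ani(a, b) == estimate_ani(b, a)

    def test_jaccard_transform_limits(self):
        assert ani_from_jaccard(0.0, 21) is None
        assert ani_from_jaccard(1.0, 21) == 100.0


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        sk = bottom_sketch(build_kmer_set([random_dna(rng, 2000)], 17, "g1"), 64)
        path = tmp_path / "g1.sketch"
        write_sketch(sk, path)
        back = read_sketch(path)
        assert back.k == sk.k and back.s == sk.s and back.seed == sk.seed
        assert back.source_id == "g1"
        assert np.array_equal(back.hashes, sk.hashes)
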