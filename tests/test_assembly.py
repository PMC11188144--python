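"""guided_assembly unit + property tests."""

import numpy as np
import pytest

from guideasm.assembly import (
    STOP_ALL_READS,
    STOP_ALL_REFS,
    STOP_CUMULATIVE,
    STOP_LONGEST,
    ClusterAssemblyState,
    GuideResult,
    assemble_against_reference,
    assemble_cluster,
    build_agp,
    check_termination,
    order_next_genome,
)
from guideasm.cull import GenomeCluster, genome_sketch
from guideasm.model import Read, ReferenceGenome
from guideasm.sketch import build_kmer_set
from tests.conftest import mutate_subs, random_dna, tile_reads


def contig_stub(length, cid="c", guide="g", interval=None):
    from guideasm.assembly import Contig

    interval = interval or (0, length)
    return Contig(cid, "A" * length, guide, interval, frozenset())


class TestOrderNextGenome:
    def test_single_genome(self, rng):
        g = ReferenceGenome("only", random_dna(rng, 5000))
        sketches = {"only": genome_sketch(g)}
        state = ClusterAssemblyState(1, ["only"], {"r1"})
        kmers = build_kmer_set([g.sequence[:200]], 21)
        assert order_next_genome(state, kmers, sketches, {"only": 5000}) == "only"

    def test_prefers_contained_genome(self):
        rng = np.random.default_rng(55)
        a_seq = random_dna(rng, 20_000)
        b_seq = random_dna(rng, 20_000)
        sample = mutate_subs(a_seq, 0.01, rng)
        reads = [sample[i : i + 100] for i in range(0, 19_900, 50)]
        sketches = {
            "a": genome_sketch(ReferenceGenome("a", a_seq)),
            "b": genome_sketch(ReferenceGenome("b", b_seq)),
        }
        state = ClusterAssemblyState(1, ["a", "b"], set())
        kmers = build_kmer_set(reads, 21)
        assert order_next_genome(state, kmers, sketches, {"a": 20_000, "b": 20_000}) == "a"

    def test_tie_prefers_longer_then_id(self, rng):
        seq = random_dna(rng, 10_000)
        long_g = ReferenceGenome("z_long", seq + random_dna(rng, 5000))
        short_g = ReferenceGenome("a_short", seq[:10_000])
        sketches = {g.genome_id: genome_sketch(g) for g in (long_g, short_g)}
        state = ClusterAssemblyState(1, ["z_long", "a_short"], set())
        empty_pool = build_kmer_set(["ACGT" * 6], 21)  # containment ~0 for both
        chosen = order_next_genome(
            state, empty_pool, sketches, {"z_long": 15_000, "a_short": 10_000}
        )
        assert chosen == "z_long"


class TestAssembleAgainstReference:
    def test_covered_prefix_one_contig(self, rng):
        guide = ReferenceGenome("g", random_dna(rng, 20_000))
        reads = tile_reads(guide.sequence[:10_000], 100, 50)
        res = assemble_against_reference(reads, guide)
        assert len(res.contigs) == 1
        c = res.contigs[0]
        assert c.guide_interval == (0, 10_000)
        assert c.sequence == guide.sequence[:10_000]
        # AGP: W row 1..10000 then N row 10001..20000
        fields = [r.to_fields() for r in res.agp]
        assert fields[0][:6] == ["g", "1", "10000", "1", "W", "g_1"]
        assert fields[1][:6] == ["g", "10001", "20000", "2", "N", "10000"]

    def test_short_runs_dropped_reads_returned(self, rng):
        guide = ReferenceGenome("g", random_dna(rng, 5000))
        # runs of 600, 450, 800 separated by gaps
        reads = (
            tile_reads(guide.sequence[0:600], 100, 100, "a")
            + tile_reads(guide.sequence[1000:1450], 100, 50, "b")
            + tile_reads(guide.sequence[2000:2800], 100, 100, "c")
        )
        # offset the b/c reads to their true positions by re-tiling via map:
        reads = [
            Read(r.read_id, r.sequence) for r in reads
        ]
        res = assemble_against_reference(reads, guide)
        lengths = sorted(len(c) for c in res.contigs)
        assert lengths == [600, 800]
        used_prefixes = {rid[0] for rid in res.used_read_ids}
        assert used_prefixes == {"a", "c"}  # 450 bp run's reads stay unassigned

    def test_single_shallow_read_no_contig(self, rng):
        guide = ReferenceGenome("g", random_dna(rng, 2000))
        res = assemble_against_reference([Read("r", guide.sequence[500:600])], guide)
        assert res.contigs == [] and res.used_read_ids == set()

    def test_zero_alignments_legal(self, rng):
        guide = ReferenceGenome("g", random_dna(rng, 2000))
        res = assemble_against_reference([Read("r", random_dna(rng, 100))], guide)
        assert res.contigs == []

    def test_contigs_are_guide_substrings(self, rng):
        guide = ReferenceGenome("g", random_dna(rng, 10_000))
        sample = mutate_subs(guide.sequence, 0.01, rng)
        reads = tile_reads(sample, 100, 30)
        res = assemble_against_reference(reads, guide)
        for c in res.contigs:
            s, e = c.guide_interval
            assert c.sequence == guide.sequence[s:e]
            assert len(c.sequence) == e - s


class TestAGP:
    def test_tiles_exactly(self, rng):
        contigs = [contig_stub(600, "c1", "g", (100, 700)), contig_stub(500, "c2", "g", (900, 1400))]
        records = build_agp("g", 2000, contigs)
        # coordinates 1-based inclusive, strictly increasing, no overlap
        cursor = 0
        for r in records:
            assert r.object_start == cursor + 1
            cursor = r.object_end
        assert cursor == 2000
        assert [r.component_type for r in records] == ["N", "W", "N", "W", "N"]

    def test_roundtrip_reconstructs_contigs(self, tmp_path, rng):
        from guideasm import io as gio

        guide = ReferenceGenome("g", random_dna(rng, 8000))
        reads = tile_reads(guide.sequence[500:2500], 100, 40, "x") + tile_reads(
            guide.sequence[4000:6000], 100, 40, "y"
        )
        res = assemble_against_reference(reads, guide)
        gio.write_agp(res.agp, tmp_path / "a.agp")
        rows = gio.read_agp(tmp_path / "a.agp")
        by_id = {c.contig_id: c for c in res.contigs}
        for row in rows:
            if row[4] != "W":
                continue
            start, end = int(row[1]) - 1, int(row[2])
            assert by_id[row[5]].sequence == guide.sequence[start:end]


class TestCheckTermination:
    def _result(self, guide, contig_lengths):
        contigs = [
            contig_stub(n, f"c{i}", guide, (i * 10_000, i * 10_000 + n))
            for i, n in enumerate(contig_lengths)
        ]
        return GuideResult(guide, contigs, [], set(), {})

    def test_all_reads_first(self):
        state = ClusterAssemblyState(1, ["g2"], set())
        reason, retain = check_termination(state, self._result("g1", [100]), 10_000, 3)
        assert reason == STOP_ALL_READS and retain

    def test_all_refs_second(self):
        state = ClusterAssemblyState(1, [], {"r1"})
        reason, retain = check_termination(state, self._result("g1", [100]), 10_000, 3)
        assert reason == STOP_ALL_REFS and retain

    def test_cumulative_below_5pct_discards(self):
        state = ClusterAssemblyState(1, ["g2"], {"r1"})
        # 4% of the guide assembled in a 3-genome cluster
        reason, retain = check_termination(state, self._result("g1", [4000]), 100_000, 3)
        assert reason == STOP_CUMULATIVE and not retain

    def test_longest_1999_triggers_criterion_iv(self):
        state = ClusterAssemblyState(1, ["g2"], {"r1"})
        # 3 x 1999 bp: cumulative 5.997% passes iii, longest fails iv
        reason, retain = check_termination(state, self._result("g1", [1999] * 3), 100_000, 3)
        assert reason == STOP_LONGEST and not retain

    def test_longest_2000_continues(self):
        state = ClusterAssemblyState(1, ["g2"], {"r1"})
        reason, retain = check_termination(state, self._result("g1", [2000] * 3), 100_000, 3)
        assert reason == "continue" and retain

    def test_singleton_retains_despite_iv(self):
        state = ClusterAssemblyState(1, ["g2"], {"r1"})
        reason, retain = check_termination(state, self._result("g1", [1500] * 10), 100_000, 1)
        assert reason == STOP_LONGEST and retain


class TestAssembleCluster:
    def _cluster(self, genomes, k=28):
        ids = tuple(sorted(g.genome_id for g in genomes))
        longest = max(genomes, key=lambda g: (len(g.sequence), g.genome_id))
        return GenomeCluster(
            1, ids, longest.genome_id,
            build_kmer_set([g.sequence for g in genomes], k),
        )

    def test_all_reads_consumed_by_first_genome(self, rng):
        seq = random_dna(rng, 10_000)
        g = ReferenceGenome("a", seq)
        reads = tile_reads(seq, 100, 20)
        contigs, agp, used, log, state, _ = assemble_cluster(
            self._cluster([g]), reads, {"a": g}
        )
        assert state.stop_reason == STOP_ALL_READS
        assert used == {r.read_id for r in reads}
        assert len(contigs) == 1

    def test_two_strain_cluster_recovers_both(self):
        rng = np.random.default_rng(66)
        a_seq = random_dna(rng, 30_000)
        b_seq = a_seq[:15_000] + random_dna(rng, 15_000)  # shares half
        ga, gb = ReferenceGenome("a", a_seq), ReferenceGenome("b", b_seq)
        reads = tile_reads(a_seq, 100, 20, "ra") + tile_reads(b_seq[15_000:], 100, 20, "rb")
        contigs, agp, used, log, state, _ = assemble_cluster(
            self._cluster([ga, gb]), reads, {"a": ga, "b": gb}
        )
        guides = {c.guide_genome_id for c in contigs}
        assert guides == {"a", "b"}
        assert state.stop_reason in (STOP_ALL_READS, STOP_ALL_REFS)

    def test_weak_third_genome_discarded(self):
        rng = np.random.default_rng(67)
        a_seq = random_dna(rng, 30_000)
        ga = ReferenceGenome("a", a_seq)
        gb = ReferenceGenome("b", mutate_subs(a_seq, 0.02, rng))
        gc_ = ReferenceGenome("c", random_dna(rng, 30_000))  # attracts ~nothing
        # noise keeps the pool nonempty after guide a, so the next guide
        # assembles ~0% and criterion iii fires with the result discarded
        reads = tile_reads(a_seq, 100, 25) + [
            Read(f"noise{i}", random_dna(rng, 100)) for i in range(30)
        ]
        contigs, agp, used, log, state, _ = assemble_cluster(
            self._cluster([ga, gb, gc_]), reads, {"a": ga, "b": gb, "c": gc_}
        )
        assert state.stop_reason == STOP_CUMULATIVE
        assert {c.guide_genome_id for c in contigs} == {"a"}
        discarded = [row for row in log if row["retained"] == "no"]
        assert len(discarded) == 1

    def test_read_partition_invariant(self, rng):
        seq = random_dna(rng, 20_000)
        g = ReferenceGenome("a", seq)
        reads = tile_reads(seq[:8000], 100, 40) + [
            Read(f"noise{i}", random_dna(rng, 100)) for i in range(20)
        ]
        contigs, agp, used, log, state, _ = assemble_cluster(
            self._cluster([g]), reads, {"a": g}
        )
        all_ids = {r.read_id for r in reads}
        assert used | state.unassigned_read_ids == all_ids
        assert used & state.unassigned_read_ids == set()

    def test_supporting_reads_disjoint_across_guides(self):
        rng = np.random.default_rng(68)
        a_seq = random_dna(rng, 20_000)
        b_seq = mutate_subs(a_seq, 0.01, rng)
        ga, gb = ReferenceGenome("a", a_seq), ReferenceGenome("b", b_seq)
        reads = tile_reads(a_seq, 100, 30)
        contigs, agp, used, log, state, _ = assemble_cluster(
            self._cluster([ga, gb]), reads, {"a": ga, "b": gb}
        )
        seen = {}
        for c in contigs:
            for rid in c.supporting_read_ids:
                assert seen.setdefault(rid, c.guide_genome_id) == c.guide_genome_id
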