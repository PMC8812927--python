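"""Fixture generation: genomes, error injection, reads and alignments."""

import numpy as np
import pytest

from oracles import semiglobal_optima
from repolish import (
    Assembly,
    ErrorProfile,
    exhaustive_align,
    inject_errors,
    make_genome,
    reverse_complement,
    simulate_reads,
)
from repolish.sim import SimRead, cigar_edit_distance, write_fastq


class TestMakeGenome:
    def test_planted_intervals_are_character_identical(self):
        genome, intervals = make_genome(10000, 1000, 2, seed=0)
        assert len(intervals) == 2
        (s1, e1), (s2, e2) = intervals
        seq = genome.contigs["chromosome"]
        assert seq[s1:e1] == seq[s2:e2]
        assert e1 - s1 == 1000

    def test_no_repeats_requested_reports_no_intervals(self):
        genome, intervals = make_genome(5000, seed=0)
        assert intervals == []
        assert genome.total_length == 5000

    def test_seeded_determinism(self):
        a, _ = make_genome(3000, 200, 2, seed=7)
        b, _ = make_genome(3000, 200, 2, seed=7)
        c, _ = make_genome(3000, 200, 2, seed=8)
        assert a.contigs == b.contigs
        assert a.contigs != c.contigs

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            make_genome(1000, 600, 2, seed=0)


class TestInjectErrors:
    def test_zero_rates_change_nothing(self):
        genome, _ = make_genome(5000, seed=1)
        profile = ErrorProfile(0.0, 0.0, 0.0, 0.0, seed=1)
        mutated, errors = inject_errors(genome, profile)
        assert mutated.contigs == genome.contigs and errors == []

    def test_seeded_runs_are_identical(self):
        genome, _ = make_genome(20000, seed=2)
        profile = ErrorProfile(seed=5)
        m1, e1 = inject_errors(genome, profile)
        m2, e2 = inject_errors(genome, profile)
        assert m1.contigs == m2.contigs and e1 == e2

    def test_error_context_rules_respected(self):
        genome, _ = make_genome(50000, seed=3)
        profile = ErrorProfile(0.002, 0.002, 0.002, 0.002, seed=3)
        _, errors = inject_errors(genome, profile)
        seq = genome.contigs["chromosome"]
        assert {e.type for e in errors} >= {"sub", "hp_ins", "hp_del"}
        for e in errors:
            p = e.position
            in_run = (p > 0 and seq[p] == seq[p - 1]) or (
                p + 1 < len(seq) and seq[p] == seq[p + 1]
            )
            if e.type in ("hp_ins", "hp_del"):
                assert in_run
                if e.type == "hp_ins":
                    assert e.alt_allele == seq[p]
            elif e.type in ("other_ins", "other_del"):
                assert not in_run
            else:
                assert e.ref_allele == seq[p] != e.alt_allele

    def test_truth_list_round_trips_through_alignment(self):
        # distance between clean and mutated equals the number of errors
        from repolish import global_align

        genome, _ = make_genome(30000, seed=4)
        profile = ErrorProfile(0.001, 0.001, 0.001, 0.001, seed=4)
        mutated, errors = inject_errors(genome, profile)
        dist, _ = global_align(
            mutated.contigs["chromosome"], genome.contigs["chromosome"]
        )
        assert dist == len(errors)

    def test_in_repeat_flag_follows_intervals(self):
        genome, intervals = make_genome(30000, 3000, 2, seed=6)
        profile = ErrorProfile(0.003, 0.0, 0.0, 0.0, seed=6)
        _, errors = inject_errors(genome, profile, repeat_intervals=intervals)
        for e in errors:
            expected = any(s <= e.position < en for s, en in intervals)
            assert e.in_repeat == expected


class TestSimulateReads:
    def test_read_count_hits_target_depth(self):
        genome, _ = make_genome(10000, seed=0)
        reads = simulate_reads(genome, read_length=150, depth=300, seed=0)
        assert len(reads) == 20000
        realized = len(reads) * 150 / 10000
        assert realized == pytest.approx(300, rel=0.05)

    def test_reverse_strand_reads_are_reverse_complemented(self):
        genome, _ = make_genome(2000, seed=1)
        seq = genome.contigs["chromosome"]
        reads = simulate_reads(genome, read_length=80, depth=5, seed=1)
        assert any(r.is_reverse for r in reads)
        for r in reads:
            origin = seq[r.start : r.start + 80]
            expected = reverse_complement(origin) if r.is_reverse else origin
            assert r.seq == expected

    def test_seeded_determinism(self):
        genome, _ = make_genome(2000, seed=1)
        a = simulate_reads(genome, read_length=50, depth=3, seed=2)
        b = simulate_reads(genome, read_length=50, depth=3, seed=2)
        assert [(r.name, r.seq) for r in a] == [(r.name, r.seq) for r in b]

    def test_paired_mode_emits_mates_with_segments(self):
        genome, _ = make_genome(3000, seed=1)
        reads = simulate_reads(
            genome, read_length=100, depth=10, seed=3, paired=True
        )
        assert {r.segment for r in reads} == {"1", "2"}
        r1, r2 = reads[0], reads[1]
        assert r1.name == r2.name and r2.is_reverse

    def test_fastq_output(self, tmp_path):
        genome, _ = make_genome(1000, seed=1)
        reads = simulate_reads(genome, read_length=60, depth=2, seed=4)
        out = tmp_path / "reads.fastq"
        write_fastq(reads, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 4 * len(reads)
        assert lines[0].startswith("@r") and lines[3] == "I" * 60


class TestExhaustiveAlign:
    def test_unique_read_gets_one_perfect_hit(self):
        genome, _ = make_genome(5000, seed=0)
        read = SimRead("q", genome.contigs["chromosome"][1000:1100],
                       "chromosome", 1000, False)
        (rh,) = exhaustive_align([read], genome, max_edits=2)
        assert len(rh.hits) == 1
        hit = rh.hits[0]
        assert (hit.start, hit.edit_distance, hit.is_reverse) == (1000, 0, False)

    def test_read_inside_exact_repeat_hits_every_copy(self):
        genome, intervals = make_genome(20000, 2000, 2, seed=5)
        s, _ = intervals[0]
        read = SimRead("q", genome.contigs["chromosome"][s + 500 : s + 650],
                       "chromosome", s + 500, False)
        (rh,) = exhaustive_align([read], genome, max_edits=2, mode="all")
        assert len(rh.hits) == 2
        starts = sorted(h.start for h in rh.hits)
        assert starts == [s + 500, intervals[1][0] + 500]

    def test_reverse_strand_read_found(self):
        genome, _ = make_genome(4000, seed=2)
        frag = genome.contigs["chromosome"][700:800]
        read = SimRead("q", reverse_complement(frag), "chromosome", 700, True)
        (rh,) = exhaustive_align([read], genome, max_edits=1)
        assert rh.hits[0].is_reverse and rh.hits[0].start == 700

    def test_junk_read_reported_unmapped(self):
        genome, _ = make_genome(3000, seed=3)
        read = SimRead("q", "ACGT" * 25, "chromosome", 0, False)
        (rh,) = exhaustive_align([read], genome, max_edits=2)
        assert rh.hits == [] and rh.primary_index is None

    def test_best_only_prefers_error_free_repeat_copy(self):
        # the coverage-starvation mechanism: a read overlapping a
        # substitution planted in one copy of a repeat aligns at
        # distance 0 to the clean copy and distance 1 to the mutated
        # one; best-only mode must pick the clean copy
        genome, intervals = make_genome(12000, 1500, 2, seed=8)
        (s1, e1), (s2, e2) = intervals
        seq = genome.contigs["chromosome"]
        mut_pos = s1 + 700
        mutated = Assembly({
            "chromosome": seq[:mut_pos]
            + ("A" if seq[mut_pos] != "A" else "C")
            + seq[mut_pos + 1 :]
        })
        read = SimRead("q", seq[s1 + 650 : s1 + 770], "chromosome", s1 + 650, False)
        (rh,) = exhaustive_align([read], mutated, max_edits=3, mode="all")
        by_start = {h.start: h.edit_distance for h in rh.hits}
        assert by_start == {s1 + 650: 1, s2 + 650: 0}
        (rh_best,) = exhaustive_align([read], mutated, max_edits=3,
                                      mode="best_only", seed=42)
        assert rh_best.hits[0].start == s2 + 650
        # independent full-DP oracle agrees on the locally optimal hits
        oracle = semiglobal_optima(read.seq, mutated.contigs["chromosome"], 3)
        assert sorted(oracle) == sorted(h.edit_distance for h in rh.hits)

    def test_hit_set_matches_full_dp_oracle_on_mutated_genome(self):
        genome, _ = make_genome(3000, 400, 2, seed=11)
        profile = ErrorProfile(0.002, 0.002, 0.002, 0.002, seed=11)
        mutated, _ = inject_errors(genome, profile)
        reads = simulate_reads(genome, read_length=100, depth=3, seed=11)
        results = exhaustive_align(reads, mutated, max_edits=4, mode="all")
        ref = mutated.contigs["chromosome"]
        for rh in results:
            expected = []
            for is_reverse in (False, True):
                q = (
                    reverse_complement(rh.read.seq)
                    if is_reverse
                    else rh.read.seq
                )
                expected.extend(semiglobal_optima(q, ref, 4))
            assert sorted(h.edit_distance for h in rh.hits) == sorted(expected)

    def test_cigar_rewalk_reproduces_edit_distance(self):
        genome, _ = make_genome(6000, 500, 2, seed=13)
        profile = ErrorProfile(0.002, 0.002, 0.002, 0.002, seed=13)
        mutated, _ = inject_errors(genome, profile)
        reads = simulate_reads(genome, read_length=120, depth=5, seed=13)
        results = exhaustive_align(reads, mutated, max_edits=4, mode="all")
        checked = 0
        for rh in results:
            for hit in rh.hits:
                q = (
                    reverse_complement(rh.read.seq)
                    if hit.is_reverse
                    else rh.read.seq
                )
                assert cigar_edit_distance(hit, q, mutated) == hit.edit_distance
                checked += 1
        assert checked >= len(reads)

    def test_deterministic_under_seed(self):
        genome, _ = make_genome(4000, 500, 2, seed=14)
        reads = simulate_reads(genome, read_length=100, depth=5, seed=14)
        a = exhaustive_align(reads, genome, max_edits=2, seed=3)
        b = exhaustive_align(reads, genome, max_edits=2, seed=3)
        assert [
            (rh.primary_index, [(h.start, h.edit_distance) for h in rh.hits])
            for rh in a
        ] == [
            (rh.primary_index, [(h.start, h.edit_distance) for h in rh.hits])
            for rh in b
        ]
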