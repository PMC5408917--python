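"""Stage 2: overlap indexing, greedy extension, and per-chain merging."""

import numpy as np
import pytest

from bcrasm.anchor_finder import Anchor, find_anchors
from bcrasm.assembler import (
    MERGED,
    PARTIAL,
    SPLIT,
    assemble_cell,
    assemble_chain,
    build_overlap_index,
    extend_3prime,
    extend_5prime,
    replay_steps,
)
from bcrasm.germline_db import Component
from bcrasm.params import PipelineParams
from bcrasm.read_io import Read, ReadSet, reverse_complement
from bcrasm.simulator import SimParams, simulate_reads, simulate_receptor

from conftest import random_dna


def make_index(seqs, m=10):
    return build_overlap_index(ReadSet([Read(f"r{i}", s) for i, s in enumerate(seqs)]), m)


def tiling_reads(transcript, read_len=50, step=20):
    """Error-free reads tiling a transcript with overlap read_len - step."""
    reads = []
    starts = list(range(0, len(transcript) - read_len + 1, step))
    if starts[-1] != len(transcript) - read_len:
        starts.append(len(transcript) - read_len)
    for i, s in enumerate(starts):
        reads.append(Read(f"t{i}", transcript[s : s + read_len]))
    return ReadSet(reads)


class TestOverlapIndex:
    def test_each_read_contributes_forward_and_revcomp_prefix(self):
        seq = "ACGTACGTACGTACG"
        idx = make_index([seq], m=10)
        assert idx.prefix_map[seq[:10]] == [("r0", "forward")]
        assert idx.prefix_map[reverse_complement(seq)[:10]] == [("r0", "revcomp")]
        assert len(idx.prefix_map) == 2

    def test_identical_reads_share_keys(self):
        seq = "ACGTACGTACGTACG"
        idx = make_index([seq, seq], m=10)
        assert idx.prefix_map[seq[:10]] == [("r0", "forward"), ("r1", "forward")]

    def test_reads_shorter_than_m_are_skipped(self):
        idx = make_index(["ACGTACGTA"], m=10)
        assert idx.prefix_map == {}
        assert idx.reads == {}

    def test_m_below_ten_rejected(self):
        with pytest.raises(ValueError, match="below 10"):
            make_index(["ACGTACGTACGTACG"], m=6)


class TestExtend3Prime:
    def test_single_overlap_appends_suffix(self):
        # read overlaps the seed's last 10 bases exactly, adds 5 more
        seed = "ACGGTTCACCGGAATTCCGG"
        read = seed[-10:] + "TTTTT"
        idx = make_index([read], m=10)
        seq, steps, reason = extend_3prime(seed, idx, set(), 1500)
        assert seq == seed + "TTTTT"
        assert len(steps) == 1 and steps[0].overlap == 10
        assert reason == "no_overlap"

    def test_no_candidate_leaves_seed_unchanged(self):
        seed = "ACGGTTCACCGGAATTCCGG"
        idx = make_index(["TTTTTTTTTTTTTTT"], m=10)
        seq, steps, reason = extend_3prime(seed, idx, set(), 1500)
        assert (seq, steps, reason) == (seed, [], "no_overlap")

    def test_longest_overlap_candidate_wins(self):
        seed = "ACGGTTCACCGGAATTCCGGTTAACC"
        long_ov = seed[-15:] + "AAAAA"  # overlap 15
        short_ov = seed[-10:] + "GGGGG"  # overlap 10
        idx = make_index([short_ov, long_ov], m=10)
        seq, steps, _ = extend_3prime(seed, idx, set(), 1500)
        assert seq.endswith("AAAAA") and steps[0].overlap == 15

    def test_repeat_stop_on_circular_reads(self):
        # one read whose suffix re-creates the seed's terminal m-mer: the
        # second step would reuse it
        seed = "ACGGTTCACCTTGGAATTCC"
        read = seed[-10:] + "AT" + seed[-10:]
        idx = make_index([read], m=10)
        seq, steps, reason = extend_3prime(seed, idx, set(), 1500)
        assert reason == "repeat"
        assert len(steps) == 1

    def test_max_length_stop(self):
        rng = np.random.default_rng(0)
        transcript = random_dna(rng, 400)
        idx = build_overlap_index(tiling_reads(transcript), m=20)
        anchor = transcript[:50]
        seq, _, reason = extend_3prime(anchor, idx, set(), max_len=120)
        assert reason == "max_length"
        assert len(seq) > 120

    def test_recovers_simulated_transcript_3prime_end(self):
        rng = np.random.default_rng(1)
        transcript = random_dna(rng, 300)
        idx = build_overlap_index(tiling_reads(transcript), m=20)
        seq, _, reason = extend_3prime(transcript[:50], idx, set(), 1500)
        assert seq == transcript
        assert reason == "no_overlap"


class TestExtend5Prime:
    def test_mirror_of_3prime_example(self):
        seed = "ACGGTTCACCGGAATTCCGG"
        read = "TTTTT" + seed[:10]
        idx = make_index([read], m=10)
        seq, steps, _ = extend_5prime(seed, idx, set(), 1500)
        assert seq == "TTTTT" + seed
        assert steps[0].direction == "5p"

    def test_no_candidates_unchanged(self):
        seed = "ACGGTTCACCGGAATTCCGG"
        idx = make_index(["GGGGGGGGGGGGGGG"], m=10)
        assert extend_5prime(seed, idx, set(), 1500)[0] == seed

    @pytest.mark.parametrize("seed_i", range(10))
    def test_equivalent_to_rc_extend3_rc(self, seed_i):
        """Metamorphic oracle: extend_5prime == rc . extend_3prime . rc."""
        rng = np.random.default_rng(seed_i)
        transcript = random_dna(rng, 250)
        reads = ReadSet(
            [
                Read(f"r{i}", transcript[s : s + 50])
                for i, s in enumerate(
                    rng.integers(0, len(transcript) - 50 + 1, size=40)
                )
            ]
        )
        idx = build_overlap_index(reads, m=20)
        seed = transcript[100:160]
        left, _, _ = extend_5prime(seed, idx, set(), 1500)
        right, _, _ = extend_3prime(reverse_complement(seed), idx, set(), 1500)
        assert left == reverse_complement(right)


class TestAssembleChain:
    def anchors_for(self, toy_db, reads, params):
        return find_anchors(reads, toy_db, params)

    def test_clean_cell_merges_and_contains_truth(self, toy_db, params, clean_cell):
        truth, reads, _ = clean_cell
        heavy, light = assemble_cell(reads, toy_db, params)
        for asm in (heavy, light):
            assert asm.status == MERGED
            assert truth.chains[asm.chain].post_mutation in asm.merged_seq

    def test_coverage_gap_forces_split(self, toy_db, params):
        rng = np.random.default_rng(21)
        sp = SimParams(seed=21, chains=("heavy",))
        truth = simulate_receptor(toy_db, sp, rng)
        vdj = truth.chains["heavy"].vdj_length
        sp_gap = SimParams(
            seed=21, chains=("heavy",), mask_interval=(vdj + 10, vdj + 50)
        )
        reads = simulate_reads(truth, sp_gap, rng)
        anchors = find_anchors(reads, toy_db, params)
        idx = build_overlap_index(reads, params.m)
        asm = assemble_chain(
            anchors[Component.IGHV], anchors[Component.IGHC], idx, params, "heavy"
        )
        assert asm.status == SPLIT
        assert asm.variable_contig is not None and asm.constant_contig is not None

    def test_missing_constant_anchor_gives_partial(self, toy_db, params, clean_cell):
        _, reads, _ = clean_cell
        anchors = find_anchors(reads, toy_db, params)
        idx = build_overlap_index(reads, params.m)
        asm = assemble_chain(anchors[Component.IGHV], None, idx, params, "heavy")
        assert asm.status == PARTIAL
        assert asm.variable_contig is not None and asm.constant_contig is None


class TestAssembleCell:
    def test_heavy_only_cell_light_absent(self, toy_db, params):
        rng = np.random.default_rng(31)
        sp = SimParams(seed=31, chains=("heavy",))
        truth = simulate_receptor(toy_db, sp, rng)
        reads = simulate_reads(truth, sp, rng)
        heavy, light = assemble_cell(reads, toy_db, params)
        assert heavy.status == MERGED
        assert light.status == "absent"

    def test_deterministic_across_runs(self, toy_db, params, clean_cell):
        _, reads, _ = clean_cell
        a = assemble_cell(reads, toy_db, params)
        b = assemble_cell(reads, toy_db, params)
        assert a[0].merged_seq == b[0].merged_seq
        assert a[1].merged_seq == b[1].merged_seq

    def test_reverse_complement_metamorphic_invariance(self, toy_db, params, clean_cell):
        """Mirroring every read leaves the merged chain sequences unchanged
        (anchors come from germline-stranded references)."""
        _, reads, _ = clean_cell
        mirrored = ReadSet([Read(r.id, reverse_complement(r.seq)) for r in reads])
        a = assemble_cell(reads, toy_db, params)
        b = assemble_cell(mirrored, toy_db, params)
        for x, y in zip(a, b):
            assert x.status == y.status == MERGED
            assert x.merged_seq == y.merged_seq


class TestContigInvariants:
    def test_anchor_containment_step_replay_and_read_uniqueness(
        self, toy_db, params, clean_cell
    ):
        _, reads, _ = clean_cell
        anchors = find_anchors(reads, toy_db, params)
        idx = build_overlap_index(reads, params.m)
        heavy, light = assemble_cell(reads, toy_db, params)
        for asm in (heavy, light):
            for contig in (asm.variable_contig, asm.constant_contig):
                assert contig.anchor.seq in contig.seq
                assert replay_steps(contig.anchor.seq, contig.steps, idx) == contig.seq
                ids = [s.read_id for s in contig.steps]
                assert len(ids) == len(set(ids))
                assert all(s.overlap >= params.m for s in contig.steps)
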