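"""Split aligner: seed index, chaining, extension scoring, full mapping."""

import numpy as np
import pytest
from Bio import Align

import smurfseq as sq
from smurfseq.align import ScoringScheme, score_path, sw_align_path
from smurfseq.genome import ParameterError
from smurfseq.simulate import reverse_complement


def _biopython_oracle(scheme: ScoringScheme = ScoringScheme()) -> Align.PairwiseAligner:
    """Independent local-alignment scorer with the mapper's scoring regime
    (first gap base costs open+extend, so a k-gap costs open + k*extend)."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scheme.match
    a.mismatch_score = -scheme.mismatch_penalty
    a.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    a.extend_gap_score = -scheme.gap_extend
    return a


class TestSeedIndex:
    def test_kmer_maps_to_all_occurrences(self):
        g = sq.ReferenceGenome(["c"], ["ACGTACGTACGT"])
        idx = sq.build_index(g, 8)
        hits = idx.lookup("ACGTACGT")
        assert {(c, p) for c, p, s in hits if s == "+"} == {("c", 0), ("c", 4)}

    def test_absent_kmer_has_no_hits(self):
        g = sq.ReferenceGenome(["c"], ["A" * 1000])
        idx = sq.build_index(g, 12)
        assert idx.lookup("C" * 12) == []

    def test_every_genome_kmer_found_at_own_position(self):
        g = sq.generate_genome(1, 10_000, 0.5, seed=55)
        idx = sq.build_index(g, 12)
        seq = g.sequences[0]
        rng = np.random.default_rng(0)
        for p in rng.integers(0, len(seq) - 12, size=50):
            hits = idx.lookup(seq[p : p + 12])
            assert ("chr1", int(p), "+") in hits

    def test_reverse_complement_queries_resolve(self):
        g = sq.generate_genome(1, 10_000, 0.5, seed=56)
        idx = sq.build_index(g, 12)
        kmer = g.sequences[0][100:112]
        hits = idx.lookup(reverse_complement(kmer))
        assert ("chr1", 100, "-") in hits

    def test_short_genome_rejected(self):
        with pytest.raises(ParameterError):
            sq.build_index(sq.ReferenceGenome(["c"], ["ACGTAC"]), 12)


class TestSeedAndChain:
    def test_exact_copy_gives_one_covering_chain(self, small_genome, small_index):
        read = small_genome["chr1"][5000:5200]
        chains = sq.seed_and_chain(read, small_index)
        assert len(chains) == 1
        ch = chains[0]
        assert (ch.read_start, ch.read_end) == (0, 200)
        assert (ch.chrom, ch.strand, ch.ref_start, ch.ref_end) == ("chr1", "+", 5000, 5200)

    def test_two_fragment_read_gives_two_chains(self, small_genome, small_index):
        read = small_genome["chr1"][1000:1250] + small_genome["chr2"][50_000:50_300]
        chains = sq.seed_and_chain(read, small_index)
        majors = [c for c in chains if c.weight > 50]
        assert sorted(c.chrom for c in majors) == ["chr1", "chr2"]

    def test_unrelated_read_yields_no_reportable_fragment(self, small_index):
        other = sq.generate_genome(1, 10_000, 0.5, seed=999)
        read = other.sequences[0][:200]
        # stray 12-mer collisions may seed a handful of featherweight chains,
        # but nothing can reach the report threshold
        assert sq.map_read(read, small_index, read_id="x") == []


@pytest.fixture(scope="module")
def genome_and_index():
    g = sq.generate_genome(1, 50_000, 0.5, seed=77)
    return g, sq.build_index(g, 12)


class TestExtendScoring:
    def test_perfect_30bp_scores_exactly_at_threshold(self, genome_and_index):
        g, idx = genome_and_index
        read = g.sequences[0][2000:2030]
        frs = sq.map_read(read, idx, read_id="t")
        assert len(frs) == 1 and frs[0].score == 120

    def test_31bp_with_central_mismatch_suppressed(self, genome_and_index):
        g, idx = genome_and_index
        seq = list(g.sequences[0][2000:2031])
        seq[15] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[15]]
        # best alignment 30*4 - 10 = 110 < 120 (or a 15/16-mer piece, lower)
        assert sq.map_read("".join(seq), idx, read_id="t") == []

    def test_40bp_with_2bp_deletion_scores_gap_formula(self, genome_and_index):
        g, idx = genome_and_index
        ref = g.sequences[0]
        read = ref[3000:3020] + ref[3022:3042]  # 2 bp deleted mid-molecule
        frs = sq.map_read(read, idx, read_id="t")
        assert len(frs) == 1
        assert frs[0].score == 40 * 4 - (6 + 2 * 3)  # 148

    def test_short_read_cannot_reach_threshold(self, genome_and_index):
        g, idx = genome_and_index
        assert sq.map_read(g.sequences[0][100:125], idx, read_id="t") == []


class TestSmithWatermanOracle:
    def test_reported_scores_match_independent_oracle(self, small_genome, small_index):
        """Reported fragment scores equal a full (unbanded) local-alignment
        oracle on the reported substrings, for fragments up to 500 bp."""
        oracle = _biopython_oracle()
        truth = sq.plant_cnv(small_genome, [])
        digest = sq.digest(small_genome, sq.SAQAI)
        frags = sq.sample_fragments(digest, truth, 120, seed=21, min_length=100)
        frags = [f for f in frags if f[2] - f[1] <= 500]
        reads = sq.concatenate(frags, small_genome, 6800)
        model = sq.ErrorModel(seed=22)
        noisy = [sq.apply_errors(r, model) for r in reads]
        checked = 0
        for r in list(reads) + list(noisy):
            for a in sq.map_read(r, small_index):
                if a.read_span > 500:
                    continue
                sub = r.sequence[a.read_start : a.read_end]
                if a.strand == "-":
                    sub = reverse_complement(sub)
                ref = small_genome[a.chrom][a.ref_start : a.ref_end]
                assert a.score == oracle.score(sub, ref)
                checked += 1
        assert checked >= 100

    def test_alignment_path_rescoring_reproduces_score(self, small_genome):
        rng = np.random.default_rng(33)
        scheme = ScoringScheme()
        for _ in range(20):
            start = int(rng.integers(0, 400_000))
            ref = small_genome["chr1"][start : start + 300]
            read = sq.apply_errors(
                sq.SmurfRead("r", ref, [sq.FragmentTruth("chr1", start, start + 300, "+", 0, 300)]),
                sq.ErrorModel(seed=int(rng.integers(0, 2**31))),
            ).sequence
            score, qs, qe, ts, te, ops = sw_align_path(read, ref, scheme)
            if score:
                assert score_path(ops, scheme) == score
                assert sum(op in "MXI" for op in ops) == qe - qs
                assert sum(op in "MXD" for op in ops) == te - ts


class TestMapRead:
    def test_recovers_all_fragments_of_clean_reads(
        self, clean_reads, small_index, small_genome
    ):
        reads = clean_reads[:10]
        preds = sq.map_reads(reads, small_index)
        rep = sq.evaluate(sq.flatten_truth(reads), preds)
        assert rep.fragment_recall >= 0.95
        assert rep.fragment_precision >= 0.99

    def test_duplicated_locus_flagged_non_unique(self):
        base = sq.generate_genome(1, 20_000, 0.5, seed=88)
        seq = base.sequences[0]
        dup = seq[:10_000] + seq[5000:5300] + seq[10_000:]
        g = sq.ReferenceGenome(["chr1"], [dup])
        idx = sq.build_index(g, 12)
        frs = sq.map_read(seq[5000:5300], idx, read_id="d")
        assert len(frs) == 1 and frs[0].is_unique is False
        frs2 = sq.map_read(seq[1000:1300], idx, read_id="u")
        assert len(frs2) == 1 and frs2[0].is_unique is True

    def test_output_sorted_with_bounded_overlap(self, noisy_reads, small_index):
        scheme = ScoringScheme()
        for r in noisy_reads[:10]:
            frs = sq.map_read(r, small_index)
            starts = [f.read_start for f in frs]
            assert starts == sorted(starts)
            for a, b in zip(frs, frs[1:]):
                ov = a.read_end - b.read_start
                if ov > 0:
                    shorter = min(a.read_span, b.read_span)
                    assert ov <= scheme.frag_overlap_frac * shorter

    def test_raising_report_threshold_is_monotone(self, noisy_reads, small_index):
        low = ScoringScheme(min_report_score=120)
        high = ScoringScheme(min_report_score=400)
        for r in noisy_reads[:5]:
            n_low = len(sq.map_read(r, small_index, low))
            n_high = len(sq.map_read(r, small_index, high))
            assert n_high <= n_low

    def test_mapping_is_deterministic(self, noisy_reads, small_index):
        a = sq.map_read(noisy_reads[0], small_index)
        b = sq.map_read(noisy_reads[0], small_index)
        assert a == b
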