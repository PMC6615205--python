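"""CNV pipeline stages: mappability, binning, masking, GC correction,
circular binary segmentation, spurious-segment merging, event calls."""

import numpy as np
import pytest

import smurfseq as sq
from smurfseq.align import FragmentAlignment
from smurfseq.cnv import (
    GenomicBin,
    Segment,
    compute_ratios,
    segment_cbs,
)
from smurfseq.genome import ParameterError


def _uniform_bins(n, count=100.0, gc=0.5, width=1000):
    return [
        GenomicBin("c", i * width, (i + 1) * width, width, gc, raw_count=int(count))
        for i in range(n)
    ]


def P(chrom, s, e, unique=True):
    return FragmentAlignment("r", 0, e - s, chrom, s, e, "+", 200, unique)


class TestMappability:
    def test_random_genome_is_almost_fully_unique(self):
        g = sq.generate_genome(1, 50_000, 0.5, seed=60)
        m = sq.compute_mappability(g, probe_len=40)["chr1"]
        interior = m[: 50_000 - 39]
        assert interior.mean() > 0.999

    def test_identical_chromosomes_have_no_unique_positions(self):
        base = sq.generate_genome(1, 20_000, 0.5, seed=61)
        g = sq.ReferenceGenome(["a", "b"], [base.sequences[0]] * 2)
        m = sq.compute_mappability(g, probe_len=40)
        assert not m["a"].any() and not m["b"].any()

    def test_planted_duplication_kills_interior_uniqueness(self):
        base = sq.generate_genome(1, 30_000, 0.5, seed=62)
        seq = base.sequences[0]
        dup = seq + seq[10_000:11_000]  # exact 1 kb duplicate at the end
        g = sq.ReferenceGenome(["chr1"], [dup])
        m = sq.compute_mappability(g, probe_len=40)["chr1"]
        assert not m[10_000 : 11_000 - 40].any()          # original copy
        assert not m[30_000 : 31_000 - 40].any()          # planted copy
        assert m[:5_000].mean() > 0.999                   # elsewhere untouched

    def test_n_probes_are_unmappable(self):
        g = sq.ReferenceGenome(["c"], ["ACGT" * 5000 + "N" * 100 + "TGCA" * 5000])
        m = sq.compute_mappability(g, probe_len=20)["c"]
        assert not m[20_000 - 19 : 20_100].any()

    def test_probe_length_validation(self):
        g = sq.generate_genome(1, 10_000, 0.5, seed=0)
        with pytest.raises(ParameterError):
            sq.compute_mappability(g, probe_len=10)
        with pytest.raises(ParameterError):
            sq.compute_mappability(g, probe_len=20_000)


class TestMakeBins:
    def test_uniform_mappability_gives_equal_bins(self):
        g = sq.generate_genome(1, 600_000, 0.5, seed=63)
        mapp = {"chr1": np.ones(600_000, dtype=bool)}
        bins = sq.make_bins(g, mapp, 1000)
        assert len(bins) == 1000
        assert all(b.end - b.start == 600 for b in bins)
        assert all(b.n_mappable == 600 for b in bins)
        assert bins[0].start == 0 and bins[-1].end == 600_000

    def test_unmappable_block_widens_its_bin(self):
        g = sq.generate_genome(1, 100_000, 0.5, seed=64)
        mapp = {"chr1": np.ones(100_000, dtype=bool)}
        mapp["chr1"][40_000:50_000] = False
        bins = sq.make_bins(g, mapp, 100)
        target = -(-90_000 // 100)
        wide = [b for b in bins if b.end - b.start > 5 * target]
        assert len(wide) == 1
        assert wide[0].start < 40_000 < 50_000 < wide[0].end
        assert wide[0].n_mappable == target

    def test_bins_partition_every_chromosome(self, small_genome):
        mapp = {c: np.ones(small_genome.lengths[c], dtype=bool) for c in small_genome.chrom_names}
        bins = sq.make_bins(small_genome, mapp, 200)
        for chrom in small_genome.chrom_names:
            cb = [b for b in bins if b.chrom == chrom]
            assert cb[0].start == 0
            assert cb[-1].end == small_genome.lengths[chrom]
            for a, b in zip(cb, cb[1:]):
                assert a.end == b.start

    def test_parameter_validation(self, small_genome):
        mapp = {c: np.zeros(small_genome.lengths[c], dtype=bool) for c in small_genome.chrom_names}
        with pytest.raises(ParameterError):
            sq.make_bins(small_genome, mapp, 100)
        full = {c: np.ones(small_genome.lengths[c], dtype=bool) for c in small_genome.chrom_names}
        with pytest.raises(ParameterError):
            sq.make_bins(small_genome, full, 1)


class TestCountFragments:
    def test_no_fragments_gives_zero_counts(self):
        bins = _uniform_bins(50, count=0)
        sq.count_fragments(bins, [])
        assert all(b.raw_count == 0 for b in bins)

    def test_midpoint_boundary_convention(self):
        bins = _uniform_bins(2, count=0)  # [0,1000) and [1000,2000)
        sq.count_fragments(bins, [P("c", 900, 1100)])  # midpoint exactly 1000
        assert (bins[0].raw_count, bins[1].raw_count) == (0, 1)

    def test_non_unique_fragments_excluded(self):
        bins = _uniform_bins(2, count=0)
        sq.count_fragments(bins, [P("c", 0, 100, unique=False), P("c", 0, 100)])
        assert bins[0].raw_count == 1

    def test_out_of_bounds_fragment_rejected(self):
        bins = _uniform_bins(2, count=0)
        with pytest.raises(ParameterError):
            sq.count_fragments(bins, [P("c", 5000, 5100)])
        with pytest.raises(ParameterError):
            sq.count_fragments(bins, [P("other", 0, 100)])

    def test_uniform_counts_are_poisson(self):
        rng = np.random.default_rng(9)
        bins = _uniform_bins(100, count=0)
        starts = rng.integers(0, 100_000 - 2, size=100_000)  # midpoint ~uniform
        frags = [P("c", int(s), int(s) + 2) for s in starts]
        sq.count_fragments(bins, frags)
        counts = np.array([b.raw_count for b in bins])
        lam = 1000
        within = np.abs(counts - lam) <= 3 * np.sqrt(lam)
        assert within.mean() >= 0.99
        assert counts.sum() == 100_000


class TestMaskBadBins:
    def test_uniform_counts_mask_nothing(self):
        bins = _uniform_bins(100)
        sq.mask_bad_bins(bins)
        assert not any(b.masked for b in bins)

    def test_extreme_bin_is_masked(self):
        rng = np.random.default_rng(1)
        bins = _uniform_bins(100)
        for b in bins:
            b.raw_count = int(rng.poisson(100))
        bins[17].raw_count = 100 * 100
        sq.mask_bad_bins(bins)
        assert bins[17].masked
        assert sum(b.masked for b in bins) == 1

    def test_two_tier_outliers_both_masked_at_fixpoint(self):
        rng = np.random.default_rng(2)
        bins = _uniform_bins(100)
        for b in bins:
            b.raw_count = int(rng.poisson(100))
        bins[5].raw_count = 5000
        bins[50].raw_count = 600
        sq.mask_bad_bins(bins)
        assert bins[5].masked and bins[50].masked
        before = [b.masked for b in bins]
        sq.mask_bad_bins(bins)  # idempotent at the fixpoint
        assert [b.masked for b in bins] == before

    def test_moderate_amplification_survives_masking(self):
        # bins at twice the median are copy-number signal, not artifacts
        rng = np.random.default_rng(3)
        bins = _uniform_bins(200)
        for b in bins:
            b.raw_count = int(rng.poisson(1000))
        for b in bins[:10]:
            b.raw_count = int(rng.poisson(2000))
        sq.mask_bad_bins(bins)
        assert not any(b.masked for b in bins[:10])

    def test_too_few_bins_rejected(self):
        with pytest.raises(ParameterError):
            sq.mask_bad_bins(_uniform_bins(10))


class TestGcCorrect:
    def test_unbiased_counts_unchanged(self):
        rng = np.random.default_rng(4)
        gcs = rng.uniform(0.35, 0.65, 300)
        bins = [
            GenomicBin("c", i * 1000, (i + 1) * 1000, 1000, g,
                       raw_count=int(rng.poisson(1000)))
            for i, g in enumerate(gcs)
        ]
        sq.gc_correct(bins, 0.3)
        raw = np.array([b.raw_count for b in bins], dtype=float)
        cor = np.array([b.corrected_count for b in bins])
        assert np.abs(cor - raw).max() < 0.02 * raw.mean()

    def test_linear_bias_flattened(self):
        gcs = np.linspace(0.3, 0.7, 200)
        bins = [
            GenomicBin("c", i * 1000, (i + 1) * 1000, 1000, g,
                       raw_count=int(round(100 + 200 * (g - 0.5))))
            for i, g in enumerate(gcs)
        ]
        sq.gc_correct(bins, 0.3)
        cor = np.array([b.corrected_count for b in bins])
        assert np.abs(cor - 100).max() < 2
        assert abs(np.corrcoef(cor, gcs)[0, 1]) < 0.05

    def test_correction_is_idempotent_on_unbiased_data(self):
        # once the GC trend is gone, a second pass must not move counts
        gcs = np.linspace(0.3, 0.7, 200)
        bins = [
            GenomicBin("c", i * 1000, (i + 1) * 1000, 1000, g,
                       raw_count=100 + 200 * (g - 0.5))
            for i, g in enumerate(gcs)
        ]
        sq.gc_correct(bins, 0.3)
        once = np.array([b.corrected_count for b in bins])
        for b, c in zip(bins, once):
            b.raw_count = c
        sq.gc_correct(bins, 0.3)
        twice = np.array([b.corrected_count for b in bins])
        assert np.abs(twice - once).max() < 0.001 * once.mean()

    def test_constant_gc_is_identity_with_warning(self):
        bins = _uniform_bins(100)
        with pytest.warns(UserWarning):
            sq.gc_correct(bins, 0.3)
        assert all(b.corrected_count == b.raw_count for b in bins)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ParameterError):
            sq.gc_correct(_uniform_bins(30), 0.3)


class TestRatios:
    def test_mean_ratio_over_unmasked_is_one(self):
        rng = np.random.default_rng(7)
        bins = _uniform_bins(100)
        for b in bins:
            b.corrected_count = float(rng.poisson(500))
        bins[3].masked = True
        compute_ratios(bins)
        ratios = [b.ratio for b in bins if not b.masked]
        assert np.mean(ratios) == pytest.approx(1.0)


class TestSegmentCbs:
    def test_null_sequence_stays_one_segment(self):
        rng = np.random.default_rng(8)
        x = rng.normal(1, 0.05, 100)
        segs = segment_cbs(x, alpha=0.01, seed=1)
        assert len(segs) == 1
        assert segs[0].mean_ratio == pytest.approx(x.mean())

    def test_obvious_step_found_exactly(self):
        # at 8 points, permutation granularity floors the p-value around
        # 0.07 (any arrangement with the high half contiguous ties the
        # statistic), so the obvious step needs alpha above that floor
        x = np.array([1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
        x += np.random.default_rng(10).normal(0, 0.02, 8)
        segs = segment_cbs(x, alpha=0.1, seed=2)
        assert [(s.first_bin, s.last_bin) for s in segs] == [(0, 3), (4, 7)]

    def test_obvious_step_found_at_default_alpha(self):
        x = np.concatenate([np.ones(30), 2 * np.ones(30)])
        x += np.random.default_rng(10).normal(0, 0.02, 60)
        segs = segment_cbs(x, seed=2)
        assert [(s.first_bin, s.last_bin) for s in segs] == [(0, 29), (30, 59)]

    def test_changepoint_matches_sse_minimizing_split(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n1 = int(rng.integers(10, 40))
            n2 = int(rng.integers(10, 40))
            x = np.concatenate([np.zeros(n1), np.ones(n2)])
            x += rng.normal(0, 0.1, n1 + n2)
            best_sse, best_k = None, None
            for k in range(1, len(x)):
                sse = ((x[:k] - x[:k].mean()) ** 2).sum() + (
                    (x[k:] - x[k:].mean()) ** 2
                ).sum()
                if best_sse is None or sse < best_sse:
                    best_sse, best_k = sse, k
            segs = segment_cbs(x, seed=trial)
            breakpoints = [s.first_bin for s in segs[1:]]
            assert best_k in breakpoints

    def test_segments_partition_and_average_members(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([np.full(30, 1.0), np.full(30, 2.0), np.full(30, 0.5)])
        x += rng.normal(0, 0.05, 90)
        segs = segment_cbs(x, seed=3)
        covered = []
        for s in segs:
            covered.extend(range(s.first_bin, s.last_bin + 1))
            assert s.mean_ratio == pytest.approx(x[s.first_bin : s.last_bin + 1].mean())
        assert covered == list(range(90))

    def test_tiny_input_is_single_trivial_segment(self):
        segs = segment_cbs(np.array([1.0]), seed=0)
        assert len(segs) == 1 and segs[0].n_bins == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        x = rng.normal(1, 0.3, 80)
        a = segment_cbs(x, seed=5)
        b = segment_cbs(x, seed=5)
        assert a == b


class TestRemoveSpuriousSegments:
    def test_clean_segmentation_unchanged(self):
        x = np.concatenate([np.full(20, 1.0), np.full(20, 2.0)])
        segs = [Segment(0, 19, 1.0), Segment(20, 39, 2.0)]
        out = sq.remove_spurious_segments(segs, x)
        assert out == segs

    def test_short_spike_merged_away(self):
        x = np.concatenate([np.full(20, 1.0), np.full(2, 1.6), np.full(20, 1.0)])
        segs = [Segment(0, 19, 1.0), Segment(20, 21, 1.6), Segment(22, 41, 1.0)]
        out = sq.remove_spurious_segments(segs, x)
        assert len(out) == 1
        assert out[0].mean_ratio == pytest.approx(x.mean())

    def test_shallow_neighbor_merged(self):
        x = np.concatenate([np.full(20, 1.00), np.full(20, 1.05), np.full(20, 2.0)])
        segs = [Segment(0, 19, 1.0), Segment(20, 39, 1.05), Segment(40, 59, 2.0)]
        out = sq.remove_spurious_segments(segs, x)
        assert [(s.first_bin, s.last_bin) for s in out] == [(0, 39), (40, 59)]

    def test_merging_terminates_at_fixpoint(self):
        rng = np.random.default_rng(14)
        x = rng.normal(1, 0.02, 60)
        segs = [Segment(i * 3, i * 3 + 2, float(x[i * 3 : i * 3 + 3].mean())) for i in range(20)]
        out = sq.remove_spurious_segments(segs, x)
        assert len(out) == 1

    def test_single_segment_kept_even_if_short(self):
        x = np.ones(3)
        segs = [Segment(0, 2, 1.0)]
        assert sq.remove_spurious_segments(segs, x) == segs


class TestCallEvents:
    def test_states_follow_cutoffs(self):
        segs = [Segment(0, 1, 1.0), Segment(2, 3, 1.3), Segment(4, 5, 0.7)]
        states = sq.call_events(segs, 6)
        assert states == ["neutral"] * 2 + ["amplified"] * 2 + ["deleted"] * 2

    def test_boundaries_are_inclusive(self):
        segs = [Segment(0, 0, 1.25), Segment(1, 1, 0.8), Segment(2, 2, 1.2499)]
        assert sq.call_events(segs, 3) == ["amplified", "deleted", "neutral"]

    def test_all_neutral_profile_has_no_events(self):
        states = sq.call_events([Segment(0, 9, 1.02)], 10)
        assert states == ["neutral"] * 10

    def test_uncovered_bin_is_an_error(self):
        with pytest.raises(ParameterError):
            sq.call_events([Segment(0, 3, 1.0)], 6)

    def test_cutoff_ordering_validated(self):
        with pytest.raises(ParameterError):
            sq.call_events([Segment(0, 0, 1.0)], 1, amp_cutoff=0.8, del_cutoff=1.25)
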