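"""Core intersection, copy-number estimators, and A/B-space accounting."""

import math

import numpy as np
import pytest

from bblocks import (
    GenomeIndex,
    Block,
    core_intersection,
    estimate_copy_number,
    quantify,
    summarize_blocks,
    block_length_histogram,
)
from bblocks.quantify import annotate_copy_numbers, requantify_core, CoreBlockSet

from conftest import make_scr_track


def blk(chrom, start, end, **kw):
    kw.setdefault("block_scr", 5.0)
    kw.setdefault("fraction_passing", 0.5)
    kw.setdefault("n_passing", 1)
    return Block(chrom, start, end, **kw)


def naive_core(block_sets, k, index):
    """Per-base brute-force oracle for the >= k-of-N intersection."""
    intervals = []
    for chrom, length in index.chroms.items():
        count = np.zeros(length, dtype=int)
        for blocks in block_sets:
            mask = np.zeros(length, dtype=bool)
            for b in blocks:
                if b.chrom == chrom:
                    mask[b.start:b.end] = True
            count += mask
        in_run = False
        for i in range(length):
            if count[i] >= k and not in_run:
                start, in_run = i, True
            elif count[i] < k and in_run:
                intervals.append((chrom, start, i))
                in_run = False
        if in_run:
            intervals.append((chrom, start, length))
    return intervals


class TestCoreIntersection:
    def test_k_of_n_support_counting(self):
        idx = GenomeIndex({"c": 1000})
        sets = [[blk("c", 100, 500)] for _ in range(12)] + [[blk("c", 900, 950)]]
        core = core_intersection(sets, k=12, index=idx)
        assert core.intervals == [("c", 100, 500)]
        assert core.support_count == [12]
        # with only 11 supporting samples the base is not core
        core11 = core_intersection(sets[:11] + [[blk("c", 900, 950)]] * 2, k=12, index=idx)
        assert core11.intervals == []

    def test_single_sample_identity(self):
        idx = GenomeIndex({"c": 1000})
        blocks = [blk("c", 10, 200), blk("c", 300, 400)]
        core = core_intersection([blocks], k=1, index=idx)
        assert core.intervals == [("c", 10, 200), ("c", 300, 400)]

    def test_k_out_of_range_rejected(self):
        idx = GenomeIndex({"c": 100})
        with pytest.raises(ValueError):
            core_intersection([[blk("c", 0, 10)]], k=2, index=idx)

    def test_k_equal_n_is_intersection_k_one_is_union(self):
        idx = GenomeIndex({"c": 1000})
        s1 = [blk("c", 0, 500)]
        s2 = [blk("c", 300, 800)]
        inter = core_intersection([s1, s2], k=2, index=idx)
        union = core_intersection([s1, s2], k=1, index=idx)
        assert inter.intervals == [("c", 300, 500)]
        assert union.intervals == [("c", 0, 800)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        idx = GenomeIndex({"cA": 3000, "cB": 2000})
        sets = []
        for _ in range(rng.integers(2, 6)):
            blocks = []
            for chrom, length in idx.chroms.items():
                for _ in range(rng.integers(0, 8)):
                    s = int(rng.integers(0, length - 10))
                    e = int(s + rng.integers(1, 400))
                    blocks.append(blk(chrom, s, min(e, length)))
            sets.append(blocks)
        k = int(rng.integers(1, len(sets) + 1))
        got = core_intersection(sets, k, idx)
        assert got.intervals == naive_core(sets, k, idx)

    def test_footprint_monotone_in_k(self):
        rng = np.random.default_rng(9)
        idx = GenomeIndex({"c": 5000})
        sets = [
            [blk("c", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 4500, 6), rng.integers(10, 400, 6))]
            for _ in range(4)
        ]
        prev = math.inf
        for k in range(1, 5):
            fp = core_intersection(sets, k, idx).total_bp
            assert fp <= prev
            prev = fp


class TestCopyNumber:
    def test_threshold_scr_three_maps_to_four_copies(self):
        est = estimate_copy_number(blk("c", 0, 1000, block_scr=3.0, male_scaled_mean=1.0))
        assert est.copies == 4.0
        assert est.estimator_used == "eq3"

    def test_unit_scr_gives_zero_copies(self):
        est = estimate_copy_number(blk("c", 0, 1000, block_scr=1.0, male_scaled_mean=1.2))
        assert est.copies == 0.0

    def test_low_male_coverage_uses_female_only_estimator(self):
        est = estimate_copy_number(
            blk("c", 0, 1000, block_scr=10.0, male_scaled_mean=0.5, female_scaled_mean=5.0)
        )
        assert est.estimator_used == "eq4"
        assert est.copies == 10.0
        assert est.b_space_bp == 10_000.0

    def test_negative_estimate_clamped_to_zero(self):
        est = estimate_copy_number(blk("c", 0, 600, block_scr=0.5, male_scaled_mean=1.0))
        assert est.copies == 0.0

    def test_switch_is_inclusive_at_one(self):
        at_one = estimate_copy_number(blk("c", 0, 600, block_scr=4.0, male_scaled_mean=1.0))
        below = estimate_copy_number(
            blk("c", 0, 600, block_scr=4.0, male_scaled_mean=0.999, female_scaled_mean=3.996)
        )
        assert at_one.estimator_used == "eq3"
        assert below.estimator_used == "eq4"

    @pytest.mark.parametrize("c", [1.0, 4.0, 8.0, 16.0, 50.0])
    def test_ratio_estimator_inverts_coverage_model(self, c):
        """With male scaled coverage 1 and noise-free means, a block generated
        at true copy number c has SCR (2+c)/2 and the estimator returns c."""
        scr = (2.0 + c) / 2.0
        est = estimate_copy_number(
            blk("c", 0, 1000, block_scr=scr, male_scaled_mean=1.0, female_scaled_mean=scr)
        )
        assert est.copies == pytest.approx(c, abs=1e-12)


class TestQuantify:
    def test_a_and_b_space_sums(self):
        blocks = [blk("c", 0, 1000, male_scaled_mean=1.0, block_scr=6.0)]
        annotate_copy_numbers(blocks)
        report = quantify(blocks, sample_id="s")
        assert report.total_a_space_bp == 1000.0
        assert report.total_b_space_bp == 10_000.0  # copies = 6*2-2 = 10

    def test_core_percent_matches_reported_style(self):
        # core 25.13 Mb of total 49.44 Mb in B space -> ~50.8%
        blocks = [blk("c", 0, 1000)]
        blocks[0].copies = 49.44e6 / 1000
        blocks[0].b_space_bp = 49.44e6
        core = [blk("c", 0, 500)]
        core[0].copies = 25.13e6 / 500
        core[0].b_space_bp = 25.13e6
        report = quantify(blocks, core)
        assert report.core_percent_of_b == pytest.approx(50.84, abs=0.05)

    def test_empty_block_set_is_degenerate_not_error(self):
        report = quantify([], [])
        assert report.total_a_space_bp == 0.0
        assert report.total_b_space_bp == 0.0
        assert report.core_percent_of_b is None

    def test_b_space_additive_and_label_invariant(self):
        rng = np.random.default_rng(2)
        blocks = []
        for i in range(10):
            b = blk("c", i * 2000, i * 2000 + int(rng.integers(600, 1500)),
                    block_scr=float(rng.uniform(3, 20)), male_scaled_mean=1.0)
            blocks.append(b)
        annotate_copy_numbers(blocks)
        total = quantify(blocks).total_b_space_bp
        assert total == pytest.approx(sum(b.b_space_bp for b in blocks))
        half = quantify(blocks[:5]).total_b_space_bp + quantify(blocks[5:]).total_b_space_bp
        assert half == pytest.approx(total)
        relabeled = [
            Block("zzz", b.start, b.end, b.block_scr, b.fraction_passing,
                  b.n_passing, b.female_scaled_mean, b.male_scaled_mean,
                  copies=b.copies, b_space_bp=b.b_space_bp)
            for b in blocks
        ]
        assert quantify(relabeled).total_b_space_bp == pytest.approx(total)

    def test_requantified_core_is_sample_specific(self):
        idx = GenomeIndex({"c": 1000})
        female = np.full(1000, 2.5)
        male = np.ones(1000)
        track = make_scr_track(idx, scr={"c": female.copy()}, female={"c": female},
                               male={"c": male})
        core = CoreBlockSet(idx, [("c", 100, 400)], [3], 3, 4)
        (cb,) = requantify_core(core, track)
        assert cb.block_scr == pytest.approx(2.5)
        assert cb.copies == pytest.approx(3.0)  # 2.5*2-2
        assert cb.b_space_bp == pytest.approx(900.0)


class TestSummaries:
    def test_single_block(self):
        stats = summarize_blocks([blk("c", 0, 800)])
        assert (stats.count, stats.mean, stats.median, stats.max) == (1, 800, 800, 800)
        assert stats.sd == 0.0

    def test_three_lengths(self):
        stats = summarize_blocks([blk("c", 0, 501), blk("c", 1000, 2000), blk("c", 3000, 4499)])
        assert stats.mean == pytest.approx(1000.0)
        assert stats.median == 1000.0
        assert stats.max == 1499

    def test_sample_sd_two_blocks(self):
        # sample sd of {600, 1600} = |1600-600| / sqrt(2) = 707.1068
        stats = summarize_blocks([blk("c", 0, 600), blk("c", 1000, 2600)])
        assert stats.sd == pytest.approx(707.1068, abs=1e-3)

    def test_histogram_one_bp_bins(self):
        blocks = [blk("c", 0, 600), blk("c", 1000, 1600), blk("c", 2000, 2700)]
        hist = block_length_histogram(blocks)
        assert hist.tolist() == [[600, 2], [700, 1]]

    def test_empty_set(self):
        stats = summarize_blocks([])
        assert stats.count == 0 and math.isnan(stats.mean)
        assert block_length_histogram([]).size == 0
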