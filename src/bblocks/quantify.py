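"""Core-block intersection, copy-number estimation, and B-length accounting.

Copy number
-----------
With one haploid B per cell, a block whose sequence has ``c`` B-located
copies on top of the diploid A pair has expected SCR (2 + c)/2, so

    copies = SCR * 2 - 2                     (male scaled coverage >= 1)

The factor 2 converts the haploid-B-vs-diploid-A ratio to copies and the
subtraction removes the A-chromosome pair's contribution. In poorly
mappable regions the male scaled coverage drops below 1 and the ratio
would overestimate copies; there the male is assumed to represent one
single-copy locus and

    copies = female scaled coverage * 2      (male scaled coverage < 1)

Copy numbers stay fractional in all sums; negative estimates (possible on
re-quantified core intervals with SCR < 1) clamp to 0.

A space vs B space
------------------
"A space" is block length on the reference; "B space" is length times
estimated copy number — the block's contribution to the physical B
chromosome. Core intervals carry no global copy number: each sample
re-estimates copies over the core footprint from its own coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from bblocks.blocks import Block
from bblocks.genome import GenomeIndex
from bblocks.stats import ScrTrack


@dataclass
class CoreBlockSet:
    """Intervals whose every base is covered by called blocks in >= k of N samples.

    Maximal runs of such bases form the intervals; no re-merging within a
    gap and no length re-filter is applied, so core intervals can be
    shorter than single-sample blocks (large blocks fragment at bases where
    support dips below k). ``support_count`` is the minimum number of
    supporting samples across the interval.
    """

    index: GenomeIndex
    intervals: list[tuple[str, int, int]]
    support_count: list[int]
    k_required: int
    n_samples: int

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def core_intersection(
    block_sets: Sequence[Sequence[Block]], k: int, index: GenomeIndex
) -> CoreBlockSet:
    """Base-resolution >= k-of-N intersection of per-sample block sets."""
    n = len(block_sets)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")

    intervals: list[tuple[str, int, int]] = []
    supports: list[int] = []
    for chrom, length in index.chroms.items():
        # a sample supports a base when ANY of its blocks covers it, so each
        # sample contributes a 0/1 coverage profile (difference array per
        # sample, clipped to presence/absence before summing)
        count = np.zeros(length, dtype=np.int32)
        for blocks in block_sets:
            diff = np.zeros(length + 1, dtype=np.int32)
            for b in blocks:
                if b.chrom == chrom:
                    index.check_interval(chrom, b.start, b.end)
                    diff[b.start] += 1
                    diff[b.end] -= 1
            count += np.cumsum(diff[:-1]) > 0
        core = count >= k
        if not core.any():
            continue
        padded = np.concatenate(([False], core, [False]))
        run_edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(run_edges[::2], run_edges[1::2]):
            intervals.append((chrom, int(s), int(e)))
            supports.append(int(count[s:e].min()))
    return CoreBlockSet(index, intervals, supports, k, n)


@dataclass(frozen=True)
class CopyEstimate:
    """Estimated B-located copy number of one block and its B-space length."""

    copies: float
    estimator_used: str  # "eq3" (ratio-based) or "eq4" (female-only)
    b_space_bp: float


def estimate_copy_number(block: Block) -> CopyEstimate:
    """Estimate B-located copies for a block (see module docstring).

    The estimator switch uses the block-mean male scaled coverage,
    inclusive >= 1 for the ratio-based form.
    """
    if block.male_scaled_mean >= 1.0:
        copies = block.block_scr * 2.0 - 2.0
        used = "eq3"
    else:
        copies = block.female_scaled_mean * 2.0
        used = "eq4"
    copies = max(copies, 0.0)
    return CopyEstimate(copies, used, copies * block.length)


def annotate_copy_numbers(blocks: Sequence[Block]) -> list[CopyEstimate]:
    """Fill ``copies`` / ``b_space_bp`` on each block in place; return estimates."""
    out = []
    for b in blocks:
        est = estimate_copy_number(b)
        b.copies = est.copies
        b.b_space_bp = est.b_space_bp
        out.append(est)
    return out


def requantify_core(core: CoreBlockSet, scr_track: ScrTrack) -> list[Block]:
    """Re-estimate per-sample statistics over core intervals.

    Core intervals are shared geometry; SCR and copy number over them are
    sample-specific, so each sample's coverage is re-averaged over every
    core interval before copy estimation.
    """
    blocks = []
    for (chrom, start, end), support in zip(core.intervals, core.support_count):
        f = scr_track.female_scaled[chrom][start:end]
        m = scr_track.male_scaled[chrom][start:end]
        f_mean = float(f.mean())
        m_mean = float(m.mean())
        if m_mean > 0:
            scr = f_mean / m_mean
        else:
            scr = float("inf") if f_mean > 0 else 0.0
        b = Block(
            chrom=chrom,
            start=start,
            end=end,
            block_scr=scr,
            fraction_passing=1.0,
            n_passing=end - start,
            female_scaled_mean=f_mean,
            male_scaled_mean=m_mean,
            block_id=f"core_{chrom}_{start}",
        )
        est = estimate_copy_number(b)
        b.copies = est.copies
        b.b_space_bp = est.b_space_bp
        blocks.append(b)
    return blocks


@dataclass
class BlockSizeStats:
    count: int
    mean: float
    sd: float
    median: float
    max: int

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "mean_bp": self.mean,
            "sd_bp": self.sd,
            "median_bp": self.median,
            "max_bp": self.max,
        }


def summarize_blocks(blocks: Sequence[Block]) -> BlockSizeStats:
    """Count / mean / sample sd / median / max of block lengths."""
    if not blocks:
        return BlockSizeStats(0, math.nan, math.nan, math.nan, 0)
    lengths = np.array([b.length for b in blocks], dtype=np.float64)
    sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    return BlockSizeStats(
        count=len(lengths),
        mean=float(lengths.mean()),
        sd=sd,
        median=float(np.median(lengths)),
        max=int(lengths.max()),
    )


def block_length_histogram(blocks: Sequence[Block]) -> np.ndarray:
    """Block-length histogram at 1 bp bins as an (length, count) array."""
    if not blocks:
        return np.empty((0, 2), dtype=np.int64)
    lengths = np.array([b.length for b in blocks])
    vals, counts = np.unique(lengths, return_counts=True)
    return np.column_stack([vals, counts])


@dataclass
class QuantReport:
    """Per-sample length accounting and block-size summary."""

    sample_id: str
    total_a_space_bp: float
    total_b_space_bp: float
    core_a_space_bp: float
    core_b_space_bp: float
    core_percent_of_b: float | None  # None when total B space is zero
    percent_genome_passing: float | None
    size_stats: BlockSizeStats = field(default_factory=lambda: summarize_blocks([]))

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_a_space_bp": self.total_a_space_bp,
            "total_b_space_bp": self.total_b_space_bp,
            "core_a_space_bp": self.core_a_space_bp,
            "core_b_space_bp": self.core_b_space_bp,
            "core_percent_of_b": self.core_percent_of_b,
            "percent_genome_passing": self.percent_genome_passing,
            **self.size_stats.to_dict(),
        }


def quantify(
    blocks: Sequence[Block],
    core_blocks: Sequence[Block] | None = None,
    sample_id: str = "",
    percent_genome_passing: float | None = None,
) -> QuantReport:
    """Sum A-space and B-space lengths over a sample's blocks and core footprint.

    Blocks must already carry copy estimates (``annotate_copy_numbers``);
    ``core_blocks`` are the sample-requantified core intervals from
    :func:`requantify_core`. An empty block set yields an all-zero report
    with an undefined core percentage.
    """
    for b in blocks:
        if b.copies is None:
            raise ValueError(f"block {b.block_id} has no copy estimate")
    total_a = float(sum(b.length for b in blocks))
    total_b = float(sum(b.b_space_bp for b in blocks))
    core_blocks = core_blocks or []
    core_a = float(sum(b.length for b in core_blocks))
    core_b = float(sum(b.b_space_bp or 0.0 for b in core_blocks))
    core_pct = 100.0 * core_b / total_b if total_b > 0 else None
    return QuantReport(
        sample_id=sample_id,
        total_a_space_bp=total_a,
        total_b_space_bp=total_b,
        core_a_space_bp=core_a,
        core_b_space_bp=core_b,
        core_percent_of_b=core_pct,
        percent_genome_passing=percent_genome_passing,
        size_stats=summarize_blocks(blocks),
    )
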