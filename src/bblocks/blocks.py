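"""B-block calling: threshold per-base statistics, merge, filter.

A base "passes" when SCR >= 3 and the binomial p-value <= 0.001 (both
inclusive). Passing positions within 300 bp of one another are merged into
a block spanning the first to the last passing base — the same result as
``bedtools merge -d 300`` on single-base features. Blocks <= 500 bp, or
with <= 10% of spanned positions passing, are removed (strict inequalities
on what is kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bblocks.stats import ScrTrack

DEFAULT_SCR_MIN = 3.0
DEFAULT_ALPHA = 0.001
DEFAULT_MERGE_GAP = 300
DEFAULT_MIN_LEN = 500
DEFAULT_MIN_FRAC = 0.10


@dataclass
class Block:
    """A called B block: a reference interval with elevated female coverage.

    ``block_scr`` is the ratio of block-mean scaled coverages (female over
    male), not the mean of per-base ratios — per-base zeros would make the
    latter unstable, and ratios of means are what the copy-number
    estimators invert. ``copies`` and ``b_space_bp`` are filled by the
    quantification step.
    """

    chrom: str
    start: int
    end: int
    block_scr: float
    fraction_passing: float
    n_passing: int = 0
    female_scaled_mean: float = 0.0
    male_scaled_mean: float = 0.0
    block_id: str | None = None
    copies: float | None = None
    b_space_bp: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, min_len: int = DEFAULT_MIN_LEN, min_frac: float = DEFAULT_MIN_FRAC) -> None:
        assert self.end > self.start, "empty block interval"
        assert self.length > min_len, f"block {self.chrom}:{self.start}-{self.end} too short"
        assert self.fraction_passing > min_frac, "block fails passing-fraction invariant"
        assert self.n_passing >= 1


def call_passing_positions(
    scr_track: ScrTrack,
    scr_min: float = DEFAULT_SCR_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, np.ndarray]:
    """Positions (0-based, sorted) where SCR >= scr_min and p <= alpha."""
    if scr_min <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    out = {}
    for chrom in scr_track.index.names:
        mask = (scr_track.scr[chrom] >= scr_min) & (scr_track.pvalue[chrom] <= alpha)
        out[chrom] = np.flatnonzero(mask)
    return out


def merge_within_gap(positions: np.ndarray, gap: int = DEFAULT_MERGE_GAP) -> list[tuple[int, int]]:
    """Cluster sorted passing positions into intervals.

    Two positions belong to one interval when their distance is <= gap
    (inclusive: exactly ``gap`` apart still merges). Each interval spans the
    first to the last passing base, end-exclusive.
    """
    positions = np.asarray(positions)
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(positions) - 1]))
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def filter_blocks(
    intervals: list[tuple[int, int]],
    chrom: str,
    scr_track: ScrTrack,
    scr_min: float = DEFAULT_SCR_MIN,
    alpha: float = DEFAULT_ALPHA,
    min_len: int = DEFAULT_MIN_LEN,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[Block]:
    """Drop short and sparsely-passing intervals; fill block statistics.

    Intervals of length <= min_len bp are removed first, then intervals
    where the fraction of spanned positions passing both thresholds is
    <= min_frac. Retained blocks get their mean scaled coverages and block
    SCR over the full span.
    """
    f = scr_track.female_scaled[chrom]
    m = scr_track.male_scaled[chrom]
    pass_mask = (scr_track.scr[chrom] >= scr_min) & (scr_track.pvalue[chrom] <= alpha)

    blocks: list[Block] = []
    for start, end in intervals:
        length = end - start
        if length <= min_len:
            continue
        n_passing = int(pass_mask[start:end].sum())
        frac = n_passing / length
        if frac <= min_frac:
            continue
        f_mean = float(f[start:end].mean())
        m_mean = float(m[start:end].mean())
        if m_mean > 0:
            block_scr = f_mean / m_mean
        else:
            block_scr = float("inf") if f_mean > 0 else 0.0
        blocks.append(
            Block(
                chrom=chrom,
                start=start,
                end=end,
                n_passing=n_passing,
                fraction_passing=frac,
                female_scaled_mean=f_mean,
                male_scaled_mean=m_mean,
                block_scr=block_scr,
            )
        )
    return blocks


def call_blocks(
    scr_track: ScrTrack,
    scr_min: float = DEFAULT_SCR_MIN,
    alpha: float = DEFAULT_ALPHA,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_len: int = DEFAULT_MIN_LEN,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[Block]:
    """Run the full calling chain genome-wide and return sorted blocks."""
    passing = call_passing_positions(scr_track, scr_min, alpha)
    blocks: list[Block] = []
    for chrom in scr_track.index.names:
        raw = merge_within_gap(passing[chrom], merge_gap)
        blocks.extend(
            filter_blocks(raw, chrom, scr_track, scr_min, alpha, min_len, min_frac)
        )
    blocks.sort(key=lambda b: (b.chrom, b.start))
    for i, b in enumerate(blocks):
        b.block_id = f"block_{i + 1}"
        b.validate(min_len, min_frac)
    return blocks


def calling_stage_counts(
    scr_track: ScrTrack,
    scr_min: float = DEFAULT_SCR_MIN,
    alpha: float = DEFAULT_ALPHA,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_len: int = DEFAULT_MIN_LEN,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> dict:
    """Stage-by-stage counters: % of genome passing, raw intervals, kept blocks."""
    passing = call_passing_positions(scr_track, scr_min, alpha)
    n_pass = sum(len(v) for v in passing.values())
    raw = sum(len(merge_within_gap(passing[c], merge_gap)) for c in scr_track.index.names)
    blocks = call_blocks(scr_track, scr_min, alpha, merge_gap, min_len, min_frac)
    return {
        "positions_passing": n_pass,
        "percent_genome_passing": 100.0 * n_pass / scr_track.index.total_length,
        "raw_intervals": raw,
        "filtered_blocks": len(blocks),
    }
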