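"""Gene / gene-fragment overlap with B blocks and shared-gene accounting.

Overlap is gene-level: a gene with >= 1 bp of overlap with a sample's block
footprint is reported, "complete" when its whole interval lies inside the
union of that sample's blocks (large B-homologous regions are often
fragmented into several abutting block calls, so containment is tested
against the union, not any single block). Genes whose overlap falls only in
introns may reflect a repeat insertion on the B rather than a gene copy;
such records are flagged and a warning logged, but — matching the gene-level
semantics — they are still counted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from bblocks.blocks import Block
from bblocks.io import GeneAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneOverlapRecord:
    gene_id: str
    overlap_class: str  # "complete" | "partial"
    overlapping_bp: int
    blocks_hit: tuple[str, ...]
    intron_only: bool = False


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _overlap_bp(ivals: list[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in ivals)


def genes_in_blocks(
    annotation: Sequence[GeneAnnotation], blocks: Sequence[Block]
) -> list[GeneOverlapRecord]:
    """One record per gene overlapping the block footprint by >= 1 bp.

    Output order is deterministic: (chrom, start, gene_id). The result is
    invariant to block fragmentation — splitting a block into abutting
    pieces changes neither a gene's class nor its overlap length.
    """
    by_chrom: dict[str, list[Block]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    footprint = {
        c: _merge_intervals([(b.start, b.end) for b in bs]) for c, bs in by_chrom.items()
    }

    records = []
    for gene in sorted(annotation, key=lambda g: (g.chrom, g.start, g.gene_id)):
        union = footprint.get(gene.chrom, [])
        ov = _overlap_bp(union, gene.start, gene.end)
        if ov < 1:
            continue
        complete = ov == gene.length
        hits = tuple(
            b.block_id or f"{b.chrom}:{b.start}-{b.end}"
            for b in by_chrom.get(gene.chrom, [])
            if b.start < gene.end and b.end > gene.start
        )
        intron_only = False
        if gene.exons:
            exon_ov = sum(_overlap_bp(union, s, e) for s, e in gene.exons)
            if exon_ov == 0:
                intron_only = True
                logger.warning(
                    "gene %s overlaps blocks only in introns (%d bp); may reflect "
                    "an intronic repeat insertion rather than a B-located gene copy",
                    gene.gene_id,
                    ov,
                )
        records.append(
            GeneOverlapRecord(
                gene_id=gene.gene_id,
                overlap_class="complete" if complete else "partial",
                overlapping_bp=ov,
                blocks_hit=hits,
                intron_only=intron_only,
            )
        )
    return records


def shared_gene_counts(
    gene_sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    min_shared: int | None = None,
) -> dict:
    """Venn-partition counts of per-sample gene-id sets.

    Returns ``{"regions": {pattern: count}, "shared_by_at_least": {k: count},
    "union": count}`` where a pattern is a '+'-joined sorted tuple of the
    member set names. The full Venn partition is enumerable for 2-5 sets;
    for more sets pass ``min_shared`` to get only the >= k totals.
    """
    if isinstance(gene_sets, Mapping):
        named = {str(k): set(v) for k, v in gene_sets.items()}
    else:
        named = {f"set{i + 1}": set(v) for i, v in enumerate(gene_sets)}
    n = len(named)
    if n < 1:
        raise ValueError("need at least one gene set")

    universe: set[str] = set().union(*named.values())
    membership = {g: frozenset(name for name, s in named.items() if g in s) for g in universe}

    shared_by_at_least = {
        k: sum(1 for m in membership.values() if len(m) >= k) for k in range(1, n + 1)
    }
    result: dict = {"union": len(universe), "shared_by_at_least": shared_by_at_least}

    if min_shared is not None:
        result["min_shared"] = min_shared
        result["n_shared"] = shared_by_at_least.get(min_shared, 0)
        return result

    if n > 5:
        raise ValueError(
            f"full Venn partition over {n} sets is not supported (max 5); "
            "pass min_shared for >= k-of-N counts"
        )
    regions = {}
    names = sorted(named)
    for r in range(1, n + 1):
        for combo in itertools.combinations(names, r):
            pattern = frozenset(combo)
            regions["+".join(combo)] = sum(
                1 for m in membership.values() if m == pattern
            )
    result["regions"] = regions
    return result


def write_gene_report(
    records: Sequence[GeneOverlapRecord], path, header_lines: Iterable[str] = ()
) -> None:
    """TSV report: gene_id, class, overlapping bp, block ids."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\toverlap_class\toverlapping_bp\tintron_only\tblocks_hit\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.overlap_class}\t{r.overlapping_bp}\t"
                f"{int(r.intron_only)}\t{','.join(r.blocks_hit)}\n"
            )
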