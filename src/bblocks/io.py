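"""Readers and writers for depth tracks, chromosome sizes, annotations, blocks.

Input contract
--------------
* chromosome sizes: FAI (first two columns used) or a two-column TSV
* per-base depth: ``samtools depth``-style TSV (chrom, 1-based position,
  integer depth) or bedGraph (chrom, 0-based start, end, depth); bases
  absent from the file are depth 0 and zeros count toward the genome mean
* gene annotations: BED (4+ columns; BED12 block fields become exons) or
  GFF3 (``gene`` features with nested ``exon`` children)
* block calls: BED6+ with columns chrom, start, end, block_id, block SCR,
  strand ".", copy_number, fraction_passing, b_space_bp

Depth inputs are assumed already deduplicated: PCR-duplicate marking is an
upstream alignment-side concern and this package's contract begins at
per-base depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from bblocks.genome import GenomeIndex, GenomeValidationError

Role = Literal["b_carrier", "nob_reference", "control"]
ROLES = ("b_carrier", "nob_reference", "control")


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line."""


# ---------------------------------------------------------------------------
# chromosome sizes


def load_genome_index(path: str | Path) -> GenomeIndex:
    """Load a chromosome-sizes table (FAI or two-column TSV).

    Only the first two columns (name, length) are used, so a ``samtools
    faidx`` .fai file works directly. Duplicate names are rejected.
    """
    path = Path(path)
    chroms: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
            if name in chroms:
                raise GenomeValidationError(
                    f"{path}:{lineno}: duplicate chromosome {name!r}"
                )
            chroms[name] = length
    if not chroms:
        raise ParseError(f"{path}: no records")
    return GenomeIndex(chroms)


# ---------------------------------------------------------------------------
# depth tracks


@dataclass
class DepthTrack:
    """Per-base raw read depth for one sample over a whole genome.

    ``depth`` holds one non-negative integer vector per chromosome, with
    length equal to the chromosome length (every base has exactly one
    value). ``genome_mean_depth`` is total depth divided by total genome
    length, zeros included.
    """

    sample_id: str
    role: Role
    index: GenomeIndex
    depth: dict[str, np.ndarray]
    genome_mean_depth: float = field(init=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        total = 0
        for name, length in self.index.chroms.items():
            if name not in self.depth:
                raise GenomeValidationError(
                    f"sample {self.sample_id}: no depth vector for chromosome {name!r}"
                )
            vec = self.depth[name]
            if len(vec) != length:
                raise GenomeValidationError(
                    f"sample {self.sample_id}: depth vector for {name!r} has "
                    f"length {len(vec)}, chromosome length is {length}"
                )
            if vec.min(initial=0) < 0:
                raise GenomeValidationError(
                    f"sample {self.sample_id}: negative depth on {name!r}"
                )
            total += int(vec.sum())
        self.genome_mean_depth = total / self.index.total_length


def _detect_depth_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".bedgraph", ".bg", ".bdg"}:
        return "bedgraph"
    return "depth_tsv"


def load_depth(
    path: str | Path,
    index: GenomeIndex,
    role: Role,
    sample_id: str | None = None,
    dialect: str | None = None,
    expected_mean: float | None = None,
) -> DepthTrack:
    """Load a per-base depth file onto a genome index.

    Dialect is auto-detected from the extension (``.bedgraph``/``.bg`` ->
    bedGraph, otherwise samtools-depth TSV) and can be overridden. Bases
    absent from the file get depth 0. If ``expected_mean`` is given, the
    recomputed genome mean must match it within 1e-6 relative.
    """
    path = Path(path)
    if dialect is None:
        dialect = _detect_depth_dialect(path)
    if dialect not in {"depth_tsv", "bedgraph"}:
        raise ValueError(f"unknown depth dialect {dialect!r}")

    arrays = {name: np.zeros(length, dtype=np.int64) for name, length in index.chroms.items()}

    ncols = 3 if dialect == "depth_tsv" else 4
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(ncols),
            dtype={0: str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed depth file: {exc}") from exc
    if df.empty:
        # legal: an all-zero track
        return DepthTrack(sample_id or path.stem, role, index, arrays)

    unknown = set(df[0].unique()) - set(index.chroms)
    if unknown:
        raise GenomeValidationError(
            f"{path}: unknown chromosome(s) {sorted(unknown)!r} not in genome index"
        )

    for chrom, sub in df.groupby(0, sort=False):
        arr = arrays[str(chrom)]
        length = len(arr)
        if dialect == "depth_tsv":
            pos = sub[1].to_numpy(dtype=np.int64)  # 1-based
            val = sub[2].to_numpy(dtype=np.int64)
            if (pos < 1).any() or (pos > length).any():
                bad = pos[(pos < 1) | (pos > length)][0]
                raise GenomeValidationError(
                    f"{path}: position {bad} out of bounds for {chrom} (length {length})"
                )
            if (val < 0).any():
                raise GenomeValidationError(f"{path}: negative depth on {chrom}")
            arr[pos - 1] = val
        else:
            start = sub[1].to_numpy(dtype=np.int64)
            end = sub[2].to_numpy(dtype=np.int64)
            val = sub[3].to_numpy()
            if (start < 0).any() or (end > length).any() or (start >= end).any():
                raise GenomeValidationError(
                    f"{path}: bedGraph interval out of bounds on {chrom} (length {length})"
                )
            if (val < 0).any():
                raise GenomeValidationError(f"{path}: negative depth on {chrom}")
            for s, e, v in zip(start, end, val):
                arr[s:e] = int(v)

    track = DepthTrack(sample_id or path.stem, role, index, arrays)
    if expected_mean is not None:
        if not math.isclose(track.genome_mean_depth, expected_mean, rel_tol=1e-6):
            raise GenomeValidationError(
                f"{path}: recomputed genome mean {track.genome_mean_depth:.6g} does "
                f"not match supplied value {expected_mean:.6g}"
            )
    return track


def write_depth_tsv(track: DepthTrack, path: str | Path) -> None:
    """Write a DepthTrack as a samtools-depth-style TSV (zero-depth bases omitted)."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in track.index.names:
            vec = track.depth[chrom]
            (nz,) = np.nonzero(vec)
            for i in nz:
                fh.write(f"{chrom}\t{i + 1}\t{vec[i]}\n")


def write_bedgraph(values: dict[str, np.ndarray], index: GenomeIndex, path: str | Path) -> None:
    """Emit a per-base track as run-length-encoded bedGraph (browser inspection)."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in index.names:
            vec = np.asarray(values[chrom])
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{vec[s]:g}\n")


# ---------------------------------------------------------------------------
# block BED output

_BLOCK_COLUMNS = (
    "chrom start end block_id block_scr strand copy_number fraction_passing b_space_bp"
).split()


def _fmt_float(x: float | None) -> str:
    if x is None:
        return "NA"
    if math.isinf(x):
        return "inf"
    return repr(float(x))


def write_blocks(blocks: Sequence, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write called blocks as BED6+ (0-based half-open).

    Extra columns after the standard six: copy_number, fraction_passing,
    b_space_bp. Blocks must be sorted by (chrom, start). Floats are written
    with full precision so a write -> read round trip is bit-exact.
    """
    path = Path(path)
    keys = [(b.chrom, b.start) for b in blocks]
    if keys != sorted(keys):
        raise ValueError("blocks must be sorted by (chrom, start) before writing")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for i, b in enumerate(blocks):
            block_id = b.block_id if b.block_id is not None else f"block_{i + 1}"
            fh.write(
                "\t".join(
                    [
                        b.chrom,
                        str(b.start),
                        str(b.end),
                        block_id,
                        _fmt_float(b.block_scr),
                        ".",
                        _fmt_float(b.copies),
                        _fmt_float(b.fraction_passing),
                        _fmt_float(b.b_space_bp),
                    ]
                )
                + "\n"
            )


def read_blocks(path: str | Path) -> list:
    """Read a block BED written by :func:`write_blocks`."""
    from bblocks.blocks import Block  # deferred: io must not depend on caller logic

    path = Path(path)
    out: list[Block] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")

            def _f(s: str) -> float | None:
                return None if s == "NA" else float(s)

            out.append(
                Block(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    block_id=fields[3],
                    block_scr=float(fields[4]),
                    copies=_f(fields[6]),
                    fraction_passing=float(fields[7]),
                    b_space_bp=_f(fields[8]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# gene annotations


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (0-based half-open) with optional exon sub-intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GenomeValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise GenomeValidationError(
                    f"gene {self.gene_id}: exon [{s}, {e}) not nested in gene interval"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


def load_genes(path: str | Path, index: GenomeIndex | None = None) -> list[GeneAnnotation]:
    """Load gene annotations from BED (4+/BED12) or GFF3 (by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        genes = _load_genes_gff3(path)
    else:
        genes = _load_genes_bed(path)
    if index is not None:
        for g in genes:
            index.check_interval(g.chrom, g.start, g.end)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _load_genes_bed(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: BED gene record needs >= 4 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            exons: tuple[tuple[int, int], ...] = ()
            if len(f) >= 12:  # BED12 blocks are exons
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(GeneAnnotation(name, chrom, start, end, exons))
    return genes


def _load_genes_gff3(path: Path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        exons = tuple(
            sorted((ex.start - 1, ex.end) for ex in db.children(feat, featuretype="exon"))
        )
        genes.append(GeneAnnotation(gene_id, feat.seqid, feat.start - 1, feat.end, exons))
    return genes
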