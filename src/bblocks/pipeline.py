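"""End-to-end orchestration: depth tracks in, blocks / core / reports out.

Each B-carrying (or control) sample is paired with a B-lacking reference
sample for the coverage-ratio statistics; B blocks are called per pair,
intersected across B carriers into the core set, re-quantified per sample,
and optionally overlapped with a gene annotation. All randomness lives in
the simulator; given identical inputs and configuration the pipeline's
outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from bblocks.genome import GenomeIndex
from bblocks.io import (
    DepthTrack,
    GeneAnnotation,
    load_depth,
    load_genes,
    load_genome_index,
    write_blocks,
)
from bblocks.stats import build_scr_track
from bblocks.blocks import (
    Block,
    call_blocks,
    calling_stage_counts,
    DEFAULT_SCR_MIN,
    DEFAULT_ALPHA,
    DEFAULT_MERGE_GAP,
    DEFAULT_MIN_LEN,
    DEFAULT_MIN_FRAC,
)
from bblocks.quantify import (
    annotate_copy_numbers,
    core_intersection,
    requantify_core,
    quantify,
    QuantReport,
    CoreBlockSet,
)
from bblocks.genes import genes_in_blocks, write_gene_report, GeneOverlapRecord

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Block-calling thresholds; defaults are the published analysis values."""

    scr_min: float = DEFAULT_SCR_MIN
    alpha: float = DEFAULT_ALPHA
    merge_gap: int = DEFAULT_MERGE_GAP
    min_len: int = DEFAULT_MIN_LEN
    min_frac: float = DEFAULT_MIN_FRAC

    def to_dict(self) -> dict:
        return {
            "scr_min": self.scr_min,
            "alpha": self.alpha,
            "merge_gap": self.merge_gap,
            "min_len": self.min_len,
            "min_frac": self.min_frac,
        }


@dataclass
class SampleSpec:
    sample_id: str
    depth_path: str
    role: str  # b_carrier | nob_reference | control
    reference_id: str | None = None  # nob_reference sample to compare against


@dataclass
class RunConfig:
    genome_path: str
    samples: list[SampleSpec]
    thresholds: Thresholds = field(default_factory=Thresholds)
    core_k: int | None = None  # default: n_carriers - 1 (>= 1)
    annotation_path: str | None = None
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "genome": self.genome_path,
                "samples": [
                    (s.sample_id, s.depth_path, s.role, s.reference_id)
                    for s in self.samples
                ],
                "thresholds": self.thresholds.to_dict(),
                "core_k": self.core_k,
                "annotation": self.annotation_path,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SampleResult:
    sample_id: str
    blocks: list[Block]
    core_blocks: list[Block]
    quant: QuantReport
    gene_overlaps: list[GeneOverlapRecord] | None
    stage_counts: dict


@dataclass
class PipelineResult:
    index: GenomeIndex
    samples: dict[str, SampleResult]
    core: CoreBlockSet
    config: RunConfig


def _resolve_pairs(samples: list[SampleSpec]) -> list[tuple[SampleSpec, SampleSpec]]:
    refs = {s.sample_id: s for s in samples if s.role == "nob_reference"}
    if not refs:
        raise ValueError("no nob_reference sample in the sample table")
    pairs = []
    for s in samples:
        if s.role == "nob_reference":
            continue
        ref_id = s.reference_id
        if ref_id is None:
            if len(refs) != 1:
                raise ValueError(
                    f"sample {s.sample_id}: reference_id required when multiple "
                    "nob_reference samples are present"
                )
            ref_id = next(iter(refs))
        if ref_id not in refs:
            raise ValueError(
                f"sample {s.sample_id}: reference {ref_id!r} is not a nob_reference sample"
            )
        pairs.append((s, refs[ref_id]))
    if not any(s.role == "b_carrier" for s, _ in pairs):
        raise ValueError("need at least one b_carrier / nob_reference pair")
    return pairs


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run calling, core intersection, quantification and gene overlap.

    Core intersection is over B-carrier samples only; controls are called
    and quantified but do not vote on the core set.
    """
    index = load_genome_index(config.genome_path)
    pairs = _resolve_pairs(config.samples)

    carriers = [s for s, _ in pairs if s.role == "b_carrier"]
    n_carriers = len(carriers)
    core_k = config.core_k if config.core_k is not None else max(1, n_carriers - 1)
    if not (1 <= core_k <= n_carriers):
        raise ValueError(
            f"core_k={core_k} out of range for {n_carriers} B-carrier sample(s)"
        )

    annotation: list[GeneAnnotation] | None = None
    if config.annotation_path:
        annotation = load_genes(config.annotation_path, index)

    th = config.thresholds
    tracks: dict[str, DepthTrack] = {}

    def get_track(spec: SampleSpec) -> DepthTrack:
        if spec.sample_id not in tracks:
            tracks[spec.sample_id] = load_depth(
                spec.depth_path, index, spec.role, sample_id=spec.sample_id
            )
        return tracks[spec.sample_id]

    scr_tracks = {}
    blocks_by_sample: dict[str, list[Block]] = {}
    stage_by_sample: dict[str, dict] = {}
    for spec, ref in pairs:
        scr = build_scr_track(get_track(spec), get_track(ref))
        scr_tracks[spec.sample_id] = scr
        blocks = call_blocks(scr, th.scr_min, th.alpha, th.merge_gap, th.min_len, th.min_frac)
        annotate_copy_numbers(blocks)
        blocks_by_sample[spec.sample_id] = blocks
        stage_by_sample[spec.sample_id] = calling_stage_counts(
            scr, th.scr_min, th.alpha, th.merge_gap, th.min_len, th.min_frac
        )
        logger.info(
            "sample %s: %.3f%% of genome passing, %d raw intervals, %d blocks",
            spec.sample_id,
            stage_by_sample[spec.sample_id]["percent_genome_passing"],
            stage_by_sample[spec.sample_id]["raw_intervals"],
            len(blocks),
        )

    core = core_intersection(
        [blocks_by_sample[s.sample_id] for s in carriers], core_k, index
    )

    results: dict[str, SampleResult] = {}
    for spec, _ in pairs:
        blocks = blocks_by_sample[spec.sample_id]
        core_blocks = requantify_core(core, scr_tracks[spec.sample_id])
        quant = quantify(
            blocks,
            core_blocks,
            sample_id=spec.sample_id,
            percent_genome_passing=stage_by_sample[spec.sample_id][
                "percent_genome_passing"
            ],
        )
        overlaps = genes_in_blocks(annotation, blocks) if annotation is not None else None
        results[spec.sample_id] = SampleResult(
            sample_id=spec.sample_id,
            blocks=blocks,
            core_blocks=core_blocks,
            quant=quant,
            gene_overlaps=overlaps,
            stage_counts=stage_by_sample[spec.sample_id],
        )

    result = PipelineResult(index=index, samples=results, core=core, config=config)
    if config.outdir:
        _write_outputs(result)
    return result


def _provenance_header(config: RunConfig) -> list[str]:
    th = config.thresholds
    return [
        f"bblocks config_hash={config.config_hash()}",
        f"thresholds scr_min={th.scr_min} alpha={th.alpha} merge_gap={th.merge_gap} "
        f"min_len={th.min_len} min_frac={th.min_frac}",
    ]


def _write_outputs(result: PipelineResult) -> None:
    outdir = Path(result.config.outdir)  # type: ignore[arg-type]
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance_header(result.config)

    summary: dict = {
        "config_hash": result.config.config_hash(),
        "thresholds": result.config.thresholds.to_dict(),
        "core_k": result.core.k_required,
        "n_core_intervals": len(result.core.intervals),
        "core_a_space_bp": result.core.total_bp,
        "samples": {},
    }
    for sid, res in result.samples.items():
        write_blocks(res.blocks, outdir / f"{sid}.blocks.bed", header)
        write_blocks(
            sorted(res.core_blocks, key=lambda b: (b.chrom, b.start)),
            outdir / f"{sid}.core_blocks.bed",
            header,
        )
        _write_quant_tsv(res.quant, outdir / f"{sid}.quant.tsv", header)
        if res.gene_overlaps is not None:
            write_gene_report(res.gene_overlaps, outdir / f"{sid}.genes.tsv", header)
        summary["samples"][sid] = res.quant.to_dict()

    with open(outdir / "core.bed", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for (chrom, start, end), sup in zip(
            result.core.intervals, result.core.support_count
        ):
            fh.write(f"{chrom}\t{start}\t{end}\tcore\t{sup}\t.\n")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def _write_quant_tsv(report: QuantReport, path: Path, header: list[str]) -> None:
    d = report.to_dict()
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("\t".join(d.keys()) + "\n")
        fh.write("\t".join("NA" if v is None else str(v) for v in d.values()) + "\n")
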