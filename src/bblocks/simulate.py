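"""Synthetic paired depth tracks with planted B segments and known truth.

Coverage model
--------------
The simulated organism is a diploid (A genome) in which the B-carrying
female additionally carries one haploid B chromosome built from copies of
A-genome segments. Expected per-base depth is proportional to local copy
number over ploidy:

* male (NoB): ``mean_depth_male`` everywhere, times a mappability factor
  inside dropout regions;
* female baseline: ``mean_depth_female``; inside a planted segment with
  ``c`` B-located copies the factor is (2 + b_ploidy * c) / 2 (diploid A
  plus the B copies); inside a female A-genome duplication the factor is
  2 (four copies over the diploid baseline — an SCR = 2 decoy that block
  calling at SCR >= 3 must ignore);
* mappability dropouts scale BOTH samples, pushing the male's scaled
  coverage below 1 to exercise the female-only copy estimator;
* retrogene artifacts: ``true_retrogene`` elevates female depth over exons
  only (a reverse-transcribed gene copy on the B); ``divergent_intron``
  elevates both samples over the whole gene (a recent repeat insertion
  whose reads pile onto one locus) and flags the introns in the truth set.

Per-base noise is Poisson by default; a negative-binomial (gamma-Poisson)
option models the overdispersion of real Illumina depth, and ``"none"``
gives the rounded expectation for noise-free limit checks. Everything is
reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from bblocks.genome import GenomeIndex, GenomeValidationError
from bblocks.io import DepthTrack, write_depth_tsv
from bblocks.blocks import Block


@dataclass(frozen=True)
class PlantedSegment:
    """An A-genome segment present in ``copies`` extra copies on the B."""

    chrom: str
    start: int
    end: int
    copies: float

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"planted segment copies must be >= 1, got {self.copies}")


@dataclass(frozen=True)
class MappabilityDropout:
    chrom: str
    start: int
    end: int
    retention: float  # fraction of expected depth retained in both samples

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention < 1.0):
            raise ValueError("retention must be in [0, 1)")


@dataclass(frozen=True)
class RetrogeneArtifact:
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    mode: Literal["true_retrogene", "divergent_intron"]
    copies: float = 8.0


@dataclass
class SimConfig:
    """Study conditions for one simulated female/male pair.

    Depth defaults follow typical individual-female (~15x) and pooled-male
    (~25x) Illumina runs. Negative-binomial dispersion 0.1 gives
    var = mu + 0.1 mu^2, mild overdispersion typical of Illumina WGS.
    """

    genome: list[tuple[str, int]]
    mean_depth_female: float = 15.0
    mean_depth_male: float = 25.0
    noise: Literal["poisson", "negative_binomial", "none"] = "poisson"
    dispersion: float = 0.1
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    a_duplications: list[tuple[str, int, int]] = field(default_factory=list)
    mappability_dropouts: list[MappabilityDropout] = field(default_factory=list)
    retrogene_artifacts: list[RetrogeneArtifact] = field(default_factory=list)
    b_ploidy: int = 1  # number of B chromosomes per cell
    seed: int = 0

    def genome_index(self) -> GenomeIndex:
        return GenomeIndex(dict(self.genome))


@dataclass
class TruthSet:
    """Ground truth of a simulation: planted segments, decoys, masks."""

    planted: list[PlantedSegment]
    decoys: list[dict]  # {"type": ..., "chrom": ..., "start": ..., "end": ..., ...}

    def planted_footprint(self) -> list[tuple[str, int, int]]:
        return [(p.chrom, p.start, p.end) for p in self.planted]

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.planted:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tplanted\t{p.copies!r}\n")
            for d in self.decoys:
                fh.write(
                    f"{d['chrom']}\t{d['start']}\t{d['end']}\t{d['type']}\t"
                    f"{d.get('copies', 0)!r}\n"
                )

    @classmethod
    def read_bed(cls, path: str | Path) -> "TruthSet":
        planted, decoys = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, start, end, kind, val = line.rstrip("\n").split("\t")
                if kind == "planted":
                    planted.append(PlantedSegment(chrom, int(start), int(end), float(val)))
                else:
                    decoys.append(
                        {
                            "type": kind,
                            "chrom": chrom,
                            "start": int(start),
                            "end": int(end),
                            "copies": float(val),
                        }
                    )
        return cls(planted, decoys)


def _expected_depths(config: SimConfig, index: GenomeIndex) -> tuple[dict, dict]:
    female = {c: np.full(n, config.mean_depth_female, dtype=np.float64) for c, n in index.chroms.items()}
    male = {c: np.full(n, config.mean_depth_male, dtype=np.float64) for c, n in index.chroms.items()}

    seen: dict[str, list[tuple[int, int]]] = {}
    for seg in config.planted_segments:
        index.check_interval(seg.chrom, seg.start, seg.end)
        for s, e in seen.get(seg.chrom, []):
            if seg.start < e and seg.end > s:
                raise GenomeValidationError(
                    f"planted segments overlap on {seg.chrom}: "
                    f"[{seg.start},{seg.end}) vs [{s},{e})"
                )
        seen.setdefault(seg.chrom, []).append((seg.start, seg.end))
        factor = (2.0 + config.b_ploidy * seg.copies) / 2.0
        female[seg.chrom][seg.start:seg.end] *= factor

    for chrom, start, end in config.a_duplications:
        index.check_interval(chrom, start, end)
        female[chrom][start:end] *= 2.0

    for art in config.retrogene_artifacts:
        index.check_interval(art.chrom, art.start, art.end)
        factor = (2.0 + config.b_ploidy * art.copies) / 2.0
        if art.mode == "true_retrogene":
            for s, e in art.exons:
                female[art.chrom][s:e] *= factor
        elif art.mode == "divergent_intron":
            female[art.chrom][art.start:art.end] *= factor
            male[art.chrom][art.start:art.end] *= factor
        else:
            raise ValueError(f"unknown retrogene mode {art.mode!r}")

    for drop in config.mappability_dropouts:
        index.check_interval(drop.chrom, drop.start, drop.end)
        female[drop.chrom][drop.start:drop.end] *= drop.retention
        male[drop.chrom][drop.start:drop.end] *= drop.retention

    return female, male


def _draw(mu: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise == "poisson":
        return rng.poisson(mu).astype(np.int64)
    if config.noise == "negative_binomial":
        # gamma-Poisson mixture: var = mu + dispersion * mu^2
        d = config.dispersion
        if d <= 0:
            raise ValueError("dispersion must be positive for negative_binomial noise")
        lam = rng.gamma(shape=1.0 / d, scale=mu * d)
        return rng.poisson(lam).astype(np.int64)
    if config.noise == "none":
        return np.rint(mu).astype(np.int64)
    raise ValueError(f"unknown noise model {config.noise!r}")


def simulate_pair(config: SimConfig) -> tuple[DepthTrack, DepthTrack, TruthSet]:
    """Draw a (female, male) depth-track pair and its ground truth."""
    index = config.genome_index()
    female_mu, male_mu = _expected_depths(config, index)
    rng = np.random.default_rng(config.seed)

    female_depth = {c: _draw(female_mu[c], config, rng) for c in index.names}
    male_depth = {c: _draw(male_mu[c], config, rng) for c in index.names}

    female = DepthTrack("sim_female_B", "b_carrier", index, female_depth)
    male = DepthTrack("sim_male_NoB", "nob_reference", index, male_depth)

    decoys: list[dict] = []
    for chrom, start, end in config.a_duplications:
        decoys.append(
            {"type": "a_duplication", "chrom": chrom, "start": start, "end": end, "copies": 2}
        )
    for drop in config.mappability_dropouts:
        decoys.append(
            {
                "type": "mappability_dropout",
                "chrom": drop.chrom,
                "start": drop.start,
                "end": drop.end,
                "copies": 0,
            }
        )
    for art in config.retrogene_artifacts:
        decoys.append(
            {
                "type": art.mode,
                "chrom": art.chrom,
                "start": art.start,
                "end": art.end,
                "copies": art.copies,
            }
        )
    truth = TruthSet(list(config.planted_segments), decoys)
    return female, male, truth


def write_simulation(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Run a simulation and write depth TSVs, truth BED, and provenance JSON."""
    import bblocks

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    female, male, truth = simulate_pair(config)
    f_path = outdir / "female_B.depth.tsv"
    m_path = outdir / "male_NoB.depth.tsv"
    t_path = outdir / "truth.bed"
    p_path = outdir / "provenance.json"
    write_depth_tsv(female, f_path)
    write_depth_tsv(male, m_path)
    truth.write_bed(t_path)
    with open(p_path, "w") as fh:
        json.dump(
            {"version": bblocks.__version__, "config": _config_to_jsonable(config)},
            fh,
            indent=2,
        )
    return f_path, m_path, t_path, p_path


def _config_to_jsonable(config: SimConfig) -> dict:
    d = asdict(config)
    d["genome"] = [list(g) for g in config.genome]
    return d


# ---------------------------------------------------------------------------
# canonical study designs

#: Planted-segment table of the recovery benchmark: (chrom, start, length,
#: copies). Lengths span 1-20 kb with the small-block skew seen in real
#: B-block size distributions (median well under 2 kb), and the highest
#: copy numbers sit on the shortest segments so that B-derived reads
#: remain a modest fraction of the female's total read mass — the regime
#: the coverage-ratio method assumes (B-derived reads inflate the female's
#: genome-wide mean, and with it every scaled coverage, so a simulated B
#: that dominated the read mass would not resemble the real measurement).
RECOVERY_SEGMENTS: tuple[tuple[str, int, int, float], ...] = (
    ("chrA", 20_000, 1_000, 50.0),
    ("chrA", 60_000, 1_000, 50.0),
    ("chrA", 100_000, 1_200, 16.0),
    ("chrA", 140_000, 1_200, 16.0),
    ("chrA", 180_000, 1_400, 8.0),
    ("chrA", 220_000, 1_400, 8.0),
    ("chrA", 260_000, 1_500, 4.0),
    ("chrA", 300_000, 1_500, 4.0),
    ("chrA", 360_000, 2_000, 16.0),
    ("chrA", 420_000, 3_000, 8.0),
    ("chrA", 500_000, 6_000, 8.0),
    ("chrA", 600_000, 20_000, 4.0),
    ("chrB", 30_000, 1_200, 16.0),
    ("chrB", 70_000, 1_200, 16.0),
    ("chrB", 110_000, 1_400, 8.0),
    ("chrB", 150_000, 1_400, 8.0),
    ("chrB", 190_000, 1_500, 4.0),
    ("chrB", 230_000, 1_500, 4.0),
    ("chrB", 300_000, 2_500, 16.0),
    ("chrB", 400_000, 4_000, 8.0),
)


def recovery_benchmark_config(seed: int = 0) -> SimConfig:
    """Canonical parameter-recovery scenario: 2 x 1 Mb genome, 20 planted
    segments of 1-20 kb with 4-50 B-located copies, Poisson 15x female /
    25x male depth."""
    return SimConfig(
        genome=[("chrA", 1_000_000), ("chrB", 1_000_000)],
        mean_depth_female=15.0,
        mean_depth_male=25.0,
        noise="poisson",
        planted_segments=[
            PlantedSegment(c, s, s + l, cp) for c, s, l, cp in RECOVERY_SEGMENTS
        ],
        seed=seed,
    )


def control_config(seed: int = 0) -> SimConfig:
    """Null scenario: same genome and depths, nothing planted.

    Emulates a B-lacking female against the male pool; any called block is
    a false positive driven by depth stochasticity alone.
    """
    return SimConfig(
        genome=[("chrA", 1_000_000), ("chrB", 1_000_000)],
        mean_depth_female=15.0,
        mean_depth_male=25.0,
        noise="poisson",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryMetrics:
    """Comparison of called blocks against a simulation's truth set."""

    n_truth: int
    n_recovered: int
    sensitivity: float
    precision: float | None  # None (NA) when nothing was called
    mean_breakpoint_error_bp: float | None
    copy_number_rel_errors: dict[str, float]  # per recovered truth segment
    recovered: dict[str, bool]

    @property
    def mean_copy_rel_error(self) -> float | None:
        if not self.copy_number_rel_errors:
            return None
        return float(np.mean(list(self.copy_number_rel_errors.values())))


def _merge(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def evaluate_recovery(
    blocks: Sequence[Block], truth: TruthSet, tolerance: int = 300
) -> RecoveryMetrics:
    """Score called blocks against planted truth segments.

    A truth segment is recovered when it has >= 50% reciprocal overlap with
    the union of blocks touching it. Precision is the fraction of the
    called footprint lying within truth segments dilated by ``tolerance``
    bp. Breakpoint error averages the distances between the outermost
    matched-block boundaries and the true segment ends. Copy-number
    relative error compares the overlap-length-weighted mean of block copy
    estimates with the true copy count.
    """
    by_chrom: dict[str, list[Block]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)

    recovered: dict[str, bool] = {}
    copy_errors: dict[str, float] = {}
    bp_errors: list[float] = []

    for seg in truth.planted:
        key = f"{seg.chrom}:{seg.start}-{seg.end}"
        touching = [
            b for b in by_chrom.get(seg.chrom, []) if b.start < seg.end and b.end > seg.start
        ]
        if not touching:
            recovered[key] = False
            continue
        union = _merge([(b.start, b.end) for b in touching])
        ov = sum(max(0, min(e, seg.end) - max(s, seg.start)) for s, e in union)
        union_len = sum(e - s for s, e in union)
        ok = ov >= 0.5 * (seg.end - seg.start) and ov >= 0.5 * union_len
        recovered[key] = ok
        if not ok:
            continue
        lo = min(s for s, _ in union)
        hi = max(e for _, e in union)
        bp_errors.append((abs(lo - seg.start) + abs(hi - seg.end)) / 2.0)
        weights = [max(0, min(b.end, seg.end) - max(b.start, seg.start)) for b in touching]
        ests = [b.copies for b in touching]
        if all(c is not None for c in ests) and sum(weights) > 0:
            est = float(np.average([float(c) for c in ests], weights=weights))
            copy_errors[key] = abs(est - seg.copies) / seg.copies

    n_truth = len(truth.planted)
    n_rec = sum(recovered.values())
    sensitivity = n_rec / n_truth if n_truth else 1.0

    footprint_bp = sum(b.length for b in blocks)
    if footprint_bp == 0:
        precision = None
    else:
        dilated: dict[str, list[tuple[int, int]]] = {}
        for seg in truth.planted:
            dilated.setdefault(seg.chrom, []).append(
                (max(0, seg.start - tolerance), seg.end + tolerance)
            )
        dilated = {c: _merge(v) for c, v in dilated.items()}
        inside = 0
        for b in blocks:
            inside += sum(
                max(0, min(e, b.end) - max(s, b.start)) for s, e in dilated.get(b.chrom, [])
            )
        precision = inside / footprint_bp

    return RecoveryMetrics(
        n_truth=n_truth,
        n_recovered=n_rec,
        sensitivity=sensitivity,
        precision=precision,
        mean_breakpoint_error_bp=float(np.mean(bp_errors)) if bp_errors else None,
        copy_number_rel_errors=copy_errors,
        recovered=recovered,
    )
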