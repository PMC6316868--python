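"""Scaled coverage, the scaled coverage ratio (SCR), and the per-base binomial test.

The statistic
-------------
Raw depth at each base is scaled by the sample's genome-wide mean depth, so
a single-copy diploid region has scaled coverage ~1. The scaled coverage
ratio compares a B-carrying female against a B-lacking (NoB) male pool:

    SCR = female scaled coverage / male scaled coverage

A haploid B chromosome carrying ``c`` copies of an A-genome segment raises
the female's expected depth by a factor (2 + c)/2, so SCR = (2 + c)/2 and
the calling threshold SCR >= 3 corresponds to >= 4 B-located copies. A
simple duplication within the female's diploid A genome only reaches
SCR = 2 and stays below threshold.

Significance is assessed per base with a binomial test on the raw read
counts: X female reads out of n = female + male total, with success
probability p equal to the female's share of the combined genome-wide
depth. Because only SCR >= 3 positions are ever kept, the test is one-sided
(upper tail); a lower tail cannot co-occur with an elevated ratio. The
p <= 0.001 cutoff is applied per base with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from bblocks.genome import GenomeIndex
from bblocks.io import DepthTrack


@dataclass(frozen=True)
class BinomialParams:
    """Expected frequency of B-female reads under the no-difference null.

    ``p`` is the female genome-wide mean depth divided by the sum of the
    female and male genome-wide mean depths; ``q = 1 - p``. Fixed
    genome-wide, not per chromosome.
    """

    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must be in (0, 1), got {self.p}")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @classmethod
    def from_tracks(cls, female: DepthTrack, male: DepthTrack) -> "BinomialParams":
        fm, mm = female.genome_mean_depth, male.genome_mean_depth
        if fm <= 0 or mm <= 0:
            raise ValueError("both samples need positive genome mean depth")
        return cls(fm / (fm + mm))


@dataclass
class ScaledCoverage:
    """Per-base scaled coverage (raw depth / genome-wide mean depth).

    The genome-wide mean of scaled values is 1 by construction.
    """

    index: GenomeIndex
    values: dict[str, np.ndarray]

    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.values.values())
        return total / self.index.total_length


def scale_coverage(track: DepthTrack) -> ScaledCoverage:
    """Divide raw depth at every base by the sample's genome mean depth."""
    mean = track.genome_mean_depth
    if mean == 0:
        raise ValueError(f"empty coverage: sample {track.sample_id} has zero total depth")
    values = {c: track.depth[c].astype(np.float64) / mean for c in track.index.names}
    return ScaledCoverage(track.index, values)


def compute_scr(female: ScaledCoverage, male: ScaledCoverage) -> dict[str, np.ndarray]:
    """Per-base SCR = female scaled / male scaled.

    Where the male has zero coverage but the female does not, the ratio is
    +inf (such a base passes any SCR threshold; the binomial test still
    gates significance). Where both are zero the ratio is 0.
    """
    if female.index.chroms != male.index.chroms:
        raise ValueError("female and male tracks are on different genome indexes")
    out = {}
    for chrom in female.index.names:
        f = female.values[chrom]
        m = male.values[chrom]
        scr = np.zeros_like(f)
        nz = m > 0
        scr[nz] = f[nz] / m[nz]
        scr[(~nz) & (f > 0)] = np.inf
        out[chrom] = scr
    return out


def binomial_upper_tail(x: int, n: int, params: BinomialParams) -> float:
    """Upper-tail p-value P(X >= x) of the binomial count model.

    ``x`` is the female raw depth, ``n`` the combined female + male raw
    depth. Evaluated through the regularized incomplete beta function, so it
    is numerically stable for large n.
    """
    if not (0 <= x <= n):
        raise ValueError(f"x must satisfy 0 <= x <= n, got x={x}, n={n}")
    # sf is P(X > k); the inclusive upper tail is sf at x - 1
    return float(binom.sf(x - 1, n, params.p))


def binomial_pmf(x, n, params: BinomialParams):
    """Binomial mass function C(n, x) p^x q^(n-x) (vectorized)."""
    return binom.pmf(x, n, params.p)


@dataclass
class ScrTrack:
    """Per-base scaled coverages, their ratio, and the binomial p-value.

    The p-value is 1.0 at bases where both samples have zero raw depth.
    """

    index: GenomeIndex
    female_scaled: dict[str, np.ndarray]
    male_scaled: dict[str, np.ndarray]
    scr: dict[str, np.ndarray]
    pvalue: dict[str, np.ndarray]
    params: BinomialParams = field(repr=False, default=None)  # type: ignore[assignment]


def build_scr_track(female: DepthTrack, male: DepthTrack) -> ScrTrack:
    """Compute the full per-base statistic track for one female/male pair."""
    if female.index.chroms != male.index.chroms:
        raise ValueError(
            f"samples {female.sample_id} and {male.sample_id} are on different genomes"
        )
    params = BinomialParams.from_tracks(female, male)
    f_scaled = scale_coverage(female)
    m_scaled = scale_coverage(male)
    scr = compute_scr(f_scaled, m_scaled)

    pvalue = {}
    for chrom in female.index.names:
        x = female.depth[chrom]
        n = x + male.depth[chrom]
        pv = np.ones(len(x), dtype=np.float64)
        covered = n > 0
        pv[covered] = binom.sf(x[covered] - 1, n[covered], params.p)
        pvalue[chrom] = pv

    return ScrTrack(
        index=female.index,
        female_scaled=f_scaled.values,
        male_scaled=m_scaled.values,
        scr=scr,
        pvalue=pvalue,
        params=params,
    )
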