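import numpy as np
import pytest

from bblocks import GenomeIndex, DepthTrack
from bblocks.stats import ScrTrack, BinomialParams


@pytest.fixture
def toy_index():
    return GenomeIndex({"chr1": 10_000, "chr2": 5_000})


def make_track(index, depths, sample_id="s", role="b_carrier"):
    """Build a DepthTrack from a {chrom: array-like} mapping."""
    arrays = {c: np.asarray(depths[c], dtype=np.int64) for c in index.names}
    return DepthTrack(sample_id, role, index, arrays)


def make_scr_track(index, scr, pvalue=None, female=None, male=None):
    """Assemble an ScrTrack directly from per-chrom arrays (tests only)."""
    scr = {c: np.asarray(scr[c], dtype=float) for c in index.names}
    if pvalue is None:
        pvalue = {c: np.zeros_like(scr[c]) for c in index.names}
    else:
        pvalue = {c: np.asarray(pvalue[c], dtype=float) for c in index.names}
    if female is None:
        female = {c: scr[c].copy() for c in index.names}
    if male is None:
        male = {c: np.ones_like(scr[c]) for c in index.names}
    return ScrTrack(
        index=index,
        female_scaled={c: np.asarray(female[c], dtype=float) for c in index.names},
        male_scaled={c: np.asarray(male[c], dtype=float) for c in index.names},
        scr=scr,
        pvalue=pvalue,
        params=BinomialParams(0.5),
    )
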