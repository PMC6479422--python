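import numpy as np
import pytest

from svdepth.depth_core import DEPTH_CAP, DepthProfile, covering_runs


def make_finalized_profile(depths, chrom="chr1") -> DepthProfile:
    """Wrap an explicit depth array as a finalized profile (test shortcut)."""
    values = np.asarray(depths, dtype=np.int16)
    return DepthProfile(chrom=chrom, length=values.size, values=values, finalized=True)


def brute_force_pileup(segments, length, count_deletions_covered=False):
    """Naive per-read per-base pileup: the oracle the diff-array must match."""
    depth = np.zeros(length, dtype=np.int64)
    for seg in segments:
        for start, end in covering_runs(
            seg.ref_start, seg.cigar, count_deletions_covered=count_deletions_covered
        ):
            for pos in range(max(start, 0), min(end, length)):
                depth[pos] += 1
    return np.minimum(depth, DEPTH_CAP)


@pytest.fixture
def profile_factory():
    return make_finalized_profile
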