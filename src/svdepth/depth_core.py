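"""Per-base depth profiles built with the diff-array / cumulative-sum algorithm.

A chromosome's coverage is accumulated by recording +1 at each position where a
reference-covering read segment starts and -1 one past where it ends, then
taking a prefix sum.  The stored per-base depth is capped at the 16-bit signed
maximum (32,767); the running sum itself is tracked at 64-bit precision so the
cap never corrupts downstream positions.

CIGAR conventions: M, = and X contribute coverage; D and N consume reference
without contributing coverage and therefore split a read into separate covering
segments (a flag flips D to covered); I, S, H and P consume no reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEPTH_CAP = 32767  # int16 maximum; per-base depths are stored capped at this

# SAM CIGAR operation codes (matching pysam's cigartuples encoding)
CIGAR_M, CIGAR_I, CIGAR_D, CIGAR_N, CIGAR_S, CIGAR_H, CIGAR_P, CIGAR_EQ, CIGAR_X = range(9)

_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}

#: ops that consume reference bases
_CONSUMES_REF = frozenset({CIGAR_M, CIGAR_D, CIGAR_N, CIGAR_EQ, CIGAR_X})
#: ops that place read bases on the reference (i.e. contribute coverage)
_COVERS = frozenset({CIGAR_M, CIGAR_EQ, CIGAR_X})

# SAM flag bits used by the default alignment filter
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400


class ProfileStateError(RuntimeError):
    """Operation applied to a profile in the wrong finalization state."""


def parse_cigar(cigar: str) -> list[tuple[int, int]]:
    """Parse a CIGAR string like ``"50M10D50M"`` into (op code, length) pairs."""
    out: list[tuple[int, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in _OP_CODE:
                raise ValueError(f"malformed CIGAR string: {cigar!r}")
            length = int(num)
            if length <= 0:
                raise ValueError(f"non-positive CIGAR length in {cigar!r}")
            out.append((_OP_CODE[ch], length))
            num = ""
    if num:
        raise ValueError(f"trailing number in CIGAR string: {cigar!r}")
    return out


@dataclass
class AlignedSegment:
    """Minimal alignment record: what depth counting needs and nothing more."""

    chrom: str
    ref_start: int
    cigar: list[tuple[int, int]]
    flags: int = 0
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ValueError(f"ref_start must be >= 0, got {self.ref_start}")
        if isinstance(self.cigar, str):
            self.cigar = parse_cigar(self.cigar)
        for op, length in self.cigar:
            if length <= 0:
                raise ValueError("CIGAR lengths must be positive")
            if not 0 <= op <= 8:
                raise ValueError(f"unknown CIGAR op code {op}")


def covering_runs(
    ref_start: int, cigar: list[tuple[int, int]], *, count_deletions_covered: bool = False
) -> list[tuple[int, int]]:
    """Maximal reference intervals covered by read bases, as half-open runs.

    D/N split the read into separate runs unless ``count_deletions_covered``
    makes D behave like M.
    """
    covers = _COVERS | ({CIGAR_D} if count_deletions_covered else frozenset())
    runs: list[tuple[int, int]] = []
    pos = ref_start
    run_start: int | None = None
    for op, length in cigar:
        if op in covers:
            if run_start is None:
                run_start = pos
            pos += length
        elif op in _CONSUMES_REF:  # D or N acting as a gap
            if run_start is not None:
                runs.append((run_start, pos))
                run_start = None
            pos += length
        # I, S, H, P: no reference consumed, run continues unbroken
    if run_start is not None:
        runs.append((run_start, pos))
    return runs


def passes_alignment_filter(flags: int, mapq: int, *, min_mapq: int = 0) -> bool:
    """Default read filter: drop unmapped / secondary / duplicate / QC-fail.

    Supplementary alignments are kept: split reads legitimately contribute
    depth. No mapping-quality floor unless requested.
    """
    if flags & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_QCFAIL | FLAG_DUPLICATE):
        return False
    return mapq >= min_mapq


@dataclass
class DepthProfile:
    """Per-base depth for one chromosome.

    Before :func:`finalize` the ``values`` array holds signed start/end
    increments; afterwards it holds capped per-base depths.
    """

    chrom: str
    length: int
    values: np.ndarray = field(repr=False)
    finalized: bool = False


def new_profile(chrom: str, length: int) -> DepthProfile:
    """Allocate an all-zero increment array for one chromosome."""
    if length <= 0:
        raise ValueError(f"chromosome length must be positive, got {length}")
    return DepthProfile(chrom=chrom, length=length, values=np.zeros(length, dtype=np.int64))


def ingest_alignment(
    profile: DepthProfile,
    seg: AlignedSegment,
    *,
    count_deletions_covered: bool = False,
) -> DepthProfile:
    """Record one aligned segment's covering runs into the increment array."""
    if profile.finalized:
        raise ProfileStateError("cannot ingest into a finalized profile")
    if seg.chrom != profile.chrom:
        raise ValueError(f"segment chrom {seg.chrom!r} != profile chrom {profile.chrom!r}")
    ingest_runs(
        profile,
        covering_runs(seg.ref_start, seg.cigar, count_deletions_covered=count_deletions_covered),
    )
    return profile


def ingest_runs(profile: DepthProfile, runs: list[tuple[int, int]]) -> None:
    """Apply +1/-1 increments for half-open covering runs, clamped to bounds."""
    if profile.finalized:
        raise ProfileStateError("cannot ingest into a finalized profile")
    length = profile.length
    values = profile.values
    for start, end in runs:
        if start >= length or end <= 0:
            logger.warning(
                "covering run [%d, %d) lies outside %s:[0, %d); skipped",
                start, end, profile.chrom, length,
            )
            continue
        if end > length or start < 0:
            logger.warning(
                "covering run [%d, %d) extends beyond %s bounds; clamped", start, end, profile.chrom
            )
        s = max(start, 0)
        e = min(end, length)
        values[s] += 1
        if e < length:
            values[e] -= 1


def finalize(profile: DepthProfile) -> DepthProfile:
    """Prefix-sum the increments into per-base depths, capped at 32,767.

    The running sum is kept at 64-bit precision; only the stored value is
    capped, so positions after a capped pile-up remain exact.
    """
    if profile.finalized:
        raise ProfileStateError("profile already finalized")
    running = np.cumsum(profile.values, dtype=np.int64)
    if running.size and running[-1] not in (0,) and (running < 0).any():
        logger.warning("negative running depth on %s: inconsistent increments", profile.chrom)
    profile.values = np.clip(running, 0, DEPTH_CAP).astype(np.int16)
    profile.finalized = True
    return profile


def median_depth(profile: DepthProfile, start: int, end: int) -> int:
    """Median depth over [start, end).

    Even-length intervals use the lower of the two middle values (element at
    index (n-1)//2 after sorting), keeping the result integral.
    """
    if not profile.finalized:
        raise ProfileStateError("profile must be finalized before querying")
    if not (0 <= start < end <= profile.length):
        raise ValueError(f"invalid interval [{start}, {end}) on length {profile.length}")
    window = profile.values[start:end]
    k = (window.size - 1) // 2
    return int(np.partition(window, k)[k])


def build_profile_from_bam(
    bam_path: str,
    chrom: str,
    *,
    reference_path: str | None = None,
    min_mapq: int = 0,
    count_deletions_covered: bool = False,
) -> DepthProfile:
    """Build and finalize a depth profile for one chromosome of a BAM/CRAM."""
    import pysam

    with pysam.AlignmentFile(bam_path, reference_filename=reference_path) as bam:
        tid = bam.get_tid(chrom)
        if tid < 0:
            raise ValueError(f"chromosome {chrom!r} not present in {bam_path}")
        profile = new_profile(chrom, bam.get_reference_length(chrom))
        for read in bam.fetch(chrom):
            if not passes_alignment_filter(read.flag, read.mapping_quality, min_mapq=min_mapq):
                continue
            cig = read.cigartuples
            if cig is None:
                continue
            ingest_runs(
                profile,
                covering_runs(
                    read.reference_start, cig, count_deletions_covered=count_deletions_covered
                ),
            )
    return finalize(profile)
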