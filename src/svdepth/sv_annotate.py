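"""The two depth fold-change statistics for structural variants.

DHFFC (flank fold-change): median depth inside the event divided by the median
depth of the 1,000 bases on either side of it, the two flanks pooled into one
multiset before taking the median.  DHBFC (bin fold-change): median depth
inside the event divided by the expected depth of 250-base reference windows
with a similar GC content.  A hemizygous deletion is expected to show roughly
half the flanking coverage (fold-change 0.5); a heterozygous duplication 1.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .depth_core import DepthProfile, median_depth
from .gc_bins import GCDepthTable, expected_depth_for_gc, gc_fraction

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 1000  # bases on each side of the event used by DHFFC

#: SV types over which a depth fold-change is meaningful (a defined interval
#: whose copy number the event may alter); INS and BND get missing values.
SPANNING_SVTYPES = frozenset({"DEL", "DUP", "INV", "CNV"})


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    BND = "BND"
    OTHER = "other"


@dataclass
class FoldChangeAnnotation:
    """The (DHBFC, DHFFC) pair; None encodes a missing value."""

    dhbfc: float | None = None
    dhffc: float | None = None


@dataclass
class SVRecord:
    """One SV call with its 0-based half-open affected interval."""

    chrom: str
    pos_1based: int
    start: int | None
    end: int | None
    svtype: str
    svlen: int | None = None
    genotype: str | None = None
    annotations: FoldChangeAnnotation = field(default_factory=FoldChangeAnnotation)

    @property
    def has_span(self) -> bool:
        return (
            self.svtype in SPANNING_SVTYPES
            and self.start is not None
            and self.end is not None
            and self.start < self.end
        )


def event_interval(
    pos_1based: int,
    end_info: int | None,
    svlen: int | None,
    svtype: str,
    ref_allele: str | None = None,
) -> tuple[int, int] | None:
    """Normalize VCF coordinates to the 0-based half-open affected interval.

    For symbolic alleles with INFO END = e the affected bases are POS+1..e
    (1-based), i.e. [POS, e) in 0-based coordinates: the padding base at POS
    is excluded.  Without END, |SVLEN| supplies the length; for
    sequence-resolved deletions len(REF) - 1 does.  Returns None (record to be
    skipped with a warning) when no valid interval can be formed.
    """
    start = pos_1based  # 0-based start of the affected bases, past the padding base
    if end_info is not None:
        end = end_info
    elif svlen is not None:
        end = start + abs(svlen)
    elif ref_allele is not None and len(ref_allele) > 1:
        end = start + len(ref_allele) - 1
    else:
        logger.warning("record at pos %d (%s) has no END/SVLEN; skipped", pos_1based, svtype)
        return None
    if end <= start:
        logger.warning(
            "record at pos %d (%s) has end %d <= start %d; skipped", pos_1based, svtype, end, start
        )
        return None
    return start, end


def dhffc(record: SVRecord, profile: DepthProfile, flank: int = DEFAULT_FLANK) -> float | None:
    """Median event depth over the pooled median depth of both flanks.

    Flanks are clamped to chromosome bounds; a flank truncated to nothing
    simply contributes no values.  Missing (None) when the pooled flank median
    is zero or both flanks vanish.
    """
    start, end = record.start, record.end
    assert start is not None and end is not None
    event_median = median_depth(profile, start, end)
    left = profile.values[max(0, start - flank) : start]
    right = profile.values[end : min(profile.length, end + flank)]
    pooled = np.concatenate([left, right])
    if pooled.size == 0:
        return None
    k = (pooled.size - 1) // 2
    flank_median = int(np.partition(pooled, k)[k])
    if flank_median == 0:
        return None
    return event_median / flank_median


def dhbfc(
    record: SVRecord,
    profile: DepthProfile,
    table: GCDepthTable,
    reference: str,
) -> float | None:
    """Median event depth over the GC-matched expected depth.

    GC is computed over the event's own reference sequence. Missing when the
    event is all-N or the expected depth is zero or unavailable.
    """
    start, end = record.start, record.end
    assert start is not None and end is not None
    gc = gc_fraction(reference[start:end])
    if gc is None:
        return None
    expected = expected_depth_for_gc(table, gc)
    if not expected:
        return None
    return median_depth(profile, start, end) / expected


def annotate_record(
    record: SVRecord,
    profile: DepthProfile,
    table: GCDepthTable,
    reference: str,
    flank: int = DEFAULT_FLANK,
) -> SVRecord:
    """Attach both fold-change statistics; spanless types get missing values."""
    if not record.has_span or record.end > profile.length or record.start < 0:
        record.annotations = FoldChangeAnnotation(None, None)
        return record
    record.annotations = FoldChangeAnnotation(
        dhbfc=dhbfc(record, profile, table, reference),
        dhffc=dhffc(record, profile, flank=flank),
    )
    return record
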