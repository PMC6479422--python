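"""GC-binned expected depths from non-overlapping reference windows.

Each chromosome is cut into non-overlapping 250-base windows; each window's GC
fraction and median depth are recorded, and windows are grouped into GC bins
(default width 0.05).  The median of a bin's window medians serves as the
expected depth for any event with a similar GC content — the denominator of
the DHBFC statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .depth_core import DepthProfile, ProfileStateError, median_depth

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 250
DEFAULT_BIN_WIDTH = 0.05
#: fraction of ambiguous (N) bases above which a window is excluded
MAX_N_FRACTION = 0.10
#: bins with fewer member windows than this fall back to the nearest occupied bin
MIN_BIN_OCCUPANCY = 5

_GC_BASES = frozenset("GCgc")
_N_BASES = frozenset("Nn")


def gc_fraction(sequence: str) -> float | None:
    """GC fraction over the non-N bases of ``sequence``; None if all bases are N."""
    if not sequence:
        raise ValueError("cannot compute GC fraction of an empty sequence")
    gc = sum(1 for b in sequence if b in _GC_BASES)
    n = sum(1 for b in sequence if b in _N_BASES)
    denom = len(sequence) - n
    if denom == 0:
        return None
    return gc / denom


def gc_bin_index(gc: float, bin_width: float, n_bins: int) -> int:
    """Bin index for a GC fraction; gc = 1.0 is clamped into the top bin.

    A tiny epsilon keeps exact bin boundaries (0.6 / 0.05) from landing one
    bin low through floating-point division.
    """
    return min(int(gc / bin_width + 1e-9), n_bins - 1)


@dataclass
class GCDepthTable:
    """Mapping from GC bin to the median depths of its member windows."""

    window_size: int = DEFAULT_WINDOW_SIZE
    bin_width: float = DEFAULT_BIN_WIDTH
    bins: dict[int, list[int]] = field(default_factory=dict)
    n_windows_used: int = 0

    @property
    def n_bins(self) -> int:
        return int(np.ceil(1.0 / self.bin_width))


def build_gc_table(
    reference: str,
    profile: DepthProfile,
    window_size: int = DEFAULT_WINDOW_SIZE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> GCDepthTable:
    """Tabulate (GC bin -> window median depths) over one chromosome.

    The trailing partial window is dropped; windows with more than 10%
    ambiguous bases are excluded entirely.
    """
    if not profile.finalized:
        raise ProfileStateError("profile must be finalized before building the GC table")
    if len(reference) != profile.length:
        raise ValueError(
            f"reference length {len(reference)} != profile length {profile.length}"
        )
    table = GCDepthTable(window_size=window_size, bin_width=bin_width)
    n_bins = table.n_bins
    for start in range(0, profile.length - window_size + 1, window_size):
        window_seq = reference[start : start + window_size]
        n_count = sum(1 for b in window_seq if b in _N_BASES)
        if n_count > MAX_N_FRACTION * window_size:
            continue
        gc = gc_fraction(window_seq)
        if gc is None:
            continue
        depth = median_depth(profile, start, start + window_size)
        table.bins.setdefault(gc_bin_index(gc, bin_width, n_bins), []).append(depth)
        table.n_windows_used += 1
    return table


def _lower_median(values: list[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def expected_depth_for_gc(table: GCDepthTable, gc: float) -> int | None:
    """Expected depth for an event of GC fraction ``gc``.

    Returns the median of member-window medians in the containing bin; sparse
    bins (fewer than MIN_BIN_OCCUPANCY windows) fall back to the nearest
    occupied bin, ties broken toward lower GC. None if the table is empty.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction must be in [0, 1], got {gc}")
    if not table.bins:
        return None
    target = gc_bin_index(gc, table.bin_width, table.n_bins)
    members = table.bins.get(target)
    if members is not None and len(members) >= MIN_BIN_OCCUPANCY:
        return _lower_median(members)
    # sparse or empty target bin: nearest adequately-occupied bin wins, then
    # nearest occupied bin; ties broken toward lower GC
    full = [b for b, m in table.bins.items() if len(m) >= MIN_BIN_OCCUPANCY]
    pool = full if full else list(table.bins)
    best = min(pool, key=lambda b: (abs(b - target), b))
    return _lower_median(table.bins[best])
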