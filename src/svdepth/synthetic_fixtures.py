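"""Self-contained synthetic fixtures: reference, alignments, truth VCF.

The generator emulates the depth signal the fold-change statistics read: a
diploid genome at uniform coverage, with the expected copy-number multiplier
inside embedded events — 0.5x for a heterozygous deletion, 0x homozygous
deletion, 1.5x heterozygous duplication, 2x homozygous duplication.  Two read
layouts are offered: deterministic tiling, which produces exact integer depth
plateaus (so the fold-changes are exact rationals), and a Poisson layout where
every base's depth is Poisson with the target mean.

It also implements the null-variant procedure used for specificity
evaluation: for every 0/1 or 1/1 call, a homozygous-reference (0/0) event of
the same size and type is placed uniformly at random inside high-confidence
regions, redrawing any placement where more than 10% of the enclosed
reference sequence is N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .depth_core import CIGAR_D, CIGAR_M, AlignedSegment

logger = logging.getLogger(__name__)

#: copy number (out of a diploid 2) inside an event, by (svtype, genotype)
EVENT_COPIES = {
    ("DEL", "0/1"): 1,
    ("DEL", "1/1"): 0,
    ("DUP", "0/1"): 3,
    ("DUP", "1/1"): 4,
}

MAX_NULL_DRAWS = 1000
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class SVEvent:
    svtype: str  # DEL or DUP
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    genotype: str  # 0/1, 1/1, or 0/0 for simulated nulls

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HighConfidenceRegions:
    """Sorted, non-overlapping 0-based half-open intervals on one chromosome."""

    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for (s1, e1), (s2, _) in zip(self.intervals, self.intervals[1:]):
            if s2 < e1:
                raise ValueError("high-confidence intervals overlap")
        for s, e in self.intervals:
            if s >= e:
                raise ValueError(f"empty interval [{s}, {e})")


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic genome and its events.

    ``gc_strata`` maps half-open intervals to target GC fractions; None means
    a single 0.5-GC stratum over the whole chromosome.  ``flank_margin`` keeps
    every event far enough from the chromosome ends for its flanks to fit.
    """

    chrom: str = "chrS"
    length: int = 100_000
    gc_strata: list[tuple[tuple[int, int], float]] | None = None
    events: list[SVEvent] = field(default_factory=list)
    haploid_coverage: int = 15
    read_length: int = 100
    layout: str = "tiling"  # or "poisson"
    seed: int = 0
    flank_margin: int = 1500
    sample: str = "sample1"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.layout not in ("tiling", "poisson"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if 4 * self.haploid_coverage > 32767:
            raise ValueError("coverage times the largest copy multiplier exceeds the depth cap")
        prev_end = 0
        for ev in sorted(self.events, key=lambda e: e.start):
            if (ev.svtype, ev.genotype) not in EVENT_COPIES:
                raise ValueError(f"unsupported event {ev.svtype} {ev.genotype}")
            if ev.start < prev_end:
                raise ValueError("events overlap")
            if ev.start < self.flank_margin or ev.end > self.length - self.flank_margin:
                raise ValueError(f"event [{ev.start}, {ev.end}) violates the flank margin")
            prev_end = ev.end


def make_reference(spec: FixtureSpec) -> str:
    """Pseudo-random sequence hitting each stratum's GC target within ±0.02.

    Each stratum gets exactly round(gc x length) G/C bases, shuffled, so the
    realized GC fraction is within half a base of the target.
    """
    rng = np.random.default_rng(spec.seed)
    strata = spec.gc_strata or [((0, spec.length), 0.5)]
    covered = sorted(iv for iv, _ in strata)
    pos = 0
    for s, e in covered:
        if s != pos:
            raise ValueError("GC strata must tile the chromosome without gaps or overlaps")
        pos = e
    if pos != spec.length:
        raise ValueError("GC strata must cover the whole chromosome")
    seq = np.empty(spec.length, dtype="U1")
    for (s, e), gc in strata:
        if not 0.0 <= gc <= 1.0:
            raise ValueError(f"infeasible GC target {gc}")
        n = e - s
        n_gc = round(gc * n)
        bases = np.concatenate(
            [
                rng.choice(np.array(["G", "C"]), size=n_gc),
                rng.choice(np.array(["A", "T"]), size=n - n_gc),
            ]
        )
        rng.shuffle(bases)
        seq[s:e] = bases
    return "".join(seq)


def copy_number_track(spec: FixtureSpec) -> np.ndarray:
    """Per-base copy number (diploid baseline 2) implied by the spec's events."""
    copies = np.full(spec.length, 2, dtype=np.int8)
    for ev in spec.events:
        copies[ev.start : ev.end] = EVENT_COPIES[(ev.svtype, ev.genotype)]
    return copies


def _constant_segments(copies: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, copy number) runs of the copy-number track."""
    boundaries = np.flatnonzero(np.diff(copies)) + 1
    edges = np.concatenate([[0], boundaries, [copies.size]])
    return [(int(s), int(e), int(copies[s])) for s, e in zip(edges[:-1], edges[1:])]


def simulate_segments(spec: FixtureSpec) -> list[AlignedSegment]:
    """Generate aligned segments realizing the spec's depth profile.

    Tiling mode lays ``depth`` abutting read tilings across each
    constant-copy-number segment (the last read of each tiling truncated at
    the segment end), giving exactly the target depth at every base.  Poisson
    mode draws read starts uniformly over the segment widened by one read
    length on the left and clips reads to the segment, making each base's
    depth Poisson with the target mean and free of edge ramps.
    """
    rng = np.random.default_rng(spec.seed + 1)
    L = spec.read_length
    reads: list[AlignedSegment] = []
    for seg_start, seg_end, copies in _constant_segments(copy_number_track(spec)):
        depth = copies * spec.haploid_coverage
        if depth == 0:
            continue
        if spec.layout == "tiling":
            for _ in range(depth):
                for s in range(seg_start, seg_end, L):
                    e = min(s + L, seg_end)
                    reads.append(AlignedSegment(spec.chrom, s, [(CIGAR_M, e - s)]))
        else:
            span = seg_end - seg_start + L
            n_reads = rng.poisson(depth * span / L)
            starts = rng.integers(seg_start - L, seg_end, size=n_reads)
            for s in starts:
                rs, re = max(int(s), seg_start), min(int(s) + L, seg_end)
                if rs < re:
                    reads.append(AlignedSegment(spec.chrom, rs, [(CIGAR_M, re - rs)]))
    reads.sort(key=lambda r: r.ref_start)
    return reads


def with_deletion_cigars(
    reads: list[AlignedSegment], gap: int = 10, every: int = 5
) -> list[AlignedSegment]:
    """Rewrite every ``every``-th sufficiently long read as M-D-M.

    Exercises the segment-splitting path of depth counting; the D gap is
    genuinely uncovered, so exact plateaus are sacrificed.
    """
    out = []
    for i, r in enumerate(reads):
        (op, length), = r.cigar
        if i % every == 0 and op == CIGAR_M and length > gap + 2:
            half = (length - gap) // 2
            cigar = [(CIGAR_M, half), (CIGAR_D, gap), (CIGAR_M, length - gap - half)]
            out.append(replace(r, cigar=cigar))
        else:
            out.append(r)
    return out


def generate_null_variants(
    real_variants: list[SVEvent],
    regions: HighConfidenceRegions,
    reference: str,
    seed: int,
    max_tries: int = MAX_NULL_DRAWS,
) -> list[SVEvent]:
    """One homozygous-reference (0/0) event per non-reference input event.

    Each null keeps the source event's type and length and is placed uniformly
    at random over all feasible starts wholly inside the high-confidence
    regions; placements where more than 10% of the enclosed reference bases
    are N are rejected and redrawn, up to ``max_tries`` draws per variant.
    """
    if not regions.intervals:
        raise ValueError("high-confidence region set is empty")
    rng = np.random.default_rng(seed)
    nulls: list[SVEvent] = []
    for ev in real_variants:
        if ev.genotype not in ("0/1", "1/1"):
            continue
        length = ev.length
        feasible = [(s, e - length) for s, e in regions.intervals if e - s >= length]
        total = sum(hi - lo + 1 for lo, hi in feasible)
        if total == 0:
            raise ValueError(
                f"no high-confidence region can hold a {length}-base {ev.svtype}"
            )
        for _ in range(max_tries):
            r = int(rng.integers(total))
            for lo, hi in feasible:
                if r <= hi - lo:
                    start = lo + r
                    break
                r -= hi - lo + 1
            window = reference[start : start + length]
            n_frac = (window.count("N") + window.count("n")) / length
            if n_frac <= MAX_N_FRACTION:
                nulls.append(SVEvent(ev.svtype, start, start + length, "0/0"))
                break
        else:
            raise ValueError(
                f"could not place a null for {ev.svtype} [{ev.start}, {ev.end}) "
                f"within {max_tries} draws (N-rich regions?)"
            )
    return nulls


def write_fasta(reference: str, chrom: str, path: str | Path) -> Path:
    """Write a single-contig FASTA (60-column wrap) and its faidx index."""
    import pysam

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(reference), 60):
            fh.write(reference[i : i + 60] + "\n")
    pysam.faidx(str(path))
    return path


def write_bam(reads: list[AlignedSegment], spec: FixtureSpec, path: str | Path) -> Path:
    """Write coordinate-sorted, indexed BAM with a read group for the sample."""
    import pysam

    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": spec.length}],
        "RG": [{"ID": "rg1", "SM": spec.sample}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(sorted(reads, key=lambda x: x.ref_start)):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.cigartuples = r.cigar
            a.flag = r.flags
            a.mapping_quality = r.mapq
            read_len = sum(l for op, l in r.cigar if op in (0, 1, 4, 7, 8))
            a.query_sequence = "A" * read_len
            a.set_tag("RG", "rg1")
            bam.write(a)
    pysam.index(str(path))
    return path


def write_truth_vcf(
    events: list[SVEvent], spec: FixtureSpec, reference: str, path: str | Path
) -> Path:
    """Write the truth VCF: symbolic DEL/DUP records with END/SVLEN/SVTYPE/GT."""
    import pysam

    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={spec.chrom},length={spec.length}>")
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the SV">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(spec.sample)
    gt_index = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for ev in sorted(events, key=lambda e: e.start):
            rec = vcf.new_record(
                contig=spec.chrom,
                start=ev.start - 1,  # 0-based padding base; POS (1-based) == ev.start
                stop=ev.end,
                alleles=(reference[ev.start - 1], f"<{ev.svtype}>"),
            )
            rec.info["SVTYPE"] = ev.svtype
            rec.info["SVLEN"] = -ev.length if ev.svtype == "DEL" else ev.length
            rec.samples[spec.sample]["GT"] = gt_index[ev.genotype]
            vcf.write(rec)
    return path


def event_free_regions(spec: FixtureSpec, pad: int = 1000) -> HighConfidenceRegions:
    """Chromosome minus the events padded by ``pad``, inset by the flank margin.

    Used as the default high-confidence set for null placement so that nulls
    stay copy-neutral: a null overlapping (or flanking into) a real event
    would inherit that event's depth signal.
    """
    intervals: list[tuple[int, int]] = []
    cursor = spec.flank_margin
    for ev in sorted(spec.events, key=lambda e: e.start):
        lo = max(cursor, 1)
        hi = ev.start - pad
        if hi - lo > 0:
            intervals.append((lo, hi))
        cursor = max(cursor, ev.end + pad)
    hi = spec.length - spec.flank_margin
    if hi - cursor > 0:
        intervals.append((cursor, hi))
    return HighConfidenceRegions(intervals)


def write_fixture(
    spec: FixtureSpec,
    outdir: str | Path,
    *,
    with_nulls: bool = True,
) -> dict[str, Path]:
    """Materialize the fixture trio: FASTA(+fai), BAM(+bai), truth VCF.

    The truth VCF carries every spec event plus, when ``with_nulls``, one
    matched homozygous-reference event per non-reference event.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = make_reference(spec)
    fasta = write_fasta(reference, spec.chrom, outdir / "ref.fa")
    bam = write_bam(simulate_segments(spec), spec, outdir / "sample.bam")
    events = list(spec.events)
    if with_nulls and events:
        events += generate_null_variants(
            events, event_free_regions(spec), reference, seed=spec.seed + 2
        )
    vcf = write_truth_vcf(events, spec, reference, outdir / "truth.vcf")
    return {"fasta": fasta, "bam": bam, "vcf": vcf}
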