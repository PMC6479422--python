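"""Synthetic reference/alignment/VCF generation with known copy-number truth."""

import numpy as np
import pysam
import pytest
from scipy.stats import chisquare

from svdepth.depth_core import build_profile_from_bam, finalize, ingest_alignment, new_profile
from svdepth.gc_bins import gc_fraction
from svdepth.synthetic_fixtures import (
    EVENT_COPIES,
    FixtureSpec,
    HighConfidenceRegions,
    SVEvent,
    copy_number_track,
    event_free_regions,
    generate_null_variants,
    make_reference,
    simulate_segments,
    with_deletion_cigars,
    write_fixture,
)


class TestMakeReference:
    def test_gc_target_hit_within_tolerance(self):
        spec = FixtureSpec(length=100_000, seed=1)
        gc = gc_fraction(make_reference(spec))
        assert 0.48 <= gc <= 0.52

    def test_all_gc_stratum(self):
        spec = FixtureSpec(length=2_000, gc_strata=[((0, 2_000), 1.0)], seed=1)
        assert set(make_reference(spec)) <= {"G", "C"}

    def test_stratified_targets(self):
        spec = FixtureSpec(
            length=40_000,
            gc_strata=[((0, 20_000), 0.3), ((20_000, 40_000), 0.7)],
            seed=2,
        )
        reference = make_reference(spec)
        assert gc_fraction(reference[:20_000]) == pytest.approx(0.3, abs=0.02)
        assert gc_fraction(reference[20_000:]) == pytest.approx(0.7, abs=0.02)

    def test_same_seed_is_byte_identical(self):
        spec = FixtureSpec(length=10_000, seed=9)
        assert make_reference(spec) == make_reference(spec)

    def test_gapped_strata_rejected(self):
        with pytest.raises(ValueError):
            make_reference(
                FixtureSpec(length=10_000, gc_strata=[((0, 4_000), 0.5)], seed=0)
            )


class TestSpecValidation:
    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FixtureSpec(
                length=30_000,
                events=[SVEvent("DEL", 5_000, 8_000, "0/1"), SVEvent("DUP", 7_000, 9_000, "0/1")],
            )

    def test_event_too_close_to_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            FixtureSpec(length=30_000, events=[SVEvent("DEL", 29_000, 29_500, "0/1")])

    def test_coverage_above_cap_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            FixtureSpec(length=10_000, haploid_coverage=9_000)


def depth_from_segments(spec, **kwargs):
    profile = new_profile(spec.chrom, spec.length)
    for seg in simulate_segments(spec):
        ingest_alignment(profile, seg, **kwargs)
    return finalize(profile).values.astype(int)


class TestSimulatedDepth:
    def test_tiling_yields_exact_plateaus(self):
        spec = FixtureSpec(
            length=30_000,
            events=[
                SVEvent("DEL", 5_000, 7_000, "0/1"),
                SVEvent("DEL", 10_000, 11_000, "1/1"),
                SVEvent("DUP", 14_000, 16_000, "0/1"),
                SVEvent("DUP", 20_000, 22_000, "1/1"),
            ],
            haploid_coverage=15,
            seed=4,
        )
        depth = depth_from_segments(spec)
        expected = copy_number_track(spec).astype(int) * spec.haploid_coverage
        assert np.array_equal(depth, expected)
        assert depth[5_500] == 15 and depth[10_500] == 0
        assert depth[15_000] == 45 and depth[21_000] == 60 and depth[3_000] == 30

    def test_poisson_mean_within_three_standard_errors(self):
        spec = FixtureSpec(
            length=30_000,
            events=[SVEvent("DEL", 10_000, 20_000, "0/1")],
            layout="poisson",
            seed=7,
        )
        depth = depth_from_segments(spec)
        in_event = depth[10_000:20_000]
        target = spec.haploid_coverage  # het DEL: one remaining copy
        # adjacent bases share reads, so the effective sample size is n / read length
        se = np.sqrt(target / (in_event.size / spec.read_length))
        assert abs(in_event.mean() - target) < 3 * se

    def test_deletion_cigar_injection_splits_coverage(self):
        spec = FixtureSpec(length=5_000, haploid_coverage=2, seed=3)
        reads = with_deletion_cigars(simulate_segments(spec), gap=10, every=1)
        assert all(len(r.cigar) == 3 for r in reads if r.cigar[0][1] > 12)
        profile = new_profile(spec.chrom, spec.length)
        for seg in reads:
            ingest_alignment(profile, seg)
        depth = finalize(profile).values
        assert depth.min() >= 0 and depth.max() <= 4
        assert (depth < 4).any()  # the D gaps really are uncovered


class TestNullVariants:
    def test_count_type_and_length_conserved(self):
        regions = HighConfidenceRegions([(1_000, 50_000)])
        reference = "ACGT" * 15_000
        events = [SVEvent("DEL", 2_000, 2_500, "0/1") for _ in range(10)]
        nulls = generate_null_variants(events, regions, reference, seed=1)
        assert len(nulls) == 10
        for null in nulls:
            assert null.genotype == "0/0"
            assert null.svtype == "DEL"
            assert null.length == 500
            assert 1_000 <= null.start and null.end <= 50_000

    def test_hom_ref_inputs_are_ignored(self):
        regions = HighConfidenceRegions([(0, 10_000)])
        events = [SVEvent("DEL", 100, 200, "0/0")]
        assert generate_null_variants(events, regions, "A" * 10_000, seed=1) == []

    def test_oversized_variant_is_an_error(self):
        regions = HighConfidenceRegions([(0, 400)])
        events = [SVEvent("DEL", 0, 500, "0/1")]
        with pytest.raises(ValueError, match="region"):
            generate_null_variants(events, regions, "A" * 1_000, seed=1)

    def test_n_rich_placements_rejected(self):
        # half the region is N: every accepted null must sit in clean sequence
        reference = "N" * 5_000 + "ACGT" * 2_500
        regions = HighConfidenceRegions([(0, 15_000)])
        events = [SVEvent("DEL", 6_000, 6_400, "0/1") for _ in range(25)]
        nulls = generate_null_variants(events, regions, reference, seed=2)
        for null in nulls:
            window = reference[null.start : null.end]
            assert window.count("N") / null.length <= 0.10

    def test_all_n_reference_exhausts_draws(self):
        regions = HighConfidenceRegions([(0, 2_000)])
        events = [SVEvent("DEL", 0, 500, "0/1")]
        with pytest.raises(ValueError, match="draws"):
            generate_null_variants(events, regions, "N" * 2_000, seed=3, max_tries=50)

    def test_placement_uniformity(self):
        # many draws of a 100-base null into a single region: starts should be
        # uniform over the feasible range (chi-square goodness of fit)
        regions = HighConfidenceRegions([(0, 10_100)])
        reference = "ACGT" * 2_525
        events = [SVEvent("DEL", 500, 600, "0/1")] * 4_000
        nulls = generate_null_variants(events, regions, reference, seed=11)
        starts = np.array([n.start for n in nulls])
        counts, _ = np.histogram(starts, bins=10, range=(0, 10_001))
        _, p = chisquare(counts)
        assert p > 0.001

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            HighConfidenceRegions([(5, 5)])


@pytest.fixture(scope="module")
def fixture_paths(tmp_path_factory):
    spec = FixtureSpec(
        length=30_000,
        events=[SVEvent("DEL", 5_000, 7_000, "0/1"), SVEvent("DUP", 12_000, 14_000, "1/1")],
        seed=5,
    )
    return spec, write_fixture(spec, tmp_path_factory.mktemp("fixture"))


class TestWrittenFixture:
    def test_files_are_consistent_and_indexed(self, fixture_paths):
        spec, paths = fixture_paths
        with pysam.FastaFile(str(paths["fasta"])) as fasta:
            assert list(fasta.references) == [spec.chrom]
            assert fasta.get_reference_length(spec.chrom) == spec.length
        with pysam.AlignmentFile(str(paths["bam"])) as bam:
            assert bam.has_index()
            assert bam.get_reference_length(spec.chrom) == spec.length
        with pysam.VariantFile(str(paths["vcf"])) as vcf:
            records = list(vcf)
        assert len(records) == 4  # two events + two matched nulls
        genotypes = sorted(
            "/".join(map(str, rec.samples[0]["GT"])) for rec in records
        )
        assert genotypes == ["0/0", "0/0", "0/1", "1/1"]

    def test_bam_depth_matches_direct_simulation(self, fixture_paths):
        spec, paths = fixture_paths
        profile = build_profile_from_bam(str(paths["bam"]), spec.chrom)
        assert np.array_equal(
            profile.values.astype(int),
            copy_number_track(spec).astype(int) * spec.haploid_coverage,
        )

    def test_fixed_seed_reproduces_fasta_and_vcf(self, fixture_paths, tmp_path):
        spec, paths = fixture_paths
        again = write_fixture(spec, tmp_path)
        assert paths["fasta"].read_text() == again["fasta"].read_text()

        def body(p):  # VCF body; header differs only in trivia
            return [l for l in p.read_text().splitlines() if not l.startswith("##")]

        assert body(paths["vcf"]) == body(again["vcf"])

    def test_event_free_regions_avoid_events_and_margins(self):
        spec = FixtureSpec(
            length=30_000, events=[SVEvent("DEL", 5_000, 7_000, "0/1")], seed=0
        )
        regions = event_free_regions(spec, pad=1_000)
        for s, e in regions.intervals:
            assert e <= 4_000 or s >= 8_000
            assert s >= spec.flank_margin and e <= spec.length - spec.flank_margin
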