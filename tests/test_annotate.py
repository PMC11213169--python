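import numpy as np
import pytest

from ragdel import annotate as ann
from ragdel.models import DeletionCall, GenomicInterval, MotifHit
from ragdel.pwm import DEFAULT_BACKGROUND

from conftest import random_sequence


def hit(name="heptamer", strand="+", offset=1, p=1e-5):
    return MotifHit(name, strand, offset, 10.0, p)


REGIONS = [
    GenomicInterval("chr14", 10_000, 20_000, "IgH"),
    GenomicInterval("chr7", 40_000, 50_000, "TRB"),
]


def deletion(chrom, left, right):
    return DeletionCall("P1", chrom, left, right, del_id="d")


class TestTargetStatus:
    def test_breakpoint_inside_locus(self):
        assert ann.classify_target_status(deletion("chr14", 15_000, 100_000), REGIONS) == "ig_tcr"

    def test_both_breakpoints_beyond_buffer(self):
        d = deletion("chr14", 21_001, 100_000)
        assert ann.classify_target_status(d, REGIONS) == "off_target"

    def test_exactly_buffer_distance_is_on_target(self):
        # right locus edge is 20_000 (exclusive); 1000 bp beyond = 20_999
        d = deletion("chr14", 20_999, 100_000)
        assert ann.classify_target_status(d, REGIONS) == "ig_tcr"
        assert ann.classify_target_status(deletion("chr14", 21_000, 100_000), REGIONS) == "off_target"

    def test_unknown_chromosome_is_off_target(self):
        assert ann.classify_target_status(deletion("chrUn", 1, 2), REGIONS) == "off_target"

    def test_agrees_with_brute_force_on_random_intervals(self):
        """1000 random trials against direct base-distance computation."""
        rng = np.random.default_rng(17)
        for _ in range(1000):
            regions = [
                GenomicInterval("c", s, s + int(rng.integers(1, 50)))
                for s in rng.integers(0, 5000, size=3)
            ]
            left = int(rng.integers(0, 6000))
            right = left + int(rng.integers(1, 500))
            d = deletion("c", left, right)
            buffer = 100

            def near(pos):
                return any(
                    iv.start - buffer <= pos < iv.end + buffer for iv in regions
                )

            want = "ig_tcr" if near(left) or near(right) else "off_target"
            assert ann.classify_target_status(d, regions, buffer=buffer) == want


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(2)
    return {"chr1": random_sequence(10_000, rng)}


class TestExtractFlanks:
    def test_long_deletion_windows(self, genome):
        d = deletion("chr1", 1000, 2000)
        left, right = ann.extract_flanks(d, genome, flank=50)
        assert left.seq == genome["chr1"][950:1050]
        assert right.seq == genome["chr1"][1950:2050]
        assert (left.breakpoint_offset, right.breakpoint_offset) == (50, 50)
        assert (left.interior_sign, right.interior_sign) == (1, -1)
        assert not left.clipped and not right.clipped

    def test_short_deletion_interiors_clip_at_midpoint(self, genome):
        d = deletion("chr1", 1000, 1060)
        left, right = ann.extract_flanks(d, genome, flank=50)
        assert left.clipped and right.clipped
        # left interior gets the ceil half [1000, 1030), right gets [1030, 1060)
        assert left.seq == genome["chr1"][950:1030]
        assert right.seq == genome["chr1"][1030:1110]

    def test_contig_edge_truncates_and_flags(self, genome):
        d = deletion("chr1", 20, 5000)
        left, _ = ann.extract_flanks(d, genome, flank=50)
        assert left.truncated
        assert left.seq == genome["chr1"][0:70]
        assert left.breakpoint_offset == 20

    def test_wide_decay_flank(self, genome):
        d = deletion("chr1", 1000, 2000)
        left, right = ann.extract_flanks(d, genome, flank=200)
        assert len(left.seq) == 400 and len(right.seq) == 400


class TestClassifyRag:
    d = deletion("chr1", 0, 10)

    def test_full_on_one_side_only(self):
        cls = ann.classify_rag(self.d, [hit("rss_full_12")], [])
        assert cls == "full_one"

    def test_full_on_both_sides(self):
        assert ann.classify_rag(self.d, [hit("rss_full_23")], [hit("rss_full_12")]) == "full_both"

    def test_no_hits_is_none(self):
        assert ann.classify_rag(self.d, [], []) == "none"

    def test_heptamer_without_full(self):
        assert ann.classify_rag(self.d, [hit()], [hit()]) == "heptamer_only"

    def test_nonamer_only(self):
        assert ann.classify_rag(self.d, [hit("nonamer")], []) == "nonamer_only"


class TestOrientation:
    def test_left_interior_plus_strand_correct(self):
        assert ann.check_orientation(hit(strand="+", offset=3), "left") is True

    def test_right_interior_plus_strand_incorrect(self):
        assert ann.check_orientation(hit(strand="+", offset=3), "right") is False

    def test_exterior_hit_has_no_orientation(self):
        assert ann.check_orientation(hit(strand="+", offset=-2), "left") is None


@pytest.fixture(scope="module")
def wide_annotations(default_cohort, scanner):
    """Off-target deletions re-scanned with 200 bp flanks."""
    cohort = default_cohort
    truth = cohort.truth.set_index("del_id")
    off = [
        d for d in cohort.deletions
        if truth.loc[d.del_id, "target_truth"] == "off_target"
    ]
    return ann.annotate_deletions(
        off, cohort.genome, cohort.regions, scanner, flank=200
    )


class TestDecayProfile:
    def make_annotation(self, offsets):
        d = deletion("chr1", 0, 10_000)
        hits = [hit("rss_full_12", offset=o) for o in offsets]
        return ann.DeletionAnnotation(d, "off_target", "full_one", hits, [])

    def test_single_hit_step_function(self):
        profile = ann.decay_profile([self.make_annotation([10])], distances=[5, 10, 50])
        assert profile.interior.tolist() == [0.0, 1.0, 1.0]
        assert profile.exterior.tolist() == [0.0, 0.0, 0.0]

    def test_empty_annotations_give_empty_profile(self):
        assert ann.decay_profile([]).empty

    def test_curves_are_monotone(self, wide_annotations):
        profile = ann.decay_profile(
            wide_annotations, motifs=("rss_full_12", "rss_full_23")
        )
        assert (profile.interior.diff().dropna() >= 0).all()
        assert (profile.exterior.diff().dropna() >= 0).all()

    def test_interior_rises_steeply_then_plateaus(self, wide_annotations):
        """Planted geometric placement: most of the interior rise happens
        before 50 bp; past it only the false-positive floor accumulates, and
        the exterior curve stays well below the interior one."""
        profile = ann.decay_profile(
            wide_annotations, motifs=("rss_full_12", "rss_full_23")
        ).set_index("distance")
        interior, exterior = profile.interior, profile.exterior
        assert interior.loc[50] - interior.loc[5] > interior.loc[200] - interior.loc[50]
        assert exterior.loc[200] < 0.5 * interior.loc[200]


class TestEndToEndRecovery:
    def test_every_deletion_gets_one_status_and_class(self, annotated_cohort):
        for a in annotated_cohort:
            assert a.target_status in ("ig_tcr", "off_target")
            assert a.rag_class in ("full_both", "full_one", "heptamer_only", "nonamer_only", "none")

    def test_group_proportions_recover_planted_values(self, default_cohort, annotated_cohort):
        """Recovered off-target RAG fractions lie within 3 binomial SDs of
        the planted 0.41 / 0.21."""
        truth = default_cohort.truth.set_index("del_id")
        for group, planted in (("high", 0.41), ("low", 0.21)):
            sel = [
                a for a in annotated_cohort
                if a.target_status == "off_target"
                and truth.loc[a.deletion.del_id, "exposure_group"] == group
            ]
            prop = np.mean([a.rag_mediated for a in sel])
            sd = np.sqrt(planted * (1 - planted) / len(sel))
            assert abs(prop - planted) <= 3 * sd
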