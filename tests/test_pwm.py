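import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ragdel.pwm import (
    DEFAULT_BACKGROUND,
    MotifScanner,
    Pwm,
    compose_full_rss,
    default_heptamer,
    default_nonamer,
    revcomp,
    scan_flank,
    score_pvalue_table,
    score_window,
)

BASES = "ACGT"


def random_pwm(width, rng, name="m"):
    probs = rng.dirichlet(np.ones(4), size=width)
    return Pwm(name, probs)


def random_seq(n, rng):
    return "".join(rng.choice(list(BASES), p=DEFAULT_BACKGROUND, size=n))


class TestScoreWindow:
    def test_uniform_pwm_hand_arithmetic(self):
        pwm = Pwm("uni", np.full((2, 4), 0.25))
        assert score_window(pwm, "AA") == pytest.approx(2 * np.log2(0.25 / 0.3))

    def test_background_equal_pwm_scores_zero_everywhere(self):
        pwm = Pwm("bg", np.tile(DEFAULT_BACKGROUND, (5, 1)))
        for w in ("ACGTA", "TTTTT", "CGCGC"):
            assert score_window(pwm, w) == pytest.approx(0.0)

    def test_consensus_is_the_maximum_over_all_windows(self):
        hep = default_heptamer()
        best = max(
            score_window(hep, "".join(w)) for w in itertools.product(BASES, repeat=7)
        )
        assert score_window(hep, hep.consensus()) == pytest.approx(best)

    def test_n_contributes_zero(self):
        hep = default_heptamer()
        full = score_window(hep, "CACAGTG")
        with_n = score_window(hep, "CACNGTG")
        assert with_n == pytest.approx(full - np.log2(0.8 / 0.3))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            score_window(default_heptamer(), "CACA")


class TestPvalueTable:
    def test_dp_equals_brute_force_enumeration_small_width(self):
        """Exact DP distribution vs enumeration over all 4^w windows."""
        rng = np.random.default_rng(5)
        for trial in range(3):
            pwm = random_pwm(4, rng, f"w4_{trial}")
            table = score_pvalue_table(pwm)
            tail = {}
            for win in itertools.product(BASES, repeat=4):
                w = "".join(win)
                s = table.int_score(w)
                p = np.prod([DEFAULT_BACKGROUND[BASES.index(c)] for c in w])
                tail[s] = tail.get(s, 0.0) + p
            acc = 0.0
            for s in sorted(tail, reverse=True):
                acc += tail[s]
                assert table.pvalue_of_int(s) == pytest.approx(acc, abs=1e-12)

    def test_background_equal_pwm_has_no_subunit_threshold(self):
        pwm = Pwm("bg", np.tile(DEFAULT_BACKGROUND, (6, 1)))
        table = score_pvalue_table(pwm)
        assert table.pvalue(0.0) == 1.0
        # no achievable window can beat any threshold below 1
        assert table.threshold_int(0.5) > 0

    def test_default_heptamer_has_subthreshold_scores(self):
        table = score_pvalue_table(default_heptamer())
        s_star = table.threshold_int(1e-4)
        assert table.pvalue_of_int(s_star) < 1e-4
        consensus_int = table.int_score("CACAGTG")
        assert consensus_int >= s_star

    def test_monotone_nonincreasing_in_score(self):
        table = score_pvalue_table(default_nonamer())
        scores = np.arange(table.lo_min, table.lo_min + len(table.tail))
        pv = table.pvalue_of_int(scores)
        assert (np.diff(pv) <= 1e-15).all()

    def test_granularity_must_be_positive(self):
        with pytest.raises(ValueError):
            score_pvalue_table(default_heptamer(), granularity=0)


class TestComposeFullRss:
    @pytest.mark.parametrize("spacer,width", [(12, 28), (23, 39)])
    def test_widths(self, spacer, width):
        full = compose_full_rss(default_heptamer(), default_nonamer(), spacer)
        assert full.width == width

    def test_other_spacers_rejected(self):
        with pytest.raises(ValueError):
            compose_full_rss(default_heptamer(), default_nonamer(), 15)

    @given(spacer=st.sampled_from([12, 23]), seed=st.integers(0, 10**6))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_score_decomposes_spacer_contributes_zero(self, spacer, seed):
        rng = np.random.default_rng(seed)
        hep, non = default_heptamer(), default_nonamer()
        full = compose_full_rss(hep, non, spacer)
        h, s, n = random_seq(7, rng), random_seq(spacer, rng), random_seq(9, rng)
        assert score_window(full, h + s + n) == pytest.approx(
            score_window(hep, h) + score_window(non, n), abs=1e-9
        )


class TestScanFlank:
    def test_planted_heptamer_three_interior(self):
        rng = np.random.default_rng(1)
        seq = random_seq(101, rng)
        # interior position 3 = index breakpoint_offset + 2
        seq = seq[:52] + "CACAGTG" + seq[59:]
        hits = scan_flank(seq, [default_heptamer()], breakpoint_offset=50)
        assert [(h.strand, h.start_offset) for h in hits if h.motif_name == "heptamer"] == [("+", 3)]

    def test_reverse_complement_reports_minus_strand(self):
        rng = np.random.default_rng(1)
        seq = random_seq(101, rng)
        seq = seq[:52] + revcomp("CACAGTG") + seq[59:]
        hits = scan_flank(seq, [default_heptamer()], breakpoint_offset=50)
        assert [(h.strand, h.start_offset) for h in hits] == [("-", 3)]

    def test_sequence_shorter_than_motif_gives_empty(self):
        assert scan_flank("ACG", [default_heptamer()], breakpoint_offset=1) == []

    def test_strand_symmetry_of_whole_scan(self, scanner):
        """Scanning revcomp(seq) returns the same hits with strands swapped
        and offsets mirrored around the mirrored breakpoint."""
        rng = np.random.default_rng(9)
        seq = random_seq(120, rng)
        seq = seq[:30] + "CACAGTG" + seq[37:]
        fwd = scanner.scan(seq, breakpoint_offset=60, interior_sign=1)
        rev = scanner.scan(revcomp(seq), breakpoint_offset=60, interior_sign=-1)

        def key(hits, swap):
            flip = {"+": "-", "-": "+"}
            return sorted(
                (h.motif_name, flip[h.strand] if swap else h.strand,
                 h.start_offset, round(h.score, 6))
                for h in hits
            )

        assert key(fwd, swap=True) == key(rev, swap=False)

    def test_background_hit_rate_matches_analytic_expectation(self):
        """Over many background flanks, the per-window hit rate equals the
        threshold tail probability within 3 binomial SDs."""
        hep = default_heptamer()
        table = score_pvalue_table(hep)
        rate = table.pvalue_of_int(table.threshold_int(1e-4))
        scanner = MotifScanner([hep], threshold=1e-4)
        rng = np.random.default_rng(42)
        n_flanks, flank_len = 1000, 101
        n_windows = (flank_len - 7 + 1) * 2  # both strands
        total = sum(
            len(scanner.scan(random_seq(flank_len, rng), breakpoint_offset=50))
            for _ in range(n_flanks)
        )
        expect = n_flanks * n_windows * rate
        sd = np.sqrt(n_flanks * n_windows * rate * (1 - rate))
        assert abs(total - expect) <= 3 * sd
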