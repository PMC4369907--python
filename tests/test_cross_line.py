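"""Cross-line pattern classes, RFC formula dispatch and HTRT selection."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from ricehnt.cross_line import (
    PATTERNS,
    classify_pattern,
    rfc_value,
    select_htrts,
    tally_patterns,
)
from ricehnt.datasets import DEG_DIRECTION_COUNTS, DEG_OVERLAP_COUNTS, HTRT_PATTERN_COUNTS
from ricehnt.expression import DEResult, compute_fpkm, de_test
from ricehnt.simulate import SimConfig, simulate_experiment


def de(tid, line, log2fc, sig=None, p=0.01):
    sig = sig if sig is not None else abs(log2fc) >= 1.0 and p <= 0.05
    direction = "none" if not sig else ("up" if log2fc > 0 else "down")
    return DEResult(tid, line, log2fc, p, sig, direction)


def brute_force_rfc(hs_log2, ht_log2, concordant):
    """Independent literal transcription of the three formulas on magnitudes."""
    ht, hs = abs(ht_log2), abs(hs_log2)
    if not concordant:
        return "C", (hs + ht) / 2
    if ht > hs:
        return "A", (ht - hs) / hs
    if ht < hs:
        return "B", (hs - ht) / ht
    return "B", 0.0


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "dir_hs,dir_ht,expected",
        [
            ("up", "up", "up_both"),
            ("down", "down", "down_both"),
            ("up", "down", "downT_upS"),
            ("down", "up", "upT_downS"),
            ("up", "none", "HS_only_up"),
            ("down", "none", "HS_only_down"),
            ("none", "up", "HT_only_up"),
            ("none", "down", "HT_only_down"),
            ("none", "none", "neither"),
        ],
    )
    def test_nine_class_mapping(self, dir_hs, dir_ht, expected):
        fc = {"up": 2.0, "down": -2.0, "none": 0.1}
        hs = de("t", "HS", fc[dir_hs], sig=dir_hs != "none")
        ht = de("t", "HT", fc[dir_ht], sig=dir_ht != "none")
        assert classify_pattern(hs, ht).pattern == expected

    def test_mismatched_transcripts_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(de("a", "HS", 2.0), de("b", "HT", 2.0))


class TestRfcValue:
    def test_formula_a_substitution(self):
        assert rfc_value(1.0, 3.0, concordant=True) == ("A", pytest.approx(2.0))

    def test_formula_b_substitution(self):
        assert rfc_value(3.0, 1.0, concordant=True) == ("B", pytest.approx(2.0))

    def test_equal_magnitudes_give_zero_via_b(self):
        assert rfc_value(-1.7, -1.7, concordant=True) == ("B", 0.0)

    def test_formula_c_on_magnitudes(self):
        assert rfc_value(2.4, -1.8, concordant=False) == ("C", pytest.approx(2.1))

    def test_concordant_zero_magnitude_rejected(self):
        with pytest.raises(ValueError):
            rfc_value(0.0, 2.0, concordant=True)

    def test_agrees_with_brute_force_on_grid(self):
        """Formula dispatch matches an independent implementation on a magnitude grid."""
        grid = np.round(np.arange(1.0, 6.0, 0.05), 10)
        for hs, ht in itertools.product(grid, grid):
            for concordant in (True, False):
                assert rfc_value(hs, ht, concordant) == brute_force_rfc(hs, ht, concordant)

    def test_concordant_selection_identity(self):
        """RFC >= 2 iff the larger magnitude is at least triple the smaller.

        The identity is exact in rational arithmetic, so it is evaluated
        through fractions.Fraction; the float result must agree within 1e-9.
        """
        steps = range(100, 600, 5)  # magnitudes 1.00 .. 5.95 in steps of 0.05
        for i, j in itertools.product(steps, steps):
            if i == j:
                continue
            hs, ht = Fraction(i, 100), Fraction(j, 100)
            a, b = max(hs, ht), min(hs, ht)
            exact = (a - b) / b
            assert (exact >= 2) == (a >= 3 * b)
            _, rfc = rfc_value(float(hs), float(ht), concordant=True)
            assert abs(rfc - float(exact)) < 1e-9


class TestSelectHtrts:
    def test_empty_candidate_set(self):
        assert select_htrts([de("t", "HS", 0.2, sig=False)], [de("t", "HT", 0.1, sig=False)]) == []

    def test_rfc_exactly_two_is_selected(self):
        recs = select_htrts([de("t", "HS", 1.0)], [de("t", "HT", 3.0)])
        assert recs[0].rfc == pytest.approx(2.0) and recs[0].selected

    def test_candidate_needs_significance_in_both_lines_by_default(self):
        recs = select_htrts([de("t", "HS", 3.0)], [de("t", "HT", 0.8, sig=False)])
        assert recs == []
        union = select_htrts(
            [de("t", "HS", 3.0)], [de("t", "HT", 0.8, sig=False)], candidates="union"
        )
        assert len(union) == 1 and union[0].formula == "B"

    def test_threshold_monotonicity(self):
        de_hs = [de(f"t{i}", "HS", fc) for i, fc in enumerate([1.0, 2.0, -1.5, 1.2])]
        de_ht = [de(f"t{i}", "HT", fc) for i, fc in enumerate([3.0, -2.0, -4.8, 1.3])]
        sizes = [
            sum(r.selected for r in select_htrts(de_hs, de_ht, threshold=th))
            for th in (1.0, 2.0, 3.0, 4.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_zero_noise_truth_recovers_exactly_the_planted_set(self):
        """On exact planted log2 values the selected set equals the brute-force one."""
        cfg = SimConfig(n_transcripts=300, seed=2)
        _, truth = simulate_experiment(cfg)
        de_hs, de_ht = [], []
        for rec in truth.itertuples():
            de_hs.append(de(rec.transcript_id, "HS", rec.planted_log2_HS))
            de_ht.append(de(rec.transcript_id, "HT", rec.planted_log2_HT))
        selected = {r.transcript_id for r in select_htrts(de_hs, de_ht) if r.selected}

        expected = set()
        for rec in truth.itertuples():
            hs, ht = rec.planted_log2_HS, rec.planted_log2_HT
            if abs(hs) < 1.0 or abs(ht) < 1.0:
                continue
            _, rfc = brute_force_rfc(hs, ht, concordant=hs * ht > 0)
            if rfc >= 2.0:
                expected.add(rec.transcript_id)
        assert selected == expected
        planted = set(
            truth[truth["class"].isin(["concordant_divergent", "discordant"])]["transcript_id"]
        )
        assert selected == planted

    def test_end_to_end_selection_is_specific(self):
        """Noisy end-to-end run: selections come from planted responding classes."""
        cfg = SimConfig(n_transcripts=1000, dispersion=0.01, seed=5)
        cm, truth = simulate_experiment(cfg)
        fpkm = compute_fpkm(cm)
        recs = select_htrts(de_test(fpkm, "HS"), de_test(fpkm, "HT"))
        selected = {r.transcript_id for r in recs if r.selected}
        planted = set(
            truth[truth["class"].isin(["concordant_divergent", "discordant"])]["transcript_id"]
        )
        assert selected, "no transcripts selected at all"
        false = selected - planted
        assert len(false) <= 0.05 * max(len(selected), 1)


class TestTallyPatterns:
    def test_study_htrt_class_counts(self):
        """The 35 cross-line HTRTs split 19 + 4 + 4 + 8 over the four classes."""
        records = [
            cls for cls, n in HTRT_PATTERN_COUNTS.items() for _ in range(n)
        ]
        tally = tally_patterns(records)
        assert tally["up_both"] == 19 and tally["down_both"] == 4
        assert tally["upT_downS"] == 4 and tally["downT_upS"] == 8
        assert sum(tally.values()) == 35

    def test_study_deg_overlap_counts_are_consistent(self):
        # overlap classes cannot exceed the per-line direction totals
        assert DEG_OVERLAP_COUNTS["up_both"] <= min(
            DEG_DIRECTION_COUNTS["HS"]["up"], DEG_DIRECTION_COUNTS["HT"]["up"]
        )
        assert sum(DEG_DIRECTION_COUNTS["HS"].values()) == 5384
        assert sum(DEG_DIRECTION_COUNTS["HT"].values()) == 5527

    def test_empty_input_gives_all_zero(self):
        tally = tally_patterns([])
        assert set(tally) == set(PATTERNS) and sum(tally.values()) == 0

    def test_permutation_invariance(self):
        records = ["up_both"] * 3 + ["neither"] * 2 + ["downT_upS"]
        assert tally_patterns(records) == tally_patterns(records[::-1])
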