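"""Confusion tables, accuracy statistics and exact binomial intervals."""

import numpy as np
import pytest
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from neosps.diagnostics import (
    TwoByTwo,
    build_confusion,
    clopper_pearson_ci,
    confusion_from_distributions,
    diagnostic_metrics,
)
from neosps.errors import InconsistencyError, ValidationError
from neosps.stratification import ScoreDistribution, band_stratification, score_distribution


class TestBuildConfusion:
    def test_two_record_example(self):
        t = build_confusion([(5, True), (1, False)], cutoff=3)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_all_above_cutoff(self):
        t = build_confusion([(4, True), (5, False), (8, True)], cutoff=3)
        assert t.fn == 0 and t.tn == 0

    def test_matches_hand_enumeration(self, ten_record_cohort):
        pairs = list(zip(ten_record_cohort["score"], ten_record_cohort["group"] == "pos"))
        for cutoff in range(1, 9):
            # independent oracle: literal counting over the four outcomes
            tp = sum(1 for s, p in pairs if s >= cutoff and p)
            fp = sum(1 for s, p in pairs if s >= cutoff and not p)
            fn = sum(1 for s, p in pairs if s < cutoff and p)
            tn = sum(1 for s, p in pairs if s < cutoff and not p)
            t = build_confusion(pairs, cutoff)
            assert (t.tp, t.fp, t.fn, t.tn) == (tp, fp, fn, tn)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            build_confusion([], cutoff=3)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError, match="tp"):
            TwoByTwo(tp=-1, fp=0, fn=0, tn=1)


def dist(counts, bands=None):
    return ScoreDistribution(counts=counts, bands=bands)


class TestConfusionFromDistributions:
    # (totals by score, septic band counts, expected tp/fp/fn/tn) — each
    # expected tuple derived by summing the published counts by hand.
    CASES = [
        ({0: 31, 1: 16, 2: 13, 3: 15, 4: 16, 5: 11, 6: 15, 7: 3},
         {(0, 2): 11, (3, 4): 23, (5, 8): 29}, (52, 8, 11, 49)),
        ({0: 2, 1: 16, 2: 41, 3: 42, 4: 30, 5: 4, 6: 6, 7: 3, 8: 1},
         {(0, 2): 22, (3, 4): 58, (5, 8): 14}, (72, 14, 22, 37)),
        ({0: 123, 1: 15, 2: 1, 3: 4, 4: 2},
         {(0, 2): 88, (3, 4): 6, (5, 8): 0}, (6, 0, 88, 51)),
    ]

    @pytest.mark.parametrize("totals, bands, expected", CASES)
    def test_reconstruction(self, totals, bands, expected):
        t = confusion_from_distributions(dist(totals), dist({}, bands), cutoff=3)
        assert (t.tp, t.fp, t.fn, t.tn) == expected

    def test_misaligned_cutoff_rejected(self):
        with pytest.raises(ValidationError, match="band boundary"):
            confusion_from_distributions(
                dist({0: 5, 4: 5}), dist({}, {(0, 2): 1, (3, 4): 2, (5, 8): 2}), cutoff=4
            )

    def test_negative_implied_cell_named(self):
        # septic count above cutoff exceeds the whole cohort above cutoff
        with pytest.raises(InconsistencyError, match="fp"):
            confusion_from_distributions(
                dist({0: 10, 3: 1}), dist({}, {(0, 2): 0, (3, 4): 5, (5, 8): 0}), cutoff=3
            )

    def test_round_trip_with_patient_level_tally(self, rng):
        """Summaries tallied from records give the same table as the records."""
        for _ in range(20):
            n = rng.integers(5, 60)
            scores = rng.integers(0, 9, size=n)
            positive = rng.random(n) < 0.5
            if positive.all() or not positive.any():
                continue
            pairs = list(zip(scores, positive))
            total = ScoreDistribution(
                counts={int(s): int((scores == s).sum()) for s in range(9)}
            )
            septic = ScoreDistribution(
                counts={int(s): int(((scores == s) & positive).sum()) for s in range(9)}
            )
            septic = band_stratification(septic)
            for cutoff in (3, 5):
                assert confusion_from_distributions(total, septic, cutoff) == \
                    build_confusion(pairs, cutoff)


class TestDiagnosticMetrics:
    def test_derivation_day0_row(self):
        m = diagnostic_metrics(TwoByTwo(tp=52, fp=8, fn=11, tn=49))
        assert m.rendered() == {
            "Se": "82.54%", "Sp": "85.96%", "PLR": "5.88", "NLR": "0.20",
            "PPV": "86.67%", "NPV": "81.67%", "Accuracy": "84.17%",
        }

    def test_perfect_specificity_makes_plr_undefined(self):
        m = diagnostic_metrics(TwoByTwo(tp=6, fp=0, fn=88, tn=51))
        r = m.rendered()
        assert r["Sp"] == "100.00%" and r["PLR"] == "-" and r["NLR"] == "0.94"
        assert r["PPV"] == "100.00%" and r["NPV"] == "36.69%" and r["Accuracy"] == "39.31%"

    def test_degenerate_denominators_return_undefined(self):
        m = diagnostic_metrics(TwoByTwo(tp=0, fp=0, fn=3, tn=7))
        assert m.se == 0.0 and m.sp == 1.0
        assert m.ppv is None and m.plr is None
        assert m.npv == pytest.approx(0.7)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValidationError):
            diagnostic_metrics(TwoByTwo(tp=0, fp=0, fn=0, tn=0))

    def test_accuracy_and_ppv_identities(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + fp + fn + tn == 0:
                continue
            t = TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)
            m = diagnostic_metrics(t)
            assert m.accuracy * t.n == pytest.approx(tp + tn)
            if m.ppv is not None:
                assert m.ppv * (tp + fp) == pytest.approx(tp)

    def test_cutoff_monotone_tradeoff(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 9, size=80)
            positive = rng.random(80) < 0.5
            pairs = list(zip(scores, positive))
            tables = [build_confusion(pairs, c) for c in range(1, 9)]
            tps = [t.tp for t in tables]
            tns = [t.tn for t in tables]
            assert tps == sorted(tps, reverse=True)
            assert tns == sorted(tns)


class TestClopperPearson:
    def test_edge_bounds(self):
        lo, hi = clopper_pearson_ci(0, 10)
        assert lo == 0.0 and 0 < hi < 1
        lo, hi = clopper_pearson_ci(10, 10)
        assert hi == 1.0 and 0 < lo < 1

    def test_contains_point_estimate(self):
        lo, hi = clopper_pearson_ci(52, 63)
        assert lo < 52 / 63 < hi

    def test_matches_statsmodels_beta_interval(self):
        for k, n in [(52, 63), (1, 20), (19, 20), (7, 7)]:
            lo, hi = clopper_pearson_ci(k, n, 0.95)
            ref = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(ref[0], abs=1e-12)
            assert hi == pytest.approx(ref[1], abs=1e-12)

    def test_exactness_via_binomial_tail(self):
        """The bounds invert the exact binomial tails at alpha/2."""
        k, n, level = 52, 63, 0.95
        lo, hi = clopper_pearson_ci(k, n, level)
        assert binom.sf(k - 1, n, lo) == pytest.approx(0.025, abs=1e-9)
        assert binom.cdf(k, n, hi) == pytest.approx(0.025, abs=1e-9)

    @pytest.mark.parametrize("k, n, level", [(-1, 10, 0.95), (11, 10, 0.95), (5, 0, 0.95), (5, 10, 1.0)])
    def test_validation(self, k, n, level):
        with pytest.raises(ValidationError):
            clopper_pearson_ci(k, n, level)
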