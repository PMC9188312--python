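"""Per-sequence loss closed forms, cutoff calibration, and rejection rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagemark.loss_rejection import (
    LossCutoffs, apply_cutoffs, calibrate_cutoffs, loss_distribution_summary,
    per_sequence_loss, score_probabilities,
)
from phagemark.sequence_io import OTHERS


def scored(cat, log10_loss, id="x"):
    from phagemark.loss_rejection import PerSequenceLoss

    return PerSequenceLoss(id=id, predicted_category=cat,
                           loss=10.0**log10_loss, log10_loss=log10_loss)


class TestPerSequenceLoss:
    def test_uniform_over_four(self):
        r = per_sequence_loss([0.25] * 4, 0)
        assert r.loss == pytest.approx(math.log(4), abs=1e-9)
        assert r.log10_loss == pytest.approx(math.log10(math.log(4)), abs=1e-6)

    def test_saturated_probability_floors_at_minus_12(self):
        r = per_sequence_loss([1.0, 0.0], 0)
        assert r.log10_loss == pytest.approx(-12.0, abs=1e-6)

    def test_near_one_probability(self):
        r = per_sequence_loss([0.999999, 1e-6], 0)
        assert r.loss == pytest.approx(1.0000005e-6, rel=1e-6)
        assert r.log10_loss == pytest.approx(-6.0, abs=1e-3)

    def test_bad_index(self):
        with pytest.raises(IndexError):
            per_sequence_loss([0.5, 0.5], 2)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_matches_one_hot_cross_entropy(self, p):
        """Eq: L equals -sum(y_k ln p_k) with one-hot y, i.e. -ln(p_class)."""
        vec = [p, 1 - p]
        literal = -sum(y * math.log(q) for y, q in zip([1, 0], vec))
        assert per_sequence_loss(vec, 0).loss == pytest.approx(literal, abs=1e-9)


class TestScoreProbabilities:
    def test_scores_against_argmax(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]])
        (s,) = score_probabilities(probs, ["q"], ["a", "b", "c", OTHERS])
        assert s.predicted_category == "a"
        assert s.loss == pytest.approx(-math.log(0.97), abs=1e-9)

    def test_uniform_tie_breaks_to_first(self):
        (s,) = score_probabilities(np.full((1, 4), 0.25), ["q"], list("abcd"))
        assert s.predicted_category == "a"
        assert s.loss == pytest.approx(math.log(4), abs=1e-7)

    def test_others_predictions_scored_but_never_cut(self):
        s = scored(OTHERS, -0.1)
        rows = apply_cutoffs([s], LossCutoffs(cutoffs={"a": -5.0}))
        assert rows[0]["final_category"] == OTHERS and rows[0]["accepted"] == 1


class TestCalibrate:
    def test_quantile_example(self):
        tps = [scored("TerL", v) for v in [-8, -7, -6, -5.5, -3]]
        cut = calibrate_cutoffs(tps, ["TerL"] * 5, quantile=0.8)
        assert cut.cutoffs["TerL"] == -5.5
        kept = sum(s.log10_loss <= cut.cutoffs["TerL"] for s in tps)
        assert kept == 4

    def test_all_equal(self):
        tps = [scored("x", -6.0) for _ in range(4)]
        cut = calibrate_cutoffs(tps, ["x"] * 4, quantile=0.99)
        assert cut.cutoffs["x"] == -6.0

    def test_quantile_one_gives_max(self):
        tps = [scored("x", v) for v in [-9, -4, -7]]
        cut = calibrate_cutoffs(tps, ["x"] * 3, quantile=1.0)
        assert cut.cutoffs["x"] == -4

    def test_zero_tp_category_error(self):
        tps = [scored("x", -6)]
        with pytest.raises(ValueError, match="'y'"):
            calibrate_cutoffs(tps, ["x"], target_categories=["x", "y"])

    def test_bad_quantile(self):
        with pytest.raises(ValueError, match="quantile"):
            calibrate_cutoffs([scored("x", -6)], ["x"], quantile=0.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=-12, max_value=1), min_size=1, max_size=60),
           st.floats(min_value=0.01, max_value=1.0))
    def test_retention_at_least_quantile(self, losses, q):
        """By construction, >= q of calibration TP fall at or below the cutoff."""
        tps = [scored("c", v, id=str(i)) for i, v in enumerate(losses)]
        cut = calibrate_cutoffs(tps, ["c"] * len(tps), quantile=q)
        kept = sum(v <= cut.cutoffs["c"] for v in losses)
        assert kept / len(losses) >= q - 1e-12

    def test_whisker_rule_capped_at_max(self):
        vals = [-8, -7.5, -7, -6.5, -1]  # -1 is an outlier above Q3+1.5IQR
        tps = [scored("x", v) for v in vals]
        cut = calibrate_cutoffs(tps, ["x"] * 5, rule="whisker")
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert cut.cutoffs["x"] == pytest.approx(min(max(vals), q3 + 1.5 * (q3 - q1)))


class TestApplyCutoffs:
    CUT = LossCutoffs(cutoffs={"TerL": -5.2, "Portal": -4.2})

    def test_low_loss_accepted(self):
        (row,) = apply_cutoffs([scored("TerL", -6.0)], self.CUT)
        assert row["final_category"] == "TerL" and row["accepted"] == 1

    def test_high_loss_reassigned_to_others(self):
        (row,) = apply_cutoffs([scored("TerL", -4.0)], self.CUT)
        assert row["final_category"] == OTHERS and row["accepted"] == 0

    def test_boundary_inclusive(self):
        (row,) = apply_cutoffs([scored("Portal", -4.2)], self.CUT)
        assert row["final_category"] == "Portal"

    def test_missing_cutoff_error(self):
        with pytest.raises(KeyError, match="TerS"):
            apply_cutoffs([scored("TerS", -6.0)], self.CUT)

    def test_rejection_never_creates_target_predictions(self):
        rng = np.random.default_rng(0)
        cats = ["a", "b", OTHERS]
        items = [scored(cats[rng.integers(3)], float(rng.uniform(-8, 0)), id=str(i))
                 for i in range(300)]
        cut = LossCutoffs(cutoffs={"a": -4.0, "b": -3.0})
        rows = apply_cutoffs(items, cut)
        for s, row in zip(items, rows):
            if row["final_category"] != OTHERS:
                assert row["final_category"] == s.predicted_category


class TestCutoffsFile:
    def test_round_trip(self, tmp_path):
        cut = LossCutoffs(cutoffs={"TerL": -5.2, "Portal": -4.2},
                          calibration_quantile=0.95, provenance="demo")
        p = tmp_path / "cutoffs.txt"
        cut.to_file(p)
        back = LossCutoffs.from_file(p)
        assert back.cutoffs == pytest.approx(cut.cutoffs)
        assert back.calibration_quantile == 0.95
        assert back.provenance == "demo"

    def test_others_cannot_have_cutoff(self):
        with pytest.raises(ValueError):
            LossCutoffs(cutoffs={OTHERS: -5.0})


class TestDistributionSummary:
    def test_quantiles_match_brute_force(self):
        vals_tp = [-8.0, -7.0, -6.5, -6.0, -2.0]
        vals_fp = [-3.0, -1.0]
        items = [scored("x", v, id=f"t{i}") for i, v in enumerate(vals_tp)]
        items += [scored("x", v, id=f"f{i}") for i, v in enumerate(vals_fp)]
        truth = ["x"] * 5 + [OTHERS] * 2
        df = loss_distribution_summary(items, truth).set_index("kind")
        row = df.loc["TP"]
        assert row["min"] == min(vals_tp) and row["max"] == max(vals_tp)
        assert row["median"] == np.quantile(vals_tp, 0.5)
        assert row["count"] == 5
        assert df.loc["FP"]["count"] == 2

    def test_single_tp_all_quantiles_equal(self):
        df = loss_distribution_summary([scored("x", -6.0)], ["x"]).set_index("kind")
        row = df.loc["TP"]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == -6.0

    def test_empty_group_na_row(self):
        df = loss_distribution_summary([scored("x", -6.0)], ["x"]).set_index("kind")
        fp = df.loc["FP"]
        assert fp["count"] == 0 and np.isnan(fp["median"])
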