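"""Logistic model: calibration, prediction, intercept updating, diagnostics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcsdecision import (
    CalibrationError,
    CosmesisLogisticModel,
    PatientPresentation,
    TumorLocation,
    auc,
    calibrate_from_printed_values,
    confusion_at_threshold,
    predict_good_cosmesis,
    update_intercept,
)
from bcsdecision.decision import ratio_cutoff

from conftest import ANCHOR, PRINTED_CUTOFFS, PRINTED_THRESHOLD


def _logit(p):
    return math.log(p / (1 - p))


def closed_form_calibration():
    """Independent oracle: eliminate unknowns by hand instead of a matrix solve.

    The upper-medial cut-off and anchor rows share the same offset, so their
    difference pins the slope; the upper-lateral row (zero offset) then gives
    the intercept, and each remaining row gives its offset directly.
    """
    thr_logit = _logit(PRINTED_THRESHOLD)
    anchor_loc, anchor_ratio, anchor_prob = ANCHOR
    slope = (_logit(anchor_prob) - thr_logit) / (anchor_ratio - PRINTED_CUTOFFS[anchor_loc])
    intercept = thr_logit - slope * PRINTED_CUTOFFS[TumorLocation.UPPER_LATERAL]
    offsets = {
        loc: thr_logit - intercept - slope * cut
        for loc, cut in PRINTED_CUTOFFS.items()
        if loc is not TumorLocation.UPPER_LATERAL
    }
    return intercept, slope, offsets


class TestCalibration:
    def test_matches_closed_form_oracle(self, default_model):
        intercept, slope, offsets = closed_form_calibration()
        assert default_model.intercept == pytest.approx(intercept, abs=1e-12)
        assert default_model.ratio_coef == pytest.approx(slope, abs=1e-12)
        for loc, off in offsets.items():
            assert default_model.location_offsets[loc] == pytest.approx(off, abs=1e-12)

    def test_frozen_derived_values(self, default_model):
        # values computed once with the closed-form oracle above
        assert default_model.intercept == pytest.approx(2.7797226058510143, abs=1e-9)
        assert default_model.ratio_coef == pytest.approx(-0.15573045940464236, abs=1e-9)
        expected_offsets = {
            TumorLocation.UPPER_MEDIAL: -1.0122479861301756,
            TumorLocation.LOWER_LATERAL: -2.7252830395812415,
            TumorLocation.LOWER_MEDIAL: -2.86544045304542,
            TumorLocation.CENTRAL: -1.0745401698920325,
        }
        for loc, off in expected_offsets.items():
            assert default_model.location_offsets[loc] == pytest.approx(off, abs=1e-9)

    def test_round_trips_every_cutoff_and_the_anchor(self, default_model):
        for loc, cut in PRINTED_CUTOFFS.items():
            assert default_model.predict(loc, cut) == pytest.approx(PRINTED_THRESHOLD, abs=1e-12)
            assert ratio_cutoff(default_model, PRINTED_THRESHOLD, loc) == pytest.approx(
                cut, abs=1e-9
            )
        loc, ratio, prob = ANCHOR
        assert default_model.predict(loc, ratio) == pytest.approx(prob, abs=1e-12)

    def test_cross_validates_against_independent_published_probabilities(self, default_model):
        # two probabilities not used in the calibration system
        assert default_model.predict(TumorLocation.LOWER_LATERAL, 15.0) == pytest.approx(
            0.10, abs=0.015
        )
        assert default_model.predict(TumorLocation.UPPER_LATERAL, 15.0) == pytest.approx(
            0.60, abs=0.015
        )

    def test_anchor_at_its_own_cutoff_is_singular(self):
        anchor = (TumorLocation.UPPER_MEDIAL, PRINTED_CUTOFFS[TumorLocation.UPPER_MEDIAL], 0.71)
        with pytest.raises(CalibrationError):
            calibrate_from_printed_values(PRINTED_CUTOFFS, PRINTED_THRESHOLD, anchor)

    def test_incomplete_cutoffs_rejected(self):
        partial = {k: v for k, v in PRINTED_CUTOFFS.items() if k is not TumorLocation.CENTRAL}
        with pytest.raises(ValueError, match="each of the five locations"):
            calibrate_from_printed_values(partial, PRINTED_THRESHOLD, ANCHOR)


class TestPredict:
    def test_worked_example_prediction(self, default_model):
        patient = PatientPresentation(3.8, 675.0, TumorLocation.UPPER_MEDIAL)
        assert predict_good_cosmesis(default_model, patient) == pytest.approx(0.71, abs=0.005)

    def test_probability_vanishes_at_extreme_ratio(self, default_model):
        assert default_model.predict(TumorLocation.UPPER_LATERAL, 1000.0) < 1e-10

    @given(
        loc=st.sampled_from(list(TumorLocation)),
        ratio=st.floats(0.01, 900.0),
        delta=st.floats(0.1, 100.0),
    )
    def test_strictly_decreasing_in_ratio(self, default_model, loc, ratio, delta):
        assert default_model.predict(loc, ratio + delta) < default_model.predict(loc, ratio)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            CosmesisLogisticModel(
                intercept=0.0,
                ratio_coef=0.1,
                location_offsets={loc: 0.0 for loc in TumorLocation},
            )

    def test_nonzero_reference_offset_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            CosmesisLogisticModel(
                intercept=0.0,
                ratio_coef=-0.1,
                location_offsets={TumorLocation.UPPER_LATERAL: 1.0},
            )


class TestUpdateIntercept:
    def test_identity_when_prior_unchanged(self, default_model):
        updated = update_intercept(default_model, 0.71, 0.71)
        assert updated == default_model

    def test_two_point_prevalence_correction(self, default_model):
        # logit(0.730) - logit(0.710), direct arithmetic
        expected_shift = math.log(0.73 / 0.27) - math.log(0.71 / 0.29)
        updated = update_intercept(default_model, 0.710, 0.730)
        assert updated.intercept - default_model.intercept == pytest.approx(
            expected_shift, abs=1e-12
        )
        assert expected_shift == pytest.approx(0.0992, abs=5e-4)

    @given(
        old=st.floats(0.05, 0.95),
        new=st.floats(0.05, 0.95),
        r1=st.floats(0.1, 50.0),
        r2=st.floats(0.1, 50.0),
        locs=st.tuples(
            st.sampled_from(list(TumorLocation)), st.sampled_from(list(TumorLocation))
        ),
    )
    def test_preserves_pairwise_odds_ratios(self, default_model, old, new, r1, r2, locs):
        updated = update_intercept(default_model, old, new)
        lo_before = default_model.linear_predictor(locs[0], r1) - default_model.linear_predictor(
            locs[1], r2
        )
        lo_after = updated.linear_predictor(locs[0], r1) - updated.linear_predictor(locs[1], r2)
        assert lo_after == pytest.approx(lo_before, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.2])
    def test_degenerate_priors_rejected(self, default_model, bad):
        with pytest.raises(ValueError):
            update_intercept(default_model, bad, 0.5)
        with pytest.raises(ValueError):
            update_intercept(default_model, 0.5, bad)


class TestConfusion:
    def test_published_counts_give_published_predictive_values(self):
        # 48 TP / 12 FP above the threshold, 8 TN / 1 FN below
        predicted = [0.9] * 60 + [0.1] * 9
        observed = ["good"] * 48 + ["poor"] * 12 + ["poor"] * 8 + ["good"]
        counts = confusion_at_threshold(predicted, observed, 0.358)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (48, 12, 8, 1)
        assert counts.ppv == pytest.approx(0.800, abs=1e-12)
        assert counts.npv == pytest.approx(8 / 9, abs=1e-12)

    def test_equality_with_threshold_is_negative(self):
        counts = confusion_at_threshold([0.358], ["good"], 0.358)
        assert (counts.tp, counts.fn) == (0, 1)

    def test_perfect_separation_gives_unit_predictive_values(self):
        counts = confusion_at_threshold([0.9, 0.9, 0.1], ["good", "good", "poor"], 0.5)
        assert counts.ppv == 1.0 and counts.npv == 1.0

    def test_no_positive_predictions_flags_ppv_undefined(self):
        counts = confusion_at_threshold([0.1, 0.2, 0.3], ["good", "poor", "poor"], 0.5)
        assert counts.ppv is None
        assert counts.npv == pytest.approx(2 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_at_threshold([], [], 0.5)


def auc_pair_counting(predicted, observed):
    """O(n^2) oracle: fraction of (good, poor) pairs ranked correctly, ties 1/2."""
    goods = [p for p, o in zip(predicted, observed) if o == "good"]
    poors = [p for p, o in zip(predicted, observed) if o == "poor"]
    wins = sum(
        1.0 if g > b else 0.5 if g == b else 0.0 for g, b in itertools.product(goods, poors)
    )
    return wins / (len(goods) * len(poors))


class TestAuc:
    def test_perfectly_separated(self):
        assert auc([0.9, 0.8, 0.1, 0.2], ["good", "good", "poor", "poor"]) == 1.0

    def test_all_tied_predictions(self):
        assert auc([0.5] * 6, ["good", "poor"] * 3) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            auc([0.2, 0.8], ["good", "good"])

    @settings(deadline=None, max_examples=50)
    @given(
        n=st.integers(5, 200),
        seed=st.integers(0, 2**20),
        tie_prone=st.booleans(),
    )
    def test_agrees_with_pair_counting_oracle(self, n, seed, tie_prone):
        rng = np.random.default_rng(seed)
        predicted = (
            rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n) if tie_prone else rng.uniform(size=n)
        )
        observed = np.where(rng.uniform(size=n) < 0.6, "good", "poor")
        if len(set(observed)) < 2:
            observed[0], observed[1] = "good", "poor"
        assert auc(predicted, observed) == pytest.approx(
            auc_pair_counting(predicted, observed), abs=1e-12
        )
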