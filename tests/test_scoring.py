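"""Point allocation, quantile ranges, totals and accuracy evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vitalgluten.scoring import (ParameterRange, ScoringConfig,
                                 allocate_points, classify_score,
                                 evaluate_accuracy, medium_quantile_ranges,
                                 score_panel, score_sample)


def _features(values, parameter="pmt"):
    return pd.DataFrame({parameter: values},
                        index=[f"S{i}" for i in range(len(values))])


class TestQuantileRanges:
    def test_hand_oracle_one_to_five(self):
        # positions h = (n-1)p + 1: h25 = 2 -> 2.0, h75 = 4 -> 4.0
        feats = _features([1.0, 2.0, 3.0, 4.0, 5.0])
        ranges = medium_quantile_ranges(feats, ["medium"] * 5, ["pmt"],
                                        {"pmt": -1})
        assert ranges["pmt"].q25 == pytest.approx(2.0)
        assert ranges["pmt"].q75 == pytest.approx(4.0)

    def test_interpolated_positions(self):
        # n = 6: h25 = 2.25 -> 2.25, h75 = 4.75 -> 4.75
        feats = _features([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ranges = medium_quantile_ranges(feats, ["medium"] * 6, ["pmt"],
                                        {"pmt": 1})
        assert ranges["pmt"].q25 == pytest.approx(2.25)
        assert ranges["pmt"].q75 == pytest.approx(4.75)

    def test_constant_group_collapses(self):
        feats = _features([7.0, 7.0, 7.0, 7.0])
        ranges = medium_quantile_ranges(feats, ["medium"] * 4, ["pmt"],
                                        {"pmt": 1})
        assert ranges["pmt"].q25 == ranges["pmt"].q75 == 7.0

    def test_quantiles_bracket_median(self, rng):
        vals = rng.normal(size=15)
        feats = _features(list(vals))
        ranges = medium_quantile_ranges(feats, ["medium"] * 15, ["pmt"],
                                        {"pmt": 1})
        med = np.median(vals)
        assert ranges["pmt"].q25 <= med <= ranges["pmt"].q75

    def test_too_few_medium_samples(self):
        feats = _features([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            medium_quantile_ranges(feats, ["medium", "good", "good"], ["pmt"],
                                   {"pmt": 1})


class TestAllocatePoints:
    def test_direction_semantics(self):
        up = ParameterRange("bem", q25=10.0, q75=20.0, direction=1)
        down = ParameterRange("pmt", q25=10.0, q75=20.0, direction=-1)
        assert allocate_points(25.0, up) == 20
        assert allocate_points(5.0, up) == 0
        assert allocate_points(15.0, up) == 10
        assert allocate_points(25.0, down) == 0
        assert allocate_points(5.0, down) == 20

    def test_boundaries_score_ten(self):
        r = ParameterRange("x", q25=1.0, q75=2.0, direction=1)
        assert allocate_points(1.0, r) == 10
        assert allocate_points(2.0, r) == 10

    def test_grid_agrees_with_three_way_oracle(self):
        r = ParameterRange("x", q25=-1.0, q75=1.5, direction=-1)
        for v in np.linspace(-3, 4, 141):
            if v < r.q25:
                expect = 20
            elif v > r.q75:
                expect = 0
            else:
                expect = 10
            assert allocate_points(float(v), r) == expect


class TestScoreSample:
    def test_published_pmt_contribution(self):
        # a good-side PMT with weight 0.53 contributes 10.6
        config = ScoringConfig(
            ranges={"pmt": ParameterRange("pmt", 280.0, 340.0, -1)},
            weights={"pmt": 0.53})
        total, breakdown = score_sample({"pmt": 250.0}, config)
        assert total == pytest.approx(10.6)
        assert breakdown.loc[0, "points"] == 20

    def test_all_poor_scores_zero(self):
        config = ScoringConfig(
            ranges={"pmt": ParameterRange("pmt", 280.0, 340.0, -1),
                    "bem": ParameterRange("bem", 25.0, 30.0, 1)},
            weights={"pmt": 0.53, "bem": 0.56})
        total, _ = score_sample({"pmt": 400.0, "bem": 20.0}, config)
        assert total == 0.0

    def test_total_invariant_to_parameter_order(self):
        r = {"a": ParameterRange("a", 0.0, 1.0, 1),
             "b": ParameterRange("b", 0.0, 1.0, -1)}
        w = {"a": 0.4, "b": 0.6}
        c1 = ScoringConfig(ranges=r, weights=w)
        c2 = ScoringConfig(ranges=dict(reversed(list(r.items()))), weights=w)
        feats = {"a": 2.0, "b": -1.0}
        assert score_sample(feats, c1)[0] == score_sample(feats, c2)[0]

    def test_missing_parameter_named(self):
        config = ScoringConfig(
            ranges={"pmt": ParameterRange("pmt", 280.0, 340.0, -1)},
            weights={"pmt": 0.53})
        with pytest.raises(KeyError, match="pmt"):
            score_sample({"bem": 30.0}, config)

    @settings(max_examples=50, derandomize=True)
    @given(v=st.floats(-10, 10), delta=st.floats(0.1, 10))
    def test_improving_one_parameter_never_lowers_total(self, v, delta):
        config = ScoringConfig(
            ranges={"x": ParameterRange("x", -1.0, 1.0, 1),
                    "y": ParameterRange("y", -1.0, 1.0, -1)},
            weights={"x": 0.5, "y": 0.5})
        base, _ = score_sample({"x": v, "y": 0.0}, config)
        better, _ = score_sample({"x": v + delta, "y": 0.0}, config)
        assert better >= base


class TestClassifyScore:
    @pytest.mark.parametrize("total,expected", [
        (85.8, "good"), (75.6, "medium"), (0.0, "poor"),
        (80.0, "medium"), (50.0, "poor"), (113.5, "good"),
    ])
    def test_thresholds(self, total, expected):
        assert classify_score(total) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_score(-1.0)


class TestAccuracy:
    def test_identical_labels(self):
        labels = pd.Series(["good", "poor"], index=["a", "b"])
        frac, confusion = evaluate_accuracy(labels, labels)
        assert frac == 1.0
        assert confusion.to_numpy().sum() == 2

    def test_thirty_of_fortysix(self):
        idx = [f"G{i}" for i in range(46)]
        ref = pd.Series(["good"] * 46, index=idx)
        pred = pd.Series(["good"] * 30 + ["poor"] * 16, index=idx)
        frac, _ = evaluate_accuracy(pred, ref)
        assert round(100 * frac, 1) == 65.2

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            evaluate_accuracy(pd.Series({"a": "good"}),
                              pd.Series({"b": "good"}))


class TestScorePanel:
    def test_majority_of_medium_samples_score_ten_per_parameter(
            self, default_features, default_panel):
        from vitalgluten.correlate import correlation_table, \
            select_scored_parameters
        import pandas as pd
        recs = default_panel.records
        vols = pd.DataFrame(
            {"volume_A_ml_per_g": [r.specific_volume_a for r in recs],
             "volume_B_ml_per_g": [r.specific_volume_b for r in recs]},
            index=[r.sample_id for r in recs])
        weights = select_scored_parameters(
            correlation_table(default_features, vols))
        directions = dict(zip(weights["parameter"], weights["direction"]))
        labels = np.array([r.quality_class for r in recs])
        labels = pd.Series(labels, index=[r.sample_id for r in recs])
        ranges = medium_quantile_ranges(
            default_features, labels.loc[default_features.index].to_numpy(),
            list(weights["parameter"]), directions)
        config = ScoringConfig(ranges=ranges,
                               weights=dict(zip(weights["parameter"],
                                                weights["weight"])),
                               threshold_mode="relative")
        report = score_panel(default_features[list(weights["parameter"])],
                             config, reference=labels)
        med_ids = labels[labels == "medium"].index
        for p in ranges:
            pts = [report.breakdowns[s].set_index("parameter").loc[p, "points"]
                   for s in med_ids]
            # the inclusive 25/75 band holds the central ~half of the
            # medium group (7 of 15 order statistics at n = 15)
            assert np.mean(np.asarray(pts) == 10) >= 0.45
        assert report.scores["total"].between(0, config.max_total).all()
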