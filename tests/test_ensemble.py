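"""Splitting, base learners, the relative-MAE-gap combination rule, and the
end-to-end ensemble fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadlink import (
    ConfigError,
    GeneratorConfig,
    MLPConfig,
    RFConfig,
    SplitSpec,
    combine_rule,
    evaluate_models,
    fit_ensemble,
    fit_mlp,
    fit_rf,
    generate_dataset,
    predict_combined,
    split_dataset,
)
from dyadlink.ensemble import decode_class

FEATURES = ["maternal_age", "education", "epds", "hads"]


class TestSplit:
    def test_sizes_50_20_30(self, dataset379):
        train, val, test = split_dataset(dataset379.head(100), SplitSpec(seed=1))
        assert (len(train), len(val), len(test)) == (50, 20, 30)

    def test_deterministic(self, dataset379):
        a = split_dataset(dataset379, SplitSpec(seed=5))
        b = split_dataset(dataset379, SplitSpec(seed=5))
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_partition_property(self, dataset379):
        train, val, test = split_dataset(dataset379, SplitSpec(seed=2))
        union = sorted(
            pd.concat([train, val, test])["dyad_id"].tolist()
        )
        assert union == sorted(dataset379["dyad_id"].tolist())

    def test_degenerate_fractions_rejected(self, dataset379):
        with pytest.raises(ConfigError):
            split_dataset(dataset379, SplitSpec(fractions=(0.5, 0.5, 0.5)))


@pytest.fixture(scope="module")
def separable_toy():
    r = np.random.default_rng(11)
    y = np.repeat([0, 1, 2], 70)
    X = np.column_stack([y / 2 + 0.05 * r.standard_normal(210),
                         r.uniform(size=210)])
    return X, y


class TestBaseLearners:
    def test_mlp_fits_separable_toy(self, separable_toy):
        X, y = separable_toy
        mlp = fit_mlp(X, y, MLPConfig(seed=0))
        assert np.mean(mlp.classes(X) == y) >= 0.95

    def test_rf_fits_pure_signal(self, separable_toy):
        X, y = separable_toy
        rf = fit_rf(X, y, RFConfig(seed=0))
        assert np.mean(rf.classes(X) == y) >= 0.99

    @pytest.mark.parametrize("fitter, cfg", [(fit_mlp, MLPConfig(seed=4)), (fit_rf, RFConfig(seed=4))])
    def test_deterministic_predictions(self, separable_toy, fitter, cfg):
        X, y = separable_toy
        p1 = fitter(X, y, cfg)
        p2 = fitter(X, y, cfg)
        assert np.array_equal(p1.scores(X), p2.scores(X))

    def test_constant_labels_predict_that_label(self, separable_toy):
        X, _ = separable_toy
        rf = fit_rf(X, np.ones(len(X), dtype=int), RFConfig(seed=0))
        assert (rf.classes(X) == 1).all()
        mlp = fit_mlp(X, np.ones(len(X), dtype=int), MLPConfig(seed=0))
        assert (mlp.classes(X) == 1).all()

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            fit_rf(np.array([[np.nan, 1.0]]), np.array([0]))

    def test_numeric_expectation_is_score_weighted(self, separable_toy):
        X, y = separable_toy
        rf = fit_rf(X, y, RFConfig(seed=0))
        scores = rf.scores(X)
        assert np.allclose(rf.expectation(X), scores @ np.array([0.0, 1.0, 2.0]))


class TestCombineRule:
    def test_equal_maes_blend_evenly(self):
        rule = combine_rule(0.30, 0.30)
        assert rule.mode == "combined"
        assert rule.delta == 0.0
        assert rule.q1 == rule.q2 == 0.5

    def test_large_gap_discards_weaker_model(self):
        rule = combine_rule(0.40, 0.20)
        assert rule.delta == pytest.approx(0.5)
        assert rule.mode == "model2_only"
        assert (rule.q1, rule.q2) == (0.0, 1.0)

    def test_small_gap_blends_with_own_mae_weights(self):
        rule = combine_rule(0.50, 0.49)
        assert rule.delta == pytest.approx(0.01 / 0.50)
        assert rule.mode == "combined"
        assert rule.q1 == pytest.approx(50 / 99)
        assert rule.q2 == pytest.approx(49 / 99)

    def test_boundary_delta_blends(self):
        # delta exactly at the threshold resolves to "combined" (<= wins);
        # dyadic values keep the comparison exact in floating point.
        rule = combine_rule(1.0, 0.9375, threshold=0.0625)
        assert rule.delta == 0.0625
        assert rule.mode == "combined"
        just_over = combine_rule(1.0, 0.9375, threshold=0.0624)
        assert just_over.mode == "model2_only"

    def test_both_zero_blend_evenly(self):
        rule = combine_rule(0.0, 0.0)
        assert rule.mode == "combined" and rule.q1 == 0.5

    def test_negative_mae_rejected(self):
        with pytest.raises(ValueError):
            combine_rule(-0.1, 0.2)

    def test_inverse_error_weights_flag(self):
        rule = combine_rule(0.50, 0.49, inverse_error_weights=True)
        assert rule.q1 == pytest.approx(49 / 99)

    def test_absolute_delta_flag_gates_better_first_model(self):
        # A much better first model: signed delta is very negative (blend),
        # |delta| gating keeps the first model only.
        assert combine_rule(0.10, 0.40).mode == "combined"
        assert combine_rule(0.10, 0.40, absolute_delta=True).mode == "model1_only"

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(1e-6, 10), st.floats(1e-6, 10))
    def test_weights_always_sum_to_one(self, m1, m2):
        rule = combine_rule(m1, m2)
        assert rule.q1 + rule.q2 == pytest.approx(1.0, abs=1e-12)
        if rule.mode == "combined":
            assert rule.delta <= 0.05 + 1e-12
        else:
            assert rule.delta > 0.05


class TestPredictCombined:
    def test_even_blend_averages(self):
        rule = combine_rule(0.3, 0.3)
        numeric, cls = predict_combined(rule, np.array([2.0]), np.array([0.0]))
        assert numeric[0] == 1.0 and cls[0] == 1

    def test_gated_output_equals_surviving_model(self):
        rule = combine_rule(0.40, 0.20)
        numeric, cls = predict_combined(rule, np.array([1.7]), np.array([0.3]))
        assert numeric[0] == 0.3 and cls[0] == 0

    def test_weighted_blend_rounds_half_down(self):
        from dyadlink.ensemble import CombinationRule

        rule = CombinationRule(0.4, 0.6, -0.33, "combined", 0.6, 0.4)
        numeric, cls = predict_combined(rule, np.array([1.0]), np.array([2.0]))
        assert numeric[0] == pytest.approx(1.4)
        assert cls[0] == 1

    @pytest.mark.parametrize(
        "value, expected", [(0.5, 0), (1.5, 1), (1.49, 1), (1.51, 2), (-0.7, 0), (2.9, 2)]
    )
    def test_class_decoding_rule(self, value, expected):
        assert decode_class(np.array([value]))[0] == expected

    def test_blend_lies_between_base_predictions(self, rng):
        rule = combine_rule(0.31, 0.30)
        p1 = rng.uniform(0, 2, size=50)
        p2 = rng.uniform(0, 2, size=50)
        numeric, _ = predict_combined(rule, p1, p2)
        assert (numeric >= np.minimum(p1, p2) - 1e-12).all()
        assert (numeric <= np.maximum(p1, p2) + 1e-12).all()


@pytest.fixture(scope="module")
def planted_dataset():
    cfg = GeneratorConfig(
        n_dyads=379, seed=8, behavior_effects={"epds": 1.2, "hads": 0.8}
    )
    return generate_dataset(cfg)


class TestFitEnsemble:
    def test_rule_invariants_on_fit(self, planted_dataset):
        fit, report = fit_ensemble(
            planted_dataset, FEATURES, SplitSpec(seed=1), MLPConfig(seed=1), RFConfig(seed=1)
        )
        rule = fit.rule
        assert rule.q1 + rule.q2 == pytest.approx(1.0, abs=1e-12)
        if rule.mode == "combined":
            assert rule.q1 == pytest.approx(rule.mae_1 / (rule.mae_1 + rule.mae_2))
            assert rule.delta <= 0.05
        assert set(report.metrics["RF-MLP"]) == {"train", "val", "test"}

    def test_end_to_end_determinism(self, planted_dataset):
        kwargs = dict(
            split=SplitSpec(seed=2), mlp_cfg=MLPConfig(seed=2), rf_cfg=RFConfig(seed=2)
        )
        _, r1 = fit_ensemble(planted_dataset, FEATURES, **kwargs)
        _, r2 = fit_ensemble(planted_dataset, FEATURES, **kwargs)
        assert r1.to_json() == r2.to_json()


@pytest.fixture(scope="module")
def comparison_report(planted_dataset):
    return evaluate_models(
        planted_dataset, FEATURES, SplitSpec(seed=3), MLPConfig(seed=3), RFConfig(seed=3)
    )


class TestEvaluateModels:
    def test_all_five_models_present(self, comparison_report):
        assert set(comparison_report.metrics) == {"MLP", "RF", "RF-MLP", "RF-SVM", "SVM-MLP"}
        frame = comparison_report.to_frame()
        assert len(frame) == 15  # 5 models x 3 splits
        assert frame["accuracy"].between(0, 1).all()

    def test_rf_overfits_train_more_than_mlp(self, comparison_report):
        assert (
            comparison_report.metrics["RF"]["train"]["accuracy"]
            > comparison_report.metrics["MLP"]["train"]["accuracy"]
        )

    def test_identical_seed_gives_identical_table(self, planted_dataset, comparison_report):
        again = evaluate_models(
            planted_dataset, FEATURES, SplitSpec(seed=3), MLPConfig(seed=3), RFConfig(seed=3)
        )
        assert again.to_json() == comparison_report.to_json()
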