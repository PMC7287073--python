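import numpy as np
import pandas as pd
import pytest

from priorselect.features import IneligibleDrug
from priorselect.modeling import (
    ExperimentProtocol,
    fit_en,
    fit_rf,
    run_drug,
    split,
)

FAST = dict(
    en_l1_ratios=(0.5, 1.0),
    en_n_alphas=10,
    rf_n_estimators=50,
    rf_max_depth_grid=(None,),
    rf_max_features_grid=("sqrt",),
    sel_n_subsamples=10,
    sel_k_grid=(5, 10),
)


class TestSplit:
    def test_seventy_thirty_arithmetic(self):
        proto = ExperimentProtocol(seed=0)
        train, test = split([f"s{i}" for i in range(100)], proto, 0)
        assert len(train) == 70 and len(test) == 30
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == {f"s{i}" for i in range(100)}

    def test_deterministic_per_repetition(self):
        ids = [f"s{i}" for i in range(40)]
        proto = ExperimentProtocol(seed=3)
        assert split(ids, proto, 2) == split(ids, proto, 2)

    def test_five_repetitions_give_distinct_test_sets(self):
        ids = [f"s{i}" for i in range(100)]
        proto = ExperimentProtocol(seed=1)
        tests = [frozenset(split(ids, proto, rep)[1]) for rep in range(5)]
        assert len(set(tests)) == 5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            split(["a"] * 5, ExperimentProtocol(), 0)


class TestFitEN:
    def test_noiseless_linear_signal_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"f": x}, index=[f"s{i}" for i in range(100)])
        y = pd.Series(2.0 * x, index=X.index)
        proto = ExperimentProtocol(**FAST, seed=0)
        fit = fit_en(X.iloc[:70], y.iloc[:70], X.iloc[70:], proto)
        np.testing.assert_allclose(fit.predictions, y.iloc[70:], atol=0.05)
        assert fit.feature_effects["f"] > 0

    def test_planted_drivers_have_top_coefficients(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.standard_normal((200, 52)),
            columns=[f"f{j:02d}" for j in range(52)],
            index=[f"s{i}" for i in range(200)],
        )
        y = pd.Series(X["f00"].to_numpy() - X["f01"].to_numpy() + rng.normal(0, 0.1, 200), index=X.index)
        proto = ExperimentProtocol(**FAST, seed=1)
        fit = fit_en(X.iloc[:150], y.iloc[:150], X.iloc[150:], proto)
        top2 = fit.feature_effects.sort_values(ascending=False).index[:2]
        assert set(top2) == {"f00", "f01"}

    def test_constant_columns_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"f": rng.standard_normal(60), "const": 5.0}, index=[f"s{i}" for i in range(60)]
        )
        y = pd.Series(X["f"].to_numpy() + rng.normal(0, 0.1, 60), index=X.index)
        proto = ExperimentProtocol(**FAST, seed=2)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_en(X.iloc[:40], y.iloc[:40], X.iloc[40:], proto)
        assert fit.feature_effects["const"] == 0.0

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"f": np.arange(30.0)}, index=[f"s{i}" for i in range(30)])
        y = pd.Series(1.0, index=X.index)
        with pytest.raises(ValueError, match="constant"):
            fit_en(X.iloc[:20], y.iloc[:20], X.iloc[20:], ExperimentProtocol(**FAST))

    def test_standardization_uses_training_statistics_only(self):
        # corrupting the held-out rows must not alter the fitted model
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            rng.standard_normal((80, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(80)],
        )
        y = pd.Series(X["a"].to_numpy() + rng.normal(0, 0.1, 80), index=X.index)
        proto = ExperimentProtocol(**FAST, seed=3)
        fit1 = fit_en(X.iloc[:60], y.iloc[:60], X.iloc[60:], proto)
        X_corrupt = X.copy()
        X_corrupt.iloc[60:] += 100.0
        fit2 = fit_en(X.iloc[:60], y.iloc[:60], X_corrupt.iloc[60:], proto)
        pd.testing.assert_series_equal(fit1.feature_effects, fit2.feature_effects)
        assert fit1.hyperparameters == fit2.hyperparameters


class TestFitRF:
    def test_binary_driver_importance_rank_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.standard_normal((150, 21)),
            columns=[f"f{j:02d}" for j in range(21)],
            index=[f"s{i}" for i in range(150)],
        )
        X["f00"] = (rng.random(150) < 0.3).astype(float)
        y = pd.Series(np.where(X["f00"] > 0.5, 0.3, 0.8) + rng.normal(0, 0.05, 150), index=X.index)
        proto = ExperimentProtocol(**FAST, seed=0)
        fit = fit_rf(X.iloc[:100], y.iloc[:100], X.iloc[100:], proto)
        assert fit.feature_effects.idxmax() == "f00"

    def test_identical_test_rows_identical_predictions(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.standard_normal((60, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(60)],
        )
        y = pd.Series(X["a"].to_numpy() + rng.normal(0, 0.2, 60), index=X.index)
        X_test = pd.concat([X.iloc[50:], X.iloc[50:]])
        X_test.index = [f"t{i}" for i in range(len(X_test))]
        proto = ExperimentProtocol(**FAST, seed=1)
        fit = fit_rf(X.iloc[:50], y.iloc[:50], X_test, proto)
        np.testing.assert_array_equal(fit.predictions.iloc[:10], fit.predictions.iloc[10:])

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"f": np.arange(30.0)}, index=[f"s{i}" for i in range(30)])
        with pytest.raises(ValueError, match="constant"):
            fit_rf(X.iloc[:20], pd.Series(0.5, index=X.index[:20]), X.iloc[20:], ExperimentProtocol(**FAST))


class TestRunDrug:
    def test_single_repetition_yields_one_fit(self, tiny_bundle):
        drug = next(d for d in tiny_bundle.drugs if d.targets)
        proto = ExperimentProtocol(**FAST, n_repetitions=1, seed=0)
        fits = run_drug(drug, "OT", tiny_bundle.dataset, tiny_bundle.responses, proto)
        assert isinstance(fits, list) and len(fits) == 1

    def test_ineligible_drug_returns_typed_skip(self, tiny_bundle):
        from priorselect.datatypes import DrugAnnotation

        drug = DrugAnnotation("NOTARGETS", frozenset(), "other")
        responses = tiny_bundle.responses.for_drug(tiny_bundle.drugs[0].drug_id)
        result = run_drug(
            drug, "OT", tiny_bundle.dataset, responses.rename("NOTARGETS"),
            ExperimentProtocol(**FAST),
        )
        assert isinstance(result, IneligibleDrug)

    def test_deterministic_given_seed(self, tiny_bundle):
        drug = next(d for d in tiny_bundle.drugs if d.targets)
        proto = ExperimentProtocol(**FAST, n_repetitions=2, seed=5)
        a = run_drug(drug, "OT", tiny_bundle.dataset, tiny_bundle.responses, proto)
        b = run_drug(drug, "OT", tiny_bundle.dataset, tiny_bundle.responses, proto)
        for fa, fb in zip(a, b):
            pd.testing.assert_series_equal(fa.predictions, fb.predictions)

    def test_gw_sel_selection_ignores_test_partition(self, tiny_bundle):
        # permuting the responses of held-out samples must not change ranking
        drug = tiny_bundle.drugs[0]
        proto = ExperimentProtocol(**FAST, n_repetitions=1, seed=2)
        y = tiny_bundle.responses.for_drug(drug.drug_id)
        fits = run_drug(drug, "GW_SEL_EN", tiny_bundle.dataset, tiny_bundle.responses, proto)
        _, test_ids = split(fits[0].train_ids + fits[0].test_ids, proto, 0)
        y_corrupt = y.copy()
        y_corrupt.loc[fits[0].test_ids] = y.loc[fits[0].test_ids].to_numpy()[::-1]
        fits2 = run_drug(drug, "GW_SEL_EN", tiny_bundle.dataset, y_corrupt, proto)
        assert fits[0].selection.ranked_features == fits2[0].selection.ranked_features
        assert fits[0].selection.k == fits2[0].selection.k

    def test_sel_strategies_force_their_family(self, tiny_bundle):
        drug = tiny_bundle.drugs[0]
        proto = ExperimentProtocol(**FAST, n_repetitions=1, seed=1)
        fits = run_drug(
            drug, "GW_SEL_RF", tiny_bundle.dataset, tiny_bundle.responses, proto,
            model_family="en",
        )
        assert fits[0].model_family == "rf"
        assert fits[0].selection is not None
        assert len(fits[0].feature_effects) == fits[0].selection.k

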