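import itertools
import math

import numpy as np
import pandas as pd
import pytest

from priorselect.datatypes import DrugAnnotation
from priorselect.evaluation import (
    aggregate_records,
    best_model_per_drug,
    correlation_test,
    exclude_drugs,
    feature_type_frequencies,
    pathway_comparison,
    records_frame,
    rel_rmse,
)
from priorselect.signatures import UndefinedScoreError


class TestRelRMSE:
    def test_dummy_against_itself_is_exactly_one(self):
        rng = np.random.default_rng(0)
        y_train = rng.uniform(0, 1, 70)
        y_test = rng.uniform(0, 1, 30)
        mean = y_train.mean()
        assert rel_rmse(y_test, np.full(30, mean), mean) == 1.0

    def test_half_the_dummy_error_doubles_the_score(self):
        y_test = np.array([0.0, 1.0])
        y_train_mean = 0.5  # dummy RMSE = 0.5
        y_pred = np.array([0.25, 0.75])  # model RMSE = 0.25
        assert rel_rmse(y_test, y_pred, y_train_mean) == pytest.approx(2.0)

    def test_matches_independent_two_rmse_computation(self):
        rng = np.random.default_rng(1)
        y_test = rng.uniform(0, 1, 50)
        y_pred = y_test + rng.normal(0, 0.1, 50)
        mean = 0.6
        expected = math.sqrt(np.mean((y_test - mean) ** 2)) / math.sqrt(
            np.mean((y_test - y_pred) ** 2)
        )
        assert rel_rmse(y_test, y_pred, mean) == pytest.approx(expected, abs=1e-12)

    def test_perfect_model_returns_infinity_with_warning(self):
        y = np.array([0.2, 0.8])
        with pytest.warns(UserWarning, match="perfect"):
            assert rel_rmse(y, y, 0.5) == math.inf

    def test_degenerate_zero_over_zero_raises(self):
        y = np.array([0.5, 0.5])
        with pytest.raises(UndefinedScoreError):
            rel_rmse(y, y, 0.5)

    def test_above_one_iff_model_beats_dummy(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1, 40)
        mean = y.mean() + 0.05
        better = y + rng.normal(0, 0.01, 40)
        worse = y + rng.normal(0, 0.5, 40)
        assert rel_rmse(y, better, mean) > 1
        assert rel_rmse(y, worse, mean) < 1


class TestCorrelationTest:
    def test_perfect_agreement(self):
        y = np.linspace(0, 1, 10)
        r, p = correlation_test(y, y)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_anticorrelation(self):
        y = np.linspace(0, 1, 10)
        r, _ = correlation_test(y, -y)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedScoreError):
            correlation_test(np.ones(10), np.arange(10.0))

    def test_p_value_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        n = 20
        y = rng.uniform(0, 1, n)
        pred = y + rng.normal(0, 0.6, n)
        r_obs, p = correlation_test(y, pred)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            r_perm = np.corrcoef(y, rng.permutation(pred))[0, 1]
            count += abs(r_perm) >= abs(r_obs)
        p_perm = count / n_perm
        # agreement within ~3 Monte-Carlo standard errors
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-4
        assert abs(p - p_perm) < 3 * se + 0.01


def _agg(rows):
    return pd.DataFrame(
        rows,
        columns=["drug_id", "strategy", "model_family", "n_features", "rel_rmse", "pearson_r"],
    )


class TestExcludeDrugs:
    def test_all_baseline_excluded(self):
        agg = _agg([("D1", "OT", "en", 5, 1.0, 0.0), ("D1", "GW", "en", 100, 0.98, 0.1)])
        assert exclude_drugs(agg) == {"D1"}

    def test_one_good_strategy_retains_drug(self):
        agg = _agg([("D1", "OT", "en", 5, 1.0, 0.0), ("D1", "GW", "en", 100, 1.5, 0.5)])
        assert exclude_drugs(agg) == set()

    def test_epsilon_widens_the_baseline_band(self):
        agg = _agg([("D1", "OT", "en", 5, 1.005, 0.1)])
        assert exclude_drugs(agg, epsilon=0.01) == {"D1"}
        assert exclude_drugs(agg, epsilon=0.0) == set()


class TestBestModel:
    def test_single_strategy_wins_by_default(self):
        agg = _agg([("D1", "OT", "en", 5, 1.2, 0.4)])
        best = best_model_per_drug(agg)
        assert best.loc[0, "strategy"] == "OT"

    def test_tie_resolved_to_fewer_features(self):
        agg = _agg([
            ("D1", "GW", "en", 17737, 1.2, 0.5),
            ("D1", "OT", "en", 7, 1.1, 0.5),
        ])
        best = best_model_per_drug(agg)
        assert best.loc[0, "strategy"] == "OT"
        assert best.loc[0, "n_features"] == 7

    def test_known_argmax_on_full_grid(self):
        rng = np.random.default_rng(4)
        rows = []
        expected = {}
        strategies = ["GW", "OT", "PG", "OT+S", "PG+S", "GW_SEL_EN", "GW_SEL_RF"]
        for d in range(4):
            rs = rng.uniform(-0.2, 0.9, len(strategies))
            for s, r in zip(strategies, rs):
                rows.append((f"D{d}", s, "en", 10, 1.1, r))
            expected[f"D{d}"] = strategies[int(np.argmax(rs))]
        best = best_model_per_drug(_agg(rows)).set_index("drug_id")
        for d, s in expected.items():
            assert best.loc[d, "strategy"] == s

    def test_invariant_to_record_order(self):
        rows = [
            ("D1", "GW", "en", 100, 1.2, 0.3),
            ("D1", "OT", "rf", 5, 1.4, 0.6),
            ("D2", "PG", "en", 50, 1.0, 0.2),
        ]
        a = best_model_per_drug(_agg(rows))
        b = best_model_per_drug(_agg(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)


def exact_mww_p(x, y):
    """One-sided p by exhaustive enumeration of group assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        gx = [pooled[i] for i in comb]
        gy = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = sum(1 for a in gx for b in gy if a > b) + 0.5 * sum(
            1 for a in gx for b in gy if a == b
        )
        count += u >= u_obs
        total += 1
    return count / total


class TestPathwayComparison:
    def _annotations(self, mapping):
        return [
            DrugAnnotation(d, frozenset({"G"}), pathway) for d, pathway in mapping.items()
        ]

    def _records(self, values):
        # values: drug -> (gw_r, bio_r)
        rows = []
        for d, (gw, bio) in values.items():
            rows.append((d, "GW", "en", 100, 1.2, gw))
            rows.append((d, "OT", "en", 5, 1.2, bio))
        return _agg(rows)

    def test_identical_groups_not_significant(self):
        values = {f"D{i}": (0.5, 0.5) for i in range(6)}
        annots = self._annotations({f"D{i}": "P1" for i in range(6)})
        out = pathway_comparison(self._records(values), annots)
        assert out.loc[0, "p_value"] >= 0.5

    def test_three_vs_three_matches_exhaustive_enumeration(self):
        gw = [0.8, 0.7, 0.65]
        bio = [0.5, 0.45, 0.6]
        values = {f"D{i}": (g, b) for i, (g, b) in enumerate(zip(gw, bio))}
        annots = self._annotations({f"D{i}": "P1" for i in range(3)})
        out = pathway_comparison(self._records(values), annots)
        assert out.loc[0, "direction"] == "gw"
        assert out.loc[0, "p_value"] == pytest.approx(exact_mww_p(gw, bio))

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        bio = rng.normal(0.3, 0.05, 10)
        gw = bio + 0.3
        values = {f"D{i}": (g, b) for i, (g, b) in enumerate(zip(gw, bio))}
        annots = self._annotations({f"D{i}": "P1" for i in range(10)})
        out = pathway_comparison(self._records(values), annots)
        assert out.loc[0, "direction"] == "gw"
        assert out.loc[0, "p_value"] < 0.05

    def test_excluded_drugs_left_out_and_small_pathways_skipped(self):
        values = {f"D{i}": (0.5, 0.4) for i in range(4)}
        mapping = {"D0": "P1", "D1": "P1", "D2": "P1", "D3": "P2"}
        out = pathway_comparison(
            self._records(values), self._annotations(mapping), excluded={"D0"}
        )
        assert list(out["target_pathway"]) == ["P1"]  # P2 has a single drug
        assert out.loc[0, "n_drugs"] == 2

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for trial in range(200):
            vals = rng.normal(0.5, 0.1, 12)
            values = {f"D{i}": (vals[i], vals[i + 6]) for i in range(6)}
            annots = self._annotations({f"D{i}": "P1" for i in range(6)})
            out = pathway_comparison(self._records(values), annots)
            ps.append(out.loc[0, "p_value"])
        # one-sided tests in the data-chosen direction stack near the middle/upper
        # range; just require no spurious excess of small p-values
        assert np.mean(np.array(ps) < 0.05) < 0.12


class TestFeatureTypeFrequencies:
    def _model(self, drug, effects, types, strategy="OT"):
        return {
            "drug_id": drug,
            "strategy": strategy,
            "model_family": "en",
            "effects": pd.Series(effects),
            "types": pd.Series(types),
        }

    def test_mutation_dominates_k1_by_construction(self):
        models = [
            self._model(f"D{i}", {"m": 1.0, "e": 0.5}, {"m": "mutation", "e": "expression"})
            for i in range(3)
        ]
        agg = _agg([(f"D{i}", "OT", "en", 2, 1.2, 0.5) for i in range(3)])
        freq = feature_type_frequencies(models, agg, top_drugs=3, k_values=(1,))
        assert freq.loc[1, "mutation"] == 1.0

    def test_frequencies_sum_to_one_for_every_k(self):
        rng = np.random.default_rng(7)
        models = []
        for i in range(5):
            cols = {f"c{j}": rng.random() for j in range(8)}
            types = {
                f"c{j}": ["expression", "mutation", "cnv", "tissue"][j % 4] for j in range(8)
            }
            models.append(self._model(f"D{i}", cols, types))
        agg = _agg([(f"D{i}", "OT", "en", 8, 1.2, 0.5) for i in range(5)])
        freq = feature_type_frequencies(models, agg, top_drugs=5, k_values=(1, 3, 8))
        np.testing.assert_allclose(freq.sum(axis=1), 1.0, atol=1e-12)

    def test_k_beyond_model_size_uses_all_features(self):
        models = [self._model("D0", {"a": 1.0, "b": 0.1}, {"a": "expression", "b": "mutation"})]
        agg = _agg([("D0", "OT", "en", 2, 1.2, 0.5)])
        freq = feature_type_frequencies(models, agg, top_drugs=1, k_values=(10,))
        assert freq.loc[10, "expression"] == 0.5
        assert freq.loc[10, "mutation"] == 0.5

    def test_only_top_drugs_contribute(self):
        models = [
            self._model("GOOD", {"m": 1.0}, {"m": "mutation"}),
            self._model("BAD", {"e": 1.0}, {"e": "expression"}),
        ]
        agg = _agg([
            ("GOOD", "OT", "en", 1, 1.5, 0.9),
            ("BAD", "OT", "en", 1, 1.0, 0.1),
        ])
        freq = feature_type_frequencies(models, agg, top_drugs=1, k_values=(1,))
        assert freq.loc[1, "mutation"] == 1.0
        assert "expression" not in freq.columns or freq.loc[1, "expression"] == 0.0


class TestAggregation:
    def test_mean_over_repetitions(self):
        rows = [
            dict(drug_id="D1", strategy="OT", model_family="en", repetition=r,
                 n_samples=50, n_features=5, rmse=0.1 + r * 0.01,
                 rel_rmse=1.0 + r * 0.1, pearson_r=0.4 + r * 0.1, p_value=0.01)
            for r in range(5)
        ]
        agg = aggregate_records(records_frame(rows))
        assert len(agg) == 1
        assert agg.loc[0, "rel_rmse"] == pytest.approx(1.2)
        assert agg.loc[0, "pearson_r"] == pytest.approx(0.6)
        assert agg.loc[0, "n_repetitions"] == 5
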