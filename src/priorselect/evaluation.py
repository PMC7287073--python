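"""Evaluation metrics and comparative analyses.

The central metric is the **relative root mean squared error**,

    RelRMSE = RMSE_dummy / RMSE_model,

where the dummy predictor always outputs the training-set mean response.  A
score of 1 means the model learned nothing beyond the mean; larger is
better.  Unlike raw RMSE, RelRMSE is comparable across drugs with very
different response spreads.  Model agreement with the held-out responses is
additionally summarized by the Pearson correlation with a two-sided t-based
p-value.

On top of the per-fit metrics this module implements the study-level
procedures: averaging over repetitions, excluding drugs whose best model
never beats the dummy baseline, picking each drug's best model by
correlation, comparing genome-wide versus biologically driven strategies
within each target-pathway class by a one-sided Mann-Whitney-Wilcoxon test,
and tabulating which feature types dominate the top of the effect rankings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import BIO_STRATEGIES, GW_STRATEGIES
from .modeling import FitResult
from .signatures import UndefinedScoreError

__all__ = [
    "rel_rmse",
    "correlation_test",
    "evaluate_fit",
    "records_frame",
    "aggregate_records",
    "exclude_drugs",
    "best_model_per_drug",
    "pathway_comparison",
    "feature_type_frequencies",
]

RECORD_COLUMNS = [
    "drug_id", "strategy", "model_family", "repetition",
    "n_samples", "n_features", "rmse", "rel_rmse", "pearson_r", "p_value",
]


def _rmse(y: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def rel_rmse(y_test, y_pred, y_train_mean: float) -> float:
    """Dummy-over-model RMSE ratio; 1 = no better than the training mean."""
    y = np.asarray(y_test, dtype=float)
    pred = np.asarray(y_pred, dtype=float)
    if y.size == 0:
        raise ValueError("empty test set")
    rmse_dummy = _rmse(y, np.full_like(y, y_train_mean))
    rmse_model = _rmse(y, pred)
    if rmse_model == 0:
        if rmse_dummy == 0:
            raise UndefinedScoreError("both model and dummy are perfect; RelRMSE undefined")
        warnings.warn("perfect model predictions; RelRMSE is infinite")
        return math.inf
    return rmse_dummy / rmse_model


def correlation_test(y_test, y_pred) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t-distribution on n-2 df."""
    y = np.asarray(y_test, dtype=float)
    pred = np.asarray(y_pred, dtype=float)
    if y.size < 3:
        raise ValueError("correlation test requires at least 3 samples")
    if y.std() == 0 or pred.std() == 0:
        raise UndefinedScoreError("zero variance in test responses or predictions")
    r, p = stats.pearsonr(y, pred)
    return float(r), float(p)


def evaluate_fit(fit: FitResult, y_test: pd.Series, drug_id: str, strategy: str, repetition: int) -> dict:
    """One evaluation record for a single repetition's fit."""
    y = y_test.loc[fit.predictions.index]
    try:
        r, p = correlation_test(y, fit.predictions)
    except (UndefinedScoreError, ValueError):
        r, p = np.nan, np.nan
    return {
        "drug_id": drug_id,
        "strategy": strategy,
        "model_family": fit.model_family,
        "repetition": repetition,
        "n_samples": len(fit.train_ids) + len(fit.test_ids),
        "n_features": int(len(fit.feature_effects)) if fit.selection is None else int(fit.selection.k),
        "rmse": _rmse(y.to_numpy(dtype=float), fit.predictions.to_numpy()),
        "rel_rmse": rel_rmse(y, fit.predictions, fit.y_train_mean),
        "pearson_r": r,
        "p_value": p,
    }


def records_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Mean over repetitions per (drug, strategy, model family)."""
    keys = ["drug_id", "strategy", "model_family"]
    agg = (
        records.groupby(keys, as_index=False)
        .agg(
            n_repetitions=("repetition", "size"),
            n_samples=("n_samples", "mean"),
            n_features=("n_features", "mean"),
            rmse=("rmse", "mean"),
            rel_rmse=("rel_rmse", "mean"),
            pearson_r=("pearson_r", "mean"),
            p_value=("p_value", "mean"),
        )
        .sort_values(keys)
        .reset_index(drop=True)
    )
    return agg


def exclude_drugs(aggregated: pd.DataFrame, epsilon: float = 0.01) -> set[str]:
    """Drugs whose best model stays at (or within epsilon of) the dummy baseline.

    A drug is excluded when the maximum over its models of the mean RelRMSE
    is <= 1 + epsilon -- no model meaningfully outperformed predicting the
    training-mean response.
    """
    best = aggregated.groupby("drug_id")["rel_rmse"].max()
    return set(best.index[best <= 1.0 + epsilon])


def best_model_per_drug(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Per drug, the model with the highest mean test correlation.

    Ties are resolved toward the model with fewer features, then by strategy
    name; the result is independent of input row order.
    """
    def pick(group: pd.DataFrame) -> pd.Series:
        g = group.sort_values(
            ["pearson_r", "n_features", "strategy", "model_family"],
            ascending=[False, True, True, True],
        )
        row = g.iloc[0]
        return pd.Series(
            {
                "strategy": row["strategy"],
                "model_family": row["model_family"],
                "pearson_r": row["pearson_r"],
                "rel_rmse": row["rel_rmse"],
                "n_features": row["n_features"],
            }
        )

    out = aggregated.groupby("drug_id").apply(pick, include_groups=False)
    return out.reset_index()


def _group_best(aggregated: pd.DataFrame, strategies) -> pd.Series:
    sub = aggregated[aggregated["strategy"].isin(strategies)]
    return sub.groupby("drug_id")["pearson_r"].max()


def pathway_comparison(
    aggregated: pd.DataFrame,
    annotations,
    excluded: set[str] | None = None,
) -> pd.DataFrame:
    """Genome-wide vs biologically driven performance within each pathway class.

    Per drug the best correlation within the genome-wide group (GW and the
    data-driven selections) and within the biologically driven group (OT, PG
    and their +S variants) is taken; per pathway the two samples are compared
    by a one-sided Mann-Whitney-Wilcoxon test in the direction of the larger
    group median.  Pathways with fewer than two drugs carrying both group
    scores are skipped.
    """
    excluded = excluded or set()
    pathway_of = {a.drug_id: a.target_pathway for a in annotations}
    gw = _group_best(aggregated, GW_STRATEGIES)
    bio = _group_best(aggregated, BIO_STRATEGIES)
    rows = []
    drugs = [d for d in sorted(set(gw.index) & set(bio.index)) if d not in excluded]
    by_pathway: dict[str, list[str]] = {}
    for d in drugs:
        if d in pathway_of:
            by_pathway.setdefault(pathway_of[d], []).append(d)
    for pathway in sorted(by_pathway):
        members = by_pathway[pathway]
        if len(members) < 2:
            continue
        gw_vals = gw.loc[members].to_numpy(dtype=float)
        bio_vals = bio.loc[members].to_numpy(dtype=float)
        med_gw, med_bio = float(np.median(gw_vals)), float(np.median(bio_vals))
        direction = "gw" if med_gw >= med_bio else "bio"
        if direction == "gw":
            stat, p = stats.mannwhitneyu(gw_vals, bio_vals, alternative="greater")
        else:
            stat, p = stats.mannwhitneyu(bio_vals, gw_vals, alternative="greater")
        rows.append(
            {
                "target_pathway": pathway,
                "n_drugs": len(members),
                "median_gw": med_gw,
                "median_bio": med_bio,
                "direction": direction,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["target_pathway", "n_drugs", "median_gw", "median_bio", "direction", "p_value"],
    )


def feature_type_frequencies(
    model_effects: list[dict],
    aggregated: pd.DataFrame,
    top_drugs: int = 50,
    k_values: tuple[int, ...] = (1, 5, 10),
) -> pd.DataFrame:
    """Share of each feature type among every model's top-k effects.

    ``model_effects`` holds dicts with keys ``drug_id``, ``strategy``,
    ``model_family``, ``effects`` (Series per feature column) and ``types``
    (Series mapping feature column to its type).  Only biologically driven
    models of the ``top_drugs`` best-performing drugs (by their best
    biologically driven correlation) contribute.  Rows are k values, columns
    feature types; every row sums to 1.
    """
    bio_best = _group_best(aggregated, BIO_STRATEGIES).sort_values(ascending=False)
    chosen = set(bio_best.index[:top_drugs])
    counts: dict[int, dict[str, int]] = {k: {} for k in k_values}
    for entry in model_effects:
        if entry["drug_id"] not in chosen or entry["strategy"] not in BIO_STRATEGIES:
            continue
        effects: pd.Series = entry["effects"]
        types: pd.Series = entry["types"]
        order = effects.sort_values(ascending=False).index
        for k in k_values:
            for col in order[: min(k, len(order))]:
                t = types.loc[col]
                counts[k][t] = counts[k].get(t, 0) + 1
    all_types = sorted({t for d in counts.values() for t in d})
    rows = []
    for k in k_values:
        total = sum(counts[k].values())
        rows.append(
            {"k": k, **{t: (counts[k].get(t, 0) / total if total else np.nan) for t in all_types}}
        )
    return pd.DataFrame(rows).set_index("k")
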