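"""Per-drug model fitting under a repeated train/test protocol.

For every (drug, feature-set strategy, model family) the data are split into
training and test sets (30% test by default), hyperparameters are tuned by
3-fold cross-validation on the training set minimizing mean squared error,
the tuned model is refit on the full training set and evaluated on the held
-out test set, and the whole procedure is repeated (5 times by default) with
different splits.  For the data-driven strategies, feature ranking and the
choice of k are nested inside each repetition's training partition, so no
test-set information leaks into selection.

Feature effects are exported per fit: absolute coefficients on the
standardized scale for the elastic net, impurity importances for the random
forest -- the two are used interchangeably downstream when ranking features
within a model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import GridSearchCV, KFold

from .datatypes import DrugAnnotation, FeatureMatrix, GeneSetCollection, OmicsDataset
from .features import IneligibleDrug, build_strategy
from .selection import choose_k, forest_importance_select, stability_select
from .signatures import SignatureScores

__all__ = ["ExperimentProtocol", "FitResult", "split", "fit_en", "fit_rf", "run_drug"]


@dataclass
class ExperimentProtocol:
    """Split/CV/tuning protocol plus the hyperparameter grids.

    Defaults: 30% of samples held out for testing, 3-fold CV for tuning by
    MSE, five repetitions with different splits.  Grids: elastic-net mixing
    parameter over {0.1, ..., 1.0} with 30 log-spaced penalty strengths;
    random forest with 500 trees and a grid over depth and features per
    split.  All grid sizes are configurable.
    """

    test_fraction: float = 0.3
    cv_folds: int = 3
    n_repetitions: int = 5
    seed: int = 0
    en_l1_ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    en_n_alphas: int = 30
    rf_n_estimators: int = 500
    rf_max_depth_grid: tuple = (None, 10, 20)
    rf_max_features_grid: tuple = ("sqrt", 0.33, 1.0)
    # GW_SEL settings
    sel_n_subsamples: int = 50
    sel_k_grid: tuple[int, ...] = (10, 30, 70, 150, 500)
    sel_choose_k: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be at least 1")


@dataclass
class FitResult:
    model_family: str  # en | rf
    hyperparameters: dict
    predictions: pd.Series  # indexed by test sample ids, AUC units
    feature_effects: pd.Series  # per input feature column
    train_ids: list[str]
    test_ids: list[str]
    y_train_mean: float
    selection: object | None = None  # SelectionResult for GW_SEL fits


def _rep_seed(seed: int, repetition_index: int) -> int:
    # stable per-repetition substream, kept within int32 range
    return int(np.random.SeedSequence([seed, repetition_index]).generate_state(1)[0] % (2**31 - 1))


def split(sample_ids, protocol: ExperimentProtocol, repetition_index: int) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/test split, deterministic per repetition."""
    ids = list(sample_ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    n_test = int(round(protocol.test_fraction * n))
    rng = np.random.default_rng(_rep_seed(protocol.seed, repetition_index))
    perm = rng.permutation(n)
    test = sorted(ids[i] for i in perm[:n_test])
    train = sorted(ids[i] for i in perm[n_test:])
    return train, test


def _is_binary(col: np.ndarray) -> bool:
    return bool(np.isin(col, (0.0, 1.0)).all())


class _Standardizer:
    """Z-scores continuous columns with training statistics; binary kept 0/1."""

    def __init__(self, X_train: pd.DataFrame):
        arr = X_train.to_numpy(dtype=float)
        self.continuous = np.array([not _is_binary(arr[:, j]) for j in range(arr.shape[1])])
        self.mu = arr.mean(axis=0)
        self.sd = arr.std(axis=0)
        self.keep = ~((self.sd == 0) & self.continuous) & ~(
            (arr == arr[0]).all(axis=0) & ~self.continuous
        )
        self.columns = X_train.columns

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[self.columns].to_numpy(dtype=float).copy()
        scale = np.where(self.continuous & (self.sd > 0), self.sd, 1.0)
        center = np.where(self.continuous, self.mu, 0.0)
        arr = (arr - center) / scale
        return arr[:, self.keep]


def fit_en(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    protocol: ExperimentProtocol,
    seed: int = 0,
) -> FitResult:
    """Tune and fit an elastic net; effects are |standardized coefficients|."""
    y = np.asarray(y_train, dtype=float)
    if y.std() == 0:
        raise ValueError("constant training response; elastic net undefined")
    std = _Standardizer(X_train)
    dropped = int((~std.keep).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} constant feature column(s)")
    Xt = std.transform(X_train)
    cv = KFold(n_splits=protocol.cv_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=list(protocol.en_l1_ratios),
        alphas=protocol.en_n_alphas,
        cv=cv,
        random_state=seed,
        n_jobs=1,
        max_iter=2000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xt, y)
    preds = model.predict(std.transform(X_test))
    effects = pd.Series(0.0, index=X_train.columns)
    effects.loc[std.columns[std.keep]] = np.abs(model.coef_)
    return FitResult(
        model_family="en",
        hyperparameters={"l1_ratio": float(model.l1_ratio_), "alpha": float(model.alpha_)},
        predictions=pd.Series(preds, index=X_test.index),
        feature_effects=effects,
        train_ids=list(X_train.index),
        test_ids=list(X_test.index),
        y_train_mean=float(y.mean()),
    )


def fit_rf(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    protocol: ExperimentProtocol,
    seed: int = 0,
) -> FitResult:
    """Tune (depth, features-per-split) and fit a random forest."""
    y = np.asarray(y_train, dtype=float)
    if y.std() == 0:
        raise ValueError("constant training response; random forest undefined")
    grid = {
        "max_depth": list(protocol.rf_max_depth_grid),
        "max_features": [
            mf if not isinstance(mf, float) or mf < 1 else None
            for mf in protocol.rf_max_features_grid
        ],
    }
    cv = KFold(n_splits=protocol.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestRegressor(
            n_estimators=protocol.rf_n_estimators, random_state=seed, n_jobs=1
        ),
        grid,
        cv=cv,
        scoring="neg_mean_squared_error",
        n_jobs=1,
    )
    Xt = X_train.to_numpy(dtype=float)
    search.fit(Xt, y)
    model = search.best_estimator_
    preds = model.predict(X_test[X_train.columns].to_numpy(dtype=float))
    return FitResult(
        model_family="rf",
        hyperparameters=dict(search.best_params_),
        predictions=pd.Series(preds, index=X_test.index),
        feature_effects=pd.Series(model.feature_importances_, index=X_train.columns),
        train_ids=list(X_train.index),
        test_ids=list(X_test.index),
        y_train_mean=float(y.mean()),
    )


def run_drug(
    drug: DrugAnnotation,
    strategy: str,
    data: OmicsDataset,
    responses,
    protocol: ExperimentProtocol,
    model_family: str = "en",
    pathways: GeneSetCollection | None = None,
    signature_scores: SignatureScores | None = None,
) -> list[FitResult] | IneligibleDrug:
    """Run the full repeated protocol for one (drug, strategy, family).

    ``GW_SEL_EN`` / ``GW_SEL_RF`` force their own model family and perform
    feature ranking plus the choice of k on each repetition's training
    partition only.
    """
    if strategy == "GW_SEL_EN":
        model_family = "en"
    elif strategy == "GW_SEL_RF":
        model_family = "rf"
    if model_family not in ("en", "rf"):
        raise ValueError("model_family must be 'en' or 'rf'")

    y_all = responses.for_drug(drug.drug_id) if hasattr(responses, "for_drug") else responses
    matrix = build_strategy(
        strategy, drug, data,
        pathways=pathways, signature_scores=signature_scores, response=y_all,
    )
    if isinstance(matrix, IneligibleDrug):
        return matrix
    if len(matrix.sample_ids) < 10:
        return IneligibleDrug(drug.drug_id, strategy, "fewer than 10 samples with data and response")

    y = y_all.loc[matrix.sample_ids]
    results: list[FitResult] = []
    for rep in range(protocol.n_repetitions):
        train, test = split(matrix.sample_ids, protocol, rep)
        rep_seed = _rep_seed(protocol.seed, rep)
        X_train = matrix.values.loc[train]
        X_test = matrix.values.loc[test]
        y_train = y.loc[train]
        selection = None
        if strategy in ("GW_SEL_EN", "GW_SEL_RF"):
            if strategy == "GW_SEL_EN":
                selection = stability_select(
                    X_train, y_train,
                    n_subsamples=protocol.sel_n_subsamples, seed=rep_seed,
                )
            else:
                selection = forest_importance_select(
                    X_train, y_train,
                    n_trees=min(protocol.rf_n_estimators, 200), seed=rep_seed,
                )
            k_grid = [k for k in protocol.sel_k_grid if k <= X_train.shape[1]]
            if protocol.sel_choose_k and len(k_grid) > 1:
                selection = choose_k(
                    selection, X_train, y_train, k_grid,
                    model_family=model_family,
                    cv_folds=protocol.cv_folds, seed=rep_seed,
                )
            else:
                selection.k = k_grid[-1] if k_grid else X_train.shape[1]
            cols = selection.top()
            X_train, X_test = X_train[cols], X_test[cols]
        fitter = fit_en if model_family == "en" else fit_rf
        result = fitter(X_train, y_train, X_test, protocol, seed=rep_seed)
        result.selection = selection
        results.append(result)
    return results
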