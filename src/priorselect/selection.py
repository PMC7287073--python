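"""Data-driven feature selection on genome-wide expression.

Two ranking mechanisms feed the ``GW_SEL_*`` strategies:

* **Stability selection** -- lasso fits on many random half-subsamples of the
  training data over a grid of penalty strengths; a feature's score is the
  highest fraction of subsamples, over the penalty grid, in which its lasso
  coefficient is nonzero.  Robust predictors are selected often regardless of
  the particular subsample.
* **Forest-importance ranking** -- mean impurity-decrease importances from a
  random-forest regressor fit once on the training data.

Either ranking is then truncated at ``k`` features, with ``k`` chosen by
inner cross-validated mean squared error of the downstream model family over
a candidate grid (ties resolved toward the smaller, more parsimonious ``k``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, lasso_path
from sklearn.model_selection import KFold, cross_val_score

__all__ = ["SelectionResult", "stability_select", "forest_importance_select", "choose_k"]


@dataclass
class SelectionResult:
    """A ranked feature list with per-feature scores and a chosen cutoff k."""

    ranked_features: list[str]
    scores: pd.Series  # indexed by feature, non-increasing along ranked_features
    method: str  # stability | forest_importance
    k: int | None = None

    def top(self, k: int | None = None) -> list[str]:
        k = self.k if k is None else k
        if k is None:
            raise ValueError("no k chosen; pass one explicitly")
        return self.ranked_features[: min(k, len(self.ranked_features))]


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if hasattr(X, "values") and hasattr(X, "feature_meta"):  # FeatureMatrix
        df = X.values
    else:
        df = pd.DataFrame(X)
    names = [str(c) for c in df.columns]
    yv = np.asarray(y, dtype=float).ravel()
    if yv.std() == 0:
        raise ValueError("response has zero variance; selection is undefined")
    return df.to_numpy(dtype=float), yv, names


def _rank(primary: np.ndarray, secondary: np.ndarray, names: list[str]) -> list[int]:
    """Order by primary desc, then secondary desc, then name ascending."""
    order = sorted(
        range(len(names)), key=lambda j: (-primary[j], -secondary[j], names[j])
    )
    return order


def stability_select(
    X,
    y,
    n_subsamples: int = 100,
    alpha_grid: list[float] | None = None,
    subsample_fraction: float = 0.5,
    seed: int = 0,
    with_replacement: bool = False,
    weakness: float = 0.5,
    max_selected: float | None = None,
) -> SelectionResult:
    """Rank features by randomized-lasso selection frequency over subsamples.

    Per subsample (``subsample_fraction`` of the samples, drawn without
    replacement by default) a lasso path is fit over ``alpha_grid`` (default:
    30 log-spaced values below the data's critical penalty) with each
    feature's penalty randomly reweighted by a factor drawn from
    ``[weakness, 1]`` -- the randomization that stops a noise feature which
    happens to correlate with the response in the full data from being
    selected consistently.  A feature's score is the maximum, over the
    penalties whose average model size stays below ``max_selected`` (default
    ``sqrt(0.2 p)``, which bounds the expected number of falsely stable
    features near one at a 0.6 frequency threshold), of its
    nonzero-coefficient frequency.  Ties are broken by mean absolute
    coefficient, then feature id.
    """
    Xv, yv, names = _as_xy(X, y)
    n, p = Xv.shape
    if n < 20:
        raise ValueError("stability selection requires at least 20 samples")
    if not 0 < weakness <= 1:
        raise ValueError("weakness must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    # standardize once so the penalty acts comparably across features
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd
    yc = yv - yv.mean()

    if alpha_grid is None:
        alpha_max = np.max(np.abs(Xs.T @ yc)) / n
        alpha_grid = list(np.geomspace(alpha_max, alpha_max * 1e-2, 30))
    alphas = np.sort(np.asarray(alpha_grid, dtype=float))[::-1]
    if max_selected is None:
        max_selected = math.sqrt(0.2 * p)

    m = max(int(round(subsample_fraction * n)), 2)
    counts = np.zeros((len(alphas), p))
    abs_coef_sum = np.zeros(p)
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=with_replacement)
        W = rng.uniform(weakness, 1.0, size=p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(Xs[idx] * W, yc[idx], alphas=alphas)
        counts += (np.abs(coefs.T) > 1e-12)
        abs_coef_sum += np.abs(coefs).mean(axis=1)

    freq = counts / n_subsamples  # per (alpha, feature)
    # restrict to the penalty region with controlled average model size
    valid = freq.sum(axis=1) <= max_selected
    if not valid.any():
        valid[0] = True  # strongest penalty is the best available fallback
    score = freq[valid].max(axis=0)
    mean_abs = abs_coef_sum / n_subsamples
    if score.max() == 0:
        warnings.warn("all stability scores are zero; ranking by mean |coefficient|")
        order = _rank(mean_abs, np.zeros(p), names)
    else:
        order = _rank(score, mean_abs, names)
    ranked = [names[j] for j in order]
    return SelectionResult(
        ranked_features=ranked,
        scores=pd.Series(score[order], index=ranked),
        method="stability",
    )


def forest_importance_select(
    X, y, n_trees: int = 500, seed: int = 0
) -> SelectionResult:
    """Rank features by random-forest mean impurity-decrease importance."""
    Xv, yv, names = _as_xy(X, y)
    if Xv.shape[0] < 20:
        raise ValueError("forest-importance selection requires at least 20 samples")
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(Xv, yv)
    imp = forest.feature_importances_
    order = _rank(np.round(imp, 12), np.zeros_like(imp), names)
    ranked = [names[j] for j in order]
    return SelectionResult(
        ranked_features=ranked,
        scores=pd.Series(imp[order], index=ranked),
        method="forest_importance",
    )


def choose_k(
    ranked: SelectionResult,
    X,
    y,
    k_grid: list[int],
    model_family: str = "en",
    cv_folds: int = 3,
    seed: int = 0,
) -> SelectionResult:
    """Pick the number of retained features by inner cross-validated MSE.

    For each candidate ``k`` the downstream model family is evaluated by
    ``cv_folds``-fold CV MSE on the top-``k`` features; the smallest ``k``
    among those minimizing the mean CV MSE wins.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    Xv, yv, names = _as_xy(X, y)
    name_pos = {c: j for j, c in enumerate(names)}
    bad = [k for k in k_grid if k > len(ranked.ranked_features)]
    if bad:
        raise ValueError(f"k={bad[0]} exceeds the {len(ranked.ranked_features)} candidates")
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse: dict[int, float] = {}
    for k in sorted(set(k_grid)):
        cols = [name_pos[c] for c in ranked.ranked_features[:k]]
        if model_family == "en":
            model = ElasticNetCV(l1_ratio=[0.5], alphas=20, cv=3, random_state=seed)
        elif model_family == "rf":
            model = RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
        else:
            raise ValueError("model_family must be 'en' or 'rf'")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(
                model, Xv[:, cols], yv, cv=cv, scoring="neg_mean_squared_error"
            )
        mse[k] = float(-scores.mean())
    # MSEs within numerical noise of the minimum count as ties -> smallest k
    floor = min(mse.values())
    tol = abs(floor) * 1e-9 + 1e-15
    best = min(k for k in mse if mse[k] <= floor + tol)
    return SelectionResult(
        ranked_features=ranked.ranked_features,
        scores=ranked.scores,
        method=ranked.method,
        k=best,
    )
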