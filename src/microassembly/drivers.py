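"""Rank environmental predictors of community composition.

Composition is encoded as the first principal coordinate of the Bray-Curtis
ordination; predictors are ranked by out-of-bag permutation importance from a
bootstrap ensemble of regression trees (each split drawn from a random subset
of ceil(p/3) predictors, the regression convention of the randomForest
literature).  Importance is the mean increase in out-of-bag MSE when the
predictor's values are permuted, so it is in response-variance units and can
be negative for uninformative predictors.

The ensemble loop is authored here so that importance is genuinely
out-of-bag (each tree is scored only on the samples left out of its
bootstrap); individual trees are scikit-learn ``DecisionTreeRegressor``s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .matrix import CommunityMatrix
from .diversity import bray_curtis, pcoa

__all__ = [
    "composition_response",
    "rf_importance",
    "rf_importance_multiaxis",
    "ImportanceResult",
]


def composition_response(matrix: CommunityMatrix, orient_by=None) -> pd.Series:
    """Axis-1 PCoA scores of the Bray-Curtis ordination, one value per sample.

    The axis sign is arbitrary; if ``orient_by`` (a per-sample covariate,
    e.g. the aridity index) is given, the sign is fixed so the response
    correlates positively with it.
    """
    if matrix.n_samples < 10:
        raise ValueError("need >= 10 samples for a composition response")
    ord_res = pcoa(bray_curtis(matrix), n_axes=1)
    if ord_res.eigenvalues[0] <= 0:
        raise ValueError("degenerate ordination: first eigenvalue is not positive")
    response = ord_res.coordinates["PCo1"]
    if orient_by is not None:
        ref = np.asarray(pd.Series(orient_by).reindex(response.index)
                         if isinstance(orient_by, pd.Series) else orient_by, dtype=float)
        if np.corrcoef(response.to_numpy(), ref)[0, 1] < 0:
            response = -response
    return response


@dataclass
class ImportanceResult:
    """Predictor importances with ranks; rank 1 = most important."""

    table: pd.DataFrame  # predictor, importance, rank [, p_perm]
    model_r2: float      # out-of-bag R^2 of the unpermuted ensemble
    n_trees: int
    seed: int
    null_importances: pd.DataFrame | None = None  # response-permutation nulls

    def top_predictor(self) -> str:
        return self.table.sort_values("rank").iloc[0]["predictor"]


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, max_features: int,
                rng: np.random.Generator):
    """Bootstrap trees plus their out-of-bag index sets."""
    n = len(y)
    trees, oob_sets = [], []
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=max_features, random_state=int(rng.integers(2**31))
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oob_sets.append(oob)
    return trees, oob_sets


def _oob_importance(trees, oob_sets, X: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator):
    """Mean OOB MSE increase per predictor, plus ensemble OOB R^2.

    Each predictor gets its own permutation stream (drawn up front per
    predictor, shared across trees) so the ranking does not depend on
    predictor column order.
    """
    n, p = X.shape
    base_mse = np.empty(len(trees))
    oob_pred_sum = np.zeros(n)
    oob_pred_cnt = np.zeros(n)
    for t, (tree, oob) in enumerate(zip(trees, oob_sets)):
        if len(oob) == 0:
            base_mse[t] = np.nan
            continue
        pred = tree.predict(X[oob])
        base_mse[t] = ((y[oob] - pred) ** 2).mean()
        oob_pred_sum[oob] += pred
        oob_pred_cnt[oob] += 1

    # per-predictor seeded permutation streams, independent of column order
    perm_rngs = [np.random.default_rng(rng.integers(2**31)) for _ in range(p)]
    increases = np.zeros(p)
    for j in range(p):
        prng = perm_rngs[j]
        deltas = []
        for t, (tree, oob) in enumerate(zip(trees, oob_sets)):
            if len(oob) == 0:
                continue
            Xp = X[oob].copy()
            Xp[:, j] = Xp[prng.permutation(len(oob)), j]
            mse_perm = ((y[oob] - tree.predict(Xp)) ** 2).mean()
            deltas.append(mse_perm - base_mse[t])
        increases[j] = float(np.mean(deltas))

    seen = oob_pred_cnt > 0
    oob_pred = oob_pred_sum[seen] / oob_pred_cnt[seen]
    ss_res = ((y[seen] - oob_pred) ** 2).sum()
    ss_tot = ((y[seen] - y[seen].mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return increases, float(r2)


def rf_importance(
    response,
    predictors: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    n_response_permutations: int = 0,
) -> ImportanceResult:
    """Out-of-bag permutation importance from a bootstrap tree ensemble.

    ``n_response_permutations`` > 0 additionally fits ensembles to permuted
    responses and reports, per predictor, the fraction of null importances
    at least as large (a permutation p-value).  Deterministic given the seed.
    """
    y = np.asarray(pd.Series(response), dtype=float)
    X_df = predictors.copy()
    if X_df.isna().any().any():
        raise ValueError("predictors contain missing values")
    if len(y) < 10:
        raise ValueError("need >= 10 samples")
    names = list(X_df.columns)
    X = X_df.to_numpy(float)
    p = X.shape[1]
    max_features = max(1, int(np.ceil(p / 3)))

    constant = X.std(axis=0) == 0
    if constant.any():
        import warnings

        warnings.warn(
            f"constant predictor(s) {list(np.array(names)[constant])}: importance 0",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    trees, oob_sets = _fit_forest(X, y, n_trees, max_features, rng)
    importances, r2 = _oob_importance(trees, oob_sets, X, y, rng)
    importances[constant] = 0.0

    table = pd.DataFrame({"predictor": names, "importance": importances})
    table["rank"] = (
        table["importance"].rank(ascending=False, method="first").astype(int)
    )

    null_df = None
    if n_response_permutations > 0:
        null = np.zeros((n_response_permutations, p))
        for b in range(n_response_permutations):
            yb = rng.permutation(y)
            tb, ob = _fit_forest(X, yb, n_trees, max_features, rng)
            null[b], _ = _oob_importance(tb, ob, X, yb, rng)
        p_perm = ((null >= importances[None, :]).sum(axis=0) + 1) / (
            n_response_permutations + 1
        )
        table["p_perm"] = p_perm
        null_df = pd.DataFrame(null, columns=names)

    return ImportanceResult(
        table=table.sort_values("rank").reset_index(drop=True),
        model_r2=r2,
        n_trees=n_trees,
        seed=seed,
        null_importances=null_df,
    )


def rf_importance_multiaxis(
    matrix: CommunityMatrix,
    predictors: pd.DataFrame,
    n_axes: int = 5,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceResult:
    """Importance against the whole ordination, not just axis 1.

    One ensemble is fitted per retained PCoA axis and the per-axis OOB MSE
    increases are summed.  Axis-k scores have variance proportional to the
    k-th eigenvalue, so the plain sum is the increase in squared
    reconstruction error of the embedding — an eigenvalue-weighted
    aggregate.  This keeps the within-group compositional signal that a
    single dominant axis discards, which is what separates the true
    gradient driver from covariates that merely co-vary with the dominant
    split.
    """
    ordi = pcoa(bray_curtis(matrix), n_axes=n_axes)
    n_axes = ordi.coordinates.shape[1]
    total = None
    r2s = []
    for k in range(n_axes):
        res = rf_importance(
            ordi.coordinates.iloc[:, k], predictors, n_trees=n_trees, seed=seed
        )
        imp = res.table.set_index("predictor")["importance"]
        total = imp if total is None else total + imp
        r2s.append(res.model_r2 * ordi.proportion_explained[k])
    table = total.rename("importance").reset_index()
    table["rank"] = (
        table["importance"].rank(ascending=False, method="first").astype(int)
    )
    return ImportanceResult(
        table=table.sort_values("rank").reset_index(drop=True),
        model_r2=float(np.sum(r2s) / ordi.proportion_explained[:n_axes].sum()),
        n_trees=n_trees,
        seed=seed,
    )
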