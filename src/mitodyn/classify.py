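"""Random-forest discrimination of fission versus fusion.

A bagged ensemble of classification trees (default 2,000 trees, 3
candidate features per split) is trained on the 11 per-organelle features.
Out-of-bag (OOB) votes — each tree voting only on the rows absent from its
bootstrap sample — give the misclassification estimate, per-class error
rates, the class-error-versus-forest-size curve, and permutation feature
importance with per-tree spreads: the importance of a feature is the mean
per-tree increase in OOB error after permuting that feature among the
tree's OOB rows, and its SD is the per-tree standard deviation divided by
the square root of the number of trees.  Class priors are taken from the
data as observed (no reweighting), so the majority class is expected to be
predicted better.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import RunConfig
from .morphometry import FEATURE_NAMES

CLASSES = ("fission", "fusion")


@dataclasses.dataclass
class ForestModel:
    """A fitted forest plus everything needed for OOB computations."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    X: np.ndarray  # imputed training matrix
    y: np.ndarray  # 0 = fission, 1 = fusion
    oob_votes: np.ndarray  # (n_samples, 2) accumulated OOB vote counts
    oob_error: float
    class_errors: dict[str, float]
    imputed_medians: dict[str, float]
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.estimator.estimators_)


def _prepare_matrix(features: pd.DataFrame, feature_names: list[str]):
    """Extract X, y from a feature table, imputing missing values with the
    class-agnostic column median."""
    missing_cols = [c for c in feature_names if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns: {missing_cols}")
    X = features[feature_names].to_numpy(dtype=float).copy()
    medians: dict[str, float] = {}
    for k, name in enumerate(feature_names):
        bad = ~np.isfinite(X[:, k])
        if bad.any():
            med = float(np.nanmedian(np.where(np.isfinite(X[:, k]), X[:, k], np.nan)))
            X[bad, k] = med
            medians[name] = med
    y = features["call"].map({"fission": 0, "fusion": 1}).to_numpy()
    if np.any(pd.isna(y)):
        raise ValueError("call column must contain only 'fission'/'fusion'")
    return X, y.astype(int), medians


def _oob_masks(model_or_estimator, n_samples: int) -> list[np.ndarray]:
    """Boolean OOB mask per tree (rows absent from the tree's bootstrap)."""
    est = (
        model_or_estimator.estimator
        if isinstance(model_or_estimator, ForestModel)
        else model_or_estimator
    )
    masks = []
    for sample_idx in est.estimators_samples_:
        mask = np.ones(n_samples, dtype=bool)
        mask[sample_idx] = False
        masks.append(mask)
    return masks


def _vote_errors(votes: np.ndarray, y: np.ndarray):
    """Overall and per-class error of the OOB majority vote (rows with at
    least one vote; ties go to class 0, matching argmax)."""
    has_vote = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    wrong = (pred != y) & has_vote
    overall = float(wrong.sum() / has_vote.sum()) if has_vote.any() else float("nan")
    per_class = {}
    for c, name in enumerate(CLASSES):
        sel = has_vote & (y == c)
        per_class[name] = float(wrong[sel].sum() / sel.sum()) if sel.any() else float("nan")
    return overall, per_class


def train_forest(features: pd.DataFrame, config: RunConfig | None = None) -> ForestModel:
    """Train the random forest on a feature table with a ``call`` column.

    Requires at least 50 rows and both classes present.  OOB error is the
    misclassification rate of the OOB majority vote — equivalently the
    class-frequency-weighted mean of the class error rates.
    """
    config = config or RunConfig()
    X, y, medians = _prepare_matrix(features, FEATURE_NAMES)
    if len(y) < 50:
        raise ValueError(f"need >= 50 rows to train, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("both fission and fusion examples are required")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("all features are constant")
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.rf_split_candidates,
        bootstrap=True,
        random_state=config.random_seed,
        n_jobs=1,
    )
    est.fit(X, y)
    votes = np.zeros((len(y), 2), dtype=np.int64)
    for tree, oob in zip(est.estimators_, _oob_masks(est, len(y))):
        if oob.any():
            pred = tree.predict(X[oob]).astype(int)
            np.add.at(votes, (np.flatnonzero(oob), pred), 1)
    overall, per_class = _vote_errors(votes, y)
    return ForestModel(
        estimator=est,
        feature_names=list(FEATURE_NAMES),
        X=X,
        y=y,
        oob_votes=votes,
        oob_error=overall,
        class_errors=per_class,
        imputed_medians=medians,
        seed=config.random_seed,
    )


def _tree_errors(tree, X, y, oob):
    """(overall, fission, fusion) error of one tree on its OOB rows."""
    pred = tree.predict(X[oob]).astype(int)
    yo = y[oob]
    out = [float(np.mean(pred != yo))]
    for c in (0, 1):
        sel = yo == c
        out.append(float(np.mean(pred[sel] != yo[sel])) if sel.any() else np.nan)
    return out


def importance_ranking(
    model: ForestModel, method: str = "permutation"
) -> pd.DataFrame:
    """Permutation feature importance with per-tree SDs, overall and per
    true class, ranked by overall importance.

    For each tree and each feature, the feature's values are permuted
    among the tree's OOB rows and the increase in that tree's OOB error is
    recorded; the importance is the mean increase over trees and the SD is
    the per-tree standard deviation scaled by 1/sqrt(n_trees).  The
    class-conditional columns restrict the error to rows of that true
    class.  ``method="refit"`` instead refits one forest per dropped
    feature and reports the increase in ensemble OOB error (no per-tree
    SD is defined for the ensemble statistic; SDs are reported as NaN).
    """
    names = model.feature_names
    if method == "refit":
        return _refit_importance(model)
    if method != "permutation":
        raise ValueError(f"unknown importance method {method!r}")
    X, y = model.X, model.y
    n_features = len(names)
    rng = np.random.default_rng(model.seed)
    masks = _oob_masks(model, len(y))
    deltas = np.full((model.n_trees, n_features, 3), np.nan)
    for t, (tree, oob) in enumerate(zip(model.estimator.estimators_, masks)):
        if not oob.any():
            continue
        base = _tree_errors(tree, X, y, oob)
        idx = np.flatnonzero(oob)
        for k in range(n_features):
            Xp = X[oob].copy()
            Xp[:, k] = Xp[rng.permutation(len(idx)), k]
            pred = tree.predict(Xp).astype(int)
            yo = y[oob]
            err = [float(np.mean(pred != yo))]
            for c in (0, 1):
                sel = yo == c
                err.append(float(np.mean(pred[sel] != yo[sel])) if sel.any() else np.nan)
            deltas[t, k, :] = np.asarray(err) - np.asarray(base)
    mean = np.nanmean(deltas, axis=0)
    sd = np.nanstd(deltas, axis=0, ddof=1) / np.sqrt(model.n_trees)
    table = pd.DataFrame(
        {
            "feature": names,
            "importance_all": mean[:, 0],
            "sd_all": sd[:, 0],
            "importance_fission": mean[:, 1],
            "sd_fission": sd[:, 1],
            "importance_fusion": mean[:, 2],
            "sd_fusion": sd[:, 2],
        }
    )
    table = table.sort_values("importance_all", ascending=False, kind="stable")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.reset_index(drop=True)


def _refit_importance(model: ForestModel) -> pd.DataFrame:
    """Drop-one-feature refit variant of the importance ranking."""
    names = model.feature_names
    rows = []
    for k, name in enumerate(names):
        keep = [i for i in range(len(names)) if i != k]
        est = RandomForestClassifier(
            n_estimators=model.n_trees,
            max_features=min(model.estimator.max_features, len(keep)),
            bootstrap=True,
            random_state=model.seed,
            n_jobs=1,
        )
        est.fit(model.X[:, keep], model.y)
        votes = np.zeros((len(model.y), 2), dtype=np.int64)
        for tree, oob in zip(est.estimators_, _oob_masks(est, len(model.y))):
            if oob.any():
                pred = tree.predict(model.X[oob][:, keep]).astype(int)
                np.add.at(votes, (np.flatnonzero(oob), pred), 1)
        overall, per_class = _vote_errors(votes, model.y)
        rows.append(
            {
                "feature": name,
                "importance_all": overall - model.oob_error,
                "sd_all": np.nan,
                "importance_fission": per_class["fission"] - model.class_errors["fission"],
                "sd_fission": np.nan,
                "importance_fusion": per_class["fusion"] - model.class_errors["fusion"],
                "sd_fusion": np.nan,
            }
        )
    table = pd.DataFrame(rows).sort_values("importance_all", ascending=False, kind="stable")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.reset_index(drop=True)


def class_error_curve(
    model: ForestModel, checkpoints: list[int] | None = None
) -> pd.DataFrame:
    """Per-class OOB error of nested sub-ensembles of increasing size.

    Trees are accumulated in training order; at each checkpoint the
    majority OOB vote over the trees so far is evaluated on rows with at
    least one vote.  The final row reproduces the fitted model's class
    errors exactly.
    """
    n = len(model.y)
    if checkpoints is None:
        checkpoints = sorted(
            {1, 2, 3, 5, 10, 25, 50, 100, 250, 500, 1000, model.n_trees} & set(range(1, model.n_trees + 1))
            | {model.n_trees}
        )
    votes = np.zeros((n, 2), dtype=np.int64)
    masks = _oob_masks(model, n)
    rows = []
    cps = set(checkpoints)
    for t, (tree, oob) in enumerate(zip(model.estimator.estimators_, masks), start=1):
        if oob.any():
            pred = tree.predict(model.X[oob]).astype(int)
            np.add.at(votes, (np.flatnonzero(oob), pred), 1)
        if t in cps:
            _, per_class = _vote_errors(votes, model.y)
            rows.append(
                {
                    "n_trees": t,
                    "fission_error": per_class["fission"],
                    "fusion_error": per_class["fusion"],
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class StumpBoundary:
    """A single-bifurcation decision boundary on one feature."""

    feature: str
    threshold: float
    fission_side: str  # 'above' or 'below'


def stump_boundary(values: np.ndarray, calls: np.ndarray, feature: str = "") -> StumpBoundary:
    """Best single split of one feature by Gini impurity.

    The threshold minimizing the size-weighted Gini impurity over all
    midpoints between consecutive sorted unique values; ties broken toward
    the smaller threshold; the fission side is the side where fission is
    the majority class.
    """
    values = np.asarray(values, dtype=float)
    calls = np.asarray(calls)
    keep = np.isfinite(values)
    values, calls = values[keep], calls[keep]
    y = (calls == "fusion").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("feature is constant")
    order = np.argsort(values, kind="stable")
    vs, ys = values[order], y[order]
    n = len(ys)
    total_pos = ys.sum()
    cum_pos = np.cumsum(ys)
    best = (np.inf, np.inf)  # (gini, threshold)
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    for thr in thresholds:
        n_left = int(np.searchsorted(vs, thr, side="right"))
        pos_left = int(cum_pos[n_left - 1])
        n_right = n - n_left
        pos_right = total_pos - pos_left
        p_l = pos_left / n_left
        p_r = pos_right / n_right
        gini = (n_left * 2 * p_l * (1 - p_l) + n_right * 2 * p_r * (1 - p_r)) / n
        if gini < best[0] - 1e-15:
            best = (gini, float(thr))
    thr = best[1]
    below = values <= thr
    fission_below = np.mean(y[below] == 0)
    fission_above = np.mean(y[~below] == 0)
    side = "below" if fission_below >= fission_above else "above"
    return StumpBoundary(feature, thr, side)
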