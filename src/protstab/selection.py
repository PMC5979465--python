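"""Two-step greedy wrapper feature selection.

Step one runs independently on each cross-validation fold: a random forest
is trained on the current feature set and the least important feature
(impurity-based importance) is removed, one per iteration, until eight
features remain.  Step two merges the five per-fold subsets (order-stable
union) and grows a single subset by greedy forward selection over the full
cross validation, accepting a candidate only while it strictly reduces the
mean CV error rate.

Error rate is 1 − accuracy, i.e. 1 − correct-prediction-ratio for
multi-class tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

#: Forest size used during selection (same as the final model default).
SELECTION_TREES = 300


@dataclass
class TraceStep:
    action: str          # "remove" or "add"
    feature: str
    error: float
    n_features: int


@dataclass
class SelectionTrace:
    steps: list[TraceStep] = field(default_factory=list)
    final_subset: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                  n_jobs=1)


def _error(clf, X, y) -> float:
    return 1.0 - float(clf.score(X, y))


def backward_eliminate(X_train: pd.DataFrame, y_train,
                       X_val: pd.DataFrame, y_val,
                       target_size: int = 8,
                       n_trees: int = SELECTION_TREES,
                       seed: int = 0,
                       keep: str = "terminal"
                       ) -> tuple[list[str], SelectionTrace]:
    """Iteratively drop the least important feature down to ``target_size``.

    Each iteration trains a forest on the surviving features, records the
    validation error, and removes the feature with the smallest importance
    (ties: first in current order).  ``keep='terminal'`` (default) returns
    the final ``target_size`` features; ``keep='best'`` returns the
    intermediate subset with the lowest validation error instead.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    current = list(X_train.columns)
    if len(current) < target_size:
        raise ValueError(
            f"{len(current)} features < target size {target_size}")
    trace = SelectionTrace()
    best_subset, best_err = list(current), np.inf
    while len(current) > target_size:
        clf = _forest(n_trees, seed).fit(X_train[current], y_train)
        err = _error(clf, X_val[current], y_val)
        if err < best_err:
            best_err, best_subset = err, list(current)
        worst = current[int(np.argmin(clf.feature_importances_))]
        trace.steps.append(TraceStep("remove", worst, err, len(current)))
        current.remove(worst)
    # score the terminal subset too, so "best" can pick it
    clf = _forest(n_trees, seed).fit(X_train[current], y_train)
    err = _error(clf, X_val[current], y_val)
    if err < best_err:
        best_err, best_subset = err, list(current)
    subset = list(current) if keep == "terminal" else best_subset
    trace.final_subset = subset
    return subset, trace


def merge_subsets(subsets: list[list[str]]) -> list[str]:
    """Order-stable union of the per-fold subsets, duplicates eliminated."""
    seen: dict[str, None] = {}
    for sub in subsets:
        for f in sub:
            seen.setdefault(f)
    return list(seen)


def _cv_error(X: pd.DataFrame, y, feats: list[str], folds,
              n_trees: int, seed: int) -> float:
    y = np.asarray(y)
    errs = []
    for train_idx, test_idx in folds:
        clf = _forest(n_trees, seed).fit(X.iloc[train_idx][feats],
                                         y[train_idx])
        errs.append(_error(clf, X.iloc[test_idx][feats], y[test_idx]))
    return float(np.mean(errs))


def forward_select(X: pd.DataFrame, y, candidates: list[str], folds,
                   n_trees: int = SELECTION_TREES,
                   seed: int = 0) -> tuple[list[str], SelectionTrace]:
    """Greedy forward selection with a strict-improvement stopping rule.

    Starting from the empty set, every round evaluates each unchosen
    candidate added to the chosen set by mean CV error and accepts the best
    one — but only if it strictly reduces the error of the previous round.
    Ties are broken by candidate order.  The accepted-error sequence is
    therefore strictly decreasing.
    """
    if not candidates:
        raise ValueError("no candidates")
    chosen: list[str] = []
    trace = SelectionTrace()
    current_err = np.inf
    while True:
        best_feat, best_err = None, np.inf
        for feat in candidates:
            if feat in chosen:
                continue
            err = _cv_error(X, y, chosen + [feat], folds, n_trees, seed)
            if err < best_err:
                best_feat, best_err = feat, err
        if best_feat is None or best_err >= current_err:
            break
        chosen.append(best_feat)
        current_err = best_err
        trace.steps.append(TraceStep("add", best_feat, best_err,
                                     len(chosen)))
    trace.final_subset = list(chosen)
    return chosen, trace


def select_features(X: pd.DataFrame, y, folds,
                    target_size: int = 8,
                    n_trees: int = SELECTION_TREES,
                    seed: int = 0,
                    keep: str = "terminal"
                    ) -> tuple[list[str], dict]:
    """The full two-step procedure over a cross-validation plan.

    Per-fold backward elimination to ``target_size`` features, order-stable
    merge, then forward selection over all folds.  Returns the final subset
    and a dict of traces.
    """
    y = np.asarray(y)
    per_fold, traces = [], {}
    for i, (train_idx, test_idx) in enumerate(folds):
        sub, tr = backward_eliminate(
            X.iloc[train_idx], y[train_idx], X.iloc[test_idx], y[test_idx],
            target_size=target_size, n_trees=n_trees, seed=seed, keep=keep)
        per_fold.append(sub)
        traces[f"backward_fold{i + 1}"] = tr
    candidates = merge_subsets(per_fold)
    final, tr = forward_select(X, y, candidates, folds, n_trees=n_trees,
                               seed=seed)
    traces["forward"] = tr
    return final, {"per_fold": per_fold, "candidates": candidates,
                   "traces": traces}
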