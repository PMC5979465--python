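"""Two-layer balanced random-forest cascade for stability classification.

The cascade first decides whether a variant *decreases* stability
(layer 1, decrease vs no-decrease); variants called no-decrease are then
classified as *increase* vs *no_effect* (layer 2).  Each layer is a random
forest (300 trees by default) trained on a class-balanced subsample and
with its own selected feature list.  A variant called decrease by layer 1
is terminal — layer 2 never overrides it.

Follows the Model/Results convention: :class:`StabilityCascade` holds the
data and configuration, ``fit()`` returns a
:class:`StabilityCascadeResults` carrying the trained forests,
out-of-bag diagnostics, feature importances, the imputation medians and a
``summary()`` table; prediction and plotting hang off the results object.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .dataset import DECREASE, INCREASE, LABELS, NO_EFFECT
from .partitioning import balance_binary

DEFAULT_TREES = 300
#: Vote-fraction decision threshold for both layers.
VOTE_THRESHOLD = 0.5

NO_DECREASE = "no_decrease"


def _registry_hash(names) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


class StabilityCascade:
    """Model object: feature table, labels and cascade configuration.

    Parameters
    ----------
    features : DataFrame
        Descriptor matrix, rows = variants.  NaN entries (e.g. masked
        external protein descriptors) are imputed with training medians.
    labels : array-like
        Three-class stability labels (increase / no_effect / decrease).
    features_decrease, features_increase : list of str, optional
        Selected feature names for layer 1 and layer 2; default is all
        columns.
    n_trees : int
        Trees per forest (default 300).
    """

    def __init__(self, features: pd.DataFrame, labels,
                 features_decrease: list[str] | None = None,
                 features_increase: list[str] | None = None,
                 n_trees: int = DEFAULT_TREES,
                 vote_threshold: float = VOTE_THRESHOLD):
        labels = np.asarray(labels)
        if len(labels) != len(features):
            raise ValueError("labels and features differ in length")
        present = set(labels)
        missing = set(LABELS) - present
        if missing:
            raise ValueError(f"missing class(es): {sorted(missing)}")
        self.features = features
        self.labels = labels
        self.features_decrease = list(features_decrease
                                      or features.columns)
        self.features_increase = list(features_increase
                                      or features.columns)
        for fl, name in ((self.features_decrease, "features_decrease"),
                         (self.features_increase, "features_increase")):
            if not fl:
                raise ValueError(f"{name} is empty")
            unknown = set(fl) - set(features.columns)
            if unknown:
                raise ValueError(f"{name} not in table: {sorted(unknown)}")
        self.n_trees = int(n_trees)
        self.vote_threshold = float(vote_threshold)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       **kwargs) -> "StabilityCascade":
        """Build from a single DataFrame holding features plus a label column."""
        meta = [c for c in ("record_id", "protein_id", label_col)
                if c in df.columns]
        features = df.drop(columns=meta)
        return cls(features, df[label_col].to_numpy(), **kwargs)

    def fit(self, seed: int = 0) -> "StabilityCascadeResults":
        """Train both balanced layers; returns a results object."""
        medians = self.features.median(numeric_only=True)
        X = self.features.fillna(medians)

        bal1 = balance_binary(self.labels, "layer1", seed=seed)
        rf1 = RandomForestClassifier(n_estimators=self.n_trees,
                                     random_state=seed, oob_score=True,
                                     n_jobs=1)
        rf1.fit(X.iloc[bal1.indices][self.features_decrease], bal1.y)

        bal2 = balance_binary(self.labels, "layer2", seed=seed + 1)
        rf2 = RandomForestClassifier(n_estimators=self.n_trees,
                                     random_state=seed + 1, oob_score=True,
                                     n_jobs=1)
        rf2.fit(X.iloc[bal2.indices][self.features_increase], bal2.y)

        manifest = {
            "n_trees": self.n_trees,
            "seed": seed,
            "vote_threshold": self.vote_threshold,
            "balancing": {"layer1": bal1.composition,
                          "layer2": bal2.composition,
                          "layer1_resampled": bal1.resampled},
            "features_decrease": self.features_decrease,
            "features_increase": self.features_increase,
            "registry_hash": _registry_hash(self.features.columns),
            "n_training_records": len(self.features),
        }
        return StabilityCascadeResults(
            model=self, layer1=rf1, layer2=rf2,
            imputation_medians=medians, manifest=manifest)


@dataclass
class StabilityCascadeResults:
    """Fitted cascade: trained forests, diagnostics and prediction."""

    model: StabilityCascade
    layer1: RandomForestClassifier
    layer2: RandomForestClassifier
    imputation_medians: pd.Series
    manifest: dict = field(default_factory=dict)

    @property
    def oob_accuracy(self) -> dict[str, float]:
        return {"layer1": float(self.layer1.oob_score_),
                "layer2": float(self.layer2.oob_score_)}

    def feature_importances(self) -> dict[str, pd.Series]:
        return {
            "layer1": pd.Series(self.layer1.feature_importances_,
                                index=self.model.features_decrease
                                ).sort_values(ascending=False),
            "layer2": pd.Series(self.layer2.feature_importances_,
                                index=self.model.features_increase
                                ).sort_values(ascending=False),
        }

    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        needed = set(self.model.features_decrease) | set(
            self.model.features_increase)
        missing = needed - set(X.columns)
        if missing:
            raise ValueError(
                f"missing feature column(s): {sorted(missing)}")
        return X.fillna(self.imputation_medians)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Cascade prediction for a feature table.

        Returns a DataFrame (index preserved) with the final ``label``,
        the layer-1 decrease vote fraction and the layer-2 increase vote
        fraction (layer-2 scores are reported for every row, but only
        decide rows not already called decrease).
        """
        if len(X) == 0:
            return pd.DataFrame(columns=["label", "score_decrease",
                                         "score_increase"], index=X.index)
        Xp = self._prepare(X)
        p1 = self.layer1.predict_proba(Xp[self.model.features_decrease])
        dec_col = list(self.layer1.classes_).index(DECREASE)
        score_dec = p1[:, dec_col]
        p2 = self.layer2.predict_proba(Xp[self.model.features_increase])
        inc_col = list(self.layer2.classes_).index(INCREASE)
        score_inc = p2[:, inc_col]
        thr = self.model.vote_threshold
        labels = np.where(score_dec >= thr, DECREASE,
                          np.where(score_inc >= thr, INCREASE, NO_EFFECT))
        return pd.DataFrame({"label": labels, "score_decrease": score_dec,
                             "score_increase": score_inc}, index=X.index)

    def predict_batch(self, X: pd.DataFrame) -> pd.DataFrame:
        """Row-order-preserving alias of :meth:`predict`."""
        return self.predict(X)

    def summary(self) -> str:
        imp = self.feature_importances()
        lines = [
            "Two-layer stability cascade".center(58),
            "=" * 58,
            f"Training records:      {self.manifest['n_training_records']}",
            f"Trees per forest:      {self.manifest['n_trees']}",
            f"Seed:                  {self.manifest['seed']}",
            f"Vote threshold:        {self.manifest['vote_threshold']}",
            "-" * 58,
            "Layer 1 (decrease vs no-decrease)",
            f"  balanced composition: "
            f"{self.manifest['balancing']['layer1']}",
            f"  out-of-bag accuracy:  {self.layer1.oob_score_:.3f}",
            f"  features ({len(self.model.features_decrease)}), top 5 by "
            f"importance:",
        ]
        for name, v in imp["layer1"].head(5).items():
            lines.append(f"    {name:<32s} {v:.4f}")
        lines += [
            "Layer 2 (increase vs no_effect)",
            f"  balanced composition: "
            f"{self.manifest['balancing']['layer2']}",
            f"  out-of-bag accuracy:  {self.layer2.oob_score_:.3f}",
            f"  features ({len(self.model.features_increase)}), top 5 by "
            f"importance:",
        ]
        for name, v in imp["layer2"].head(5).items():
            lines.append(f"    {name:<32s} {v:.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_importances(self, layer: str = "layer1", top: int = 10,
                         ax=None):
        """Horizontal bar chart of the top forest importances of a layer."""
        import matplotlib.pyplot as plt
        imp = self.feature_importances()[layer].head(top)[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(imp) + 1))
        ax.barh(imp.index, imp.values)
        ax.set_xlabel("impurity importance")
        ax.set_title(f"{layer}: top {len(imp)} features")
        return ax

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path, expected_registry=None) -> "StabilityCascadeResults":
        """Load a saved results object, optionally checking feature order.

        ``expected_registry`` is an iterable of feature names; a hash
        mismatch (feature-order drift) raises at load time.
        """
        res = joblib.load(path)
        if expected_registry is not None:
            if _registry_hash(expected_registry) != res.manifest[
                    "registry_hash"]:
                raise ValueError("feature registry hash mismatch: the "
                                 "model was trained on a different "
                                 "feature order")
        return res
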