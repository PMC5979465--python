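"""Confusion-matrix metrics with class-size normalization.

Binary one-vs-rest measures (accuracy, PPV, NPV, sensitivity, specificity,
MCC), the correct prediction ratio (CPR = trace/N, the multi-class
analogue of accuracy), and the generalized squared correlation

    GC2 = sum_ij (z_ij − e_ij)^2 / (e_ij · N · (K−1)),   e_ij = x_i y_j / N,

a chi-square-based association measure in [0, 1] (for 2×2 matrices with
non-zero margins GC2 equals MCC²).  Because stability classes are heavily
imbalanced (increase : no_effect : decrease ≈ 1 : 2 : 4), metrics are also
reported after *class-size normalization*: each true-class row of the
confusion matrix is rescaled so its total equals the size of a reference
class (the no-effect class), which preserves within-row proportions while
making sensitivities comparable across classes.

Undefined quantities (zero denominators, zero margins) are reported as NaN
and rendered "NA", never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (0.365 → 0.37 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BinaryCounts:
    tp: float
    tn: float
    fp: float
    fn: float

    @property
    def n(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


class ConfusionMatrix:
    """K×K counts, rows = true class, columns = predicted class.

    Counts may be non-integral (e.g. after normalization or per-fold
    averaging).
    """

    def __init__(self, z, classes: list[str]):
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("confusion matrix must be square")
        if z.shape[0] != len(classes):
            raise ValueError("class names do not match matrix size")
        if (z < 0).any():
            raise ValueError("negative counts")
        if z.sum() <= 0:
            raise ValueError("empty confusion matrix")
        self.z = z
        self.classes = list(classes)

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def n(self) -> float:
        return float(self.z.sum())

    @classmethod
    def from_labels(cls, y_true, y_pred,
                    classes: list[str] | None = None) -> "ConfusionMatrix":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(classes)}
        z = np.zeros((len(classes), len(classes)))
        for t, p in zip(y_true, y_pred):
            z[index[t], index[p]] += 1
        return cls(z, classes)

    @classmethod
    def from_tsv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(c) for c in df.columns])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.z, index=self.classes,
                     columns=self.classes).to_csv(path, sep="\t")

    def one_vs_rest(self, cls_name: str) -> BinaryCounts:
        """Collapse to binary counts for one class; conserves N."""
        i = self.classes.index(cls_name)
        tp = self.z[i, i]
        fn = self.z[i].sum() - tp
        fp = self.z[:, i].sum() - tp
        tn = self.n - tp - fn - fp
        return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)

    def cpr(self) -> float:
        """Correct prediction ratio: trace / N."""
        return float(np.trace(self.z) / self.n)

    def gc2(self) -> float:
        """Generalized squared correlation; NaN when a margin is zero."""
        row = self.z.sum(axis=1)
        col = self.z.sum(axis=0)
        if (row == 0).any() or (col == 0).any():
            return float("nan")
        e = np.outer(row, col) / self.n
        return float(np.sum((self.z - e) ** 2 / e) / (self.n * (self.k - 1)))

    def normalize_to_reference(self, reference_class: str
                               ) -> "ConfusionMatrix":
        """Rescale every true-class row to the reference class size.

        Row i is multiplied by rowsum(reference)/rowsum(i), preserving
        within-row proportions exactly and equalizing all row sums.
        Column-derived quantities (FP, TN, PPV, NPV, specificity) must be
        recomputed from the scaled matrix.
        """
        row = self.z.sum(axis=1)
        if (row == 0).any():
            raise ValueError("cannot normalize a matrix with an empty row")
        ref = row[self.classes.index(reference_class)]
        factors = ref / row
        return ConfusionMatrix(self.z * factors[:, None], self.classes)

    def permuted(self, order: list[str]) -> "ConfusionMatrix":
        idx = [self.classes.index(c) for c in order]
        return ConfusionMatrix(self.z[np.ix_(idx, idx)], order)

    def __repr__(self) -> str:
        return (f"ConfusionMatrix(classes={self.classes}, "
                f"n={self.n:g}, cpr={self.cpr():.3f})")


def binary_metrics(c: BinaryCounts) -> dict[str, float]:
    """Accuracy, PPV, NPV, TPR, TNR and MCC from binary counts.

    Any measure whose denominator is zero is NaN (undefined), not 0.
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    mcc_den = ((c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn)
               * (c.tn + c.fp))
    return {
        "accuracy": ratio(c.tp + c.tn, c.n),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "tpr": ratio(c.tp, c.tp + c.fn),
        "tnr": ratio(c.tn, c.tn + c.fp),
        "mcc": ((c.tp * c.tn - c.fp * c.fn) / np.sqrt(mcc_den)
                if mcc_den > 0 else float("nan")),
    }


def cpr(m: ConfusionMatrix) -> float:
    return m.cpr()


def gc2(m: ConfusionMatrix) -> float:
    return m.gc2()


def matrix_from_margins(tp, fn, fp, classes: list[str]) -> ConfusionMatrix:
    """Reconstruct a K×K matrix from per-class TP/FN/FP one-vs-rest counts.

    The diagonal and both margins are fixed by the inputs; the off-diagonal
    split is recovered by non-negative least squares.  The completion is
    not unique in general, but every quantity that depends only on the
    diagonal and the row sums — CPR, row normalization, sensitivities —
    is invariant to it.
    """
    tp = np.asarray(tp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    fp = np.asarray(fp, dtype=float)
    k = len(classes)
    if not (len(tp) == len(fn) == len(fp) == k):
        raise ValueError("tp/fn/fp must match the class list")
    if abs(fn.sum() - fp.sum()) > 1e-9:
        raise ValueError("inconsistent margins: sum(FN) != sum(FP)")
    off = [(i, j) for i in range(k) for j in range(k) if i != j]
    a = np.zeros((2 * k, len(off)))
    b = np.concatenate([fn, fp])
    for col, (i, j) in enumerate(off):
        a[i, col] = 1.0        # row-sum constraint for true class i
        a[k + j, col] = 1.0    # column-sum constraint for predicted class j
    from scipy.optimize import nnls
    x, residual = nnls(a, b)
    if residual > 1e-6 * max(1.0, b.sum()):
        raise ValueError("margins admit no non-negative completion")
    z = np.diag(tp)
    for col, (i, j) in enumerate(off):
        z[i, j] = x[col]
    return ConfusionMatrix(z, classes)


@dataclass
class MetricsReport:
    """Per-class measures plus CPR and GC², raw and normalized."""

    per_class: pd.DataFrame          # MultiIndex (measure, class) x (raw, normalized)
    cpr_raw: float
    cpr_normalized: float
    gc2_raw: float
    gc2_normalized: float
    classes: list[str]
    reference_class: str | None

    def to_frame(self) -> pd.DataFrame:
        extra = pd.DataFrame(
            {"raw": [self.cpr_raw, self.gc2_raw],
             "normalized": [self.cpr_normalized, self.gc2_normalized]},
            index=pd.MultiIndex.from_tuples([("cpr", ""), ("gc2", "")],
                                            names=["measure", "class"]))
        return pd.concat([self.per_class, extra])

    def to_tsv(self, path) -> None:
        df = self.to_frame().reset_index()
        df["raw"] = df["raw"].map(_fmt)
        df["normalized"] = df["normalized"].map(_fmt)
        df.to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        df = self.to_frame().copy()
        for c in df.columns:
            df[c] = df[c].map(_fmt)
        return df.to_string()


def _fmt(x) -> str:
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return f"{x:.3f}"


_MEASURES = ("tpr", "tnr", "ppv", "npv", "accuracy", "mcc")


def full_report(m: ConfusionMatrix,
                reference_class: str | None = None) -> MetricsReport:
    """Comprehensive report: one-vs-rest measures per class, CPR and GC².

    Each measure is given raw and after class-size normalization to
    ``reference_class`` (defaults to the last class).  For K = 2 the MCC
    is included.
    """
    if reference_class is None:
        reference_class = m.classes[-1]
    norm = m.normalize_to_reference(reference_class)
    measures = _MEASURES if m.k == 2 else tuple(x for x in _MEASURES
                                                if x != "mcc")
    rows, index = [], []
    for meas in measures:
        for cls_name in m.classes:
            raw = binary_metrics(m.one_vs_rest(cls_name))[meas]
            scaled = binary_metrics(norm.one_vs_rest(cls_name))[meas]
            rows.append({"raw": raw, "normalized": scaled})
            index.append((meas, cls_name))
    per_class = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index,
                                              names=["measure", "class"]))
    return MetricsReport(per_class=per_class, cpr_raw=m.cpr(),
                         cpr_normalized=norm.cpr(), gc2_raw=m.gc2(),
                         gc2_normalized=norm.gc2(), classes=m.classes,
                         reference_class=reference_class)
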