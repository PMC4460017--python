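"""Agreement and per-class diagnostics for activity classification.

Everything is computed from a square confusion matrix of real (rows) by
classified (columns) 5-s epoch counts in a fixed class order.  Implemented
here rather than delegated: per-class sensitivity, positive predictive
value, F-score and specificity; overall accuracy; Cohen's kappa; and
linearly / quadratically weighted kappa, whose category distances depend
on the class ordering.  Weighted kappa uses agreement weights

    w_ij = 1 - d          (linear)      d = |i - j| / (k - 1)
    w_ij = 1 - d^2        (quadratic)

so the diagonal carries weight 1 and the most distant disagreement 0;
kappa = (p_o,w - p_e,w) / (1 - p_e,w) with observed and chance-expected
weighted agreement.  Unweighted kappa is the special case w = identity.

Weighted kappa is order-DEPENDENT: permuting the class list changes the
category distances and hence the statistic.  The default order is the
canonical confusion-matrix order (walking, sitting, running, lying down,
dynamic standing).

Undefined ratios (e.g. sensitivity of an empty class) are reported as
``None`` rather than NaN so that per-person summaries can exclude them
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from actitime.activities import Activity, CANONICAL_ORDER


@dataclass
class ConfusionMatrix:
    """Square count matrix of real (rows) x classified (columns) epochs.

    Class order is fixed at construction; for the five activities the
    canonical order is walking, sitting, running, lying down, dynamic
    standing.  Merged classes are represented by tuple keys.
    """

    classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        names = [_class_name(c) for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ConfusionMatrix":
        """Read a matrix CSV whose first column holds the real-class names."""
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column class orders differ")
        classes = tuple(Activity(c) for c in df.index)
        return cls(classes=classes, counts=df.to_numpy(dtype=np.int64))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path)


def _class_name(c) -> str:
    if isinstance(c, Activity):
        return c.value
    if isinstance(c, tuple):
        return "+".join(_class_name(x) for x in c)
    return str(c)


def confusion_matrix(
    real: Sequence[Activity],
    predicted: Sequence[Activity],
    classes: Sequence[Activity] = CANONICAL_ORDER,
) -> ConfusionMatrix:
    """Count real x classified pairs into a matrix in the given class order."""
    if len(real) != len(predicted):
        raise ValueError(f"length mismatch: {len(real)} real vs {len(predicted)} predicted")
    classes = tuple(classes)
    pos = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(real, predicted):
        try:
            counts[pos[Activity(r)], pos[Activity(p)]] += 1
        except KeyError as e:
            raise ValueError(f"label {e.args[0]} not in class list") from None
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class ClassMetrics:
    """Per-class diagnostics plus overall accuracy.

    Each per-class dict maps class -> proportion in [0, 1], or ``None``
    where the defining ratio has a zero denominator.
    """

    classes: tuple
    sensitivity: dict
    positive_predictive_value: dict
    f_score: dict
    specificity: dict
    overall_accuracy: float


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def class_metrics(m: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity, PPV, F-score and specificity per class; overall accuracy.

    sensitivity_i = c_ii / row_i, ppv_i = c_ii / col_i,
    specificity_i = TN_i / (TN_i + FP_i), F_i = harmonic mean of
    sensitivity and PPV, overall accuracy = trace / n.
    """
    if m.n == 0:
        raise ValueError("empty confusion matrix")
    c = m.counts.astype(float)
    diag = np.diag(c)
    rows, cols, n = m.row_totals.astype(float), m.col_totals.astype(float), float(m.n)
    sens, ppv, f, spec = {}, {}, {}, {}
    for i, cls in enumerate(m.classes):
        s = _safe_div(diag[i], rows[i])
        p = _safe_div(diag[i], cols[i])
        sens[cls], ppv[cls] = s, p
        if s is None or p is None or s + p == 0:
            f[cls] = None
        else:
            f[cls] = 2 * s * p / (s + p)
        tn = n - rows[i] - cols[i] + diag[i]
        fp = cols[i] - diag[i]
        spec[cls] = _safe_div(tn, tn + fp)
    return ClassMetrics(
        classes=m.classes,
        sensitivity=sens,
        positive_predictive_value=ppv,
        f_score=f,
        specificity=spec,
        overall_accuracy=float(diag.sum() / n),
    )


@dataclass
class KappaResult:
    """Chance-corrected agreement under a weighting scheme."""

    scheme: str  # 'unweighted' | 'linear' | 'quadratic'
    observed_agreement: float
    expected_agreement: float
    kappa: Optional[float]  # None when p_e = 1 (degenerate marginals)


def _weight_matrix(k: int, scheme: str) -> np.ndarray:
    if scheme == "unweighted":
        return np.eye(k)
    d = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _kappa(m: ConfusionMatrix, scheme: str) -> KappaResult:
    if m.n == 0:
        raise ValueError("empty confusion matrix")
    w = _weight_matrix(len(m.classes), scheme)
    n = float(m.n)
    po = float((w * m.counts).sum() / n)
    pe = float((w * np.outer(m.row_totals, m.col_totals)).sum() / n**2)
    kappa = (po - pe) / (1 - pe) if pe < 1 else None
    return KappaResult(scheme=scheme, observed_agreement=po, expected_agreement=pe, kappa=kappa)


def cohen_kappa(m: ConfusionMatrix) -> KappaResult:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e)."""
    return _kappa(m, "unweighted")


def weighted_kappa(m: ConfusionMatrix, scheme: str) -> KappaResult:
    """Linearly or quadratically weighted kappa in the matrix's class order."""
    if scheme not in ("linear", "quadratic"):
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    return _kappa(m, scheme)


def merge_classes(m: ConfusionMatrix, group: Iterable) -> ConfusionMatrix:
    """Sum the rows and columns of a class group into one merged class.

    The merged class takes the position of the group's first member in
    the existing order and is keyed by the tuple of merged classes; the
    total count is conserved.
    """
    group = tuple(group)
    if len(group) < 2:
        raise ValueError("merge group needs at least two classes")
    if not set(group).issubset(m.classes):
        missing = set(group) - set(m.classes)
        raise ValueError(f"classes not in matrix: {missing}")
    idx = {c: i for i, c in enumerate(m.classes)}
    grp = sorted((idx[c] for c in group))
    anchor = grp[0]
    new_classes, sources = [], []
    for i, c in enumerate(m.classes):
        if i == anchor:
            new_classes.append(tuple(m.classes[j] for j in grp))
            sources.append(grp)
        elif i not in grp:
            new_classes.append(c)
            sources.append([i])
    k = len(new_classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, rows in enumerate(sources):
        for b, cols in enumerate(sources):
            counts[a, b] = m.counts[np.ix_(rows, cols)].sum()
    return ConfusionMatrix(classes=tuple(new_classes), counts=counts)


@dataclass
class GroupSummary:
    """Per-person values with mean and sample (n-1) standard deviation."""

    values: tuple[float, ...]
    mean: float
    sd: Optional[float]  # None for a single value


def summarize_group(values: Sequence[Optional[float]]) -> GroupSummary:
    """Mean and sample SD over per-person metric values.

    ``None`` entries (undefined per-person ratios) are excluded rather
    than coerced to zero.
    """
    vals = tuple(float(v) for v in values if v is not None)
    if len(vals) == 0:
        raise ValueError("no defined values to summarize")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return GroupSummary(values=vals, mean=mean, sd=sd)


def compare_paired_wilcoxon(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, bool]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Returns ``(p, all_zero)``.  Zero differences are dropped; when every
    difference is zero the test is degenerate and ``(1.0, True)`` is
    returned.  The exact null distribution is used for n <= 25.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return 1.0, True
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method, zero_method="wilcox")
    return float(res.pvalue), False


def compare_welch(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, Satterthwaite df, p).

    When both groups have zero variance and equal means the statistic is
    degenerate; (0, n_a + n_b - 2, 1.0) is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def report(
    m: ConfusionMatrix,
    merge: Optional[Iterable] = None,
) -> dict:
    """JSON-ready evaluation report: matrix, per-class metrics, kappas.

    Kappas are rounded to 2 decimals and percentages to integers for
    display keys; exact values are reported alongside.
    """
    out: dict = {
        "classes": [_class_name(c) for c in m.classes],
        "matrix": m.counts.tolist(),
        "n": m.n,
    }
    cm = class_metrics(m)
    def pct(d):
        return {
            _class_name(c): (None if v is None else round(100 * v)) for c, v in d.items()
        }
    out["overall_accuracy"] = cm.overall_accuracy
    out["overall_accuracy_pct"] = round(100 * cm.overall_accuracy)
    out["sensitivity_pct"] = pct(cm.sensitivity)
    out["positive_predictive_value_pct"] = pct(cm.positive_predictive_value)
    out["f_score_pct"] = pct(cm.f_score)
    out["specificity_pct"] = pct(cm.specificity)
    for scheme, fn in (
        ("kappa", cohen_kappa),
        ("linear_weighted_kappa", lambda x: weighted_kappa(x, "linear")),
        ("quadratic_weighted_kappa", lambda x: weighted_kappa(x, "quadratic")),
    ):
        k = fn(m)
        out[scheme] = None if k.kappa is None else round(k.kappa, 2)
        out[scheme + "_exact"] = k.kappa
    if merge:
        merged = merge_classes(m, merge)
        mm = class_metrics(merged)
        key = _class_name(tuple(merge))
        out["merged"] = {
            "classes": [_class_name(c) for c in merged.classes],
            "matrix": merged.counts.tolist(),
            "sensitivity_pct": {
                _class_name(c): (None if v is None else round(100 * v))
                for c, v in mm.sensitivity.items()
            },
        }
    return out
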