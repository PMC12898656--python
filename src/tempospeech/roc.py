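"""Single-variable ROC analysis with Youden cut-points.

Each temporal speech parameter is evaluated on its own as a case/control
classifier: empirical AUC via the Mann-Whitney probability estimator,
Hanley-McNeil nonparametric standard error, an asymptotic normal test of
H0: AUC = 0.5, a Bonferroni gate across the analyzed variables, and the
Youden-index cut-point (maximizing sensitivity + specificity − 1) with its
sensitivity and specificity.

The classification direction of a variable is not assumed: it is set from
the group means (case mean higher → higher values predict case status), so
rate-like and tempo-like variables come out with opposite orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .stats import bonferroni

__all__ = [
    "ROCResult",
    "empirical_auc",
    "auc_se",
    "auc_asymptotic_p",
    "youden_cutpoint",
    "roc_curve_points",
    "roc_batch",
    "UnivariateROC",
]

Direction = Literal["higher_is_positive", "lower_is_positive"]


@dataclass(frozen=True)
class ROCResult:
    """Per-variable ROC summary: one row of an AUC table plus its cut-point."""

    variable: str
    direction: Direction
    auc: float
    se: float
    p_asymptotic: float
    significant_after_bonferroni: bool
    youden_cutoff: float
    sensitivity: float
    specificity: float
    curve: list[tuple[float, float, float]]  # (cutpoint, sensitivity, 1-specificity)
    n_pos: int
    n_neg: int

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def empirical_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Mann-Whitney probability estimate P(pos > neg) + 0.5 P(pos = neg).

    Computed via midranks, which is exactly the all-pairs count (ties half)
    divided by n_pos * n_neg.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes need at least one score")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil nonparametric standard error of an empirical AUC.

    Uses the exponential-model moments Q1 = A/(2−A), Q2 = 2A²/(1+A).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc must be in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class counts must be >= 1")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc_asymptotic_p(auc: float, se: float) -> float:
    """Two-tailed normal p for H0: AUC = 0.5 with z = (AUC − 0.5)/SE."""
    if se == 0:
        return 1.0 if auc == 0.5 else 0.0
    z = (auc - 0.5) / se
    return float(2 * sps.norm.sf(abs(z)))


def _oriented(scores: np.ndarray, direction: Direction) -> np.ndarray:
    return scores if direction == "higher_is_positive" else -scores


def roc_curve_points(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_is_positive",
) -> list[tuple[float, float, float]]:
    """(cutpoint, sensitivity, 1−specificity) at every candidate cut-point.

    Candidates are midpoints between consecutive distinct sorted scores plus
    ±inf sentinels; a subject is called positive when its (oriented) score
    exceeds the (oriented) cut-point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    o = 1.0 if direction == "higher_is_positive" else -1.0
    distinct = np.unique(scores * o)
    cuts = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    out = []
    for c in cuts:
        sens = float(np.mean(pos * o > c))
        fpr = float(np.mean(neg * o > c))
        out.append((float(c * o) if np.isfinite(c) else float(c) * o, sens, fpr))
    return out


def youden_cutpoint(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_is_positive",
) -> tuple[float, float, float]:
    """Cut-point maximizing the Youden index J = sensitivity + specificity − 1.

    Ties on J are broken toward higher sensitivity, then toward the lower
    (oriented) cut-point.  With a single distinct score J is degenerately 0.
    """
    curve = roc_curve_points(scores, labels, direction)
    if len(curve) == 2:  # single distinct score: only the +-inf sentinels
        import warnings

        warnings.warn(
            "single distinct score: ROC is degenerate, Youden J = 0",
            RuntimeWarning,
            stacklevel=2,
        )
    o = 1.0 if direction == "higher_is_positive" else -1.0
    best = None
    for cut, sens, fpr in curve:
        j = sens - fpr
        key = (j, sens, -cut * o)  # maximize J, then sensitivity, then low cut
        if best is None or key > best[0]:
            best = (key, (cut, sens, 1.0 - fpr))
    return best[1]


def roc_batch(
    ft: pd.DataFrame,
    kept: Sequence[str],
    alpha: float = 0.05,
    m: int | None = None,
    group_column: str = "group",
    case_label: str | None = None,
) -> list[ROCResult]:
    """Run the per-variable ROC analysis over the retained feature set.

    ``case_label`` names the positive class (default: the lexicographically
    later of the two group labels is NOT assumed — it must be supplied unless
    the table has exactly the labels {control-like, case-like} in which case
    the caller should still pass it; here the default takes the second sorted
    label).  The Bonferroni family size ``m`` defaults to ``len(kept)``.
    Missing cells are dropped per variable.  Results sorted by AUC
    descending.
    """
    labels = sorted(pd.unique(ft[group_column].dropna()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    if case_label is None:
        case_label = labels[1]
    if case_label not in labels:
        raise ValueError(f"unknown case label {case_label!r}")
    missing_cols = [v for v in kept if v not in ft.columns]
    if missing_cols:
        raise ValueError(f"variables not in table: {missing_cols}")
    threshold = bonferroni(alpha, m if m is not None else len(kept)).exact
    is_case = (ft[group_column] == case_label).to_numpy()
    results = []
    for var in kept:
        col = ft[var].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        scores, y = col[ok], is_case[ok]
        pos, neg = scores[y], scores[~y]
        direction: Direction = (
            "higher_is_positive" if pos.mean() >= neg.mean() else "lower_is_positive"
        )
        o_pos = _oriented(pos, direction)
        o_neg = _oriented(neg, direction)
        auc = empirical_auc(o_pos, o_neg)
        se = auc_se(auc, len(pos), len(neg))
        p = auc_asymptotic_p(auc, se)
        cut, sens, spec = youden_cutpoint(scores, y, direction)
        results.append(
            ROCResult(
                variable=var,
                direction=direction,
                auc=auc,
                se=se,
                p_asymptotic=p,
                significant_after_bonferroni=p <= threshold,
                youden_cutoff=cut,
                sensitivity=sens,
                specificity=spec,
                curve=roc_curve_points(scores, y, direction),
                n_pos=int(len(pos)),
                n_neg=int(len(neg)),
            )
        )
    results.sort(key=lambda r: -r.auc)
    return results


def roc_results_to_frame(results: Sequence[ROCResult]) -> pd.DataFrame:
    """AUC-table view (area, SE, asymptotic p, cut-point columns)."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "direction": r.direction,
                "auc": r.auc,
                "se": r.se,
                "p_asymptotic": r.p_asymptotic,
                "significant_after_bonferroni": r.significant_after_bonferroni,
                "youden_cutoff": r.youden_cutoff,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
            }
            for r in results
        ]
    )


class UnivariateROC(BaseEstimator):
    """Fit-style per-variable ROC screen with Youden thresholds.

    ``fit(X, y)`` evaluates every numeric column of ``X`` as a standalone
    classifier of ``y == case_label`` and exposes ``results_`` sorted by
    AUC.  ``predict(X)`` classifies with the Youden cut-point of the best
    Bonferroni-surviving variable (or the top-AUC variable if none survive).
    """

    def __init__(self, case_label: str | None = None, alpha: float = 0.05,
                 m: int | None = None):
        self.case_label = case_label
        self.alpha = alpha
        self.m = m

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "UnivariateROC":
        X = pd.DataFrame(X)
        numeric = X.select_dtypes(include=[np.number])
        table = numeric.copy()
        table["__group__"] = np.asarray(y, dtype=object)
        self.results_ = roc_batch(
            table,
            kept=list(numeric.columns),
            alpha=self.alpha,
            m=self.m,
            group_column="__group__",
            case_label=self.case_label,
        )
        labels = sorted(pd.unique(pd.Series(list(y)).dropna()))
        self.case_label_ = self.case_label if self.case_label is not None else labels[1]
        self.control_label_ = next(l for l in labels if l != self.case_label_)
        survivors = [r for r in self.results_ if r.significant_after_bonferroni]
        self.best_ = survivors[0] if survivors else self.results_[0]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        r = self.best_
        scores = pd.DataFrame(X)[r.variable].to_numpy(dtype=float)
        if r.direction == "higher_is_positive":
            is_case = scores > r.youden_cutoff
        else:
            is_case = scores < r.youden_cutoff
        return np.where(is_case, self.case_label_, self.control_label_)
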