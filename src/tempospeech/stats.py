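"""Case-control statistics for temporal speech parameters.

Implements the comparison chain used in small case-control speech studies:

* per-variable normality screening (Shapiro-Wilk or Lilliefors-corrected
  Kolmogorov-Smirnov) deciding between *t*-tests and Mann-Whitney U;
* a variance-equality gate deciding pooled-variance vs Welch *t* — Levene
  (mean-centred) on raw data, a two-sided variance-ratio F test when only
  printed group summaries (n, mean, SD) are available;
* Cohen's d with an n−1-weighted pooled SD;
* greedy correlation pruning of near-duplicate features (|r| > threshold);
* the Bonferroni family-wise threshold.

Sign conventions (they differ, deliberately, to match the reporting
convention of SPSS-style tables): the *t* statistic is computed as
control − case with the control group listed first, while Cohen's d is
case − control so that a case-elevated variable has positive d.

Everything t/Welch-related works from summary statistics alone, so printed
tables of group means and SDs are a first-class input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .features import TSP_COLUMNS

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "PruningResult",
    "BonferroniThreshold",
    "summarize",
    "pooled_t",
    "welch_t",
    "cohens_d",
    "choose_test",
    "mann_whitney",
    "chi_square_2x2",
    "bonferroni",
    "prune_correlated",
    "compare_all",
    "compare_from_summaries",
    "GroupComparison",
    "CorrelationPruner",
]

TestName = Literal["pooled_t", "welch_t", "mann_whitney_u"]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD (n−1 denominator) of one variable in one group."""

    n: int
    mean: float
    sd: float
    median: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @property
    def var(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class ComparisonResult:
    """One row of a group-comparison table for one variable."""

    variable: str
    test: TestName
    statistic: float
    p: float
    df: float | None = None
    z: float | None = None
    effect_size_d: float | None = None
    significant_at: float = 0.05
    control: GroupSummary | None = None
    case: GroupSummary | None = None

    @property
    def significant(self) -> bool:
        return self.p <= self.significant_at

    @property
    def effect_class(self) -> str | None:
        """Cohen's rule of thumb: |d| >= 0.8 large, >= 0.5 medium, >= 0.2 small."""
        if self.effect_size_d is None:
            return None
        d = abs(self.effect_size_d)
        if d >= 0.8:
            return "large"
        if d >= 0.5:
            return "medium"
        if d >= 0.2:
            return "small"
        return "negligible"


class BonferroniThreshold(NamedTuple):
    exact: float
    rounded: float  # at 4 decimals, the form such thresholds are reported in


def summarize(values: Sequence[float]) -> GroupSummary:
    """n, mean, sample SD and median of the non-missing values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError(f"need >= 2 non-missing values, got {arr.size}")
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        median=float(np.median(arr)),
    )


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    return math.sqrt(
        ((a.n - 1) * a.var + (b.n - 1) * b.var) / (a.n + b.n - 2)
    )


def pooled_t(
    a: GroupSummary, b: GroupSummary, variable: str = "", alpha: float = 0.05
) -> ComparisonResult:
    """Classical equal-variance two-sample t from summaries; a is the control.

    t = (mean_a − mean_b) / (s_p · sqrt(1/n_a + 1/n_b)), df = n_a + n_b − 2.
    """
    sp = _pooled_sd(a, b)
    if sp == 0:
        if a.mean == b.mean:
            raise ZeroDivisionError(
                "both SDs zero with equal means: t statistic undefined"
            )
        t = math.inf if a.mean > b.mean else -math.inf
        p = 0.0
    else:
        se = sp * math.sqrt(1 / a.n + 1 / b.n)
        t = (a.mean - b.mean) / se
        p = 2 * sps.t.sf(abs(t), a.n + b.n - 2)
    return ComparisonResult(
        variable=variable,
        test="pooled_t",
        statistic=float(t),
        df=float(a.n + b.n - 2),
        p=float(p),
        effect_size_d=cohens_d(a, b) if sp > 0 else None,
        significant_at=alpha,
        control=a,
        case=b,
    )


def welch_t(
    a: GroupSummary, b: GroupSummary, variable: str = "", alpha: float = 0.05
) -> ComparisonResult:
    """Unequal-variance t with Welch-Satterthwaite degrees of freedom."""
    va, vb = a.var / a.n, b.var / b.n
    if va + vb == 0:
        raise ZeroDivisionError("both SDs zero: Welch statistic undefined")
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2 * sps.t.sf(abs(t), df)
    sp = _pooled_sd(a, b)
    return ComparisonResult(
        variable=variable,
        test="welch_t",
        statistic=float(t),
        df=float(df),
        p=float(p),
        effect_size_d=cohens_d(a, b) if sp > 0 else None,
        significant_at=alpha,
        control=a,
        case=b,
    )


def cohens_d(control: GroupSummary, case: GroupSummary) -> float:
    """Cohen's d = (mean_case − mean_control) / pooled SD (n−1 weights).

    Positive when the case group is higher — the opposite sign of the t
    statistic, whose convention is control − case.
    """
    sp = _pooled_sd(control, case)
    if sp == 0:
        raise ZeroDivisionError("pooled SD is zero: d undefined")
    return (case.mean - control.mean) / sp


def _normality_p(values: np.ndarray, method: str) -> float:
    if np.ptp(values) == 0:
        return 0.0  # constant sample: treat as maximally non-normal
    if method == "shapiro":
        return float(sps.shapiro(values).pvalue)
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        return float(lilliefors(values, dist="norm")[1])
    raise ValueError(f"unknown normality method {method!r}")


def choose_test(
    a_raw: Sequence[float],
    b_raw: Sequence[float],
    normality_method: Literal["shapiro", "lilliefors"] = "shapiro",
    alpha: float = 0.05,
) -> TestName:
    """Pick the two-sample test for raw data.

    Either group non-normal at ``alpha`` → Mann-Whitney U; otherwise Levene
    (mean-centred) at ``alpha`` decides Welch vs pooled t.  Constant samples
    fall through to Mann-Whitney (normality tests are undefined on them).
    """
    a = np.asarray(a_raw, dtype=float)
    b = np.asarray(b_raw, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if min(a.size, b.size) < 3:
        raise ValueError("need >= 3 values per group to screen normality")
    if _normality_p(a, normality_method) < alpha or _normality_p(b, normality_method) < alpha:
        return "mann_whitney_u"
    if sps.levene(a, b, center="mean").pvalue < alpha:
        return "welch_t"
    return "pooled_t"


def mann_whitney(
    a_raw: Sequence[float],
    b_raw: Sequence[float],
    variable: str = "",
    alpha: float = 0.05,
    exact: bool | None = None,
) -> ComparisonResult:
    """Mann-Whitney U with a tie-corrected normal z (no continuity correction).

    U counts pairs where an ``a`` value exceeds a ``b`` value (ties 0.5), the
    reporting convention of SPSS-style tables.  The default p is the
    two-tailed normal approximation; ``exact=True`` switches to the exact U
    distribution (sensible for n1+n2 <= 20 without ties).
    """
    a = np.asarray(a_raw, dtype=float)
    b = np.asarray(b_raw, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # pairs a > b, ties counted half
    n = n1 + n2
    # tie-corrected variance of U under H0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u == 0:
        z = 0.0
        p = 1.0
    else:
        z = (u - n1 * n2 / 2.0) / math.sqrt(var_u)
        p = 2 * sps.norm.sf(abs(z))
    if exact:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    return ComparisonResult(
        variable=variable,
        test="mann_whitney_u",
        statistic=float(u),
        z=float(z),
        p=float(p),
        significant_at=alpha,
    )


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 count table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-squared undefined")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def bonferroni(alpha: float, m: int) -> BonferroniThreshold:
    """Family-wise threshold alpha/m, with its conventional 4-decimal form."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    exact = alpha / m
    return BonferroniThreshold(exact=exact, rounded=round(exact, 4))


# ---------------------------------------------------------------------------
# Correlation pruning
# ---------------------------------------------------------------------------

@dataclass
class PruningResult:
    """Outcome of greedy |r|-threshold pruning of near-duplicate features."""

    correlation_matrix: pd.DataFrame
    threshold: float
    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (variable, kept proxy, r)
    constant: list[str] = field(default_factory=list)  # flagged: r undefined


def prune_correlated(
    ft: pd.DataFrame,
    threshold: float = 0.9,
    relevance: Sequence[str] | None = None,
    group_column: str = "group",
) -> PruningResult:
    """Drop features that duplicate an already-kept, more relevant feature.

    Pearson correlations are computed on pairwise-complete observations.
    Variables are scanned in ``relevance`` order (default: descending
    |Cohen's d| between the two groups of ``group_column``, the natural
    operationalization of "most relevant"); a variable is dropped when its
    |r| with any already-kept variable exceeds ``threshold``.  Deterministic
    given the relevance order and invariant to input column order.

    Constant columns have undefined correlations; they are kept and flagged
    in ``constant``.
    """
    numeric = ft.drop(columns=[group_column], errors="ignore")
    numeric = numeric.select_dtypes(include=[np.number])
    if len(numeric.dropna(how="any")) < 3 and len(numeric) < 3:
        raise ValueError("need >= 3 rows to estimate correlations")
    corr = numeric.corr(method="pearson", min_periods=2)
    constant = [c for c in numeric.columns if numeric[c].nunique(dropna=True) <= 1]

    if relevance is None:
        if group_column not in ft.columns:
            raise ValueError(
                "default relevance order needs a group column to compute "
                f"Cohen's d; none named {group_column!r}"
            )
        groups = [g for g in pd.unique(ft[group_column].dropna())]
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {groups}")
        d_by_var = {}
        for col in numeric.columns:
            if col in constant:
                d_by_var[col] = -np.inf
                continue
            ga = summarize(ft.loc[ft[group_column] == groups[0], col])
            gb = summarize(ft.loc[ft[group_column] == groups[1], col])
            try:
                d_by_var[col] = abs(cohens_d(ga, gb))
            except ZeroDivisionError:
                d_by_var[col] = -np.inf
        relevance = sorted(numeric.columns, key=lambda c: -d_by_var[c])
    else:
        missing = set(numeric.columns) - set(relevance)
        if missing:
            raise ValueError(f"relevance order misses columns: {sorted(missing)}")
        relevance = [c for c in relevance if c in numeric.columns]

    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for var in relevance:
        proxy = None
        for k in kept:
            r = corr.loc[var, k]
            if pd.notna(r) and abs(r) > threshold:
                proxy = (k, float(r))
                break
        if proxy is None:
            kept.append(var)
        else:
            dropped.append((var, proxy[0], proxy[1]))
    return PruningResult(
        correlation_matrix=corr,
        threshold=threshold,
        kept=kept,
        dropped=dropped,
        constant=constant,
    )


# ---------------------------------------------------------------------------
# Whole-table comparison
# ---------------------------------------------------------------------------

def _variance_gate_from_summaries(
    a: GroupSummary, b: GroupSummary, alpha: float = 0.05
) -> TestName:
    # Two-sided variance-ratio F test: the only variance-equality screen
    # available from printed summaries.
    if a.sd == 0 and b.sd == 0:
        return "pooled_t"
    if a.sd == 0 or b.sd == 0:
        return "welch_t"
    if a.var >= b.var:
        f, dfn, dfd = a.var / b.var, a.n - 1, b.n - 1
    else:
        f, dfn, dfd = b.var / a.var, b.n - 1, a.n - 1
    p = 2 * sps.f.sf(f, dfn, dfd)
    return "welch_t" if min(p, 1.0) < alpha else "pooled_t"


def compare_from_summaries(
    summaries: dict[str, tuple[GroupSummary, GroupSummary]],
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Compare variables from printed (control, case) summary pairs.

    The pooled-vs-Welch choice uses the two-sided F variance-ratio gate; the
    normality screen is not available from summaries and is the caller's
    responsibility (printed tables normally report only variables already
    screened as normal).
    """
    results = []
    for variable, (a, b) in summaries.items():
        gate = _variance_gate_from_summaries(a, b, alpha)
        fn = pooled_t if gate == "pooled_t" else welch_t
        results.append(fn(a, b, variable=variable, alpha=alpha))
    return results


def compare_all(
    ft: pd.DataFrame,
    group_column: str = "group",
    control_label: str | None = None,
    normality_method: Literal["shapiro", "lilliefors"] = "shapiro",
    alpha: float = 0.05,
    variables: Sequence[str] | None = None,
) -> list[ComparisonResult]:
    """One comparison per TSP column of a raw feature table.

    For every variable: normality screen on both groups, then Mann-Whitney U
    or a (Levene-gated) pooled/Welch t.  Missing cells are excluded per
    variable.  ``control_label`` names the group listed first (t convention
    control − case, d convention case − control); defaults to the first
    label in sorted order.
    """
    if group_column not in ft.columns:
        raise ValueError(f"feature table has no group column {group_column!r}")
    labels = sorted(pd.unique(ft[group_column].dropna()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    if control_label is None:
        control_label = labels[0]
    if control_label not in labels:
        raise ValueError(f"unknown control label {control_label!r}; groups are {labels}")
    case_label = next(g for g in labels if g != control_label)

    if variables is None:
        variables = [c for c in TSP_COLUMNS if c in ft.columns]
        if not variables:
            variables = [
                c for c in ft.columns
                if c != group_column and pd.api.types.is_numeric_dtype(ft[c])
            ]
    results = []
    for var in variables:
        a = ft.loc[ft[group_column] == control_label, var].dropna().to_numpy(float)
        b = ft.loc[ft[group_column] == case_label, var].dropna().to_numpy(float)
        test = choose_test(a, b, normality_method=normality_method, alpha=alpha)
        if test == "mann_whitney_u":
            res = mann_whitney(a, b, variable=var, alpha=alpha)
        else:
            sa, sb = summarize(a), summarize(b)
            fn = pooled_t if test == "pooled_t" else welch_t
            res = fn(sa, sb, variable=var, alpha=alpha)
        results.append(res)
    return results


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of comparison results."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "control_n": r.control.n if r.control else None,
                "control_mean": r.control.mean if r.control else None,
                "control_sd": r.control.sd if r.control else None,
                "case_n": r.case.n if r.case else None,
                "case_mean": r.case.mean if r.case else None,
                "case_sd": r.case.sd if r.case else None,
                "test": r.test,
                "statistic": r.statistic,
                "df": r.df,
                "z": r.z,
                "p": r.p,
                "cohens_d": r.effect_size_d,
                "effect_class": r.effect_class,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


class GroupComparison(BaseEstimator):
    """Fit-style wrapper around the per-variable comparison chain.

    ``fit(X, y)`` takes the numeric feature frame and a two-level group
    label vector, runs the normality-gated test per column, and exposes
    ``results_`` (list of :class:`ComparisonResult`), ``significant_`` and
    ``summary_frame_``.
    """

    def __init__(
        self,
        control_label: str | None = None,
        normality_method: Literal["shapiro", "lilliefors"] = "shapiro",
        alpha: float = 0.05,
    ):
        self.control_label = control_label
        self.normality_method = normality_method
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "GroupComparison":
        X = pd.DataFrame(X).copy()
        X["__group__"] = np.asarray(y, dtype=object)
        self.results_ = compare_all(
            X,
            group_column="__group__",
            control_label=self.control_label,
            normality_method=self.normality_method,
            alpha=self.alpha,
        )
        self.significant_ = [r.variable for r in self.results_ if r.significant]
        self.summary_frame_ = results_to_frame(self.results_)
        return self


class CorrelationPruner(TransformerMixin, BaseEstimator):
    """Feature selector dropping near-duplicate columns (|r| > threshold).

    Greedy scan in relevance order; default relevance is descending |Cohen's
    d| against the ``y`` passed to ``fit``.  ``transform`` keeps the
    surviving columns.
    """

    def __init__(
        self,
        threshold: float = 0.9,
        relevance: Sequence[str] | None = None,
    ):
        self.threshold = threshold
        self.relevance = relevance

    def fit(self, X: pd.DataFrame, y: Sequence[str] | None = None) -> "CorrelationPruner":
        X = pd.DataFrame(X)
        if self.relevance is None:
            if y is None:
                raise ValueError(
                    "default relevance (|Cohen's d|) needs group labels y"
                )
            X = X.copy()
            X["__group__"] = np.asarray(y, dtype=object)
            pr = prune_correlated(
                X, threshold=self.threshold, relevance=None, group_column="__group__"
            )
        else:
            pr = prune_correlated(
                X, threshold=self.threshold, relevance=self.relevance,
                group_column="__nonexistent__",
            )
        self.pruning_ = pr
        self.kept_ = pr.kept
        self.dropped_ = pr.dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.kept_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.kept_, dtype=object)
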