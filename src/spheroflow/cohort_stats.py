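"""Cohort comparisons: chi-square on categorical outcomes, one-tailed
Student's t on rolling velocities, median fold changes, star annotation.

Categorical outcomes (adherent / not adherent, tethered / not tethered) are
compared between conditions with Pearson's chi-square on the pooled counts,
without continuity correction by default; rolling-velocity distributions
with the unpaired one-tailed Student's t test (pooled variance; Welch
available).  No multiple-testing adjustment is applied by default, matching
per-comparison reporting; a Holm adjustment helper is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi_square_test",
    "one_tailed_t_test",
    "median_fold_change",
    "annotate_stars",
    "risk_ratio_ci",
    "holm_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test, with the figure-legend star label."""

    method: str
    statistic: float
    df: float
    pvalue: float
    tail: str
    stars: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContingencyTable:
    """2 x k non-negative integer counts: rows = conditions, cols = outcomes."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need at least a 2x2 table")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_counts(
        cls, hits_a: int, total_a: int, hits_b: int, total_b: int,
        row_labels: tuple[str, str] = ("A", "B"),
    ) -> "ContingencyTable":
        """Classified-vs-not 2x2 table from per-condition hits and totals."""
        if hits_a > total_a or hits_b > total_b:
            raise ValueError("hits cannot exceed totals")
        return cls(
            ((hits_a, total_a - hits_a), (hits_b, total_b - hits_b)),
            row_labels=row_labels,
            col_labels=("classified", "not_classified"),
        )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def annotate_stars(p: float) -> str:
    """Figure-legend significance label: ns / * / ** / *** at 0.05 / 0.01 /
    0.001 (strict inequalities; boundary p gets the weaker label)."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def chi_square_test(
    table: ContingencyTable | np.ndarray, yates_correction: bool = False
) -> TestResult:
    """Pearson chi-square test of homogeneity on an r x k count table.

    chi2 = sum (O - E)^2 / E with E from the product of the marginals;
    df = (r - 1)(k - 1); upper-tail p.  Continuity (Yates) correction is off
    by default and only applies to 2x2 tables.  A warning flags expected
    counts below 5.
    """
    obs = (
        table.as_array()
        if isinstance(table, ContingencyTable)
        else np.asarray(table, dtype=float)
    )
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("every row and column must have a positive total")
    expected = np.outer(row, col) / n
    flags: tuple[str, ...] = ()
    if np.any(expected < 5):
        warnings.warn("expected cell count below 5; chi-square approximation is weak")
        flags = ("expected_below_5",)
    diff = np.abs(obs - expected)
    if yates_correction and obs.shape == (2, 2):
        diff = np.clip(diff - 0.5, 0, None)
    statistic = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(
        method="chi-square" + (" (Yates)" if yates_correction else ""),
        statistic=statistic,
        df=df,
        pvalue=p,
        tail="upper",
        stars=annotate_stars(p),
        flags=flags,
    )


def one_tailed_t_test(
    sample_a, sample_b, direction: str = "a_greater", welch: bool = False
) -> TestResult:
    """Unpaired one-tailed Student's t test (pooled variance by default).

    ``direction`` states the alternative: "a_greater" tests mean(a) >
    mean(b), "b_greater" the reverse.  The statistic is always t = (mean_a -
    mean_b) / SE.  With zero variance in both samples and equal means the
    test is uninformative and returns p = 0.5, flagged.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if direction not in ("a_greater", "b_greater"):
        raise ValueError("direction must be 'a_greater' or 'b_greater'")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    mean_diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if mean_diff == 0:
            return TestResult(
                method="student-t" if not welch else "welch-t",
                statistic=0.0,
                df=na + nb - 2,
                pvalue=0.5,
                tail=direction,
                stars="ns",
                flags=("degenerate_zero_variance",),
            )
        raise ValueError("zero variance with unequal means: t is undefined")
    if welch:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        method = "welch-t"
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        method = "student-t"
    t = float(mean_diff / se)
    p = float(stats.t.sf(t, df) if direction == "a_greater" else stats.t.cdf(t, df))
    return TestResult(
        method=method,
        statistic=t,
        df=float(df),
        pvalue=p,
        tail=direction,
        stars=annotate_stars(p),
    )


def median_fold_change(sample_a, sample_b) -> tuple[float, float]:
    """(median(a)/median(b), percent change of a relative to b)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    mb = float(np.median(b))
    if mb == 0:
        raise ZeroDivisionError("median of the reference sample is zero")
    ma = float(np.median(a))
    return ma / mb, 100.0 * (ma - mb) / mb


def risk_ratio_ci(
    hits_a: int, n_a: int, hits_b: int, n_b: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Ratio of two proportions with its Katz log-scale confidence interval.

    Returns (ratio, low, high) for (hits_a/n_a) / (hits_b/n_b).
    """
    if min(hits_a, hits_b) < 1 or min(n_a, n_b) < 1:
        raise ValueError("need at least one hit per arm for a log-scale CI")
    p_a, p_b = hits_a / n_a, hits_b / n_b
    ratio = p_a / p_b
    se = np.sqrt((1 - p_a) / (n_a * p_a) + (1 - p_b) / (n_b * p_b))
    z = stats.norm.ppf(0.5 + confidence / 2)
    return ratio, ratio * np.exp(-z * se), ratio * np.exp(z * se)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]
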