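"""Univariate candidate-peak selection and demographic comparisons.

Continuous variables go through a Shapiro-Wilk normality gate: Student's
pooled-variance *t* test when both groups look normal, the Mann-Whitney
U-test otherwise.  Categorical 2x2 comparisons use Pearson's chi-square
without continuity correction.  Per-peak discrimination is summarised by
the ROC AUC with a Hanley-McNeil confidence interval; the AUC is computed
from ranks and is exactly the Mann-Whitney U statistic divided by
``n1 * n2``.

Candidate selection applies the gate and test to every reference peak,
assigns the tendency (up/down in cases versus controls) from the group
means, and keeps peaks with P below the screening level.  No
multiple-testing adjustment is applied by default, matching the plain
``P < 0.05`` screen such discovery studies use; a Benjamini-Hochberg
option is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from pepdiscover.matrix import PeakMatrix

__all__ = [
    "PeakStats",
    "shapiro_wilk_gate",
    "two_sample_t",
    "mann_whitney",
    "roc_auc",
    "chi_square_2x2",
    "select_candidates",
]


class StatError(ValueError):
    pass


@dataclass(frozen=True)
class PeakStats:
    """Univariate summary for one reference peak."""

    mz_ref: float
    tendency: str  # "up" | "down": cases versus controls
    mean_case: float
    mean_control: float
    p_value: float
    test_used: str  # "t" | "mann_whitney"
    auc: float
    auc_ci: tuple[float, float]


def shapiro_wilk_gate(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> str:
    """Choose the two-sample test: ``"t"`` iff both groups pass Shapiro-Wilk.

    Degenerate (constant) groups, for which normality is undefined, fall
    through to the rank test.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise StatError("Shapiro-Wilk gate needs n >= 3 in each group")
    for g in (x, y):
        if np.ptp(g) == 0:
            return "mann_whitney"
        if stats.shapiro(g).pvalue <= alpha:
            return "mann_whitney"
    return "t"


def two_sample_t(
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    *,
    summary: tuple[tuple[float, float, int], tuple[float, float, int]] | None = None,
) -> float:
    """Two-tailed pooled-variance Student t-test P-value.

    Accepts either raw samples or the summary form
    ``summary=((mean1, sd1, n1), (mean2, sd2, n2))``, the latter for
    published group summaries.
    """
    if summary is not None:
        (m1, s1, n1), (m2, s2, n2) = summary
    else:
        if x is None or y is None:
            raise StatError("provide raw samples or summary statistics")
        x, y = np.asarray(x, float), np.asarray(y, float)
        if len(x) < 2 or len(y) < 2:
            raise StatError("t-test needs n >= 2 per group")
        m1, s1, n1 = float(np.mean(x)), float(np.std(x, ddof=1)), len(x)
        m2, s2, n2 = float(np.mean(y)), float(np.std(y, ddof=1)), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(t), df))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + half-credit for ties."""
    gt = np.sum(x[:, None] > y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    return float(gt + 0.5 * ties)


def mann_whitney(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-tailed P-value.

    The P-value is exact (full permutation enumeration of group
    assignments, valid under ties) when the pooled size is at most
    ``exact_max_n``, and a tie-corrected normal approximation otherwise.
    The two-tailed exact P is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise StatError("Mann-Whitney needs n >= 1 per group")
    u = _u_statistic(x, y)

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        us = []
        for c in combinations(idx, n1):
            chosen = set(c)
            rest = [i for i in idx if i not in chosen]
            us.append(_u_statistic(pooled[list(c)], pooled[rest]))
        us = np.array(us)
        total = len(us)
        lo = np.sum(us <= u + 1e-12) / total
        hi = np.sum(us >= u - 1e-12) / total
        p = min(1.0, 2.0 * min(lo, hi))
        return u, float(p)

    pooled = np.concatenate([x, y])
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u, 1.0
    z = (u - mean_u) / sqrt(var_u)
    return u, float(2.0 * stats.norm.sf(abs(z)))


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """ROC AUC (cases scored high) with a Hanley-McNeil 95% interval.

    Computed from average ranks with half-credit for ties, hence exactly
    equal to the Mann-Whitney U divided by ``n1 * n2``.  The raw
    orientation is reported: an AUC below 0.5 means the marker scores
    controls higher.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    mask = labels == 1 if labels.dtype.kind in "iufb" else labels == "case"
    case, ctrl = scores[mask], scores[~mask]
    n1, n2 = len(case), len(ctrl)
    if n1 == 0 or n2 == 0:
        raise StatError("ROC needs both classes present")
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    u = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n2)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)
    return auc, (lo, hi)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square P (df=1, no continuity correction) for rows (a,b),(c,d)."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise StatError("counts must be non-negative integers")
    if a + b == 0 or c + d == 0:
        raise StatError("each group (row) must contain at least one observation")
    n = a + b + c + d
    det = a * d - b * c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:  # one category unobserved in both groups
        return 1.0
    chi2 = n * det**2 / denom
    return float(stats.chi2.sf(chi2, df=1))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def peak_stats(m: PeakMatrix, gate_alpha: float = 0.05) -> list[PeakStats]:
    """Univariate summary for every reference peak in the matrix."""
    labels = np.asarray(m.labels)
    y = (labels == "case").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise StatError("matrix must contain both cases and controls")
    out: list[PeakStats] = []
    for j, ref in enumerate(m.reference_peaks):
        col = m.intensities[:, j]
        xc, xn = col[y == 1], col[y == 0]
        test = shapiro_wilk_gate(xc, xn, gate_alpha)
        if test == "t":
            p = two_sample_t(xc, xn)
        else:
            _, p = mann_whitney(xc, xn)
        auc, ci = roc_auc(col, y)
        mean_c, mean_n = float(np.mean(xc)), float(np.mean(xn))
        out.append(
            PeakStats(
                mz_ref=ref.mz_ref,
                tendency="up" if mean_c > mean_n else "down",
                mean_case=mean_c,
                mean_control=mean_n,
                p_value=p,
                test_used=test,
                auc=auc,
                auc_ci=ci,
            )
        )
    return out


def select_candidates(
    m: PeakMatrix,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[PeakStats]:
    """Screen reference peaks for class differences at level ``alpha``.

    Returns the significant peaks sorted by m/z.  ``bh_correct`` switches
    the screen to Benjamini-Hochberg adjusted P-values (off by default).
    """
    all_stats = peak_stats(m, gate_alpha)
    pvals = np.array([s.p_value for s in all_stats])
    screened = bh_adjust(pvals) if bh_correct else pvals
    selected = [s for s, p in zip(all_stats, screened) if p < alpha]
    return sorted(selected, key=lambda s: s.mz_ref)


def stats_to_frame(stats_list: list[PeakStats]) -> pd.DataFrame:
    """Tabulate peak statistics (one row per peak, ascending m/z)."""
    return pd.DataFrame(
        {
            "mz": [round(s.mz_ref, 1) for s in stats_list],
            "tendency": [s.tendency for s in stats_list],
            "mean_case": [s.mean_case for s in stats_list],
            "mean_control": [s.mean_control for s in stats_list],
            "p_value": [s.p_value for s in stats_list],
            "test": [s.test_used for s in stats_list],
            "auc": [s.auc for s in stats_list],
            "auc_lo": [s.auc_ci[0] for s in stats_list],
            "auc_hi": [s.auc_ci[1] for s in stats_list],
        }
    )
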