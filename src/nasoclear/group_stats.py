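"""Group-level statistics for cohort clearance outputs.

Implements the statistical battery applied to the clearance tables and TAC
matrices: Mann-Whitney (Wilcoxon rank-sum) group tests, Spearman rank
correlations, 2x2 chi-square tests, a two-way mixed-design repeated-measures
ANOVA (between-subject amyloid group, within-subject time) with the
Greenhouse-Geisser sphericity correction, Benjamini-Hochberg FDR adjustment,
and pointwise per-timepoint group comparisons with FDR control across the
timepoint family.

Small-sample p values are exact: the rank-sum test enumerates all group
assignments when the combined sample is at most EXACT_MW_MAX_N (with
midrank ties), and the Spearman test enumerates all pairings when
n <= EXACT_SPEARMAN_MAX_N.  Larger samples use the standard normal / t
approximations with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "AnovaEffect",
    "AnovaTable",
    "TacMatrix",
    "EXACT_MW_MAX_N",
    "EXACT_SPEARMAN_MAX_N",
    "mann_whitney",
    "wilcoxon_rank_sum",
    "spearman",
    "chi_square_2x2",
    "rm_anova_group_time",
    "bh_fdr",
    "pointwise_group_tests",
]

#: largest combined sample for which the rank-sum p value is enumerated
EXACT_MW_MAX_N = 10
#: largest n for which the Spearman permutation p value is enumerated
EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    approach: str = "asymptotic"  # "exact" | "asymptotic"
    sided: str = "two"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df1: float
    df2: float
    F: float
    epsilon: float
    df1_gg: float
    df2_gg: float
    p_value: float


@dataclass(frozen=True)
class AnovaTable:
    group: AnovaEffect
    time: AnovaEffect
    interaction: AnovaEffect

    def effects(self) -> dict[str, AnovaEffect]:
        return {"group": self.group, "time": self.time,
                "interaction": self.interaction}


@dataclass
class TacMatrix:
    """Complete subjects x timepoints SUV matrix with group labels."""

    values: np.ndarray  # (n_subjects, n_timepoints)
    groups: np.ndarray  # (n_subjects,) labels
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D subjects x timepoints array")
        if self.groups.shape != (self.values.shape[0],):
            raise ValueError("one group label per subject required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC matrix must be complete (no missing cells)")


# ----------------------------------------------------------------------
# rank-based tests
# ----------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with midrank tie handling."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Exact p by full enumeration of the C(n1+n2, n1) group assignments when
    the combined sample has at most EXACT_MW_MAX_N observations; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return TestResult(method="mann_whitney", statistic=u_obs,
                          p_value=count / total, n_per_group=(n1, n2),
                          approach="exact")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return TestResult(method="mann_whitney", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n_per_group=(n1, n2),
                      approach="asymptotic")


#: alias — "Wilcoxon rank sum" and "Mann-Whitney" name the same test
wilcoxon_rank_sum = mann_whitney


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p.

    rho is the Pearson correlation of midranks.  For n <= 8 the p value is
    exact, enumerating all n! pairings; otherwise the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D samples")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= EXACT_SPEARMAN_MAX_N:
        count = 0
        total = 0
        for perm in permutations(ry):
            if abs(_spearman_rho(rx, np.array(perm))) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return TestResult(method="spearman", statistic=rho,
                          p_value=count / total, n_per_group=(n,),
                          approach="exact")
    res = stats.spearmanr(x, y)
    return TestResult(method="spearman", statistic=rho,
                      p_value=float(res.pvalue), n_per_group=(n,),
                      approach="asymptotic")


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table, df = 1.

    Continuity (Yates) correction off by default; enable with
    ``correction=True``.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=correction)
    return TestResult(method="chi_square", statistic=float(chi2),
                      p_value=float(p),
                      n_per_group=tuple(int(r) for r in tab.sum(axis=1)),
                      approach="asymptotic")


# ----------------------------------------------------------------------
# mixed-design repeated-measures ANOVA
# ----------------------------------------------------------------------

def _gg_epsilon(deviations: np.ndarray, df_pool: int) -> float:
    """Greenhouse-Geisser epsilon from pooled within-group deviations.

    ``deviations`` holds each subject's timecourse minus its group's mean
    timecourse; the pooled covariance is double-centered and epsilon is
    ``tr(S)^2 / ((k-1) sum(S^2))``, clamped to [1/(k-1), 1].
    """
    k = deviations.shape[1]
    s = deviations.T @ deviations / df_pool
    c = np.eye(k) - np.full((k, k), 1.0 / k)
    sc = c @ s @ c
    tr = np.trace(sc)
    denom = (k - 1) * float((sc * sc).sum())
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova_group_time(data: TacMatrix) -> AnovaTable:
    """Two-way mixed ANOVA: between-subject group, within-subject time.

    Sums of squares follow the classical weighted-means decomposition for a
    design balanced over time (every subject observed at every timepoint)
    with possibly unequal group sizes.  The group effect is tested against
    subjects-within-groups; time and the group x time interaction against
    the within-subject residual, with Greenhouse-Geisser-corrected degrees
    of freedom (epsilon estimated from the pooled within-group covariance).
    """
    y = data.values
    n, k = y.shape
    labels, inv = np.unique(data.groups, return_inverse=True)
    g = labels.size
    if g < 2:
        raise ValueError("need at least two groups")
    if k < 2:
        raise ValueError("need at least two timepoints")
    n_g = np.bincount(inv)
    if np.any(n_g < 2):
        raise ValueError("need at least two subjects per group")

    grand = y.mean()
    subj_mean = y.mean(axis=1)  # (n,)
    group_mean = np.array([subj_mean[inv == j].mean() for j in range(g)])
    time_mean = y.mean(axis=0)  # (k,)
    cell_mean = np.vstack([y[inv == j].mean(axis=0) for j in range(g)])  # (g,k)

    ss_group = k * float((n_g * (group_mean - grand) ** 2).sum())
    ss_subj = k * float(((subj_mean - group_mean[inv]) ** 2).sum())
    ss_time = n * float(((time_mean - grand) ** 2).sum())
    inter_dev = cell_mean - group_mean[:, None] - time_mean[None, :] + grand
    ss_inter = float((n_g[:, None] * inter_dev**2).sum())
    resid = y - subj_mean[:, None] - cell_mean[inv] + group_mean[inv][:, None]
    ss_resid = float((resid**2).sum())

    df_group, df_subj = g - 1, n - g
    df_time = k - 1
    df_inter = (g - 1) * (k - 1)
    df_resid = (n - g) * (k - 1)

    eps = _gg_epsilon(y - cell_mean[inv], n - g)

    def f_ratio(ss_eff, df_eff, ss_err, df_err):
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        if ms_err == 0.0:  # degenerate (e.g. exactly repeated data)
            return 0.0 if ms_eff == 0.0 else np.inf
        return ms_eff / ms_err

    f_group = f_ratio(ss_group, df_group, ss_subj, df_subj)
    f_time = f_ratio(ss_time, df_time, ss_resid, df_resid)
    f_inter = f_ratio(ss_inter, df_inter, ss_resid, df_resid)

    p_group = float(stats.f.sf(f_group, df_group, df_subj))
    p_time = float(stats.f.sf(f_time, eps * df_time, eps * df_resid))
    p_inter = float(stats.f.sf(f_inter, eps * df_inter, eps * df_resid))

    return AnovaTable(
        group=AnovaEffect("group", ss_group, df_group, df_subj, f_group,
                          1.0, df_group, df_subj, p_group),
        time=AnovaEffect("time", ss_time, df_time, df_resid, f_time,
                         eps, eps * df_time, eps * df_resid, p_time),
        interaction=AnovaEffect("interaction", ss_inter, df_inter, df_resid,
                                f_inter, eps, eps * df_inter, eps * df_resid,
                                p_inter),
    )


# ----------------------------------------------------------------------
# multiplicity
# ----------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pointwise_group_tests(data: TacMatrix, alpha: float = 0.05):
    """Per-timepoint rank-sum group tests with BH-FDR across the family.

    The family is all timepoints of one panel.  Timepoints where every
    subject shares one value (e.g. t = 0) are trivially non-significant
    (p = 1).  Returns ``(results, p_adjusted, significant_indices)``.
    """
    labels = np.unique(data.groups)
    if labels.size != 2:
        raise ValueError("pointwise tests require exactly two groups")
    a = data.values[data.groups == labels[0]]
    b = data.values[data.groups == labels[1]]
    results: list[TestResult] = []
    for j in range(data.values.shape[1]):
        col_a, col_b = a[:, j], b[:, j]
        if np.ptp(data.values[:, j]) == 0:
            results.append(TestResult(method="mann_whitney",
                                      statistic=col_a.size * col_b.size / 2.0,
                                      p_value=1.0,
                                      n_per_group=(col_a.size, col_b.size)))
        else:
            results.append(mann_whitney(col_a, col_b))
    p_adj = bh_fdr([r.p_value for r in results])
    significant = np.flatnonzero(p_adj <= alpha)
    return results, p_adj, significant
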