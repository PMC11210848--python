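"""Group-level statistics: nonparametric tests, the voxelwise
group-by-time interaction map, and the brain-behavior regression.

Cluster medians and task performance are compared with the Wilcoxon
rank-sum test (between groups at one time point) and the Wilcoxon
signed-rank test (between time points within a group); neurocognitive-
style continuous measures use Student's and paired t-tests.  All p
values are two-sided and reported raw: the analyses are exploratory and
no multiple-comparison adjustment is applied anywhere in this module.

The signed-rank and rank-sum tests are exact for small samples: the
null distribution of the statistic is enumerated by dynamic programming
over (mid)ranks, so the reported p is the exact permutation p rather
than an asymptotic approximation.  Larger samples fall back to the
normal approximation with tie and continuity corrections.

The group-by-time interaction on a named contrast is computed in the
two-stage form that is exact for two time points: each participant's
follow-up minus baseline difference map is formed, and the differences
are compared between groups with a pooled-variance t statistic per
voxel (df = n_participants - 2).  This avoids committing to a
within-participant covariance structure while testing exactly the
interaction contrast of the full factorial layout.

The brain-behavior model regresses the per-cluster 2-back BOLD change
on the 2-back omission-error change with a group main effect and a
group-by-change interaction:

    E[BOLD_diff | OM_diff, grp] = b0 + b1*OM_diff + b2*grp + b3*OM_diff*grp

with grp coded control = 0, treated = 1, so the control slope is b1 and
the treated slope b1 + b3 (standard error by the delta method from the
coefficient covariance).  Change scores default to follow-up minus
baseline; the opposite convention only flips slope signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grid import VoxelGrid

__all__ = [
    "TestResult",
    "InteractionMap",
    "RegressionFit",
    "SlopeTest",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "t_tests",
    "factorial_interaction_map",
    "brain_behavior_regression",
    "cluster_timepoint_tests",
    "cluster_group_tests",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    n: tuple
    test: str
    description: str = ""
    method: str = ""  # "exact" or "normal-approximation"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} out of [0, 1]")


def _signed_rank_exact_cdf(double_ranks: np.ndarray, w2: int) -> float:
    """P(2*W+ <= w2) by DP over all 2^n equiprobable sign assignments.

    ``double_ranks`` are midranks times two (integers even with ties).
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    return float(counts[: min(w2, total) + 1].sum())


def wilcoxon_signed_rank(differences, exact_max_n: int = 25, description: str = "") -> TestResult:
    """Wilcoxon signed-rank test on paired differences (two-sided).

    Zero differences are dropped (Wilcoxon's original rule), |d| are
    midranked, and the statistic is W = min(W+, W-).  For n <= 25 pairs
    the p value is exact over all sign assignments; beyond that a normal
    approximation with tie and continuity corrections is used.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be one-dimensional")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the signed-rank test is degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= exact_max_n:
        double_ranks = np.round(2 * ranks).astype(int)
        p = min(1.0, 2.0 * _signed_rank_exact_cdf(double_ranks, int(round(2 * w))))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w - mean + 0.5) / np.sqrt(var)  # w <= mean, continuity toward the mean
        p = min(1.0, 2.0 * stats.norm.cdf(z))
        method = "normal-approximation"
    return TestResult(
        statistic=w,
        p_value=p,
        n=(n,),
        test="wilcoxon-signed-rank",
        description=description,
        method=method,
    )


def _rank_sum_exact_cdf(n_a: int, n_total: int, w: int) -> tuple[float, float]:
    """(P(W <= w), P(W >= w)) for the rank sum of n_a untied ranks of 1..n_total."""
    # DP over subsets: ways[k][s] = #subsets of size k with rank sum s
    max_sum = n_total * (n_total + 1) // 2
    ways = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(n_a, r), 0, -1):
            ways[k, r:] += ways[k - 1, : max_sum + 1 - r]
    dist = ways[n_a]
    dist /= dist.sum()
    lo = float(dist[: w + 1].sum())
    hi = float(dist[w:].sum())
    return lo, hi


def wilcoxon_rank_sum(sample_a, sample_b, exact_max_n: int = 10, description: str = "") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    The statistic is the rank sum of ``sample_a`` in the pooled
    midranked data.  When the smaller sample has at most ``exact_max_n``
    observations and there are no ties, the p value is exact by
    enumeration of rank assignments; otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    has_ties = np.unique(pooled).size < n

    if min(n_a, n_b) <= exact_max_n and not has_ties:
        lo, hi = _rank_sum_exact_cdf(n_a, n, int(round(w)))
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact"
    else:
        mean = n_a * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p, z = 1.0, 0.0
        else:
            shift = w - mean
            z = (shift - np.sign(shift) * 0.5) / np.sqrt(var) if shift != 0 else 0.0
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        method = "normal-approximation"
    return TestResult(
        statistic=w,
        p_value=p,
        n=(n_a, n_b),
        test="wilcoxon-rank-sum",
        description=description,
        method=method,
    )


def t_tests(a, b, paired: bool = False, description: str = "") -> TestResult:
    """Student's (unpaired) or paired-sample t test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equally sized samples")
        if a.size < 2:
            raise ValueError("paired test needs at least 2 pairs")
        d = a - b
        if np.all(d == d[0]):
            raise ValueError(
                "paired differences are constant (zero standard error); t is undefined"
            )
        res = stats.ttest_rel(a, b)
        n = (a.size,)
        name = "paired-t"
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("two-sample test needs n >= 2 per sample")
        res = stats.ttest_ind(a, b, equal_var=True)
        n = (a.size, b.size)
        name = "student-t"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        test=name,
        description=description,
    )


@dataclass(eq=False)
class InteractionMap:
    """Voxelwise T map of the group-by-time interaction on a contrast."""

    grid: VoxelGrid | None
    t_values: np.ndarray
    df: int
    contrast: str
    mask: np.ndarray | None = None


def factorial_interaction_map(
    baseline_maps: np.ndarray,
    followup_maps: np.ndarray,
    groups,
    grid: VoxelGrid | None = None,
    mask: np.ndarray | None = None,
    contrast: str = "",
) -> InteractionMap:
    """Group-by-time interaction T statistic per voxel.

    ``baseline_maps`` and ``followup_maps`` stack one contrast map per
    participant along axis 0; ``groups`` codes control = 0, treated = 1.
    The interaction is tested as a pooled-variance two-sample t on the
    within-participant difference maps (treated minus control), which
    for two time points is exactly the factorial interaction contrast.
    A positive T means the treated group's change exceeds the controls'.
    Voxels with zero difference everywhere get T = 0.
    """
    base = np.asarray(baseline_maps, dtype=float)
    follow = np.asarray(followup_maps, dtype=float)
    groups = np.asarray(groups)
    if base.shape != follow.shape or base.shape[0] != groups.size:
        raise ValueError("map stacks and group labels are inconsistent")
    g1 = groups.astype(bool)
    n1, n0 = int(g1.sum()), int((~g1).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each group needs >= 2 participants (got control={n0}, treated={n1})")

    diff = follow - base
    d1, d0 = diff[g1], diff[~g1]
    m1, m0 = d1.mean(axis=0), d0.mean(axis=0)
    ss = ((d1 - m1) ** 2).sum(axis=0) + ((d0 - m0) ** 2).sum(axis=0)
    df = n1 + n0 - 2
    pooled_var = ss / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n0))
    num = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, num / np.where(se > 0, se, 1.0), np.where(num == 0, 0.0, np.inf * np.sign(num)))
    if mask is not None:
        t = np.where(mask, t, np.nan)
    return InteractionMap(grid=grid, t_values=t, df=df, contrast=contrast, mask=mask)


@dataclass(frozen=True)
class SlopeTest:
    """A per-group slope estimate with its uncertainty."""

    estimate: float
    se: float
    t: float
    p_value: float


@dataclass(eq=False)
class RegressionFit:
    """Fitted brain-behavior interaction regression."""

    params: np.ndarray  # b0, b1 (OM_diff), b2 (grp), b3 (OM_diff x grp)
    bse: np.ndarray
    cov: np.ndarray
    df_resid: int
    n: int
    slopes: dict  # "control" -> SlopeTest (b1), "treated" -> SlopeTest (b1+b3)
    result: object  # statsmodels results, for diagnostics


def brain_behavior_regression(bold_diff, om_diff, grp) -> RegressionFit:
    """OLS fit of BOLD change on omission change with group interaction.

    Requires both groups present and at least 4 distinct design rows
    (the model has 4 coefficients).  Returns the coefficient vector and
    the two slopes of interest: b1 (control group) and b1 + b3 (treated
    group), each with delta-method SE and two-sided p.
    """
    y = np.asarray(bold_diff, dtype=float)
    om = np.asarray(om_diff, dtype=float)
    g = np.asarray(grp, dtype=float)
    if not (y.size == om.size == g.size):
        raise ValueError("bold_diff, om_diff, grp must be equally sized")
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("grp must be coded control = 0, treated = 1")
    if np.unique(g).size < 2:
        raise ValueError("both groups must be present; b2 and b3 are inestimable otherwise")
    X = np.column_stack([np.ones_like(y), om, g, om * g])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("design matrix is rank deficient (need >= 4 distinct rows)")
    if y.size <= 4:
        raise ValueError("need more observations than the 4 coefficients")

    model = sm.OLS(y, X)
    res = model.fit()
    cov = np.asarray(res.cov_params())
    df = int(res.df_resid)

    def slope(idx: tuple[int, ...]) -> SlopeTest:
        est = float(sum(res.params[i] for i in idx))
        var = float(sum(cov[i, j] for i in idx for j in idx))
        se = float(np.sqrt(max(var, 0.0)))
        if se > 0:
            t = est / se
            p = float(2 * stats.t.sf(abs(t), df))
        else:  # exact interpolation: zero residual variance
            t = 0.0 if est == 0 else float(np.inf) * np.sign(est)
            p = 1.0 if est == 0 else 0.0
        return SlopeTest(estimate=est, se=se, t=float(t), p_value=p)

    return RegressionFit(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        cov=cov,
        df_resid=df,
        n=int(y.size),
        slopes={"control": slope((1,)), "treated": slope((1, 3))},
        result=res,
    )


# --- convenience sweeps over cluster-median tables ----------------------


def cluster_timepoint_tests(median_table: pd.DataFrame, level: int = 2) -> pd.DataFrame:
    """Within-group signed-rank test across time points, per cluster."""
    rows = []
    for (cluster_id, group), sub in median_table.groupby(["cluster_id", "group"]):
        sub = sub[sub["level"] == level]
        wide = sub.pivot(index="participant", columns="time_point", values="median_bold")
        if not {"baseline", "followup"} <= set(wide.columns):
            continue
        d = (wide["followup"] - wide["baseline"]).dropna().to_numpy()
        if d.size == 0 or np.all(d == 0):
            continue
        r = wilcoxon_signed_rank(d, description=f"cluster {cluster_id} {group}: followup vs baseline")
        rows.append(
            {
                "cluster_id": cluster_id,
                "group": group,
                "level": level,
                "n": r.n[0],
                "W": r.statistic,
                "p": r.p_value,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)


def cluster_group_tests(median_table: pd.DataFrame, time_point: str = "followup", level: int = 2) -> pd.DataFrame:
    """Between-group rank-sum test at one time point, per cluster."""
    rows = []
    for cluster_id, sub in median_table.groupby("cluster_id"):
        sub = sub[(sub["level"] == level) & (sub["time_point"] == time_point)]
        a = sub.loc[sub["group"] == "control", "median_bold"].to_numpy()
        b = sub.loc[sub["group"] == "treated", "median_bold"].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        r = wilcoxon_rank_sum(a, b, description=f"cluster {cluster_id}: control vs treated at {time_point}")
        rows.append(
            {
                "cluster_id": cluster_id,
                "time_point": time_point,
                "level": level,
                "n_control": r.n[0],
                "n_treated": r.n[1],
                "W": r.statistic,
                "p": r.p_value,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)
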