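"""Recovery trajectories, trajectory AUC and group comparisons.

The daily 0-18 composites form one recovery trajectory per animal
(baseline day 0 through post-operative day 6).  Overall recovery is
summarised by the trapezoidal area under that trajectory (score x days;
a naive animal holding the assumed mean score of 17 over the 6-day window
has AUC 102).  Group differences are tested nonparametrically with a
tie-corrected Kruskal-Wallis H (exact permutation p-value at small n) and
Dunn's rank-based post-hoc z-tests against a reference group; parametric
counterparts (repeated-measures ANOVA with Dunnett post-hoc, one-way ANOVA
on AUCs) delegate to statsmodels/scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Trajectory",
    "GroupComparison",
    "trajectories_from_composites",
    "trajectory_auc",
    "kruskal_wallis",
    "exact_kw_pvalue",
    "dunn_posthoc",
    "group_trajectory_summary",
    "required_sample_size",
    "repeated_measures_anova",
    "dunnett_posthoc",
    "anova_oneway",
]


class InsufficientTrajectoryError(ValueError):
    """A trajectory needs at least two observed days for an AUC."""


@dataclass(frozen=True)
class Trajectory:
    """Ordered (day, composite total) series for one animal, baseline included."""

    animal_id: str
    group: str
    days: tuple[int, ...]
    totals: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))
        object.__setattr__(self, "totals", tuple(float(t) for t in self.totals))
        if len(self.days) != len(self.totals):
            raise ValueError("days and totals must have equal length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(not 0.0 <= t <= 18.0 for t in self.totals):
            raise ValueError("composite totals must lie in [0, 18]")


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus statistic plus optional per-group post-hoc adjusted p-values."""

    method: str
    statistic: float
    df: float | None
    p_value: float
    exact_p_value: float | None = None
    exact_mid_p_value: float | None = None
    posthoc: Mapping[str, float] | None = None


def trajectories_from_composites(
    composites: pd.DataFrame, baseline_total: float = 18.0
) -> list[Trajectory]:
    """Build per-animal trajectories from a composite table.

    The baseline day 0 is not itself scored (every %MPE is 0 by
    construction), so a day-0 point at ``baseline_total`` (default: the
    maximum 18) is prepended when absent.
    """
    out = []
    for (animal, group), sub in composites.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("day")
        days = sub["day"].tolist()
        totals = sub["total"].tolist()
        if 0 not in days:
            days = [0] + days
            totals = [baseline_total] + totals
        out.append(Trajectory(animal_id=str(animal), group=str(group),
                              days=tuple(days), totals=tuple(totals)))
    return out


def trajectory_auc(traj: Trajectory) -> float:
    """Trapezoidal area under a recovery trajectory (score x days).

    Integration runs over the observed days only; a constant score c over a
    span of T days gives exactly c*T.
    """
    if len(traj.days) < 2:
        raise InsufficientTrajectoryError(
            f"trajectory for {traj.animal_id!r} has fewer than 2 points"
        )
    return float(np.trapezoid(traj.totals, traj.days))


def _kw_statistic(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Tie-corrected Kruskal-Wallis H and total sample size."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom == 0.0:  # every value identical
        return 0.0, n_total
    return h / denom, n_total


def exact_kw_pvalue(
    groups: Sequence[Sequence[float]], convention: str = "standard"
) -> float:
    """Exact permutation p-value for the Kruskal-Wallis statistic.

    Enumerates every assignment of the pooled observations to groups of the
    observed sizes.  ``convention="standard"`` counts the fraction of
    assignments with H at least as large as observed (conservative: the
    whole observed atom is included); ``convention="mid"`` counts half the
    observed atom (the mid-p summary of a discrete null, the right
    comparator for a continuous approximation).  Feasible for total n up to
    ~12.
    """
    p_std, p_mid = _exact_kw_pvalues([np.asarray(g, dtype=float) for g in groups])
    if convention == "standard":
        return p_std
    if convention == "mid":
        return p_mid
    raise ValueError(f"unknown convention {convention!r}")


def _exact_kw_pvalues(arrays: Sequence[np.ndarray]) -> tuple[float, float]:
    """(standard, mid-p) exact permutation p-values by full enumeration."""
    h_obs, _ = _kw_statistic(arrays)
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    n = pooled.size
    above = tied = total = 0

    # enumerate partitions of indices into ordered groups of the given sizes
    def partitions(remaining: frozenset, sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        rem_sorted = sorted(remaining)
        for combo in itertools.combinations(rem_sorted, k):
            rest = remaining - set(combo)
            for tail in partitions(frozenset(rest), sizes_left[1:]):
                yield [combo] + tail

    for part in partitions(frozenset(range(n)), sizes):
        h, _ = _kw_statistic([pooled[list(idx)] for idx in part])
        total += 1
        if h > h_obs + 1e-12:
            above += 1
        elif h >= h_obs - 1e-12:
            tied += 1
    return (above + tied) / total, (above + 0.5 * tied) / total


def kruskal_wallis(
    groups: Sequence[Sequence[float]] | Mapping[str, Sequence[float]],
    exact_max_n: int = 10,
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis test across two or more groups.

    Returns the H statistic with its chi-square (k-1 df) p-value; when the
    total sample size is at most ``exact_max_n`` an exact permutation
    p-value is computed as well.  If every pooled value is identical,
    H = 0 and p = 1.
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    h, n_total = _kw_statistic(arrays)
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
    exact_p = exact_mid_p = None
    if n_total <= exact_max_n:
        exact_p, exact_mid_p = _exact_kw_pvalues(arrays)
    return GroupComparison(method="kruskal-wallis", statistic=float(h),
                           df=float(df), p_value=p, exact_p_value=exact_p,
                           exact_mid_p_value=exact_mid_p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    adjustment: str = "holm",
) -> dict[str, dict[str, float]]:
    """Dunn's rank-based post-hoc comparisons against a reference group.

    z-statistics use mean ranks from the pooled ranking with the pooled
    tie-corrected rank variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    Two-sided p-values are adjusted across the comparisons (``holm`` by
    default; any method understood by statsmodels' ``multipletests``, or
    ``"none"``).
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} absent")
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([arrays[k] for k in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for k in labels:
        size = arrays[k].size
        mean_ranks[k] = float(ranks[start:start + size].mean())
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    others = [k for k in labels if k != reference]
    zs, ps = [], []
    for k in others:
        se = math.sqrt(var_unit * (1.0 / arrays[k].size + 1.0 / arrays[reference].size))
        z = 0.0 if se == 0 else (mean_ranks[k] - mean_ranks[reference]) / se
        zs.append(z)
        ps.append(float(2.0 * sps.norm.sf(abs(z))))
    if adjustment in (None, "none"):
        adj = list(ps)
    else:
        adj = list(multipletests(ps, method=adjustment)[1])
    return {
        k: {"z": zs[i], "p": ps[i], "p_adj": float(min(adj[i], 1.0))}
        for i, k in enumerate(others)
    }


def group_trajectory_summary(composites: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-day median and interquartile range of the composite.

    Percentiles use the linear-interpolation convention (numpy default).
    """
    if composites.empty:
        raise ValueError("no composites to summarise")
    out = (
        composites.groupby(["group", "day"])["total"]
        .agg(median="median",
             q1=lambda s: float(np.percentile(s, 25)),
             q3=lambda s: float(np.percentile(s, 75)),
             n="count")
        .reset_index()
    )
    return out


def required_sample_size(
    mean: float,
    sd: float,
    reduction_fraction: float,
    power: float = 0.8,
    alpha: float = 0.05,
    max_n: int = 10_000,
) -> int:
    """Smallest n per group detecting a fractional reduction of the mean.

    Power of a two-sided two-sample t-test at level ``alpha`` for effect
    size d = mean*reduction_fraction/sd, computed iteratively from the
    noncentral t distribution.  The design assumption behind the composite
    (mean 17, SD 4, 50% reduction, power 0.8) yields n = 5 per group.
    """
    if not 0.0 < reduction_fraction < 1.0:
        raise ValueError("reduction_fraction must lie in (0, 1)")
    if not 0.0 < power < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("power and alpha must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = mean * reduction_fraction / sd
    for n in range(2, max_n + 1):
        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2.0)
        tcrit = sps.t.isf(alpha / 2.0, df)
        achieved = float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
        if achieved >= power:
            return n
    raise ValueError("infeasible parameters: required n exceeds max_n")


def repeated_measures_anova(composites: pd.DataFrame) -> pd.DataFrame:
    """One-way repeated-measures ANOVA of the composite over days.

    Thin delegation to statsmodels ``AnovaRM`` (subject = animal, within =
    day); the bespoke machinery of this package is the score, AUC and
    rank-based tests.
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(data=composites, depvar="total", subject="animal_id",
                  within=["day"]).fit()
    return res.anova_table


def dunnett_posthoc(
    groups: Mapping[str, Sequence[float]], reference: str
) -> dict[str, float]:
    """Dunnett many-to-one comparisons vs a control group (scipy delegation)."""
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} absent")
    others = [k for k in groups if k != reference]
    res = sps.dunnett(*[np.asarray(groups[k], dtype=float) for k in others],
                      control=np.asarray(groups[reference], dtype=float))
    return {k: float(p) for k, p in zip(others, res.pvalue)}


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across groups (used for trajectory AUCs)."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    return GroupComparison(method="anova-oneway", statistic=float(f),
                           df=float(k - 1), p_value=float(p))
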