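"""Domain coalescence time courses, number ratios, and group statistics.

Phase-separated vesicles demix into many Ld domains that coarsen by
coalescence; a branched actin network polymerized on the domains arrests
this.  The "domain number ratio" N_t / N_0 (domain count at t = 10 or 60
minutes over the initial count) quantifies stabilization: 1 means no
coalescence, the minimum means complete coarsening.  Initial counts are
binned into the three categories used to relate domain number to actin
structure: n_d = 2, 2 < n_d <= 10, and n_d > 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DomainTrajectory",
    "GroupComparison",
    "build_trajectory",
    "categorize_by_nd",
    "compare_groups",
    "compare_all_pairs",
    "significance_tier",
]

CONDITIONS = ("bare", "spvca", "actin")


@dataclass
class DomainTrajectory:
    times_min: np.ndarray
    counts: np.ndarray
    condition: str
    N0: int | None = None
    N10: int | None = None
    N60: int | None = None
    ratio_10: float | None = None
    ratio_60: float | None = None
    initial_group: str = "other"      # "32-36", "8-12" or "other"
    flags: list[str] = field(default_factory=list)


def _nearest_count(times, counts, target, tol):
    d = np.abs(times - target)
    i = int(np.argmin(d))
    if d[i] > tol:
        return None
    return int(counts[i])


def _ratio(n_t, n0, flags, label):
    if n_t is None:
        flags.append(f"no_frame_{label}")
        return None
    r = n_t / n0
    if r > 1.0:
        # the model forbids fission; counts above N0 are counting noise
        warnings.warn(f"domain ratio {label} = {r:.3f} > 1 clipped to 1", stacklevel=3)
        flags.append(f"clipped_{label}")
        r = 1.0
    return float(r)


def build_trajectory(
    counts,
    times_min,
    condition: str = "bare",
    t_tol_min: float = 2.0,
) -> DomainTrajectory:
    """Assemble per-frame domain counts into a trajectory with N_t/N_0 ratios.

    ``counts`` may be integers or objects exposing ``n_d``.  N0, N10 and N60
    are taken from the frames nearest to 0, 10 and 60 min within
    ``t_tol_min``; a missing 60-min frame leaves ratio_60 absent (flagged).
    """
    counts = np.array([c.n_d if hasattr(c, "n_d") else int(c) for c in counts])
    times_min = np.asarray(times_min, dtype=float)
    if len(counts) != len(times_min):
        raise ValueError("one count per timestamp required")
    if len(counts) < 2:
        raise ValueError("need at least two frames")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    order = np.argsort(times_min)
    times_min, counts = times_min[order], counts[order]
    if np.min(np.abs(times_min)) > t_tol_min:
        raise ValueError(f"no frame within {t_tol_min} min of t=0")

    flags: list[str] = []
    n0 = _nearest_count(times_min, counts, 0.0, t_tol_min)
    traj = DomainTrajectory(times_min=times_min, counts=counts,
                            condition=condition, N0=n0, flags=flags)
    if n0 == 0:
        flags.append("N0_zero_ratio_undefined")
        return traj
    traj.N10 = _nearest_count(times_min, counts, 10.0, t_tol_min)
    traj.N60 = _nearest_count(times_min, counts, 60.0, t_tol_min)
    traj.ratio_10 = _ratio(traj.N10, n0, flags, "10")
    traj.ratio_60 = _ratio(traj.N60, n0, flags, "60")
    if 32 <= n0 <= 36:
        traj.initial_group = "32-36"
    elif 8 <= n0 <= 12:
        traj.initial_group = "8-12"
    return traj


def categorize_by_nd(trajectories) -> dict[str, list]:
    """Partition trajectories by initial domain count.

    a: n_d = 2; b: 2 < n_d <= 10 (upper bound inclusive); c: n_d > 10.
    Trajectories without a defined N0 >= 2 are collected under "excluded".
    """
    cats: dict[str, list] = {"a": [], "b": [], "c": [], "excluded": []}
    for tr in trajectories:
        n0 = tr.N0 if hasattr(tr, "N0") else int(tr)
        if n0 is None or n0 < 2:
            cats["excluded"].append(tr)
        elif n0 == 2:
            cats["a"].append(tr)
        elif n0 <= 10:
            cats["b"].append(tr)
        else:
            cats["c"].append(tr)
    return cats


def significance_tier(p: float) -> str:
    """n.s. p > 0.05; * p <= 0.05; ** p <= 0.01; *** p <= 0.001."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must be in [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    values: dict[str, np.ndarray]
    test: str
    statistic: float
    p_value: float
    tier: str


def compare_groups(
    values_by_group: dict,
    design: str = "independent",
    normality_assumed: bool = False,
    exact_max_n: int = 8,
) -> GroupComparison:
    """Two-sided two-group comparison following the study's testing policy.

    independent + nonparametric -> Mann-Whitney U (exact for groups of at
    most ``exact_max_n`` without ties, normal approximation with tie
    correction otherwise); paired -> Wilcoxon signed-rank; independent +
    normal -> Welch's t.  The significance tier uses the n.s./*/**/***
    thresholds.
    """
    if len(values_by_group) != 2:
        raise ValueError("compare_groups takes exactly two groups; see compare_all_pairs")
    (la, a), (lb, b) = [(k, np.asarray(v, dtype=float)) for k, v in values_by_group.items()]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")

    if design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires equal group sizes")
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a, b, alternative="two-sided")
        test = "wilcoxon_signed_rank"
    elif normality_assumed:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        test = "welch_t"
    else:
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(a), len(b)) <= exact_max_n and not has_ties) else "asymptotic"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                     use_continuity=False)
        stat, p = res.statistic, res.pvalue
        if np.isnan(p):              # all observations tied: no evidence either way
            p = 1.0
        test = "mann_whitney_u"
    p = float(min(p, 1.0))
    return GroupComparison(labels=(la, lb), values={la: a, lb: b}, test=test,
                           statistic=float(stat), p_value=p, tier=significance_tier(p))


def compare_all_pairs(values_by_group: dict, **kwargs) -> list[GroupComparison]:
    """Pairwise :func:`compare_groups` over every pair of groups."""
    labels = list(values_by_group)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = {labels[i]: values_by_group[labels[i]],
                    labels[j]: values_by_group[labels[j]]}
            out.append(compare_groups(pair, **kwargs))
    return out
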