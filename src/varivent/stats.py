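"""The study's statistical battery.

Paired t-tests for BASELINE-to-END changes, a balanced two-way
repeated-measures (split-plot) ANOVA with group as the between-subject and
timepoint as the within-subject factor, Kruskal-Wallis with Dunn's pairwise
rank tests, Spearman correlation, Holm-Sidak step-down adjustment,
Bonferroni level splitting, exact noncentral-t power analysis, and the
per-animal percent-change summary.

Cohort data are exchanged as long-format DataFrames with columns
``animal_id, group, timepoint, variable, value``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PowerSpec",
    "ComparisonResult",
    "bonferroni_alpha",
    "power_two_sample_t",
    "required_n_two_sample_t",
    "holm_sidak",
    "paired_t",
    "spearman",
    "kruskal_dunn",
    "one_way_anova",
    "rm_anova_two_way",
    "percent_change_table",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the two-sample t-test power / sample-size calculation."""

    effect_size_d: float = 2.21
    alpha: float = 0.05
    n_comparisons: int = 6
    target_power: float = 0.8
    alpha_star: float | None = None  # defaults to alpha / n_comparisons

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")
        if self.effect_size_d <= 0:
            raise ValueError("effect_size_d must be > 0")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.alpha_star is not None and not 0 < self.alpha_star <= self.alpha:
            raise ValueError("alpha_star must be in (0, alpha]")

    @property
    def level(self) -> float:
        """Per-comparison significance level actually used."""
        return self.alpha_star if self.alpha_star is not None else bonferroni_alpha(self.alpha, self.n_comparisons)


@dataclass(frozen=True)
class ComparisonResult:
    """One contrast with raw and family-adjusted p-values."""

    contrast: str
    statistic: float
    raw_p: float
    adjusted_p: float
    method: str
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "contrast": self.contrast,
            "statistic": self.statistic,
            "raw_p": self.raw_p,
            "adjusted_p": self.adjusted_p,
            "method": self.method,
        }
        d.update(self.extra)
        return d


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison level alpha / m."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def power_two_sample_t(n: int, d: float, alpha: float) -> float:
    """Exact power of a two-sided two-sample t-test with n per group.

    Uses the noncentral t distribution with df = 2n - 2 and noncentrality
    d * sqrt(n / 2).
    """
    if n < 2:
        raise ValueError("need n >= 2 per group")
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    if math.isnan(power):
        # scipy's noncentral t underflows at extreme noncentrality; fall back
        # to the asymptotic normal form, which is exact in that limit
        power = sps.norm.sf(tcrit - nc) + sps.norm.cdf(-tcrit - nc)
    return float(power)


def required_n_two_sample_t(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest per-group n reaching the target power at the adjusted level."""
    level = spec.level
    for n in range(2, n_max + 1):
        if power_two_sample_t(n, spec.effect_size_d, level) >= spec.target_power:
            return n
    raise RuntimeError(f"target power not reached by n = {n_max}")


def holm_sidak(
    pvalues,
    alpha: float = 0.05,
    labels: list[str] | None = None,
    statistics=None,
) -> list[ComparisonResult]:
    """Holm-Sidak step-down adjustment.

    With p-values sorted ascending, the i-th (1-based) adjusted value is
    ``max_{j<=i} 1 - (1 - p_(j))^(m - j + 1)`` clipped to 1; rejection at
    ``alpha`` is monotone. Results are returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, step)
        adj_sorted[i] = min(running, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted

    labels = labels if labels is not None else [f"p{i}" for i in range(m)]
    stats_arr = statistics if statistics is not None else [float("nan")] * m
    return [
        ComparisonResult(
            contrast=labels[i],
            statistic=float(stats_arr[i]),
            raw_p=float(p[i]),
            adjusted_p=float(adjusted[i]),
            method="holm-sidak",
            extra={"reject": bool(adjusted[i] <= alpha)},
        )
        for i in range(m)
    ]


def paired_t(before, after) -> ComparisonResult:
    """Two-sided paired t-test on (after - before)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be 1-D arrays of equal length")
    if len(before) < 2:
        raise ValueError("need >= 2 pairs")
    diff = after - before
    if np.std(diff, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t statistic undefined")
    t, p = sps.ttest_rel(after, before)
    return ComparisonResult(
        contrast="after - before",
        statistic=float(t),
        raw_p=float(p),
        adjusted_p=float(p),
        method="paired-t",
        extra={"df": len(before) - 1},
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p via the t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_dunn(
    groups,
    alpha: float = 0.05,
    labels: list[str] | None = None,
    adjust: str = "holm-sidak",
) -> dict:
    """Kruskal-Wallis H test with Dunn's pairwise z-tests on mean ranks.

    Ties are handled through the standard correction in both the H statistic
    (scipy) and the Dunn variance term. Pairwise p-values are adjusted by
    Holm-Sidak (default) or Bonferroni.

    Returns a dict with keys ``H``, ``p``, ``df``, and ``pairwise`` (a list
    of ComparisonResult).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs >= 1 observation")
    if adjust not in ("holm-sidak", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    labels = labels if labels is not None else [f"g{i}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        k = len(groups)
        return {"H": 0.0, "p": 1.0, "df": k - 1, "pairwise": []}

    H, p_kw = sps.kruskal(*groups)

    ranks = sps.rankdata(pooled)
    N = len(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i
    # tie correction for the Dunn variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))

    zs, raw_ps, pair_labels = [], [], []
    for i, j in itertools.combinations(range(len(groups)), 2):
        var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        zs.append(z)
        raw_ps.append(2.0 * sps.norm.sf(abs(z)))
        pair_labels.append(f"{labels[i]} vs {labels[j]}")

    if adjust == "holm-sidak":
        pairwise = holm_sidak(raw_ps, alpha=alpha, labels=pair_labels, statistics=zs)
    else:
        adj = np.minimum(np.asarray(raw_ps) * len(raw_ps), 1.0)
        pairwise = [
            ComparisonResult(
                contrast=pair_labels[i],
                statistic=float(zs[i]),
                raw_p=float(raw_ps[i]),
                adjusted_p=float(adj[i]),
                method="bonferroni",
                extra={"reject": bool(adj[i] <= alpha)},
            )
            for i in range(len(raw_ps))
        ]
    return {"H": float(H), "p": float(p_kw), "df": len(groups) - 1, "pairwise": pairwise}


def one_way_anova(groups, alpha: float = 0.05, labels: list[str] | None = None) -> dict:
    """One-way ANOVA with Holm-Sidak-adjusted pairwise t-tests.

    Returns a dict with ``F``, ``p``, and ``pairwise`` ComparisonResults.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = labels if labels is not None else [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("zero variance in the response: F undefined")
    F, p = sps.f_oneway(*groups)
    labels_, stats_, raw_ps = [], [], []
    for i, j in itertools.combinations(range(len(groups)), 2):
        st, pv = sps.ttest_ind(groups[i], groups[j])
        labels_.append(f"{labels[i]} vs {labels[j]}")
        stats_.append(float(st))
        raw_ps.append(float(pv))
    return {
        "F": float(F),
        "p": float(p),
        "pairwise": holm_sidak(raw_ps, alpha=alpha, labels=labels_, statistics=stats_),
    }


def _pivot_dv(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Wide (animal x timepoint) frame for one dependent variable."""
    sub = table[table["variable"] == dv]
    if sub.empty:
        raise ValueError(f"no records for variable {dv!r}")
    dup = sub.duplicated(["animal_id", "timepoint"])
    if dup.any():
        raise ValueError(f"duplicate records for variable {dv!r}")
    return sub.pivot(index=["animal_id", "group"], columns="timepoint", values="value")


def rm_anova_two_way(
    table: pd.DataFrame,
    dv: str,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> dict:
    """Balanced two-way repeated-measures (split-plot) ANOVA.

    Between-subject factor: ``group``; within-subject factor: ``timepoint``.
    The group effect is tested against subjects-within-groups, time and the
    group x time interaction against the within-subject residual. Unbalanced
    or incomplete designs are rejected.

    Post-hoc contrasts (Holm-Sidak adjusted as one family): pairwise group
    differences within each timepoint (two-sample t) and the within-group
    timepoint change (paired t).

    Returns a dict with ``anova`` (per-effect F, df, p) and ``posthoc``.
    """
    wide = _pivot_dv(table, dv)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.get_level_values("animal_id").tolist()
        raise ValueError(f"missing timepoint cells for animals {missing}")

    groups = wide.index.get_level_values("group")
    group_names = sorted(set(groups))
    a = len(group_names)
    timepoints = list(wide.columns)
    t = len(timepoints)
    if a < 2 or t < 2:
        raise ValueError("need >= 2 groups and >= 2 timepoints")
    sizes = {g: int((groups == g).sum()) for g in group_names}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"unbalanced design: group sizes {sizes}")
    n = next(iter(sizes.values()))
    if n < 2:
        raise ValueError("need >= 2 subjects per group")

    y = wide.to_numpy(dtype=float)  # (a*n) x t, rows grouped by subject
    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero variance in the response: F undefined")

    subj_means = y.mean(axis=1)
    ss_between_subj = t * float(((subj_means - gm) ** 2).sum())

    group_means = np.array([subj_means[groups == g].mean() for g in group_names])
    ss_group = n * t * float(((group_means - gm) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group

    time_means = y.mean(axis=0)
    ss_time = a * n * float(((time_means - gm) ** 2).sum())

    cell_means = np.array([y[groups == g].mean(axis=0) for g in group_names])  # a x t
    ss_cells = n * float(((cell_means - gm) ** 2).sum())
    ss_interaction = ss_cells - ss_group - ss_time

    ss_error = ss_total - ss_between_subj - ss_time - ss_interaction

    df_group, df_subj = a - 1, a * (n - 1)
    df_time, df_int = t - 1, (a - 1) * (t - 1)
    df_error = a * (n - 1) * (t - 1)
    if ss_subj_within <= 0 or ss_error <= 0:
        raise ValueError("zero-variance error term: F undefined")

    def f_and_p(ss_effect, df_effect, ss_err, df_err):
        F = (ss_effect / df_effect) / (ss_err / df_err)
        return float(F), float(sps.f.sf(F, df_effect, df_err))

    F_g, p_g = f_and_p(ss_group, df_group, ss_subj_within, df_subj)
    F_t, p_t = f_and_p(ss_time, df_time, ss_error, df_error)
    F_i, p_i = f_and_p(ss_interaction, df_int, ss_error, df_error)

    anova = {
        "group": {"F": F_g, "df1": df_group, "df2": df_subj, "p": p_g},
        "time": {"F": F_t, "df1": df_time, "df2": df_error, "p": p_t},
        "interaction": {"F": F_i, "df1": df_int, "df2": df_error, "p": p_i},
    }

    result = {"anova": anova, "dv": dv, "n_per_group": n, "posthoc": []}
    if not posthoc:
        return result

    labels_, stats_, raw_ps = [], [], []
    for tp_idx, tp in enumerate(timepoints):
        for gi, gj in itertools.combinations(range(a), 2):
            xi = y[groups == group_names[gi], tp_idx]
            xj = y[groups == group_names[gj], tp_idx]
            st, pv = sps.ttest_ind(xi, xj)
            labels_.append(f"{group_names[gi]} vs {group_names[gj]} @ {tp}")
            stats_.append(float(st))
            raw_ps.append(float(pv))
    if t == 2:
        for gi, g in enumerate(group_names):
            sub = y[groups == g]
            diff = sub[:, 1] - sub[:, 0]
            if np.std(diff, ddof=1) > 0:
                st, pv = sps.ttest_rel(sub[:, 1], sub[:, 0])
                labels_.append(f"{timepoints[1]} vs {timepoints[0]} @ {g}")
                stats_.append(float(st))
                raw_ps.append(float(pv))
    result["posthoc"] = holm_sidak(raw_ps, alpha=alpha, labels=labels_, statistics=stats_)
    return result


def percent_change_table(
    table: pd.DataFrame,
    baseline: str = "BASELINE",
    end: str = "END",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Group-mean per-animal percent change END vs BASELINE.

    The percent change is computed per animal, 100 * (END - BASELINE) /
    BASELINE, and then averaged within each group. This is not the percent
    change of the group means; the two differ whenever baselines vary.
    """
    variables = variables or sorted(table["variable"].unique())
    rows = []
    for dv in variables:
        wide = _pivot_dv(table, dv)
        if baseline not in wide.columns or end not in wide.columns:
            continue
        if (wide[baseline] == 0).any():
            bad = wide.index[wide[baseline] == 0].get_level_values("animal_id").tolist()
            raise ValueError(f"zero baseline for {dv!r} in animals {bad}")
        pct = 100.0 * (wide[end] - wide[baseline]) / wide[baseline]
        for g, vals in pct.groupby(level="group"):
            rows.append({"variable": dv, "group": g, "mean_pct_change": float(vals.mean())})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no paired BASELINE/END variables found")
    return out.pivot(index="variable", columns="group", values="mean_pct_change")
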