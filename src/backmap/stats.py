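"""Group-level inference for map metrics.

The statistical layer compares each map metric across pain-mechanism groups:
Shapiro-Wilk normality diagnostics, a Levene (median-centred) variance gate,
classic one-way ANOVA with Duncan's multiple range test when variances are
homogeneous, Welch's heteroscedasticity-robust ANOVA with Games-Howell pairwise
tests otherwise, eta-squared effect sizes, and Spearman rank correlations with
pain intensity.  No multiplicity adjustment is applied anywhere (exploratory
design).

Both omnibus tests are also available directly from printed group summaries
(mean, SD, n) -- the classic F and Welch F are functions of the sufficient
statistics only, which allows published tables to be recomputed without raw
data:

``F = [sum n_i (m_i - m)^2 / (k-1)] / [sum (n_i - 1) s_i^2 / (N-k)]``,
``eta^2 = SSB / (SSB + SSW)``.

Eta-squared is always the classic SSB / (SSB + SSW), including alongside the
Welch F (the convention used with published Welch rows).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSamples",
    "SummaryStats",
    "ComparisonResult",
    "PosthocResult",
    "CorrelationResult",
    "shapiro_wilk",
    "variance_homogeneity",
    "oneway_anova",
    "welch_anova",
    "anova_from_summary",
    "welch_from_summary",
    "duncan_posthoc",
    "games_howell",
    "spearman",
    "run_group_report",
    "GroupReport",
]


@dataclass
class GroupSamples:
    """Raw values of one metric, keyed by group label."""

    metric: str
    groups: dict[str, np.ndarray]
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def require(self, min_groups: int = 2, min_n: int = 2) -> None:
        if len(self.groups) < min_groups:
            raise ValueError(f"need >= {min_groups} groups, got {len(self.groups)}")
        for label, v in self.groups.items():
            if v.size < min_n:
                raise ValueError(f"group {label!r} has n={v.size} < {min_n}")


@dataclass(frozen=True)
class SummaryStats:
    """Per-group (mean, SD, n) summaries, e.g. transcribed from a published table."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise ValueError("labels, means, sds, ns must have equal length")
        if k < 2:
            raise ValueError("need >= 2 groups")
        if any(s < 0 for s in self.sds):
            raise ValueError("SDs must be non-negative")
        if any(n < 2 for n in self.ns):
            raise ValueError("each group needs n >= 2")

    @classmethod
    def from_samples(cls, samples: GroupSamples) -> "SummaryStats":
        labels = tuple(samples.labels)
        return cls(
            labels=labels,
            means=tuple(float(np.mean(samples.groups[g])) for g in labels),
            sds=tuple(float(np.std(samples.groups[g], ddof=1)) for g in labels),
            ns=tuple(int(samples.groups[g].size) for g in labels),
        )


@dataclass(frozen=True)
class ComparisonResult:
    F: float
    df1: float
    df2: float
    p: float
    eta_squared: float
    method: str  # "classic" | "welch"


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    p: float
    method: str  # "duncan" | "games_howell"
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    group: str
    rho: float
    p: float
    n: int


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (reported diagnostic; does not gate anything)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def variance_homogeneity(samples: GroupSamples, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Levene's test with median centering; equal_variances = (p >= alpha)."""
    samples.require()
    stat, p = sps.levene(*samples.groups.values(), center="median")
    return float(stat), float(p), bool(p >= alpha)


def _classic_eta(ssb: float, ssw: float) -> float:
    tot = ssb + ssw
    return ssb / tot if tot > 0 else 0.0


def oneway_anova(samples: GroupSamples) -> ComparisonResult:
    """Classic one-way ANOVA on raw data: F = MSB/MSW, eta^2 = SSB/(SSB+SSW)."""
    samples.require()
    groups = list(samples.groups.values())
    all_vals = np.concatenate(groups)
    gm = all_vals.mean()
    k = len(groups)
    N = all_vals.size
    ssb = sum(g.size * (g.mean() - gm) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, N - k
    if ssw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return ComparisonResult(
        F=float(f), df1=df1, df2=df2, p=p, eta_squared=_classic_eta(ssb, ssw), method="classic"
    )


def anova_from_summary(summary: SummaryStats) -> ComparisonResult:
    """Classic one-way ANOVA from per-group (mean, SD, n) only.

    Identical to ``oneway_anova`` on any raw data with these summaries:
    SSB = sum n_i (m_i - grand mean)^2, SSW = sum (n_i - 1) s_i^2.
    """
    m = np.asarray(summary.means)
    s = np.asarray(summary.sds)
    n = np.asarray(summary.ns, dtype=float)
    k = m.size
    N = n.sum()
    gm = (n * m).sum() / N
    ssb = float((n * (m - gm) ** 2).sum())
    ssw = float(((n - 1) * s**2).sum())
    df1, df2 = k - 1, N - k
    if ssw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return ComparisonResult(
        F=float(f), df1=df1, df2=float(df2), p=p, eta_squared=_classic_eta(ssb, ssw),
        method="classic",
    )


def _welch(means: np.ndarray, variances: np.ndarray, ns: np.ndarray) -> tuple[float, float, float, float]:
    """Welch F, df1, df2, p from sufficient statistics (weights n_i / s_i^2)."""
    if np.any(variances <= 0):
        raise ValueError("Welch ANOVA requires positive within-group variance in every group")
    k = means.size
    w = ns / variances
    W = w.sum()
    mh = (w * means).sum() / W
    a = (w * (means - mh) ** 2).sum() / (k - 1)
    t = (((1 - w / W) ** 2) / (ns - 1)).sum()
    b = 2.0 * (k - 2) / (k**2 - 1) * t
    f = a / (1.0 + b)
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * t)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), float(df1), float(df2), p


def welch_anova(samples: GroupSamples) -> ComparisonResult:
    """Welch's heteroscedasticity-robust one-way ANOVA on raw data.

    Eta-squared is still the classic SSB/(SSB+SSW) of the same data.
    """
    samples.require()
    groups = list(samples.groups.values())
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    ns = np.array([g.size for g in groups], dtype=float)
    f, df1, df2, p = _welch(means, variances, ns)
    gm = np.concatenate(groups).mean()
    ssb = float((ns * (means - gm) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    return ComparisonResult(F=f, df1=df1, df2=df2, p=p, eta_squared=_classic_eta(ssb, ssw), method="welch")


def welch_from_summary(summary: SummaryStats) -> ComparisonResult:
    """Welch ANOVA from per-group (mean, SD, n); equals ``welch_anova`` on
    matching raw data (Welch F depends only on the sufficient statistics)."""
    m = np.asarray(summary.means)
    s = np.asarray(summary.sds)
    n = np.asarray(summary.ns, dtype=float)
    f, df1, df2, p = _welch(m, s**2, n)
    gm = (n * m).sum() / n.sum()
    ssb = float((n * (m - gm) ** 2).sum())
    ssw = float(((n - 1) * s**2).sum())
    return ComparisonResult(F=f, df1=df1, df2=df2, p=p, eta_squared=_classic_eta(ssb, ssw), method="welch")


def duncan_posthoc(samples: GroupSamples, alpha: float = 0.05) -> list[PosthocResult]:
    """Duncan's multiple range test.

    Group means are ranked; a pair spanning r ordered means is compared against
    the studentized-range critical value at the span-dependent protection level
    1 - (1-alpha)^(r-1).  The reported p per pair is the smallest
    protection-adjusted alpha at which the pair separates,
    ``1 - (1 - P_r(q_obs))^(1/(r-1))``, with the multiple-range monotonicity
    constraint applied (a pair inside a non-separated span cannot separate).
    Unequal group sizes use the harmonic mean n of the pair.
    """
    samples.require()
    labels = samples.labels
    groups = [samples.groups[g] for g in labels]
    k = len(groups)
    res = oneway_anova(samples)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_err = res.df2
    msw = ssw / df_err if df_err > 0 else 0.0
    order = np.argsort([-g.mean() for g in groups])  # descending means
    pos = {labels[idx]: rank for rank, idx in enumerate(order)}
    raw_p: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        a, b = sorted((pos[labels[i]], pos[labels[j]]))
        r = b - a + 1
        gi, gj = groups[i], groups[j]
        nh = 2.0 / (1.0 / gi.size + 1.0 / gj.size)
        diff = abs(gi.mean() - gj.mean())
        if msw == 0:
            p_span = 0.0 if diff > 0 else 1.0
        else:
            q = diff / np.sqrt(msw / nh)
            p_span = float(sps.studentized_range.sf(q, r, df_err))
        p_adj = 1.0 - (1.0 - p_span) ** (1.0 / (r - 1)) if r > 2 else p_span
        raw_p[(a, b)] = min(max(p_adj, 0.0), 1.0)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = sorted((pos[labels[i]], pos[labels[j]]))
        # a pair cannot separate unless every span containing it separates
        p_final = max(
            p for (a2, b2), p in raw_p.items() if a2 <= a and b2 >= b
        )
        out.append(
            PosthocResult(
                pair=(labels[i], labels[j]), p=p_final, method="duncan",
                significant=bool(p_final < alpha),
            )
        )
    return out


def games_howell(samples: GroupSamples, alpha: float = 0.05) -> list[PosthocResult]:
    """Games-Howell pairwise comparisons for unequal variances.

    Each pair gets a studentized-range statistic ``q = |m_i - m_j| /
    sqrt((v_i/n_i + v_j/n_j)/2)`` with Welch-Satterthwaite degrees of freedom;
    p comes from the studentized range distribution with k groups.
    """
    samples.require()
    labels = samples.labels
    k = len(labels)
    out = []
    for gi_label, gj_label in itertools.combinations(labels, 2):
        gi, gj = samples.groups[gi_label], samples.groups[gj_label]
        vi, vj = gi.var(ddof=1), gj.var(ddof=1)
        ni, nj = gi.size, gj.size
        se2 = vi / ni + vj / nj
        if se2 == 0:
            raise ValueError(f"zero variance in both groups of pair ({gi_label}, {gj_label})")
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        q = abs(gi.mean() - gj.mean()) / np.sqrt(se2 / 2.0)
        p = float(sps.studentized_range.sf(q, k, df))
        out.append(
            PosthocResult(
                pair=(gi_label, gj_label), p=p, method="games_howell",
                significant=bool(p < alpha),
            )
        )
    return out


def spearman(values: Sequence[float], pain: Sequence[float], metric: str = "", group: str = "") -> CorrelationResult:
    """Spearman rank correlation between a map metric and pain NRS.

    Average (mid-)ranks for ties; constant input gives an undefined rho (NaN).
    """
    values = np.asarray(values, dtype=float)
    pain = np.asarray(pain, dtype=float)
    if values.size != pain.size:
        raise ValueError("paired vectors required")
    if values.size < 3:
        raise ValueError("Spearman requires n >= 3")
    if np.all(values == values[0]) or np.all(pain == pain[0]):
        return CorrelationResult(metric=metric, group=group, rho=float("nan"), p=float("nan"), n=values.size)
    rho, p = sps.spearmanr(values, pain)
    return CorrelationResult(metric=metric, group=group, rho=float(rho), p=float(p), n=values.size)


@dataclass
class GroupReport:
    """Result of the group-comparison layer for a set of metrics.

    ``omnibus``/``posthoc``/``summary``/``normality`` are pandas DataFrames;
    ``skipped`` lists (variable, reason) for metrics whose omnibus test could
    not run (e.g. a group reduced below 2 usable subjects).
    """

    summary: "object"
    omnibus: "object"
    posthoc: "object"
    normality: "object"
    skipped: list[tuple[str, str]] = field(default_factory=list)


def run_group_report(
    metrics: "object",
    alpha: float = 0.05,
    variance_gate: Optional[str] = None,
) -> GroupReport:
    """Compare every metric across groups, Table-style.

    ``metrics`` is a long-format pandas DataFrame with columns
    ``subject_id, group, variable, value``.  Per variable: groups with fewer
    than 2 non-missing values are dropped (reported with reduced n); the
    Levene gate selects classic ANOVA + Duncan or Welch + Games-Howell unless
    ``variance_gate`` forces ``"classic"`` or ``"welch"``.
    """
    import pandas as pd

    required = {"subject_id", "group", "variable", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame must have columns {sorted(required)}")
    if variance_gate not in (None, "classic", "welch"):
        raise ValueError("variance_gate must be None, 'classic' or 'welch'")

    summary_rows, omni_rows, post_rows, norm_rows, skipped = [], [], [], [], []
    for variable, sub in metrics.groupby("variable", sort=True):
        sub = sub.dropna(subset=["value"])
        by_group = {g: v["value"].to_numpy() for g, v in sub.groupby("group", sort=True)}
        for g, vals in by_group.items():
            summary_rows.append(
                {
                    "variable": variable, "group": g, "mean": float(np.mean(vals)) if vals.size else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan, "n": int(vals.size),
                }
            )
            if vals.size >= 3:
                w, p = shapiro_wilk(vals)
                norm_rows.append({"variable": variable, "group": g, "W": w, "p": p})
        usable = {g: v for g, v in by_group.items() if v.size >= 2}
        dropped = sorted(set(by_group) - set(usable))
        if len(usable) < 2:
            skipped.append((str(variable), f"fewer than 2 usable groups (dropped: {dropped})"))
            continue
        samples = GroupSamples(metric=str(variable), groups=usable)
        if variance_gate is None:
            try:
                _, _, equal = variance_homogeneity(samples, alpha)
            except ValueError:
                equal = True
            gate = "classic" if equal else "welch"
        else:
            gate = variance_gate
        if gate == "welch" and any(v.var(ddof=1) == 0 for v in usable.values()):
            gate = "classic"  # Welch undefined with a zero-variance group
        res = oneway_anova(samples) if gate == "classic" else welch_anova(samples)
        omni_rows.append(
            {
                "variable": variable, "method": res.method, "F": res.F, "df1": res.df1,
                "df2": res.df2, "p": res.p, "eta_squared": res.eta_squared,
                "dropped_groups": ",".join(dropped),
            }
        )
        pairs = duncan_posthoc(samples, alpha) if gate == "classic" else games_howell(samples, alpha)
        for pr in pairs:
            post_rows.append(
                {
                    "variable": variable, "group_a": pr.pair[0], "group_b": pr.pair[1],
                    "method": pr.method, "p": pr.p, "significant": pr.significant,
                }
            )
    return GroupReport(
        summary=pd.DataFrame(summary_rows),
        omnibus=pd.DataFrame(omni_rows),
        posthoc=pd.DataFrame(post_rows),
        normality=pd.DataFrame(norm_rows),
        skipped=skipped,
    )
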