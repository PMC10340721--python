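"""Hierarchical averaging, group summaries and ANOVA with Fisher's LSD.

The replication unit is the cell: frame-level values are averaged per cell
first and only the per-cell values enter group summaries and ANOVA. Results
are reported as mean ± SEM (sample SD / √n). Fission/fusion dynamics use a
two-way fixed-effects ANOVA (treatment × event type); all other metrics a
one-way ANOVA; both are followed by Fisher's LSD pairwise t-tests on the
pooled residual mean square. Fisher's LSD applies NO multiplicity correction —
that is its definition — so pairwise p-values are nominal, not family-wise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CellMeasurement:
    """One per-cell value of one metric (already averaged over frames)."""

    cell_id: str
    group: str
    metric: str
    value: float
    factor2: str | None = None  # e.g. event type for the two-way design


@dataclass
class GroupSummary:
    group: str
    metric: str
    n: int
    mean: float
    sem: float | None  # None (undefined) when n == 1


@dataclass
class LSDComparison:
    level_a: str
    level_b: str
    estimate: float  # mean(a) - mean(b)
    t: float
    p: float
    significant: bool


@dataclass
class ANOVAResult:
    design: str  # "one_way" | "two_way"
    metric: str
    f_stats: dict[str, float]
    p_values: dict[str, float]
    df: dict[str, int]
    ss: dict[str, float]
    residual_ms: float
    residual_df: int
    lsd: list[LSDComparison] = field(default_factory=list)
    alpha: float = 0.05


def _to_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in measurements],
            "group": [m.group for m in measurements],
            "metric": [m.metric for m in measurements],
            "value": [m.value for m in measurements],
            "factor2": [m.factor2 for m in measurements],
        }
    )


def summarise_groups(measurements: list[CellMeasurement]) -> list[GroupSummary]:
    """Per-(group, metric) mean ± SEM over cells."""
    if not measurements:
        raise ValueError("no measurements")
    df = _to_frame(measurements)
    out = []
    for (group, metric), sub in df.groupby(["group", "metric"], sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None
        out.append(GroupSummary(group=str(group), metric=str(metric), n=n,
                                mean=float(vals.mean()), sem=sem))
    return out


def _lsd(
    cell_means: dict[str, float],
    cell_ns: dict[str, int],
    ms_error: float,
    df_error: int,
    alpha: float,
) -> list[LSDComparison]:
    comps = []
    for a, b in itertools.combinations(sorted(cell_means), 2):
        est = cell_means[a] - cell_means[b]
        se = np.sqrt(ms_error * (1.0 / cell_ns[a] + 1.0 / cell_ns[b]))
        t = est / se
        p = float(2 * sps.t.sf(abs(t), df_error))
        comps.append(LSDComparison(a, b, float(est), float(t), p, p < alpha))
    return comps


def one_way_anova_lsd(
    measurements: list[CellMeasurement], metric: str, alpha: float = 0.05
) -> ANOVAResult:
    """One-way fixed-effects ANOVA followed by Fisher's LSD post-hoc."""
    df = _to_frame(measurements)
    df = df[df["metric"] == metric]
    groups = {g: sub["value"].to_numpy(dtype=float) for g, sub in df.groupby("group")}
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("one-way ANOVA needs >= 2 values per group")

    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(groups)

    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between, df_within = k - 1, n_total - k
    if ss_within <= 0:
        raise ValueError("zero residual variance: ANOVA undefined")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))

    means = {g: float(v.mean()) for g, v in groups.items()}
    ns = {g: len(v) for g, v in groups.items()}
    return ANOVAResult(
        design="one_way",
        metric=metric,
        f_stats={"group": float(f)},
        p_values={"group": p},
        df={"group": df_between, "residual": df_within},
        ss={"group": float(ss_between), "residual": float(ss_within),
            "total": float(ss_between + ss_within)},
        residual_ms=float(ms_within),
        residual_df=df_within,
        lsd=_lsd(means, ns, ms_within, df_within, alpha),
        alpha=alpha,
    )


def two_way_anova_lsd(
    measurements: list[CellMeasurement], metric: str, alpha: float = 0.05
) -> ANOVAResult:
    """Balanced two-way crossed fixed-effects ANOVA (e.g. treatment × event type).

    Requires a complete crossing with equal replicate numbers (≥2) per cell of
    the design; missing combinations raise an error naming them. LSD pairwise
    comparisons are computed over the factor-A (group) levels within each
    factor-B level, plus the factor-A marginal means.
    """
    df = _to_frame(measurements)
    df = df[df["metric"] == metric]
    if df["factor2"].isna().any():
        raise ValueError("two-way design requires factor2 on every measurement")
    a_levels = sorted(df["group"].unique())
    b_levels = sorted(df["factor2"].unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels per factor")

    cells: dict[tuple[str, str], np.ndarray] = {}
    for a in a_levels:
        for b in b_levels:
            vals = df[(df["group"] == a) & (df["factor2"] == b)]["value"].to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"missing design cell: group={a!r}, factor2={b!r}")
            cells[(a, b)] = vals
    ns = {k: len(v) for k, v in cells.items()}
    n_rep = next(iter(ns.values()))
    if n_rep < 2 or len(set(ns.values())) != 1:
        raise ValueError("two-way ANOVA requires a balanced design with >= 2 replicates per cell")

    grand = np.concatenate(list(cells.values())).mean()
    I, J = len(a_levels), len(b_levels)
    a_means = {a: np.concatenate([cells[(a, b)] for b in b_levels]).mean() for a in a_levels}
    b_means = {b: np.concatenate([cells[(a, b)] for a in a_levels]).mean() for b in b_levels}
    cell_means = {k: v.mean() for k, v in cells.items()}

    ss_a = n_rep * J * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = n_rep * I * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = n_rep * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in a_levels for b in b_levels
    )
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_err = I * J * (n_rep - 1)
    if ss_err <= 0:
        raise ValueError("zero residual variance: ANOVA undefined")
    ms_err = ss_err / df_err

    f_stats, p_values = {}, {}
    for name, ss, d in (("group", ss_a, df_a), ("factor2", ss_b, df_b),
                        ("interaction", ss_ab, df_ab)):
        f = (ss / d) / ms_err
        f_stats[name] = float(f)
        p_values[name] = float(sps.f.sf(f, d, df_err))

    # LSD on cell means within each factor-B level
    lsd = []
    for b in b_levels:
        means = {f"{a}|{b}": float(cell_means[(a, b)]) for a in a_levels}
        cns = {f"{a}|{b}": n_rep for a in a_levels}
        lsd.extend(_lsd(means, cns, ms_err, df_err, alpha))
    # plus factor-A marginal comparisons
    lsd.extend(_lsd({a: float(m) for a, m in a_means.items()},
                    {a: n_rep * J for a in a_levels}, ms_err, df_err, alpha))

    return ANOVAResult(
        design="two_way",
        metric=metric,
        f_stats=f_stats,
        p_values=p_values,
        df={"group": df_a, "factor2": df_b, "interaction": df_ab, "residual": df_err},
        ss={"group": float(ss_a), "factor2": float(ss_b),
            "interaction": float(ss_ab), "residual": float(ss_err),
            "total": float(ss_a + ss_b + ss_ab + ss_err)},
        residual_ms=float(ms_err),
        residual_df=df_err,
        lsd=lsd,
        alpha=alpha,
    )
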