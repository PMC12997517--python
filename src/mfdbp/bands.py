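"""Group-wise variance analysis across breakpoint-defined age bands.

The breakpoint and its confidence interval define three age strata -
Early, Transitional and Late - and every morphometric variable is compared
across them.  Test selection is gated: when all groups pass Shapiro-Wilk
normality and Levene's homogeneity (both at p >= 0.05), a one-way ANOVA
with Tukey's HSD post hoc is used; otherwise Kruskal-Wallis with the
Conover-Iman rank post hoc.  Pairwise p-values are Benjamini-Hochberg
FDR-adjusted within each variable's family of three comparisons.  Effect
sizes per pair are Hedges' d (parametric route) and Cliff's delta (rank
route), oriented older-minus-younger, with percentile bootstrap confidence
intervals from stratified resampling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort

logger = logging.getLogger("mfdbp")

__all__ = [
    "BandedGroups",
    "BandTestResult",
    "DEFAULT_BAND_BOUNDARIES",
    "assign_bands",
    "gate_and_omnibus",
    "posthoc_pairwise",
    "hedges_d",
    "cliffs_delta",
    "bootstrap_effect_ci",
    "analyse_variable",
]

#: Early/Transitional/Late boundaries (years): [min, 5), [5, 7.5), [7.5, max].
DEFAULT_BAND_BOUNDARIES = (5.0, 7.5)

BAND_LABELS = ("Early", "Transitional", "Late")

_GATE_ALPHA = 0.05


@dataclass
class BandedGroups:
    """Cohort partitioned into half-open age bands."""

    boundaries: tuple[float, float]
    members: dict[str, pd.DataFrame]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.members.items()}

    def values(self, variable: str) -> dict[str, np.ndarray]:
        return {k: v[variable].to_numpy(dtype=float) for k, v in self.members.items()}


@dataclass
class BandTestResult:
    variable: str
    route: str                       # "parametric" | "rank"
    gate: dict                       # per-group Shapiro p, Levene p
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame | None = None   # raw + adjusted p per pair
    effects: pd.DataFrame | None = None    # effect sizes + bootstrap CIs


def assign_bands(
    cohort: Cohort, boundaries: tuple[float, float] = DEFAULT_BAND_BOUNDARIES
) -> BandedGroups:
    """Partition records into Early [min, b1), Transitional [b1, b2), Late [b2, max].

    Boundaries must be strictly increasing and interior to the age range.
    Empty bands are legal but logged; downstream pairwise tests skip pairs
    involving an empty band.
    """
    b1, b2 = boundaries
    ages = cohort.ages
    if not b1 < b2:
        raise ValueError(f"boundaries must be strictly increasing, got {boundaries}")
    df = cohort.records
    members = {
        "Early": df[df["abx_years"] < b1],
        "Transitional": df[(df["abx_years"] >= b1) & (df["abx_years"] < b2)],
        "Late": df[df["abx_years"] >= b2],
    }
    for name, grp in members.items():
        if grp.empty:
            logger.warning("band %r is empty for boundaries %s", name, boundaries)
    assert sum(len(g) for g in members.values()) == len(cohort)
    return BandedGroups(boundaries=(float(b1), float(b2)), members=members)


def gate_and_omnibus(groups: dict[str, np.ndarray]) -> tuple[str, dict, float, float]:
    """Test-selection gate and omnibus test across the groups.

    Returns (route, gate record, omnibus statistic, omnibus p).  The
    parametric route requires Shapiro-Wilk p >= 0.05 in every group and
    Levene p >= 0.05; a zero-variance group forces the rank route.
    """
    usable = {k: v for k, v in groups.items() if len(v) >= 3}
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with n >= 3")
    vals = list(usable.values())
    gate: dict = {"shapiro_p": {}, "levene_p": np.nan}
    normal = True
    degenerate = False
    for name, v in usable.items():
        if np.ptp(v) == 0:
            degenerate = True
            gate["shapiro_p"][name] = np.nan
            continue
        p = float(stats.shapiro(v).pvalue)
        gate["shapiro_p"][name] = p
        normal &= p >= _GATE_ALPHA
    if degenerate:
        logger.info("zero-variance group: rank-based route forced")
        route = "rank"
    else:
        lev_p = float(stats.levene(*vals).pvalue)
        gate["levene_p"] = lev_p
        route = "parametric" if (normal and lev_p >= _GATE_ALPHA) else "rank"
    if route == "parametric":
        stat, p = stats.f_oneway(*vals)
    else:
        stat, p = stats.kruskal(*vals)
    return route, gate, float(stat), float(p)


def _conover_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Conover-Iman all-pairs rank comparison after Kruskal-Wallis.

    Based on joint ranks over all observations: the pairwise statistic is a
    t ratio of mean-rank differences with a pooled rank variance deflated
    by the Kruskal-Wallis statistic, on N - k degrees of freedom.
    """
    names = list(groups.keys())
    all_vals = np.concatenate([groups[g] for g in names])
    sizes = np.array([len(groups[g]) for g in names])
    N, k = len(all_vals), len(names)
    ranks = stats.rankdata(all_vals)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    mean_ranks = {g: r.mean() for g, r in zip(names, split)}
    H = stats.kruskal(*[groups[g] for g in names]).statistic
    s2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(s2 * ((N - 1 - H) / (N - k)) * (1.0 / na + 1.0 / nb))
        t = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.t.sf(abs(t), N - k)
        rows.append({"group_a": a, "group_b": b, "statistic": float(t), "p_raw": float(p)})
    return pd.DataFrame(rows)


def _tukey_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    res = stats.tukey_hsd(*groups.values())
    names = list(groups.keys())
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {"group_a": names[i], "group_b": names[j],
             "statistic": float(res.statistic[i, j]), "p_raw": float(res.pvalue[i, j])}
        )
    return pd.DataFrame(rows)


def posthoc_pairwise(groups: dict[str, np.ndarray], route: str) -> pd.DataFrame:
    """All-pairs post hoc table with BH/FDR-adjusted p-values.

    Tukey HSD on the parametric route, Conover-Iman on the rank route; the
    adjustment family is the set of pairwise comparisons for this variable.
    Pairs involving a group with fewer than 2 observations are skipped.
    """
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    table = _tukey_pairwise(usable) if route == "parametric" else _conover_pairwise(usable)
    table["p_fdr"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table


def hedges_d(group_a, group_b) -> float:
    """Bias-corrected standardised mean difference (b minus a).

    Cohen's d with the pooled SD, times the small-sample correction
    J = 1 - 3 / (4 (n_a + n_b) - 9).  Orientation: second group minus
    first, so Late-vs-Early effects carry the sign of the age trend.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ZeroDivisionError("zero pooled SD")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float((b.mean() - a.mean()) / pooled * j)


def cliffs_delta(group_a, group_b) -> float:
    """Cliff's delta: P(b > a) - P(b < a) over all cross-pairs, in [-1, 1].

    Ties contribute zero.  Orientation matches :func:`hedges_d` (second
    group versus first).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("groups must be non-empty")
    diff = b[:, None] - a[None, :]
    return float((np.sign(diff)).sum() / (len(a) * len(b)))


def bootstrap_effect_ci(
    kind: str,
    group_a,
    group_b,
    reps: int = 5000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for an effect size, stratified within groups.

    ``kind`` is ``"hedges_d"`` or ``"cliffs_delta"``.  Resamples that
    degenerate (zero pooled SD for d) are redrawn, capped at 1% of reps.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    stat = {"hedges_d": hedges_d, "cliffs_delta": cliffs_delta}[kind]
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    redraws = 0
    max_redraws = max(1, reps // 100)
    i = 0
    while i < reps:
        ra = rng.choice(a, len(a), replace=True)
        rb = rng.choice(b, len(b), replace=True)
        try:
            out[i] = stat(ra, rb)
        except ZeroDivisionError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        i += 1
    q = (1.0 - level) / 2.0
    lo, hi = np.quantile(out, [q, 1.0 - q])
    return float(lo), float(hi)


def analyse_variable(
    bands: BandedGroups,
    variable: str,
    bootstrap_reps: int = 5000,
    seed: int = 0,
) -> BandTestResult:
    """Full per-variable analysis: gate, omnibus, post hoc, effect sizes.

    The effect-size kind follows the route (Hedges' d on the parametric
    route, Cliff's delta on the rank route); both orientations are
    older-band versus younger-band.
    """
    groups = bands.values(variable)
    route, gate, stat, p = gate_and_omnibus(groups)
    pairwise = posthoc_pairwise(groups, route)
    kind = "hedges_d" if route == "parametric" else "cliffs_delta"
    eff_rows = []
    order = {name: i for i, name in enumerate(BAND_LABELS)}
    for _, row in pairwise.iterrows():
        a, b = row["group_a"], row["group_b"]
        younger, older = sorted([a, b], key=order.get)
        ga, gb = groups[younger], groups[older]
        est = hedges_d(ga, gb) if kind == "hedges_d" else cliffs_delta(ga, gb)
        lo, hi = bootstrap_effect_ci(kind, ga, gb, reps=bootstrap_reps, seed=seed)
        eff_rows.append(
            {"younger": younger, "older": older, "kind": kind,
             "estimate": est, "ci_low": lo, "ci_high": hi, "reps": bootstrap_reps}
        )
    return BandTestResult(
        variable=variable,
        route=route,
        gate=gate,
        omnibus_stat=stat,
        omnibus_p=p,
        pairwise=pairwise,
        effects=pd.DataFrame(eff_rows),
    )
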