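"""Group statistics and hit calling for the behavioral screen.

The screen compares a sleep metric (by default siesta minutes, ZT3-9)
across genotypes with a classical one-way ANOVA followed by a Tukey HSD
post hoc; unequal group sizes use the Tukey-Kramer standard error.  A
genotype is called a hit when its Tukey-adjusted p-value is below alpha
versus *every* listed control genotype and its mean lies on the required
side (lower, for a reduced-sleep screen).  Two usage modes mirror common
designs: a wide screen against a single Cas9 driver control, and a focused
follow-up requiring significance against both the Cas9 and the guide-only
control.

ANOVA and Tukey are implemented directly (the studentized-range and F
distributions come from scipy); scipy's own implementations serve as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


@dataclass
class TukeyResult:
    group_a: str
    group_b: str
    mean_diff: float                      # mean(a) - mean(b)
    q: float                              # studentized-range statistic
    p_adj: float


@dataclass
class ScreenHit:
    genotype: str
    direction: str                        # "decrease" or "increase"
    p_vs_controls: dict
    hit: bool


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g in out:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
    return out


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA."""
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = k - 1, int(ns.sum()) - k
    if df_w < 1 or ssw == 0:
        raise ValueError("zero within-group variance: F undefined")
    msb, msw = ssb / df_b, ssw / df_w
    f = msb / msw
    return AnovaResult(f=f, df_between=df_b, df_within=df_w,
                       p=float(stats.f.sf(f, df_b, df_w)), ms_within=msw)


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Sequence[str] | None = None) -> list[TukeyResult]:
    """All-pairs Tukey HSD with Tukey-Kramer handling of unequal n.

    For a pair (a, b): q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b)),
    with the adjusted p from the studentized range distribution with k
    groups and the ANOVA within-group df.
    """
    gs = _as_groups(groups)
    k = len(gs)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels/groups length mismatch")
    an = oneway_anova(gs)
    out = []
    for i, j in combinations(range(k), 2):
        diff = gs[i].mean() - gs[j].mean()
        se = np.sqrt(an.ms_within / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, an.df_within))
        out.append(TukeyResult(group_a=labels[i], group_b=labels[j],
                               mean_diff=float(diff), q=float(q),
                               p_adj=min(1.0, p)))
    return out


def group_stats(table: pd.DataFrame, metric: str = "siesta") -> pd.DataFrame:
    """Per-genotype n / mean / median / SD / SEM of a window metric."""
    g = table.groupby("genotype")[metric]
    out = g.agg(n="count", mean="mean", median="median", sd="std")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index()


def call_screen_hits(table: pd.DataFrame, controls: Sequence[str],
                     metric: str = "siesta", alpha: float = ALPHA,
                     direction: str = "decrease") -> list[ScreenHit]:
    """Call screen hits on a per-fly window-sleep table.

    ``table`` needs columns ``genotype`` and ``metric``.  A non-control
    genotype is a hit iff its Tukey-adjusted p is < ``alpha`` against every
    control *and* its mean is below (``direction="decrease"``) or above
    (``"increase"``) each control's mean.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    genotypes = list(dict.fromkeys(table["genotype"]))
    missing = [c for c in controls if c not in genotypes]
    if missing:
        raise ValueError(f"control genotype(s) missing from table: {missing}")
    groups = [table.loc[table["genotype"] == g, metric].to_numpy() for g in genotypes]
    an = oneway_anova(groups)
    k = len(groups)
    ns = {g: len(arr) for g, arr in zip(genotypes, groups)}
    means = {g: arr.mean() for g, arr in zip(genotypes, groups)}

    # Tukey-Kramer q for the experimental-vs-control pairs only; the
    # adjusted p is identical to the full all-pairs table, so restricting
    # to the pairs that decide hits changes nothing but the runtime.
    tests = [(g, c) for g in genotypes if g not in controls for c in controls]
    qs = np.array([abs(means[g] - means[c])
                   / np.sqrt(an.ms_within / 2.0 * (1.0 / ns[g] + 1.0 / ns[c]))
                   for g, c in tests])
    ps = np.minimum(1.0, stats.studentized_range.sf(qs, k, an.df_within))
    pmap = {pair: float(p) for pair, p in zip(tests, ps)}

    hits = []
    sign = -1.0 if direction == "decrease" else 1.0
    for g in genotypes:
        if g in controls:
            continue
        pvs = {c: pmap[(g, c)] for c in controls}
        ok_dir = all(sign * (means[g] - means[c]) > 0 for c in controls)
        hits.append(ScreenHit(genotype=g, direction=direction, p_vs_controls=pvs,
                              hit=bool(ok_dir and all(p < alpha for p in pvs.values()))))
    return hits


def hit_table(hits: Sequence[ScreenHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {"genotype": h.genotype, "direction": h.direction, "hit": h.hit}
        for c, p in h.p_vs_controls.items():
            row[f"p_vs_{c}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
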