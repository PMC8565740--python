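"""Group statistics and headline tables.

Nonparametric throughout: two groups are compared with a two-sided
Mann-Whitney U test; three or more with a Kruskal-Wallis omnibus test
followed by all pairwise two-sided Mann-Whitney tests, p-values adjusted by
the Holm-Bonferroni step-down procedure.  Penetrance is the percentage of
perturbed bundles showing altered targeting.  Angle summaries treat wedge-unit
angles as linear quantities (they occupy a narrow range around zero), a
documented limitation rather than circular statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedPenetranceError


@dataclass
class PenetranceCount:
    """Bundle counts behind one penetrance value."""

    genotype: str
    age_hrs_apf: float
    n_altered: int
    n_wildtype_like: int

    @property
    def total(self) -> int:
        return self.n_altered + self.n_wildtype_like


def penetrance(count: PenetranceCount | tuple[int, int]) -> float:
    """Percent of scored bundles with altered targeting, to one decimal."""
    if isinstance(count, tuple):
        n_alt, n_wt = count
    else:
        n_alt, n_wt = count.n_altered, count.n_wildtype_like
    total = n_alt + n_wt
    if total <= 0:
        raise UndefinedPenetranceError("no scored bundles")
    return round(100.0 * n_alt / total, 1)


def holm_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values, clipped to 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def star_code(p: float) -> str:
    """Significance stars: ns for p >= 0.05, then *, **, *** at 0.05/0.01/0.001."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p >= 0.05:
        return "ns"
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    return "***"


def mannwhitney_p(a, b) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small untied samples,
    normal approximation with tie correction otherwise)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    method = ("exact" if max(len(a), len(b)) <= 8
              and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
              else "asymptotic")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method=method).pvalue)


@dataclass
class GroupComparison:
    """Omnibus p (None for two groups) plus the pairwise table."""

    omnibus_p: float | None
    table: pd.DataFrame


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Nonparametric comparison of two or more named samples.

    Two groups: a single two-sided Mann-Whitney test.  More: Kruskal-Wallis
    omnibus, then all pairwise Mann-Whitney tests with Holm adjustment.
    The table carries ``group_a, group_b, p_raw, p_adj, stars``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"group {name!r} is empty")
    if len(names) == 2:
        p = mannwhitney_p(groups[names[0]], groups[names[1]])
        table = pd.DataFrame([{
            "group_a": names[0], "group_b": names[1],
            "p_raw": p, "p_adj": p, "stars": star_code(p)}])
        return GroupComparison(omnibus_p=None, table=table)
    omnibus = float(sps.kruskal(*[np.asarray(groups[n], float)
                                  for n in names]).pvalue)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = [mannwhitney_p(groups[a], groups[b]) for a, b in pairs]
    adj = holm_bonferroni(raw)
    table = pd.DataFrame([{
        "group_a": a, "group_b": b, "p_raw": pr, "p_adj": pa,
        "stars": star_code(pa)}
        for (a, b), pr, pa in zip(pairs, raw, adj)])
    return GroupComparison(omnibus_p=omnibus, table=table)


def timecourse_table(measurements: pd.DataFrame,
                     by: Sequence[str] = ("cell_type", "time_hrs_apf"),
                     drop_ambiguous: bool = True) -> pd.DataFrame:
    """Mean/SD of relative length and angle per group.

    ``measurements`` follows the measurements-table schema.  Rows flagged
    ambiguous are excluded before grouping.  SD is 0 (with n = 1) for
    singleton groups.
    """
    df = measurements.copy()
    if drop_ambiguous and "flags" in df.columns:
        flags = df["flags"].fillna("").astype(str)
        df = df[~flags.str.contains("ambiguous")]
    if df.empty:
        return pd.DataFrame()
    g = df.groupby(list(by), sort=True)
    out = g.agg(
        rel_length_mean=("rel_length", "mean"),
        rel_length_sd=("rel_length", lambda s: float(np.std(s, ddof=1))
                       if len(s) > 1 else 0.0),
        rel_angle_mean=("rel_angle", "mean"),
        rel_angle_sd=("rel_angle", lambda s: float(np.std(s, ddof=1))
                      if len(s) > 1 else 0.0),
        n=("rel_length", "size"),
    ).reset_index()
    return out


def target_bands(bundles, target_for: Mapping[str, str] = None) -> pd.DataFrame:
    """Standardized target band per cell type: mean target-centre radius and
    the mean radii where the ellipse boundary crosses the ray through its
    centre (the band drawn behind time-course plots).

    ``target_for`` maps cell type to target label (default R3->T3, R4->T4).
    """
    from .frame import build_frame, image_to_polar

    target_for = dict(target_for or {"R3": "T3", "R4": "T4"})
    rows = []
    for b in bundles:
        frame = build_frame(b)
        for ctype, label in target_for.items():
            if label not in b.targets:
                continue
            ell = b.targets[label]
            rc, thc = image_to_polar(ell.center.asarray(), frame)
            br, bth = image_to_polar(ell.boundary(256), frame)
            # radii of boundary points nearest (in angle) to the centre ray
            near = np.abs(bth - float(thc)) <= 0.05
            if near.any():
                lower, upper = float(br[near].min()), float(br[near].max())
            else:
                lower = upper = float(rc)
            rows.append({"cell_type": ctype, "target": label,
                         "r_center": float(rc), "r_lower": lower,
                         "r_upper": upper})
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return (df.groupby(["cell_type", "target"], sort=True)
            [["r_center", "r_lower", "r_upper"]].mean().reset_index())


def penetrance_table(counts: Sequence[PenetranceCount]) -> pd.DataFrame:
    """Table-style penetrance report (one row per genotype/age)."""
    rows = [{
        "genotype": c.genotype, "age_hrs_apf": c.age_hrs_apf,
        "n_altered": c.n_altered, "n_wt_like": c.n_wildtype_like,
        "total": c.total, "penetrance_pct": penetrance(c)}
        for c in counts]
    return pd.DataFrame(rows)
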