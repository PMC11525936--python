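"""Proliferation analysis from Ki67 intensity.

Cells are classified as proliferating when their background-subtracted
Ki67 intensity exceeds a per-week percentile threshold of that week's
Ki67 distribution (the thresholds that separate the Ki67-positive mode:
70th percentile at weeks 6 and 8.5, 85th at weeks 11 and 12, 86th at
week 13).  Downstream comparisons: per-type proliferating fractions,
homotypic-adjacency contrasts between proliferating and non-proliferating
cells, and Fisher's exact test of proliferation between airway region
groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point
from shapely.prepared import prep

__all__ = [
    "DEFAULT_PERCENTILES",
    "classify_proliferating",
    "proliferation_summary",
    "compare_homotypic_adjacency",
    "region_proliferation_fisher",
    "fisher_exact_2x2",
]

#: week -> Ki67 percentile threshold
DEFAULT_PERCENTILES = {6.0: 70.0, 8.5: 70.0, 11.0: 85.0, 12.0: 85.0, 13.0: 86.0}


def classify_proliferating(table: pd.DataFrame, spec=None, ki67_col: str = "Ki67",
                           week_col: str = "week") -> pd.Series:
    """Proliferating iff Ki67 > that week's percentile threshold.

    The percentile is taken over the analysed (post-exclusion) cells of
    the week, with linear interpolation between order statistics; the
    strict inequality means an all-equal Ki67 column yields no
    proliferating cells.
    """
    spec = DEFAULT_PERCENTILES if spec is None else spec
    if ki67_col not in table.columns:
        raise KeyError(f"no {ki67_col!r} column in table")
    weeks = table[week_col] if week_col in table.columns else pd.Series(0.0, index=table.index)
    out = pd.Series(False, index=table.index)
    for week, sub in table.groupby(weeks):
        if week not in spec:
            raise KeyError(f"no Ki67 percentile configured for week {week}")
        p = float(spec[week])
        if not 0.0 < p < 100.0:
            raise ValueError(f"percentile for week {week} must be in (0, 100)")
        x = sub[ki67_col].to_numpy(dtype=float)
        thr = np.percentile(x, p)  # linear interpolation
        out.loc[sub.index] = x > thr
    return out


def proliferation_summary(table: pd.DataFrame, prolif_col: str = "proliferating",
                          type_col: str = "cell_type", week_col: str = "week"):
    """Three summaries per week: overall fraction, per-type fraction, and
    the distribution of proliferating cells across types (sums to 100%)."""
    weeks = table[week_col] if week_col in table.columns else pd.Series(0.0, index=table.index)
    overall = (table.groupby(weeks)[prolif_col].mean() * 100.0).rename("pct_proliferating")
    per_type = (table.groupby([weeks, table[type_col]])[prolif_col].mean()
                * 100.0).rename("pct_proliferating")
    prolif = table[table[prolif_col]]
    dist = prolif.groupby([weeks.loc[prolif.index], prolif[type_col]]).size()
    dist = dist.groupby(level=0).transform(lambda s: s / s.sum() * 100.0).rename("pct_of_proliferating")
    return overall.reset_index(), per_type.reset_index(), dist.reset_index()


def compare_homotypic_adjacency(scaled_by_week_state: dict, types):
    """Contrast homotypic adjacency of non-proliferating vs proliferating
    cells of each type across weeks.

    ``scaled_by_week_state`` maps week -> scaled enrichment matrix whose
    labels are '<type>|proliferating' / '<type>|non-proliferating'.  For
    each type the diagonal scaled Z values across weeks are compared by a
    two-sided two-sample Student t-test (equal variance), and the per-week
    ratio non-proliferating / proliferating is reported (guarding
    near-zero denominators with NaN).
    """
    rows = []
    ratio_rows = []
    for t in types:
        non_key, pro_key = f"{t}|non-proliferating", f"{t}|proliferating"
        non_vals, pro_vals = [], []
        for week in sorted(scaled_by_week_state):
            m = scaled_by_week_state[week]
            if non_key in m.index and pro_key in m.index:
                nv = float(m.loc[non_key, non_key])
                pv = float(m.loc[pro_key, pro_key])
                non_vals.append(nv)
                pro_vals.append(pv)
                ratio_rows.append({
                    "cell_type": t, "week": week,
                    "ratio": nv / pv if abs(pv) > 1e-9 else np.nan,
                })
        if len(non_vals) >= 2 and len(pro_vals) >= 2:
            tt = sps.ttest_ind(non_vals, pro_vals, equal_var=True)
            stat, p = float(tt.statistic), float(tt.pvalue)
        else:
            stat, p = np.nan, np.nan
        rows.append({"cell_type": t, "t_stat": stat, "p_value": p,
                     "n_weeks": len(non_vals),
                     "mean_non_proliferating": np.mean(non_vals) if non_vals else np.nan,
                     "mean_proliferating": np.mean(pro_vals) if pro_vals else np.nan})
    return pd.DataFrame(rows), pd.DataFrame(ratio_rows)


def fisher_exact_2x2(table2x2) -> tuple:
    """Two-sided Fisher's exact test (point-probability method: sum of
    all tables with fixed margins whose probability does not exceed the
    observed one).  Returns (odds_ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table2x2, dtype=np.int64), alternative="two-sided")
    return float(odds), float(p)


def region_proliferation_fisher(table: pd.DataFrame, regions,
                                prolif_col: str = "proliferating") -> pd.DataFrame:
    """Pairwise Fisher tests of proliferation between airway region groups.

    ``regions`` is a RegionSet whose airway roles (airway-small-SOX2,
    airway-large-SOX2, airway-SOX9) group the polygons.  Cells are
    assigned to a group when their centroid falls inside any of its
    polygons (boundary counts as inside).
    """
    groups = {}
    for role in ("airway-small-SOX2", "airway-large-SOX2", "airway-SOX9"):
        polys = [prep(r["polygon"]) for r in regions.with_role(role)]
        if not polys:
            continue
        xs = table["x_um"].to_numpy(dtype=float)
        ys = table["y_um"].to_numpy(dtype=float)
        inside = np.array([any(g.intersects(Point(x, y)) for g in polys)
                           for x, y in zip(xs, ys)])
        groups[role] = table.loc[inside]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty region groups")
    for role, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"region group {role!r} selects no cells")
    rows = []
    roles = sorted(groups)
    for i in range(len(roles)):
        for j in range(i + 1, len(roles)):
            a, b = groups[roles[i]], groups[roles[j]]
            tab = [[int(a[prolif_col].sum()), int((~a[prolif_col]).sum())],
                   [int(b[prolif_col].sum()), int((~b[prolif_col]).sum())]]
            odds, p = fisher_exact_2x2(tab)
            rows.append({"group_a": roles[i], "group_b": roles[j],
                         "prolif_a": tab[0][0], "non_prolif_a": tab[0][1],
                         "prolif_b": tab[1][0], "non_prolif_b": tab[1][1],
                         "odds_ratio": odds, "p_value": p})
    return pd.DataFrame(rows)
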