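"""Immune-compartment subanalysis.

Immune cells are subclustered on a dedicated marker subset (CD3, CD4,
CD44, CD45, CD56, CD68, CD163, HLA-DR, Ki67, MRC1) at low resolution
(0.2 by default; 0.3 at weeks 8.5 and 12).  B and NK cells, too rare for
unsupervised subclustering, enter through manual-style gates (CD19+CD45
and CD56+CD45 co-expression) which take precedence over subcluster
labels.  Summaries cover subtype composition, per-subtype proliferating
fractions, and a physical-proximity network built from the observed
neighbor-pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = ["ImmunePanel", "immune_summary", "build_proximity_network"]

IMMUNE_MARKERS = ("CD3", "CD4", "CD44", "CD45", "CD56", "CD68",
                  "CD163", "HLA-DR", "Ki67", "MRC1")


@dataclass
class ImmunePanel:
    markers: tuple = IMMUNE_MARKERS
    resolution_default: float = 0.2
    resolution_by_week: dict = dc_field(default_factory=lambda: {8.5: 0.3, 12.0: 0.3})

    def resolution(self, week: float) -> float:
        r = self.resolution_by_week.get(week, self.resolution_default)
        if r <= 0:
            raise ValueError("resolution must be > 0")
        return r

    def validate(self, panel_markers) -> None:
        missing = set(self.markers) - set(panel_markers)
        if missing:
            raise ValueError(f"immune markers not in panel: {sorted(missing)}")


def immune_summary(table: pd.DataFrame, subtype_col: str = "immune_subtype",
                   prolif_col: str = "proliferating", week_col: str = "week"):
    """Subtype percentages and per-subtype proliferating fraction per
    week.  Weeks without immune cells get an empty row set (with a
    notice column)."""
    weeks = table[week_col] if week_col in table.columns else pd.Series(0.0, index=table.index)
    comp_rows, prolif_rows = [], []
    for week, sub in table.groupby(weeks):
        lab = sub[subtype_col].dropna()
        lab = lab[lab != ""]
        if len(lab) == 0:
            comp_rows.append({"week": week, "subtype": None, "pct": np.nan,
                              "note": "no immune cells"})
            continue
        counts = lab.value_counts()
        for st, n in counts.items():
            comp_rows.append({"week": week, "subtype": st,
                              "pct": 100.0 * n / counts.sum(), "note": ""})
            cells = sub[sub[subtype_col] == st]
            prolif_rows.append({"week": week, "subtype": st,
                                "pct_proliferating": 100.0 * cells[prolif_col].mean(),
                                "n": len(cells)})
    return pd.DataFrame(comp_rows), pd.DataFrame(prolif_rows)


def build_proximity_network(counts: pd.DataFrame) -> pd.DataFrame:
    """Weighted proximity network from observed neighbor-pair counts.

    Nodes are immune subtypes (optionally split by proliferation state);
    the weight of edge (a, b) is the observed pair count normalized by the
    total count over unordered pairs, so weights sum to 1.  Returns an
    edge-list DataFrame (node_a, node_b, count, weight).
    """
    if counts.size == 0:
        raise ValueError("empty counts matrix")
    labels = list(counts.index)
    m = counts.to_numpy(dtype=float)
    total = np.triu(m).sum()
    if total <= 0:
        raise ValueError("counts matrix has no observed pairs")
    rows = []
    for i, a in enumerate(labels):
        for j in range(i, len(labels)):
            c = m[i, j]
            if c > 0:
                rows.append({"node_a": a, "node_b": labels[j],
                             "count": c, "weight": c / total})
    return pd.DataFrame(rows)
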