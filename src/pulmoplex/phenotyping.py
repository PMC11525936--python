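"""Cell phenotyping: clustering of normalized marker profiles, rule-based
annotation of clusters to cell types, manual-style gating for rare types,
and composition summaries.

Clustering follows the standard single-cell recipe: PCA on the marker
matrix, a k-nearest-neighbour graph (k = 10 by default, Euclidean in PC
space), and Leiden community detection at a given resolution.  Analyses
are run per developmental week; merged-week clustering is intentionally
not provided (per-week annotation is the more accurate route for this
kind of data).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "ClusterResult",
    "Rule",
    "AnnotationRulebook",
    "Gate",
    "cluster_cells",
    "annotate_clusters",
    "subcluster",
    "gate_cells",
    "composition",
    "marker_correlation",
]

DEFAULT_N_PCS = 20
UNASSIGNED = "unassigned"


@dataclass
class ClusterResult:
    labels: np.ndarray            # per-cell cluster id, contiguous from 0
    means: pd.DataFrame           # cluster x marker mean profile
    params: dict

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class Rule:
    """Marker-predicate -> label.

    A marker is 'high' for a cluster when its z-scored cluster mean
    (z across clusters, per marker — the way a dot plot column is read)
    is >= ``min_z`` and the mean lies above the two-class Otsu split of
    that marker's cluster means; 'low' is the mirror image.  A cluster
    satisfies the rule when every ``high`` and ``low`` marker qualifies.
    """

    label: str
    high: tuple = ()
    low: tuple = ()
    min_z: float = 0.25


@dataclass
class AnnotationRulebook:
    """Ordered rules; the first satisfied rule wins, clusters matching no
    rule are labelled 'unassigned'."""

    rules: list = dc_field(default_factory=list)

    def validate(self, markers) -> None:
        panel = set(markers)
        for r in self.rules:
            unknown = (set(r.high) | set(r.low)) - panel
            if unknown:
                raise ValueError(
                    f"rule {r.label!r} references markers not in panel: {sorted(unknown)}"
                )


def _otsu_split(values: np.ndarray) -> float:
    """Two-class Otsu cut over a small 1-D set of cluster means."""
    u = np.unique(values)
    if len(u) < 2:
        return u[0] if len(u) else 0.0
    if len(u) == 2:
        return u.mean()
    best, best_t = -1.0, u.mean()
    for t in (u[:-1] + u[1:]) / 2.0:
        lo, hi = values[values <= t], values[values > t]
        w = len(lo) / len(values)
        var = w * lo.mean() ** 2 + (1 - w) * hi.mean() ** 2
        if var > best:
            best, best_t = var, t
    return best_t


def _leiden(graph_csr, resolution: float, seed: int) -> np.ndarray:
    sources, targets = graph_csr.nonzero()
    keep = sources < targets
    edges = list(zip(sources[keep].tolist(), targets[keep].tolist()))
    g = igraph.Graph(n=graph_csr.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


def cluster_cells(table: pd.DataFrame, markers, k_neighbors: int = 10,
                  resolution: float = 1.0, seed: int = 0,
                  n_pcs: int = DEFAULT_N_PCS) -> ClusterResult:
    """PCA + kNN graph + Leiden on the normalized marker columns."""
    markers = list(markers)
    n = len(table)
    if n <= k_neighbors:
        raise ValueError(f"need more than k={k_neighbors} cells, got {n}")
    X = table[markers].to_numpy(dtype=float)
    n_comp = min(n_pcs, len(markers) - 1, n - 1)
    if n_comp >= 1 and len(markers) > 2:
        X_red = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)
    else:
        X_red = X
    knn = kneighbors_graph(X_red, n_neighbors=k_neighbors, mode="connectivity")
    knn = knn.maximum(knn.T)  # symmetrize: undirected graph
    labels = _leiden(knn.tocsr(), resolution, seed)
    means = (pd.DataFrame(X, columns=markers)
             .groupby(labels).mean().rename_axis("cluster"))
    params = {"k_neighbors": k_neighbors, "resolution": resolution,
              "seed": seed, "n_pcs": n_comp, "markers": markers}
    return ClusterResult(labels=labels, means=means, params=params)


def annotate_clusters(result: ClusterResult, rulebook: AnnotationRulebook):
    """Map each cluster to the first rule its z-scored mean profile
    satisfies; returns (per-cell labels, per-cluster evidence table).

    z-scores are computed across cluster means (per marker), mirroring how
    a dot plot is read; evidence records each cluster's top-3 markers.
    """
    means = result.means
    rulebook.validate(means.columns)
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (means - mu) / sd
    cuts = {m: _otsu_split(means[m].to_numpy()) for m in means.columns}

    cluster_label = {}
    evidence_rows = []
    for cid in means.index:
        zrow = z.loc[cid]
        mrow = means.loc[cid]
        label = UNASSIGNED
        for rule in rulebook.rules:
            ok = all(zrow[m] >= rule.min_z and mrow[m] >= cuts[m]
                     for m in rule.high)
            ok = ok and all(zrow[m] <= -rule.min_z and mrow[m] <= cuts[m]
                            for m in rule.low)
            if ok:
                label = rule.label
                break
        cluster_label[cid] = label
        top = zrow.sort_values(ascending=False).index[:3]
        evidence_rows.append({"cluster": cid, "label": label,
                              "top_markers": "|".join(top)})
    cell_labels = np.asarray([cluster_label[c] for c in result.labels], dtype=object)
    return cell_labels, pd.DataFrame(evidence_rows)


def subcluster(table: pd.DataFrame, labels, parent: str, markers,
               resolution: float, seed: int = 0, k_neighbors: int = 10):
    """Re-cluster the cells of one annotated type at a (usually lower)
    resolution; sublabels are namespaced '<parent>/<k>'.  Returns
    (per-cell labels for the whole table with non-parent cells unchanged,
    ClusterResult of the subset)."""
    labels = np.asarray(labels, dtype=object)
    sel = labels == parent
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no cells with parent label {parent!r}")
    if n <= k_neighbors:
        raise ValueError(f"parent {parent!r} has only {n} cells (need > {k_neighbors})")
    sub = cluster_cells(table.loc[sel], markers, k_neighbors=k_neighbors,
                        resolution=resolution, seed=seed)
    out = labels.copy()
    out[sel] = [f"{parent}/{k}" for k in sub.labels]
    return out, sub


@dataclass
class Gate:
    """Conjunction of per-marker thresholds.  Each conjunct is
    (marker, kind, value) with kind 'percentile' (within the gated table)
    or 'absolute'."""

    label: str
    conjuncts: list


def gate_cells(table: pd.DataFrame, gates) -> pd.Series:
    """Label cells that satisfy all conjuncts of a gate; later gates do
    not override earlier ones.  Returns a Series of labels ('' = no gate)."""
    out = pd.Series([""] * len(table), index=table.index, dtype=object)
    for gate in gates:
        mask = np.ones(len(table), dtype=bool)
        for (marker, kind, value) in gate.conjuncts:
            if marker not in table.columns:
                raise KeyError(f"gate {gate.label!r} references unknown marker {marker!r}")
            x = table[marker].to_numpy(dtype=float)
            thr = np.percentile(x, value) if kind == "percentile" else float(value)
            mask &= x > thr
        mask &= (out == "").to_numpy()
        out.iloc[np.flatnonzero(mask)] = gate.label
    return out


def composition(table: pd.DataFrame, label_col: str = "cell_type",
                week_col: str = "week") -> pd.DataFrame:
    """Per-type percentage per week; percentages sum to 100 per week."""
    if label_col not in table.columns or table[label_col].isna().all():
        raise ValueError("no annotated cells")
    weeks = table[week_col] if week_col in table.columns else pd.Series(0.0, index=table.index)
    counts = table.groupby([weeks, table[label_col]]).size().unstack(fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.index.name = "week"
    return pct


def marker_correlation(table: pd.DataFrame, markers) -> pd.DataFrame:
    """Pearson correlation matrix between marker columns."""
    return table[list(markers)].corr(method="pearson")
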