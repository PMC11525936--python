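"""Spatial neighbor graph and permutation neighborhood enrichment.

Cells are nodes; an undirected edge joins two cells whose centroids are
within a fixed radius (50 um by default, in physical micrometres).  For a
labelling of the nodes, enrichment compares the observed count of
neighboring label pairs against a null obtained by permuting the labels
over nodes with the graph fixed, summarized per pair as a Z-score

    Z(a, b) = (obs(a, b) - mean_perm(a, b)) / sd_perm(a, b).

Scaled matrices (column-wise centre/unit-variance) make weeks comparable
and feed the temporal series of adjacency changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "NeighborGraph",
    "EnrichmentMatrix",
    "build_neighbor_graph",
    "nhood_enrichment",
    "scale_enrichment",
    "temporal_series",
]

DEFAULT_RADIUS_UM = 50.0
DEFAULT_N_PERMS = 1000


@dataclass
class NeighborGraph:
    cell_ids: np.ndarray
    edges: np.ndarray      # (m, 2) int indices into cell_ids, i < j
    radius_um: float
    coords: np.ndarray     # (n, 2) um, kept for verification

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def neighbor_lists(self) -> list:
        adj = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass
class EnrichmentMatrix:
    labels: list
    observed: pd.DataFrame
    perm_mean: pd.DataFrame
    perm_sd: pd.DataFrame
    zscore: pd.DataFrame
    degenerate: pd.DataFrame  # True where sd_perm == 0 (Z forced to 0)
    n_perms: int
    seed: int


def build_neighbor_graph(table: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM) -> NeighborGraph:
    """Exact fixed-radius graph on the centroid coordinates (um)."""
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    coords = table[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=int)
    order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else []
    return NeighborGraph(
        cell_ids=table["cell_id"].to_numpy() if "cell_id" in table.columns
        else np.arange(len(table)),
        edges=pairs[order] if len(pairs) else pairs,
        radius_um=radius_um,
        coords=coords,
    )


def _pair_counts(codes_i, codes_j, n_labels) -> np.ndarray:
    """Symmetric label-pair count matrix; each unordered edge counted once
    (homotypic diagonal counts pairs, not cells)."""
    flat = codes_i * n_labels + codes_j
    counts = np.bincount(flat, minlength=n_labels * n_labels).reshape(n_labels, n_labels)
    sym = counts + counts.T
    np.fill_diagonal(sym, np.diag(sym) // 2)  # each homotypic edge was counted twice
    return sym


def nhood_enrichment(graph: NeighborGraph, labels, n_perms: int = DEFAULT_N_PERMS,
                     seed: int = 0) -> EnrichmentMatrix:
    """Permutation neighborhood enrichment over the fixed graph.

    Labels are shuffled over nodes; the graph never changes.  Pairs whose
    permutation distribution is degenerate (sd 0) get Z = 0 and a flag.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    labels = np.asarray(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError("one label per node required")
    cats = pd.Categorical(labels)
    names = list(cats.categories)
    codes = cats.codes.astype(np.int64)
    L = len(names)
    e = graph.edges
    obs = _pair_counts(codes[e[:, 0]], codes[e[:, 1]], L)

    rng = np.random.default_rng(seed)
    acc = np.zeros((L, L))
    acc2 = np.zeros((L, L))
    perm = codes.copy()
    for _ in range(n_perms):
        rng.shuffle(perm)
        c = _pair_counts(perm[e[:, 0]], perm[e[:, 1]], L)
        acc += c
        acc2 += c.astype(float) ** 2
    mean = acc / n_perms
    var = np.clip(acc2 / n_perms - mean ** 2, 0.0, None)
    sd = np.sqrt(var)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    z[degenerate] = 0.0

    def df(a):
        return pd.DataFrame(a, index=names, columns=names)

    return EnrichmentMatrix(
        labels=names, observed=df(obs), perm_mean=df(mean), perm_sd=df(sd),
        zscore=df(z), degenerate=df(degenerate), n_perms=n_perms, seed=seed,
    )


def scale_enrichment(z: pd.DataFrame):
    """Column-wise centre and unit-variance scaling (sample sd, n-1).

    Constant columns are set to 0 and flagged.  Returns (scaled, flags).
    """
    if len(z) < 2:
        raise ValueError("need at least 2 rows to scale")
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    flags = sd == 0
    safe_sd = sd.replace(0.0, 1.0)
    scaled = (z - mean) / safe_sd
    scaled.loc[:, flags] = 0.0
    return scaled, flags


def temporal_series(scaled_by_week: dict, common_labels) -> pd.DataFrame:
    """Per label-pair series of scaled Z across weeks.

    Each week is scaled first, then subset to the common labels (scaling
    before subsetting, so the scaling context is the full week matrix).
    Returns a long DataFrame (focal, other, week, scaled_z).
    """
    common = list(common_labels)
    rows = []
    for week in sorted(scaled_by_week):
        m = scaled_by_week[week]
        for lab in common:
            if lab not in m.index or lab not in m.columns:
                raise ValueError(f"label {lab!r} missing from week {week}")
        sub = m.loc[common, common]
        for a in common:
            for b in common:
                rows.append({"focal": a, "other": b, "week": week,
                             "scaled_z": float(sub.loc[a, b])})
    return pd.DataFrame(rows)
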