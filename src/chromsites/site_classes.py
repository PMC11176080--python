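"""Clustering and grouping of CTCF sites by their accessibility/binding
responses, plus chromatin-state annotation with a priority rule.

Sites are clustered on their (delta_atac, delta_chip) log2 fold changes
with k-means (k = 5 by default).  Cluster labels are renumbered by
decreasing mean delta_atac so the numbering is reproducible across seeds.
Persistent-binding sites — linear binding fold change within +/-20 % —
are split into groups by accessibility-change quantile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

DEFAULT_FEATURES = ("delta_atac", "delta_chip")

# chromHMM-style state mergers applied before priority assignment
STATE_MERGERS = {
    "StrongEnhancer": "Enhancer",
    "WeakEnhancer": "Enhancer",
    "Heterochromatin": "RepressedChromatin",
    "Repressed": "RepressedChromatin",
}

STATE_PRIORITY = (
    "ActivePromoter",
    "BivalentChromatin",
    "Enhancer",
    "RepressedChromatin",
    "Insulator",
)
FALLBACK_STATE = "Intergenic"


def kmeans_cluster(
    table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 25,
    features=DEFAULT_FEATURES,
    scale: bool = False,
) -> pd.DataFrame:
    """Lloyd's k-means (k-means++ init, best of ``n_restarts`` by WCSS) on
    the response features; clusters renumbered 1..k by decreasing mean
    delta_atac.  Features are used unscaled by default (log2 fold changes
    are already commensurate)."""
    X = table.loc[:, list(features)].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if k < 2 or k > len(table):
        raise ValueError(f"k={k} outside [2, n={len(table)}]")
    if scale:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                algorithm="lloyd", random_state=seed)
    raw = km.fit_predict(X)
    out = table.copy()
    out["cluster"] = _relabel_by_mean(raw, table[features[0]].to_numpy(float), k)
    return out


def _relabel_by_mean(labels: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    means = np.array([
        values[labels == c].mean() if np.any(labels == c) else -np.inf
        for c in range(k)
    ])
    # cluster 1 = highest mean value; ties broken by original label
    order = np.argsort(-means, kind="stable")
    mapping = {int(c): i + 1 for i, c in enumerate(order)}
    return np.array([mapping[int(c)] for c in labels])


def elbow_scan(
    table: pd.DataFrame,
    k_range=range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
    features=DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Total within-cluster sum of squares per k, for elbow plots; makes
    no automatic choice."""
    X = table.loc[:, list(features)].to_numpy(float)
    rows = []
    for k in k_range:
        if not 2 <= k <= len(table) - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                    algorithm="lloyd", random_state=seed)
        km.fit(X)
        rows.append((k, float(km.inertia_)))
    return pd.DataFrame(rows, columns=["k", "wcss"])


def persistent_groups(
    table: pd.DataFrame,
    fc_window: tuple[float, float] = (0.8, 1.2),
    n_groups: int = 4,
    chip_column: str = "delta_chip",
    atac_column: str = "delta_atac",
) -> pd.DataFrame:
    """Split persistently bound sites into accessibility-change groups.

    A site is persistent when its linear binding fold change,
    2**delta_chip, lies in the closed interval ``fc_window``.  Persistent
    sites are ranked by delta_atac and cut into ``n_groups`` rank
    quantiles of equal size (+/-1): group 1 keeps the most accessibility
    (highest delta_atac), group ``n_groups`` loses the most.  Non-persistent
    sites get group 0.
    """
    lo, hi = fc_window
    fc = np.power(2.0, table[chip_column].to_numpy(float))
    # closed endpoints, with a whisker of relative tolerance so that a
    # fold change stored as log2 and converted back still counts as 0.8
    tol = 1e-9
    persistent = (fc >= lo * (1 - tol)) & (fc <= hi * (1 + tol))
    n_pers = int(persistent.sum())
    if n_pers < n_groups:
        raise ValueError(
            f"persistent set ({n_pers}) smaller than n_groups ({n_groups})"
        )
    out = table.copy()
    out["persistent"] = persistent
    groups = np.zeros(len(table), dtype=int)
    sub = out.loc[persistent]
    # rank by delta_atac descending, stable in input order for ties
    order = np.argsort(-sub[atac_column].to_numpy(float), kind="stable")
    bounds = np.linspace(0, n_pers, n_groups + 1).round().astype(int)
    g = np.empty(n_pers, dtype=int)
    for gi in range(n_groups):
        g[order[bounds[gi]: bounds[gi + 1]]] = gi + 1
    groups[np.flatnonzero(persistent)] = g
    out["group"] = groups
    return out


def read_state_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            rows.append((p[0], int(p[1]), int(p[2]), p[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def annotate_state(
    sites: pd.DataFrame,
    states: pd.DataFrame,
    priority=STATE_PRIORITY,
    mergers: dict = STATE_MERGERS,
) -> pd.DataFrame:
    """Label each site with the highest-priority overlapping chromatin
    state; sites overlapping none are Intergenic.  State mergers are
    applied before the priority rule; an unknown state label raises."""
    from intervaltree import IntervalTree

    merged = states.copy()
    merged["state"] = merged["state"].map(lambda s: mergers.get(s, s))
    unknown = sorted(set(merged["state"]) - set(priority))
    if unknown:
        raise ValueError(f"unknown chromatin state label(s): {unknown}")
    rank = {s: i for i, s in enumerate(priority)}

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in merged.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row in sub.itertuples():
            tree.addi(row.start, row.end, row.state)
        trees[chrom] = tree

    labels = []
    for row in sites.itertuples():
        tree = trees.get(row.chrom)
        hits = tree.overlap(row.start, row.end) if tree is not None else ()
        if not hits:
            labels.append(FALLBACK_STATE)
        else:
            labels.append(min((h.data for h in hits), key=lambda s: rank[s]))
    out = sites.copy()
    out["chrom_state"] = labels
    return out
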