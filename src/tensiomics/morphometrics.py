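"""Trajectory clustering and compression into the four oxygen-response groups.

Per-gene z-ratio triples over the (1%, 4%, 9% vs 20% O2) contrasts are
clustered with k-means, and clusters (or individual genes) are compressed
into four canonical trajectory shapes:

    ONE    elevation at 4% O2 relative to both 1% and 9%
    TWO    reduction at 4% O2 relative to both 1% and 9%
    THREE  monotone potentiation with increasing hypoxia (largest at 1%)
    FOUR   the mirror of THREE

plus UNCLASSIFIED for profiles matching none of the four patterns. A
morphometric sign-pattern class (a triple over {+, -, 0}) is recorded
alongside as the finer-grained descriptor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

GROUPS = ("ONE", "TWO", "THREE", "FOUR")
CONTRAST_ORDER = (1, 4, 9)

__all__ = [
    "build_profiles",
    "kmeans_profiles",
    "classify_group",
    "classify_profiles",
    "morph_class",
    "assign_groups",
    "group_summary",
    "GROUPS",
]


def build_profiles(
    zratios: pd.DataFrame,
    significant: dict | None = None,
    scope: str = "union",
) -> pd.DataFrame:
    """Gene x contrast profile matrix with columns fixed to (1, 4, 9).

    ``significant`` maps tension -> significant gene set. scope='union'
    keeps genes significant in any contrast (profiles completed from the
    full z-ratio table, which covers every gene); 'intersection' keeps genes
    significant in all three; 'all' keeps every gene with a complete profile.
    """
    for t in CONTRAST_ORDER:
        if t not in zratios.columns:
            raise KeyError(f"z-ratio table lacks the {t}% contrast")
    if scope == "all" or significant is None:
        genes = list(zratios.index)
    elif scope == "union":
        genes = sorted(set().union(*significant.values()))
    elif scope == "intersection":
        genes = sorted(set.intersection(*[set(v) for v in significant.values()]))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    missing = [g for g in genes if g not in zratios.index]
    if missing:
        raise KeyError(f"genes with no z-ratio profile: {missing[:5]}")
    profiles = zratios.loc[genes, list(CONTRAST_ORDER)].astype(float)
    if profiles.isna().any().any():
        raise ValueError("incomplete profiles (NaN z-ratios)")
    return profiles


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> pd.Series:
    """Seeded k-means over trajectory profiles (Euclidean, best of n_init)."""
    X = profiles.to_numpy(dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct profiles")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    out = pd.Series(labels, index=profiles.index, name="cluster")
    out.attrs["centroids"] = km.cluster_centers_
    out.attrs["inertia"] = float(km.inertia_)
    return out


def classify_group(m1: float, m4: float, m9: float, epsilon: float = 0.0) -> str:
    """Assign a trajectory (m1, m4, m9) to ONE/TWO/THREE/FOUR/UNCLASSIFIED.

    The four rules are mutually exclusive for any epsilon >= 0:

        ONE    m4 > m1 + eps and m4 > m9 + eps
        TWO    m4 < m1 - eps and m4 < m9 - eps
        THREE  m1 > m4 + eps and m4 > m9 + eps
        FOUR   m1 < m4 - eps and m4 < m9 - eps
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if m4 > m1 + epsilon and m4 > m9 + epsilon:
        return "ONE"
    if m4 < m1 - epsilon and m4 < m9 - epsilon:
        return "TWO"
    if m1 > m4 + epsilon and m4 > m9 + epsilon:
        return "THREE"
    if m1 < m4 - epsilon and m4 < m9 - epsilon:
        return "FOUR"
    return "UNCLASSIFIED"


def classify_profiles(profiles: pd.DataFrame, epsilon: float = 0.0) -> pd.Series:
    """Vectorised :func:`classify_group` over a profile matrix."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    m1, m4, m9 = (profiles[t].to_numpy(dtype=float) for t in CONTRAST_ORDER)
    out = np.full(len(profiles), "UNCLASSIFIED", dtype=object)
    one = (m4 > m1 + epsilon) & (m4 > m9 + epsilon)
    two = (m4 < m1 - epsilon) & (m4 < m9 - epsilon)
    three = (m1 > m4 + epsilon) & (m4 > m9 + epsilon)
    four = (m1 < m4 - epsilon) & (m4 < m9 - epsilon)
    out[one] = "ONE"
    out[two] = "TWO"
    out[three] = "THREE"
    out[four] = "FOUR"
    return pd.Series(out, index=profiles.index, name="group")


def morph_class(m1: float, m4: float, m9: float, epsilon: float = 0.0) -> str:
    """Sign-pattern class over {+, -, 0}^3 with |value| <= epsilon mapped to 0."""
    def s(v):
        if v > epsilon:
            return "+"
        if v < -epsilon:
            return "-"
        return "0"
    return s(m1) + s(m4) + s(m9)


def assign_groups(
    profiles: pd.DataFrame,
    k: int = 40,
    seed: int = 0,
    epsilon: float = 0.0,
    per_gene: bool = False,
    gene_epsilon: float = 0.5,
) -> pd.DataFrame:
    """Cluster profiles and compress into the four oxygen-response groups.

    By default groups are assigned per k-means cluster from the cluster mean
    profile (cluster means are already denoised, so epsilon defaults to 0);
    ``per_gene=True`` classifies each gene's own profile with the noise-guard
    ``gene_epsilon`` instead, which is the mode used for recovery checks.
    """
    k = min(k, np.unique(profiles.to_numpy(dtype=float), axis=0).shape[0])
    clusters = kmeans_profiles(profiles, k, seed=seed)
    centroids = clusters.attrs["centroids"]
    out = profiles.copy()
    out.columns = [f"z_{t}" for t in CONTRAST_ORDER]
    out["cluster"] = clusters
    if per_gene:
        out["group"] = classify_profiles(profiles, epsilon=gene_epsilon)
        eps_used = gene_epsilon
    else:
        cluster_group = {
            c: classify_group(*centroids[c], epsilon=epsilon) for c in range(k)
        }
        out["group"] = out["cluster"].map(cluster_group)
        eps_used = epsilon
    out["morph_class"] = [
        morph_class(r[0], r[1], r[2], epsilon=eps_used)
        for r in profiles.to_numpy(dtype=float)
    ]
    out.attrs["centroids"] = centroids
    return out


def _sem(values: np.ndarray) -> float:
    """SEM with SD of a single value defined as 0 (degenerate policy)."""
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def group_summary(assignments: pd.DataFrame):
    """Mean +/- SEM trajectory per group and the cluster-size histogram.

    Returns ``(summary, cluster_sizes)``: a DataFrame indexed by group with
    mean/SEM columns per contrast plus member counts, and a Series of
    k-means cluster sizes carrying overall ``size_mean``/``size_sem`` attrs.
    Groups without members are omitted with a warning.
    """
    rows = []
    for group in GROUPS:
        sub = assignments.loc[assignments["group"] == group]
        if sub.empty:
            warnings.warn(f"group {group} has no members; omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        row = {"group": group, "n_genes": len(sub)}
        for t in CONTRAST_ORDER:
            vals = sub[f"z_{t}"].to_numpy(dtype=float)
            row[f"mean_{t}"] = float(vals.mean())
            row[f"sem_{t}"] = _sem(vals)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame()
    sizes = assignments["cluster"].value_counts().sort_index()
    sizes.name = "cluster_size"
    vals = sizes.to_numpy(dtype=float)
    sizes.attrs["size_mean"] = float(vals.mean()) if vals.size else float("nan")
    sizes.attrs["size_sem"] = _sem(vals)
    return summary, sizes
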