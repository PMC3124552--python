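"""Gene-set enrichment: PAGE standardized/cumulative Z and hybrid pathway score.

PAGE (parametric analysis of gene set enrichment) scores a gene set against
the distribution of all per-gene z-ratios in a contrast:

    page_Z = (Sm - mu) * sqrt(m) / delta

with ``Sm`` the mean z-ratio of the set's m scored members and ``mu``,
``delta`` the mean and SD of all z-ratios. The cumulative Z of a set is the
plain sum of the z-ratios of its significantly regulated members; its sign
reads as concerted up- vs down-regulation.

Canonical-pathway over-representation is condensed into a single hybrid
index: ``R * (-log10 p)`` where ``R = (k/n)/(K/N)`` is the enrichment ratio
against a background universe and ``p`` the hypergeometric upper tail.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .setops import venn_partition

__all__ = [
    "page_score",
    "hybrid_pathway_score",
    "page_venn",
    "classify_z_trajectory",
]


def page_score(
    zratios: pd.Series,
    gene_sets: dict,
    significant=None,
    min_genes: int = 2,
    alpha: float = 0.05,
    zcut: float = 1.5,
) -> pd.DataFrame:
    """Score every gene set in one contrast with PAGE.

    Parameters
    ----------
    zratios : Series
        Per-gene z-ratio for the contrast (index: gene ids). The background
        mean/SD are taken over *all* of these genes.
    gene_sets : dict
        Set name -> iterable of gene ids.
    significant : iterable, optional
        Genes counted into the cumulative Z (the significantly regulated
        members). Defaults to members with ``|z_ratio| >= zcut``.
    min_genes, alpha
        Reporting gate: a set is flagged ``reported`` when it has at least
        ``min_genes`` scored members and two-sided normal p <= alpha. All
        sets are retained in the returned table.

    Returns a DataFrame with columns
    ``set, m, Sm, page_z, p_value, cumulative_z, n_significant, reported``.
    """
    z = zratios.astype(float)
    mu = float(z.mean())
    delta = float(z.std(ddof=1))
    if not delta > 0:
        raise ValueError("degenerate z-ratio background (delta = 0)")
    universe = set(z.index)
    if significant is None:
        sig = set(z.index[z.abs() >= zcut])
    else:
        sig = set(significant)
    rows = []
    for name, members in gene_sets.items():
        scored = sorted(set(members) & universe)
        m = len(scored)
        if m == 0:
            rows.append((name, 0, np.nan, np.nan, np.nan, 0.0, 0, False))
            continue
        sm = float(z.loc[scored].mean())
        page_z = (sm - mu) * np.sqrt(m) / delta
        p = 2.0 * stats.norm.sf(abs(page_z))
        sig_members = [g for g in scored if g in sig]
        cum_z = float(z.loc[sig_members].sum()) if sig_members else 0.0
        rows.append(
            (name, m, sm, page_z, p, cum_z, len(sig_members),
             m >= min_genes and p <= alpha)
        )
    return pd.DataFrame(
        rows,
        columns=["set", "m", "Sm", "page_z", "p_value", "cumulative_z",
                 "n_significant", "reported"],
    )


def hybrid_pathway_score(
    hits,
    pathways: dict,
    background,
    min_genes: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation with the hybrid R*(-log10 p) index.

    ``k`` of the ``n`` input genes land in a pathway of size ``K`` within the
    ``N``-gene background; ``p = P(X >= k)`` under sampling without
    replacement and ``R = (k/n)/(K/N)``. Pathways are flagged ``reported``
    when k >= min_genes and p <= alpha.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene universe")
    hit_set = set(hits) & bg
    stray = set(hits) - bg
    if stray:
        warnings.warn(
            f"{len(stray)} hit gene(s) outside the background were dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    n = len(hit_set)
    N = len(bg)
    rows = []
    for name, members in pathways.items():
        pw = set(members) & bg
        K = len(pw)
        k = len(pw & hit_set)
        if K == 0 or n == 0:
            rows.append((name, k, K, n, N, 0.0, 1.0, 0.0, False))
            continue
        # upper tail P(X >= k); sf(k-1) includes k
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        R = (k / n) / (K / N)
        hybrid = R * (-np.log10(p))
        rows.append((name, k, K, n, N, R, p, hybrid, k >= min_genes and p <= alpha))
    return pd.DataFrame(
        rows,
        columns=["pathway", "k", "K", "n", "N", "R", "p_value", "hybrid",
                 "reported"],
    )


def classify_z_trajectory(z1: float, z4: float, z9: float) -> str:
    """Shape class of a PAGE Z triple across the 1/4/9% contrasts.

    ``4%-pivot``: scores at 1% and 9% both exceed the 4% score (the bimodal
    pattern pivoting around physiological normoxia). ``ascending``: strictly
    increasing Z with falling oxygen (z1 > z4 > z9). ``descending``: the
    mirror. Anything else is ``other``.
    """
    if z1 > z4 and z9 > z4:
        return "4%-pivot"
    if z1 > z4 > z9:
        return "ascending"
    if z1 < z4 < z9:
        return "descending"
    return "other"


def page_venn(page_results: dict) -> tuple:
    """Venn partition of reported PAGE set names across the three contrasts.

    ``page_results`` maps tension (1, 4, 9) to the DataFrame produced by
    :func:`page_score`. Returns ``(VennPartition, trajectories)`` where
    ``trajectories`` is a DataFrame classifying each multi-tension (subset G)
    collection's page-Z triple.
    """
    reported = {
        t: set(df.loc[df["reported"], "set"]) for t, df in page_results.items()
    }
    partition = venn_partition(
        reported.get(1, set()), reported.get(4, set()), reported.get(9, set())
    )
    z_by_tension = {
        t: df.set_index("set")["page_z"] for t, df in page_results.items()
    }
    rows = []
    for name in sorted(partition["G"]):
        z1, z4, z9 = (z_by_tension[t][name] for t in (1, 4, 9))
        rows.append(
            {
                "set": name,
                "z_1": z1,
                "z_4": z4,
                "z_9": z9,
                "trajectory": classify_z_trajectory(z1, z4, z9),
            }
        )
    trajectories = pd.DataFrame(
        rows, columns=["set", "z_1", "z_4", "z_9", "trajectory"]
    )
    return partition, trajectories
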