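"""Recompute printed summary statistics from user-supplied supplementary tables.

Users convert the published supplementary tables to TSV by hand; this module
re-derives the headline statistics (Venn unique fractions, polarity
divergence percentages, mean cluster size) from them with the same
operations the pipeline uses. Expected layouts:

* per-contrast significant-gene tables ``sig_1.tsv``, ``sig_4.tsv``,
  ``sig_9.tsv``: at least a ``gene`` column;
* intersection tables ``intersection_D.tsv`` .. ``intersection_G.tsv``:
  ``gene`` plus z-ratio columns ``z_1``/``z_4``/``z_9`` for the defining
  contrasts;
* ``clusters.tsv``: ``gene`` and ``cluster`` columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .setops import polarity_divergence, venn_partition

DEFINING = {"D": (1, 4), "E": (1, 9), "F": (4, 9), "G": (1, 4, 9)}

__all__ = ["reproduce_supplementary"]


def _read(path: Path) -> pd.DataFrame | None:
    if not path.exists():
        warnings.warn(f"{path.name} missing; statistic skipped",
                      RuntimeWarning, stacklevel=3)
        return None
    return pd.read_csv(path, sep="\t")


def reproduce_supplementary(tables_dir) -> pd.DataFrame:
    """Report of recomputed statistics; empty (with warnings) when tables are absent."""
    tables_dir = Path(tables_dir)
    rows = []

    sig = {}
    for t in (1, 4, 9):
        df = _read(tables_dir / f"sig_{t}.tsv")
        if df is not None:
            sig[t] = set(df["gene"])
    if len(sig) == 3:
        part = venn_partition(sig[1], sig[4], sig[9])
        for t, frac in part.unique_fractions.items():
            rows.append({"statistic": f"unique_fraction_{t}pct",
                         "value": 100 * frac, "unit": "%"})

    for label, contrasts in DEFINING.items():
        df = _read(tables_dir / f"intersection_{label}.tsv")
        if df is None:
            continue
        cols = [f"z_{t}" for t in contrasts]
        zr = df.set_index("gene")[cols]
        zr.columns = list(contrasts)
        frac, _ = polarity_divergence(set(zr.index), zr, contrasts)
        rows.append({"statistic": f"divergence_{label}",
                     "value": 100 * frac, "unit": "%"})

    df = _read(tables_dir / "clusters.tsv")
    if df is not None:
        sizes = df.groupby("cluster").size().to_numpy(dtype=float)
        rows.append({"statistic": "mean_cluster_size",
                     "value": float(sizes.mean()), "unit": "genes"})
        sem = sizes.std(ddof=1) / np.sqrt(sizes.size) if sizes.size > 1 else 0.0
        rows.append({"statistic": "cluster_size_sem",
                     "value": float(sem), "unit": "genes"})

    return pd.DataFrame(rows, columns=["statistic", "value", "unit"])
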