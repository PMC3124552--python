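"""Venn partition of per-contrast significant genes and polarity divergence.

The three contrasts (1, 4, 9 % O2 vs the 20% control) induce seven disjoint
subsets of the union of significant genes:

    A  unique to 1%          D  1% & 4% only   ("low tension")
    B  unique to 4%          E  1% & 9% only   ("cross tension")
    C  unique to 9%          F  4% & 9% only   ("intermediate tension")
                             G  all three      ("multi tension")
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSET_LABELS = ("A", "B", "C", "D", "E", "F", "G")

# which contrasts define each subset (membership pattern over (1, 4, 9))
SUBSET_PATTERNS = {
    "A": (True, False, False),
    "B": (False, True, False),
    "C": (False, False, True),
    "D": (True, True, False),
    "E": (True, False, True),
    "F": (False, True, True),
    "G": (True, True, True),
}

__all__ = ["VennPartition", "venn_partition", "polarity_divergence", "SUBSET_LABELS"]


@dataclass
class VennPartition:
    """Seven pairwise-disjoint subsets labelled A-G over a shared id space."""

    subsets: dict = field(default_factory=dict)
    per_contrast_sizes: dict = field(default_factory=dict)

    def __getitem__(self, label: str):
        return self.subsets[label]

    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.subsets.items()}

    @property
    def unique_fractions(self) -> dict:
        """|A|/|sig@1%|, |B|/|sig@4%|, |C|/|sig@9%| (NaN when empty)."""
        out = {}
        for label, tension in zip("ABC", (1, 4, 9)):
            n = self.per_contrast_sizes.get(tension, 0)
            out[tension] = len(self.subsets[label]) / n if n else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "subset": label}
            for label in SUBSET_LABELS
            for g in sorted(self.subsets[label])
        ]
        return pd.DataFrame(rows, columns=["gene", "subset"])


def venn_partition(sig_1, sig_4, sig_9) -> VennPartition:
    """Partition three significant-gene sets into the seven Venn subsets.

    Empty inputs are allowed; the subsets are pairwise disjoint and their
    union equals the union of the three inputs.
    """
    s1, s4, s9 = set(sig_1), set(sig_4), set(sig_9)
    membership = (s1, s4, s9)
    subsets = {}
    for label, pattern in SUBSET_PATTERNS.items():
        keep = [m for m, k in zip(membership, pattern) if k]
        drop = [m for m, k in zip(membership, pattern) if not k]
        genes = set.intersection(*keep)
        for m in drop:
            genes -= m
        subsets[label] = frozenset(genes)
    return VennPartition(
        subsets=subsets,
        per_contrast_sizes={1: len(s1), 4: len(s4), 9: len(s9)},
    )


def polarity_divergence(subset, zratios: pd.DataFrame, contrasts):
    """Fraction of a subset's genes whose regulation polarity is not coherent.

    A gene is divergent iff its z-ratios over the listed contrasts include
    both a strictly positive and a strictly negative value; exact zeros are
    compatible with either polarity and never trigger divergence on their
    own. Returns ``(fraction, divergent_genes)``.
    """
    genes = sorted(subset)
    if not genes:
        raise ValueError("polarity divergence is undefined for an empty subset")
    missing = [g for g in genes if g not in zratios.index]
    if missing:
        raise KeyError(f"genes without z-ratios: {missing[:5]}")
    vals = zratios.loc[genes, list(contrasts)].to_numpy(dtype=float)
    divergent_mask = (vals > 0).any(axis=1) & (vals < 0).any(axis=1)
    divergent = [g for g, m in zip(genes, divergent_mask) if m]
    return len(divergent) / len(genes), divergent


def divergence_report(partition: VennPartition, zratios: pd.DataFrame) -> pd.DataFrame:
    """Polarity divergence for the shared subsets D, E, F, G.

    D/E/F use their two defining contrasts; G uses all three. Empty subsets
    are skipped.
    """
    defining = {"D": (1, 4), "E": (1, 9), "F": (4, 9), "G": (1, 4, 9)}
    rows = []
    for label, contrasts in defining.items():
        members = partition[label]
        if not members:
            continue
        frac, div = polarity_divergence(members, zratios, contrasts)
        rows.append(
            {
                "subset": label,
                "n_genes": len(members),
                "n_divergent": len(div),
                "divergent_fraction": frac,
            }
        )
    return pd.DataFrame(
        rows, columns=["subset", "n_genes", "n_divergent", "divergent_fraction"]
    )
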