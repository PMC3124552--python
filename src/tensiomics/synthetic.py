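"""Synthetic study generator: expression, truth labels, gene sets, corpus.

Emulates the design the analysis assumes — four oxygen tensions (1, 4, 9,
20 % O2) x replicate arrays, log-normal intensity noise, and planted gene
"programs" following the four canonical z-ratio trajectory shapes — plus a
gene-set collection enriched in the planted programs and a literature-like
corpus whose term co-occurrence links planted genes to interrogation terms.

Planted effects are defined in z-ratio space and inverted to log-intensity
space: a target z-ratio tau for a contrast becomes an additive condition
offset ``tau * sqrt(2/n_replicates) * noise_sd``, the scale at which the
null difference distribution lives. Because the z-ratio normalises by the
SD of differences over *all* genes, planting a nonzero fraction of genes
attenuates realised planted z-ratios by the analytic factor
``sqrt(1 + sum_g frac_g * tau_{g,t}^2)`` per contrast; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .morphometrics import GROUPS

TENSIONS = (1, 4, 9, 20)

DEFAULT_TERMS = (
    "neurodegeneration",
    "alzheimer's",
    "aging",
    "ischemia",
    "neuroprotective",
    "cognition",
    "hyperoxia",
    "hypoxia",
    "astrocyte",
)

# trajectory shapes in z-ratio space, as multiples of effect_size, over the
# (1%, 4%, 9%) contrasts: bimodal pivot around 4% with half-amplitude flanks
# (ONE/TWO) and monotone through zero (THREE/FOUR)
TRAJECTORY_SHAPES = {
    "ONE": (-0.5, 1.0, -0.5),
    "TWO": (0.5, -1.0, 0.5),
    "THREE": (1.0, 0.0, -1.0),
    "FOUR": (-1.0, 0.0, 1.0),
}

__all__ = [
    "SynthConfig",
    "generate_expression",
    "generate_genesets",
    "generate_corpus",
    "DEFAULT_TERMS",
    "TRAJECTORY_SHAPES",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the generator.

    frac_planted is the fraction of genes per group ONE..FOUR; effect_size
    is the target |z-ratio| magnitude of planted genes; noise_sd is the
    replicate-level log-intensity noise SD; term_signal is the expected
    extra topic-word count in a linked gene's document.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    tensions: tuple = TENSIONS
    frac_planted: float = 0.05
    effect_size: float = 3.0
    noise_sd: float = 0.25
    baseline_mu_range: tuple = (6.0, 12.0)
    seed: int = 0
    corpus_terms: tuple = DEFAULT_TERMS
    term_signal: float = 20.0
    linked_groups: tuple = ("ONE", "TWO")

    def validate(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if tuple(self.tensions) != TENSIONS:
            raise ValueError(f"tensions must be {TENSIONS}")
        if not 0 <= self.frac_planted or 4 * self.frac_planted >= 1:
            raise ValueError("frac_planted must satisfy 0 <= 4*frac_planted < 1 "
                             "(null genes must exist)")
        if not self.effect_size > 0:
            raise ValueError("effect_size must be > 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.baseline_mu_range
        if not lo < hi:
            raise ValueError("baseline_mu_range must be a nonempty interval")
        if self.term_signal < 0:
            raise ValueError("term_signal must be >= 0")
        return self

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _truth_table(config: SynthConfig) -> pd.DataFrame:
    genes = _gene_ids(config.n_genes)
    n_per = int(round(config.frac_planted * config.n_genes))
    groups = []
    for g in GROUPS:
        groups.extend([g] * n_per)
    groups.extend(["NULL"] * (config.n_genes - len(groups)))
    if len(groups) != config.n_genes:
        raise ValueError("planted fractions exceed the gene pool")
    e = config.effect_size
    rows = []
    terms = list(config.corpus_terms)
    link_counter = 0
    for gene, grp in zip(genes, groups):
        if grp == "NULL":
            tau = (0.0, 0.0, 0.0)
            linked = ""
        else:
            tau = tuple(e * s for s in TRAJECTORY_SHAPES[grp])
            if grp in config.linked_groups and terms:
                linked = terms[link_counter % len(terms)]
                link_counter += 1
            else:
                linked = ""
        rows.append({
            "gene": gene, "group": grp,
            "tau_1": tau[0], "tau_4": tau[1], "tau_9": tau[2],
            "linked_terms": linked,
        })
    return pd.DataFrame(rows).set_index("gene")


def generate_expression(config: SynthConfig):
    """Expression matrix + sample sheet + truth table for one synthetic study.

    Returns ``(expression, samples, truth)``: a gene x sample DataFrame of
    positive intensities, a sample sheet with (sample, tension, replicate),
    and the truth table mapping genes to planted groups, target z-ratio
    triples and linked interrogation terms. Identical config (including
    seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _truth_table(config)
    n = config.n_genes
    reps = config.n_replicates
    lo, hi = config.baseline_mu_range
    baseline = rng.uniform(lo, hi, size=n)
    # z-ratio -> log-intensity inversion scale (null difference SD)
    c = np.sqrt(2.0 / reps) * config.noise_sd
    tau = truth[["tau_1", "tau_4", "tau_9"]].to_numpy()
    offsets = {1: tau[:, 0] * c, 4: tau[:, 1] * c, 9: tau[:, 2] * c,
               20: np.zeros(n)}
    cols = {}
    sample_rows = []
    for t in config.tensions:
        for r in range(1, reps + 1):
            sid = f"O2_{t:02d}pct_r{r}"
            noise = rng.normal(0.0, config.noise_sd, size=n)
            cols[sid] = np.exp(baseline + offsets[t] + noise)
            sample_rows.append({"sample": sid, "tension": t, "replicate": r})
    expression = pd.DataFrame(cols, index=truth.index)
    samples = pd.DataFrame(sample_rows)
    return expression, samples, truth


def generate_genesets(
    truth: pd.DataFrame,
    sets_per_group: int = 5,
    decoys: int = 10,
    set_size: int = 20,
    purity: float = 0.8,
    seed: int = 0,
) -> dict:
    """Gene sets enriched in the planted groups plus uniform decoy sets.

    Each group set draws ``round(purity * set_size)`` genes from its group
    (capped at the group size) and the rest uniformly from all genes; decoy
    sets are uniform draws. Every set has at least 2 genes.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    if set_size < 2:
        raise ValueError("sets must have at least 2 genes")
    if not 0 <= purity <= 1:
        raise ValueError("purity must lie in [0, 1]")
    all_genes = np.array(truth.index)
    if set_size > len(all_genes):
        raise ValueError("set_size exceeds the available gene pool")
    rng = np.random.default_rng(seed)
    collection = {}
    for grp in GROUPS:
        pool = np.array(truth.index[truth["group"] == grp])
        for i in range(sets_per_group):
            n_core = min(int(round(purity * set_size)), len(pool))
            core = rng.choice(pool, size=n_core, replace=False) if n_core else []
            rest_pool = np.setdiff1d(all_genes, core)
            rest = rng.choice(rest_pool, size=set_size - n_core, replace=False)
            collection[f"PLANTED_{grp}_{i + 1}"] = sorted(
                set(core).union(rest))
    for i in range(decoys):
        collection[f"DECOY_{i + 1}"] = sorted(
            rng.choice(all_genes, size=set_size, replace=False))
    return collection


def _topic_vocab(term: str) -> list:
    slug = "".join(ch for ch in term.lower() if ch.isalnum())
    return [term.lower()] + [f"{slug}_topic{i}" for i in range(1, 6)]


def generate_corpus(truth: pd.DataFrame, config: SynthConfig) -> dict:
    """One literature-like document per gene.

    Every document draws 50 words from a Zipf-weighted background
    vocabulary; a gene linked to an interrogation term additionally receives
    ``Poisson(term_signal)`` words from that term's topic vocabulary (the
    term itself plus co-occurring topic words). term_signal = 0 removes the
    linkage signal entirely.
    """
    config.validate()
    if not config.corpus_terms:
        raise ValueError("corpus_terms must be non-empty")
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(config.seed + 1)
    background = [f"bgword{i:03d}" for i in range(150)]
    bg_p = 1.0 / np.arange(1, len(background) + 1)
    bg_p /= bg_p.sum()
    topics = {t: _topic_vocab(t) for t in config.corpus_terms}
    # term itself carries 40% of topic mass, companions share the rest
    topic_p = np.array([0.4] + [0.6 / 5] * 5)
    corpus = {}
    doc_len = 50
    for gene, row in truth.iterrows():
        counts = rng.multinomial(doc_len, bg_p)
        words = [w for w, k in zip(background, counts) for _ in range(int(k))]
        term = row["linked_terms"]
        if term:
            n_topic = rng.poisson(config.term_signal)
            if n_topic:
                tcounts = rng.multinomial(n_topic, topic_p)
                words += [w for w, k in zip(topics[term], tcounts)
                          for _ in range(int(k))]
        corpus[gene] = " ".join(words)
    return corpus
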