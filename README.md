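# tensiomics

Analysis of bulk gene-expression responses to ambient **oxygen tension**.
Cultured CNS cells (the motivating system is primary cortical astrocytes)
experience very different oxygen levels *in vivo* (~1–9 % O₂) than on the
bench (~20 % O₂). Profiling the transcriptome at several tensions — 1 %, 4 %
and 9 % O₂, each contrasted against a 20 % control — reveals distinct
"programs" of co-regulated transcripts whose activity depends on how far,
and in which direction, oxygen departs from the physiological set point.
`tensiomics` implements the complete analysis chain for such designs, plus a
synthetic-data generator that emulates the study design so every stage can
be exercised and validated without any external download.

## The statistics at the core

**Z-ratio differential expression.** Each array is log-transformed and
standardized over genes to z-scores. For a contrast of tension *t* against
the control, with replicate-averaged z-scores z̄,

```
d_g      = z̄_exp(g) − z̄_ctrl(g)
z-ratio  = d_g / SD({d_g : all genes g})
```

A transcript is *significantly regulated* (selector score ±3) when it
jointly passes |z-ratio| ≥ 1.5, Benjamini–Hochberg FDR q ≤ 0.01 (on the
two-sided normal p of the z-ratio) and a per-gene across-tension ANOVA
p ≤ 0.05.

**Venn / polarity analysis.** The three per-contrast significant-gene lists
are partitioned into seven disjoint subsets A–G (unique, pairwise-shared,
multi-tension); within shared subsets, the fraction of transcripts with
mixed up/down polarity across contrasts quantifies how rare regulation
reversal is.

**PAGE enrichment.** A gene set with m scored members of mean z-ratio Sm is
scored against the background mean μ and SD δ of all z-ratios:
`Z = (Sm − μ)·√m / δ`, with a two-sided normal p. The set's **cumulative Z**
— the plain sum of its significantly regulated members' z-ratios — reads as
concerted up- (positive) or down- (negative) regulation. Canonical-pathway
over-representation is condensed to the **hybrid score** `R · (−log₁₀ p)`,
where `R = (k/n)/(K/N)` is the enrichment ratio against a background
universe and p the hypergeometric upper tail.

**Morphometric group clusters.** Per-gene z-ratio triples (z₁, z₄, z₉) are
clustered with seeded k-means (default k = 40) and compressed into four
canonical trajectory shapes: **ONE** (elevated at 4 % vs both 1 % and 9 %),
**TWO** (the mirror trough), **THREE** (monotone potentiation with
increasing hypoxia), **FOUR** (the mirror), with mean ± SEM trajectories
per group.

**Cumulative transcript LSI score.** A gene–document corpus is weighted
(log-entropy), factorized by truncated SVD, and each gene is correlated
with interrogation terms (e.g. *hypoxia*, *astrocyte*, *aging*) as the
cosine of their latent projections. Genes with correlation > 0.1 are
*implicitly correlated*; per (group cluster, term) the score is
`N × mean correlation` over those genes.

## Worked example

```python
import warnings
from tensiomics import OxygenResponseModel
from tensiomics.synthetic import (SynthConfig, generate_expression,
                                  generate_genesets, generate_corpus,
                                  DEFAULT_TERMS)

cfg = SynthConfig(n_genes=500, seed=42)
expression, samples, truth = generate_expression(cfg)
gene_sets = generate_genesets(truth, sets_per_group=3, decoys=20, seed=42)
corpus = generate_corpus(truth, cfg)

model = OxygenResponseModel(expression, samples, gene_sets=gene_sets,
                            corpus=corpus, terms=DEFAULT_TERMS,
                            cluster_scope="all", n_clusters=20)
results = model.fit(seed=42)
print(results.summary())
```

prints

```
Oxygen-tension transcriptomic response analysis

Significantly regulated transcripts (selector +/-3):
   1% vs 20% O2: 0
   4% vs 20% O2: 0
   9% vs 20% O2: 0
Venn subset sizes (A-G): A=0, B=0, C=0, D=0, E=0, F=0, G=0
PAGE collections reported at 1% O2: 13/32
PAGE collections reported at 4% O2: 6/32
PAGE collections reported at 9% O2: 14/32
Group cluster trajectories (mean z-ratio at 1/4/9%):
    ONE: n=125, (-0.30, +0.88, -0.20)
    TWO: n=192, (+0.18, -0.70, +0.06)
  THREE: n=55, (+1.32, +0.39, -0.93)
   FOUR: n=128, (-0.53, +0.03, +0.51)
Mean cumulative transcript LSI score per group:
   FOUR: 0.000
    ONE: 2.438
  THREE: 0.000
    TWO: 2.427
```

Reading the output: no individual transcript clears the stringent
three-gate selector on this synthetic dataset (the z-ratio's
self-normalization caps attainable values when a fifth of genes carry
effects — see `docs/methods.md`), yet the set-level statistics recover the
planted structure clearly: roughly a third of the PAGE collections
(the planted ones) are reported per contrast, the four group-cluster mean
trajectories reproduce the planted shapes (peak at 4 %, trough at 4 %, and
the two monotone ramps), and only the two groups whose documents the
generator linked to interrogation terms (ONE and TWO) attain nonzero
cumulative LSI scores. `results.to_dir("out/")` writes every stage's TSV
tables plus a JSON summary; re-running with the same seed reproduces them
byte-for-byte.

A console script exposes the same stages:
`tensiomics simulate|zratio|venn|page|pathways|morph|lsi|run|reproduce`
(see `tensiomics --help`).

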