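# Methods

This note documents the models, conventions and numerical choices behind
`tensiomics`, and what the synthetic-data validation does and does not show
about real data.

## The z-ratio model

Raw intensities must be strictly positive; each array (sample column) is
log-transformed and standardized over genes. The result is invariant to the
logarithm base, since a base change rescales a column by a constant that
cancels in standardization. All standard deviations in the package use the
sample convention (n − 1), including per-column standardization; with the
population convention a three-gene column of logs (1, 2, 3) would
standardize to (−1.2247, 0, 1.2247) instead of the (−1, 0, 1) this package
produces.

For a contrast (tension t vs the 20 % control), replicate z-scores are
averaged per condition *before* differencing — the only reduction that
leaves a single per-contrast scale — and the difference d_g is divided by
the sample SD of {d_g} over **all** genes in the contrast. Consequences:

* the z-ratio vector of a contrast has SD exactly 1 by construction;
* swapping experimental and control labels negates every z-ratio exactly;
* on null data the z-ratio is asymptotically standard normal (the package
  verifies Kolmogorov–Smirnov distance < 0.05 at 2000 genes).

**Gene-level p-values** are two-sided normal tails of the z-ratio,
p = 2·(1 − Φ(|z|)): the statistic is built as a standardized difference, so
the normal reference is its natural null. **FDR** is Benjamini–Hochberg,
applied per contrast (matching per-tension significant-gene lists).
**ANOVA** is a per-gene one-way fixed-effects F-test across the four
tensions with replicates as observations; a second (blocking) factor cannot
be recovered from the design metadata this package consumes, so none is
fitted. Genes with zero variance are degenerate: their ANOVA p is reported
as 1 with a warning rather than failing the run.

The **selector score** is the conjunction ±3 ⇔ (z-ratio ≥ +1.5 / ≤ −1.5) ∧
(FDR q ≤ 0.01) ∧ (ANOVA p ≤ 0.05), else 0. All thresholds are parameters of
`OxygenResponseModel`.

## Venn subsets and polarity

The seven subsets A–G are exact set algebra over the three per-contrast
significant-gene lists; the partition is checked to be pairwise disjoint and
to tile the union. A gene is *polarity divergent* over a set of contrasts
iff its z-ratios include both a strictly positive and a strictly negative
value. An exact zero is compatible with either polarity and never triggers
divergence by itself (a measure-zero tie-break that avoids spurious
divergence). Subsets D/E/F are assessed over their two defining contrasts;
G over all three.

## PAGE and the hybrid pathway score

The PAGE background (μ, δ) is computed over **all** genes with a z-ratio in
the contrast, not only significant ones; the **cumulative Z**, by contrast,
sums only the set's significantly regulated members (callers pass the
selector-significant set; standalone calls default to members with
|z-ratio| ≥ 1.5). PAGE p-values are two-sided, since collections are
reported for both concerted up- and down-regulation. Reporting requires
m ≥ 2 scored members and p ≤ 0.05; unreported sets are retained in the full
table.

Pathway over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) — the standard reading of "probability of enrichment" for pathway
population — and R = (k/n)/(K/N) against an explicit background universe.
A p of exactly zero cannot occur in exact arithmetic, but underflow is
floored at the smallest positive double so the hybrid score R·(−log₁₀ p)
stays finite.

## Morphometric compression

Trajectory profiles are ordered (1 %, 4 %, 9 %) regardless of input order.
The default gene scope for clustering is the union of the per-contrast
significant lists, with profiles completed from the full z-ratio table
(z-ratios exist for every gene); `scope="all"` clusters every gene, which
is the mode used for recovery validation on synthetic data. k-means uses
scikit-learn with a seeded initialization and 10 restarts (best
within-cluster SS kept); k defaults to 40 clusters and is clipped to the
number of distinct profiles.

Group compression applies four mutually exclusive inequalities to a
trajectory (m₁, m₄, m₉) with tie tolerance ε:

| group | rule |
|---|---|
| ONE   | m₄ > m₁ + ε and m₄ > m₉ + ε |
| TWO   | m₄ < m₁ − ε and m₄ < m₉ − ε |
| THREE | m₁ > m₄ + ε and m₄ > m₉ + ε |
| FOUR  | m₁ < m₄ − ε and m₄ < m₉ − ε |

Pairwise exclusivity follows directly from the inequalities (each pair
contains a contradictory comparison); profiles matching none are
UNCLASSIFIED. By default groups are assigned per k-means cluster from the
cluster mean (ε = 0: means are already denoised); the per-gene mode uses
ε = 0.5 as a noise guard, since individual z-ratio triples carry unit-scale
noise. The finer "morphometric class" recorded alongside is the sign triple
over {+, −, 0}³ with |value| ≤ ε mapped to 0. SEM uses SD/√n with the SD of
a single value defined as 0 (flagged by a warning).

## LSI scoring

The LSI component is a standard, transparent implementation — a functional
stand-in for proprietary literature-indexing tools, with no claim of
reproducing any of their numeric scores. Documents are lowercased,
tokenized on word characters (apostrophes kept internally, so "Alzheimer's"
is one token), and a minimal English stop list is removed; domain
vocabulary is never stripped. The default weighting is log-entropy
(local log(1 + tf), global 1 + Σ p log p / log n_docs); tf-idf
(tf · log(N/df)) is available. All-zero rows/columns after weighting are
dropped with a warning.

The factorization keeps the top-r left singular vectors U_r and represents
documents and queries by projection U_rᵀx. The projection is an isometry of
the retained subspace, so when r equals the matrix rank and the weighted
matrix has full row rank, the cosine between a query and a document equals
the raw cosine on the weighted matrix (verified to 1e−8). Multi-word
interrogation terms are projected as pseudo-documents of their tokens; a
term absent from the vocabulary scores 0 with a warning (not an error), and
a rank exceeding the matrix rank is clipped with a warning. The default
rank is min(100, matrix rank).

*Implicit correlation* uses strict `> 0.1` by default with an `inclusive`
flag switching to `≥` (both conventions appear in the source literature;
the main-text strict reading is the default). The cumulative transcript
LSI score is N × mean correlation over a group's implicitly correlated
members — not N × N, a variant description that also circulates; score 0
iff N = 0, and the score is bounded by N.

## The synthetic study design

The generator emulates the motivating design: 4 tensions (1/4/9/20 % O₂) ×
3 replicate arrays, 2000 genes, per-gene baseline log-intensity uniform on
(6, 12), replicate-level Gaussian log-intensity noise with SD 0.25, and 5 %
of genes planted per group. No probe-level structure (bead redundancy,
background correction) is modeled. The source study publishes no noise or
effect-size parameters, so these defaults are this package's own choices of
a realistic regime, fixed once.

Planted trajectories are defined in z-ratio space — the pipeline's native
scale, making `effect_size` directly interpretable against the ±1.5 cutoff —
as multiples of effect_size e (default 3.0) over the (1 %, 4 %, 9 %)
contrasts:

* ONE (−e/2, +e, −e/2) and TWO (+e/2, −e, +e/2): the bimodal patterns
  pivoting around 4 % O₂, with half-amplitude flanks;
* THREE (+e, 0, −e) and FOUR (−e, 0, +e): the monotone ramps, symmetric
  through zero.

A target z-ratio τ is inverted to an additive condition offset
τ·√(2/n_reps)·noise_sd in log-intensity space — the scale of the null
difference distribution.

**Self-normalization attenuation.** Because the z-ratio divides by the SD
of differences over *all* genes, planting a fraction f_g of genes at target
τ_g inflates that SD by √(1 + Σ_g f_g τ_g²) per contrast (≈1.4–1.7 at the
defaults), so realized planted z-ratios are ≈1.8–2.2 rather than 3. Exact
compensation is infeasible — the fixed point requires Σ f_g τ_g² < 1, and
the defaults give 0.9–1.125 — and is not attempted. Two consequences,
verified by the suite: (i) the per-gene trajectory classification still
recovers ≳95 % of planted genes (the shapes survive attenuation), and
(ii) the three-gate selector, whose FDR ≤ 0.01 gate needs |z| ≳ 3.3 under
the normal null, fires on essentially nothing, so Venn subsets and
cumulative-Z terms are near-empty on synthetic data at these defaults.
Set-level statistics (PAGE Z, group trajectories, LSI) carry the recovery
signal instead. Real studies, with smaller planted fractions, sit closer to
the unattenuated regime; passing the synthetic suite demonstrates the
machinery's correctness and calibration, not the selector's power at this
specific planted density.

The gene-set generator draws each group set with configurable purity
(default 0.8) from its group's genes and decoy sets uniformly. The corpus
gives every gene a 50-word document from a Zipf-weighted background
vocabulary; genes in the linked groups (default ONE and TWO, cycling
through the nine default interrogation terms) additionally receive
Poisson(term_signal) topic words (the term itself at 40 % of topic mass
plus five co-occurring companions). The corpus has two-level vocabulary
structure only — no grammar, no polysemy, no citation structure — so LSI
results on it validate the algebra and thresholding, not performance on
real literature.

All generators are driven by `numpy.random.default_rng(seed)`; identical
configuration gives bit-identical output, and the pipeline's TSV outputs
are byte-reproducible under a fixed seed.

## Known limitations

* The selector's FDR gate is conservative by construction when many genes
  carry effects (see attenuation above).
* The "two-way" blocking factor of the original ANOVA design is not
  modeled; only tension is fitted.
* The morphometric classes are explicit sign-pattern stand-ins for
  figure-defined classes that have no published numeric definition.
* k = 40 mirrors the published cluster count but the original hierarchical
  k-means procedure is not reproducible from its description; cluster
  *boundaries* will differ even where group compression agrees.
* Venn rendering is out of scope; the partition is exact set algebra.
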