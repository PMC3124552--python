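"""Z-ratio differential expression statistics.

The workflow standardizes each array (sample) to z-scores over genes,
averages replicate z-scores per condition, and forms the z-ratio for an
experimental tension against the normoxic control:

    d_g     = zbar_exp(g) - zbar_ctrl(g)
    sigma_d = sample SD of {d_g} over all genes in the contrast
    z_ratio = d_g / sigma_d

A transcript is called significantly regulated (selector score +3 or -3)
when it jointly passes three gates: |z_ratio| >= 1.5, Benjamini-Hochberg
FDR q <= 0.01 and a per-gene across-tension ANOVA p <= 0.05.

All standard deviations in this package use the sample convention
(n - 1 denominator).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTRAST_TENSIONS = (1, 4, 9)
CONTROL_TENSION = 20

__all__ = [
    "log_normalize",
    "zratio",
    "zratio_table",
    "gene_pvalues",
    "bh_fdr",
    "anova_per_gene",
    "selector_scores",
    "differential_expression",
]


def _replicate_columns(samples: pd.DataFrame, tension: int) -> list:
    """Sample ids mapped to an oxygen tension (%O2) in the sample sheet."""
    hit = samples.loc[samples["tension"] == tension, "sample"]
    return list(hit)


def log_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """Log-transform intensities and standardize each sample column to z-scores.

    Parameters
    ----------
    expression : DataFrame
        Gene x sample matrix of positive fluorescence intensities
        (genes as the index).

    Returns
    -------
    DataFrame of the same shape whose columns each have mean 0 and sample SD 1.

    Notes
    -----
    The result is invariant to the logarithm base: a base change rescales a
    column by a constant, which cancels in the standardization.
    """
    if expression.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if expression.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    vals = expression.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensity values")
    if (vals <= 0).any():
        g, s = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"nonpositive intensity for gene {expression.index[g]!r} in "
            f"sample {expression.columns[s]!r}; log transform requires > 0"
        )
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = expression.columns[np.nonzero(sd == 0)[0][0]]
        raise ValueError(f"zero within-sample variance in sample {bad!r}")
    z = (logged - logged.mean(axis=0)) / sd
    return pd.DataFrame(z, index=expression.index, columns=expression.columns)


def zratio(
    zscores: pd.DataFrame,
    samples: pd.DataFrame,
    tension: int,
    control: int = CONTROL_TENSION,
) -> pd.DataFrame:
    """Z-ratio of one experimental tension against the control tension.

    Replicate z-scores are averaged per condition before differencing; the
    difference distribution over all genes supplies the single per-contrast
    scale ``sigma_d``. Swapping experimental and control labels negates
    every z-ratio exactly.

    Returns a DataFrame indexed by gene with columns
    ``z_exp, z_ctrl, d, z_ratio`` and the scalar ``sigma_d`` in ``.attrs``.
    """
    exp_cols = _replicate_columns(samples, tension)
    ctrl_cols = _replicate_columns(samples, control)
    if not exp_cols:
        raise ValueError(f"no samples at tension {tension}% O2")
    if not ctrl_cols:
        raise ValueError(f"no samples at control tension {control}% O2")
    z_exp = zscores[exp_cols].mean(axis=1)
    z_ctrl = zscores[ctrl_cols].mean(axis=1)
    d = z_exp - z_ctrl
    sigma_d = float(d.std(ddof=1))
    if not sigma_d > 0:
        raise ValueError(
            f"degenerate contrast {tension} vs {control}: sigma_d = {sigma_d}"
        )
    out = pd.DataFrame(
        {"z_exp": z_exp, "z_ctrl": z_ctrl, "d": d, "z_ratio": d / sigma_d}
    )
    out.attrs["sigma_d"] = sigma_d
    out.attrs["contrast"] = (tension, control)
    return out


def zratio_table(
    zscores: pd.DataFrame,
    samples: pd.DataFrame,
    tensions=CONTRAST_TENSIONS,
    control: int = CONTROL_TENSION,
) -> pd.DataFrame:
    """Wide gene x contrast table of z-ratios (columns are tension labels)."""
    cols = {}
    sigmas = {}
    for t in tensions:
        zr = zratio(zscores, samples, t, control=control)
        cols[t] = zr["z_ratio"]
        sigmas[t] = zr.attrs["sigma_d"]
    table = pd.DataFrame(cols)
    table.attrs["sigma_d"] = sigmas
    table.attrs["control"] = control
    return table


def gene_pvalues(z_ratios) -> np.ndarray:
    """Two-sided p-values treating the z-ratio as standard normal under the null.

    p = 2 * (1 - Phi(|z_ratio|)); the z-ratio is built as a standardized
    difference, so the normal reference is the natural null.
    """
    z = np.asarray(z_ratios, dtype=float)
    return 2.0 * stats.norm.sf(np.abs(z))


def bh_fdr(pvalues, q: float = 0.01):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, passed)`` where ``passed[i]`` is True iff the
    adjusted value is <= q. Adjusted values are monotone in the sorted order
    and never below the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted, adjusted <= q


def anova_per_gene(zscores: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """One-way fixed-effects ANOVA across oxygen tensions, per gene.

    Replicates are the observations within each tension group. Genes with
    zero total variance are degenerate: their p is reported as 1 with a
    warning rather than raising.
    """
    groups = []
    for t in sorted(samples["tension"].unique()):
        cols = _replicate_columns(samples, t)
        if len(cols) < 2:
            raise ValueError(f"tension {t}% O2 has fewer than 2 replicates")
        groups.append(zscores[cols].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with degenerate (zero-variance) "
            "profiles; ANOVA p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        p[bad] = 1.0
    return pd.Series(p, index=zscores.index, name="anova_p")


def selector_scores(
    z_ratio,
    fdr_q,
    anova_p,
    zcut: float = 1.5,
    fdr_alpha: float = 0.01,
    anova_alpha: float = 0.05,
) -> np.ndarray:
    """Three-gate selector score in {-3, 0, +3}.

    +3 iff z_ratio >= zcut, fdr_q <= fdr_alpha and anova_p <= anova_alpha;
    -3 for the mirrored down-regulation; 0 otherwise.
    """
    z = np.asarray(z_ratio, dtype=float)
    q = np.asarray(fdr_q, dtype=float)
    a = np.asarray(anova_p, dtype=float)
    gates = (q <= fdr_alpha) & (a <= anova_alpha)
    out = np.zeros(z.shape, dtype=int)
    out[(z >= zcut) & gates] = 3
    out[(z <= -zcut) & gates] = -3
    return out


def differential_expression(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    control: int = CONTROL_TENSION,
    tensions=CONTRAST_TENSIONS,
    zcut: float = 1.5,
    fdr_alpha: float = 0.01,
    anova_alpha: float = 0.05,
):
    """Full differential pipeline: z-scores, z-ratios, gates and selectors.

    Returns ``(zscores, zratios_wide, records)`` where ``records`` is a long
    DataFrame with one row per (gene, contrast) carrying ``z_ratio, gene_p,
    fdr_q, anova_p, selector``. FDR is adjusted per contrast.
    """
    zscores = log_normalize(expression)
    zr_wide = zratio_table(zscores, samples, tensions=tensions, control=control)
    anova_p = anova_per_gene(zscores, samples)
    frames = []
    for t in tensions:
        z = zr_wide[t].to_numpy()
        gene_p = gene_pvalues(z)
        fdr_q, _ = bh_fdr(gene_p, q=fdr_alpha)
        sel = selector_scores(
            z, fdr_q, anova_p.to_numpy(),
            zcut=zcut, fdr_alpha=fdr_alpha, anova_alpha=anova_alpha,
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": zr_wide.index,
                    "contrast": t,
                    "z_ratio": z,
                    "gene_p": gene_p,
                    "fdr_q": fdr_q,
                    "anova_p": anova_p.to_numpy(),
                    "selector": sel,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return zscores, zr_wide, records


def significant_genes(records: pd.DataFrame) -> dict:
    """Per-contrast sets of genes with a nonzero selector score."""
    out = {}
    for t, sub in records.groupby("contrast"):
        out[t] = set(sub.loc[sub["selector"] != 0, "gene"])
    return out
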