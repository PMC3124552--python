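"""Model/Results interface orchestrating the oxygen-tension response analysis.

:class:`OxygenResponseModel` holds the data and thresholds; ``fit()`` runs
the stage sequence (z-ratio differential statistics -> Venn/polarity
analysis -> PAGE and pathway enrichment -> trajectory clustering into the
four oxygen-response groups -> cumulative LSI scoring) and returns an
:class:`OxygenResponseResults` carrying every stage's tables plus a
``summary()`` report. Re-running with the same inputs and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from . import enrichment, morphometrics, semantics, setops
from . import differential

__all__ = ["OxygenResponseModel", "OxygenResponseResults"]

FLOAT_FMT = "%.6g"


@dataclass
class OxygenResponseResults:
    """Fitted results bundle; every attribute is a plain pandas object."""

    params: dict
    zscores: pd.DataFrame
    zratios: pd.DataFrame
    records: pd.DataFrame
    significant: dict
    venn: setops.VennPartition | None = None
    divergence: pd.DataFrame | None = None
    page: dict = field(default_factory=dict)
    page_venn: setops.VennPartition | None = None
    page_trajectories: pd.DataFrame | None = None
    assignments: pd.DataFrame | None = None
    groups: pd.DataFrame | None = None
    cluster_sizes: pd.Series | None = None
    pathway: dict = field(default_factory=dict)
    lsi_table: pd.DataFrame | None = None
    lsi_grand_means: pd.Series | None = None

    @property
    def group_members(self) -> dict:
        if self.assignments is None:
            return {}
        return {
            g: list(sub.index)
            for g, sub in self.assignments.groupby("group")
            if g in morphometrics.GROUPS
        }

    def summary(self) -> str:
        lines = ["Oxygen-tension transcriptomic response analysis", ""]
        counts = {t: len(s) for t, s in self.significant.items()}
        lines.append("Significantly regulated transcripts (selector +/-3):")
        for t in sorted(counts):
            lines.append(f"  {t:>2}% vs {self.params['control']}% O2: {counts[t]}")
        if self.venn is not None:
            lines.append("Venn subset sizes (A-G): "
                         + ", ".join(f"{k}={v}" for k, v in self.venn.sizes().items()))
        if self.divergence is not None and not self.divergence.empty:
            for _, row in self.divergence.iterrows():
                lines.append(
                    f"  polarity divergence {row['subset']}: "
                    f"{row['n_divergent']}/{row['n_genes']} "
                    f"({100 * row['divergent_fraction']:.1f}%)")
        for t, df in self.page.items():
            lines.append(f"PAGE collections reported at {t}% O2: "
                         f"{int(df['reported'].sum())}/{len(df)}")
        if self.groups is not None and not self.groups.empty:
            lines.append("Group cluster trajectories (mean z-ratio at 1/4/9%):")
            for g, row in self.groups.iterrows():
                lines.append(
                    f"  {g:>5}: n={int(row['n_genes'])}, "
                    f"({row['mean_1']:+.2f}, {row['mean_4']:+.2f}, "
                    f"{row['mean_9']:+.2f})")
        if self.lsi_grand_means is not None and not self.lsi_grand_means.empty:
            lines.append("Mean cumulative transcript LSI score per group:")
            for g, v in self.lsi_grand_means.items():
                lines.append(f"  {g:>5}: {v:.3f}")
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        out = {
            "significant_counts": {str(t): len(s) for t, s in self.significant.items()},
        }
        if self.venn is not None:
            out["venn_sizes"] = self.venn.sizes()
        if self.divergence is not None:
            out["divergence"] = {
                row["subset"]: row["divergent_fraction"]
                for _, row in self.divergence.iterrows()
            }
        if self.page:
            out["page_reported"] = {
                str(t): int(df["reported"].sum()) for t, df in self.page.items()
            }
        if self.groups is not None and not self.groups.empty:
            out["group_sizes"] = {
                g: int(r["n_genes"]) for g, r in self.groups.iterrows()
            }
            out["group_trajectories"] = {
                g: [r["mean_1"], r["mean_4"], r["mean_9"]]
                for g, r in self.groups.iterrows()
            }
        if self.lsi_grand_means is not None:
            out["mean_cumulative_lsi"] = {
                g: float(v) for g, v in self.lsi_grand_means.items()
            }
        return out

    def to_dir(self, outdir):
        """Write the per-stage TSVs and the JSON summary deterministically."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def tsv(df, name, **kw):
            df.to_csv(outdir / name, sep="\t", float_format=FLOAT_FMT, **kw)

        tsv(self.records, "significance.tsv", index=False)
        tsv(self.zratios, "zratios.tsv", index_label="gene")
        if self.venn is not None:
            tsv(self.venn.to_frame(), "venn_subsets.tsv", index=False)
        if self.divergence is not None:
            tsv(self.divergence, "divergence.tsv", index=False)
        for t, df in self.page.items():
            tsv(df, f"page_{t}pct.tsv", index=False)
        if self.page_trajectories is not None:
            tsv(self.page_trajectories, "page_multi_tension.tsv", index=False)
        if self.assignments is not None:
            tsv(self.assignments, "morphometrics.tsv", index_label="gene")
        if self.groups is not None:
            tsv(self.groups, "group_summary.tsv", index_label="group")
        for g, df in self.pathway.items():
            tsv(df, f"pathways_{g}.tsv", index=False)
        if self.lsi_table is not None:
            tsv(self.lsi_table, "cumulative_lsi.tsv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True) + "\n")

    def plot_group_trajectories(self, ax=None):
        """Mean +/- SEM group-cluster z-ratio trajectories (convenience plot)."""
        import matplotlib.pyplot as plt

        if self.groups is None or self.groups.empty:
            raise ValueError("no fitted group summary to plot")
        if ax is None:
            _, ax = plt.subplots()
        x = [1, 4, 9]
        for g, row in self.groups.iterrows():
            means = [row[f"mean_{t}"] for t in x]
            sems = [row[f"sem_{t}"] for t in x]
            ax.errorbar(x, means, yerr=sems, marker="o", capsize=3, label=g)
        ax.set_xlabel("oxygen tension (% O2, vs 20% control)")
        ax.set_ylabel("mean z-ratio")
        ax.legend()
        return ax


class OxygenResponseModel:
    """Multi-oxygen-tension transcriptomic response model.

    Parameters mirror the analysis gates: z-ratio cutoff 1.5, FDR 0.01,
    ANOVA 0.05, PAGE alpha 0.05 with >= 2 genes per set, LSI implicit-
    correlation threshold 0.1, k = 40 trajectory clusters.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        samples: pd.DataFrame,
        gene_sets: dict | None = None,
        pathway_sets: dict | None = None,
        corpus: dict | None = None,
        terms=None,
        control: int = 20,
        zratio_cutoff: float = 1.5,
        fdr_alpha: float = 0.01,
        anova_alpha: float = 0.05,
        page_alpha: float = 0.05,
        min_set_genes: int = 2,
        lsi_threshold: float = 0.1,
        lsi_inclusive: bool = False,
        lsi_rank: int = 100,
        n_clusters: int = 40,
        epsilon: float = 0.0,
        cluster_scope: str = "union",
        stages=("zratio", "venn", "page", "morph", "pathways", "lsi"),
    ):
        for name, val, lo, hi in [
            ("zratio_cutoff", zratio_cutoff, 0, None),
            ("fdr_alpha", fdr_alpha, 0, 1),
            ("anova_alpha", anova_alpha, 0, 1),
            ("page_alpha", page_alpha, 0, 1),
            ("lsi_threshold", lsi_threshold, 0, None),
            ("epsilon", epsilon, 0, None),
        ]:
            if val < lo or (hi is not None and val > hi):
                raise ValueError(f"{name}={val} outside its valid range")
        self.expression = expression
        self.samples = samples
        self.gene_sets = gene_sets
        self.pathway_sets = pathway_sets if pathway_sets is not None else gene_sets
        self.corpus = corpus
        self.terms = list(terms) if terms is not None else None
        self.params = dict(
            control=control, zratio_cutoff=zratio_cutoff, fdr_alpha=fdr_alpha,
            anova_alpha=anova_alpha, page_alpha=page_alpha,
            min_set_genes=min_set_genes, lsi_threshold=lsi_threshold,
            lsi_inclusive=lsi_inclusive, lsi_rank=lsi_rank,
            n_clusters=n_clusters, epsilon=epsilon,
            cluster_scope=cluster_scope, stages=tuple(stages),
        )

    @classmethod
    def from_files(cls, expression, samples, gmt=None, pathway_gmt=None,
                   corpus=None, terms=None, **kwargs):
        """Build the model from the on-disk formats (TSV/GMT/JSONL/txt)."""
        return cls(
            expression=tio.read_expression(expression),
            samples=tio.read_samples(samples),
            gene_sets=tio.read_gmt(gmt) if gmt else None,
            pathway_sets=tio.read_gmt(pathway_gmt) if pathway_gmt else None,
            corpus=tio.read_corpus(corpus) if corpus else None,
            terms=tio.read_terms(terms) if terms else None,
            **kwargs,
        )

    def fit(self, seed: int = 0) -> OxygenResponseResults:
        p = self.params
        stages = p["stages"]
        zs, zr_wide, records = differential.differential_expression(
            self.expression, self.samples, control=p["control"],
            zcut=p["zratio_cutoff"], fdr_alpha=p["fdr_alpha"],
            anova_alpha=p["anova_alpha"],
        )
        sig = differential.significant_genes(records)
        results = OxygenResponseResults(
            params=dict(p, seed=seed), zscores=zs, zratios=zr_wide,
            records=records, significant=sig,
        )
        if "venn" in stages:
            results.venn = setops.venn_partition(sig[1], sig[4], sig[9])
            results.divergence = setops.divergence_report(results.venn, zr_wide)
        if "page" in stages and self.gene_sets:
            for t in (1, 4, 9):
                results.page[t] = enrichment.page_score(
                    zr_wide[t], self.gene_sets, significant=sig[t],
                    min_genes=p["min_set_genes"], alpha=p["page_alpha"],
                    zcut=p["zratio_cutoff"],
                )
            results.page_venn, results.page_trajectories = \
                enrichment.page_venn(results.page)
        if "morph" in stages:
            profiles = morphometrics.build_profiles(
                zr_wide, sig, scope=p["cluster_scope"])
            if len(profiles) >= 1:
                results.assignments = morphometrics.assign_groups(
                    profiles, k=p["n_clusters"], seed=seed,
                    epsilon=p["epsilon"])
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    results.groups, results.cluster_sizes = \
                        morphometrics.group_summary(results.assignments)
        if "pathways" in stages and self.pathway_sets and \
                results.assignments is not None:
            background = set(self.expression.index)
            for g, members in results.group_members.items():
                results.pathway[g] = enrichment.hybrid_pathway_score(
                    members, self.pathway_sets, background,
                    min_genes=p["min_set_genes"], alpha=p["page_alpha"],
                )
        if "lsi" in stages and self.corpus and self.terms:
            model = semantics.fit_corpus(self.corpus, rank=p["lsi_rank"])
            groups = results.group_members
            if groups:
                results.lsi_table, results.lsi_grand_means = \
                    semantics.cumulative_lsi(
                        groups, self.terms, model,
                        threshold=p["lsi_threshold"],
                        inclusive=p["lsi_inclusive"],
                    )
        return results
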