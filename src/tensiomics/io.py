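"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression and sample sheets are TSV, gene sets are GMT (name, description,
genes...), corpora are JSON lines with ``gene`` and ``text`` fields, and
interrogation terms are one-per-line text.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_gmt",
    "write_gmt",
    "read_corpus",
    "write_corpus",
    "read_terms",
    "write_terms",
]

FLOAT_FMT = "%.10g"


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "tension", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    return df


def write_samples(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """GMT: one set per line — name <tab> description <tab> gene1 <tab> ..."""
    sets = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = [g for g in parts[2:] if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict, path, description: str = "synthetic"):
    lines = [
        "\t".join([name, description] + [str(g) for g in genes])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_corpus(path) -> dict:
    corpus = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        rec = json.loads(line)
        corpus[rec["gene"]] = rec["text"]
    return corpus


def write_corpus(corpus: dict, path):
    with open(path, "w") as fh:
        for gene in sorted(corpus):
            fh.write(json.dumps({"gene": gene, "text": corpus[gene]}) + "\n")


def read_terms(path) -> list:
    return [
        line.strip() for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_terms(terms, path):
    Path(path).write_text("\n".join(terms) + "\n")
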