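"""Latent semantic indexing of a gene-document corpus.

Each gene carries a literature-like document. A weighted term-document
matrix (log-entropy by default, tf-idf optional) is factorised with a
truncated SVD; the correlation of a gene with an interrogation term is the
cosine between their projections into the latent space. A gene is
"implicitly correlated" with a term when that score exceeds 0.1.

The cumulative transcript LSI score of a (group, term) pair is

    score = N x mean_corr

with N the number of implicitly correlated member genes and mean_corr their
mean correlation. This is a functional stand-in for proprietary
literature-indexing tools, not a numeric replication of any of them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "tokenize",
    "build_term_doc",
    "LsiModel",
    "lsi_fit",
    "correlate",
    "implicit_genes",
    "cumulative_lsi",
]

# minimal English stop list; domain words are never stripped
STOPWORDS = frozenset(
    """a an and are as at be by for from has have in is it its of on or that
    the this to was were which with we our their not no""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list:
    """Lowercase word tokens with stop words removed."""
    tokens = _TOKEN_RE.findall(text.lower())
    return [t.strip("'") for t in tokens if t.strip("'") and t.strip("'") not in STOPWORDS]


def _count_matrix(corpus: dict):
    docs = sorted(corpus)
    vocab = {}
    counts = []
    for d in docs:
        text = corpus[d]
        if not str(text).strip():
            raise ValueError(f"gene {d!r} has an empty document")
        row = {}
        for tok in tokenize(str(text)):
            row[tok] = row.get(tok, 0) + 1
        counts.append(row)
    for row in counts:
        for tok in row:
            vocab.setdefault(tok, len(vocab))
    if not vocab:
        raise ValueError("empty vocabulary after tokenization/stop-word removal")
    X = np.zeros((len(vocab), len(docs)))
    for j, row in enumerate(counts):
        for tok, c in row.items():
            X[vocab[tok], j] = c
    terms = sorted(vocab, key=vocab.get)
    return X, terms, docs


def _apply_weighting(X: np.ndarray, weighting: str):
    """Return (weighted matrix, per-term global weights, local scheme id)."""
    n_docs = X.shape[1]
    if weighting == "log-entropy":
        gf = X.sum(axis=1, keepdims=True)
        gf[gf == 0] = 1.0
        p = X / gf
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        if n_docs > 1:
            g = 1.0 + plogp.sum(axis=1) / np.log(n_docs)
        else:
            g = np.ones(X.shape[0])
        W = np.log1p(X) * g[:, None]
        return W, g
    if weighting == "tf-idf":
        df = (X > 0).sum(axis=1)
        idf = np.log(n_docs / df)
        W = X * idf[:, None]
        return W, idf
    raise ValueError(f"unknown weighting {weighting!r}")


def build_term_doc(corpus: dict, weighting: str = "log-entropy"):
    """Weighted term-document matrix from a gene -> document mapping.

    Returns ``(matrix, terms, docs, global_weights)``; rows or columns that
    are entirely zero after weighting are dropped with a warning (e.g. a
    term present in every document under tf-idf).
    """
    X, terms, docs = _count_matrix(corpus)
    W, g = _apply_weighting(X, weighting)
    keep_rows = ~(W == 0).all(axis=1)
    if not keep_rows.all():
        warnings.warn(
            f"dropping {int((~keep_rows).sum())} all-zero term row(s)",
            RuntimeWarning, stacklevel=2,
        )
        W = W[keep_rows]
        terms = [t for t, k in zip(terms, keep_rows) if k]
        g = g[keep_rows]
    keep_cols = ~(W == 0).all(axis=0)
    if not keep_cols.all():
        warnings.warn(
            f"dropping {int((~keep_cols).sum())} all-zero document column(s)",
            RuntimeWarning, stacklevel=2,
        )
        W = W[:, keep_cols]
        docs = [d for d, k in zip(docs, keep_cols) if k]
    return W, terms, docs, g


@dataclass
class LsiModel:
    """Rank-r factorisation of a weighted term-document matrix.

    Documents and queries are represented by projection onto the top-r left
    singular vectors (``U_r^T x``); the projection is an isometry of the
    retained subspace, so at full rank the cosine between a document and a
    query equals the raw cosine on the weighted matrix.
    """

    weighting: str
    rank: int
    terms: list
    docs: list
    u: np.ndarray                 # terms x rank
    doc_vecs: np.ndarray          # rank x docs
    global_weights: np.ndarray
    term_index: dict = field(default_factory=dict)
    doc_index: dict = field(default_factory=dict)

    def __post_init__(self):
        self.term_index = {t: i for i, t in enumerate(self.terms)}
        self.doc_index = {d: j for j, d in enumerate(self.docs)}

    def query_vector(self, term: str):
        """Project an interrogation term (possibly multi-word) as a pseudo-doc."""
        counts = np.zeros(len(self.terms))
        known = 0
        for tok in tokenize(term):
            i = self.term_index.get(tok)
            if i is not None:
                counts[i] += 1
                known += 1
        if known == 0:
            warnings.warn(f"term {term!r} absent from the vocabulary; score 0",
                          RuntimeWarning, stacklevel=3)
            return None
        if self.weighting == "log-entropy":
            q = np.log1p(counts) * self.global_weights
        else:
            q = counts * self.global_weights
        return self.u.T @ q


def lsi_fit(matrix: np.ndarray, rank: int, terms=None, docs=None,
            weighting: str = "log-entropy",
            global_weights=None) -> LsiModel:
    """Truncated SVD of a weighted term-document matrix.

    ``rank`` is clipped (with a warning) to the number of positive singular
    values.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    W = np.asarray(matrix, dtype=float)
    u, s, _ = np.linalg.svd(W, full_matrices=False)
    eff_rank = int((s > s[0] * max(W.shape) * np.finfo(float).eps).sum())
    if rank > eff_rank:
        warnings.warn(f"rank {rank} exceeds matrix rank {eff_rank}; clipped",
                      RuntimeWarning, stacklevel=2)
        rank = eff_rank
    u_r = u[:, :rank]
    n_terms, n_docs = W.shape
    terms = list(terms) if terms is not None else [f"t{i}" for i in range(n_terms)]
    docs = list(docs) if docs is not None else [f"d{j}" for j in range(n_docs)]
    if global_weights is None:
        global_weights = np.ones(n_terms)
    return LsiModel(
        weighting=weighting,
        rank=rank,
        terms=terms,
        docs=docs,
        u=u_r,
        doc_vecs=u_r.T @ W,
        global_weights=np.asarray(global_weights, dtype=float),
    )


def fit_corpus(corpus: dict, rank: int = 100,
               weighting: str = "log-entropy") -> LsiModel:
    """Convenience: weighted matrix + truncated SVD in one call.

    The default rank follows min(100, matrix rank) via clipping in lsi_fit.
    """
    W, terms, docs, g = build_term_doc(corpus, weighting=weighting)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = lsi_fit(W, rank=min(rank, min(W.shape)), terms=terms,
                        docs=docs, weighting=weighting, global_weights=g)
    return model


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def correlate(model: LsiModel, term: str, genes=None):
    """LSI correlation score(s) of gene document(s) with an interrogation term.

    Returns a Series over ``genes`` (default: all documents) in [-1, 1].
    Genes without a document score 0 with a warning.
    """
    qv = model.query_vector(term)
    if genes is None:
        genes = model.docs
    genes = list(genes)
    scores = np.zeros(len(genes))
    if qv is not None:
        missing = 0
        for i, g in enumerate(genes):
            j = model.doc_index.get(g)
            if j is None:
                missing += 1
                continue
            scores[i] = _cosine(qv, model.doc_vecs[:, j])
        if missing:
            warnings.warn(f"{missing} gene(s) without a document; score 0",
                          RuntimeWarning, stacklevel=2)
    return pd.Series(scores, index=genes, name=term)


def implicit_genes(model: LsiModel, term: str, genes=None,
                   threshold: float = 0.1, inclusive: bool = False) -> pd.Series:
    """Genes implicitly correlated with a term (score > threshold).

    ``inclusive=True`` switches the comparison to >=.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    scores = correlate(model, term, genes=genes)
    mask = scores >= threshold if inclusive else scores > threshold
    return scores[mask]


def cumulative_lsi(groups: dict, terms, model: LsiModel,
                   threshold: float = 0.1, inclusive: bool = False):
    """Cumulative transcript LSI score per (group cluster, interrogation term).

    Returns ``(table, grand_means)``: a DataFrame with one row per
    (group, term) carrying ``n_implicit, mean_corr, score = n x mean`` and a
    Series of per-group grand means over terms.
    """
    if not groups or not list(terms):
        raise ValueError("groups and terms must be non-empty")
    rows = []
    for group, members in groups.items():
        members = list(members)
        for term in terms:
            if members:
                hits = implicit_genes(model, term, genes=members,
                                      threshold=threshold, inclusive=inclusive)
            else:
                hits = pd.Series(dtype=float)
            n = int(len(hits))
            mean_corr = float(hits.mean()) if n else 0.0
            rows.append({
                "group": group,
                "term": term,
                "n_implicit": n,
                "mean_corr": mean_corr,
                "score": n * mean_corr,
            })
    table = pd.DataFrame(rows)
    grand = table.groupby("group")["score"].mean()
    grand.name = "mean_cumulative_lsi"
    return table, grand
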