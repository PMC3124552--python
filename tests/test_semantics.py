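"""Unit tests for the LSI gene-literature scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from tensiomics import semantics as sem

TOY = {
    "d1": "apple banana apple",
    "d2": "banana cherry",
    "d3": "cherry durian elderberry cherry",
}


class TestTermDoc:
    def test_identical_documents_identical_columns(self):
        corpus = {"a": "apple banana", "b": "apple banana", "c": "cherry"}
        W, terms, docs, _ = sem.build_term_doc(corpus)
        i, j = docs.index("a"), docs.index("b")
        assert np.allclose(W[:, i], W[:, j])

    def test_ubiquitous_term_dropped_under_tfidf(self):
        corpus = {"a": "common apple", "b": "common banana", "c": "common"}
        with pytest.warns(RuntimeWarning, match="all-zero"):
            W, terms, docs, _ = sem.build_term_doc(corpus, weighting="tf-idf")
        assert "common" not in terms
        # document c becomes all-zero and is dropped too
        assert "c" not in docs

    def test_hand_computed_tfidf(self):
        W, terms, docs, idf = sem.build_term_doc(TOY, weighting="tf-idf")
        log3, log15 = np.log(3.0), np.log(1.5)
        expected = {
            ("apple", "d1"): 2 * log3,
            ("banana", "d1"): log15,
            ("banana", "d2"): log15,
            ("cherry", "d2"): log15,
            ("cherry", "d3"): 2 * log15,
            ("durian", "d3"): log3,
            ("elderberry", "d3"): log3,
        }
        for (term, doc), value in expected.items():
            assert W[terms.index(term), docs.index(doc)] == \
                pytest.approx(value), (term, doc)
        assert W.sum() == pytest.approx(sum(expected.values()))

    def test_empty_document_rejected(self):
        with pytest.raises(ValueError, match="empty document"):
            sem.build_term_doc({"a": "word", "b": "   "})

    def test_stopword_only_corpus_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            sem.build_term_doc({"a": "the and of", "b": "is was"})


class TestLsi:
    def _fit(self, corpus, rank=None, weighting="log-entropy"):
        W, terms, docs, g = sem.build_term_doc(corpus, weighting=weighting)
        rank = rank or min(W.shape)
        return sem.lsi_fit(W, rank, terms=terms, docs=docs,
                           weighting=weighting, global_weights=g), W, docs

    def test_identical_query_and_document_full_rank(self):
        corpus = {f"d{i}": t for i, t in enumerate(
            ["apple banana", "cherry durian", "banana cherry",
             "apple durian", "apple cherry banana"])}
        model, _, _ = self._fit(corpus)
        scores = sem.correlate(model, "apple banana", genes=["d0"])
        assert scores["d0"] == pytest.approx(1.0, abs=1e-10)

    def test_disjoint_vocabulary_scores_zero(self):
        corpus = {"d0": "apple banana", "d1": "cherry durian"}
        model, _, _ = self._fit(corpus)
        scores = sem.correlate(model, "cherry durian", genes=["d0", "d1"])
        assert scores["d0"] == pytest.approx(0.0, abs=1e-12)
        assert scores["d1"] == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_equals_raw_cosine(self, rng):
        # more documents than terms -> the left factors span the whole term
        # space and the projection is an isometry
        vocab = [f"w{i}" for i in range(8)]
        corpus = {
            f"d{j}": " ".join(rng.choice(vocab,
                                         size=rng.integers(5, 15)))
            for j in range(20)
        }
        model, W, docs = self._fit(corpus)
        q = model.query_vector("w0 w3 w3")
        # raw query vector in term space
        raw_q = np.zeros(len(model.terms))
        for tok, mult in (("w0", 1), ("w3", 2)):
            raw_q[model.terms.index(tok)] = np.log1p(mult) * \
                model.global_weights[model.terms.index(tok)]
        for j, d in enumerate(docs):
            raw = raw_q @ W[:, j] / (np.linalg.norm(raw_q)
                                     * np.linalg.norm(W[:, j]))
            lsi = sem.correlate(model, "w0 w3 w3", genes=[d])[d]
            assert lsi == pytest.approx(raw, abs=1e-8)

    def test_rank2_against_independent_svd(self, rng):
        # 8-term, 5-doc corpus at rank 2 vs a brute-force scipy SVD
        vocab = [f"w{i}" for i in range(8)]
        corpus = {
            f"d{j}": " ".join(rng.choice(vocab, size=12)) for j in range(5)
        }
        W, terms, docs, g = sem.build_term_doc(corpus)
        model = sem.lsi_fit(W, 2, terms=terms, docs=docs,
                            weighting="log-entropy", global_weights=g)
        U, s, Vt = linalg.svd(W, full_matrices=False)
        U2 = U[:, :2]
        query = "w1 w5"
        qraw = np.zeros(len(terms))
        for tok in ("w1", "w5"):
            qraw[terms.index(tok)] = np.log1p(1) * g[terms.index(tok)]
        q2 = U2.T @ qraw
        for j, d in enumerate(docs):
            d2 = U2.T @ W[:, j]
            denom = np.linalg.norm(q2) * np.linalg.norm(d2)
            expected = q2 @ d2 / denom if denom else 0.0
            got = sem.correlate(model, query, genes=[d])[d]
            assert got == pytest.approx(expected, abs=1e-8)

    def test_scores_bounded(self, rng):
        vocab = [f"w{i}" for i in range(30)]
        corpus = {f"d{j}": " ".join(rng.choice(vocab, size=25))
                  for j in range(40)}
        model, _, _ = self._fit(corpus, rank=5)
        for term in ("w0", "w1 w2", "w10 w10 w3"):
            scores = sem.correlate(model, term)
            assert (scores <= 1.0 + 1e-12).all()
            assert (scores >= -1.0 - 1e-12).all()

    def test_unknown_term_warns_and_scores_zero(self):
        corpus = {"d0": "apple banana", "d1": "cherry apple"}
        model, _, _ = self._fit(corpus)
        with pytest.warns(RuntimeWarning, match="absent"):
            scores = sem.correlate(model, "zebra")
        assert (scores == 0.0).all()

    def test_excess_rank_clipped_with_warning(self):
        corpus = {"d0": "apple banana", "d1": "cherry apple"}
        W, terms, docs, g = sem.build_term_doc(corpus)
        with pytest.warns(RuntimeWarning, match="clipped"):
            model = sem.lsi_fit(W, 50, terms=terms, docs=docs,
                                global_weights=g)
        assert model.rank <= min(W.shape)


class TestImplicitAndCumulative:
    def _model(self):
        corpus = {
            "gA": "hypoxia oxygen stress hypoxia",
            "gB": "hypoxia response factor",
            "gC": "ribosome translation subunit",
            "gD": "membrane channel transport",
        }
        W, terms, docs, g = sem.build_term_doc(corpus)
        return sem.lsi_fit(W, min(W.shape), terms=terms, docs=docs,
                           weighting="log-entropy", global_weights=g)

    def test_threshold_strict_vs_inclusive(self):
        model = self._model()
        scores = sem.correlate(model, "hypoxia")
        # manufacture an exact-threshold case via the public API contract
        hits_strict = sem.implicit_genes(model, "hypoxia", threshold=0.1)
        assert set(hits_strict.index) <= {"gA", "gB"}
        assert (hits_strict > 0.1).all()
        at = float(scores["gA"])
        exactly = sem.implicit_genes(model, "hypoxia", threshold=at)
        assert "gA" not in exactly.index
        inclusive = sem.implicit_genes(model, "hypoxia", threshold=at,
                                       inclusive=True)
        assert "gA" in inclusive.index

    def test_all_below_threshold_empty(self):
        model = self._model()
        hits = sem.implicit_genes(model, "hypoxia", genes=["gC", "gD"],
                                  threshold=0.99)
        assert hits.empty

    def test_cumulative_hand_arithmetic(self, monkeypatch):
        model = self._model()
        fixed = pd.Series({"gA": 0.25, "gB": 0.35, "gC": 0.05})
        monkeypatch.setattr(
            sem, "correlate",
            lambda m, t, genes=None: fixed.loc[list(genes)])
        table, grand = sem.cumulative_lsi(
            {"grp": ["gA", "gB", "gC"]}, ["hypoxia"], model)
        row = table.iloc[0]
        assert row["n_implicit"] == 2
        assert row["mean_corr"] == pytest.approx(0.30)
        assert row["score"] == pytest.approx(0.60)
        assert grand["grp"] == pytest.approx(0.60)

    def test_no_members_above_threshold_scores_zero(self):
        model = self._model()
        table, _ = sem.cumulative_lsi({"grp": ["gC", "gD"]}, ["hypoxia"],
                                      model, threshold=0.99)
        assert (table["score"] == 0.0).all()
        assert (table["n_implicit"] == 0).all()

    def test_single_member_score_is_its_correlation(self, monkeypatch):
        model = self._model()
        fixed = pd.Series({"gA": 0.5})
        monkeypatch.setattr(
            sem, "correlate",
            lambda m, t, genes=None: fixed.loc[list(genes)])
        table, _ = sem.cumulative_lsi({"grp": ["gA"]}, ["hypoxia"], model)
        assert table.iloc[0]["score"] == pytest.approx(0.5)

    def test_score_monotone_in_strong_new_member(self, monkeypatch):
        model = self._model()
        fixed = pd.Series({"gA": 0.3, "gB": 0.4, "gX": 0.8})
        monkeypatch.setattr(
            sem, "correlate",
            lambda m, t, genes=None: fixed.loc[list(genes)])
        small, _ = sem.cumulative_lsi({"g": ["gA", "gB"]}, ["t"], model)
        grown, _ = sem.cumulative_lsi({"g": ["gA", "gB", "gX"]}, ["t"], model)
        assert grown.iloc[0]["score"] > small.iloc[0]["score"]

    def test_empty_inputs_rejected(self):
        model = self._model()
        with pytest.raises(ValueError):
            sem.cumulative_lsi({}, ["t"], model)
        with pytest.raises(ValueError):
            sem.cumulative_lsi({"g": ["gA"]}, [], model)
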