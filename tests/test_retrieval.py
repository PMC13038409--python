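"""Retrieval engines against brute-force scoring oracles."""

import math

import numpy as np
import pytest

from nerprompt import (
    Corpus,
    HashingEncoder,
    Sentence,
    build_index,
    retrieve,
    score_dual_encoder,
    score_late_interaction,
    score_lexical,
    score_tfidf,
    subsample_pool,
)
from nerprompt.retrieval import sentence_text


def make_sentence(i, words):
    toks = tuple(words)
    return Sentence(f"p{i}", toks, tuple(["O"] * len(toks)))


def tfidf_oracle_matrix(texts):
    """Hand-rolled tf-idf: raw counts, idf=ln((1+N)/(1+df))+1, L2 rows."""
    vocab = sorted({w for t in texts for w in t.split()})
    n = len(texts)
    df = {w: sum(1 for t in texts if w in t.split()) for w in vocab}
    idf = {w: math.log((1 + n) / (1 + df[w])) + 1.0 for w in vocab}
    mat = np.zeros((n, len(vocab)))
    for i, t in enumerate(texts):
        for w in t.split():
            mat[i, vocab.index(w)] += idf[w]
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mat / norms, vocab, idf


class TestTfidf:
    def test_doc_matrix_matches_hand_computed_oracle(self):
        texts = ["a b a", "b c", "c d e", "a e", "f f f"]
        pool = [make_sentence(i, t.split()) for i, t in enumerate(texts)]
        index = build_index(pool, "tfidf")
        oracle, vocab, _ = tfidf_oracle_matrix(texts)
        cols = [index.vocab[w] for w in vocab]
        np.testing.assert_allclose(index.doc_matrix[:, cols], oracle, atol=1e-12)

    def test_single_document_idf(self):
        index = build_index([make_sentence(0, ["x", "y"])], "tfidf")
        # N=1, df=1 for every term: idf = ln(2/2)+1 = 1
        assert index.doc_matrix.shape == (1, 2)
        np.testing.assert_allclose(
            index.doc_matrix[0], [1 / math.sqrt(2)] * 2, atol=1e-12
        )

    def test_identical_multisets_score_one(self):
        pool = [make_sentence(0, ["a", "b", "a"])]
        index = build_index(pool, "tfidf")
        assert score_tfidf(["a", "a", "b"], 0, index) == pytest.approx(1.0)

    def test_disjoint_terms_score_zero(self):
        pool = [make_sentence(0, ["a", "b"])]
        index = build_index(pool, "tfidf")
        assert score_tfidf(["c", "d"], 0, index) == 0.0

    def test_exact_duplicate_ranks_first(self):
        texts = ["x q r", "a b c", "m n"]
        pool = [make_sentence(i, t.split()) for i, t in enumerate(texts)]
        index = build_index(pool, "tfidf")
        top = retrieve(index, make_sentence(9, ["a", "b", "c"]), 1)[0]
        assert top.sentence.id == "p1"
        assert top.score == pytest.approx(1.0)

    def test_no_shared_terms_ranks_by_pool_order(self):
        pool = [make_sentence(i, [f"w{i}"]) for i in range(4)]
        index = build_index(pool, "tfidf")
        out = retrieve(index, make_sentence(9, ["zzz"]), 4)
        assert [se.sentence.id for se in out] == ["p0", "p1", "p2", "p3"]
        assert all(se.score == 0.0 for se in out)

    def test_irrelevant_document_never_reorders_existing(self):
        rng = np.random.default_rng(5)
        words = [f"w{i}" for i in range(12)]
        pool = [
            make_sentence(i, rng.choice(words, size=5).tolist()) for i in range(10)
        ]
        query = make_sentence(99, rng.choice(words, size=5).tolist())
        before = [s.sentence.id for s in retrieve(build_index(pool, "tfidf"), query, 10)]
        pool_plus = pool + [make_sentence(10, ["qqq", "zzz"])]
        after = [
            s.sentence.id
            for s in retrieve(build_index(pool_plus, "tfidf"), query, 11)
        ]
        assert [i for i in after if i != "p10"] == before


class TestDenseScores:
    def test_maxsim_one_hot_subset(self):
        eye = np.eye(5)
        q = eye[[0, 2]]
        d = eye[[0, 1, 2, 3]]
        assert score_late_interaction(q, d) == pytest.approx(2.0)

    def test_maxsim_orthogonal_vocabulary(self):
        eye = np.eye(6)
        assert score_late_interaction(eye[[0, 1]], eye[[4, 5]]) == 0.0

    def test_maxsim_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = rng.standard_normal((4, 8))
            d = rng.standard_normal((6, 8))
            oracle = sum(max(qi @ dj for dj in d) for qi in q)
            assert score_late_interaction(q, d) == pytest.approx(oracle)

    def test_maxsim_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            score_late_interaction(np.ones((2, 3)), np.ones((2, 4)))

    def test_dual_encoder_identical_unit_vectors(self):
        v = np.array([0.6, 0.8])
        assert score_dual_encoder(v, v) == pytest.approx(1.0)

    def test_dual_encoder_orthogonal(self):
        assert score_dual_encoder(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_dual_encoder_inner_product_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(16), rng.standard_normal(16)
        assert score_dual_encoder(a, b, normalize=False) == pytest.approx(
            float(np.sum(a * b))
        )

    def test_lexical_jaccard(self):
        assert score_lexical(["A", "b"], ["a", "c"]) == pytest.approx(1 / 3)


class TestHashingEncoder:
    def test_deterministic_across_instances(self):
        a = HashingEncoder(seed=3).sentence_vector("codeine addict")
        b = HashingEncoder(seed=3).sentence_vector("codeine addict")
        np.testing.assert_array_equal(a, b)

    def test_unit_token_vectors(self):
        vecs = HashingEncoder().token_vectors(["pain", "ache"])
        np.testing.assert_allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-12)

    def test_dense_engine_requires_encoder(self, tiny_corpus):
        with pytest.raises(ValueError, match="encoder"):
            build_index(tiny_corpus.sentences, "dual_encoder")


class TestRetrieveEquivalence:
    """retrieve() == exhaustive score-and-sort (small-scale spot check)."""

    @pytest.mark.parametrize("engine", ["tfidf", "dual_encoder", "late_interaction", "lexical"])
    def test_matches_exhaustive_oracle(self, engine):
        from nerprompt.retrieval import score_all

        rng = np.random.default_rng(17)
        words = [f"w{i}" for i in range(15)]
        encoder = HashingEncoder()
        for trial in range(5):
            pool = [
                make_sentence(i, rng.choice(words, size=int(rng.integers(2, 6))).tolist())
                for i in range(12)
            ]
            index = build_index(pool, engine, encoder)
            query = make_sentence(99, rng.choice(words, size=4).tolist())
            scores = score_all(index, query)
            oracle_order = sorted(range(len(pool)), key=lambda i: (-scores[i], i))
            got = retrieve(index, query, len(pool))
            assert [s.sentence.id for s in got] == [pool[i].id for i in oracle_order]
            assert [s.rank for s in got] == list(range(1, len(pool) + 1))
            diffs = np.diff([s.score for s in got])
            assert (diffs <= 1e-12).all()


class TestSubsamplePool:
    def test_full_size_is_identity_membership(self, synthetic_corpus):
        sub = subsample_pool(synthetic_corpus, len(synthetic_corpus), seed=0)
        assert sub.sentences == synthetic_corpus.sentences

    def test_seeded_determinism(self, synthetic_corpus):
        a = subsample_pool(synthetic_corpus, 30, seed=4)
        b = subsample_pool(synthetic_corpus, 30, seed=4)
        assert a.sentences == b.sentences

    def test_oversize_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="exceeds"):
            subsample_pool(tiny_corpus, 10, seed=0)

    def test_two_seeds_overlap_near_hypergeometric_expectation(self):
        from nerprompt import generate_corpus, make_default_spec

        corpus = generate_corpus(make_default_spec(n_sentences=100, seed=2))
        k = 40
        overlaps = [
            len(
                {s.id for s in subsample_pool(corpus, k, seed=2 * t)}
                & {s.id for s in subsample_pool(corpus, k, seed=2 * t + 1)}
            )
            for t in range(50)
        ]
        expected = k * k / 100  # E[|A∩B|] for independent uniform subsets
        var = k * k * (100 - k) ** 2 / (100**2 * 99)  # hypergeometric variance
        se = math.sqrt(var / 50)
        assert abs(np.mean(overlaps) - expected) < 4 * se


class TestPersistence:
    def test_tfidf_index_roundtrip(self, tmp_path, synthetic_corpus):
        from nerprompt.retrieval import load_index, save_index

        index = build_index(synthetic_corpus.sentences, "tfidf")
        save_index(index, tmp_path / "index.json")
        back = load_index(tmp_path / "index.json")
        query = synthetic_corpus[7]
        assert [s.sentence.id for s in retrieve(back, query, 5)] == [
            s.sentence.id for s in retrieve(index, query, 5)
        ]
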