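import json

import numpy as np
import pytest
from scipy.special import gammaln

from collotopics.preprocess import AnnotatedToken
from collotopics.synthetic_data import sample_lda_corpus
from collotopics.topic_model import (
    BagCorpus,
    LatentDirichletAllocation,
    LDAResults,
    build_bags,
    fit_lda,
    match_topics,
    _sample_token,
)


def _stream(lemmas):
    return [AnnotatedToken(w, w, "NOUN", True, i, i) for i, w in enumerate(lemmas)]


class TestBagCorpus:
    def test_index_bounds_checked(self):
        with pytest.raises(ValueError):
            BagCorpus(["a"], [[0, 1]])

    def test_empty_vocab_rejected(self):
        with pytest.raises(ValueError):
            BagCorpus([], [[]])

    def test_nonempty_listing(self):
        bags = BagCorpus(["a", "b"], [[0], [], [1, 1]])
        assert bags.nonempty() == [0, 2]
        assert bags.n_tokens == 3


class TestBuildBags:
    def test_window_tokens_restricted_to_shortlist(self):
        doc = _stream(["pregnant", "kill", "revenge", "attack", "noise"])
        bags = build_bags(
            [doc], [{"doc_id": "a"}], ["kill", "revenge", "attack"], {"pregnant"}
        )
        assert sorted(bags.vocab[i] for i in bags.docs[0]) == ["attack", "kill", "revenge"]

    def test_target_with_no_shortlisted_window_tokens_gives_empty_bag(self):
        doc = _stream(["pregnant", "noise"])
        bags = build_bags([doc], [{"doc_id": "a"}], ["kill"], {"pregnant"})
        assert bags.docs[0] == [] and bags.nonempty() == []

    def test_shortlisted_token_outside_window_excluded(self):
        lemmas = ["kill"] + [f"w{i}" for i in range(7)] + ["pregnant"]
        bags = build_bags([_stream(lemmas)], [{"doc_id": "a"}], ["kill"], {"pregnant"})
        assert bags.docs[0] == []

    def test_empty_shortlist_rejected(self):
        with pytest.raises(ValueError):
            build_bags([_stream(["a"])], [{"doc_id": "a"}], [], {"pregnant"})

    def test_region_attached_from_country(self):
        doc = _stream(["pregnant", "kill"])
        bags = build_bags(
            [doc], [{"doc_id": "a", "country": "Kenya"}], ["kill"], {"pregnant"}
        )
        assert bags.doc_meta[0]["region"] == "Africa"


class TestFitLDA:
    def test_single_topic_degenerate_case(self):
        bags = BagCorpus(["a", "b"], [[0, 1, 0], [1, 1]])
        res = fit_lda(bags, K=1, n_iter=5, burn_in=1, seed=0)
        assert (np.concatenate(res.z_by_doc) == 0).all()
        assert res.n_dk[:, 0].tolist() == [3, 2]

    def test_count_invariants_after_fit(self):
        bags, _, _ = sample_lda_corpus(K=3, V=30, D=20, doc_length_mean=15, seed=2)
        res = fit_lda(bags, K=3, alpha=0.5, n_iter=20, burn_in=5, seed=3)
        res.validate()

    def test_seed_determinism_bit_identical(self):
        bags, _, _ = sample_lda_corpus(K=3, V=30, D=20, doc_length_mean=15, seed=2)
        r1 = fit_lda(bags, K=3, n_iter=15, burn_in=5, seed=11)
        r2 = fit_lda(bags, K=3, n_iter=15, burn_in=5, seed=11)
        assert (r1.n_kw == r2.n_kw).all()
        assert all((a == b).all() for a, b in zip(r1.z_by_doc, r2.z_by_doc))
        r3 = fit_lda(bags, K=3, n_iter=15, burn_in=5, seed=12)
        assert (r1.n_kw != r3.n_kw).any()

    def test_document_order_exchangeability(self):
        bags, _, _ = sample_lda_corpus(K=2, V=20, D=12, doc_length_mean=10, seed=4)
        perm = np.random.Generator(np.random.PCG64(0)).permutation(12)
        shuffled = BagCorpus(
            bags.vocab,
            [bags.docs[p] for p in perm],
            [bags.doc_meta[p] for p in perm],
        )
        r1 = fit_lda(bags, K=2, n_iter=10, burn_in=2, seed=5)
        r2 = fit_lda(shuffled, K=2, n_iter=10, burn_in=2, seed=5)
        assert (r1.n_kw == r2.n_kw).all()
        for new_pos, old_pos in enumerate(perm):
            assert (r1.n_dk[old_pos] == r2.n_dk[new_pos]).all()

    def test_restarts_deterministic_and_keep_best_likelihood(self):
        bags, _, _ = sample_lda_corpus(K=3, V=30, D=20, doc_length_mean=15, seed=2)
        best = fit_lda(bags, K=3, n_iter=15, burn_in=5, seed=11, n_restarts=3)
        again = fit_lda(bags, K=3, n_iter=15, burn_in=5, seed=11, n_restarts=3)
        assert (best.n_kw == again.n_kw).all()
        singles = [
            fit_lda(bags, K=3, n_iter=15, burn_in=5, seed=(11 + 7919 * r) % 2**31)
            for r in range(3)
        ]
        assert best.log_likelihood() == max(s.log_likelihood() for s in singles)

    def test_invalid_arguments_rejected(self):
        bags = BagCorpus(["a"], [[0]])
        with pytest.raises(ValueError):
            fit_lda(bags, K=0, n_iter=5, burn_in=1)
        with pytest.raises(ValueError):
            fit_lda(bags, K=2, n_iter=5, burn_in=5)
        with pytest.raises(ValueError):
            LatentDirichletAllocation(bags, 2, alpha=-1.0)
        with pytest.raises(ValueError):
            LatentDirichletAllocation(BagCorpus(["a"], [[]]), 2)

    def test_disjoint_vocabularies_separate(self):
        """Two document groups with disjoint vocabularies: K=2 recovers one
        topic per vocabulary half (up to relabeling) in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.Generator(np.random.PCG64(seed))
            docs = [list(rng.integers(0, 10, size=30)) for _ in range(15)]
            docs += [list(rng.integers(10, 20, size=30)) for _ in range(15)]
            bags = BagCorpus([f"w{i}" for i in range(20)], docs)
            res = fit_lda(bags, K=2, alpha=0.1, n_iter=200, burn_in=100, seed=seed)
            halves = []
            for k in range(2):
                top = {w for w, _ in res.top_words(k, 10).top_words}
                halves.append(
                    all(int(w[1:]) < 10 for w in top) or all(int(w[1:]) >= 10 for w in top)
                )
            hits += all(halves)
        assert hits >= 9

    def test_gibbs_kernel_preserves_counts(self):
        bags, _, _ = sample_lda_corpus(K=3, V=10, D=5, doc_length_mean=8, seed=6)
        res = fit_lda(bags, K=3, n_iter=5, burn_in=1, seed=7)
        n_kw = res.n_kw.copy()
        n_dk = res.n_dk[bags.nonempty()].copy()
        n_k = res.n_k.copy()
        k_new = _sample_token(0, bags.docs[0][0], int(res.z_by_doc[0][0]),
                              n_kw, n_dk, n_k, 0.1, 0.01, 0.5)
        assert 0 <= k_new < 3
        assert n_kw.sum() == res.n_kw.sum() and (n_kw >= 0).all()
        assert (n_kw.sum(axis=1) == n_k).all()


class TestLogLikelihood:
    def test_single_topic_matches_dirichlet_multinomial_marginal(self):
        """With K=1 the collapsed likelihood reduces to one Dirichlet-
        multinomial marginal over the vocabulary, computable in closed form."""
        bags = BagCorpus(["a", "b", "c"], [[0, 0, 1], [2, 1]])
        beta = 0.3
        res = fit_lda(bags, K=1, alpha=0.7, beta=beta, n_iter=3, burn_in=1, seed=0)
        V, N = 3, 5
        counts = np.array([2, 2, 1])
        expected = (
            gammaln(V * beta) - V * gammaln(beta)
            + gammaln(counts + beta).sum() - gammaln(N + V * beta)
        )
        assert res.log_likelihood() == pytest.approx(float(expected), abs=1e-10)

    def test_finite_over_trace(self):
        bags, _, _ = sample_lda_corpus(K=2, V=15, D=10, doc_length_mean=12, seed=8)
        res = fit_lda(bags, K=2, n_iter=30, burn_in=5, seed=9)
        assert np.isfinite(res.loglik_trace).all()

    def test_trace_improves_from_random_start(self):
        bags, _, _ = sample_lda_corpus(K=3, V=50, D=50, doc_length_mean=40,
                                       phi_concentration=0.02, seed=10)
        res = fit_lda(bags, K=3, alpha=0.1, n_iter=60, burn_in=20, seed=11)
        assert np.mean(res.loglik_trace[-10:]) > np.mean(res.loglik_trace[:5])


class TestTopWords:
    def test_point_mass_topic(self):
        bags = BagCorpus(["a", "b"], [[0, 0, 0, 0]])
        res = fit_lda(bags, K=1, beta=0.5, n_iter=3, burn_in=1, seed=0)
        (w, p), (w2, p2) = res.top_words(0, 2).top_words
        assert w == "a" and p == pytest.approx((4 + 0.5) / (4 + 2 * 0.5))
        assert w2 == "b"

    def test_k_larger_than_vocabulary_returns_all(self):
        bags = BagCorpus(["a", "b", "c"], [[0, 1, 2]])
        res = fit_lda(bags, K=1, n_iter=3, burn_in=1, seed=0)
        assert len(res.top_words(0, 50).top_words) == 3

    def test_out_of_range_topic_rejected(self):
        bags = BagCorpus(["a"], [[0]])
        res = fit_lda(bags, K=1, n_iter=3, burn_in=1, seed=0)
        with pytest.raises(ValueError):
            res.top_words(1)

    def test_probabilities_descending_with_lexicographic_ties(self):
        bags = BagCorpus(["b", "a", "c"], [[0, 1, 2, 2]])
        res = fit_lda(bags, K=1, n_iter=3, burn_in=1, seed=0)
        words = [w for w, _ in res.top_words(0, 3).top_words]
        assert words == ["c", "a", "b"]


class TestSerialization:
    def test_round_trip_and_byte_identical(self, tmp_path):
        bags, _, _ = sample_lda_corpus(K=2, V=10, D=6, doc_length_mean=8, seed=12)
        res = fit_lda(bags, K=2, n_iter=10, burn_in=2, seed=13)
        p1, p2 = tmp_path / "s1.json", tmp_path / "s2.json"
        res.save(p1)
        loaded = LDAResults.load(p1)
        loaded.save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert (loaded.n_kw == res.n_kw).all()
        assert loaded.log_likelihood() == pytest.approx(res.log_likelihood())

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"format": "other"}))
        with pytest.raises(ValueError):
            LDAResults.load(p)


class TestRecovery:
    def test_planted_topics_recovered_on_one_seed(self):
        """Moderate-size single-seed version of the phi-recovery check
        (the full 10-seed version runs in the acceptance suite)."""
        bags, phi, _ = sample_lda_corpus(K=5, V=100, D=200, doc_length_mean=60,
                                         alpha=0.1, seed=20)
        res = fit_lda(bags, K=5, alpha=0.1, n_iter=250, burn_in=100, seed=21)
        _, cos = match_topics(res.phi, phi)
        assert cos >= 0.8

    def test_match_topics_identity(self):
        phi = np.random.Generator(np.random.PCG64(1)).dirichlet(np.ones(8), size=4)
        perm, cos = match_topics(phi, phi)
        assert sorted(perm.tolist()) == [0, 1, 2, 3]
        assert cos == pytest.approx(1.0)


def test_summary_mentions_key_dimensions():
    bags, _, _ = sample_lda_corpus(K=2, V=10, D=6, doc_length_mean=8, seed=30)
    res = fit_lda(bags, K=2, n_iter=10, burn_in=2, seed=31)
    text = res.summary()
    assert "Topics (K):               2" in text
    assert "topic  0" in text and "topic  1" in text
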