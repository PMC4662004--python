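"""Collapsed Gibbs LDA: enumeration oracle, log-joint, inference, rendering."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

import topicscreen as ts
from topicscreen.errors import ValidationError
from topicscreen.lda import LatentDirichletAllocationGibbs


def collapsed_log_prob(z, w_ids, d_ids, D, K, V, alpha, beta):
    """Oracle: log p(z, w) with theta and phi integrated out analytically."""
    z = np.asarray(z)
    lp = 0.0
    for d in range(D):
        nd = z[d_ids == d]
        ndk = np.bincount(nd, minlength=K)
        lp += gammaln(K * alpha) - gammaln(len(nd) + K * alpha)
        lp += np.sum(gammaln(ndk + alpha) - gammaln(alpha))
    for k in range(K):
        wk = w_ids[z == k]
        nkw = np.bincount(wk, minlength=V)
        lp += gammaln(V * beta) - gammaln(len(wk) + V * beta)
        lp += np.sum(gammaln(nkw + beta) - gammaln(beta))
    return lp


def enumerate_z_marginals(w_ids, d_ids, D, K, V, alpha, beta):
    """Exact per-position topic marginals by summing over all K^N assignments."""
    N = len(w_ids)
    logps = []
    assignments = list(itertools.product(range(K), repeat=N))
    for z in assignments:
        logps.append(collapsed_log_prob(np.array(z), w_ids, d_ids,
                                        D, K, V, alpha, beta))
    logps = np.array(logps)
    p = np.exp(logps - logps.max())
    p /= p.sum()
    marg = np.zeros((N, K))
    for prob, z in zip(p, assignments):
        for i, k in enumerate(z):
            marg[i, k] += prob
    return marg


class TestGibbsSampler:
    def test_k1_degenerate(self):
        docs = [["a", "b", "a"], ["b", "c"]]
        m = LatentDirichletAllocationGibbs(
            n_topics=1, n_iter=20, burn_in=5, thin=1, random_state=0
        ).fit(docs)
        assert np.allclose(m.doc_topic_, 1.0)
        # phi equals smoothed empirical frequencies: (n_w + beta)/(N + V beta)
        counts = np.array([2, 2, 1], dtype=float)
        expected = (counts + m.beta) / (5 + 3 * m.beta)
        assert np.allclose(m.components_[0], expected)

    def test_normalisation(self, small_screening_corpus, quick_lda_config):
        cfg = quick_lda_config
        m = LatentDirichletAllocationGibbs(
            n_topics=cfg.n_topics, n_iter=cfg.iterations, burn_in=cfg.burn_in,
            thin=cfg.thin, random_state=0,
        ).fit(small_screening_corpus.corpus)
        assert np.allclose(m.components_.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(m.doc_topic_.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m.components_ > 0)

    def test_determinism(self):
        docs = [["a", "b", "c", "a"], ["c", "d"], ["b", "b", "d"]]
        fits = [
            LatentDirichletAllocationGibbs(
                n_topics=3, n_iter=60, burn_in=20, thin=2, random_state=42
            ).fit(docs)
            for _ in range(2)
        ]
        assert np.array_equal(fits[0].state_.z, fits[1].state_.z)
        assert np.allclose(fits[0].components_, fits[1].components_)
        assert np.allclose(fits[0].doc_topic_, fits[1].doc_topic_)

    def test_marginals_match_enumeration(self):
        """Sampler z-marginals agree with exact enumeration (2 docs x 3
        tokens, V=3, K=2) within total variation 0.02 per position."""
        docs = [["a", "b", "a"], ["b", "c", "c"]]
        K, V = 2, 3
        m = LatentDirichletAllocationGibbs(
            n_topics=K, alpha=0.5, beta=0.5, n_iter=20000, burn_in=2000,
            thin=1, random_state=0, collect_z_stats=True,
        ).fit(docs)
        vocab = m.vocabulary_
        w_ids = np.array([vocab[t] for doc in docs for t in doc])
        d_ids = np.array([i for i, doc in enumerate(docs) for _ in doc])
        exact = enumerate_z_marginals(w_ids, d_ids, 2, K, V, 0.5, 0.5)
        tv = 0.5 * np.abs(m.z_marginal_ - exact).sum(axis=1)
        assert tv.max() < 0.02

    def test_empty_document_uniform_theta(self, caplog):
        docs = [["a", "b"], [], ["b", "a"]]
        m = LatentDirichletAllocationGibbs(
            n_topics=2, n_iter=30, burn_in=10, thin=1, random_state=0
        ).fit(docs)
        assert np.allclose(m.doc_topic_[1], 0.5)

    def test_count_matrix_input(self):
        X = np.array([[2, 1, 0], [0, 1, 3]])
        m = LatentDirichletAllocationGibbs(
            n_topics=2, n_iter=30, burn_in=10, thin=1, random_state=0
        ).fit(X)
        assert m.components_.shape == (2, 3)
        assert m.state_.nkw.sum() == X.sum()


class TestLogJoint:
    def test_hand_computed_single_token(self):
        """One doc, one token, K=1: four closed-form log terms."""
        docs = [["a"]]
        m = LatentDirichletAllocationGibbs(
            n_topics=1, alpha=0.5, beta=0.5, n_iter=10, burn_in=2, thin=1,
            random_state=0,
        ).fit(docs)
        cfg = ts.LDAConfig(n_topics=1, alpha=0.5, beta=0.5)
        theta = np.array([[1.0]])
        phi = m.components_
        got = ts.log_joint(m.state_, theta, phi, cfg)
        # log phi[0, a] + log theta (=0) + log Dir(theta|a) + log Dir(phi|b)
        expected = (
            math.log(phi[0, 0])
            + 0.0
            + float(gammaln(0.5) - gammaln(0.5))  # K=1 Dirichlet is trivial
            + float(gammaln(0.5) - gammaln(0.5) - 0.5 * math.log(phi[0, 0]))
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_label_permutation_invariance(self):
        docs = [["a", "b", "a"], ["b", "c"]]
        K = 3
        m = LatentDirichletAllocationGibbs(
            n_topics=K, n_iter=40, burn_in=10, thin=1, random_state=1
        ).fit(docs)
        cfg = ts.LDAConfig(n_topics=K)
        base = ts.log_joint(m.state_, m.doc_topic_, m.components_, cfg)
        perm = np.array([2, 0, 1])
        state2 = ts.GibbsState(
            z=perm[m.state_.z], doc_of=m.state_.doc_of,
            word_of=m.state_.word_of, ndk=m.state_.ndk[:, np.argsort(perm)],
            nkw=m.state_.nkw[np.argsort(perm)], nk=m.state_.nk[np.argsort(perm)],
        )
        permuted = ts.log_joint(
            state2, m.doc_topic_[:, np.argsort(perm)],
            m.components_[np.argsort(perm)], cfg,
        )
        assert permuted == pytest.approx(base, rel=1e-9)

    def test_uniform_case_closed_form(self):
        """Uniform theta and phi: the token part collapses to N(-log V - log K)
        plus the (constant) Dirichlet densities of uniform vectors."""
        docs = [["a", "b"], ["c", "a"]]
        K, V, N = 2, 3, 4
        m = LatentDirichletAllocationGibbs(
            n_topics=K, alpha=1.0, beta=1.0, n_iter=10, burn_in=2, thin=1,
            random_state=0,
        ).fit(docs)
        cfg = ts.LDAConfig(n_topics=K, alpha=1.0, beta=1.0)
        theta = np.full((2, K), 1 / K)
        phi = np.full((K, V), 1 / V)
        got = ts.log_joint(m.state_, theta, phi, cfg)
        # Dir(1) density at any simplex point is (K-1)!; log = gammaln(K)
        expected = (
            N * (-math.log(V) - math.log(K))
            + 2 * float(gammaln(K))
            + K * float(gammaln(V))
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_probability_gives_neg_inf(self):
        docs = [["a", "b"]]
        m = LatentDirichletAllocationGibbs(
            n_topics=1, n_iter=10, burn_in=2, thin=1, random_state=0
        ).fit(docs)
        cfg = ts.LDAConfig(n_topics=1)
        phi = np.array([[1.0, 0.0]])
        assert ts.log_joint(m.state_, np.array([[1.0]]), phi, cfg) == -np.inf


@pytest.fixture(scope="module")
def fitted():
    spec = ts.SyntheticSpec(K=4, V=200, n_docs=150, mean_doc_len=50,
                            beta=0.05, alpha=0.1, seed=5)
    syn = ts.generate_lda_corpus(spec)
    model = LatentDirichletAllocationGibbs(
        n_topics=4, alpha=0.1, beta=0.05, n_iter=250, burn_in=80, thin=5,
        random_state=0,
    ).fit(syn.corpus)
    return model, syn


class TestInferTheta:

    def test_unseen_tokens_uniform(self, fitted):
        model, _ = fitted
        theta = ts.infer_theta(model, ["neverseenzz", "alsonotseenzz"], seed=0)
        assert np.allclose(theta, 0.25)

    def test_same_seed_identical(self, fitted):
        model, syn = fitted
        doc = syn.corpus.documents[0].tokens
        t1 = ts.infer_theta(model, doc, seed=9)
        t2 = ts.infer_theta(model, doc, seed=9)
        assert np.array_equal(t1, t2)

    def test_single_topic_docs_recover_topic(self, fitted):
        """Docs drawn from one topic put their mass on a single fitted topic
        consistently (>=95% of trials agree after matching)."""
        model, syn = fitted
        rng = np.random.default_rng(3)
        true_topic = 1
        hits = []
        assignments = []
        for trial in range(100):
            ids = rng.choice(len(syn.entries), size=60, p=syn.phi[true_topic])
            tokens = [syn.entries[i] for i in ids]
            theta = ts.infer_theta(model, tokens, seed=trial)
            assignments.append(int(np.argmax(theta)))
        # the fitted topic index that corresponds to the true topic
        matched = np.bincount(assignments).argmax()
        agree = np.mean([a == matched for a in assignments])
        assert agree >= 0.95


class TestTopTerms:
    def test_k1_reduces_to_frequency_ranking(self):
        docs = [["a", "a", "a", "b", "b", "c"]]
        m = LatentDirichletAllocationGibbs(
            n_topics=1, n_iter=10, burn_in=2, thin=1, random_state=0
        ).fit(docs)
        ranked = [t.token for t in ts.top_terms(m, 0, 3)]
        assert ranked == ["a", "b", "c"]

    def test_multiword_rendering(self):
        docs = [["teen_birth_rates", "school", "teen_birth_rates"]]
        m = LatentDirichletAllocationGibbs(
            n_topics=1, n_iter=10, burn_in=2, thin=1, random_state=0
        ).fit(docs)
        top = ts.top_terms(m, 0, 2)
        assert top[0].display == "teen birth rates"
        assert top[0].multiword
        assert not top[1].multiword

    def test_n_zero_empty(self):
        m = LatentDirichletAllocationGibbs(
            n_topics=1, n_iter=10, burn_in=2, thin=1, random_state=0
        ).fit([["a", "b"]])
        assert ts.top_terms(m, 0, 0) == []

    def test_n_capped_at_vocabulary(self):
        m = LatentDirichletAllocationGibbs(
            n_topics=1, n_iter=10, burn_in=2, thin=1, random_state=0
        ).fit([["a", "b"]])
        assert len(ts.top_terms(m, 0, 10)) == 2

    def test_bad_topic_index_rejected(self):
        m = LatentDirichletAllocationGibbs(
            n_topics=1, n_iter=10, burn_in=2, thin=1, random_state=0
        ).fit([["a", "b"]])
        with pytest.raises(ValidationError):
            ts.top_terms(m, 5, 1)


class TestConfigAndSerialisation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            ts.LDAConfig(n_topics=0)
        with pytest.raises(ValidationError):
            ts.LDAConfig(n_topics=2, iterations=10, burn_in=10)
        with pytest.raises(ValidationError):
            ts.LDAConfig(n_topics=2, beta=-1)

    def test_default_grid_is_the_density_sweep_row_set(self):
        assert len(ts.DEFAULT_K_GRID) == 16
        assert ts.DEFAULT_K_GRID[0] == 2 and ts.DEFAULT_K_GRID[-1] == 500

    def test_model_roundtrip(self, tmp_path):
        docs = [["a", "b", "c"], ["b", "c", "d"]]
        m = LatentDirichletAllocationGibbs(
            n_topics=2, n_iter=30, burn_in=10, thin=2, random_state=0
        ).fit(docs)
        ts.save_model(m, tmp_path / "model")
        back = ts.load_model(tmp_path / "model")
        assert np.allclose(back.components_, m.components_, atol=1e-10)
        assert back.vocabulary_ == m.vocabulary_
        doc = ["a", "c"]
        assert np.allclose(
            ts.infer_theta(back, doc, seed=4), ts.infer_theta(m, doc, seed=4)
        )
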