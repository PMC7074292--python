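import numpy as np
import pytest
import scipy.sparse as sp

from _oracles import enumerate_posterior
from kmertopics.kmer_corpus import CorpusMatrix
from kmertopics.lda import (
    LdaConfig,
    LdaModel,
    _sweeps_nb,
    _sweeps_py,
    fit_lda,
    log_likelihood,
    match_topics,
    run_gibbs,
    token_stream,
    word_probability,
)


def corpus_from_dense(rows, vocab=None):
    rows = np.asarray(rows, dtype=np.int64)
    vocab = vocab or [f"w{i}" for i in range(rows.shape[1])]
    counts = sp.csr_matrix(rows)
    return CorpusMatrix(
        doc_ids=[f"d{i}" for i in range(rows.shape[0])],
        vocabulary=list(vocab),
        counts=counts,
        doc_freq=np.asarray((counts > 0).sum(axis=0)).ravel(),
        min_df=0,
    )


def test_single_topic_closed_form():
    corpus = corpus_from_dense([[3, 1], [0, 2]])
    config = LdaConfig(n_topics=1, beta=0.5, n_iter=10, burn_in=0, seed=1)
    model = fit_lda(corpus, config)
    assert np.all(model.theta == 1.0)
    expected_phi = (np.array([3.0, 3.0]) + 0.5) / (6 + 2 * 0.5)
    np.testing.assert_allclose(model.phi[0], expected_phi)


def test_identical_inputs_reproduce_bit_identical_models():
    corpus = corpus_from_dense([[4, 2, 0], [1, 0, 5]])
    config = LdaConfig(n_topics=2, n_iter=50, burn_in=10, seed=42)
    a = fit_lda(corpus, config)
    b = fit_lda(corpus, config)
    assert np.array_equal(a.assignments, b.assignments)
    assert np.array_equal(a.theta, b.theta)
    assert np.array_equal(a.phi, b.phi)


def test_numba_kernel_matches_python_reference():
    """The compiled sampler and the pure-Python mirror walk the same chain
    given the same uniforms."""
    rng = np.random.default_rng(0)
    corpus = corpus_from_dense(rng.integers(0, 4, size=(3, 6)))
    token_doc, token_word = token_stream(corpus)
    n = token_doc.size
    T, V, M = 3, 6, 3
    z0 = rng.integers(0, T, n)
    uniforms = rng.random((20, n))

    def init(z):
        ndj = np.zeros((M, T), dtype=np.int64)
        njv = np.zeros((T, V), dtype=np.int64)
        np.add.at(ndj, (token_doc, z), 1)
        np.add.at(njv, (z, token_word), 1)
        return ndj, njv, njv.sum(axis=1)

    empty = np.empty(0, dtype=np.int64)
    z_nb = z0.copy()
    ndj, njv, nj = init(z_nb)
    _sweeps_nb(token_doc, token_word, z_nb, ndj, njv, nj, 0.7, 0.3, uniforms, empty)
    z_py = z0.copy()
    ndj_py, njv_py, nj_py = init(z_py)
    _sweeps_py(token_doc, token_word, z_py, ndj_py, njv_py, nj_py, 0.7, 0.3, uniforms, empty)
    assert np.array_equal(z_nb, z_py)
    assert np.array_equal(ndj, ndj_py)
    assert np.array_equal(njv, njv_py)


def test_count_matrices_tabulate_assignments():
    corpus = corpus_from_dense([[2, 3], [4, 1]])
    model = fit_lda(corpus, LdaConfig(n_topics=2, n_iter=30, burn_in=5, seed=3))
    token_doc, token_word = token_stream(corpus)
    ndj = np.zeros_like(model.doc_topic_counts)
    njv = np.zeros_like(model.topic_word_counts)
    np.add.at(ndj, (token_doc, model.assignments), 1)
    np.add.at(njv, (model.assignments, token_word), 1)
    assert np.array_equal(ndj, model.doc_topic_counts)
    assert np.array_equal(njv, model.topic_word_counts)
    assert np.allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_two_block_corpus_separates(seed):
    """Two documents over disjoint vocabularies land on different dominant
    topics with high confidence."""
    corpus = corpus_from_dense([[20, 20, 0, 0], [0, 0, 20, 20]])
    config = LdaConfig(n_topics=2, alpha=0.5, n_iter=500, burn_in=100, seed=seed)
    model = fit_lda(corpus, config)
    dom = model.theta.argmax(axis=1)
    assert dom[0] != dom[1]
    assert model.theta.max(axis=1).min() > 0.9


def test_full_conditional_matches_enumerated_posterior():
    """The sampler's full-conditional probabilities equal the ratio of exact
    collapsed posteriors of the neighboring states."""
    token_doc = np.array([0, 0, 1, 1])
    token_word = np.array([0, 1, 2, 0])
    T, V, M, alpha, beta = 2, 3, 2, 0.8, 0.5
    posterior = enumerate_posterior(token_doc, token_word, M, T, V, alpha, beta)
    rng = np.random.default_rng(5)
    for _ in range(20):
        z = tuple(rng.integers(0, T, 4))
        t = int(rng.integers(0, 4))
        # exact conditional from the enumerated posterior
        neighbors = [tuple(z[:t]) + (j,) + tuple(z[t + 1 :]) for j in range(T)]
        exact = np.array([posterior[nb] for nb in neighbors])
        exact /= exact.sum()
        # sampler formula on decremented counts
        ndj = np.zeros((M, T))
        njv = np.zeros((T, V))
        for i, j in enumerate(z):
            if i != t:
                ndj[token_doc[i], j] += 1
                njv[j, token_word[i]] += 1
        nj = njv.sum(axis=1)
        d, w = token_doc[t], token_word[t]
        p = (ndj[d] + alpha) * (njv[:, w] + beta) / (nj + V * beta)
        np.testing.assert_allclose(p / p.sum(), exact, rtol=1e-10)


def test_word_probability_mixture_forms():
    corpus = corpus_from_dense([[1, 1]])
    model = fit_lda(corpus, LdaConfig(n_topics=1, n_iter=5, burn_in=0, seed=0))
    assert word_probability(model, 0) == dict(zip(model.vocabulary, model.phi[0]))

    phi = np.array([[0.7, 0.3], [0.1, 0.9]])
    model2 = LdaModel(
        config=LdaConfig(n_topics=2, n_iter=2, burn_in=0),
        doc_ids=["d0", "d1"],
        vocabulary=["a", "b"],
        theta=np.array([[1.0, 0.0], [0.5, 0.5]]),
        phi=phi,
        assignments=np.zeros(1, dtype=np.int64),
        doc_topic_counts=np.zeros((2, 2), dtype=np.int64),
        topic_word_counts=np.zeros((2, 2), dtype=np.int64),
    )
    assert word_probability(model2, 0) == pytest.approx(dict(zip("ab", phi[0])))
    assert word_probability(model2, 1) == pytest.approx(
        dict(zip("ab", phi.mean(axis=0)))
    )
    assert sum(word_probability(model2, 1).values()) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(IndexError):
        word_probability(model2, 2)


def test_log_likelihood_probability_one_corpus():
    # one document, one-word vocabulary: phi is exactly (n + beta)/(n + V beta) = 1
    corpus = corpus_from_dense([[2]])
    model = fit_lda(corpus, LdaConfig(n_topics=1, n_iter=5, burn_in=0, seed=0))
    assert log_likelihood(model, corpus) == pytest.approx(0.0, abs=1e-12)


def test_log_likelihood_invariant_under_topic_permutation():
    corpus = corpus_from_dense([[3, 1, 2], [0, 4, 1]])
    model = fit_lda(corpus, LdaConfig(n_topics=3, n_iter=40, burn_in=10, seed=9))
    ll = log_likelihood(model, corpus)
    perm = [2, 0, 1]
    permuted = LdaModel(
        config=model.config,
        doc_ids=model.doc_ids,
        vocabulary=model.vocabulary,
        theta=model.theta[:, perm],
        phi=model.phi[perm],
        assignments=model.assignments,
        doc_topic_counts=model.doc_topic_counts,
        topic_word_counts=model.topic_word_counts,
    )
    assert log_likelihood(permuted, corpus) == pytest.approx(ll, rel=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_likelihood_improves_during_sampling(seed):
    rng = np.random.default_rng(seed)
    block = np.zeros((6, 30), dtype=np.int64)
    for d in range(6):
        lo = (d // 2) * 10
        block[d, lo : lo + 10] = rng.integers(5, 15, 10)
    corpus = corpus_from_dense(block)
    early = fit_lda(
        corpus, LdaConfig(n_topics=3, alpha=0.5, n_iter=1, burn_in=0, seed=seed)
    )
    late = fit_lda(
        corpus,
        LdaConfig(n_topics=3, alpha=0.5, n_iter=300, burn_in=100, seed=seed, ll_every=50),
    )
    assert log_likelihood(late, corpus) > log_likelihood(early, corpus)
    # the trace is recorded at the requested interval
    assert [s for s, _ in late.log_likelihood_trace] == list(range(50, 301, 50))


def test_match_topics_recovers_permutation():
    rng = np.random.default_rng(1)
    phi = rng.dirichlet(np.ones(8), size=4)
    perm = np.array([2, 0, 3, 1])
    assert np.array_equal(match_topics(phi, phi[perm]), np.argsort(perm))
    np.testing.assert_allclose(phi[perm][match_topics(phi, phi[perm])], phi)


def test_average_samples_option_returns_valid_distributions():
    corpus = corpus_from_dense([[10, 0, 2], [1, 8, 0]])
    config = LdaConfig(
        n_topics=2, n_iter=60, burn_in=20, seed=4, average_samples=True, sample_every=5
    )
    model = fit_lda(corpus, config)
    assert np.allclose(model.theta.sum(axis=1), 1.0)
    assert np.allclose(model.phi.sum(axis=1), 1.0)


def test_rejects_empty_documents_and_warns_on_many_topics():
    corpus = corpus_from_dense([[1, 0], [0, 0]])
    with pytest.raises(ValueError, match="zero tokens"):
        fit_lda(corpus, LdaConfig(n_topics=1, n_iter=5, burn_in=0))
    corpus2 = corpus_from_dense([[1, 0], [0, 1]])
    with pytest.warns(UserWarning, match="exceeds total token count"):
        fit_lda(corpus2, LdaConfig(n_topics=5, n_iter=5, burn_in=0))


def test_config_validation():
    with pytest.raises(ValueError):
        LdaConfig(n_topics=0)
    with pytest.raises(ValueError):
        LdaConfig(n_topics=2, beta=-1.0)
    with pytest.raises(ValueError):
        LdaConfig(n_topics=2, n_iter=10, burn_in=10)
    assert LdaConfig(n_topics=4).resolved_alpha == pytest.approx(12.5)
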