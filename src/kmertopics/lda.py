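"""Latent Dirichlet Allocation fitted by collapsed Gibbs sampling.

The corpus is modeled as M documents, each a mixture over T latent topics,
each topic a multinomial over the V-word vocabulary:

    P(w_i) = sum_j P(w_i | z = z_j) P(z = z_j)

with Dirichlet priors Dir(alpha) on the document-topic mixtures theta and
Dir(beta) on the topic-word distributions phi.  Inference integrates theta and
phi out and resamples each token's topic from its full conditional

    p(z = j | rest) ∝ (n_dj + alpha) (n_jv + beta) / (n_j + V beta)

where the counts exclude the token being resampled.  The sampler is
single-threaded and driven by one seeded NumPy generator, so identical
(corpus, config, seed) reproduce the chain bit for bit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment

from .kmer_corpus import CorpusMatrix

#: Sweeps per chunk are sized so the pre-drawn uniform block stays small.
_UNIFORMS_PER_CHUNK = 4_000_000


@dataclass
class LdaConfig:
    """Sampler settings.

    alpha defaults to the conventional Gibbs-LDA value 50/T and beta to 0.1;
    the point estimate is taken from the final Gibbs state unless
    ``average_samples`` is set, in which case post-burn-in samples (every
    ``sample_every`` sweeps, topics aligned by Hungarian matching on phi) are
    averaged.
    """

    n_topics: int
    alpha: float | None = None
    beta: float = 0.1
    n_iter: int = 2000
    burn_in: int = 1000
    seed: int = 0
    average_samples: bool = False
    sample_every: int = 20
    ll_every: int = 100

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")

    @property
    def resolved_alpha(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else self.alpha


@dataclass
class LdaModel:
    """Fitted topic model: smoothed posterior means theta (M×T) and phi (T×V)."""

    config: LdaConfig
    doc_ids: list[str]
    vocabulary: list[str]
    theta: np.ndarray
    phi: np.ndarray
    assignments: np.ndarray
    doc_topic_counts: np.ndarray
    topic_word_counts: np.ndarray
    log_likelihood_trace: list[tuple[int, float]] = field(default_factory=list)


@njit(cache=False)
def _sweeps_nb(token_doc, token_word, z, ndj, njv, nj, alpha, beta, uniforms, states):
    n_sweeps, n_tokens = uniforms.shape
    n_topics = nj.shape[0]
    vocab_size = njv.shape[1]
    probs = np.empty(n_topics, dtype=np.float64)
    record = states.shape[0] == n_sweeps
    for s in range(n_sweeps):
        for t in range(n_tokens):
            d = token_doc[t]
            w = token_word[t]
            old = z[t]
            ndj[d, old] -= 1
            njv[old, w] -= 1
            nj[old] -= 1
            total = 0.0
            for j in range(n_topics):
                total += (
                    (ndj[d, j] + alpha)
                    * (njv[j, w] + beta)
                    / (nj[j] + vocab_size * beta)
                )
                probs[j] = total
            u = uniforms[s, t] * total
            new = 0
            while probs[new] < u and new < n_topics - 1:
                new += 1
            z[t] = new
            ndj[d, new] += 1
            njv[new, w] += 1
            nj[new] += 1
        if record:
            code = 0
            for t in range(n_tokens):
                code = code * n_topics + z[t]
            states[s] = code


def _sweeps_py(token_doc, token_word, z, ndj, njv, nj, alpha, beta, uniforms, states):
    """Pure-Python mirror of :func:`_sweeps_nb`, arithmetic op-for-op identical."""
    n_sweeps, n_tokens = uniforms.shape
    n_topics = nj.shape[0]
    vocab_size = njv.shape[1]
    probs = np.empty(n_topics, dtype=np.float64)
    record = states.shape[0] == n_sweeps
    for s in range(n_sweeps):
        for t in range(n_tokens):
            d = token_doc[t]
            w = token_word[t]
            old = z[t]
            ndj[d, old] -= 1
            njv[old, w] -= 1
            nj[old] -= 1
            total = 0.0
            for j in range(n_topics):
                total += (
                    (ndj[d, j] + alpha)
                    * (njv[j, w] + beta)
                    / (nj[j] + vocab_size * beta)
                )
                probs[j] = total
            u = uniforms[s, t] * total
            new = 0
            while probs[new] < u and new < n_topics - 1:
                new += 1
            z[t] = new
            ndj[d, new] += 1
            njv[new, w] += 1
            nj[new] += 1
        if record:
            code = 0
            for t in range(n_tokens):
                code = code * n_topics + int(z[t])
            states[s] = code


def token_stream(corpus: CorpusMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Expand the count matrix into per-token (doc, word) arrays.

    Tokens appear in vocabulary order within each document; the model is
    exchangeable, so the layout does not affect the posterior.
    """
    csr = corpus.counts.tocsr()
    docs, words = [], []
    for d in range(csr.shape[0]):
        start, end = csr.indptr[d], csr.indptr[d + 1]
        idx = csr.indices[start:end]
        cnt = csr.data[start:end]
        order = np.argsort(idx, kind="stable")
        words.append(np.repeat(idx[order], cnt[order]))
        docs.append(np.full(int(cnt.sum()), d, dtype=np.int64))
    return (
        np.concatenate(docs) if docs else np.empty(0, dtype=np.int64),
        np.concatenate(words).astype(np.int64) if words else np.empty(0, dtype=np.int64),
    )


def _smoothed(ndj, njv, nj, alpha, beta):
    theta = (ndj + alpha) / (ndj.sum(axis=1, keepdims=True) + ndj.shape[1] * alpha)
    phi = (njv + beta) / (nj[:, None] + njv.shape[1] * beta)
    return theta, phi


def match_topics(phi_ref: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Permutation aligning the topics of ``phi`` to ``phi_ref``.

    Mixture likelihoods are invariant to topic relabeling, so any comparison
    of two fits must first solve this assignment; the Hungarian algorithm
    minimizes the total L1 distance between matched topic-word rows.

    Returns ``perm`` with ``phi[perm]`` aligned to ``phi_ref``.
    """
    cost = np.abs(phi_ref[:, None, :] - phi[None, :, :]).sum(axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols


def run_gibbs(
    corpus: CorpusMatrix, config: LdaConfig, record_states: bool = False
) -> tuple[LdaModel, np.ndarray | None]:
    """Run the collapsed Gibbs chain; optionally record the full topic-assignment
    state after every sweep as an integer code (tiny corpora only)."""
    token_doc, token_word = token_stream(corpus)
    n_tokens = token_doc.size
    if n_tokens == 0:
        raise ValueError("corpus has no tokens")
    per_doc = np.asarray(corpus.counts.sum(axis=1)).ravel()
    if (per_doc == 0).any():
        empty = [corpus.doc_ids[i] for i in np.flatnonzero(per_doc == 0)]
        raise ValueError(f"documents with zero tokens: {empty}")
    T = config.n_topics
    V = len(corpus.vocabulary)
    M = len(corpus.doc_ids)
    if T > n_tokens:
        warnings.warn(f"n_topics={T} exceeds total token count {n_tokens}")
    if record_states and float(T) ** n_tokens >= 2.0**62:
        raise ValueError("corpus too large to record full assignment states")
    alpha, beta = config.resolved_alpha, config.beta

    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, T, size=n_tokens).astype(np.int64)
    ndj = np.zeros((M, T), dtype=np.int64)
    njv = np.zeros((T, V), dtype=np.int64)
    np.add.at(ndj, (token_doc, z), 1)
    np.add.at(njv, (z, token_word), 1)
    nj = njv.sum(axis=1)

    states = (
        np.empty(config.n_iter, dtype=np.int64)
        if record_states
        else np.empty(0, dtype=np.int64)
    )
    trace: list[tuple[int, float]] = []
    avg_theta = avg_phi = None
    n_avg = 0
    phi_ref = None

    chunk = max(1, _UNIFORMS_PER_CHUNK // max(n_tokens, 1))
    if config.average_samples:
        chunk = 1  # sample boundaries must fall on exact sweeps
    done = 0
    while done < config.n_iter:
        s = min(chunk, config.n_iter - done)
        uniforms = rng.random((s, n_tokens))
        sub_states = states[done : done + s] if record_states else states
        _sweeps_nb(token_doc, token_word, z, ndj, njv, nj, alpha, beta, uniforms, sub_states)
        for sweep in range(done + 1, done + s + 1):
            if config.ll_every and sweep % config.ll_every == 0:
                theta, phi = _smoothed(ndj, njv, nj, alpha, beta)
                trace.append((sweep, _ll_from(theta, phi, corpus)))
        done += s
        if config.average_samples and done > config.burn_in:
            if (done - config.burn_in) % max(config.sample_every, 1) == 0:
                theta, phi = _smoothed(ndj, njv, nj, alpha, beta)
                if phi_ref is None:
                    phi_ref = phi
                    perm = np.arange(T)
                else:
                    perm = match_topics(phi_ref, phi)
                if avg_theta is None:
                    avg_theta = np.zeros_like(theta)
                    avg_phi = np.zeros_like(phi)
                avg_theta += theta[:, perm]
                avg_phi += phi[perm]
                n_avg += 1

    theta, phi = _smoothed(ndj, njv, nj, alpha, beta)
    if config.average_samples and n_avg > 0:
        theta = avg_theta / n_avg
        phi = avg_phi / n_avg
    model = LdaModel(
        config=config,
        doc_ids=list(corpus.doc_ids),
        vocabulary=list(corpus.vocabulary),
        theta=theta,
        phi=phi,
        assignments=z,
        doc_topic_counts=ndj,
        topic_word_counts=njv,
        log_likelihood_trace=trace,
    )
    return model, (states if record_states else None)


def fit_lda(corpus: CorpusMatrix, config: LdaConfig) -> LdaModel:
    """Fit LDA to a corpus by collapsed Gibbs sampling (see module docstring)."""
    model, _ = run_gibbs(corpus, config, record_states=False)
    return model


def word_probability(model: LdaModel, d: int) -> dict[str, float]:
    """Marginal word distribution of document d: P(w) = sum_j phi[j, w] theta[d, j]."""
    if not 0 <= d < model.theta.shape[0]:
        raise IndexError(f"document index {d} out of range")
    p = model.theta[d] @ model.phi
    return dict(zip(model.vocabulary, p.tolist()))


def _ll_from(theta: np.ndarray, phi: np.ndarray, corpus: CorpusMatrix) -> float:
    csr = corpus.counts.tocsr()
    rows, cols = csr.nonzero()
    p = np.einsum("ij,ji->i", theta[rows], phi[:, cols])
    return float(np.sum(csr.data * np.log(p)))


def log_likelihood(model: LdaModel, corpus: CorpusMatrix) -> float:
    """Corpus log likelihood under the mixture P(w_i) = sum_j phi theta."""
    if model.theta.shape[0] != corpus.counts.shape[0]:
        raise ValueError("model and corpus document counts differ")
    if model.phi.shape[1] != corpus.counts.shape[1]:
        raise ValueError("model and corpus vocabulary sizes differ")
    return _ll_from(model.theta, model.phi, corpus)


def save_model(model: LdaModel, out_dir: str | Path) -> None:
    """theta / phi as TSV plus a JSON sidecar with config, seed and trace."""
    import json

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topics = [f"topic_{j + 1}" for j in range(model.config.n_topics)]
    pd.DataFrame(model.theta, index=model.doc_ids, columns=topics).to_csv(
        out / "theta.tsv", sep="\t", index_label="doc_id"
    )
    pd.DataFrame(model.phi, index=topics, columns=model.vocabulary).to_csv(
        out / "phi.tsv", sep="\t", index_label="topic"
    )
    sidecar = {
        "n_topics": model.config.n_topics,
        "alpha": model.config.resolved_alpha,
        "beta": model.config.beta,
        "n_iter": model.config.n_iter,
        "burn_in": model.config.burn_in,
        "seed": model.config.seed,
        "log_likelihood_trace": model.log_likelihood_trace,
    }
    (out / "lda.json").write_text(json.dumps(sidecar, sort_keys=True))
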