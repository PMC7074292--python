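"""Independent reference implementations used only to check the package."""
from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy.special import gammaln, logsumexp

VALID = set("ACGT")


def naive_kmer_counts(sequence: str, k: int) -> tuple[Counter, int]:
    """Count k-windows by direct substring enumeration."""
    counts: Counter = Counter()
    n_valid = 0
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if set(w) <= VALID:
            counts[w] += 1
            n_valid += 1
    return counts, n_valid


def collapsed_log_posterior(
    z: tuple[int, ...],
    token_doc: np.ndarray,
    token_word: np.ndarray,
    n_docs: int,
    n_topics: int,
    vocab_size: int,
    alpha: float,
    beta: float,
) -> float:
    """Unnormalized log posterior of a full topic assignment with theta and phi
    integrated out (Dirichlet-multinomial in both blocks)."""
    ndj = np.zeros((n_docs, n_topics))
    njv = np.zeros((n_topics, vocab_size))
    for t, j in enumerate(z):
        ndj[token_doc[t], j] += 1
        njv[j, token_word[t]] += 1
    nj = njv.sum(axis=1)
    lp = gammaln(ndj + alpha).sum()
    lp += gammaln(njv + beta).sum() - gammaln(nj + vocab_size * beta).sum()
    return float(lp)


def enumerate_posterior(
    token_doc: np.ndarray,
    token_word: np.ndarray,
    n_docs: int,
    n_topics: int,
    vocab_size: int,
    alpha: float,
    beta: float,
) -> dict[tuple[int, ...], float]:
    """Exact collapsed posterior over all T^n assignment states."""
    n = len(token_doc)
    states = list(itertools.product(range(n_topics), repeat=n))
    logps = np.array(
        [
            collapsed_log_posterior(
                z, token_doc, token_word, n_docs, n_topics, vocab_size, alpha, beta
            )
            for z in states
        ]
    )
    probs = np.exp(logps - logsumexp(logps))
    return dict(zip(states, probs))


def state_code(z, n_topics: int) -> int:
    """Mixed-radix packing matching the sampler's state recording."""
    code = 0
    for zt in z:
        code = code * n_topics + int(zt)
    return code
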