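"""Feature-frequency-profile baseline: k-mer frequencies + Jensen-Shannon trees.

Each genome is reduced to its normalized k-mer frequency vector over a shared
vocabulary and genomes are compared by the Jensen-Shannon divergence (base 2,
bounded by [0, 1]).  No over- or under-represented words are removed, so the
baseline and the topic model see exactly the same lexicon.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .clustering import ClusterTree, DistanceMatrix, hierarchical_cluster
from .kmer_corpus import CorpusMatrix, KmerTable


@dataclass
class FrequencyProfile:
    """Normalized word-frequency vector of one genome over a shared vocabulary."""

    doc_id: str
    vocabulary: list[str]
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.vocabulary),):
            raise ValueError("frequency vector length does not match vocabulary")
        if abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def frequency_profile(table: KmerTable, vocabulary: Sequence[str]) -> FrequencyProfile:
    """Counts of vocabulary words, renormalized within the document.

    Words outside the vocabulary are ignored; vocabulary words absent from the
    document get frequency 0.
    """
    if not len(vocabulary):
        raise ValueError("empty vocabulary")
    counts = np.array([table.counts.get(w, 0) for w in vocabulary], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"document {table.doc_id!r} shares no words with vocabulary")
    return FrequencyProfile(
        doc_id=table.doc_id, vocabulary=list(vocabulary), freq=counts / total
    )


def profiles_from_corpus(corpus: CorpusMatrix) -> list[FrequencyProfile]:
    """One profile per corpus row, over the corpus vocabulary."""
    dense = np.asarray(corpus.counts.todense(), dtype=float)
    profiles = []
    for doc_id, row in zip(corpus.doc_ids, dense):
        total = row.sum()
        if total == 0:
            raise ValueError(f"document {doc_id!r} has no tokens")
        profiles.append(
            FrequencyProfile(
                doc_id=doc_id, vocabulary=list(corpus.vocabulary), freq=row / total
            )
        )
    return profiles


def jsd(p: FrequencyProfile | np.ndarray, q: FrequencyProfile | np.ndarray) -> float:
    """Jensen-Shannon divergence in bits; symmetric, in [0, 1]."""
    pv = p.freq if isinstance(p, FrequencyProfile) else np.asarray(p, dtype=float)
    qv = q.freq if isinstance(q, FrequencyProfile) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError("profiles must share a vocabulary")
    return float(jensenshannon(pv, qv, base=2) ** 2)


def jsd_matrix(profiles: Sequence[FrequencyProfile]) -> DistanceMatrix:
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jsd(profiles[i], profiles[j])
    return DistanceMatrix(ids=[p.doc_id for p in profiles], d=d)


def ffp_tree(profiles: Sequence[FrequencyProfile], linkage: str = "average") -> ClusterTree:
    """Hierarchical tree over pairwise Jensen-Shannon divergences."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    return hierarchical_cluster(jsd_matrix(profiles), linkage=linkage)
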