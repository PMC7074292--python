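"""Synthetic corpora and genomes with the statistical structure the method assumes.

Two levels of fixture are generated, so every pipeline stage is testable
without downloads:

* bag-of-words corpora drawn exactly from the LDA generative process
  (document length N ~ Poisson(xi); for each token draw a topic from the
  document's mixture, then a word from that topic's distribution);
* DNA sequences — either order-m Markov chains over {A, C, G, T} (fixtures
  for the relative-entropy machinery) or genomes assembled by concatenating
  words sampled from planted family lexicons.  Concatenation creates junction
  k-mers that the planted model does not describe; planted-word tokens make up
  at least 1/k of all windows, and the pipeline must tolerate the rest as
  noise, exactly as it must tolerate unmodeled structure in real genomes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .genome_io import GenomeDocument, write_fasta
from .kmer_corpus import CorpusMatrix, decode_kmer

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedTopicModel:
    """Ground-truth topic model used to generate corpora and genomes."""

    n_topics: int
    vocabulary: list[str]
    phi_true: np.ndarray
    theta_true: dict[str, np.ndarray]
    xi: float
    seed: int

    def __post_init__(self) -> None:
        self.phi_true = np.asarray(self.phi_true, dtype=float)
        if self.phi_true.shape != (self.n_topics, len(self.vocabulary)):
            raise ValueError("phi_true shape does not match topics × vocabulary")
        if np.any(self.phi_true.sum(axis=1) == 0):
            raise ValueError("phi_true has a zero row")
        if not np.allclose(self.phi_true.sum(axis=1), 1.0):
            raise ValueError("phi_true rows must sum to 1")
        for fam, th in self.theta_true.items():
            th = np.asarray(th, dtype=float)
            if th.shape != (self.n_topics,) or not np.isclose(th.sum(), 1.0):
                raise ValueError(f"theta_true[{fam!r}] is not a topic distribution")
            self.theta_true[fam] = th
        if self.xi <= 0:
            raise ValueError("xi must be positive")


def planted_bag_model(
    n_topics: int = 3,
    vocab_size: int = 1000,
    xi: float = 5000.0,
    n_families: int = 3,
    dominant: float = 0.8,
    phi_concentration: float = 0.1,
    seed: int = 0,
) -> PlantedTopicModel:
    """Default study conditions for bag-of-words corpora.

    Three families of documents, each dominated by its own topic
    (``dominant`` mass on the family topic, the rest spread evenly); topic-word
    rows drawn from a sparse Dirichlet so topics overlap only lightly.
    """
    if n_families > n_topics:
        raise ValueError("each family needs a dominant topic")
    rng = np.random.default_rng(seed)
    vocabulary = [f"w{i:05d}" for i in range(vocab_size)]
    phi = rng.dirichlet(np.full(vocab_size, phi_concentration), size=n_topics)
    theta = {}
    if n_topics == 1:
        dominant, rest = 1.0, 0.0
    else:
        rest = (1.0 - dominant) / (n_topics - 1)
    for f in range(n_families):
        vec = np.full(n_topics, rest)
        vec[f] = dominant
        theta[f"family_{f + 1}"] = vec
    return PlantedTopicModel(
        n_topics=n_topics,
        vocabulary=vocabulary,
        phi_true=phi,
        theta_true=theta,
        xi=xi,
        seed=seed,
    )


def planted_kmer_model(
    n_topics: int = 3,
    vocab_size: int = 300,
    k: int = 8,
    xi: float = 5000.0,
    n_families: int = 3,
    dominant: float = 0.8,
    phi_concentration: float = 0.1,
    seed: int = 0,
) -> PlantedTopicModel:
    """Planted model whose vocabulary is distinct random k-mers (for DNA fixtures)."""
    rng = np.random.default_rng(seed)
    if vocab_size > 4**k:
        raise ValueError(f"cannot draw {vocab_size} distinct {k}-mers")
    codes = rng.choice(4**k, size=vocab_size, replace=False)
    codes.sort()
    vocabulary = [decode_kmer(int(c), k) for c in codes]
    base = planted_bag_model(
        n_topics=n_topics,
        vocab_size=vocab_size,
        xi=xi,
        n_families=n_families,
        dominant=dominant,
        phi_concentration=phi_concentration,
        seed=seed,
    )
    return PlantedTopicModel(
        n_topics=n_topics,
        vocabulary=vocabulary,
        phi_true=base.phi_true,
        theta_true=base.theta_true,
        xi=xi,
        seed=seed,
    )


def generate_corpus(
    planted: PlantedTopicModel,
    family_sizes: Mapping[str, int],
    seed: int | None = None,
) -> tuple[CorpusMatrix, dict[str, str], np.ndarray]:
    """Draw a corpus from the planted generative process.

    For each document: N ~ Poisson(xi), token topics ~ Multinomial(theta of
    its family), words ~ Multinomial(phi of the topic).  Returns the count
    matrix, the doc_id -> family map, and the true per-document theta (M×T).
    """
    unknown = set(family_sizes) - set(planted.theta_true)
    if unknown:
        raise ValueError(f"families without planted theta: {sorted(unknown)}")
    rng = np.random.default_rng(planted.seed if seed is None else seed)
    V = len(planted.vocabulary)
    rows, labels, thetas, doc_ids = [], {}, [], []
    for family in sorted(family_sizes):
        theta = planted.theta_true[family]
        for i in range(family_sizes[family]):
            doc_id = f"{family}_{i + 1:02d}"
            n = int(rng.poisson(planted.xi))
            topic_counts = rng.multinomial(n, theta)
            row = np.zeros(V, dtype=np.int64)
            for j, nj in enumerate(topic_counts):
                if nj:
                    row += rng.multinomial(int(nj), planted.phi_true[j])
            rows.append(row)
            labels[doc_id] = family
            thetas.append(theta)
            doc_ids.append(doc_id)
    counts = sp.csr_matrix(np.vstack(rows))
    doc_freq = np.asarray((counts > 0).sum(axis=0)).ravel().astype(np.int64)
    # min_df=0: unfiltered vocabulary, kept aligned with phi_true columns even
    # if a rare word happens to be drawn in no document
    corpus = CorpusMatrix(
        doc_ids=doc_ids,
        vocabulary=list(planted.vocabulary),
        counts=counts,
        doc_freq=doc_freq,
        min_df=0,
    )
    return corpus, labels, np.vstack(thetas)


def generate_markov_genome(
    order: int,
    transition: np.ndarray,
    length: int,
    seed: int,
    doc_id: str = "markov",
    family: str = "synthetic",
    initial: np.ndarray | None = None,
) -> GenomeDocument:
    """Sample an order-``order`` Markov sequence over {A, C, G, T}.

    ``transition`` has shape ``(4**order, 4)`` (shape ``(4,)`` is accepted for
    order 0): row ``c`` is the next-base distribution given the context whose
    2-bit packing is ``c``.  The first ``order`` bases are drawn from
    ``initial`` (uniform by default).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    trans = np.asarray(transition, dtype=float)
    if order == 0 and trans.shape == (4,):
        trans = trans.reshape(1, 4)
    if trans.shape != (4**order, 4):
        raise ValueError(f"transition must have shape ({4 ** order}, 4)")
    if np.any(trans < 0) or not np.allclose(trans.sum(axis=1), 1.0):
        raise ValueError("transition rows must be probability distributions")
    if length < max(order, 1):
        raise ValueError("length too short for the requested order")
    rng = np.random.default_rng(seed)
    if order == 0:
        idx = rng.choice(4, size=length, p=trans[0])
    else:
        p0 = np.full(4, 0.25) if initial is None else np.asarray(initial, dtype=float)
        idx = np.empty(length, dtype=np.int64)
        idx[:order] = rng.choice(4, size=order, p=p0)
        cum = np.cumsum(trans, axis=1)
        u = rng.random(length)
        mask = 4 ** (order - 1)
        ctx = 0
        for i in range(order):
            ctx = ctx * 4 + idx[i]
        for i in range(order, length):
            row = cum[ctx]
            b = int(np.searchsorted(row, u[i], side="right"))
            b = min(b, 3)
            idx[i] = b
            ctx = (ctx % mask) * 4 + b if order > 1 else b
    sequence = "".join(_BASES[idx])
    return GenomeDocument(
        doc_id=doc_id,
        accession=doc_id,
        organism=f"order-{order} Markov chain",
        family=family,
        sequence=sequence,
        length_bp=length,
    )


def generate_family_genomes(
    planted: PlantedTopicModel,
    families: Mapping[str, str],
    lengths: Mapping[str, int] | int,
    seed: int = 0,
) -> list[GenomeDocument]:
    """Assemble genomes by concatenating words from each family's planted mixture.

    ``families`` maps doc_id -> family; ``lengths`` gives target lengths in bp
    (one int applies to all).  Each genome is ``length // k`` whole words, so
    the realized length is the largest word multiple not exceeding the target.
    """
    word_lengths = {len(w) for w in planted.vocabulary}
    if len(word_lengths) != 1:
        raise ValueError("planted vocabulary words must share one length k")
    k = word_lengths.pop()
    rng = np.random.default_rng(seed)
    vocab = np.array(planted.vocabulary)
    docs = []
    for doc_id in sorted(families):
        family = families[doc_id]
        target = lengths if isinstance(lengths, int) else lengths[doc_id]
        if target < k:
            raise ValueError(f"length {target} shorter than word size {k}")
        mixture = planted.theta_true[family] @ planted.phi_true
        n_words = target // k
        words = rng.choice(vocab, size=n_words, p=mixture)
        sequence = "".join(words)
        docs.append(
            GenomeDocument(
                doc_id=doc_id,
                accession=doc_id,
                organism=f"synthetic {family} genome",
                family=family,
                sequence=sequence,
                length_bp=len(sequence),
            )
        )
    return docs


def write_fixture(
    docs: Sequence[GenomeDocument],
    out_dir: str | Path,
    truth: Mapping | None = None,
) -> Path:
    """Write genomes as per-document FASTA plus a manifest TSV (and truth JSON).

    Returns the manifest path; the fixture flows through the normal
    manifest-driven pipeline unchanged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["accession\tfamily\torganism\tpath"]
    for doc in docs:
        fasta = out / f"{doc.doc_id}.fasta"
        write_fasta([doc], fasta)
        lines.append(f"{doc.accession}\t{doc.family}\t{doc.organism}\t{fasta.name}")
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, sort_keys=True))
    return manifest
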