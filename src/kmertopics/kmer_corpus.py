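"""Decompose genomes into overlapping k-mer words and build the corpus matrix.

A genome of length ``l`` contributes ``l - k + 1`` overlapping windows; windows
containing anything outside ``{A, C, G, T}`` (ambiguity codes, record
separators) are skipped.  Words are counted on the forward strand only — no
reverse-complement canonicalization.  The corpus is the documents × vocabulary
sparse count matrix after a document-frequency filter.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .genome_io import GenomeDocument

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_BASES = "ACGT"

#: 2-bit packing limit for a 64-bit word code.
MAX_K = 31


def sequence_codes(sequence: str) -> np.ndarray:
    """Map a sequence to int8 base codes (A=0, C=1, G=2, T=3, other=-1)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_kmer(code: int, k: int) -> str:
    """Inverse of the 2-bit packing: integer code -> k-mer string."""
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def window_code_counts(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Count valid k-windows as packed integer codes.

    Returns ``(codes, counts, n_valid_windows)`` with ``codes`` sorted
    ascending, which coincides with lexicographic order of the k-mer strings.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > MAX_K:
        raise ValueError(f"k={k} exceeds the packing limit {MAX_K}")
    vals = sequence_codes(sequence).astype(np.int64)
    n = vals.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 0
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    for off in range(k):
        codes = (codes << 2) | np.maximum(vals[off : off + m], 0)
    bad = (vals < 0).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    window_bad = (cs[k:] - cs[:-k]) > 0
    valid = codes[~window_bad]
    uniq, counts = np.unique(valid, return_counts=True)
    return uniq, counts, int(valid.size)


@dataclass
class KmerTable:
    """Multiset of overlapping k-mers of one genome, for one k."""

    doc_id: str
    k: int
    counts: dict[str, int]
    n_valid_windows: int


def extract_kmers(doc: GenomeDocument | str, k: int) -> KmerTable:
    """Slide a size-k window (step 1) over a genome and count clean windows.

    ``doc`` may be a :class:`GenomeDocument` or a raw sequence string.
    """
    if isinstance(doc, str):
        sequence, doc_id, length_bp = doc, "", len(doc)
    else:
        sequence, doc_id, length_bp = doc.sequence, doc.doc_id, doc.length_bp
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > length_bp:
        raise ValueError(f"k={k} exceeds genome length {length_bp}")
    codes, counts, n_valid = window_code_counts(sequence, k)
    table = {decode_kmer(int(c), k): int(n) for c, n in zip(codes, counts)}
    return KmerTable(doc_id=doc_id, k=k, counts=table, n_valid_windows=n_valid)


@dataclass
class CorpusMatrix:
    """Documents × filtered-vocabulary sparse count matrix.

    ``vocabulary`` is sorted lexicographically; ``doc_freq[v]`` is the number
    of documents containing word ``v`` at least once; all retained words have
    ``doc_freq >= min_df``.
    """

    doc_ids: list[str]
    vocabulary: list[str]
    counts: sp.csr_matrix
    doc_freq: np.ndarray
    min_df: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class CorpusStats:
    """Summary of corpus construction.

    union_distinct: distinct words in at least one document before filtering.
    selected_vocab: vocabulary size after the document-frequency filter.
    presence_sum: total number of (document, word) presence pairs over the
        selected vocabulary, i.e. sum of document frequencies.
    token_sum: total word occurrences over the filtered matrix.
    """

    union_distinct: int
    selected_vocab: int
    presence_sum: int
    token_sum: int


def resolve_min_df(min_df: int | float, n_docs: int) -> int:
    """A float in (0, 1) is a fraction of documents; an int is absolute."""
    if isinstance(min_df, float) and 0 < min_df < 1:
        return max(1, int(np.ceil(min_df * n_docs)))
    return int(min_df)


def build_corpus(tables: Sequence[KmerTable], min_df: int | float) -> CorpusMatrix:
    """Build the document-term matrix over words with document frequency >= min_df."""
    if not tables:
        raise ValueError("no k-mer tables supplied")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"mixed k values in tables: {sorted(ks)}")
    m = len(tables)
    min_df = resolve_min_df(min_df, m)
    if not 1 <= min_df <= m:
        raise ValueError(f"min_df={min_df} outside [1, {m}]")
    df: Counter[str] = Counter()
    for t in tables:
        df.update(t.counts.keys())
    vocabulary = sorted(w for w, c in df.items() if c >= min_df)
    index = {w: i for i, w in enumerate(vocabulary)}
    rows, cols, vals = [], [], []
    for d, t in enumerate(tables):
        for w, c in t.counts.items():
            i = index.get(w)
            if i is not None:
                rows.append(d)
                cols.append(i)
                vals.append(c)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(m, len(vocabulary)), dtype=np.int64
    )
    doc_freq = np.array([df[w] for w in vocabulary], dtype=np.int64)
    return CorpusMatrix(
        doc_ids=[t.doc_id for t in tables],
        vocabulary=vocabulary,
        counts=counts,
        doc_freq=doc_freq,
        min_df=min_df,
    )


def corpus_stats(tables: Sequence[KmerTable], corpus: CorpusMatrix) -> CorpusStats:
    """Corpus summary: pre-filter union size and post-filter vocabulary/presence/token sums."""
    union: set[str] = set()
    for t in tables:
        union.update(t.counts.keys())
    return CorpusStats(
        union_distinct=len(union),
        selected_vocab=len(corpus.vocabulary),
        presence_sum=int(corpus.doc_freq.sum()),
        token_sum=int(corpus.counts.sum()),
    )


# ---------------------------------------------------------------------------
# serialization


def save_kmer_table(table: KmerTable, path: str | Path) -> None:
    """Two-column TSV (kmer, count) with a commented header carrying metadata."""
    with open(path, "w") as fh:
        fh.write(f"# doc_id={table.doc_id}\tk={table.k}\tn_valid_windows={table.n_valid_windows}\n")
        for w in sorted(table.counts):
            fh.write(f"{w}\t{table.counts[w]}\n")


def load_kmer_table(path: str | Path) -> KmerTable:
    with open(path) as fh:
        meta = dict(
            field.split("=", 1) for field in fh.readline().lstrip("# ").split("\t")
        )
        counts = {}
        for line in fh:
            w, c = line.split("\t")
            counts[w] = int(c)
    return KmerTable(
        doc_id=meta["doc_id"],
        k=int(meta["k"]),
        counts=counts,
        n_valid_windows=int(meta["n_valid_windows"]),
    )


def save_corpus(corpus: CorpusMatrix, out_dir: str | Path) -> None:
    """MatrixMarket matrix plus vocabulary / doc-id sidecar text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "counts.mtx", corpus.counts)
    (out / "vocabulary.txt").write_text("\n".join(corpus.vocabulary) + "\n")
    (out / "doc_ids.txt").write_text("\n".join(corpus.doc_ids) + "\n")
    meta = {"min_df": corpus.min_df, "doc_freq": corpus.doc_freq.tolist()}
    (out / "corpus.json").write_text(json.dumps(meta, sort_keys=True))


def load_corpus(out_dir: str | Path) -> CorpusMatrix:
    out = Path(out_dir)
    counts = sp.csr_matrix(scipy.io.mmread(out / "counts.mtx"), dtype=np.int64)
    meta = json.loads((out / "corpus.json").read_text())
    return CorpusMatrix(
        doc_ids=(out / "doc_ids.txt").read_text().splitlines(),
        vocabulary=(out / "vocabulary.txt").read_text().splitlines(),
        counts=counts,
        doc_freq=np.asarray(meta["doc_freq"], dtype=np.int64),
        min_df=int(meta["min_df"]),
    )
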