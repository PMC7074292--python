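"""Choose the k-mer length by cumulative relative entropy (CRE).

For each word length ``j`` a genome's observed j-mer frequencies are compared
against a second-order Markov extrapolation built from its own (j-1)- and
(j-2)-mer frequencies:

    expected(n1..nj) = f(n1..n_{j-1}) * f(n2..nj) / f(n2..n_{j-1})

The relative entropy RE_j is the Kullback-Leibler divergence (base 2) of the
observed distribution from that expectation — the information a length-j word
adds beyond what shorter words predict.  CRE(k) = sum_{j>=k} RE_j; the working
k is the smallest one at which CRE drops below a threshold for every genome,
i.e. where longer words stop paying for their exponential cost.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeDocument
from .kmer_corpus import window_code_counts

#: Exact in-memory counting horizon for the CRE tail sum.
DEFAULT_K_MAX = 16

#: CRE threshold (bits) below which word length k is considered sufficient.
DEFAULT_THRESHOLD = 0.1


@dataclass
class CREProfile:
    """Per-genome relative entropies RE_j and tail sums CRE(k) over [k_min, k_max]."""

    doc_id: str
    k_min: int
    k_max: int
    re: dict[int, float]
    cre: dict[int, float]


def markov_expected(
    freq_km1: Mapping[str, float],
    freq_km2: Mapping[str, float],
    kmers: Iterable[str],
) -> dict[str, float]:
    """Second-order Markov expectation for each k-mer from (k-1)/(k-2)-mer frequencies.

    Words whose required sub-words are absent get expectation 0.
    """
    expected: dict[str, float] = {}
    for w in kmers:
        k = len(w)
        if k < 3:
            raise ValueError(f"no second-order estimate exists for k={k} < 3")
        prefix, suffix, middle = w[:-1], w[1:], w[1:-1]
        mid = freq_km2.get(middle, 0.0)
        if mid == 0.0:
            expected[w] = 0.0
        else:
            expected[w] = freq_km1.get(prefix, 0.0) * freq_km1.get(suffix, 0.0) / mid
    return expected


def relative_entropy(
    observed: Mapping[str, float], expected: Mapping[str, float]
) -> float:
    """KL divergence (bits) of observed from expected over their common support."""
    total = 0.0
    support = 0
    for w, o in observed.items():
        if o <= 0.0:
            continue
        e = expected.get(w, 0.0)
        if e <= 0.0:
            continue
        support += 1
        total += o * math.log2(o / e)
    if support == 0:
        raise ValueError("observed and expected share no support")
    return total


def _re_from_codes(
    counts_j: tuple[np.ndarray, np.ndarray, int],
    counts_p: tuple[np.ndarray, np.ndarray, int],
    counts_m: tuple[np.ndarray, np.ndarray, int],
    j: int,
) -> float:
    """RE_j on packed codes; the expected distribution is renormalized over the
    observed support so Gibbs' inequality guarantees a non-negative value."""
    codes, cnt, _ = counts_j
    codes_p, cnt_p, _ = counts_p
    codes_m, cnt_m, _ = counts_m
    o = cnt / cnt.sum()
    fp = cnt_p / cnt_p.sum()
    fm = cnt_m / cnt_m.sum()
    mask_p = (1 << (2 * (j - 1))) - 1
    prefix = codes >> 2
    suffix = codes & mask_p
    middle = suffix >> 2
    # every sub-window of a valid window is itself valid, so lookups always hit
    ip = np.searchsorted(codes_p, prefix)
    isuf = np.searchsorted(codes_p, suffix)
    im = np.searchsorted(codes_m, middle)
    e = fp[ip] * fp[isuf] / fm[im]
    e /= e.sum()
    return max(float(np.sum(o * np.log2(o / e))), 0.0)


def cre_profile(
    doc: GenomeDocument | str,
    k_min: int = 3,
    k_max: int = DEFAULT_K_MAX,
) -> CREProfile:
    """Relative-entropy profile of one genome over word lengths [k_min, k_max]."""
    if not 3 <= k_min <= k_max:
        raise ValueError(f"need 3 <= k_min <= k_max, got [{k_min}, {k_max}]")
    if isinstance(doc, str):
        sequence, doc_id, length_bp = doc, "", len(doc)
    else:
        sequence, doc_id, length_bp = doc.sequence, doc.doc_id, doc.length_bp
    if length_bp < k_max:
        raise ValueError(f"genome length {length_bp} shorter than k_max={k_max}")
    counts = {j: window_code_counts(sequence, j) for j in range(k_min - 2, k_max + 1)}
    re = {
        j: _re_from_codes(counts[j], counts[j - 1], counts[j - 2], j)
        for j in range(k_min, k_max + 1)
    }
    cre: dict[int, float] = {}
    tail = 0.0
    for j in range(k_max, k_min - 1, -1):
        tail += re[j]
        cre[j] = tail
    return CREProfile(doc_id=doc_id, k_min=k_min, k_max=k_max, re=re, cre=dict(sorted(cre.items())))


def select_k(
    profiles: Sequence[CREProfile], threshold: float = DEFAULT_THRESHOLD
) -> int:
    """Smallest k with CRE(k) below threshold for every genome."""
    if not profiles:
        raise ValueError("no CRE profiles supplied")
    ranges = {(p.k_min, p.k_max) for p in profiles}
    if len(ranges) != 1:
        raise ValueError(f"profiles span different k ranges: {sorted(ranges)}")
    k_min, k_max = ranges.pop()
    for k in range(k_min, k_max + 1):
        if all(p.cre[k] < threshold for p in profiles):
            return k
    raise ValueError(
        f"no k in [{k_min}, {k_max}] has CRE below {threshold} for all genomes; "
        "raise k_max and retry"
    )


def profiles_to_frame(profiles: Sequence[CREProfile]) -> pd.DataFrame:
    """Tidy table (doc_id, j, re, cre) for export and box-plotting."""
    rows = [
        {"doc_id": p.doc_id, "j": j, "re": p.re[j], "cre": p.cre[j]}
        for p in profiles
        for j in range(p.k_min, p.k_max + 1)
    ]
    return pd.DataFrame(rows, columns=["doc_id", "j", "re", "cre"])
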