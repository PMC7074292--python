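"""Genome input/output: FASTA records, manifests, and normalized documents.

A *document* is one genome: the whole nucleotide sequence of an organism,
uppercased, with multi-record inputs (chromosome + plasmids, draft contigs)
joined by a single separator character that no k-mer window may span.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Uppercase IUPAC nucleotide one-letter codes (including U for RNA input).
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

#: Joins records of a multi-record genome; outside the IUPAC alphabet so that
#: k-mer extraction can never produce a word spanning two records.
RECORD_SEPARATOR = "-"

MANIFEST_COLUMNS = ("accession", "family", "organism", "path")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


@dataclass(frozen=True)
class GenomeDocument:
    """One genome treated as a document.

    ``sequence`` holds only uppercase IUPAC codes plus :data:`RECORD_SEPARATOR`
    characters at record joins; ``length_bp`` counts nucleotides only.
    """

    doc_id: str
    accession: str
    organism: str
    family: str
    sequence: str
    length_bp: int

    def __post_init__(self) -> None:
        n_sep = self.sequence.count(RECORD_SEPARATOR)
        if self.length_bp != len(self.sequence) - n_sep:
            raise ValueError(
                f"length_bp={self.length_bp} does not match sequence "
                f"({len(self.sequence)} chars, {n_sep} separators)"
            )
        bad = set(self.sequence) - IUPAC_CODES - {RECORD_SEPARATOR}
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into ``(record_id, sequence)`` pairs.

    Sequences are uppercased and stripped of whitespace; record order is
    preserved.  An empty file yields an empty list.  A sequence line appearing
    before any ``>`` header raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: sequence data before any FASTA header at line {lineno}"
                )
            break
    with _open_text(path) as fh:
        return [
            (rec.id, "".join(str(rec.seq).split()).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(
    entries: Iterable[tuple[str, str]] | Iterable[GenomeDocument],
    path: str | Path,
    width: int = 70,
) -> None:
    """Write ``(id, sequence)`` pairs or :class:`GenomeDocument` s to FASTA."""
    with open(path, "w") as fh:
        for entry in entries:
            if isinstance(entry, GenomeDocument):
                name, seq = entry.doc_id, entry.sequence
            else:
                name, seq = entry
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_document(
    records: Sequence[tuple[str, str]],
    manifest_row: Mapping[str, str],
) -> GenomeDocument:
    """Assemble one :class:`GenomeDocument` from FASTA records and a manifest row.

    Multiple records are joined with :data:`RECORD_SEPARATOR` so that no k-mer
    window spans a record boundary; ``length_bp`` excludes the separators.
    """
    if not records:
        raise ValueError("no FASTA records supplied")
    parts = []
    for _, seq in records:
        seq = "".join(seq.split()).upper()
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ValueError(f"non-IUPAC characters in record: {sorted(bad)!r}")
        parts.append(seq)
    sequence = RECORD_SEPARATOR.join(parts)
    length_bp = sum(len(p) for p in parts)
    if length_bp == 0:
        raise ValueError("empty sequence after normalization")
    accession = str(manifest_row.get("accession", ""))
    return GenomeDocument(
        doc_id=str(manifest_row.get("doc_id", accession) or accession),
        accession=accession,
        organism=str(manifest_row.get("organism", "")),
        family=str(manifest_row.get("family", "")),
        sequence=sequence,
        length_bp=length_bp,
    )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load a TSV/CSV manifest with columns accession, family, organism, path."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    if df["accession"].duplicated().any():
        dup = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"duplicate accessions in manifest: {dup}")
    if (df["family"].str.len() == 0).any():
        raise ValueError("manifest has rows with empty family labels")
    return df


def load_documents(
    manifest: pd.DataFrame | str | Path,
    base_dir: str | Path | None = None,
) -> list[GenomeDocument]:
    """Read every genome listed in a manifest into :class:`GenomeDocument` s."""
    if not isinstance(manifest, pd.DataFrame):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = load_manifest(manifest)
    base = Path(base_dir) if base_dir is not None else Path(".")
    docs = []
    for _, row in manifest.iterrows():
        fasta_path = Path(row["path"])
        if not fasta_path.is_absolute():
            fasta_path = base / fasta_path
        docs.append(make_document(read_fasta(fasta_path), row))
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate doc_ids in document collection")
    return docs
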