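"""Reading, writing and assembly of barcode datasets.

A dataset couples an alignment of COI-style barcode sequences (one record
per specimen) with a four-rank taxonomy (species, genus, family, order).
Sequences are stored upper-case over the IUPAC nucleotide alphabet plus the
gap symbol ``-``; shorter sequences are right-padded with ``-`` so that all
records share one coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide one-letter codes accepted in input sequences.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN-")

#: Canonical unambiguous bases.
CANONICAL_BASES = "ACGT"

TAXONOMY_RANKS = ("species", "genus", "family", "order")

# integer encoding used by the distance layer: A=0 C=1 G=2 T=3, everything
# else (gaps, N, IUPAC ambiguity codes) = 4 ("missing")
_ENCODING = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(CANONICAL_BASES):
    _ENCODING[ord(_b)] = _i
MISSING_CODE = 4


class BarcodeIOError(ValueError):
    """Raised for malformed sequence or taxonomy input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen: an aligned barcode sequence plus taxonomic labels."""

    specimen_id: str
    sequence: str
    species: str
    genus: str
    family: str
    order: str

    def __post_init__(self):
        if not self.specimen_id:
            raise BarcodeIOError("specimen_id must be non-empty")
        if not self.sequence:
            raise BarcodeIOError(f"empty sequence for specimen {self.specimen_id!r}")
        for rank in TAXONOMY_RANKS:
            if not getattr(self, rank):
                raise BarcodeIOError(
                    f"missing {rank} label for specimen {self.specimen_id!r}"
                )


@dataclass
class Dataset:
    """Ordered collection of :class:`SequenceRecord` on one alignment frame."""

    records: list[SequenceRecord]
    alignment_length: int

    def __post_init__(self):
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BarcodeIOError(f"duplicate specimen ids: {', '.join(dupes)}")
        for r in self.records:
            if len(r.sequence) != self.alignment_length:
                raise BarcodeIOError(
                    f"record {r.specimen_id!r} has length {len(r.sequence)}, "
                    f"expected {self.alignment_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def taxonomy_frame(self) -> pd.DataFrame:
        """Taxonomy table indexed by specimen id."""
        return pd.DataFrame(
            {rank: [getattr(r, rank) for r in self.records] for rank in TAXONOMY_RANKS},
            index=pd.Index(self.ids, name="specimen_id"),
        )

    def encoded(self) -> np.ndarray:
        """(n_records, alignment_length) uint8 array; A,C,G,T -> 0..3, other -> 4."""
        buf = np.frombuffer(
            "".join(r.sequence for r in self.records).encode("ascii"), dtype=np.uint8
        )
        return _ENCODING[buf].reshape(len(self.records), self.alignment_length)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(specimen_id, sequence)`` pairs.

    The id is the header token up to the first whitespace; sequences are
    upper-cased. Duplicate ids, empty files and non-IUPAC symbols raise
    :class:`BarcodeIOError`.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        seq = str(rec.seq).upper()
        if sid in seen:
            raise BarcodeIOError(f"duplicate FASTA id: {sid!r}")
        seen.add(sid)
        bad = sorted(set(seq) - IUPAC_NUCLEOTIDES)
        if bad:
            raise BarcodeIOError(
                f"non-IUPAC symbols in record {sid!r}: {', '.join(bad)}"
            )
        entries.append((sid, seq))
    if not entries:
        raise BarcodeIOError(f"no FASTA records found in {path}")
    return entries


def write_fasta(dataset: Dataset, path: str | Path) -> None:
    """Write dataset sequences as FASTA, one record per specimen."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in dataset.records
    ]
    SeqIO.write(records, str(path), "fasta")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated taxonomy table keyed by ``specimen_id``.

    Requires header columns ``specimen_id``, ``species``, ``genus``,
    ``family`` and ``order``; extra columns are preserved as opaque
    metadata. All four rank fields must be non-empty.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("specimen_id",) + TAXONOMY_RANKS if c not in table.columns]
    if missing:
        raise BarcodeIOError(f"taxonomy table missing column(s): {', '.join(missing)}")
    if table["specimen_id"].duplicated().any():
        dupes = sorted(table.loc[table["specimen_id"].duplicated(), "specimen_id"])
        raise BarcodeIOError(f"duplicate specimen_id in taxonomy: {', '.join(dupes)}")
    for rank in TAXONOMY_RANKS:
        empty = table.loc[table[rank].str.strip() == "", "specimen_id"]
        if len(empty):
            raise BarcodeIOError(
                f"empty {rank} label for specimen(s): {', '.join(empty)}"
            )
    return table.set_index("specimen_id")


def write_taxonomy(dataset: Dataset, path: str | Path) -> None:
    dataset.taxonomy_frame().to_csv(path, sep="\t")


def assemble_dataset(
    seqs: Iterable[tuple[str, str]],
    taxonomy: pd.DataFrame,
    strict: bool = True,
) -> Dataset:
    """Join sequences with taxonomy into a :class:`Dataset`.

    The alignment length is the maximum sequence length; shorter sequences
    are right-padded with ``-`` (missing data). Records are ordered by
    specimen id. In strict mode (default) any id mismatch between the two
    inputs is an error; otherwise unmatched sequences are dropped.
    """
    seqs = list(seqs)
    seq_ids = {sid for sid, _ in seqs}
    tax_ids = set(taxonomy.index)
    only_seq = sorted(seq_ids - tax_ids)
    only_tax = sorted(tax_ids - seq_ids)
    if strict and (only_seq or only_tax):
        parts = []
        if only_seq:
            parts.append(f"ids missing from taxonomy: {', '.join(only_seq)}")
        if only_tax:
            parts.append(f"ids missing from FASTA: {', '.join(only_tax)}")
        raise BarcodeIOError("; ".join(parts))
    keep = sorted(seq_ids & tax_ids) if not strict else sorted(seq_ids)
    if len(keep) == 0:
        raise BarcodeIOError("no specimens shared between sequences and taxonomy")
    length = max(len(s) for sid, s in seqs if sid in set(keep))
    by_id = {sid: s for sid, s in seqs}
    records = []
    for sid in keep:
        seq = by_id[sid].ljust(length, "-")
        row = taxonomy.loc[sid]
        records.append(
            SequenceRecord(
                specimen_id=sid,
                sequence=seq,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                order=row["order"],
            )
        )
    return Dataset(records=records, alignment_length=length)


def load_dataset(
    fasta_path: str | Path, taxonomy_path: str | Path, strict: bool = True
) -> Dataset:
    """Convenience: :func:`read_fasta` + :func:`read_taxonomy` + assembly."""
    return assemble_dataset(
        read_fasta(fasta_path), read_taxonomy(taxonomy_path), strict=strict
    )
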