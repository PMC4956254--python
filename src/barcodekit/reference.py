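"""Retrieval of a published reference library from GenBank.

Builds an analysis-ready dataset from a run of GenBank nucleotide
accessions: fetches the records over NCBI E-utilities, derives the
taxonomy (species and genus from the organism name; family and order from
the lineage string), aligns the sequences with MAFFT when lengths differ,
and assembles the standard :class:`~barcodekit.io.Dataset`.

Network access is required; offline environments cannot use this module.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd
from Bio import Entrez, SeqIO

from .io import Dataset, assemble_dataset

#: GenBank accession span of the Lower Paraná River COI reference library.
DEFAULT_ACCESSION_RANGE = ("KU288760", "KU289067")

Entrez.email = "barcodekit@example.org"
Entrez.tool = "barcodekit"


def accession_range(first: str, last: str) -> list[str]:
    """Expand an inclusive accession run sharing one alphabetic prefix."""
    prefix = first.rstrip("0123456789")
    if last.rstrip("0123456789") != prefix:
        raise ValueError("accession range must share a prefix")
    lo, hi = int(first[len(prefix):]), int(last[len(prefix):])
    width = len(first) - len(prefix)
    return [f"{prefix}{k:0{width}d}" for k in range(lo, hi + 1)]


def _rank_from_lineage(lineage: list[str], suffix: str) -> str:
    for name in lineage:
        if name.endswith(suffix):
            return name
    return "unknown"


def fetch_genbank_records(
    accessions: list[str], batch_size: int = 200, timeout: float = 60.0
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Fetch sequences + taxonomy for the given accessions.

    Returns ``(seqs, taxonomy)`` in the shapes :func:`assemble_dataset`
    expects. Species is the organism binomial; genus its first word;
    family and order are read from the lineage (-idae / -iformes names).
    """
    import socket

    socket.setdefaulttimeout(timeout)
    seqs: list[tuple[str, str]] = []
    rows = []
    for start in range(0, len(accessions), batch_size):
        chunk = accessions[start : start + batch_size]
        with Entrez.efetch(
            db="nuccore", id=",".join(chunk), rettype="gb", retmode="text"
        ) as handle:
            for rec in SeqIO.parse(handle, "genbank"):
                organism = rec.annotations.get("organism", "unknown unknown")
                lineage = rec.annotations.get("taxonomy", [])
                seqs.append((rec.name, str(rec.seq).upper()))
                rows.append(
                    {
                        "specimen_id": rec.name,
                        "species": organism,
                        "genus": organism.split()[0],
                        "family": _rank_from_lineage(lineage, "idae"),
                        "order": _rank_from_lineage(lineage, "iformes"),
                    }
                )
    taxonomy = pd.DataFrame(rows).set_index("specimen_id")
    return seqs, taxonomy


def align_with_mafft(seqs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Multiple-align sequences with MAFFT (required on PATH)."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        with open(infile, "w") as fh:
            for sid, seq in seqs:
                fh.write(f">{sid}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = []
        sid = None
        chunks: list[str] = []
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                if sid is not None:
                    out.append((sid, "".join(chunks).upper()))
                sid = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.strip())
        if sid is not None:
            out.append((sid, "".join(chunks).upper()))
    return out


def fetch_reference_dataset(
    first: str = DEFAULT_ACCESSION_RANGE[0],
    last: str = DEFAULT_ACCESSION_RANGE[1],
) -> Dataset:
    """Download, align and assemble a GenBank accession run as a Dataset."""
    accessions = accession_range(first, last)
    seqs, taxonomy = fetch_genbank_records(accessions)
    lengths = {len(s) for _, s in seqs}
    if len(lengths) > 1:
        seqs = align_with_mafft(seqs)
    return assemble_dataset(seqs, taxonomy)
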