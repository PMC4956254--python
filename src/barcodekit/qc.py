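"""Barcode quality control: stop-codon screening and composition.

Putative COI barcodes from vertebrate mitochondria must translate without
internal stop codons; stops (or frame-shifting indels) are the classic
signature of NUMT co-amplification. The reading frame of an amplicon is
auto-detected as the forward frame with the fewest internal stops under the
vertebrate mitochondrial genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .io import CANONICAL_BASES, Dataset, SequenceRecord

#: NCBI translation table 2, "Vertebrate Mitochondrial" (AGA/AGG are stops).
VERTEBRATE_MITO = CodonTable.unambiguous_dna_by_id[2]
_STOP_CODONS = frozenset(VERTEBRATE_MITO.stop_codons)


@dataclass(frozen=True)
class QCResult:
    """Outcome of the stop-codon / ambiguity screen for one specimen."""

    specimen_id: str
    has_stop_codon: bool
    frame_used: int  # 1, 2 or 3
    ambiguous_fraction: float
    length: int  # ungapped length
    length_deviates: bool  # differs from the configured expected length
    passed: bool


def _count_stops(ungapped: str, frame: int) -> int:
    """Internal stop codons of ``ungapped`` read in forward frame 1-3.

    Codons containing ambiguity codes never count as stops; the terminal
    codon is excluded (a trailing stop is legitimate).
    """
    sub = ungapped[frame - 1 :]
    n_codons = len(sub) // 3
    stops = 0
    for k in range(n_codons - 1):  # skip the final (possibly terminal) codon
        if sub[3 * k : 3 * k + 3] in _STOP_CODONS:
            stops += 1
    return stops


def qc_check(
    record: SequenceRecord,
    max_ambiguous: float = 0.01,
    expected_length: int | None = 648,
) -> QCResult:
    """Screen one record for stop codons and ambiguous content.

    The ungapped sequence is read in all three forward frames under the
    vertebrate mitochondrial code; ``frame_used`` is the frame with fewest
    internal stops (ties favour the lowest frame). ``has_stop_codon`` is
    true when even the best frame retains a stop. ``ambiguous_fraction``
    counts non-ACGT symbols over the ungapped length. A deviation from
    ``expected_length`` (a proxy for insertions/deletions relative to the
    expected amplicon) is flagged but does not fail the record.
    """
    ungapped = record.sequence.replace("-", "")
    if not ungapped:
        raise ValueError(f"record {record.specimen_id!r} is all gaps")
    stops = [_count_stops(ungapped, f) for f in (1, 2, 3)]
    frame_used = int(np.argmin(stops)) + 1
    has_stop = stops[frame_used - 1] > 0
    n_ambig = sum(1 for b in ungapped if b not in CANONICAL_BASES)
    ambiguous_fraction = n_ambig / len(ungapped)
    deviates = expected_length is not None and len(ungapped) != expected_length
    return QCResult(
        specimen_id=record.specimen_id,
        has_stop_codon=has_stop,
        frame_used=frame_used,
        ambiguous_fraction=ambiguous_fraction,
        length=len(ungapped),
        length_deviates=deviates,
        passed=(not has_stop) and ambiguous_fraction <= max_ambiguous,
    )


def qc_dataset(
    dataset: Dataset,
    max_ambiguous: float = 0.01,
    expected_length: int | None = 648,
) -> list[QCResult]:
    return [qc_check(r, max_ambiguous, expected_length) for r in dataset.records]


def composition(dataset: Dataset) -> dict[str, float]:
    """Pooled A/C/G/T proportions over all records.

    Gaps and ambiguity codes are ignored. Proportions sum to 1.
    """
    enc = dataset.encoded()
    counts = np.bincount(enc[enc < 4].ravel(), minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("dataset contains no unambiguous bases")
    freqs = counts / total
    return dict(zip(CANONICAL_BASES, freqs.tolist()))
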