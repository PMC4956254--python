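"""Taxonomy vs OTU concordance auditing and haplotype sharing.

Given an OTU partition of the specimens and their taxonomy, each OTU is
audited the way barcode-database discordance reports do: an OTU is
*concordant* when all of its (>= 2) records carry one species name,
*discordant* when it mixes species, and a *singleton* when it holds a
single record. Symmetrically each species is a *match* (one OTU, not
shared), a *split* (spread over >= 2 OTUs) or *merged* (shares its OTU
with another species). The audit is local to the supplied records —
optionally extended with externally labelled sequences — it does not query
any remote database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CANONICAL_BASES, Dataset
from .otu import Partition


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0**decimals
    return float(np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor)


@dataclass
class ConcordanceReport:
    per_otu: pd.DataFrame  # otu_label, n_records, n_species, status
    per_species: pd.DataFrame  # species, n_otus, status
    summary: dict  # counts + percentages by OTU status

    @property
    def percent_concordant(self) -> float:
        return self.summary["percent"]["concordant"]


def concordance_report(partition: Partition, taxonomy: pd.DataFrame) -> ConcordanceReport:
    """Audit agreement between an OTU partition and the taxonomy.

    ``partition`` must cover every specimen in ``taxonomy``. Summary
    percentages are 100 * count / total OTUs, rounded half away from zero
    to one decimal.
    """
    missing = set(taxonomy.index) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition missing specimens: {sorted(missing)[:5]}")
    species_of = taxonomy["species"]
    otu_rows = []
    for label, members in partition.groups().items():
        sp = sorted({species_of[m] for m in members})
        if len(members) == 1:
            status = "singleton"
        elif len(sp) >= 2:
            status = "discordant"
        else:
            status = "concordant"
        otu_rows.append(
            {
                "otu_label": label,
                "n_records": len(members),
                "n_species": len(sp),
                "species": ";".join(sp),
                "status": status,
            }
        )
    per_otu = pd.DataFrame(otu_rows).set_index("otu_label")

    otu_of = partition.assignment
    shared_otus = set(per_otu.index[per_otu["n_species"] >= 2])
    sp_rows = []
    for sp in sorted(set(species_of)):
        members = [i for i in taxonomy.index if species_of[i] == sp]
        otus = sorted({otu_of[m] for m in members})
        if len(otus) >= 2:
            status = "split"
        elif otus[0] in shared_otus:
            status = "merged"
        else:
            status = "match"
        sp_rows.append({"species": sp, "n_otus": len(otus), "status": status})
    per_species = pd.DataFrame(sp_rows).set_index("species")

    counts = {
        s: int((per_otu["status"] == s).sum())
        for s in ("concordant", "discordant", "singleton")
    }
    summary = {
        "n_otus": len(per_otu),
        "n_records": int(per_otu["n_records"].sum()),
        "counts": counts,
        "records_by_status": {
            s: int(per_otu.loc[per_otu["status"] == s, "n_records"].sum())
            for s in counts
        },
        "percent": summary_percentages(counts),
    }
    return ConcordanceReport(per_otu=per_otu, per_species=per_species, summary=summary)


def summary_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percentages of a status count table, to one decimal (half away from zero)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty count table")
    return {k: round_half_away(100.0 * v / total, 1) for k, v in counts.items()}


@dataclass
class HaplotypeTable:
    """Partition of the records into identical-sequence classes."""

    table: pd.DataFrame  # haplotype_id, representative_id, members, species

    @property
    def n_haplotypes(self) -> int:
        return len(self.table)

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["members"] = out["members"].map(";".join)
        out["species"] = out["species"].map(";".join)
        out.to_csv(path, sep="\t", index=False)


def collapse_haplotypes(dataset: Dataset, mode: str = "tolerant") -> HaplotypeTable:
    """Group records into haplotypes.

    ``tolerant`` (default): two records share a haplotype when their
    sequences agree at every site where both are unambiguous A/C/G/T —
    terminal gaps or Ns do not separate otherwise identical sequences.
    Compatibility is not transitive, so groups are the connected
    components of the pairwise-compatibility graph. ``strict``: exact
    string identity.
    """
    n = len(dataset)
    if mode == "strict":
        labels: dict[str, int] = {}
        comp = []
        for r in dataset.records:
            if r.sequence not in labels:
                labels[r.sequence] = len(labels)
            comp.append(labels[r.sequence])
    elif mode == "tolerant":
        enc = dataset.encoded()
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                both = (enc[i] < 4) & (enc[j] < 4)
                if not (enc[i][both] != enc[j][both]).any():
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comp = [find(i) for i in range(n)]
    else:
        raise ValueError(f"unknown haplotype mode: {mode!r}")

    groups: dict[int, list[int]] = {}
    for k, c in enumerate(comp):
        groups.setdefault(c, []).append(k)
    rows = []
    for h, idxs in enumerate(
        sorted(groups.values(), key=lambda g: dataset.records[g[0]].specimen_id)
    ):
        members = [dataset.records[k].specimen_id for k in idxs]
        species = sorted({dataset.records[k].species for k in idxs})
        rows.append(
            {
                "haplotype_id": f"H{h + 1}",
                "representative_id": members[0],
                "members": members,
                "species": species,
            }
        )
    return HaplotypeTable(table=pd.DataFrame(rows))


def shared_haplotypes(haplotypes: HaplotypeTable) -> pd.DataFrame:
    """Unordered species pairs sharing >= 1 haplotype, with shared counts."""
    pair_counts: dict[tuple[str, str], int] = {}
    for species in haplotypes.table["species"]:
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                key = (species[i], species[j])
                pair_counts[key] = pair_counts.get(key, 0) + 1
    rows = [
        {"species_a": a, "species_b": b, "n_shared_haplotypes": c}
        for (a, b), c in sorted(pair_counts.items())
    ]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "n_shared_haplotypes"])


def diagnostic_characters(
    dataset: Dataset, species_a: str, species_b: str
) -> list[int]:
    """Alignment columns (1-based) diagnostic between two species.

    A column qualifies when every member of each species carries one
    unambiguous state, the two states differ, and no member of either
    species is ambiguous there (any N or gap disqualifies the column).
    """
    idx_a = [k for k, r in enumerate(dataset.records) if r.species == species_a]
    idx_b = [k for k, r in enumerate(dataset.records) if r.species == species_b]
    if not idx_a or not idx_b:
        raise ValueError("both species need at least one record")
    enc = dataset.encoded()
    a = enc[idx_a]
    b = enc[idx_b]
    ok_a = (a < 4).all(axis=0) & (a == a[0]).all(axis=0)
    ok_b = (b < 4).all(axis=0) & (b == b[0]).all(axis=0)
    diag = ok_a & ok_b & (a[0] != b[0])
    return [int(c) + 1 for c in np.flatnonzero(diag)]
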