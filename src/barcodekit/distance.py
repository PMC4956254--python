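"""Kimura two-parameter (K2P) distances and divergence summaries.

The K2P model separates transitions (A<->G, C<->T) from transversions.
With transition proportion P and transversion proportion Q over the L
sites comparable in a pair, the distance in substitutions/site is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

which is undefined (saturated) when 1 - 2P - Q <= 0 or 1 - 2Q <= 0.
Distances are held internally in substitutions/site; summary tables are
reported in percent, the convention of barcode reference libraries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING_CODE, Dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteComparison:
    """Transition/transversion proportions over the comparable sites of a pair."""

    P: float  # transition proportion
    Q: float  # transversion proportion
    L: int  # number of sites where both sequences are unambiguous

    @property
    def p_distance(self) -> float:
        return self.P + self.Q


class SaturatedPairError(ValueError):
    """K2P distance undefined: divergence beyond the model's valid region."""


def count_differences(seq_a, seq_b) -> SiteComparison | None:
    """Compare two equal-length sequences site by site (pairwise deletion).

    Only sites where both symbols are unambiguous A/C/G/T are compared;
    gaps, N and IUPAC ambiguity codes are excluded pair by pair. Returns
    ``None`` when no site is comparable.

    Accepts strings or uint8-encoded arrays (A,C,G,T -> 0..3, other -> 4).
    """
    a = _as_codes(seq_a)
    b = _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    valid = (a < MISSING_CODE) & (b < MISSING_CODE)
    L = int(valid.sum())
    if L == 0:
        return None
    diff = valid & (a != b)
    # purines (A=0, G=2) are even codes, pyrimidines (C=1, T=3) odd:
    # a mismatch within one parity class is a transition
    transitions = int((diff & ((a & 1) == (b & 1))).sum())
    transversions = int(diff.sum()) - transitions
    return SiteComparison(P=transitions / L, Q=transversions / L, L=L)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    from .io import _ENCODING

    return _ENCODING[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def k2p_distance(c: SiteComparison) -> float:
    """Closed-form K2P distance for one site comparison.

    Raises :class:`SaturatedPairError` outside the model's valid region.
    """
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedPairError(
            f"saturated comparison (P={c.P:.4f}, Q={c.Q:.4f})"
        )
    return max(0.0, -0.5 * math.log(w1) - 0.25 * math.log(w2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over specimen ids.

    ``values`` is an (n, n) float array in substitutions/site with zeros on
    the diagonal; undefined pairs (no comparable sites, or saturation) are
    NaN and listed in ``undefined_pairs``.
    """

    ids: list[str]
    values: np.ndarray
    model: str = "K2P"
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return bool(np.isnan(self.values[off]).any())

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index_of(id_a), self.index_of(id_b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy's condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        sub = self.values[np.ix_(idx, idx)].copy()
        return DistanceMatrix(ids=list(ids), values=sub, model=self.model)

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        vals = self.values * 100.0 if percent else self.values
        return pd.DataFrame(vals, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path, percent: bool = False) -> None:
        frame = self.to_frame(percent=percent)
        unit = "percent" if percent else "substitutions/site"
        with open(path, "w") as fh:
            fh.write(f"# model={self.model} unit={unit}\n")
            frame.to_csv(fh, sep="\t", index_label="specimen_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        model = "K2P"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("model="):
                        model = tok.split("=", 1)[1]
            else:
                fh.seek(0)
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(ids=list(frame.index), values=frame.to_numpy(float), model=model)

    def write_phylip(self, path: str | Path) -> None:
        """Lower-triangle PHYLIP-style matrix (substitutions/site)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{self.values[i, j]:.8f}" for j in range(i))
                fh.write(f"{sid}\t{row}\n" if row else f"{sid}\n")


def distance_matrix(dataset: Dataset, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P distance matrix for a dataset.

    ``deletion`` selects the missing-data rule: ``"pairwise"`` drops
    non-ACGT sites pair by pair; ``"complete"`` first removes every
    alignment column containing any non-ACGT symbol. Undefined pairs are
    stored as NaN, never dropped silently.
    """
    if len(dataset) < 2:
        raise ValueError("distance analysis needs at least 2 records")
    enc = dataset.encoded()
    if deletion == "complete":
        keep = (enc < MISSING_CODE).all(axis=0)
        enc = enc[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode: {deletion!r}")
    n = len(dataset)
    vals = np.zeros((n, n), dtype=float)
    undefined: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        comp = count_differences(enc[i], enc[j])
        try:
            d = k2p_distance(comp) if comp is not None else math.nan
        except SaturatedPairError:
            d = math.nan
        if math.isnan(d):
            undefined.append((dataset.ids[i], dataset.ids[j]))
        vals[i, j] = vals[j, i] = d
    if undefined:
        logger.warning(
            "%d undefined distance pair(s): %s", len(undefined), undefined[:10]
        )
    return DistanceMatrix(
        ids=dataset.ids, values=vals, model="K2P", undefined_pairs=undefined
    )


@dataclass(frozen=True)
class TaxonSummary:
    """Min/mean/max pairwise divergence (percent) at one taxonomic rank."""

    rank: str
    n_comparisons: int
    min: float
    mean: float
    max: float
    se: float  # sd of pair distances / sqrt(n), in percent


def _pair_distances_at_rank(
    dm: DistanceMatrix, taxonomy: pd.DataFrame, rank: str
) -> np.ndarray:
    """Percent distances of the pair set defining one rank comparison.

    species: conspecific pairs; genus: congeneric heterospecific pairs;
    family: confamilial pairs from different genera. Excluding the lower
    rank keeps the comparison sets disjoint.
    """
    tax = taxonomy.loc[dm.ids]
    species = tax["species"].to_numpy()
    genus = tax["genus"].to_numpy()
    family = tax["family"].to_numpy()
    iu, ju = np.triu_indices(len(dm.ids), k=1)
    same_sp = species[iu] == species[ju]
    same_gen = genus[iu] == genus[ju]
    same_fam = family[iu] == family[ju]
    if rank == "species":
        mask = same_sp
    elif rank == "genus":
        mask = same_gen & ~same_sp
    elif rank == "family":
        mask = same_fam & ~same_gen
    else:
        raise ValueError(f"unknown rank: {rank!r}")
    d = dm.values[iu, ju][mask]
    return d[~np.isnan(d)] * 100.0


def summarize_by_rank(
    dm: DistanceMatrix, taxonomy: pd.DataFrame, rank: str
) -> TaxonSummary:
    """Divergence summary (percent) at ``rank``: species, genus or family."""
    d = _pair_distances_at_rank(dm, taxonomy, rank)
    if d.size == 0:
        raise ValueError(f"no qualifying comparison at rank {rank!r}")
    se = float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else 0.0
    return TaxonSummary(
        rank=rank,
        n_comparisons=int(d.size),
        min=float(d.min()),
        mean=float(d.mean()),
        max=float(d.max()),
        se=se,
    )


def summary_table(dm: DistanceMatrix, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Species/genus/family summary rows in reference-table column order."""
    rows = [summarize_by_rank(dm, taxonomy, r) for r in ("species", "genus", "family")]
    return pd.DataFrame(
        {
            "rank": [f"within_{r.rank}" for r in rows],
            "comparisons": [r.n_comparisons for r in rows],
            "min": [r.min for r in rows],
            "mean": [r.mean for r in rows],
            "max": [r.max for r in rows],
            "se": [r.se for r in rows],
        }
    )


def genus_pair_ranges(dm: DistanceMatrix, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-genus min/max interspecific distance (percent), genera with >=2 species.

    Columns: genus, n_species, min, max; one row per qualifying genus,
    sorted by genus name.
    """
    tax = taxonomy.loc[dm.ids]
    species = tax["species"].to_numpy()
    genus = tax["genus"].to_numpy()
    iu, ju = np.triu_indices(len(dm.ids), k=1)
    hetero = (species[iu] != species[ju]) & (genus[iu] == genus[ju])
    rows = []
    for g in sorted(set(genus)):
        n_sp = len(set(species[genus == g]))
        if n_sp < 2:
            continue
        mask = hetero & (genus[iu] == g)
        d = dm.values[iu, ju][mask]
        d = d[~np.isnan(d)] * 100.0
        rows.append(
            {"genus": g, "n_species": n_sp, "min": float(d.min()), "max": float(d.max())}
        )
    return pd.DataFrame(rows, columns=["genus", "n_species", "min", "max"])
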