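"""Barcoding-gap analysis.

Distance-based identification works when every species' distance to its
nearest heterospecific neighbour (NN) exceeds its own maximum intraspecific
distance. This module builds the per-species report behind that comparison
(the classic max-intra vs NN scatter) and a dataset-level summary of the
gap between the conspecific and congeneric distance distributions.

All distances reported here are percent K2P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, _pair_distances_at_rank


def _species_arrays(dm: DistanceMatrix, taxonomy: pd.DataFrame):
    tax = taxonomy.loc[dm.ids]
    return tax["species"].to_numpy(), dm.values * 100.0


def max_intraspecific(dm: DistanceMatrix, taxonomy: pd.DataFrame) -> pd.Series:
    """Per-species maximum conspecific distance (percent); NaN for singletons."""
    species, d = _species_arrays(dm, taxonomy)
    out = {}
    for sp in sorted(set(species)):
        idx = np.flatnonzero(species == sp)
        if len(idx) < 2:
            out[sp] = math.nan
            continue
        sub = d[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        out[sp] = float(np.nanmax(vals)) if not np.isnan(vals).all() else math.nan
    return pd.Series(out, name="max_intra")


def nearest_neighbor(dm: DistanceMatrix, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-species nearest-neighbour species and distance (percent).

    The NN distance is the minimum over all (conspecific, heterospecific)
    specimen pairs; ties between species break lexicographically.
    """
    species, d = _species_arrays(dm, taxonomy)
    all_species = sorted(set(species))
    if len(all_species) < 2:
        raise ValueError("nearest-neighbour analysis needs at least 2 species")
    rows = {}
    for sp in all_species:
        own = np.flatnonzero(species == sp)
        best_sp, best_d = None, math.inf
        for other in all_species:
            if other == sp:
                continue
            idx = np.flatnonzero(species == other)
            sub = d[np.ix_(own, idx)]
            if np.isnan(sub).all():
                continue
            m = float(np.nanmin(sub))
            if m < best_d or (m == best_d and (best_sp is None or other < best_sp)):
                best_sp, best_d = other, m
        rows[sp] = {"nn_species": best_sp, "nn_distance": best_d}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("species")


@dataclass
class GapSummary:
    n_species: int
    n_discriminated: int
    discrimination_percent: float
    deep_divergence_species: list[str]
    deep_divergence_threshold: float  # percent


def gap_report(
    dm: DistanceMatrix,
    taxonomy: pd.DataFrame,
    deep_threshold: float = 2.0,
) -> tuple[pd.DataFrame, GapSummary]:
    """Per-species barcoding-gap table plus a dataset-level summary.

    A species is discriminated when its NN distance strictly exceeds its
    maximum intraspecific distance (singletons count 0 intraspecific
    variation). ``deep_threshold`` (percent) flags species whose
    intraspecific divergence is suspiciously deep — candidate cryptic
    species complexes.

    The returned table is also the max-intra vs NN scatter: one row per
    species with columns n_specimens, max_intra, nn_species, nn_distance,
    discriminated, deep_divergence.
    """
    species, _ = _species_arrays(dm, taxonomy)
    mi = max_intraspecific(dm, taxonomy)
    nn = nearest_neighbor(dm, taxonomy)
    counts = pd.Series(species).value_counts()
    table = pd.DataFrame(
        {
            "n_specimens": counts.reindex(mi.index).astype(int),
            "max_intra": mi,
            "nn_species": nn["nn_species"],
            "nn_distance": nn["nn_distance"],
        }
    ).rename_axis("species")
    effective_intra = table["max_intra"].fillna(0.0)
    table["discriminated"] = table["nn_distance"] > effective_intra
    table["deep_divergence"] = effective_intra > deep_threshold
    deep = sorted(table.index[table["deep_divergence"]])
    n_disc = int(table["discriminated"].sum())
    summary = GapSummary(
        n_species=len(table),
        n_discriminated=n_disc,
        discrimination_percent=100.0 * n_disc / len(table),
        deep_divergence_species=deep,
        deep_divergence_threshold=deep_threshold,
    )
    return table, summary


@dataclass
class GlobalGap:
    conspecific: np.ndarray  # percent distances
    congeneric: np.ndarray  # percent distances
    lower: float  # max conspecific after exclusions (percent)
    upper: float  # min congeneric after exclusions (percent)
    interval: tuple[float, float] | None  # (lower, upper) when lower < upper
    overlap: bool


def global_gap_summary(
    dm: DistanceMatrix,
    taxonomy: pd.DataFrame,
    exclude_species: list[str] | None = None,
    exclude_genera: list[str] | None = None,
) -> GlobalGap:
    """Dataset-level gap between conspecific and congeneric distances.

    The interval is bounded below by the maximum conspecific distance
    (optionally excluding listed outlier species, e.g. deep-divergence
    complexes) and above by the minimum congeneric distance (optionally
    excluding listed outlier genera, e.g. recently radiated groups). The
    exclusion lists are explicit configuration, not defaults.
    """
    exclude_species = set(exclude_species or [])
    exclude_genera = set(exclude_genera or [])
    conspecific = _pair_distances_at_rank(dm, taxonomy, "species")
    congeneric = _pair_distances_at_rank(dm, taxonomy, "genus")
    if conspecific.size == 0 or congeneric.size == 0:
        raise ValueError("need both conspecific and congeneric comparisons")

    tax = taxonomy.loc[dm.ids]
    species = tax["species"].to_numpy()
    genus = tax["genus"].to_numpy()
    d = dm.values * 100.0
    iu, ju = np.triu_indices(len(dm.ids), k=1)
    same_sp = species[iu] == species[ju]
    keep_sp = same_sp & ~np.isin(species[iu], list(exclude_species))
    cons_kept = d[iu, ju][keep_sp]
    cons_kept = cons_kept[~np.isnan(cons_kept)]
    congen = (genus[iu] == genus[ju]) & ~same_sp
    keep_gen = congen & ~np.isin(genus[iu], list(exclude_genera))
    cong_kept = d[iu, ju][keep_gen]
    cong_kept = cong_kept[~np.isnan(cong_kept)]
    if cons_kept.size == 0 or cong_kept.size == 0:
        raise ValueError("exclusion lists removed all comparisons")
    lower = float(cons_kept.max())
    upper = float(cong_kept.min())
    has_gap = lower < upper
    return GlobalGap(
        conspecific=conspecific,
        congeneric=congeneric,
        lower=lower,
        upper=upper,
        interval=(lower, upper) if has_gap else None,
        overlap=not has_gap,
    )
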