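"""End-to-end reference-library build.

``run_all`` sequences the whole analysis — QC, K2P distances, rank
summaries, NJ + bootstrap, barcoding-gap report, single-linkage and
barcode-gap OTU delimitation, concordance audit and haplotype collapse —
and writes every artifact plus a machine-readable manifest. Outputs are a
pure function of (inputs, configuration, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import collapse_haplotypes, concordance_report, shared_haplotypes
from .distance import distance_matrix, genus_pair_ranges, summary_table
from .gap import gap_report, global_gap_summary
from .io import Dataset, load_dataset
from .otu import abgd_partition, partition_agreement, single_linkage_clusters
from .qc import composition, qc_dataset
from .tree import bootstrap_support, write_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    fasta: str
    taxonomy: str
    outdir: str
    deletion: str = "pairwise"  # missing-data rule for distances
    bootstrap_replicates: int = 1000
    abgd_pmin: float = 0.001
    abgd_pmax: float = 0.1
    abgd_steps: int = 20
    abgd_x: float = 1.0
    abgd_nbins: int = 20
    linkage_threshold: float = 0.022  # single-linkage OTU seed threshold
    deep_divergence_threshold: float = 0.02  # subs/site
    max_ambiguous: float = 0.01
    expected_length: int | None = 648
    haplotype_mode: str = "tolerant"
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        for name in ("linkage_threshold", "deep_divergence_threshold", "max_ambiguous"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _write_qc(results, path: Path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
    frame.to_csv(path, sep="\t", index=False)


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"barcodekit {__version__}",
        "config": dataclasses.asdict(config),
        "warnings": [],
    }

    dataset = load_dataset(config.fasta, config.taxonomy)
    taxonomy = dataset.taxonomy_frame()
    manifest["n_records"] = len(dataset)
    manifest["n_species"] = int(taxonomy["species"].nunique())

    qc = qc_dataset(dataset, config.max_ambiguous, config.expected_length)
    _write_qc(qc, out / "qc_report.tsv")
    manifest["qc"] = {
        "n_failed": sum(1 for r in qc if not r.passed),
        "n_stop_codon": sum(1 for r in qc if r.has_stop_codon),
        "composition": composition(dataset),
    }

    dm = distance_matrix(dataset, deletion=config.deletion)
    dm.write_tsv(out / "distance_matrix.tsv")
    if dm.undefined_pairs:
        manifest["warnings"].append(
            f"{len(dm.undefined_pairs)} undefined distance pair(s)"
        )

    summary = summary_table(dm, taxonomy)
    with open(out / "rank_summary.tsv", "w") as fh:
        fh.write("# K2P divergence, percent\n")
        summary.to_csv(fh, sep="\t", index=False)
    genus_ranges = genus_pair_ranges(dm, taxonomy)
    with open(out / "genus_ranges.tsv", "w") as fh:
        fh.write("# K2P divergence, percent\n")
        genus_ranges.to_csv(fh, sep="\t", index=False)
    manifest["rank_summary"] = summary.to_dict(orient="records")

    tree = bootstrap_support(
        dataset, replicates=config.bootstrap_replicates, seed=config.seed
    )
    write_newick(tree, out / "nj_tree.nwk")

    gap_table, gap_summary = gap_report(
        dm, taxonomy, deep_threshold=100.0 * config.deep_divergence_threshold
    )
    with open(out / "gap_report.tsv", "w") as fh:
        fh.write("# distances in percent\n")
        gap_table.to_csv(fh, sep="\t")
    try:
        gg = global_gap_summary(dm, taxonomy)
        gap_interval = gg.interval
    except ValueError:
        gg, gap_interval = None, None
    manifest["gap"] = {
        "discrimination_percent": gap_summary.discrimination_percent,
        "n_species": gap_summary.n_species,
        "deep_divergence_species": gap_summary.deep_divergence_species,
        "gap_interval_percent": list(gap_interval) if gap_interval else None,
    }

    linkage_part = single_linkage_clusters(dm, config.linkage_threshold)
    linkage_part.write_tsv(out / "partition_single_linkage.tsv")
    scan = abgd_partition(
        dm,
        pmin=config.abgd_pmin,
        pmax=config.abgd_pmax,
        steps=config.abgd_steps,
        x=config.abgd_x,
        nbins=config.abgd_nbins,
    )
    scan.to_json(out / "abgd_scan.json")
    with open(out / "abgd_histogram.tsv", "w") as fh:
        fh.write("# pairwise K2P distances, substitutions/site\n")
        scan.histogram.to_csv(fh, sep="\t", index=False)
    for p, part in zip(scan.priors, scan.partitions):
        part.write_tsv(out / f"abgd_partition_P{p:.6f}.tsv")
    identical, ari = partition_agreement(linkage_part, scan.partitions[0])
    manifest["otu"] = {
        "single_linkage_n_otus": linkage_part.n_otus,
        "abgd_group_counts": scan.group_counts(),
        "linkage_vs_abgd_ari": ari,
    }

    report = concordance_report(linkage_part, taxonomy)
    report.per_otu.to_csv(out / "concordance_per_otu.tsv", sep="\t")
    report.per_species.to_csv(out / "concordance_per_species.tsv", sep="\t")
    with open(out / "concordance_summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2)
    manifest["concordance"] = report.summary

    haplotypes = collapse_haplotypes(dataset, mode=config.haplotype_mode)
    haplotypes.write_tsv(out / "haplotypes.tsv")
    shared = shared_haplotypes(haplotypes)
    shared.to_csv(out / "shared_haplotypes.tsv", sep="\t", index=False)
    manifest["haplotypes"] = {
        "n_haplotypes": haplotypes.n_haplotypes,
        "n_shared_pairs": len(shared),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
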