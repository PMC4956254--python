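"""Synthetic barcode datasets with known ground truth.

The generator emulates the statistical structure a barcode reference
library assumes: well-separated species (expected between-species
divergence ``inter_depth``, default 8%), small conspecific variation
(expected ``intra_theta``, default 0.4%), and transition-biased
substitution (``kappa``, default 3.5, matching typical fitted COI ti/tv
ratios). Species relationships follow a random coalescent-shaped tree
rescaled to the requested mean depth; conspecific specimens radiate from
each species' ancestral sequence on a star genealogy of depth
``intra_theta / 2``, which puts the expected pairwise conspecific distance
at ``intra_theta`` exactly. Sequences evolve under a continuous-time
Kimura two-parameter process, so the analysis model matches the
generative model.

Scenarios reproduce the situations a real library audit must detect:

* ``clean_gap`` — every species recoverable: conspecific variation capped
  at one private substitution per specimen and the species tree padded so
  the smallest between-species path is at least half the mean (a
  guaranteed, comfortably wide barcoding gap).
* ``cryptic_split`` — one species harbours two deeply divergent lineages
  (8 * intra_theta apart), as a cryptic species complex would.
* ``merged_pair`` — two nominal species share their ancestral haplotype;
  at least one specimen of each is identical to it (nearest-neighbour
  distance 0).
* ``mislabeled`` — one specimen carries another species' labels while its
  sequence stays with its true group.
* ``none`` — the plain model with no guarantees, for calibration studies.

All outputs are a pure function of the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .io import Dataset, SequenceRecord, write_fasta, write_taxonomy
from .otu import Partition
from .tree import write_newick

SCENARIOS = ("clean_gap", "cryptic_split", "merged_pair", "mislabeled", "none")

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_species: int = 10
    n_per_species: int | list[int] = 4
    inter_depth: float = 0.08  # expected between-species divergence (subs/site)
    intra_theta: float = 0.004  # expected conspecific divergence (subs/site)
    kappa: float = 3.5  # transition/transversion rate ratio
    seq_length: int = 648
    base_freqs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    species_per_genus: int = 2
    genera_per_family: int = 2
    seed: int = 0
    scenario: str = "clean_gap"

    def __post_init__(self):
        if not (self.inter_depth > self.intra_theta >= 0):
            raise ValueError("need inter_depth > intra_theta >= 0")
        total = sum(self.base_freqs.values())
        if abs(total - 1.0) > 1e-9:
            self.base_freqs = {b: f / total for b, f in self.base_freqs.items()}
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid: {', '.join(SCENARIOS)}"
            )

    def counts(self) -> list[int]:
        if isinstance(self.n_per_species, int):
            return [self.n_per_species] * self.n_species
        if len(self.n_per_species) != self.n_species:
            raise ValueError("n_per_species list must have n_species entries")
        return list(self.n_per_species)


@dataclass
class SimResult:
    dataset: Dataset
    truth_partition: Partition
    truth_tree: TreeNode
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.dataset, outdir / "sequences.fasta")
        write_taxonomy(self.dataset, outdir / "taxonomy.tsv")
        self.truth_partition.write_tsv(outdir / "truth_partition.tsv")
        write_newick(self.truth_tree, outdir / "truth_tree.nwk")
        cfg = dataclasses.asdict(self.config)
        with open(outdir / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=2)


def simulate_species_tree(
    n_species: int,
    inter_depth: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Random coalescent-shaped species tree, leaves ``species_01``...

    Branch lengths are rescaled so the mean leaf-to-leaf path length is
    exactly ``2 * inter_depth`` substitutions/site. Deterministic given
    the seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if rng is None:
        rng = np.random.default_rng(seed)
    lineages = [
        TreeNode(name=f"species_{i + 1:02d}") for i in range(n_species)
    ]
    heights = [0.0] * n_species
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        a.length = t - heights[i]
        b.length = t - heights[j]
        parent = TreeNode(children=[a, b])
        lineages = [lineages[m] for m in range(k) if m not in (i, j)] + [parent]
        heights = [heights[m] for m in range(k) if m not in (i, j)] + [t]
    root = lineages[0]
    root.length = None
    _rescale_mean_path(root, 2.0 * inter_depth)
    return root


def _tip_paths(tree: TreeNode) -> np.ndarray:
    dm = tree.tip_tip_distances()
    iu = np.triu_indices(dm.shape[0], k=1)
    return dm.data[iu]


def _rescale_mean_path(tree: TreeNode, target_mean: float) -> None:
    mean = float(_tip_paths(tree).mean())
    factor = target_mean / mean
    for node in tree.traverse(include_self=False):
        if node.length is not None:
            node.length *= factor


def _pad_tips_for_gap(tree: TreeNode, target_mean: float) -> None:
    """Lengthen tip edges until min path >= mean path / 2, keep mean fixed.

    Adding a constant c to every tip edge adds 2c to every path, raising
    the min/mean ratio; afterwards the tree is rescaled back to the
    target mean, so the smallest between-species path ends up at least
    ``target_mean / 2``.
    """
    paths = _tip_paths(tree)
    p_min, p_mean = float(paths.min()), float(paths.mean())
    c = max(0.0, (p_mean - 2.0 * p_min) / 2.0)
    if c > 0:
        for tip in tree.tips():
            tip.length += c
    _rescale_mean_path(tree, target_mean)


def _transition_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after branch length t subs/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_ti, p_tv


def _evolve(seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One K2P step of length t along a branch (codes A=0 C=1 G=2 T=3)."""
    if t <= 0:
        return seq.copy()
    p_ti, p_tv = _transition_probs(t, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    out[u < p_ti] ^= 2  # transition partner: A<->G, C<->T
    m1 = (u >= p_ti) & (u < p_ti + p_tv)
    m2 = (u >= p_ti + p_tv) & (u < p_ti + 2 * p_tv)
    out[m1] ^= 1  # one transversion partner
    out[m2] ^= 3  # the other
    return out


def _mutate_fixed(
    seq: np.ndarray, n_subs: int, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Exactly ``n_subs`` substitutions at distinct random sites."""
    out = seq.copy()
    sites = rng.choice(seq.size, size=n_subs, replace=False)
    for s in sites:
        if rng.random() < kappa / (kappa + 2.0):
            out[s] ^= 2
        else:
            out[s] ^= 1 if rng.random() < 0.5 else 3
    return out


def _root_sequence(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    probs = [config.base_freqs[b] for b in _BASES]
    return rng.choice(4, size=config.seq_length, p=probs).astype(np.uint8)


def _species_ancestors(
    tree: TreeNode, config: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve the root sequence down the species tree; one sequence per leaf."""
    seqs: dict[int, np.ndarray] = {id(tree): _root_sequence(config, rng)}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        seqs[id(node)] = _evolve(parent_seq, node.length or 0.0, config.kappa, rng)
        if node.is_tip():
            out[node.name] = seqs[id(node)]
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[c] for c in seq)


def _taxonomy_labels(config: SimConfig, species_index: int) -> tuple[str, str, str]:
    g = species_index // config.species_per_genus
    f = g // config.genera_per_family
    return (f"genus_{g + 1:02d}", f"family_{f + 1:02d}", "order_01")


def evolve_sequences(
    tree: TreeNode, config: SimConfig, rng: np.random.Generator | None = None
) -> SimResult:
    """Plain (scenario-free) dataset: star radiation within each species."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ancestors = _species_ancestors(tree, config, rng)
    records, truth = [], {}
    for si, sp in enumerate(sorted(ancestors)):
        genus, family, order = _taxonomy_labels(config, si)
        for k in range(config.counts()[si]):
            sid = f"{sp}_s{k + 1:02d}"
            seq = _evolve(ancestors[sp], config.intra_theta / 2.0, config.kappa, rng)
            records.append(
                SequenceRecord(sid, _decode(seq), sp, genus, family, order)
            )
            truth[sid] = sp
    dataset = Dataset(records=records, alignment_length=config.seq_length)
    partition = Partition(assignment=truth, method="truth", params={}).relabeled()
    return SimResult(dataset=dataset, truth_partition=partition, truth_tree=tree, config=config)


def make_scenario(name: str, config: SimConfig | None = None) -> SimResult:
    """Build a dataset for one named scenario (see module docstring)."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}")
    config = dataclasses.replace(config or SimConfig(), scenario=name)
    rng = np.random.default_rng(config.seed)
    tree = simulate_species_tree(config.n_species, config.inter_depth, rng=rng)
    if name == "clean_gap":
        _pad_tips_for_gap(tree, 2.0 * config.inter_depth)
    if name == "none":
        return evolve_sequences(tree, config, rng)

    ancestors = _species_ancestors(tree, config, rng)
    species_names = sorted(ancestors)
    counts = config.counts()
    L = config.seq_length

    # scenario-specific sequence surgery on species ancestors
    split_species = species_names[0] if name == "cryptic_split" else None
    split_anc = None
    if name == "cryptic_split":
        n_deep = round(8.0 * config.intra_theta * L)  # two lineages 8*theta apart
        split_anc = _mutate_fixed(ancestors[split_species], n_deep, config.kappa, rng)
    if name == "merged_pair":
        ancestors[species_names[1]] = ancestors[species_names[0]].copy()

    records, truth = [], {}
    p_one = 1.0 - math.exp(-config.intra_theta * L / 2.0)  # censored Poisson
    for si, sp in enumerate(species_names):
        genus, family, order = _taxonomy_labels(config, si)
        for k in range(counts[si]):
            sid = f"{sp}_s{k + 1:02d}"
            anc = ancestors[sp]
            group = sp
            if name == "clean_gap":
                # at most one private substitution per specimen
                n_sub = 1 if rng.random() < p_one else 0
                seq = _mutate_fixed(anc, n_sub, config.kappa, rng)
            elif name == "merged_pair" and si in (0, 1) and k == 0:
                seq = anc.copy()  # guaranteed shared identical haplotype
            elif name == "cryptic_split" and sp == split_species and k >= counts[si] // 2:
                seq = _evolve(split_anc, config.intra_theta / 2.0, config.kappa, rng)
                group = f"{sp}_deep"
            else:
                seq = _evolve(anc, config.intra_theta / 2.0, config.kappa, rng)
            if name == "merged_pair" and si in (0, 1):
                group = f"{species_names[0]}+{species_names[1]}"
            records.append(
                SequenceRecord(sid, _decode(seq), sp, genus, family, order)
            )
            truth[sid] = group

    if name == "mislabeled":
        # first specimen of the second species gets the first species' labels
        victim = f"{species_names[1]}_s01"
        genus, family, order = _taxonomy_labels(config, 0)
        records = [
            SequenceRecord(r.specimen_id, r.sequence, species_names[0], genus, family, order)
            if r.specimen_id == victim
            else r
            for r in records
        ]
        # truth keeps the sequence with its true group

    dataset = Dataset(records=records, alignment_length=L)
    partition = Partition(assignment=truth, method="truth", params={"scenario": name})
    return SimResult(
        dataset=dataset,
        truth_partition=partition.relabeled(),
        truth_tree=tree,
        config=config,
    )
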