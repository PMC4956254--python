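# Methods

This note documents the models, numerical choices and known limitations
behind `barcodekit`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Distance model

Pairwise divergence uses the Kimura two-parameter (K2P) model, the
de-facto standard for COI barcode libraries. For a pair of aligned
sequences, only sites where both symbols are unambiguous A/C/G/T are
compared (*pairwise deletion*; `-`, `N` and all IUPAC ambiguity codes are
treated as missing). With transition proportion `P` (A↔G, C↔T),
transversion proportion `Q` and `L` compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site].

The estimate is undefined when `1 - 2P - Q ≤ 0` or `1 - 2Q ≤ 0`
(saturation); such pairs are stored as explicit missing values and listed
in `DistanceMatrix.undefined_pairs`, never dropped silently. Distances
are held in substitutions/site internally; all report tables are percent.

* Pairwise vs complete deletion is a switch on `distance_matrix`
  (`deletion="pairwise"` default). Pairwise deletion matches the
  behaviour of the barcode-database summary tools and prevents one ragged
  record from deleting columns globally; complete deletion is provided
  for sensitivity checks.
* The per-rank comparison sets are disjoint: *within species* =
  conspecific pairs; *within genus* = congeneric pairs from different
  species; *within family* = confamilial pairs from different genera.
  Without the exclusions the family minimum could undercut the congeneric
  minimum, which would make the rank table internally inconsistent.
* The summary `se` column is sd(pair distances)/√n, in percent. Pair
  distances are not independent (each specimen joins many pairs), so this
  is a descriptive figure, not a confidence statement; no test relies on
  it.
* The K2P point estimate is convex in the observed proportions, so it
  carries a small upward Jensen bias of order `d²/L` (≈ 2% relative at
  d = 0.004, L = 648). This is far below the per-pair binomial noise
  `√(d/L)` and is visible only when averaging thousands of replicates;
  the simulator calibration tests use tolerances (3 Monte-Carlo SE) that
  account for it.

## Quality control

Putative COI barcodes must translate without internal stop codons under
the vertebrate mitochondrial genetic code (NCBI table 2, where AGA/AGG
are stops); stops or frame-shifting indels are the classic NUMT
signature. Because the amplicon's reading frame is not fixed by the data
format, the frame is auto-detected: the ungapped sequence is read in all
three forward frames and the frame with the fewest internal stops wins
(ties go to the lowest frame). The final complete codon of each frame is
excluded — a terminal stop is legitimate — and codons containing
ambiguity codes never count as stops. Indel screening without a reference
alignment reduces to a length check: deviation from the expected amplicon
length (default 648 bp) is flagged but does not fail a record.

## Trees and bootstrap

Neighbour joining is the standard Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion. Ties in Q break deterministically on the
lowest index pair, so the tree is a pure function of the matrix. Negative
branch-length estimates are clamped to zero with the deficit moved to the
sister edge, preserving the pair's path length — the usual practice for
distance trees meant for display and bipartition analysis. On an additive
matrix NJ recovers the generating tree exactly; the tests verify this
with a path-length oracle and cross-check topologies against an
independent NJ implementation (scikit-bio).

Bootstrap support resamples alignment columns with replacement
(Felsenstein bootstrap), recomputes K2P + NJ per replicate, and scores
each internal edge of the original tree by the fraction of replicate
trees containing the same bipartition. Replicates that produce undefined
distances are skipped and counted (warning above 1% skipped). Supports
are deterministic given the seed.

Newick output quotes any label containing metacharacters (spaces,
parentheses, colons, quotes) rather than mangling it; bootstrap supports
are written as internal-node labels.

## Barcoding-gap analysis

Per species: maximum conspecific distance (`NA` for singletons — a single
record cannot exhibit intraspecific variation) and the nearest-neighbour
(NN) distance, the minimum distance from any of its specimens to any
heterospecific specimen (ties between species break lexicographically). A
species is *discriminated* when NN > max-intra, with singleton `NA`
treated as 0 — so a singleton is discriminated unless another species
carries an identical (or closer-than-zero, i.e. identical) sequence.
Species whose max-intra exceeds a configurable threshold (default 2%) are
flagged as deep-divergence candidates (possible cryptic complexes).

The dataset-level gap report returns the conspecific and congeneric
distance multisets and the interval between the maximum of the former and
the minimum of the latter. Outlier exclusion lists (species and genera)
are explicit configuration with empty defaults; excluding outliers can
only widen the interval, and the interval is reported only when its lower
bound is below its upper bound (otherwise an overlap flag is set).

## OTU delimitation

**Single-linkage threshold clustering.** OTUs are connected components of
the graph joining pairs at distance ≤ t (components via
`scipy.sparse.csgraph`). Missing distances never link. The default
t = 0.022 is the conventional seed threshold for database BIN clusters;
because the production BIN algorithm (RESL) is not public, every
BIN-style output of this package is labelled a *single-linkage
surrogate*. Raising t can only merge components, so OTU counts are
monotone non-increasing in t.

**Recursive barcode-gap partitioning.** For each prior maximum
intraspecific divergence `P` on a log-spaced grid (defaults
Pmin = 0.001, Pmax = 0.1, 20 steps), the sorted pairwise distances are
scanned for the first *gap*: a consecutive pair `(d_i, d_{i+1})` with
width `d_{i+1} − d_i > X·max(d_i, P)` (relative width X, default 1.0).
The scan considers pairs with `d_i ≥ P` **and** the pair straddling the
prior (`d_{i+1} > P` even if `d_i < P`), so a gap sitting immediately
above the prior is detectable; a strict-inequality epsilon (1e-12)
prevents exactly uniform spacing from qualifying. The mid-gap value
`(d_i + d_{i+1})/2` becomes a single-linkage threshold, and the procedure
recurses inside each resulting group on its sub-matrix until no group
splits; groups of fewer than 3 specimens are final (a gap is undefined on
fewer than 2 distances). With no top-level gap the partition is one OTU.
The scan also emits a distance histogram (diagnostic) and the maximal
prior ranges over which the partition is stable.

This is a deliberate simplification of the published ABGD procedure,
which detects gaps through the slope of ranked distances and a
theoretically derived intraspecific limit. The simplified detector is
validated *behaviourally* — exact recovery of known partitions on
simulated data across the prior grid, monotonicity, order invariance —
not byte-for-byte against the original program. Like all gap methods it
over-splits when the prior is set below the true intraspecific scale.

Partition comparison uses the adjusted Rand index (scikit-learn) plus an
exact identical-up-to-relabelling check.

## Concordance audit and haplotypes

An OTU is *concordant* when its ≥ 2 records carry one species name,
*discordant* when it mixes names, *singleton* with one record; a species
is a *match*, *split* (≥ 2 OTUs) or *merged* (shares an OTU). Percentages
are rounded half away from zero to one decimal — note that printed report
tables in the literature occasionally disagree with their own counts at
the last decimal; this package reports the exact fraction. The audit is
local to the supplied records (optionally extended with external labelled
sequences); database-wide discordance against a global barcode repository
is out of scope.

Haplotype collapsing has two modes. *Tolerant* (default): records share a
haplotype when they agree at every site where both are unambiguous, so
terminal Ns or gaps do not separate otherwise identical sequences; since
that compatibility relation is not transitive, haplotypes are the
connected components of the compatibility graph. *Strict*: exact string
identity. Diagnostic characters between two species are alignment columns
fixed for different unambiguous states in each species, with any
ambiguity in either species disqualifying the column — shared haplotypes
therefore imply an empty diagnostic set.

## Synthetic data

The generator produces datasets whose statistical structure matches what
the analysis assumes, with full ground truth (true partition, species
tree, parameters):

* **Species tree**: random Kingman-coalescent shape over `n_species`
  lineages, branch lengths rescaled so the mean leaf-to-leaf path is
  exactly `2·inter_depth` (default 0.08 ≈ congeneric-scale divergence).
* **Sequence evolution**: continuous-time K2P process with
  transition/transversion rate ratio `kappa` (default 3.5, near typical
  fitted COI values), total rate 1 substitution/site per unit branch
  length; root drawn from `base_freqs` (default uniform).
* **Conspecific variation**: a star genealogy of depth `intra_theta/2`
  per specimen, giving expected pairwise conspecific distance
  `intra_theta` (default 0.004) exactly. A star is used instead of a full
  coalescent because the analysis consumes only pairwise distances, and
  the star gives direct control of the expected divergence.
* Defaults: 10 species × 4 specimens (matching typical reference-library
  sampling depth), 648 bp.

Scenarios modify this base:

* `clean_gap` — guaranteed recoverable structure. Two construction
  guarantees are enforced rather than left to chance: (i) each specimen
  carries at most one private substitution (realized conspecific
  divergence ≤ ~0.3%, as in real libraries where most conspecific pairs
  differ by 0–2 sites) — an unconstrained Poisson star occasionally
  produces within-species distance gaps wide enough for any gap-based
  delimiter to split a species; and (ii) tip edges of the species tree
  are padded so the minimum between-species path is at least half the
  mean (≥ `inter_depth` at defaults) — an unconstrained coalescent
  occasionally places two species arbitrarily close. The truth partition
  equals the species map.
* `cryptic_split` — the first species' specimens split into two lineages
  `8·intra_theta` apart (3.2% at defaults, the scale of real deep
  conspecific splits), safely above the 2% deep-divergence flag; the
  truth partition has `n_species + 1` groups.
* `merged_pair` — the first two species share their ancestral sequence
  and each contributes one specimen identical to it, so their NN distance
  is 0 and they share a haplotype; the truth partition merges them.
* `mislabeled` — one specimen's species/genus/family labels are swapped
  to another species while its sequence stays with its true group.
* `none` — the unmodified base model, used for calibration tests
  (distance and parameter recovery).

All outputs are byte-identical across runs with the same seed
(`numpy.random.default_rng` is the only randomness source).

## Problem sizes used in the automated checks

The test suite and the acceptance script run on simulated libraries of
10 species × 4 specimens × 648 bp (40 records), 100 bootstrap
replicates, 20 seeds for partition recovery and 50–100 Monte-Carlo
replicates for parameter recovery — sizes at which every behavioural
property is already sharply testable. The end-to-end reproduction of the
published reference-library summaries runs on the 308 deposited GenBank
records and requires network access for retrieval.

## Known limitations

* The gap partitioner is a behavioural analogue of ABGD, not a
  reimplementation; numerical agreement with the original program on
  arbitrary data is not claimed.
* Single-linkage at 2.2% is a surrogate for BIN assignment, not the RESL
  algorithm; BIN identities cannot be reproduced locally.
* Maximum-likelihood trees, substitution-model selection, and
  tree-based delimitation (PTP) are out of scope; externally produced
  partitions can still be audited via `Partition.read_tsv`.
* The simulator omits recombination, indels, NUMT artefacts and
  sequencing error; passing tests demonstrate correctness of the
  analysis chain under the stated generative model, not robustness to
  alignment error or contamination in real data.
* Singleton species make the discrimination rate optimistic (they cannot
  fail the max-intra comparison except through sequence identity with
  another species); the per-species table makes singleton status
  explicit so downstream users can filter.
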