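# barcodekit

Tools for building and validating **DNA-barcode reference libraries** from
COI-5P sequences (the ~648 bp 5' fragment of mitochondrial cytochrome c
oxidase subunit I used as the standard animal barcode).

A reference library couples expert-identified voucher specimens with their
barcode sequences. Before such a library can be trusted for identification,
the data must be audited: do conspecific sequences cluster tightly? Does
every species' distance to its nearest heterospecific neighbour exceed its
own maximum intraspecific divergence (the *barcoding gap*)? Do
taxonomy-free sequence clusters (OTUs) coincide with the named species?
`barcodekit` implements this audit end to end, plus a synthetic-data
generator with known ground truth so every stage is testable without any
download.

## What it computes

* **Quality control** — translation of each barcode in all three forward
  frames under the vertebrate mitochondrial code; stop codons flag
  putative NUMTs. Pooled A/C/G/T composition.
* **K2P distances** — pairwise Kimura two-parameter distances with
  pairwise deletion of ambiguous sites:
  `d = -½ ln(1 - 2P - Q) - ¼ ln(1 - 2Q)`, with `P`/`Q` the
  transition/transversion proportions. Divergence summaries within
  species, within genus (excluding conspecific pairs) and within family
  (excluding congeneric pairs), plus per-genus interspecific ranges.
* **Neighbour-joining trees** with Felsenstein bootstrap supports
  (column resampling; support = fraction of replicate trees containing
  the same bipartition).
* **Barcoding-gap analysis** — per-species maximum intraspecific distance
  vs nearest-neighbour distance, species discrimination rate, and the
  dataset-level gap between the conspecific and congeneric distance
  distributions.
* **OTU delimitation** — single-linkage clustering at a distance
  threshold (default 2.2%, a documented surrogate for database BIN
  assignment), and a recursive barcode-gap partitioner in the spirit of
  ABGD, scanned over a log-spaced grid of prior intraspecific divergences
  (defaults Pmin = 0.001, Pmax = 0.1, 20 steps, relative gap width
  X = 1.0).
* **Concordance auditing** — per-OTU status
  (concordant / discordant / singleton) and per-species status
  (match / split / merged) for any partition against the taxonomy;
  haplotype collapsing, shared-haplotype detection and diagnostic
  characters between species pairs.
* **Simulation** — species trees with coalescent shape, K2P sequence
  evolution with transition bias, star-shaped conspecific radiation, and
  named stress scenarios (`clean_gap`, `cryptic_split`, `merged_pair`,
  `mislabeled`).

## Worked example

```bash
# simulate a 10-species dataset with a clean barcoding gap
barcodekit simulate --scenario clean_gap --seed 7 --outdir demo

# full analysis bundle
barcodekit run --fasta demo/sequences.fasta --taxonomy demo/taxonomy.tsv \
               --outdir demo/out --replicates 100 --seed 7

# one stage at a time
barcodekit summary --fasta demo/sequences.fasta --taxonomy demo/taxonomy.tsv --rank species
```

The `summary` command prints (percent K2P):

```
rank	comparisons	min	mean	max	se
within_species	60	0.15	0.27	0.31	0.01
```

i.e. 60 conspecific pairs with mean divergence 0.27% and maximum 0.31% —
an order of magnitude below the between-species distances, so the gap
report in `demo/out/gap_report.tsv` marks every species discriminated and
`demo/out/manifest.json` records `"discrimination_percent": 100.0`. The
same manifest lists the OTU counts found by the gap partitioner at each
prior and the concordance summary (here 100% concordant OTUs).

Python API equivalents live in `barcodekit.io`, `.qc`, `.distance`,
`.tree`, `.gap`, `.otu`, `.concordance`, `.simulate` and `.pipeline`; see
the module docstrings.

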