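# barcodekit

Distance- and character-based evaluation of short DNA barcode markers for
species identification, built around the 18S rRNA V4 region workflow:

* **seqio** — labelled FASTA I/O (pipe headers or a TSV side table),
  label overrides with an audit trail, in-silico PCR amplicon extraction
  (Hamming matching over IUPAC codes, default primers D512/D978),
  alignment trimming to a core window (default 333 columns),
  deduplication of identical sequences, and alignment validation.
* **distances** — uncorrected p-distances and K2P distances with
  pairwise (or complete) deletion of gap/ambiguity columns, all-pairs
  distance matrices with differing/compared site counts, partitioning
  into intraspecific / interspecific / intergeneric sets, and
  barcode-region vs full-gene comparisons.
* **threshold** — per-species separation at a p-distance threshold under
  three selectable criteria (nearest-neighbor, all-pairs, barcode-gap),
  intraspecific overlap counts, threshold sweeps, and low-divergence
  "problem pair" listings.
* **characters** — variable-site indexing; exhaustive search for pure,
  compound (2-site) and doubly-compound (3-site) diagnostic characters
  and private characters against a guide grouping (species labels, or
  clusters cut from the built-in neighbor-joining guide tree);
  rule-based classification of query sequences.
* **synthesis** — seeded generator of species-structured alignments with
  planted intra/interspecific divergences, problem pairs, indel columns,
  ambiguity codes and diagnostic characters, plus a ground-truth record,
  so every stage is testable without external data.
* **cli** — `barcodekit` command with `extract`, `distances`,
  `threshold`, `characters`, `classify`, `simulate` and `run`
  subcommands; `run` writes a full report bundle (TSV/newick/JSON) with
  a reproducibility manifest.

All user-facing coordinates are 1-based closed intervals. Distances are
reported at 4 decimals; internal precision is full.

## CLI quick start

```sh
# synthetic data with ground truth
barcodekit simulate --n-species 10 --seqs-per-species 3 --ncols 333 \
    --seed 1 -o sim/

# full analysis: distance matrix, partition summaries, threshold sweep,
# problem pairs, character table, guide tree, classification, manifest
barcodekit run sim/synthetic.fasta -o report/

# single stages
barcodekit extract genes.fasta -o amplicons.fasta
barcodekit distances aligned.fasta -o dist/
barcodekit threshold aligned.fasta --thresholds 0.01,0.02 -o thr/
barcodekit characters aligned.fasta -o chars/
barcodekit classify reference.fasta queries.fasta -o assignments.tsv
```

FASTA headers are `id|species|genus|group` by default; a TSV side table
(`--metadata`, columns `id species genus group strain accession`)
overrides header labels, and `--overrides` applies curated species
relabellings by id.

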