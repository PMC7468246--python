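# coralbaits

Hybrid-capture bait design and post-capture locus curation for
scleractinian (stony coral) phylogenomics.

Stony coral phylogenies are starved of informative markers: corals are
sequenced as holobionts (host plus algal and microbial symbionts), whole
genomes are scarce, and loci assembled by different studies rarely
overlap. Target enrichment solves this by hybridizing biotinylated
120 nt probes ("baits") to genomic libraries so that a fixed panel of
orthologous loci is captured in every sample. `coralbaits` implements
the full informatic arc of that approach for people building or reusing
such panels:

* **Design time** — from clustered ortholog alignments to a screened
  probe set: taxon-representation and genome-anchoring filters,
  removal of non-cnidarian transcripts by best local-alignment hit
  (identity >= 80% over >= 100 bp), codon-level back-translation,
  exon-aware window search with iterative 240/200/160/120 bp windows
  tiled at a 20 bp offset (7/5/3/1 baits per window), plus COI and
  histone H3 barcoding baits tiled across the whole gene; then symbiont
  cross-hybridization screening (>= 70% identity over >= 70% of the
  bait, or blast-style e <= 1e-4), region pruning (>= 3 baits lost or
  <= 1 remaining), duplicate removal, and self-hybridization removal
  (reverse-complementary runs >= 21 nt).
* **Post capture** — from assembled contigs and gene trees to a curated
  supermatrix: barcode identity verification (best hit >= 98% over
  >= 200 bp, cross-contaminants recognised by >= 100-fold lower
  coverage), paralog resolution (keep `.main`, else `0.0`), removal of
  loci with deep (Type II) duplications, tree-based contamination
  criteria (wrong-clade placement, unusually long branches), and
  concatenation into a partitioned matrix with missing-data and
  parsimony-informative-site statistics.

All similarity screens run on a built-in seeded Smith-Waterman engine
with Karlin-Altschul statistics (bit scores, e-values), verified in the
test suite against an independent quadratic dynamic-programming oracle.
A deterministic synthetic-data generator (`coralbaits.fixtures`)
produces a complete workspace with planted anomalies — contaminant
transcripts, symbiont-derived segments, misplaced taxa, paralog copies,
a barcode cross-contaminant — and a truth ledger against which pipeline
recovery is measured.

See `docs/methods.md` for the models, parameter defaults and design
choices.

## Worked example

Generate a small synthetic workspace (12 loci, 12 taxa) and run both
workflows:

```bash
coralbaits make-fixtures --seed 7 --out demo/ws \
    --n-loci 12 --n-robust 5 --n-complex 5 --n-outgroup 2
coralbaits design --workspace demo/ws --out demo/design
coralbaits postcapture --workspace demo/ws --out demo/post
```

which prints

```
input_loci: 12
represented: 12
anchored: 12
post_contaminant: 12
regions_designed: 13
baits_designed: 1357
baits_retained: 1350
matrix: 12 loci, 4887 sites, 12.13% missing, 1448 PI sites (29.63%)
```

Reading the counts: all 12 loci pass the representation filter (>= 6
scleractinian taxa, >= 2 per major clade) and anchor to a reference gene
model at >= 50 bits; 13 exon regions host valid bait windows; 1,357
baits are tiled (targets plus `coi`/`h3` barcode baits) and 1,350
survive the symbiont / duplicate / self-hybridization screens — the
seven removed baits sit on a planted symbiont segment, and the screen
ledger (`demo/design/screen_ledger.tsv`) names each one. The
post-capture run verifies every sample's barcode, prunes the planted
paralog copies and misplaced taxa from the gene trees, and concatenates
the curated loci into a 4,887-site matrix with 12.13% missing data and
1,448 parsimony-informative sites.

Key outputs: `baits.fasta` (headers
`<locus>|<start>-<end>|tile<k>|<taxon>|<label>`), `regions.tsv` (window
coordinates, tile and bait counts, mean identity per region),
`audit_log.tsv` and `screen_ledger.tsv` (every filtered locus, member
and bait with its reason), `supermatrix.fasta`/`.phy`, `partitions.txt`
(RAxML dialect, 1-based inclusive), and JSON summaries of both runs.

The same operations are available as a library:

```python
from coralbaits import tile_positions, run_design
tile_positions(240)   # [0, 20, 40, 60, 80, 100, 120] -> 7 baits
```

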