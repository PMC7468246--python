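# Methods

`coralbaits` implements a transcriptome-based target-enrichment workflow
for stony corals (Scleractinia): the design of tiled 120 bp hybridization
baits from clustered ortholog alignments, the screening of that probe set
against off-target sources, and the curation of post-capture data into a
partitioned phylogenomic supermatrix. This note describes the models and
procedures, the parameters that matter, the synthetic-data generator used
for validation, and the numerical and design choices made where the
problem was genuinely open.

## The design-time workflow

### Input model

The unit of design is the *orthogroup*: a set of amino-acid sequences
(one or more per taxon, with parallel coding sequences) annotated with a
taxon label and a major-clade label. Scleractinia splits into two deep
primary lineages — the "Robust" and "Complex" clades — and this split is
used throughout both as a sampling-balance criterion and as a
contamination detector. Inputs arrive as FASTA with
`taxon=...;clade=...` header tags; all coordinates in the package are
0-based half-open.

### Filtering cascade

1. **Taxon representation.** An orthogroup is retained when it covers at
   least `min_taxa` (default 6) distinct scleractinian taxa, at least
   `min_per_clade` (default 2) from *each* of the Robust and Complex
   clades. The each-clade reading enforces even phylogenetic
   representation; setting `min_per_clade=0` recovers the weaker
   either-clade reading. Distinctness counts taxon labels, not
   sequences, so upstream paralogs do not inflate representation.
2. **Genome anchoring.** Members are searched (protein mode, e-value
   1e-6) against the gene models of the reference genomes; the
   orthogroup is kept when any member reaches a bit score of at least 50
   (inclusive). The orthogroup is *binned* to the genome of its best
   hit — ordered by bit score (desc), e-value (asc), percent identity
   (desc), subject id — and that hit's gene model becomes the reference
   for exon projection.
3. **Contaminant transcripts.** Coral holobiont transcriptomes carry
   symbiont, microbial and other non-coral sequence. Each coding
   sequence is searched (nucleotide mode, e-value 1e-6) against a
   labelled reference set in which each record is tagged cnidarian or
   non-cnidarian (`source=` header tag); only the single best hit is
   judged. A member is removed when that best hit is non-cnidarian with
   identity >= 80% over an alignment length >= 100 columns (both
   inclusive). If removals push the orthogroup below six scleractinian
   taxa it is dropped whole. Only the six-taxon condition is re-checked
   at this point, not the per-clade condition.

### The similarity engine

All similarity screens go through one seeded local-alignment engine.  A
query/subject pair is considered only when it shares an exact seed word
(11 nt in nucleotide mode, searched on both strands; 4 residues in
protein mode); a seeded pair is scored with a full optimal
Smith-Waterman/Gotoh alignment (match +2 / mismatch -3 and affine gap
penalties 5/2 in nucleotide mode; BLOSUM62 with the same gap penalties in
protein mode). Running the full optimal alignment on seeded pairs —
rather than a banded extension from the seed — makes the engine agree
*exactly* with an unseeded Smith-Waterman whenever the optimal alignment
contains a seed word, a property the test suite verifies against an
independent quadratic DP oracle.

Bit scores and e-values follow Karlin-Altschul statistics with fixed
constants per scheme (nucleotide: lambda = 0.625, K = 0.41; protein:
the published gapped BLOSUM62 values lambda = 0.267, K = 0.041), with
`e = K * m * n * exp(-lambda * S)` over the query length m and total
subject length n of the search. Any fixed, consistent pair preserves
the *ranking* semantics the thresholds rely on; the engine does not aim
for numerical BLAST+ replication (no composition-based statistics,
masking, or multi-HSP sum statistics — the screens here use single best
local alignments only). Percent identity is measured over alignment
columns including gap columns, matching the "similarity across an
alignment length" reading used by the thresholds.

### Codon alignment and exon projection

Surviving orthogroups are codon-aligned by back-translating the
amino-acid alignment: each residue column expands to its source codon,
each gap to `---`, so nucleotide columns are exactly three times the
protein columns and degapping any row recovers its coding sequence. A
translation mismatch aborts with the offending taxon and codon index —
a silent frame error would corrupt every bait downstream. The protein
alignment itself is pluggable: pre-aligned input is accepted as-is
(equal-length rows), or the `mafft` executable is wrapped for unaligned
input. Alignment quality is not part of this package's contribution.

The reference gene model's coding sequence is attached as an extra
alignment row, and its exon coordinates are projected onto alignment
columns: reference columns inherit the exon of their coding position,
insertion columns inherit the preceding reference position's exon
(leading insertions the first exon). This is simple, deterministic and
testable.

### Window search and tiling

Bait design looks for a window that lies wholly inside one projected
exon (so probes remain contiguous on genomic DNA) and satisfies the gap
rule — by default *strict*: no gap in any member row at any window
column; a tolerant mode (column gap fraction <= 50%, gapped rows skipped
per tile) recovers more loci. Window lengths are tried longest-first:
240, 200, 160, 120 nt. Among valid windows of the chosen length the one
maximising mean pairwise identity wins, ties going to the leftmost.
Mean pairwise identity is the package's stand-in for an unpublished
"best region" criterion: conservation across taxa is the natural proxy
for capture efficiency across divergent lineages. (Per-column pair
identity averaged over columns equals pair identity averaged over pairs,
which allows an O(columns) prefix-sum search.)

A chosen window of length W is tiled with 120 bp baits every 20 bp —
(W-120)/20 + 1 tiles, i.e. 7/5/3/1 baits for 240/200/160/120 nt windows
— and every distinct gap-free, N-free 120-mer among member rows becomes
one bait (duplicates within a tile collapse to the first contributing
taxon in input order). By default one region is designed per projected
exon (`multi_region`), reproducing the observed multiplicity of exon
regions per locus; a single-best-region mode (longest window, then
highest identity, then leftmost) is available.

Barcode baits (mitochondrial COI and nuclear histone H3, for
post-capture identity verification) are tiled across the *entire* gene
at the same 120/20 geometry, with the final tile anchored at the gene
end when the length is not offset-aligned; baits are labelled `coi`/`h3`
so users can drop them.

### Bait screening

Screens run in a fixed order; every removal is ledgered and counts are
conserved (input = survivors + removals) at every stage:

1. **Symbiont screen.** Baits matching Symbiodiniaceae references are
   removed under either of two criteria: a read-mapping-style criterion
   — best hit with identity >= 70% covering >= 70% of the bait
   (>= 84 of 120 positions; the length fraction is read as
   bait-relative, mirroring read-mapping semantics) — or a blast-style
   criterion, any hit with e-value <= 1e-4.
2. **Region pruning.** A region that lost >= 3 baits, or that would
   retain fewer than 2, is removed whole: a heavily off-target or
   depleted window is not worth synthesising.
3. **Duplicate removal.** Exact-sequence duplicates collapse to the
   first occurrence in input order.
4. **Self-hybridization.** Baits sharing a reverse-complementary exact
   run of >= 21 nt with an earlier bait (or with themselves —
   palindromes) are removed. The 21 nt default approximates one seed
   word plus modest extension under typical nucleotide-search defaults;
   an exact-run criterion is deterministic and directly testable against
   an all-pairs scan. Only the later bait of a pair is removed —
   removing both would discard capture capacity without need; a
   both-members mode is a one-line change in the screen.
5. **Final region re-check.** The pruning rule is re-applied against
   each region's cumulative losses, so the region invariant survives
   duplicate/self-hyb removals.

## The post-capture workflow

### Barcode identity verification

Captured barcode contigs (>= 200 bp; shorter ones are ignored with a log
entry) are matched against a taxon-tagged barcode reference panel. A
per-contig best hit qualifies at identity >= 98% over >= 200 aligned
columns (inclusive). The qualifying hit with the highest assembly
coverage decides the sample's identity:

* top hit's taxon = expected taxon -> **VERIFIED**;
* top hit's taxon != expected -> **MISIDENTIFIED_SUSPECT** (the
  pipeline refuses to build the matrix unless forced);
* no qualifying hit -> **UNVERIFIED**.

Other-taxon qualifying hits are interpreted through their coverage
ratio: at least 100-fold below the top hit is the signature of low-level
cross-contamination — recorded as a detected contaminant but not a
failure; a foreign hit above that threshold keeps the VERIFIED verdict
(the expected taxon still dominates) but raises an explicit warning.
Coverage is consumed from a user-supplied per-contig table (k-mer depth
or mapped-read depth; the rule only needs ratios) — assembly is out of
scope.

### Gene-tree curation

Per locus, a gene tree with tip labels `<taxon>` or
`<taxon>.<paralog-tag>` (`main`, `0.0`, `0.1`, ... as emitted by
target-capture assemblers) is curated:

1. **Support collapsing.** Internal edges below 10% bootstrap support
   are contracted to polytomies (absent support keeps the edge).
2. **Type II paralogy.** A duplication deeper than the taxon level makes
   a locus unusable for species phylogeny. Operationalised as: some
   internal edge has >= 2 multi-copy taxa with copies on both sides
   (the copies partition into two clades that each span multiple taxa).
   Flagged loci are dropped whole. Note the rule requires two taxa
   straddling *one* edge; a single duplicated taxon, however placed, is
   treated as Type I.
3. **Contamination criteria.** The tree is rooted on outgroup tips when
   present, else midpoint-rooted. Each tip's *observed* major clade is
   read from the smallest enclosing clade with >= 3 other tips, and is
   called only when the scleractinian tips there are **unanimous**.
   Unanimity, rather than majority, is deliberate: a contaminant truly
   nested in the wrong clade is surrounded by it, whereas a tip that
   merely sits with a small party of its own clade (low locus occupancy)
   has a mixed neighbourhood and must not be flagged — a majority vote
   wrongly removes whole small clades in exactly that situation. Then:
   (a) a taxon with copies observed in different major clades loses the
   copy outside its expected clade; (b) a single-copy taxon observed in
   the wrong major clade is removed; (c) a tip whose pendant branch
   exceeds `long_branch_factor` (default 5) times the median pendant
   branch is removed — a scale-free stand-in for "unusually long".
   Criterion (c) is computed on the pre-removal tree so the criteria
   commute for disjoint removals. Trees with fewer than four tips skip
   (a) and (b).
4. **Type I resolution.** Per taxon the `.main` copy is kept, else
   `0.0`, else the untagged copy (after contamination pruning, the
   lexicographically smallest remaining tag as a fallback).
5. **Locus filters.** Loci with fewer than three scleractinian taxa or
   fewer than `min_pi_sites` (default 1) parsimony-informative sites are
   dropped. "Spurious topology" is a human judgment and is *not*
   automated; a quarantine list (manual exclusion) is the supported
   mechanism.

### Supermatrix

Curated locus alignments are column-trimmed by a transparent gap-fraction
rule (columns with > 80% gaps removed) — a documented stand-in for
external trimming heuristics — then concatenated over the taxon
universe, partitioned by locus, with `?` padding for absent loci.
Matrix statistics follow the conventions used for concatenated
matrices: missing data counts both `?` (absent locus) and `-`
(alignment gap); a column is parsimony-informative when at least two
distinct non-missing states each occur in at least two rows, counted
matrix-wide. Outputs are FASTA, relaxed PHYLIP, and a RAxML-style
partition file in 1-based inclusive coordinates.

## The synthetic-data generator

`coralbaits.fixtures` materialises every input the pipeline consumes,
with planted ground truth, under a single seed (full byte determinism is
a tested property). Coding sequences evolve along a fixed
((Robust),(Complex),Outgroup) topology under an equal-rates substitution
model — root-to-clade depth 0.10 substitutions/site, within-clade 0.03,
outgroup 1.5x — with stop codons repaired deterministically and no
indels inside coding positions; alignment gaps arise from
lineage-specific exon absence. Defaults are the validation study
conditions: 20 taxa (8 Robust, 8 Complex, 4 outgroup), 60 loci of
60-200 codons, three reference genomes, 10% contaminant members, 10%
symbiont inserts, 10% paralog loci, 3 misplaced taxa, one barcode
cross-contaminant at 1/150 coverage. Locus lengths and counts are desk
scale, chosen so the full pipeline and its tests complete comfortably on
one CPU; the decision rules being exercised are size-independent.

Planted anomalies and the reasoning behind their construction:

* **Contaminant members** are drawn from an unrelated random backbone at
  95% identity; the backbone enters the screen database labelled
  non-cnidarian, while each locus's ancestral gene enters labelled
  cnidarian. Genuine members sit near ~87% identity to their cnidarian
  record and share no seed with foreign backbones, so best-hit screening
  separates the classes with margin.
* **Symbiont inserts** are verbatim 80-codon (240 nt) blocks written
  into *all* member rows and embedded in a symbiont reference. A full
  window of identical foreign sequence pins the window search (mean
  pairwise identity exactly 1 inside the block), making detection by the
  symbiont screen deterministic rather than dependent on where the best
  window happens to fall. Inserts go flush against one end of the
  largest exon, only in loci retaining >= 55 contiguous native codons,
  so insert-bearing loci still anchor to their gene models.
* **Misplacements** graft a scleractinian tip into the other major clade
  in the gene tree (sequence content untouched — the curation reads
  trees). **Paralog loci** give one taxon a second, lightly mutated
  copy under assembler-style tags. **The barcode cross-contaminant** is
  another taxon's COI reference planted in one sample's contigs at 1/150
  of the true barcode's coverage.
* Capture dropout removes each taxon from each locus with probability
  0.1, topping each major clade back up to >= 3 captured taxa so every
  gene tree's clade structure stays readable (the validation study's
  per-locus occupancy was similarly dense).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: alignment error and indels (rows are
positionally aligned by construction), sequencing/assembly error and
chimeric contigs, rate heterogeneity across sites and lineages,
incomplete lineage sorting (gene trees match the species topology apart
from planted edits), base-composition bias, and real Symbiodiniaceae
sequence (references are random backbones carrying the planted
segments). The planted-recovery results demonstrate that the decision
rules fire exactly as specified at the stated thresholds, not that those
thresholds are optimal for real transcriptomes.

## Numerical and degenerate-input choices

* Thresholds are inclusive (>=) everywhere; boundary behaviour is pinned
  by tests at 80%/100 bp, 70%/84 bp and 98%/200 bp.
* Ties in window search and best-region selection resolve leftmost; hit
  ordering ends in subject id; duplicate baits keep the first
  occurrence in input order — all total orders, making outputs
  byte-stable under a fixed seed and input.
* Raw alignment scores are integers; with integer match/mismatch/gap
  parameters the optimum is integral.
* Baits containing N are never emitted (ambiguity cannot be synthesised
  and weakens hybridization); N in matrix statistics counts as missing
  for the PI census but not toward the missing-data percentage (which
  counts `?` and `-`).
* Empty inputs fail loudly: empty FASTA, empty reference sets, and
  trimming a locus to zero columns are errors or logged drops, never
  silent successes.
* A single-observation coverage class reports its SD as undefined
  (absent), not zero.

## Known limitations

* The engine's e-values use fixed Karlin-Altschul constants; absolute
  values differ from BLAST+ (rankings and thresholds are unaffected).
  Protein seeding uses exact 4-mers rather than neighbourhood words, so
  very divergent protein pairs without an exact shared 4-mer are not
  scored — immaterial at the identity levels the filters target.
* Exon projection assumes the reference coding sequence length matches
  the codon-alignment width (no indels against the reference); loci
  violating this are dropped with an audit entry rather than re-aligned.
* The self-hybridization rule is an exact-run criterion, not a duplex
  thermodynamics model; melting temperature and GC optimisation are out
  of scope.
* Type II paralogy detection needs two straddling multi-copy taxa; a
  deep duplication visible in only one sampled taxon is resolved as
  Type I.
* The curation criteria assume the two-clade (Robust/Complex) frame;
  taxa outside it participate only as outgroup for rooting.
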