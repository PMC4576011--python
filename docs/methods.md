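# Methods

`florthograph` implements a reference-anchored comparative pipeline for
predicting and characterizing flowering-time gene orthologs in two
cereal-like genomes — a hexaploid with A/B/D subgenomes and a diploid —
starting from a curated set of flowering genes in an Arabidopsis-like
reference. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Ortholog prediction

### Search engine

All similarity searches run on an exact affine-gap aligner:
Smith–Waterman for local search, Needleman–Wunsch for the global alignments
behind the per-pathway similarity summaries. Genome-scale practice uses
heuristic tools for this step; at the desk scale this package targets, an
exact engine is affordable and buys determinism and oracle-checkability
(scores are verified against an independent recursive oracle on short
sequences in the test suite). Externally produced 12-column tabular hit
files can be ingested interchangeably through `core_io`.

Conventions:

* a gap of length *L* costs `gap_open + L·gap_extend` (defaults −11/−1,
  BLOSUM62);
* significance uses the Karlin–Altschul form `E = K·m·n·exp(−λS)` with
  gapped protein defaults `K = 0.041`, `λ = 0.267`; `m` is the query length
  and `n` the total residue count of the database searched at that step, so
  E-values carry database-size semantics;
* bit score `S′ = (λS − ln K)/ln 2`;
* hits are ranked by ascending E-value, then descending bit score, then
  lexicographic subject id — a total order, so rankings (and everything
  downstream of the top-*k* rule) are deterministic and independent of
  database ordering.

The score kernel is a numba-compiled rolling-array Smith–Waterman
(score-only); full tracebacks (identity, similarity, aligned intervals,
match length) are computed with Biopython's `PairwiseAligner` only for
pairs that already pass the E-value gate, which keeps the all-vs-all stages
fast. Global-similarity calls canonicalize argument order before aligning,
so symmetry is exact even when several global alignments are co-optimal.

### Two-round reciprocal screen

Round 1 searches every reference flowering protein against each target
proteome at `E < 1e-5` (microRNA reference entries carry no protein and are
excluded). Round 2 searches every hit target protein back against the
reference proteome; a target gene is retained only if its originating
reference gene ranks among its top-3 reverse hits (distinct subject genes,
after collapsing multiple HSPs per pair to the best one). Ranking uses the
E-value order above; whether the original protocol ranked by E-value or bit
score is not documented, so the choice is explicit here and configurable
through the scoring scheme. Targets with no reverse hits cannot satisfy the
rule and are rejected. Retention is monotone in *k* by construction.

### Similarity graph and Markov clustering

Reference plus retained candidates enter an all-vs-all comparison. A
directed hit contributes to an edge only if `E < 1e-5` **and** the aligned
length is at least 50% of the shorter sequence (the classic orthogroup
admission criterion; the denominator choice — shorter sequence — is
configurable). Edge weight is the mean over contributing directions of
`−log10 E`, with E-values at or below `1e-300` clamped to 300 so vanishing
E-values stay finite. The graph is species-agnostic: the in-paralog weight
rescaling of the full OrthoMCL algorithm is not implemented (the upstream
protocol used the hosted service as a black box); at this scale the
inflation parameter controls granularity adequately.

Markov clustering iterates expansion (matrix squaring) and inflation
(entry-wise power 1.5, column renormalization) with pruning of entries
below `1e-5`, from a column-stochastic matrix built with self-loops equal
to each node's maximum incident weight (1 for isolated nodes). Columns that
prune to zero mass are re-seeded on the diagonal. Convergence is a maximum
entry change below `1e-6`; non-convergence after 100 iterations returns the
current state with a warning. Clusters are the connected components of the
converged matrix's symmetrized support — this always yields a partition and
merges overlapping attractor systems deterministically.

Clusters without a reference flowering gene are dropped; the survivors
become orthogroups with ids assigned by sorted member content (stable
across clustering order). Per species pair, member counts map to
one-to-one / one-to-many / many-to-one / many-to-many / absent. Each target
gene inherits the description and functional group of its best reference
hit; a target without hits is annotated "no transfer" and counted as
uncharacterized in the annotation-status summary (it stays in the
denominator).

A robustness mode (`cluster_scope="all"`) clusters the reference plus the
*entire* target proteomes instead of the screened candidates; on the
default synthetic scenario both scopes retain the same number of
orthogroups.

## Characterization

* **Structure summaries** pool exon counts and exon/intron sizes over all
  transcripts of all genes (not a canonical transcript; the original
  report's choice is not documented, so the pooled definition is fixed here
  and mirrored by the brute-force oracle in the tests). Intron statistics
  use only transcripts with ≥ 2 exons; single-exon genes contribute no
  intron values and a species or orthogroup whose members are all
  single-exon reports NA, never zero. Gene length is the gene-feature span.
  Coordinates are GFF3 1-based inclusive; lengths are `end − start + 1`.
* **Chromosome distributions** count genes per chromosome × functional
  group. Genes with a known chromosome but unknown position receive
  uniform-random coordinates on that chromosome under a caller-supplied
  seed (flagged approximate); placement never changes counts. Unknown
  chromosome names count as unplaced.
* **Longest isoform** selection breaks length ties by smallest transcript
  id.
* **Shared domains**: a domain is shared in an orthogroup iff it occurs in
  at least one member of *every* species represented (configurable to
  any-pair). The sharing rate is computed over orthogroups with at least
  one target-species member. Rows of domain input without an integrated
  IPR accession are retained but never enter sharing computations.
* **Per-pathway similarity** aggregates global-alignment percent similarity
  (fraction of alignment columns with a positive substitution score) over
  all cross-species member pairs within orthogroups whose reference members
  belong to the pathway; an orthogroup whose reference members span several
  pathways contributes its pairs to each. SD is the sample SD (n−1),
  reported as NA for a single pair. Best-hit-only aggregation would also be
  defensible; the all-pairs population is the documented default.
* Percentages are rounded half away from zero — one decimal where the
  summary tables print decimals, integers elsewhere.

## Expression analysis

Inputs are normalized log2 matrices (probe sets × tissue-replicate
samples) with a sidecar sample table; array normalization is out of scope.
Probe sets map to genes by best infix alignment of the probe target
sequence inside the gene sequence (edit-distance identity
`100·(1 − d/len)`, thresholds 95% identity and 100 nt minimum length);
several probes may map to one gene, in which case the gene profile is their
mean.

"Expressed" means at least one tissue mean (over replicates) at or above
the detection threshold τ. The arrays behind the original presence calls
define no intensity cutoff, so τ is an explicit parameter, default 6.0 log2
units; the published expressed-fraction worked examples are therefore
checked on count-level fixtures, not by threshold sensitivity. "Highly
expressed" is a grand mean over all replicate-level samples strictly above
10 log2 units (the boundary value is excluded).

Cross-species comparison first intersects tissue vocabularies (keeping
species-A order; with the default designs this drops exactly the diploid's
two extra developing-caryopsis samples, 10 and 16 days after pollination),
then computes Pearson correlation (Spearman optional) over shared tissues
for every cross-species member pair per orthogroup. Pairs with an
unexpressed member are reported with correlation NA and status
`inactive-partner` — these are the silenced-paralog candidates — and pairs
with an unmapped member or a zero-variance profile are flagged rather than
dropped. Heatmap ordering uses complete-linkage agglomerative clustering on
euclidean distance (correlation distance optional) of both axes; the
reordered TSV is the reproducible artifact, the SVG is a convenience
rendering.

## Synthetic data generator

The generator produces the whole input bundle with known ground truth:

* ~200 reference genes split over 7 functional groups (proportions
  7:41:19:7:32:69:15) and 5 chromosomes (48:33:32:25:52), protein lengths
  lognormal with mean 529 aa; 14 protein-less microRNA entries excluded
  from search input;
* per reference gene, 0–3 hexaploid homoeologs on distinct A/B/D
  subgenomes of the homologous chromosome group (distribution
  {0: .05, 1: .25, 2: .30, 3: .40}) and 0–2 diploid copies
  ({0: .05, 1: .55, 2: .40}, mean 1.35 — the scaled-down counterpart of the
  ~1.5 diploid copy average);
* planted proteins mutated to 70% mean identity (per-group offsets make
  vernalization least conserved: −10 points), substitutions biased 70%
  toward BLOSUM62-positive partners, with at most two short indels (≤ 2% of
  length) so realized global identity lands within a few points of the
  request;
* 40 decoys per species drawn i.i.d. from the reference residue
  frequencies — a clean negative class unrelated to any family;
* exon/intron structures with species intron-length scales 468 bp
  (reference), 924 bp (hexaploid), 856 bp (diploid) and ~8% single-exon
  genes; alternative-splicing propensity per species (1.4 / 1.0 / 2.8 mean
  transcripts);
* chromosome placement rates 1.0 / 0.58 / 0.97, so the hexaploid has the
  realistic share of position-less genes;
* family-conserved synthetic IPR accessions (1–13 per family, retention
  0.95 per member; decoy domains disjoint);
* expression: each family has a latent standardized tissue profile; a
  member's tissue means are `8 + 2·(√r·z + √(1−r)·ε)` with replicate noise
  N(0, 0.5²), where `r` is the configured ortholog profile correlation
  (default 0.8) inflated analytically to compensate for the replicate
  noise surviving tissue averaging, so the *observed* tissue-mean
  correlation targets the configured value; duplicate copies are silenced
  (constant ≈ 2 log2 units) with probability 0.1 each, emulating virtually
  unexpressed paralogs; probe targets are exact 200-nt substrings of
  synthetic transcripts, so mapping truth is exact; the diploid design
  carries the two extra caryopsis samples.

What the generator does *not* emulate: phylogenetically realistic sequence
evolution (no tree, no codon model), probe-level intensity physics,
cross-hybridization, genes absent from the chip, and real genome assembly
artifacts. Passing the recovery tests therefore shows that the pipeline's
logic is correct under its own assumptions — clean planted homology against
random decoys — not that its thresholds are optimal for real proteomes.

## Problem sizes and determinism

The default recovery scenario (200 reference genes, ~680 planted copies
plus 80 decoys, full-length proteins) involves roughly 4×10⁵ exact pairwise
comparisons; a shared symmetric score cache (`build_scorer`) lets the
candidate-scope run and the whole-proteome robustness check reuse every
alignment, and the same cache serves both search directions since
Smith–Waterman scores and alignment statistics are pair-symmetric while
E-values stay directional. Unit tests run on a compact study (20 reference
genes, 220-aa proteins) with the same structure.

Every stochastic step — generation, placement, clustering — is driven by
explicit seeds; identical inputs and seeds give byte-identical outputs,
which the tests assert at file level.

## Known limitations

* The in-paralog normalization of the full OrthoMCL weighting scheme is
  absent; very large within-species expansions may fragment differently
  than the hosted service would.
* E-value calibration uses fixed gapped Karlin–Altschul parameters rather
  than composition-adjusted statistics.
* The detection threshold τ has no empirical anchor in presence-call data;
  expressed fractions on real arrays depend on it.
* Probe mapping by edit distance ignores splice-aware alignment; for real
  probe sets designed across exon junctions, identities are conservative.
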