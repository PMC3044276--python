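# Methods

## Assignment model

`blastbin` treats a BLAST tabular file as the complete evidence for a
sample: each read's candidate origins are its alignments, ranked by bit
score. The bit score is the only ranking key (e-values are carried but
unused for ranking; they compress to 0 for strong hits and rank less
stably across query lengths). Ties in bit score are broken by ascending
subject accession so that "best hit" is a deterministic function of the
hit *set* — assignments are invariant under permutation of input lines.

Two pre-filters run per read, in a fixed order:

1. **Score floor** `min_score` (default 35 bits): hits below it are
   discarded. 35 bits is the conventional import default for short-read
   LCA binning; lower values admit spurious alignments of short reads.
2. **Top-percent window** `top_percent` (default 10): among hits above
   the floor, only those within 10% of the best retained score are kept.
   The window is computed from the best hit that *survived the floor* —
   a sub-threshold best hit cannot set the window. This ordering makes
   the filter idempotent.

**SEED roles.** A read is assigned to the role of its best filtered hit
whose accession appears in the accession→role table. Restricting the
argmax to *mapped* hits (rather than failing when the single top hit is
unmapped) uses more of the evidence and matches the KO rule below; a
`strict` flag switches to top-hit-only semantics for users who want the
more conservative reading. Exactly one role per read; no fractional
assignment.

**KO.** Identical semantics against the accession→KO table: the best hit
*for which a KO is known* wins.

**Taxa.** The read is placed on the LCA of the taxa of all filtered
mapped hits. The LCA is computed by root-path intersection (trees here
are ~10⁴ nodes and reads have ≤ tens of hits; no sparse-table machinery
is warranted). Accessions mapped to taxa absent from the loaded taxonomy
(version drift between map and tree) are skipped with a warning rather
than failing the run; if nothing remains the read is `NotAssigned`.

**Bins.** `NoHits` = the read produced no parseable alignments;
`NotAssigned` = it had filtered hits but none with a usable mapping.
Bins are never promoted, summarized or normalized into the tree.

**Min-support promotion** (`min_support`, default 5, taxonomy only):
after profiling, any non-root node with 0 < assigned < `min_support`
moves its reads to its immediate parent, deepest nodes first, iterated to
a fixpoint. Reads are conserved exactly; promotion moves, never drops.

## Counting on a multi-labeled tree

The SEED tree may carry one role on several leaves. A read assigned to
such a role is displayed at *every* leaf bearing it — the tree view then
shows the role inside each subsystem it belongs to — so tree-view counts
overcount by the label multiplicity. Alongside, a unique-read tally per
role is kept: summing it over distinct roles equals the number of
functionally assigned reads, which is the conservation audit and the
count used for between-sample distances. Whether per-subsystem totals
should count a shared role once or once-per-subsystem is a genuine
convention choice; both views are emitted so either audit is possible.

Profiles store `assigned(n)` (reads exactly at n) and derive
`summarized(n) = assigned(n) + Σ_children summarized` bottom-up on
demand; the recurrence is asserted in tests for every generated profile.

## Distance indices

All six ecological indices operate on column-relative abundances of a
row × sample table. The recommended (and CLI-default) rows are the
functional-role unique-read counts: one hierarchy level, no read counted
at both a node and its ancestor. Formulas are in the module docstring;
two warrant comment:

* **Chi-square** weights each row by its mean relative abundance across
  all samples, so the pairwise distance depends on the full table
  (zero-mass rows are dropped). It is unbounded above, unlike
  Bray-Curtis/Kulczynski/Goodall/UniFrac which live in [0, 1].
* **Goodall** is named in the comparative-metagenomics literature without
  a formula; we implement Goodall's probabilistic similarity as
  operationalized in standard ecology texts. Per row, a pair's agreement
  `1 − |x_i − y_i| / range_i` is converted to the fraction `p_i` of all
  sample pairs at least that similar (rows with zero range are skipped);
  Fisher's method combines them (`χ² = −2 Σ ln p_i`, `2m` d.f., `m` =
  contributing rows) and the distance is the upper-tail probability.
  When no row varies the samples are indistinguishable and the distance
  is defined as 0. This is a documented variant — the index family is
  pluggable, and with only two samples every `p_i` is 1, so Goodall is
  only informative for ≥ 3 samples.

**UniFrac** runs on the hierarchy with unit branch lengths (the trees
here are classifications, not phylograms). Every non-root node is a
branch whose mass is the total assigned count in its subtree; the input
table must therefore hold per-node *assigned* counts (a summarized-mode
table would double count). Unweighted = unique read-carrying branches /
all read-carrying branches; weighted-normalized = Σ|A_b/A_T − B_b/B_T| /
Σ(A_b/A_T + B_b/B_T). Both are verified against a brute-force
per-branch enumeration and against scikit-bio's implementation on
tip-only tables.

Matrix writers (PHYLIP square, NEXUS Distances, edge TSV) emit 6 decimal
digits, locale-independent.

## Synthetic data generator

The generator fabricates the entire reference world and the BLAST output,
not sequences — sequence simulation would exercise an aligner, which is
upstream of this artifact. Defaults: a depth-3, 3-ary taxonomy (27 leaf
taxa); 6 subsystems × 4 roles with 25% of roles labeling a second leaf in
the neighboring subsystem; 60 reference accessions (round-robin over
roles so none is empty); one KO per role, each KO in 1–2 of 4 pathways;
200 reads per sample with 1–5 hits each; 2% of reads hitless.

Per read, the intended reference's hit gets a bit score uniform in
[80, 200] and all decoys score below 0.85× of it — strictly outside the
10% top-percent window — so at noise 0 the pipeline *must* recover the
truth table exactly; any miss is a defect, not sampling error. With
probability `noise_rate` the top hit is swapped for a reference annotated
with a different role, emulating a wrongly annotated database entry, so
role-recovery accuracy falls roughly as 1 − noise. All randomness flows
from one `numpy` generator seeded by the spec; bundles are byte-identical
across runs.

The 8-sample canned design (`eight_sample_bergen_like`) emulates a paired
mesocosm study in *shape* only: four DNA samples share a Dirichlet(2)
base role profile with lognormal jitter (σ = 0.1); the four cDNA samples
apply a systematic 4× up-shift to half the roles before renormalizing,
plus the same jitter, and carry 5% annotation noise. This guarantees the
property the comparison figures rely on — same-condition samples mutually
closer than cross-condition pairs — without claiming any biological
realism. What the generator does not emulate: alignment-score/identity
correlation, conserved multi-gene families (hit taxa are independent),
database composition bias, chimeras, and read-length effects. Passing
recovery tests therefore validates the binning logic and bookkeeping, not
annotation accuracy on real communities.

## Cross-tool comparison report

The reporting helper takes published assignment counts as inputs and
recomputes rates: given 1408 reads with 727 and 831 assignments by two
tools, it reports 51.6% / 59.0% of reads assigned and 87.5% of the
reference tool's assignments (the benchmark that originally publicized
this comparison printed this ratio as 88%, consistent with rounding the
one-decimal value). Re-running the underlying large-scale annotations
requires the NCBI-NR database and the original reads and is out of scope;
the counts themselves are the inputs.

## Numerical and degenerate-input choices

* Relative normalization refuses zero-total columns by name; UniFrac
  refuses zero-mass samples. Empty assignment lists produce valid all-zero
  profiles; empty mapping files load with a warning.
* Duplicate mapping rows are tolerated when consistent and fatal (naming
  the accession) when conflicting.
* Hierarchy validation rejects cycles, multiple roots and roles on
  internal nodes at construction; every query operates on a validated
  tree.
* Problem sizes in the test and acceptance runs (≤ 50-node random trees,
  ≤ 20 hits/read, 100 oracle fixtures, 10 seeds × 4 noise levels at
  50–200 reads) were chosen so the full suite exercises every code path
  in seconds while keeping Monte-Carlo effects far smaller than the
  effects asserted.

## Known limitations

* No rarefaction, significance testing of distances, or ordination — the
  matrices are exported for dedicated tools.
* Newick input is labels-only; branch lengths are discarded (UniFrac is
  deliberately unit-length on classifications).
* Only tabular BLAST (outfmt 6) is parsed; DIAMOND/SAM and pairwise text
  reports need external conversion.
* The strict-mode/mapped-mode distinction for SEED assignment changes
  results only when top hits are unmapped; with sparse mapping tables the
  two can differ materially, and the default (mapped mode) assigns more
  reads.
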