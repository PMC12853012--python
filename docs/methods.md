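# Methods

## Scope and model

`drpeptidome` analyses HLA-DRB1-restricted immunopeptidomes eluted from
antigen-presenting cells of HLA-heterozygous donors. The driving question
is how the two co-expressed DRB1 alleles of a donor divide the presented
peptide repertoire between them, and how exposure to a tumour-cell-lysate
"pulse" reshapes that division. The package operates downstream of mass
spectrometry: its inputs are identified peptide sequences with source
proteins, per-sample DRB1 typings, and per-(peptide, allele) predicted
binding percentile ranks in the NetMHCIIpan output dialect. It does not
search spectra and does not re-implement a neural binding predictor.

## Repertoire cleaning

Eluted-peptide lists are cleaned by provenance and length:

* peptides whose source accession is in a caller-supplied contaminant
  list (keratins, bovine serum proteins) are removed — removal is
  accession-driven, not homology-driven, so it is reproducible without an
  external database; a peptide is treated as contaminant when *any* of
  its source accessions is in the list;
* peptides outside the 9–25 residue class II length window are removed.

Rules apply in that order and each removed record carries exactly one
reason, so the report counts partition the input exactly.

Within each source protein, peptides are grouped into **nested sets**:
the relation "shares a contiguous substring of ≥ 9 residues" (the typical
class II binding-core length) is closed transitively, and each connected
group reports the longest substring common to all members as its core
(ties broken by leftmost occurrence in the longest member). In long
transitive chains the all-member core can fall below 9 residues; this is
logged rather than forbidden.

## Binding classes and dual-peptide assignment

Percent ranks are discretised with `sb_max = 1`, `wb_max = 5`:
SB = [0, 1), WB = [1, 5], NB = (5, 100]. The usual strict-inequality
phrasing leaves ranks of exactly 1 and 5 undefined; the half-open
convention closes those gaps without reclassifying any interior value.

A peptide predicted to bind both co-expressed alleles (SB or WB on both)
is a **dual peptide**. Two assignment conditions are computed:

* **non-filtered** — every binder peptide is credited to each allele it
  binds; dual peptides appear under both alleles;
* **filtered** — every peptide is credited only to the allele with the
  lower percent rank. Raw ranks, not SB/WB classes, decide the winner;
  exact ties go to the canonically first allele with a logged warning so
  runs are reproducible.

Peptides binding neither allele are excluded. Homozygous samples put all
binders on their single allele; the dual category is not applicable.

## Repertoire statistics

The unit of comparison is an **allele unit**, one (sample, allele) pair;
the same allele in two donors is deliberately kept as two units.

* **Dominance**: ratio of exclusive-peptide counts of the two alleles of
  a sample (canonical order), computed on filtered assignments by
  default; ratio > 1 means the first allele dominates presentation. The
  inverse ratio is reported alongside; zero denominators yield +inf or a
  flagged undefined result.
* **SB/WB fractions**: per allele unit, the fractions of its assigned
  peptides that are strong vs weak binders for that allele, normalised to
  sum to one.
* **Overlap matrix**: off-diagonal (i, j) is |items_i ∩ items_j| /
  |items_i| — the fraction of unit i's repertoire shared with unit j.
  Row normalisation makes the matrix symmetric in support but not in
  value; both directions are emitted. The diagonal holds the exclusivity
  fraction: items of unit i found in no other unit. Computed at peptide
  or at source-protein level.
* **Sharing classes**: every (peptide, unit) association is classified
  as `unique` (one unit overall), `dual` (both alleles of one sample,
  nowhere else), `allele_exclusive` (≥ 2 samples, always the same
  allele), or `multiple` (anything spanning several alleles across
  samples). A peptide that is dual in one sample and also seen elsewhere
  is `multiple`: cross-sample presence dominates, keeping the four
  classes mutually exclusive and exhaustive.

## Pulse-induced proteins

With P = source proteins of pulsed-sample binder peptides, C = source
proteins of control samples, and L = the lysate proteome, the
pulse-induced set is `(P ∩ L) − C`. A pulsed peptide counts as induced
when at least one of its source accessions is induced (such peptides may
also map to non-induced proteins; the output flags them). Derived
quantities: the induced share of the lysate proteome, the induced share
of the pulsed immunopeptidome (denominator: distinct binder peptides of
the pulsed sample set — the source text does not pin the denominator
down, so this choice is stated rather than hidden), the Spearman rank
correlation between lysate protein abundance and per-protein distinct
induced-peptide counts, and per-compartment Welch t-tests between sample
groups on compartment percentages. Multi-localised proteins count once in
every compartment they carry, so per-sample percentages may exceed 100.
P-values are adjusted by step-down Sidak (Holm-Sidak): the i-th smallest
of m is adjusted to `1 − (1 − p)^(m − i + 1)` with running-maximum
monotonicity, the convention of the usual multiple-unpaired-t-test
workflow at α = 0.05.

## Alignment-based MDS of allele units

1. All pooled binder peptides are pairwise globally aligned
   (Needleman–Wunsch, BLOSUM62, affine gaps). Gap penalties are not
   dictated by the method description; the standard BLOSUM62 pairing of
   open 11 / extend 1 is the default and both are configurable. A gap of
   length L costs open + L·extend.
2. Scores become dissimilarities via `d(a,b) = 1 − S(a,b) /
   min(S(a,a), S(b,b))`, clipped to [0, 1]. Min-self normalisation makes
   identical sequences distance 0 and a contained subsequence score near
   0; max-self normalisation is available. The result is a dissimilarity,
   not a metric — the triangle inequality is not asserted.
3. Average-linkage hierarchical clustering groups homologous peptides and
   nested sets; the cluster count k maximises the mean silhouette width
   over a grid (default 2..min(50, n−1)), ties to the smallest k. Both
   choices favour determinism over stochastic alternatives.
4. Each allele unit becomes a relative-frequency vector over the k
   clusters; in non-filtered mode dual peptides feed both co-expressed
   units. Empty units get a zero vector with a warning.
5. Classical (Torgerson) metric MDS — double-centred squared distances,
   eigendecomposition, top-2 axes, deterministic sign convention (first
   nonzero loading positive) — projects inter-unit Euclidean feature
   distances to 2D. Classical MDS is chosen over SMACOF because it has no
   random start; rank-deficient inputs embed in 1D and zero-pad.
6. The filtered and non-filtered configurations are brought into a common
   frame by Procrustes alignment (translation + rotation/reflection, no
   rescaling, so non-filtered distances keep their own scale) and the
   per-sample co-expressed-pair distance change
   `delta = dist_filtered − dist_nonfiltered` is reported. Positive delta
   means dual peptides pull the pair together.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with full ground truth, so every stage is testable without any external
download.

* **Motifs.** Each allele has a 9×20 log-odds matrix with anchor
  positions P1/P4/P6/P9; anchor columns put weight `strength` on one
  residue, non-anchor columns are near-uniform (noise scaled by
  strength; strength 0 is exactly uniform). The built-in anchor table
  gives overlapping anchors to allele pairs whose real counterparts share
  binding preferences (e.g., both Asp-at-P4 alleles) and higher strength
  to the alleles that dominate presentation in practice.
* **Percent ranks.** A peptide's score is the best 9-mer-window PWM sum;
  its rank is the percentage of a fixed seeded background (10 000 random
  15-mers, shared across alleles so ranks are comparable within a
  sample) scoring strictly higher, with background ties broken by a
  deterministic per-sequence hash draw so ranks stay continuous even for
  flat motifs. This mirrors percentile-rank semantics only loosely — a
  real predictor calibrates per allele and models peptide context — and
  that limitation is intentional: the pipeline consumes ranks, it does
  not validate predictors.
* **Cohorts.** Defaults are the study conditions: 14 samples (8 control,
  6 pulsed; one homozygous; 13 alleles in 11 unique heterozygous
  combinations), per-sample totals summing to 2899 with median 195,
  truncated-normal 15 ± 2.5 lengths in 9–25, per-sample dual fractions
  spanning 0.14–0.62, planted dominance ratios spanning 0.1–20.25, a
  1292-protein lysate with 58 induced proteins yielding 120 peptides,
  ~0.8% planted contaminants and ~0.5% length outliers, and a 31.5%
  non-binder rate — proportions that reproduce the 2863/2899 and
  1947/2899 cleaning/binder ratios. Exclusive peptides are rejection-
  sampled from one allele's motif and must not bind the other; dual
  peptides are sampled from the blended PWM and must bind both, with the
  winner split chosen so the filtered-count ratio realises the planted
  dominance; bounded rejection failure raises an error advising anchor
  sharing. A fraction of binders is reused across samples carrying the
  same allele (cross-donor sharing), nested-set families share a core and
  a source protein, and induced peptides are fresh singletons so set
  logic recovers the planted counts exactly. Everything derives from one
  seed; identical configs give byte-identical outputs.
* **What is not modelled.** MS intensity structure and missingness,
  decoys/FDR, peptide-flanking-residue effects, HLA-DM editing, secondary
  DRB loci, I/L indistinguishability. Passing tests therefore demonstrate
  correctness of the set/ratio/embedding machinery under the planted
  statistical structure, not predictor accuracy on real spectra.

## Problem sizes and numerics

The default test and acceptance runs keep pairwise alignment pools at or
below a few hundred peptides (the acceptance script subsamples the pooled
binders to 450 for the MDS stage; recovery experiments use single samples
of 500 peptides over 10–20 seeds), sizes at which every stage is exact
and the whole analysis completes in well under a minute per cohort on one
core. Distances are clipped to [0, 1]; eigenvalues below 1e-10 are
treated as zero in the MDS; silhouette ties resolve to the smallest k;
rank ties in filtered assignment resolve to the canonical allele with a
warning. Degenerate inputs (all-identical peptides, empty units,
zero-binder samples, homozygous donors) are handled explicitly and
exercised in the test suite.

## Known limitations

* Peptide identity is exact string equality; isoleucine/leucine are
  distinct symbols as reported by the search engine even though MS cannot
  distinguish them.
* Contaminant removal is provenance-based; an exact-match screen against
  a bovine proteome would be a natural extension.
* The overlap heatmap normalisation (row-wise) is one of several
  defensible conventions; qualitative statements (co-expressed alleles
  sharing > 0.2 of their repertoires) are robust to the choice, exact
  cell values are not.
* Whether allele units should be pooled across donors carrying the same
  allele is left to the caller; the default keeps per-donor units.
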