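# drpeptidome

Analysis of HLA-DRB1-restricted immunopeptidomes from HLA-heterozygous
donors. The package is written for immunopeptidomics groups who elute
HLA-DR-bound peptides from antigen-presenting cells (e.g.,
monocyte-derived dendritic cells, optionally pulsed with a tumour-cell
lysate), identify them by LC-MS/MS, and predict per-allele binding with
NetMHCIIpan-style percentile ranks. Starting from those tables it
answers: how do the two co-expressed DRB1 alleles of each donor divide
the presented repertoire, which allele dominates in which pairing, and
which proteins enter presentation only after lysate pulsing?

## What it computes

* **Repertoire cleaning** — removal of handling contaminants (keratins,
  bovine serum proteins) by accession and of peptides outside the 9–25
  residue class II window; nested-set grouping of peptides sharing a
  ≥ 9-mer core within one source protein.
* **Binding classes and assignment** — percent ranks discretised as
  SB (%Rank < 1), WB (1 ≤ %Rank ≤ 5), NB; each binder peptide assigned
  either to every allele it binds (*non-filtered*, dual peptides counted
  twice) or only to its best-ranked allele (*filtered*).
* **Dominance** — the ratio X/Y of exclusive peptide counts between
  co-expressed alleles; X/Y > 1 means allele X dominates presentation.
* **Overlap and sharing** — row-normalised overlap matrices between
  (sample, allele) units at peptide or protein level, with per-unit
  exclusivity fractions on the diagonal; four-way sharing classes
  (unique / dual / multiple / allele-exclusive).
* **Pulse-induced proteins** — set logic `(P ∩ L) − C` over pulsed,
  control and lysate protein sets, the induced share of the lysate
  proteome and of the pulsed immunopeptidome, abundance-vs-representation
  Spearman correlation, and per-compartment Welch t-tests with
  Holm-Sidak correction.
* **MDS allele embedding** — BLOSUM62 global-alignment peptide distances,
  silhouette-selected average-linkage clustering, per-unit cluster
  frequency vectors, classical (Torgerson) MDS to 2D, and
  Procrustes-aligned distance changes between the filtered and
  non-filtered conditions (dual peptides pull co-expressed alleles
  together).
* **Synthetic cohorts** — a fully ground-truthed generator (PWM motifs
  with P1/P4/P6/P9 anchors, emulated percentile ranks against a seeded
  background, planted dual fractions, dominance ratios, nested sets and
  induced proteins) so the whole pipeline is testable end to end without
  any external data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Run the whole pipeline on a simulated 14-sample cohort (8 control, 6
lysate-pulsed, 13 DRB1 alleles) with 120 eluted peptides per sample:

```python
import drpeptidome as dp

cfg = dp.RunConfig(
    outdir="results/demo",
    seed=7,
    simulate={"peptides_per_sample": 120},
    mds_max_peptides=300,
    mds_k_max=25,
)
report = dp.run_pipeline(cfg)

for k in (
    "n_peptide_observations", "n_after_cleaning", "n_binder_peptides",
    "n_induced_proteins", "n_induced_peptides",
    "induced_pct_of_lysate", "mean_mds_delta",
):
    print(k, "=", report[k])
print("dual_fraction[P-1912] =", round(report["dual_fraction"]["P-1912"], 3))
print("dominance[P-1901] =", round(report["dominance"]["P-1901"], 2))
print("dominance[C-2102] =", round(report["dominance"]["C-2102"], 2))
```

which prints (seed 7):

```
n_peptide_observations = 1680
n_after_cleaning = 1652
n_binder_peptides = 1120
n_induced_proteins = 58
n_induced_peptides = 120
induced_pct_of_lysate = 4.489164086687307
mean_mds_delta = 0.16717718454614167
dual_fraction[P-1912] = 0.625
dominance[P-1901] = 10.43
dominance[C-2102] = 19.0
```

Reading the numbers: of 1680 eluted peptide observations, 1652 survive
contaminant/length cleaning and 1120 bind at least one of their sample's
alleles. The 58 planted lysate proteins absent from controls are
recovered exactly (4.5 % of the 1292-protein lysate proteome, 120
peptides). Sample P-1912 presents 62 % of its binders on both alleles
(dual peptides), while in P-1901 the dominant allele holds ~10× more
exclusive peptides than its partner. The positive mean MDS delta says
co-expressed alleles sit closer together once dual peptides are included
(non-filtered) than when each peptide is forced onto its best allele
(filtered). Per-stage tables (assignments, dominance, overlap matrices,
sharing classes, induced sets, MDS coordinates and distance changes) are
written under `results/demo/`, followed by a `manifest.json` whose
presence marks a complete run.

The same stages are available as a CLI:

```bash
drpeptidome simulate --seed 7 --out cohort/
drpeptidome filter --peptides cohort/peptides.tsv \
    --contaminants cohort/contaminants.txt --out clean.tsv
drpeptidome assign --peptides clean.tsv --samples cohort/samples.tsv \
    --binding cohort/binding_calls.tsv --out assigned.tsv
drpeptidome dominance --assignments assigned.tsv \
    --samples cohort/samples.tsv --out dominance.tsv
drpeptidome run --config run.yaml --seed 7
```

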