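# Methods

This note records the statistical model, the defaults and the design
choices behind `lipdiff`, and what the synthetic benchmark does and does
not establish about real data.

## Coordinates and peptide provenance

Residue coordinates are 1-based inclusive; a cut-site index *i* means
cleavage between residues *i* and *i*+1. Trypsin specificity is cleavage
after K or R, suppressed before proline. The proline rule is a package
choice (it matches the default trypsin definition of common search
engines) and is isolated in a single predicate, so an alternative rule is
a one-line change.

A peptide terminus is *tryptic-consistent* if it coincides with a protein
terminus, follows a K/R not before P, or begins at residue 2 of a
Met-initiated protein (N-terminal methionine excision is protein
processing, not a PK cut). The four provenance classes follow from the
two termini: fully tryptic, half-tryptic with a PK-derived N- or
C-terminus, and non-tryptic (both termini PK-derived). Half-tryptic
peptides map to one PK-inferred cut-site, non-tryptic peptides to two.
Fully tryptic peptides are *retained* as evidence keyed by their span
rather than dropped or collapsed to a residue: PK consumption of a region
depletes the overlapping tryptic peptide, so its abundance change reports
on internal cleavage, and downstream statistics treat span keys and site
keys uniformly. The exact span-merging convention of upstream LiP
processing tools is not standardized; the span-key choice is documented
here as this package's convention rather than asserted as anyone else's.

## Differential model

All statistics run on log2-transformed merged intensities; a fold change
is a difference of group means on that scale. This is standard label-free
practice: multiplicative noise becomes additive, and Welch's test does
not assume equal variances between conditions.

* **Imputation.** Floor = the 1st-percentile (configurable) of all
  non-missing LiP intensities in the compared samples, one constant per
  dataset, not per protein. An ion observed in ≥ `min_observed_per_group`
  (default 2) replicates of one group and 0 of the other has the empty
  group set to the floor and is flagged `imputed`; ions below the
  observation minimum in both groups are dropped. A per-dataset constant
  keeps exclusive-ion fold changes large but capped and their p-values
  computable (the imputed group has zero variance, which Welch handles).
* **Merging.** Per cut-site and per sample, intensities of contributing
  ions are summed; a sample with no observed ion stays missing. Merge
  first, then test: the alternative (test per ion, then combine) is noted
  as an option but not implemented, since summing first uses the full ion
  evidence in one test and keeps the per-site fold change interpretable.
* **Welch's t-test.** Hand-vectorized (NaN-aware) with the
  Welch–Satterthwaite degrees of freedom; `scipy.stats.ttest_ind` is the
  cross-check oracle in the tests. Sites need ≥ 2 observed replicates per
  group. Degenerate cases: both groups constant and equal → p = 1 (no
  evidence of change); both constant and unequal → t = ±∞, p = 0 (this
  arises only in noise-free synthetic data).
* **Normalization.** Protein abundance per sample is the sum of fully
  tryptic ion intensities in trypsin-only controls — a deliberately simple
  label-free summary whose defining property (a uniform abundance shift
  moves every peptide equally, hence cancels exactly in the subtraction)
  is what the normalization needs and what the tests verify. The
  protein-level log2 ratio is subtracted from each site's raw log2 fold
  change; proteins absent from the control analysis keep their raw value
  and are flagged `normalized=False`. Refolding-style analyses skip
  normalization entirely (`normalize=False`), since refolded and native
  aliquots come from the same material.
* **FDR.** Benjamini–Hochberg step-up with monotonicity enforcement,
  applied within each protein across its cut-sites ("protein-wise"): each
  protein is one hypothesis family, so a protein with many quantified
  sites does not pay for the whole proteome's multiplicity. A global-BH
  mode (`bh_scope="global"`) is provided for sensitivity analysis.
* **Significance.** |log2FC_norm| ≥ log2(2) AND p_adj < 0.05 (strict
  inequality on alpha; ties at exactly 0.05 are not significant). When a
  protein lacks an abundance estimate the criterion applies to the best
  available (raw) value, with the unnormalized flag carried through.

## Protein calls

Perturbed ⇔ ≥ 2 significant sites; excluded ⇔ < 2 quantified sites;
otherwise unperturbed. Exclusion takes precedence: one quantified site
cannot assess a protein even if it is significant. Significance is
decided entirely in the differential layer — the calling layer never
re-tests, so thresholds have a single source of truth. The headline
percentage is 100 × perturbed / (perturbed + unperturbed), excluded
proteins reported separately.

## Comparative statistics

Fisher's exact test is two-sided by the probability-mass rule (sum of
all tables with the observed margins whose probability does not exceed
the observed table's), matching the common default readers will compare
against; a zero margin returns p = 1 with a warning. The chi-square
across feature groups is Pearson's on the k × 2 table without continuity
correction, df = k − 1, with a warning (not a failure) when an expected
cell drops below 1. The two-sample KS test uses the exact null
distribution when both n ≤ 10 (equivalent to permutation enumeration for
tie-free data) and the asymptotic distribution otherwise. Cross-condition
contingency tables are restricted to proteins confidently assessed
(non-excluded) in both call sets. Default bins — pI in 0.5-pH steps over
4–11, molecular weight in 20-kDa steps with a dedicated > 80 kDa bin,
domain counts 1 / 2 / 3 / ≥ 4 — are package defaults and fully
configurable; empty bins are dropped from both the table and the test.
Identifier joins never guess: proteins missing from an annotation table
are logged and dropped.

## Synthetic-data generator

The generator emulates the statistical structure the chain assumes:

* Proteomes are rejection-sampled uniform-composition sequences
  (default 150–400 residues) constrained to yield ≥ 3 tryptic peptides of
  length ≥ 6.
* Per protein, base abundance is log-uniform over 10⁶–10⁹ with
  per-ion response factors log-uniform over 10⁻²–10⁰; tryptic peptides of
  length ≥ 4 become observable ions, and PK cut positions are drawn
  uniformly inside tryptic peptides until half-tryptic ions make up
  ~55% of LiP ions (controls get ~10% spurious half-tryptics at low
  intensity). About 20% of ions appear at a second charge state, which
  exercises ion merging. Position 1 of Met-initiated proteins is never
  used as a PK cut, since the product would be indistinguishable from
  Met excision.
* A designated perturbed site multiplies its half-tryptic ion by the
  configured fold in the test condition, with a compensating decrease of
  the overlapping fully tryptic ion (mass balance — significant "lobes"
  contain both tryptic and half-tryptic evidence). With probability 0.3 a
  perturbed site is *exclusive* instead: its half-tryptic ion is absent
  from the reference condition. Exclusivity is tied to perturbation by
  design — a site cuttable in only one condition is a true structural
  difference — so the null configuration (no perturbed proteins) is a
  clean null for calibration.
* Abundance-shifted proteins multiply *all* their ions (LiP and control)
  in the test condition by a factor drawn from the configured range, in a
  random direction.
* Replicate noise is log-normal with σ² = ln(1 + cv²) (default cv 0.2);
  detection is Bernoulli per ion per sample (default 0.95). Counts
  derived from fractions use round-half-up, so truth sizes are exact.
* One root seed feeds named substreams (proteome / truth / abundance /
  ions / noise / detection / annotation); changing the effect size does
  not change which sites are chosen or which noise is drawn, which makes
  sensitivity monotone comparisons across effect sizes deterministic.

What passing on this benchmark shows: the chain is correctly calibrated
under its own assumptions, rejects abundance confounds exactly in the
noise-free limit, recovers planted effects with high specificity, and
recovers peptide provenance without error. What it does not show:
robustness to retention-time-dependent missingness, shared peptides
between proteins, modification-driven intensity shifts, correlated
replicate noise, or real PK positional preferences — none of which the
generator models.

## Problem sizes and numerics

The test suite runs its calibration at 1000 null proteins and its
recovery benchmark at 500 proteins × {2×, 4×, 8×} effects, sizes at which
every empirical rate in the acceptance checks is stable across seeds
while the whole suite stays fast. The acceptance script uses 500-protein
simulations for the same reason. Floating-point policy: BH uses a stable
mergesort; result tables are written with a fixed `%.10g` float format so
identical inputs give byte-identical files; `manifest.json` is the one
output excluded from byte-identity, since it records a timestamp.

## Known limitations

* Protein inference is out of scope: each ion row carries one protein id.
* The abundance summary is not MaxLFQ; it shares MaxLFQ's invariance to
  uniform shifts but not its robustness to missing peptides.
* Match-between-runs, retention-time alignment and spectrum-level
  modeling happen upstream of this package.
* With fewer than three replicates per group the Welch test is legal but
  weak; the design layer enforces only the ≥ 2 minimum.
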