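# Methods

This note documents the models behind `dicpipe`, the parameters that matter,
what the synthetic scenes do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Differential peak comparison

Read counts in each peak are scaled to reads-per-million of an explicitly
supplied library size, a pseudocount (default 1) is added, and each matched
peak receives `A = ½(log₂ d₁ + log₂ d₂)` and `M_raw = log₂(d₂/d₁)`.  Library
sizes are inputs rather than in-peak totals on purpose: a condition-wide
ChIP-efficiency imbalance must survive the density computation so that the
MA trend fit can measure and remove it — scaling by in-peak totals would
silently absorb it.

The trend `M_raw = a + b·A` is fitted on the matched common peaks with the
Theil–Sen estimator (median of pairwise slopes).  A median-based fit is
robust to the genuinely changed minority of peaks, which would bias ordinary
least squares toward their direction; OLS remains available
(`method="ols"`).  For more than 2,000 common peaks the fit subsamples
deterministically (the estimator is O(n²) in pairs).  Degenerate A (all
equal) fixes the slope at 0 and the intercept at the median M with a
warning.  Change classes use strict inequalities at τ = 0.5: increased iff
`M > τ`, decreased iff `M < −τ`.

Peak matching across conditions: candidate partners overlap by ≥ 1 bp; each
peak pairs with at most one partner, greatest overlap first, ties to the
leftmost partner.  Condition-unique peaks enter the union table with a zero
count on the missing side (the pseudocount keeps their M defined).

## DIC extraction

The call is the conjunction of four predicates — width ≤ 3 kb, normalized
M < −0.5, summit inside an intragenic region, host gene responsive — so
relaxing any one of them can only grow the set (a property the tests
assert).  Intragenic regions are gene body minus 10-kb flanks around TSS and
TES, restricted to genes strictly longer than 20 kb; an optional
extra-exclusion interval list (e.g. alternative promoters) is subtracted,
keeping the largest remaining piece.  Site location uses the peak summit
(midpoint when no summit is given): within 10 kb of any TSS → `aroundTSS`
(the same 10-kb scale as the flank exclusion), else inside an intragenic
region → `intragenic` (host = nearest TSS among overlapping genes), else
`intergenic`.

Responsive genes require an elongation-signal ratio strictly above 1.2
between stimulated and control **and** expression validation, operationalized
as log₂ fold change above a threshold (default 0).  The elongation ratio is
taken over the gene body minus the same 10-kb flanks; this is recorded in
output metadata because the promoter-proximal contribution is a genuine
degree of freedom.

The LC/HC split clusters `log(ctcf_density + 1)` with two-component 1-D
k-means after dropping sites with Rad21 density below `min_rad21` (default
1 per-million); the higher-mean component is HC.  Clustering on logs makes
the split invariant to monotone rescaling of the densities.  An explicit
numeric cutoff overrides clustering when a reproducible published threshold
is preferred.

## Hi-C metrics

All metrics are ratio or log-ratio constructions and therefore invariant to
uniform scaling of the matrix; balancing (iterative proportional scaling of
covered bins to equal row sums, tolerance 10⁻³) is available but not
required by any metric.

* **DLR** per anchor bin: cis contacts at distance > `local_cutoff` over cis
  contacts at distance ≤ `local_cutoff`, each aggregated over a centered
  window; `ΔDLR = DLR_B − DLR_A`, positive where a locus de-compacts.  The
  default cutoff is 3 Mb at genome scale; synthetic scenes use 500 kb,
  proportional to their 20-Mb chromosomes.  Both 5-kb and 25-kb working
  resolutions are supported — resolution is an explicit required parameter
  because both appear in practice.
* **ICF** per bin: inter-chromosomal contacts over total contacts.
* **Insulation score**: log₂ of the mean of the off-diagonal square
  (rows `[i−w, i)` × columns `(i, i+w]`) over the chromosome-wide expected
  mean at the same distance band.  The expectation is the plain per-distance
  mean — simple and exactly reproducible; no smoothing.  Boundaries are
  local minima below a depth threshold (default −0.5) within a ±2-bin
  radius.
* **APA**: `(2r+1)²` submatrices centered on each anchor-pair pixel are
  summed after division by the distance-expected value (`norm="none"` for
  raw counts); score = center over the mean of the r×r lower-left corner
  block — rows below and columns left of center, i.e. the shorter-distance
  background, the conservative corner.  Pairs closer than `2r` bins are
  dropped and counted.  Condition comparison is a paired two-sided t test on
  per-pair central enrichment: pairing on the same anchor list is the
  natural unit when the question is whether the *same* loops weaken.

## Statistics

Fisher's exact test uses the probability-mass two-sided rule (sum of all
fixed-margin tables no more probable than the observed one; this is also
what `scipy.stats.fisher_exact` implements, and the tests verify it against
exhaustive enumeration).  A zero margin returns p = 1 by convention with a
warning.  Mann–Whitney U enumerates all group assignments exactly for
combined samples ≤ 16 (ties handled by the midrank convention) and falls
back to the tie-corrected normal approximation above that.
Benjamini–Hochberg adjustment is the standard step-up transform; note it is
*not* idempotent — re-adjusting adjusted values inflates them again — so
adjusted values must be computed once from raw p-values.

## Machine learning

Binary features are 1 iff the dataset overlaps the site by ≥ 1 bp;
continuous features are z-scored at matrix construction, which is what makes
signed logistic coefficients comparable as feature importances.  The
supervised variant excludes the M value, location and CTCF columns so the
model cannot read the label definition off its inputs.

Evaluation is chromosome-held-out: all sites on the designated test
chromosomes (chr16–22 in the full-genome setting) are untouchable, and the
remainder is divided by 5-fold CV.  SMOTE (synthetic minority rows
`x_i + u·(x_nn − x_i)`, u ~ U(0,1), among the k = 5 nearest minority
neighbors, classes balanced exactly, binary columns re-rounded) is applied
to training rows only — never to validation or test rows.

Elastic-net selection minimizes `RSS/(2n) + λ((1−α)/2‖β‖² + α‖β‖₁)` at
α = 0.5 with λ from 5-fold cross-validation.  The default selection rule is
the **1-SE rule** (largest λ whose CV error is within one standard error of
the minimum): the minimum-error λ is tuned for prediction and is known to
retain many small noise coefficients, which defeats the purpose when the
nonzero set *is* the result; `rule="min"` is available.  The selected-λ fit
is refined at tolerance 10⁻¹⁰ and checked against the subgradient optimality
conditions (`subgradient_residual`).  λ = 0 falls back to OLS exactly.
Survivors get univariate OLS fits `Y = a + bX` for effect-direction
reporting.

Cross-cell-type prediction refits on the feature subset shared between cell
types (a name mismatch is a hard error — silent subsetting would invalidate
the normalization assumption) and scores the overlap between predicted and
experimentally called sites with the upper-tail hypergeometric test.

## Synthetic scenes

The default scene is desk-scale: 2 chromosomes × 20 Mb, 300 non-overlapping
genes (70% longer than 20 kb), ~3,000 cohesin sites (1,000 around TSSs,
1,200 intragenic, 800 intergenic), 90 responsive genes, 100 planted DICs at
fold change 0.5, Hi-C at 25-kb resolution with 100 planted boundaries, 100
DIC-anchored loops (removed in the stimulated condition), 100 stable loops
and 10 de-compaction regions of 5 bins.  Everything is a pure function of
(parameters, seed); the two conditions share per-chromosome Poisson seed
streams so that unperturbed scenes produce literally identical maps.

Peak counts are negative binomial parametrized by a constant overdispersion
factor: variance = μ(1 + φ), i.e. NB size r = μ/φ, with φ = 0.1 and baseline
mean 200.  This keeps the coefficient of variation falling with coverage, as
for well-covered ChIP peaks; under the alternative constant-CV
parametrization (variance = μ + φμ²) the M-value noise floor would be ~0.65
log₂ units regardless of coverage and no threshold at −0.5 could separate a
2-fold loss reliably — a generator property, worth knowing when mapping φ
onto real data.

Contact maps are Poisson around `base/(1+d)^γ` (γ = 1), with boundaries as
per-crossing 0.1× attenuation, loops as 5× single-pixel enrichment, and
de-compaction as complementary scaling of a planted bin's row: local
contacts ×(1−f), distal ×(1+f), f = 0.2.  Exact mass transfer from local to
distal was deliberately not used: with attenuated distal backgrounds it
multiplies a few distal pixels many-fold and leaks the planted signal into
the DLR of every bin sharing those pixels; complementary scaling keeps the
perturbation confined to the planted rows.

What the scenes do **not** emulate: read-level noise and mappability,
realistic gene-density and peak-width distributions, replicate structure,
distance-dependent loop strength, compartment (A/B) structure, and the
correlation structure of real epigenomic feature panels.  Passing recovery
tests therefore demonstrates that the estimators are correct and well-posed
under their stated models — not that real data meet those models.

## Problem sizes and determinism

The default scene and all recovery experiments (including the 50-replicate
APA null and the 10-seed clustering check) complete in well under a minute
on one CPU; sizes were chosen so a full developer loop stays interactive.
All randomness flows from a single seed through stable per-stage hashes
(`pipeline.stage_seed`), so any stage can be rerun independently and
deterministic outputs are byte-reproducible.
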