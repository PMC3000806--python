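# Methods

This note documents the models, conventions and numerical choices behind the
pipeline, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## Differential expression

All comparisons in the workflow are two-group contrasts on log2 intensities
(treated vs vehicle, stimulated vs unstimulated, siRNA vs mock); no
multi-factor design-matrix solver is provided because no stage needs one.
For genes g the pooled residual variance s²_g with d_g = n_A + n_B − 2 df is
moderated through the standard empirical-Bayes hierarchy

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),

with the prior estimated by matching the first two moments of log s²_g:
Var[log s²_g] in excess of trigamma(d_g/2) identifies d₀ through the inverse
trigamma (Newton iteration), the mean then identifies s₀².  This is the same
closed form the reference microarray implementation uses, and a test checks
agreement with Bioconductor limma to ~1e-12.  Edge cases: homoscedastic data
legitimately drive d₀ → ∞ (complete pooling, z-like test); an all-zero
variance matrix (the noise-free limit of the generator) short-circuits to
p = 0 where the means differ and p = 1 where they do not, which keeps the
noiseless recovery checks exact.  Genes with zero sample variance are
excluded from prior estimation.  FDR is Benjamini–Hochberg within each
contrast separately; adjusted p-values are thresholded everywhere.
Regulation calls: `up` iff p_adj < α ∧ LR ≥ lr_min, `down` symmetrically;
with lr_min = 0 the sign of LR decides.

Defaults: α = 0.01, lr_min = 1.0 for treatment/off-target calls,
on_target_lr_min = 0 for the stimulation filter (the on-target derivation is
deliberately significance-driven rather than fold-change-driven; fold-change
cut-offs would make the pathway signature depend on an arbitrary scale).

## Dose-trend test

The trend statistic is E² = (SS₀ − SS_iso)/SS₀, where SS_iso is the residual
of the least-squares monotone fit across ordered dose groups and SS₀ the
residual about the grand mean; E² is evaluated in both directions and the
maximum taken (two-sided monotonicity).  Significance comes from permuting
the sample-to-dose assignment: p = (1 + #{E²_perm ≥ E²_obs})/(B + 1),
B = 1000 by default (config `permutations_B`).  SS₀ = 0 (constant response)
is defined as E² = 0, p = 1.

Implementation notes: the isotonic fit uses the min–max representation
fit_i = max_{j≤i} min_{l≥i} mean(y_j..y_l) on the dose-group means with
group-size weights — algebraically identical to pool-adjacent-violators on
the raw observations but vectorizable over genes × permutations as a few
array operations per dose-level pair (the permutation engine runs millions
of 7-level fits; a unit test checks equality with sklearn's isotonic
regression).  Because the total sum of squares is permutation-invariant, E²
is assembled from permuted group means alone.  Permutations are drawn
independently per gene so that genome-wide error rates are binomial.
Permuted statistics within 1e-12 of the observed count as ties (conservative
direction).  At B = 500 and strict p < 0.05 the exact null rejection rate is
25/501 ≈ 0.0499.

## Signatures

**On-target (per time point).**  Filter 1: stimulated vs unstimulated
vehicle, call ≠ none at (α, on_target_lr_min).  Filter 2: adjusted p < α for
at least one compound concentration under stimulation.  Filter 3: dose-trend
p < α on the replicate-level log2 ratios (each treated replicate minus the
stimulated-vehicle mean, grouped by the 7 doses) — replicate-level rather
than per-dose means because the permutation null needs the within-dose
spread, and triplicates per dose are what give the test its power.
Per-compound survivors are unioned; the recorded direction is the Filter-1
call.  The siRNA signature replaces filters 2–3 with: adjusted p < α for the
active siRNA vs transfection vehicle AND call = none for the control siRNA.

**Off-target (per compound).**  A gene is a member iff at some read-out
concentration (default 0.08 and 2 µM, the doses at which unstimulated arms
exist) and some time it is called in both the stimulated and the
unstimulated arm — any sign combination; both calls must come from the SAME
concentration (the pairing is what certifies stimulus-independence).
Direction is recorded from the unstimulated arm.  Per-time sets are kept and
pooled.

**Profile classes.**  Decision tree per (gene, compound, time), first match
wins: (1) bipolar — opposite-signed calls at low vs high read-out
concentration in either arm; (2) common — same-direction unstimulated-arm
calls for all compounds at both concentrations and dose-trend p ≥ α on the
stimulated-arm ratios (the unstimulated arm has only two doses, too few for
a trend test); (3) pure off-target — not stimulation-responsive, both arms
called in the same direction at some concentration; (4) additive /
(5) inverse — stimulation-responsive with the compound-alone call matching /
opposing the stimulation direction; (6) pure on-target — in the on-target
signature with a silent unstimulated arm; otherwise unclassified.  The
precedence order resolves genes matching several qualitative patterns; in
the noise-free limit the classifier reproduces the generator's planted
classes exactly, which is the main correctness check.

**Counter-therapeutic count.**  Among on-target genes, those whose
compound-alone (unstimulated-arm) call equals the stimulation direction at
any supplied concentration/time — the compound pushes the gene toward the
stimulated state it is meant to reverse.  This is a different convention
from the "inverse" profile class (which is relative to the stimulation
effect at the transcript level); both are computed and labelled.

**Treatment clustering.**  Profiles (compound × concentration) are compared
as signed LR vectors over the union of genes significant in ≥ 1 profile —
signed values rather than binary calls retain effect sizes — with manhattan
distance and complete linkage; dendrograms are serialized as newick.

## Enrichment

One-sided hypergeometric tail p = P(X ≥ overlap), exact rational arithmetic
for universes up to 10⁴ genes (scipy's survival function above).  The
universe is all genes in the study matrix; gene sets are intersected with
the universe before testing.  Significance is −log10 p > 2 on the raw p by
default (no across-set correction; BH available as a flag) because the
pathway heat-map convention thresholds raw Fisher p.  Enrichment matrices
keep rows significant for ≥ 1 condition and are ordered by the same
manhattan/complete clustering.

## Kinase panel and surrogate markers

Selection: inhibition ≥ 90 % at 2 µM AND ≥ 50 % at 200 nM, boundaries
inclusive; negative single-point values (apparent activation) are legal and
fail the thresholds.  "Expressed in the cellular system" is an input list,
by default the kinases that appear as genes in the study matrix, so the rule
stays explicit rather than inferred.  Overlay evidence reports marker counts
and ambiguity (a regulated marker mapping to > 1 selected kinase) without a
confirmation verdict — the evidence for a specific kinase is inherently
ambiguous when markers are redundant.  Coverage percentages are truncated
(rounded toward zero) to one decimal, the convention such panel reports use
(84 of 366 markers reads 22.9 %).

## Scorecard

Per-criterion average ranks (direction-aware), rank-sum total, ascending
final order with alphabetical tie-break, tertile colour buckets for
reporting.  Rank-sum was chosen over z-scoring because the criteria live on
incommensurable scales and ranking is invariant to monotone transformations;
the criteria list is config-driven (potency columns are wet-lab inputs, not
computed).

## Synthetic-data generator

The generator plants each gene in one of seven classes (null 80 %, pure
on-target 8 %, pure off-target 4 %, additive/inverse/bipolar/common 2 %
each) and emits the full campaign layout: 7 compounds × 7 concentrations
(0.0032–50 µM) × 3 times × triplicates under stimulation (441 samples),
unstimulated compound arms only at 0.08 and 2 µM (126), DMSO vehicles in
both arms, and stimulated siRNA / control-siRNA / mock-transfection arms
(612 samples total; the real campaign's 640 arrays include control layouts
that are not documented, so no attempt is made to match that count).

Mean model per gene and sample:
baseline + stimulated·tgf_lr·(1 − inhibition) + off_effect, with
inhibition = c/(c + IC50_compound) under a compound at dose c (Hill
exponent 1 — the data motivating the design show dose dependence only
qualitatively, so the simplest saturating curve is used) and a fixed 0.6
under the active siRNA (a partial knockdown: receptor protein outlives the
mRNA, so even an efficient siRNA removes only part of the signalling; 0.6
is used as the removed fraction of the transcriptional effect).
Off-target effects follow a per-gene Hill curve (IC50 log-uniform in
0.02–0.5 µM so the 2 µM read-out sits on the plateau), except bipolar
(+off_lr below 0.4 µM, −off_lr at or above — the toxicity-like sign flip)
and common (constant shift for every compound).  Effect magnitudes are
uniform in 1.5–3 log2 units; gene-wise noise sd is Gamma-distributed with
mean 0.35 (shape 49, so sd of the sd ≈ 0.05), independent Gaussian on the
log2 scale.  Off-target genes are assigned to a single compound (weight-
proportional) or, with probability 0.2, to that compound's whole chemotype;
the default weights make the first indolinone and the two pyridopyrimidinones
promiscuous in roughly the proportions a selectivity-driven campaign shows
(the heaviest compound ≈ 2.7× the clean ones, the competitor chemotype
≈ 1.3×).

What the generator does **not** emulate: probe-level bead structure, batch
and chip effects, correlated noise between genes, missing values,
transfection-procedure signatures on the control siRNA, and secondary
(time-cascading) regulation — effects at different time points are
identical apart from noise.  Passing the recovery checks therefore
demonstrates that the statistical machinery is correct and calibrated under
the declared model, not that real beadchip data would yield the published
signature sizes; those depend on the deposited 640-array dataset and are
out of scope.

## Problem sizes and tolerances in the validation suite

Planted-recovery checks run at 5000 genes (noisy, sd 0.35, triplicates;
sensitivity ≥ 0.90 and false-discovery proportion ≤ 0.10 for the on-target
signature) and 2000 genes (noise-free classifier, exact agreement).
Trend-test calibration uses 2000 null genes at B = 500 (empirical type-I in
[0.04, 0.06] at α = 0.05) and 1000 genes for power (saturating effect of
1.5 log2 units, power ≥ 0.9).  Oracle comparisons: 500 random hypergeometric
tables (agreement ≤ 1e-12) and 1000 random BH vectors (≤ 1e-12).  These
sizes keep the whole validation under ~2 minutes on one CPU while leaving
the binomial error of the calibration estimates well inside the asserted
bands.

## Known limitations

- Two-group contrasts only; no covariates or batch correction.
- Per-contrast variance priors: a gene's moderation differs slightly between
  contrasts (the original analyses likely shared one array-wide fit).
- The permutation trend test is stochastic; seeds fix it, but p-values near
  α can cross the threshold between seeds at small B.
- Probe-to-gene collapsing is out of scope: rows are independent features.
- The off-target rule requires both arms at the same concentration; a gene
  regulated at 0.08 µM in one arm and 2 µM in the other does not qualify.
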