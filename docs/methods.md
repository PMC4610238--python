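# Methods

## Dose-response model

Each sample × compound dilution series is modelled as log-logistic
inhibition with a fixed bottom asymptote of 0%:

    y(x) = Rmax / (1 + 10^(s (m − x))),   x = log10(concentration, nM)

with Rmax ∈ [0, 100] (% inhibition), slope s ∈ [0.2, 10] and m = log10(IC50
nM) constrained to the tested log-range ± 1 decade. Four-dose series — the
reference screen design — cannot identify a free bottom asymptote, hence the
three-parameter form. Viability input is converted as inhibition = 100 −
viability (an explicit reader orientation), and responses are clipped to
[0, 100] before fitting because normalised screens routinely stray outside
that range.

**Fitting.** Rmax enters the model linearly, so for fixed (s, m) the optimal
Rmax is `clip(Σ y·g / Σ g², 0, 100)` with `g = 1/(1 + 10^(s(m−x)))`. The fit
is therefore a 2-D profiled problem: a coarse grid over 4 slopes × 13 m
values picks the start, and bounded Nelder-Mead (xatol 1e-7, fatol 1e-10,
≤ 400 iterations) polishes it; on non-convergence three further slope seeds
(1.0, 0.5, 3.0) are tried and the best objective kept with
`converged=False`. A direct 3-parameter trust-region least-squares solve was
tried first and abandoned: on flat, unidentifiable series (inactive
compound + noise) it wanders the Rmax/m degeneracy for hundreds of
iterations at substantial per-iteration cost, while the profiled search
returns the same optima orders of magnitude faster. Noiseless 8-dose series
are recovered to ≲ 1e-6 in all three parameters; in the 4-dose, 5%-noise
regime the median |log10 IC50| error is ≈ 0.08 decades (the test suite
asserts < 0.25). All-constant series short-circuit to Rmax = the constant,
slope at its lower bound, m below the tested range.

**DSS.** With activity threshold Amin (default 10% inhibition) and
integration window [x_min, x_max] (default: the tested range), the score is

    x1 = clamp(m − (1/s) log10(Rmax/Amin − 1), x_min, x_max)
    I  = F(x_max) − F(x1) − Amin (x_max − x1),
    F(x) = (Rmax / (s ln 10)) ln(1 + 10^(s(x−m)))
    DSS1 = 100 I / ((100 − Amin)(x_max − x_min))

so DSS1 = 0 whenever Rmax ≤ Amin and → 100 for a saturated curve over the
whole window. DSS2 = DSS1 · log10(Rmax)/2 additionally down-weights partial
efficacy (factor 1 at Rmax = 100); DSS1 is the default and the variant is
recorded in output metadata. The antiderivative is evaluated in a
log1p-stable form; agreement with adaptive quadrature is ≤ 1e-6 relative
over a 500-point random parameter grid (asserted in the suite). AUC is
computed over the *observed* responses (trapezoid on the log10 scale,
normalised by 100 × window width), not the fitted curve. pIC50 values from
non-converged fits are treated as missing rather than floor-substituted.

## Network assembly

Edges are retained per evidence source: confidence-scored edges by
(experimental > 10 AND combined > 500) OR (experimental < 10 AND
combined ≥ 900), plus experimental ≥ 300 for compounds on a caller-supplied
relaxed list; bioactivity edges (IC50/Kd/Ki/potency) by ≤ 35 nM inclusive;
curated primary-target annotations pass unfiltered. Boundary semantics are
deliberately literal (strict at 10 and 500, inclusive at 900, 300 and
35 nM). Where a pair carries several bioactivity records the most potent
decides — implemented as per-record filtering followed by pair
deduplication, which is equivalent. Metabolism families (CYP*, ABC* glob
patterns, configurable) are excluded last, but the filters commute and a
validation pass can re-derive the network from the raw edges. Target ids
are uppercased gene symbols; multi-protein complexes are out of scope.

## Target addiction score

TAS[s, t] is the unweighted mean of the responses of the compounds hitting
t — exactly the defining formula, with no potency weighting. Missing
responses are excluded from the mean (a sample screened with a subset of
the panel is still scored) and the per-entry effective compound count is
recorded; an entry is missing iff no targeting compound was measured.
Implementation is one masked matrix product; the suite asserts exact
equality with a per-target Python loop on random instances. TAS columns are
clustered raw by default — the scores share the input metric's scale, and
standardising would inflate low-n_t, low-signal targets; a z-scaling flag
is available on the distance layer for callers who want it.

## Clustering and robustness

The default profile distance is cosangle (uncentered correlation),
d = 1 − x·y/(‖x‖‖y‖) ∈ [0, 2], scale-invariant; Euclidean, Manhattan and
1 − Pearson/Spearman/Kendall are available under the same interface, and
tissue-type labels map to the 0/1 binary distance. Missing entries use
pairwise-complete coordinates with a minimum of 3 shared coordinates.
Trees use Ward linkage on the distance matrix in ward.D2 semantics
(squared distances in the Lance-Williams update) via scipy; merge ties
resolve deterministically to the smallest pair index. Cuts renumber
clusters in order of first appearance so labels are stable across runs.

Bootstrap support resamples **feature columns** with replacement, re-clusters
each replicate with the same distance/linkage, and scores each original
node by the fraction of replicate trees containing its exact leaf set.
Resampling the feature dimension (not the clustered objects) keeps the leaf
set fixed, which is what makes per-cluster counting well defined; this is
the single-scale probability, without the multiscale extrapolation
correction. Each node's probability is multiplied by the linear height
weight 0.1 + 0.9·h/h_root ∈ [0.1, 1], so robustness of deep, trivially
tight merges is discounted relative to tall sub-clusters.

**Projection.** New samples are appended to the reference TAS matrix, the
combined panel re-clustered and cut into k groups; each new sample's
auxiliary profile (e.g. expression) is scored by its mean Spearman
correlation with reference co-members, against the null of all pairwise
reference correlations, p = (1 + #{null ≥ observed})/(1 + #null). When a
sub-cluster holds a single reference co-member this p is exactly calibrated
under independence; with many co-members the mean concentrates relative to
the single-pair null and the p-value becomes conservative in both tails —
the calibration test therefore uses a fine cut (most co-member sets of size
≤ 1), and users comparing across cluster sizes should read p as a ranking
device, not a strict tail probability. Orphan samples (no reference
co-member) are flagged with undefined p.

## Congruence

Distance matrices over the same samples are unfolded to upper-triangle
vectors ((1,2), (1,3), … row-major). Kendall's W uses average ranks and the
classical tie correction T = Σ(t³ − t):

    W = 12 Σ_j (R_j − R̄)² / (m²(N³ − N) − m T)

For m = 2 tie-free matrices W = (1 + ρ_s)/2 exactly; the suite asserts this
identity to 1e-12 and cross-checks W against the independent R
implementation (ape::CADM.global). The permutation null jointly permutes
the object order of every matrix but the first (holding one fixed is
equivalent under the null), with p = (1 + #{W_perm ≥ W_obs})/(1 + n_perm).
Because permuting objects only reorders a matrix's unfolded entries, ranks
permute along and tie corrections are invariant, so the whole null is
computed vectorised from pre-ranked matrices — 10,000 permutations on a
60-sample panel take a few seconds. The Mantel test is the Pearson
correlation of the two unfolded vectors under the same permutation scheme.
Both tests reject at 0.05 within Monte-Carlo error of nominal on
independent random matrices (asserted: 1000 replicates, n = 15,
999 permutations).

## Cohort statistics

Sample ranking by a target's addiction is a stable descending sort (ties
keep input order; missing entries last, flagged). Group comparison is the
Wilcoxon rank-sum / Mann-Whitney U test, two-sided by default: the exact
null when both groups have ≤ 12 observations and no ties, otherwise the
normal approximation with continuity and tie correction (scipy's
implementation; an independent full-enumeration oracle in the test suite
checks the exact branch for all group sizes ≤ 6). Co-addiction correlates
the anchor target's TAS column with every other target (Spearman,
pairwise-complete, ≥ 5 shared samples), Bonferroni-corrects over the number
of targets actually tested (reported), and flags partners at rho >
threshold (default 0.94) and adjusted p < alpha (default 1e-5). The number
of inhibitors shared with the anchor is annotated so that correlation
forced by shared compounds — identical compound sets give rho = 1 by
construction — can be told apart from co-addiction seen through distinct
inhibitors.

## Synthetic screens

The generator emulates a small kinase-inhibitor screen: four serial
ten-fold dilutions spanning 1–1000 nM, viability normalised to no-drug
controls, a 40-compound panel over a 25-target pool with 1–4 targets per
compound drawn without replacement (overlap, hence polypharmacology, arises
from the shared pool), 60 samples in 3 balanced sub-populations each
addicted to 3 reserved targets, and a binary biomarker label (half the
samples) coupled to one reserved target's addiction — the biomarker target
is guaranteed at least one inhibitor by a degree-preserving edge repoint.
The baseline IC50 sits one decade above the top dose; addiction shifts it
down by `addiction_effect` decades per unit addiction (default 2), taking
the *maximum* addiction over a compound's targets. Viability noise is
additive Gaussian (default 5%), clipped to [−10, 120]% as in raw screens.
Identical configurations are bit-identical; the network and screen draw
from separate seed streams so the network does not change when only the
screen is consumed.

What the generator does **not** model: pharmacokinetics, drug synergy or
combination dosing, assay plate effects, heteroscedastic or correlated
noise, partial-efficacy compounds (Rmax < 100 is configurable but not
varied per compound), or realistic marginal distributions of bioactivities.
Passing recovery tests therefore demonstrates correctness of the
transformation and statistics under the declared generative model, not
performance on any particular real screen.

### Validation problem sizes

The suite validates cluster recovery on 18-sample/24-compound screens with
addiction_effect 0.75 at 5% noise — a TAS-scale between-cluster shift of
about 7× the within-cluster spread, comfortably above the ≥ 5× regime where
exact recovery is expected — over 20 seeds, with 500 bootstrap replicates;
biomarker power on 20 vs 20 cohorts at addiction_effect 0.5 (TAS shift
≈ 3–4× spread) over 100 seeds; permutation calibration on 1000 replicates;
and projection calibration pooling ≈ 230 p-values over 50 seeds at a fine
cut (k = 28 of 40 combined samples, see above). Repeated-seed simulations
score responses with AUC, which needs no curve fitting and leaves the
TAS-and-downstream machinery under test identical; DSS fitting is exercised
by its own dedicated tests and by the end-to-end acceptance run. The
acceptance script runs the full default-conditions study (60 × 40 screen,
DSS metric, 10,000-permutation congruence tests, 500 bootstrap replicates).

## Known limitations

* TAS inherits the biases of the network: promiscuous compounds dilute
  signal across all their targets, and targets hit by overlapping compound
  sets have correlated scores by construction (surfaced via the
  shared-compound annotation, not corrected).
* Bootstrap support is single-scale; approximately-unbiased multiscale
  correction is not implemented.
* The exact rank-sum branch requires tie-free data; tied small samples fall
  back to the tie-corrected normal approximation.
* Logistic fits on 4-dose series with IC50 outside the tested range are
  reported at the parameter bounds with `converged` possibly False;
  downstream DSS is well-behaved there (≈ 0 or ≈ saturated) but IC50-based
  metrics are not trustworthy outside the tested window.
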