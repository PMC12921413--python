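# Methods

## The analysis problem

A two-group circadian metabolomics experiment measures a panel of metabolite
intensities in hippocampal (or other) tissue from independent animals,
sampled at a small set of Zeitgeber times — here ZT 0, 6, 12, 18 with n = 4
animals per group per timepoint (32 samples for a two-group design).  One
group is entrained to a 12:12 light/dark cycle (LD); the other experiences a
rhythm-disrupting treatment such as continuous light (LL).  The questions,
in order: which metabolites oscillate at all under control conditions; which
of those change phase or amplitude under treatment; which metabolites differ
in abundance globally or at specific timepoints; and which pathways those
hits concentrate in.

## Rhythmicity screening: JTK_CYCLE

JTK_CYCLE correlates the *ranks* of a series with the rank pattern of a
cosine evaluated at the sampling times, for every lag on a grid tiling the
period.  Replicates enter as tied timepoints (no averaging), preserving the
within-cell variance.  Cosine values are rounded to 9 decimals before
ranking so analytically tied values (e.g. cos at ±6 h from the peak) tie
exactly; waveforms with identical rank patterns are deduplicated.

The score is Kendall's S restricted to pairs untied in both rankings, with
the tau-b normalisation.  Under the permutation null with distinct data
values and a reference whose ranks tie in groups of sizes t₁…t_k, the
number of cross-group concordant pairs is distributed as the inversion
count of a multiset word, whose generating function is the q-multinomial
coefficient ∏ᵢ [(t₁+…+tᵢ) choose tᵢ]_q.  We evaluate it with exact integer
polynomial arithmetic, so tail probabilities are exact to one float ulp —
the test suite checks total-variation distance < 1e-12 against full n!
enumeration.  When the data themselves contain ties the generating function
no longer applies; the null is then enumerated exactly for n ≤ 8 and
estimated by seeded Monte-Carlo permutation (≥ 10⁴ draws) otherwise.
Continuous abundances essentially never tie, so the exact path dominates in
practice.

Per waveform we take the one-sided p for positive association, P(S ≥ s);
the reported p is the minimum over the lag grid, Bonferroni-multiplied by
the number of distinct waveforms — the standard JTK convention.  `best_lag`
is the lag maximising |S|, ties broken toward the smaller lag for
determinism.  Defaults: period 24 h, lag step = the timepoint spacing (4
timepoints cannot resolve finer phase; the harmonic model below does the
precise phase work).  The screen calls a metabolite rhythmic at p < 0.05
per metabolite.  An optional `across_metabolite_fdr` switch applies BH
across the panel instead; it is off by default because the per-metabolite
threshold is the convention in this design, at the cost of ≈ α·(number of
flat metabolites) expected false calls, which the calibration tests and the
acceptance metrics make explicit.  Measured type-I error on iid null series
is ≈ 0.045 at α = 0.05 (Bonferroni over lags is mildly conservative).

## Differential rhythmicity: harmonic interaction model

For metabolites passing the LD screen we fit, by ordinary least squares,

    y = β₀ + β_g·g + (a₀ + a₁g)·cos(ωt) + (b₀ + b₁g)·sin(ωt),
    g ∈ {0 = LD, 1 = LL}, ω = 2π/period.

Every sample is an independent animal, so there are no repeated measures to
support random effects; fixed-effects least squares of this formula is the
estimator.  Per group, amplitude and acrophase follow exactly from the
(a, b) pair: A = √(a²+b²), φ = (period/2π)·atan2(b, a) mod period —
acrophase is expressed as the peak time on the ZT clock, not in negative
radians, because that is how circadian figures are drawn.  A disruption is
called by the joint 2-df F-test of a₁ = b₁ = 0: the two interaction terms
gate a single claim, so a joint test rather than per-term t-tests.  An
exact fit (zero residual variance, e.g. noiseless synthetic input) is
flagged degenerate and yields no p-value rather than a spurious claim.

Phase differences (LL − LD) are wrapped to (−period/2, period/2], positive
meaning the treated peak occurs later (a delay); the boundary case +12 h is
kept positive.  Amplitude change is (A_LL − A_LD)/A_LD × 100 and is
undefined (flagged) when the control amplitude is zero.  Day/night peak
classification uses half-open intervals [0, 12) / [12, 24) with lights-on
at ZT0.

Calibration measured by the test suite: noiseless recovery of
mesor/amplitude/acrophase to 1e-8; interaction type-I error within
[0.04, 0.06] over 10⁴ null fits; with noise σ = 0.25·A on the 4 ZT × 4
replicate design, a planted +6.4 h delay is recovered with median error
well under 1 h and a planted −21% amplitude change within 10 points.

## Differential abundance

Normality routing follows the Shapiro–Wilk convention: both groups pass at
α = 0.05 → pooled-variance Student t with Cohen's d = Δmean/pooled SD;
otherwise Mann–Whitney U with midranks.  The effect size for U is the
rank-biserial r = Z/√N, with Z from the tie-corrected normal approximation
*without* continuity correction — the form that reproduces published r
values from (U, n₁, n₂) alone; the 1 − 2U/(n₁n₂) form is also available.
Exact U p-values are used for small untied samples (n₁+n₂ ≤ 12).  The t
path accepts either raw vectors or printed (mean, SD, n) summaries and the
two agree exactly when the summaries come from the same data.

The global screen pools all timepoints: FC = mean(LL)/mean(LD), passing
when max(FC, 1/FC) > 1.2 and the routed univariate p < 0.05 — the
two-sided form of the volcano criterion, symmetric under label swap.
Timepoint screens fit a PLS-DA per ZT (two components, autoscaled) and pass
metabolites with VIP > 1.5 and routed p < 0.05.  PLS-DA is computed by
scikit-learn's NIPALS-family `PLSRegression` on a ±1 class vector; VIP,
R²Y, cross-validated Q² (leave-one-out up to 24 samples, else 7-fold, with
preprocessing re-estimated inside each training fold) and the
label-permutation validation p = (1 + #{perm ≥ observed})/(1 + n_perm) are
computed here.  VIP uses the standard weight form, so ΣVIP² = number of
variables — asserted for every fitted model.  Orthogonalised variants
(OPLS-DA) are deliberately out of scope: the orthogonal rotation does not
change VIP-relevant predictive variance, and permutation validation covers
the reliability question.  The permutation default statistic is R²Y (one
fit per permutation); Q² is available where the CV cost is acceptable.

Preprocessing defaults: unit-variance autoscaling on, log-transform off;
both are config switches since acquisition pipelines differ on this and the
choice is not derivable from the data format.

## Over-representation analysis

One-sided hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n),
with the background defaulting to the measured-and-mappable panel —
standard for targeted panels, where a whole-database background inflates
significance.  BH step-up adjustment is applied across the tested pathways.
Pathway definitions are supplied as a TSV; a small bundled toy map (11
KEGG-style pathways over ~60 named metabolites) supports demonstrations
and tests.  Database-derived enrichment numbers are inherently tied to the
database version and background choice and are therefore not treated as
reproducible targets.

## Synthetic data: what it emulates and what it does not

Each metabolite follows y(t) = M + A·cos(2π(t−φ)/period) + ε on the study
grid.  Defaults are fixed to the study conditions: 398 metabolites; 58
rhythmic in LD with acrophases drawn nocturnally biased (P(dark phase) =
0.569); 8 "core disrupted" metabolites given a +6.4 h delay and ×0.79
amplitude in LL; 33 further rhythmic metabolites abolished in LL
(amplitude × 0), chosen night-peaked-first so the treated group loses its
nocturnal peak dominance the way the modelled study does (58 → 25 rhythmic,
56.9% reduction); 39 flat metabolites given a global 1.5-fold shift.
Timepoint-specific differences are not planted separately — they emerge
from the phase shifts and fold changes, which is how they arise in tissue.

Parameter choices the source design does not pin down, fixed once here:
mesor ~ LogNormal(log 100, 0.4) (arbitrary intensity units), relative
amplitude ~ U(0.3, 0.6) of mesor, noise σ = 0.25·A for rhythmic and
0.10·M for flat metabolites.  Gaussian noise can produce negatives at low
mesor; values are clipped at 0 and the clip count logged, and a lognormal
noise mode (multiplicative on the log scale, CV matched to σ/M) is offered
for strictly positive data.  One RNG stream is spawned per metabolite from
the master seed, so enlarging the panel never changes existing metabolites;
role assignment is index-deterministic so the planted counts are exact.

What the generator does **not** emulate: LC-MS peak shapes, batch and run
order effects, missingness, non-sinusoidal waveforms, and inter-metabolite
correlation.  Passing tests therefore demonstrate correctness and
calibration of the statistics under the stated sampling model, not
robustness to instrument artefacts.

## Numerical and degenerate-input conventions

* Exact JTK nulls use integer polynomial arithmetic; probabilities are
  exact rational values rounded once to float.
* Constant series: JTK returns p = 1 with a flag; fully tied Mann–Whitney
  input returns U = n₁n₂/2, p = 1, r = 0.
* Acrophase of a zero-amplitude fit is undefined and flagged, never 0.
* Rank-deficient harmonic designs raise with the collinear columns named;
  fewer than 3 distinct timepoints per group is rejected as unidentifiable.
* CSV round-trips are bitwise exact: floats are written with shortest
  round-trip repr and parsed with a correctly rounded strtod.
* All Monte-Carlo machinery (permutation nulls, permutation validation,
  the generator) is reproducible under a fixed seed; pipeline stages derive
  their streams from the master seed with fixed labels.

## Problem sizes used by the test and acceptance suites

Oracle comparisons run at enumerable sizes (n ≤ 8 for full permutation
nulls, N ≤ 12 for hypergeometric enumeration); calibration uses 10⁴ null
series for the rank test and 10⁴ null fits for the interaction test;
recovery uses 10³ noisy replicates of the planted disruption and the full
398 × 32 study-scale dataset.  The entire suite completes in well under a
minute on one CPU.

## Known limitations

* Four timepoints cannot distinguish period changes from phase changes; the
  period is fixed (default 24 h) by design, and multi-period scans are out
  of scope.
* The JTK lag grid at the timepoint spacing quantises `best_lag`; precise
  phase estimates come from the harmonic fit, not the screen.
* The fold-change screen uses pooled means across timepoints; a pure phase
  shift leaves pooled means unchanged on a balanced grid, so phase-only
  disruptions are invisible to it by construction (they are caught by the
  interaction test instead).
* With the conventional per-metabolite screening threshold, detected
  rhythmic counts include ≈ α × (number of arrhythmic metabolites) false
  positives; the across-panel BH switch trades convention for specificity.
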