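# Methods

This note documents the statistical procedures, the synthetic-data
model, and the numerical conventions the package commits to. It is the
reference for every deliberate design choice; the README covers usage.

## 1. Uncertainty score

The per-nodule uncertainty score is the mean binary entropy (bits) of
the N ensemble member probabilities,
H̄ = (1/N) Σᵢ −[pᵢ log₂ pᵢ + (1 − pᵢ) log₂(1 − pᵢ)].
The 0·log 0 = 0 limit is implemented exactly (a masked branch, not a
clamp), so H̄ = 0 iff every member lies in {0, 1} and H̄ = 1 iff every
member equals 0.5. Two properties worth keeping in mind:

* H̄ measures *per-member confidence*, not inter-member disagreement: a
  vector alternating between 0 and 1 scores H̄ = 0 although the members
  disagree maximally. This is intrinsic to the mean-of-entropies
  definition and is preserved, not "fixed" — a disagreement-sensitive
  score (variance, mutual information) would be a different statistic.
* Moving any single member toward 0.5 never decreases H̄ (binary entropy
  is unimodal with its peak at 0.5).

The ensemble risk is the unweighted arithmetic mean of the member
probabilities. How the deployed ensemble actually pooled its members
(probabilities vs logits, weighting) is not public; the unweighted
probability mean is the only defensible default and is used throughout.

## 2. Threshold calibration and triage

Cutoffs are empirical quantiles of the development cohort's H̄
distribution at the requested percentiles (defaults 90 and 95).

* **Quantile convention.** We use linear interpolation at plotting
  position q(n+1) (Hyndman–Fan type 6, numpy's `method="weibull"`).
  The more common type-7 convention interpolates at q(n−1)+1 and, on a
  cohort of 883 distinct scores at q = 90, retains only 794/883 = 89.92%
  — i.e. it *under*-covers the nominal retention. Type 6 retains
  795/883 = 90.03%, and for q ∈ {90, 95} it guarantees a certain
  fraction in [q/100, q/100 + 1/n] on the calibration data for any
  distinct-score multiset. Since the whole point of the percentile
  thresholds is the "q% retained as certain" reading, type 6 is the
  convention that makes the nominal statement true, and the package uses
  it everywhere quantiles appear (thresholds, medians, IQRs) for
  internal consistency.
* **Tie rule.** A score exactly equal to the cutoff is *certain*
  (uncertain iff H̄ > cutoff). With heavy ties at the cutoff the certain
  fraction can exceed q/100 + 1/n (degenerate example: all scores
  identical → everything certain); the coverage guarantee above is
  stated for distinct scores, which is the almost-sure case for
  continuous entropy scores.
* Calibration warns (but proceeds) below 20 scores; percentiles must lie
  strictly inside (0, 100). Thresholds serialize to JSON with their
  source cohort and n for auditability when transferred to an external
  cohort.

## 3. Discrimination metrics

* **AUC** is the Mann–Whitney statistic, P(score⁺ > score⁻) + ½ P(tie),
  computed via midranks; malignant is the positive class and higher
  ensemble risk means more malignant. Single-class groups raise a
  degenerate-group error rather than returning NaN.
* **Bootstrap CI**: percentile interval (2.5th, 97.5th) over
  nodule-level resamples with replacement (default 1000 replicates);
  resamples that lose a class are redrawn. The point estimate is
  included in the reported interval by construction (the interval is
  widened to contain it in the rare resampling configurations where the
  percentile interval would exclude it). BCa is deliberately not used:
  the plain percentile method is the simplest scheme consistent with
  "bootstrap, n = 1000" reporting.
* **Sensitivity at 95% specificity**: maximum sensitivity over all
  thresholds t (swept over observed scores plus ±∞) with
  specificity ≥ 0.95, where "positive" means score > t. With constant
  scores only the all-negative threshold qualifies, giving 0.
* **DeLong variance**: V = var(V₁₀)/m + var(V₀₁)/n with sample (ddof 1)
  variances of the structural components (per-positive and per-negative
  mean tie-corrected indicators). Verified against hand-enumerated
  components on small instances and against the bootstrap variance
  (within 15%) on cohorts of 2000.
* **AUC comparison**: unpaired z = (AUC_a − AUC_b)/√(V_a + V_b) with a
  two-sided normal p-value. Certain vs uncertain groups are disjoint, so
  the unpaired test is exact in structure. Full vs certain overlap; the
  covariance between their AUCs is not estimable from group-level
  summaries, so the same unpaired statistic is reported but flagged
  `overlapping=True` (and `paired=False`). Because the shared nodules
  induce positive covariance, ignoring it overstates the variance of the
  difference, making the flagged test conservative. Two-sided tests at
  α = 0.05 throughout; no multiple-testing correction is applied across
  subgroup tests.

## 4. Subgroup characterization

Size classes follow Lung-RADS 2022 diameters: small < 6 mm ≤ medium
< 8 mm ≤ large (closed lower bounds at 6 and 8). The subgroup table
reports, per (benign/malignant × certain/uncertain) cell, counts and
percentages by nodule type and size class and the mean ± SD and median
[IQR] of diameter; empty cells are kept as zero counts.

Between-group tests per label (emitted only when both groups have ≥ 2
nodules):

* **Diameter**: independent-samples t-test, pooled-variance Student by
  default with Welch selectable. The classical "independent samples
  t-test" is the pooled variant; Welch is offered because group
  variances visibly differ in practice.
* **Composition**: chi-square on solid vs subsolid (part-solid and
  non-solid pooled — their standalone counts are too small for stable
  expected frequencies). 2×2 tables default to the Yates continuity
  correction; this is the choice that reproduces the published
  benign-composition p ≈ 0.305 from the source cohorts' counts
  (695/123 vs 136/31) — the uncorrected Pearson test gives p ≈ 0.25.
  Larger tables never receive a correction. A zero row/column margin is
  a domain error (the statistic is undefined), not a silent NaN.

## 5. Synthetic cohort generator

Real screening/clinical CT cohorts and the CNN ensemble weights behind
this kind of analysis are not redistributable, so the generator is a
first-class, tested component that emulates the *statistical regime*
the analysis operates in, not any particular dataset.

Per nodule, with label y ∈ {0, 1}:

1. **Metadata.** Label counts are exact (round(n · malignant_fraction),
   positions permuted). Types are drawn from per-label mixes; defaults
   emulate a screening case mix (benign: 85/3.3/11.7% solid/part-solid/
   non-solid; malignant: 69/19/12%). Diameters are log-normal per label
   (benign median 5 mm, σ_log 0.41; malignant median 11 mm, σ_log 0.56),
   truncated below at 2 mm by resampling.
2. **Latent difficulty** d ∈ [0, 1]:
   d = base + subsolid_shift·1[subsolid]
       + atypical_benign_shift·(1−y)·σ((D − m)/s)
       + atypical_malignant_shift·y·(1 − σ((D − m)/s))
       + ε,  ε ~ N(0, noise_sd²), clipped to [0, 1],
   with σ the logistic function, D the diameter, m = 11 mm, s = 3 mm.
   The "atypical size" construction encodes that risk models key on
   size-like appearance: *large benign* and *small malignant* nodules
   are the hard ones, and subsolid morphology is hard regardless of
   label. Defaults: base 0.06 (development) / 0.18 (external — the
   domain shift of heterogeneous clinical acquisitions), subsolid 0.32,
   atypical-benign 0.65, atypical-malignant 0.70, noise 0.13.
3. **Ensemble response.** The consensus leans toward the correct class
   with probability σ(accuracy · (1 − d)^decay) (accuracy 6, decay 3):
   at low difficulty the ensemble is almost always right; as d → 1 the
   lean becomes a coin flip. The consensus probability is
   σ(lean · magnitude) with magnitude = separation · (1 − d) ·
   exp(jitter · d · ε) (separation 5, jitter 0.5): easy cases are
   confidently extreme, hard cases hover near 0.5. Note the lean can be
   *confidently wrong* at low d — a realistic failure mode that puts
   H̄ = 0 on some misclassified nodules.
4. **Members** are conditionally i.i.d. Beta draws centred on the
   consensus with concentration interpolating geometrically from 4000
   (d = 0) to 12 (d = 1). Members are exchangeable; no 2D-vs-3D member
   substructure is modelled because the analysis only ever uses the
   pooled members.

Consequences (all property-tested): cohort mean H̄ increases strictly
with difficulty; d = 0 cohorts have H̄ < 0.1 everywhere; d = 1 cohorts
have mean H̄ > 0.9 with risks near 0.5; the uncertain decile is enriched
for subsolid and atypically sized nodules; and the uncertain stratum's
AUC collapses toward ~0.6 while the certain stratum stays ≥ 0.9. At the
default study-scale compositions (development 883 nodules / 65
malignant; external 374 / 207) the generator produces full-cohort AUCs
near 0.92 and 0.88 and external uncertain fractions near 25%/16% under
development-calibrated thresholds. `calibrate_accuracy` tunes the
accuracy parameter by log-space bisection on a large fixed-seed probe
cohort to hit any requested full-cohort AUC (within ±0.03 at n = 2000).

**What the generator does not emulate** — and hence what green tests do
not establish about real data: patient-level clustering (multiple
nodules per participant are simulated as independent), scanner/protocol
covariates, member-level correlation structure within the ensemble,
label noise in the reference standard, and the exact operating-point
sensitivities of a real ensemble (the synthetic ensemble's confidently
wrong benign cases depress sensitivity at 95% specificity relative to
what a well-calibrated clinical model may achieve). Conclusions about
the triage machinery transfer; absolute metric values do not.

## 6. Reproducibility and problem sizes

One global seed fans out through `numpy.random.SeedSequence` into
independent substreams for cohort generation and each group's bootstrap,
so changing bootstrap replication does not perturb generation and
identical config + seed yields a byte-identical report bundle (CSV
floats are written as `%.17g` and read back with round-trip parsing; the
manifest contains no timestamps).

The statistical test-bench sizes were chosen to keep the default suite
fast while leaving Monte-Carlo error well below the margins being
asserted: 200 replicate dev/external pairs for the degradation-recovery
check (uncertain-vs-certain DeLong p < 0.001 in ≥ 95% of replicates, on
both cohorts), 2000 null replicates for type-I calibration of the
unpaired DeLong test (observed rejection ≈ 0.056 at nominal 0.05, well
inside the (0.03, 0.07) acceptance band; the mild liberality is the
usual normal-approximation behaviour at n ≈ 120 per group), 2000
bootstrap replicates when cross-checking the DeLong variance, and 2000
nodules for variance and calibration checks.

## 7. Known limitations

* The percentile thresholds are descriptive, not optimized; the right
  referral rate is a clinical-workflow decision and is out of scope.
* The full-vs-certain comparison is a flagged approximation (Section 3).
* Sensitivity CIs reuse the nodule-level bootstrap; no analytic
  small-sample correction is attempted.
* The Beta member model is a modelling choice — the empirical
  distribution of real ensemble members is not publicly documented, so
  any bounded two-parameter family with independent location/spread
  control would serve; Beta is the simplest.
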