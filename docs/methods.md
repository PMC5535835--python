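# Methods

This note records the statistical model behind `fingerpls`, the
defaults and why they were chosen, and what the synthetic benchmark can
and cannot say about real fingerprint data.

## PLS1 calibration

The core regression is univariate-response partial least squares fitted
by NIPALS deflation. Predictors and response are mean-centered only (no
variance scaling): fingerprint components are already on a common
relative-concentration scale after internal-standard normalisation, and
autoscaling would inflate near-noise components. For PLS1 the NIPALS
weight of each component is the (normalised) covariance `Xᵀy` of the
deflated matrices, so the algorithm is deterministic — no iteration or
random start. The regression vector is folded back to the original
variable space, `b = W(PᵀW)⁻¹q`, making prediction a plain affine map.

Guarantees covered by tests: at full rank the fit coincides with
centered least squares; fitted values agree with an independent SIMPLS
implementation and with scikit-learn's PLS to 1e-8; training scores are
orthogonal; RMSEC is non-increasing in the number of latent variables.

**Latent-variable count.** Selected by k-fold cross-validation
(k = 10, seeded random partition, fold sizes within one of each other);
RMSECV is pooled over all held-out predictions and the argmin wins,
ties to the smaller count. The candidate ceiling is
`min(15, smallest-training-fold − 1, p)`: beyond ~15 latent variables a
49-sample fingerprint model is pure variance. Error conventions: RMSE
uses divisor n (population form); Q² is referenced to the
calibration-set mean, the natural choice in a prediction setting where
the validation mean is unknown at calibration time (the validation-mean
variant is available through `metrics(..., reference_mean=None)`).

## Kennard–Stone partitioning

The calibration set takes `floor(fraction·n)` samples (so 49 → 39/10
and 43 → 34/9 at the default 0.8). Distances are Euclidean on the same
unscaled representation used for modelling; the first two picks are the
globally farthest pair, each later pick maximises its minimum distance
to the already-picked set, and ties break toward the lower row index so
the algorithm is fully deterministic.

## MCCV outlier screening

Each of `n_iterations` (default 2000) seeded iterations draws a random
`floor(0.8·n)`-sample training set, fits PLS1, and records signed
held-out residuals. Per sample, the scan reports the mean absolute
residual, the mean signed residual, the SD of signed residuals and the
holdout count (an error names any sample held out fewer than
`min_holdout` = 50 times). The four-zone rule flags a sample whose mean
absolute residual (X-axis) or residual SD (Y-axis) exceeds 2.5× the
respective across-sample arithmetic mean; elimination is single-pass.

The number of latent variables inside the scan is selected once by
10-fold CV on the full (possibly contaminated) data and reused across
iterations; re-selecting per iteration would multiply the cost by the
candidate count for no measurable gain in flagging accuracy (fixed
low-rank and trimmed-CV alternatives were evaluated on planted-outlier
simulations and were no better). On contaminated data this CV tends to
pick very few latent variables — complex models chase outliers in
training — which is visible in pipeline reports as a small `n_lv` for
the pre-elimination model.

## Variable selection

VIP follows the standard Wold definition (so `Σ_j VIP_j² = p` exactly);
RC is the coefficient times the per-component SD, equivalent for
ranking purposes to the coefficient of an autoscaled refit but without
a second preprocessing pipeline. Rankings are taken from the
post-elimination calibration model, and the Kennard–Stone split is held
fixed across the whole scan so Q² values are comparable between subset
sizes. Each top-k subset re-selects its latent-variable count by
10-fold CV (capped at k).

**Parsimonious winner.** The selected subset is the smallest k whose
validation Q² is within `0.25·(1 − maxQ²)` of the maximum, rather than
the strict argmax. With a 9–10-sample external validation set the Q²
curve rises steeply while informative components enter and then
plateaus; differences along the plateau are smaller than the sampling
noise of Q² itself, so a strict argmax picks an arbitrary plateau
member. The tolerance is proportional to the unexplained fraction so
that near-perfect models demand near-exact ties while weak models allow
proportionally more slack; `parsimony=0` restores the strict argmax,
and exact ties always resolve to the smaller subset.

## DPPH quantitation

The standard curve is an ordinary least-squares line of absorbance on
quercetin concentration over the 5–50 µg/mL dilution series; a
non-negative fitted slope triggers a warning because the assay chemistry
(radical bleaching) requires absorbance to fall with antioxidant
concentration. Replicate sample absorbances are averaged on the
absorbance scale before conversion — the conversion is affine, so the
ordering is immaterial for the mean — and the replicate SD propagates
as `sd(A)/|slope|`. No blank-well correction is modelled. The simulated
plate (default slope −0.018 AU per µg/mL, intercept 1.0 AU) keeps
absorbances positive over the whole 11.6–42 µg/mL activity span, and
the round trip generator → curve fit → conversion is exact at zero
read noise.

## Retention indices

Temperature-programmed (van den Dool–Kratz) linear interpolation
between the bracketing C8–C20 n-alkanes,
`RI = 100(n + (t − t_n)/(t_{n+1} − t_n))`. The linear form, not the
logarithmic Kováts formula, is the standard for temperature-programmed
runs. No extrapolation outside the ladder span: behaviour there is
undefined and an error is raised.

## The synthetic benchmark

The generator emulates the study conditions the workflow targets: a
49 × 80 relative-concentration matrix whose noiseless activity spans
exactly 11.60–41.99 µg/mL quercetin equivalents, with 11 informative
components. Its structure, chosen once:

* The informative components share one dominant **bioactive factor**
  (variance share `informative_correlation` = 0.5), as volatiles of
  common biosynthetic origin do. This is not merely cosmetic: with 11
  mutually independent equal-variance informative columns among 80, each
  column carries ~1/√11 of the signal and is statistically
  indistinguishable from the 69 noise columns at n = 49 — no method
  could recover the pattern, so a benchmark built that way would only
  measure its own impossibility.
* The factor is drawn uniform(−√3, √3) rather than Gaussian: a
  deliberately collected calibration set spans its activity range
  roughly evenly, and the bounded leverage keeps per-sample prediction
  variance homogeneous.
* Uninformative components form blocks of 5 with within-block
  correlation 0.6 (co-elution / shared-pathway mimicry); all marginals
  are log-normal (log-SD 0.3), keeping concentrations positive and
  right-skewed.
* Activity = informative linear combination (equal unit weights),
  affinely rescaled so its noiseless extremes hit the target range
  exactly, plus Gaussian noise of SD 1.0 µg/mL — a plausible
  repeatability for a triplicate spectrophotometric assay on this
  scale.
* Planted outliers: Y-direction plants shift the response by
  `magnitude × noise_sd` with alternating signs (mean-balanced
  contamination; same-signed outliers that landed near each other in
  composition space would otherwise partially mask one another);
  X-direction plants move the concentration row by `magnitude` units of
  per-column SD along a random direction. The default magnitude is 24 ×
  noise_sd (24 µg/mL, most of the activity span): the screening rule is
  designed for gross errors — mislabelled vials, failed assays — not
  marginal 2–3σ deviations, and the planted-recovery guarantees are
  stated for such gross plants. Smaller plants (8×) are still flagged
  in the large majority of runs but can occasionally be masked by a
  co-planted neighbour.

Problem sizes in the test suite (50 seeded replicates for each recovery
property; 2000 MCCV iterations for flagging runs, 500 for
ranking-only runs; the latent-rank check uses a 40 × 20 three-factor
design with factor scales 3:2:1) were chosen to keep the full suite
around a minute while leaving the assertions statistically meaningful.

**What passing does and does not show.** The benchmark demonstrates the
machinery is correct and that the workflow recovers planted structure
under favourable, explicitly stated conditions: a dominant activity
factor, moderate noise, gross outliers. Real fingerprints bring
retention-time drift, co-elution that correlates informative and
uninformative peaks, nonlinear detector response, heteroscedastic assay
error and activity driven by synergy rather than a linear combination —
none of which the generator emulates. Recovery rates on the benchmark
are therefore upper bounds, not predictions, for field performance.

## Degenerate inputs and tie-breaks

Zero-variance responses, zero/negative internal-standard areas,
out-of-span retention times, insufficient MCCV coverage, and
fewer-than-two standard concentrations raise named errors rather than
propagating NaNs. Ties: Kennard–Stone breaks distance ties toward the
lower sample index; latent-variable and subset-size ties resolve toward
the smaller model; VIP/RC rank ties keep the lower component index
first (stable sort).

## Known limitations

* PLS1 only — a single activity response; no multivariate Y, kernel
  variants, or orthogonal signal correction.
* Outlier elimination is a single pass; samples that become outlying
  only after others are removed are not re-scanned.
* The "common" model is the plain intersection of the RC- and
  VIP-selected sets and can in principle be empty (reported as an empty
  selection with NaN metrics).
* The linear DPPH standard curve is appropriate for the 5–50 µg/mL
  range; saturating plates would need a four-parameter logistic, which
  is out of scope.
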