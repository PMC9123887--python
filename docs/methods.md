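# Methods

This note documents the statistical machinery, the default parameter
choices and what the synthetic testbed does and does not establish.

## The response: detection-positive 10-min intervals per hour

Whistle detections are reduced to dp10m h⁻¹: each clock hour splits into
six aligned bins [h:00, h:10), …; a bin is positive when it holds at least
one whistle *and* at least one minute of recording; the hour's dp10m is the
count of positive bins (0–6).  Two readings of "pooling detections closer
than 10 min" exist — gap-based pooling of events into bouts, or fixed
10-min bins.  Only fixed bins make dp10m a bounded per-hour count with
maximum 6, so fixed bins are implemented; gap-based pooling would need a
separate bout statistic.  Hours with zero recorded minutes are dropped, not
zero-filled: the model population is monitored hours.  Partial first/last
hours keep fractional effort (1–60 min), and effort enters the model as a
covariate.  Timestamps are treated as local civil time without DST
adjustment; the timezone is a configuration concern of the ingest step.

## Covariates

* **Moon** — fraction of the mean synodic month (29.530588 d) anchored at a
  reference new moon (2000-01-06 18:14 UTC); 0 = new, 0.5 = full.  Drift
  against a true ephemeris stays below ~0.02 cycle over a two-year study,
  which is why moon-dependent statistics are only reproducible to a few
  percent across ephemeris choices.
* **Tide** — height interpolated from a ≥10-min-resolution series;
  **flow** = h(t) − h(t−60 min); **dtide** = the slope at the window end of
  the first derivative of a least-squares cubic over the trailing 3 h
  (2a₂ + 6a₃τ at τ = 3 h; time in hours).  With hour units dtide is
  O(ω²·A) ≈ ±0.2 m h⁻² for a semidiurnal tide; published tables using
  other time units differ by fixed factors only.  The endpoint curvature of
  a 3-h cubic fit is accurate only for oscillations much slower than the
  window (truncation error ~7% at diurnal, ~100%+ at semidiurnal
  frequency); it is a *trend index*, not an estimator of h″.
* **Daylength** — civil dawn→dusk via the standard NOAA solar-position
  equations with zenith 96°; latitudes beyond ±60° are rejected.
* **Daily environment** — SST inside and outside the lagoon, their
  difference, chlorophyll; same-calendar-day joins, missing days flagged
  (never imputed).
* **Screens** — greedy Spearman collinearity filter: variables visited in a
  configurable priority order, dropped when an already-retained partner has
  |ρ| > 0.7 (undefined ρ from constant columns never triggers a drop).  KMO
  = Σr²/(Σr² + Σq²) over off-diagonal simple (r) and partial (q)
  correlations, the latter from the inverse correlation matrix.

## Circular statistics

Each detection-positive 10-min interval contributes one angle (hour-of-day
or moon fraction × 2π).  When only hourly counts are available, an hour's k
positive intervals are represented by k *distinct* bin midpoints spread
evenly across the hour: replicating one midpoint k times reads as spurious
clumping against a continuous-uniform null.  The Hermans–Rasson statistic

T = n⁻¹ Σ_{i<j} [ |π − |θᵢ−θⱼ|| − π/2 − 2.895(|sin(θᵢ−θⱼ)| − 2/π) ]

is exactly rotation-invariant and mean-zero under uniformity; p-values are
Monte-Carlo, (1 + #{T₀ ≥ T})/(B+1), with B ≥ 99 enforced and B = 9,999 the
default.  Its type-I error at α = 0.05 is verified to lie in [0.03, 0.07]
over 1,000 uniform samples.  Note one caveat established while building the
generator: *unbalanced monitoring effort across hours alone makes detection
angles non-uniform*.  A significant circular test conflates animal rhythm
with effort allocation unless effort is hour-balanced or accounted for —
the GAM, which carries effort and all covariates, is the protected
analysis.

CircSiZer maps estimate the derivative of a von Mises kernel intensity on a
96-point angle grid across 10 log-spaced concentrations (κ ∈ [1, 50];
large κ = small bandwidth), with percentile bootstrap CIs (default 500
resamples) deciding rise/fall; cells whose local effective sample size
Σ K(θ−θᵢ)/K(0) falls below 5 are marked insufficient.

## The GAM engine

Smooths are cubic regression splines parameterized by knot values, so the
order-2 penalty is exactly ∫(f″)² of the fitted spline (verified against
numeric integration of the natural interpolant).  Cyclic terms use evenly
spaced knots over the declared period and wrap value and both derivatives.
"Thin-plate" terms are genuine 1-D thin-plate regression splines — radial
basis r³/12 on up to 150 centers, eigen-truncated to rank k−2, polynomial
null space handled by constraint absorption — with the covariate
standardized internally so fits are exactly equivariant to centering and
scaling.  Tensor terms are row-wise Kronecker products of two marginal
cubic bases with one penalty (and one smoothing parameter) per margin.
Every smooth is sum-to-zero centered over the data (per group level for
factor smooths), with group main effects entering through the factor.

Fitting is penalized IRLS (convergence: relative penalized-deviance change
< 1e-9 or coefficient step < 1e-10; smoothing parameters are capped at e²⁰
to keep the normal equations well conditioned — beyond that the fit is
numerically the null-space GLM anyway).  Smoothing parameters minimize the
Laplace-approximate restricted-likelihood criterion

V(λ) = −ℓ(β̂) + ½β̂ᵀS_λβ̂ + ½log|XᵀWX + S_λ| − ½log|S_λ|₊ − M_p/2·log 2π

via Nelder–Mead on log λ (GCV with γ = 1.4 available as the
prediction-error alternative).  AIC = −2ℓ(β̂) + 2·edf with conditional
effective degrees of freedom tr[(XᵀWX+S_λ)⁻¹XᵀWX]; ΔAIC comparisons are
therefore internally consistent, and no external library's AIC constant is
promised.  Fits agree with an independent reference GAM implementation (R,
REML, same bases) to r > 0.999 in fitted means on a shared fixture.
Smooth p-values are Wald-type on the term's coefficient block with
pseudo-inverse rank ≈ round(edf) — adequate for flagging non-significant
terms at p > 0.01, not for fine inference near the threshold.

Basis dimensions default to k = 10 for free-standing univariate smooths,
k = 8 in the assembled pipeline model, 4×4 for the tensor, shrunk when a
covariate has few distinct values.  Because k and the smoothing criterion
are free choices, only sign/shape and rank-order conclusions (which terms
dominate the deviance, where smooths peak) are contracts; exact AIC values
are not.

The deviance decomposition zeroes one term's *centered* contribution at
fixed coefficients (uncentered columns — linear terms, factor dummies —
keep their mean level in the intercept, otherwise the exclusion would
change the model's overall level) and reports
(DE_full − DE_excluded)/DE_full.  Forward selection adds the candidate with
the lowest AIC each round and stops when the best improvement is weaker
than −2; exact ties resolve lexicographically and are flagged.

## Grouped models and contrasts

For a grouped variable: S replicates its smooth per cluster under one
shared smoothing parameter; I gives each cluster its own; GS adds a global
smooth; GI adds a global smooth penalized on ∫(f′)² — first-derivative
penalization of the *global* component, shrinking it toward constancy
harder than the cluster smooths.  The published framework this family
descends from also admits the opposite reading (group smooths penalized
toward the global); the global-first-derivative form is the default and the
alternative is a one-line model-spec change (`penalty_order` on the group
term).  AIC weights are reported both across the full compared set and
within each variable's row of four variants, since either convention is
defensible.

The smooth-difference contrast builds prediction rows over a 200-point grid
for each cluster, zeroes all columns outside the two compared smooth
blocks, differences them, and propagates V̂β: diff = X_newβ̂,
se² = diag(X_new V̂β X_newᵀ).  Intervals are **pointwise** 95% bands, so
~5% of grid points flag under the null; a simultaneous band is not claimed.
Contrasts are exactly antisymmetric and transitive, and a self-contrast is
identically zero with zero variance (differencing a block against itself
cancels — no uncertainty survives).  By default the cluster main-effect
offset is excluded (pure shape difference); `include_group_offset=True`
adds it.

## Clustering and rank tests

HCPC: correlation-matrix PCA on per-deployment environmental means
(mean, not median, over the deployment's monitored hours), retaining the
smallest component prefix with ≥70% cumulative variance; Ward linkage
(squared-Euclidean updates) on the retained scores; k from the largest
relative merge-height gap within k ∈ [2, 6] (overridable); k-means
consolidation initialized at the cut's centroids, which provably never
increases within-cluster sum of squares.  Kruskal–Wallis uses the standard
tie correction; Nemenyi all-pairs defaults to the chi-square formulation
(which reduces exactly to the KW statistic for two groups) with the
Studentized-range variant available.  Anderson–Darling normality p-values
use the Stephens modified-statistic formula, since the usual library route
exposes only critical values.

## The synthetic generator

The generator is the study's condition set made executable: 21 deployments
of ≤48 h (7 in May–Jul, 6 in Aug–Oct, 8 in Nov–Mar, matching the
environmental-cluster sizes), three stations with fixed depth/distance/
bottom descriptors, totals rescaled to ≈640 monitored hours; a mixed
semidiurnal tide (M2+S2+K1+O1, amplitude sum 0.95 m) that alternates
between one and two daily highs over the fortnight; daily SST as an annual
sinusoid (mean 25 °C, amplitude 5 °C, late-August peak) with AR(1) noise
clipped to 19.6–30.4 °C; chlorophyll as a seasonal lognormal.  Counts are
Poisson draws truncated at the recorded-bin cap (a documented truncation;
at the study's rates the cap binds in <1% of hours), with log-rate

−1.936 + 0.028·effort + f_sst + f_moon + f_hour(·, cluster) + f_tide + …

whose intercept and effort slope are the study's fitted values and whose
centered effect shapes encode its findings: an SST bump near 24.5 °C with
suppression above ~28 °C (dominant term), a diel effect peaking at 05:00
and dipping at 19:30 with May–Jul amplitude twice the other clusters',
a moon peak between waning and new moon, and small tide/depth/distance
terms.  Under these defaults a realization yields ≈1.1 dp10m per hour and
≈700 positive intervals of ≈3,860 — the study's detection level.

What passing tests on this twin shows: the pipeline recovers known effect
shapes, deviance-share orderings, cluster-varying diel structure and
calibrated CIs at the study's sample size.  What it does not show:
robustness to overdispersion beyond Poisson, serial dependence between
consecutive hours (real detections are autocorrelated within bouts),
detection-probability variation with noise/range, or ephemeris-grade moon
phases.  Real-data totals, test statistics and AICs therefore need the
actual deposited dataset (see `data/README.md`).

## Problem sizes in the shipped runs

Test-suite and acceptance runs use the study-scale synthetic data
(≈660 hours) for single fits, 400-hour two-group models for the
100-replicate CI-coverage check, 50 replicates for grouped-variant
detection power, and 1,000 samples of n = 100 with 199 Monte-Carlo draws
each for the type-I calibration of the circular test — sizes at which every
targeted property is measured with comfortable margin on a single CPU.
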