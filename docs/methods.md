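# Methods

This note documents the statistical models implemented in `bearsurv`, the
design decisions taken where the methodology left choices open, what the
synthetic-data generator does and does not emulate, and the package's known
limitations. No empirical claims are made here beyond what the test suite
and `scripts/acceptance.py` compute at run time.

## The estimation problem

Aerial line-transect surveys of brown bears record, for each detected
group, a one-sided perpendicular distance x (meters), a group size s, and —
under the double-observer protocol — a capture history in {pilot only,
observer only, both}. Transect lengths are kilometers and areas km²; the
covered strip for a transect of length L is L × (w − c) with w the
truncation distance and c any left truncation (one-sided, because the crew
searches a single side of the aircraft).

Detection declines with distance but *peaks away from the line*: the strip
under the aircraft is poorly visible, so the detection curve rises to an
apex at distance c and falls thereafter. Abundance estimation must
therefore deal with (i) the humped detection shape, (ii) possibly
incomplete detection at the apex, and (iii) *availability* — bears present
but invisible (cover, behavior) on a given day.

## MRDS with point independence (`mrds`, `detfun`)

The detection shape is a two-piece normal,

    g(x) = exp(−(x−c)²/(2σ₁²))  for x ≤ c,
    g(x) = exp(−(x−c)²/(2σ₂²))  for x > c,

with g(c) = 1 by construction. It is fitted by maximizing the renormalized
distance density Π g(xᵢ)/μ, μ = ∫₀ʷ g — no vertical scaling parameter, so
the shape fit never claims anything about absolute detection. Absolute
detection at the apex comes from the capture histories: conditioning on
detection by at least one observer, the intercept-only mark–recapture MLEs
are p̂₁ = n11/(n01+n11), p̂₂ = n11/(n10+n11), and the joint apex
probability p̂· = 1 − (1−p̂₁)(1−p̂₂). Under the intercept model the two
likelihood factors share no parameters, so the joint MLE is the pair of
separate MLEs and the log-likelihoods add.

*Point independence* means observer detections are assumed independent only
at the apex. Conditional observer probabilities are treated as constant in
distance (duplicate fractions do not vary with x); no distance-dependent
dependence model δ(x) and no detection covariates are fitted.

Abundance is Horvitz–Thompson over individual bears,
N̂_cov = Σ sᵢ/(p̂·ĝ(xᵢ)), converted to study-area abundance by
density × study area with density = N̂_cov / covered area. Overlapping
strips are not de-duplicated: each strip is treated as an independent
design-based sample of density, which is one defensible reading when
surveyed area exceeds the study area under repeated coverage.

Numerical choices:

* Optimization is multi-start L-BFGS-B from 8 deterministic Latin-grid
  starts over c ∈ [0, w/2], σ₁, σ₂ ∈ [w/50, w]; ties within 1e−6 of the
  best objective resolve to the smallest apex. The apex box stops at w/2
  because an apex beyond half the strip leaves too little declining tail to
  identify σ₂ (configurable via `c_max`).
* The two-piece likelihood is multimodal in c; the Latin starts are what
  make the fit reproducible. At n = 400 the apex MLE has a sampling sd of
  roughly 30 m.
* Horvitz–Thompson terms with ĝ(x) < 1e−6 are excluded with a warning: a
  far-tail detection under a tight σ̂₂ would otherwise dominate the sum.
* Uncertainty is a nonparametric bootstrap over transects (the independent
  design unit), default B = 500, percentile intervals, CV = bootstrap
  SD / point estimate. Replicates with no duplicate detections (n11 = 0)
  are redrawn and counted; bootstrap refits start the shape optimizer from
  the full-data fit plus two perturbed starts for speed.

## Bayesian CDS by data augmentation (`cds`)

Left-truncating at the apex of the composite curve (and shifting distances
so the retained interval is [0, w′), w′ = w − c) restores a monotone
declining distance distribution; the capture histories are then discarded
and a half-normal model fitted. A detection exactly at c is retained at
shifted distance 0 (half-open convention, deterministic).

Unknown group abundance in the covered strips is handled by
parameter-expanded data augmentation over M candidate groups:

    z_i ~ Bernoulli(ψ)           inclusion
    x_i ~ Uniform(0, w′)         latent distance where undetected
    s_i = 1 + e_i, e_i ~ Poisson(λ)
    y_i | z_i, x_i ~ Bernoulli(z_i · exp(−x_i²/(2σ²)))

Group size is modeled as 1 + Poisson(λ) rather than plain Poisson: a
detected group has at least one bear, and the shift is the minimal fix that
keeps conjugacy. Per draw, N_cov = Σ z_i s_i and abundance scales by study
area / covered area.

Sampling is Metropolis-within-Gibbs, fully vectorized over the M slots:
Bernoulli full conditionals for z, prior-proposal Metropolis for the latent
distances, conjugate Beta and Gamma updates for ψ and λ, and a log-scale
random-walk Metropolis step for σ whose step size adapts toward 30–45%
acceptance during burn-in only and is frozen afterwards to preserve
detailed balance. Defaults: 3 chains, 20,000 iterations, 10,000 burn-in,
thin 5; per-chain seeds are master seed + chain index.

Priors default to σ ~ Uniform(1 m, 2w′), ψ ~ Uniform(0, 1),
λ ~ Gamma(1, 1) — deliberately vague. The augmentation size defaults to
M = max(5n, n + 200); a posterior mean ψ above 0.8 triggers a warning that
M is pinching the posterior. Informed priors on σ are lognormal,
moment-matched to the log of posterior draws from a donor survey
(`fit_prior_from_posterior`; degenerate draw sets with sdlog < 0.01 are
rejected rather than silently floored).

Two cross-checks guard the sampler. `marginal_loglik_cds` integrates z and
the latent distances out analytically — each undetected slot contributes
(1 − ψp̄) with p̄ = μ/w′ — and the test suite verifies that the sampled
(σ, ψ) posterior matches a fine-grid posterior built from this marginal
likelihood. Convergence is screened with the Gelman–Rubin potential scale
reduction factor √[((n−1)/n·W + B/n)/W]; note B = 0 (identical chains)
gives √((n−1)/n), marginally below 1. Posterior summaries use the median,
central 95% interval with linear interpolation between order statistics
(numpy's default quantile rule), and CV = posterior SD / posterior mean.

One pooled ψ is used; transect-level density heterogeneity is not modeled.
Unmodeled detection heterogeneity is left to the pooling robustness of
conventional distance sampling.

## Open-distance availability model (`open_distance`)

On a T-day survey whose daily transect sets each represent the study area,
availability is treated as temporary emigration from a shared
superpopulation: each candidate group additionally carries
a_i ~ Bernoulli(φ_{t(i)}) for its survey date, detection requires
z_i·a_i = 1, and φ_t ~ Beta(α, β) with α, β ~ Gamma(1, rate 0.1) truncated
to α + β ≤ 50. Augmented slots are assigned dates proportionally to
per-date effort (largest-remainder, fixed before sampling) so each date's
candidate pool represents the study area. Since Σ z_i s_i counts
superpopulation bears across T per-date covered samples, density divides by
T × (mean per-date covered area), i.e. by total covered effort, before
scaling to the study area. p_p (presence in the study area) is fixed at 1.

ψ and mean availability p̄_a = (1/T)Σφ_t are only weakly separately
identified: the detected counts constrain mainly their product, and the
between-day variation plus the Beta hierarchy and priors supply the rest.
Two consequences are built in deliberately:

* the sampler includes a *ridge-swap* Metropolis move (ψ′ = κψ,
  φ′ = φ/κ) computed with the inclusion/availability indicators
  marginalized out and followed by their conditional refresh — without it,
  single-site Gibbs mixes very slowly along the ridge and short runs
  report availability wherever they were initialized;
* any incomplete detection of available bears at the apex is absorbed into
  φ̂ (it is not separable from availability in this design), and the test
  suite asserts exactly that behavior rather than pretending the two are
  distinguishable.

Because identification is partly prior-driven, availability estimates
carry wide credible intervals, and the validation tolerance for recovering
a true mean availability of 0.65 is ±0.12 — this reflects the model's
intrinsic weak identifiability, not sampler quality, and should not be
tightened without additional design information (e.g. revisited transects).

## Synthetic-data generator (`synth`, `scenarios`)

The generator emulates the field protocol: groups placed per transect with
Poisson counts at density/(1+λ) groups per km² of strip, distances uniform
on (0, w) on one side, sizes 1 + Poisson(λ), per-date Bernoulli
availability, a two-piece normal detection shape, and two observers with
apex probabilities p₁, p₂. Default design matches a real preserve-scale
survey: 288 transects × 15 km, w = 800 m, 1,254 km² study area, density
0.058 bears/km² (chosen to yield on the order of 90 detections per pass),
λ = 0.5, apex 300 m, σ₁ = 120 m, σ₂ = 260 m, p₁ = 0.9, p₂ = 0.85.

`observer_mode` controls the dependence structure. The default
`point_independence` realizes the estimators' model: the joint probability
p· scales the shape and duplicate fractions are constant in distance.
`full_independence` (each observer independently pᵢ·q(x) at every
distance) is also available; under that world the intercept-only MR
estimator provably recovers a distance-averaged probability
(≈ p₁·E[q²|det]/E[q|det], roughly 0.65 when the apex truth is 0.9) and the
test suite demonstrates the attenuation. Validation worlds use the
default; worlds meant for pure CDS validation use a single effective
observer (p₁ = 1, p₂ = 0) so the combined detection curve is exactly the
assumed half-normal (two perfect observers would combine to 2q − q²).

What the generator does *not* emulate: spatial point processes across the
study area (groups are placed by strip, so physically overlapping strips
are not simulated), terrain/visibility covariates, observer dependence at
intermediate distances beyond the two modes above, animal movement between
days, or serially correlated availability. A green recovery test therefore
establishes correctness of the estimators *under their own assumptions* at
realistic survey scale — not robustness to the field phenomena the real
protocol contends with.

The fixed validation worlds in `bearsurv.scenarios` (CDS recovery at
n ≈ 300, MRDS recovery at n ≈ 350, six-day availability world with
φ_t ~ Beta(mean 0.65, sd 0.1), sparse n ≈ 60 world, and a large n ≈ 2,000
comparison world) are part of the package's validation design; their sizes
were chosen once, at the scale of the real surveys, and are not tuned.

## Known limitations

* The MRDS variance is bootstrap-only; no analytic variance or
  delta-method alternative is provided.
* The CDS model assumes the left-truncation point is known when the
  posterior is computed; apex-estimation uncertainty from the MRDS stage is
  not propagated into the CDS credible interval.
* The open model's availability scale is prior-sensitive (see above);
  with unequal per-date effort its covered-area normalization assumes each
  date's sample is representative regardless of effort share.
* Seeds reproduce results exactly only on the same numpy generation
  stream (PCG64 defaults).
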