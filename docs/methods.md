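# Methods

`ferticast` projects the total fertility rate (TFR) of a panel of
sub-national regions on the 5-year period grid used by demographic
estimates (periods "1950-1955", "1955-1960", ...), producing probabilistic
trajectories to 2100. The model treats the TFR's evolution as three
regimes fitted and simulated separately.

## Phase segmentation

Every region's history is first segmented deterministically.

The **transition onset** τ_c is the latest period that is a local maximum
of the series (ties allowed, one-sided comparison at the endpoints), lies
within 0.5 children of the series maximum M_c, and exceeds 5.5 children.
Regions whose peak never reaches 5.5 children began declining before the
observation window and receive the sentinel `BEFORE_OBSERVATION`; their
whole observed history is treated as transition (the onset TFR then enters
the model as a parameter, see below). The local-maximum convention is
isolated in one function (`phases._local_maxima`) so it can be swapped;
the rule as stated reproduces, for example, τ at the *second* 6.9 in the
series 6.9, 7.0, 6.9, 6.6, 6.9, 6.2, 5.0 — the last near-global peak
before sustained decline.

The **post-transition onset** λ_c is the first period t (searched after τ)
with f_{t−1} < f_t < f_{t+1} and all three values below 2 children: two
consecutive increases at sub-replacement fertility. Boundary periods
cannot qualify because the rule references both neighbours. When no period
qualifies, the region is still in transition at the end of observation
(`NOT_REACHED`).

Periods before τ (Phase I) are excluded from all likelihoods; a region
observed in Phase I is simply assumed to be in the transition from the
following period.

## Transition model (Phase II)

For transition steps τ ≤ t < λ the TFR follows a random walk with a
level-dependent drift:

    f_{c,t+1} = f_{c,t} − d(θ_c, f_{c,t}) + ε_{c,t}

The drift is the **double-logistic decrement**, the sum of two logistic
curves in the current level f with region parameters
θ_c = (Δ_c1, Δ_c2, Δ_c3, Δ_c4, d_c):

    g(θ, f) = −d_c · L( (2 ln 9 / Δ_1)(f − ΣΔ + 0.5 Δ_1) )
              + d_c · L( (2 ln 9 / Δ_3)(f − Δ_4 − 0.5 Δ_3) ),
    L(x) = 1/(1+e^{−x})

so each logistic rises from 10% to 90% of its height over its Δ interval.
The Δ's partition the transition's TFR range top-down: U_c = ΣΔ_ci is the
onset level, Δ_c4 the end-of-transition level, and d_c (children per
5-year period) the maximum pace of decline, reached mid-transition. The
decrement is gated to 0 for f ≤ 1. The second logistic's midpoint sits at
Δ_4 + 0.5Δ_3 (its sign convention is fixed here so that the two midpoints
bracket the transition range symmetrically, matching the worked values in
the test suite).

The distortion ε is Gaussian: N(m_τ, s_τ²) at an *observed* onset step,
else N(0, σ(f)²) with the level- and era-dependent sd

    σ(f) = c(t) · ( σ0 + (f − S)(−a·1[f ≥ S] + b·1[f < S]) )

σ0 is the maximum sd, reached at TFR level S; a and b are the linear decay
rates above and below S; c(t) = c_1975 inflates the sd for the periods
1950-1955 through 1970-1975 (older estimates are noisier) and is 1 from
1975-1980 on, including all projected periods. σ is floored at 0.01
children in the likelihood to keep it proper (the linear model can go
non-positive at extreme levels); simulation paths use the un-floored σ so
that zero-noise configurations are exactly deterministic.

### Hierarchy and priors

Region parameters are tied together through transforms with bounded
ranges implied by demographic plausibility:

* d* = log((d_c − 0.25)/(2.5 − d_c)), so d_c ∈ (0.25, 2.5) children/period,
  with d* ~ N(χ, ψ²);
* Δ4* = log((Δ_c4 − 1)/(2.5 − Δ_c4)), so Δ_c4 ∈ (1, 2.5), with
  Δ4* ~ N(Δ̄_4, δ_4²);
* the shares p_i = Δ_ci/(U_c − Δ_c4), i = 1..3, are a softmax of
  γ_c ∈ R³ with γ_ci ~ N(α_i, δ_i²).

γ is identified only up to an additive constant; the proper normal priors
on all three coordinates remove that flat direction from the sampler, and
the canonical storage transform (`to_transformed`) gauge-fixes Σγ = 0.

For regions whose transition predates the window, the onset level carries
the uniform prior U_c ~ U(min{5.5, max_t f_{c,t}}, 8.8). Otherwise
U_c = f_{c,τ} is fixed.

No published priors exist for the hyperparameters, so all get uniform
priors on wide, configurable supports (defaults: χ, Δ̄_4, α_i on (−5, 5);
ψ, δ_4, δ_i on (0.01, 5); σ0 on (0.01, 0.6); S on (3.5, 6.5); a, b on
(0, 0.2); c_1975 on (0.8, 2); m_τ on (−1, 1); s_τ on (0.01, 1)) — proper,
diffuse, and centred on plausible ranges. The distortion parameters can
also be clamped via `MCMCConfig.fixed_params` (fixed-variance run mode).

### Sampler

`run_mcmc` is single-site Gaussian random-walk Metropolis within a Gibbs
sweep over every scalar coordinate: per-region (d*, Δ4*, γ, optionally
U_c), then hyperparameters (which touch only the region-prior terms, never
the data), then the shared distortion parameters (vectorized over all
transition steps with cached residuals). Proposal scales adapt toward 44%
acceptance in windows of 50 iterations during burn-in and are frozen
afterwards, preserving the correct invariant distribution for the retained
draws. Runs are bit-reproducible given the seed (per-chain streams are
`default_rng([seed, chain])`); acceptance rates per parameter are recorded
and a warning is raised if any free parameter never moves after burn-in.

Defaults are 3 chains × 20,000 iterations (burn-in 10,000, thin 10); the
reduced preset used throughout the tests and examples is 2 × 2,000
(burn-in 1,000, thin 5), which is small enough that split-R̂ flags on the
18-region demo panel are expected and reported rather than suppressed.
Summaries report mean, sd, naive SE, batch-means time-series SE and the
2.5/25/50/75/97.5% quantiles; split-R̂ and an autocorrelation-based
effective sample size are computed in-package and cross-checked against
arviz in the tests.

Correctness is audited three ways: stored log-posteriors are recomputed
from the public density functions for retained states; no retained draw
may violate a support; and with all but one coordinate clamped the MCMC
histogram must match dense grid integration of the conditional posterior
(total-variation distance < 0.05 at 20,000 draws).

## Post-transition model (Phase III)

After λ the TFR is a stationary AR(1) around the replacement level
μ = 2.1 children per woman (fixed, not estimated):

    f_{t+1} ~ N( μ + ρ (f_t − μ), s² ),  |ρ| < 1.

ρ and s are estimated by *conditional* maximum likelihood (conditioning on
each pair's f_t) from consecutive post-transition steps pooled across all
regions — the conditional form has a closed-form maximizer and makes
pooling across regions with different Phase III lengths trivial; a config
switch restricts the fit to the national series. ρ̂ is clipped into
(−0.999, 0.999) with a warning when the raw estimate is non-stationary,
which genuinely occurs on weak-recovery panels (including the packaged
demo panel) and then yields near-random-walk projections.

## Projection

Trajectories are simulated per region from the last observed value. Each
trajectory draws one posterior state with replacement and keeps it along
the path, so the fan charts propagate parameter uncertainty and step noise
together. While in the transition regime a step applies the decrement and
a N(0, σ(f)) distortion; the trajectory switches permanently to AR(1)
dynamics when the post-transition pattern (two consecutive increases, all
three values < 2) first holds on the simulated path — the same rule used
in-sample — or immediately if the level falls to f ≤ 1, where the drift
gate closes and the transition model has nothing more to say
(`phase3_rule` configures this; `"never"` keeps transition dynamics as a
diagnostic mode). Regions already post-transition at the end of
observation start directly with AR(1) steps. All simulated values are
floored at 0.5 children (`tfr_floor`), a guard against the Gaussian
distortions producing non-physical TFR.

Summaries per future period are the mean, sd and the nine empirical
quantiles {2.5, 5, 10, 25, 50, 75, 90, 95, 97.5}%; the **median** is the
point projection (robust to tail behaviour). High/low fertility variants
are the median ± 0.5 children, the low variant floored. Output years label
each 5-year period by its start year + 3 (midpoint rounding), so the first
period after 2015-2020 prints as 2023 and the horizon period 2095-2100 as
2098. Per-region simulation streams are keyed by a stable hash of the
region id, making panel results independent of region ordering.

## Synthetic data

`generate_panel` emulates the generative structure above with known
truth: region parameters drawn from the hierarchy, an onset period in a
configurable window (default periods 0–3 of a 14-period 1950–2020 grid),
an onset level U_c ~ U(6.0, 7.5), a flat pre-onset plateau 0.25 children
below the peak, transition steps by the random walk with distortions
(default σ0 = 0.08, s_τ = 0.1, c_1975 = 1.25), and a switch to AR(1)
dynamics (default ρ = 0.9, s = 0.05) once the TFR first falls below the
region's Δ_c4. The switch-at-completion rule is deliberate: recoveries in
real low-fertility panels come from mean reversion, not from noise
fighting a downward drift, and it makes the detectable λ pattern emerge
naturally on most regions while some remain in-transition — the mix the
three-phase model is built for. The recorded λ is the period where the
pattern first holds on the generated values, so deterministic detection
recovers it exactly; τ is recovered exactly whenever realized distortions
stay below the early-transition drift (~0.1·d_c), which holds for the
low-noise settings used in the recovery tests and for ~95% of regions at
the default noise.

What the generator does **not** emulate: age-structured fertility,
tempo/quantum distinctions, migration-driven regional heterogeneity,
correlated errors across regions, and revision structure in historical
estimates. Passing recovery tests therefore show the estimation machinery
is self-consistent under the model, not that the model captures every
feature of register data.

`spain_like_fixture` is a hand-authored 18-series demo panel (17 regions
plus a national aggregate) built from smooth parametric curves: 1950s
levels of 2.6–3.3 children, decline from the 1970s, sub-replacement minima
in the late 1990s, mild recoveries and a slight post-2010 decline. It is
synthetic by construction (documented in its docstring), peaks below 5.5
children everywhere — so all onset levels enter the model as parameters —
and triggers the post-transition pattern in 12 of 18 series.

## Numerical choices and scales

* Logistic evaluations guard against overflow (saturating beyond |x| > 700).
* The likelihood hot path is a plain-float loop (a region contributes ~10
  steps, below the crossover where vectorization pays off); the shared
  distortion updates are vectorized over all steps with cached residuals.
  A 30-region panel runs 2 × 5,000 iterations in ~30 s on one core.
* Tests and the acceptance script use reduced problem sizes chosen to
  exercise every contract at interactive runtimes: 2 × 2,000–5,000 MCMC
  iterations, 400–10,000 trajectories, 100–200 calibration replicates.
* Ties in the τ rule are handled by ≥ comparisons (plateaus count as local
  maxima); ties in max{t} cannot occur since indices are distinct.
* Onset-level bounds: when a sampled U_c proposal falls below the
  inverse-mapped Δ_c4, the state is rejected through a −∞ log-posterior
  rather than clamped.

## Known limitations

* Single-site random-walk Metropolis mixes slowly on strongly correlated
  blocks (γ and Δ4*, U_c with flat likelihoods); the production preset and
  the split-R̂/ESS diagnostics exist to surface this honestly rather than
  hide it.
* The λ rule is sensitive to single-period wiggles near the 2-children
  ceiling; it is the model's definition, applied verbatim, not smoothed.
* ρ̂ near the stationarity boundary makes long-horizon projections hug the
  last observed level with widening bands — an honest consequence of
  weak observed recoveries, visible in the demo panel.
* μ = 2.1 is fixed; panels whose post-transition fertility plateaus far
  below replacement will show slow upward drift in projections by
  construction.
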