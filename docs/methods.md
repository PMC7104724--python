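# Methods

## Model

Coverage depth along a circular replicon is modelled as repeated sampling of
genome positions with a circular observation probability.  Position
i ∈ {1..I} maps to the angle θ_i = i/I · 2π (the bin's upper index by
convention; a bin-center convention would shift μ by π/I, which is
negligible but fixed here for bit-reproducibility).  Given total
observations T_s = Σ_i d_{i,s} for sample s, the bin counts are multinomial
with cell probabilities proportional to a circular density P(θ | ω_s), so
the parameter-dependent part of the log-likelihood is the depth-weighted sum

    log L(ω) = Σ_s Σ_i d_{i,s} log P(θ_i | ω_s).

The remaining multinomial terms (log T_s! − Σ log d_{i,s}!) are data-only
constants; `loglik_multinomial_full` includes them, the fitting routines do
not need them.  Marginally each bin count is Binomial(T_s, p_i) with
p_i = P(θ_i)·2π/I (the density–probability discretization is the package's
convention; probabilities then sum to ≈1 across bins).

The location μ (replication origin) is shared across samples; the
concentration is per sample.  The continuous density is used directly; an
opt-in discrete normalization constant c_ω is provided
(`discrete_normalization_constant`) with direct summation for von Mises and
wrapped Cauchy and the adopted closed forms N/2π (cardioid) and (N+2)/2π
(linear cardioid).

### Families

| family | density kernel (Δ = θ−μ) | pPTR | concentration bound |
|---|---|---|---|
| von Mises | exp(κ cos Δ) / 2π I₀(κ) | e^{2κ} | κ ≥ 0 |
| cardioid | (1 + 2ρ cos Δ)/2π | (1+2ρ)/(1−2ρ) | 0 ≤ ρ < 1/2 |
| wrapped Cauchy | (1−ρ²)/2π(1+ρ²−2ρ cos Δ) | ((1+ρ)/(1−ρ))² | 0 ≤ ρ < 1 |
| Jones–Pewsey | (cosh κψ + sinh κψ cos Δ)^{1/ψ} / C | e^{2κ} | κ ≥ 0, ψ real |
| linear cardioid | (1 + 2ρ(\|\|Δ\|−π\|−π/2))/2π | (1+πρ)/(1−πρ) | 0 ≤ ρ < 1/π |
| exp. linear cardioid | ρ e^{2ρ(\|\|Δ\|−π\|−π/2)} / (e^{πρ}−e^{−πρ}) | e^{2πρ} | 0 ≤ ρ < 1/π |

Bounds are enforced as open intervals at the poles with a 1e-8 margin.  The
Jones–Pewsey normalization constant is computed by adaptive quadrature of
the kernel (cached per (κ, ψ)) rather than through the associated Legendre
function, avoiding its edge cases near ψ = 0; ψ = 0 reduces exactly to the
von Mises case, and any real ψ is admitted with sign-aware quadrature.  The
exponential-linear-cardioid exponent is grouped as 2ρ(||Δ|−π| − π/2), the
grouping under which the stated normalizer and pPTR are exact.

pPTR is the max/min ratio of the fitted density and the growth proxy; the
matched-shape conversions ρ_c = tanh(κ)/2 and ρ_wC = tanh(κ/2) relate the
families' concentrations.  The mean resultant length is provided as the
model-free alternative statistic.

### Shape extensions

Written in mode-centered coordinates x = θ − μ with symmetric base density
f₀:

* **SE** (Batschelet peakedness): f ∝ f₀(x + λ sin x), renormalized by
  composite Simpson quadrature with 20 subintervals.
* **InvSE** (inverse Batschelet): f = f₀(g(x))·g′(x) with
  g(x) = (1−λ)/(1+λ)·x + 2λ/(1+λ)·t⁻¹(x), t(y) = y − ½(1+λ) sin y.  The
  Jacobian factor makes this the exact change-of-variables density of a base
  draw pushed through g⁻¹, so it integrates to 1 with no quadrature.  (A
  pure argument substitution f₀(g(x)) provably loses mass — its integral is
  ≈ 1/g′(0) for peaked bases — so the normalization-free property belongs to
  the transformed-variable density.)
* **MIAE** (mode-invariant skewness): f ∝ f₀(x − ν sin²x), Simpson(20)
  renormalized.
* **InvMIAE**: f = f₀(s⁻¹(x)) with s(y) = y + ν sin²y; normalization, mode
  and pPTR are all unchanged for any ν (s fixes 0 and ±π and is strictly
  increasing for |ν| < 1).

Both skew maps use sin²(x): with that form the maps are strictly increasing
on the admissible range, the mode stays exactly at μ, and mirroring the
density about μ is equivalent to flipping the sign of ν.  λ and ν live in
(−1, 1), the range on which all four maps are monotone; this range is
implementation-defined (only the 0.8 root-finder switch is prescribed).

Inverse transforms are solved pointwise: Newton iteration started at the
target angle when |λ| or |ν| < 0.8 (tolerance = single-precision machine
epsilon ≈ 1.19e-7 on |f|, 30 iterations max), otherwise the Illinois
variant of regula falsi on the bracket [θ−π, θ+π] (tolerance 1e-13, 100
iterations max; the bracket always sign-changes because the maps deviate
from the identity by less than π).  At the 0.8 boundary Illinois is used
(the conservative choice).  Non-convergence raises an error carrying the
last iterate.

## Priors

* concentration: half-Student-t(df 2.5, scale 0.2 for von Mises and
  Jones–Pewsey, 0.1 cardioid, 0.17 wrapped Cauchy, 0.105 linear cardioid,
  0.1103 exponential linear cardioid).  For the von Mises family the prior
  CDF at the κ giving pPTR = 2 is 0.80, encoding that most environmental
  PTRs fall in [1, 2]; for the ρ families with their own printed scales the
  same quantile is ≈ 0.6 (the scale approximately equals the ρ at pPTR 2).
* ψ, λ, ν: standard normal, guarding against overfitting the shape.
* μ: flat on the circle.
* mixture weights: Dirichlet(A) with A = 50/M per component — strongly
  equalizing, reflecting that multiple origins tend to fire with similar
  activity.

## Estimation

**Unconstrained reparameterization.** μ is a 2-vector through atan2 (no
0/2π seam); κ = exp(z); ρ = bound·logistic(z) (keeps ρ in [0, bound), which
an atanh scaling would not); ψ unconstrained; λ, ν = tanh(z); α = softmax
with the final logit pinned at 0.  A standard-normal term on the location
vector's two components pins its non-identified radius without touching the
angle's marginal.

**Optimizing mode.** L-BFGS on the negative log posterior with seeded
restarts (seed + 0..n_seeds−1); the restart with the highest posterior wins,
so results are deterministic given the seed.  Defaults: 1 restart for plain
single-origin models, 5 for shape-extended models (their ψ/λ/ν surfaces are
multimodal and a single start can stall at ψ ≈ 0), 30 for mixtures.

**Sampling mode.** Affine-invariant ensemble MCMC (emcee, differential-
evolution moves), walkers initialized in a small ball around the MAP.
Defaults follow the optimizing/sampling protocol of the single-origin model
(500 steps, 300 warm-up) and the mixture model (1500 steps, 1000 warm-up);
"iterations" count ensemble steps.  The estimate is the EAP over post-warmup
draws (circular mean for locations).  Convergence: each requested chain's
ensemble, flattened step-major, is treated as one chain and split-Rhat
(rank-normalized, via arviz) is computed per parameter; the fit is accepted
only if every Rhat ≤ 1.1.  A constant chain has Rhat 1 by convention.  With
a single chain this is the split-Rhat caveat: only within-run stationarity
is checked.

**Model selection.** AIC = 2k − 2 log L, BIC = k log n with n = Σ_s T_s
(the total observation count; the choice of n is the package's), WAIC from
pointwise (per nonzero bin, depth-weighted) log-likelihood draws via the
log-mean-exp/variance form.  Parameter counts: 1 + S for vanilla non-
Jones–Pewsey models, 1 + 2S for Jones–Pewsey (ψ is per-sample, which is
what the 1 + 2S count implies), +1 for a λ/ν extension (shared across
samples), and M + M·S + (M−1) for an M-origin mixture (an implementation-
defined count; none is prescribed for mixtures).  Nested pairs are compared
by Wilks' chi-squared likelihood-ratio test with the statistic clipped at
zero.  Origin-count selection fits M ∈ {1..4} by multi-seed MAP (AIC) and
an MCMC run seeded at the MAP (WAIC); ties break toward smaller M, and when
AIC and WAIC disagree the smaller winner is chosen, since the mixture is a
singular model and neither criterion alone is trusted with the larger
count.  Mixture label switching is resolved by sorting components by μ.

## Preprocessing and QC

Raw `samtools depth`-style tables (3-column ref/pos/depth or 2-column
pos/depth, 1-based, absent positions = 0) are median-binned with window =
stride = 100 nt (denoising and ~100× compression in one step; medians of
even windows average the middle pair; the tail bin uses the positions
available; windows do not wrap).  The top 1% highest bins are then blanked
and refilled with zero — exactly ⌈1% of bins⌉, counted on the binned track —
to remove conserved-region coverage spikes; the filter order (after
binning) and the bin-counting interpretation are fixed conventions here.

Sample eligibility: under uniform random sequencing the zero-coverage
fraction should be f̂ = exp(−a) at average coverage a (Lander–Waterman).
For samples below 5× the sample is flagged when log f > 0.56·log f̂ — both
logs are negative, so this catches samples with substantially more zero
coverage than random sampling predicts (concentrated/noisy coverage).  The
multiplier's operand is ambiguous in principle (log-scale vs raw score);
the log-scale reading is the default and the raw-score variant is available
behind a flag.  Fitted pPTR ≥ 3.0 flags residual noise.  Zero fractions are
computed on the binned track.

Evaluation statistics: absolute relative error |est − ref|/ref with the 15%
reference threshold; log2 growth rates from abundance time series (centered
or forward differences); lag-scanned Pearson correlation requiring ≥ 3
overlapping pairs per lag.

## Simulator

`generate_coverage` draws T = mean_depth·I events from a multinomial whose
cell probabilities are the chosen density at the bin angles — exactly the
generative process the likelihood assumes.  Defaults mirror the artificial-
coverage protocol: 1 Mnt of positions, 20× average depth, concentrations
aligned to pPTR = 2.  Perturbations: `add_peak_noise` adds uniform depth
boosts in randomly placed regions (conserved-region spikes);
`rarefy` binomially thins each bin to a lower target coverage.  All
randomness flows from one seeded generator per call, recorded in metadata.

What the simulator does *not* emulate: read length and the resulting
correlation of adjacent positions, alignment and mapping error, GC bias,
strand asymmetry, reference mutations.  Passing recovery/robustness tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to alignment artifacts.  In
particular, rarefaction tests operate at nucleotide resolution (thinning
position-level events of a 1 Mnt track), because without read-level
clumping a median filter would annihilate ultra-sparse coverage that real
overlapping reads would preserve.

## Test problem sizes

The suite exercises: simulator fidelity at 10⁴ bins × 20× over 100
replicates per family; parameter recovery over a 4 location × 3
concentration × 3 coverage grid with 10 seeds (10³ bins); rarefaction of a
1 Mnt 20× track to 0.01× (20 replicates) and single-spike peak noise at 10⁴
bins (20 replicates); and origin-count selection on a three-origin 10³-bin
track with the full 30-seed mixture protocol.  These sizes are the
package's validation defaults; all are generated programmatically at test
time.

## Known limitations

* The wPTR/mwPTR scores assume replisomes stop where they meet and that
  multi-origin effects add; both are better established in bacteria than in
  archaea or eukaryotes.
* pPTR is a growth *proxy*: converting it to a doubling time requires the
  species' replication period, so cross-species comparisons of raw pPTR are
  not meaningful.
* The Simpson(20) renormalization constant of the SE/MIAE extensions is
  spectrally accurate in the working range (pPTR ≤ ~3) but degrades for
  very concentrated wrapped-Cauchy bases (ρ → 1); increase the subinterval
  count for such regimes.
* GC-content correction is intentionally omitted; apply upstream correction
  if needed.
* Split-Rhat from a single ensemble run detects non-stationarity, not
  failure to find other posterior modes.
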