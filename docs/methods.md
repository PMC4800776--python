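# Methods

## The optical model

The holobiont is treated as a single absorbing layer (host tissue +
in-hospite *Symbiodinium* pigments) over a diffusely reflecting
skeleton. Downwelling light is partly absorbed on its first pass
(fraction I_a1); the remainder reaches the skeleton and can be returned
through the tissue once or repeatedly, where a further fraction is
absorbed (I_a2 = I_a − I_a1, the *skeleton-dependent* absorption). The
balance equations close over two measurable reflectances — the bare
skeleton R_S and the intact holobiont R_H, both relative to a white
standard — and three dimensionless transport coefficients:

* **α = a₂/I_a1 ≥ 1** — absorption amplification of skeleton-reflected
  light by path elongation. Grows as pigment density falls.
* **β = R_S/R₁ ≥ 1** — relates R_S to R₁, the fraction of unabsorbed
  light leaving the holobiont after skeletal reflection including all
  re-entries; β > 1 for non-flat geometries.
* **γ ∈ (0, 1]** — scale of absorption by processes other than the
  first or reflected pass.

Inverting R′ = R_H/R_S gives I_a1 as the negative root of
α·I_a1² − (1+α)·I_a1 + (1 − βR′) = 0. The radicand is evaluated as
(1−α)² + 4αβR′ — algebraically identical to (1+α)² − 4α(1−βR′) but free
of cancellation as R′ → 0, which matters for darkly pigmented corals
whose R_H is orders of magnitude below R_S. The flat-coral special case
is β = γ = 1 with 1 < α ≤ 2; at α = β = 1 the inversion reduces to
I_a1 = 1 − √R′, and at R_S = 1 the total reduces to the classical
estimate I_a = 1 − R′. Setting **α = β = γ = 1 yields a lower bound on
I_a2** (verified numerically over the admissible coefficient grid in
the test suite); all headline feedback statistics use this conservative
bound. When noise pushes βR′ above 1 (nearly bare skeleton), I_a1 is
clamped to 0 and the result flagged `over-bright` rather than raising.

The **feedback statistic** per species is
−Δ(I_a2/ρ|HT-HL − I_a2/ρ|HT-CL)/Δρ: how fast the light-driven excess of
absorbed light per unit pigment grows as pigment ρ declines. Series are
formed from species × day means (ramet-averaged R_H and Chl *a*),
differenced across the two thermal-stress light treatments on shared
days, and regressed against the HT-HL pigment series; the negated
least-squares slope is the rate. Temporal rates generally use
least-squares slopes over the stress window rather than endpoint
difference quotients (noise robustness; the two-point mode is retained
for oracle tests). ρ defaults to Chl *a* areal density (µg cm⁻²). The
per-species rates are fitted as an inverse power law y = a·μ′^(−b) by
OLS of ln y on ln μ′; species with non-positive rates cannot enter the
log fit and are excluded with a warning.

## Photophysiology

Fv/Fm = (Fm − F0)/Fm from dark-adapted minimal/maximal fluorescence.
From a 13-cycle induction curve, steady-state F′ and Fm′ are the means
of the final 3 cycles by default — the protocol defines "steady state"
only loosely, so the window is a parameter (`steady_cycles`), never a
hard-coded truth. The yield partition
Φ_PSII = (Fm′−F′)/Fm′, Φ_NPQ = F′/Fm′ − F′/Fm, Φ_NO = F′/Fm sums to 1
as an algebraic identity (asserted to 1e−12). Q_m = 1 − Φ_PSII/(Fv/Fm)
may fall outside [0, 1] with noisy inputs; values are returned
unclamped for callers to flag.

## Reflectance

Reflectance is the dark-corrected ratio of sample to adjacent
white-standard counts, per wavelength, with no smoothing anywhere (the
value at a wavelength depends only on that wavelength's inputs). Scalar
R_H/R_S is the unweighted mean over the closed 400–700 nm visible band
(configurable); the spectrum→scalar reduction is a package convention,
as is the n−1 estimator inside the replicate SEM/COV summary over the
ten spots per ramet. The "minimal resolvable relative change" is
operationalized as 2·SEM/mean·100 % — with ten replicates at COV 38 %
this sits near 24 %, an interpretation documented here rather than a
measured fact.

## Bleaching statistics

PE (temporal rate of Fv/Fm or Q_m change) is a per-ramet OLS slope over
the stress window (days 0–11). Because ramets are distinct physical
individuals across treatment cells, the Taylor-expansion difference
ΔPE is realized at the species × cell level: PE per cell is the mean of
ramet slopes, then ΔPE(T_j) = PE(T_j, HL) − PE(T_j, CL) for the light
basis and ΔPE(I_j) = PE(HT, I_j) − PE(CT, I_j) for the temperature
basis. Any additive per-species offset constant across the differenced
factor cancels exactly — the property that removes unknown confounders
such as flow microenvironment or tissue-thickness differences.

Scattering groups: species with μ′_S,m below the across-species mean
are "low", at or above it "high" (ties to high, fixed and documented).

The clustered longitudinal model `metric ~ group × day` uses colonies
(nested in species) as clusters. Three estimators are provided and
agree on point estimates for balanced designs, where each group slope
equals the within-group pooled OLS slope:

* `colony_slopes` (default) — two-stage cluster summary: OLS slope per
  colony, group slope = mean of colony slopes, interaction p from a
  Welch t-test between the two colony-slope sets. For balanced clusters
  with cluster-level random effects this test is exactly calibrated,
  which the 1000-replicate null simulation in the test suite confirms
  (rejection rate ≈ 5 % at nominal α = 0.05).
* `cluster_robust` — pooled OLS with CR1 cluster-robust covariance and
  a t reference on G−1 degrees of freedom. With only ~20 clusters this
  is mildly anti-conservative (~8 % empirical size), the known
  small-G behaviour of CR1; it is kept as the conventional benchmark.
* `mixedlm` — random-intercept-per-colony linear mixed model (REML).

Marginal per-day comparisons optionally normalize each ramet by its own
day-0 (or earliest baseline) value before comparing group means with
colony-cluster-robust variance; per-day p-values are reported
unadjusted. Baseline comparisons are two-sample t-tests on ramet-level
pre-stress means. α = 0.05 throughout.

Whether colony or species is the right cluster unit is genuinely
ambiguous in this design; colony is the default, exposed as `cluster=`.

## The synthetic-data generator

The generator defines the study conditions the estimators are validated
against; its defaults are fixed, not tuning knobs.

* **Design**: 10 species × 4 cells (CT-CL, CT-HL, HT-CL, HT-HL;
  26.2/32.3 °C × 83/328 µmol photons m⁻² s⁻¹) × 8 ramets per cell,
  drawn 4 each from 2 parent colonies per species; assessments every
  second day at days −10…−2 (baseline) and 0…10 (stress), window
  [−10, 11]. Ramets are removed by necrosis with probability 1.3 % from
  a uniformly drawn day onward.
* **Species fixture**: μ′_S,m values are synthesized to reproduce the
  documented range (1.53–5.8 mm⁻¹) and group means (2.01 low /
  4.58 high under mean-threshold classification); R_S spans 0.24–0.71.
  Per-species values are a constructed fixture, not measurements.
* **Trajectories**: Fv/Fm and Q_m are piecewise linear — flat baseline,
  linear stress decline at group × treatment rates (combined-stress
  defaults −0.0319/−0.0144 day⁻¹ for Fv/Fm and +0.043/+0.011 day⁻¹ for
  Q_m in the low/high groups; ~0 under full control). Linear-in-time is
  the simplest shape consistent with slope-based estimands. Low-group
  baselines are higher for Fv/Fm and Chl *a* and lower for cell
  density. Φ_NPQ steps from its baseline by a group fold (1.8 low,
  1.2 high) under thermal stress.
* **Pigments and reflectance**: Chl *a* decays exponentially during
  stress at base rates per treatment scaled by (μ′_S,m/μ̄)^(−1) — weakly
  scattering corals bleach faster — times a per-species log-normal
  heterogeneity factor (σ = 0.42). Holobiont reflectance comes through
  the forward optical model with a first-pass link
  I_a1 = 1 − exp(−σ_s·Chl a), σ_s = 0.10·(μ′_S,m/μ̄)^(−1.5) cm² µg⁻¹:
  the exponent encodes the feedback premise that light per pigment
  rises more steeply over weakly scattering skeletons. R_H therefore
  rises toward R_S as pigment is lost.
* **Noise**: additive Gaussian for yields and reflectance (Fv/Fm 0.02,
  Q_m 0.03, Φ_NPQ 0.02, R_H 0.008), log-normal multiplicative for
  densities (σ = 0.08), plus colony-level random intercepts. Values are
  clipped to physical ranges with a clip counter (clipping is rare at
  default settings). The real experiment's variance components are
  unreported; these are plausible placeholders for PAM and fiber-probe
  instrumentation, and are flagged as such.
* **Calibration**: the species-level ΔPE simulator draws
  ΔPE = c₀ + c₁·μ′_S,m + N(0, σ) per basis/conditioning cell. The noise
  σ values (4.815e−3, 3.348e−3, 9.241e−3 day⁻¹) were fixed once by
  root-finding so the *expected* 10-species sample r² equals the
  documented 0.62 (light basis, HT), 0.35 (light basis, CT) and 0.18
  (temperature basis); likewise the pigment-decay heterogeneity σ=0.42
  sets the expected log-log r² of the feedback power law to 0.79. These
  constants make the documented coefficients of determination
  *recoverable targets* for the estimation machinery rather than
  assertions about real corals.
* **Determinism**: a single `numpy` generator seeded from the config;
  identical (config, seed) gives bit-identical tables.

**What passing tests show — and don't.** Recovery tests demonstrate
that the estimators are unbiased and correctly calibrated under the
generator's assumptions (linear trends, exponential decay, Gaussian /
log-normal noise, independence across ramets given colony effects).
Real corals add dynamics the generator omits: photoacclimation
plateaus, day-4-style trajectory inversions, tissue-optical effects
(lateral scattering, host fluorescent pigments, tissue contraction),
non-stationary noise, and α, β, γ drifting with pigment loss. Passing
here validates the machinery, not any claim about field data.

## Numerical choices and degenerate inputs

* Inversion cross-checks: the balance expression for I_a and the
  forward reconstruction of R_H are asserted to 1e−10 inside
  `infer_absorption`.
* Perfect 2-point slopes get se = 0 and an undefined p rather than NaN
  propagation; constant-y power laws return b = 0, r² = 0 with a
  degeneracy flag; single-replicate aggregates define sd = 0 and are
  flagged.
* Ties at the group threshold go high; single-species inputs stay
  unassigned with a warning.
* CSV writers emit 17 significant digits and the reader parses with
  correctly rounded `float()`, making write→read round trips
  bit-exact.

## Problem sizes

The default test and acceptance runs use the full experimental design
(3520 observations per experiment) with 20 replicate experiments for
rate and fold-change recovery, 200 replicate species-level datasets per
ΔPE cell, 100 experiments for the feedback power law, and 1000 null
simulations for the interaction-test size check — enough replication to
estimate each mean to well inside its stated tolerance.
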