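# coraloptics

Analysis toolkit for the **optical feedback** view of coral bleaching:
as heat stress strips *Symbiodinium* cells and their photopigments from
coral tissue, the highly scattering calcium-carbonate skeleton becomes
progressively exposed and reflects ever more light back through the
remaining symbionts — a positive feedback whose pace is governed by the
skeleton's *microscopic reduced scattering coefficient*
μ′<sub>S,m</sub> (mm⁻¹), the light-transport property of the top
~100–200 µm of skeletal material.

The package is written for ecophysiologists analysing repeated-measures
heat/light stress experiments on coral fragments (ramets), and for
anyone who wants a tested reference implementation of the underlying
bio-optical model.

## What it computes

**Skeleton-dependent light absorption.** The holobiont is modelled as a
pigment layer over a diffusely reflecting skeleton. With R′ = R_H/R_S
(holobiont over bare-skeleton reflectance) and transport coefficients
α ≥ 1 (path-elongation amplification), β = R_S/R₁ ≥ 1 (re-entry /
non-flatness) and γ ∈ (0, 1]:

```
R_H  = (R_S/β)(1 − I_a1)(1 − α I_a1)
I_a1 = (1 + α − √((1−α)² + 4αβR′)) / (2α)
I_a2 = (1 − I_a1)(α/β · I_a1 + γ(β−1)/β) R_S ,   I_a = I_a1 + I_a2
```

where I_a1 is the fraction of incident light absorbed on the first pass
and I_a2 the skeleton-dependent fraction absorbed after reflection.
α = β = γ = 1 gives a conservative lower bound on I_a2, the default for
all headline statistics. The feedback statistic
−Δ(I_a2/ρ|HT-HL − I_a2/ρ|HT-CL)/Δρ (excess absorbed light per unit
pigment, per unit pigment lost) follows an inverse power law in
μ′<sub>S,m</sub>.

**Photophysiology.** PAM-fluorometry metrics: dark-adapted yield
Fv/Fm = (Fm − F0)/Fm, the steady-state partition
Φ_PSII + Φ_NPQ + Φ_NO = 1 from induction curves, and maximum excitation
pressure Q_m = 1 − Φ_PSII(peak)/(Fv/Fm at dawn).

**Bleaching statistics.** Temporal rates PE = Δ(Fv/Fm)/Δt per ramet;
first-order Taylor-expansion differencing ΔPE across the light factor at
fixed temperature (or vice versa), which cancels every ramet-specific
additive confounder exactly; clustered longitudinal group × day models
with colony-level clustering; marginal per-day and baseline group
comparisons; species classified low/high by the across-species mean of
μ′<sub>S,m</sub>.

**Synthetic experiments.** A seeded generator emulating the full
10-species × 4-treatment (26.2/32.3 °C × 83/328 µmol photons m⁻² s⁻¹)
× 8-ramet repeated-measures design, with holobiont reflectance produced
through the forward optical model so the analysis-side inversion is
exercised against known ground truth.

## Worked example

```python
import coraloptics as co

cfg = co.default_config(seed=1)
table = co.generate_experiment(cfg)
gm = co.group_map(cfg.species_profiles)

m = co.clustered_rate_model(table, "fvfm", gm)   # HT-HL, stress window
print({g: round(s, 4) for g, s in m.slopes.items()},
      "interaction p =", f"{m.interaction_p:.2e}")

res = co.infer_absorption(r_h=0.26, r_s=0.71)    # lower-bound parameters
print(f"I_a1={res.i_a1:.3f}  I_a2={res.i_a2:.3f}  I_a={res.i_a:.3f}")

fa = co.feedback_power_law_analysis(table, cfg.species_profiles)
print(f"feedback power law: a={fa.fit.a:.5f}, b={fa.fit.b:.2f}, r2={fa.fit.r2:.2f}")
```

prints

```
{'low': -0.0318, 'high': -0.0145} interaction p = 2.02e-12
I_a1=0.395  I_a2=0.170  I_a=0.565
feedback power law: a=0.00600, b=1.20, r2=0.90
```

The first line says symbionts in weakly scattering (low-μ′<sub>S,m</sub>)
corals lost photochemical efficiency at −0.032 day⁻¹ under combined heat
and light stress, more than twice the high-group rate, with a strongly
significant group × day interaction. The second line inverts a
holobiont/skeleton reflectance pair into absorbed-light fractions. The
third recovers the inverse-power-law dependence of the optical feedback
rate on μ′<sub>S,m</sub> from a full simulated experiment.

A command-line pipeline wraps the same stages
(`coraloptics --seed 1 --outdir run all` runs
simulate → absorb → rates → depe → stats → report and writes delimited
result tables, figures, and a reproducibility manifest).

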