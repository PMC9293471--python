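# Methods

This note documents the models implemented in `mesocond`, the parameter
choices where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and known limitations.

## Measurement model and estimation chain

The package treats a leaf as two serial CO₂ supply steps feeding the FvCB
biochemical demand:

```
Ci = Ca − An/gsc          gsc = gsw/1.6
Cc = Ci − An/gm
An = min(Ac, Aj) − Rd
Ac = Vcmax (Cc − Γ*) / (Cc + Kc(1 + O/Ko))
Aj = J (Cc − Γ*) / (4Cc + 8Γ*)
```

All mole fractions are µmol mol⁻¹ (O in mmol mol⁻¹), fluxes µmol m⁻² s⁻¹,
conductances mol m⁻² s⁻¹. Kinetic constants default to the Bernacchi
parameterization (Kc25 = 404.9 µmol mol⁻¹, Ko25 = 278.4 mmol mol⁻¹,
Γ*25 = 42.75 µmol mol⁻¹, activation energies 79 430 / 36 380 / 37 830 J mol⁻¹,
and 65 330 / 43 540 J mol⁻¹ for Vcmax / Jmax normalization); all are
overridable through `KineticConstants`. Temperature scaling is simple
Arrhenius (`normalize_25` / `denormalize_25` are exact inverses); a peaked
form was considered and not implemented because none of the supported
analyses requires temperatures beyond the 20–40 °C range where the simple
form is adequate.

### Fluorescence calibration

Under non-photorespiratory conditions (1 % O₂) CO₂ fixation is the only
electron sink, so Φ_PSII and Φ_CO₂ = (An + Rd)/PPFD are linearly related.
The calibration regresses Φ_PSII (y) on Φ_CO₂ (x) by OLS, restricted to the
linear region Φ_CO₂ < 0.05 and Φ_PSII < 0.5, and the slope k and intercept b
define Jcal = 4(Φ_PSII − b)/k · PPFD, with the implied absorbance × PSII
partitioning product α·β = 4/k. OLS rather than orthogonal regression is
used because the calibrated J formula inverts exactly that regression
direction. The Rd inside Φ_CO₂ defaults to the Laisk estimate (configurable):
a separate 1 %-O₂ Rd would differ only marginally and would add a protocol.

### Laisk step

Low-Ci A–Ci responses at 100/200/400 µmol m⁻² s⁻¹ PPFD are fitted linearly
inside the window Ci ≤ 150 µmol mol⁻¹ (configurable; the protocol steps at
50–150 µmol mol⁻¹ sit inside it). The three pairwise line intersections are
averaged; the mean x is Ci\*, the negated mean y is Rd (stored positive).
Γ\* is resolved from Ci\* under three conventions:

* `ci_star_as_gamma_star` (default): Γ\* = Ci\*, the common shortcut when no
  gm estimate exists yet;
* `bernacchi_constant`: the temperature function value, ignoring the
  intersection;
* `iterative`: the completed conversion Γ\* = Ci\* + Rd/gm by damped fixed
  point (damping 0.5, tolerance 0.01 µmol mol⁻¹, ≤ 50 iterations), where gm
  may itself be re-estimated per trial Γ\* (`estimate_gm_chain`).

The shortcut biases Γ\* low by Rd/gm (≈ 3 µmol mol⁻¹ at Rd = 1, gm = 0.3),
which propagates multiplicatively through Cc and typically inflates to a
~20 % underestimate of gm. Parameter-recovery runs therefore use the
iterative mode; the shortcut remains available for strict protocol
replication.

**Noise sensitivity.** The intersection coordinates are ratios of small
slope differences. At instrument noise σ_A = 0.3 µmol m⁻² s⁻¹ with
low-light slopes of 0.02–0.06, the per-protocol Ci\* has a median error of
~6–7 µmol mol⁻¹ even under a joint least-squares refit — enough to corrupt
downstream gm by ~30 %. This is an intrinsic property of the method, not of
the implementation. Consequently Rd, Ci\*, k and b are treated as
genotype-level constants estimated once from dedicated protocol curves
(long steady-state averages, simulated noise-free by default in the study
generator), exactly as such studies run them; they are not re-estimated per
response curve.

### Variable-J gm

The instrument Ci is first corrected for cuticular water loss: the total
water conductance El/(Wi − Wa) includes a cuticular component that carries
no CO₂, so the stomatal-only conductance is g′ = El/(Wi − Wa) − 2·Ec with
Ec = 0.005 mol m⁻² s⁻¹ per surface, and Ci = Ca − 1.6·An/g′. Ec enters as a
per-surface conductance-equivalent (so 2·Ec·(Wi − Wa) is the two-surface
cuticular water flux); this is the dimensionally consistent reading of the
correction and can be disabled (`mode="off"`).

Cc then follows from the Harley inversion and gm from Fick's law. The
method is singular as J → 4(An + Rd); estimates are flagged unreliable
outside the classic sensitivity window 10 ≤ dCc/dAn ≤ 50 or when
J − 4(An + Rd) ≤ 0.05·J (both configurable). Unreliable, negative or
infinite estimates are retained with flags, never silently dropped.

Curve-level gm (feeding the A–Ci → A–Cc conversion) is the mean of reliable
estimates at the Ca ≈ 400 µmol mol⁻¹ reference steps — the protocol visits
that step twice, and both visits are used. For noisy-replicate scoring the
robust summary `robust_curve_gm` (median over all reliable steps) damps the
heavy-tailed noise amplification near the singularity; the two definitions
agree exactly on noise-free data.

### FvCB fitting

A–Cc curves are fitted by Levenberg–Marquardt least squares (lmfit) for
Vcmax and J, with Rd fixed to the Laisk estimate by default. The limitation
transition is the analytic crossover Cc = (J·Km − 8Γ*Vcmax)/(4Vcmax − J);
curves with no points on one side of it flag the corresponding parameter as
weakly identified instead of failing. The fitted J is the electron transport
at the measurement irradiance; at saturating light it approximates Jmax, and
the 25 °C-normalized values use the Arrhenius factors above. No TPU
limitation term is included.

## One-dimensional anatomical gm model

Gas phase: g_ias = Da·f_ias/(ΔL_ias·τ) with Da = 1.51 × 10⁻⁴ m² s⁻¹,
tortuosity τ = 1.57 (dimensionless — a path-length ratio), and ΔL_ias half
the leaf thickness (the available proxy for mesophyll thickness in the trait
table). Liquid components per unit exposed surface: g_i = Dw·rf_i·p_i/ΔL_i
with Dw = 1.79 × 10⁻⁹ m² s⁻¹; porosity 0.3 for the cell wall, 1.0 for
cytosol and stroma; diffusivity-reduction factor 1.0 for the wall and 0.3
for cytosol and stroma; membrane permeabilities g_pl = g_env = 0.0035 m s⁻¹.
Path lengths: ΔL_cw = T_cw, ΔL_cyt = T_cyt, ΔL_st = T_chl/2 (CO₂ is consumed
throughout the stroma, so the effective path is half the chloroplast
thickness).

Per leaf area, wall and plasma-membrane resistances are divided by the
mesophyll surface S_m and the intracellular components (cytosol, envelope,
stroma) by the chloroplast surface S_c; their sum inverts to g_liq, and

```
gm = 1 / (1/g_ias + (R·Tk/H) / g_liq)
```

with H = 2941 Pa m³ mol⁻¹ (CO₂ at 25 °C) supplying the dimensionless
gas/liquid partition factor R·Tk/H ≈ 0.84, and the molar density of air
(P/R·Tk ≈ 40.9 mol m⁻³) converting m s⁻¹ to mol m⁻² s⁻¹. Genotype contrasts
report per-surface reductions for individual components (independent of
S_m/S_c) and the per-leaf-area reduction for the liquid-phase total; both
views are emitted because the two scalings answer different questions
(membrane/wall property vs whole-leaf supply).

f_ias is not part of the bundled trait table; it defaults to 0.3, a typical
rice mesophyll value. It affects only the gas phase, which carries < 2 % of
the total resistance here, so the default is immaterial to the liquid-phase
contrasts.

## Drought pipeline

RSWC (%) = 100·(PW − DW)/(t₀W − DW) from daily pot weights. Stages:
well-watered (RSWC > 50), moderate (35 < RSWC ≤ 50), severe (RSWC ≤ 35);
boundary values fall to the drier stage (the stated strict inequalities
leave the boundaries undefined; the drier assignment is conservative toward
stress classification). Each record is one observation; contrasts are Welch
two-sample t-tests (robust to unequal variances; a pooled option exists),
with no cross-variable multiplicity adjustment. Degenerate identical groups
report p = 1 by convention.

## Synthetic-data generator

`simulate_point` solves the coupled supply/demand system by Brent
root-finding (residual < 10⁻¹⁰) and sets the fluorescence-visible electron
transport from the electron budget J = (An + Rd)(4Cc + 8Γ\*)/(Cc − Γ\*), so
the variable-J inversion is exact on noise-free data. Light response of
potential J is a non-rectangular hyperbola (θ = 0.7, initial slope α·β).
Default truth: gm = 0.30, gsw = 0.30 mol m⁻² s⁻¹, Vcmax = 100, Jmax = 180,
Rd = 1 µmol m⁻² s⁻¹, Γ\* = 42.75 µmol mol⁻¹, α·β = 0.45 — a healthy
well-watered rice leaf. Instrument noise is Gaussian: σ_A = 0.3 µmol m⁻² s⁻¹
on An and σ_Φ = 0.005 on Φ_PSII at snapshot logging; the instrument-reported
Ci is recomputed from the noisy fluxes as a real analyzer would.

Three deliberate idealizations define what recovery tests do and do not
show:

* **Non-photorespiratory conditions are ideal.** At O₂ ≤ 2 % the simulator
  sets Γ\* = 0 and J = 4(An + Rd) — the exact linearity the calibration
  assumes. Real 1 %-O₂ leaves retain ~5 % residual oxygenation, so real
  calibrations carry a small bias the tests cannot see.
* **Low-Ci protocols are exactly linear.** Laisk fixtures are straight-line
  pencils through (Ci\*, −Rd) with slopes proportional to the light-limited
  J (0.5 × 10⁻³ per unit J, giving slopes 0.02–0.06 at 100–400 PPFD). A full
  FvCB forward solve is measurably convex over any practical low-Ci window
  and shifts the fitted-line intersection by several µmol mol⁻¹; real Laisk
  estimates inherit exactly that curvature bias, which recovery tests on
  the linear pencils do not probe.
* **Transpiration closes the cuticular loop.** Wi − Wa is fixed at
  0.02 mol mol⁻¹ and El = (gsw + 2Ec)(Wi − Wa), so the Boyer correction is
  an exact inverse of the simulated stomatal drawdown.

The study generator (`simulate_study`) adds exponential soil drying
(e-folding 8 days), stomatal closure roughly linear below RSWC = 60 % with a
5 % floor, and a gentler square-root decline of gm below RSWC = 50 % — the
qualitative drought phenomenology (genotype-constant gm ratio maintained
through drying). It does not simulate leaf energy balance, ABA signaling,
temperature drift, or anatomical change during drought. Dedicated protocol
curves (calibration, Laisk) are generated noise-free by default
(`protocol_noise_free`), reflecting their long steady-state averaging;
setting it false demonstrates how snapshot noise on the Laisk protocol
corrupts genotype-level constants (see the noise-sensitivity paragraph
above).

## Numerical choices

* Root brackets for the forward solve: An ∈ [−Rd − 2, min(Vcmax, J/4)];
  the demand clamps Cc at 10⁻⁹ to stay defined at extreme brackets.
* Γ\* fixed point: damping 0.5, tolerance 0.01 µmol mol⁻¹, max 50
  iterations; non-convergence raises with the last iterate.
* Parallel Laisk lines (slope difference < 10⁻¹²) raise a degenerate-
  geometry error naming the pair; window fits require ≥ 3 points.
* FvCB fit starts at Vcmax = 80, J = 136 with positivity bounds; the hard
  `min(Ac, Aj)` is used (no smoothing), matching the analytic transition.
* Ties at stage boundaries go to the drier stage (see above).

## Problem sizes

Validation suites use the sizes the analyses themselves use: 12-step CO₂
response curves (the instrument sequence 400…50, 400…1600), 6-point low-Ci
curves at three irradiances, 500-replicate Monte-Carlo runs for noisy
recovery, 1000 random anatomies for the resistor-chain equivalence check,
and a 2-genotype × 5-plant × 21-day synthetic study.

## Known limitations

* The variable-J method degrades sharply outside its sensitivity window;
  points at very low and very high Ci are structurally unreliable and are
  reported flagged rather than used.
* The Laisk intersection is noise-amplifying (ratio of small slope
  differences); treat per-protocol Ci\*/Rd as uncertain at ±5 µmol mol⁻¹ /
  ±0.3 µmol m⁻² s⁻¹ under snapshot noise unless protocols are averaged.
* The anatomical model is one-dimensional: no lateral heterogeneity,
  chloroplast gaps, or dynamic chloroplast repositioning; membrane
  permeabilities are literature constants, not measurements.
* gm is assumed constant along a response curve when converting A–Ci to
  A–Cc (the default curve-level gm); a per-point conversion is available
  where that assumption is too strong.
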