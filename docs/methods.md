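# Methods

## Scope and model structure

`mapbpk` couples an intradermal microarray-patch (MAP) depot model to a
whole-body, blood-flow-limited PBPK model for long-acting cabotegravir in
rats and humans, plus the surrounding workflow: virtual-cohort generation,
empirical-model parameter estimation, ratio/AAFE verification, and
once-weekly dose-ladder prediction against protein-adjusted IC90 (PA-IC90)
efficacy thresholds.

States (amounts, µg): per skin layer the nanoparticle (ND), released (RD)
and penetrating (PD) pools; an IM depot; eleven systemic organs plus a
lumped "rest" tissue; arterial and venous blood; cumulative elimination.
Canonical internal units are µg, mL and h; files state units explicitly
because the source tables mix µg·day/mL and µg·h/mL.

Key assumptions, inherited from the model family this implements:

* only drug released from the nanoparticle formulation can enter skin, and
  trans-layer transport is unidirectional SC → VE → DE;
* no hair-follicle or lymphatic pathways;
* the dermis exchanges with blood by perfusion; all skin coefficients
  (K_NP, K_SKIN, PC, TP_SKIN) are constant;
* organs are well-stirred and blood-flow-limited; plasma concentration is
  venous blood concentration divided by the blood:plasma ratio R.

## Parameters that matter

| parameter | unit | default | note |
|---|---|---|---|
| K_NP (rat IM / rat MAP / human IM) | h⁻¹ | 3e-3 / 3.43e-3 / 4.54e-4 | nanoparticle release; human MAP reuses the rat MAP value |
| K_SKIN | cm³/h | 1.73e-3 | trans-skin volumetric rate, rat-derived, reused in humans |
| CL/F (rat IM / rat MAP / human IM / human MAP) | L/h | 0.6 / 0.01 / 0.197 / 0.985 | human MAP = 0.197 / 0.20 (20 % MAP bioavailability); F is inside CL/F, never applied again |
| Vd correction (rat IM / rat MAP / human) | – | 5 / 0.05 / 0.01 | multiplies every tissue:plasma coefficient |
| R | – | 0.5 | blood:plasma ratio; clearance acts on venous *blood* concentration |
| PC_SC/W, PC_VE/W, PC_DE/W | cm/h | 0.304 / 0.106 / 0.106 | needle-to-skin permeability |
| PC_SC/VE, PC_VE/DE | – | 3.993 / 1 | inter-layer partition scaling of K_SKIN |
| dose loading / insertion | mg/cm², – | 5.86 / 0.97 | patch design; geometry as in the README |
| Q_DE | mL/h/cm² | 1.0 | see below |
| thresholds | µg/mL | 0.664 / 1.33 | 4× and 8× PA-IC90 |

**Clearance placement.** CL/F is applied to the venous blood concentration
with plasma = blood/R.  This is the only placement whose scale is
consistent with the published human IM exposure (AUC₀₋∞,plasma =
dose/(CL·R); with CL/F = 0.197 L/h and K_NP = 4.54e-4 h⁻¹ it reproduces
the predicted AUC₀₋w12 ≈ 4.8 × 10³ µg·h/mL and Cmax ≈ 3.4 µg/mL).

**Dermal blood flow Q_DE** is an explicit exception to the cardiac-output
fractions and its source value is not available; it is shipped as a
configurable per-area perfusion (default 1.0 mL/h/cm² of patch-covered
skin, a resting dermal perfusion scale) and flagged in every report.
Sensitivity is low: with the corrected tissue:plasma coefficient the
dermis washout rate Q_DE·R/(V_DE·TP_SKIN) is fast (≫ 1 h⁻¹) for any
plausible perfusion, so release — not dermal washout — controls the
plasma profile.

**Dermis equation reading.** As printed, the dermis exchange term drives
washout with the *venous* amount and a stray 1/1000 factor, and provides no
dermis → blood source anywhere; taken literally the skin never drains (the
`literal_eq9` switch demonstrates this).  The implemented form drains the
dermis itself, +Q_DE·C_art − Q_DE·(PD_DE/V_DE)·(R/TP_SKIN) with V_DE in
mL, which conserves mass and is the standard well-stirred venous
equilibrium.

**Vd correction** multiplies all tissue:plasma coefficients (equivalently
the tissue part of Vss).  The source states only that a correction was
applied to the volume-of-distribution equations; the multiplicative
reading is the simplest that reproduces the stated factors.

## Physiology and partitioning

Reference physiology ships as editable YAML (`data/physiology.yaml`):
organ masses as fractions of body weight with densities (a "rest" tissue
closes the mass balance exactly), blood flows as fractions of an
allometric cardiac output (13.2 L/h/kg^0.75), sex-specific adult height
(normal) and BMI (log-normal) distributions truncated at ±3 SD, and
fractional tissue compositions.  These constants are standard reference
compilations re-stated as config, not outputs of this package; the exact
regression sets used upstream are not printed anywhere, so any compatible
set is admissible and everything is overridable.

Rat cohorts draw weight from a truncated normal (±3 SD, resampled) and
scale the reference rat's organ volumes and flows linearly with weight —
the simplest defensible allometry at this scale.  Human cohorts allocate
sex deterministically (round(n·f) females), ages uniform on 18–60.

Tissue:plasma coefficients use the tissue-composition method: non-adipose
tissues use the octanol:water partition coefficient with the
unbound-fraction ratio fu_p/fu_t (fu_t from the standard half-binding
assumption); adipose uses the zwitterion-adjusted vegetable-oil:buffer
coefficient D*vo:w = 10^(1.115·logD* − 1.35), with logD* correcting logP
for ionisation at both centres at pH 7.4 (negligible for cabotegravir,
pKa 10.04 / −0.7).  Vss = plasma volume + Σ V_t·tp_t with the route
correction applied to the tissue term.

## Geometry

Needle volumes and lateral areas follow from similarity: a right
rectangular pyramid truncated at distance s from the tip has
V(s) = w·l·s³/(3h²) and lateral area scaling as (s/h)².  Layer
partitioning slices the inserted frustum (tip at 0.97·h below the surface;
the non-inserted 3 % of tip and the cuboidal base stay outside) at the
layer boundaries; dose fractions are normalised over the *inserted* volume
(delivered dose = nominal dose; losses are absorbed by the fitted CL/F and
the 20 % bioavailability, avoiding double counting).  Closed forms are
verified in tests against 0.5–1 µm brute-force slab integration to 0.1 %.

## Numerics

Between dose events the full system is linear and time-invariant, so the
default solver advances the state with one matrix exponential per grid
step (default grid 0.5 h): exact at machine precision, unconditionally
stable for this dissipative system, and mass-conserving to ~1e-9 relative
— tighter than the 1e-6 acceptance bound.  Dose events add amounts to the
depot states (MAP residue from earlier patches is retained).  An adaptive
stiff integrator (BDF, rtol 1e-8, atol 1e-9 µg) is retained behind
`solver="ivp"` and cross-checked against the propagator in tests; it
exists because the matrix-exponential route assumes linearity, which any
future nonlinear extension would break.  Arbitrary-time output (used by
curve fitting) bridges each gap with one exponential.

Dose ladders share the largest dose's patch-skin interface (one set of
transport rate constants), treating K_SKIN and the compartment volumes as
formulation/skin properties rather than per-patch quantities.  This makes
predictions exactly dose-proportional — consistent with the published
ladder, whose trough ratios are exact 4:2:1 multiples — while each dose's
nominal patch area (dose ÷ 5.86 mg/cm²) is still reported.

## Estimation

Empirical fits use multi-start (default 10, seeded) trust-region least
squares in log-parameter space; the objective is untransformed
concentration by default (mirroring common nonlinear-regression practice),
with a log-concentration option that is the appropriate weighting for
proportional error and is used in the noisy recovery tests.  Bounds
default to ka ∈ [1e-5, 1] h⁻¹ and wide positive boxes elsewhere.
First-order-depot models are identifiable only up to an exchange of the
exponential rates; fits are canonicalised to the flip-flop representative
(ka = slowest rate), the physically meaningful branch for long-acting
depots.  The two-compartment inter-compartmental clearance Q maps
one-to-one onto K_SKIN (cm³/h) — an interpretation, since the formal
correspondence is not printed.  The PBPK curve-fit estimator wraps the
full simulator and may free CL/F, K_NP, K_SKIN and the Vd correction.

## Synthetic data

Real concentration–time curves exist upstream only as digitised figures,
so the package ships no eyeballed curves — only the printed summary-metric
tables (`load_fixture`).  Profile-level testing uses synthetic studies:
two-compartment truth at the rat-estimated K_NP = 3.43e-3 h⁻¹, CL/V
placing the curves on the observed µg/mL scale, and Q/V2 chosen so all
three exponential rates are well separated (a prerequisite for the
global-identifiability round-trip tests; a near-degenerate pair would make
separate recovery of ka and the slow disposition rate ill-posed at any
design).  Noise is proportional (CV 0.15) + additive (0.01 µg/mL),
truncated at zero, with optional LLOQ flagging — an assumed assay model,
documented as such.  Sampling schedules (11 points over 28 days
single-dose; weekly troughs, 24 h post dose 4 and day 42 for the
multi-dose study) are design assumptions since exact times are not
printed.  Passing recovery tests therefore shows the estimation machinery
is correct under the assumed error model, not that the in vivo studies
were this well behaved: real data add inter-animal kinetics variability,
model misspecification and correlated errors that the generator does not
emulate.

## Problem sizes

Simulations in tests and the acceptance script use the study-defined
sizes: 100-subject cohorts, 6-month horizons (26 weekly doses) on a 0.5 h
grid.  The exact propagator makes these cheap (a full 100-subject ladder
runs in seconds), so no scaling down was needed.

## Known limitations

* Rat absolute exposure predictions are not reproducible from the printed
  parameter set (e.g. the published rat MAP AUC is orders of magnitude
  away from dose/(CL/F) with CL/F_MAP,rat = 0.01 L/h); the rat arm is
  therefore verified by structural properties (mass balance, linearity,
  analytic limits), not value matching.
* Anthropometric and organ-reference constants are representative
  defaults, not the uncited originals; human cohort dispersion (not the
  mean) depends on them.
* No hair follicles, lymphatics, nonlinear binding, sex-specific skin
  thickness, paediatric/pregnancy physiology, or inter-occasion
  variability.
* Time-to-target is evaluated on the cohort-mean curve at daily
  resolution; "minimum concentration at steady state" is the trough of
  the final dosing interval of the mean curve (per-subject distributions
  are available in `CohortResult`).
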