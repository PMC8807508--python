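# Methods

This note records the model, its assumptions, the parameter choices that
matter, and what the test suite does and does not establish.

## Body model

The reference adult is the standard 18-compartment small-molecule layout:
fourteen perfused organs (lung, brain, heart, kidney, liver, gut wall,
stomach, spleen, pancreas, muscle, adipose, skin, bone, gonads), portal
vein, arterial and venous blood, and a gut lumen handled by the absorption
sub-model. Splanchnic organs drain through the portal vein into the
liver; the lung sits in series with the venous return. Organ volumes and
flow fractions are ICRP-style reference values stored in versioned
key–value constants files (`src/gestpbpk/data/reference_physiology_*.yaml`)
that can be overridden by path; the test suite pins them. Blood-to-plasma
ratio defaults to 1, so venous blood concentration is reported as plasma
concentration; this is configurable on the compound but untested territory
away from 1.

Pregnancy adds placenta, uterus and mammary glands as perfused
compartments growing from zero, plus a lumped fetal mass and amniotic
fluid as inert volumes: no maternal–fetal drug transfer is modelled, so
fetal exposure is out of scope by construction. Gestational trajectories
(body weight, cardiac output +45% by FW 34, GFR +50% with a plateau near
FW 36, kidney volume +18%, blood volume +35%, haemodilution, ~12 kg term
weight gain) are smooth documented functions of fertilization week chosen
to match the pregnancy-physiology literature in magnitude; their exact
shape only weakly affects the ratio-type endpoints this package reports.
The cardiac-output increment is allocated 60% to the utero-placental
unit, 15% to the kidneys, and the rest to mammary glands, skin and
adipose, while the **absolute liver perfusion is held at its non-pregnant
value** — the conservative assumption for hepatically cleared drugs given
conflicting reports on hepatic flow in pregnancy.

## Partitioning

Tissue-to-plasma partition coefficients use a Schmitt-type composition
scheme. Referenced to the neutral unbound species, the tissue affinity is

    K_tissue = α(pH_t)·f_water + (P + c·P_ion)·f_nl
             + (P + c·P_ion·F_elec)·f_pl + K_prot·f_protein

with α the total/neutral ratio of the monoprotic base (pKa 7.24), c the
cation/neutral ratio, `P = 10^logP`, `P_ion = P·10^-3.5`, and an
electrostatic factor F_elec = 20 for cation–phospholipid binding. The
plasma affinity is fixed by the measured f_u (`α(7.4)/f_u`), and the
protein affinity K_prot is back-calculated from it, so a tissue with
plasma's composition has Kp = 1 exactly. In pregnancy the plasma side
uses the gestational f_u while K_prot — an albumin affinity — is scaled by
the albumin ratio `P(FW)/P(0)`, since the tissue albumin-like pool
(interstitial albumin) follows the plasma decline. This keeps the
gestational rise of the distribution volume close to the rise of
clearance, leaving the terminal half-life nearly unchanged, which is the
behaviour expected for a binding-driven change. With the packaged
composition table the baseline model has Vss ≈ 574 L and Kp(liver) ≈ 4,
Kp(adipose) ≈ 24.

## Clearance: middle-out anchoring

The five whole-body intrinsic clearances (Table of compound inputs;
Σ = 53.74 L/h) were originally fitted inside a platform whose enzymes
carry individual expression scalings, so the raw values alone cannot
reproduce the in-vivo dose fractions (they are not proportional:
CLint 26.67 vs 20.06 L/h for CYP1A2 vs UGT1A4, but f_m 0.50 vs 0.23).
The engine therefore applies a dimensionless activity scaling A_E per
enzyme, solved once in closed form at the non-pregnant reference so that
the plasma-referenced hepatic clearance of each enzyme stands in the
published proportion to the renal clearance, `CL_E/CL_R = f_m,E/f_R`
(f_m = 0.50/0.23/0.067/0.067/0.067, f_R = 0.07). The A_E are fixed
thereafter: pregnancy and inter-individual variability act only through
CLint(FW) and f_u(FW). This mirrors the middle-out strategy by which the
clearances were derived (mass balance plus a CYP1A2-inhibition DDI study
inverted through the Rowland–Matin relation) and makes the simulated
baseline breakdown reproduce the in-vivo fractions by construction —
asserted, not assumed, in the tests.

Renal elimination is passive: filtration of unbound drug
(`GFR_fraction·GFR·f_u`) plus tubular secretion normalized to kidney
volume and acting on unbound drug (`CL_TSspec·V_kidney·60·f_u`). Treating
secretion as clearing total rather than unbound plasma would make renal
clearance ~7× the value consistent with f_R = 0.07 and the published
apparent clearance, so the unbound convention is used throughout.

## Absorption

A single lumped lumen: first-order dissolution (ln2 / 10 min), first-order
transcellular uptake with rate `P_trans·A_eff/V_lumen`, and a competing
first-order transit to feces. Two constants are free because the source
platform's absorption settings are unpublished: the effective absorptive
surface (25 m²) and the absorbable-gut residence time (20 h, small
intestine plus absorptive colon). They were set middle-out so that the
published transcellular permeability (3.85·10⁻⁶ cm/min) yields a fraction
absorbed ≈ 0.8 — consistent with olanzapine's known good but incomplete
oral absorption — and the published baseline apparent-clearance scale;
they are frozen in the constants files. Predicted tmax (~3 h) is earlier
than observed (~5–6 h); peak-time predictions are the weakest part of
this absorption model, as they are for the validation set generally
(tmax GMFE 1.44). Solubility (145.4 µg/mL) is checked at dose time and
non-limiting at 10 mg in 250 mL.

## Numerics

The ODE system is linear and time-invariant between dosing events, so the
default integrator propagates `expm(M·Δt)` on the fixed 0.1 h output
grid — exact for the model, bit-reproducible, and mass-conserving to
~1e-12 of the dose (the acceptance bar is 1e-6). An adaptive stiff BDF
route with user tolerances is retained and cross-checked against the
exponential route in the tests (AUC agreement < 0.1%). Steady state is
declared when the plasma AUC over successive 24 h intervals changes by
< 0.5% (cap 40 doses, error on failure); a 240 h drug-free washout is
appended for terminal-slope estimation. NCA uses the linear-up/log-down
trapezoid; the terminal slope is a log-linear regression on the last
three points, extended backwards while r² improves. Single-dose AUC is
extrapolated to infinity with C_last/λz.

Representative problem sizes: a 240 h single-dose run is ~2,400 grid
steps of a ~30-state system (≈30 ms); the full trimester steady-state
comparison runs in well under a second, which is why the package can
afford paired n = 200 population checks inside the test suite.

## Populations

The population-variability settings of the source platform are
unpublished; defaults here are log-normal multipliers with CV 0.35 on
each hepatic CLint, 0.25 on tubular secretion, and 0.15 on body weight
(volumes scale linearly, flows and GFR with exponent 0.75), FW uniform in
the trimester range, all under a mandatory seed. The FW quantile is drawn
even for non-pregnant populations so that two populations generated from
the same seed are paired draw-by-draw; trimester-vs-baseline population
contrasts therefore cancel most sampling noise. Band widths are
package-specific and not comparable to the source figures in detail.

## Synthetic data

The generators emulate the *structure* of the external inputs, not their
values: observed mean±SD profiles are the simulated truth with mean-one
multiplicative log-normal noise per subject; gestational
clearance-change points are the published cubic evaluated at chosen
weeks with Gaussian noise scaled by 1/√(study size) and study-size
weights (7/11/53). Passing tests show the estimators (weighted cubic
refit, profile summaries) are unbiased and seed-stable under these
conditions — they cannot show anything about digitization error or
between-study heterogeneity in the real validation data. The ten-study
predicted/observed PK table is shipped verbatim as a packaged CSV.

## Design choices on genuinely open points

* The albumin association constant K_A is calibrated at FW 0 against the
  FW-0 albumin of the gestational trajectory (46.4 g/L); calibrating at
  the asymptotic 31.7 g/L instead does not reproduce the published
  trimester f_u row (0.075/0.085/0.091), which this calibration hits to
  three decimals.
* The CYP3A4 activity cubic is applied raw (1.00736 at FW 0), matching
  the published pregnant clearance values; the ~0.7% offset at baseline
  is kept rather than renormalized.
* The FMO3 step ("late pregnancy") is placed at FW 27, the start of the
  third trimester; the canonical trimester table implies a +75.6% step
  while the underlying probe study reports +58% — both are available
  (`fmo3_activity(..., mode="literature")`), the canonical value is the
  default.
* The canonical trimester parameter table is used verbatim at FW 6/20/34;
  the equation-generated mode covers arbitrary FW, is continuous
  (except the documented FMO3 step), and deviates a few percent for
  CYP1A2 where the published table does not exactly match its own
  quadratic.
* The fluvoxamine interaction is represented by static competitive
  inhibition (`CLint → CLint/(1+I_u/K_i)`) rather than a mechanistic
  co-simulation; with near-complete CYP1A2 inhibition the exposure ratio
  approaches 1/(1−f_m,CYP1A2) ≈ 2, bracketing the reported interaction.

## Known limitations

* Fetal and placental drug transfer is not modelled; the fetal
  compartment is an inert volume.
* Terminal half-life runs long (~45 h vs ~33 h reported) because the
  distribution model's deep adipose pool dominates the terminal phase;
  ratio-type endpoints (trimester changes) are insensitive to this, and
  absolute trough concentrations land within ~10% of the reported values
  regardless.
* A permeation-limited distribution mode (charge-dependent cellular
  permeabilities) is not implemented; distribution is perfusion-limited.
* Enzyme genotype, smoking, and pediatric ontogeny are out of scope.
* The goodness-of-fit machinery operates on any predicted/observed pairs,
  but the packaged validation fixture contains study-level PK parameters,
  not the full digitized concentration grids of the original validation
  set.
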