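# gestpbpk

Whole-body physiologically based pharmacokinetic (PBPK) simulation of the
antipsychotic **olanzapine** in non-pregnant adults and across pregnancy.

Olanzapine is prescribed to pregnant women with schizophrenia, and its
recommended therapeutic-drug-monitoring range (20–80 ng/mL) makes the
question of gestational dose adjustment clinically concrete. Pregnancy
lowers plasma albumin (raising the unbound fraction f_u), sharply reduces
CYP1A2 activity, and induces UGT1A4, CYP3A4 and FMO3 — opposing effects
whose net impact on maternal exposure is not obvious. This package builds
the whole question into a tested, reusable simulation: an 18-compartment
perfusion-limited PBPK model of the reference adult, a gestational
physiology transformation (fertilization week FW as the driving variable),
and the evaluation machinery (non-compartmental analysis, fold-error
statistics, local sensitivity analysis, virtual populations) needed to
validate it. Its headline prediction: under 10 mg once daily, maternal
steady-state exposure changes by **less than ~28%** at any stage of
pregnancy.

## Model

* **Distribution** — perfusion-limited organ exchange
  `dA_i/dt = Q_i (C_art − A_i/(V_i·Kp_i))` with tissue-to-plasma partition
  coefficients Kp from a Schmitt-type composition scheme (water with
  pH-dependent ion accumulation of the monoprotic base, neutral lipid,
  phospholipid with electrostatic cation binding, and protein whose
  affinity is back-calculated from the measured plasma f_u).
* **Absorption** — first-order dissolution (t50 = 10 min) in a lumped gut
  lumen, transcellular uptake (permeability × effective surface area)
  competing with first-order lumen transit to feces.
* **Elimination** — first-order metabolism `v = CLint,E · S` per enzyme
  (CYP1A2, CYP3A4, CYP2C8, FMO3, UGT1A4) acting on the unbound hepatic
  concentration, with per-enzyme activity scalings calibrated middle-out
  so the simulated baseline dose fractions match the in-vivo anchors
  (f_m,CYP1A2 = 0.50, f_m,UGT1A4 = 0.23, f_R = 0.07); renal elimination as
  passive filtration (GFR · f_u) plus kidney-volume-normalized tubular
  secretion of unbound drug.
* **Pregnancy** — albumin `P(FW) = 14.7·exp(−0.0454·FW) + 31.7` g/L drives
  f_u through a 1:1 association model
  `f_u = 1/(1 + K_A·P/MW_alb)`; enzyme activities follow published
  probe-substrate trajectories (caffeine quadratic for CYP1A2, lamotrigine
  cubic for UGT1A4, midazolam cubic for CYP3A4, a late-pregnancy FMO3
  step); organ volumes, cardiac output, GFR and gestational compartments
  follow documented smooth trajectories with absolute liver perfusion held
  constant.
* **Evaluation** — geometric mean fold error
  `GMFE = 10^(Σ|log10(pred/obs)|/n)`, two-fold/1.25-fold goodness-of-fit
  fractions, Rowland–Matin DDI algebra
  `AUCR = Fg_r / (Σf_m·f_m,CYP1A2/(1+I_u/K_i) + 1 − Σf_m·f_m,CYP1A2)`, and
  local sensitivities `S = (ΔAUC/AUC)·(p/Δp)`.

Because the system is linear and time-invariant between doses, the engine
propagates the exact matrix exponential on a 0.1 h grid (an adaptive BDF
integrator is kept as an independent cross-check), so trajectories are
bit-reproducible and mass balance holds to machine precision.

## Worked example

```python
import gestpbpk as g

# single 10 mg oral dose in the reference non-pregnant adult
model, sim, m = g.baseline_single_dose()
print(f"AUC_0-inf = {m.auc:.1f} ng*h/mL   Cmax = {m.cmax:.1f} ng/mL   "
      f"t1/2 = {m.t_half:.1f} h   CL/F = {m.cl_over_f:.1f} L/h")

# steady-state 10 mg daily: trimesters vs baseline
frame = g.trimester_comparison()
print(frame[["scenario", "cmax", "auc", "cl_over_f", "c_trough",
             "auc_change_pct", "cl_over_f_change_pct",
             "c_trough_change_pct"]].round(1).to_string(index=False))
```

prints

```
AUC_0-inf = 687.6 ng*h/mL   Cmax = 18.9 ng/mL   t1/2 = 45.0 h   CL/F = 14.5 L/h
   scenario  cmax   auc  cl_over_f  c_trough  auc_change_pct  cl_over_f_change_pct  c_trough_change_pct
   baseline  38.6 680.4       14.7      20.8             NaN                   NaN                  NaN
trimester_1  35.5 618.2       16.2      18.8            -9.1                  10.1                 -9.7
trimester_2  32.2 562.9       17.8      17.4           -17.3                  20.9                -16.5
trimester_3  29.2 510.6       19.6      15.9           -25.0                  33.3                -23.7
```

Reading: a 10 mg oral dose gives a baseline exposure of ~688 ng·h/mL
(apparent clearance ~14.5 L/h). By the third trimester apparent clearance
rises by a third — CYP1A2 activity falls ~63% but UGT1A4/CYP3A4/FMO3
induction and the higher unbound fraction more than compensate — so the
steady-state AUC over a dosing interval drops by 25% and the trough
concentration (the quantity used in therapeutic drug monitoring) falls
from ~21 to ~16 ng/mL, approaching the 20 ng/mL effective threshold from
below. No trimester exceeds a 28% exposure change, which is the argument
against pre-emptive dose adjustment.

The same experiments are available from the shell:

```bash
gestpbpk simulate --config scenarios/baseline_single_10mg.yaml --out-dir results
gestpbpk populations --out-dir results
gestpbpk sensitivity --endpoint auc_single
gestpbpk evaluate
```

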