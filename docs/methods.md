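# Methods

## Model structure

All structures are linear compartmental ODE systems on drug *amounts*
(dose-units: dpm for radiotracers, ng otherwise), with unbound
concentrations `C_i = A_i / V_i` reported in dose-units/mL.  Volumes are in
µL, flows and clearances in µL/min, time in minutes.  Plasma-model volumes
and clearances are entered in mL and mL/min and converted once at model
assembly.

Compartments: plasma central (plus up to two peripheral compartments), brain
microvessels (`mv`), choroid-plexus microvessels (`cpmv`, revised structure
only), brain ECF (`ecf`), and the CSF axis `lv` (both lateral ventricles
lumped, 7.5 µL), `tfv`, `cm`, `sas`; the surface-compartment variant appends
`bsc`.  An absorbing `eliminated` state collects plasma clearance so the
augmented system conserves mass exactly — the mass-balance diagnostic
reports the worst-case relative deviation of the augmented total from the
cumulative dose.

Flux wiring:

* **Legacy structure (`PK30`)** — unidirectional CSF flow
  `lv → tfv → cm → sas → plasma` at `Q_CSF` = 2.2 µL/min; blood–CSF barrier
  (BCSFB) on the whole-brain microvessel compartment.
* **Revised structure (`PK31`)** — bidirectional exchange: downward `venQ_D`
  (lv→tfv, tfv→cm) and `cisQ_D` (cm→sas), upward rates `r·venQ_D`,
  `r·cisQ_D` with a single upward/downward ratio `r`; BCSFB moved onto the
  choroid-plexus microvessel compartment, which is perfused from plasma at
  `Q_CP`.  SAS exchanges with plasma through the signed clearance `sasQ`:
  `flux = max(sasQ,0)·C_sas − max(−sasQ,0)·C_plasma`, so a negative estimate
  is a plasma→SAS uptake clearance.  (How a negative value should act was an
  open choice; the signed two-term form keeps the system linear and
  mass-consistent.)
* **Surface-compartment variant (`PK31_BSC`)** — a brain/spinal-cord surface
  compartment exchanges with SAS at `q_ex` = 100 mL/min (fixed; effectively
  instantaneous equilibration) and clears to plasma at `CL_BSC`; SAS→plasma
  is pinned to the passive absorption clearance `sasQ_abs` (the inulin
  value).
* **Periventricular variant (`PK31_PV`)** — adds a symmetric clearance
  `CL_pv` between each of lv/tfv and the brain microvessels; `cf_ppa` is
  fixed at 1 in this variant.

Barrier clearances combine transcellular and paracellular components,
`CL = CL_trans + cf_ppa·CL_para`, where `cf_ppa ∈ (0, 1.5]` corrects for the
tendency of diffusivity-based paracellular estimates to overpredict
permeability for hydrophilic molecules.  Passive clearances are drug
*inputs*; an aqueous-diffusivity helper (`D = a·MW^(−b)`, configurable
coefficients, hard 5000 Da validity limit) exists for users deriving their
own paracellular values.  The BCSFB clearance is split 50/50 between lv and
tfv (equal lumped volumes; configurable).  An ECF→CM bulk-flow hook exists
but defaults to zero; intracellular-fluid and lysosomal sub-compartments are
out of scope.

## Physiological constants

Printed, load-bearing values: single lateral ventricle 3.75 µL, cisterna
magna 17 µL, ventricles+CM total 32 µL (which fixes the third/fourth
ventricle at 7.5 µL), choroid plexus 4 mg with 196 µL/g blood volume and
4 mL/min/g blood flow (hence `V_CPMV` = 0.784 µL, `Q_CP` = 16 µL/min),
legacy CSF flow 2.2 µL/min, whole brain 1.8 mL.  Values not printed
anywhere authoritative carry provenance tags in the physiology config and
are overridable: subarachnoid space 218 µL (total CSF ≈ 250 µL),
brain ECF 290 µL (≈16% of brain volume), microvessel blood 54 µL (3% of
brain), cerebral blood flow 1.2 mL/min.  These affect mainly dilution and
blood-side kinetics, not the CSF transport-rate estimates, but they are
implementer-chosen and labelled as such.

## Dosing

Intra-CSF injection volumes exceed the site volume, so the dosing solution
fills the site and overflows strictly downstream (ICV: injected ventricle →
tfv → cm → sas; IC: cm → sas; IT: sas), never upstream.  The cascade is
allowed to continue past the tfv when the remainder exceeds its volume — a
modelling convention; whether that happens in vivo is untested.  When an ICV
study does not report its volume, 12.5 µL is assumed (midpoint of the
10–15 µL range of comparable studies).  Dosing is instantaneous by default;
finite durations are supported as zero-order inputs into the apportioned
compartments.  Counted radioactivity (cpm/g) is converted to dpm/mL by
anchoring the end-of-administration cisterna-magna concentration to the
dosing-solution concentration, with CSF/plasma density 1 g/mL.

## Asymmetry-factor calibration

Asymmetry factors (≥1) multiply the influx or efflux side of a barrier
clearance.  Given a steady-state Kp_uu target (ECF/plasma for the BBB,
CM/plasma for the BCSFB) the calibration solves the steady-state equations
numerically (Brent root finding on the single active factor; exact linear
steady state per evaluation, no time stepping) until the re-simulated ratio
matches the target to 1e-6 relative.  The active side is chosen by comparing
the target with the *passive baseline* ratio (all factors 1): at the BBB the
baseline is exactly 1, recovering the usual "Kp_uu < 1 → efflux" rule; at
the BCSFB, CSF turnover pushes the baseline well below 1, and comparing
against the baseline keeps every positive target reachable with one-sided
factors.  A target of exactly 1 is treated as the flow-marker convention (no
asymmetry assumed; all factors returned as 1).

## Estimation

Fitting is naive-pooled least squares on log10 concentrations — the data
this workflow emulates are digitized mean profiles, so no random-effects
estimation is attempted; inter-individual and residual variability enter
only in prediction-interval simulation.  Each observation has equal weight
across arms.  The optimizer is trust-region-reflective least squares under
box bounds (`venQ_D`, `cisQ_D` ∈ (0, 50] µL/min, U/D ratio ∈ [0, 10],
`sasQ` ∈ [−20, 50] µL/min, `cf_ppa` ∈ (0, 1.5]), globalized by a seeded
latin-hypercube multi-start (16 starts by default).  Standard errors come
from the Gauss–Newton covariance `s²(JᵀJ)⁻¹` of the log-residuals; the
profile objective of the U/D ratio is unimodal around the truth on the
reference design (an identifiability guard).  During fitting, trajectories
are computed by exact matrix-exponential propagation of the linear system;
production simulation defaults to stiff BDF integration with rtol 1e-8 and
atol 1e-12 in dose-units, tolerances chosen because compartment volumes span
0.784 µL to mL scale (the surface-compartment variant's 100 mL/min exchange
makes the system genuinely stiff).

Plasma models (1/2/3 mammillary compartments) are fitted the same way from
IV data, selecting the lowest objective with a parsimony tie-break (fewer
compartments within 1e-3); peripheral compartments are canonicalized by
volume since their labels are exchangeable.

## Synthetic data and reference values

The generator simulates a known truth on a study-like grid and multiplies by
`exp(ε)`, `ε ~ N(0, log(1+CV²))`, i.e. log-normal noise whose coefficient of
variation equals the design CV (default 10%).  Sampling grids
(15/30/60/120/180/240 min) are implementer-chosen within the reported study
durations; the exact grids of the source studies were never printed.

The reference transport parameters shipped with the package —
`venQ_D` = 0.5, `cisQ_D` = 2.0, U/D ratio = 1.4, `sasQ` = 4.0 µL/min,
`cf_ppa` = 0.5 — are representative values chosen once to satisfy the
established qualitative structure: the cisternal rate four times the
ventricular rate, a U/D ratio near the 1.4 reported for human aqueductal
pulsation and above 1 (net upward flow), ventricular movement well below the
classical 2.2 µL/min bulk-flow figure, and a paracellular correction below
1.  They are *not* fitted to in-vivo data within this package.  Passing
tests therefore demonstrate structural and statistical correctness of the
machinery on data with the assumed structure (linear kinetics, proportional
log-normal noise, exact dosing); they do not validate the parameter values
against animals, and real data bring features the generator omits —
assay LLOQ censoring (only an optional floor is provided), microdialysis
probe recovery, inter-animal physiology differences, and sampling-induced
CSF disturbance.

The sensitivity-sweep and half-life analyses regress log-concentration on
the elimination-phase window (15–120 min of the reference grid, or the last
four points of a supplied grid): at later times the cisterna-magna profile
rides the slow blood→CSF return mode (plasma and ECF act as a depot), which
is kinetically meaningful but not the cisternal-outflow phase the sweep
interrogates.

## Known limitations

* The model represents pulsatile CSF motion as net bidirectional exchange
  rates; within-cycle oscillatory waveforms and convective effects of the
  injection itself (a computational-fluid-dynamics problem) are out of
  scope, as are saturable transport, disease-state physiology and human
  scaling.
* Intrathecal dosing deposits into the single SAS compartment; the
  lumbar/cranial distinction is not resolved structurally.
* `sasQ` lumps passive absorption with drug-dependent perivascular/barrier
  pathways and is estimable only from in-vivo profiles, not predictable from
  physicochemical properties.
* Negative `sasQ` (plasma→SAS uptake) is practically identifiable only from
  designs with appreciable plasma exposure (e.g. an IV arm observing SAS).
* The exploratory surface-compartment and periventricular variants are
  descriptive devices, not physiologically grounded structures.
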