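# csfpbpk

A physiologically based pharmacokinetic (PBPK) model of the rat central
nervous system built around **bidirectional, site-dependent cerebrospinal
fluid (CSF) solute movement**, for scientists studying drug disposition in
CSF after intra-CSF (intracerebroventricular, intracisternal, intrathecal)
or intravenous administration.

## The scientific problem

Classical CNS PBPK models move drug through the CSF compartments —
lateral ventricles (LV), third/fourth ventricles (TFV), cisterna magna (CM)
and subarachnoid space (SAS) — by a single unidirectional bulk flow
(2.2 µL/min in rats), rooted in the traditional picture of CSF secreted at
the choroid plexus, circulating downward, and absorbed at the arachnoid
villi.  That structure cannot reproduce a striking feature of CSF
flow-marker kinetics after ventricular injection: cisterna-magna and
subarachnoid concentrations decline at *similar* rates.  Any single flow
rate empties the CM either too fast (while matching SAS) or too slowly
(while matching CM).

This package implements the revised structure in which solute exchange
between adjacent CSF compartments is **bidirectional**, with downward rates
`venQ_D` (LV→TFV, TFV→CM) and `cisQ_D` (CM→SAS) and upward rates given by a
common upward/downward ratio `r` (U/D ratio):

```
d(A_CM)/dt = venQ_D·C_TFV − (r·venQ_D + cisQ_D)·C_CM + r·cisQ_D·C_SAS + barrier terms
```

with `C_i = A_i / V_i` the unbound concentration in each compartment.
`r > 1` encodes a *net upward* (caudocranial) solute movement.  Around the
CSF axis sit plasma (a 1–3 compartment empirical model), brain microvessels,
a dedicated **choroid-plexus microvessel compartment** feeding the blood–CSF
barrier (preventing unphysical instantaneous CSF→brain-ECF shortcuts), and
brain ECF behind the blood–brain barrier.  Active transport and metabolism
at either barrier enter as asymmetry factors calibrated so that the
steady-state unbound ratio (Kp_uu) matches a measured target.  Two
exploratory variants add a brain/spinal-cord surface compartment on the SAS
or a periventricular clearance between ventricles and microvessels.

The five transport parameters (`venQ_D`, `cisQ_D`, U/D ratio, the SAS↔plasma
clearance `sasQ` — signed: negative means plasma→SAS uptake — and a
paracellular-permeability correction `cf_ppa`) are estimated by jointly
fitting CSF flow-marker (sucrose-like) concentration–time data from a
ventricular-injection arm observed in CM and SAS and a cisternal-injection
arm observed in CM and plasma, by multi-start least squares on log10
concentrations.

Because the in-vivo datasets this workflow was designed around are digitized
mean profiles that cannot be redistributed, the package ships a synthetic
data generator (`csfpbpk.synthetic_data`) that simulates a known truth on
study-like sampling grids with proportional log-normal noise, plus the
reference study designs.

## Worked example

`python examples/fit_flow_marker.py` generates the two flow-marker reference
arms with 10% proportional noise and re-estimates all five transport
parameters from an uninformative starting point:

```
 parameter   estimate       se    truth
    venQ_D      0.572    0.151    0.500
    cisQ_D      1.849    0.158    2.000
  ud_ratio      1.431    0.125    1.400
      sasQ      3.972    0.129    4.000
    cf_ppa      0.515    0.048    0.500

objective (SSR of log10 residuals): 0.0284 on 24 observations
cisternal/ventricular rate ratio: 3.23
```

The estimates scatter around the generating values: the cisternal rate is
about four times the ventricular rate, and the U/D ratio above 1 indicates
net upward CSF solute movement.  `python examples/simulate_icv_tracer.py`
shows the forward problem — a 12.5 µL ventricular tracer dose apportioned by
the overflow rule (3.75 µL fills the injected ventricle, 7.5 µL the
third/fourth ventricle, 1.25 µL the cisterna magna) and integrated over four
hours with a mass-balance residual of ~5e-16:

```
 t (min)    CM (dpm/mL)   SAS (dpm/mL)     plasma
      15      6.146e+06      8.203e+05       4062
      60      1.632e+06      8.105e+05       4055
     240      5.548e+04      3.799e+04      192.9
```

CM and SAS decline in parallel after ~60 min — the behaviour a
unidirectional flow cannot produce (`examples/cisternal_flow_sensitivity.py`
quantifies this: the best unidirectional fit to bidirectional truth leaves a
residual SSR of 0.06, the bidirectional fit reaches 1e-28).  The other
examples cover asymmetry-factor calibration against Kp_uu targets and
95% prediction intervals over 200 replicate simulations.

A thin CLI wraps the same functions:

```
csfpbpk generate --design sucrose --seed 1 --out sucrose.csv
csfpbpk fit sucrose --icv icv.csv --ic ic.csv --config run.yaml
csfpbpk sensitivity --config run.yaml --parameter cisQ_D
```

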