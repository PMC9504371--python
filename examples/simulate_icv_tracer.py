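"""Simulate a ventricular tracer injection and print CSF concentration profiles.

A 12.5 µL intracerebroventricular dose of a sucrose-like CSF flow marker is
apportioned by the overflow rule (3.75 µL fills the injected ventricle, the
rest cascades to the third/fourth ventricle and beyond) and integrated over
four hours.  The printed table shows unbound concentrations in cisterna
magna and subarachnoid space declining at similar rates — the signature of
fast bidirectional cisternal exchange.
"""

import numpy as np

from csfpbpk import DoseEvent, Route, apportioned_volumes, simulate
from csfpbpk.synthetic_data import sucrose_reference_spec

spec = sucrose_reference_spec()
dose = DoseEvent(route=Route.ICV, amount=1e6, solution_volume=12.5)

print("dose apportionment (µL):", apportioned_volumes(dose, spec.physiology))

times = np.array([15.0, 30.0, 60.0, 120.0, 180.0, 240.0])
res = simulate(spec, [dose], times)

print(f"\n{'t (min)':>8} {'CM (dpm/mL)':>14} {'SAS (dpm/mL)':>14} {'plasma':>10}")
for i, t in enumerate(times):
    print(
        f"{t:8.0f} {res.profile('cm')[i]:14.4g} {res.profile('sas')[i]:14.4g} "
        f"{res.profile('plasma')[i]:10.4g}"
    )
print(f"\nmass-balance residual: {res.diagnostics['mass_balance_residual']:.2e}")
print("CM and SAS fall roughly in parallel after ~60 min: the cisternal")
print("exchange (down + up) is an order of magnitude faster than the")
print("ventricular rate, so the two compartments share one kinetic phase.")
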