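"""Why a unidirectional CSF flow cannot describe tracer kinetics in CM and SAS.

Sweeps the cisternal flow rate of a unidirectional model (no upward
movement) from 10% to 60% of the classical 2.2 µL/min and prints the
cisterna-magna elimination half-life over the 15–120 min phase: it falls
monotonically, so any single rate either empties the cisterna magna too
fast (matching SAS) or too slowly (matching CM) — never both.  The second
part quantifies that dilemma as fit residuals.
"""

import numpy as np

from csfpbpk import CSFTransportParams, DoseEvent, Route, sensitivity_sweep
from csfpbpk.fitting import fit_transport
from csfpbpk.synthetic_data import generate, sucrose_reference_design, sucrose_reference_spec

spec = sucrose_reference_spec()
uni = spec.model_copy(
    update={"transport": CSFTransportParams(venQ_D=2.2, cisQ_D=2.2, ud_ratio=0.0, sasQ=2.2, cf_ppa=0.5)}
)
dose = DoseEvent(route=Route.ICV, amount=1e6, solution_volume=12.5)
window = np.array([15.0, 30.0, 60.0, 120.0])

table = sensitivity_sweep(uni, [dose], window, "cisQ_D", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
print("cisternal-rate multiplier vs CM elimination half-life (min):")
print(table.round(2).to_string(index=False))

truth_data = generate(spec, sucrose_reference_design(noise_cv=0.0), seed=0)
icv_arms = [truth_data.arm("icv")]
neutral = uni.model_copy(
    update={"transport": CSFTransportParams(venQ_D=1.0, cisQ_D=1.0, ud_ratio=1.0, sasQ=1.0, cf_ppa=1.0)}
)
best_uni = fit_transport(icv_arms, neutral, ["venQ_D", "cisQ_D", "sasQ", "cf_ppa"],
                         fixed={"ud_ratio": 0.0}, n_starts=12, seed=5)
best_bi = fit_transport(icv_arms, neutral,
                        ["venQ_D", "cisQ_D", "ud_ratio", "sasQ", "cf_ppa"], n_starts=12, seed=5)
print(f"\nbest unidirectional fit to bidirectional truth: SSR = {best_uni.objective:.4f}")
print(f"best bidirectional fit to the same data:        SSR = {best_bi.objective:.2e}")
print("The unidirectional residual stays bounded away from zero; the")
print("bidirectional structure reproduces both profiles exactly.")
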