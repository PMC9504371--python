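"""Calibrate barrier asymmetry factors against steady-state Kp_uu targets.

Asymmetry factors multiply the passive influx or efflux clearance at the
blood–brain barrier (BBB) or blood–CSF barrier (BCSFB) to encode active
transport and metabolism.  Given a measured steady-state unbound ratio
(ECF/plasma for the BBB, cisterna-magna/plasma for the BCSFB), the
calibration inverts the model's steady-state equations numerically so the
simulated ratio matches the target exactly.
"""

from csfpbpk import build_model, calibrate_af, steady_state
from csfpbpk.synthetic_data import sucrose_reference_spec

spec = sucrose_reference_spec()

print(f"{'barrier':>7} {'Kp_uu target':>13} {'active factor':>24} {'achieved':>10}")
for barrier, comp in (("BBB", "ecf"), ("BCSFB", "cm")):
    for target in (0.1, 0.5, 2.0):
        afs = calibrate_af(spec, target, barrier)
        model = build_model(spec.model_copy(update={"afs": afs}))
        conc = model.concentrations(steady_state(model, infusion_rate=1.0))
        achieved = conc[model.index[comp]] / conc[model.index["plasma"]]
        active = {k: v for k, v in afs.model_dump().items() if v != 1.0}
        label = ", ".join(f"{k}={v:.3f}" for k, v in active.items()) or "all = 1"
        print(f"{barrier:>7} {target:13.2f} {label:>24} {achieved:10.4f}")

print("\nOnly one direction per barrier is ever scaled above 1; a flow marker")
print("(Kp_uu consistent with pure passive transport) keeps all factors at 1.")
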