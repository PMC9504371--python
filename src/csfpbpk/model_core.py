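"""Assembly of the CNS PBPK ODE systems and their steady-state machinery.

Two structural families are provided:

* the legacy structure (``PK30``): unidirectional, constant CSF flow
  LV → TFV → CM → SAS → plasma at the classical rate of 2.2 µL/min, with the
  blood–CSF barrier (BCSFB) wired onto the whole-brain microvessel
  compartment;
* the revised structure (``PK31``): a dedicated choroid-plexus microvessel
  compartment feeds the BCSFB, and solute movement between CSF compartments
  is bidirectional and site-dependent — downward rates ``venQ_D`` (LV→TFV,
  TFV→CM) and ``cisQ_D`` (CM→SAS), with upward rates given by a common
  upward/downward ratio.  A U/D ratio above 1 encodes net caudocranial
  (upward) solute movement.  Two exploratory extensions add a brain/spinal
  cord surface compartment hanging off the SAS (``PK31_BSC``) or a
  periventricular clearance between the ventricles and brain microvessels
  (``PK31_PV``).

All models are linear in the state (amounts per compartment), which the
steady-state solver and asymmetry-factor calibration exploit.  An absorbing
"eliminated" state collects plasma clearance so that total mass is conserved
in the augmented system — the basis of the mass-balance diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq

from .dosing import DoseEvent
from .physiology import (
    CPMicrovessel,
    DrugProperties,
    RatCNSPhysiology,
    UL_PER_ML,
    derive_cp_microvessel,
)
from .plasma_pk import PlasmaModel


class Structure(str, Enum):
    PK30 = "PK30"
    PK31 = "PK31"
    PK31_BSC = "PK31_BSC"
    PK31_PV = "PK31_PV"


class CSFTransportParams(BaseModel):
    """The estimated CSF solute-transport parameters.

    Upward rates are always derived (``venQ_U = ud_ratio·venQ_D`` etc.),
    never stored.  ``sasQ`` is a signed clearance between SAS and the
    systemic circulation: positive values clear SAS→plasma; a negative value
    is interpreted as a plasma→SAS uptake clearance acting on unbound plasma
    concentration (flux = max(sasQ,0)·C_SAS − max(−sasQ,0)·C_plasma).
    """

    model_config = ConfigDict(extra="forbid")

    venQ_D: float = Field(..., ge=0, description="µL/min, downward LV→TFV→CM")
    cisQ_D: float = Field(..., ge=0, description="µL/min, downward CM→SAS")
    ud_ratio: float = Field(..., ge=0, description="upward/downward rate ratio")
    sasQ: float = Field(..., description="µL/min, signed SAS↔plasma clearance")
    cf_ppa: float = Field(..., gt=0, description="paracellular-permeability correction")
    sasQ_abs: Optional[float] = Field(
        None, ge=0, description="µL/min, passive CSF absorption (BSC variant)"
    )
    q_ex: float = Field(100.0, gt=0, description="mL/min, SAS⇄BSC exchange (fixed)")
    V_BSC: Optional[float] = Field(None, gt=0, description="mL, BSC variant")
    CL_BSC: Optional[float] = Field(None, ge=0, description="µL/min, BSC variant")
    CL_pv: Optional[float] = Field(None, ge=0, description="µL/min, periventricular variant")

    @property
    def venQ_U(self) -> float:
        return self.ud_ratio * self.venQ_D

    @property
    def cisQ_U(self) -> float:
        return self.ud_ratio * self.cisQ_D


class AsymmetryFactors(BaseModel):
    """Multipliers (≥1) encoding active transport/metabolism at each barrier.

    Per barrier at most one of the influx/efflux factors exceeds 1: the
    direction is dictated by whether the target Kp_uu is below or above
    unity.
    """

    model_config = ConfigDict(extra="forbid")

    af_bbb_in: float = Field(1.0, ge=1.0)
    af_bbb_out: float = Field(1.0, ge=1.0)
    af_bcsfb_in: float = Field(1.0, ge=1.0)
    af_bcsfb_out: float = Field(1.0, ge=1.0)

    @model_validator(mode="after")
    def _one_sided(self) -> "AsymmetryFactors":
        for pair in (("af_bbb_in", "af_bbb_out"), ("af_bcsfb_in", "af_bcsfb_out")):
            a, b = (getattr(self, p) for p in pair)
            if a > 1.0 + 1e-12 and b > 1.0 + 1e-12:
                raise ValueError(f"at most one of {pair} may exceed 1")
        return self


class ModelSpec(BaseModel):
    """A fully assembled model description, config-file constructible."""

    model_config = ConfigDict(extra="forbid")

    structure: Structure
    physiology: RatCNSPhysiology
    drug: DrugProperties
    transport: CSFTransportParams
    plasma: PlasmaModel
    cp: Optional[CPMicrovessel] = None
    afs: AsymmetryFactors = Field(default_factory=AsymmetryFactors)
    bcsfb_split_lv: float = Field(0.5, ge=0, le=1, description="BCSFB CL fraction on LV")
    ecf_bulk_flow: float = Field(0.0, ge=0, description="µL/min, ECF→CM hook; default off")

    @model_validator(mode="after")
    def _variants(self) -> "ModelSpec":
        t = self.transport
        if self.structure is Structure.PK31_BSC:
            missing = [k for k in ("V_BSC", "CL_BSC", "sasQ_abs") if getattr(t, k) is None]
            if missing:
                raise ValueError(f"PK31_BSC requires transport parameters {missing}")
        if self.structure is Structure.PK31_PV:
            if t.CL_pv is None:
                raise ValueError("PK31_PV requires transport parameter CL_pv")
            if abs(t.cf_ppa - 1.0) > 1e-12:
                raise ValueError("PK31_PV fixes cf_ppa to 1")
        if self.cp is None:
            object.__setattr__(self, "cp", derive_cp_microvessel(self.physiology))
        return self


ELIMINATED = "eliminated"


@dataclass
class CompiledModel:
    """A compiled linear ODE system: dx/dt = A·x (+ inputs added by the simulator).

    ``names`` excludes the absorbing elimination state, which is always the
    last row/column of ``A``; ``volumes_uL`` aligns with ``names``.
    """

    spec: ModelSpec
    names: list[str]
    index: dict[str, int]
    volumes_uL: np.ndarray
    A: np.ndarray  # (n+1) x (n+1), last state absorbs plasma clearance

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_compartments(self) -> int:
        return len(self.names)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.A @ x

    def concentrations(self, amounts: np.ndarray) -> np.ndarray:
        """Amounts → concentrations (dose-units/mL) for the named compartments.

        ``amounts`` may carry the trailing elimination state; it is dropped.
        """
        a = np.asarray(amounts, dtype=float)
        a = a[..., : self.n_compartments]
        return a / (self.volumes_uL * (1.0 / UL_PER_ML))


def _add_cl(A: np.ndarray, V: np.ndarray, src: int, dst: int, cl: float) -> None:
    """Wire a first-order transfer flux cl·C_src (amount/min) from src to dst."""
    if cl == 0.0:
        return
    k = cl / V[src]
    A[src, src] -= k
    A[dst, src] += k


def build_model(spec: ModelSpec) -> CompiledModel:
    """Assemble the rate matrix for the requested structure.

    Barrier clearances combine transcellular and (corrected) paracellular
    components: CL_barrier = CL_trans + cf_ppa·CL_para, then influx/efflux
    asymmetry factors multiply the respective directions.
    """
    phys, drug, t, afs = spec.physiology, spec.drug, spec.transport, spec.afs
    pm = spec.plasma

    names = ["plasma"]
    vols = [pm.Vc * UL_PER_ML]
    if pm.n_compartments >= 2:
        names.append("periph1")
        vols.append(pm.V2 * UL_PER_ML)
    if pm.n_compartments == 3:
        names.append("periph2")
        vols.append(pm.V3 * UL_PER_ML)
    names += ["mv"]
    vols += [phys.V_MV]
    if spec.structure is not Structure.PK30:
        names.append("cpmv")
        vols.append(spec.cp.V_CPMV)
    names += ["ecf", "lv", "tfv", "cm", "sas"]
    vols += [phys.V_ECF, phys.V_LV_lumped, phys.V_TFV, phys.V_CM, phys.V_SAS]
    if spec.structure is Structure.PK31_BSC:
        names.append("bsc")
        vols.append(t.V_BSC * UL_PER_ML)

    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    V = np.asarray(vols, dtype=float)
    A = np.zeros((n + 1, n + 1))
    elim = n

    # --- plasma submodel ---
    p = idx["plasma"]
    _add_cl(A, V, p, elim, pm.CL * UL_PER_ML)
    if pm.n_compartments >= 2:
        q2 = pm.Q2 * UL_PER_ML
        _add_cl(A, V, p, idx["periph1"], q2)
        _add_cl(A, V, idx["periph1"], p, q2)
    if pm.n_compartments == 3:
        q3 = pm.Q3 * UL_PER_ML
        _add_cl(A, V, p, idx["periph2"], q3)
        _add_cl(A, V, idx["periph2"], p, q3)

    # --- cerebral blood ---
    mv = idx["mv"]
    _add_cl(A, V, p, mv, phys.Q_cerebral_blood)
    _add_cl(A, V, mv, p, phys.Q_cerebral_blood)
    if spec.structure is not Structure.PK30:
        cpmv = idx["cpmv"]
        _add_cl(A, V, p, cpmv, spec.cp.Q_CP)
        _add_cl(A, V, cpmv, p, spec.cp.Q_CP)

    # --- BBB: microvessel ⇄ brain ECF ---
    ecf = idx["ecf"]
    cl_bbb = drug.CL_BBB_trans + t.cf_ppa * drug.CL_BBB_para
    _add_cl(A, V, mv, ecf, afs.af_bbb_in * cl_bbb)
    _add_cl(A, V, ecf, mv, afs.af_bbb_out * cl_bbb)
    if spec.ecf_bulk_flow > 0:
        _add_cl(A, V, ecf, idx["cm"], spec.ecf_bulk_flow)

    # --- BCSFB: blood ⇄ ventricular CSF (split between LV and TFV) ---
    lv, tfv, cm, sas = idx["lv"], idx["tfv"], idx["cm"], idx["sas"]
    bcsfb_blood = mv if spec.structure is Structure.PK30 else idx["cpmv"]
    cl_bcsfb = drug.CL_BCSFB_trans + t.cf_ppa * drug.CL_BCSFB_para
    for csf_i, frac in ((lv, spec.bcsfb_split_lv), (tfv, 1.0 - spec.bcsfb_split_lv)):
        _add_cl(A, V, bcsfb_blood, csf_i, afs.af_bcsfb_in * cl_bcsfb * frac)
        _add_cl(A, V, csf_i, bcsfb_blood, afs.af_bcsfb_out * cl_bcsfb * frac)

    # --- CSF axis ---
    if spec.structure is Structure.PK30:
        q = phys.Q_CSF_legacy
        _add_cl(A, V, lv, tfv, q)
        _add_cl(A, V, tfv, cm, q)
        _add_cl(A, V, cm, sas, q)
        _add_cl(A, V, sas, p, q)
    else:
        _add_cl(A, V, lv, tfv, t.venQ_D)
        _add_cl(A, V, tfv, lv, t.venQ_U)
        _add_cl(A, V, tfv, cm, t.venQ_D)
        _add_cl(A, V, cm, tfv, t.venQ_U)
        _add_cl(A, V, cm, sas, t.cisQ_D)
        _add_cl(A, V, sas, cm, t.cisQ_U)
        if spec.structure is Structure.PK31_BSC:
            bsc = idx["bsc"]
            qex = t.q_ex * UL_PER_ML
            _add_cl(A, V, sas, bsc, qex)
            _add_cl(A, V, bsc, sas, qex)
            _add_cl(A, V, bsc, p, t.CL_BSC)
            _add_cl(A, V, sas, p, t.sasQ_abs)
        else:
            _add_cl(A, V, sas, p, max(t.sasQ, 0.0))
            _add_cl(A, V, p, sas, max(-t.sasQ, 0.0))
        if spec.structure is Structure.PK31_PV:
            for csf_i in (lv, tfv):
                _add_cl(A, V, csf_i, mv, t.CL_pv)
                _add_cl(A, V, mv, csf_i, t.CL_pv)

    return CompiledModel(spec=spec, names=names, index=idx, volumes_uL=V, A=A)


def steady_state(model: CompiledModel, infusion_rate: float) -> np.ndarray:
    """Exact steady-state amounts under a constant-rate IV infusion.

    Solves the linear algebraic system A·x + b = 0 on the non-absorbing
    states (no time stepping).  Requires elimination to be present,
    otherwise the system is singular.
    """
    n = model.n_compartments
    Ared = model.A[:n, :n]
    b = np.zeros(n)
    b[model.index["plasma"]] = infusion_rate
    if infusion_rate == 0.0:
        return np.zeros(n)
    if np.linalg.cond(Ared) > 1e3 / np.finfo(float).eps:
        raise ValueError(
            "steady-state system is singular: the model has no elimination "
            "pathway (plasma clearance is zero?)"
        )
    x = np.linalg.solve(Ared, -b)
    if not np.all(np.isfinite(x)):
        raise ValueError("steady-state solve produced non-finite amounts")
    return x


def _ss_kpuu(spec: ModelSpec, compartment: str) -> float:
    model = build_model(spec)
    x = steady_state(model, infusion_rate=1.0)
    c = model.concentrations(x)
    return float(c[model.index[compartment]] / c[model.index["plasma"]])


def calibrate_af(
    spec: ModelSpec,
    kpuu_target: float,
    barrier: str,
    rtol: float = 1e-9,
) -> AsymmetryFactors:
    """Calibrate asymmetry factors so the steady-state unbound ratio matches Kp_uu.

    The target ratio is ECF/plasma for the BBB and CM/plasma for the BCSFB.
    Only one factor per barrier is active: the efflux factor when the target
    lies below the passive baseline ratio (all AFs = 1), the influx factor
    when it lies above.  At the BBB the passive baseline is exactly 1, so
    this reduces to the usual "Kp_uu < 1 → efflux, Kp_uu > 1 → influx" rule;
    at the BCSFB the baseline sits below 1 whenever CSF turnover dilutes the
    ventricular compartments, and the comparison against the baseline keeps
    every positive target reachable.  A target of exactly 1 is the
    flow-marker convention — no transport asymmetry assumed — and returns
    all factors equal to 1 without solving.  The equation is inverted
    numerically by monotone root finding; the round-trip (re-simulated
    steady-state ratio equals the target) is the correctness contract.
    """
    if kpuu_target <= 0:
        raise ValueError("kpuu_target must be positive")
    barrier = barrier.upper()
    if barrier not in ("BBB", "BCSFB"):
        raise ValueError("barrier must be 'BBB' or 'BCSFB'")
    comp = "ecf" if barrier == "BBB" else "cm"
    drug = spec.drug
    cl_pass = (
        drug.CL_BBB_trans + spec.transport.cf_ppa * drug.CL_BBB_para
        if barrier == "BBB"
        else drug.CL_BCSFB_trans + spec.transport.cf_ppa * drug.CL_BCSFB_para
    )
    if cl_pass <= 0:
        raise ValueError(f"passive {barrier} clearance must be positive to calibrate AFs")

    base = spec.afs.model_copy(
        update={f"af_{barrier.lower()}_in": 1.0, f"af_{barrier.lower()}_out": 1.0}
    )
    if kpuu_target == 1.0:
        return base

    k1 = _ss_kpuu(spec.model_copy(update={"afs": base}), comp)
    if abs(k1 - kpuu_target) <= 1e-9 * kpuu_target:
        return base
    active = f"af_{barrier.lower()}_{'out' if kpuu_target < k1 else 'in'}"

    def kpuu(af: float) -> float:
        afs = base.model_copy(update={active: af})
        return _ss_kpuu(spec.model_copy(update={"afs": afs}), comp)

    increasing = active.endswith("_in")

    lo, hi = 1.0, 2.0
    while True:
        k = kpuu(hi)
        if (increasing and k >= kpuu_target) or (not increasing and k <= kpuu_target):
            break
        lo, hi = hi, hi * 4.0
        if hi > 1e12:
            raise ValueError(f"Kp_uu target {kpuu_target} unreachable at the {barrier}")
    af = brentq(lambda a: kpuu(a) - kpuu_target, lo, hi, rtol=1e-13, maxiter=200)
    result = base.model_copy(update={active: float(af)})
    achieved = _ss_kpuu(spec.model_copy(update={"afs": result}), comp)
    if abs(achieved - kpuu_target) > 1e-6 * kpuu_target:
        raise RuntimeError(
            f"AF calibration failed the round-trip contract: achieved {achieved}, "
            f"target {kpuu_target}"
        )
    return result


def dosed_amount(doses: Iterable[DoseEvent], t: float) -> float:
    """Cumulative administered amount by time t (zero-order infusions prorated)."""
    total = 0.0
    for ev in doses:
        if ev.duration == 0:
            if t >= ev.time:
                total += ev.amount
        else:
            frac = np.clip((t - ev.time) / ev.duration, 0.0, 1.0)
            total += ev.amount * float(frac)
    return total


def mass_balance_residual(
    model: CompiledModel,
    times: np.ndarray,
    amounts: np.ndarray,
    doses: Iterable[DoseEvent],
) -> float:
    """Worst-case relative mass-balance error of a simulated trajectory.

    ``amounts`` must include the trailing elimination state (as returned by
    the simulator), so the augmented total should equal the cumulative dose
    at every time.
    """
    doses = list(doses)
    total_dose = sum(ev.amount for ev in doses)
    if total_dose <= 0:
        raise ValueError("mass balance is undefined for a zero total dose")
    totals = np.asarray(amounts).sum(axis=1)
    expected = np.array([dosed_amount(doses, t) for t in np.asarray(times)])
    return float(np.max(np.abs(totals - expected)) / total_dose)
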