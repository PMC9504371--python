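"""Synthetic observation datasets with the structure the analysis assumes.

The in-vivo profiles this package's estimation workflow was designed around
are mean concentration–time curves of CSF flow markers (sucrose, inulin) and
of example small molecules after intra-CSF dosing.  Those raw data are not
redistributable, so this module generates stand-ins: it simulates a known
truth, samples it on a study-like grid and multiplies by log-normal
proportional noise.  Every generated dataset is synthetic and is labelled as
such by construction.

The reference parameter values used by the generators are representative
physiological values chosen once for this package: the cisternal downward
rate is four times the ventricular downward rate, the upward/downward ratio
is 1.4 (net caudocranial flow), and the ventricular rate sits well below the
classical 2.2 µL/min bulk-flow figure.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .datasets import COMPARTMENT_NAMES, Arm, ObservationDataset
from .dosing import DoseEvent, Route
from .model_core import CSFTransportParams, ModelSpec, Structure
from .physiology import DrugProperties, default_rat_physiology
from .plasma_pk import RUV, PlasmaModel
from .simulate import simulate

#: Representative physiological CSF transport parameters of the healthy rat
#: (sucrose-derived; see the methods note for provenance of each choice).
REFERENCE_TRANSPORT = dict(venQ_D=0.5, cisQ_D=2.0, ud_ratio=1.4, sasQ=4.0, cf_ppa=0.5)

#: Default sampling grid (min) shared by the flow-marker reference designs.
REFERENCE_TIMES = (15.0, 30.0, 60.0, 120.0, 180.0, 240.0)


class DesignArm(BaseModel):
    model_config = ConfigDict(extra="forbid")

    arm_id: str
    route: Route
    amount: float = Field(..., gt=0)
    amount_unit: str = "dpm"
    volume_uL: Optional[float] = Field(None, gt=0)
    compartments: list[str]
    times: list[float]

    @model_validator(mode="after")
    def _check(self) -> "DesignArm":
        t = np.asarray(self.times, dtype=float)
        if len(t) == 0 or t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        bad = set(self.compartments) - set(COMPARTMENT_NAMES)
        if bad:
            raise ValueError(f"unknown compartments {sorted(bad)}")
        return self


class StudyDesign(BaseModel):
    """Arms, sampling grids and the observation-noise level of one study."""

    model_config = ConfigDict(extra="forbid")

    drug: str
    arms: list[DesignArm] = Field(min_length=1)
    noise_cv: float = Field(0.0, ge=0, description="proportional CV of observations")
    seed: Optional[int] = None


def generate(
    spec: ModelSpec, design: StudyDesign, seed: Optional[int] = None
) -> ObservationDataset:
    """Simulate the truth and sample noisy observations.

    Observations are conc·exp(ε) with ε ~ Normal(0, log(1+CV²)), the
    log-normal whose coefficient of variation equals the design CV.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    sigma = float(np.sqrt(np.log(1.0 + design.noise_cv**2)))
    arms = []
    for da in design.arms:
        dose = DoseEvent(route=da.route, amount=da.amount, solution_volume=da.volume_uL)
        res = simulate(spec, [dose], np.asarray(da.times, dtype=float), method="expm")
        rows = []
        for comp in da.compartments:
            truth = res.profile(comp)
            eps = rng.normal(0.0, sigma, size=truth.shape) if sigma > 0 else 0.0
            obs = truth * np.exp(eps)
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": da.times,
                        "compartment": comp,
                        "conc": obs,
                        "conc_unit": f"{da.amount_unit}/mL",
                    }
                )
            )
        arms.append(
            Arm(arm_id=da.arm_id, dose=dose, observations=pd.concat(rows, ignore_index=True))
        )
    return ObservationDataset(drug=design.drug, arms=arms)


# ---------------------------------------------------------------------------
# reference drugs and model specs
# ---------------------------------------------------------------------------


def sucrose_drug() -> DrugProperties:
    """Sucrose: the reference CSF bulk-flow marker (no transport asymmetry)."""
    return DrugProperties(
        name="sucrose",
        MW=342.3,
        logP=-3.7,
        fu_plasma=1.0,
        CL_BBB_trans=0.0,
        CL_BBB_para=1.0,
        CL_BCSFB_trans=0.0,
        CL_BCSFB_para=1.0,
    )


def sucrose_plasma_model() -> PlasmaModel:
    """One-compartment unbound plasma model for sucrose (renal-type clearance)."""
    return PlasmaModel(
        n_compartments=1,
        CL=2.0,
        Vc=60.0,
        iiv_omega2={"CL": 0.05, "Vc": 0.05},
        ruv=RUV(type="proportional", sigma2_prop=0.01),
    )


def sucrose_reference_spec(structure: Structure = Structure.PK31) -> ModelSpec:
    """The sucrose model at the package's reference transport parameters."""
    return ModelSpec(
        structure=structure,
        physiology=default_rat_physiology(),
        drug=sucrose_drug(),
        transport=CSFTransportParams(**REFERENCE_TRANSPORT),
        plasma=sucrose_plasma_model(),
    )


def sucrose_reference_design(noise_cv: float = 0.10) -> StudyDesign:
    """Two flow-marker arms mirroring the data the five-parameter fit consumes.

    An ICV arm (12.5 µL — the assumed midpoint of the 10–15 µL range, since
    the source study did not report its volume) sampled in cisterna magna and
    subarachnoid space, and an IC arm (100 µL, filling the cisterna magna)
    sampled in cisterna magna and plasma, both on a 15–240 min grid.
    """
    return StudyDesign(
        drug="sucrose",
        noise_cv=noise_cv,
        arms=[
            DesignArm(
                arm_id="icv",
                route=Route.ICV,
                amount=1e6,
                volume_uL=12.5,
                compartments=["cm", "sas"],
                times=list(REFERENCE_TIMES),
            ),
            DesignArm(
                arm_id="ic",
                route=Route.IC,
                amount=1e6,
                volume_uL=100.0,
                compartments=["cm", "plasma"],
                times=list(REFERENCE_TIMES),
            ),
        ],
    )


def inulin_reference_spec() -> ModelSpec:
    """Inulin: a large flow marker; lower paracellular clearances, AFs = 1."""
    drug = DrugProperties(
        name="inulin",
        MW=5000.0,
        logP=-7.0,
        fu_plasma=1.0,
        CL_BBB_para=0.3,
        CL_BCSFB_para=0.3,
    )
    transport = CSFTransportParams(
        **{**REFERENCE_TRANSPORT, "sasQ": 1.0, "cf_ppa": 0.3}
    )
    plasma = PlasmaModel(n_compartments=1, CL=1.5, Vc=50.0)
    return ModelSpec(
        structure=Structure.PK31,
        physiology=default_rat_physiology(),
        drug=drug,
        transport=transport,
        plasma=plasma,
    )


def inulin_reference_design(noise_cv: float = 0.10) -> StudyDesign:
    return StudyDesign(
        drug="inulin",
        noise_cv=noise_cv,
        arms=[
            DesignArm(
                arm_id="icv",
                route=Route.ICV,
                amount=1e6,
                volume_uL=12.5,
                compartments=["cm"],
                times=list(REFERENCE_TIMES),
            ),
            DesignArm(
                arm_id="ic",
                route=Route.IC,
                amount=1e6,
                volume_uL=100.0,
                compartments=["cm", "plasma"],
                times=list(REFERENCE_TIMES),
            ),
        ],
    )


def surface_compartment_example_spec() -> ModelSpec:
    """Morphine-like example of the brain/spinal-cord surface-compartment variant.

    The surface compartment's distribution volume (5.24 mL) exceeds the whole
    brain volume, emulating strong binding of the drug to CSF-facing
    parenchymal tissue; passive CSF absorption is pinned to the inulin value.
    """
    drug = DrugProperties(
        name="morphine-like",
        MW=285.3,
        pKb_base=8.2,
        logP=0.9,
        fu_plasma=0.7,
        CL_BBB_trans=1.0,
        CL_BBB_para=2.0,
        CL_BCSFB_trans=1.0,
        CL_BCSFB_para=2.0,
    )
    transport = CSFTransportParams(
        **{**REFERENCE_TRANSPORT, "sasQ": 0.0, "cf_ppa": 1.0},
        sasQ_abs=1.0,
        V_BSC=5.24,
        CL_BSC=50.0,
    )
    plasma = PlasmaModel(n_compartments=2, CL=10.0, Vc=200.0, Q2=5.0, V2=400.0)
    return ModelSpec(
        structure=Structure.PK31_BSC,
        physiology=default_rat_physiology(),
        drug=drug,
        transport=transport,
        plasma=plasma,
    )


def surface_compartment_example_design(noise_cv: float = 0.10) -> StudyDesign:
    return StudyDesign(
        drug="morphine-like",
        noise_cv=noise_cv,
        arms=[
            DesignArm(
                arm_id="icv",
                route=Route.ICV,
                amount=1e5,
                amount_unit="ng",
                volume_uL=12.5,
                compartments=["cm", "sas"],
                times=list(REFERENCE_TIMES),
            )
        ],
    )


def periventricular_example_spec() -> ModelSpec:
    """Acetaminophen-like example of the periventricular-clearance variant.

    High paracellular permeability makes choroid-plexus blood flow
    rate-limiting; the added ventricle↔microvessel clearance supplies the
    extra elimination pathway.  cf_ppa is fixed at 1 in this variant.
    """
    drug = DrugProperties(
        name="acetaminophen-like",
        MW=151.2,
        pKa_acid=9.5,
        logP=0.5,
        fu_plasma=0.85,
        CL_BBB_trans=5.0,
        CL_BBB_para=10.0,
        CL_BCSFB_trans=5.0,
        CL_BCSFB_para=10.0,
    )
    transport = CSFTransportParams(
        **{**REFERENCE_TRANSPORT, "sasQ": 5.0, "cf_ppa": 1.0}, CL_pv=30.0
    )
    plasma = PlasmaModel(
        n_compartments=1,
        CL=15.0,
        Vc=250.0,
        iiv_omega2={"CL": 0.04, "Vc": 0.04},
        ruv=RUV(type="proportional", sigma2_prop=0.01),
    )
    return ModelSpec(
        structure=Structure.PK31_PV,
        physiology=default_rat_physiology(),
        drug=drug,
        transport=transport,
        plasma=plasma,
    )


def periventricular_example_design(noise_cv: float = 0.10) -> StudyDesign:
    return StudyDesign(
        drug="acetaminophen-like",
        noise_cv=noise_cv,
        arms=[
            DesignArm(
                arm_id="icv",
                route=Route.ICV,
                amount=1e5,
                amount_unit="ng",
                volume_uL=10.0,
                compartments=["cm", "plasma"],
                times=list(REFERENCE_TIMES),
            )
        ],
    )


def design_registry() -> dict[str, tuple[ModelSpec, StudyDesign]]:
    """Shipped (model spec, study design) pairs, one per structure in use."""
    return {
        "sucrose": (sucrose_reference_spec(), sucrose_reference_design()),
        "inulin": (inulin_reference_spec(), inulin_reference_design()),
        "surface_compartment_example": (
            surface_compartment_example_spec(),
            surface_compartment_example_design(),
        ),
        "periventricular_example": (
            periventricular_example_spec(),
            periventricular_example_design(),
        ),
    }
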