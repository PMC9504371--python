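"""Anatomical and physiological constants of the rat CNS, and drug input parameters.

Unit conventions used throughout the package:

* amounts: dose-units (dpm for radiotracers, ng otherwise)
* volumes: microlitres (µL) — plasma-model volumes are entered in mL and
  converted once at model-assembly time
* time: minutes
* flows and clearances: µL/min
* concentrations: dose-units/mL
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

ML_PER_UL = 1e-3
UL_PER_ML = 1e3


class RatCNSPhysiology(BaseModel):
    """Drug-independent anatomy of the 250 g rat CNS.

    Ventricular volumes are small relative to typical intra-CSF dosing
    volumes, which is why dose apportionment (overflow into downstream
    compartments) matters.  The two lateral ventricles are lumped into a
    single CSF compartment for the dynamics; ``V_LV_single`` is used only by
    the dosing overflow rule, which fills one (the injected) ventricle.

    Fields whose ``provenance`` entry reads ``companion-publication/derived``
    or ``implementer-chosen`` are not primary measurements of this package
    and may be overridden from config.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    body_weight: float = Field(250.0, gt=0, description="g")
    V_LV_single: float = Field(3.75, gt=0, description="µL, one lateral ventricle")
    n_LV: int = Field(2, gt=0)
    V_TFV: float = Field(7.5, gt=0, description="µL, third+fourth ventricles")
    V_CM: float = Field(17.0, gt=0, description="µL, cisterna magna")
    V_SAS: float = Field(218.0, gt=0, description="µL, subarachnoid space")
    V_ECF: float = Field(290.0, gt=0, description="µL, brain extracellular fluid")
    V_brain: float = Field(1.8, gt=0, description="mL, whole brain")
    V_MV: float = Field(54.0, gt=0, description="µL, brain microvessel blood")
    CP_mass: float = Field(4.0, gt=0, description="mg, choroid plexus")
    CP_blood_vol_density: float = Field(196.0, gt=0, description="µL/g tissue")
    CP_blood_flow_density: float = Field(4.0, gt=0, description="mL/min/g tissue")
    Q_CSF_legacy: float = Field(2.2, gt=0, description="µL/min, unidirectional CSF flow")
    Q_cerebral_blood: float = Field(1200.0, gt=0, description="µL/min")
    provenance: dict[str, str] = Field(
        default_factory=lambda: {
            "V_LV_single": "reported",
            "V_TFV": "derived: 2·V_LV_single + V_TFV + V_CM = 32 µL",
            "V_CM": "reported",
            "V_SAS": "implementer-chosen",
            "V_ECF": "companion-publication/derived",
            "V_MV": "companion-publication/derived",
            "V_brain": "reported",
            "CP_mass": "reported",
            "CP_blood_vol_density": "reported",
            "CP_blood_flow_density": "reported",
            "Q_CSF_legacy": "reported",
            "Q_cerebral_blood": "companion-publication/derived",
        }
    )

    @property
    def V_LV_lumped(self) -> float:
        """Volume (µL) of the lumped lateral-ventricle compartment."""
        return self.n_LV * self.V_LV_single

    @property
    def ventricular_cm_volume(self) -> float:
        """Summed volume (µL) of lateral ventricles, TFV and CM."""
        return self.n_LV * self.V_LV_single + self.V_TFV + self.V_CM

    @property
    def total_csf_volume(self) -> float:
        return self.ventricular_cm_volume + self.V_SAS


class DrugProperties(BaseModel):
    """Physicochemical and disposition inputs of one molecule.

    Passive barrier clearances are inputs, not derived from structure; the
    paracellular components are the ones scaled by the correction factor
    ``cf_ppa`` of the transport-parameter set.  The unbound fraction in CSF
    is 1 unless explicitly overridden.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    MW: float = Field(..., gt=0, description="Da")
    pKa_acid: Optional[float] = None
    pKb_base: Optional[float] = None
    logP: float = 0.0
    fu_plasma: float = Field(1.0, gt=0, le=1.0)
    fu_CSF: float = Field(1.0, gt=0, le=1.0)
    Kpuu_ECF: Optional[float] = Field(None, gt=0)
    Kpuu_CSF: Optional[float] = Field(None, gt=0)
    CL_BBB_trans: float = Field(0.0, ge=0, description="µL/min")
    CL_BBB_para: float = Field(0.0, ge=0, description="µL/min")
    CL_BCSFB_trans: float = Field(0.0, ge=0, description="µL/min")
    CL_BCSFB_para: float = Field(0.0, ge=0, description="µL/min")


class CPMicrovessel(BaseModel):
    """Choroid-plexus microvessel compartment: the local blood space feeding
    the blood–CSF barrier."""

    model_config = ConfigDict(extra="forbid")

    V_CPMV: float = Field(..., gt=0, description="µL")
    Q_CP: float = Field(..., gt=0, description="µL/min")


def default_rat_physiology(**overrides) -> RatCNSPhysiology:
    """Default physiology of the healthy 250 g rat.

    The printed constraint that lateral ventricles + TFV + CM sum to 32 µL
    fixes V_TFV at 7.5 µL given two 3.75 µL lateral ventricles and a 17 µL
    cisterna magna.
    """
    phys = RatCNSPhysiology(**overrides)
    return phys


def derive_cp_microvessel(phys: RatCNSPhysiology) -> CPMicrovessel:
    """Derive the choroid-plexus microvessel volume and blood flow.

    V_CPMV = CP mass × blood volume density; Q_CP = CP mass × blood flow
    density, reconciled to µL and µL/min (CP mass is entered in mg, the
    densities per g tissue).
    """
    mass_g = phys.CP_mass * 1e-3
    v = mass_g * phys.CP_blood_vol_density  # µL
    q = mass_g * phys.CP_blood_flow_density * UL_PER_ML  # mL/min → µL/min
    return CPMicrovessel(V_CPMV=v, Q_CP=q)


#: Default aqueous-diffusivity power law D = a·MW^(−b) in cm²/min.  The
#: coefficients are configuration (they calibrate the optional paracellular
#: permeability helper), not assertions of this package.
DEFAULT_DIFFUSIVITY_COEFFS = (5.94e-3, 0.453)

#: The diffusivity–MW correlation is only validated up to 5000 Da; large
#: molecules (proteins, oligonucleotides) are out of this model's scope.
MW_DIFFUSIVITY_LIMIT = 5000.0


def aqueous_diffusivity(
    MW: float, coeffs: tuple[float, float] = DEFAULT_DIFFUSIVITY_COEFFS
) -> float:
    """Aqueous diffusivity (cm²/min) from molar mass via a power law.

    Raises ``ValueError`` above the 5000 Da validity limit of the
    correlation.
    """
    if MW <= 0:
        raise ValueError("MW must be positive")
    if MW > MW_DIFFUSIVITY_LIMIT:
        raise ValueError(
            f"MW {MW} Da exceeds the 5000 Da upper limit of the "
            "aqueous-diffusivity correlation"
        )
    a, b = coeffs
    return a * MW ** (-b)
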