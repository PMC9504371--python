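"""Administration events and their translation into model initial conditions.

Intra-CSF injection volumes typically exceed the physiological volume of the
injection site, so the dosing solution overflows downstream (never upstream)
along the CSF axis at the end of administration: an intracerebroventricular
(ICV) dose first fills the injected lateral ventricle (3.75 µL), the
remainder cascades to the third/fourth ventricle, then cisterna magna, then
subarachnoid space; an intracisternal (IC) dose fills the cisterna magna
(17 µL) with the remainder reaching the subarachnoid space; an intrathecal
(IT) dose deposits entirely in the subarachnoid space.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .physiology import RatCNSPhysiology

#: Assumed ICV dosing volume when an arm does not report one: the midpoint
#: of the 10–15 µL range used by the other ICV studies.
DEFAULT_ICV_VOLUME_UL = 12.5


class Route(str, Enum):
    IV = "IV"
    ICV = "ICV"
    IC = "IC"
    IT = "IT"


INTRA_CSF_ROUTES = {Route.ICV, Route.IC, Route.IT}


class DoseEvent(BaseModel):
    """One administration: route, amount, solution volume and timing.

    ``duration == 0`` means instantaneous administration (the default; dosing
    is fast relative to the sampling timescale).
    """

    model_config = ConfigDict(extra="forbid")

    route: Route
    amount: float = Field(..., gt=0, description="dose-units")
    solution_volume: Optional[float] = Field(None, description="µL, intra-CSF routes")
    time: float = Field(0.0, ge=0, description="min")
    duration: float = Field(0.0, ge=0, description="min; 0 = instantaneous")

    @model_validator(mode="after")
    def _fill_volume(self) -> "DoseEvent":
        if self.route in INTRA_CSF_ROUTES:
            if self.solution_volume is None:
                if self.route is Route.ICV:
                    object.__setattr__(self, "solution_volume", DEFAULT_ICV_VOLUME_UL)
                else:
                    raise ValueError(f"{self.route.value} dose requires solution_volume")
            if self.solution_volume <= 0:
                raise ValueError("solution_volume must be positive for intra-CSF routes")
        return self


class DoseApportionment(BaseModel):
    """Volume fractions of the dosing solution reaching each compartment."""

    model_config = ConfigDict(extra="forbid")

    fractions: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "DoseApportionment":
        vals = np.array(list(self.fractions.values()))
        if (vals < -1e-12).any():
            raise ValueError("negative apportionment fraction")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("apportionment fractions must sum to 1")
        return self


def apportion_dose(event: DoseEvent, phys: RatCNSPhysiology) -> DoseApportionment:
    """Apportion an administration among compartments by the overflow rule.

    The solution fills the injection site up to its physiological volume and
    the excess cascades strictly downstream (ICV: injected LV → TFV → CM →
    SAS; IC: CM → SAS; IT: SAS).  No upward transfer of dosing solution is
    assumed.  IV doses go entirely to the plasma central compartment.
    """
    if event.route is Route.IV:
        return DoseApportionment(fractions={"plasma": 1.0})

    vol = float(event.solution_volume)
    if event.route is Route.ICV:
        chain = [
            ("lv", phys.V_LV_single),  # the injected ventricle only
            ("tfv", phys.V_TFV),
            ("cm", phys.V_CM),
            ("sas", phys.V_SAS),
        ]
    elif event.route is Route.IC:
        chain = [("cm", phys.V_CM), ("sas", phys.V_SAS)]
    else:  # IT
        chain = [("sas", phys.V_SAS)]

    if vol > sum(v for _, v in chain):
        raise ValueError(
            f"dosing volume {vol} µL exceeds the downstream CSF space "
            f"({sum(v for _, v in chain)} µL) for route {event.route.value}"
        )

    fractions: dict[str, float] = {}
    remaining = vol
    for name, cap in chain:
        placed = min(remaining, cap)
        if placed > 0:
            fractions[name] = placed / vol
        remaining -= placed
        if remaining <= 0:
            break
    return DoseApportionment(fractions=fractions)


def apportioned_volumes(event: DoseEvent, phys: RatCNSPhysiology) -> dict[str, float]:
    """Volumes (µL) of dosing solution reaching each compartment."""
    app = apportion_dose(event, phys)
    return {k: f * float(event.solution_volume) for k, f in app.fractions.items()}


def initial_state(
    events: Iterable[DoseEvent],
    phys: RatCNSPhysiology,
    index: dict[str, int],
    n_states: int,
) -> np.ndarray:
    """Initial amount vector from instantaneous dose events at t = 0.

    Each event's amount is split by its apportionment; stacked events
    superpose (the model is linear).
    """
    x0 = np.zeros(n_states)
    for ev in events:
        if ev.duration > 0 or ev.time > 0:
            continue  # handled as an input function by the simulator
        app = apportion_dose(ev, phys)
        for comp, frac in app.fractions.items():
            x0[index[comp]] += ev.amount * frac
    return x0


def normalize_radioactivity(
    profile: Sequence[float] | np.ndarray,
    dose_conc: float,
    cm_end_value: float,
) -> np.ndarray:
    """Convert counted radioactivity (cpm/g) to dpm/mL.

    Anchored on the assumption that the cisterna-magna concentration at the
    end of administration equals the dosing-solution concentration (valid
    when the injected volume fills the compartment), with CSF/plasma density
    taken as 1 g/mL so per-gram equals per-mL.  Every value is scaled by
    ``dose_conc / cm_end_value``, preserving all concentration ratios.
    """
    if cm_end_value <= 0:
        raise ValueError("cm_end_value anchor must be positive")
    if dose_conc <= 0:
        raise ValueError("dose_conc must be positive")
    return np.asarray(profile, dtype=float) * (dose_conc / cm_end_value)
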