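"""Observation datasets: dosing arms with tabular concentration data.

This is the currency of fitting: each arm couples one dose event with a
table of (time, compartment, concentration) observations, all in one
concentration unit per arm.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dosing import DoseEvent

#: Fixed compartment name set observations may refer to.
COMPARTMENT_NAMES = (
    "plasma",
    "mv",
    "cpmv",
    "ecf",
    "lv",
    "tfv",
    "cm",
    "sas",
    "bsc",
)


class Arm(BaseModel):
    """One dosing arm: a dose event plus its observation table."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    arm_id: str
    dose: DoseEvent
    observations: pd.DataFrame  # columns: time_min, compartment, conc, conc_unit

    @model_validator(mode="after")
    def _check(self) -> "Arm":
        obs = self.observations
        required = {"time_min", "compartment", "conc", "conc_unit"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"arm {self.arm_id}: missing observation columns {sorted(missing)}")
        if len(obs) == 0:
            raise ValueError(f"arm {self.arm_id}: empty observations")
        bad = set(obs["compartment"]) - set(COMPARTMENT_NAMES)
        if bad:
            raise ValueError(f"arm {self.arm_id}: unknown compartment names {sorted(bad)}")
        if (np.asarray(obs["conc"], dtype=float) <= 0).any():
            raise ValueError(
                f"arm {self.arm_id}: non-positive concentrations are not representable "
                "under log-residual fitting"
            )
        if obs["conc_unit"].nunique() != 1:
            raise ValueError(f"arm {self.arm_id}: mixed concentration units within one arm")
        return self

    @property
    def conc_unit(self) -> str:
        return str(self.observations["conc_unit"].iloc[0])


class ObservationDataset(BaseModel):
    """A drug's dosing arms and their observations."""

    model_config = ConfigDict(extra="forbid")

    drug: str
    arms: list[Arm] = Field(min_length=1)

    def arm(self, arm_id: str) -> Arm:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(f"no arm {arm_id!r} in dataset {self.drug!r}")

    @property
    def n_obs(self) -> int:
        return int(sum(len(a.observations) for a in self.arms))
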