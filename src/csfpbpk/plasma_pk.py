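"""Empirical mammillary plasma PK models (1–3 compartments) for unbound drug.

These serve double duty: as forcing inputs of the CNS model (the plasma
central compartment exchanges mass with the CNS in both directions) and as
fittable models when only IV concentration–time data are available.
Inter-individual variability (IIV) enters as exponential random effects on
clearance and central volume; residual unexplained variability (RUV) as a
proportional or combined error model — both used only for prediction-interval
simulation, not estimation (the fitted data are mean profiles).
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import qmc

from .datasets import ObservationDataset
from .dosing import Route


class RUV(BaseModel):
    model_config = ConfigDict(extra="forbid")

    type: Literal["proportional", "combined"] = "proportional"
    sigma2_prop: float = Field(0.0, ge=0)
    sigma2_add: float = Field(0.0, ge=0)


class PlasmaModel(BaseModel):
    """Mammillary IV plasma model with parameters in mL and mL/min."""

    model_config = ConfigDict(extra="forbid")

    n_compartments: Literal[1, 2, 3] = 1
    CL: float = Field(..., gt=0, description="mL/min")
    Vc: float = Field(..., gt=0, description="mL")
    Q2: Optional[float] = Field(None, gt=0, description="mL/min")
    V2: Optional[float] = Field(None, gt=0, description="mL")
    Q3: Optional[float] = Field(None, gt=0, description="mL/min")
    V3: Optional[float] = Field(None, gt=0, description="mL")
    iiv_omega2: dict[str, float] = Field(default_factory=dict)  # keys: CL, Vc
    ruv: RUV = Field(default_factory=RUV)

    @model_validator(mode="after")
    def _check(self) -> "PlasmaModel":
        if self.n_compartments >= 2 and (self.Q2 is None or self.V2 is None):
            raise ValueError("2-compartment model requires Q2 and V2")
        if self.n_compartments == 3 and (self.Q3 is None or self.V3 is None):
            raise ValueError("3-compartment model requires Q3 and V3")
        for k, v in self.iiv_omega2.items():
            if k not in ("CL", "Vc"):
                raise ValueError(f"IIV supported on CL and Vc only, got {k!r}")
            if v < 0:
                raise ValueError("IIV variance must be non-negative")
        return self

    def rate_matrix(self) -> np.ndarray:
        """Micro-rate-constant matrix (1/min) acting on amounts, central first."""
        n = self.n_compartments
        A = np.zeros((n, n))
        A[0, 0] -= self.CL / self.Vc
        if n >= 2:
            A[0, 0] -= self.Q2 / self.Vc
            A[1, 0] += self.Q2 / self.Vc
            A[0, 1] += self.Q2 / self.V2
            A[1, 1] -= self.Q2 / self.V2
        if n == 3:
            A[0, 0] -= self.Q3 / self.Vc
            A[2, 0] += self.Q3 / self.Vc
            A[0, 2] += self.Q3 / self.V3
            A[2, 2] -= self.Q3 / self.V3
        return A


def plasma_concentration(
    model: PlasmaModel, dose: float, times: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Unbound plasma concentration (dose-units/mL) after an IV bolus."""
    times = np.asarray(times, dtype=float)
    A = model.rate_matrix()
    x0 = np.zeros(model.n_compartments)
    x0[0] = dose
    out = np.empty(times.shape)
    for i, t in enumerate(times):
        out[i] = (expm(A * t) @ x0)[0] / model.Vc
    return out


_PARAM_NAMES = {1: ["CL", "Vc"], 2: ["CL", "Vc", "Q2", "V2"], 3: ["CL", "Vc", "Q2", "V2", "Q3", "V3"]}


def _model_from_vector(n: int, logx: np.ndarray) -> PlasmaModel:
    vals = dict(zip(_PARAM_NAMES[n], 10.0 ** logx))
    return PlasmaModel(n_compartments=n, **vals)


def _canonicalize(model: PlasmaModel) -> PlasmaModel:
    """Order peripheral compartments by volume (they are exchangeable labels)."""
    if model.n_compartments == 3 and model.V2 > model.V3:
        return model.model_copy(
            update={"Q2": model.Q3, "V2": model.V3, "Q3": model.Q2, "V3": model.V2}
        )
    return model


def fit_plasma(
    iv_dataset: ObservationDataset,
    n_starts: int = 16,
    seed: int = 0,
    candidates: Sequence[int] = (1, 2, 3),
    tie_tol: float = 1e-3,
) -> PlasmaModel:
    """Fit 1/2/3-compartment candidates to IV plasma data; pick the best.

    Naive pooled least squares on log10 concentrations, multi-start from a
    seeded latin-hypercube around data-informed scales.  The lowest-objective
    candidate wins; within ``tie_tol`` of objective the model with fewer
    compartments is preferred.
    """
    times, concs, doses = [], [], []
    for arm in iv_dataset.arms:
        if arm.dose.route is not Route.IV:
            continue
        obs = arm.observations
        mask = obs["compartment"] == "plasma"
        times.append(np.asarray(obs.loc[mask, "time_min"], dtype=float))
        concs.append(np.asarray(obs.loc[mask, "conc"], dtype=float))
        doses.append(np.full(mask.sum(), arm.dose.amount))
    if not times:
        raise ValueError("dataset has no IV plasma observations")
    t = np.concatenate(times)
    c = np.concatenate(concs)
    d = np.concatenate(doses)
    if len(t) < 4:
        raise ValueError("need at least 4 plasma observations to fit")

    # data-informed scales: Vc ~ dose / Cmax, CL ~ dose / AUC
    dose0 = d[0]
    vc0 = dose0 / c.max()
    order = np.argsort(t)
    auc = np.trapezoid(c[order], t[order])
    cl0 = dose0 / max(auc, 1e-12)
    center = {"CL": cl0, "Vc": vc0, "Q2": cl0, "V2": vc0, "Q3": cl0, "V3": vc0}

    best: Optional[tuple[float, PlasmaModel]] = None
    selected: Optional[PlasmaModel] = None
    best_obj_by_n: dict[int, float] = {}
    rng = np.random.default_rng(seed)
    for n in candidates:
        names = _PARAM_NAMES[n]
        lo = np.array([np.log10(center[p]) - 1.5 for p in names])
        hi = np.array([np.log10(center[p]) + 1.5 for p in names])
        sampler = qmc.LatinHypercube(d=len(names), seed=rng.integers(2**31 - 1))
        starts = qmc.scale(sampler.random(n_starts), lo, hi)
        starts = np.vstack([np.log10([center[p] for p in names]), starts])

        def resid(logx: np.ndarray) -> np.ndarray:
            try:
                m = _model_from_vector(n, logx)
            except Exception:
                return np.full(len(t), 1e3)
            pred = np.empty(len(t))
            for dose in np.unique(d):
                mask = d == dose
                pred[mask] = plasma_concentration(m, dose, t[mask])
            pred = np.clip(pred, 1e-300, None)
            return np.log10(pred) - np.log10(c)

        best_n: Optional[tuple[float, np.ndarray]] = None
        for x0 in starts:
            try:
                res = least_squares(resid, x0, bounds=(lo - 2, hi + 2), method="trf", max_nfev=300)
            except Exception:
                continue
            if best_n is None or res.cost < best_n[0]:
                best_n = (res.cost, res.x)
        if best_n is None:
            continue
        obj = 2 * best_n[0]  # SSR
        best_obj_by_n[n] = obj
        m = _canonicalize(_model_from_vector(n, best_n[1]))
        if best is None or obj < best[0] - tie_tol:
            best = (obj, m)
            selected = m
    if selected is None:
        raise RuntimeError("no plasma model candidate converged")
    return selected


def sample_individual(model: PlasmaModel, rng: np.random.Generator) -> PlasmaModel:
    """Draw one individual from exponential IIV on CL and Vc."""
    updates = {}
    for name in ("CL", "Vc"):
        omega2 = model.iiv_omega2.get(name, 0.0)
        eta = rng.normal(0.0, np.sqrt(omega2)) if omega2 > 0 else 0.0
        updates[name] = getattr(model, name) * np.exp(eta)
    return model.model_copy(update=updates)


def apply_ruv(
    conc: np.ndarray | Sequence[float],
    ruv: RUV,
    rng: np.random.Generator,
    lloq: float = 0.0,
) -> np.ndarray:
    """Apply the residual-error model to noiseless concentrations.

    proportional: y = c·(1 + ε₁);  combined: y = c·(1 + ε₁) + ε₂ with
    ε ~ Normal(0, σ²).  Results below ``lloq`` are floored there.
    """
    c = np.asarray(conc, dtype=float)
    eps1 = (
        rng.normal(0.0, np.sqrt(ruv.sigma2_prop), size=c.shape)
        if ruv.sigma2_prop > 0
        else np.zeros(c.shape)
    )
    y = c * (1.0 + eps1)
    if ruv.type == "combined" and ruv.sigma2_add > 0:
        y = y + rng.normal(0.0, np.sqrt(ruv.sigma2_add), size=c.shape)
    return np.maximum(y, lloq)
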