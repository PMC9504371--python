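"""Estimation of CSF transport parameters from concentration–time data.

The headline estimation problem is the joint fit of the five transport
parameters — venQ_D, cisQ_D, the U/D ratio, sasQ and the paracellular
correction factor — to flow-marker (sucrose-like) data from two arms at
once: an intracerebroventricular arm observed in cisterna magna and
subarachnoid space, and an intracisternal arm observed in cisterna magna and
plasma.  Fitting is naive-pooled least squares on log10 concentrations
(the datasets this emulates are digitized mean profiles; no subject-level
data exist), globalized by a seeded latin-hypercube multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .datasets import Arm, ObservationDataset
from .model_core import ModelSpec, Structure, build_model
from .simulate import simulate

#: Estimation bounds, µL/min for flows/clearances (V_BSC in mL).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "venQ_D": (1e-4, 50.0),
    "cisQ_D": (1e-4, 50.0),
    "ud_ratio": (0.0, 10.0),
    "sasQ": (-20.0, 50.0),
    "cf_ppa": (1e-4, 1.5),
    "V_BSC": (1e-3, 50.0),
    "CL_BSC": (1e-4, 500.0),
    "CL_pv": (1e-4, 500.0),
}

SUCROSE_PARAMS = ("venQ_D", "cisQ_D", "ud_ratio", "sasQ", "cf_ppa")

#: Allowed drug-dependent free-parameter sets per structure.
FREE_SETS: dict[Structure, frozenset[str]] = {
    Structure.PK31: frozenset({"sasQ", "cf_ppa"}),
    Structure.PK31_BSC: frozenset({"V_BSC", "CL_BSC"}),
    Structure.PK31_PV: frozenset({"CL_pv", "sasQ"}),
}


@dataclass
class FitResult:
    """Point estimates, uncertainty and diagnostics of one fit."""

    estimates: dict[str, float]
    se: Optional[dict[str, float]]
    objective: float  # sum of squared log10 residuals
    converged: bool
    n_obs: int
    residuals: pd.DataFrame
    n_starts: int = 0
    fixed: dict[str, float] = field(default_factory=dict)


def _apply_params(template: ModelSpec, values: dict[str, float]) -> ModelSpec:
    transport = template.transport.model_copy(update=values)
    return template.model_copy(update={"transport": transport})


def _predict(spec: ModelSpec, arm: Arm) -> np.ndarray:
    obs = arm.observations
    t = np.asarray(obs["time_min"], dtype=float)
    grid = np.unique(t)
    res = simulate(spec, [arm.dose], grid, method="expm")
    pos = {v: i for i, v in enumerate(grid)}
    pred = np.empty(len(obs))
    for k, (ti, comp) in enumerate(zip(t, obs["compartment"])):
        pred[k] = res.conc[pos[ti], res.model.index[comp]]
    return pred


def _pooled_residuals(spec: ModelSpec, arms: Sequence[Arm]) -> np.ndarray:
    parts = []
    for arm in arms:
        pred = np.clip(_predict(spec, arm), 1e-300, None)
        obs = np.asarray(arm.observations["conc"], dtype=float)
        parts.append(np.log10(pred) - np.log10(obs))
    return np.concatenate(parts)


def fit_transport(
    arms: Sequence[Arm],
    template: ModelSpec,
    free: Sequence[str],
    fixed: Optional[dict[str, float]] = None,
    n_starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Multi-start least-squares fit of transport parameters to pooled arms.

    ``free`` names the estimated parameters; ``fixed`` pins others (on top of
    the template's values).  Starts are drawn from a seeded latin hypercube
    over the parameter bounds, plus the template's own values when inside
    the bounds.
    """
    fixed = dict(fixed or {})
    free = list(free)
    unknown = [p for p in free if p not in PARAM_BOUNDS]
    if unknown:
        raise ValueError(f"unknown fit parameters {unknown}")
    lo = np.array([PARAM_BOUNDS[p][0] for p in free])
    hi = np.array([PARAM_BOUNDS[p][1] for p in free])

    base = _apply_params(template, fixed)

    def residuals(x: np.ndarray) -> np.ndarray:
        spec = _apply_params(base, dict(zip(free, x)))
        return _pooled_residuals(spec, arms)

    starts: list[np.ndarray] = []
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        starts = list(qmc.scale(sampler.random(n_starts), lo, hi))
    x_template = np.array([getattr(template.transport, p) or 0.0 for p in free])
    if np.all((x_template >= lo) & (x_template <= hi)):
        starts.insert(0, x_template)

    best = None
    any_converged = False
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        any_converged = any_converged or res.status > 0
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not any_converged:
        raise RuntimeError(
            "no start converged; best objective "
            f"{None if best is None else 2 * best.cost}"
        )

    estimates = dict(zip(free, best.x.tolist()))
    n_obs = sum(len(a.observations) for a in arms)
    ssr = float(2 * best.cost)
    dof = max(n_obs - len(free), 1)
    se = None
    try:
        J = best.jac
        cov = (ssr / dof) * np.linalg.pinv(J.T @ J)
        diag = np.diag(cov)
        if np.all(diag >= 0):
            se = dict(zip(free, np.sqrt(diag).tolist()))
    except Exception:
        se = None

    spec_hat = _apply_params(base, estimates)
    rows = []
    for arm in arms:
        pred = _predict(spec_hat, arm)
        obs = arm.observations
        rows.append(
            pd.DataFrame(
                {
                    "arm_id": arm.arm_id,
                    "time_min": obs["time_min"].to_numpy(),
                    "compartment": obs["compartment"].to_numpy(),
                    "observed": obs["conc"].to_numpy(),
                    "predicted": pred,
                    "log10_residual": np.log10(np.clip(pred, 1e-300, None))
                    - np.log10(obs["conc"].to_numpy(dtype=float)),
                }
            )
        )
    return FitResult(
        estimates=estimates,
        se=se,
        objective=ssr,
        converged=True,
        n_obs=n_obs,
        residuals=pd.concat(rows, ignore_index=True),
        n_starts=len(starts),
        fixed=fixed,
    )


def fit_sucrose_joint(
    icv_arm: ObservationDataset,
    ic_arm: ObservationDataset,
    template: ModelSpec,
    n_starts: int = 16,
    seed: int = 0,
    fixed: Optional[dict[str, float]] = None,
) -> FitResult:
    """Jointly estimate the five CSF transport parameters from flow-marker data.

    The ICV arm must carry cisterna-magna and subarachnoid-space
    observations, the IC arm cisterna-magna and plasma observations; the two
    are fit simultaneously.  Asymmetry factors must be 1 (a flow marker has
    no transport asymmetry).  ``fixed`` can pin a subset (e.g. ``ud_ratio=0``
    to force a unidirectional structure for comparison).
    """
    afs = template.afs
    if any(
        getattr(afs, f) != 1.0
        for f in ("af_bbb_in", "af_bbb_out", "af_bcsfb_in", "af_bcsfb_out")
    ):
        raise ValueError("flow-marker fitting requires all asymmetry factors fixed at 1")
    icv_comps = set()
    for a in icv_arm.arms:
        icv_comps |= set(a.observations["compartment"])
    ic_comps = set()
    for a in ic_arm.arms:
        ic_comps |= set(a.observations["compartment"])
    if not {"cm", "sas"} <= icv_comps:
        raise ValueError("ICV arm must observe cm and sas")
    if not {"cm", "plasma"} <= ic_comps:
        raise ValueError("IC arm must observe cm and plasma")
    fixed = dict(fixed or {})
    free = [p for p in SUCROSE_PARAMS if p not in fixed]
    arms = list(icv_arm.arms) + list(ic_arm.arms)
    return fit_transport(arms, template, free, fixed=fixed, n_starts=n_starts, seed=seed)


def fit_drug(
    dataset: ObservationDataset,
    fixed: dict[str, float],
    template: ModelSpec,
    free: Sequence[str],
    n_starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Estimate the drug-dependent parameters with physiology-level rates fixed.

    ``fixed`` must supply the three drug-independent CSF movement parameters
    (venQ_D, cisQ_D, ud_ratio); ``free`` must match the structure: {sasQ,
    cf_ppa} for the base structure, {V_BSC, CL_BSC} for the surface-compartment
    variant (exchange flow and passive absorption fixed), {CL_pv, sasQ} for
    the periventricular variant (cf_ppa fixed at 1).
    """
    required = {"venQ_D", "cisQ_D", "ud_ratio"}
    missing = required - set(fixed)
    if missing:
        raise ValueError(f"fixed must supply drug-independent parameters {sorted(missing)}")
    allowed = FREE_SETS.get(template.structure)
    if allowed is None:
        raise ValueError(f"fit_drug does not support structure {template.structure}")
    if not set(free) <= allowed:
        raise ValueError(
            f"free parameters {sorted(set(free) - allowed)} are inconsistent with "
            f"structure {template.structure.value} (allowed: {sorted(allowed)})"
        )
    return fit_transport(
        list(dataset.arms), template, list(free), fixed=fixed, n_starts=n_starts, seed=seed
    )
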