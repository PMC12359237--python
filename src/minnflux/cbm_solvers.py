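"""Linear- and quadratic-programming services over metabolic models.

Thin, typed wrappers around cobra/optlang for flux balance analysis (FBA),
parsimonious FBA and flux variability analysis, plus the quadratic projection
of measured fluxes onto the FBA solution space ("FBA fit"): isotope-derived
flux measurements generally lie outside the solution space of a full
genome-scale model, and the nearest feasible flux distribution in Euclidean
distance provides a mechanically consistent surrogate reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import cobra
from cobra.flux_analysis import flux_variability_analysis as _cobra_fva
from cobra.flux_analysis import pfba as _cobra_pfba
from cobra.exceptions import Infeasible, OptimizationError
from scipy.optimize import Bounds, LinearConstraint, minimize

from .gem_toolkit import (
    InfeasibleModelError,
    ProjectionMatrix,
    stoichiometric_matrix,
)

__all__ = [
    "FluxVector",
    "solve_fba",
    "solve_pfba",
    "run_fva",
    "fit_to_solution_space",
]

#: maximum tolerated steady-state violation ||S v||_inf of a reported solution
STEADY_STATE_TOL = 1e-6


@dataclass
class FluxVector:
    """A named flux assignment over a model's reactions (mmol gDW^-1 h^-1).

    ``status`` is ``optimal`` for solver optima, ``feasible`` for
    constraint-satisfying non-optimal vectors, ``infeasible`` when no vector
    exists (``fluxes`` is then empty).
    """

    fluxes: pd.Series
    model_id: str
    status: str = "optimal"
    objective_value: float | None = None

    @property
    def values(self) -> np.ndarray:
        return self.fluxes.to_numpy(dtype=float)

    def total_flux(self) -> float:
        return float(self.fluxes.abs().sum())


def _apply_overrides(model: cobra.Model, overrides) -> None:
    for rid, (lb, ub) in (overrides or {}).items():
        model.reactions.get_by_id(rid).bounds = (lb, ub)


def solve_fba(model: cobra.Model, overrides=None) -> FluxVector:
    """Maximize the model objective subject to S v = 0 and flux bounds.

    ``overrides`` maps reaction ids to temporary ``(lb, ub)`` pairs applied
    for this solve only. An infeasible problem yields a FluxVector with
    ``status='infeasible'`` and no fluxes.
    """
    import warnings

    with model, warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Solver status is")
        _apply_overrides(model, overrides)
        sol = model.optimize(raise_error=False)
        if sol.status != "optimal":
            return FluxVector(pd.Series(dtype=float), model.id, "infeasible", None)
        return FluxVector(sol.fluxes.copy(), model.id, "optimal", sol.objective_value)


def solve_pfba(model: cobra.Model, overrides=None) -> FluxVector:
    """Parsimonious FBA: among objective optima, minimize the total flux.

    Implemented as the standard two-stage program (fix the objective at its
    optimum, then minimize the sum of absolute fluxes; on a split model all
    fluxes are non-negative so this is the plain flux sum).
    """
    objective_ids = [r.id for r in model.reactions if r.objective_coefficient != 0]
    with model:
        _apply_overrides(model, overrides)
        try:
            sol = _cobra_pfba(model)
        except (Infeasible, OptimizationError):
            return FluxVector(pd.Series(dtype=float), model.id, "infeasible", None)
        growth = float(sum(sol.fluxes[rid] for rid in objective_ids))
        return FluxVector(sol.fluxes.copy(), model.id, "optimal", growth)


def run_fva(model: cobra.Model, fraction_of_optimum: float = 0.0) -> pd.DataFrame:
    """Per-reaction attainable [minimum, maximum] flux via 2n LPs."""
    if np.isnan(model.slim_optimize()):
        raise InfeasibleModelError(f"model {model.id!r} is infeasible")
    fva = _cobra_fva(model, fraction_of_optimum=fraction_of_optimum, processes=1)
    return fva[["minimum", "maximum"]]


def fit_to_solution_space(
    model: cobra.Model,
    pref: ProjectionMatrix,
    v_measured: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[FluxVector, float]:
    """Project measured fluxes onto the model's steady-state solution space.

    Solves the quadratic program

        min_v || W (P v - v_measured) ||_2^2
        s.t.  S v = 0,  lb <= v <= ub

    and returns the feasible flux vector together with the achieved
    (unweighted) Euclidean distance ``||P v - v_measured||_2``. ``weights``
    (optional, default uniform) can down-weight noisy measurements.
    """
    d = np.asarray(v_measured, dtype=float)
    if d.shape != (len(pref.target_ids),):
        raise ValueError(
            f"measured vector has shape {d.shape}, expected ({len(pref.target_ids)},)"
        )
    rids = [r.id for r in model.reactions]
    if pref.reaction_ids != rids:
        raise ValueError("projection matrix is not aligned to this model")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)

    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    P = pref.matrix
    Pw = P * w[:, None]
    dw = d * w
    H = 2.0 * Pw.T @ Pw

    start = solve_pfba(model)
    if start.status != "optimal":
        raise InfeasibleModelError(
            f"model {model.id!r} has no feasible starting point for the QP"
        )
    x0 = np.clip(start.values, lb, ub)

    def fun(v):
        r = Pw @ v - dw
        return float(r @ r)

    def jac(v):
        return 2.0 * Pw.T @ (Pw @ v - dw)

    res = minimize(
        fun,
        x0,
        jac=jac,
        hess=lambda v: H,
        method="trust-constr",
        bounds=Bounds(lb, ub),
        constraints=[LinearConstraint(S, 0.0, 0.0)],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000, "verbose": 0},
    )
    v = np.asarray(res.x)
    if np.max(np.abs(S @ v)) > STEADY_STATE_TOL or np.any(v < lb - 1e-6) or np.any(
        v > ub + 1e-6
    ):
        raise InfeasibleModelError(
            "QP projection did not return a feasible flux vector "
            f"(constraint violation {res.constr_violation:.2e})"
        )
    distance = float(np.linalg.norm(P @ v - d))
    flux = FluxVector(pd.Series(v, index=rids), model.id, "feasible", None)
    return flux, distance
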