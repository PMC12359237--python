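"""Preparation of genome-scale metabolic models (GEMs) for hybrid modeling.

A GEM enters the pipeline as an SBML file (Level 3 + FBC) and is transformed
into the *split* form the mechanistic layer consumes: every reversible
reaction is decomposed into a forward and a reverse reaction so that all
fluxes are non-negative. Two reduction strategies then shrink the model to
the subnetwork that can actually carry flux under the growth condition:

* flux-variability reduction — drop every reaction whose attainable flux
  range is indistinguishable from zero;
* FBA-sampling reduction — run many parsimonious-FBA simulations under random
  single-gene knockouts and varying glucose availability, and drop reactions
  that never carry flux in any of them.

Models are handled as :class:`cobra.Model` objects throughout; this module
adds the transformations and the projection matrices that link reactions of
the split model to measured quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import cobra
from cobra.flux_analysis import flux_variability_analysis
from cobra.io import read_sbml_model

logger = logging.getLogger("minnflux")

#: flux magnitudes at or below this value are treated as zero everywhere
#: (FVA spans, sampled-flux activity tests, feasibility checks).
FLUX_TOL = 1e-9

FWD_SUFFIX = "_fwd"
REV_SUFFIX = "_rev"

__all__ = [
    "FLUX_TOL",
    "FWD_SUFFIX",
    "REV_SUFFIX",
    "ProjectionMatrix",
    "load_sbml",
    "split_reversible",
    "fva_reduce",
    "fba_sample_reduce",
    "build_projection",
    "net_flux_targets",
    "input_projection",
    "stoichiometric_matrix",
]


class SBMLFormatError(ValueError):
    """Raised when an SBML file cannot be interpreted as a usable GEM."""


class InfeasibleModelError(RuntimeError):
    """Raised when an operation requires a feasible model but the LP is not."""


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_sbml(path: str) -> cobra.Model:
    """Read an SBML (Level 3 + FBC) file into a :class:`cobra.Model`.

    Raises
    ------
    SBMLFormatError
        If the file is not parseable SBML, or any reaction comes back without
        explicit finite-or-default bounds (no silent defaulting is accepted:
        a model whose bounds were invented by the reader is rejected).
    """
    try:
        model = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises CobraSBMLError / libsbml errors
        raise SBMLFormatError(f"cannot parse SBML file {path!r}: {exc}") from exc
    for rxn in model.reactions:
        if rxn.lower_bound is None or rxn.upper_bound is None:
            raise SBMLFormatError(
                f"reaction {rxn.id!r} in {path!r} has no flux bounds"
            )
        if rxn.lower_bound > rxn.upper_bound:
            raise SBMLFormatError(
                f"reaction {rxn.id!r} has lower bound above upper bound"
            )
    if not _objective_ids(model):
        raise SBMLFormatError(f"model {path!r} declares no objective reaction")
    return model


def _objective_ids(model: cobra.Model) -> list[str]:
    return [
        rxn.id for rxn in model.reactions if rxn.objective_coefficient != 0
    ]


# ---------------------------------------------------------------------------
# reversible splitting
# ---------------------------------------------------------------------------

def split_reversible(model: cobra.Model) -> cobra.Model:
    """Split every reversible reaction into a forward/reverse pair.

    A reaction with ``lower_bound < 0`` is replaced by ``<id>_fwd`` with
    bounds ``(0, max(ub, 0))`` and ``<id>_rev`` with the negated
    stoichiometry and bounds ``(0, -lb)``. Irreversible reactions are left
    untouched, so the operation is idempotent. In the split model every
    flux is non-negative; uptake through an exchange reaction appears as
    positive flux on its ``_rev`` member.
    """
    new = model.copy()
    objective_ids = _objective_ids(new)
    reverse_rxns = []
    for rxn in list(new.reactions):
        if rxn.lower_bound >= 0:
            continue
        lb, ub = rxn.lower_bound, rxn.upper_bound
        rev = cobra.Reaction(rxn.id + REV_SUFFIX, lower_bound=0.0, upper_bound=-lb)
        rev.add_metabolites({met: -coef for met, coef in rxn.metabolites.items()})
        rev.gene_reaction_rule = rxn.gene_reaction_rule
        reverse_rxns.append(rev)
        rxn.id = rxn.id + FWD_SUFFIX
        rxn.bounds = (0.0, max(ub, 0.0))
    new.add_reactions(reverse_rxns)
    new.repair()
    # re-point the objective at the (possibly renamed) forward reaction
    new.objective = {
        new.reactions.get_by_id(_split_id(new, rid)): 1.0 for rid in objective_ids
    }
    return new


def _split_id(model: cobra.Model, rxn_id: str) -> str:
    """Resolve a pre-split reaction id in a split model (identity if present)."""
    if rxn_id in model.reactions:
        return rxn_id
    if rxn_id + FWD_SUFFIX in model.reactions:
        return rxn_id + FWD_SUFFIX
    raise KeyError(f"reaction {rxn_id!r} not found in model {model.id!r}")


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _protected_ids(model: cobra.Model, keep_ids) -> set[str]:
    keep = set(_objective_ids(model))
    for rid in keep_ids or ():
        keep.add(_split_id(model, rid))
    return keep


def _reduce_to(model: cobra.Model, keep: set[str]) -> cobra.Model:
    reduced = model.copy()
    drop = [rxn for rxn in reduced.reactions if rxn.id not in keep]
    reduced.remove_reactions(drop, remove_orphans=True)
    return reduced


def fva_reduce(
    model: cobra.Model,
    flux_tol: float = FLUX_TOL,
    fraction_of_optimum: float = 0.0,
    keep_ids=(),
) -> cobra.Model:
    """Drop reactions whose flux-variability span is indistinguishable from zero.

    Flux variability analysis is run under the model's growth medium; a
    reaction is retained when its [min, max] interval either has span above
    ``flux_tol`` or is pinned away from zero (a forced flux such as a
    maintenance requirement must survive the reduction). Metabolites left
    without reactions are dropped with their rows. By default the FVA does
    not constrain the objective to its optimum (``fraction_of_optimum=0``),
    so alternative pathways that are silent at maximal growth are retained;
    raise the fraction to tighten the reduction.

    The objective reaction and any ``keep_ids`` (e.g. measured exchange
    reactions) are never removed.
    """
    growth = model.slim_optimize()
    if growth is None or np.isnan(growth):
        raise InfeasibleModelError(f"model {model.id!r} is infeasible under its medium")

    fva = flux_variability_analysis(
        model, fraction_of_optimum=fraction_of_optimum, processes=1
    )
    span = fva["maximum"] - fva["minimum"]
    active = (span > flux_tol) | (fva["minimum"].abs() > flux_tol) | (
        fva["maximum"].abs() > flux_tol
    )
    keep = set(fva.index[active]) | _protected_ids(model, keep_ids)
    reduced = _reduce_to(model, keep)
    if np.isnan(reduced.slim_optimize()):
        raise InfeasibleModelError(
            f"FVA reduction left model {model.id!r} infeasible"
        )
    return reduced


def fba_sample_reduce(
    model: cobra.Model,
    n_sim: int,
    glc_range: tuple[float, float],
    seed: int,
    glc_uptake_id: str,
    flux_tol: float = FLUX_TOL,
    keep_ids=(),
) -> cobra.Model:
    """Drop reactions that never carry flux across sampled pFBA simulations.

    Each simulation knocks out one randomly chosen gene and draws the maximum
    glucose uptake uniformly from ``glc_range`` (set as the upper bound of
    ``glc_uptake_id``, the uptake-direction exchange reaction of a split
    model). Parsimonious FBA is solved and reactions with ``|flux| >
    flux_tol`` are marked active. Simulations that are infeasible or support
    no growth are discarded (they mark every reaction inactive and would
    carry no information); at least one informative simulation is required.
    Reactions inactive in every informative simulation are removed, except
    the objective and ``keep_ids``.
    """
    from .cbm_solvers import solve_pfba  # local import: avoid cycle at import time

    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    glc_id = _split_id(model, glc_uptake_id)
    genes = [g.id for g in model.genes]
    active = pd.Series(False, index=[r.id for r in model.reactions])
    objective_ids = _objective_ids(model)
    informative = 0
    for _ in range(n_sim):
        uptake = rng.uniform(*glc_range)
        gene = rng.choice(genes) if genes else None
        with model:
            model.reactions.get_by_id(glc_id).upper_bound = uptake
            if gene is not None:
                model.genes.get_by_id(gene).knock_out()
            sol = solve_pfba(model)
        if sol.status != "optimal":
            continue
        if all(abs(sol.fluxes[rid]) <= flux_tol for rid in objective_ids):
            continue  # lethal knockout: zero flux everywhere, uninformative
        informative += 1
        active |= sol.fluxes.abs() > flux_tol
    if informative == 0:
        raise InfeasibleModelError(
            f"all {n_sim} sampled simulations were infeasible or growthless"
        )
    logger.info(
        "fba_sample_reduce: %d/%d informative simulations, %d active reactions",
        informative, n_sim, int(active.sum()),
    )
    keep = set(active.index[active]) | _protected_ids(model, keep_ids)
    return _reduce_to(model, keep)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

@dataclass
class ProjectionMatrix:
    """Sparse signed selection of reactions, as a dense k x n matrix.

    Row ``i`` picks out target ``target_ids[i]`` as a signed combination of
    reaction fluxes (+1/-1 entries only); for split models a net flux is the
    ``_fwd`` column minus the ``_rev`` column. ``role`` distinguishes the
    upper-bound projection (``input_bounds``, one +1 per row) from the
    reference-flux projection (``reference_fluxes``).
    """

    matrix: np.ndarray
    target_ids: list[str]
    reaction_ids: list[str]
    role: str = "reference_fluxes"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.target_ids), len(self.reaction_ids)):
            raise ValueError("projection matrix shape mismatch")
        nz = self.matrix[self.matrix != 0]
        if len(self.target_ids) and (
            not np.all(np.isin(nz, (1.0, -1.0)))
            or np.any((self.matrix != 0).sum(axis=1) == 0)
        ):
            raise ValueError("each row needs >=1 nonzero entry, entries must be +/-1")
        if self.role == "input_bounds" and (
            np.any(nz != 1.0) or np.any((self.matrix != 0).sum(axis=1) != 1)
        ):
            raise ValueError("input_bounds rows must have exactly one +1 entry")

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Project flux vector(s); accepts (n,) or (N, n) arrays."""
        return np.asarray(v, dtype=float) @ self.matrix.T


def build_projection(
    model: cobra.Model,
    targets: list[tuple[str, dict[str, float]]],
    role: str = "reference_fluxes",
) -> ProjectionMatrix:
    """Build a projection matrix from ``(label, {reaction_id: sign})`` pairs."""
    reaction_ids = [r.id for r in model.reactions]
    index = {rid: j for j, rid in enumerate(reaction_ids)}
    unknown = sorted(
        {rid for _, combo in targets for rid in combo if rid not in index}
    )
    if unknown:
        raise KeyError(f"unknown reaction ids in projection targets: {unknown}")
    P = np.zeros((len(targets), len(reaction_ids)))
    for i, (_, combo) in enumerate(targets):
        for rid, sign in combo.items():
            P[i, index[rid]] = sign
    return ProjectionMatrix(P, [label for label, _ in targets], reaction_ids, role)


def net_flux_targets(
    model: cobra.Model, base_ids: list[str]
) -> list[tuple[str, dict[str, float]]]:
    """Net-flux target declarations for (possibly split) reaction ids.

    For each base id, resolves to ``{id: +1}`` if present as-is, or to
    ``{id_fwd: +1, id_rev: -1}`` on a split model.
    """
    targets = []
    for rid in base_ids:
        if rid in model.reactions:
            targets.append((rid, {rid: +1.0}))
            continue
        fwd, rev = rid + FWD_SUFFIX, rid + REV_SUFFIX
        if fwd in model.reactions:
            combo = {fwd: +1.0}
            if rev in model.reactions:
                combo[rev] = -1.0
            targets.append((rid, combo))
        else:
            raise KeyError(f"reaction {rid!r} not found in model {model.id!r}")
    return targets


def input_projection(model: cobra.Model, input_ids: list[str]) -> ProjectionMatrix:
    """Unit-indicator projection selecting the measured input-flux reactions.

    ``input_ids`` name the directional reactions carrying the measured input
    (for uptake through a split exchange, the ``_rev`` member).
    """
    return build_projection(
        model, [(rid, {rid: +1.0}) for rid in input_ids], role="input_bounds"
    )


def stoichiometric_matrix(model: cobra.Model) -> np.ndarray:
    """Dense m x n stoichiometric matrix in model metabolite/reaction order."""
    from cobra.util.array import create_stoichiometric_matrix

    return np.asarray(create_stoichiometric_matrix(model, array_type="dense"))
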