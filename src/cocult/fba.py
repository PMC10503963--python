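"""Flux balance analysis, flux variability analysis, and medium constraints.

All linear programs are solved with scipy's HiGHS interface. The sign
convention for exchange reactions is the dominant one in constraint-based
modelling: an exchange is written ``met[e] <->`` (the metabolite leaves the
system at positive flux), so *uptake is negative flux* and a medium entry of
magnitude ``u`` sets the exchange lower bound to ``-u``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .netcore import FluxVector, MetabolicModel, list_exchanges, stoichiometric_matrix

STEADY_STATE_TOL = 1e-6
BOUND_TOL = 1e-6

__all__ = [
    "OptimizationResult",
    "FluxRange",
    "Medium",
    "InfeasibleError",
    "fba_optimize",
    "fva",
    "apply_medium_constraints",
    "read_medium_tsv",
]


class InfeasibleError(RuntimeError):
    """Raised where an operation requires a feasible/optimal base problem."""


@dataclass
class OptimizationResult:
    """Outcome of one LP solve."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None = None
    fluxes: FluxVector | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """FVA range of one reaction; midpoint is the reported representative."""

    reaction_id: str
    minimum: float
    maximum: float

    @property
    def midpoint(self) -> float:
        return (self.minimum + self.maximum) / 2.0


@dataclass
class Medium:
    """Growth-medium composition as maximum uptake rates (mmol/gDW/h).

    ``uptake`` maps extracellular metabolite ids to non-negative maximum
    uptake magnitudes. ``free_species`` are metabolites always exchangeable
    in both directions (species not captured by measured data, e.g. CO2,
    protons, water).
    """

    uptake: dict[str, float] = field(default_factory=dict)
    free_species: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for met, val in self.uptake.items():
            if val < 0:
                raise ValueError(f"medium uptake for {met!r} is negative: {val}")


def _solve_lp(
    model: MetabolicModel,
    objective: dict[str, float],
    direction: str = "max",
    extra_fixed: dict[str, float] | None = None,
) -> OptimizationResult:
    """Solve max/min c'v s.t. S v = 0, lb <= v <= ub."""
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    rxn_pos = {r.id: j for j, r in enumerate(model.reactions)}
    c = np.zeros(n)
    for rid, coef in objective.items():
        c[rxn_pos[rid]] = coef
    sign = -1.0 if direction == "max" else 1.0
    bounds = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if extra_fixed and r.id in extra_fixed:
            lb = ub = extra_fixed[r.id]
        bounds.append((None if np.isneginf(lb) else lb, None if np.isposinf(ub) else ub))
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    if res.status == 2:
        return OptimizationResult(status="infeasible")
    if res.status == 3:
        return OptimizationResult(status="unbounded")
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = {r.id: float(res.x[j]) for j, r in enumerate(model.reactions)}
    return OptimizationResult(
        status="optimal",
        objective_value=float(-res.fun if direction == "max" else res.fun),
        fluxes=fluxes,
    )


def fba_optimize(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> OptimizationResult:
    """Optimize a single reaction flux under steady state and bounds.

    Defaults to the model's registered (biomass) objective. Infeasibility and
    unboundedness are reported in ``status``, never as silent zeros.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("model has no objective and none was given")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    model.reaction(objective_id)  # KeyError if absent
    return _solve_lp(model, {objective_id: 1.0}, direction)


def fva(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    objective_fraction: float = 1.0,
) -> list[FluxRange]:
    """Flux variability analysis at a fixed fraction of the biomass optimum.

    For each reaction the flux is minimised and maximised subject to steady
    state, bounds, and objective >= fraction x optimum. The per-range
    midpoint (the mean of the two extremes) is the representative flux used
    throughout the co-culture workflow.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    if reaction_ids is None:
        reaction_ids = model.reaction_ids

    work = model
    if model.objective_id is not None and objective_fraction > 0:
        base = fba_optimize(model)
        if not base.optimal:
            raise InfeasibleError(
                f"base FBA problem is {base.status}; cannot run FVA"
            )
        work = model.copy()
        obj = work.reaction(model.objective_id)
        floor = objective_fraction * base.objective_value
        # never raise above the existing upper bound
        obj.lower_bound = min(max(obj.lower_bound, floor), obj.upper_bound)

    out: list[FluxRange] = []
    for rid in reaction_ids:
        lo = _solve_lp(work, {rid: 1.0}, "min")
        hi = _solve_lp(work, {rid: 1.0}, "max")
        if not (lo.optimal and hi.optimal):
            raise InfeasibleError(f"FVA subproblem for {rid!r} not optimal")
        mn, mx = lo.objective_value, hi.objective_value
        if mn > mx:  # numerical jitter on degenerate ranges
            mn, mx = mx, mn
        out.append(FluxRange(reaction_id=rid, minimum=mn, maximum=mx))
    return out


def apply_medium_constraints(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Constrain exchange reactions to a medium composition.

    Exchanges of listed species get uptake bound ``-value``; all other
    exchanges have uptake closed (lower bound 0), except ``free_species``
    which stay open in both directions. Secretion bounds are untouched.
    Returns a new model.
    """
    new = model.copy()
    exchange_of: dict[str, str] = {}
    for rid in list_exchanges(new):
        (met_id,) = new.reaction(rid).stoichiometry
        exchange_of[met_id] = rid

    missing = [m for m in list(medium.uptake) + sorted(medium.free_species)
               if m not in exchange_of]
    if missing:
        raise ValueError(
            "medium species without exchange reactions: " + ", ".join(sorted(set(missing)))
        )

    for met_id, rid in exchange_of.items():
        rxn = new.reaction(rid)
        # exchange convention: coefficient -1 (met leaves at positive flux)
        coef = rxn.stoichiometry[met_id]
        uptake_is_negative = coef < 0
        if met_id in medium.free_species:
            continue
        if met_id in medium.uptake:
            cap = medium.uptake[met_id]
            if uptake_is_negative:
                rxn.lower_bound = -cap
            else:
                rxn.upper_bound = cap
        else:
            if uptake_is_negative:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
            else:
                rxn.upper_bound = min(rxn.upper_bound, 0.0)
    return new


def read_medium_tsv(path: str) -> Medium:
    """Read a medium table (columns ``metabolite_id``, ``max_uptake``)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "max_uptake"}
    if not required.issubset(df.columns):
        raise ValueError(f"medium TSV must have columns {sorted(required)}")
    return Medium(uptake=dict(zip(df["metabolite_id"], df["max_uptake"].astype(float))))
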