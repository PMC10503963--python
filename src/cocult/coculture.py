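"""Two-cell co-culture assembly and its downstream analyses.

Assembly follows the shared-extracellular-space convention: internal
compartments of each cell are retagged with a cell label (``pyr[c]`` of the
stromal cell becomes ``pyr[c_bm]``), extracellular metabolites are unified
by id, and duplicated exchange reactions are collapsed to one. Both biomass
reactions are retained, giving a genuinely multi-objective model analysed by
an epsilon-constraint Pareto scan.

The staged respirometry protocol mirrors a high-resolution oxygraph run:
basal respiration, ATP-synthase inhibition (oligomycin), uncoupling (FCCP,
simulated as maximal complex IV flux), and complex I/III inhibition
(rotenone + antimycin A). Each stage is solved from the unperturbed model
with the stage's constraint set; the oxygen flux is reported as the
magnitude of the FVA midpoint of the oxygen exchange at the stage optimum,
which makes the read-out deterministic under alternate optima.

Phenotype tuning intersects reaction bounds with externally estimated flux
intervals (e.g. 95% confidence intervals from 13C metabolic flux analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fba import InfeasibleError, OptimizationResult, fba_optimize, fva
from .netcore import (
    FluxVector,
    MetabolicModel,
    Metabolite,
    Reaction,
    GPR,
    list_exchanges,
    split_compartment,
)

__all__ = [
    "CellTag",
    "CocultureModel",
    "ETCMap",
    "RespirationProfile",
    "ParetoPoint",
    "merge_models",
    "pareto_front",
    "respiration_protocol",
    "apply_flux_intervals",
    "growth_rate_from_biomass_flux",
]


@dataclass(frozen=True)
class CellTag:
    """Label of one cell in the co-culture (e.g. ``bm``, ``cm``)."""

    label: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.label or self.label == "e":
            raise ValueError("cell tag must be non-empty and different from 'e'")


@dataclass
class CocultureModel:
    """A merged two-cell model with per-cell bookkeeping."""

    model: MetabolicModel
    cell_of_reaction: dict[str, str]  # reaction id -> tag label or "shared"
    biomass_ids: dict[str, str]  # tag label -> biomass reaction id
    tags: tuple[CellTag, CellTag]


@dataclass
class ETCMap:
    """Reaction ids of the lumped electron-transport-chain machinery."""

    complex_i: str
    complex_iii: str
    complex_iv: str
    complex_v: str
    oxygen_exchange: str
    proton_leak: str | None = None

    def resolve(self, model: MetabolicModel) -> None:
        ids = [self.complex_i, self.complex_iii, self.complex_iv,
               self.complex_v, self.oxygen_exchange]
        if self.proton_leak is not None:
            ids.append(self.proton_leak)
        known = set(model.reaction_ids)
        missing = [i for i in ids if i not in known]
        if missing:
            raise ValueError(f"ETC map ids not in model: {missing}")


@dataclass
class RespirationProfile:
    """Staged oxygen fluxes (all magnitudes, mmol O2/gDW/h)."""

    basal_o2: float
    oligomycin_o2: float  # proton-leak respiration
    fccp_o2: float  # maximal (uncoupled) respiration
    rot_aa_o2: float  # non-mitochondrial respiration

    def __post_init__(self) -> None:
        for name in ("basal_o2", "oligomycin_o2", "fccp_o2", "rot_aa_o2"):
            v = getattr(self, name)
            if v < -1e-9:
                raise ValueError(f"{name} must be a magnitude >= 0, got {v}")
            setattr(self, name, max(v, 0.0))

    @property
    def atp_linked(self) -> float:
        return self.basal_o2 - self.oligomycin_o2

    @property
    def spare_capacity(self) -> float:
        return self.fccp_o2 - self.basal_o2


@dataclass
class ParetoPoint:
    """One feasible trade-off point between the two biomass objectives."""

    biomass_a: float
    biomass_b: float
    fluxes: FluxVector


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------


def _retag(met_id: str, comp: str, tag: str) -> tuple[str, str]:
    """New (id, compartment) for an internal metabolite of a tagged cell."""
    base, suffix = split_compartment(met_id)
    new_comp = f"{comp}_{tag}"
    if suffix is not None:
        return f"{base}[{new_comp}]", new_comp
    return f"{met_id}_{tag}", new_comp


def merge_models(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    tag_a: CellTag | str,
    tag_b: CellTag | str,
) -> CocultureModel:
    """Merge two cell models into one co-culture model.

    Internal metabolites/reactions get cell-tag suffixes; extracellular
    metabolites are unified by id and duplicated exchange reactions are
    collapsed (keeping the union of their bound intervals). Both biomass
    reactions are retained and registered per cell.
    """
    if isinstance(tag_a, str):
        tag_a = CellTag(tag_a)
    if isinstance(tag_b, str):
        tag_b = CellTag(tag_b)
    if tag_a.label == tag_b.label:
        raise ValueError("cell tags must differ")
    for model, tag in ((model_a, tag_a), (model_b, tag_b)):
        if model.objective_id is None:
            raise ValueError(f"model {model.id!r} has no biomass objective")
        comps = {m.compartment for m in model.metabolites}
        if tag.label in comps:
            raise ValueError(
                f"tag {tag.label!r} collides with a compartment of {model.id!r}"
            )

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    cell_of: dict[str, str] = {}
    seen_ext_mets: dict[str, Metabolite] = {}
    exchange_by_met: dict[str, Reaction] = {}

    for model, tag in ((model_a, tag_a), (model_b, tag_b)):
        exchanges = set(list_exchanges(model))
        met_rename: dict[str, str] = {}
        for m in model.metabolites:
            if m.compartment == "e":
                met_rename[m.id] = m.id
                if m.id not in seen_ext_mets:
                    new_m = Metabolite(m.id, m.name, m.compartment, m.formula,
                                       m.delta_g_formation)
                    seen_ext_mets[m.id] = new_m
                    mets.append(new_m)
            else:
                new_id, new_comp = _retag(m.id, m.compartment, tag.label)
                met_rename[m.id] = new_id
                mets.append(
                    Metabolite(new_id, m.name, new_comp, m.formula,
                               m.delta_g_formation)
                )
        for r in model.reactions:
            stoich = {met_rename[k]: v for k, v in r.stoichiometry.items()}
            if r.id in exchanges:
                (met_id,) = stoich
                if met_id in exchange_by_met:
                    prev = exchange_by_met[met_id]
                    prev.lower_bound = min(prev.lower_bound, r.lower_bound)
                    prev.upper_bound = max(prev.upper_bound, r.upper_bound)
                    continue
                new_r = Reaction(r.id, stoich, r.lower_bound, r.upper_bound,
                                 GPR(r.gpr.node), r.subsystem, r.name)
                exchange_by_met[met_id] = new_r
                rxns.append(new_r)
                cell_of[new_r.id] = "shared"
            else:
                new_id = f"{r.id}_{tag.label}"
                rxns.append(
                    Reaction(new_id, stoich, r.lower_bound, r.upper_bound,
                             GPR(r.gpr.node), r.subsystem, r.name)
                )
                cell_of[new_id] = tag.label

    biomass_ids = {
        tag_a.label: f"{model_a.objective_id}_{tag_a.label}",
        tag_b.label: f"{model_b.objective_id}_{tag_b.label}",
    }
    merged = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=biomass_ids[tag_a.label],
        id=f"{model_a.id}__{model_b.id}",
    )
    return CocultureModel(
        model=merged,
        cell_of_reaction=cell_of,
        biomass_ids=biomass_ids,
        tags=(tag_a, tag_b),
    )


# ---------------------------------------------------------------------------
# Multi-objective Pareto scan
# ---------------------------------------------------------------------------


def pareto_front(
    cc: CocultureModel, n_points: int = 21, tol: float = 1e-9
) -> list[ParetoPoint]:
    """Epsilon-constraint scan of the (biomass_a, biomass_b) Pareto front.

    Biomass A is floored at ``n_points`` uniform levels spanning [0, max_a]
    and biomass B is maximised at each level. The returned points are
    mutually non-dominated and the endpoints equal the two single-objective
    optima.
    """
    tag_a, tag_b = cc.tags
    bid_a, bid_b = cc.biomass_ids[tag_a.label], cc.biomass_ids[tag_b.label]
    opt_a = fba_optimize(cc.model, bid_a)
    opt_b = fba_optimize(cc.model, bid_b)
    if not (opt_a.optimal and opt_b.optimal):
        raise InfeasibleError("single-objective biomass problems must be optimal")
    if not (np.isfinite(opt_a.objective_value) and np.isfinite(opt_b.objective_value)):
        raise InfeasibleError("single-objective biomass optima must be finite")

    points: list[ParetoPoint] = []
    for eps in np.linspace(0.0, opt_a.objective_value, n_points):
        work = cc.model.copy()
        rxn = work.reaction(bid_a)
        rxn.lower_bound = max(rxn.lower_bound, float(eps))
        res = fba_optimize(work, bid_b)
        if not res.optimal:
            continue
        # report the level actually attained, maximising a at fixed b
        work2 = work.copy()
        r2 = work2.reaction(bid_b)
        r2.lower_bound = max(r2.lower_bound, res.objective_value - tol)
        res2 = fba_optimize(work2, bid_a)
        fl = res2.fluxes if res2.optimal else res.fluxes
        points.append(
            ParetoPoint(
                biomass_a=float(fl[bid_a]),
                biomass_b=float(fl[bid_b]),
                fluxes=fl,
            )
        )
    return _nondominated(points)


def _nondominated(points: list[ParetoPoint], tol: float = 1e-7) -> list[ParetoPoint]:
    out = []
    for p in points:
        dominated = any(
            (q.biomass_a >= p.biomass_a + tol and q.biomass_b >= p.biomass_b - tol)
            or (q.biomass_a >= p.biomass_a - tol and q.biomass_b >= p.biomass_b + tol)
            for q in points
            if q is not p
        )
        if not dominated:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# In-silico respirometry
# ---------------------------------------------------------------------------


def _o2_midpoint_at_optimum(
    model: MetabolicModel,
    objective_id: str,
    o2_reaction: str,
    fixed: dict[str, tuple[float, float]] | None = None,
    lower_floor: dict[str, float] | None = None,
) -> tuple[float, OptimizationResult]:
    """Optimize a stage objective, pin it, and read the O2 FVA midpoint."""
    work = model.copy()
    for rid, (lo, hi) in (fixed or {}).items():
        r = work.reaction(rid)
        r.lower_bound, r.upper_bound = lo, hi
    for rid, lo in (lower_floor or {}).items():
        r = work.reaction(rid)
        r.lower_bound = max(r.lower_bound, lo)
    res = fba_optimize(work, objective_id)
    if not res.optimal:
        raise InfeasibleError(
            f"respirometry stage with objective {objective_id!r} and constraints "
            f"{sorted((fixed or {}) | (lower_floor or {}))} is {res.status}"
        )
    obj = work.reaction(objective_id)
    obj.lower_bound = max(obj.lower_bound, res.objective_value - 1e-9)
    rng = fva(work, [o2_reaction], objective_fraction=0.0)[0]
    return abs(rng.midpoint), res


def respiration_protocol(
    model: MetabolicModel,
    etc: ETCMap,
    basal_mode: str = "midpoint",
    o2_reaction: str | None = None,
) -> RespirationProfile:
    """Simulate the four-stage oxygraph respirometry protocol.

    Stages, each starting from the unperturbed model:

    1. *basal* — biomass optimum; O2 read as the FVA midpoint of the oxygen
       flux at that optimum (``basal_mode="midpoint"``, default, which
       honours the minimisation-under-a-biomass-objective read-out) or as
       the plain FBA solution flux (``basal_mode="fba"``).
    2. *oligomycin* — ATP synthase fixed to 0, ETC complexes floored at 0
       (no reversal), biomass maximised.
    3. *FCCP* — stage-2 constraints relaxed; complex IV flux maximised.
    4. *rotenone + antimycin A* — complexes I and III fixed to 0, biomass
       maximised.
    """
    etc.resolve(model)
    if model.objective_id is None:
        raise ValueError("model needs a biomass objective for respirometry")
    o2 = o2_reaction or etc.oxygen_exchange

    # stage 1: basal
    if basal_mode == "midpoint":
        basal, _ = _o2_midpoint_at_optimum(model, model.objective_id, o2)
    elif basal_mode == "fba":
        res = fba_optimize(model)
        if not res.optimal:
            raise InfeasibleError(f"basal FBA is {res.status}")
        basal = abs(res.fluxes[o2])
    else:
        raise ValueError(f"unknown basal_mode {basal_mode!r}")

    # stage 2: oligomycin — ATP synthase off, complexes not reversible
    oligo, _ = _o2_midpoint_at_optimum(
        model,
        model.objective_id,
        o2,
        fixed={etc.complex_v: (0.0, 0.0)},
        lower_floor={etc.complex_i: 0.0, etc.complex_iii: 0.0, etc.complex_iv: 0.0},
    )

    # stage 3: FCCP — uncoupled, maximise complex IV
    fccp, _ = _o2_midpoint_at_optimum(model, etc.complex_iv, o2)

    # stage 4: rotenone + antimycin A — complexes I and III off
    rot_aa, _ = _o2_midpoint_at_optimum(
        model,
        model.objective_id,
        o2,
        fixed={etc.complex_i: (0.0, 0.0), etc.complex_iii: (0.0, 0.0)},
    )

    return RespirationProfile(
        basal_o2=basal, oligomycin_o2=oligo, fccp_o2=fccp, rot_aa_o2=rot_aa
    )


# ---------------------------------------------------------------------------
# Phenotype tuning
# ---------------------------------------------------------------------------


def apply_flux_intervals(
    model: MetabolicModel,
    intervals: dict[str, tuple[float, float]],
) -> MetabolicModel:
    """Intersect reaction bounds with estimated flux intervals.

    This is the phenotype-tuning entry point: confidence intervals from
    metabolic flux analysis act as lower and upper bounds in the
    constraint-based model. Unmatched ids are reported (warning + model
    annotation) and skipped; an empty bound intersection or post-tuning
    infeasibility raises, the latter with a greedy hint listing tuned
    reactions whose relaxation restores feasibility.
    """
    new = model.copy()
    known = set(new.reaction_ids)
    unmatched = sorted(set(intervals) - known)
    if unmatched:
        warnings.warn("flux intervals without matching reactions: "
                      + ", ".join(unmatched))
        new.annotations["unmatched_intervals"] = unmatched

    applied: dict[str, tuple[float, float]] = {}
    for rid in sorted(set(intervals) & known):
        lo, hi = intervals[rid]
        if lo > hi:
            raise ValueError(f"interval for {rid!r} has lo > hi")
        rxn = new.reaction(rid)
        new_lo = max(rxn.lower_bound, lo)
        new_hi = min(rxn.upper_bound, hi)
        if new_lo > new_hi + 1e-12:
            raise ValueError(
                f"interval ({lo}, {hi}) for {rid!r} does not intersect its "
                f"bounds [{rxn.lower_bound}, {rxn.upper_bound}]"
            )
        applied[rid] = (rxn.lower_bound, rxn.upper_bound)
        rxn.lower_bound, rxn.upper_bound = new_lo, min(new_hi, max(new_lo, new_hi))

    res = fba_optimize(new) if new.objective_id else None
    if res is not None and not res.optimal:
        hint = _greedy_relaxation_hint(new, applied)
        raise InfeasibleError(
            "model infeasible after tuning; relaxing these tuned reactions "
            f"restores feasibility: {hint}"
        )
    return new


def _greedy_relaxation_hint(
    model: MetabolicModel, applied: dict[str, tuple[float, float]]
) -> list[str]:
    work = model.copy()
    relaxed: list[str] = []
    for rid in sorted(applied):
        lo, hi = applied[rid]
        rxn = work.reaction(rid)
        rxn.lower_bound, rxn.upper_bound = lo, hi
        relaxed.append(rid)
        if fba_optimize(work).optimal:
            break
    return relaxed


def growth_rate_from_biomass_flux(
    biomass_flux: float, grams_per_mmol: float = 1.0
) -> float:
    """Convert a biomass flux (mmol/gDW/h) to a specific growth rate (/h).

    With the standard assumption that one gram of dry cell weight equals one
    millimole of biomass, a biomass flux of 0.0306 mmol/gDW/h is a growth
    rate of 0.0306 /h.
    """
    if biomass_flux < 0 or grams_per_mmol < 0:
        raise ValueError("biomass flux and conversion factor must be >= 0")
    return biomass_flux * grams_per_mmol
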