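"""Thermodynamic reaction directionality from metabolite formation energies.

Given per-metabolite standard Gibbs energies of formation and physiological
concentration ranges, each reaction's transformed reaction energy is

    dG(c) = sum_i s_i dGf_i + R T sum_i s_i ln c_i

with stoichiometric coefficients ``s_i`` (negative for substrates) and
concentrations ``c_i`` in mol/L. Because dG is monotone in each ``ln c_i``
(slope ``R T s_i``), its extrema over the concentration box are attained at
box corners: the minimum has substrates at their maximum and products at
their minimum concentration, and vice versa for the maximum.

A reaction whose whole dG range lies below zero is thermodynamically forced
forward (lower flux bound raised to 0); a range wholly above zero forces it
in reverse. Ranges straddling zero leave the bounds untouched. Loop
detection certifies that a flux solution carries no internal circulation
that would survive with every exchange closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .netcore import FluxVector, MetabolicModel, list_exchanges

R_KJ = 8.314e-3  # kJ/mol/K
DEFAULT_TEMPERATURE = 310.15  # K, physiological
DEFAULT_CONC_MIN = 1e-6  # mol/L
DEFAULT_CONC_MAX = 2e-2  # mol/L
#: species excluded from the RT concentration term (activity ~ constant)
DEFAULT_EXEMPT_SPECIES = ("h2o", "h")

__all__ = [
    "ThermoTable",
    "ReactionDeltaG",
    "DirectionalityConflictError",
    "MissingThermoDataError",
    "reaction_delta_g_range",
    "model_delta_g_ranges",
    "fix_directionality",
    "detect_flux_loops",
    "read_thermo_tsv",
]


class MissingThermoDataError(KeyError):
    """A participating metabolite has no thermodynamic entry."""


class DirectionalityConflictError(ValueError):
    """A thermodynamically forced direction contradicts an existing bound."""


@dataclass
class ThermoEntry:
    delta_g_formation: float  # kJ/mol
    conc_min: float = DEFAULT_CONC_MIN  # mol/L
    conc_max: float = DEFAULT_CONC_MAX  # mol/L

    def __post_init__(self) -> None:
        if not (0 < self.conc_min <= self.conc_max):
            raise ValueError(
                f"invalid concentration range [{self.conc_min}, {self.conc_max}]"
            )


@dataclass
class ThermoTable:
    """Per-metabolite formation energies and concentration ranges.

    Keys are *base* metabolite ids (without the compartment suffix) or full
    ids; full-id entries take precedence. ``exempt_species`` (base ids) are
    skipped in the RT term — their formation energy still counts.
    """

    entries: dict[str, ThermoEntry] = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE
    exempt_species: tuple[str, ...] = DEFAULT_EXEMPT_SPECIES

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def lookup(self, met_id: str) -> ThermoEntry | None:
        from .netcore import split_compartment

        if met_id in self.entries:
            return self.entries[met_id]
        base, _ = split_compartment(met_id)
        return self.entries.get(base)

    def is_exempt(self, met_id: str) -> bool:
        from .netcore import split_compartment

        base, _ = split_compartment(met_id)
        return base in self.exempt_species or met_id in self.exempt_species


@dataclass
class ReactionDeltaG:
    """Range of possible reaction Gibbs energies (kJ/mol)."""

    reaction_id: str
    dg_min: float
    dg_max: float

    def __post_init__(self) -> None:
        if self.dg_min > self.dg_max:
            raise ValueError(f"{self.reaction_id}: dg_min > dg_max")


def reaction_delta_g_range(
    model: MetabolicModel, thermo: ThermoTable, reaction_id: str
) -> ReactionDeltaG:
    """Extremal reaction dG over the metabolite concentration box."""
    rxn = model.reaction(reaction_id)
    rt = R_KJ * thermo.temperature
    dg_min = 0.0
    dg_max = 0.0
    missing: list[str] = []
    for met_id, s in rxn.stoichiometry.items():
        entry = thermo.lookup(met_id)
        if entry is None:
            if thermo.is_exempt(met_id):
                continue
            missing.append(met_id)
            continue
        dg_min += s * entry.delta_g_formation
        dg_max += s * entry.delta_g_formation
        if thermo.is_exempt(met_id):
            continue
        lo, hi = math.log(entry.conc_min), math.log(entry.conc_max)
        # dG is increasing in ln c for products (s>0), decreasing for substrates
        if s > 0:
            dg_min += rt * s * lo
            dg_max += rt * s * hi
        else:
            dg_min += rt * s * hi
            dg_max += rt * s * lo
    if missing:
        raise MissingThermoDataError(
            f"reaction {reaction_id!r}: no thermodynamic data for "
            + ", ".join(sorted(missing))
        )
    return ReactionDeltaG(reaction_id=reaction_id, dg_min=dg_min, dg_max=dg_max)


def model_delta_g_ranges(
    model: MetabolicModel, thermo: ThermoTable, skip_exchanges: bool = True
) -> tuple[list[ReactionDeltaG], list[str]]:
    """dG ranges for every reaction with full thermodynamic coverage.

    Exchange pseudo-reactions are boundary constructs with no defined
    reaction energy and are skipped by default. Reactions with missing
    entries are collected in the second return value rather than raising.
    """
    exchanges = set(list_exchanges(model)) if skip_exchanges else set()
    ranges: list[ReactionDeltaG] = []
    skipped: list[str] = []
    for r in model.reactions:
        if r.id in exchanges:
            continue
        try:
            ranges.append(reaction_delta_g_range(model, thermo, r.id))
        except MissingThermoDataError:
            skipped.append(r.id)
    return ranges, skipped


def fix_directionality(
    model: MetabolicModel, ranges: list[ReactionDeltaG]
) -> MetabolicModel:
    """Project thermodynamically forced directions onto flux bounds.

    Never widens a bound. A forced direction that contradicts a strict
    existing bound (e.g. a forward-only reaction forced in reverse) raises
    :class:`DirectionalityConflictError`.
    """
    new = model.copy()
    for rng in ranges:
        rxn = new.reaction(rng.reaction_id)
        if rng.dg_max < 0:  # exergonic over the whole box: forward only
            if rxn.upper_bound <= 0 and rxn.lower_bound < 0:
                raise DirectionalityConflictError(
                    f"reaction {rxn.id!r} is bounded reverse-only but "
                    f"thermodynamics forces it forward (dG_max={rng.dg_max:.3g})"
                )
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        elif rng.dg_min > 0:  # endergonic everywhere: reverse only
            if rxn.lower_bound >= 0 and rxn.upper_bound > 0:
                raise DirectionalityConflictError(
                    f"reaction {rxn.id!r} is bounded forward-only but "
                    f"thermodynamics forces it in reverse (dG_min={rng.dg_min:.3g})"
                )
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
        # straddling zero: leave untouched
    return new


def detect_flux_loops(
    model: MetabolicModel, fluxes: FluxVector, tol: float = 1e-6
) -> list[set[str]]:
    """Find internal circulations supported by a flux solution.

    The non-zero internal (non-exchange) flux pattern of ``fluxes`` is tested
    for the part that remains feasible with *all exchanges closed*: each
    internal reaction's flux is restricted to its original sign with
    magnitude at most its original value, and total circulation is maximised
    by LP. Reactions still carrying flux form the loops, grouped into
    connected components by shared metabolites. An empty list certifies the
    solution loop-free at tolerance ``tol``.
    """
    from scipy.optimize import linprog

    from .netcore import stoichiometric_matrix

    exchanges = set(list_exchanges(model))
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    c = np.zeros(n)
    bounds: list[tuple[float, float]] = []
    for j, r in enumerate(model.reactions):
        v = fluxes.get(r.id, 0.0)
        if r.id in exchanges or abs(v) <= tol:
            bounds.append((0.0, 0.0))
        elif v > 0:
            bounds.append((0.0, v))
            c[j] = -1.0  # maximise
        else:
            bounds.append((v, 0.0))
            c[j] = 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if not res.success:
        return []
    support = [model.reactions[j].id for j in range(n) if abs(res.x[j]) > tol]
    if not support:
        return []

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(support)
    for rid in support:
        for met in model.reaction(rid).stoichiometry:
            g.add_edge(rid, ("met", met))
    comps: list[set[str]] = []
    for comp in nx.connected_components(g):
        rxns = {x for x in comp if isinstance(x, str)}
        if rxns:
            comps.append(rxns)
    return comps


def read_thermo_tsv(path: str, **kwargs) -> ThermoTable:
    """Read a thermo table TSV with columns
    ``metabolite_id, dgf_kj_mol, conc_min_M, conc_max_M``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "dgf_kj_mol"}
    if not required.issubset(df.columns):
        raise ValueError(f"thermo TSV must have columns {sorted(required)}")
    entries = {}
    for _, row in df.iterrows():
        entries[str(row["metabolite_id"])] = ThermoEntry(
            delta_g_formation=float(row["dgf_kj_mol"]),
            conc_min=float(row.get("conc_min_M", DEFAULT_CONC_MIN))
            if "conc_min_M" in df.columns
            else DEFAULT_CONC_MIN,
            conc_max=float(row.get("conc_max_M", DEFAULT_CONC_MAX))
            if "conc_max_M" in df.columns
            else DEFAULT_CONC_MAX,
        )
    return ThermoTable(entries=entries, **kwargs)
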