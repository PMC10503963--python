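"""Core representation of stoichiometric metabolic models.

A :class:`MetabolicModel` holds metabolites, reactions (with flux bounds and
gene-protein-reaction rules) and a biomass objective, i.e. everything needed
to form the stoichiometric matrix ``S`` and reason about steady-state flux
vectors ``v`` with ``S v = 0``.

Two on-disk formats are supported:

* SBML Level 3 with the FBC package (via python-libsbml), and
* a deterministic JSON dialect (sorted keys, schema-versioned) documented in
  ``docs/formats.md``.

Compartments follow the bracket-suffix convention ``met[tag]`` (e.g.
``glc[e]`` for extracellular glucose); the shared extracellular space is
always tagged ``e``. Flux units are mmol/gDW/h throughout.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

JSON_SCHEMA_VERSION = 1

__all__ = [
    "Metabolite",
    "GPR",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "ModelParseError",
    "parse_gpr",
    "read_model",
    "write_model",
    "stoichiometric_matrix",
    "check_balance",
    "BalanceReport",
    "list_exchanges",
    "parse_formula",
    "split_compartment",
]


class ModelValidationError(ValueError):
    """A model violates a structural invariant (message names the offender)."""


class ModelParseError(ValueError):
    """A model file could not be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_ID_SUFFIX_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")


def split_compartment(met_id: str) -> tuple[str, str | None]:
    """Split ``"glc[e]"`` into ``("glc", "e")``; no suffix gives ``(id, None)``."""
    m = _ID_SUFFIX_RE.match(met_id)
    if m:
        return m.group("base"), m.group("comp")
    return met_id, None


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``id`` conventionally carries the bracket suffix (``pyr[c]``);
    ``compartment`` is the bare tag (``c``). ``delta_g_formation`` is the
    standard Gibbs energy of formation in kJ/mol, if known.
    """

    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    delta_g_formation: float | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            _, comp = split_compartment(self.id)
            if comp:
                self.compartment = comp
        if not self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment tag is empty"
            )


# --- GPR boolean expression trees ------------------------------------------


class GPR:
    """Boolean gene-protein-reaction rule.

    A tree over gene identifiers with AND/OR nodes. The empty rule (no gene
    association) is represented by ``GPR(None)``. Evaluation with continuous
    gene scores follows the usual convention AND -> min, OR -> max.
    """

    __slots__ = ("node",)

    def __init__(self, node=None):
        # node: None | str (gene) | ("and"|"or", [children])
        self.node = node

    @property
    def is_empty(self) -> bool:
        return self.node is None

    def genes(self) -> set[str]:
        out: set[str] = set()

        def walk(n):
            if n is None:
                return
            if isinstance(n, str):
                out.add(n)
            else:
                for c in n[1]:
                    walk(c)

        walk(self.node)
        return out

    def evaluate(self, scores: Mapping[str, float], default: float = 0.0) -> float:
        """Evaluate with AND=min, OR=max; missing genes take ``default``."""
        if self.node is None:
            raise ValueError("cannot evaluate an empty GPR")

        def ev(n):
            if isinstance(n, str):
                return scores.get(n, default)
            op, children = n
            vals = [ev(c) for c in children]
            return min(vals) if op == "and" else max(vals)

        return ev(self.node)

    def to_string(self) -> str:
        def fmt(n, parent_op=None):
            if isinstance(n, str):
                return n
            op, children = n
            inner = f" {op} ".join(fmt(c, op) for c in children)
            if parent_op is not None and op != parent_op:
                return f"({inner})"
            return inner

        return "" if self.node is None else fmt(self.node)

    def __eq__(self, other) -> bool:
        return isinstance(other, GPR) and self.node == other.node

    def __repr__(self) -> str:
        return f"GPR({self.to_string()!r})"


class _GPRTokenizer:
    _TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

    def __init__(self, text: str):
        self.tokens = self._TOKEN_RE.findall(text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ModelParseError("unexpected end of GPR expression")
        self.pos += 1
        return tok


def parse_gpr(text: str | None) -> GPR:
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a tree.

    AND binds tighter than OR; ``&``/``|`` are accepted as synonyms.
    """
    if text is None or not text.strip():
        return GPR(None)
    tz = _GPRTokenizer(text)

    def parse_or():
        terms = [parse_and()]
        while tz.peek() is not None and tz.peek().lower() in ("or", "|"):
            tz.next()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        factors = [parse_atom()]
        while tz.peek() is not None and tz.peek().lower() in ("and", "&"):
            tz.next()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_atom():
        tok = tz.next()
        if tok == "(":
            node = parse_or()
            if tz.next() != ")":
                raise ModelParseError(f"unbalanced parentheses in GPR {text!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or", "&", "|"):
            raise ModelParseError(f"malformed GPR {text!r}: unexpected {tok!r}")
        return tok

    node = parse_or()
    if tz.peek() is not None:
        raise ModelParseError(f"trailing tokens in GPR {text!r}")
    return GPR(node)


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds (mmol/gDW/h) and a GPR."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GPR = field(default_factory=GPR)
    subsystem: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """Metabolites + reactions + a biomass objective; houses S and v."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str | None = None
    annotations: dict = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return out

    def validate(self) -> None:
        """Check all structural invariants; raise naming the offending id."""
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        self._met_index = {m.id: m for m in self.metabolites}
        rseen: set[str] = set()
        for r in self.reactions:
            if r.id in rseen:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            rseen.add(r.id)
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
        self._rxn_index = {r.id: r for r in self.reactions}
        if self.objective_id is not None and self.objective_id not in self._rxn_index:
            raise ModelValidationError(
                f"objective {self.objective_id!r} is not a reaction"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[
                Metabolite(m.id, m.name, m.compartment, m.formula, m.delta_g_formation)
                for m in self.metabolites
            ],
            reactions=[
                Reaction(
                    r.id,
                    dict(r.stoichiometry),
                    r.lower_bound,
                    r.upper_bound,
                    GPR(r.gpr.node),
                    r.subsystem,
                    r.name,
                )
                for r in self.reactions
            ],
            objective_id=self.objective_id,
            annotations=dict(self.annotations),
            id=self.id,
        )


# FluxVector is a plain mapping reaction-id -> flux (mmol/gDW/h).
FluxVector = dict


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S (metabolites x reactions) in model list order."""
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[met_pos[met_id], j] = coef
    return S


def list_exchanges(model: MetabolicModel) -> list[str]:
    """Reactions touching exactly one metabolite, which is extracellular."""
    out = []
    for r in model.reactions:
        if len(r.stoichiometry) == 1:
            (met_id,) = r.stoichiometry
            if model.metabolite(met_id).compartment == "e":
                out.append(r.id)
    return out


_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula string like ``C6H12O6`` into counts.

    Raises ValueError on anything that does not tokenize fully (charges,
    parentheses, R-groups).
    """
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    counts: dict[str, float] = {}
    for m in _FORMULA_TOKEN_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        if not m.group(0):
            break
        elem = m.group(1)
        num = m.group(2)
        counts[elem] = counts.get(elem, 0.0) + (float(num) if num else 1.0)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


@dataclass
class BalanceReport:
    """Outcome of an elemental mass-balance audit."""

    imbalanced: dict[str, dict[str, float]]  # rxn id -> element -> net atoms
    unchecked: list[str]  # reactions skipped (missing/unparseable formulas)
    exempt: list[str]  # exchange reactions, exempt by definition

    @property
    def clean(self) -> bool:
        return not self.imbalanced


def check_balance(model: MetabolicModel, tol: float = 1e-9) -> BalanceReport:
    """Audit elemental balance of every non-exchange reaction.

    A reaction is reported imbalanced iff for some element the summed
    coefficient x atom-count is non-zero. Reactions involving a metabolite
    with a missing or unparseable formula are listed as unchecked (with a
    warning for unparseable ones). Exchange reactions are exempt.
    """
    if not any(m.formula for m in model.metabolites):
        raise ValueError("check_balance requires at least one metabolite formula")
    exchanges = set(list_exchanges(model))
    parsed: dict[str, dict[str, float] | None] = {}
    for m in model.metabolites:
        if m.formula is None:
            parsed[m.id] = None
        else:
            try:
                parsed[m.id] = parse_formula(m.formula)
            except ValueError:
                warnings.warn(
                    f"metabolite {m.id!r}: unparseable formula {m.formula!r}; "
                    "reactions involving it are left unchecked"
                )
                parsed[m.id] = None

    imbalanced: dict[str, dict[str, float]] = {}
    unchecked: list[str] = []
    exempt: list[str] = []
    for r in model.reactions:
        if r.id in exchanges:
            exempt.append(r.id)
            continue
        if any(parsed[met] is None for met in r.stoichiometry):
            unchecked.append(r.id)
            continue
        net: dict[str, float] = {}
        for met, coef in r.stoichiometry.items():
            for elem, n in parsed[met].items():
                net[elem] = net.get(elem, 0.0) + coef * n
        bad = {e: v for e, v in net.items() if abs(v) > tol}
        if bad:
            imbalanced[r.id] = bad
    return BalanceReport(imbalanced=imbalanced, unchecked=unchecked, exempt=exempt)


# ---------------------------------------------------------------------------
# I/O — JSON dialect
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "objective_id": model.objective_id,
        "annotations": model.annotations,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "delta_g_formation": m.delta_g_formation,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    if "metabolites" not in data or "reactions" not in data:
        raise ModelParseError("JSON model missing 'metabolites' or 'reactions'")
    mets = [
        Metabolite(
            id=d["id"],
            name=d.get("name", ""),
            compartment=d.get("compartment", ""),
            formula=d.get("formula"),
            delta_g_formation=d.get("delta_g_formation"),
        )
        for d in data["metabolites"]
    ]
    rxns = [
        Reaction(
            id=d["id"],
            stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
            lower_bound=float(d.get("lower_bound", -1000.0)),
            upper_bound=float(d.get("upper_bound", 1000.0)),
            gpr=parse_gpr(d.get("gpr")),
            subsystem=d.get("subsystem"),
            name=d.get("name", ""),
        )
        for d in data["reactions"]
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=data.get("objective_id"),
        annotations=data.get("annotations", {}),
        id=data.get("id", "model"),
    )


# ---------------------------------------------------------------------------
# I/O — SBML Level 3 + FBC
# ---------------------------------------------------------------------------

_SBML_SANITIZE_RE = re.compile(r"[^A-Za-z0-9_]")


def _sbml_id(raw: str) -> str:
    """Encode an id with bracket suffix into a valid SBML SId."""
    sid = raw.replace("[", "__LSQBKT__").replace("]", "__RSQBKT__")
    sid = _SBML_SANITIZE_RE.sub("_", sid)
    if sid and sid[0].isdigit():
        sid = "_" + sid
    return sid


def _from_sbml_id(sid: str) -> str:
    return sid.replace("__LSQBKT__", "[").replace("__RSQBKT__", "]")


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_id(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    comps = sorted({m.compartment for m in model.metabolites})
    for c in comps:
        comp = sbml_model.createCompartment()
        comp.setId(_sbml_id(c))
        comp.setConstant(True)
        comp.setSize(1.0)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sbml_id(m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sbml_id(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if m.formula is not None:
            splug.setChemicalFormula(m.formula)

    # flux bound parameters (deduplicated by value)
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for gene in sorted(model.genes()):
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_id(gene))
        gp.setLabel(gene)

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(_sbml_id(r.id))
        rxn.setName(r.name or r.id)
        rxn.setFast(False)
        rxn.setReversible(r.lower_bound < 0)
        for met_id, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                sr = rxn.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = rxn.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(_sbml_id(met_id))
            sr.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(
                r.gpr.to_string().replace("[", "").replace("]", ""), True, False
            )
        if r.subsystem:
            rxn.appendNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_id(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"could not write SBML to {path!r}")


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path!r}: no SBML model element")

    mets: list[Metabolite] = []
    for sp in sbml_model.getListOfSpecies():
        raw_id = _from_sbml_id(sp.getId())
        base, suffix_comp = split_compartment(raw_id)
        sbml_comp = _from_sbml_id(sp.getCompartment()) if sp.getCompartment() else None
        # SBML compartment attribute takes precedence over bracket suffix
        comp = sbml_comp or suffix_comp or ""
        if suffix_comp and sbml_comp and suffix_comp != sbml_comp:
            warnings.warn(
                f"species {raw_id!r}: bracket suffix [{suffix_comp}] conflicts with "
                f"SBML compartment {sbml_comp!r}; using the SBML attribute"
            )
        splug = sp.getPlugin("fbc")
        formula = None
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        mets.append(
            Metabolite(
                id=raw_id,
                name=sp.getName() or raw_id,
                compartment=comp,
                formula=formula,
            )
        )

    params = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }
    rxns: list[Reaction] = []
    for rx in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in rx.getListOfReactants():
            met = _from_sbml_id(sr.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - sr.getStoichiometry()
        for sr in rx.getListOfProducts():
            met = _from_sbml_id(sr.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + sr.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -math.inf, math.inf
        gpr = GPR(None)
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), -math.inf)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), math.inf)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                assoc = gpa.getAssociation()
                gpr = parse_gpr(_association_to_string(assoc))
        subsystem = None
        if rx.isSetNotes():
            notes = rx.getNotesString()
            m = re.search(r"SUBSYSTEM:\s*([^<]+)", notes)
            if m:
                subsystem = m.group(1).strip()
        rxns.append(
            Reaction(
                id=_from_sbml_id(rx.getId()),
                stoichiometry={k: v for k, v in stoich.items() if v != 0},
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
                name=rx.getName() or "",
            )
        )

    objective_id = None
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            objective_id = _from_sbml_id(obj.getFluxObjective(0).getReaction())

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=objective_id,
        id=_from_sbml_id(sbml_model.getId() or "model"),
    )


def _association_to_string(assoc) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getGeneProduct()
        return _from_sbml_id(gp)
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _association_to_string(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _association_to_string(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    raise ModelParseError(f"unsupported gene association node {assoc!r}")


# ---------------------------------------------------------------------------
# Public I/O surface
# ---------------------------------------------------------------------------


def read_model(path: str, format: str = "json") -> MetabolicModel:
    """Read a model from ``path`` in the named format (``json`` or ``sbml``)."""
    if format == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path!r}: invalid JSON at line {exc.lineno}") from exc
        return _model_from_dict(data)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str, format: str = "json") -> None:
    """Write a model; round-trips through :func:`read_model`."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if format == "sbml":
        _write_sbml(model, path)
        return
    raise ValueError(f"unknown model format {format!r}")
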