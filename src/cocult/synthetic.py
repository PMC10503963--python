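"""Deterministic generators for every input the pipeline consumes.

The toy cell model is a lumped central-carbon network — glycolysis, a serine
side-branch, the TCA cycle, glutaminolysis, oxidative phosphorylation with
explicit complexes I/III/IV/V plus an optional proton leak across the inner
membrane, lactate/pyruvate/alanine/citrate transport, and a biomass drain —
small enough (~40 reactions) that brute-force oracles run in seconds, yet
structured enough to exercise thermodynamic directionality, expression-based
pruning, co-culture assembly, respirometry and flux analysis.

Compartments: ``e`` extracellular, ``c`` cytosol, ``m`` mitochondrial
matrix, ``i`` intermembrane space (proton gradient only). Internal reactions
are elementally balanced (H and O closed automatically with water/protons
after C/N/P/S balance by construction); the biomass pseudo-reaction is the
only unchecked internal reaction.

The two cell kinds differ by documented bound asymmetries: the myeloma-like
cell has higher glycolytic and glutamine-transport capacity but lower
respiratory-chain capacity than the stromal-like cell, so merging them
creates a genuine substrate trade-off and a stroma-to-myeloma pyruvate
shuttle becomes metabolically attractive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coculture import ETCMap
from .extraction import ExpressionDataset
from .fba import Medium
from .mfa import (
    AtomNetwork,
    EMU,
    MIDMeasurement,
    Tracer,
    decompose_emus,
    make_emu,
    parse_atom_network,
    simulate_mids,
)
from .netcore import MetabolicModel, Metabolite, Reaction, parse_formula, parse_gpr
from .thermo import ThermoEntry, ThermoTable

__all__ = [
    "ToySpec",
    "LabellingTruth",
    "make_toy_cell_model",
    "make_expression_dataset",
    "make_atom_mapped_toynet",
    "toy_mfa_truth_fluxes",
    "toy_target_fragments",
    "simulate_labelling_experiment",
    "generate_fixture_dir",
]


@dataclass
class ToySpec:
    """Parameters of the toy cell generator; the seed fixes all randomness."""

    seed: int = 0
    include_leak: bool = True
    leak_capacity: float = 0.1  # mmol H+/gDW/h through the inner membrane
    pump_stoichiometry: float = 10.0  # protons pumped per 1/2 O2 (per NADH)
    atp_synthase_h: float = 4.0  # protons per ATP
    biomass_composition: dict[str, float] = field(
        default_factory=lambda: {
            "pyr[c]": 20.0,
            "ser[c]": 5.0,
            "cit[c]": 3.0,
            "ala[c]": 3.0,
        }
    )
    atp_per_biomass: float = 35.0
    maintenance_atp: float = 0.2  # lower bound on non-growth ATP hydrolysis
    shared_substrates: list[str] = field(
        default_factory=lambda: ["glc", "gln", "o2"]
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.biomass_composition.values()):
            raise ValueError("biomass coefficients must be positive")
        if self.pump_stoichiometry <= 0 or self.atp_synthase_h <= 0:
            raise ValueError("proton stoichiometries must be positive")


_FORMULAS = {
    "glc": "C6H12O6",
    "pyr": "C3H4O3",
    "lac": "C3H6O3",
    "ala": "C3H7NO2",
    "ser": "C3H7NO3",
    "gln": "C5H10N2O3",
    "glu": "C5H9NO4",
    "akg": "C5H6O5",
    "oaa": "C4H4O5",
    "cit": "C6H8O7",
    "accoa": "C23H38N7O17P3S",
    "coa": "C21H36N7O16P3S",
    "nad": "C21H26N7O14P2",
    "nadh": "C21H27N7O14P2",
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "pi": "HO4P",
    "nh3": "H3N",
    "co2": "CO2",
    "o2": "O2",
    "h2o": "H2O",
    "h": "H",
    "q": "C9H10O4",
    "qh2": "C9H12O4",
    "cytc_ox": "X",
    "cytc_red": "XH",
    "biomass": None,
}

#: synthetic formation energies (kJ/mol); directions they imply are toy
#: choices, not measured values
_DGF = {
    "glc": 0.0, "pyr": -120.0, "lac": -121.0, "ala": -130.0, "ser": -55.0,
    "gln": -200.0, "glu": -210.0, "akg": -250.0, "oaa": -215.0, "cit": -310.0,
    "accoa": -60.0, "coa": 0.0, "nad": 0.0, "nadh": 0.0,
    "atp": 0.0, "adp": 0.0, "pi": 0.0, "nh3": -10.0, "co2": -90.0,
    "o2": 240.0, "h2o": 0.0, "h": 0.0, "q": 0.0, "qh2": -30.0,
    "cytc_ox": 0.0, "cytc_red": -20.0,
}


def _met(base: str, comp: str) -> str:
    return f"{base}[{comp}]"


def make_toy_cell_model(
    spec: ToySpec | None = None, cell_kind: str = "stromal_like"
) -> tuple[MetabolicModel, ETCMap, ThermoTable, Medium]:
    """Build one toy cell model plus its ETC map, thermo table and medium."""
    spec = spec or ToySpec()
    if cell_kind not in ("stromal_like", "myeloma_like"):
        raise ValueError(f"unknown cell kind {cell_kind!r}")
    myeloma = cell_kind == "myeloma_like"

    # bound asymmetries making co-culture trade-offs non-trivial
    glyc_cap = 2.0 if myeloma else 1.0
    glc_cap = 0.9 if myeloma else 0.5
    gln_cap = 1.0 if myeloma else 0.7
    civ_cap = 1.5 if myeloma else 5.0

    P = spec.pump_stoichiometry
    p1, p2 = 4.0, 2.0
    if P <= p1 + p2:
        p1, p2 = 0.4 * P, 0.2 * P
    p3 = P - p1 - p2

    mets: list[Metabolite] = []

    def add_met(base: str, comp: str) -> str:
        mid = _met(base, comp)
        mets.append(Metabolite(id=mid, name=base, compartment=comp,
                               formula=_FORMULAS[base],
                               delta_g_formation=_DGF.get(base)))
        return mid

    for base in ("glc", "gln", "o2", "lac", "pyr", "ala", "ser", "co2",
                 "h2o", "h", "nh3"):
        add_met(base, "e")
    for base in ("glc", "gln", "pyr", "lac", "ala", "ser", "glu", "akg",
                 "cit", "nad", "nadh", "atp", "adp", "pi", "nh3", "h2o",
                 "h", "biomass"):
        add_met(base, "c")
    for base in ("pyr", "gln", "glu", "akg", "oaa", "cit", "accoa", "coa",
                 "nad", "nadh", "atp", "adp", "pi", "co2", "o2", "nh3",
                 "h2o", "h", "q", "qh2", "cytc_ox", "cytc_red"):
        add_met(base, "m")
    add_met("h", "i")

    R: list[Reaction] = []

    def add(rid, stoich, lb, ub, gpr="", subsystem=None, name=""):
        R.append(Reaction(rid, dict(stoich), lb, ub, parse_gpr(gpr), subsystem, name))

    # --- exchanges (met[e] leaves at positive flux) ---
    for base in ("glc", "gln", "o2", "lac", "pyr", "ala", "ser", "co2",
                 "h2o", "h", "nh3"):
        add(f"EX_{base}", {_met(base, "e"): -1.0}, -1000.0, 1000.0,
            subsystem="exchange")

    # --- transport ---
    add("GLCt", {_met("glc", "e"): -1, _met("glc", "c"): 1}, 0, glc_cap,
        gpr=f"g_GLCt_{cell_kind[0]}", subsystem="transport")
    add("GLNt", {_met("gln", "e"): -1, _met("gln", "c"): 1}, 0, gln_cap,
        gpr="g_GLNt", subsystem="transport")
    add("O2t", {_met("o2", "e"): -1, _met("o2", "m"): 1}, 0, 1000,
        subsystem="transport")
    add("LACt", {_met("lac", "c"): -1, _met("lac", "e"): 1}, -1000, 1000,
        gpr="g_MCT1 or g_MCT4", subsystem="transport")
    add("PYRte", {_met("pyr", "c"): -1, _met("pyr", "e"): 1}, -1000, 1000,
        gpr="g_MCT1", subsystem="transport")
    add("ALAt", {_met("ala", "c"): -1, _met("ala", "e"): 1}, -1000, 1000,
        gpr="g_ALAt", subsystem="transport")
    add("SERt", {_met("ser", "c"): -1, _met("ser", "e"): 1}, -1000, 1000,
        gpr="g_SERt", subsystem="transport")
    add("CO2t", {_met("co2", "m"): -1, _met("co2", "e"): 1}, -1000, 1000,
        subsystem="transport")
    add("NH3t", {_met("nh3", "c"): -1, _met("nh3", "e"): 1}, -1000, 1000,
        subsystem="transport")
    add("NH3tm", {_met("nh3", "m"): -1, _met("nh3", "c"): 1}, -1000, 1000,
        subsystem="transport")
    add("H2Ot", {_met("h2o", "c"): -1, _met("h2o", "e"): 1}, -1000, 1000,
        subsystem="transport")
    add("H2Otm", {_met("h2o", "m"): -1, _met("h2o", "c"): 1}, -1000, 1000,
        subsystem="transport")
    add("Ht", {_met("h", "c"): -1, _met("h", "e"): 1}, -1000, 1000,
        subsystem="transport")
    add("Htm", {_met("h", "m"): -1, _met("h", "c"): 1}, -1000, 1000,
        subsystem="transport")
    add("PYRtm", {_met("pyr", "c"): -1, _met("pyr", "m"): 1}, 0, 1000,
        gpr="g_MPC1 and g_MPC2", subsystem="transport")
    add("GLNtm", {_met("gln", "c"): -1, _met("gln", "m"): 1}, 0, 1000,
        subsystem="transport")
    add("GLUtm", {_met("glu", "m"): -1, _met("glu", "c"): 1}, -1000, 1000,
        gpr="g_GLUt", subsystem="transport")
    add("AKGtm", {_met("akg", "c"): -1, _met("akg", "m"): 1}, -1000, 1000,
        gpr="g_SLC25A11", subsystem="transport")
    add("CITtc", {_met("cit", "m"): -1, _met("cit", "c"): 1}, 0, 1000,
        gpr="g_SLC25A1", subsystem="transport")
    add("ANT", {_met("atp", "m"): -1, _met("adp", "c"): -1,
                _met("atp", "c"): 1, _met("adp", "m"): 1}, -1000, 1000,
        gpr="g_ANT", subsystem="transport")
    add("PIt", {_met("pi", "c"): -1, _met("pi", "m"): 1}, -1000, 1000,
        subsystem="transport")
    # malate-aspartate shuttle, lumped as a reversible redox transfer
    add("MAS", {_met("nadh", "c"): -1, _met("nad", "m"): -1,
                _met("nad", "c"): 1, _met("nadh", "m"): 1}, -1000, 1000,
        gpr="g_MDH1 and g_GOT1", subsystem="shuttle")

    # --- cytosolic metabolism ---
    # declared reversible on purpose: the thermodynamic step will force it
    add("GLYC", {_met("glc", "c"): -1, _met("adp", "c"): -2,
                 _met("pi", "c"): -2, _met("nad", "c"): -2,
                 _met("pyr", "c"): 2, _met("atp", "c"): 2,
                 _met("nadh", "c"): 2}, -glyc_cap, glyc_cap,
        gpr="(g_HK1 and g_PFK1 and g_PKM) or g_GLYC_iso", subsystem="glycolysis")
    add("LDH", {_met("pyr", "c"): -1, _met("nadh", "c"): -1,
                _met("lac", "c"): 1, _met("nad", "c"): 1}, -1000, 1000,
        gpr="g_LDHA or g_LDHB", subsystem="glycolysis")
    add("SERSYN", {_met("glc", "c"): -1, _met("nh3", "c"): -2,
                   _met("nad", "c"): -2, _met("ser", "c"): 2,
                   _met("nadh", "c"): 2}, 0, 1000,
        gpr="g_PHGDH and g_PSAT1", subsystem="serine")
    add("ALT", {_met("pyr", "c"): -1, _met("glu", "c"): -1,
                _met("ala", "c"): 1, _met("akg", "c"): 1}, -1000, 1000,
        gpr="g_GPT", subsystem="amino acids")
    add("GLS", {_met("gln", "c"): -1, _met("h2o", "c"): -1,
                _met("glu", "c"): 1, _met("nh3", "c"): 1}, 0, 1000,
        gpr="g_GLS", subsystem="glutaminolysis")
    add("ATPM", {_met("atp", "c"): -1, _met("h2o", "c"): -1,
                 _met("adp", "c"): 1, _met("pi", "c"): 1},
        spec.maintenance_atp, 1000, subsystem="maintenance")

    # --- mitochondrial metabolism ---
    add("PDH", {_met("pyr", "m"): -1, _met("coa", "m"): -1,
                _met("nad", "m"): -1, _met("accoa", "m"): 1,
                _met("co2", "m"): 1, _met("nadh", "m"): 1}, 0, 1000,
        gpr="g_PDHA1 and g_DLAT", subsystem="tca")
    add("PC", {_met("pyr", "m"): -1, _met("co2", "m"): -1,
               _met("atp", "m"): -1, _met("oaa", "m"): 1,
               _met("adp", "m"): 1, _met("pi", "m"): 1}, 0, 1000,
        gpr="g_PC", subsystem="tca")
    add("CS", {_met("accoa", "m"): -1, _met("oaa", "m"): -1,
               _met("h2o", "m"): -1, _met("cit", "m"): 1,
               _met("coa", "m"): 1}, 0, 1000, gpr="g_CS", subsystem="tca")
    add("IDH", {_met("cit", "m"): -1, _met("nad", "m"): -1,
                _met("akg", "m"): 1, _met("co2", "m"): 1,
                _met("nadh", "m"): 1}, 0, 1000,
        gpr="g_ACO2 and g_IDH3", subsystem="tca")
    add("AKGD", {_met("akg", "m"): -1, _met("nad", "m"): -2,
                 _met("adp", "m"): -1, _met("pi", "m"): -1,
                 _met("oaa", "m"): 1, _met("co2", "m"): 1,
                 _met("nadh", "m"): 2, _met("atp", "m"): 1}, 0, 1000,
        gpr="g_OGDH and g_SDHA and g_MDH2", subsystem="tca")
    # lumped malic-enzyme route: lets anaplerotic carbon leave the cycle,
    # so glutamine can be fully oxidised
    add("ME", {_met("oaa", "m"): -1, _met("pyr", "m"): 1,
               _met("co2", "m"): 1}, 0, 1000,
        gpr="g_ME2", subsystem="tca")
    add("GDH", {_met("glu", "m"): -1, _met("nad", "m"): -1,
                _met("h2o", "m"): -1, _met("akg", "m"): 1,
                _met("nadh", "m"): 1, _met("nh3", "m"): 1}, 0, 1000,
        gpr="g_GLUD1", subsystem="glutaminolysis")
    add("GLSm", {_met("gln", "m"): -1, _met("h2o", "m"): -1,
                 _met("glu", "m"): 1, _met("nh3", "m"): 1}, 0, 1000,
        gpr="g_GLS2", subsystem="glutaminolysis")

    # --- electron transport chain ---
    add("CxI", {_met("nadh", "m"): -1, _met("q", "m"): -1,
                _met("h", "m"): -(1 + p1), _met("nad", "m"): 1,
                _met("qh2", "m"): 1, _met("h", "i"): p1}, 0, 1000,
        gpr="g_NDUFS1", subsystem="oxphos", name="complex I")
    add("CxIII", {_met("qh2", "m"): -1, _met("cytc_ox", "m"): -2,
                  _met("h", "m"): -p2, _met("q", "m"): 1,
                  _met("cytc_red", "m"): 2, _met("h", "i"): p2}, 0, 1000,
        gpr="g_UQCRC1", subsystem="oxphos", name="complex III")
    add("CxIV", {_met("cytc_red", "m"): -2, _met("o2", "m"): -0.5,
                 _met("h", "m"): -(2 + p3), _met("cytc_ox", "m"): 2,
                 _met("h2o", "m"): 1, _met("h", "i"): p3}, 0, civ_cap,
        gpr="g_COX4I1", subsystem="oxphos", name="complex IV")
    add("CxV", {_met("adp", "m"): -1, _met("pi", "m"): -1,
                _met("h", "i"): -spec.atp_synthase_h, _met("atp", "m"): 1,
                _met("h2o", "m"): 1, _met("h", "m"): spec.atp_synthase_h - 1},
        0, 1000, gpr="g_ATP5F1A", subsystem="oxphos", name="ATP synthase")
    if spec.include_leak:
        add("LEAK", {_met("h", "i"): -1, _met("h", "m"): 1},
            0, spec.leak_capacity, subsystem="oxphos", name="proton leak")

    # --- biomass ---
    bio_stoich = {mid: -coef for mid, coef in spec.biomass_composition.items()}
    bio_stoich[_met("atp", "c")] = -spec.atp_per_biomass
    bio_stoich[_met("h2o", "c")] = -spec.atp_per_biomass
    bio_stoich[_met("adp", "c")] = spec.atp_per_biomass
    bio_stoich[_met("pi", "c")] = spec.atp_per_biomass
    bio_stoich[_met("biomass", "c")] = 1.0
    add("BIOMASS", bio_stoich, 0, 1000, subsystem="biomass")
    add("DM_biomass", {_met("biomass", "c"): -1}, 0, 1000, subsystem="biomass")

    model = MetabolicModel(
        metabolites=mets,
        reactions=R,
        objective_id="BIOMASS",
        id=f"toy_{cell_kind}",
        annotations={"cell_kind": cell_kind},
    )
    _autobalance(model)

    etc = ETCMap(
        complex_i="CxI",
        complex_iii="CxIII",
        complex_iv="CxIV",
        complex_v="CxV",
        oxygen_exchange="EX_o2",
        proton_leak="LEAK" if spec.include_leak else None,
    )

    thermo = ThermoTable(
        entries={base: ThermoEntry(delta_g_formation=dgf)
                 for base, dgf in _DGF.items()},
    )

    medium = Medium(
        uptake={_met("glc", "e"): 0.45, _met("gln", "e"): 0.63,
                _met("o2", "e"): 5.0},
        free_species={_met(b, "e") for b in ("co2", "h", "h2o", "nh3")},
    )
    return model, etc, thermo, medium


def _autobalance(model: MetabolicModel) -> None:
    """Close H and O balances with water and protons, in place.

    C/N/P/S are balanced by construction; any residual H/O (from lumping) is
    absorbed by the reaction compartment's h2o and h pools.
    """
    formulas = {m.id: parse_formula(m.formula) if m.formula else None
                for m in model.metabolites}
    for r in model.reactions:
        if len(r.stoichiometry) == 1:
            continue
        if any(formulas[m] is None for m in r.stoichiometry):
            continue
        comp = _reaction_compartment(model, r)
        h2o_id, h_id = _met("h2o", comp), _met("h", comp)
        for _ in range(2):
            net: dict[str, float] = {}
            for mid, coef in r.stoichiometry.items():
                for el, n in formulas[mid].items():
                    net[el] = net.get(el, 0.0) + coef * n
            d_o = net.get("O", 0.0)
            if abs(d_o) > 1e-9:
                r.stoichiometry[h2o_id] = r.stoichiometry.get(h2o_id, 0.0) - d_o
                if r.stoichiometry[h2o_id] == 0:
                    del r.stoichiometry[h2o_id]
                continue
            d_h = net.get("H", 0.0)
            if abs(d_h) > 1e-9:
                r.stoichiometry[h_id] = r.stoichiometry.get(h_id, 0.0) - d_h
                if r.stoichiometry[h_id] == 0:
                    del r.stoichiometry[h_id]
            break


def _reaction_compartment(model: MetabolicModel, r: Reaction) -> str:
    comps = [model.metabolite(m).compartment for m in r.stoichiometry]
    for preferred in ("m", "c"):
        if preferred in comps:
            return preferred
    return comps[0]


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------


def make_expression_dataset(
    model: MetabolicModel,
    n_samples: int = 12,
    presence_profile: dict[str, float] | float = 0.9,
    seed: int = 0,
) -> ExpressionDataset:
    """Sample binary presence calls per gene and sample.

    ``presence_profile`` assigns each gene a Bernoulli presence probability
    (a scalar applies to every gene).
    """
    genes = sorted(model.genes())
    if isinstance(presence_profile, (int, float)):
        presence_profile = {g: float(presence_profile) for g in genes}
    probs = []
    for g in genes:
        p = presence_profile.get(g, 0.0)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"presence probability for {g!r} outside [0,1]: {p}")
        probs.append(p)
    rng = np.random.default_rng(seed)
    calls = (rng.random((len(genes), n_samples)) < np.array(probs)[:, None]).astype(int)
    samples = [f"sample_{i + 1:02d}" for i in range(n_samples)]
    return ExpressionDataset(genes=genes, samples=samples, calls=calls)


# ---------------------------------------------------------------------------
# Atom-mapped flux-analysis toy network
# ---------------------------------------------------------------------------

_TOYNET_TEXT = """\
# lumped central-carbon atom-transition network for 13C flux analysis
external: Glc_x Gln_x Lac_x Ala_x CO2_x Bio_x
symmetric: Suc

v_glc:     Glc_x (abcdef) -> Glc (abcdef)
v_gly:     Glc (abcdef) -> Pyr (cba) + Pyr (def)
v_ldh:     Pyr (abc) -> Lac (abc)
v_lac_out: Lac (abc) -> Lac_x (abc)
v_pdh:     Pyr (abc) -> AcCoA (bc) + CO2 (a)
v_pc:      Pyr (abc) + CO2 (d) -> OAA (abcd)
v_cs:      OAA (abcd) + AcCoA (ef) -> Cit (abcdef)
v_idh:     Cit (abcdef) -> AKG (abcde) + CO2 (f)
v_akgd:    AKG (abcde) -> Suc (bcde) + CO2 (a)
v_sdh:     Suc (abcd) -> OAA (abcd)
v_gln:     Gln_x (abcde) -> Gln (abcde)
v_gls:     Gln (abcde) -> Glu (abcde)
v_gdh:     Glu (abcde) -> AKG (abcde)
v_alt:     Pyr (abc) -> Ala (abc)
v_ala_out: Ala (abc) -> Ala_x (abc)
v_co2_out: CO2 (a) -> CO2_x (a)
v_bio:     OAA (abcd) -> Bio_x (abcd)
"""


def make_atom_mapped_toynet() -> tuple[AtomNetwork, dict[str, int]]:
    """The bundled atom-mapped network and its per-metabolite carbon counts.

    Anaplerosis enters the TCA cycle both via pyruvate carboxylase and via
    glutamine -> glutamate -> alpha-ketoglutarate; the symmetric four-carbon
    intermediate (declared as succinate) scrambles the cycle's carbons.
    """
    net = parse_atom_network(_TOYNET_TEXT)
    return net, net.carbon_counts()


def toy_mfa_truth_fluxes() -> dict[str, float]:
    """The generator's reference steady-state flux vector (mmol/gDW/h scale).

    Glucose and glutamine uptakes mirror typical measured magnitudes
    (0.45 and 0.63); the remaining fluxes close every internal balance.
    """
    v = {
        "v_glc": 0.45,
        "v_gly": 0.45,
        "v_ldh": 0.25,
        "v_lac_out": 0.25,
        "v_pdh": 0.40,
        "v_pc": 0.14,
        "v_cs": 0.40,
        "v_idh": 0.40,
        "v_akgd": 1.03,
        "v_sdh": 1.03,
        "v_gln": 0.63,
        "v_gls": 0.63,
        "v_gdh": 0.63,
        "v_alt": 0.11,
        "v_ala_out": 0.11,
        "v_co2_out": 1.69,
        "v_bio": 0.77,
    }
    return v


def toy_target_fragments() -> list[EMU]:
    """Measured fragments: lactate, alanine, citrate, AKG and OAA backbones."""
    return [
        make_emu("Lac", (1, 2, 3)),
        make_emu("Ala", (1, 2, 3)),
        make_emu("Cit", (1, 2, 3, 4, 5, 6)),
        make_emu("AKG", (1, 2, 3, 4, 5)),
        make_emu("OAA", (1, 2, 3, 4)),
    ]


@dataclass
class LabellingTruth:
    """Ground truth for a simulated tracing experiment."""

    fluxes: dict[str, float]
    tracers: list[Tracer]
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_labelling_experiment(
    truth: LabellingTruth,
    fragments: list[EMU] | None = None,
    network: AtomNetwork | None = None,
    min_reported_sd: float = 1e-3,
) -> list[MIDMeasurement]:
    """Forward-simulate MIDs from a known flux vector and add Gaussian noise.

    Noise is additive on mole fractions, clipped at zero and renormalised to
    sum one. The reported standard deviation is ``max(noise_sd,
    min_reported_sd)`` so zero-noise datasets stay usable as weights.
    Deterministic given ``truth.seed``.
    """
    net = network or make_atom_mapped_toynet()[0]
    frags = fragments or toy_target_fragments()
    S, mets = net.stoichiometric_matrix()
    v = np.array([truth.fluxes.get(r, 0.0) for r in net.reaction_ids])
    if np.abs(S @ v).max() > 1e-6:
        raise ValueError("truth fluxes are not at steady state on the network")
    emunet = decompose_emus(net, frags)
    sims = simulate_mids(emunet, truth.fluxes, truth.tracers)
    rng = np.random.default_rng(truth.seed)
    sd = max(truth.noise_sd, min_reported_sd)
    out = []
    for mid in sims:
        vals = mid.fractions.copy()
        if truth.noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, truth.noise_sd, vals.shape), 0, None)
            vals = vals / vals.sum()
        out.append(
            MIDMeasurement(
                fragment=mid.fragment,
                values=vals,
                sds=np.full(vals.shape, sd),
            )
        )
    return out


def toy_mfa_model(
    noise_sd: float = 0.005,
    seed: int = 0,
    fluxes: dict[str, float] | None = None,
    flux_measurement_sd: float = 0.01,
    default_upper_bound: float = 5.0,
):
    """Assemble the standard two-tracer toy flux-analysis problem.

    Parallel U-13C glucose and U-13C glutamine experiments are simulated
    from ``fluxes`` (default :func:`toy_mfa_truth_fluxes`) with additive
    Gaussian noise, alongside measured uptake/secretion rates for glucose,
    glutamine, lactate and alanine — the four rates a tracer study measures
    directly, and without which the lactate/alanine efflux split is not
    identifiable from labelling alone.
    """
    from .mfa import Experiment, MFAModel

    net, _ = make_atom_mapped_toynet()
    v = fluxes or toy_mfa_truth_fluxes()
    experiments = []
    for i, (name, tracer) in enumerate(
        (("glc", Tracer("Glc_x", "U")), ("gln", Tracer("Gln_x", "U")))
    ):
        truth = LabellingTruth(fluxes=v, tracers=[tracer], noise_sd=noise_sd,
                               seed=(seed * 7919 + i) % (2**31 - 1))
        mids = simulate_labelling_experiment(truth, network=net)
        experiments.append(Experiment(name=name, tracers=[tracer],
                                      measurements=mids))
    meas = {
        rid: (v[rid], flux_measurement_sd)
        for rid in ("v_glc", "v_gln", "v_lac_out", "v_ala_out")
    }
    return MFAModel(
        network=net,
        experiments=experiments,
        flux_measurements=meas,
        default_upper_bound=default_upper_bound,
    ), v


# ---------------------------------------------------------------------------
# Whole fixture directories
# ---------------------------------------------------------------------------


def default_presence_profile(model: MetabolicModel, seed: int = 0) -> dict[str, float]:
    """High presence for core-pathway genes, low for dispensable transport."""
    low = {"g_ALAt", "g_SERt", "g_GLYC_iso", "g_MCT4", "g_GLS2"}
    return {g: (0.15 if g in low else 0.9) for g in sorted(model.genes())}


def generate_fixture_dir(outdir, spec: ToySpec | None = None, seed: int = 0):
    """Write a complete input fixture (models, tables, network, labelling).

    Returns the manifest of written relative paths.
    """
    import json
    import pathlib

    import pandas as pd

    from .extraction import write_expression_tsv
    from .mfa import write_mid_csv
    from .netcore import write_model

    spec = spec or ToySpec(seed=seed)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    models = {}
    for kind, tagname in (("stromal_like", "bm"), ("myeloma_like", "cm")):
        model, etc, thermo, medium = make_toy_cell_model(spec, kind)
        models[tagname] = (model, etc, thermo, medium)
        write_model(model, str(outdir / f"model_{tagname}.json"), "json")
        written.append(f"model_{tagname}.json")
        expr = make_expression_dataset(
            model, n_samples=12,
            presence_profile=default_presence_profile(model), seed=seed,
        )
        write_expression_tsv(expr, str(outdir / f"expression_{tagname}.tsv"))
        written.append(f"expression_{tagname}.tsv")

    _, etc, thermo, medium = models["bm"]
    pd.DataFrame(
        [
            {"metabolite_id": k, "dgf_kj_mol": e.delta_g_formation,
             "conc_min_M": e.conc_min, "conc_max_M": e.conc_max}
            for k, e in sorted(thermo.entries.items())
        ]
    ).to_csv(outdir / "thermo.tsv", sep="\t", index=False)
    written.append("thermo.tsv")
    pd.DataFrame(
        [{"metabolite_id": k, "max_uptake": u} for k, u in sorted(medium.uptake.items())]
    ).to_csv(outdir / "medium.tsv", sep="\t", index=False)
    written.append("medium.tsv")
    (outdir / "free_species.txt").write_text(
        "\n".join(sorted(medium.free_species)) + "\n"
    )
    written.append("free_species.txt")

    net, _ = make_atom_mapped_toynet()
    (outdir / "atom_network.txt").write_text(net.to_text())
    written.append("atom_network.txt")

    fluxes = toy_mfa_truth_fluxes()
    for name, tracer in (
        ("glc", Tracer("Glc_x", "U")),
        ("gln", Tracer("Gln_x", "U")),
    ):
        truth = LabellingTruth(fluxes=fluxes, tracers=[tracer], seed=seed)
        mids = simulate_labelling_experiment(truth, network=net)
        write_mid_csv(mids, str(outdir / f"mids_{name}.csv"))
        written.append(f"mids_{name}.csv")
    with open(outdir / "truth_fluxes.json", "w") as fh:
        json.dump(fluxes, fh, indent=1, sort_keys=True)
    written.append("truth_fluxes.json")
    return written
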