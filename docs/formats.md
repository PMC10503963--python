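# File formats

## JSON model dialect (schema_version 1)

A deterministic serialisation of a metabolic model: keys are sorted, floats
are written as-is, and two writes of the same model are byte-identical.

```json
{
 "schema_version": 1,
 "id": "toy_stromal_like",
 "objective_id": "BIOMASS",
 "annotations": {},
 "metabolites": [
  {"id": "glc[e]", "name": "glc", "compartment": "e",
   "formula": "C6H12O6", "delta_g_formation": 0.0}
 ],
 "reactions": [
  {"id": "GLCt", "name": "", "stoichiometry": {"glc[c]": 1.0, "glc[e]": -1.0},
   "lower_bound": 0.0, "upper_bound": 0.5,
   "gpr": "g_GLCt_s", "subsystem": "transport"}
 ]
}
```

Conventions:

* metabolite ids carry a bracket compartment suffix, `met[tag]`; the shared
  extracellular space is always `e`;
* flux bounds are mmol/gDW/h; exchange reactions are written
  `met[e] ->` (coefficient −1), so **uptake is negative flux**;
* `gpr` is a boolean expression over gene ids with `and`/`or` and
  parentheses; an empty string means no gene association;
* reactions with zero coefficients are rejected at load.

SBML Level 3 + FBC is supported in parallel (`format="sbml"`); bounds,
objective and gene associations go through the FBC package, and bracket
suffixes are encoded into valid SBML SIds. If a species carries both an SBML
compartment attribute and a bracket suffix and they disagree, the SBML
attribute wins with a warning.

## Tables (TSV/CSV, header row required)

* **Medium TSV** — columns `metabolite_id`, `max_uptake` (mmol/gDW/h,
  magnitudes). Free species (always exchangeable both directions) are given
  separately, e.g. one id per line in `free_species.txt`.
* **Thermo TSV** — columns `metabolite_id`, `dgf_kj_mol` and optional
  `conc_min_M`, `conc_max_M`. Ids may be base ids (`glc`) applying to every
  compartment, or full ids (`glc[c]`) which take precedence.
* **Expression TSV** — first column `gene`, remaining columns one per
  sample, entries 0/1 (absent/present calls).
* **MID CSV** — columns `fragment_id`, `mass_shift`, `value`, `sd`. Fragment
  ids are `Met:1,2,3` (1-based carbon positions).
* **Intervals CSV** — columns `reaction_id`, `lo`, `hi` (bounds intersected
  onto the model by phenotype tuning).

## Atom-transition network grammar

One reaction per line; `#` starts a comment. Carbon atoms are letters;
within a line every letter appears exactly once on each side.

```
external: Glc_x Lac_x          # sources/sinks outside the mass balance
symmetric: Suc                 # rotationally symmetric metabolites

v_gly: Glc (abcdef) -> Pyr (cba) + Pyr (def)
v_cs:  OAA (abcd) + AcCoA (ef) -> Cit (abcdef)
```

Reactions are unidirectional; write a reversible step as two lines.
Producing a `symmetric` metabolite expands the mapping into the two atom
orientations at probability 1/2 each.
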