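"""End-to-end pipeline orchestration with provenance capture.

A :class:`PipelineConfig` names the stages to run, in order, with per-stage
parameters and one global seed. Stages must respect the workflow's partial
order (thermodynamic constraining and expression-based extraction happen per
cell before merging; flux analysis must precede phenotype tuning). Every
output file is hashed into a run manifest so that a rerun with the same
config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import yaml

log = logging.getLogger("cocult.pipeline")

STAGES = (
    "generate",
    "extract",
    "thermo",
    "merge",
    "mfa_fit",
    "tune",
    "respire",
    "pareto",
)

#: stage -> stages that must appear earlier in the list
_STAGE_PREREQS: dict[str, set[str]] = {
    "extract": {"generate"},
    "thermo": {"generate"},
    "merge": {"thermo", "extract"},
    "mfa_fit": {"generate"},
    "tune": {"mfa_fit", "merge"},
    "respire": {"merge"},
    "pareto": {"merge"},
}

__all__ = ["PipelineConfig", "PipelineConfigError", "run_pipeline", "STAGES"]


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    stages: list[str]
    params: dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineConfigError(f"unknown stages: {unknown}")
        seen: set[str] = set()
        for s in self.stages:
            missing = _STAGE_PREREQS.get(s, set()) - seen
            if missing:
                raise PipelineConfigError(
                    f"stage {s!r} requires {sorted(missing)} to run first"
                )
            seen.add(s)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            stages=data.get("stages", []),
            params=data.get("params", {}),
            seed=int(data.get("seed", 0)),
            log_level=data.get("log_level", "INFO"),
        )


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run the configured stages; return the manifest (also written to disk).

    Outputs land in ``outdir``; the manifest maps every artifact to its
    sha256 so reruns are comparable. A failing stage stops the run with the
    stage named.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s [%(name)s] %(message)s"))
    log.addHandler(fh)

    state: dict = {"seed": config.seed}
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    try:
        for stage in config.stages:
            log.info("stage %s: start", stage)
            params = config.params.get(stage, {})
            _STAGE_IMPLS[stage](state, params, out)
            manifest["stages"].append(stage)
            log.info("stage %s: done", stage)
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json" and p.name != "pipeline.log":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as mh:
        json.dump(manifest, mh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations (operate on a shared in-memory state dict)
# ---------------------------------------------------------------------------


def _stage_generate(state: dict, params: dict, out: pathlib.Path) -> None:
    from .synthetic import (
        ToySpec,
        default_presence_profile,
        make_expression_dataset,
        make_toy_cell_model,
    )

    spec = ToySpec(seed=state["seed"], **params.get("toy_spec", {}))
    state["spec"] = spec
    state["cells"] = {}
    for kind, tag in (("stromal_like", "bm"), ("myeloma_like", "cm")):
        model, etc, thermo, medium = make_toy_cell_model(spec, kind)
        expr = make_expression_dataset(
            model,
            n_samples=params.get("n_samples", 12),
            presence_profile=default_presence_profile(model),
            seed=state["seed"],
        )
        state["cells"][tag] = {
            "model": model, "etc": etc, "thermo": thermo,
            "medium": medium, "expr": expr,
        }
        from .netcore import write_model

        write_model(model, str(out / f"model_{tag}.json"), "json")


def _stage_extract(state: dict, params: dict, out: pathlib.Path) -> None:
    from .extraction import (
        connectivity_update,
        gene_ubiquity,
        prune_model,
        score_reactions,
    )
    from .netcore import write_model

    threshold = params.get("threshold", 0.5)
    frac = params.get("min_objective_fraction", 0.9)
    for tag, cell in state["cells"].items():
        scores = connectivity_update(
            cell["model"],
            score_reactions(cell["model"], gene_ubiquity(cell["expr"])),
        )
        # Only gene-associated reactions are candidates: absence of
        # expression evidence says nothing about non-enzymatic steps
        # (exchanges, passive transport, the proton leak, maintenance,
        # biomass machinery), so everything without a GPR is core.
        core = {cell["model"].objective_id, "DM_biomass"}
        core |= {r.id for r in cell["model"].reactions if r.gpr.is_empty}
        core |= set(params.get("core", []))
        core &= set(cell["model"].reaction_ids)
        cell["model"] = prune_model(cell["model"], scores, core, threshold, frac)
        write_model(cell["model"], str(out / f"model_{tag}_extracted.json"), "json")
        log.info("extract[%s]: %d reactions kept", tag, len(cell["model"].reactions))


def _stage_thermo(state: dict, params: dict, out: pathlib.Path) -> None:
    from .netcore import write_model
    from .thermo import fix_directionality, model_delta_g_ranges

    for tag, cell in state["cells"].items():
        ranges, skipped = model_delta_g_ranges(cell["model"], cell["thermo"])
        cell["model"] = fix_directionality(cell["model"], ranges)
        log.info("thermo[%s]: %d ranges, %d skipped", tag, len(ranges), len(skipped))
        write_model(cell["model"], str(out / f"model_{tag}_thermo.json"), "json")


def _stage_merge(state: dict, params: dict, out: pathlib.Path) -> None:
    from .coculture import merge_models
    from .fba import apply_medium_constraints
    from .netcore import write_model

    from .fba import Medium

    cells = state["cells"]
    (tag_a, cell_a), (tag_b, cell_b) = sorted(cells.items())
    cc = merge_models(cell_a["model"], cell_b["model"], tag_a, tag_b)
    # the shared boundary carries the sum of the two cells' allowances
    uptake: dict[str, float] = {}
    free: set[str] = set()
    for cell in (cell_a, cell_b):
        for met, u in cell["medium"].uptake.items():
            uptake[met] = uptake.get(met, 0.0) + u
        free |= cell["medium"].free_species
    cc.model = apply_medium_constraints(cc.model, Medium(uptake, free))
    state["coculture"] = cc
    write_model(cc.model, str(out / "model_coculture.json"), "json")


def _stage_mfa_fit(state: dict, params: dict, out: pathlib.Path) -> None:
    from .mfa import fit_fluxes, monte_carlo_ci
    from .synthetic import toy_mfa_model

    model, truth = toy_mfa_model(
        noise_sd=params.get("noise_sd", 0.005), seed=state["seed"]
    )
    est = fit_fluxes(
        model,
        n_restarts=params.get("n_restarts", 100),
        seed=state["seed"],
    )
    est = monte_carlo_ci(
        model, est, n_samples=params.get("n_mc_samples", 50), seed=state["seed"]
    )
    state["mfa"] = {"model": model, "estimate": est, "truth": truth}
    with open(out / "mfa_estimate.json", "w") as fh:
        json.dump(
            {
                "fluxes": est.fluxes,
                "ssr": est.ssr,
                "dof": est.dof,
                "chi2_pass": est.chi2_pass,
                "intervals": est.intervals,
            },
            fh, indent=1, sort_keys=True,
        )


def _stage_tune(state: dict, params: dict, out: pathlib.Path) -> None:
    from .coculture import apply_flux_intervals
    from .mfa import export_intervals
    from .netcore import write_model

    est = state["mfa"]["estimate"]
    cc = state["coculture"]
    tag_a = cc.tags[0].label
    # map measured uptake fluxes onto the first cell's transporters
    id_map = {
        "v_glc": f"GLCt_{tag_a}",
        "v_gln": f"GLNt_{tag_a}",
        "v_lac_out": f"LACt_{tag_a}",
    }
    table, unmapped = export_intervals(est, id_map, path=str(out / "intervals.csv"))
    intervals = {row.reaction_id: (row.lo, row.hi) for row in table.itertuples()}
    cc.model = apply_flux_intervals(cc.model, intervals)
    log.info("tune: %d intervals applied, %d unmapped", len(table), len(unmapped))
    write_model(cc.model, str(out / "model_coculture_tuned.json"), "json")


def _stage_respire(state: dict, params: dict, out: pathlib.Path) -> None:
    from .coculture import respiration_protocol
    from .fba import apply_medium_constraints

    profiles = {}
    for tag, cell in state["cells"].items():
        model = apply_medium_constraints(cell["model"], cell["medium"])
        prof = respiration_protocol(model, cell["etc"])
        profiles[tag] = {
            "basal_o2": prof.basal_o2,
            "oligomycin_o2": prof.oligomycin_o2,
            "fccp_o2": prof.fccp_o2,
            "rot_aa_o2": prof.rot_aa_o2,
            "atp_linked": prof.atp_linked,
            "spare_capacity": prof.spare_capacity,
        }
    state["respiration"] = profiles
    with open(out / "respiration.json", "w") as fh:
        json.dump(profiles, fh, indent=1, sort_keys=True)


def _stage_pareto(state: dict, params: dict, out: pathlib.Path) -> None:
    from .coculture import pareto_front

    cc = state["coculture"]
    points = pareto_front(cc, n_points=params.get("n_points", 21))
    state["pareto"] = points
    with open(out / "pareto.json", "w") as fh:
        json.dump(
            [{"biomass_a": p.biomass_a, "biomass_b": p.biomass_b} for p in points],
            fh, indent=1,
        )


_STAGE_IMPLS = {
    "generate": _stage_generate,
    "extract": _stage_extract,
    "thermo": _stage_thermo,
    "merge": _stage_merge,
    "mfa_fit": _stage_mfa_fit,
    "tune": _stage_tune,
    "respire": _stage_respire,
    "pareto": _stage_pareto,
}
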