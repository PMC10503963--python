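"""Expression-driven extraction of cell-specific models from a generic one.

The procedure follows the classic context-specific extraction recipe:

1. *Gene ubiquity* — each gene is scored by the fraction of samples in which
   a binary presence/absence call marks it present.
2. *Reaction expression scores* — gene scores are propagated through GPR
   rules (AND -> min, OR -> max). Reactions without a gene association get
   no expression score (distinct from a score of 0).
3. *Connectivity update* — each reaction's score is blended with the mean
   expression score of its network neighbours (reactions sharing at least
   one non-currency metabolite), so weakly-expressed reactions embedded in
   well-expressed pathways survive.
4. *Pruning* — non-core reactions are visited in ascending combined-score
   order and removed when their score falls below a threshold, provided the
   pruned model still grows (objective above a configured fraction of the
   original optimum) and every core reaction can still carry flux.

The original algorithm's evidence classes and salvage checks are not
reproduced; scoring here is the simplified, documented variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fba import fba_optimize, fva
from .netcore import MetabolicModel

DEFAULT_EXPRESSION_WEIGHT = 0.75
#: currency metabolites excluded from connectivity adjacency (base ids)
DEFAULT_CURRENCY_METABOLITES = (
    "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph",
    "h2o", "h", "co2", "pi", "ppi", "coa", "o2", "nh3", "nh4",
)

__all__ = [
    "ExpressionDataset",
    "ReactionScore",
    "gene_ubiquity",
    "score_reactions",
    "connectivity_update",
    "prune_model",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionDataset:
    """Binary gene presence/absence calls over samples."""

    genes: list[str]
    samples: list[str]
    calls: np.ndarray  # genes x samples, entries in {0, 1}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("expression calls must be binary (0/1)")


@dataclass
class ReactionScore:
    """Per-reaction evidence scores, each in [0, 1] when present."""

    reaction_id: str
    expression_score: float | None = None  # None = no gene association
    connectivity_score: float | None = None
    combined: float | None = None


def gene_ubiquity(expr: ExpressionDataset) -> dict[str, float]:
    """Fraction of samples calling each gene present."""
    if len(expr.samples) < 1:
        raise ValueError("expression dataset has no samples")
    means = expr.calls.mean(axis=1)
    return {g: float(means[i]) for i, g in enumerate(expr.genes)}


def score_reactions(
    model: MetabolicModel, gene_scores: dict[str, float]
) -> list[ReactionScore]:
    """Propagate gene ubiquity scores through GPR rules.

    Genes absent from ``gene_scores`` default to 0 with a warning; reactions
    with an empty GPR get ``expression_score=None``.
    """
    missing = sorted(
        g for r in model.reactions for g in r.gpr.genes() if g not in gene_scores
    )
    if missing:
        warnings.warn(
            "genes without expression scores default to 0: "
            + ", ".join(sorted(set(missing)))
        )
    out = []
    for r in model.reactions:
        if r.gpr.is_empty:
            out.append(ReactionScore(reaction_id=r.id, expression_score=None))
        else:
            out.append(
                ReactionScore(
                    reaction_id=r.id,
                    expression_score=r.gpr.evaluate(gene_scores, default=0.0),
                )
            )
    return out


def connectivity_update(
    model: MetabolicModel,
    scores: list[ReactionScore],
    weight: float = DEFAULT_EXPRESSION_WEIGHT,
    currency_metabolites: tuple[str, ...] = DEFAULT_CURRENCY_METABOLITES,
) -> list[ReactionScore]:
    """Blend expression scores with network-topology support.

    A reaction's connectivity score is the mean expression score of the
    reactions sharing at least one non-currency metabolite with it
    (neighbours without an expression score are excluded from the mean).
    ``combined = weight * expression + (1 - weight) * connectivity``;
    reactions without an expression score use the connectivity score alone.
    """
    from .netcore import split_compartment

    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    expr_of = {s.reaction_id: s.expression_score for s in scores}

    def is_currency(met_id: str) -> bool:
        base, _ = split_compartment(met_id)
        return base in currency_metabolites

    met_to_rxns: dict[str, set[str]] = {}
    for r in model.reactions:
        for met in r.stoichiometry:
            if not is_currency(met):
                met_to_rxns.setdefault(met, set()).add(r.id)

    out = []
    for s in scores:
        rxn = model.reaction(s.reaction_id)
        neighbours: set[str] = set()
        for met in rxn.stoichiometry:
            if not is_currency(met):
                neighbours |= met_to_rxns.get(met, set())
        neighbours.discard(s.reaction_id)
        vals = [expr_of[n] for n in sorted(neighbours) if expr_of.get(n) is not None]
        conn = float(np.mean(vals)) if vals else 0.0
        if s.expression_score is None:
            combined = conn
        else:
            combined = weight * s.expression_score + (1.0 - weight) * conn
        out.append(
            ReactionScore(
                reaction_id=s.reaction_id,
                expression_score=s.expression_score,
                connectivity_score=conn,
                combined=combined,
            )
        )
    return out


def prune_model(
    model: MetabolicModel,
    scores: list[ReactionScore],
    core_ids: set[str],
    threshold: float,
    min_objective_fraction: float = 0.9,
    flux_tol: float = 1e-6,
) -> MetabolicModel:
    """Remove low-evidence non-core reactions while preserving function.

    Non-core reactions are visited in ascending combined-score order (ties
    broken lexicographically by id). A reaction is removed iff its score is
    below ``threshold`` AND the reduced model still attains at least
    ``min_objective_fraction`` of the original biomass optimum AND every
    core reaction can still carry non-zero flux (checked by FVA without an
    objective floor). Deterministic for identical inputs.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    unknown = core_ids - set(model.reaction_ids)
    if unknown:
        raise ValueError(f"core ids not in model: {sorted(unknown)}")
    base = fba_optimize(model)
    if not base.optimal or base.objective_value <= flux_tol:
        raise ValueError(
            "model cannot attain a positive objective; nothing to preserve"
        )
    floor = min_objective_fraction * base.objective_value

    score_of = {s.reaction_id: (s.combined if s.combined is not None else 0.0)
                for s in scores}
    candidates = sorted(
        (r.id for r in model.reactions if r.id not in core_ids),
        key=lambda rid: (score_of.get(rid, 0.0), rid),
    )

    current = model.copy()
    for rid in candidates:
        if score_of.get(rid, 0.0) >= threshold:
            continue
        trial = _without_reaction(current, rid)
        res = fba_optimize(trial)
        if not res.optimal or res.objective_value < floor - 1e-9:
            continue
        if not _cores_can_flux(trial, core_ids, flux_tol):
            continue
        current = trial
    return current


def _without_reaction(model: MetabolicModel, rid: str) -> MetabolicModel:
    keep_rxns = [r for r in model.reactions if r.id != rid]
    used = {m for r in keep_rxns for m in r.stoichiometry}
    return MetabolicModel(
        metabolites=[m for m in model.metabolites if m.id in used],
        reactions=keep_rxns,
        objective_id=model.objective_id,
        annotations=dict(model.annotations),
        id=model.id,
    )


def _cores_can_flux(model: MetabolicModel, core_ids: set[str], tol: float) -> bool:
    present = [rid for rid in sorted(core_ids) if rid in set(model.reaction_ids)]
    try:
        ranges = fva(model, present, objective_fraction=0.0)
    except Exception:
        return False
    return all(max(abs(rng.minimum), abs(rng.maximum)) > tol for rng in ranges)


def read_expression_tsv(path: str) -> ExpressionDataset:
    """Read a genes x samples 0/1 matrix (first column = gene ids)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionDataset(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        calls=df.to_numpy(dtype=int),
    )


def write_expression_tsv(expr: ExpressionDataset, path: str) -> None:
    import pandas as pd

    pd.DataFrame(expr.calls, index=expr.genes, columns=expr.samples).to_csv(
        path, sep="\t", index_label="gene"
    )
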