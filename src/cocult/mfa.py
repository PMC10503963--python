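"""13C metabolic flux analysis with the elementary metabolite unit framework.

An atom-mapped reaction network is written one reaction per line in a plain
grammar (see ``docs/formats.md``):

    v1: A (abc) -> B (ab) + C (c)
    external: Gluc_ext Lac_ext
    symmetric: Suc

Letters name carbon atoms; within one line every letter appears exactly once
on each side, so atom fate is unambiguous. Reactions are unidirectional
(declare a reversible step as two lines). ``external`` metabolites are
sources/sinks excluded from the steady-state balance; ``symmetric``
metabolites are rotationally symmetric molecules (e.g. succinate) whose
producing mappings are expanded into two equal-probability alternatives with
the molecule's letters reversed.

The labelling state of a fragment (an EMU: a metabolite plus an ordered
subset of its carbons) is its mass isotopomer distribution (MID): the
fractions at masses m+0 … m+n. The EMU decomposition finds the minimal set
of fragments needed to simulate a target MID; steady-state MIDs are then
solved size-by-size as linear systems, with convolutions where a product
fragment draws carbons from two reactant fragments.

Flux estimation is variance-weighted least squares over a free-flux
parameterisation (QR column pivoting on the internal stoichiometric matrix)
with multistart, a chi-square goodness-of-fit verdict, and Monte-Carlo
confidence intervals. Parallel-tracer experiments (e.g. U-13C glucose and
U-13C glutamine) are fitted simultaneously against one flux vector.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import qr
from scipy.optimize import least_squares

MID_SUM_TOL = 1e-9
DEFAULT_PURITY = 0.99

__all__ = [
    "AtomTransition",
    "AtomNetwork",
    "EMU",
    "MIDVector",
    "Tracer",
    "MIDMeasurement",
    "Experiment",
    "MFAModel",
    "FluxEstimate",
    "EMUNetwork",
    "parse_atom_network",
    "decompose_emus",
    "simulate_mids",
    "ssr",
    "fit_fluxes",
    "monte_carlo_ci",
    "export_intervals",
    "fragment_id",
    "parse_fragment_id",
]


class AtomNetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Atom-mapped network
# ---------------------------------------------------------------------------


@dataclass
class AtomTransition:
    """One atom-mapped reaction.

    ``mappings`` holds (probability, products) alternatives; probabilities
    sum to 1. Reactants are shared across alternatives.
    """

    id: str
    reactants: list[tuple[str, str]]  # (metabolite, letters)
    products: list[tuple[str, str]]
    mappings: list[tuple[float, list[tuple[str, str]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mappings:
            self.mappings = [(1.0, list(self.products))]
        lhs = "".join(s for _, s in self.reactants)
        if len(set(lhs)) != len(lhs):
            raise AtomNetworkError(f"{self.id}: duplicate atom letters on the left")
        for prob, prods in self.mappings:
            rhs = "".join(s for _, s in prods)
            if len(set(rhs)) != len(rhs):
                raise AtomNetworkError(
                    f"{self.id}: duplicate atom letters on the right"
                )
            if set(lhs) != set(rhs) or len(lhs) != len(rhs):
                raise AtomNetworkError(
                    f"{self.id}: atom letters not conserved "
                    f"({lhs!r} vs {rhs!r})"
                )
        total = sum(p for p, _ in self.mappings)
        if abs(total - 1.0) > 1e-9:
            raise AtomNetworkError(f"{self.id}: mapping probabilities sum to {total}")

    def to_line(self) -> str:
        lhs = " + ".join(f"{m} ({s})" for m, s in self.reactants)
        rhs = " + ".join(f"{m} ({s})" for m, s in self.products)
        return f"{self.id}: {lhs} -> {rhs}"


@dataclass
class AtomNetwork:
    """Parsed atom network plus its directives."""

    transitions: list[AtomTransition]
    external: set[str] = field(default_factory=set)
    symmetric: set[str] = field(default_factory=set)

    @property
    def reaction_ids(self) -> list[str]:
        return [t.id for t in self.transitions]

    def carbon_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.transitions:
            for m, s in t.reactants + t.products:
                if counts.setdefault(m, len(s)) != len(s):
                    raise AtomNetworkError(
                        f"inconsistent carbon count for {m!r} in {t.id}"
                    )
        return counts

    def metabolites(self) -> set[str]:
        return set(self.carbon_counts())

    def internal_metabolites(self) -> list[str]:
        return sorted(self.metabolites() - self.external)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """S over internal metabolites (rows) x transitions (columns)."""
        mets = self.internal_metabolites()
        pos = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.transitions)))
        for j, t in enumerate(self.transitions):
            for m, _ in t.reactants:
                if m in pos:
                    S[pos[m], j] -= 1.0
            for m, _ in t.products:
                if m in pos:
                    S[pos[m], j] += 1.0
        return S, mets

    def to_text(self) -> str:
        lines = []
        if self.external:
            lines.append("external: " + " ".join(sorted(self.external)))
        if self.symmetric:
            lines.append("symmetric: " + " ".join(sorted(self.symmetric)))
        lines.extend(t.to_line() for t in self.transitions)
        return "\n".join(lines) + "\n"


_RXN_LINE_RE = re.compile(r"^(?P<id>[\w.\-]+)\s*:\s*(?P<lhs>.+?)->(?P<rhs>.+)$")
_TERM_RE = re.compile(r"^\s*(?P<met>[\w.\-\[\]]+)\s*\(\s*(?P<letters>[a-zA-Z]+)\s*\)\s*$")


def _parse_side(side: str, rxn_id: str, lineno: int) -> list[tuple[str, str]]:
    terms = []
    for chunk in side.split("+"):
        m = _TERM_RE.match(chunk)
        if not m:
            raise AtomNetworkError(
                f"line {lineno}: cannot parse term {chunk.strip()!r} in {rxn_id}"
            )
        terms.append((m.group("met"), m.group("letters")))
    return terms


def parse_atom_network(text: str) -> AtomNetwork:
    """Parse the plain-text atom-mapped network grammar.

    Raises :class:`AtomNetworkError` with a line number on unbalanced atom
    letters or malformed lines. Symmetric metabolites are expanded into
    equal-probability alternative product mappings (letters reversed).
    """
    external: set[str] = set()
    symmetric: set[str] = set()
    raw: list[tuple[int, str, list, list]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("external:"):
            external |= set(line.split(":", 1)[1].split())
            continue
        if line.startswith("symmetric:"):
            symmetric |= set(line.split(":", 1)[1].split())
            continue
        m = _RXN_LINE_RE.match(line)
        if not m:
            raise AtomNetworkError(f"line {lineno}: cannot parse {line!r}")
        rid = m.group("id")
        lhs = _parse_side(m.group("lhs"), rid, lineno)
        rhs = _parse_side(m.group("rhs"), rid, lineno)
        if sorted("".join(s for _, s in lhs)) != sorted("".join(s for _, s in rhs)):
            raise AtomNetworkError(
                f"line {lineno}: atom letters not conserved in {rid}"
            )
        raw.append((lineno, rid, lhs, rhs))

    transitions = []
    for lineno, rid, lhs, rhs in raw:
        mappings = _expand_symmetric(rhs, symmetric)
        try:
            transitions.append(
                AtomTransition(id=rid, reactants=lhs, products=rhs, mappings=mappings)
            )
        except AtomNetworkError as exc:
            raise AtomNetworkError(f"line {lineno}: {exc}") from exc
    return AtomNetwork(transitions=transitions, external=external, symmetric=symmetric)


def _expand_symmetric(
    products: list[tuple[str, str]], symmetric: set[str]
) -> list[tuple[float, list[tuple[str, str]]]]:
    """All orientation combinations of symmetric products, equal probability."""
    variants: list[list[tuple[str, str]]] = [[]]
    n_sym = 0
    for met, letters in products:
        if met in symmetric and len(letters) > 1:
            n_sym += 1
            variants = [v + [(met, letters)] for v in variants] + [
                v + [(met, letters[::-1])] for v in variants
            ]
        else:
            variants = [v + [(met, letters)] for v in variants]
    p = 1.0 / len(variants)
    return [(p, v) for v in variants]


# ---------------------------------------------------------------------------
# EMUs and their decomposition
# ---------------------------------------------------------------------------

# An EMU is (metabolite, tuple of sorted 1-based atom indices).
EMU = tuple


def make_emu(met: str, atoms) -> EMU:
    return (met, tuple(sorted(int(a) for a in atoms)))


def fragment_id(emu: EMU) -> str:
    met, atoms = emu
    return f"{met}:{','.join(str(a) for a in atoms)}"


def parse_fragment_id(fid: str) -> EMU:
    met, _, atoms = fid.partition(":")
    if not atoms:
        raise ValueError(f"bad fragment id {fid!r}; expected 'Met:1,2,3'")
    return make_emu(met, (int(a) for a in atoms.split(",")))


@dataclass
class EMUReaction:
    """One production route of a target EMU."""

    flux_id: str
    weight: float  # mapping probability
    sources: tuple[EMU, ...]  # >1 entries = convolution
    target: EMU


@dataclass
class EMUNetwork:
    """Size-layered EMU reaction graph sufficient to simulate the targets."""

    network: AtomNetwork
    targets: list[EMU]
    reactions: list[EMUReaction]
    emus: list[EMU]  # all EMUs, including substrates

    def substrates(self) -> set[EMU]:
        produced = {r.target for r in self.reactions}
        return {e for e in self.emus if e not in produced}

    def by_size(self) -> dict[int, list[EMU]]:
        out: dict[int, list[EMU]] = {}
        for e in sorted(self.emus):
            out.setdefault(len(e[1]), []).append(e)
        return out


def decompose_emus(network: AtomNetwork, target_fragments: list[EMU]) -> EMUNetwork:
    """Backward-trace the EMUs required to simulate the target fragments."""
    counts = network.carbon_counts()
    targets = [make_emu(m, a) for m, a in target_fragments]
    for met, atoms in targets:
        if met not in counts:
            raise AtomNetworkError(f"target metabolite {met!r} not in network")
        if atoms and atoms[-1] > counts[met]:
            raise AtomNetworkError(
                f"target {fragment_id((met, atoms))} exceeds {met!r}'s "
                f"{counts[met]} carbons"
            )

    producers: dict[str, list[tuple[AtomTransition, float, list[tuple[str, str]]]]] = {}
    for t in network.transitions:
        for prob, prods in t.mappings:
            for met, _ in prods:
                producers.setdefault(met, []).append((t, prob, prods))

    emu_reactions: list[EMUReaction] = []
    seen: set[EMU] = set()
    stack: list[EMU] = list(targets)
    while stack:
        emu = stack.pop()
        if emu in seen:
            continue
        seen.add(emu)
        met, atoms = emu
        if met in network.external:
            continue  # substrate leaf
        routes = producers.get(met, [])
        if not routes:
            raise AtomNetworkError(
                f"fragment {fragment_id(emu)} is unreachable: nothing produces {met!r}"
            )
        for t, prob, prods in routes:
            for pmet, letters in prods:
                if pmet != met:
                    continue
                picked = {letters[a - 1] for a in atoms}
                sources: list[EMU] = []
                for rmet, rletters in t.reactants:
                    pos = [j + 1 for j, ch in enumerate(rletters) if ch in picked]
                    if pos:
                        sources.append(make_emu(rmet, pos))
                emu_reactions.append(
                    EMUReaction(
                        flux_id=t.id,
                        weight=prob,
                        sources=tuple(sorted(sources)),
                        target=emu,
                    )
                )
                for s in sources:
                    if s not in seen:
                        stack.append(s)
    return EMUNetwork(
        network=network,
        targets=targets,
        reactions=emu_reactions,
        emus=sorted(seen),
    )


# ---------------------------------------------------------------------------
# MID simulation
# ---------------------------------------------------------------------------


@dataclass
class Tracer:
    """An isotopically labelled substrate.

    ``positions`` are the 1-based labelled carbons ("U" = all). ``purity``
    is the per-position isotopic purity; ``fraction`` the molar fraction of
    the labelled species in the substrate pool.
    """

    metabolite: str
    positions: str | list[int] = "U"
    purity: float = DEFAULT_PURITY
    fraction: float = 1.0


@dataclass
class MIDVector:
    """Mass fractions m+0 … m+n of one fragment; sums to 1."""

    fragment: EMU
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        n = len(self.fragment[1])
        if self.fractions.shape != (n + 1,):
            raise ValueError(
                f"{fragment_id(self.fragment)}: expected {n + 1} mass fractions"
            )
        if self.fractions.min() < -1e-9 or abs(self.fractions.sum() - 1.0) > MID_SUM_TOL:
            raise ValueError(
                f"{fragment_id(self.fragment)}: invalid MID {self.fractions}"
            )


def _substrate_mid(emu: EMU, tracers: dict[str, Tracer], counts: dict[str, int]) -> np.ndarray:
    met, atoms = emu
    n = len(atoms)
    tracer = tracers.get(met)
    if tracer is None:
        mid = np.zeros(n + 1)
        mid[0] = 1.0
        return mid
    if tracer.positions == "U":
        labelled = set(range(1, counts[met] + 1))
    else:
        labelled = set(tracer.positions)
    # labelled species: each EMU atom is 13C independently with prob purity
    dist = np.array([1.0])
    for a in atoms:
        p = tracer.purity if a in labelled else 0.0
        dist = np.convolve(dist, [1.0 - p, p])
    unlab = np.zeros(n + 1)
    unlab[0] = 1.0
    return tracer.fraction * dist + (1.0 - tracer.fraction) * unlab


def simulate_mids(
    emunet: EMUNetwork,
    fluxes: dict[str, float],
    tracers: dict[str, Tracer] | list[Tracer],
    flux_tol: float = 1e-9,
) -> list[MIDVector]:
    """Steady-state MIDs of the target fragments, solved size-by-size.

    ``fluxes`` must be non-negative (the atom network is unidirectional);
    only flux *ratios* matter for the labelling state.
    """
    if isinstance(tracers, list):
        tracers = {t.metabolite: t for t in tracers}
    counts = emunet.network.carbon_counts()
    substrates = emunet.substrates()
    mids: dict[EMU, np.ndarray] = {}
    for e in substrates:
        mids[e] = _substrate_mid(e, tracers, counts)

    inflows: dict[EMU, list[EMUReaction]] = {}
    for r in emunet.reactions:
        inflows.setdefault(r.target, []).append(r)

    for size, emus in sorted(emunet.by_size().items()):
        unknown = [e for e in emus if e not in mids]
        if not unknown:
            continue
        idx = {e: i for i, e in enumerate(unknown)}
        n = len(unknown)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e in unknown:
            i = idx[e]
            total = 0.0
            for r in inflows.get(e, []):
                v = fluxes.get(r.flux_id, 0.0)
                if v < -flux_tol:
                    raise ValueError(
                        f"negative flux {v} for {r.flux_id!r}; atom-network "
                        "fluxes must be non-negative"
                    )
                w = max(v, 0.0) * r.weight
                if w <= 0:
                    continue
                total += w
                if len(r.sources) == 1 and r.sources[0] in idx:
                    A[i, idx[r.sources[0]]] -= w
                else:
                    mid = np.array([1.0])
                    for s in r.sources:
                        mid = np.convolve(mid, mids[s])
                    B[i, :] += w * mid
            if total <= flux_tol:
                raise ValueError(
                    f"singular balance: no inflow to {fragment_id(e)} "
                    "at this flux vector"
                )
            A[i, i] += total
        X = np.linalg.solve(A, B)
        for e in unknown:
            mid = X[idx[e]]
            mid = np.clip(mid, 0.0, None)
            mids[e] = mid / mid.sum()
    return [MIDVector(fragment=t, fractions=mids[t]) for t in emunet.targets]


# ---------------------------------------------------------------------------
# Measurements, model, fitting
# ---------------------------------------------------------------------------


@dataclass
class MIDMeasurement:
    fragment: EMU
    values: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.values.shape != self.sds.shape:
            raise ValueError("values and sds must have the same shape")
        if (self.sds <= 0).any():
            raise ValueError("measurement sds must be positive")


@dataclass
class Experiment:
    """One tracer experiment: a labelling scheme plus measured MIDs."""

    name: str
    tracers: list[Tracer]
    measurements: list[MIDMeasurement]


@dataclass
class MFAModel:
    """Everything needed to estimate fluxes from labelling data."""

    network: AtomNetwork
    experiments: list[Experiment]
    flux_measurements: dict[str, tuple[float, float]] = field(default_factory=dict)
    flux_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_upper_bound: float = 100.0

    def bounds_for(self, rid: str) -> tuple[float, float]:
        return self.flux_bounds.get(rid, (0.0, self.default_upper_bound))


@dataclass
class FluxEstimate:
    """Fitted fluxes with goodness-of-fit and confidence intervals."""

    fluxes: dict[str, float]
    free_flux_ids: list[str]
    ssr: float
    dof: int
    chi2_pass: bool
    alpha: float
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_restarts: int = 0
    best_restart_seed: int | None = None


class _FluxParameterisation:
    """Free-flux parameterisation of S v = 0 via QR column pivoting."""

    def __init__(self, model: MFAModel):
        S, self.internal_mets = model.network.stoichiometric_matrix()
        rids = model.network.reaction_ids
        self.rids = rids
        n = len(rids)
        if S.size == 0:
            rank = 0
            piv = np.arange(n)
        else:
            _, Rm, piv = qr(S, pivoting=True)
            diag = np.abs(np.diag(Rm)) if Rm.ndim == 2 else np.array([])
            tol = max(S.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
            rank = int((diag > tol).sum())
        self.dep_idx = list(piv[:rank])
        self.free_idx = sorted(set(range(n)) - set(self.dep_idx))
        self.free_ids = [rids[j] for j in self.free_idx]
        self.S_dep = S[:, self.dep_idx] if rank else np.zeros((S.shape[0], 0))
        S_free = S[:, self.free_idx]
        # v_dep = M @ v_free
        if rank:
            self.M = -np.linalg.pinv(self.S_dep) @ S_free
        else:
            self.M = np.zeros((0, len(self.free_idx)))
        self.lb = np.array([model.bounds_for(r)[0] for r in self.free_ids])
        self.ub = np.array([model.bounds_for(r)[1] for r in self.free_ids])
        self.dep_lb = np.array([model.bounds_for(rids[j])[0] for j in self.dep_idx])
        self.dep_ub = np.array([model.bounds_for(rids[j])[1] for j in self.dep_idx])

    @property
    def n_free(self) -> int:
        return len(self.free_idx)

    def fluxes(self, u: np.ndarray) -> dict[str, float]:
        v = np.empty(len(self.rids))
        for k, j in enumerate(self.free_idx):
            v[j] = u[k]
        v_dep = self.M @ u
        for k, j in enumerate(self.dep_idx):
            v[j] = v_dep[k]
        return dict(zip(self.rids, v))

    def dependent_violation(self, u: np.ndarray) -> np.ndarray:
        v_dep = self.M @ u
        return np.concatenate(
            [np.maximum(self.dep_lb - v_dep, 0.0), np.maximum(v_dep - self.dep_ub, 0.0)]
        )


def ssr(
    measured: list[MIDMeasurement],
    simulated: list[MIDVector],
    flux_measurements: dict[str, tuple[float, float]] | None = None,
    fluxes: dict[str, float] | None = None,
) -> float:
    """Variance-weighted sum of squared residuals."""
    sim_of = {m.fragment: m.fractions for m in simulated}
    total = 0.0
    for meas in measured:
        if meas.fragment not in sim_of:
            raise ValueError(f"no simulated MID for {fragment_id(meas.fragment)}")
        r = (meas.values - sim_of[meas.fragment]) / meas.sds
        total += float((r**2).sum())
    if flux_measurements:
        if fluxes is None:
            raise ValueError("flux measurements given but no flux vector")
        for rid, (val, sd) in flux_measurements.items():
            total += ((fluxes[rid] - val) / sd) ** 2
    return total


class _Objective:
    def __init__(self, model: MFAModel, param: _FluxParameterisation,
                 penalty: float = 1e4):
        self.model = model
        self.param = param
        self.penalty = penalty
        self.emunets = []
        for exp in model.experiments:
            frags = [m.fragment for m in exp.measurements]
            self.emunets.append(decompose_emus(model.network, frags))

    def residuals(self, u: np.ndarray) -> np.ndarray:
        fluxes = self.param.fluxes(u)
        parts = []
        for exp, emunet in zip(self.model.experiments, self.emunets):
            try:
                sims = simulate_mids(emunet, {k: max(v, 0.0) for k, v in fluxes.items()},
                                     exp.tracers)
            except (ValueError, np.linalg.LinAlgError):
                # infeasible labelling system: large flat residual
                n = sum(len(m.values) for m in exp.measurements)
                parts.append(np.full(n, 1e3))
                continue
            sim_of = {m.fragment: m.fractions for m in sims}
            for meas in exp.measurements:
                parts.append((sim_of[meas.fragment] - meas.values) / meas.sds)
        for rid, (val, sd) in sorted(self.model.flux_measurements.items()):
            parts.append(np.array([(fluxes[rid] - val) / sd]))
        parts.append(self.penalty * self.param.dependent_violation(u))
        return np.concatenate(parts)

    @property
    def n_measurements(self) -> int:
        return sum(
            len(m.values) for exp in self.model.experiments for m in exp.measurements
        ) + len(self.model.flux_measurements)


def _random_feasible_start(
    param: _FluxParameterisation, rng: np.random.Generator, tries: int = 200
) -> np.ndarray:
    ub = np.where(np.isfinite(param.ub), param.ub, 100.0)
    lb = np.where(np.isfinite(param.lb), param.lb, -100.0)
    best, best_viol = None, np.inf
    for _ in range(tries):
        u = rng.uniform(lb, ub)
        viol = param.dependent_violation(u).sum()
        if viol <= 1e-9:
            return u
        if viol < best_viol:
            best, best_viol = u, viol
    return best


def fit_fluxes(
    model: MFAModel,
    n_restarts: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    check_identifiability: bool = True,
) -> FluxEstimate:
    """Multistart bound-constrained least-squares flux estimation.

    ``n_restarts`` random feasible starting points (at least 100 for
    production fits) are refined by trust-region least squares; the best
    sum of squared residuals wins. Deterministic for a given seed. The
    chi-square verdict compares the best SSR against the upper alpha
    quantile at dof = (independent measurements - free fluxes).
    """
    param = _FluxParameterisation(model)
    obj = _Objective(model, param)
    dof = obj.n_measurements - param.n_free
    if dof < 1:
        raise ValueError(
            f"under-determined fit: {obj.n_measurements} measurements for "
            f"{param.n_free} free fluxes"
        )
    rng = np.random.default_rng(seed)

    if check_identifiability:
        u0 = _random_feasible_start(param, rng)
        J = _numeric_jacobian(obj.residuals, u0)
        sv = np.linalg.svd(J, compute_uv=False)
        if sv.size and sv.min() < 1e-10 * sv.max():
            warnings.warn(
                "near-singular Jacobian at a random feasible point; some free "
                "fluxes may be unidentifiable"
            )

    best = None
    best_seed = None
    failures = []
    for k in range(n_restarts):
        u0 = _random_feasible_start(param, rng)
        if u0 is None:
            failures.append((k, "no feasible start"))
            continue
        try:
            res = least_squares(
                obj.residuals, u0, bounds=(param.lb, param.ub), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception as exc:  # pragma: no cover - solver pathologies
            failures.append((k, str(exc)))
            continue
        cost = 2.0 * res.cost
        if best is None or cost < best[0] - 1e-12:
            best = (cost, res.x)
            best_seed = k
    if best is None:
        raise RuntimeError(f"no restart converged; diagnostics: {failures}")

    ssr_val, u_best = best
    fluxes = param.fluxes(u_best)
    chi2_crit = stats.chi2.ppf(1.0 - alpha, dof)
    return FluxEstimate(
        fluxes=fluxes,
        free_flux_ids=param.free_ids,
        ssr=float(ssr_val),
        dof=dof,
        chi2_pass=bool(ssr_val <= chi2_crit),
        alpha=alpha,
        n_restarts=n_restarts,
        best_restart_seed=best_seed,
    )


def _numeric_jacobian(fun, x, eps: float = 1e-6) -> np.ndarray:
    f0 = fun(x)
    J = np.empty((len(f0), len(x)))
    for j in range(len(x)):
        xp = x.copy()
        xp[j] += eps
        J[:, j] = (fun(xp) - f0) / eps
    return J


def monte_carlo_ci(
    model: MFAModel,
    best: FluxEstimate,
    n_samples: int = 100,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> FluxEstimate:
    """Monte-Carlo 95% confidence intervals for every flux.

    Synthetic datasets are resampled around the fitted labelling state with
    the measurement standard deviations, each refit (starting from the best
    fit), and per-flux 2.5/97.5 percentiles form the intervals. The point
    estimate itself is included in the percentile sample, so intervals
    always contain it.
    """
    param = _FluxParameterisation(model)
    obj = _Objective(model, param)
    u_best = np.array([best.fluxes[r] for r in param.free_ids])

    # fitted labelling state per experiment
    fitted_sims = []
    for exp, emunet in zip(model.experiments, obj.emunets):
        sims = simulate_mids(emunet, {k: max(v, 0.0) for k, v in best.fluxes.items()},
                             exp.tracers)
        fitted_sims.append({m.fragment: m.fractions for m in sims})

    rng = np.random.default_rng(seed)
    samples = [np.array([best.fluxes[r] for r in param.rids])]
    failures = 0
    for _ in range(n_samples):
        resampled = MFAModel(
            network=model.network,
            experiments=[
                Experiment(
                    name=exp.name,
                    tracers=exp.tracers,
                    measurements=[
                        MIDMeasurement(
                            fragment=m.fragment,
                            values=np.clip(
                                sim_of[m.fragment] + rng.normal(0, m.sds), 0, None
                            ),
                            sds=m.sds,
                        )
                        for m in exp.measurements
                    ],
                )
                for exp, sim_of in zip(model.experiments, fitted_sims)
            ],
            flux_measurements={
                rid: (val + rng.normal(0, sd), sd)
                for rid, (val, sd) in model.flux_measurements.items()
            },
            flux_bounds=model.flux_bounds,
            default_upper_bound=model.default_upper_bound,
        )
        robj = _Objective(resampled, param)
        try:
            res = least_squares(
                robj.residuals,
                np.clip(u_best, param.lb, param.ub),
                bounds=(param.lb, param.ub),
                method="trf",
                xtol=1e-9, ftol=1e-9, gtol=1e-9,
            )
            samples.append(np.array(list(param.fluxes(res.x).values())))
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_samples:
        raise RuntimeError(
            f"{failures}/{n_samples} Monte-Carlo refits failed"
        )

    arr = np.vstack(samples)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    intervals = {
        rid: (float(lo[j]), float(hi[j])) for j, rid in enumerate(param.rids)
    }
    return FluxEstimate(
        fluxes=best.fluxes,
        free_flux_ids=best.free_flux_ids,
        ssr=best.ssr,
        dof=best.dof,
        chi2_pass=best.chi2_pass,
        alpha=best.alpha,
        intervals=intervals,
        n_restarts=best.n_restarts,
        best_restart_seed=best.best_restart_seed,
    )


def export_intervals(
    est: FluxEstimate,
    id_map: dict[str, str | tuple[str, float]],
    path: str | None = None,
) -> tuple["pandas.DataFrame", list[str]]:
    """Export per-flux confidence intervals as bounds for phenotype tuning.

    ``id_map`` maps MFA reaction ids to constraint-based-model reaction ids,
    optionally with a sign/scale factor (use -1 for exchange reactions where
    uptake is negative flux). Returns (table, unmapped sidecar); duplicate
    targets raise. Columns: ``reaction_id, lo, hi``.
    """
    import pandas as pd

    if not est.intervals:
        raise ValueError("estimate has no confidence intervals; run monte_carlo_ci")
    targets = []
    rows = []
    for mfa_id in sorted(id_map):
        spec = id_map[mfa_id]
        cbm_id, scale = spec if isinstance(spec, tuple) else (spec, 1.0)
        if cbm_id in targets:
            raise ValueError(f"duplicate tuning target {cbm_id!r}")
        targets.append(cbm_id)
        if mfa_id not in est.intervals:
            raise KeyError(f"no interval for MFA reaction {mfa_id!r}")
        lo, hi = est.intervals[mfa_id]
        a, b = lo * scale, hi * scale
        rows.append({"reaction_id": cbm_id, "lo": min(a, b), "hi": max(a, b)})
    unmapped = sorted(set(est.intervals) - set(id_map))
    df = pd.DataFrame(rows, columns=["reaction_id", "lo", "hi"])
    if path is not None:
        df.to_csv(path, index=False)
        with open(str(path) + ".unmapped.txt", "w") as fh:
            fh.write("\n".join(unmapped) + ("\n" if unmapped else ""))
    return df, unmapped


# ---------------------------------------------------------------------------
# MID dataset CSV I/O (fragment_id, mass_shift, value, sd)
# ---------------------------------------------------------------------------


def write_mid_csv(measurements: list[MIDMeasurement], path: str) -> None:
    import pandas as pd

    rows = []
    for m in measurements:
        for shift, (val, sd) in enumerate(zip(m.values, m.sds)):
            rows.append(
                {"fragment_id": fragment_id(m.fragment), "mass_shift": shift,
                 "value": val, "sd": sd}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mid_csv(path: str) -> list[MIDMeasurement]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for fid, grp in df.groupby("fragment_id", sort=True):
        grp = grp.sort_values("mass_shift")
        out.append(
            MIDMeasurement(
                fragment=parse_fragment_id(str(fid)),
                values=grp["value"].to_numpy(),
                sds=grp["sd"].to_numpy(),
            )
        )
    return out
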