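"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — enumeration, recursion, fixed-point
iteration — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from cocult.netcore import GPR, MetabolicModel, Metabolite, Reaction, parse_gpr


# ---------------------------------------------------------------------------
# LP optimum by basic-feasible-solution enumeration
# ---------------------------------------------------------------------------


def vertex_enumeration_optimum(S, lb, ub, c, maximize=True):
    """Optimum of max/min c'v s.t. S v = 0, lb <= v <= ub by enumerating
    basic solutions: for every choice of n - rank(S) variables fixed at a
    bound, solve the equality system for the rest and keep feasible points.

    Only valid for small problems (n <= ~10). Returns None if infeasible.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    best = None
    for free_idx in itertools.combinations(range(n), n_fix):
        basic_idx = [j for j in range(n) if j not in free_idx]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in free_idx]):
            if any(not np.isfinite(b) for b in bounds_choice):
                continue
            rhs = np.zeros(m)
            for j, val in zip(free_idx, bounds_choice):
                rhs -= S[:, j] * val
            A = S[:, basic_idx]
            sol, residuals, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.zeros(n)
            for j, val in zip(free_idx, bounds_choice):
                v[j] = val
            for k, j in enumerate(basic_idx):
                v[j] = sol[k]
            if np.abs(S @ v).max() > 1e-8:
                continue
            if ((v < np.asarray(lb) - 1e-8) | (v > np.asarray(ub) + 1e-8)).any():
                continue
            val = float(np.dot(c, v))
            if best is None or (val > best if maximize else val < best):
                best = val
    return best


# ---------------------------------------------------------------------------
# Reaction dG range by corner enumeration
# ---------------------------------------------------------------------------


def corner_delta_g_range(stoich, dgf, conc_ranges, temperature=310.15,
                         exempt=()):
    """Extrema of dG = sum s_i dGf_i + RT sum s_i ln c_i over all corners of
    the concentration box (exempt species skip the RT term)."""
    R = 8.314e-3
    rt = R * temperature
    mets = sorted(stoich)
    base = sum(stoich[m] * dgf[m] for m in mets)
    varying = [m for m in mets if m not in exempt]
    best_lo, best_hi = math.inf, -math.inf
    for corner in itertools.product(*[(conc_ranges[m][0], conc_ranges[m][1])
                                      for m in varying]):
        val = base + rt * sum(
            stoich[m] * math.log(ci) for m, ci in zip(varying, corner)
        )
        best_lo = min(best_lo, val)
        best_hi = max(best_hi, val)
    if not varying:
        best_lo = best_hi = base
    return best_lo, best_hi


# ---------------------------------------------------------------------------
# GPR evaluation by plain recursion over a freshly parsed string
# ---------------------------------------------------------------------------


def recursive_gpr_eval(expr: str, scores: dict[str, float]) -> float:
    tree = parse_gpr(expr)

    def ev(node):
        if isinstance(node, str):
            return scores.get(node, 0.0)
        op, children = node
        vals = [ev(c) for c in children]
        return min(vals) if op == "and" else max(vals)

    return ev(tree.node)


# ---------------------------------------------------------------------------
# Full isotopomer-state labelling simulation (fixed point of the exact
# isotopomer balances; enumerates all 2^n states per metabolite)
# ---------------------------------------------------------------------------


def isotopomer_mids(network, fluxes, tracers, tol=1e-13, max_iter=50000):
    """Return a function EMU -> MID computed from full isotopomer states."""
    counts = network.carbon_counts()
    tr = {t.metabolite: t for t in tracers}

    def substrate_dist(m):
        n = counts[m]
        t = tr.get(m)
        p = np.zeros(2 ** n)
        if t is None:
            p[0] = 1.0
            return p
        lab = set(range(1, n + 1)) if t.positions == "U" else set(t.positions)
        for mask in range(2 ** n):
            pr = 1.0
            for pos in range(1, n + 1):
                bit = (mask >> (pos - 1)) & 1
                pl = t.purity if pos in lab else 0.0
                pr *= pl if bit else (1 - pl)
            p[mask] = pr
        unlab = np.zeros(2 ** n)
        unlab[0] = 1.0
        return t.fraction * p + (1 - t.fraction) * unlab

    state = {}
    for m, n in counts.items():
        p = np.zeros(2 ** n)
        p[0] = 1.0
        state[m] = p
    for m in network.external:
        if m in counts:
            state[m] = substrate_dist(m)
    internal = [m for m in counts if m not in network.external]

    for _ in range(max_iter):
        new = {}
        maxdiff = 0.0
        for m in internal:
            n = counts[m]
            acc = np.zeros(2 ** n)
            tot = 0.0
            for t in network.transitions:
                v = fluxes.get(t.id, 0.0)
                if v <= 0:
                    continue
                for prob, prods in t.mappings:
                    for pmet, letters in prods:
                        if pmet != m:
                            continue
                        w = v * prob
                        tot += w
                        src = {}
                        for ri, (rmet, rl) in enumerate(t.reactants):
                            for j, ch in enumerate(rl):
                                src[ch] = (ri, j)
                        dist = np.zeros(2 ** n)
                        rstates = [state[rm] for rm, _ in t.reactants]

                        def rec(ri, pr, labels):
                            if pr < 1e-16:
                                return
                            if ri == len(t.reactants):
                                mask = 0
                                for pos in range(1, n + 1):
                                    rri, j = src[letters[pos - 1]]
                                    if (labels[rri] >> j) & 1:
                                        mask |= 1 << (pos - 1)
                                dist[mask] += pr
                                return
                            for msk in range(len(rstates[ri])):
                                q = rstates[ri][msk]
                                if q > 0:
                                    rec(ri + 1, pr * q, labels + [msk])

                        rec(0, 1.0, [])
                        acc += w * dist
            new[m] = acc / tot if tot > 0 else state[m]
            maxdiff = max(maxdiff, np.abs(new[m] - state[m]).max())
        state.update(new)
        if maxdiff < tol:
            break

    def emu_mid(emu):
        m, atoms = emu
        mid = np.zeros(len(atoms) + 1)
        for mask, pr in enumerate(state[m]):
            k = sum(1 for a in atoms if (mask >> (a - 1)) & 1)
            mid[k] += pr
        return mid

    return emu_mid


# ---------------------------------------------------------------------------
# EMU requirement count by exhaustive atom-subset traversal
# ---------------------------------------------------------------------------


def emu_count_by_reachability(network, targets):
    """Number of distinct EMUs needed for the targets, found by breadth-first
    traversal over all producing mappings (independent of the layered
    decomposition code path)."""
    seen = set()
    frontier = [(m, tuple(sorted(a))) for m, a in targets]
    while frontier:
        met, atoms = frontier.pop()
        if (met, atoms) in seen:
            continue
        seen.add((met, atoms))
        if met in network.external:
            continue
        for t in network.transitions:
            for prob, prods in t.mappings:
                for pmet, letters in prods:
                    if pmet != met:
                        continue
                    picked = {letters[a - 1] for a in atoms}
                    for rmet, rl in t.reactants:
                        pos = tuple(
                            j + 1 for j, ch in enumerate(rl) if ch in picked
                        )
                        if pos:
                            frontier.append((rmet, pos))
    return len(seen)


# ---------------------------------------------------------------------------
# Random small network generator (for FVA/merge/extraction sweeps)
# ---------------------------------------------------------------------------


def random_chain_model(rng, n_internal=4, n_branches=2, model_id="rand"):
    """A random feasible growth network: a linear backbone from a substrate
    exchange to a biomass drain, with random branch reactions and bounds."""
    mets = [Metabolite(id="s[e]", name="s", compartment="e")]
    for i in range(n_internal):
        mets.append(Metabolite(id=f"m{i}[c]", name=f"m{i}", compartment="c"))
    rxns = [
        Reaction("EX_s", {"s[e]": -1.0}, -float(rng.integers(2, 12)), 1000.0),
        Reaction("T_s", {"s[e]": -1.0, "m0[c]": 1.0}, 0.0, 1000.0),
    ]
    for i in range(n_internal - 1):
        rev = bool(rng.random() < 0.3)
        rxns.append(
            Reaction(
                f"R{i}",
                {f"m{i}[c]": -1.0, f"m{i + 1}[c]": 1.0},
                -float(rng.integers(1, 8)) if rev else 0.0,
                float(rng.integers(2, 10)),
            )
        )
    for b in range(n_branches):
        i = int(rng.integers(0, n_internal - 1))
        j = int(rng.integers(i + 1, n_internal))
        rxns.append(
            Reaction(
                f"B{b}",
                {f"m{i}[c]": -1.0, f"m{j}[c]": 1.0},
                0.0,
                float(rng.integers(1, 6)),
            )
        )
    rxns.append(
        Reaction("BIO", {f"m{n_internal - 1}[c]": -1.0}, 0.0, 1000.0)
    )
    return MetabolicModel(
        metabolites=mets, reactions=rxns, objective_id="BIO", id=model_id
    )
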