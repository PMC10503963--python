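# Methods

`cocult` implements a constraint-based workflow for two-cell co-cultures:
starting from a generic stoichiometric model per cell type, it (1) fixes
thermodynamically forced reaction directions, (2) prunes the model down to
its expression-supported core, (3) merges the two cell-specific models into
one co-culture model sharing an extracellular space and growth medium,
(4) analyses the merged model by flux balance/variability analysis,
multi-objective Pareto scans and staged in-silico respirometry, and
(5) tightens ("tunes") the model's bounds with flux confidence intervals
estimated from ¹³C labelling data by EMU-based metabolic flux analysis.

## Steady-state constraint-based model

All analyses work on the linear system S·v = 0, lb ≤ v ≤ ub, where S is the
stoichiometric matrix (metabolites × reactions) and v the flux vector in
mmol/gDW/h. The steady-state assumption is appropriate when metabolite
concentrations change slowly relative to the simulated window, which holds
for exponentially growing cultures. Exchange reactions are written
`met[e] →` so that uptake is negative flux; a growth medium is a set of
maximum uptake magnitudes applied to exchange lower bounds, with a
configurable list of freely exchangeable species (CO₂, protons, water,
ammonia by default) that measured media compositions do not track.

Linear programs are solved with HiGHS through `scipy.optimize.linprog`
(feasibility tolerance 1e−9; reported values trusted to 1e−6). Infeasible
and unbounded problems are reported as statuses, never as zeros. Flux
variability analysis (FVA) minimises and maximises each reaction's flux at a
configurable fraction of the biomass optimum (default 1.0) and reports the
midpoint of each range; the midpoint is the workflow's representative flux
wherever alternate optima would otherwise make a read-out ambiguous.

## Thermodynamic directionality

Each metabolite may carry a standard Gibbs formation energy (kJ/mol) and a
physiological concentration range (defaults 1e−6–2e−2 mol/L; temperature
310.15 K; R = 8.314 J/mol/K). The reaction energy

ΔG(c) = Σᵢ sᵢ ΔGf,ᵢ + RT Σᵢ sᵢ ln cᵢ

is monotone in each ln cᵢ, so its extrema over the concentration box sit at
box corners (substrates at maximal / products at minimal concentration for
the minimum, and vice versa); the implementation evaluates the two corners
directly and the tests verify it against full 2^k corner enumeration. Water
and protons are exempt from the RT term (near-constant activity). A
reaction whose whole ΔG range is negative is clamped forward (lower bound
raised to 0); wholly positive clamps it in reverse; ranges straddling zero
leave bounds untouched, and the projection never widens a bound. Exchange
pseudo-reactions have no defined reaction energy and are skipped. A full
thermodynamic FBA with explicit ΔG variables inside the LP is deliberately
not implemented: the directionality projection plus the loop detector below
deliver the step's purpose (no thermodynamically infeasible flux loops) at
a fraction of the complexity.

Loop detection takes a flux solution, closes every exchange, restricts each
internal reaction to its solution sign and magnitude, and maximises the
remaining circulation by LP; any surviving support is grouped into
connected components (shared metabolites) and reported as loops. An empty
report certifies the solution loop-free at the given tolerance.

## Expression-based extraction

Binary present/absent calls per gene and sample are summarised as gene
ubiquity (fraction of samples present), propagated through GPR rules
(AND → min, OR → max), and blended with a topology score: a reaction's
connectivity score is the mean expression score of reactions sharing at
least one non-currency metabolite (ATP, NAD(H), water, protons, CO₂, Pi …
configurable), and `combined = w·expression + (1−w)·connectivity` with
w = 0.75 by default. Reactions without a gene association have *no*
expression score (not zero) and fall back to connectivity alone.

Pruning visits non-core reactions in ascending combined score (ties broken
by id, for determinism) and removes a reaction only when its score is below
the threshold *and* the pruned model still reaches the configured fraction
of the original biomass optimum *and* every core reaction can still carry
flux (checked by FVA without an objective floor). The score threshold is a
required analysis parameter with no privileged default. The end-to-end
pipeline treats all reactions without a GPR — exchanges, passive transport,
the proton leak, maintenance, the biomass machinery — as core, because
absent expression evidence says nothing about non-enzymatic steps. This is
a simplified, documented variant of the classic context-specific extraction
recipe; evidence classes and salvage-pathway checks of the original are out
of scope.

## Co-culture assembly and multi-objective analysis

Merging retags each cell's internal compartments with the cell label
(`pyr[c]` → `pyr[c_bm]`), suffixes internal reaction ids, unifies
extracellular metabolites by id, and collapses duplicated exchange
reactions to one (keeping the union of their bound intervals — the medium
is reapplied to the merged model afterwards, with per-cell allowances
summed at the shared boundary). Both biomass reactions are retained, making
the model genuinely bi-objective.

The Pareto front of the two growth rates is mapped by an epsilon-constraint
scan: biomass A is floored at n uniformly spaced levels spanning [0, max_A]
(default n = 21) and biomass B maximised at each; a second solve maximises
A at the attained B so every reported point is itself non-dominated, and a
pairwise filter removes dominated points. Endpoints coincide with the
single-objective optima. The front is exposed in full rather than any
single "co-culture growth rate"; the acceptance script additionally reports
the equal-growth point (the largest t feasible with both biomasses ≥ t,
found by bisection) as a convenient scalar summary.

## In-silico respirometry

The staged oxygraph protocol is simulated as four solves, each from the
unperturbed model:

1. **basal** — maximise biomass; pin it at the optimum; report the oxygen
   exchange's FVA midpoint. The midpoint convention resolves the ambiguity
   between "minimum flux distribution" and "biomass objective" read-outs
   deterministically; a plain FBA read-out is available via
   `basal_mode="fba"`.
2. **oligomycin** — ATP synthase fixed to 0, complexes I/III/IV floored at
   0 (no reversal), biomass maximised; the remaining oxygen flux is the
   proton leak.
3. **FCCP** — stage-2 constraints relaxed; complex IV flux maximised
   (uncoupled maximal respiration).
4. **rotenone + antimycin A** — complexes I and III fixed to 0, biomass
   maximised; remaining oxygen flux is non-mitochondrial.

Derived quantities: ATP-linked respiration = basal − oligomycin; spare
capacity = FCCP − basal. On the bundled toy cell the oligomycin stage is
leak-limited and equals L/(2P) mmol O₂/gDW/h for leak capacity L and pump
stoichiometry P protons per ½O₂ — a value the tests verify against the hand
calculation — and the rotenone/antimycin stage is exactly zero because the
toy has no complex-I/III bypass or extra-mitochondrial oxidase.

## ¹³C metabolic flux analysis (EMU)

Atom-mapped reactions are written in a plain-text grammar
(`docs/formats.md`); symmetric metabolites (succinate-like) expand their
producing mappings into the two atom orientations at probability ½ each.
The decomposition walks backward from the measured fragments, collecting
exactly the EMUs (metabolite + carbon subset) required, with convolution
nodes where a product fragment draws carbons from two reactants. Simulation
proceeds size-by-size: per size one linear system A·X = B couples the
same-size EMU MIDs, with substrate MIDs built from tracer definitions
(labelled positions, purity — default 0.99 — and labelled molar fraction)
and smaller-size convolutions on the right-hand side. Only flux ratios
affect the labelling state; the tests assert invariance under flux scaling
and agreement (≤1e−8) with an independent brute-force simulator that
enumerates all 2ⁿ isotopomer states per metabolite and iterates the exact
isotopomer balances to a fixed point.

Estimation minimises the variance-weighted SSR over all parallel tracer
experiments simultaneously (one flux vector, one residual vector spanning
both datasets plus measured uptake/secretion rates), over a free-flux
parameterisation obtained by QR column pivoting on the internal
stoichiometric matrix. Bound-constrained trust-region least squares
(`scipy.optimize.least_squares`, finite-difference Jacobian) is run from
many random feasible starts — production fits use at least 100 restarts;
the best SSR wins, deterministically for a given seed. Goodness of fit is a
chi-square test at α = 0.05 with dof = measurements − free fluxes.
Confidence intervals are Monte-Carlo: datasets resampled around the fitted
labelling state with the measurement SDs, each refit from the best
estimate, per-flux 2.5/97.5 percentiles reported with the point estimate
included in the percentile sample (so intervals always contain it; >20%
refit failures abort). Isotopic steady state is assumed throughout; natural
abundance correction is upstream of this package.

Exported intervals become bounds in the constraint-based model
(`apply_flux_intervals`): bounds are intersected, unmatched ids are
reported and skipped, and a post-tuning infeasibility raises with a greedy
relaxation hint (tuned reactions whose restoration makes the model feasible
again). The id map may carry a sign/scale factor per flux (−1 for exchange
reactions, where uptake is negative).

Growth-rate conversion treats one gram dry weight as one millimole of
biomass by default, so a biomass flux of 0.0306 mmol/gDW/h reads as
0.0306 /h; the factor is an explicit argument.

## Synthetic data generator

The generator emulates the study conditions end to end so every stage is
testable without downloads:

* **Toy cell models** (~54 reactions, 4 compartments): lumped glycolysis
  (declared reversible so the thermodynamic step has work to do), a serine
  side-branch, pyruvate/lactate/alanine/citrate transport, TCA cycle with a
  malic-enzyme-type exit (so glutamine can be fully oxidised),
  glutaminolysis in both cytosol and mitochondrion, an electron transport
  chain with explicit complexes I/III/IV/V, a configurable proton leak
  (default capacity 0.1 mmol H⁺/gDW/h) and pump stoichiometry (default 10
  H⁺ per ½O₂; ATP synthase 4 H⁺/ATP), ATP maintenance (lower bound
  0.2 mmol/gDW/h), and a biomass drain (20 pyruvate + 5 serine + 3 citrate
  + 3 alanine + 35 ATP per unit biomass — an invented, documented
  composition, not any published biomass equation). All internal reactions
  are elementally balanced; H/O are closed with water/protons after C/N/P/S
  balance by construction. The stromal-like and myeloma-like variants
  differ only by bounds: the myeloma-like cell has double the glycolytic
  and higher glutamine-transport capacity but less than a third of the
  respiratory-chain capacity, so the merged pair faces a real substrate
  trade-off and a stroma→myeloma pyruvate shuttle is feasible (asserted by
  maximising the transfer flux).
* **Medium**: glucose 0.45, glutamine 0.63, O₂ 5 mmol/gDW/h, echoing
  measured uptake magnitudes for cultured human cells; CO₂/H⁺/H₂O/NH₃ free.
* **Thermo table**: synthetic formation energies chosen so catabolic steps
  are clearly downhill, near-equilibrium steps (lactate dehydrogenase,
  transaminases, transporters) straddle zero, and the lumped glycolysis is
  forced forward. They are labelled synthetic and imply toy directions, not
  measured energetics.
* **Expression matrices**: independent Bernoulli presence calls per gene
  and sample from a configurable profile (default: 0.9 for core-pathway
  genes, 0.15 for a handful of dispensable isoforms/transporters),
  seed-reproducible.
* **Atom-mapped toy network** (17 reactions, 12 metabolites, ≤6 carbons
  each): lumped glycolysis, lactate/alanine efflux, pyruvate dehydrogenase
  and carboxylase, citrate synthase, the oxidative TCA branch with a
  symmetric four-carbon intermediate, glutamine anaplerosis, and an
  oxaloacetate biomass drain. The reference flux vector uses glucose uptake
  0.45 and glutamine uptake 0.63 with every internal balance closed.
* **Labelling datasets**: forward-simulated MIDs plus additive Gaussian
  noise on mole fractions (default SD 0.005, clipped at zero and
  renormalised), with the truth written alongside for recovery tests. The
  standard fitting problem pairs U-¹³C glucose and U-¹³C glutamine
  experiments with measured glucose/glutamine/lactate/alanine rates —
  without the efflux rates the lactate/alanine split is structurally
  unidentifiable from labelling alone.

What the generator does *not* emulate: microarray intensity distributions
and batch effects (calls are ideal Bernoulli draws), kinetic or regulatory
constraints, natural-abundance contamination of MIDs, compartment-specific
metabolite pools in the labelling network, or realistic genome-scale model
size. Passing tests therefore demonstrate correctness of the algorithms
under clean, known-truth conditions, not robustness to the artefacts of
real transcriptomic or GC-MS data.

## Numerical choices and problem sizes

Steady-state residuals are accepted at ≤1e−6; FVA range endpoints that
cross by solver jitter on degenerate ranges are swapped; the epsilon floor
in Pareto and respirometry re-solves is 1e−9. The brute-force LP oracle
enumerates basic solutions on networks of ≤8 reactions; the isotopomer
oracle enumerates all per-metabolite labelling states (≤2⁶ here) and
iterates to 1e−13. The test suite and the acceptance script run the
estimation studies at deliberately modest sizes — 100 restarts for the
headline noisy fit, 6 restarts and 25 Monte-Carlo samples per replicate for
the 12-replicate coverage study — which keeps the whole acceptance run
under a few minutes on one core while the binomial tolerance on pooled
coverage (≈200 checks) remains informative.

## Known limitations

* Two cells only; no dynamic (dFBA) or spatial co-culture.
* The directionality projection is not a full thermodynamic FBA; reactions
  with ΔG ranges straddling zero stay unconstrained.
* The extraction step reimplements the scoring idea in simplified form;
  results will not numerically match the original algorithm.
* The MFA engine assumes isotopic steady state and unidirectional
  atom-network reactions (no exchange-flux parameterisation of reversible
  steps), and measured MIDs are assumed natural-abundance corrected.
* Monte-Carlo intervals are percentile intervals around the fitted state;
  they are accurate for well-identified fluxes but can undercover near
  active bounds.
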