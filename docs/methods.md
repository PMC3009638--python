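# Methods

## Model representation and file formats

A model is metabolites (with an `external` flag for unbalanced boundary
species, an optional traced carbon count, and a cofactor flag used only
for filtering), reactions (signed stoichiometries; bounds in
mmol·gDW⁻¹·h⁻¹ with `inf` for symbolically unbounded sides), boolean
GPR rules, and one biomass objective. The stoichiometric matrix has one
row per internal metabolite; external species never enter the mass
balances.

Flat-file I/O follows the OptGene/BioOpt lineage: section headers
`-REACTIONS`, `-CONSTRAINTS`, `-EXTERNAL METABOLITES`, `-OBJ`,
`-DESIGNOBJ` (case-insensitive, leading dash optional), equations
`Rid : A + 2 B -> C` (`->` irreversible with bounds [0, ∞); `<->`
reversible, (−∞, ∞)), bound overrides `Rid [lo, hi]`, `%`/`#` comments.
Coefficient and section ordering in the writer is deterministic, so two
writes are byte-identical and write∘read is the identity on structure.
GPR rules travel in a separate two-column TSV (`reaction_id`, rule with
`and`/`or`/parentheses) because the flat dialect has no GPR syntax.
Cofactor flags are likewise not part of the format; `mark_cofactors`
re-applies the configurable currency list (H₂O, ATP/ADP/AMP, GTP/GDP,
phosphate, diphosphate, H⁺, NAD(P)(H), CO₂, O₂, NH₃, CoA) after
parsing.

## Linear programming

All LPs (FBA, the photon-minimization second phase, each FVA
subproblem) go through `scipy.optimize.linprog` (HiGHS) with primal
feasibility tolerance 1e-9. Symbolically unbounded bounds are replaced
by ±1e6 before solving; fluxes below 1e-6 are reported as zero. Joint
caps that no single bound can express — the net-carbon budget
Σ (carbons·uptake) ≤ C_total shared by glucose, CO₂ and HCO₃⁻ — are
extra linear inequality rows carried by the `ConstraintSet`.

Infeasibility is a distinct outcome (`InfeasibleProblem`), never
conflated with feasible zero growth; the two-phase procedure attaches
the maximum achievable growth to the error when the requested target is
out of reach. Degenerate optima are accepted as returned by the solver
(an arbitrary optimal vertex); condition comparisons therefore always
report FVA intervals alongside the point fluxes. The second phase pins
growth inside a two-sided band target·(1 ± 1e-6) to avoid infeasibility
from round-off, and FVA holds the objective at `fraction_of_optimum`
(default 1.0) minus a 1e-9 relative slack.

## The MOMA solver

MOMA minimizes ‖x − w‖² over the mutant polytope. The implementation
first eliminates every equality — mass balances, knocked-out reactions,
and fixed bounds (lower = upper, e.g. the maintenance flux) — through an
orthonormal nullspace basis N of the stacked equality matrix, with a
feasible particular point x₀ obtained from an LP (which doubles as the
feasibility check). Because N is orthonormal, the reduced problem is a
least-distance projection onto a polytope containing t = 0. Constraint
rows that cannot be reached within the ball ‖t‖ ≤ 2‖N'(w−x₀)‖ + 1 (in
particular the ±1e6 pseudo-unbounded bounds) are pruned; the active set
is located via the Lawson–Hanson dual-NNLS construction on normalized
rows and then polished by exact least-squares projections with a
bounded add/drop loop on the KKT conditions. Mass balance of the
result holds to machine precision by construction; the test suite
cross-checks distances against an independent SLSQP solve on a small
bounded network.

One consequence of accepting arbitrary LP vertices as the wild-type
reference w (the default; any `FluxDistribution` can be passed instead)
is that w may carry internal-cycle fluxes sitting at the ±1e6 bound.
The projection handles this correctly — the mutant simply matches the
cycle — but reported distances are then dominated by those cycles, which
is why screens classify on growth, not distance.

## Growth regimes

Conditions are matched per carbon atom: a budget of 3.4 mmol
C·gDW⁻¹·h⁻¹ means 3.4 mmol CO₂/HCO₃⁻ but only 0.567 mmol of six-carbon
glucose. Literature caps (glucose ≤ 0.85, CO₂ ≤ 3.7 mmol·gDW⁻¹·h⁻¹)
are enforced unless overridden. Maintenance ATP is a fixed flux of
1.67 × the glucose-equivalent uptake on a dedicated ATP-hydrolysis
reaction, applied in every regime (the light-fed regimes inherit the
same absolute requirement as the matched heterotrophic case).

* autotrophy — glucose closed; CO₂ and HCO₃⁻ open under the joint
  carbon cap (their split left to the solver); photons ≤ cap per
  photosystem (default 0.8 mE·gDW⁻¹·h⁻¹).
* dark heterotrophy — glucose ≤ C/6; photons (0, 0); CO₂ release only.
* light-activated heterotrophy — as dark, plus photons ≤ cap.
* mixotrophy — by default glucose ≤ C/6 **and** CO₂/HCO₃⁻ ≤ C are both
  open under the joint net-carbon cap, i.e. the mixotrophic feasible
  set contains both single-source sets (this is what makes the
  mixotrophic optimum provably ≥ either pure regime, and it reproduces
  the behavior of published mixotrophic comparisons where the full
  glucose uptake runs alongside CO₂). Passing
  `glucose_carbon_fraction=f` instead reserves f of the budget for
  glucose and 1−f for CO₂.

Net-carbon accounting uses signed uptake, so carbon released as CO₂ or
exported as product counts against the budget only while inside it —
the conservation test checks that net external carbon influx equals
growth × biomass carbon exactly.

## The synthetic phototroph

The toy condenses a cyanobacterial genome-scale architecture into 70
reactions / 73 metabolites / 63 genes: two photon exchanges feeding
condensed photosystems that share a plastoquinone pool with the
respiratory chain (NADH dehydrogenase, terminal oxidase), water
splitting with O₂ evolution, ATP synthase driven by a proton-motive
pseudo-metabolite (3 pmf per ATP; 2 pmf per photochemical event at
either photosystem), RuBisCO with a condensed Calvin cycle
(5 G3P → 3 Ru5P regeneration lump, phosphoribulokinase), a glucose
transporter, glycolysis with both ATP- and GTP-dependent pyruvate
kinases plus PEP synthetase, the oxidative pentose-phosphate lump, PEP
carboxylase anaplerosis, and a TCA cycle **without** 2-oxoglutarate
dehydrogenase, completed by the glyoxylate shunt. Succinate
dehydrogenase feeds the quinone pool; succinate has an export drain; an
optional bidirectional hydrogenase links NADH to H₂. Because the
shunt is the only way to oxidize acetyl-CoA fully, the succinate branch
carries real flux in glucose-fed growth — the property the knockout
design analyses exploit, and the reason succinate overflows in the dark
wild type.

Each photon-exchange flux unit delivers a packet of 10 photochemical
excitations, standing for one milli-einstein of captured light; this
keeps physiological mE-scale uptake caps commensurate with mmol-scale
carbon fluxes (≈10 photons per CO₂ fixed, the realistic order). The
biomass drain pulls 7 precursor proxies (pyruvate ← alanine,
3-phosphoglycerate ← glycine, 2-oxoglutarate ← glutamate, oxaloacetate
← aspartate, ribose-5-phosphate ← AMP, glucose-6-phosphate ← glycogen,
acetyl-CoA ← 16C lipid) with the published biomass-composition
coefficients, preserving their proportions without the ~80 biosynthesis
routes a full composition would need, plus 30 ATP and 10 NADPH per unit
growth — chosen so the four regimes grow at realistic relative rates
(dark slowest). Carbon is tracked for backbone skeletons only
(cofactors count 0), and every non-exchange, non-biomass reaction is
carbon-balanced by construction.

GPR rules include an isozyme pair (phosphoglucose isomerase), and
multi-subunit complexes (photosystem II, succinate dehydrogenase, the
GTP-dependent pyruvate kinase). 24 decoy genes (default) each gate a
dead-end side reaction hanging off a seeded-random internal metabolite:
they are never essential, give FVA genuinely blocked reactions in every
condition, and populate the reporter statistics with null genes.
`dead_end_decoy_genes` identifies them structurally.

The expression generator plants p ~ Beta(α, 1) on the genes neighboring
chosen metabolites (α = 0.1 default; Beta(α,1) is the canonical
monotone-density alternative on [0,1], and α = 1 recovers the uniform
null exactly — the generator then draws the same stream as an unplanted
dataset). Planting `g6p` makes glucose-6-phosphate the designed
reporter: its four neighbor genes (glucokinase, both PGI isozymes,
G6P dehydrogenase) are distinctive, whereas central hubs like PEP share
most of their genes with pyruvate and recover less reliably — a genuine
property of neighborhood-mean scores on hub metabolites, worth
remembering with real data.

What the toy does **not** emulate: nitrogen/sulfur metabolism,
compartments, thermodynamic (loopless) constraints, enzyme capacities,
and realistic transcriptional correlation structure (planted genes are
independent draws). Tests passing on it show the algorithms are
correct, not that any particular organism behaves this way.

## Reporter statistics

p-values are clamped to [1e-10, 1−1e-10] before Φ⁻¹ inversion so scores
stay finite. Metabolite neighborhoods exclude cofactors (else ATP and
water connect everything) and external species; metabolites with no
scored gene are skipped and listed. Backgrounds draw 10,000 random
aggregates per distinct neighborhood size, with replacement, from the
scored genes in canonical (sorted) order so results are invariant to
input ordering; identical scores for all genes raise a degenerate-input
error rather than dividing by zero. Aggregation is the plain
arithmetic mean of neighbor z-scores (the 1/√k-scaled variant found
elsewhere in the reporter literature is deliberately not used).

The co-regulated-subnetwork search is a documented stand-in for an
under-specified published procedure: genes are adjacent when their
reactions share a non-cofactor metabolite; from each top-decile gene a
set grows greedily by the neighbor that maximizes the
background-corrected aggregate score, stopping when the score drops or
a size limit (20) is reached. Because the best-of-many-starts raw
score is selection-inflated even on null data, the returned score is
calibrated against the same search on 30 gene-label permutations
((raw − mean)/sd; the permuted data reuse the same background since the
score multiset is unchanged). Under the uniform null the calibrated
score stays below 3 in practice; its sets are not claimed to match any
published gene list.

## Strain design

Deletions are reaction-centered; implied gene sets are reported post
hoc as minimal hitting sets of the GPR (exact by enumeration at these
rule sizes). Candidates exclude exchange reactions, the objectives and
GPR-less (spontaneous/transport) reactions — deleting an uptake would
trivially dominate. The exhaustive search enumerates all sets of size
≤ k (guarded at 200,000 evaluations); the genetic algorithm uses binary
deletion vectors capped at k set bits, tournament selection (size 2),
uniform crossover, per-bit mutation 0.02, elitism 1, population 40,
200 generations, mandatory seed, and memoizes evaluations. Designs
failing the growth filter (default ≥ 10% of wild type) score zero.
Design runs here use the glucose-fed dark regime, where the
TCA/glyoxylate route carries flux and knockouts visibly redirect it;
in the light-dominated regimes the succinate branch is idle at the
optimum and deletions have nothing to reroute.

## Deletion screens

Classes: `no_growth` below 1e-6 h⁻¹ absolute, `wild_type_growth` at
≥ 99% of the unperturbed optimum, `reduced_growth` between — both
thresholds are conventions exposed as parameters, applied identically
to FBA and MOMA growth. Genes absent from every GPR are wild-type by
construction. Infeasible mutants are `no_growth`.

## Problem sizes and determinism

The packaged analyses run on the 70-reaction toy: a full FVA is ~140
LPs (&lt;1 s), both genome-wide screens a few hundred LP/QP solves
(~1 s), the k ≤ 3 succinate enumeration over the 16-reaction central
candidate set ~700 MOMA solves (~20 s), and the reporter experiments
(20 recovery + 50 null replicates) a few seconds. Every stochastic
component (toy decoy placement, expression draws, backgrounds,
permutations, GA) takes an explicit seed; fixed seeds give
bit-reproducible tables, and float table output is written at 6
significant digits to keep reruns byte-identical.

## Known limitations

* FBA optima are vertices; alternate optima make individual point
  fluxes arbitrary (FVA intervals are the stable quantity).
* No loopless/thermodynamic constraints: pseudo-unbounded internal
  cycles can appear in solutions at the ±1e6 cap.
* The MOMA reference defaults to one FBA vertex; a different vertex
  changes distances (not growth classifications in the packaged tests).
* The subnetwork search is greedy; it returns a good connected set, not
  a global optimum, and its calibrated score is a heuristic
  significance measure, not a p-value.
* GPR inversion reports one minimal gene set; isozyme families with
  many members would make the enumeration expensive (irrelevant at toy
  scale).
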