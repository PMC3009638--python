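# synflux

Constraint-based analysis of cyanobacterial genome-scale metabolic
models: flux balance analysis of phototrophic growth regimes, flux
variability, MOMA mutant prediction, gene-essentiality screens,
OptGene-style knockout strain design, and reporter-metabolite
integration of transcriptome data — with OptGene/BioOpt flat-file I/O
and a fully synthetic phototroph network so every pipeline stage runs
without external data.

It is written for systems-biology practitioners who study
photoautotrophic microorganisms such as *Synechocystis* sp. PCC6803 —
organisms that grow on CO₂ and light, on sugar in the dark, or on both
at once — and who want a compact, fully tested Python stack for the
standard constraint-based workflow on such models.

## The models and statistics

**Flux balance analysis (FBA).** A metabolic network with stoichiometric
matrix *S* (one row per internal metabolite, one column per reaction) is
assumed at steady state, *S·v = 0*. Growth is the flux of a biomass
drain reaction whose coefficients are the cell's precursor demands
(mmol·gDCW⁻¹). FBA solves the LP

&nbsp;&nbsp;&nbsp;&nbsp;max *v*_biomass&nbsp;&nbsp; s.t. &nbsp;*S·v* = 0,&nbsp; *l* ≤ *v* ≤ *u*,

where the bounds encode reversibility, measured uptake caps and
maintenance ATP. Photon "uptakes" are bounded either by a physiological
two-phase estimate (fix growth, then minimize total photon flux) or by
the geometric maximum a spherical cell intercepts, *I·4πr²/m·3600*
(mE·gDW⁻¹·h⁻¹).

**Flux variability analysis (FVA).** With the objective held at a
fraction of its optimum, each reaction's flux is minimized and maximized
in turn; reactions whose interval is {0} in every condition are
*blocked*.

**MOMA.** A knockout mutant's flux state *x* is predicted as the point
of the mutant's feasible space minimizing the Euclidean distance
*D(w, x) = √Σᵢ(wᵢ−xᵢ)²* to the wild-type flux vector *w* — growth is
read off, not optimized. The convex QP is solved exactly via a
nullspace reduction and a least-distance projection.

**Knockout screens and strain design.** Gene deletions propagate to
reactions through boolean gene-protein-reaction (GPR) rules (AND =
complex subunits, OR = isozymes); mutants are classed as no-growth /
reduced / wild-type. Strain design searches reaction-deletion sets
maximizing a design flux (e.g. succinate export or H₂ evolution) while
MOMA or FBA fixes the biological flux state, by exhaustive enumeration
(k ≤ 3) or a seeded genetic algorithm.

**Reporter metabolites.** Per-gene p-values become z-scores,
*z*_gene = Φ⁻¹(1−*p*); a metabolite's score is the mean over its
neighboring genes, standardized against random aggregates of the same
size *N*: *z*corr = (*z* − *m_N*)/*s_N*. High-scoring metabolites mark
network regions where transcriptional change concentrates. A greedy,
permutation-calibrated search extracts co-regulated connected gene sets.

## Worked example

```python
import synflux as sf

model, gprs = sf.generate_toy_phototroph()
conditions = sf.standard_conditions(sf.toy_exchange_map())
for mode, cond in conditions.items():
    sol = sf.fba(model, cond.constraints)
    print(mode, round(sol.objective_value, 4))
```

prints

```
autotrophy 0.2573
dark_heterotrophy 0.0713
light_heterotrophy 0.487
mixotrophy 0.487
```

— the specific growth rates (h⁻¹) of the synthetic phototroph under a
matched carbon budget of 3.4 mmol C·gDW⁻¹·h⁻¹ (0.567 mmol glucose when
glucose is fed) and 0.8 mE per photosystem. Dark growth is slowest
because respiration must cover all ATP demand; mixotrophy, having every
source available, grows at least as fast as either pure regime. The
`examples/` scripts walk through each capability the same way (photon
minimization, essentiality screening, succinate designs, reporter
metabolites, model I/O) and print a line explaining each number.

A thin CLI mirrors the library for batch runs:

```
synflux make-toy --seed 7 --out-dir run/
synflux simulate --model run/toy_model.bo --gpr run/toy_gpr.tsv --mode autotrophy --out-dir run/
synflux knockout --model run/toy_model.bo --gpr run/toy_gpr.tsv --method moma --out-dir run/
```

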