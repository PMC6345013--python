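# Methods

## Scope and model

`mycoflux` implements the constraint-based analysis workflow used to build
and interrogate a genome-scale metabolic model (GSMM) of a
resveratrol-producing endophytic fungus: ortholog-driven draft
reconstruction, curation (balance checking, de-duplication, gap filling),
biomass-objective assembly, flux balance analysis (FBA) and flux
variability analysis (FVA), robustness scans, single-gene essentiality
screening, minimization of metabolic adjustment (MOMA), and an
overexpression-target scan for stilbene overproduction.  The genome-scale
model itself is distributed as journal supplementary material and is not
bundled; every procedure instead runs end to end on a bundled synthetic
mini-network (below) that mirrors the organism's pathway topology.

All flux analyses solve variants of

```
max  c' v    s.t.  S v = 0,   lb <= v <= ub
```

with `S` the stoichiometric matrix (metabolites x reactions), `v` fluxes
in mmol/gDW/h, and the biomass pseudo-reaction's flux equal to the
specific growth rate mu (1/h).  The steady-state assumption, fixed
reaction bounds, and a linear biomass objective are the standard FBA
idealizations; none of the regulatory, kinetic or thermodynamic structure
of the organism is represented.

## Reconstruction rules

* Ortholog filtering keeps BLAST-like hits with identity >= 40% and
  e-value <= 1e-30, both inclusive.  Mapping is one-way (no
  reciprocal-best filter); multi-hits are kept as sets.
* A reference reaction is imported into the draft iff its
  gene-protein-reaction (GPR) rule is satisfiable when exactly the mapped
  subject genes are present.  Imported GPRs are rewritten in target gene
  ids; reactions shared between references are merged by canonical
  stoichiometry (sorted metabolite ids, coefficients scaled so the first
  is one — a normalization that also identifies a reaction with its
  reverse), OR-ing their GPRs and widening bounds.  Groups whose members
  disagree in orientation or reversibility are flagged, not auto-resolved.
* Balance checking reports elemental and charge residuals per reaction;
  exchange/sink/demand/biomass reactions and reactions touching a
  species without a formula are skipped, never flagged.  The checker does
  not auto-correct proton conventions: the bundled network's printed
  acetate-activation equation balances exactly when diphosphate is taken
  as the fully deprotonated species (O7P2, charge −4), and that
  convention is used throughout.
* Gap filling is a deterministic add-all-then-prune procedure: all
  universal candidates are added (failure here is reported as
  "unfillable" with the list of objective precursors that cannot be
  synthesized), then candidates are removed in candidate order whenever
  removal keeps the objective above the target.  The result is minimal —
  removing any returned reaction breaks the target — and LP-only (no
  MILP).

## Biomass objective

Macromolecular mass fractions (g/gDW) are split into monomers by
per-macromolecule mass-fraction tables; monomer coefficients are
`macro_fraction * monomer_fraction / molar_mass` in mmol/gDW, so the
consumed monomer mass is exactly 1 g/gDW (verified to 1e-6 after
coefficients are rounded to 9 decimals, the serialization precision).
The organism's measured composition is 32% cell wall, 20% protein, 15%
mannitol, 15% ash, 14% lipid and 4% nucleic acid.  DNA monomer fractions
follow the genomic GC content (50.96%): dGMP = dCMP = GC/2,
dAMP = dTMP = (1−GC)/2, converted to mass fractions with dNMP molar
masses.  The amino-acid, lipid and cell-wall monomer profiles are
documented placeholders in a typical filamentous-fungus range, since the
measured tables are not published numerically.  Ash is a non-elemental
pseudo-species (assigned 0.1 g/mmol) excluded from balance checking;
mannitol is treated as a freely drained cytosolic storage compound.

Maintenance energy: growth-associated maintenance (GAM, default 60 mmol
ATP/gDW) enters the biomass reaction as an ATP-hydrolysis term;
non-growth-associated maintenance (NGAM, default 1.0 mmol ATP/gDW/h) is a
lower bound on a standalone ATP-hydrolysis reaction.  Both defaults are
assumptions in the range used for related filamentous fungi; the source
study adopted values from *Aspergillus terreus* without printing them.

## Flux analysis conventions

* LP backend: HiGHS via `scipy.optimize.linprog`; feasibility and
  optimality tolerances 1e-9, well below the 4 significant digits at
  which fluxes are reported; reported fluxes below 1e-6 are treated as
  zero by downstream consumers.
* Media set exchange lower bounds to minus the uptake rate; basic
  nutrients (water, protons, oxygen, ammonium, sulfite, phosphate) are
  left at −1000 mmol/gDW/h to mimic minimal medium; the rich-medium
  approximation opens glucose at 2.0 and each amino-acid exchange at
  0.01 mmol/gDW/h.
* Degenerate optima: the objective value is the deterministic contract;
  flux vectors are single optimal vertices and are only asserted through
  FVA ranges.
* Production analyses at fixed growth pin the biomass reaction
  (lb = ub = 0.055 1/h with glucose at 1.0 mmol/gDW/h and trace aromatic
  amino-acid uptake, the constraint set of the cofactor and ethanol
  analyses).  Robustness scans move one bound of the control reaction per
  point (a pure LP relaxation, hence monotone optima); pinning the flux
  instead is available via a flag.
* Metabolite connectivity is provided both structurally (all reactions
  touching a species) and flux-weighted (only reactions with |flux| above
  1e-6 in a given state), since either reading is defensible; ranking is
  by descending count with ties broken by id.

## Essentiality, MOMA and the overexpression scan

* A gene is essential when knockout growth falls below 1% of wild type
  (configurable; the threshold guards against LP round-off).  Knockouts
  disable exactly the reactions whose GPR becomes unsatisfiable.  The
  same 1e-6 growth-call threshold is used wherever growth is called
  "+" or "−".
* MOMA minimizes the squared Euclidean distance over *all* reactions
  (exchanges included) subject to the perturbed bounds.  The strictly
  convex QP is solved by operator splitting (ADMM alternating an exact
  nullspace projection with a box clamp, with residual-balanced penalty
  updates), finished by an exact active-set projection that is accepted
  only when it passes a KKT certificate — sufficient for global
  optimality here.  Perturbed-model feasibility is certified by an LP
  before the QP runs.
* The overexpression scan fixes the product exchange's lower bound at
  0.001 mmol/gDW/h, solves wild-type FBA, then forces each
  nonzero-flux reaction to twice its wild-type flux (fold configurable;
  the default mirrors the twofold in-silico observation that motivated
  it) and scores the product rate of the MOMA-adjusted state (plain FBA
  re-optimization is available as an option).
* Product measure: in a network that derivatizes resveratrol downstream
  (methylation to pterostilbene, hydroxylation to piceatannol), the
  quadratic adjustment may route forced extra synthesis through the
  derivative exchanges while the resveratrol exchange sits at its lower
  bound — a property of the QP geometry, not of the biology.  The
  mini-network analyses therefore score **total stilbene export**
  (resveratrol + pterostilbene + piceatannol), which equals the
  committed-pathway (stilbene-synthase) flux; forcing 4CL or CHS then
  doubles the product exactly, by stoichiometric necessity.  Scoring a
  single exchange remains the default for models without such branches.

## The synthetic mini-network

`generate_mini_model()` emits a deterministic, fully element- and
charge-balanced network (~95 reactions over cytosol and extracellular
space, ~50 of them internal enzymatic steps) standing in for the
genome-scale reconstruction.  It contains glycolysis, an
oxidative/non-oxidative pentose phosphate shunt, the seven-step shikimate
chain, prephenate branches to tyrosine and phenylalanine, the
phenylpropanoid/stilbene route (PTAL, C4H, 4CL, ACC, CHS with
stilbene-synthase stoichiometry `p-coumaroyl-CoA + 3 malonyl-CoA + 3 H+ →
resveratrol + 4 CO2 + 4 CoA`, plus a naringenin-chalcone reaction from
the same substrates embodying the CHS/STS overlap), pterostilbene and
piceatannol side branches, sucrose and rhamnose utilization, an ethanol
assimilation route whose acetate-activating step is the network's g0770
reaction, pyruvate-decarboxylase/acetate overflow, fatty-acid synthesis,
a truncated TCA entry to 2-oxoglutarate and glutamate, respiratory
lumps for NADH and cytosolic NADPH (P/O 2.5), and the biomass reaction
assembled by the biomass module.

Deliberate simplifications, and what they imply for test evidence:

* Multi-step segments are exact lumps of balanced elementary reactions
  (e.g. lower glycolysis, the oxidative PPP, AMP de-novo synthesis), so
  flux magnitudes are comparable to, but not identical with, a full
  reconstruction; tests that pass here demonstrate the correctness of
  the *procedures*, not organism-specific flux values.
* The TCA cycle is truncated at 2-oxoglutarate; full respiration of
  acetyl-CoA is impossible and excess carbon leaves as acetate or
  2-oxoglutarate (documented fungal overflow products).  Growth yields
  are therefore on the low side of realistic.
* Naringenin chalcone is a dead end (downstream flavonoid processing is
  out of scope), so the CHS/STS overlap is structural, carrying no
  steady-state flux.
* The methylation cycle behind pterostilbene is a boundary
  (S-adenosylmethionine sink / S-adenosylhomocysteine drain), not a
  regenerating pathway.
* Only two compartments are used; the eight-compartment structure of the
  full model is represented by the type system, not by the fixture.
* Gene ids are enzyme symbols (PFK1, CHS, ...), matching how the scan and
  deletion results are read in practice.

Defaults in the generator are fixed (no randomness); a seed only matters
when optional bound jitter is requested.  The medium conditions used by
tests and the acceptance script are the study conditions: glucose 2.0
mmol/gDW/h (validation and screening; amino acids 0.01 in the rich
approximation) and glucose 1.0 with growth fixed at 0.055 1/h (production
analyses, ethanol sweep on [0, 0.05]).

## Transcribed comparison tables

The growth-phenotype table bundles 20 carbon and 12 nitrogen substrates
with their in vivo / in silico growth calls (three carbon and one
nitrogen mismatches; starch, sucrose, rhamnose and dextrin flagged as
growing only after gap filling), giving agreement scores of 17/20 = 85%
and 11/12 → 92% (integer percents are reported round-half-up; the raw
fraction is retained).  Growth-rate deviations are computed as
`100 * |predicted − observed| / observed`, the in-vivo denominator
reproducing all three printed values (12.95% for 0.1247 vs 0.1104 1/h on
minimal medium; 1.3% for 0.1013 vs 0.1000 on glucose; 0.9% for 0.0885 vs
0.0893 on sucrose).  Genome coverage is 100 × 1539 / 13606 ≈ 11.31% of
predicted protein-coding genes.

## Experimental context (not simulated)

Several published outcomes are wet-lab results that no constraint-based
calculation reproduces, and this package does not claim to: the 26.31%
resveratrol increase under 4% ethanol and the growth inhibition at 5%;
the 33.32% increase under salicylic acid elicitation with ~1.8- and
~1.6-fold *4CL* and *CHS* transcript increases (methyl jasmonate showed
no effect); and the cerulenin growth-inhibition evidence for the
importance of lipid metabolism.  They are recorded here only as the
experimental context that the in-silico analyses (ethanol robustness,
overexpression targets, lipid-gene essentiality) qualitatively point
toward.

## Known limitations

* The balance checker reports residuals under one fixed
  protonation/charge convention; models mixing conventions will show
  spurious residuals rather than being corrected.
* Gap filling is greedy and order-dependent by design (deterministic
  given candidate order); it returns *a* minimal set, not a
  globally-minimum-cardinality set.
* MOMA's flux vector is the unique QP minimizer, but the scan's
  biological reading depends on the product measure chosen (see above).
* SBML round-trips are exact for coefficients with finite decimal
  expansions (all bundled fixtures); arbitrary rationals round-trip
  through doubles.
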