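# mycoflux

Constraint-based metabolic modeling of fungal secondary metabolism,
built around the workflow used to reconstruct and interrogate a
genome-scale metabolic model (GSMM) of the resveratrol-producing grape
endophyte *Alternaria* sp. MG1: draft reconstruction from ortholog hits,
curation (mass/charge balance checking, duplicate removal, gap filling),
biomass-objective assembly, flux balance and flux variability analysis,
robustness scans, gene-essentiality screening, MOMA, and an
overexpression-target scan for stilbene overproduction.

It is aimed at systems-biology practitioners who want these procedures as
a small, readable, fully tested Python library rather than a monolithic
toolbox.  Because the organism's genome-scale model is journal
supplementary material, the package ships a deterministic synthetic
mini-network with the same pathway topology (glycolysis, pentose
phosphate, shikimate, phenylpropanoid/stilbene, malonyl-CoA, ethanol
assimilation) on which every pipeline stage runs with no downloads.

## The model

Flux balance analysis (FBA) solves the linear program

```
max  c'v    subject to    S v = 0,    lb <= v <= ub
```

where `S` is the stoichiometric matrix, `v` the flux vector
(mmol/gDW/h) and the biomass pseudo-reaction's flux is the specific
growth rate μ (h⁻¹).  MOMA (minimization of metabolic adjustment)
predicts the immediate post-perturbation state as the unique solution of
the strictly convex quadratic program

```
min  Σ_j (v_j − v_ref,j)²    subject to    S v = 0,    lb' <= v <= ub'
```

solved here by operator splitting with an exact, KKT-certified
active-set finish.  The LP backend is HiGHS (scipy); cobrapy is used
only as an independent cross-check in the test suite.

## Worked example

```python
import mycoflux as mf

model = mf.generate_mini_model()                      # 93 reactions, 58 genes
medium = mf.set_medium(model, mf.minimal_medium())    # glucose 2.0 mmol/gDW/h
print(round(mf.solve_fba(medium).objective_value, 4))

study = mf.set_medium(model, mf.stilbene_study_medium())  # glucose 1.0
fixed = mf.fix_growth(study, 0.055)                       # mu pinned, h-1
print(round(mf.solve_fba(fixed, objective="EX_resv").objective_value, 4))

from mycoflux.minimodel import STILBENE_EXPORTS
targets = mf.scan_overexpression_targets(
    study, "EX_resv", min_product=0.001, fold=2.0,
    product_reactions=STILBENE_EXPORTS)
for t in targets:
    if t.reaction_id in ("4CL", "CHS", "PFK"):
        print(t.reaction_id, round(t.fold_change, 3))
```

prints

```
0.1694
0.1759
PFK 3.342
CHS 2.0
4CL 2.0
```

— the growth rate on glucose minimal medium (h⁻¹), the maximum
resveratrol export at fixed growth (mmol/gDW/h), and the stilbene-output
fold changes when phosphofructokinase, the 4-coumarate-CoA ligase or the
stilbene-forming chalcone synthase is computationally overexpressed
twofold: forcing either committed-pathway enzyme doubles total stilbene
export, which is how ethanol feeding and *4CL*/*CHS* up-regulation were
identified as overproduction strategies for this organism.

The same library surface is exposed on the command line:

```
mycoflux fixtures mini-model --out model.json
mycoflux fba solve --model model.json --medium medium.yaml
mycoflux perturb scan --model model.json --product EX_resv --fold 2
mycoflux validate phenotypes
```

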