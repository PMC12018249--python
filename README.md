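# immunoqsp

A mechanistic, multiscale quantitative systems pharmacology (QSP) simulator
for immune-checkpoint-targeting monoclonal (mAb) and bispecific (BsAb)
antibodies in syngeneic mouse tumor models.

## Who this is for

Modelers and pharmacologists in preclinical immuno-oncology who want to ask,
*in silico*: which pair of checkpoints should a bispecific antibody target?
What dose and schedule maintain efficacy? Does adding a third checkpoint (a
mAb on top of a BsAb) help, and in which tumor phenotypes?

## What the model contains

The simulator couples four layers into one ODE system per scenario:

1. **Checkpoint binding.** Mass-action reversible ligation of the
   physiological pairs (PD-1·PD-L1, TIGIT·CD155, CD28·CD80/86 and
   CTLA4·CD80/86 competing for the shared ligand pool, OX40·OX40L,
   4-1BB·4-1BBL, TCR·MHC, LAG3 engagement) plus drug binding: a mAb forms a
   1:1 drug–target dimer; a BsAb first forms dimers with either target and
   then bridges into a trimer, with a crosslink (avidity) factor α applied
   symmetrically on both association paths so the thermodynamic cycle closes.
2. **T cell signaling.** Five hub proteins with normalized active fractions
   x\* ∈ [0, 1]: TCR/CD28 inputs drive ZAP70 and PI3K, which drive AKT, ERK
   and NF-κB via

   dx\*/dt = k_f · (∏ upstream activities) · (∏ checkpoint factors) · (1 − x\*) − k_r · x\*

   Checkpoint complexes act through saturating Hill factors — inhibitory
   `1/(1 + (C/km)^h)`, stimulatory `1 + e_max·C^h/(km^h + C^h)` — the km4…km12
   family. LAG3 gates TCR initiation upstream of every hub. Active NF-κB,
   ERK and AKT drive IL-2 and IFN-γ release; CTLA4 surface expression is
   activation-induced (all other checkpoints constant).
3. **Cells and tumor.** Logistic tumor growth toward a prespecified maximal
   volume with a clearance term `k_kill · V · H`, where H is a multiplicative
   Hill composite of T cell activation, the effector:target ratio and IFN-γ;
   IL-2 boosts T cell proliferation. In vivo the tumor seeds 1e5 tumor
   cells, 370 T cells and 10 APCs per mm³.
4. **Pharmacokinetics.** Linear two-compartment mouse IgG PK with repeat IV
   bolus dosing (closed-form biexponential superposition); intratumoral
   concentration is the plasma concentration scaled by a partition
   coefficient K_p.

Population analyses sample 100-mouse virtual populations (Latin hypercube
over physiological ranges), screen all 21 bispecific combinations of the 7
targetable checkpoints by tumor growth inhibition
(TGI = 100·(1 − V_treated/V_control) at day 25), compare dosing regimens
(Wilcoxon rank-sum, response-depth binning at 20/40% TGI), run triple
(BsAb + mAb) combinations in checkpoint-low subgroups, and compute Sobol
global sensitivity indices of day-25 tumor volume.

## Worked example

```python
import numpy as np
from immunoqsp import (
    default_scenario, make_bsab, Treatment, DoseRegimen,
    simulate_invivo, compute_tgi,
)

cfg = default_scenario("invivo")            # 100 mm^3 tumor, 25-day study
control = simulate_invivo(cfg.control())
drug = make_bsab("TIGIT", "PD-L1")          # blocking/blocking bispecific
treated = simulate_invivo(cfg.with_treatments(
    [Treatment(drug=drug, regimen=DoseRegimen.qw(10.0, cfg.horizon))]
))
print(round(control.states["tumor"][0, -1]))          # 2467
print(round(float(compute_tgi(treated, control)[0]), 1))  # 39.9
```

The untreated tumor grows from 100 mm³ to ≈ 2467 mm³ by day 25; weekly
10 mg/kg of the TIGIT/PD-L1 bispecific inhibits that growth by ≈ 39.9%
(volume-ratio TGI at day 25). A population-level screen of all 21 target
pairs is one call:

```python
from immunoqsp import sample_population, screen_bsab_pairs
pop = sample_population(seed=1)             # 100 virtual mice
screen = screen_bsab_pairs(pop, (1.0, 10.0))
print(screen.matrix(1.0).round(1))          # checkpoint x checkpoint TGI
```

Under the shipped defaults the 4-1BB- and OX40-containing bispecifics (the
agonist arms) outrank every purely blocking pair at 1 mg/kg, and the
across-pair efficacy spread shrinks at 10 mg/kg as the blocking arms
approach target saturation.

A command-line interface wraps the same functions:

```bash
immunoqsp simulate --config scenario.yaml --out results/
immunoqsp vpop screen --seed 1 --out screen.csv
immunoqsp vpop gsa --seed 1 --out gsa.csv
immunoqsp fixtures-make --seed 1 --out fixture.csv
```

## Configuration

Everything is driven by a YAML/JSON scenario file (see
`src/immunoqsp/configs/schema.json` and the shipped defaults under
`src/immunoqsp/configs/default/`). The parameter registry is unit-annotated
and range-bounded; every default documents its rationale in its `source`
field, and all analyses are pure functions of the configuration, so
calibrated values can be substituted without touching code.

## Documentation

`docs/methods.md` describes the model equations and assumptions, the
default parameterization and its provenance, the synthetic-data generator,
numerical choices, and known limitations.
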