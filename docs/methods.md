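# Methods

This note documents the model, its default parameterization, the numerical
machinery, and the limits of what the test suite demonstrates.

## Model structure

### Units and compartments

Concentrations are nM, time is days, tumor volume is mm³, PK volumes are mL.
Surface species convert to concentration pools via
`copies/cell × cells/mm³ / N_A` (1 mm³ ≡ 1 µL). Cells are well-mixed
compartments: surface species share one concentration pool with soluble
antibody, with no explicit synapse geometry. Consequently the checkpoint
ligation dissociation constants are *effective* 3-D values that absorb
membrane/synapse confinement; they are orders of magnitude tighter than
solution-phase SPR constants and are documented as such in the registry.

### Binding layer

All checkpoint–ligand and drug–target binding is reversible 1:1 mass
action. CD80/86 is a single shared pool bound competitively by CD28
(effective K_d 0.02 nM) and CTLA4 (0.002 nM, ten-fold tighter — the
canonical affinity ordering). Monoclonals are monovalent 1:1 binders (no
cross-arm avidity; bivalency is a possible extension). Bispecifics form
two dimers and a bridged trimer; the crosslink factor α (default 10)
multiplies the trimer-forming on-rate on *both* association paths, which
preserves detailed-balance cycle consistency by construction. A
blocking-arm-bound checkpoint is sequestered and feeds no regulatory link;
an agonist-arm-bound receptor (dimer plus trimer, trimer weighted by a
configurable factor, default 1) counts toward the stimulatory pool exactly
like natural-ligand-bound receptor.

Inside the dynamic model, binding is treated as a **rapid equilibrium**:
antibody–antigen and ligation kinetics relax on the minutes-to-hours scale
while the cell, cytokine and PK states evolve over days, so at every
right-hand-side evaluation the complex levels are computed by an algebraic
equilibrium solve given the current totals. This makes mass conservation
exact by construction, removes the stiff binding kinetics from the
integrator, and is what makes 100-mouse batched screens tractable. The full
kinetic layer still exists (`ReactionNetwork.simulate_kinetics`) and the
test suite holds the two routes to ≤1e-5 relative agreement on randomized
networks, including dimer/trimer and shared-ligand competition motifs.

The equilibrium solver expresses each complex through cumulative
association constants and solves the conservation system for free species
with a damped Newton iteration in log-concentration space, batched over
subjects; isolated pairs short-circuit to the stable closed-form quadratic
`B = 2RL/(R+L+K_d+√((R+L+K_d)²−4RL))`. Convergence tolerance is 1e-12
relative on every conservation residual; absent species are floored at
1e-30 nM, and a solve that cannot reach 1e-6 raises with its residual.

### Signaling layer

Five hubs (ZAP70, PI3K → AKT, ZAP70 → ERK, ZAP70 → NF-κB) carry active
fractions obeying multiplicative activation kinetics with unconsumed
upstream modulators:

    dx*/dt = kf · (∏ upstream) · (∏ modulation) · (1 − x*) − kr · x*

The checkpoint→hub map is fixed, with half-effect constants km4…km12 (nM of
driving complex):

| index | complex | hub | sign |
|---|---|---|---|
| km4 | PD-1·PD-L1 | ZAP70 | inhibitory |
| km5 | PD-1·PD-L1 | PI3K | inhibitory |
| km6 | TIGIT·CD155 | ZAP70 | inhibitory |
| km7 | TIGIT·CD155 | NF-κB | inhibitory |
| km8 | engaged 4-1BB | ERK | stimulatory |
| km9 | engaged 4-1BB | AKT | stimulatory |
| km10 | engaged OX40 | AKT | stimulatory |
| km11 | engaged OX40 | NF-κB | stimulatory |
| km12 | CTLA4·CD80/86 | ZAP70 | inhibitory (direct link; CTLA4 additionally acts through CD80/86 competition) |

LAG3 is distinct: its engaged complex gates TCR initiation upstream of all
hubs (`1/(1+(C/km_LAG3)^h)`), reflecting adaptor sequestration from the
CD4/CD8 co-receptors rather than hub-level phosphatase recruitment. CD28
costimulation is a stimulatory factor on PI3K. Adaptors (SHP2, SHIP1, Lck,
TRAFs) are not explicit states; their action is absorbed into these Hill
factors. Hub regulation reads bulk complex concentrations: as T cells
expand they compete for the shared ligand pools, a density feedback that
stabilizes the baseline. (A per-T-cell normalization was evaluated and
rejected — it removes this competition and makes the untreated baseline
self-igniting.)

Transient phospho-dynamics arise from first-order desensitization of the
responsive TCR pool, `dR/dt = krec(1−R) − kdes·occupancy·R`: under a step
anti-CD3 stimulus pZAP70 rises and then falls toward a lower plateau
(peak/plateau ≈ 1.27 at the default 20 nM bath). The decay mechanism is a
modeling choice; the observable data constrain only the transient shape.

Cytokines: IL-2 and IFN-γ are produced at `kf_cyt · g` with the normalized
multiplicative drive `g = NF-κB*·ERK*·AKT*` ∈ [0,1] and cleared first
order. IL-2 feeds back on T cell proliferation; IFN-γ feeds the kill
drive. Surface CTLA4 relaxes first-order toward an activation-dependent
ceiling (basal 1000 → up to 10,000 copies/cell at full NF-κB activity);
every other checkpoint total is constant per cell.

### Cell layer

Tumor volume is an exact linear map of tumor cell count (10⁵ cells/mm³;
immune cells do not add measured volume):

    dV/dt = kg·V·(1 − V/Vmax) − kkill·V·H
    H = [g/(g+km_act)] · [r/(r+km_ET)] · [IFNγ/(IFNγ+km_IFNγ)]

with r the effector:target ratio N_T/N_tumor (a count basis is available
by option). T cells proliferate logistically with an IL-2 Hill boost and
die first order; the carrying capacity scales with current tumor volume
(default 2000 cells/mm³), which bounds the effector:target feedback. APC
count is constant, so APC-carried ligands (CD80/86, OX40L, 4-1BBL) dilute
as the tumor grows — the CTLA4/CD28-axis half-effects are therefore
anchored at the diluted mid-study complex scale. Volumes below 0.5 mm³ are
treated as eradicated for density bookkeeping.

The kill-drive half-effects sit near the *realized baseline* levels of
their inputs (g ≈ 0.03–0.1 along an untreated trajectory), so each factor
operates in a partially saturated regime. This is deliberate: over a
25-day study any sustained kill-rate difference is exponentially
amplified, and half-effects far below baseline would make every treatment
arm collapse to all-or-nothing outcomes instead of the graded day-25 TGI
range the defaults are calibrated to show.

### Pharmacokinetics

Standard linear two-compartment model, one shared mouse IgG parameter set
for every antibody (CL 0.2 mL/day, Vc = Vp = 1 mL, Q 0.5 mL/day; β-half-life
≈ 7 d), overridable per configuration. IV bolus only. Because the system is
linear, the engine evaluates plasma concentration as the closed-form
superposition of shifted biexponentials (exact; integration restarts at
dose times), and the tumor concentration is `Kp · C_plasma` (Kp 0.3,
instantaneous; a first-order delay variant sits behind a config flag).
Drug consumed by tumor target binding is not fed back into the plasma mass
balance — the tumor is a sink of negligible volume, keeping plasma PK
linear. A numeric ODE path exists solely as a cross-check.

## Default parameterization

Calibrated parameter values from the original multi-study fits are not
available, so the shipped registry is curated: every entry carries a
provenance note (typical surface densities, typical antibody kinetics,
standard mouse PK). Arm affinities default per target (anti-PD-L1 1 nM,
anti-LAG3 and agonist arms 2 nM, otherwise 10 nM). The free constants —
regulatory strengths km4…km12, stimulatory e_max values, kill-drive
half-effects and kkill — were calibrated so the documented qualitative
behaviors hold under the defaults:

- untreated MC38-scale growth: 100 → ≈ 2500 mm³ in 25 days;
- dose-monotone TGI for each of the seven single-target antibodies;
- every 4-1BB/OX40-containing bispecific outranks all purely blocking
  pairs at 1 mg/kg (agonism adds signal that blockade can only disinhibit);
- the across-pair TGI spread shrinks from 1 to 10 mg/kg (blocking arms
  approach target saturation);
- the LAG3/PD-L1 bispecific saturates near 3 mg/kg (both arms are
  high-affinity against small/abundant-but-titratable targets);
- half-dose twice-weekly ≈ full-dose weekly at equal cumulative dose (long
  antibody half-life);
- adding a third-checkpoint mAb to a BsAb never hurts (no antagonistic
  mechanism is modeled).

These are properties of the shipped defaults, verified by the test suite;
users substituting their own calibrated values inherit none of them
automatically.

## Virtual populations and analyses

Populations are Latin-hypercube samples (deterministic per seed):
3-fold log-uniform ranges around the default for rates and per-cell
expression (initial tumor volume and T cell seeding density ±50% uniform),
clipped to registry bounds; default n = 100. "Checkpoint-low" subgroups
resample that checkpoint's expression log-uniformly within the lower
decile of its range. Sobol first/total-order indices use Saltelli-type
estimators on Sobol' sequences (via `scipy.stats.sobol_indices`) with
bootstrap confidence intervals; the GSA output functional is untreated
day-25 tumor volume from 100 mm³. Failed evaluations are mean-imputed and
counted. The rank-sum test uses the exact null for untied samples with
n ≤ 10 and the tie-corrected normal approximation otherwise; regimen
comparisons report raw p-values plus a Holm-adjusted column.

## Synthetic data generator

`fixtures.generate_fixture` simulates a scenario at known parameters,
samples a schedule, applies mean-one multiplicative lognormal noise
(defaults: CV 10% for signaling readouts, 20% for tumor volumes) and
optionally max-normalizes traces, mirroring how phospho-protein panels are
reported. It emulates the *classes* of calibration data (normalized
phospho time courses, cytokine dose-responses, tumor volume curves) — not
any specific experimental dataset — so passing recovery tests demonstrate
identifiability and optimizer correctness under the model's own noise
assumptions, not agreement with real measurements.

The standard recovery fixture is a three-arm anti-PD-1 study (dose scale
0×/0.1×/1× of 30 mg/kg weekly, one shared scenario structure) plus a
T-cell-dense co-culture arm: in vivo volumes pin kg and kkill, while the
co-culture IFN-γ trace — where the PD-1 complex sits far above its
half-effect — pins km4, which in-vivo volumes constrain only weakly at
physiological infiltration. Recovery runs use 10% volume CV (within the
5–20% band the generator supports) and a 15-day in-vivo horizon.

## Numerics

- Integration: explicit RK45, rtol 1e-6 / atol 1e-9 (per-state atol scaled
  by magnitude: volumes mm³-scale, counts cell-scale). Binding is
  algebraic (above), so the remaining dynamics are non-stiff; tightening
  tolerances 10× changes day-25 volume by <0.1%. Dose events restart the
  integrator at each bolus.
- Batching: everything is vectorized over subjects; a 100-mouse arm is one
  ODE solve. Poll sets in calibration and dose grids ride the same batch
  axis (`dose:<drug>` and `bath:<drug>` override columns scale exposure
  per subject).
- Pattern search: generalized coordinate polling on a normalized box,
  contraction 0.5, expansion 2.0, default budget 2000 evaluations,
  deterministic given the start point; calibration searches in log
  coordinates by default (rates and affinities are multiplicative).
  Objective: sum of squared residuals, each observable trace weighted by
  1/max|value| within its arm.
- Depleted pools are frozen at zero (no negative excursions); hub states
  are clipped to [0, 1] on read.
- The composite stimulatory boost any hub receives from convergent inputs
  is capped at 10-fold (shared downstream signaling capacity saturates).
  The cap only binds when two agonist arms multiply on one hub — where the
  hub is near-saturated anyway — and it bounds the activation-flux
  timescale the explicit integrator must resolve.
- After tumor collapse the infiltrate contracts at a bounded rate (at most
  10/day) toward the volume-scaled carrying capacity, which shares the
  0.5 mm³ eradication floor; both guards act only post-eradication.

## Problem sizes used in shipped analyses

Screens run 21 pairs × 2 doses × 100 mice; regimen and saturation
comparisons reuse the shared untreated arm; the acceptance script runs 10
noisy recovery replicates (the test suite runs 20) and the Ishigami oracle
at N = 1024 with 100 bootstrap resamples.

## Known limitations

- No NK cells, CD4/CD8 subsets, or exhaustion compartments; APC count is
  fixed.
- Checkpoint expression is constant except CTLA4; no cytokine-induced
  PD-L1 dynamics.
- No FcγR-mediated crosslinking, no TMDD plasma nonlinearity, no
  spatial/synapse geometry; mAbs are monovalent.
- The in-vitro modes use effective contact densities mirroring the in-vivo
  operating point; absolute in-vitro killing magnitudes are not calibrated
  to any particular assay format.
- Defaults are curated, not fitted to the original experimental corpus;
  quantitative predictions should be re-calibrated against user data
  (`calibrate_parameters`) before being trusted for design decisions.
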