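# Methods

## The model

`oxcascade` models the oxygen-regulation cascade that the pea
microsymbiont *Rhizobium leguminosarum* bv. *viciae* 3841 uses to switch
on its symbiotic respiration machinery.  Two sensors with very different
O₂ set points are wired into one pathway:

* **hFixL**, a membrane kinase inactivated by O₂ binding, half active
  near 12 µM dissolved O₂ (≈1% headspace O₂ at 1 atm).  Active hFixL
  phosphorylates the response regulator **FxkR**, which induces the
  transcription factor **FixK** through a K-box operator
  (GTTACA-N₄-GTTACA).
* **FnrN**, an FNR-family factor whose O₂-labile Fe-S cluster restricts
  activity to near-anoxia (half point ≈120 nM, ≈0.01% headspace).

FixK and active FnrN both bind anaerobox operators (TTGAT-N₄-ATCAA) as
dimers and are assumed to induce identically when bound; FnrN binds more
tightly.  The *fnrN* promoter carries two anaeroboxes — a distal
activating box and a proximal box that represses by steric hindrance —
so FnrN auto-activates and auto-represses.  *fixNOQP* (the cbb₃ oxidase
operon, the pathway's symbiotic readout) is driven by a single
activating anaerobox.

Five species are tracked: hFixL (L), FxkR (R), FixK (K), FnrN (N) and
FixNOQP (F).  With δ the shared first-order removal rate and c the
dissolved O₂:

```
f_L(c) = K_L² / (K_L² + c²)          hFixL active fraction (cooperative)
f_N(c) = K_NO2 / (K_NO2 + c)         FnrN active fraction (first order)
R_a    = R · f_L(c) · L/(β_L/δ)      active FxkR (quasi-steady phosphorylation)

dL/dt = β_L − δL
dR/dt = β_R − δR
dK/dt = α_K + β_K · R_a/(K_RK + R_a) − δK
dN/dt = α_N + β_N · θ_dist · (1 − θ_prox) − δN
dF/dt = α_F + β_F · θ_fix − δF
```

θ is the competitive occupancy of one anaerobox,
θ = (x + y)/(1 + x + y) with x = (K/A_K)², y = (N·f_N(c)/A_N)²; the
proximal *fnrN* box uses affinities penalised by ρ_K, ρ_N > 1, and the
*fixNOQP* box has its own pair (A_K_fix, A_N_fix).  Hill exponent 2
throughout the cooperative steps (hFixL–O₂, FixK–DNA, FnrN–DNA); the
FnrN–O₂ step is first order because it is not among the cooperative
processes.  Knocking out a gene zeroes all of its synthesis terms and
nothing else; reporter readout is the instantaneous promoter
transcription rate (what a plasmid-borne transcriptional fusion
measures), so knocked-out genes still have a defined promoter activity.

Design choices made where the design was genuinely open:

* **Sensor-abundance scaling of R_a.**  A pure transfer-function rule
  ("active FxkR = R × f_L") would leave the pathway live in an hfixL
  knockout; scaling by L relative to its wild-type steady level
  (β_L/δ) is identical at the WT steady state and zero in the knockout.
* **Separate fixNOQP-box affinities.**  Sharing one affinity pair
  between the *fnrN* distal box and the *fixNOQP* box makes the
  in-planta calibration targets provably contradictory (the knockout's
  fixNOQP ratio would be pinned to its fnrN ratio); distinct operator
  context justifies distinct affinities and removes the degeneracy.
* **Constitutive hfixL and fxkR.**  The real fixK₉a–hfixL₉ operon sits
  behind a K-box, but the simplified network carries one copy of each
  gene and no feedback onto the sensor; the model keeps both inputs
  constitutive.  FxkR negative auto-regulation is likewise omitted.
* **Nondimensionalisation.**  Protein concentrations are in arbitrary
  units (ratios to wild type are the only calibrated observables) and
  time is in turnover units, δ = 1.  Dissolved O₂ is in molar, linked to
  headspace fractions by a Henry constant of 1.2×10⁻³ M·atm⁻¹, fixed so
  that 1% ↔ 12 µM and 0.01% ↔ 120 nM exactly.

## Steady states and bifurcation structure

The cascade is triangular — L, R and K feed forward with no feedback
from downstream — so every steady state is a root of a scalar
fixed-point equation in N.  Two independent solvers are implemented and
cross-checked: a generic multi-start damped Newton iteration on the full
5-dimensional right-hand side (50 Latin-hypercube starts plus the basal
state and continuation seeds; root tolerance 10⁻⁹ max-norm;
deduplication at 10⁻⁴ relative distance) and the exact scalar reduction
(dense sign scan of the N-balance with Brent refinement).  Stability is
read from the eigenvalues of a central finite-difference Jacobian with a
10⁻⁷ real-part margin; borderline spectra are flagged and classified
unstable rather than silently labelled.

Oxygen sweeps run high→low (a bacterium's journey into the nodule) over
a log-spaced grid, 21% to 0.001% headspace equivalents, 200 points by
default, seeding each point's Newton starts with the previous point's
roots.  The bistable window is the maximal contiguous run of grid points
with ≥2 stable states, its edges refined by bisection between grid
points.  When a genotype is multistable, the physically selected state
follows the **history rule**: forward integration from that genotype's
free-living steady state (itself reached from the atmospheric state),
then snapping to the nearest exact root.  The nodule-zone profile
applies the same rule marching tip→root along a prescribed log-linear
gradient (12 µM → 30 nM over 80 positions by default; the 12 µM tip
value is this package's anchor for hFixL activity in zone I, and the
gradient is prescribed, not computed — leghaemoglobin transport is out
of scope).

## Calibration

Nine published observables calibrate the free parameters: seven
mutant/WT reporter percentages (free-living microaerobic and in-planta
bacteroid assays; where two *fixNOQP* operons are reported the pRL9 copy
is used, as the model has one FixNOQP species), plus the wild-type
fixNOQP fold induction (~5) between 21% and 1% O₂.  The objective is
unweighted least squares on log-ratios — log scale so that the large and
small percentages weigh equally — with the published bound that the
fnrN fold induction is "more than double" the fixNOQP one entering as a
soft penalty barrier rather than a squared term.  K_L is bounded to
[6, 24] µM and K_NO2 to [60, 240] nM around the stated activity
thresholds; n_L = n_DNA = 2, δ = 1 and β_L = β_R = 1 are fixed;
A_N < A_K is enforced for both operator pairs.  Two further soft
barriers encode qualitative biology that the ratio rows alone do not
pin down: the hfixL knockout's low-expression branch must persist, with
a real basin, through the published bacteroid O₂ range (20–50 nM) and on
to the bottom of the sweep — knockout bacteroids show reduced, smooth
expression throughout the fixing zone, which a population deterministically
forced past a fold could not produce.  Optimisation is multi-start
bounded least squares in log-parameter space; a converged candidate is
accepted only if it also reproduces the qualitative structure of the
published behaviour — wild type monostable over the full sweep, hfixL
knockout bistable entirely below 120 nM with the low branch persisting
as above, the descending knockout still on its low branch at bacteroid
O₂, wild-type fnrN rising to an interior maximum before declining,
wild-type fixNOQP monotone — otherwise the next-best start is taken.
Identifiability is claimed at the level of the nine predictions only,
never of raw parameters.

The shipped calibration reproduces seven of the nine observables within
15% relative.  The two in-planta fnrN reductions (knockouts at 22% and
28% of WT) are **structurally out of reach** of a deterministic
single-state readout: under the history rule the hfixL knockout reads
out its low branch, whose fnrN promoter activity is near-basal (the
shipped fit predicts ≈8%, not 28%), while the fnrN-knockout row is
capped by promoter saturation against the free-living constraints
(predicted ≈32%, not 22%).  In the model's own narrative the measured
in-planta knockout values are averages over a *partially committed
population* — exactly the stochastic-commitment regime the ensemble
module simulates — which a deterministic branch readout cannot
represent.  Attempts to force these two rows quantitatively either
destabilise the knockout's low branch (contradicting the observed
reduced expression) or place its fold exactly at bacteroid O₂, which
produces an artefactual near-vertical onset in the spatial profile.
The misfit is documented here rather than hidden by reweighting.

## Stochastic ensembles

Commitment is simulated with Euler–Maruyama on the deterministic
right-hand side plus additive noise of shared amplitude σ on every
synthesis term (knocked-out genes have no synthesis term and hence no
noise); negative excursions reflect at zero.  Defaults: dt = 10⁻³
turnover times, horizon t_end = 50, σ chosen once so that the shipped
knockout's commitment curve spans roughly 5–95% across its bistable
window, and stored in the defaults file.  At each O₂ point all cells
start on the low/basal stable state; a cell is committed when its final
state is nearest the high-FnrN stable state.  Above the window there is
no high basin (fraction 0); below its lower edge the low basin is gone
(fraction 1); the wild type, having a single basin everywhere, reports a
degenerate (NaN) fraction.  Molecule counts and master-equation detail
are out of scope; σ is an illustrative scale, not a measured quantity.

## Synthetic reporter data

The generator emulates the assays' statistical structure: model
predictions × unit-mean lognormal noise (positive, right-skewed, like
Fluo/OD₆₀₀ ratios), coefficient of variation 0.2 for plate assays and
0.35 for bacteroid assays (plant-to-plant variability), ≥3 biological
replicates, and normalisation of each (scenario, reporter) group so the
wild-type mean is exactly 100.  It deliberately does **not** emulate
instrument drift, growth-phase coupling, plasmid copy-number effects or
the ANOVA/Dunnett testing of the original figures — so a passing
round-trip shows the estimation machinery is self-consistent at realistic
noise, not that the model fits any particular real plate.  Parameter
recovery refits the model to group means of a synthetic dataset and
compares generating and recovered predictions row by row.

## Operator scanning

The anaerobox consensus TTGAT-N₄-ATCAA is an exact palindrome, so
forward and reverse matches coincide; each site is reported once on the
forward strand.  The K-box GTTACA-N₄-GTTACA is a direct repeat and is
scanned on both strands.  Offsets follow the no-zero convention (TSS
base = +1, upstream negative) and anchor the motif's 5′-most base on the
forward strand — the published operator tables do not state which base
is anchored, so this is a documented convention of the package, not an
inference.  Matching is exact by default (the consensus is treated as
exact); an N in the sequence never matches a fixed consensus base.
Fixtures are rejection-sampled motif-free backgrounds with one operator
planted at a known offset, and the scanner is tested against an
independent regular-expression oracle.

## Numerical choices and degenerate inputs

* c = 0 (anoxia) is legal and handled in closed form; negative
  concentrations and oxygen are errors, never clamped.
* Time integration uses LSODA; `integrate_to_steady` reports
  non-convergence as an explicit error rather than returning a drifting
  state.  Basin identification during history selection integrates at
  looser tolerance and then snaps to the exact root.
* Newton iterates are projected to the non-negative orthant; step
  halving guards against overshooting folds.
* Headspace fractions above 0.21 warn (not error): not physically
  meaningful at 1 atm but occasionally useful in tests.
* Sweep grids must be strictly descending; window edges at the end of
  the swept range are reported at the grid boundary, as the window may
  extend beyond it.

## Problem sizes

Shipped analyses use 200-point sweeps for bifurcation figures, 60–80
point grids for structure checks and profiles, 500 cells per O₂ point
for reported commitment fractions, and 8 optimisation starts for a full
calibration; all were chosen as the smallest sizes at which the reported
quantities are stable to further refinement.

## Known limitations

NifA and the nitrogenase machinery sit downstream of the modelled
pathway and are excluded, so acetylene-reduction phenotypes are outside
the model's reach.  The single FixNOQP species aggregates the two
plasmid operons.  The O₂ gradient in the nodule is prescribed, not
solved.  Concentrations are unitless; only ratios and fold changes are
meaningful.  The two calibration rows noted above are known structural
misfits of this promoter model.
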