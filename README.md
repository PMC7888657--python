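# oxcascade

Modelling the dual-sensor oxygen regulation cascade of *Rhizobium
leguminosarum* bv. *viciae* 3841 (Rlv3841), the pea microsymbiont.

Rhizobia experience a drop of three orders of magnitude in oxygen as
they move from soil into the near-anoxic nitrogen-fixing core of a
legume nodule, and they stage their response with two sensors wired
into one pathway.  The O₂-tolerant membrane kinase **hFixL** (half
active near 12 µM dissolved O₂, ≈1% headspace) signals through the
response regulator **FxkR** (K-box operator, GTTACA-N₄-GTTACA) to
induce the transcription factor **FixK**.  FixK and the near-anaerobic
sensor **FnrN** (half active near 120 nM, ≈0.01%) both bind palindromic
anaerobox operators (TTGAT-N₄-ATCAA) as dimers, driving the *fnrN* gene
itself — distal box activating, proximal box sterically repressing, so
FnrN auto-activates and auto-represses — and the *fixNOQP* operon
encoding the cbb₃ terminal oxidase needed for bacteroid respiration.

`oxcascade` is a Python library for analysing this cascade as a
five-species ODE system:

```
dL/dt = β_L − δL                                   hFixL
dR/dt = β_R − δR                                   FxkR
dK/dt = α_K + β_K·R_a/(K_RK + R_a) − δK            FixK   (K-box, R_a = R·f_L(c)·L/L_wt)
dN/dt = α_N + β_N·θ_dist·(1 − θ_prox) − δN         FnrN   (dual anaerobox)
dF/dt = α_F + β_F·θ_fix − δF                       FixNOQP (single anaerobox)
```

with Hill-2 transfer functions for hFixL–O₂ and for FixK/FnrN DNA
binding, competitive anaerobox occupancy
θ = (x + y)/(1 + x + y), x = (K/A_K)², y = (N·f_N(c)/A_N)², and
first-order FnrN–O₂ inactivation.  The package provides:

* steady states by two independent routes (multi-start damped Newton
  and an exact scalar reduction), stability from the Jacobian spectrum,
  bifurcation sweeps over O₂ and bistable-window detection;
* the published experimental scenarios (21%, 1% headspace; 30 nM
  in-planta) with knockout genotypes, mutant/WT expression ratios, fold
  inductions and nodule-zone expression profiles under a history-based
  state-selection rule;
* calibration of the free parameters to the published mutant/WT ratio
  table (shipped as the default parameter set);
* Langevin ensembles quantifying stochastic commitment to high
  expression in the bistable hfixL-knockout regime;
* a synthetic reporter-data generator (lognormal plate/bacteroid noise)
  with parameter-recovery round trips;
* an anaerobox / K-box promoter scanner with TSS-relative coordinates
  (FASTA + BED-like TSS tables).

See `docs/methods.md` for model assumptions, parameters and numerical
choices, and `examples/` for one narrative script per capability.

## Worked example

Knockout phenotypes at the two assay oxygen levels, with the shipped
calibrated parameters (`examples/02_knockout_ratios.py`):

```
$ python examples/02_knockout_ratios.py
   scenario genotype reporter  observed  predicted  rel_error
free_living   dhfixl     fnrN      25.0       21.5        0.1
free_living    dfnrn     fnrN     100.0      100.0        0.0
free_living   dhfixl  fixNOQP      17.0       18.7        0.1
free_living    dfnrn  fixNOQP      73.0       77.4        0.1
  in_planta    dfnrn     fnrN      22.0       32.3        0.5
  in_planta   dhfixl     fnrN      28.0        7.9        0.7
  in_planta    dfnrn  fixNOQP       5.0        5.0        0.0
  in_planta   dhfixl  fixNOQP      68.0       69.7        0.0
       fold       wt  fixNOQP       5.0        5.5        0.1
```

Each row compares a published reporter-fusion measurement (mutant
activity as % of wild type, or the wild-type fixNOQP fold induction
between 21% and 1% O₂) with the calibrated model's steady-state
promoter activity.  Losing hFixL collapses free-living induction —
FnrN is still oxidised at 12 µM O₂ — while losing FnrN barely matters
in culture but removes almost all fixNOQP expression at bacteroid
oxygen.  Seven of the nine observables are reproduced within 15%; the
two in-planta fnrN rows sit beyond the reach of a deterministic
single-state readout, because the measured values average over a
partially committed cell population — `docs/methods.md` explains why.

The bifurcation sweep (`examples/03_bifurcation_sweep.py`) shows the
central mechanistic result: the wild type is monostable over the whole
oxygen range — the hFixL pathway primes *fnrN* expression before FnrN
activates, so every cell commits — whereas the hfixL knockout becomes
bistable below the FnrN threshold, and commitment to high expression is
left to stochastic fluctuations (`examples/04_stochastic_commitment.py`).

A thin CLI mirrors the library:

```sh
oxcascade sweep --genotype dhfixl --n-points 200 --out sweep.tsv
oxcascade knockout
oxcascade scan promoters.fasta tss.tsv
```

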