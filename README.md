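# synabm

Agent-based simulation of cancer-cell growth under two-drug exposure,
with calibration against dose–inhibition assays and Loewe-additivity
prediction of drug-combination synergy.

## The problem

Whether two anti-cancer drugs act synergistically depends on dose, and
exhaustive wet-lab screening of the dose-combination space is
expensive.  `synabm` addresses this with a 3D multiscale agent-based
model: individual cancer cells live on a 100 × 100 × 100 lattice
(5 µm spacing, about one cell radius per site), switch phenotype
stochastically — apoptosis, proliferation, migration, reversible
quiescence — and respond to two spatially uniform drug concentrations
that decay with their elimination half-lives.  The model is calibrated
on a small number of measured inhibition rates and then interrogated
*in silico* across the full dose space.  It is aimed at computational
biologists studying combination therapies at the cell-line level.

## Model core

**Microenvironment.** Each drug concentration follows half-life decay

    drug_i(t) = drug_i(t0) · (1/2)^(t/T_i)

**Phenotype switching.** Per 0.72 h time step, each cell faces an
apoptosis decision mixing a natural exponential hazard with a
drug-computed linear mortality:

    Mnrate = 1 − e^(−λt)   (t > 0; 0 otherwise, t = cell age)
    Mcrate = θ0 + θ1·d1 + θ2·d2
    apoptosis  ⇔  c1·Mnrate + c2·Mcrate > P_rand,  P_rand ~ U(0,1)

Apoptotic cells occupy their site for 10 further steps before being
absorbed.  Surviving resting cells enter the 24-step division cycle
with probability P_pro = 0.8 per decision; cells that complete M phase
divide into a free neighboring site, and cells with no free site become
reversibly quiescent.  Candidate sites are ranked by a distance kernel
times a crowding preference V_l ∈ {1/16, 1/8, 1/4, 1} and selected by
roulette wheel.

**Calibration.** Stage one fits θ by gradient descent on
J(θ) = 1/(2m) Σ (Mcrate_j − Merate_j)², where Merate is the
bootstrap-stabilized measured inhibition; the fit must agree with the
closed-form least-squares solution.  Stage two estimates (c1, c2, λ)
with a global-best particle swarm minimizing

    Σ_j ω_j (Msrate_j(Θ) − Merate_j)²,   ω_j = (1 / max Merate_j)²

where Msrate = (N_t0 − N_t1)/N_t0 is the simulated mortality at the
48 h assay endpoint, replicate-averaged under common random numbers.

**Synergy.** For a drug pair at mixing ratio a:b, the combination dose
reaching 50% simulated mortality is located by bisection and scored by
the Loewe combination index

    CI = d1/D_X,1 + d2/D_X,2

with D_X,i the single-agent iso-effective doses.  CI ≥ 1.1 is called
antagonism, [0.9, 1.1) additive, [0.3, 0.9) synergism, and < 0.3
strong synergism.

## Worked example

Generate synthetic dose–inhibition tables for three drug pairs (the
package ships a generator with known ground truth in place of
proprietary assay data) and fit the dose–mortality coefficients:

```bash
$ synabm synthesize --pairs 3 --seed 11 --out assay_tables.csv
wrote 90 rows to assay_tables.csv

$ synabm fit-local --data assay_tables.csv --bootstrap-B 500 --seed 1 --out local.csv
gefitinib+rosiglitazone: theta = (0.1677, 0.0069, 0.0019), J = 1.067e-04, p = 0.0000
erlotinib+imatinib: theta = (0.1819, 0.0075, 0.0032), J = 1.634e-04, p = 0.0000
gefitinib+quinacrine: theta = (0.0050, 0.0084, 0.0102), J = 1.797e-04, p = 0.0000
```

Each line shows the fitted intercept and per-µM slopes of the linear
dose–mortality surface, the final loss J(θ), and the overall
regression F-test p-value.  The generating truths were
(0.1686, 0.0067, 0.0019), (0.1789, 0.0076, 0.0031) and
(0.0006, 0.0085, 0.0101): all coefficients are recovered to within the
replicate noise.

Simulate a drug-exposed population (100 cells seeded centrally,
72 h horizon):

```bash
$ synabm simulate --config demo.yaml --out traj.csv
wrote 101 steps to traj.csv
```

```
 step  time_h  n_cells  n_apoptotic  drug1_uM  drug2_uM  msrate
    0     0.0      100            0 10.000000 10.000000    0.00
   20    14.4       48           18  8.122524  0.577400    0.52
   40    28.8       47           16  6.597540  0.033339    0.53
   60    43.2       64           13  5.358867  0.001925    0.36
   80    57.6       81           24  4.352753  0.000111    0.19
  100    72.0      105           20  3.535534  0.000006   -0.05
```

The population falls while drug exposure is high, then regrows as the
short-half-life drug is cleared; `msrate` is the running simulated
mortality against the initial count (negative once the population
exceeds it).  `fit-global`, `crossvalidate` and `synergy` subcommands
complete the pipeline: swarm estimation of (c1, c2, λ), held-out
relative error, and a combination-index table per mixing ratio.

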