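# Methods

## Model overview

`synabm` simulates a population of cancer cells as agents on a bounded
cubic lattice with at most one cell per site.  The default geometry is
100 sites per axis at 5 µm spacing — one site is roughly one cell
radius — and 100 cells are seeded in a compact blob around the lattice
center with initial ages drawn uniformly from [0, 24] h.  Time advances
in steps of 0.72 h; the default horizon of 100 steps covers a 72 h
experiment, and the mortality readout used for calibration is taken at
the 48 h assay endpoint (step 67).  Both horizon and endpoint are
configurable because figure-level readouts could plausibly be taken at
either time.

Two drugs are modeled as spatially uniform concentration scalars with
first-order half-life decay, recomputed from t0 in closed form each
step so no incremental floating-point drift accumulates.  The type is
shaped so a per-site concentration field could replace the scalar
later, but no diffusion term is modeled: the decay law has no spatial
argument, and treating exposure as uniform is the reading most
consistent with a well-mixed culture.

## Per-step schedule

Within a step the stages run in a fixed order, iterating cells in
seeded random order inside each stage so no sweep direction is
privileged:

1. **Apoptosis decisions.**  Each living cell draws u ~ U(0,1) and
   starts apoptosis iff `c1·Mnrate + c2·Mcrate > u`, where
   `Mnrate = 1 − exp(−λ·age)` (zero at non-positive age) and
   `Mcrate = θ0 + θ1·d1(t) + θ2·d2(t)` computed from the current
   decayed concentrations and clamped to [0, 1] (the raw linear value
   is reserved for fitting).  The decision direction follows the
   explicit inequality of the decision rule; apoptotic cells block
   their site for exactly `apoptosis_duration_steps` (default 10) more
   steps and are then absorbed.
2. **Cycle advance / proliferation decisions.**  Cycling cells advance
   one position through a 24-step cycle partitioned G0/G1 = 11, S = 8,
   G2 = 4, M = 1 (proportions of a canonical 24 h mammalian cycle; the
   split is configurable since only the phase names are constrained).
   Resting cells re-test the proliferation rule each step: ON iff
   u < P_pro (the measure-zero boundary draw is OFF).
3. **Division attempts.**  Cells completing M place a daughter
   (age and cycle reset to zero) on a selected free site; a cell with
   no free candidate keeps its division readiness and waits,
   reversibly quiescent, retrying while space is blocked.
4. **Migration.**  All other living cells migrate to a selected free
   face neighbor; fully enclosed cells become reversibly quiescent
   (their cycle position resets, since a blocked migration interrupts
   progression).

Site selection ranks each free candidate by
`R_l = (1/4)·P(r_l)·V_l` with the distance kernel
`P(r) = exp(−r²/(4πD·Δt))/(4πD·Δt)` and the crowding preference
`V_l`: 1 for 1–2 occupied face neighbors, 1/4 for 3–4, 1/8 for 5–6,
1/16 for none.  Normalized ranks feed a roulette wheel over [0, 1)
with half-open intervals (the last closed at 1).  The 1/4 prefactor
and the 4π inside the exponent are kept literally as the model defines
them; both cancel under normalization whenever all candidates share
one radius.  Because the default search set is the six face neighbors
(all at r = 5 µm), the engine uses an equal-radius fast path that
skips the kernel entirely; a distributional test pins it to the
general ranking path.  Division can optionally search a radius-2
neighborhood, where the kernel does matter.  The motility constants
D = 10 µm²/h and Δt = one step are defaults of plausible magnitude;
results at the default search radius are insensitive to them.

Population bookkeeping is audited per step: the viable count changes
exactly by births minus newly apoptotic cells, and the apoptotic count
by new minus completed apoptoses.  `n_cells` in trajectories counts
viable (non-apoptotic) cells; cells in progress of apoptosis are
reported separately and still occupy sites.

## Parameters

| Parameter | Meaning | Unit | Default |
|---|---|---|---|
| `n_per_axis` | lattice sites per axis | — | 100 |
| `spacing_um` | lattice spacing | µm | 5 |
| `n_cells` | initial population | cells | 100 |
| `age_max_h` | initial age range | h | 24 |
| `time_step_h` | step length | h | 0.72 |
| `horizon_steps` | steps per run | — | 100 |
| `λ` (`lam`) | apoptosis hazard | 1/h | fit |
| `c1, c2` | mortality mixing weights | — | fit |
| `θ0, θ1, θ2` | dose–mortality coefficients | —, 1/µM | fit |
| `P_pro` | proliferation probability | — | 0.8 |
| `cell_cycle_steps` | division cycle length | steps | 24 |
| `apoptosis_duration_steps` | decision → absorption | steps | 10 |
| `motility_D` | kernel diffusivity | µm²/h | 10 |

λ is stored per hour and multiplies the cell's **age** in hours, not
global simulation time: the hazard describes a per-cell mortality
frequency, and age is the per-cell clock.  Note the consequence: with
λ of order 1/h, `Mnrate` saturates near 1 within a few hours of age,
so `c1` effectively becomes a per-step baseline death probability.
Reference estimates put `c1` between about 0.008 and 0.24 and λ at 1;
in the upper part of that range the population is extinguished well
before 48 h at any dose and the endpoint mortality surface saturates
near 1.  A per-step reading of λ would not change this materially
(1 per step = 1.39 per hour).

## Two-stage calibration

Triplicate inhibition fractions are stabilized row-wise by a bootstrap
mean (B = 1000 resamples by default — standard practice, configurable).
CSV input whose values exceed 1.5 is auto-detected as percentages and
normalized to fractions.

**Stage one** fits θ by gradient descent on
`J(θ) = 1/(2m)·Σ(Mcrate_j − Merate_j)²` against the *nominal* assay
doses (decay acts only inside the simulator; the measured endpoint is
referenced to what was pipetted).  The raw dose design (doses up to
100 µM against a unit intercept) is badly conditioned for plain
gradient descent, so the dose columns are standardized internally and
the coefficients mapped back to the µM scale; the converged fit is
required — and tested on randomly generated tables — to agree with the
closed-form least-squares solution to 1e-7.  A rank-deficient design
(e.g. all-zero doses) raises a collinearity error rather than
returning meaningless slopes.  The reported p-value is the overall
regression F-test, the conventional p-value attached to a
least-squares fit.

**Stage two** estimates (c1, c2, λ) with a global-best particle swarm
(inertia w = 0.72, cognitive = social = 1.49, velocities clamped to
20% of each bound's range, positions clipped; default box c1, c2 ∈
[0, 1], λ ∈ [0, 2]/h, comfortably containing the reference
estimates).  The objective weights each pair by `(1/max Merate)²`,
taking the max over that pair's rows — the one reading of the weight
that changes relative pair weighting.  Each objective evaluation runs
the simulator at the row's doses and averages the endpoint mortality
over a fixed set of replicate seeds (common random numbers), making
the stochastic response quasi-deterministic so the swarm can make
progress.  Simulated mortality is floored at zero before comparison:
Msrate is negative under net growth, while measured inhibition is
floored at zero, and without the floor net-growth rows contribute
large spurious residuals.

**Validation.**  The cross-validation protocol trains on one third of
each pair's rows (every third row, spanning the dose range) and
evaluates the relative error `RE = (Msrate − Merate)/Merate` on the
held-out two thirds; a true leave-one-out option exists for cheap
predictors.  Held-out rows with `Merate = 0` are excluded with a
warning — the relative error is undefined there, and near-zero
denominators make RE arbitrarily large, which is the metric's
intrinsic weakness at low-effect rows.  A paired two-sided Wilcoxon
signed-rank test (t-test optional) compares simulated and experimental
series; p > 0.1 is read as no significant difference.

## Synergy

Single-agent iso-effective doses D_50 are found by bisection on the
effect curve after a bracketing check; stochastic (replicate-averaged)
curves are first smoothed by isotonic regression over a 12-point dose
grid and inverted on the smoothed interpolant, which guards the search
against Monte-Carlo non-monotonicity.  Along a mixing ratio a:b the
total dose reaching 50% effect is located the same way (effect
tolerance 0.01).  The combination index partitions as: antagonism at
CI ≥ 1.1, additive in [0.9, 1.1), synergism in [0.3, 0.9), strong
synergism below 0.3.  The published interval bounds leave exactly 0.9
unassigned; it is placed with the additive band so the partition is
gapless.  Ratios on which 50% is unreachable within the 0–100 µM
working range are flagged rather than dropped.

## Synthetic assay data

The generator stands in for triplicate 30-combination inhibition
tables of three drug pairs.  Its grid — four mixing ratios (4:1, 3:2,
2:3, 1:4) at six total doses {5, 10, 20, 40, 60, 80} µM plus three
single-agent anchors per drug ({10, 40, 80} µM) — reproduces the
documented row count and the 0–100 µM working range but is otherwise a
stand-in, not a claim about the original assays.  Replicates add
Gaussian noise (sd 0.03, a realistic plate-reader CV at mid-range
inhibition) truncated to [0, 1].  Two surfaces are available: a linear
dose–mortality surface (for fitting-stage recovery with analytic
standard errors) and a simulator-consistent surface whose row means
are the engine's own replicate-averaged endpoint mortality at known
(c1, c2, λ) — closing the loop for global-stage recovery.  Default
ground-truth mixtures use c1 = 0.1, c2 = 0.3, λ = 1/h, central in the
reference ranges.

What the generator does *not* emulate: plate-reader absorbance
mechanics beyond the inhibition ratio, heteroscedastic or correlated
replicate noise, batch effects, and any deviation of the true
dose–response from the model family itself.  Passing recovery tests
therefore demonstrates internal consistency of the pipeline, not
fidelity to any particular wet-lab dataset.

## Problem sizes and numerical choices

Recovery and validation tests run at the reference population size
(100 initial cells) with a 67-step endpoint horizon.  Monte-Carlo
replicate budgets are chosen so simulator noise is small relative to
the injected assay noise: 20 replicate seeds for data generation and
held-out prediction, 3 (common-random-number) replicates inside the
swarm objective, swarm size 8 × 10 iterations for the in-suite fit.
One endpoint simulation costs tens of milliseconds in death-dominated
regimes and up to ~150 ms under net growth.

Other numerical conventions: seeded `numpy` PCG64 generators
everywhere (identical seeds give bit-identical trajectories); the
proliferation boundary draw u = P_pro is OFF; wheel intervals are
half-open with the final interval closed; `endpoint_msrate` maps the
endpoint to the nearest whole step; gradient descent stops on a
1e-12 gradient norm with a convergence warning otherwise; the
extinction of the population cleanly pads the remaining trajectory
with N = 0.

## Known limitations

- No nutrient or oxygen fields, no drug diffusion, no vasculature, no
  intracellular signaling, toxicity or mutation — the model is a
  phenotype-switching caricature aimed at dose–response calibration.
- The linear Mcrate surface cannot represent sigmoidal dose–response;
  it is clamped to [0, 1] inside the simulator and will mis-specify
  strongly non-linear assays.
- Relative error is uninformative on rows whose measured inhibition is
  near zero (net-growth regimes); absolute-scale checks are preferable
  there.
- With hazard-saturating parameter ranges (λ ~ 1/h and c1 ≳ 0.05) the
  endpoint mortality surface flattens near 1 and carries little
  information about (c1, c2, λ) individually; predictive recovery
  remains well-posed but parameter identification does not.
- Two drugs at most; one concentration scalar per drug.
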