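# Methods

## The model family

The deterministic core is a family of ODE models for one prey species
under simultaneous attack by *Bdellovibrio bacteriovorus* and a lytic
phage, in a closed, well-mixed 48-h batch culture.  The family is
spanned by six discrete axes (`ModelVariant`):

* **prey phenotypes** `N1`–`N4`: sensitive only; + phage-resistant
  (`N_R`); + plastic *Bdellovibrio*-resistant (`N_P`); + doubly
  resistant (`N_D`);
* **plastic-resistance conversion** `I`/`IG`/`S`/`SG`: forward
  conversion `N_S -> N_P` intrinsic (first order, `r_I`) or triggered by
  a signal (`k_sig * C`); back conversion intrinsic (`r_back`) or
  growth-coupled (every `N_P` division yields `N_S` offspring, so `N_P`
  never accumulates through growth and reverts whenever it grows —
  plastic resistance is not inherited);
* **signal source**: the signal `C` accumulates in proportion to the
  prey-entry (attack) flux of *Bdellovibrio*, the phage, or both, with
  yield `sigma_C` per predation event and no decay;
* **phage-resistance origin**: a preexisting fraction `f_R` of the
  inoculum (the fluctuation-test picture), de novo mutation of a
  fraction `m` of `N_S` divisions (growth-coupled, not a constant-rate
  conversion), or both.  Under `N4`, the same `m` diverts `N_P`
  divisions into `N_D`;
* **attack saturation**: mass action (`Pi`/`Vi`) or Holling type II in
  total susceptible prey (`Pii`/`Vii`), apportioned over susceptible
  phenotypes by abundance.  *Bdellovibrio* attacks `N_S` and `N_R`; the
  phage attacks `N_S` and `N_P`;
* **mortality mode**: free-*Bdellovibrio* mortality `d_P` pinned to a
  literature value (0.06/h) or fitted.  Prey and phage carry no
  mortality term over the 48-h horizon.

Shared processes: Monod growth on a resource `M` denominated in
prey-cell equivalents with unit yield; attack converts one predator and
one prey into one intracellular structure (bdelloplast `B`, infected
cell `I`); first-order resolution (`k_B`, `k_I`) releases `beta_P`
(resp. `beta_V`) progeny and `eps_B` (resp. `eps_I`) cell-equivalents of
nutrients back into `M`.  Maturation and lysis are collapsed into that
single first-order step because no observable in the assay separates
two sequential intracellular stages.  `eps_* < 1` is enforced: lysis
debris cannot rebuild a whole prey cell.

Plaque counts cannot distinguish a free predator from an infected cell
(both found one plaque), so observables are prey CFU = `ΣN`,
*Bdellovibrio* PFU = `P + B`, phage PFU = `V + I`.

Variants are nested: `N4 -> N3` when nothing feeds `N_D` (`m = 0`),
`N3 -> N2` when conversion rates vanish, `N2 -> N1` when
`f_R = m = 0`.  The test suite asserts these collapses at integrator
tolerance.

## Numerics

States are integrated in linear space (hours, per-ml densities) with an
adaptive Dormand–Prince 5(4) stepper (numba-compiled), clamped at zero
after each accepted step; densities below 1e-12/ml are reported as 0.
An explicit adaptive method was chosen over a stiff solver because the
selected dynamics are only mildly stiff and the SMC machinery needs
~1e5 integrations per competition; correctness is cross-checked in the
tests against scipy's LSODA and against an independently coded
fixed-step RK4 oracle (1e-6 relative agreement on all compartments
above 1e-6/ml, gated on oracle self-consistency near eradication
separatrices, where no deterministic comparison is meaningful).

The user-facing `simulate` uses rtol 1e-8 / atol 1e-6 and a 2e6-step
budget.  The batched ABC path (`simulate_conditions`) stacks all
culture conditions into one system and integrates at rtol 1e-5 /
atol 1e-2 with an 8000-step budget: the fit distance lives on a log10
scale where 1e-5 relative error is invisible, and parameter draws whose
kinetics outrun the budget (attack rates orders of magnitude above the
plausible region) fail fast and receive an infinite distance rather
than a silently truncated trajectory.

## Synthetic data

The generator emulates the predation-kinetics assay: four culture
conditions (prey only, each single predator, both), initial densities
2.9e8 CFU/ml prey, 2.8e6 PFU/ml *Bdellovibrio*, 3.7e6 PFU/ml phage,
sampling every 2 h for 48 h, three replicates, detection limit
10 CFU/ml.  Replicate noise is multiplicative lognormal with 0.15 log10
units standard deviation — plated dilution counts at these densities
are dominated by dilution/pipetting error, not Poisson counting error
(a Poisson stage for counts below 100/ml exists but is off by default).
The 0.15 figure is a package default, not a measured quantity; the
mean-recovery test shows what it implies.  Censored counts are stored
as flags, never zeros, and enter the fit at the detection limit.

What the generator does **not** emulate: plating dilution series,
biological-repeat batch effects, timing jitter between samples, OD600,
or model misspecification of any kind.  Passing selection and recovery
tests on these data therefore demonstrates that the pipeline is
self-consistent (it recovers what generated the data), not that the
model is a correct description of any particular real culture.

## The typical parameter set

The shipped `ParameterSet` defaults play the role of the fitted
"typical" parameters.  They were calibrated once, by hand plus a small
grid refinement, against the study's printed anchors — initial
densities; phage-only prey minimum ~2e3 CFU/ml at 6 h followed by
regrowth to the starting density; *Bdellovibrio*-only minimum ~2e4
CFU/ml with a plastic-resistant plateau; dual-culture eradication
(<10 CFU/ml) by 14 h with ~1e10 phage and ~1e6 *Bdellovibrio* PFU/ml
yields; preexisting resistant fraction `f_R` = 2.6e-6; and prey escape
from dual predation exactly when the prey inoculum is 10-fold higher,
the *Bdellovibrio* inoculum 10-fold lower, or the phage inoculum
10-fold higher — and then frozen.  Key values: `mu_max` 0.4/h, `K_M`
5e7/ml, `a_P` 0.5/h with `K_P` 8e6/ml, `a_V` 2e-10 ml/h, `k_B` 0.42/h,
`beta_P` 4, `k_I` 1.0/h, `beta_V` 100, `eps_B` 0.2, `eps_I` 0.4,
`d_P` 0.06/h, `m` 5e-8, `f_R` 2.6e-6, `M0` 4e8 cell-equivalents/ml.

## Inference

ABC-SMC in the joint (model, parameter) space.  Priors are log-uniform
over four decades for rate constants (uniform for the `eps` yields),
with the measured inocula pinned; `sigma_C` is pinned because only the
product `sigma_C * k_sig` is identifiable.  Parameters no candidate
variant uses are pinned rather than fitted, keeping the particle
dimension minimal for each competition.

The distance is the sum over condition x population x time of squared
log10 differences, with observed replicates averaged on the log10 scale
(censored replicates at the detection limit) and both sides floored at
the detection limit, so sub-detection disagreement carries no weight.
Replicates are aggregated before the distance so its scale does not
depend on replicate count.

Generation 0 is rejection sampling at the alpha-quantile of a pilot
sample's distances; later generations resample a particle from the
previous generation by weight (the model proposal therefore follows the
previous generation's weighted model marginal — proposals concentrate
on models that retain posterior mass), perturb parameters with an
adaptive multivariate Gaussian kernel whose covariance is twice the
weighted empirical covariance of the previous generation (log10 space
for log-uniform parameters; out-of-support proposals are redrawn), and
reweight with the standard importance ratio.  A generation that
exhausts its proposal budget (50 x particles) before filling is kept at
its reduced size; a generation with zero acceptances is an error, never
silently skipped.

Defaults: tolerance quantile alpha 0.3 for fits — chosen so that an
8-generation budget reaches tolerances informative about individual
parameters — and 0.5 for model competitions, which only need coarse
discrimination between variant families and run several-fold faster at
the milder schedule.  A competition "win" is the plurality model of the
final generation; repeated competitions use seeds derived from the base
seed.

The "typical" parameter set of a fit is the PCA medoid of the final
generation: log-parameters standardised, projected by PCA, and the real
accepted particle closest to the weighted centroid returned — always
simulable, unlike a synthetic average.

## Problem sizes

Analysis defaults: fits at 150 particles x 6 generations, the stage
ladder at 100 x 4 x 3 runs.  The test suite uses 200 x 8 for parameter
recovery, 200 x 5 x 10 runs for the reduced prey-phenotype competition,
and smaller toys elsewhere.  `scripts/acceptance.py` runs 150 x 6
(three-phenotype fit), 100 x 5 (four-phenotype fit) and 150 x 4 x 5
(competition).  These sizes make a full run a matter of minutes on one
CPU while leaving the qualitative conclusions stable across seeds.

## Known limitations

* Equations are built from the process descriptions; exact printed term
  forms of the source figures were not machine-readable, so details
  (Monod growth, Holling-II apportionment, signal without decay) are
  this package's canonical choices, documented above.
* The signal `C` neither decays nor is consumed by conversion; over
  48 h this is indistinguishable from slow decay, but extrapolation
  beyond the assay horizon would need a decay term.
* No spatial structure, no stochastic (CTMC) dynamics: densities are
  continuous, so "eradication" means crossing the detection limit, not
  extinction of the last cell.  Sub-cell densities (e.g. the doubly
  resistant prediction of ~0.1 cells/ml) are expectations, not counts.
* ABC posteriors at the shipped problem sizes are exploratory; ridge
  correlations (e.g. `a_P` with `K_P` and `k_B`) remain wide and only
  shrink with more generations.
* Predicting the dual-predation outcome from single-predator fits sits
  on a knife edge (the *Bdellovibrio* kill rate on `N_R` vs. its growth
  rate), so it needs a reasonably converged posterior: at 200 particles
  and 8 generations roughly one seed in three still places the typical
  particle on the non-eradicating side of that margin.  Likewise the
  terminal doubly-resistant density under `N4` amplifies posterior
  spread exponentially and is only bounded by data that were fitted
  with the `N4` equations themselves.
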