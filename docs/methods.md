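# Methods

## Scope

`perfusiontwin` implements a hybrid model-plus-agent stack for upstream
bioprocess development: (i) a step-wise Gaussian-process (SW-GP) model of
daily-sampled perfusion/fed-batch cultivations, (ii) ensemble-based
prediction intervals and rRMSE evaluation, (iii) online retraining with
cross-clone transfer, (iv) a daily setpoint optimizer, and (v) a closed-loop
agent.  Because real parallel-bioreactor campaigns of this kind are
proprietary, the package also contains a mechanistic synthetic plant that
generates the training campaign, the in-silico fed-batch clones, and serves
as the closed-loop hardware stand-in.  Everything the tests and the
acceptance script assert is computed on that synthetic plant.

## The SW-GP hybrid model

State variables are treated on a daily grid (sampling interval 1 d; slower
than every relevant process dynamic except within-day washout, which the
flow terms carry).  For each day interval, the discrete production rate of
every species is recovered from the discretized mass balance

    R(s(t_i)) = [c(t_{i+1}) − c(t_i)]/Δt − (u_f − u_b − u_p − c·dV/dt)/V

with feed (u_f), bleed (u_b) and permeate (u_p) interval totals in
mass/day.  Membrane-retained species (viable and dead cells) have no
permeate term; viability and mean diameter are carried as plain daily
increments without flow terms.  A GP with anisotropic squared-exponential
kernel plus additive noise learns R per output from the state vector
(modeled variables + the four setpoints + a one-hot clone encoding; volume
is excluded because it is constant in perfusion).  Kernel hyperparameters
are set by marginal-likelihood maximization (L-BFGS capped at 35 iterations,
optionally multi-start, on a seeded subsample of at most 192 points).

Ensembling: the training set is split into 20 subsets — at run level when at
least 20 runs are available, else at sample level — and submodel *i* is
trained on all but subset *i*.  By default the fitted kernel hyperparameters
are shared across submodels (fitted once per output), so submodels differ
only in their training subsets; this keeps daily retraining and 24-fold
leave-one-out studies tractable (hundreds of ensemble fits) while retaining
the subset-resampling variability the ensemble exists to express.  Fully
independent per-submodel hyperparameter fits are available via
`share_hyperparameters=False`.

Two numerical choices matter and were made deliberately:

* **Length-scale floor.**  Designed factors take only three levels in the
  training campaign; unconstrained marginal-likelihood fits collapse their
  length-scales and make the GP revert to the prior mean *between* the
  design levels — fatal for an optimizer that must evaluate interpolated
  setpoints.  Standardized length-scales are therefore bounded below by 1.0
  (a smoothness prior matched to a 3-level design).  Clone indicator
  columns are exempt (floor 0.3) so genuine clone differences can still be
  expressed.
* **Clone encoding scale.**  One-hot clone columns are *not* standardized:
  z-scoring a rare indicator (a new clone with few samples) places it
  several standard deviations away from all other data and severs
  cross-clone transfer.  Raw 0/1 coding keeps a new clone within one kernel
  length-scale of the known clone, so its predictions start from the known
  clone's behavior and differentiate as data accumulates.  A clone column
  that is constant in the training data (clone absent) is dropped from the
  kernel's active dimensions with a warning — the new clone is then treated
  exactly like the known one, which is the desired cold-start behavior.

## Forecasting

Each submodel is rolled forward independently, one day per step, predicting
R from the current (possibly predicted) state; concentrations are clipped at
zero and viability at 100 after every step.  Percentiles (10/50/90, linear
interpolation on sorted values) across the 20 trajectories give the median
forecast and the 80 % interval.

For interval construction the rollout draws each submodel's rates from its
GP predictive distribution (seeded, hence deterministic) rather than using
the posterior mean: with shared hyperparameters the submodels' mean
predictions are nearly identical, so the bare trajectory spread would
collapse far below the real predictive error.  The sampling standard
deviation is floored at the ensemble's *out-of-subset residual scale* —
each submodel scored on its own held-out subset at fit time — an
empirical-Bayes correction for the tendency of marginal likelihood to
underestimate noise in smooth high-dimensional fits.  With this convention
the 10–90 band covers held-out observations at roughly its nominal level
(tested ≥60 % of (day, variable) cells at the default noise).  Median-based
consumers (the optimizer and rRMSE evaluation) use the cheaper mean-rate
rollout; the two medians coincide up to sampling jitter.

Flow handling differs by mode:

* **Hindsight evaluation** (LOO validation, retraining comparison) uses the
  recorded flow totals of the evaluated run, so the step is the exact
  inverse of rate extraction (round-trip identity, tested to 1e-10).
* **Planning** (optimizer, notifications) derives flows from the protocol:
  media exchange at the planned VVD, the glucose-bolus rule applied to the
  predicted glucose, and a bleed cap on predicted VCV.  The media exchange
  uses the exact one-day integrator of the linear exchange dynamics,
  `c⁺ = c + R(1−e^(−D))/D + (media − c)(1−e^(−D))`, rather than the Euler
  term `D(media − c)`: rates extracted from *integrated* flow records equal
  mean biological production rates, and with that convention the
  exponential step is exact when R is predicted correctly, while the Euler
  step grossly over-washes elevated states (it made the optimizer respond
  in the wrong direction to an ammonium spike during development).

## Evaluation

rRMSE per variable follows the horizon-truncated definition in the README;
σ_x is pooled over all observations of the variable in the evaluation
campaign (pooling across runs makes errors comparable between runs).  The
prediction-pair count n_p uses the closed form h·t_f − h(h−1)/2 for h ≤ t_f
and the brute-force enumeration t_f(t_f+1)/2 in the degenerate corner
h > t_f (the two agree wherever both are defined; tested exhaustively to
t_f = 60).  The retraining comparison trains the "without" model on the
known clone only and, for each day t, a "with" model on the known clone
plus all new-clone data through day t; per-day errors average the 3-day-
ahead predictions of all evaluation runs and are reported only for origins
with a full horizon (t ≤ t_f − h).

## Optimizer and agent

The daily objective is the 3-step tracking loss OFV = Σ(ŷ_{t+j} − y_tar)²
on the ensemble-median forecast, with candidate setpoints held constant over
the horizon (the loop re-optimizes daily, so only the first day is ever
applied).  Because the surrogate is cheap, the search is a seeded
Latin-hypercube sweep over the active controls (incumbent always included)
plus two successively shrunk local refinements; near-ties (within 5 % of
the optimum) resolve toward the smallest setpoint change, which damps
day-to-day actuation jitter without constraining genuine moves.  The
returned vector is clipped to bounds; stir is capped at 1050 rpm in control
mode because higher agitation is deleterious to viability.  Exploration
terms are deliberately absent from the objective (pure target tracking).

The agent's daily cycle per reactor is: sample (noisy) → apply scheduled
disturbances → retrain the shared ensemble on base + all live data →
optimize each reactor's objective → write setpoints → advance the plant one
day.  Setpoints decided on day t apply to the interval [t, t+1).  Before
the control start day (default 9) the reference protocol runs (perfusion
ramp 0 → 1.3 d⁻¹ until the state-of-control VCV target, then reference
setpoints).  Retraining reuses the previous ensemble's kernel
hyperparameters unless the active feature set changed (e.g. a new clone's
first data), in which case they are re-optimized.  An optimizer failure
holds the previous setpoints and logs an alarm (fail-safe); every action is
recorded in an append-only log.

## The synthetic plant

Monod-type CHO kinetics with: growth on glucose and glutamine, ammonium and
lactate growth inhibition, a Gaussian temperature optimum at 36.5 °C;
death from a temperature-sensitive base rate, an ammonium term (quadratic),
shear above 1050 rpm, and glutamine starvation; fast clearance of dead
cells (lysis) so viability reflects the death/clearance balance; glutamine
maintenance demand dominating at steady state (CSPR-limited perfusion);
spontaneous glutamine degradation feeding ammonium and glutamate; ammonium
release proportional to glutamine consumption, attenuated by pyruvate feed
(1/(1+α·Pyr) — pyruvate feeds the TCA cycle and spares amino-acid
catabolism); growth-associated lactate production; temperature-boosted
specific productivity under mild hypothermia; and a cell diameter relaxing
toward a target that grows with specific growth rate, perfusion rate and
mild hypothermia.  Within a day the ODEs are integrated with fixed-step
RK4 (substep 0.01 d); cumulative feed/permeate mass integrals ride in the
same RK4 vector, so recorded interval flows match the trajectory to
machine precision, and discrete events (boluses, bleeds, disturbances,
fed-batch feeds) are booked algebraically.  The glucose bolus tops the
broth up to exactly 5.00 g/L (volume restored through the cell-retaining
membrane); the bleed removes whole broth (media-replaced) to pin VCV at
its ceiling (38 %, a safety cap above every operating target).

No published kinetic parameter values exist for the emulated system; all
values here are the package's own calibration, fixed once against these
anchors and then frozen: steady VCV < 20 % at reference setpoints
(VVD 1.25, 35.25 °C, 1050 rpm, no pyruvate) with ammonium drifting to
≈4 mM by day 9; ≥30 % VCV attainable within the design space (high VVD,
mild hypothermia); viability responding positively to mild hypothermia and
negatively to >1050 rpm agitation and to ammonium; a clone "B" that is
more death-prone and ammonium-sensitive than the training clone "A"; and
ammonium steerable to 1 mM within the 0–2 g/(L·d) pyruvate range.  The
in-silico fed-batch clones X and Y differ *only* in a lactate-consumption
flag; consumed lactate feeds the TCA cycle and attenuates ammonium release
(same mechanism as pyruvate), which is what makes clone Y's late-run
ammonium diverge once glucose is depleted — the regime in which online
retraining visibly beats the static cross-clone model.

Measurement noise emulates at-line analysis: multiplicative Gaussian CVs
(5 % cell counts, 2 % diameter, 3 % metabolites/titer), truncated at zero;
observed viability is recomputed from the noisy viable/dead counts so the
identity Via = 100·VCD/(VCD+DCD) holds in every stored record (an absolute
0.5 pp viability perturbation is applied instead when no dead-cell channel
exists).  Inoculum density varies 5 % between runs.  Setpoints, volumes and
flow totals are recorded exactly.

The training campaign is a seeded 24-run design over VVD 0.5–2 d⁻¹,
temperature 34–36.5 °C, stir 700–1400 rpm, pyruvate 0–2 g/(L·d): 16
two-level corners, 4 center replicates, and 4 seeded axial picks, each run
following the reference ramp until state of control and then its design
setpoints for a 20-day horizon.  The growth phase ends at the VCV trigger
(14 %) or day 7, whichever comes first — the cutover also covers slow-growing
clones that never reach the trigger.

## What the synthetic plant does and does not show

Passing tests demonstrate that the modeling/control machinery works under
realistic dynamics, noise levels and design-space coverage — rate recovery,
interval calibration, transfer to an unseen clone, disturbance rejection.
They do not certify performance on real cultures: the plant has smooth
Monod kinetics with no unmodeled covariates (pH, osmolality, CO₂), no
sensor drift or missing samples, exact flow records, and clone differences
expressed only through the implemented mechanisms.  Quantities like the
rRMSE levels reached here should be read as "achievable under these
conditions", not as predictions for any particular cell line.

## Problem sizes and defaults

Campaign: 24 runs × 20 day-intervals (~480 rate samples); ensemble: 20
submodels, shared hyperparameters fitted on ≤192-point subsamples, one
L-BFGS start by default in study-scale scripts; closed loop: 27 days with
control and daily retraining from day 9; use-case metrics take the median
over three seeds; fed-batch retraining study: 14-day runs, 10–24 runs per
clone.  These sizes keep a full study (campaign + 24-fold LOO + three
use cases + benchmarks) around a quarter of an hour on a single CPU while
leaving every qualitative conclusion unchanged at larger settings.

## Known limitations

* Independent single-output GPs per species; no cross-output covariance.
* The optimizer scores candidates on the ensemble median only; forecast
  spread is reported (notifications) but not exploited for exploration.
* Subset assignment is random per training call (seeded), not stratified
  by design region.
* The exponential-exchange planning step assumes within-day-constant VVD
  and media composition (true for the implemented protocol).
* Fed-batch mode models neither viability/diameter dynamics nor perfusion
  flows; it exists for the cross-clone retraining study.
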