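# Methods

`copsim` is a simulation laboratory for one question: when does a
test-negative design (TND) with a continuous immune measurement recover
the true relationship between a scalar correlate of protection (COP) and
the incidence rate ratio (IRR) of infection?  Everything in the package
serves that question: an individual-based epidemic model generates ground
truth, a TND sampler mimics how such studies collect data, four
regression estimators model the sampled data, and an evaluation layer
scores the fitted curves against the truth.

## Transmission model

A closed population of N = 50,000 agents moves through susceptible (S),
latently exposed (E), and asymptomatically (A) or symptomatically (I)
infectious states in daily time steps over 600 days.  Each agent carries
a scalar COP level X(t) in [0, 1] and a fixed baseline risk multiplier
R in {1, 2}.

Per day, in order:

1. **Infection.** Each susceptible is infected with probability
   `min(1, gamma * (1 - psi(X)) * (I + A) * R)`, where
   `gamma = R0 / (N * t_infectious)` with R0 = 2 and t_infectious = 7
   days.  This is a discrete-time hazard with *leaky* protection: the
   fraction psi(X) of the hazard is removed at every exposure rather
   than fully protecting a fraction of agents.  Symptomatic fate is
   drawn once at infection (probability alpha = 1/3), independent of
   COP, time, and risk group.
2. **Progression.** After exactly t_latent = 5 days, an exposed agent
   becomes infectious, symptomatic or not per its fate.  Stage durations
   are fixed point values, not distributions.
3. **Recovery and boosting.** After exactly 7 infectious days the agent
   returns to S with a boosted COP: 0.75 if this was its first-ever
   exposure, 1.00 otherwise.  There is no removed class — returning
   boosted susceptibles are what generates repeat waves and the
   depletion-of-susceptibles dynamics the study is about.
4. **Waning.** Susceptibles lose w = 0.01 COP units per day (floored at
   0).  Exposed and infectious agents hold their COP frozen until the
   recovery boost — including when they are vaccinated while latent or
   asymptomatic (the dose then only stamps the revaccination clock).
   This freeze is what makes a case's COP at sampling equal its
   exposure-proximal value.
5. **Vaccination.** Every 15 days (days 1, 16, ..., 586; 40 rounds) a
   uniform random 0.5% of eligible agents — not symptomatically
   infectious, and at least 56 days since their last dose — receive a
   dose, which applies the same first/subsequent boost rule to
   susceptibles.  Over 40 rounds this leaves roughly
   1 - 0.995^40 ≈ 18% of the population ever-dosed; the figure is below
   the nominal 0.5% x 40 = 20% because some doses revaccinate
   already-dosed agents.

Initial conditions: 48,950 naive susceptibles at X = 0; 1,000
prior-exposure susceptibles at X = 0.75 (the post-first-exposure level;
their starting point is a modeling choice, as only their count is
specified); 25 exposed; 25 infectious split I ~ Binomial(25, 1/3) with
A the complement so compartments sum to N.  Risk group is i.i.d.
Bernoulli(p_high_risk), independent of COP: scenario 1 sets
p_high_risk = 0, scenario 2 sets 0.2.  In scenario 2 high-risk agents
are infected more often, accumulate immunity faster, and risk group
becomes positively correlated with COP over time — a time-dependent
confounder of the COP–IRR relationship.

The population is stored as a struct of numpy arrays, which keeps one
600-day run near a second; the update order above (infect, progress,
recover, wane, vaccinate) is fixed, and all randomness flows from a
single seeded generator per replicate.

## Protection functions and ground truth

psi(X) is X (primary), X^2 or X^3 (sensitivity analyses); all satisfy
psi(0) = 0, psi(1) = 1, monotone on [0, 1].  Because the hazard scales
with (1 - psi(X)) * R, the true IRR relative to an unprotected low-risk
agent is exactly `(1 - psi(X)) * R` — the curve every estimator is
scored against, and for linear protection simply 1 - X.

## TND sampling

On a sampling day, **cases** are the agents currently symptomatically
infectious.  Their measured COP is the snapshot value, which — thanks to
the freeze rule — equals their COP immediately before infection.
**Controls** are drawn uniformly at random, four per case without
replacement within a match set, from the day's susceptible pool
(previously exposed or not).  Latently infected agents are excluded from
the control pool: they carry the pathogen, so they would not test
negative, and admitting their case-like frozen COPs into the controls
measurably attenuates every estimator (about -0.03 on the transformed
logit's slope in endemic conditions).  Control selection reads only
epidemiological state, never COP or risk group, and match sets are
matched on sampling day only.

Multi-day windows (days 50–140 and 500–590, every 10 days) pool per-day
match sets — incidence-density sampling, with each control at risk on
its case's day.  The 10-day spacing exceeds the 7-day infectious period,
so no agent is a case twice within a window.  When the pooled cases
exceed the target (300/1250/5000 aggregated; 125/500 single-day), whole
match sets are uniformly subsampled; a shortfall returns everything with
a metadata flag.  Testing is perfect: every symptomatic infectious agent
tests positive, every sampled control negative.

Using *prevalent* symptomatic agents as cases (rather than same-day
symptom onsets) is what makes the stated sample sizes attainable — the
endemic phase produces ~140 onsets but ~1,000 prevalent symptomatic
agents per day — and is consistent with how a real TND enrolls anyone
currently symptomatic.  The COP freeze during the latent and infectious
stages makes the two definitions measure the same exposure-proximal
quantity.

## Estimators

All four estimators are binomial-likelihood regressions of case status,
fitted to the pooled rows (the matched-set structure is ignored at fit
time, mirroring a pooled unconditional analysis):

* transformed logit: `logit(p) = b0 + b1 ln(1 - X)`
* untransformed logit: `logit(p) = b0 + b1 X`
* transformed GAM: `logit(p) = b0 + f(ln(1 - X))`
* untransformed GAM: `logit(p) = b0 + f(X)`

each optionally with a high-risk main effect `b2 I(R = 2)` (never an
interaction).  Under TND sampling OR(X, 0) estimates IRR(X, 0) =
(1 - X), i.e. log odds differ by ln(1 - X); hence the log transform, and
b1 = 1 recovers the truth exactly.  The sensitivity transforms
ln(1 - X^2) and ln(1 - X^3) are correctly specified when protection is
squared or cubic.  The transform floor epsilon = 1e-6 keeps ln(1 - X)
finite for the few agents boosted to exactly X = 1 on a sampling day.

The GAM smooth is a cubic B-spline basis of dimension 5 with a
statsmodels second-order penalty; the penalty weight is selected by
minimizing `deviance + 2 * edf` (the UBRE/AIC criterion appropriate for
a binomial model with known scale) over a fixed 13-point log-spaced
grid, which is deterministic and fast.  Two design details matter in
practice:

* **Basis anchoring.** Knot bounds are the union of the observed
  covariate range and the transformed evaluation range (COP 0 to 0.99),
  so predictions are finite on the whole grid; rows beyond the anchored
  range (X above 0.99 under a log transform) are clamped to the basis
  boundary rather than stretching the knots over a data-free tail.
* **Nesting.** The penalty null space contains straight lines in the
  transformed covariate, so as the penalty grows the GAM collapses onto
  the corresponding logistic model — the conformance property checked in
  the test suite, alongside a cross-check against R mgcv's penalized
  binomial smooth on identical data.

Estimators are scikit-learn style (`fit(X, y)`, `get_params`, fitted
attributes `coef_`, `alpha_`, ...), with `ModelSpec`/`fit`/`predict_irr`
as thin functional wrappers.

## Evaluation

Within one replicate, the fitted model's IRR curve is compared with the
truth as a mean absolute difference over the COP grid 0.00–0.99 in steps
of 0.01; these per-replicate MAEs are then averaged across replicates.
X = 1.00 is excluded from the grid because the transformed predictor is
degenerate there, while the true IRR still approaches 0 on the grid.

With heterogeneous risk the curve is scored per group: the model's
*within-group* protection shape `exp(eta(x, g) - eta(0, g))` is scaled
by the group's known multiplier R and compared against `R (1 - psi(x))`.
Normalizing within group isolates how well the COP–IRR relationship is
recovered in each group; letting the estimated risk coefficient enter
the high-risk curve instead would add exp(b2) sampling noise (sd ≈ 0.6
at 125 cases) that swamps the shape comparison the study is about.
For the low-risk group, and in scenario 1, the two definitions coincide.

Replicate r of a condition uses seed `base_seed + r` for the epidemic
and an independent stream (derived from the seed, the replicate, and a
stable hash of the condition) for sampling, so results are
bit-reproducible and independent of which conditions are batched
together; conditions sharing a scenario and protection form reuse the
same epidemics.  Replicates whose fit fails are excluded from the
average and counted (none occur under the default design).

## Problem sizes and defaults

The package defaults to 200 replicates per condition in the experiment
driver (`--reps` reaches any replication level); the bundled benchmark
suite and `scripts/acceptance.py` use 100 replicates per condition,
which puts the Monte-Carlo standard error of the small late-phase cells
near 5% of their value while keeping a full run in minutes on one core.
Reference values quoted in the tests come from the 1000-replicate
versions of the same cells.

## What the generator does and does not emulate

The simulator produces the features that matter for TND validity —
leaky protection, waning and boosting immunity, depletion of
susceptibles, epidemic waves, selection on symptomatic testing, and
(scenario 2) measured confounding by baseline risk.  It deliberately
omits: imperfect test sensitivity/specificity, care-seeking
heterogeneity, age or contact structure, births/deaths, nonlinear
waning, COP measurement error, and any gap between vaccine- and
infection-induced immunity.  Passing tests therefore show that the
estimators recover the truth *under these idealized mechanics*; they do
not certify performance when the COP is an imperfect or differentially
measured correlate.

## Numerical and degenerate-input choices

Double precision throughout; no interpolation tables.  COP values live
on the lattice generated by boosts of 0.75/1.00 minus multiples of 0.01,
with atoms at 0 and (briefly) 1.  A logistic fit on constant exposure,
all-case or all-control data is rejected with an informative error.  The
daily infection probability is clipped at 1, though with the default
parameters the unclipped value stays far below it.  Vaccination doses
per round are rounded to the nearest integer of 0.5% of eligibles.

## Known limitations

* Wave timing after the first epidemic peak is emergent and
  seed-sensitive; cells anchored to a single early day (day 150) show
  the largest run-to-run variability, especially in scenario 2.
* The GAM's behaviour in sparse COP regions depends on the penalty
  criterion and basis; the package matches mgcv on shared data, but
  small-sample GAM cells remain the noisiest quantities in the study.
* The reported coverage of the vaccination schedule (~18% ever-dosed)
  is the mechanical consequence of dosing 0.5% of eligibles for 40
  rounds while allowing revaccination after 56 days; the nominal 20%
  would require every dose to reach a never-dosed agent.
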