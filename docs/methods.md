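# Methods

## Model family

All eight variants share the two-boundary Wiener diffusion core: evidence
`x(t)` starts at `β·α` between absorbing boundaries 0 (healthy choice) and
`α` (tasty choice), drifts at rate `v = d · VD` with unit diffusion noise,
and the observed RT adds a non-decision time nDT to the first-passage time.
The variants differ only in how the value difference VD responds to gaze;
the four equations nest exactly (`φ_T = φ_H` → common `φ`; `φ = 1` →
option-level discounting only; `θ = 1` → gaze-free weighted difference), and
the unit tests assert those identities at machine precision.

Sign convention: option *i* is the option with the larger scaled taste value
(the "tasty" option) and maps to the upper boundary. Exact taste ties are
broken by item id and flagged in the oriented table (`tie_broken`); they are
measure-zero for continuous ratings.

One deliberate property worth noting: with an option-level discount `θ < 1`
and *unbalanced* gaze, VD is nonzero even for identical options — fixating
an option pushes evidence toward it. That is the attentional mechanism these
models exist to express, so the "identical options ⇒ VD = 0" symmetry is
asserted only under balanced dwell.

`θ`, `φ_T`, `φ_H` are left mathematically unconstrained (only `α`, nDT, `β`,
`ω` are transform-restricted); estimates above 1 are legal and reported
as-is.

### Value scaling

Ratings enter the drift on a common [1, 10] axis. The default map is a
participant-wise affine min–max transform per attribute; a constant rating
column maps to the midpoint 5.5. The scaling function is order-preserving
and pluggable (`scale_values`), since downstream maths needs only the range
and monotonicity.

## Likelihood

Fitting uses the piecewise-constant-averaging shortcut: a trial's
gaze-dependent drift schedule is collapsed to its dwell-weighted mean drift,
which equals `d · VD` evaluated at the trial's dwell shares, and the (choice,
RT) pair is evaluated under the constant-drift two-boundary Wiener density.
The simulator, by contrast, supports true piecewise drift, so the quality of
the averaging approximation is itself measurable (the test suite checks that
flat-schedule piecewise simulation matches the constant-drift closed form).

The density uses the standard small-time (image-charge) and large-time
(Fourier sine) series with the Navarro–Fuss elementwise switching rule and
an absolute truncation error of 1e−7 (`SERIES_EPS`). RTs at or below nDT
have log-density −∞. A numba-compiled kernel fuses parameter transforms, VD,
density and per-participant summation for the sampler's inner loop; a pure
numpy series implementation of the same density is kept and cross-checked in
the tests, and quadrature of the density against the closed-form choice
probability serves as an independent oracle.

Simulation is Euler–Maruyama (default dt = 1 ms) with a Brownian-bridge
within-step crossing correction; without it the absorption probability
carries an O(√dt) bias that is clearly visible against the closed form at
100k paths. Paths not absorbed by `t_max` (default 60 s) take the nearer
boundary; when a drift schedule is exhausted the last segment's drift
persists.

## Hierarchical estimation

Parameterization: per participant a raw-scale baseline vector (sated) and a
raw-scale change vector, `raw_hungry = raw_baseline + change`, both
hierarchical with group mean/SD. Hyperpriors (baseline): `α ~ N(2,1)` /
`HN(0,3)`; `nDT ~ N(−1,1)` / `HN(0,1)`; all others `N(0,0.5)` / `HN(0,0.5)`.
Change block: `α`, nDT `N(0,1)` / `HN(0,1)`; all others `N(0,0.25)` /
`HN(0,0.25)`. Transforms: softplus for `α`, nDT; standard normal CDF for
`ω`, `β`. Reporting follows the interpretable convention: transformed values
per condition, raw-scale values for the hunger effect. The diffusion noise
SD is fixed at 1 throughout (no registered variant estimates it).

The sampler is an adaptive Metropolis-within-Gibbs scheme:

* componentwise random-walk updates of participant parameters, vectorized
  across participants (their likelihoods are conditionally independent);
* a per-participant joint update along an adaptively estimated covariance
  (2.38²/D scaling), which handles the strong posterior correlations among
  `d`, `ω` and `α`;
* conjugate Gibbs draws for group means and log-scale random-walk updates
  (three repeats — they are likelihood-free) for group SDs;
* an interweaving (ASIS) step per parameter: holding the standardized
  participant values fixed, (group mean, log SD) move jointly with a
  likelihood-informed acceptance. This is what rescues mixing in the
  hierarchical funnel of the weakly informed change block; without it the
  change-block Rhat stalls around 1.2 at desk-scale chain lengths.

All proposal scales adapt toward standard acceptance targets (0.44
componentwise, 0.234 joint) with a Robbins–Monro schedule during burn-in and
are frozen afterwards, so the post-burn-in chain is a valid MCMC. Chains are
initialized from jittered prior locations with the nDT component capped
below each participant's fastest RT (otherwise the first likelihood is −∞).
Chains run sequentially from independently spawned seed streams; two runs
with the same seed are draw-for-draw identical.

Presets: `test` = 4 chains × 4 000 iterations (2 000 burn-in, thinning 2);
`paper` = 8 × 60 000 (30 000 burn-in, thinning 12, i.e. 2 500 draws per
chain). Convergence is declared iff every estimated quantity (group and
participant level) has split-chain Rhat ≤ 1.05; a non-converged fit is
returned with a failure flag and a warning, never silently accepted.

DIC is reported in both standard forms: `pD = D̄ − D(θ̄)` with the deviance
evaluated at the posterior mean of the *raw* participant parameters
(transformation-consistent), and the variance-based `pV = var(D)/2`. The
fitted deviance trace is recorded at every retained draw.

## Synthetic cohort

The generator mirrors the study design: 66 items (Nutri-Score classes
A:13 B:13 C:12 D:14 E:14, half sweet / half savory), 70 participants,
190 trials per session, two sessions (sated, hungry). Ratings are 0–100
continuous sliders driven by two near-orthogonal latent factors
(taste/wanting vs. health/calories, with the Nutri-Score and objective
energy content tied to the health factor); the first two principal
components of the six measures explain well over 70 % of their variance,
reproducing the two-component structure that justifies the taste-vs-health
framing.

Gaze is exogenous: fixation streams alternate between options, choose the
image (taste) region over the score (health) region with probability
`p_image` (defaults 0.80 sated, 0.85 hungry — a strong, hunger-amplified
image bias), and draw log-normal dwell durations (mean 350 ms, log-scale SD
0.45). The empirical dwell-duration distribution of the original task is not
documented, so the log-normal is a stand-in chosen for realism (positive,
right-skewed); nothing downstream depends on its exact shape because the
likelihood consumes dwell shares only.

Choices and RTs come from piecewise-drift first-passage simulation under the
trial's fixation schedule; the stream is then truncated (or its final
fixation extended) to span exactly the decision time, so dwell shares are
well defined and consistent with what the model would have integrated.
Default group truths (raw scale): α ≈ 2.2, nDT = 0.35 s, d = 0.06, ω = 0.77
sated with a +0.3 raw hunger shift (ω ≈ 0.85 hungry), θ = 0.8, φ_T = 0.9,
φ_H = 0.8 sated with a −0.35 raw hunger shift — magnitudes chosen to sit
inside the effect ranges a study of this design reports, with
between-participant SDs of 0.1–0.3 (raw). Roughly 40 % of trials are
conflict trials by construction (configurable).

What the generator does **not** emulate: evidence-dependent gaze (no
feedback from the accumulator to fixations), saccade dynamics, blinks or
calibration drift, item-level familiarity effects, session-order effects,
and any questionnaire-level covariates. Passing tests on synthetic data
therefore demonstrate internal consistency of the pipeline — likelihood,
sampler, diagnostics — not the adequacy of the model for any real dataset.

## Preprocessing

RT exclusion is single-pass: a trial goes if rt < 250 ms (strict) or
rt > mean + 4·SD, with mean and SD computed per participant × condition on
the *pre-exclusion* trials. One subtlety the fixtures encode: a 4-SD outlier
cannot exist in a group of ≤ 16 trials (the largest attainable z with ddof=1
is (n−1)/√n), so small-group demonstrations of the SD rule are impossible by
arithmetic, not by implementation. Single-trial groups skip the SD rule with
a warning. AOI assignment inflates each nominal rectangle by 5 % in width
and height about its center and errors out if inflated rectangles overlap;
points outside all rectangles are `none`. Dwell shares normalize the four
AOI dwell sums over the four AOIs only (`none` time is ignored); zero-dwell
trials are flagged and dropped from fitting, since the likelihood needs
shares. Conflict trials are those where one option is strictly tastier and
strictly less healthy; ties on either attribute do not count.

## Posterior predictive checks and recovery

PPCs replay the empirical gaze (dwell shares) of every trial, draw parameter
vectors from the participant-level posterior, and forward-simulate replica
datasets (batched Euler–Maruyama at dt = 2.5 ms — coarser than the fitting
dt because only distribution-level statistics are read off, and the bridge
correction keeps boundary probabilities unbiased). Tracked statistics: RT
quantiles 0.1/0.3/0.5/0.7/0.9 per condition × choice type plus the tasty-
choice proportion per condition, each compared against its 95 % highest-
density interval (HDIs proper, not equal-tailed intervals) across replicas.

Recovery studies run generate → preprocess → fit end to end and report
participant-level truth-vs-posterior-mean correlations (on the constrained
scale, pooling both conditions) and group-level truth-in-HDI indicators.

### Calibration-study design

The recovery, profile-likelihood and PPC experiments use a moderately
image-biased gaze, `p_image = 0.7` in both conditions, rather than the
cohort default 0.80/0.85: attribute-level discounts are identified only by
dwell on the score regions, and a 0.8+ image bias starves that contrast at
desk-scale trial counts. The DIC model-selection study runs under the
unmodified cohort gaze — the condition whose data the comparison is about.
The cohort defaults themselves are never changed.

Problem sizes (fixed): profile likelihood on 500 single-participant trials
with a 0.01-step ω grid; recovery correlations from 20 participants × 150
trials/session (2 chains × 3 000, thinning 1); group-coverage from 10 seeds
of 12 participants × 100 trials (3 × 2 000); model-selection calibration
from 10 replications of 10 × 100 with φ_T = 0.9, φ_H = 0.4 (2 × 2 000 per
fit); PPC coverage from 3 seeds of 6 × 60 with 150 posterior draws;
mediation recovery from 50 subjects × 100 trials/condition (a = 0.05,
b = 4, c′ = 0.2) plus a 30 × 60 null cohort. These sizes keep a full run in
the tens of minutes on one CPU.

### What recovers, and what does not, at desk scale

Group-level parameters recover well: the generating group taste weight sits
inside its 95% HDI across seeds for the DDM, and profile likelihoods peak
at the generating ω to within grid resolution. Participant-level recovery
is sharply parameter-dependent. Boundary separation and non-decision time
(wide true heterogeneity, strong per-trial signal) recover with
correlations above 0.9. The attentional block does not: per-participant `d`
varies by only ±25 % around its mean in the generating cohort, so posterior
noise attenuates any ranking; and `ω` is entangled with `φ_H` — during
image fixations health information enters the drift as the product
`(1−ω)·φ_H`, so the two separate only through the rarer score-region dwell
(empirically, estimated ω anti-correlates with true φ_H). At 20 × 150
trials the participant-level correlations for ω and d plateau around
0.2–0.5 even with chains several times the test preset. Recovering
individual attentional parameters reliably requires cohort-scale data
(dozens of participants × hundreds of trials with long chains), which is
exactly why studies of this design run at that scale.

The same information limit shows up in single-dataset profile likelihoods:
at 500 trials from one synthetic participant at the cohort drift scaling,
the observed-information standard error of the ω profile peak is ≈ 0.19
(the surface does peak at the generating value in expectation, but any one
dataset's argmax scatters widely). Point identification of ω to a few
hundredths needs thousands of trials — worth keeping in mind when reading
single-subject fits of this model family.

## Mediation

Within-subject multilevel mediation on conflict trials: a Gaussian equation
for the mediator (dwell proportion on the tasty option, person-mean-centered
so only the within-person contrast identifies the paths) and a
Bernoulli-logit equation for the binary choice — the natural likelihood for
a binary outcome, and the scale on which path *b* magnitudes in the
literature (≈ 5) are interpretable. Subject slopes (a_j, b_j) are bivariate
normal with free correlation, because the population indirect effect is
`a·b + cov(a_j, b_j)`; subject intercepts and direct-path deviations are
independent normals (the full 5×5 covariance would add ten more
weakly-identified parameters for no inferential gain at these sample sizes).
Priors: N(0, 10) on fixed effects, half-normal(1) on all SDs, uniform on the
slope correlation. Centering note: person-mean centering is computed across
both conditions — centering within person × condition would absorb the
condition effect on the mediator and force `a = 0` by construction. The
difference-score mediator (dwell on tasty minus dwell on healthy) is
available via configuration.

The path identity `c ≈ c′ + a·b + cov(a_j,b_j)` is exact in the mediator
equation's linear scale but only approximate under the logit outcome; the
reported `c` is defined as `c′ + indirect`.

## Known limitations

* The averaged-drift likelihood is the standard speed-up, not the exact
  piecewise likelihood; its error grows with long trials and strongly
  alternating gaze.
* DIC margins between the common-φ and two-φ models are small at desk scale
  (a few units at 10 × 100); decisive separation needs cohort-scale data, as
  expected for nested models differing by one parameter.
* The sampler is a general-purpose MCMC; it matches a Gibbs toolchain at
  the level of posterior summaries, not draw-by-draw.
* Group SDs with ≤ 10 participants mix slowest; their Rhat values are the
  binding constraint for short chains.
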