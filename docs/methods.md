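# Methods

`rinatt` models two-alternative forced-choice (2AFC) orientation
discrimination in head-fixed mice as a problem of *rational inattention*:
the animal's sensory system has bounded encoding precision, that precision
is costly, and how it is distributed over orientation space should — and,
in the experiments the package emulates, does — depend on the reward rules
of the environment. This note documents the models, the numerical choices,
and what the synthetic experiments do and do not establish.

## Task and coordinate conventions

Two oriented gratings are shown; the subject must pick the more *vertical*
one. Orientations live on [0°, 180°) with grating periodicity, so all
circular computation uses the doubled angle ψ = 2θ in radians. The decision
rule operates in **verticality** space, v(θ) = 90 − |90 − θ|: 0° and 180°
map to 0 (horizontal), 90° maps to 90 (vertical). Stimulus orientations are
drawn from a horizontal-heavy prior π(θ), implemented as a von Mises density
on the doubled circle centered at horizontal. A horizontal-to-vertical
density ratio of roughly 2–3 is typical of such rigs and of natural-scene
orientation statistics; the default concentration 0.5 gives e ≈ 2.7 and is
configurable. The default grid step
is 2° (90 grid points), matching the discretization used by the learning
model.

Angle differences between the two gratings span 20°–90° of verticality in
10° steps, with a small (default 2 %, configurable) fraction of equal-angle
trials rewarded on a random side. Contrasts are drawn independently per side
from {0.3, 0.6, 1}. Rewards for correct choices follow one of three
environments: constant (5 µl), increasing (1 µl at horizontal to 8 µl at
vertical, linear in verticality), or decreasing (the reverse).

## Observer model

Each grating θ₀ produces a noisy internal measurement m, von Mises on the
doubled circle with concentration k(c)·g(θ₀):

* k(c) = k_max c^q / (c^q + c50^q) — the Naka–Rushton contrast response,
  interpreted as encoding precision;
* g(θ) — the resource gain function, a positive normalized allocation of
  precision over orientation (normalized to unit mean on the grid, i.e.
  ∫ g dx = 1 on the unit-normalized domain, so the uniform allocation is
  g ≡ 1 and k·g keeps the scale of a von Mises concentration).

The observer decodes m with the Bayesian least-squares (BLS) rule: the
posterior mean of p(θ|m) ∝ p(m|θ) π(θ) on the grid, computed as a circular
mean in doubled-angle space. Because the concentration varies with θ, the
likelihood over θ includes the von Mises normalizer 1/(2π I₀(k g(θ)));
omitting it would implicitly favor high-gain orientations.

Estimator moments E[θ̂|θ₀] and Var[θ̂|θ₀] are obtained by integrating the
decoder over the measurement distribution. By default every decoded
estimate is folded to verticality **before** taking linear moments, because
the probit decision rule operates in verticality space; the alternative
(circular moments on the doubled circle, mean by atan2 and variance by
−2 log R², folded afterwards) is available behind
`convention="circular"`. The two agree closely away from the fold points at
high precision and differ at low precision, where no linearization is
exact.

Choice follows a probit rule on the difference of expected verticality
estimates, scaled by the total SD (estimator variances plus late-noise
variance σ_late², the stimulus-unspecific Gaussian noise of downstream
decision circuits), plus bias terms: a side bias β₀, a previous-choice bias
β₁·D (D = +1/−1/0 for previous left/right/none), and a contrast-difference
bias β₂(c_l − c_r). The lapse rate is fixed at zero in this family; the
descriptive models carry lapses instead. The generative simulator draws
actual measurements, decodes, folds, and adds late noise, so the probit
expression is its Gaussian approximation; agreement is within 0.02 absolute
probability over the task's trial grid at mouse-like parameters (asserted
in the tests), degrading only at very low encoding precision.

Exactly noiseless observers (zero estimator variance and σ_late = 0) are
handled by flooring the decision SD at 10⁻¹², which turns the probit into
the correct step rule instead of an indeterminate 0/0.

## Endogenous allocation

The rational-inattention agent chooses g and k_max to minimize expected
reward loss plus a precision cost:

* loss: the reward-weighted error probability, averaged over contrast pairs
  (uniform 3×3 product) and stimulus pairs weighted π(θ_l)π(θ_r). The
  per-pair weight is the reward a correct choice would deliver —
  max(R_l, R_r) in the increasing environment, min(R_l, R_r) in the
  decreasing one, and 5 µl in the constant one (the constant environment's
  flat reward is included so all three environments report µl/trial and the
  reward accounting is uniform; it rescales but does not reorder optima).
* cost: η·k̄ with k̄ the average invested precision
  (mean over contrasts of ∫ π g k(c) dθ), or alternatively η·I(θ;m) with
  the mutual information computed exactly on the grid
  (`cost_kind="mutual_information"`).

Stimulus pairs default to the task's difficulty set (|Δv| ∈ {20,…,90}) and
can instead integrate over **all** unequal grid pairs (`dense=True`), which
approximates the continuous double integral over the stimulus space. The
dense objective is used for the allocation-regime and swap experiments
because the small-difference pairs it includes are what make local
discriminability (and hence the classic prior-tracking limit) matter; the
difficulty-restricted set is the right evaluation measure for task-level
quantities such as accuracy and collected reward.

g is parametrized through its antiderivative on the normalized half-domain
x = v/90 ∈ [0,1]: G(x) = x[1 + (x−1)(g₀ + g₁x + g₂x²)], g̃ = G′ sampled at
half-grid cell midpoints, mirrored about the vertical meridian to cover
[0°, 180°), and renormalized. Order 2 spans the smooth allocations of
interest; coefficients with non-monotone G (checked on a 257-point fine
grid plus the sample points) are rejected and act as a penalty during
optimization. Optimization is multi-start Nelder–Mead over
(g₀, g₁, g₂, log k_max); the default 50 starts is scaled down to 8–12 in
the packaged experiments, which we found sufficient for stable optima at
these problem sizes. Starts draw coefficients uniformly from [−2, 2]
(resampled until feasible) and log k_max from [log 5, log 150].

### Allocation regimes

With the dense objective the optimizer reproduces the qualitative regimes
of the theory: at low cost and low late noise the optimum tracks the prior
(more gain at horizontal than vertical); as late noise grows the optimum
becomes "myopic" to the prior peak and shifts toward intermediate
orientations; at the mouse-calibrated setting the increasing environment
allocates more gain to vertical orientations and the decreasing environment
more to horizontal ones.

### Swap experiment

The cost of misallocation is measured by optimizing (g, k_max) separately
for the increasing and decreasing environments at η = 0.2, σ_late = 12 —
calibrated so pooled task-distribution accuracy sits in the 70–80 % band
typical of trained mice (≈0.82 and 0.69 for the two environments, ≈0.75
pooled) — and cross-evaluating expected per-trial reward over the task's
stimulus/contrast distribution. The headline number is the increasing
environment's percent reward loss under the decreasing environment's
optimum. The reverse direction is reported too but is not a loss: the
decreasing environment's stakes are lower (its correct-choice rewards are
the pair minima), so its optimal k_max is much smaller, and swapping in the
increasing environment's higher-precision solution can *gain* gross reward
there while overpaying in precision cost.

## Descriptive models (DM1–DM6)

Nested probit models on the verticality difference: DM1 (single sensory SD,
side and history biases, lapse), DM2 (per-contrast SDs), DM3 (+ contrast-
difference bias), DM4 (side-specific lapses, mixed as
P = Φ(z)(1 − λ_l − λ_r) + λ_l so λ_l/λ_r are the left/right guess rates),
DM5 (+ previous-trial reward × choice term), DM6 (DM4 + DM5). Maximized
log-likelihoods obey the nesting inequalities by construction; this is
asserted on synthetic sessions.

## Fitting

One likelihood engine serves all families: −Σ log p(choice | stimuli, Ψ)
with probabilities clipped to [10⁻⁹, 1 − 10⁻⁹]. Fits are multi-start
Nelder–Mead over an unconstrained vector (log transforms for positive
parameters, logit for rates), with starts drawn from documented ranges
under a fixed master seed. AIC = 2k − 2LL; BIC uses log n. Model comparison
requires identical datasets (checked by content fingerprint) and breaks AIC
ties by parameter count.

Observer variants: `g-const` (uniform gain; fits k_max, q, c50, σ_late,
β₀–β₂), `g-free` (adds the three gain coefficients), and `g-endog` (fits η
instead of the gain; g* and k_max* are derived by the internal optimizer,
so the variant has the same parameter count as DM3). The inner optimization
is memoized on rounded (η, q, c50, σ_late) and runs on a coarse 6° grid —
the optimal coefficients are grid-free and are re-sampled on the analysis
grid — because a full inner optimization per likelihood evaluation would
dominate the fit.

### Covariate-modulated precision readout

To separate sensory from downstream precision changes (e.g. across arousal
states), the observer is extended with a binary covariate: the first level
is the reference described by the shared base parameters, and the second
level carries two multiplicative factors — one on k(c) (sensory precision)
and one on 1/σ_late² (late precision). Both factors are fitted by MLE with
everything else shared, on a bounded log scale ([0.1, 10]) with a coarse
grid profile before Nelder–Mead, because the two factors are anti-correlated
along a likelihood ridge (raising either one improves overall performance;
they are separated only by the contrast profile and the bias structure).

The recovery experiment simulates 20 datasets of 45 000 trials (half per
covariate level) from this model with factors drawn log-uniformly from
[0.4, 2.5], refits them, and scores pooled log-factor pairs by R² about the
identity line. The dataset size follows a Fisher-information power
calculation with a safety factor for the ridge's nonlinearity: per-level
sessions of a few thousand trials are simply too small to pin the late
factor, and the experiment is meant to demonstrate that the *estimator* is
consistent and well-identified at realistic pooled-data sizes, not that
tiny sessions suffice. The base condition (k_max = 10, q = 2, c50 = 0.4,
σ_late = 20) keeps the sensory and late variance shares comparable and the
error rate informative.

## Learning model

Instead of a static optimum, a distributional RL rule maintains a reward
belief R̂(θ) on the 2° grid (initialized flat at the constant environment's
5 µl — the pre-training reward — since no initialization is prescribed).
After choosing θ̃ and receiving R_t:

* confidence C_t = max(p, 1−p) from the bias-free choice probability — the
  model probability that the chosen option is correct, ≥ 0.5;
* learning rate α_t = C_t/(C_t + α̃⁺) after positive prediction errors and
  C_t/(C_t + α̃⁻) otherwise (divisive constants: smaller α̃ means faster
  learning);
* prediction-error vector with a von Mises kernel
  K(θ) = exp(k̃(cos(ψ̃ − ψ) − 1)) centered on the chosen angle. Two readings
  are implemented: the default `smoothed_error`,
  δ(θ) = (R_t − R̂(θ̃))·K(θ), spreads the scalar error locally, and its
  fixed point tracks the locally expected reward, which differentiates the
  reward environments; the alternative `scaled_belief`,
  δ(θ) = R_t − R̂(θ̃)·K(θ), kernels the belief term only — its fixed point
  equates a choice-density-weighted neighborhood of R̂ to the mean reward
  and is therefore insensitive to the reward map, so it cannot produce
  environment-specific allocations. Both reduce to R_t − R̂(θ̃) at the
  chosen angle.
* update R̂ ← R̂ + α_t δ_t, floored at zero (the divisive normalization
  needs a nonnegative vector; the update rule itself does not guarantee
  it), then g = R̂/ΣR̂ — divisive normalization to a unit-sum gain. When
  this gain drives the encoder it is rescaled to unit mean (the encoder's
  normalization); zero cells are lifted to 10⁻⁹ to stay a valid
  concentration.

The closed loop feeds each trial's gain back into the encoder before the
next choice. Convergence is probed against the static optimum at the
late-noise calibration (η = 0.6, σ_late = 5, dense objective; accuracy
≈ 0.70): sessions of 3 000 trials, α̃⁺ = 0.3, α̃⁻ = 0.6, k̃ = 2, comparing
the mean gain of the last 500 trials with g* by Spearman correlation. The
increasing and constant environments converge tightly (ρ ≈ 0.99 and 0.94).
The decreasing environment does **not** converge to its static optimum
(ρ ≈ −0.1), and the failure is structural, not numeric: the RL gain is
normalized reward expectation, which in that environment peaks at
mid-verticality angles (the more-vertical-but-low-reward choices), while
the static optimum still concentrates precision near the decision-relevant
vertical band; moreover orientations within 20° of horizontal are never the
chosen option under the task's difficulty set, so the learning rule cannot
deposit gain where the optimizer does. This divergence is a genuine
limitation of the belief-normalization mechanism and is reported as such by
the corresponding test.

## Poisson population code

An implementational variant: N = 30 independent Poisson neurons with
tuning f_n(θ) = g(θ_n) k(c) exp(κ̂(cos(ψ_n − ψ) − 1)) + Δ, preferred
orientations placed by the prior's inverse CDF at quantile midpoints (local
density ∝ π), κ̂ = 4 by default (≈30° tuning half-width, a stand-in chosen
in config since the empirical estimate comes from imaging data outside this
package's scope), and base rate Δ = 0.5 spikes/trial. With
prior-proportional spacing the discrete BLS decoder reduces to a
likelihood-weighted circular mean over the preferred orientations,
evaluated with log-sum-exp. The network objective is expected reward
(closed-loop simulation of the task with additive late noise on the
decision variable, common random numbers for a deterministic objective)
minus η per expected spike; optimization reuses the polynomial gain family
with log-parametrized peak rate. The optimized network reproduces the
algorithmic regimes: activity concentrates at high-prior orientations when
noise and spike cost are low, and average firing falls as the spike cost
rises.

## Synthetic sessions

The generator draws the correct-side orientation from the prior conditioned
on feasibility (verticality ≥ difficulty; the exact equivalent of
resampling rejections), places the distractor at the required verticality
on a uniformly chosen mirror branch, randomizes sides and contrasts, and
inserts equal-angle trials at the configured fraction. Choices come either
from the observer simulator or from a sequential DM simulation threading
choice and reward history. The rig's anti-bias protocol (incorrect trials
repeated with the same correct side but resampled orientations, excluded
from analysis) is emulated behind `repeat_incorrect`, with repeats marked
`excluded` so fits drop them.

What the synthetic data do *not* emulate: reaction times, wheel kinematics,
pupil dynamics, satiety and engagement drifts, session boundaries, and any
within-session nonstationarity other than the RL loop's own. Passing tests
therefore establish internal consistency of the inference machinery and
the theory's qualitative predictions, not that real mice are fit by these
exact parameter values.

## Psychometric geometry

Pairwise psychometric distances are P(correct discrimination) − 0.5 per
angle pair (zero diagonal, entries in [0, 0.5]), from the model's error
probabilities averaged over contrast pairs or pooled from trials. Classical
(Torgerson) MDS embeds them: double-center the squared distances,
eigendecompose, keep the leading nonnegative components, with eigen-signs
fixed deterministically (largest-magnitude loading positive) for
reproducible plots. Metric MDS was chosen over nonmetric variants for
determinism and because the distances are already on a ratio scale.
Trial-pooled matrices are only defined on angle grids whose pairwise
verticality differences the task actually samples (20° spacing and up).

## Reproducibility

Every stochastic step takes a seed; pipelines fan a single master seed out
through `numpy.random.SeedSequence.spawn`, and all derived seeds stay below
2³¹. The demo pipeline writes a manifest with content hashes of every
artifact; repeated runs with the same master seed produce byte-identical
artifacts.

## Problem sizes

The packaged experiments use desk-scale sizes chosen once: 20 × 45 000
trials for the covariate recovery sweep; 12-start dense optimizations for
the swap experiment; 10⁶-draw Monte Carlo oracles on a 5×3 (θ, c) grid;
3 000-trial closed-loop RL sessions; 1 500–4 000-trial sessions for fitting
tests with 2–6 starts (the full multi-start schedule of 50–2000 starts
remains configurable).
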