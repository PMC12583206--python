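# Methods

## The model

`responsenet` models a patient's response to sequential treatment as a
partially observed Markov decision process.  Each patient contributes a
trajectory {(x_t, a_t, y_t, m_t)}, t = 1..T: covariates x_t ∈ ℝ^{d_x},
a categorical treatment a_t, outcomes y_t ∈ ℝ^k and a binary mask m_t
marking which outcome entries were observed.  Time is an integer visit
index; calendar-time alignment and irregular sampling are out of scope.
Covariates are assumed fully observed; masking applies to outcomes only
(it enters exactly one place: the outcome likelihood).

A latent health state z_t ∈ ℝ^{d_z} evolves as

    z_{t+1} = f_θ(z_t, e(a_t)) + ε_t,   ε_t ~ N(0, σ²I),

where e(a) is a learned treatment embedding and f_θ is an affine map plus
a residual multilayer perceptron on [z; e].  The affine-plus-residual form
is deliberate: with the residual weights at zero the transition is exactly
linear, so the model family contains classical linear-Gaussian state-space
models as a special case — this is what makes exact validation possible
(see "Validation oracles").  A second-order refinement,

    z_{t+1} = z_t + γ·(f_θ(z_t, e(a_t)) − f_θ(z_{t−1}, e(a_{t−1}))),

captures latent inertia (γ is a learnable scalar).  By default the
first-order form provides the transition density in the objective and the
second-order form is available for deterministic mean-path rollouts; a
config switch (`transition_mode="second_order"`) uses the second-order
mean inside the transition density instead, with the first-order form at
the initial step where only one lag exists.

Observations are decoded by

    ŷ_t = W_y·ReLU(z_t) + b_y,   x̂_t = W_x·tanh(z_t) + b_x,

with a heteroscedastic outcome variance head σ_j²(z) = softplus(·) + 10⁻⁴
(the floor avoids degenerate likelihood spikes).  The outcome likelihood is
a masked diagonal Gaussian: Σ_j m_{t,j} log N(y_{t,j}; μ_j(z_t), σ_j²(z_t)).
The covariate reconstruction likelihood is Gaussian with a learnable scalar
variance — the decoder alone defines only a mean, and the evidence bound
needs a density.  Both decoder activations can be switched to identity
(`decoder_activation`, `covariate_activation`), which together with the
affine transition recovers the linear-Gaussian special case.

Inference is amortized: a GRU over the history (x_t, e(a_t), m_t⊙y_t, m_t)
parameterizes a diagonal-Gaussian posterior q(z_t | H_t) with softplus
variances.  Masked outcome entries are zero-imputed with the mask appended,
so the posterior is a function of observed history only, and it is causal
by construction (perturbing the future cannot change the posterior at t;
this is tested).  The evidence lower bound is estimated with
reparameterized Monte Carlo:

    ELBO = E_q[ Σ_t log p(x_t|z_t) + log p(y_t|z_t)  (masked)
              + log p₀(z_1) + Σ_{t≥2} log p(z_t|z_{t−1}, a_{t−1})
              − Σ_t log q(z_t|H_t) ].

One sample per step is used during training (configurable for evaluation).
The sum of transition terms runs over t ≥ 2 together with an initial-state
prior term — the only reading under which the bound is exact against a
marginal likelihood.

## Treatment semantics

Embeddings are compositional: e(a) = E_sym(α(a)) + E_spec(a), a
class-shared prototype plus a treatment-specific offset, with α(·) the
ontology's class map (ATC-style therapeutic classes).  Three regularizers
act on embedding geometry:

* margin loss: hinge on intra-class squared distances above δ (default
  0.1), enumerated over unordered pairs i < j;
* kernel alignment: (‖e_i − e_j‖² − (1 − K(a_i, a_j)))² over all unordered
  vocabulary pairs, where the affinity kernel K defaults to 1 within a
  class and 0 across classes when no explicit value is given;
* an entropy term on class attention α_c(z) ∝ exp⟨Pz, e_c⟩ (P a learned
  projection when d_z ≠ m).  Its sign is chosen so that a positive weight
  *rewards* entropy, discouraging attention collapse onto one class.  The
  attention can optionally gate the treatment input to the transition
  (embedding scaled by its own class's attention weight); this gating is
  an interpretation without a defining formula, so it ships disabled by
  default (`attention_gating=False`).

## Knowledge infusion

All clinical-prior losses act on the latent shift Δ(z, a) = f_θ(z, e(a)) − z:

* consistency: treatments joined by an ontology similarity edge must
  induce similar shifts; the expectation over z uses the minibatch's
  posterior means;
* cumulative influence Γ_T = Σ_t ρ^{T−t} Δ(z_{t−1}, a_t) with geometric
  decay ρ ∈ (0, 1] (the simplest monotone decay; exposed in config);
* corridor: squared Euclidean distance of Γ_T to a convex safe region,
  closed-form projection for boxes (clamp) and balls (radial scaling);
  general convex hulls are out of scope;
* drift: squared change between consecutive shifts;
* anchoring: closed-form diagonal-Gaussian KL from q(z_t) to a clinical
  prior π(z_t) (single Gaussian, shared or per-timestep; mixtures are a
  noted extension, not implemented);
* stage penalty: squared distance of decoded outcomes to a stage-specific
  expected curve; patients without a stage label contribute nothing, and
  the weight is effectively 0 when no curves are configured.

## Adversarial counterfactual training

A discriminator D_ψ(z, e(a)) scores whether a (latent, treatment) pair
comes from the factual stream or from a randomly substituted alternative
treatment (uniform over the vocabulary excluding the factual action).  Its
objective L_disc = E_cf[log(1 − D)] + E_real[log D] ≤ 0 is ascended by the
discriminator.  The generator's composite loss is

    L = −ELBO + λ1·L_consist + λ2·R_corridor + λ3·R_anchor − λ4·L_disc
      + λ5·R_temp + λ_sym·R_sym + λ_align·R_align + λ_smooth·R_smooth
      + λ_stage·R_stage + λ_drift·R_drift + λ_shift·R_shift + λ_wd·‖θ‖².

Two conventions deserve emphasis.  First, the loss is written so the
generator descends every term (maximizing the ELBO, minimizing the
penalties); a sign-literal reading of the composite objective would
minimize the evidence bound, which cannot be intended.  Second, the
generator carries −λ4·L_disc, i.e. it co-ascends the discriminator
objective rather than descending it as in a classical adversarial pair;
this follows the stated composite form and is kept as specified — with the
default λ4 = 0.1 its practical effect on the other terms is small, and
λ4 = 0 exactly decouples the discriminator (verified bitwise in tests).
The shift-alignment penalty ‖Δ(z, a) − Δ(z, ã)‖² additionally ties factual
and counterfactual latent shifts together.

λ1..λ5 default to 0.1 each and the auxiliary weights (sym, align, smooth)
to 10⁻²; the remaining auxiliary weights default to 0, so the five-term
composite objective is reachable by configuration.  No weight values are
prescribed by the source method; these defaults are package choices.

Optimization alternates `n_critic` discriminator Adam steps (on detached
latents) with one generator Adam step.  Patients are padded to the batch's
maximum length with a validity mask; every sum over time respects the
per-patient horizon.  All randomness (shuffling, Monte-Carlo noise,
alternative-treatment draws) comes from separate per-epoch streams derived
from the seed, so runs are bitwise reproducible, λ4 = 0 runs are bitwise
identical to discriminator-free runs, and a resumed checkpoint (parameters
+ Adam moments + epoch counter) continues exactly.

## Counterfactual decoding

The one-step mean-path counterfactual is ŷ^cf = D_y(f_θ(z, e(ã))) from the
posterior-mean latent; the expectation version integrates over posterior
and transition noise by Monte Carlo.  Longer horizons chain deterministic
transition means (mean-path counterfactuals).  The discriminator input is
literally (z, e(a)); a config flag can append the decoded next outcome,
reflecting an ambiguity between the objective's inputs and its textual
description — the literal form is the default.

## The simulator

The bundled generator instantiates the assumed data-generating process
with a *linear-Gaussian* ground truth rather than a neural one: evidence
is then exactly computable, counterfactual twins are exact, and effects
are known vectors.  Defaults (the study conditions): 300 patients, T = 12
visits, d_z = 4, d_x = 6, k = 2, 3 treatment classes × 3 treatments,
class-effect directions sampled with pairwise |cos| < 0.6 and unit norm,
specific offsets with norm 0.1 × the mean class-effect norm
(`within_class_spread`), transition A = 0.7 × (random orthogonal), noise
scales σ_z = σ_x = σ_y = 0.1, z_1 ~ N(0, I), 20% outcome missingness
(missing completely at random — no mechanism is specified for the
missingness, so the simplest one is used), and randomized treatment
assignment.  Confounded assignment is a multinomial logit in the current
latent state with tunable strength; strength 0 recovers randomization.
Per-patient noise blocks (innovations, emission noise, assignment and
masking uniforms) are pre-drawn from seeded streams, so an intervened twin
shares every draw with its factual counterpart and the pair's outcome
difference isolates the treatment effect.

What the simulator does *not* emulate: informative missingness,
pharmacokinetics, dose, time-varying confounding beyond the logit policy,
irregular visit schedules, and non-Gaussian or nonlinear emissions.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the assumed model class, not performance on real
EHR data.

## Validation oracles

* **Kalman filter**: with identity decoder activations and the residual
  network zeroed, the model reproduces the simulator's linear-Gaussian
  process exactly; a forward Kalman filter (with the treatment sequence as
  control input and masked outcome rows dropped per step) computes the
  exact log-evidence.  The Monte-Carlo ELBO must never exceed it beyond
  Monte-Carlo error, for any encoder parameters.  The filter itself is
  cross-checked against a stacked joint-Gaussian evidence computation.
* **Brute-force loops**: every loss primitive is compared to a naive
  double-loop implementation at 10⁻¹⁰ tolerance on random instances.
* **Finite differences**: analytic gradients of the composite objective
  and of each term are compared against central differences on a
  sub-500-parameter fixture at 10⁻³ relative tolerance.

## Effect recovery scoring

Latent spaces are identified only up to an invertible transform, so the
learned shifts are mapped through the linear part of a least-squares
affine fit from posterior means to the simulator's latent paths before
comparison.  The learned class shift averages Δ(z, e(a)) over class
members and ~200 reference posterior-mean latents.  Both learned class
shifts and true class effects are centered across classes before computing
cosines: the treatment-independent component of f(z) − z (e.g. (A − I)z̄
in the linear case) is common to all classes and not attributable to any
treatment; centering removes it on both sides, and makes scoring the true
parameterization itself return cosines of exactly 1.  Reported matches use
optimal one-to-one assignment on the cosine matrix; label-matched cosines
are reported alongside because the assignment maximization is positively
biased under the null (a random model scores ≈ 0.5 assignment-matched but
≈ 0 label-matched), which matters when interpreting near-threshold values.

## Problem sizes and defaults used in the shipped studies

The recovery/counterfactual/calibration studies train for 100 epochs with
batch size 50 and Adam step 10⁻² (encoder width 32, transition width 32,
discriminator width 16); the zero-effect study uses 150 patients and 40
epochs — in that world the fitted decoder often settles in a regime where
predictions are treatment-invariant, which is exactly the desired null
behaviour and is handled as a degenerate (zero-variance) case by the
paired test.  The ELBO-validity study uses 20 trajectories (d_z = 2,
T = 10) at 1,000 Monte-Carlo samples.  These sizes are the package's
standard demonstration settings; all of them are parameters, not
constants.

## Known limitations

* The adversarial sign convention follows the composite objective as
  specified (see above); users wanting classical generator-fools-
  discriminator dynamics can negate λ4's contribution by subclassing the
  loss, but that variant is not shipped.
* The ReLU outcome decoder cannot represent maps that are linear on the
  whole latent space; the model compensates by shifting latents into the
  positive orthant, which works but makes raw latent coordinates
  uninterpretable without the alignment step.
* Full-covariance posteriors, non-Gaussian emissions, continuous time,
  Gaussian-mixture anchors and convex-hull safe regions are not
  implemented.
* Counterfactual validity relies on the simulator's randomized or weakly
  confounded assignment; no identification guarantees are offered under
  hidden confounding.
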