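# Methods

`dualhebb` simulates a two-layer inference circuit in which synaptic
*connectivity* and synaptic *weights* are separate, jointly plastic
substrates of representation, and provides the analytic and
information-theoretic machinery needed to compare them.  This note records
the model, the parameter choices, the numerical decisions, and the places
where the package had to resolve genuinely open design questions.

## Model

At every time step a hidden state `s ∈ {0,…,p−1}` is drawn uniformly.
Input neuron `j` responds with a stochastic rate drawn from a
one-parameter exponential family

    f(r | θ_{s j}) = exp[ h(θ) g(r) − A(θ) + B(r) ],

with tuning matrix `θ` (states × inputs).  Two families are implemented:
Gaussian rates (`h(θ) = θ/σ_X²`, optionally with per-input noise scales
`σ_{X,j}`) and Poisson counts (`h(θ) = log θ`).  The natural parameter
`q = h(θ)` is the evidence weight an ideal observer applies to the
sufficient statistic `g(r) = r`.

Output neuron `i` integrates its connected inputs,
`v_i = Σ_j c_ij (w_ij g(r_j) − h_w)`, and global inhibition normalizes the
population through a softmax: `r_{Y,i} = rY⁰·exp(v_i − logΣ_l exp v_l)`.
With all-to-all wiring and `w_ij = q_{σ_i j}` (σ_i the state neuron `i`
represents, `σ_i = floor(p·i/N)`), the group-summed output equals the
exact Bayes posterior; this identity holds because the per-state
log-partition sums `Σ_j α(q_{μj})` are constant across states under the
generator's normalization, and it is verified to 1e-10 in the tests.

### Tuning generators

* **Gaussian model** — raw tuning values from a truncated normal
  N(μ_M, σ_M) on [0, ∞) (sampled exactly through `scipy.stats.truncnorm`,
  equivalent to rejection; clipping would put an atom at zero the
  analytics do not assume), then each state row scaled so its
  root-mean-square rate is `rX⁰`.  Defaults: p = 10, M = 200, μ_M = σ_M =
  σ_X = rX⁰ = 1.
* **Poisson model** — truncated log-normal raw values on (0.2, 20), each
  row scaled to mean rate `rX⁰ = 0.3`; the reference rate is fixed at half
  the smallest tuning value so the optimal weights `log(θ/θ_o)` stay
  positive.
* **Mixed model** — normalized convex mixture
  `θ ∝ κ_m·θ_const + (1−κ_m)·θ_var` (dynamic environments).
* **Inhomogeneous noise** — per-input scales
  `σ_X·exp(2ζ_j log σ_r)/σ_r`, log-uniform over `[σ_X/σ_r, σ_X σ_r)`.
* **Constant-response model** — a quarter of inputs respond with the same
  (largest) value to every state, the rest are binary high/low with
  probability ½ per state.  The contrast values (1.2 / 1.0 / 0.2 after
  choosing `θ_low < θ_high < θ_const`) are package defaults chosen once so
  that both regimes of interest are observable: the constant group still
  attracts the largest optimal weights (so cut-off pruning spends its
  entire budget on uninformative inputs and falls to chance) while the
  informative minority keeps a probabilistically wired network well above
  chance.  With much larger contrasts the constant group's weights
  dominate the membrane variance quadratically and every sparse strategy
  degenerates to chance, which makes comparisons meaningless.

Gaussian rates may be negative: the emission model is a genuine unbounded
Gaussian and no rectification is applied.

## Coding strategies

With `q̄` the grand mean of `q` and sparseness parameter `γ`:

| strategy     | wiring                     | weights        |
|--------------|----------------------------|----------------|
| weight       | Bernoulli(ρ), ρ = γq̄      | q/ρ            |
| connectivity | Bernoulli(min(γq, 1))      | 1/γ            |
| dual         | Bernoulli(min(γq, 1))      | q/ρ̄, ρ̄ = γq̄  |
| cut-off      | top round(Mρ_o) per neuron | q/ρ_o          |
| random       | Bernoulli(ρ_o)             | q/ρ_o          |

Cut-off ties are broken uniformly at random so the inbound count is
exact.  For the inhomogeneous-noise model `q̄` uses the baseline noise
scale (`mean(θ)/σ_X²`), not the per-input scales, so a handful of
low-noise inputs cannot dominate the normalization.  Threshold presets:
`h_w = q̄/γ` for the static-coding studies (and dual coding), `q̄/ρ_o` for
cut-off/random, `rX⁰/γ` for the learning runs, where the mean response
depends on the mixture ratio.

## Plasticity

Per step, in this fixed order: sample input → output rates → weight
update → connection-probability update → rewiring.

* **Weight rule** (existing connections only):
  `Δw = (η_X/γ)·( r_Y [g(r) − α′(ρ̄ w)] + b_h [rY⁰/N − r_Y] )`, weights
  floored at 1e-12 (implementing strict positivity).  `ρ̄` is measured
  once from the initial connection matrix.  Note the *stochastic* fixed
  point exceeds the mean-field value `q/ρ̄` by the positive covariance
  between a neuron's rate and its own input noise (about 10–30% on strong
  inputs); convergence tests therefore assert proportionality rather than
  exact equality.
* **Wiring rule (dual Hebbian)**: for every pair, connected or not,
  `Δρ = η_ρ r_Y [g(r) − α′(ρ w_o)]`, `ρ` clipped to [0, 1],
  `w_o = rX⁰/γ`.
* **Approximated rule**: connected pairs relax toward `γ²w`
  (`Δρ = η_ρ(γ²w − ρ)`); absent pairs are pinned at the baseline `γ²w_o`
  (assignment, not increment) — random, activity-independent spine
  creation.
* **Rewiring**: eliminate with probability `(1−ρ)/τ_c`, create with
  `ρ/τ_c` per step, which satisfies detailed balance so each pair's
  stationary occupancy is exactly `ρ` and total spine number is conserved
  without global regulation.  New spines get weight
  `(1 + 0.1·N(0,1))·w_o` (at `rX⁰ = 1` identical to `(1+0.1ζ)/γ`).  The
  per-pair Bernoulli sweep is implemented by exact thinning with bound
  `max(1, elimination multiplier)/τ_c`, so large `τ_c` costs almost
  nothing per step; a dense sweep is used when the bound exceeds 0.05.
  An elimination multiplier (default 1, 5 in the enhanced-elimination
  training protocols) scales only the elimination probability.

Defaults: `η_X = 0.01`, `b_h = 0.1`, `η_ρ = 0.001`, `τ_c = 1e6`,
`σ_w^init = 0.1`.

## Evaluation

* **Bootstrap accuracy** — selectivity groups are assigned from one
  window of `T_o = 1000` steps (arg-max conditional mean rate, ties to the
  lowest state) and scored on the next: a step counts as correct only if
  the own-state group mean *strictly* exceeds every other group mean.
* **Transfer entropy** — `TE = ⟨H(s) − H(s | r, C)⟩`, with the
  conditional posterior computed per output neuron from its connected
  inputs using the *true* tuning parameters, averaged within groups, then
  renormalized over states (an entropy needs a proper distribution) —
  Monte-Carlo over sampled inputs.
* **Model error** — mean squared difference between the true tuning
  matrix and the read-out of the synaptic structure (`Σ c·w`, `Σ c`, or
  mean weight per group), each state row rescaled to RMS `rX⁰` so global
  weight scalings drop out.
* **Connectivity optimality** — the state-averaged divergence
  `I(C_all, C)` between the dense-network group posterior and the one
  obtained from `C`, with the Gaussian noise integrated in closed form
  *inside* the softmax: the per-neuron exponent reduces to
  `Σ_j c_ij θ_{μj}θ_{νj}/σ_j²`.  Two deliberate properties: (i) the group
  average is *not* renormalized over states — renormalizing flips the
  sign of the per-connection information gain and destroys the
  near-linear weight–gain relation in the homogeneous model (verified
  numerically); (ii) the noise-inside-the-softmax integral overestimates
  the Monte-Carlo divergence by roughly a constant factor (~1.4 at unit
  noise) while preserving the ordering of structures (Pearson ≈ 0.8),
  which is what its consumers (hill-climbing, information gain) need.
  Hill-climbing minimizes the divergence by random single-swap descent at
  fixed connection count with restarts; the result is a bound, not a
  certificate.
* **Information capacity** — exact log-binomial `I_C = log C(MN, ρMN)`
  versus `I_w = ρMN·log b`; break-even `b* = exp(H(ρ)/ρ)`, i.e.
  `H(ρ)/(ρ ln 2)` bits per synapse (≈ 5.46 bits at ρ = 0.06).
* **Gradient alignment** — the raw cosine between the wiring-rule update
  and the transfer-entropy gradient direction is reported as computed; on
  selective networks it is near zero rather than positive, because the
  `(1 + log r_Y)` prefactor is negative for every non-winning neuron
  (`r_Y ≪ rY⁰/e`) and the `α(q)/q`, `B(r)/q` normalization terms dominate
  the gradient norm.  Both per-sample and mean-update aggregations are
  available.

## Analytic moment theory

For the Gaussian model the membrane potential
`u_i = Σ_j c_ij (w_ij r_j − w_o)` of a selective and a non-selective
output neuron is approximated as bivariate Gaussian.  The normalized
tuning moments are `μ_θ = μ rX⁰/√(μ²+s²)`, `σ_θ² = s²rX⁰²/(μ²+s²)`
(hence `μ_θ² + σ_θ² = rX⁰²`), where `μ, s` are the mean and standard
deviation of the *unnormalized truncated* tuning distribution — for
truncnorm(1, 1) on [0, ∞): μ ≈ 1.2876, s ≈ 0.7935.  Feeding the
pre-truncation parameters instead biases every moment (the truncated mean
is 29% larger); `truncated_normal_moments` performs the conversion.

The variance expressions are *exact* given Gaussian i.i.d. tuning (we
re-derived them; the error probability follows from the normal tail of
the potential difference, and accuracy uses the independence
approximation `(1−ε_w)^{p−1}`).  The two covariance expressions differ in
kind: the weight-coding covariance keeps only the shared-input-noise
(trial) component, whose exact sampling ensemble drives the distractor
with an independent tuning copy under the same noise; the
connectivity-coding covariance is the full (trial + tuning-heterogeneity)
covariance, realized by sharing the presented tuning.  The Monte-Carlo
moment validation therefore checks each entry in the ensemble in which
its derivation is exact: means and trial covariance against the actual
truncated-normalized generator (whose exact row normalization removes the
tuning-heterogeneity terms), variances and full covariance against the
Gaussian tuning ensemble.  Standard errors come from a jackknife over
tuning draws, which correctly accounts for the hierarchical (tuning ×
trial) sampling.

Two caveats the tests make explicit rather than hide:

* The independence approximation across the `p−1` distractors is crude
  for a full network: distractor potentials are strongly positively
  correlated through the shared input, so the measured bootstrap accuracy
  of a frozen network lies far above `(1−ε_w)^{p−1}` at sparse
  connectivity.  The quantitative analytic-versus-simulation agreement
  (within a few percentage points) is therefore checked on the
  pairwise-potential statistic the formula actually describes, while the
  frozen-network simulations are held to the qualitative claims: the
  connectivity-coding advantage in the sparse regime and its fading with
  density.
* A frozen network additionally *quenches* the wiring disorder, which the
  bootstrap's data-driven selectivity assignment partially compensates;
  this is a second reason measured network accuracy exceeds the annealed
  analytic value.

## Protocols and time compression

A "day" is `1e5` steps at full scale.  The compressed presets used by the
long studies shrink the day (or the environment period `T_2`) tenfold and
keep the full-scale protocols' *dimensionless ratios* fixed rather than
the raw rates:

* dynamic environment: `T_2 = 1e4`, `τ_c/T_2 = 10` (as at full scale),
  learning rates scaled with the compression (`η_X = 0.1`,
  `η_ρ = 0.01`) so learning progress per epoch is preserved.  Twenty
  epochs are run and the first four are excluded from the early-phase
  trend: during the global convergence transient *any* rule's post-switch
  accuracy rises, so including it would conflate ordinary learning with
  the constant-component capture the comparison is about;
* spine protocols: day = `1e4` steps, `τ_c = 3·day` (as at full scale),
  per-step rates unchanged (`η_ρ = 1e-4`), preserving turnover per day;
* the sparse learning comparison runs `5e5` steps with `τ_c = 1e5`, the
  value used in the spine-trace illustrations, giving a few-fold synapse
  turnover over the run.

The training protocol burns in on a control input structure (20
compressed days; the spine-statistics run uses 30 days because its drift
summaries are stationary quantities), switches to a training structure at
day 0, and takes daily connectivity snapshots.  New spines are pairs
absent at day 0 and present at day 2; pre-existing spines are present at
both; survival is presence at a later daily snapshot (rewiring within a
day is deliberately ignored, as transient re-creation is rare).  The
similarity parameter mixes the control structure into the training one;
at κ = 1 the two structures coincide and the training arm reproduces the
control arm exactly.  Training/control comparisons share the seed, so the
burn-in trajectory is identical and differences are purely post-switch.
Whether plasticity stays on during the test phase is configurable; the
default keeps it on (continued exposure).

Spine drift statements concern the surviving cloud: eliminated spines sit
at relative change −1 and are summarized separately by elimination rates
(which decrease steeply with ρ).  Among survivors the drift is positive
below ρ ≈ 0.2 (regression of noise-depressed spines toward their
weight-determined target) and non-positive at saturation (ρ ≥ 0.8), where
the [0, 1] bound caps growth.

## What the generator does and does not emulate

All inputs are synthetic draws from the stated exponential-family world
models; there is no neural recording data anywhere.  Passing tests
demonstrate the internal consistency of the theory and the learning
dynamics under these models — uniform state priors, conditionally
independent inputs, stationary (or piecewise-stationary) tuning.  They do
not show that cortical spine dynamics follow these rules; the spine-level
comparisons are qualitative shape properties (survival versus age,
training effects on cohort stability), not fits to experimental datasets.

## Known limitations

* The closed-form divergence and the analytic accuracy both inherit
  documented approximation error (constant-factor overestimate; crude
  distractor independence).  They are used for orderings and for the
  statistics they exactly describe, never as calibrated absolute values
  for full networks.
* The Poisson family shares the full learning machinery, but the analytic
  moment theory, the closed-form divergence and the alignment diagnostic
  are Gaussian-only.
* `estimate_accuracy` scores states with no assigned neurons as failures;
  with very few output neurons per state this makes the bootstrap
  pessimistic.
* Each connection is binary (at most one synapse per pair) and there is
  no axonal/dendritic geometry or wiring cost.
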