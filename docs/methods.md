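# Methods

## The model

`clfads` fits a sequential variational autoencoder to trial-structured spike
counts x ∈ ℕ^{trials × T × N}.  The decoder is a GRU "generator" rolled out
from an inferred initial condition; its output is read out (optionally through
a low-dimensional factor bottleneck) as log Poisson rates:

    g_0 ~ Q_g0(· | x_1:T)            initial condition (dim = gen_dim)
    b   ~ Q_b (· | x_1:T)            per-trial bias (dim = bias_dim, constant)
    u_t ~ Q_u (· | x_1:T)            optional per-step input (dim = input_dim)
    g_t = GRU(g_{t-1}, [u_t, b])
    f_t = W_fac g_t + b_fac
    r_t = exp(clip(W_rate f_t, ±clamp_log_rate))
    x_t ~ Poisson(r_t)               rates are counts per bin

The per-trial bias is the point of the package.  It is inferred once per
trial by its own bidirectional-GRU encoder and concatenated to the generator
input at every step, so a single set of generator weights parameterizes a
*family* of dynamical systems indexed by a low-dimensional context vector.
With `bias_dim = 0` the model reduces to the standard architecture, in which
condition identity can only be carried by the initial condition — which is
what forces the generator into multi-stable dynamics when the data contain a
family of conditions.

All three posteriors are diagonal Gaussians (encoder final states mapped
linearly to mean and log-std) with standard-normal priors.  Training
maximizes the ELBO

    LL_Poisson(x | r) − κ · [KL(Q_g0 ‖ N(0,I)) + KL(Q_b ‖ N(0,I)) + KL(Q_u ‖ N(0,I))]

with the KL weight κ ramped linearly 0 → 1 over `kl_warmup_steps` optimizer
steps.  The ramp matters: at full KL pressure from step 0 the posteriors
collapse to the prior before the generator can reconstruct anything.  The
objective and fitting defaults follow the published LFADS conventions
(Pandarinath et al. 2018); where the original description leaves details
open, the choices here are declared defaults, not reconstructions.

### GRU convention

    r  = σ(x W_r + h U_r + c_r)
    z  = σ(x W_z + h U_z + c_z)
    h~ = tanh(x W_h + (r∘h) U_h + c_h)
    h' = (1 − z)∘h + z∘h~

so all-zero parameters give the contraction h → h/2.  The new state is a
convex combination of the old state and a tanh output, hence bounded by the
unit box whenever the previous state is.

### Numerical core

There is no GPU path.  The whole model is NumPy; gradients come from
`autograd`, with one deliberate exception: the GRU *sequence* is registered
as a single autograd primitive (`clfads.nn.gru_scan`) whose backward pass is
hand-written backpropagation-through-time.  Collapsing ~10³ traced per-step
operations into one node makes CPU training roughly 5× faster than naive
tracing.  The hand-written VJP is tested against autograd's own gradient of
the equivalent per-step loop to 1e-10 (`test_model.py`).

Training runs in float32 (parameters, data, Adam state); analyses that feed
eigendecompositions or Newton iterations (fixed points, Jacobians, speed
shifts) cast the model to float64 first (`GeneratorModel.astype`).  Log
rates are clamped to ±10 before exponentiation — far outside plausible
per-bin log counts, so the clamp is inactive except as overflow protection.

### Training defaults

| parameter | default | why |
|---|---|---|
| optimizer | Adam, lr 1e-3 (pendulum runs use 3e-3) | standard for this model class |
| lr schedule | ×0.95 on validation plateau (patience 6 epochs) | conventional LFADS recipe |
| KL warm-up | 200–400 steps | posterior collapse otherwise |
| gradient clip | global norm 200 | conventional LFADS value |
| batching | shuffled minibatches, epoch-indexed seed | bitwise reproducibility |
| early stop | patience 25 epochs on validation loss | returns best-validation weights |

Validation loss is the posterior-*mean* ELBO at κ = 1 (no sampling noise), so
model selection is deterministic.  `train` is bitwise reproducible given the
seeds and never returns parameters worse (in validation loss) than the
initialization.

## The synthetic benchmark

A family of damped pendulums, m l² θ̈ + d θ̇ + m g l sin θ = 0 with m = 1,
l = 5, d = 1, and gravity g varying across conditions (default grid 0.5 to
4.5 in steps of 0.5).  Gravity sets the oscillation frequency
(≈ √(g/l − (d/2ml²)²)/2π in the small-angle limit), so condition identity is
expressed purely in the *dynamics* — the situation the contextual bias is
designed for.  Each trial starts at rest from θ₀ ~ U[0.3, 1.2] rad and is
integrated with fixed-step RK4; halving dt changes the endpoint of a default
trial by < 1e-3 (tested).

The 2-D state s = (θ, θ̇) drives N Poisson neurons through a clipped-linear
map, counts ~ Poisson(max(Ks + μ, 0)), with K_ij ~ N(0, 2²) and
μ_i ~ U[2, 8] drawn once per dataset and recorded in provenance.  These
scales put the typical drive at a few counts per bin with modulation of the
same order — clearly resolvable but far from noise-free.  Declared defaults:
dt = 0.05 s, the θ₀ range, and the (K, μ) distributions are choices of this
package; only m, l, d, the gravity grid, the 192-neuron default and the
125 × 300-sample trial format are taken from the study design this benchmark
reproduces.

Two controlled corruptions support the session-level analyses:

* `inject_drift` adds `magnitude(acquisition_index) · drift_vector` to the
  pre-clip drive, i.e. additive firing-rate drift over a session.  Each
  channel has its own Poisson stream, so channels outside the drift support
  are bit-identical to the undrifted draw — convenient for controls.
* `inject_speed_variation` integrates trial i with time-step dt·s_i, so the
  same state path is traversed s_i times faster in fixed wall time.  True
  factors are stored per trial.

What the generator does **not** emulate about real recordings: non-Poisson
dispersion, electrode cross-talk, within-trial non-stationarity, behavioral
variability beyond the injected speed factor, and any nonlinearity in the
state-to-rate map.  Passing tests on this benchmark show the machinery is
correct and that contextual structure is recoverable under Poisson noise;
they do not certify performance on cortical data.

## Reverse engineering

Fixed points of the autonomous map F(g) = GRU(g, [0, b]) are found by
descending q(g) = ½‖F(g) − g‖² with Adam from many starts in parallel
(default 256 per trial: states subsampled from the trial's posterior-mean
rollout plus N(0, 0.5²) perturbations), then Newton-polishing the surviving
candidates on F(g) − g = 0 and accepting residuals ‖F(g*) − g*‖ below
1e-6·√gen_dim.  Points within `dedupe_radius = 0.1` (state units) merge to
the lowest-residual representative.  The residual of every accepted point is
re-verified outside the optimizer (tested).  An empty result is a warning,
not an error — slow points that never reach tolerance are a real outcome.

Jacobians are exact reverse-mode derivatives of the step map; a central
finite-difference cross-check (h = 1e-5) agrees to 1e-4 on trained models
(tested).  Discrete-time eigenvalues λ convert to oscillation frequency
|arg λ| / (2π·bin_width) Hz and per-step decay |λ|; each conjugate pair is
reported once, with the rotation plane given by the orthonormalized real and
imaginary parts of one eigenvector.  `dominant_mode` picks the mode nearest
a target frequency, breaking ties toward slower decay (larger |λ|).

Plane similarity between trials is the fraction of one trial's
fixed-point-relative trajectory variance captured by orthogonal projection
onto another trial's eigen-plane, ‖XP‖²_F / ‖X‖²_F ∈ [0, 1].  The similarity
matrix is symmetrized by averaging with its transpose before spectral
embedding (normalized graph Laplacian; coordinates are the random-walk
eigenvectors of the 2 smallest nonzero eigenvalues, with a
permutation-invariant sign convention).  A disconnected similarity graph is
an error naming the components rather than a silent block-wise embedding.

## Bias-space operations

**Drift correction.**  With early/late trial sets (defaults: first and last
quartiles by acquisition index), b_early and b_late are the set means of the
training-partition bias posteriors; every early bias is shifted by
b_late − b_early, and the same construction is applied to initial
conditions.  Inputs u are never touched.  The correction is exactly
idempotent.  `augment_trials` re-rolls the generator with corrected (b, g0)
and the original u posterior means, and unions the corrected-early rates
with the unmodified late-trial inferred rates — a decoder-training corpus
that is both large and late-session-matched.

**Speed axis.**  For a speed factor α, `solve_speed_shift` finds the bias
shift Δb minimizing Σ_{i,t} ‖F(g_it, b_i + Δb) − g_it − α(F(g_it, b_i) −
g_it)‖², i.e. the shift that scales one-step updates by α over the visited
states.  The problem is smooth and low-dimensional (bias_dim ≤ 10), so it is
solved full-batch by L-BFGS with exact autograd gradients, warm-starting
each α from the previous one; on a linear generator the solution matches the
normal equations to 1e-5 (tested), and the returned shift is never worse
than Δb = 0.  The default α grid is {0.7, 0.8, 0.9, 1.1, 1.2, 1.3}: a
regular grid on [0.7, 1.3] with α = 1 excluded (the stated grid of "7 points
excluding 1" is not realizable at step 0.1; six is the consistent count).
The common speed axis is the top left singular vector of the
bias_dim × n_α shift matrix, sign-fixed so the largest-α shift projects
positively — speed increases along +axis.  Sorting trials by bᵢᵀ·axis orders
them by traversal speed.

Two practical refinements in the packaged speed experiment
(`experiments.speed_sorting_experiment`): the shift is solved over each
trial's *transient* states (first half of the trial) because decayed
near-equilibrium states barely move and therefore do not constrain Δb; and
the axis orientation is verified functionally — one-step update norms are
evaluated with biases displaced by ± one cloud-scale probe along the axis,
and the axis is flipped if + slows the dynamics.  The solved shifts are
small (‖Δb‖ ~ 1–3% of the bias-cloud scale) — the α-objective is a
compromise over all trials — so it is the shift *direction* that carries
the information; the SVD sign convention alone can misfire at that
magnitude, which the functional check repairs without using any ground
truth.

**Drift axis.**  The unit regression direction of centered biases on the
centered acquisition index — the direction in bias space most correlated
with session time; translation-invariant by construction.

## Design choices that were genuinely open

* **Separate encoders** for g0 and b (same architecture, independent
  weights): the bias is described as having its own probabilistic encoder,
  and sharing would couple the two posteriors through a single feature
  space.
* **u_t prior**: i.i.d. standard normal per step.  An autoregressive prior
  is a plausible alternative but adds a correlation-time hyperparameter; the
  pendulum study runs without u entirely (`input_dim = 0`), matching the
  autonomous ground truth.
* **No controller RNN**: the input encoder reads the whole spike train
  bidirectionally rather than closing the loop through the generator, which
  matches the bias encoder's design and keeps the generator purely
  autonomous at analysis time.
* **Rate readout offset off by default** (`use_rate_readout_offset`): the
  generative equations expose no per-channel offset; a config switch enables
  it for data with strong baseline heterogeneity.
* **Factors bottleneck optional**: `factors_dim = None` means factors equal
  generator states through a learned (initially near-identity-scaled)
  linear map; setting `factors_dim < gen_dim` reproduces the bottlenecked
  variant.

## The packaged study conditions

The shipped tests train real models, scaled to a single CPU:

* **Pendulum-family dynamics** (contextual vs standard): 8 conditions × 30
  trials × 150 bins × 64 neurons, 64-unit generator, bias_dim 4 (and 0 for
  the bias-free contrast), ~250 epochs.
* **Session-drift re-enactment**: 3 conditions × 30 trials of 60 bins × 48
  neurons at sparse counts (~1.5 counts/bin, the regime of intracortical
  threshold crossings, where decoder training-set size genuinely matters),
  with a mid-session step disturbance of the baseline drive on half the
  channels — a discrete electrode disturbance, the case for which the
  mean-shift correction is the exact transport.  All pre-disturbance trials
  are corrected; decoders are compared on the session's final quarter;
  5 replicate sessions.  The decoder gain from augmentation is small and
  positive on average at this scale, and its per-session sign is noisy —
  the replicate majority is the robust readout.
* **Speed sorting**: 1 condition × 80 trials of 100 bins × 48 neurons,
  hidden per-trial time-rescaling factors in [0.7, 1.3]; 5 replicate fits.

The acceptance script (`scripts/acceptance.py`) runs the same pipelines at
the same scale from a single `--seed` (about 13 minutes on one CPU; three
drift sessions instead of five).  These sizes are
this package's declared study conditions for the synthetic benchmark; the
full-scale format (125 trials of 300 samples, 192 neurons, 9-gravity grid)
remains the generator default for users.

## Known limitations

* Poisson observations only; no Gaussian or zero-inflated variants.
* The per-trial bias is constant within a trial; piecewise-constant context
  (task phases) is out of scope.
* Fixed-point search is local: it characterizes the dynamics only in the
  region seeded by the initial states.
* Single-threaded CPU implementation; fitting hundreds of channels at
  thousands of trials is feasible but slow (hours, not minutes).
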