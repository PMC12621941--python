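# clfads — contextual latent dynamics from spike trains

`clfads` fits a sequential variational autoencoder to trial-structured spike
counts in which an RNN "generator" rolls latent dynamics out from an inferred
initial condition and reads them out as Poisson firing rates.  Its defining
feature is a **per-trial contextual bias**: a low-dimensional vector `b`
(dim ≤ 10) inferred once per trial by its own encoder and fed to the
generator as a constant input at every time step,

    g_t = GRU(g_{t-1}, [u_t, b]),    f_t = W_fac g_t + b_fac,
    r_t = exp(W_rate f_t),           x_t ~ Poisson(r_t).

The bias turns one generator into a *family* of dynamical systems indexed by
`b`.  When trial-to-trial structure (task condition, slow recording drift,
behavioral speed) is absorbed by the bias, the per-trial dynamics stay
simple — typically a single fixed point that moves smoothly with `b` —
instead of the multi-stable landscapes a bias-free model must build to store
condition identity in its initial condition.  Simple dynamics are dynamics
you can reverse-engineer, so the package ships the full toolkit:

* **Model + training** — bidirectional-GRU encoders for `g0`, `b` and an
  optional time-varying input `u_t`; Poisson ELBO with KL warm-up; Adam with
  plateau decay and early stopping; bit-reproducible from seeds.  Pure
  NumPy/autograd with a hand-written BPTT core — no GPU required.
* **Reverse engineering** — batched fixed-point search for
  `F(g*, u=0, b) ≈ g*` with Newton polishing; exact Jacobians; eigenvalues
  as oscillation frequency (Hz) and per-step decay; eigen-plane similarity
  between trials and its 2-D spectral embedding.
* **Bias-space operations** — session-drift correction
  `b_corrected = b − b_early + b_late` (and the same shift for initial
  conditions) with generator re-rollout to augment decoder training data;
  a speed axis solved from `argmin_Δb Σ‖F(g, b+Δb) − g − α(F(g, b) − g)‖²`
  over a grid of speed factors α, for sorting trials by traversal speed.
* **Benchmark** — a fully synthetic test bed: a family of damped pendulums
  (`m l² θ̈ + d θ̇ + m g l sin θ = 0`, gravity varies per condition) observed
  through Poisson neurons via `counts ~ Poisson(max(Ks + μ, 0))`, plus
  controlled drift and per-trial time-rescaling corruptions with stored
  ground truth.

Intended users: systems/computational neuroscientists analyzing
multi-electrode spike recordings (motor cortex, iBCI) who want single-trial
latent dynamics they can interpret mechanically.

## Worked example

Two pendulum conditions (gravity 1.0 vs 4.0) observed through 32 Poisson
neurons; fit a contextual model, then reverse-engineer it:

```python
import numpy as np
import clfads as cl

pend = cl.PendulumConfig(gravity_values=(1.0, 4.0),
                         n_trials_per_condition=40, n_steps=100, seed=1)
emb = cl.EmbeddingConfig(n_neurons=32, seed=2)
train, valid, test = cl.make_pendulum_dataset(pend, emb)

cfg = cl.ModelConfig(n_channels=32, gen_dim=32, bias_dim=2, encoder_dim=24,
                     bin_width=pend.dt, dtype="float32", seed=0)
tc = cl.TrainConfig(max_epochs=300, batch_size=16, kl_warmup_steps=300,
                    learning_rate=3e-3, seed=0)
model, report = cl.train(train, valid, cfg, tc)
print(f"validation Poisson LL/bin: {report.epochs[report.best_epoch]['valid_ll_per_bin']:.3f}")

m = model.astype(np.float64)           # analyses run in float64
post, roll = cl.infer(test, m)

for g in (1.0, 4.0):                   # one fixed point per trial; its
    i = int(np.where(test.condition_label == g)[0][0])   # linearization
    starts = cl.default_initial_states(roll.g[i], n_starts=64, seed=i)
    recs = cl.find_fixed_points(m, post.b_mean[i], starts)
    modes = [md for md in cl.eigen_modes(recs[0].jacobian, cfg.bin_width)
             if md.frequency > 0]
    dom = max(modes, key=lambda md: md.decay)
    print(f"g={g}: {len(recs)} fixed point(s), dominant mode "
          f"{dom.frequency:.3f} Hz (decay {dom.decay:.3f})")
```

Output of this exact script (a few minutes on one CPU):

```
validation Poisson LL/bin: -2.112
g=1.0: 1 fixed point(s), dominant mode 0.065 Hz (decay 0.942)
g=4.0: 1 fixed point(s), dominant mode 0.233 Hz (decay 0.928)
```

Reading it: each trial's conditioned dynamics implement exactly one fixed
point, and the linearized oscillation frequency at that fixed point tracks
gravity.  The small-angle ground-truth frequencies are 0.071 Hz (g=1) and
0.142 Hz (g=4): the slow condition is recovered almost exactly and the fast
one is over-estimated at this small training budget, but the ordering — the
contextual signature — is unambiguous.  At the scale the test suite uses
(8 conditions, 64 neurons, 64-unit generator) the rank correlation between
gravity and recovered frequency across conditions exceeds 0.9.

The same workflow is available from the shell:

```bash
clfads simulate --gravity 1.0 --gravity 4.0 --n-trials 20 --n-steps 80 \
       --n-neurons 32 --out data/pend
clfads train --data data/pend.train.h5 --valid data/pend.valid.h5 --out run/
clfads fixed-points --data data/pend.test.h5 --model run/model.h5 --out run/fps.h5
clfads modes --fixed-points run/fps.h5 --bin-width 0.05 --out run/modes.csv
```

(plus `infer`, `augment`, `speed-axis`, and `run` for the whole pipeline
from one YAML config; every command writes a `manifest.json` recording the
effective configuration, seeds and input checksums).

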