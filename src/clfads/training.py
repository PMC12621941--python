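"""ELBO training with KL warm-up, plateau LR decay and early stopping.

The optimizer is Adam on the flattened parameter tree, with gradient-norm
clipping.  The KL weight ramps linearly from 0 to 1 over
``kl_warmup_steps`` optimizer steps — without the ramp the posterior
collapses to the prior before the generator learns to reconstruct anything.
Validation loss (posterior-mean ELBO at full KL weight) drives both the
learning-rate schedule and early stopping; the parameters returned are those
of the best validation epoch.

Everything is deterministic given the seeds: minibatch order uses an
epoch-indexed seed and the reparameterization noise a step-indexed one.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from .containers import TrialSet
from .model import (GeneratorModel, LatentRollout, ModelConfig,
                    PosteriorParams, elbo_loss, elbo_terms)

__all__ = ["TrainConfig", "TrainReport", "train", "infer", "TrainingError"]


class TrainingError(RuntimeError):
    """Non-finite loss or gradients during fitting."""


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 0.95
    lr_patience: int = 6          # epochs without validation improvement
    kl_warmup_steps: int = 200    # optimizer steps for the 0 -> 1 KL ramp
    batch_size: int = 64
    max_epochs: int = 120
    early_stop_patience: int = 25
    grad_clip_norm: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.lr_decay, self.batch_size,
               self.max_epochs + 1, self.early_stop_patience,
               self.grad_clip_norm) <= 0 or self.kl_warmup_steps < 0:
            raise ValueError("invalid training configuration")


@dataclasses.dataclass
class TrainReport:
    epochs: list = dataclasses.field(default_factory=list)
    best_epoch: int = -1
    best_valid_loss: float = np.inf
    wall_time_s: float = 0.0

    def history(self, key: str) -> np.ndarray:
        return np.array([e[key] for e in self.epochs])


def _spikes_f(trials: TrialSet, dtype) -> np.ndarray:
    return np.asarray(trials.spikes, dtype=dtype)


def train(train_set: TrialSet, valid_set: TrialSet,
          model_cfg: ModelConfig, train_cfg: TrainConfig | None = None,
          callback=None) -> tuple[GeneratorModel, TrainReport]:
    """Fit a model to `train_set`, monitoring `valid_set`.

    Returns the model restored to its best-validation parameters and a
    per-epoch report.  ``max_epochs=0`` returns the freshly initialized
    model untouched.
    """
    tc = train_cfg or TrainConfig()
    if train_set.n_channels != valid_set.n_channels \
            or train_set.bin_width != valid_set.bin_width:
        raise ValueError("train/valid sets must share channels and bin width")
    cfg = model_cfg
    model = GeneratorModel(cfg)
    report = TrainReport()
    if tc.max_epochs == 0:
        report.best_epoch = -1
        return model, report

    t_start = time.time()
    dtype = model.dtype
    x_train = _spikes_f(train_set, dtype)
    x_valid = _spikes_f(valid_set, dtype)
    n = x_train.shape[0]

    flat, unflatten = flatten(model.params)
    flat = flat.copy()
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    lr = tc.learning_rate
    step = 0

    def loss_flat(fp, batch, klw, eps):
        return elbo_loss(unflatten(fp), cfg, batch, klw, eps)

    vg = value_and_grad(loss_flat)

    def draw_eps(rng, B, T):
        eps = {"g0": rng.standard_normal((B, cfg.gen_dim)).astype(dtype)}
        if cfg.bias_dim > 0:
            eps["b"] = rng.standard_normal((B, cfg.bias_dim)).astype(dtype)
        if cfg.input_dim > 0:
            eps["u"] = rng.standard_normal((B, T, cfg.input_dim)).astype(dtype)
        return eps

    best_flat = flat.copy()
    best_valid = np.inf
    best_epoch = -1
    epochs_since_best = 0
    epochs_since_lr_drop = 0

    # epoch 0 baseline validation (initialized model)
    valid0 = elbo_terms(unflatten(flat), cfg, x_valid, 1.0, None)

    for epoch in range(tc.max_epochs):
        order = np.random.default_rng(tc.seed * 100003 + epoch).permutation(n)
        train_losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            batch = x_train[idx]
            klw = min(1.0, step / tc.kl_warmup_steps) if tc.kl_warmup_steps > 0 else 1.0
            eps = draw_eps(np.random.default_rng(tc.seed * 911 + step + 1),
                           batch.shape[0], batch.shape[1])
            val, g = vg(flat, batch, klw, eps)
            if not np.isfinite(val):
                raise TrainingError(
                    f"non-finite training loss at step {step}; "
                    "last finite checkpoint retained")
            gnorm = float(np.linalg.norm(g))
            if gnorm > tc.grad_clip_norm:
                g = g * (tc.grad_clip_norm / gnorm)
            step += 1
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** step)
            vhat = v / (1 - beta2 ** step)
            flat = flat - lr * mhat / (np.sqrt(vhat) + eps_adam)
            train_losses.append(float(val))

        valid = elbo_terms(unflatten(flat), cfg, x_valid, 1.0, None)
        entry = {"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                 "valid_loss": valid["loss"],
                 "valid_ll_per_bin": valid["ll_per_bin"],
                 "kl_weight": min(1.0, step / tc.kl_warmup_steps)
                 if tc.kl_warmup_steps > 0 else 1.0,
                 "lr": lr}
        for k, val_ in valid.items():
            if k.startswith("kl_"):
                entry[f"valid_{k}"] = val_
        report.epochs.append(entry)
        if callback is not None:
            callback(entry)

        if valid["loss"] < best_valid:
            best_valid = valid["loss"]
            best_flat = flat.copy()
            best_epoch = epoch
            epochs_since_best = 0
            epochs_since_lr_drop = 0
        else:
            epochs_since_best += 1
            epochs_since_lr_drop += 1
            if epochs_since_lr_drop >= tc.lr_patience:
                lr *= tc.lr_decay
                epochs_since_lr_drop = 0
            if epochs_since_best >= tc.early_stop_patience:
                break

    report.best_epoch = best_epoch
    report.best_valid_loss = float(min(best_valid, valid0["loss"]))
    report.wall_time_s = time.time() - t_start
    if best_valid <= valid0["loss"]:
        model.params = unflatten(best_flat)
    # else: initialization was never improved upon; keep initial parameters
    return model, report


def infer(trials: TrialSet, model: GeneratorModel
          ) -> tuple[PosteriorParams, LatentRollout]:
    """Posterior-mean reconstruction pass.

    Encodes, takes posterior means (no sampling) and rolls the generator
    out; ``rollout.rates`` are the denoised single-trial firing rates used
    for downstream decoding.
    """
    post = model.encode(trials)
    g0, b, u = model.sample_posterior(post, seed=None)
    n_steps = trials.n_bins if hasattr(trials, "n_bins") else np.asarray(trials).shape[1]
    roll = model.rollout(g0, b if model.cfg.bias_dim > 0 else None,
                         u, n_steps=n_steps)
    return post, roll


def constant_rate_baseline_ll_per_bin(train_set: TrialSet,
                                      eval_set: TrialSet) -> float:
    """Per-bin Poisson log likelihood of the best constant-rate model.

    The per-channel mean count over the training partition is the
    maximum-likelihood constant rate; a fitted dynamics model should beat
    this floor on held-out data.
    """
    from .model import poisson_log_likelihood
    rate = np.asarray(train_set.spikes, dtype=np.float64).mean(axis=(0, 1))
    rate = np.maximum(rate, 1e-10)
    rates = np.broadcast_to(rate, eval_set.spikes.shape)
    ll = poisson_log_likelihood(eval_set.spikes, rates)
    return float(np.mean(ll) / (eval_set.n_bins * eval_set.n_channels))
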