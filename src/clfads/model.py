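"""The contextual-LFADS generative model.

A sequential variational autoencoder for binned spike counts.  Per trial i,
the generative process is

    g_0 ~ Q_g0(. | x_1:T)                 inferred initial condition
    b   ~ Q_b (. | x_1:T)                 inferred per-trial bias (constant)
    u_t ~ Q_u (. | x_1:T)                 optional time-varying input
    g_t = GRU(g_{t-1}, [u_t, b])          generator step
    f_t = W_fac g_t + b_fac               factors
    r_t = exp(W_rate f_t [+ b_rate])      Poisson rates (counts / bin)
    x_t ~ Poisson(r_t)

The bias b is the contextual modification: a low-dimensional vector inferred
once per trial and concatenated to the generator input at *every* step, so a
single generator parameterizes a family of dynamical systems indexed by b.
Setting ``bias_dim=0`` recovers the standard model in which condition
identity must be carried by the initial condition alone.

All encoders are bidirectional GRUs whose final states map linearly to
(mean, log-std) of diagonal Gaussian posteriors; priors are standard normal.
Training maximizes the ELBO: Poisson log likelihood minus KL terms.

Functions here are pure in the parameter dict so `autograd` can
differentiate them; :class:`GeneratorModel` is the stateful wrapper users
interact with.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import autograd.numpy as anp
import h5py
import numpy as np
from scipy.special import gammaln

from .nn import gru_cell, gru_scan, init_gru

__all__ = [
    "ModelConfig",
    "PosteriorParams",
    "LatentRollout",
    "GeneratorModel",
    "poisson_log_likelihood",
    "kl_to_standard_normal",
    "elbo_terms",
    "elbo_loss",
]


@dataclasses.dataclass
class ModelConfig:
    """Architecture and observation settings.

    Parameters
    ----------
    n_channels
        Number of observed spike channels.
    gen_dim
        Generator (GRU) state size.
    bias_dim
        Dimension of the per-trial bias; 0 disables it (standard model).
        Kept small (<= 10) so the bias is an interpretable embedding.
    input_dim
        Dimension of the optional time-varying input u_t; 0 disables it.
    factors_dim
        Factor bottleneck size; None means no bottleneck (equals gen_dim).
    encoder_dim
        Hidden size of each bidirectional encoder direction.
    bin_width
        Seconds per time bin; used to convert eigenvalue angles to Hz.
    clamp_log_rate
        Log rates are clamped to +/- this bound before exponentiation.
    init_posterior_log_std
        Initial bias of every log-std readout (std ~ exp of this).
    dtype
        Parameter dtype; float32 is adequate for fitting, analyses can cast
        to float64 (see ``GeneratorModel.astype``).
    """

    n_channels: int
    gen_dim: int = 64
    bias_dim: int = 4
    input_dim: int = 0
    factors_dim: int | None = None
    encoder_dim: int = 48
    bin_width: float = 0.05
    use_rate_readout_offset: bool = False
    clamp_log_rate: float = 10.0
    init_posterior_log_std: float = -1.0
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_channels, self.gen_dim, self.encoder_dim) < 1:
            raise ValueError("n_channels, gen_dim and encoder_dim must be >= 1")
        if self.bias_dim < 0 or self.input_dim < 0:
            raise ValueError("bias_dim and input_dim must be >= 0")
        if self.factors_dim is not None and self.factors_dim < 1:
            raise ValueError("factors_dim must be >= 1 (or None)")
        if self.bias_dim > self.gen_dim:
            import warnings
            warnings.warn("bias_dim exceeds gen_dim; the bias is meant to be "
                          "a low-dimensional context", stacklevel=2)

    @property
    def n_factors(self) -> int:
        return self.gen_dim if self.factors_dim is None else self.factors_dim

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


@dataclasses.dataclass
class PosteriorParams:
    """Per-trial Gaussian posterior parameters (diagonal)."""

    g0_mean: np.ndarray
    g0_std: np.ndarray
    b_mean: np.ndarray
    b_std: np.ndarray
    u_mean: np.ndarray | None = None
    u_std: np.ndarray | None = None

    def __post_init__(self):
        for s in (self.g0_std, self.b_std, self.u_std):
            if s is not None and s.size and not np.all(np.asarray(s) > 0):
                raise ValueError("posterior std must be strictly positive")


@dataclasses.dataclass
class LatentRollout:
    """Generator states, factors and rates for a batch of trials."""

    g: np.ndarray            # (B, T, gen_dim)
    f: np.ndarray            # (B, T, n_factors)
    rates: np.ndarray        # (B, T, n_channels), counts per bin
    g0: np.ndarray
    b: np.ndarray
    u: np.ndarray | None = None


# ---------------------------------------------------------------------------
# parameter initialization

def init_params(cfg: ModelConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    dt = np.dtype(cfg.dtype).type
    E, G, N = cfg.encoder_dim, cfg.gen_dim, cfg.n_channels
    F = cfg.n_factors

    def linear(nin, nout, scale=None):
        scale = scale if scale is not None else 1.0 / np.sqrt(nin)
        return {"W": rng.normal(0, scale, (nin, nout)).astype(dt),
                "c": np.zeros(nout, dtype=dt)}

    def posterior_readout(nin, d):
        ro = linear(nin, 2 * d, scale=0.1 / np.sqrt(nin))
        ro["c"][d:] = cfg.init_posterior_log_std
        return ro

    params: dict[str, Any] = {
        "enc_g0_f": init_gru(N, E, rng, dt),
        "enc_g0_b": init_gru(N, E, rng, dt),
        "ro_g0": posterior_readout(2 * E, G),
        "gen": init_gru(cfg.input_dim + cfg.bias_dim, G, rng, dt),
        "fac": linear(G, F),
        "rate": linear(F, N, scale=0.1 / np.sqrt(F)),
    }
    if cfg.bias_dim > 0:
        params["enc_b_f"] = init_gru(N, E, rng, dt)
        params["enc_b_b"] = init_gru(N, E, rng, dt)
        params["ro_b"] = posterior_readout(2 * E, cfg.bias_dim)
    if cfg.input_dim > 0:
        params["enc_u_f"] = init_gru(N, E, rng, dt)
        params["enc_u_b"] = init_gru(N, E, rng, dt)
        params["ro_u"] = posterior_readout(2 * E, cfg.input_dim)
    if not cfg.use_rate_readout_offset:
        params["rate"]["c"] = np.zeros(0, dtype=dt)  # sentinel: no offset
    return params


# ---------------------------------------------------------------------------
# pure forward functions (autograd-differentiable in `params`)

def _bidir_final(pf, pb, x, x_rev):
    B = x.shape[0]
    E = pf["Uh"].shape[0]
    h0 = anp.zeros((B, E), dtype=x.dtype)
    hf = gru_scan(pf["W"], pf["Urz"], pf["Uh"], pf["c"], x, h0)[:, -1]
    hb = gru_scan(pb["W"], pb["Urz"], pb["Uh"], pb["c"], x_rev, h0)[:, -1]
    return anp.concatenate([hf, hb], axis=1)


def _bidir_seq(pf, pb, x, x_rev):
    B, T, _ = x.shape
    E = pf["Uh"].shape[0]
    h0 = anp.zeros((B, E), dtype=x.dtype)
    hf = gru_scan(pf["W"], pf["Urz"], pf["Uh"], pf["c"], x, h0)
    hb = gru_scan(pb["W"], pb["Urz"], pb["Uh"], pb["c"], x_rev, h0)[:, ::-1]
    return anp.concatenate([hf, hb], axis=2)


def _split_mean_logstd(e, readout):
    out = anp.dot(e, readout["W"]) + readout["c"]
    d = out.shape[-1] // 2
    return out[..., :d], out[..., d:]


def encode_raw(params: dict, cfg: ModelConfig, spikes) -> dict:
    """Posterior (mean, log-std) for g0, b and u; pure in `params`.

    `spikes` is a float array (B, T, N).  Returns a dict with keys
    g0_mean, g0_logstd, b_mean, b_logstd [, u_mean, u_logstd].
    """
    x = spikes
    x_rev = np.ascontiguousarray(np.asarray(x)[:, ::-1])
    out = {}
    e = _bidir_final(params["enc_g0_f"], params["enc_g0_b"], x, x_rev)
    out["g0_mean"], out["g0_logstd"] = _split_mean_logstd(e, params["ro_g0"])
    if cfg.bias_dim > 0:
        eb = _bidir_final(params["enc_b_f"], params["enc_b_b"], x, x_rev)
        out["b_mean"], out["b_logstd"] = _split_mean_logstd(eb, params["ro_b"])
    if cfg.input_dim > 0:
        eu = _bidir_seq(params["enc_u_f"], params["enc_u_b"], x, x_rev)
        out["u_mean"], out["u_logstd"] = _split_mean_logstd(eu, params["ro_u"])
    return out


def generator_step(params: dict, cfg: ModelConfig, g, u=None, b=None):
    """One step of the conditioned generator, F(g, u, b).

    External input is the concatenation (u, b); omitted parts must match the
    configured dimensions.  Differentiable in everything via autograd.
    """
    parts = []
    if cfg.input_dim > 0:
        if u is None:
            raise ValueError("model expects a time-varying input u")
        parts.append(u)
    if cfg.bias_dim > 0:
        if b is None:
            raise ValueError("model expects a per-trial bias b")
        parts.append(b)
    if parts:
        x = parts[0] if len(parts) == 1 else anp.concatenate(parts, axis=-1)
    else:
        x = anp.zeros(g.shape[:-1] + (0,), dtype=np.result_type(np.float64))
    if anp.shape(x)[-1] != cfg.input_dim + cfg.bias_dim:
        raise ValueError(
            f"generator input has dim {anp.shape(x)[-1]}, expected "
            f"{cfg.input_dim + cfg.bias_dim}")
    return gru_cell(params["gen"], x, g)


def _gen_input_seq(cfg: ModelConfig, B, T, b, u, dtype):
    """(B, T, input_dim + bias_dim) generator input sequence."""
    parts = []
    if cfg.input_dim > 0:
        parts.append(u)
    if cfg.bias_dim > 0:
        bseq = anp.repeat(anp.reshape(b, (B, 1, cfg.bias_dim)), T, axis=1)
        parts.append(bseq)
    if not parts:
        return np.zeros((B, T, 0), dtype=dtype)
    return parts[0] if len(parts) == 1 else anp.concatenate(parts, axis=2)


def rollout_raw(params: dict, cfg: ModelConfig, g0, b=None, u=None,
                n_steps: int | None = None):
    """Iterate the generator from g0; returns (g_seq, f_seq, log_rates).

    Pure in `params`/latents, so usable inside the ELBO and directly
    differentiable.  `n_steps` defaults to u's length and must be given when
    there is no u.
    """
    B = anp.shape(g0)[0]
    if n_steps is None:
        if u is None:
            raise ValueError("n_steps required when no input sequence is given")
        n_steps = anp.shape(u)[1]
    # .dtype works for both raw arrays and autograd boxes (asarray would
    # wrap a box into an object scalar)
    dtype = params["fac"]["W"].dtype
    if n_steps == 0:
        z = np.zeros((B, 0, 0), dtype=dtype)
        return (np.zeros((B, 0, cfg.gen_dim), dtype=dtype),
                np.zeros((B, 0, cfg.n_factors), dtype=dtype),
                np.zeros((B, 0, cfg.n_channels), dtype=dtype))
    x_seq = _gen_input_seq(cfg, B, n_steps, b, u, dtype)
    p = params["gen"]
    g_seq = gru_scan(p["W"], p["Urz"], p["Uh"], p["c"], x_seq, g0)
    f_seq = anp.dot(g_seq, params["fac"]["W"]) + params["fac"]["c"]
    log_r = anp.dot(f_seq, params["rate"]["W"])
    if cfg.use_rate_readout_offset:
        log_r = log_r + params["rate"]["c"]
    log_r = anp.clip(log_r, -cfg.clamp_log_rate, cfg.clamp_log_rate)
    return g_seq, f_seq, log_r


# ---------------------------------------------------------------------------
# likelihood / divergence (closed forms; autograd-safe)

def poisson_log_likelihood(spikes, rates) -> np.ndarray:
    """Poisson log likelihood per trial: sum_t,n [x log r - r - log x!].

    `rates` are expected counts per bin; returns shape (B,).
    """
    x = np.asarray(spikes, dtype=np.float64)
    logfact = gammaln(x + 1.0)
    ll = x * anp.log(rates) - rates - logfact
    return anp.sum(anp.reshape(ll, (x.shape[0], -1)), axis=1)


def _poisson_ll_from_log_rates(x, log_r, logfact):
    ll = x * log_r - anp.exp(log_r) - logfact
    return anp.sum(anp.reshape(ll, (x.shape[0], -1)), axis=1)


def kl_to_standard_normal(mean, std) -> np.ndarray:
    """KL( N(mean, diag std^2) || N(0, I) ) per row, summed over the last axis
    (and any middle axes): sum 0.5 (mean^2 + std^2 - 1 - 2 log std)."""
    kl = 0.5 * (mean ** 2 + std ** 2 - 1.0) - anp.log(std)
    B = anp.shape(mean)[0]
    return anp.sum(anp.reshape(kl, (B, -1)), axis=1)


# ---------------------------------------------------------------------------
# ELBO

def sample_posterior(post: dict, eps: dict | None):
    """Reparameterized samples; `eps` maps name -> standard-normal array.
    eps=None (mean mode) returns posterior means."""
    out = {}
    for name in ("g0", "b", "u"):
        if f"{name}_mean" not in post:
            continue
        m = post[f"{name}_mean"]
        if eps is None:
            out[name] = m
        else:
            out[name] = m + eps[name] * anp.exp(post[f"{name}_logstd"])
    return out


def elbo_loss(params: dict, cfg: ModelConfig, spikes, kl_weight: float,
              eps: dict | None, _logfact=None):
    """Scalar training loss: mean over trials of -LL + kl_weight * sum KL."""
    x = spikes
    B, T, _ = x.shape
    logfact = gammaln(np.asarray(x, dtype=np.float64) + 1.0) \
        if _logfact is None else _logfact
    post = encode_raw(params, cfg, x)
    z = sample_posterior(post, eps)
    _, _, log_r = rollout_raw(params, cfg, z["g0"], z.get("b"), z.get("u"),
                              n_steps=T)
    ll = _poisson_ll_from_log_rates(x, log_r, logfact)
    kl = 0.0
    for name in ("g0", "b", "u"):
        if f"{name}_mean" in post:
            kl = kl + kl_to_standard_normal(post[f"{name}_mean"],
                                            anp.exp(post[f"{name}_logstd"]))
    loss = anp.mean(-ll + kl_weight * kl)
    return loss


def elbo_terms(params: dict, cfg: ModelConfig, spikes, kl_weight: float,
               eps: dict | None) -> dict:
    """Diagnostics: the ELBO pieces as plain floats (no gradient)."""
    x = np.asarray(spikes, dtype=np.float64)
    B, T, _ = x.shape
    post = encode_raw(params, cfg, x)
    z = sample_posterior(post, eps)
    _, _, log_r = rollout_raw(params, cfg, z["g0"], z.get("b"), z.get("u"),
                              n_steps=T)
    ll = _poisson_ll_from_log_rates(x, log_r, gammaln(x + 1.0))
    terms = {"neg_log_lik": float(-np.mean(ll)),
             "ll_per_bin": float(np.mean(ll) / (T * cfg.n_channels))}
    total_kl = 0.0
    for name in ("g0", "b", "u"):
        if f"{name}_mean" in post:
            k = float(np.mean(kl_to_standard_normal(
                post[f"{name}_mean"], np.exp(post[f"{name}_logstd"]))))
            terms[f"kl_{name}"] = k
            total_kl += k
    terms["kl_total"] = total_kl
    terms["loss"] = terms["neg_log_lik"] + kl_weight * total_kl
    terms["kl_weight"] = float(kl_weight)
    return terms


# ---------------------------------------------------------------------------
# the stateful wrapper

class GeneratorModel:
    """A contextual-LFADS model: config + parameters + convenience methods."""

    def __init__(self, cfg: ModelConfig, params: dict | None = None):
        self.cfg = cfg
        self.params = init_params(cfg) if params is None else params

    # -- encoding / generation ------------------------------------------
    def encode(self, trials) -> PosteriorParams:
        """Amortized posterior for a TrialSet (or raw count array)."""
        spikes = trials.spikes if hasattr(trials, "spikes") else trials
        spikes = np.asarray(spikes)
        if spikes.shape[-1] != self.cfg.n_channels:
            raise ValueError(
                f"trials have {spikes.shape[-1]} channels, model expects "
                f"{self.cfg.n_channels}")
        x = spikes.astype(self.dtype)
        raw = encode_raw(self.params, self.cfg, x)
        def std(k):
            return np.exp(np.asarray(raw[k], dtype=np.float64))
        has_b = self.cfg.bias_dim > 0
        has_u = self.cfg.input_dim > 0
        zb = np.zeros((x.shape[0], 0))
        return PosteriorParams(
            g0_mean=np.asarray(raw["g0_mean"], dtype=np.float64),
            g0_std=std("g0_logstd"),
            b_mean=np.asarray(raw["b_mean"], dtype=np.float64) if has_b else zb,
            b_std=std("b_logstd") if has_b else zb,
            u_mean=np.asarray(raw["u_mean"], dtype=np.float64) if has_u else None,
            u_std=std("u_logstd") if has_u else None,
        )

    def sample_posterior(self, post: PosteriorParams, seed=None):
        """Draw (g0, b, u) by the reparameterization trick; seed=None gives
        the posterior mean (analysis mode)."""
        if seed is None:
            return post.g0_mean, post.b_mean, post.u_mean
        rng = np.random.default_rng(seed)
        g0 = post.g0_mean + rng.standard_normal(post.g0_mean.shape) * post.g0_std
        b = post.b_mean + rng.standard_normal(post.b_mean.shape) * post.b_std
        u = None
        if post.u_mean is not None:
            u = post.u_mean + rng.standard_normal(post.u_mean.shape) * post.u_std
        return g0, b, u

    def step(self, g, u=None, b=None):
        """One generator step F(g, u, b) in float64."""
        p64 = self._params64()
        g = np.asarray(g, dtype=np.float64)
        return generator_step(p64, self.cfg, g, u, b)

    def step_fn(self, b=None):
        """Autonomous one-step map g -> F(g, u=0, b) with the bias frozen;
        the object probed by fixed-point analysis.  Differentiable."""
        p64 = self._params64()
        cfg = self.cfg
        if cfg.input_dim > 0:
            def fn(g):
                u0 = anp.zeros(anp.shape(g)[:-1] + (cfg.input_dim,))
                return generator_step(p64, cfg, g, u0, b)
        elif cfg.bias_dim > 0:
            def fn(g):
                return generator_step(p64, cfg, g, None, b)
        else:
            def fn(g):
                return generator_step(p64, cfg, g, None, None)
        return fn

    def rollout(self, g0, b=None, u=None, n_steps: int | None = None
                ) -> LatentRollout:
        g0 = np.atleast_2d(np.asarray(g0, dtype=self.dtype))
        if b is not None:
            b = np.atleast_2d(np.asarray(b, dtype=self.dtype))
        if u is not None:
            u = np.asarray(u, dtype=self.dtype)
        g, f, log_r = rollout_raw(self.params, self.cfg, g0, b, u, n_steps)
        return LatentRollout(g=np.asarray(g), f=np.asarray(f),
                             rates=np.exp(np.asarray(log_r)),
                             g0=np.asarray(g0), b=None if b is None else np.asarray(b),
                             u=None if u is None else np.asarray(u))

    # -- plumbing --------------------------------------------------------
    @property
    def dtype(self):
        return np.dtype(self.cfg.dtype)

    def _params64(self):
        if self.dtype == np.float64:
            return self.params
        return _map_arrays(self.params, lambda a: np.asarray(a, dtype=np.float64))

    def astype(self, dtype) -> "GeneratorModel":
        """Copy of the model with parameters cast to `dtype`."""
        cfg = dataclasses.replace(self.cfg, dtype=np.dtype(dtype).name)
        params = _map_arrays(self.params,
                             lambda a: np.asarray(a, dtype=np.dtype(dtype)))
        return GeneratorModel(cfg, params)

    def save(self, path) -> None:
        """Checkpoint to HDF5; bit-exact round trip."""
        with h5py.File(path, "w") as f:
            f.attrs["config"] = self.cfg.to_json()
            _write_tree(f.create_group("params"), self.params)

    @classmethod
    def load(cls, path) -> "GeneratorModel":
        with h5py.File(path, "r") as f:
            cfg = ModelConfig.from_json(f.attrs["config"])
            params = _read_tree(f["params"])
        return cls(cfg, params)


def _map_arrays(tree, fn):
    if isinstance(tree, dict):
        return {k: _map_arrays(v, fn) for k, v in tree.items()}
    return fn(tree)


def _write_tree(group, tree):
    for k, v in tree.items():
        if isinstance(v, dict):
            _write_tree(group.create_group(k), v)
        else:
            group.create_dataset(k, data=np.asarray(v))


def _read_tree(group):
    out = {}
    for k, v in group.items():
        out[k] = _read_tree(v) if isinstance(v, h5py.Group) else v[...]
    return out
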