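"""Synthetic benchmark: a family of damped pendulums observed through
Poisson-spiking neurons.

The physical system is a damped pendulum, m l^2 th'' + d th' + m g l sin(th) = 0,
integrated with fixed-step RK4.  A *family* of such pendulums is built by
varying the gravity constant g across conditions: gravity sets the oscillation
frequency, so condition identity is expressed purely as a change in the
dynamics, not in the observation map.  The 2-D state s = (th, th') drives a
population of Poisson neurons through a clipped-linear embedding,
counts ~ Poisson(max(K s + mu, 0)).

Two controlled corruptions support the non-stationarity and behavioral-speed
analyses: `inject_drift` adds a slowly growing offset to the pre-clip drive
(additive firing-rate drift across a session) and `inject_speed_variation`
rescales time per trial so the same state path is traversed at different
speeds.  Both store their ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .containers import TrialSet

__all__ = [
    "PendulumConfig",
    "EmbeddingConfig",
    "simulate_pendulum",
    "embed_as_spikes",
    "make_pendulum_dataset",
    "inject_drift",
    "inject_speed_variation",
    "IntegrationFailure",
]

DEFAULT_GRAVITIES = tuple(np.arange(0.5, 4.51, 0.5))


class IntegrationFailure(RuntimeError):
    """Non-finite state encountered during ODE integration."""


@dataclasses.dataclass
class PendulumConfig:
    """Damped-pendulum family: m l^2 th'' + d th' + m g l sin(th) = 0.

    `gravity_values` enumerates the task conditions; each trial starts at
    rest, s0 = (th0, 0), with th0 drawn from `theta0_range` uniformly.
    """

    mass: float = 1.0
    length: float = 5.0
    damping: float = 1.0
    gravity_values: Sequence[float] = DEFAULT_GRAVITIES
    dt: float = 0.05
    n_steps: int = 300
    n_trials_per_condition: int = 125
    theta0_range: tuple[float, float] = (0.3, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.mass <= 0 or self.length <= 0 or self.dt <= 0:
            raise ValueError("mass, length and dt must be positive")
        if self.damping < 0:
            raise ValueError("damping must be non-negative")
        if any(g <= 0 for g in self.gravity_values):
            raise ValueError("all gravity values must be positive")


@dataclasses.dataclass
class EmbeddingConfig:
    """Clipped-linear Poisson embedding, counts ~ Poisson(max(K s + mu, 0)).

    K is (n_neurons, 2) with i.i.d. N(0, k_scale^2) entries; mu is uniform on
    `mu_range` (positive offsets), so the typical pre-clip drive is a few
    counts per bin.  Drawn once per dataset from `seed` and recorded in the
    TrialSet provenance.
    """

    n_neurons: int = 192
    k_scale: float = 2.0
    mu_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0
    K: np.ndarray | None = None
    mu: np.ndarray | None = None

    def realize(self) -> "EmbeddingConfig":
        """Draw (K, mu) if not given explicitly; idempotent."""
        if self.K is not None and self.mu is not None:
            K = np.asarray(self.K, dtype=np.float64)
            if K.shape != (self.n_neurons, 2):
                raise ValueError(
                    f"K must have shape ({self.n_neurons}, 2); got {K.shape}")
            return self
        rng = np.random.default_rng(self.seed)
        K = rng.normal(0.0, self.k_scale, (self.n_neurons, 2))
        mu = rng.uniform(*self.mu_range, self.n_neurons)
        return dataclasses.replace(self, K=K, mu=mu)


def _pendulum_rhs(state, g, cfg: PendulumConfig):
    th, om = state[..., 0], state[..., 1]
    dom = -(cfg.damping * om) / (cfg.mass * cfg.length ** 2) \
        - (g / cfg.length) * np.sin(th)
    return np.stack([om, dom], axis=-1)


def simulate_pendulum(cfg: PendulumConfig, g: float, theta0: float,
                      dt: float | None = None,
                      n_steps: int | None = None) -> np.ndarray:
    """Integrate one trial; returns states (n_steps, 2) = (th, th') at t = dt..n_steps*dt.

    Fixed-step classical RK4 at the configured dt.  Raises
    :class:`IntegrationFailure` naming the step if the state becomes
    non-finite.
    """
    if g <= 0:
        raise ValueError("gravity must be positive")
    if not np.isfinite(theta0):
        raise ValueError("theta0 must be finite")
    dt = cfg.dt if dt is None else dt
    n_steps = cfg.n_steps if n_steps is None else n_steps
    s = np.array([theta0, 0.0])
    out = np.empty((n_steps, 2))
    for t in range(n_steps):
        k1 = _pendulum_rhs(s, g, cfg)
        k2 = _pendulum_rhs(s + 0.5 * dt * k1, g, cfg)
        k3 = _pendulum_rhs(s + 0.5 * dt * k2, g, cfg)
        k4 = _pendulum_rhs(s + dt * k3, g, cfg)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(s)):
            raise IntegrationFailure(f"non-finite pendulum state at step {t}")
        out[t] = s
    return out


def pendulum_energy(states: np.ndarray, cfg: PendulumConfig, g: float) -> np.ndarray:
    """Total mechanical energy 0.5 m l^2 th'^2 + m g l (1 - cos th) per step."""
    th, om = states[..., 0], states[..., 1]
    return 0.5 * cfg.mass * cfg.length ** 2 * om ** 2 \
        + cfg.mass * g * cfg.length * (1.0 - np.cos(th))


def embed_as_spikes(states: np.ndarray, embed: EmbeddingConfig, seed: int,
                    bin_width: float,
                    condition_label=None,
                    drive_offset: np.ndarray | None = None) -> TrialSet:
    """Map latent states (trials, T, 2) to Poisson counts.

    Per-bin rate is max(K s_t + mu [+ drive_offset], 0) per neuron;
    `drive_offset` (trials, n_neurons) is applied before the clip (used by
    :func:`inject_drift`).
    """
    states = np.asarray(states, dtype=np.float64)
    if states.ndim != 3 or not np.all(np.isfinite(states)):
        raise ValueError("states must be a finite (trials, T, state_dim) array")
    embed = embed.realize()
    K, mu = embed.K, embed.mu
    if K.shape[1] != states.shape[2]:
        raise ValueError(
            f"embedding K has state dim {K.shape[1]} but states have {states.shape[2]}")
    drive = states @ K.T + mu
    if drive_offset is not None:
        drive = drive + np.asarray(drive_offset)[:, None, :]
    rates = np.maximum(drive, 0.0)
    # independent stream per channel: a channel's draws depend only on its
    # own rates, so controlled manipulations of one channel subset leave the
    # others' spikes bit-identical
    child_seeds = np.random.SeedSequence(seed).spawn(embed.n_neurons)
    spikes = np.empty(rates.shape, dtype=np.uint32)
    for j in range(embed.n_neurons):
        spikes[:, :, j] = np.random.default_rng(child_seeds[j]).poisson(rates[:, :, j])
    n = states.shape[0]
    if condition_label is None:
        condition_label = np.zeros(n)
    return TrialSet(
        spikes=spikes,
        bin_width=bin_width,
        condition_label=condition_label,
        acquisition_index=np.arange(n),
        ground_truth_state=states,
        provenance={"embedding": {"n_neurons": embed.n_neurons,
                                  "K": K.tolist(), "mu": mu.tolist(),
                                  "seed": embed.seed},
                    "spike_seed": int(seed)},
    )


def _simulate_family(cfg: PendulumConfig, rng: np.random.Generator,
                     speed_factors: np.ndarray | None = None):
    """All trials of the family; returns (states, labels, theta0s, factors)."""
    n_cond = len(cfg.gravity_values)
    n = n_cond * cfg.n_trials_per_condition
    states = np.empty((n, cfg.n_steps, 2))
    labels = np.empty(n)
    theta0s = rng.uniform(*cfg.theta0_range, n)
    if speed_factors is None:
        speed_factors = np.ones(n)
    i = 0
    for g in cfg.gravity_values:
        for _ in range(cfg.n_trials_per_condition):
            states[i] = simulate_pendulum(cfg, g, theta0s[i],
                                          dt=cfg.dt * speed_factors[i])
            labels[i] = g
            i += 1
    return states, labels, theta0s, speed_factors


def _split_per_condition(labels: np.ndarray, fractions, rng: np.random.Generator):
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("split fractions must be positive and sum to 1")
    parts = [[] for _ in fractions]
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        idx = rng.permutation(idx)
        counts = np.floor(fractions * len(idx)).astype(int)
        # distribute the remainder in fraction order so every condition
        # appears in every partition when possible
        rem = len(idx) - counts.sum()
        for j in np.argsort(-fractions)[:rem]:
            counts[j] += 1
        start = 0
        for j, c in enumerate(counts):
            parts[j].append(idx[start:start + c])
            start += c
    return [np.sort(np.concatenate(p)) for p in parts]


def make_pendulum_dataset(cfg: PendulumConfig,
                          embed: EmbeddingConfig,
                          split_fractions=(0.6, 0.2, 0.2),
                          ) -> tuple[TrialSet, TrialSet, TrialSet]:
    """Generate the full pendulum-family dataset and split per condition.

    Every condition contributes trials to every partition.  Acquisition order
    is a global random interleaving of conditions, so "early" vs "late" in a
    session is not confounded with condition.  Fully determined by
    (cfg.seed, embed.seed).
    """
    rng = np.random.default_rng(cfg.seed)
    states, labels, theta0s, _ = _simulate_family(cfg, rng)
    embed = embed.realize()
    trials = embed_as_spikes(states, embed,
                             seed=int(rng.integers(2 ** 31)),
                             bin_width=cfg.dt,
                             condition_label=labels)
    # global acquisition order: random interleave of all trials
    order = rng.permutation(trials.n_trials)
    acq = np.empty(trials.n_trials, dtype=np.int64)
    acq[order] = np.arange(trials.n_trials)
    trials.acquisition_index = acq
    trials.provenance["pendulum"] = {
        "mass": cfg.mass, "length": cfg.length, "damping": cfg.damping,
        "gravity_values": [float(g) for g in cfg.gravity_values],
        "dt": cfg.dt, "n_steps": cfg.n_steps,
        "n_trials_per_condition": cfg.n_trials_per_condition,
        "theta0_range": list(cfg.theta0_range), "seed": cfg.seed,
    }
    part_idx = _split_per_condition(labels, split_fractions, rng)
    return tuple(trials.subset(ix) for ix in part_idx)


def inject_drift(trials: TrialSet,
                 drift_vector: np.ndarray,
                 schedule: Callable[[np.ndarray], np.ndarray] | np.ndarray,
                 seed: int = 0) -> TrialSet:
    """Re-embed a synthetic TrialSet with additive pre-clip drive drift.

    `schedule` maps acquisition_index to a scalar magnitude (callable or a
    per-trial array); trial i's drive becomes K s + mu + magnitude_i * drift_vector
    before clipping.  Requires ground_truth_state and embedding provenance.
    The applied magnitudes are stored in ``trial_info['drift_magnitude']``.
    """
    if trials.ground_truth_state is None or "embedding" not in trials.provenance:
        raise ValueError("drift injection needs a synthetic TrialSet with "
                         "ground truth state and embedding provenance")
    emb = trials.provenance["embedding"]
    embed = EmbeddingConfig(n_neurons=emb["n_neurons"],
                            K=np.array(emb["K"]), mu=np.array(emb["mu"]),
                            seed=emb["seed"])
    drift_vector = np.asarray(drift_vector, dtype=np.float64)
    if callable(schedule):
        mags = np.asarray(schedule(trials.acquisition_index), dtype=np.float64)
    else:
        mags = np.asarray(schedule, dtype=np.float64)
    offsets = mags[:, None] * drift_vector[None, :]
    out = embed_as_spikes(trials.ground_truth_state, embed, seed,
                          bin_width=trials.bin_width,
                          condition_label=trials.condition_label,
                          drive_offset=offsets)
    out.acquisition_index = trials.acquisition_index.copy()
    out.trial_info = {k: np.asarray(v).copy() for k, v in trials.trial_info.items()}
    out.trial_info["drift_magnitude"] = mags
    out.provenance = dict(trials.provenance)
    out.provenance["drift"] = {"vector": drift_vector.tolist(),
                               "seed": int(seed)}
    return out


def inject_speed_variation(cfg: PendulumConfig,
                           embed: EmbeddingConfig,
                           speed_factors: np.ndarray | None = None,
                           factor_range: tuple[float, float] = (0.7, 1.3),
                           ) -> TrialSet:
    """Pendulum trials traversed at per-trial speeds.

    Trial i is integrated with time-step dt * factor_i, so in fixed wall time
    the same state path is traversed factor_i times faster.  True factors go
    to ``trial_info['speed_factor']``.  If `speed_factors` is None they are
    drawn uniformly from `factor_range`.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(cfg.gravity_values) * cfg.n_trials_per_condition
    if speed_factors is None:
        speed_factors = rng.uniform(*factor_range, n)
    else:
        speed_factors = np.asarray(speed_factors, dtype=np.float64)
        if speed_factors.shape != (n,):
            raise ValueError(f"speed_factors must have shape ({n},)")
    if np.any(speed_factors <= 0):
        raise ValueError("speed factors must be positive")
    states, labels, _, _ = _simulate_family(cfg, rng, speed_factors)
    trials = embed_as_spikes(states, embed.realize(),
                             seed=int(rng.integers(2 ** 31)),
                             bin_width=cfg.dt,
                             condition_label=labels)
    order = rng.permutation(n)
    acq = np.empty(n, dtype=np.int64)
    acq[order] = np.arange(n)
    trials.acquisition_index = acq
    trials.trial_info["speed_factor"] = speed_factors
    trials.provenance["speed_variation"] = {"factor_range": list(factor_range)}
    return trials
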