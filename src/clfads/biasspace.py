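"""Operations in the per-trial bias space.

The bias vectors inferred per trial form a low-dimensional embedding of the
family of dynamical systems the generator implements.  Two session-level
problems reduce to simple geometry in this space:

* **Non-stationarity.**  Slow recording drift shows up as a displacement of
  the bias cloud over a session.  Shifting early-session biases (and initial
  conditions) by the early-to-late mean difference and regenerating rates
  through the generator yields drift-corrected activity for decoder training.

* **Behavioral speed.**  A direction in bias space along which shifting the
  bias uniformly scales the generator's one-step updates acts as a speed
  axis; projecting per-trial biases onto it sorts trials by traversal speed.
"""

from __future__ import annotations

import dataclasses

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from scipy.optimize import minimize

from .containers import TrialSet
from .model import GeneratorModel

__all__ = [
    "BiasEmbedding",
    "correct_bias_drift",
    "correct_initial_conditions",
    "augment_trials",
    "AugmentedRates",
    "solve_speed_shift",
    "speed_axis",
    "sort_by_speed",
    "drift_axis",
    "DEFAULT_ALPHA_GRID",
]

# regular alpha grid in [0.7, 1.3] with alpha = 1 excluded
DEFAULT_ALPHA_GRID = (0.7, 0.8, 0.9, 1.1, 1.2, 1.3)


@dataclasses.dataclass
class BiasEmbedding:
    """Per-trial bias means with their principal-component structure."""

    b_mean: np.ndarray                 # (n_trials, bias_dim)
    acquisition_index: np.ndarray      # (n_trials,)
    principal_axes: np.ndarray         # (bias_dim, bias_dim), rows = PCs
    explained_variance_ratio: np.ndarray

    @classmethod
    def from_biases(cls, b_mean, acquisition_index) -> "BiasEmbedding":
        from sklearn.decomposition import PCA
        b = np.asarray(b_mean, dtype=np.float64)
        if b.ndim != 2:
            raise ValueError("b_mean must be (n_trials, bias_dim)")
        acq = np.asarray(acquisition_index)
        if acq.shape[0] != b.shape[0]:
            raise ValueError("acquisition_index must have one entry per trial")
        pca = PCA(n_components=min(b.shape))
        pca.fit(b)
        return cls(b_mean=b, acquisition_index=acq,
                   principal_axes=pca.components_,
                   explained_variance_ratio=pca.explained_variance_ratio_)

    @classmethod
    def from_model(cls, model: GeneratorModel, trials: TrialSet
                   ) -> "BiasEmbedding":
        post = model.encode(trials)
        return cls.from_biases(post.b_mean, trials.acquisition_index)

    def projections(self, axis: np.ndarray) -> np.ndarray:
        return self.b_mean @ np.asarray(axis, dtype=np.float64)


def _mean_shift_correct(values: np.ndarray, early_ids, late_ids):
    values = np.asarray(values, dtype=np.float64)
    early = np.asarray(early_ids, dtype=int)
    late = np.asarray(late_ids, dtype=int)
    if early.size == 0 or late.size == 0:
        raise ValueError("early and late id sets must be nonempty")
    if np.intersect1d(early, late).size:
        raise ValueError("early and late id sets must be disjoint")
    v_early = values[early].mean(axis=0)
    v_late = values[late].mean(axis=0)
    corrected = values.copy()
    corrected[early] += v_late - v_early
    return corrected, v_late - v_early


def correct_bias_drift(biases, early_ids, late_ids) -> np.ndarray:
    """Shift early-trial biases by (b_late - b_early).

    b_early / b_late are means over the given id sets; late (and unlisted)
    trials are unchanged.  After correction the mean of the early-trial
    biases equals b_late exactly, so applying the correction twice (with
    recomputed means) is the identity.
    """
    corrected, _ = _mean_shift_correct(biases, early_ids, late_ids)
    return corrected


def correct_initial_conditions(g0_means, early_ids, late_ids) -> np.ndarray:
    """The same mean-shift construction applied in initial-condition space.
    Time-varying inputs are never touched."""
    corrected, _ = _mean_shift_correct(g0_means, early_ids, late_ids)
    return corrected


@dataclasses.dataclass
class AugmentedRates:
    """Drift-corrected rate corpus for decoder training."""

    rates: np.ndarray          # (n_out, T, n_channels)
    source_trial: np.ndarray   # index into the input TrialSet
    is_corrected: np.ndarray   # True where the trial was early and shifted


def augment_trials(model: GeneratorModel, trials: TrialSet,
                   early_ids, late_ids) -> AugmentedRates:
    """Regenerate early trials with late-session bias/initial condition.

    Encodes all trials, applies the early-to-late mean shift to the bias and
    initial-condition posterior means of early trials, rolls the generator
    out with the original (untouched) input posterior means, and returns the
    union of corrected-early rates and unmodified late-trial inferred rates.
    """
    early = np.asarray(early_ids, dtype=int)
    late = np.asarray(late_ids, dtype=int)
    if late.size == 0:
        raise ValueError("late id set is empty: no drift target to shift to")
    post = model.encode(trials)
    b_corr = correct_bias_drift(post.b_mean, early, late)
    g0_corr = correct_initial_conditions(post.g0_mean, early, late)
    ids = np.concatenate([early, late])
    g0 = np.concatenate([g0_corr[early], post.g0_mean[late]])
    b = np.concatenate([b_corr[early], post.b_mean[late]])
    u = None
    if post.u_mean is not None:
        u = np.concatenate([post.u_mean[early], post.u_mean[late]])
    roll = model.rollout(g0, b if model.cfg.bias_dim > 0 else None, u,
                         n_steps=trials.n_bins)
    return AugmentedRates(
        rates=roll.rates,
        source_trial=ids,
        is_corrected=np.concatenate([np.ones(early.size, dtype=bool),
                                     np.zeros(late.size, dtype=bool)]))


def solve_speed_shift(model: GeneratorModel, states, biases, alpha: float,
                      warm_start: np.ndarray | None = None,
                      max_iter: int = 1000,
                      ) -> tuple[np.ndarray, float]:
    """Bias shift that scales one-step updates by `alpha`.

    Minimizes over db

        J(db) = sum_{i,t} || F(g_it, u=0, b_i + db) - g_it
                             - alpha (F(g_it, u=0, b_i) - g_it) ||^2

    where g_it are the supplied states (typically posterior-mean rollout
    states of all trials; a (B, T, gen_dim) array is flattened with biases
    repeated per step) and b_i the matching per-trial biases.
    Returns (db, J(db)); see :func:`solve_speed_shift_fn` for the solver.
    """
    bias_dim = model.cfg.bias_dim
    if bias_dim == 0:
        raise ValueError("speed shifts need a model with a per-trial bias")
    G = np.asarray(states, dtype=np.float64)
    if G.ndim == 3:
        B, T, gd = G.shape
        G = G.reshape(B * T, gd)
        biases = np.repeat(np.asarray(biases, dtype=np.float64), T, axis=0)
    else:
        biases = np.asarray(biases, dtype=np.float64)

    p64 = model._params64()
    cfg = model.cfg
    from .model import generator_step
    u0 = np.zeros((G.shape[0], cfg.input_dim)) if cfg.input_dim > 0 else None

    def F(Gm, Bm):
        return generator_step(p64, cfg, Gm, u0, Bm)

    return solve_speed_shift_fn(F, G, biases, alpha, bias_dim,
                                warm_start=warm_start, max_iter=max_iter)


def solve_speed_shift_fn(F, states, biases, alpha: float, bias_dim: int,
                         warm_start: np.ndarray | None = None,
                         max_iter: int = 1000,
                         ) -> tuple[np.ndarray, float]:
    """Core speed-shift solver for an arbitrary differentiable step map.

    `F(states, biases)` maps matched (M, gen_dim), (M, bias_dim) batches to
    next states.  Solved by quasi-Newton descent (L-BFGS with exact autograd
    gradients, full batch) from `warm_start` (or 0), iterating until the
    relative objective change is negligible; the returned shift never has a
    larger objective than db = 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    G = np.asarray(states, dtype=np.float64)
    biases = np.asarray(biases, dtype=np.float64)
    if biases.shape[0] != G.shape[0]:
        raise ValueError("states and biases must align row-wise")
    F0 = np.asarray(F(G, biases))
    target = G + alpha * (F0 - G)

    def objective(db):
        d = F(G, biases + db) - target
        return anp.sum(d * d)

    j0 = float(objective(np.zeros(bias_dim)))
    x0 = np.zeros(bias_dim) if warm_start is None \
        else np.asarray(warm_start, dtype=np.float64).copy()
    res = minimize(value_and_grad(objective), x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12})
    db = res.x
    j = float(objective(db))
    if j > j0:  # never worse than the no-shift solution
        db = np.zeros(bias_dim)
        j = j0
    return db, j


def speed_axis(shifts, alphas=None) -> np.ndarray:
    """Common speed direction from per-alpha shifts.

    `shifts` is (bias_dim, n_alpha) with columns b_speed,alpha (or a dict
    alpha -> shift).  Returns the left singular vector of the matrix for the
    largest singular value, sign-fixed so the shift at the largest alpha
    projects positively (speed increases along +axis).
    """
    if isinstance(shifts, dict):
        alphas = sorted(shifts)
        M = np.stack([np.asarray(shifts[a], dtype=np.float64)
                      for a in alphas], axis=1)
    else:
        M = np.asarray(shifts, dtype=np.float64)
        if alphas is None:
            raise ValueError("alphas required when shifts is a matrix")
        alphas = list(alphas)
        if M.shape[1] != len(alphas):
            raise ValueError("one shift column per alpha required")
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    axis = U[:, 0]
    j_max = int(np.argmax(alphas))
    if float(M[:, j_max] @ axis) < 0:
        axis = -axis
    return axis


def sort_by_speed(biases, axis) -> np.ndarray:
    """Trial indices ordered by the scalar projection b_i . axis, ascending
    (stable sort, so equal projections keep their input order)."""
    proj = np.asarray(biases, dtype=np.float64) @ np.asarray(axis, dtype=np.float64)
    return np.argsort(proj, kind="stable")


def drift_axis(embedding: BiasEmbedding) -> np.ndarray:
    """Unit direction in bias space most correlated with acquisition order.

    The least-squares regression direction of (centered) bias on centered
    acquisition index, normalized; invariant to translating the bias cloud.
    """
    b = embedding.b_mean
    t = embedding.acquisition_index.astype(np.float64)
    c = t - t.mean()
    v = c @ (b - b.mean(axis=0))
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("acquisition index carries no bias-space trend")
    return v / n
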