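"""Reverse-engineering a trained generator.

Given the autonomous one-step map F(g) = GRU(g, [u=0, b]) with the bias
frozen at one trial's value, this module locates fixed points g* with
F(g*) ~ g*, linearizes around them, reads oscillation frequency and decay
off the Jacobian eigenvalues, and compares rotation planes across trials.

Fixed points are found by descending q(g) = 1/2 ||F(g) - g||^2 from many
initial states in parallel (Adam on the batched objective), then polishing
candidate minima with Newton's method on F(g) - g = 0, and finally merging
near-duplicates.  Discrete-time eigenvalues lambda convert to frequency
|arg lambda| / (2 pi dt) in Hz and per-step decay |lambda|.
"""

from __future__ import annotations

import dataclasses
import logging

import autograd.numpy as anp
import numpy as np
from autograd import grad, jacobian
from scipy.linalg import eigh, qr
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "FixedPointRecord",
    "OscillatoryMode",
    "find_fixed_points",
    "find_fixed_points_fn",
    "linearize",
    "linearize_fd",
    "eigen_modes",
    "dominant_mode",
    "plane_similarity",
    "spectral_embed",
    "default_initial_states",
]


@dataclasses.dataclass
class FixedPointRecord:
    """A located fixed point of the conditioned generator."""

    g_star: np.ndarray
    bias: np.ndarray | None
    residual: float                 # ||F(g*) - g*||
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    trial_id: int | None = None
    n_basin_starts: int = 0         # initial states that converged here


@dataclasses.dataclass
class OscillatoryMode:
    """One (conjugate-pair or real) eigenmode of a linearization."""

    frequency: float                # Hz
    decay: float                    # |lambda| per step
    eigenvalue: complex
    plane: np.ndarray | None        # (gen_dim, 2) orthonormal, None if real
    trial_id: int | None = None


def default_initial_states(trajectory: np.ndarray, n_starts: int = 256,
                           noise_scale: float = 0.5,
                           seed: int = 0) -> np.ndarray:
    """Subsample a rollout's states and add Gaussian perturbations.

    Covers the visited region of state space plus its surroundings, the
    standard seeding strategy for fixed-point searches.
    """
    traj = np.asarray(trajectory, dtype=np.float64).reshape(-1, trajectory.shape[-1])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, traj.shape[0], size=n_starts)
    starts = traj[idx]
    n_clean = max(1, n_starts // 4)  # keep some unperturbed
    noise = rng.normal(0.0, noise_scale, starts.shape)
    noise[:n_clean] = 0.0
    return starts + noise


def _newton_polish(F, g0, max_iter=20, tol=1e-12):
    """Newton iterations on F(g) - g = 0 from a single state."""
    J = jacobian(F)
    g = g0.copy()
    for _ in range(max_iter):
        r = F(g) - g
        rn = np.linalg.norm(r)
        if rn < tol:
            break
        A = J(g) - np.eye(g.shape[0])
        try:
            step = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) > 1e3:
            break
        g = g + step
    return g, float(np.linalg.norm(F(g) - g))


def find_fixed_points(model, b=None, initial_states=None,
                      tol: float | None = None,
                      dedupe_radius: float = 0.1,
                      max_iter: int = 2000,
                      learning_rate: float = 0.05,
                      trial_id: int | None = None,
                      advance_steps: int = 200) -> list[FixedPointRecord]:
    """Locate fixed points of a trained generator, g -> F(g, u=0, b).

    Thin wrapper over :func:`find_fixed_points_fn` that freezes the bias and
    records it on the returned points.
    """
    if initial_states is None:
        raise ValueError("initial_states required (see default_initial_states)")
    if b is not None:
        b = np.asarray(b, dtype=np.float64).ravel()
    G = np.asarray(initial_states, dtype=np.float64)
    if G.ndim == 1:
        G = G[None]
    F = model.step_fn(b)
    records = find_fixed_points_fn(
        F, G, gen_dim=model.cfg.gen_dim, tol=tol,
        dedupe_radius=dedupe_radius, max_iter=max_iter,
        learning_rate=learning_rate, trial_id=trial_id,
        advance_steps=advance_steps)
    for rec in records:
        rec.bias = None if b is None else b.copy()
    return records


def find_fixed_points_fn(F, initial_states, gen_dim: int | None = None,
                         tol: float | None = None,
                         dedupe_radius: float = 0.1,
                         max_iter: int = 2000,
                         learning_rate: float = 0.05,
                         trial_id: int | None = None,
                         advance_steps: int = 200
                         ) -> list[FixedPointRecord]:
    """Locate fixed points of an arbitrary differentiable map F.

    `F` must accept a batch (n, gen_dim) or a single state (gen_dim,) and be
    autograd-differentiable.  The seed set is the given `initial_states`
    plus, when `advance_steps > 0`, copies advanced through F that many
    steps — forward iteration converges onto attracting fixed points that
    plain residual descent approaches too slowly, while the unadvanced seeds
    keep saddles reachable.  From every seed the batched residual
    q(g) = 1/2 ||F(g) - g||^2 is descended with Adam; survivors are
    Newton-polished, kept if ||F(g*) - g*|| < `tol` (default
    1e-6 * sqrt(gen_dim)), and merged within `dedupe_radius` (Euclidean) to
    the lowest-residual representative.  Returns records sorted by residual;
    empty list (with a warning) when nothing converges.
    """
    G = np.asarray(initial_states, dtype=np.float64)
    if G.ndim == 1:
        G = G[None]
    if gen_dim is None:
        gen_dim = G.shape[1]
    if tol is None:
        tol = 1e-6 * np.sqrt(gen_dim)
    if advance_steps > 0:
        adv = G.copy()
        for _ in range(advance_steps):
            adv = np.asarray(F(adv))
        if np.all(np.isfinite(adv)):
            G = np.concatenate([G, adv], axis=0)

    # one scalar objective over the whole batch; rows are independent so the
    # gradient decomposes into per-state gradients
    def q_total(Gm):
        d = F(Gm) - Gm
        return 0.5 * anp.sum(d * d)

    gq = grad(q_total)
    m = np.zeros_like(G)
    v = np.zeros_like(G)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = learning_rate
    prev_q = np.inf
    for it in range(1, max_iter + 1):
        gr = gq(G)
        m = beta1 * m + (1 - beta1) * gr
        v = beta2 * v + (1 - beta2) * gr * gr
        G = G - lr * (m / (1 - beta1 ** it)) / (np.sqrt(v / (1 - beta2 ** it)) + eps)
        if it % 50 == 0:
            qn = q_total(G)
            if prev_q - qn < 1e-14 * max(1.0, abs(prev_q)):
                break
            prev_q = qn

    # per-state residuals after descent
    res = np.linalg.norm(np.asarray(F(G)) - G, axis=1)
    # generous pre-filter; Newton decides final acceptance
    cand = np.where(res < max(1e3 * tol, 1e-2))[0]
    if cand.size == 0:
        logger.warning("no fixed-point candidates below pre-filter "
                       "(best residual %.3g)", res.min() if res.size else np.nan)
        return []

    # dedupe candidates before the (per-point) Newton stage
    order = cand[np.argsort(res[cand])]
    reps: list[int] = []
    basin_counts: list[int] = []
    for i in order:
        for k, j in enumerate(reps):
            if np.linalg.norm(G[i] - G[j]) < dedupe_radius:
                basin_counts[k] += 1
                break
        else:
            reps.append(i)
            basin_counts.append(1)

    jac_fn = jacobian(F)
    records = []
    kept: list[np.ndarray] = []
    for j, nb in zip(reps, basin_counts):
        g_star, r = _newton_polish(F, G[j])
        if r >= tol or not np.all(np.isfinite(g_star)):
            continue
        merged = False
        for rec, gk in zip(records, kept):
            if np.linalg.norm(g_star - gk) < dedupe_radius:
                rec.n_basin_starts += nb
                if r < rec.residual:
                    rec.g_star = g_star
                    rec.residual = r
                    rec.jacobian = np.asarray(jac_fn(g_star))
                    rec.eigenvalues, rec.eigenvectors = np.linalg.eig(rec.jacobian)
                merged = True
                break
        if merged:
            continue
        A = np.asarray(jac_fn(g_star))
        w, V = np.linalg.eig(A)
        records.append(FixedPointRecord(
            g_star=g_star, bias=None,
            residual=r, jacobian=A, eigenvalues=w, eigenvectors=V,
            trial_id=trial_id, n_basin_starts=nb))
        kept.append(g_star)
    if not records:
        logger.warning("no fixed point reached residual < %.3g", tol)
    records.sort(key=lambda rec: rec.residual)
    return records


def linearize(model, g_star, b=None) -> np.ndarray:
    """Jacobian dF/dg of the autonomous step at (g*, u=0, b), by autodiff."""
    F = model.step_fn(b)
    g_star = np.asarray(g_star, dtype=np.float64)
    return np.asarray(jacobian(F)(g_star))


def linearize_fd(model, g_star, b=None, h: float = 1e-5) -> np.ndarray:
    """Finite-difference Jacobian (central differences); the independent
    cross-check for :func:`linearize`."""
    F = model.step_fn(b)
    g_star = np.asarray(g_star, dtype=np.float64)
    n = g_star.size
    A = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        A[:, j] = (np.asarray(F(g_star + e)) - np.asarray(F(g_star - e))) / (2 * h)
    return A


def eigen_modes(A: np.ndarray, bin_width: float,
                trial_id: int | None = None) -> list[OscillatoryMode]:
    """Eigenvalues of a discrete-time Jacobian as oscillatory modes.

    Each conjugate pair contributes one mode with frequency
    |arg lambda| / (2 pi bin_width) Hz, per-step decay |lambda| and an
    orthonormalized rotation plane spanned by Re(v), Im(v).  Real
    eigenvalues give frequency 0 and no plane.
    """
    w, V = np.linalg.eig(np.asarray(A, dtype=np.float64))
    modes = []
    used = np.zeros(len(w), dtype=bool)
    for i in range(len(w)):
        if used[i]:
            continue
        lam = w[i]
        if abs(lam.imag) < 1e-12:
            used[i] = True
            modes.append(OscillatoryMode(
                frequency=0.0, decay=float(abs(lam)),
                eigenvalue=complex(lam.real, 0.0), plane=None,
                trial_id=trial_id))
            continue
        # find and mark the conjugate partner
        partner = None
        for j in range(i + 1, len(w)):
            if not used[j] and abs(w[j] - np.conj(lam)) < 1e-8 * max(1.0, abs(lam)):
                partner = j
                break
        used[i] = True
        if partner is not None:
            used[partner] = True
        if lam.imag < 0:  # represent the pair by its upper-half-plane member
            lam = np.conj(lam)
        vec = V[:, i]
        P = np.stack([vec.real, vec.imag], axis=1)
        Q, _ = qr(P, mode="economic")
        freq = abs(np.arctan2(lam.imag, lam.real)) / (2 * np.pi * bin_width)
        modes.append(OscillatoryMode(
            frequency=float(freq), decay=float(abs(lam)),
            eigenvalue=complex(lam), plane=Q, trial_id=trial_id))
    return modes


def dominant_mode(modes: list[OscillatoryMode],
                  target_frequency: float) -> OscillatoryMode:
    """Mode with frequency closest to `target_frequency`; ties go to the
    slower-decaying (larger |lambda|) mode."""
    if not modes:
        raise ValueError("no modes to choose from")
    return min(modes, key=lambda m: (abs(m.frequency - target_frequency),
                                     -m.decay))


def plane_similarity(trajectory: np.ndarray, plane: np.ndarray) -> float:
    """Fraction of a trajectory's variance captured by a 2-D plane.

    `trajectory` holds states *relative to the fixed point* (T, gen_dim);
    `plane` is an orthonormal (gen_dim, 2) basis.  Returns
    ||X P||_F^2 / ||X||_F^2 in [0, 1].
    """
    X = np.asarray(trajectory, dtype=np.float64)
    P = np.asarray(plane, dtype=np.float64)
    total = float(np.sum(X * X))
    if total == 0.0:
        return 1.0
    proj = X @ P
    return float(np.sum(proj * proj) / total)


def spectral_embed(similarity: np.ndarray, dims: int = 2) -> np.ndarray:
    """Spectral embedding of a trial-by-trial similarity matrix.

    Symmetrizes S, forms the normalized graph Laplacian
    L = I - D^{-1/2} S D^{-1/2}, and returns the random-walk coordinates
    D^{-1/2} u for the eigenvectors u of the `dims` smallest nonzero
    eigenvalues.  Raises if the similarity graph is disconnected (each
    component would embed independently).
    """
    S = np.asarray(similarity, dtype=np.float64)
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 0.0)
    if np.any(S < 0):
        raise ValueError("similarities must be non-negative")
    adj = (S > 0).astype(np.int8)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"similarity graph is disconnected: {n_comp} components "
            f"with sizes {sizes.tolist()}")
    d = S.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    L = np.eye(S.shape[0]) - (d_isqrt[:, None] * S) * d_isqrt[None, :]
    L = 0.5 * (L + L.T)
    w, U = eigh(L)
    # skip the trivial eigenvector (eigenvalue 0 of the connected graph)
    coords = U[:, 1:1 + dims] * d_isqrt[:, None]
    # permutation-invariant sign convention: largest-|.| entry positive
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords
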