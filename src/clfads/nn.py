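"""Low-level recurrent building blocks on top of autograd.

The workhorse is :func:`gru_scan`, a fused GRU sequence registered as a single
autograd primitive.  Its forward pass is plain NumPy (one pre-multiplied input
projection, then a Python loop over time) and its backward pass is hand-written
backpropagation-through-time.  Collapsing the whole sequence into one primitive
keeps the autograd tape tiny, which matters on CPU where per-node tracing
overhead would otherwise dominate the arithmetic.

Gate convention (fixed throughout the package)::

    r  = sigmoid(x W_r + h U_r + c_r)          reset gate
    z  = sigmoid(x W_z + h U_z + c_z)          update gate
    h~ = tanh   (x W_h + (r*h) U_h + c_h)      candidate, reset-gated state
    h' = (1 - z) * h + z * h~

With all parameters zero this maps h -> 0.5 * h (z = 0.5, h~ = 0).

Parameter packing: the three input projections are stored as one matrix
``W`` of shape (n_in, 3H) in gate order (r, z, h); the recurrent weights are
``Urz`` (H, 2H) for the r/z gates and ``Uh`` (H, H) for the candidate; the
biases are one vector ``c`` of length 3H.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive

__all__ = ["GRUParams", "gru_cell", "gru_scan", "init_gru", "sigmoid"]


def sigmoid(x):
    # tanh-based form: numerically stable and autograd-friendly for both
    # numpy arrays and autograd boxes
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def _sigmoid_np(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


# GRU weights are a plain dict (keys W, Urz, Uh, c): autograd registers its
# container logic on the exact ``dict`` type, so no subclassing.
GRUParams = dict


def init_gru(n_in: int, n_hidden: int, rng: np.random.Generator,
             dtype=np.float64) -> GRUParams:
    """Initialize a GRU cell.

    Input weights are scaled ~1/sqrt(n_in); recurrent weights use scaled
    random-normal initialization.  Biases start at zero, which under the gate
    convention above gives a mildly contracting map (h -> ~0.5 h), a safe
    starting point for a generator that must learn oscillations rather than
    saturate.
    """
    w_scale = 1.0 / np.sqrt(max(n_in, 1))
    u_scale = 1.0 / np.sqrt(n_hidden)
    return dict(
        W=rng.normal(0.0, w_scale, (n_in, 3 * n_hidden)).astype(dtype),
        Urz=rng.normal(0.0, u_scale, (n_hidden, 2 * n_hidden)).astype(dtype),
        Uh=rng.normal(0.0, u_scale, (n_hidden, n_hidden)).astype(dtype),
        c=np.zeros(3 * n_hidden, dtype=dtype),
    )


def _gru_forward(W, Urz, Uh, c, x_seq, h0):
    B, T, _ = x_seq.shape
    H = h0.shape[1]
    n_in = W.shape[0]
    a_all = (np.ascontiguousarray(x_seq).reshape(B * T, n_in) @ W + c)
    a_all = a_all.reshape(B, T, 3 * H)
    h = h0
    hs = np.empty((B, T, H), dtype=h0.dtype)
    rs = np.empty((B, T, H), dtype=h0.dtype)
    zs = np.empty((B, T, H), dtype=h0.dtype)
    hhs = np.empty((B, T, H), dtype=h0.dtype)
    for t in range(T):
        a = a_all[:, t]
        urz = h @ Urz
        r = _sigmoid_np(a[:, :H] + urz[:, :H])
        z = _sigmoid_np(a[:, H:2 * H] + urz[:, H:])
        hh = np.tanh(a[:, 2 * H:] + (r * h) @ Uh)
        h = (1.0 - z) * h + z * hh
        hs[:, t] = h
        rs[:, t] = r
        zs[:, t] = z
        hhs[:, t] = hh
    return hs, (rs, zs, hhs)


@primitive
def gru_scan(W, Urz, Uh, c, x_seq, h0):
    """Run a GRU over ``x_seq`` (B, T, n_in) from state ``h0`` (B, H).

    Returns the full state sequence (B, T, H).  Registered as an autograd
    primitive with a hand-written BPTT backward; gradients flow to all six
    arguments.
    """
    hs, cache = _gru_forward(W, Urz, Uh, c, x_seq, h0)
    # strong reference to hs keeps the (output, cache) pairing unambiguous
    gru_scan._fwd_caches.append((hs, cache))
    if len(gru_scan._fwd_caches) > 8:
        gru_scan._fwd_caches.pop(0)
    return hs


gru_scan._fwd_caches = []  # type: ignore[attr-defined]


def _gru_backward(dhs, ans, W, Urz, Uh, c, x_seq, h0):
    B, T, n_in = x_seq.shape
    H = h0.shape[1]
    cache = None
    for stored_hs, stored_cache in getattr(gru_scan, "_fwd_caches", []):
        if stored_hs is ans:
            cache = stored_cache
            break
    if cache is not None:
        rs, zs, hhs = cache
    else:  # cache evicted (too many scans since); recompute activations
        _, (rs, zs, hhs) = _gru_forward(W, Urz, Uh, c, x_seq, h0)
    dt_ = h0.dtype
    dW = np.zeros_like(W)
    dUrz = np.zeros_like(Urz)
    dUh = np.zeros_like(Uh)
    dc = np.zeros_like(c)
    dx = np.empty((B, T, n_in), dtype=dt_)
    dh = np.zeros((B, H), dtype=dt_)
    dhs = np.asarray(dhs, dtype=dt_)
    for t in range(T - 1, -1, -1):
        hprev = ans[:, t - 1] if t > 0 else h0
        r, z, hh = rs[:, t], zs[:, t], hhs[:, t]
        dht = dh + dhs[:, t]
        dz = dht * (hh - hprev)
        dpre_hh = (dht * z) * (1.0 - hh * hh)
        dh = dht * (1.0 - z)
        dUh += (r * hprev).T @ dpre_hh
        drh = dpre_hh @ Uh.T
        dh += drh * r
        dpre_r = (drh * hprev) * r * (1.0 - r)
        dpre_z = dz * z * (1.0 - z)
        dprerz = np.concatenate([dpre_r, dpre_z], axis=1)
        dUrz += hprev.T @ dprerz
        dh += dprerz @ Urz.T
        da = np.concatenate([dprerz, dpre_hh], axis=1)
        dW += x_seq[:, t].T @ da
        dc += da.sum(axis=0)
        dx[:, t] = da @ W.T
    return dW, dUrz, dUh, dc, dx, dh


def _make_vjp(argnum):
    # autograd queries each argument's VJP separately; memoize the full BPTT
    # sweep (keyed by object identity of the output and upstream gradient,
    # with strong references so ids cannot be recycled) so it runs once.
    def vjp(ans, W, Urz, Uh, c, x_seq, h0):
        def apply(g):
            cached = getattr(gru_scan, "_bwd_cache", None)
            if cached is not None and cached[0] is ans and cached[1] is g:
                grads = cached[2]
            else:
                grads = _gru_backward(g, ans, W, Urz, Uh, c, x_seq, h0)
                gru_scan._bwd_cache = (ans, g, grads)
            return grads[argnum]
        return apply
    return vjp


defvjp(gru_scan, *[_make_vjp(i) for i in range(6)])


def gru_cell(params: GRUParams, x, h):
    """One GRU step (autograd-differentiable the ordinary way).

    Used for fixed-point work and Jacobians, where the one-step map F(g, u, b)
    itself is the object of study.  Numerically identical to one step of
    :func:`gru_scan`.
    """
    H = params["Uh"].shape[0]
    a = anp.dot(x, params["W"]) + params["c"]
    urz = anp.dot(h, params["Urz"])
    r = sigmoid(a[..., :H] + urz[..., :H])
    z = sigmoid(a[..., H:2 * H] + urz[..., H:])
    hh = anp.tanh(a[..., 2 * H:] + anp.dot(r * h, params["Uh"]))
    return (1.0 - z) * h + z * hh
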