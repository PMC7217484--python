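"""Minimal numpy neural-network primitives used by the solubility model.

Implements exactly what the architecture needs — gated recurrent unit
(GRU) layers over padded batches, run in both directions for two
subnetworks at once, with manual backpropagation — plus the Adam
optimizer.  The GRU follows the convention with separate input/hidden
weight matrices and two bias vectors per direction per layer (gates
ordered reset, update, new):

    r_t = sigmoid(W_ir x_t + b_ir + W_hr h_{t-1} + b_hr)
    z_t = sigmoid(W_iz x_t + b_iz + W_hz h_{t-1} + b_hz)
    n_t = tanh(  W_in x_t + b_in + r_t * (W_hn h_{t-1} + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

The independent recurrences of one layer (predictor/attention subnet x
forward/backward direction) are stacked along a leading axis S and
advanced with broadcast 3-D matmuls, so each timestep costs a constant
number of BLAS calls regardless of how many recurrences run.

Padding is handled by layout rather than by gating: batches keep real
residues leading and padding trailing in every direction (the backward
direction reverses each row *within its true length*), so padded steps
can never influence real positions, and their parameter gradients
vanish because the upstream gradient is zero there.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Glorot/Xavier uniform draw for a (fan_out, fan_in)-shaped weight."""
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Orthogonal initialization via QR of a Gaussian matrix."""
    rows, cols = shape
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix the sign ambiguity of the decomposition
    return q if rows >= cols else q.T


def init_gru_params(
    rng: np.random.Generator, input_dim: int, hidden_dim: int
) -> dict[str, np.ndarray]:
    """One direction of one layer: Glorot input kernel, orthogonal
    recurrent kernel (per gate block), zero biases."""
    return {
        "W_ih": glorot_uniform(rng, (3 * hidden_dim, input_dim)),
        "W_hh": np.concatenate(
            [orthogonal(rng, (hidden_dim, hidden_dim)) for _ in range(3)], axis=0
        ),
        "b_ih": np.zeros(3 * hidden_dim),
        "b_hh": np.zeros(3 * hidden_dim),
    }


def stack_gru_params(param_dicts: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Stack S per-recurrence parameter dicts into (S, ...) arrays."""
    return {
        "W_ih": np.stack([p["W_ih"] for p in param_dicts]),
        "W_hh": np.stack([p["W_hh"] for p in param_dicts]),
        "b_ih": np.stack([p["b_ih"] for p in param_dicts])[:, None, :],
        "b_hh": np.stack([p["b_hh"] for p in param_dicts])[:, None, :],
    }


def unstack_gru_grads(grads: dict[str, np.ndarray], s: int) -> dict[str, np.ndarray]:
    """Slice stacked gradients back to the per-recurrence layout."""
    return {
        "W_ih": grads["W_ih"][s],
        "W_hh": grads["W_hh"][s],
        "b_ih": grads["b_ih"][s, 0],
        "b_hh": grads["b_hh"][s, 0],
    }


def reverse_within_length(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse rows of a (..., B, T, ...) array over the first ``lengths[b]`` steps.

    The batch and time axes are the last two when ``X.ndim == 2``,
    otherwise axes -3 and -2 (features trailing).  Padding positions
    keep their (trailing) place, so reversed batches retain the
    real-residues-first layout the recurrences rely on.
    """
    t_axis = X.ndim - 1 if X.ndim == 2 else X.ndim - 2
    B, T = X.shape[t_axis - 1], X.shape[t_axis]
    pos = np.arange(T)[None, :]
    lens = np.asarray(lengths)[:, None]
    idx = np.where(pos < lens, lens - 1 - pos, pos)  # (B, T)
    if X.ndim == 2:
        return X[np.arange(B)[:, None], idx]
    return X[..., np.arange(B)[:, None], idx, :]


def gru_forward_stacked(
    X: np.ndarray, params: dict[str, np.ndarray], want_cache: bool = True
) -> tuple[np.ndarray, dict | None]:
    """Advance S independent GRU recurrences over a (S, B, T, D) input.

    Returns hidden states of shape (S, B, T, H).  ``want_cache=False``
    skips storing intermediates (inference only).
    """
    S, B, T, D = X.shape
    H = params["W_hh"].shape[2]
    W_ih_T = params["W_ih"].transpose(0, 2, 1)  # (S, D, 3H)
    W_hh_T = params["W_hh"].transpose(0, 2, 1)  # (S, H, 3H)
    Xp = np.matmul(X.reshape(S, B * T, D), W_ih_T) + params["b_ih"]
    Xp = Xp.reshape(S, B, T, 3 * H)
    b_hh = params["b_hh"]

    dt = X.dtype
    h = np.zeros((S, B, H), dtype=dt)
    out = np.empty((S, B, T, H), dtype=dt)
    if want_cache:
        R = np.empty((S, B, T, H), dtype=dt)
        Z = np.empty((S, B, T, H), dtype=dt)
        N = np.empty((S, B, T, H), dtype=dt)
        Q = np.empty((S, B, T, H), dtype=dt)  # hidden-side preactivation of the n gate
    for t in range(T):
        gh = np.matmul(h, W_hh_T)
        gh += b_hh
        rz = sigmoid(Xp[:, :, t, : 2 * H] + gh[:, :, : 2 * H])
        r = rz[:, :, :H]
        z = rz[:, :, H:]
        q = gh[:, :, 2 * H :]
        n = np.tanh(Xp[:, :, t, 2 * H :] + r * q)
        if want_cache:
            R[:, :, t], Z[:, :, t], N[:, :, t], Q[:, :, t] = r, z, n, q
        h = n + z * (h - n)
        out[:, :, t] = h
    cache = None
    if want_cache:
        cache = {"X": X, "R": R, "Z": Z, "N": N, "Q": Q, "out": out, "params": params}
    return out, cache


def gru_backward_stacked(
    dOut: np.ndarray, cache: dict
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backprop the stacked recurrences; returns (dX, stacked parameter grads)."""
    X, R, Z, N, Q = cache["X"], cache["R"], cache["Z"], cache["N"], cache["Q"]
    out, params = cache["out"], cache["params"]
    S, B, T, H = out.shape
    W_hh = params["W_hh"]  # (S, 3H, H)

    dt = out.dtype
    dA = np.empty((S, B, T, 3 * H), dtype=dt)  # grads of input-side preactivations
    dG = np.empty((S, B, T, 3 * H), dtype=dt)  # grads of hidden-side preactivations
    dh_next = np.zeros((S, B, H), dtype=dt)
    zeros = np.zeros((S, B, H), dtype=dt)
    for t in range(T - 1, -1, -1):
        h_prev = out[:, :, t - 1] if t > 0 else zeros
        r, z, n, q = R[:, :, t], Z[:, :, t], N[:, :, t], Q[:, :, t]
        dh = dOut[:, :, t] + dh_next
        dz = dh * (h_prev - n) * z * (1.0 - z)
        dn = dh * (1.0 - z) * (1.0 - n * n)
        dr = dn * q * r * (1.0 - r)
        dA[:, :, t, :H] = dr
        dA[:, :, t, H : 2 * H] = dz
        dA[:, :, t, 2 * H :] = dn
        dG[:, :, t, :H] = dr
        dG[:, :, t, H : 2 * H] = dz
        dG[:, :, t, 2 * H :] = dn * r
        dh_next = dh * z + np.matmul(dG[:, :, t], W_hh)

    Hprev = np.concatenate([np.zeros((S, B, 1, H), dtype=dt), out[:, :, :-1]], axis=2)
    dA2 = dA.reshape(S, B * T, 3 * H)
    dG2 = dG.reshape(S, B * T, 3 * H)
    grads = {
        "W_ih": np.matmul(dA2.transpose(0, 2, 1), X.reshape(S, B * T, -1)),
        "W_hh": np.matmul(dG2.transpose(0, 2, 1), Hprev.reshape(S, B * T, H)),
        "b_ih": dA2.sum(axis=1, keepdims=True),
        "b_hh": dG2.sum(axis=1, keepdims=True),
    }
    dX = np.matmul(dA2, params["W_ih"]).reshape(X.shape)
    return dX, grads


def bigru_layer_forward(
    inputs: list[np.ndarray],
    lengths: np.ndarray,
    mask: np.ndarray,
    param_dicts: list[dict[str, np.ndarray]],
    want_cache: bool = True,
) -> tuple[list[np.ndarray], dict | None]:
    """One bidirectional layer for several subnetworks at once.

    ``inputs`` holds one (B, T, D) array per subnetwork; ``param_dicts``
    holds the per-direction GRU parameters in the order
    [net0.fwd, net0.bwd, net1.fwd, net1.bwd, ...].  Returns the
    (B, T, 2H) concatenated outputs per subnetwork, zeroed at padding.
    """
    ns = len(inputs)
    stacked_in = np.empty((2 * ns,) + inputs[0].shape, dtype=inputs[0].dtype)
    for k, x in enumerate(inputs):
        stacked_in[2 * k] = x
        stacked_in[2 * k + 1] = reverse_within_length(x, lengths)
    sp = stack_gru_params(param_dicts)
    out, cache = gru_forward_stacked(stacked_in, sp, want_cache)
    results = []
    m = mask[:, :, None]
    for k in range(ns):
        fwd = out[2 * k]
        bwd = reverse_within_length(out[2 * k + 1], lengths)
        results.append(np.concatenate([fwd, bwd], axis=2) * m)
    layer_cache = {"gru": cache, "lengths": lengths, "mask": mask, "ns": ns} if want_cache else None
    return results, layer_cache


def bigru_layer_backward(
    dOuts: list[np.ndarray], cache: dict
) -> tuple[list[np.ndarray], list[dict[str, np.ndarray]]]:
    """Backprop one fused layer; returns per-subnet dX and per-recurrence grads."""
    ns = cache["ns"]
    lengths, mask = cache["lengths"], cache["mask"]
    H = cache["gru"]["out"].shape[3]
    m = mask[:, :, None]
    dStack = np.empty((2 * ns,) + dOuts[0].shape[:2] + (H,), dtype=dOuts[0].dtype)
    for k, dOut in enumerate(dOuts):
        dOut = dOut * m
        dStack[2 * k] = dOut[:, :, :H]
        dStack[2 * k + 1] = reverse_within_length(dOut[:, :, H:], lengths)
    dX, grads = gru_backward_stacked(dStack, cache["gru"])
    dInputs = [
        dX[2 * k] + reverse_within_length(dX[2 * k + 1], lengths) for k in range(ns)
    ]
    per_rec = [unstack_gru_grads(grads, s) for s in range(2 * ns)]
    return dInputs, per_rec


class Adam:
    """Adam with L2 regularization folded into the gradient (weight decay)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
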