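"""GRU and decay-modified GRUI recurrent cells, and the bidirectional runner.

The GRUI cell handles irregular sampling by attenuating the previous hidden
state before gating. Given the per-feature time lag vector d_t (time since the
last observation of each input feature), the decay is

    beta_t = exp(-max(0, W_beta d_t + b_beta))          (componentwise, in (0,1])

and the concatenated-weight update reads

    R_t = sigma(W_r [x_t, h_{t-1} . beta_t] + b_r)
    Hc  = tanh (W_h [x_t, R_t . h_{t-1} . beta_t] + b_h)
    Z_t = sigma(W_z [x_t, h_{t-1} . beta_t] + b_z)
    h_t = (1 - Z_t) . (h_{t-1} . beta_t) + Z_t . Hc

where "." is the Hadamard product and [a, b] concatenation. When every decay
pre-activation is <= 0, beta = 1 and the cell reduces exactly to a standard
(concatenated-weight) GRU. A bidirectional pass runs an independent cell in
each direction (forward with the forward lags, backward with the backward
lags, both from a zero initial state) and averages the two hidden states
per timestep.

Weights live in autodiff tensors so the same forward code serves training;
the public step/run functions accept and return plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "GRUIParams",
    "decay_vector",
    "gru_step",
    "grui_step",
    "run_direction",
    "run_bidirectional",
]

# exp(-x) underflows to exactly 0 near x ~ 745; clipping the decay
# pre-activation at +50 keeps beta >= 1.9e-22 (documented floor 1e-20).
DECAY_PREACT_CLIP = 50.0


@dataclass
class GRUIParams:
    """Concatenated-weight GRUI cell parameters.

    Gate weights act on [x_t, h_{t-1}] so each W_* has shape (H, D_in + H);
    W_beta maps the D_in-dimensional lag vector into hidden space.
    """

    W_r: Tensor
    W_h: Tensor
    W_z: Tensor
    b_r: Tensor
    b_h: Tensor
    b_z: Tensor
    W_beta: Tensor
    b_beta: Tensor

    @property
    def hidden_size(self) -> int:
        return self.W_r.value.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_r.value.shape[1] - self.hidden_size

    @classmethod
    def initialize(cls, input_size: int, hidden_size: int, rng: np.random.Generator):
        """Glorot-uniform gate weights, zero biases."""

        def glorot(out_dim, in_dim):
            limit = np.sqrt(6.0 / (in_dim + out_dim))
            return ad.parameter(rng.uniform(-limit, limit, size=(out_dim, in_dim)))

        zeros = lambda n: ad.parameter(np.zeros(n))
        cat = input_size + hidden_size
        return cls(
            W_r=glorot(hidden_size, cat),
            W_h=glorot(hidden_size, cat),
            W_z=glorot(hidden_size, cat),
            b_r=zeros(hidden_size),
            b_h=zeros(hidden_size),
            b_z=zeros(hidden_size),
            W_beta=glorot(hidden_size, input_size),
            b_beta=zeros(hidden_size),
        )

    @classmethod
    def from_arrays(cls, arrays: dict):
        return cls(**{k: ad.parameter(v) for k, v in arrays.items()})

    def tensors(self) -> list:
        return [
            self.W_r, self.W_h, self.W_z,
            self.b_r, self.b_h, self.b_z,
            self.W_beta, self.b_beta,
        ]

    def arrays(self) -> dict:
        return {
            "W_r": self.W_r.value, "W_h": self.W_h.value, "W_z": self.W_z.value,
            "b_r": self.b_r.value, "b_h": self.b_h.value, "b_z": self.b_z.value,
            "W_beta": self.W_beta.value, "b_beta": self.b_beta.value,
        }


# ---- batched tensor core (shared by public API and the trainer) ----------


def _decay_t(delta: Tensor, params: GRUIParams) -> Tensor:
    pre = ad.linear(delta, params.W_beta, params.b_beta)
    return ad.exp(-ad.clip(ad.relu(pre), hi=DECAY_PREACT_CLIP))


def _cell_t(x: Tensor, h_prev: Tensor, params: GRUIParams, delta: Tensor | None) -> Tensor:
    if delta is not None:
        h_prev = h_prev * _decay_t(delta, params)
    xh = ad.concat([x, h_prev], axis=1)
    r = ad.sigmoid(ad.linear(xh, params.W_r, params.b_r))
    z = ad.sigmoid(ad.linear(xh, params.W_z, params.b_z))
    cand = ad.tanh(
        ad.linear(ad.concat([x, r * h_prev], axis=1), params.W_h, params.b_h)
    )
    return (1.0 - z) * h_prev + z * cand


def _run_direction_t(xs, lags, params: GRUIParams, reverse: bool) -> list:
    """Hidden states in time order; xs/lags are lists of (B, D_in) tensors."""
    T = len(xs)
    B = xs[0].value.shape[0]
    h = Tensor(np.zeros((B, params.hidden_size)))
    order = range(T - 1, -1, -1) if reverse else range(T)
    hidden: list = [None] * T
    for t in order:
        h = _cell_t(xs[t], h, params, lags[t])
        hidden[t] = h
    return hidden


# ---- public numpy-facing API ---------------------------------------------


def _row(x, name, dim=None):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    if dim is not None and x.shape[0] != dim:
        raise ValueError(f"{name} has length {x.shape[0]}, expected {dim}")
    return x[None, :]


def decay_vector(delta_t, params: GRUIParams) -> np.ndarray:
    """beta_t = exp(-max(0, W_beta d_t + b_beta)); components in (0, 1]."""
    delta = _row(delta_t, "delta_t", params.input_size)
    if (delta < 0).any():
        raise ValueError("time lags must be nonnegative")
    return _decay_t(Tensor(delta), params).value[0]


def gru_step(x_t, h_prev, params: GRUIParams) -> np.ndarray:
    """One standard (concatenated-weight) GRU update."""
    x = _row(x_t, "x_t", params.input_size)
    h = _row(h_prev, "h_prev", params.hidden_size)
    return _cell_t(Tensor(x), Tensor(h), params, None).value[0]


def grui_step(x_t, h_prev, delta_t, params: GRUIParams) -> np.ndarray:
    """One GRUI update: decay the hidden state by beta(delta_t), then gate."""
    x = _row(x_t, "x_t", params.input_size)
    h = _row(h_prev, "h_prev", params.hidden_size)
    delta = _row(delta_t, "delta_t", params.input_size)
    if (delta < 0).any():
        raise ValueError("time lags must be nonnegative")
    return _cell_t(Tensor(x), Tensor(h), params, Tensor(delta)).value[0]


def _as_step_list(arr, name):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be (T, D_in)")
    return arr


def run_direction(inputs, lags, params: GRUIParams, direction: str = "forward") -> np.ndarray:
    """Run one GRUI direction over a sequence.

    `inputs` and `lags` are (T, D_in): forward uses the forward lags and
    iterates t = 1..T from a zero state; backward uses the backward lags and
    iterates t = T..1 from a zero state. Returns hidden states (T, H) in
    time order either way.
    """
    inputs = _as_step_list(inputs, "inputs")
    lags = _as_step_list(lags, "lags")
    if inputs.shape != lags.shape:
        raise ValueError("inputs and lags must share the (T, D_in) shape")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if (lags < 0).any():
        raise ValueError("time lags must be nonnegative")
    xs = [Tensor(inputs[t][None, :]) for t in range(inputs.shape[0])]
    ls = [Tensor(lags[t][None, :]) for t in range(inputs.shape[0])]
    hidden = _run_direction_t(xs, ls, params, reverse=(direction == "backward"))
    return np.stack([h.value[0] for h in hidden], axis=0)


def run_bidirectional(inputs, delta_f, delta_b, params_f: GRUIParams,
                      params_b: GRUIParams) -> np.ndarray:
    """Mean of forward and backward GRUI trajectories, (T, H)."""
    if params_f.hidden_size != params_b.hidden_size:
        raise ValueError("forward and backward cells must share hidden size")
    hf = run_direction(inputs, delta_f, params_f, "forward")
    hb = run_direction(inputs, delta_b, params_b, "backward")
    return 0.5 * (hf + hb)
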