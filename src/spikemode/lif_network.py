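"""Discrete-time leaky-integrate-and-fire layer dynamics.

The membrane update per step is

    V_t = ReLU[ w_input^T x_t + lam * V_{t-1} * gate(V_{t-1}) ],
    y_t = step(V_t - V_thresh),

with leak factor ``lam = 1 - dt / t_decay`` (equivalently ``1 - w_leak*dt``
for leak term ``w_leak = 1/t_decay``). ``gate`` is the reset gate: it is 0
whenever the previous potential reached threshold, so every spike is
followed by a reset of the carried-over state. The inner state is clamped
at zero (no negative membrane potentials).

Step-function conventions at the boundary (the two must be consistent so a
spike is always followed by a reset):

* ``step(0) = 1`` — a membrane exactly at threshold spikes;
* ``gate`` at exactly threshold is 0 — that membrane also resets.

The recorded potential ``V`` is the *pre-reset* value at spike steps: the
reset acts on the next step's carry term, exactly as the update is written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .encoding import SpikeTrainBatch
from .errors import ValidationError

DEFAULT_V_THRESH = 1.0
DEFAULT_DT_MS = 5.0
DEFAULT_N_STEPS = 100


@dataclass(frozen=True)
class ThresholdConvention:
    """Values of the two step functions at argument zero.

    Fixed: a membrane exactly at threshold spikes (``theta1_at_zero = 1``)
    and resets on the next step (``theta2_at_zero = 0``).
    """

    theta1_at_zero: int = 1
    theta2_at_zero: int = 0

    def __post_init__(self):
        if (self.theta1_at_zero, self.theta2_at_zero) != (1, 0):
            raise ValidationError(
                "the threshold convention is fixed at theta1(0)=1, theta2(0)=0")


@dataclass
class LIFParams:
    """Parameters of one LIF layer.

    Attributes
    ----------
    w_input : ndarray, shape (n_channels, n_neurons)
        Trainable input weights (negative values allowed).
    t_decay : ndarray, shape (n_neurons,)
        Per-neuron membrane decay time in ms; the leak term is its inverse
        (``w_leak = 1 / t_decay``). Must satisfy ``t_decay >= dt`` so the
        leak factor lies in [0, 1); ``inf`` is admitted as the explicit
        no-leak integrator limit (leak factor exactly 1).
    v_thresh : float
        Spike threshold (dimensionless, 1 by convention).
    dt : float
        Temporal resolution in ms (5 by default).
    n_steps : int
        Number of simulation steps (100 by default: 500 ms / 5 ms).
    """

    w_input: np.ndarray
    t_decay: np.ndarray
    v_thresh: float = DEFAULT_V_THRESH
    dt: float = DEFAULT_DT_MS
    n_steps: int = DEFAULT_N_STEPS
    convention: ThresholdConvention = field(default_factory=ThresholdConvention)

    def __post_init__(self):
        self.w_input = np.asarray(self.w_input, dtype=np.float64)
        self.t_decay = np.asarray(self.t_decay, dtype=np.float64)
        if self.w_input.ndim != 2:
            raise ValidationError("w_input must be (n_channels, n_neurons)")
        if self.t_decay.shape != (self.w_input.shape[1],):
            raise ValidationError("t_decay must have one entry per neuron")
        if np.any(self.t_decay < self.dt):
            raise ValidationError(
                f"t_decay must be >= dt={self.dt} ms for every neuron "
                "(shorter values are sampling artifacts)")
        if self.v_thresh <= 0:
            raise ValidationError("v_thresh must be positive")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValidationError("dt must be positive and n_steps >= 1")

    @property
    def n_channels(self) -> int:
        return self.w_input.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.w_input.shape[1]

    @property
    def w_leak(self) -> np.ndarray:
        """Per-neuron leak term, 1/ms (0 for the integrator limit)."""
        with np.errstate(divide="ignore"):
            return np.where(np.isinf(self.t_decay), 0.0, 1.0 / self.t_decay)

    @property
    def leak_factor(self) -> np.ndarray:
        """Per-step retention factor ``lam = 1 - dt / t_decay`` in [0, 1]."""
        return np.where(np.isinf(self.t_decay), 1.0, 1.0 - self.dt / self.t_decay)


@dataclass
class MembraneTrace:
    """Recorded state of a simulated LIF layer.

    Attributes
    ----------
    V : ndarray, shape (n_samples, n_steps, n_neurons)
        Membrane potential per step; pre-reset at spike steps.
    y : ndarray of uint8, same shape
        Binary output spikes.
    zero_flags : ndarray of bool, same shape
        True where the state carried into the *next* step is zero: the
        potential was clamped at zero, or the neuron spiked (reset). The
        initial resting state (before step 0) is implicitly zero.
    dt : float
        Step duration in ms; step times are ``t_n = (n + 1) * dt``.
    """

    V: np.ndarray
    y: np.ndarray
    zero_flags: np.ndarray
    dt: float

    def output_spikes(self) -> SpikeTrainBatch:
        """The layer's output spike train."""
        return SpikeTrainBatch(spikes=self.y, dt=self.dt)


def lif_step(V_prev: np.ndarray, x_t: np.ndarray, params: LIFParams):
    """One membrane update for a batch of samples.

    Parameters
    ----------
    V_prev : ndarray, shape (n_samples, n_neurons)
        Previous potentials (pre-reset values; the reset gate is applied
        here).
    x_t : ndarray, shape (n_samples, n_channels)
        Input spikes at this step.

    Returns
    -------
    (V_t, y_t) : pair of ndarrays, shape (n_samples, n_neurons)
        New potential (non-negative) and binary output spikes.
    """
    V_prev = np.atleast_2d(np.asarray(V_prev, dtype=np.float64))
    x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    if x_t.shape[1] != params.n_channels or V_prev.shape[1] != params.n_neurons:
        raise ValidationError(
            f"shape mismatch: x_t has {x_t.shape[1]} channels "
            f"(expected {params.n_channels}), V_prev has {V_prev.shape[1]} "
            f"neurons (expected {params.n_neurons})")
    if np.any(V_prev < 0):
        raise ValidationError("V_prev must be non-negative")
    lam = params.leak_factor
    gate = V_prev < params.v_thresh  # theta2(v_thresh - V_prev), theta2(0)=0
    V_t = np.maximum(x_t @ params.w_input + lam * V_prev * gate, 0.0)
    y_t = (V_t >= params.v_thresh).astype(np.uint8)  # theta1(0)=1
    return V_t, y_t


def simulate_layer(spikes: SpikeTrainBatch, params: LIFParams) -> MembraneTrace:
    """Run the layer over a full spike-train batch, recording all state.

    The potential starts at 0. At spike steps the recorded ``V`` is the
    suprathreshold pre-reset value; the reset takes effect in the next
    step's carry term.
    """
    if spikes.n_channels != params.n_channels:
        raise ValidationError(
            f"input has {spikes.n_channels} channels, weights expect "
            f"{params.n_channels}")
    n_steps = spikes.n_steps
    B, H = spikes.n_samples, params.n_neurons
    x = spikes.spikes.astype(np.float64)
    lam = params.leak_factor
    w = params.w_input
    vth = params.v_thresh

    V = np.empty((B, n_steps, H))
    y = np.empty((B, n_steps, H), dtype=np.uint8)
    V_prev = np.zeros((B, H))
    for t in range(n_steps):
        gate = V_prev < vth
        V_t = np.maximum(x[:, t, :] @ w + lam * V_prev * gate, 0.0)
        V[:, t, :] = V_t
        y[:, t, :] = V_t >= vth
        V_prev = V_t
    zero_flags = (V == 0.0) | (y == 1)
    return MembraneTrace(V=V, y=y, zero_flags=zero_flags, dt=spikes.dt)


def readout(hidden: SpikeTrainBatch, w_out: np.ndarray) -> np.ndarray:
    """Spike-count readout: time-normalized spike counts mapped to classes.

    ``score = (sum_t y_t / n_steps) @ w_out``. Normalizing by the number of
    steps keeps scores on the scale of one-hot targets; the argmax is
    unchanged by it.
    """
    w_out = np.asarray(w_out, dtype=np.float64)
    if w_out.ndim != 2 or w_out.shape[0] != hidden.n_channels:
        raise ValidationError(
            f"w_out must be (n_neurons={hidden.n_channels}, n_classes)")
    rates = hidden.spikes.sum(axis=1) / hidden.n_steps
    return rates @ w_out


def predict(scores: np.ndarray) -> np.ndarray:
    """Argmax class per sample; ties break toward the lower class index."""
    return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------------
# Persistence: scalars/conventions as JSON, matrices as HDF5.
# ---------------------------------------------------------------------------

def save_params(params: LIFParams, json_path, h5_path) -> None:
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("w_input", data=params.w_input)
        f.create_dataset("t_decay", data=params.t_decay)
    scalars = {
        "v_thresh": params.v_thresh,
        "dt": params.dt,
        "n_steps": params.n_steps,
        "theta1_at_zero": params.convention.theta1_at_zero,
        "theta2_at_zero": params.convention.theta2_at_zero,
    }
    with open(json_path, "w") as f:
        json.dump(scalars, f, indent=2, sort_keys=True)


def load_params(json_path, h5_path) -> LIFParams:
    with open(json_path) as f:
        scalars = json.load(f)
    with h5py.File(h5_path, "r") as f:
        w_input = f["w_input"][...]
        t_decay = f["t_decay"][...]
    return LIFParams(
        w_input=w_input, t_decay=t_decay, v_thresh=scalars["v_thresh"],
        dt=scalars["dt"], n_steps=scalars["n_steps"],
        convention=ThresholdConvention(scalars["theta1_at_zero"],
                                       scalars["theta2_at_zero"]))
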