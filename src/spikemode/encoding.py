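"""Poisson (rate) encoding of pixel intensities into binary spike trains.

Each pixel intensity on [0, 255] becomes an independent Bernoulli spike
probability ``p = intensity / 255`` per time step; this is the only place
the [0, 255] scale is normalized. Channels are the row-major flattened
pixels, so weights are portable across runs for a fixed image shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic_data import ImageDataset

#: Default simulation length: 500 ms at 5 ms resolution.
DEFAULT_N_STEPS = 100
DEFAULT_DT_MS = 5.0


@dataclass
class SpikeTrainBatch:
    """Binary spike tensor, shape ``(n_samples, n_steps, n_channels)``.

    ``dt`` is the duration of one time step in milliseconds. Values are
    strictly {0, 1}; stored as uint8.
    """

    spikes: np.ndarray
    dt: float = DEFAULT_DT_MS

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 3:
            raise ValidationError("spikes must be (samples, steps, channels)")
        if self.spikes.shape[1] < 1:
            raise ValidationError("n_steps must be >= 1")
        vals = np.unique(self.spikes)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValidationError("spike values must be binary")
        self.spikes = self.spikes.astype(np.uint8)
        if self.dt <= 0:
            raise ValidationError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[2]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt


def poisson_encode(ds: ImageDataset, n_steps: int = DEFAULT_N_STEPS,
                   seed: int = 0, dt: float = DEFAULT_DT_MS) -> SpikeTrainBatch:
    """Encode images as independent per-step Bernoulli spike trains.

    Parameters
    ----------
    ds : ImageDataset
        Images with intensities on [0, 255].
    n_steps : int
        Number of discrete time steps (default 100 = 500 ms / 5 ms).
    seed : int
        RNG seed; encoding is bit-reproducible.
    dt : float
        Step duration in ms (bookkeeping only; the per-step probability is
        intensity/255 independent of dt).
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    p = ds.pixels.reshape(ds.n_samples, -1) / 255.0  # row-major flattening
    rng = np.random.default_rng(seed)
    draws = rng.random((ds.n_samples, n_steps, p.shape[1]))
    spikes = (draws < p[:, None, :]).astype(np.uint8)
    return SpikeTrainBatch(spikes=spikes, dt=dt)


def decode_rate(spikes: SpikeTrainBatch) -> np.ndarray:
    """Empirical per-sample, per-channel spike rate: mean over time, in [0, 1]."""
    return spikes.spikes.mean(axis=1)


# ---------------------------------------------------------------------------
# Persistence: sparse event-list CSV and dense HDF5.
# ---------------------------------------------------------------------------

def to_event_frame(spikes: SpikeTrainBatch) -> pd.DataFrame:
    """Sparse event-list view: columns ``sample, time_step, channel``."""
    s, t, c = np.nonzero(spikes.spikes)
    return pd.DataFrame({"sample": s, "time_step": t, "channel": c})


def save_events_csv(spikes: SpikeTrainBatch, path) -> None:
    to_event_frame(spikes).to_csv(path, index=False)


def load_events_csv(path, n_samples: int, n_steps: int, n_channels: int,
                    dt: float = DEFAULT_DT_MS) -> SpikeTrainBatch:
    df = pd.read_csv(path)
    spikes = np.zeros((n_samples, n_steps, n_channels), dtype=np.uint8)
    spikes[df["sample"], df["time_step"], df["channel"]] = 1
    return SpikeTrainBatch(spikes=spikes, dt=dt)


def save_hdf5(spikes: SpikeTrainBatch, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=spikes.spikes, compression="gzip")
        f.attrs["dt"] = spikes.dt


def load_hdf5(path) -> SpikeTrainBatch:
    with h5py.File(path, "r") as f:
        return SpikeTrainBatch(spikes=f["spikes"][...], dt=float(f.attrs["dt"]))
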