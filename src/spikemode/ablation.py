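"""Cumulative decay-ordered neuron ablation.

Trained binned-uniform models are degraded by removing hidden neurons bin
by bin, ordered by decay time: ascending removes coincidence detectors
first, descending removes integrators first. Ablation masks hidden output
spikes (equivalently zeroes the readout rows); nothing is retrained, and
every step of a curve is evaluated on the same encoded spike trains so the
mask is the only difference between steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import poisson_encode
from .errors import ValidationError
from .lif_network import simulate_layer
from .synthetic_data import ImageDataset, make_dataset, subset
from .training import (DecayInitScheme, Metrics, TrainConfig, TrainedModel,
                       compute_metrics, train)

ORDERS = ("ascending", "descending")


@dataclass
class AblationCurve:
    """Metrics after cumulatively ablating 0, 1, ... n_bins bins."""

    order: str
    steps: list  # list of (n_bins_ablated, Metrics)
    baseline: Metrics

    def accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for _, m in self.steps])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "order": self.order, "n_bins_ablated": n,
            "accuracy": m.accuracy, "macro_f1": m.macro_f1, "auc": m.auc,
        } for n, m in self.steps])


def ablate_cumulative(model: TrainedModel, dataset: ImageDataset,
                      order: str, seed: int = 0,
                      per_neuron: bool = False) -> AblationCurve:
    """Cumulatively ablate decay-time bins and re-evaluate at each step.

    The dataset is encoded once with ``seed`` and the hidden layer simulated
    once; each curve step only changes which neurons' spikes are zeroed
    before the readout. Step 0 is the un-ablated baseline; the final step
    has every hidden neuron ablated. ``per_neuron=True`` ablates one neuron
    at a time (within the same decay ordering) instead of whole bins.

    Raises
    ------
    ValidationError
        For models with a single distinct decay time (ordering undefined)
        or an unknown ``order``.
    """
    if order not in ORDERS:
        raise ValidationError(f"order must be one of {ORDERS}")
    t_decay = model.lif_params.t_decay
    if np.unique(t_decay).size < 2:
        raise ValidationError(
            "ablation ordering is undefined for constant-decay models")

    spikes = poisson_encode(dataset, n_steps=model.lif_params.n_steps,
                            seed=seed, dt=model.lif_params.dt)
    trace = simulate_layer(spikes, model.lif_params)
    counts = trace.y.sum(axis=1) / spikes.n_steps  # (samples, neurons)

    if per_neuron:
        groups = [[h] for h in np.argsort(t_decay, kind="stable")]
    else:
        values = np.unique(t_decay)
        groups = [list(np.flatnonzero(t_decay == v)) for v in values]
    if order == "descending":
        groups = groups[::-1]

    mask = np.ones(t_decay.size)
    steps = []
    baseline = compute_metrics(dataset.labels, (counts * mask) @ model.w_out)
    steps.append((0, baseline))
    for i, grp in enumerate(groups, start=1):
        mask[grp] = 0.0
        metrics = compute_metrics(dataset.labels, (counts * mask) @ model.w_out)
        steps.append((i, metrics))
    return AblationCurve(order=order, steps=steps, baseline=baseline)


def ablation_gap(asc: AblationCurve, desc: AblationCurve) -> float:
    """Mean over steps of (ascending accuracy - descending accuracy).

    Positive values mean removing integrators first hurts more (descending
    curve lies below the ascending one).
    """
    a, d = asc.accuracies(), desc.accuracies()
    if a.size != d.size:
        raise ValidationError("curves have different numbers of steps")
    return float(np.mean(a - d))


def _holdout_split(ds: ImageDataset, test_fraction: float = 0.25):
    """Deterministic tail holdout; balanced because labels cycle classes."""
    n_test = max(ds.n_classes, int(ds.n_samples * test_fraction))
    split = ds.n_samples - n_test
    return subset(ds, np.arange(split)), subset(ds, np.arange(split, ds.n_samples))


def ablation_brightness_sweep(dataset_specs: list, config: TrainConfig,
                              scheme: DecayInitScheme | None = None,
                              eval_seed: int = 0) -> list[dict]:
    """Full generate -> train -> ablate pipeline per brightness level.

    ``dataset_specs`` must contain at least two :class:`DatasetSpec` entries
    (differing in target brightness). For each, a binned-uniform model is
    trained on a holdout split and both ablation curves are computed on the
    held-out samples with a shared encoding seed. Returns one record per
    spec: ``{brightness, ascending, descending, gap}``.
    """
    if len(dataset_specs) < 2:
        raise ValidationError("sweep needs >= 2 brightness levels")
    scheme = scheme or DecayInitScheme(
        mode="binned_uniform",
        n_bins=config.hidden_size // 4, neurons_per_bin=4)
    records = []
    for spec in dataset_specs:
        ds = make_dataset(spec)
        train_ds, test_ds = _holdout_split(ds)
        model = train(train_ds, config, scheme)
        asc = ablate_cumulative(model, test_ds, "ascending", seed=eval_seed)
        desc = ablate_cumulative(model, test_ds, "descending", seed=eval_seed)
        records.append({
            "brightness": ds.mean_brightness(),
            "target_brightness": spec.target_mean_brightness,
            "ascending": asc, "descending": desc,
            "gap": ablation_gap(asc, desc),
        })
    return records
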