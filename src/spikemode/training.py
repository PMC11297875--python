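"""Feed-forward SNN assembly and surrogate-gradient BPTT training.

The network is Poisson encoder -> one dense LIF layer -> spike-count
readout. Training minimizes the mean squared error between time-normalized
readout scores and one-hot labels with Adam. Gradients flow through the
unrolled membrane recurrence; in the backward pass the hard spike function
is replaced by the derivative of a logistic sigmoid of sharpness ``beta``
(the forward pass stays binary). Membrane decay times are never trainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .encoding import SpikeTrainBatch, poisson_encode
from .errors import TrainingError, ValidationError
from .lif_network import LIFParams, readout, simulate_layer
from .synthetic_data import ImageDataset, subset

DECAY_RANGE_MS = (15.0, 480.0)
DEFAULT_N_BINS = 32
DEFAULT_NEURONS_PER_BIN = 4


# ---------------------------------------------------------------------------
# Decay-time initialization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayInitScheme:
    """How per-neuron membrane decay times are assigned.

    ``constant`` gives every neuron the same decay time. ``binned_uniform``
    spreads ``n_bins`` equidistant values over ``decay_range`` (inclusive),
    assigning each value to ``neurons_per_bin`` consecutive neurons. The
    defaults (32 bins of 4 neurons over [15, 480] ms) give 15 ms spacing.
    """

    mode: str
    constant_value: float | None = None
    decay_range: tuple[float, float] = DECAY_RANGE_MS
    n_bins: int = DEFAULT_N_BINS
    neurons_per_bin: int = DEFAULT_NEURONS_PER_BIN

    def __post_init__(self):
        if self.mode not in ("constant", "binned_uniform"):
            raise ValidationError(f"unknown decay init mode {self.mode!r}")
        if self.mode == "constant" and self.constant_value is None:
            raise ValidationError("constant mode requires constant_value")
        lo, hi = self.decay_range
        if not lo < hi:
            raise ValidationError("decay_range must be increasing")
        if self.n_bins < 1 or self.neurons_per_bin < 1:
            raise ValidationError("n_bins and neurons_per_bin must be >= 1")

    def bin_values(self) -> np.ndarray:
        """The distinct decay values, equidistant over the range inclusive."""
        return np.linspace(self.decay_range[0], self.decay_range[1], self.n_bins)


def init_decay(scheme: DecayInitScheme, hidden_size: int) -> np.ndarray:
    """Per-neuron decay times (ms) for a hidden layer of ``hidden_size``.

    For ``binned_uniform`` the layer size must equal
    ``n_bins * neurons_per_bin``; each bin's value goes to a block of
    consecutive neurons.
    """
    if scheme.mode == "constant":
        return np.full(hidden_size, float(scheme.constant_value))
    if scheme.n_bins * scheme.neurons_per_bin != hidden_size:
        raise ValidationError(
            f"binned_uniform needs n_bins*neurons_per_bin == hidden_size, "
            f"got {scheme.n_bins}*{scheme.neurons_per_bin} != {hidden_size}")
    return np.repeat(scheme.bin_values(), scheme.neurons_per_bin)


# ---------------------------------------------------------------------------
# Configuration / results containers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    hidden_size: int = 128
    n_steps: int = 100
    dt: float = 5.0
    epochs: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    surrogate_beta: float = 10.0
    #: if True, the backward pass also differentiates the reset gate via the
    #: surrogate; by default the gate is treated as constant.
    reset_surrogate: bool = False
    seed: int = 0
    k_folds: int = 5

    def __post_init__(self):
        for name in ("hidden_size", "n_steps", "batch_size", "k_folds"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.learning_rate <= 0 or self.surrogate_beta <= 0 or self.dt <= 0:
            raise ValidationError("rates, beta and dt must be positive")


@dataclass
class Metrics:
    """Classification metrics, each in [0, 1]."""

    accuracy: float
    macro_f1: float
    auc: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedModel:
    lif_params: LIFParams
    w_out: np.ndarray
    training_history: list = field(default_factory=list)
    fold_id: int | None = None
    scheme: DecayInitScheme | None = None

    @property
    def n_classes(self) -> int:
        return self.w_out.shape[1]


# ---------------------------------------------------------------------------
# Surrogate gradient and BPTT core
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def surrogate_grad(V: np.ndarray, beta: float = 10.0,
                   v_thresh: float = 1.0) -> np.ndarray:
    """Pseudo-derivative of the spike function at ``V - v_thresh``.

    The logistic-derivative surrogate ``beta * s * (1 - s)`` with
    ``s = sigmoid(beta * (V - v_thresh))``: smooth, non-negative, peaked at
    threshold with maximum ``beta / 4``.
    """
    s = _sigmoid(beta * (np.asarray(V, dtype=np.float64) - v_thresh))
    return beta * s * (1.0 - s)


def _forward(x, w_in, w_out, lam, beta, vth, smoothed):
    """Unrolled forward pass.

    Returns (scores, rate, V) where V is the full potential history. With
    ``smoothed=True`` the readout uses the sigmoid-smoothed spike function
    instead of the hard one (the membrane dynamics are identical either
    way); this variant is exactly differentiable and is what the
    finite-difference checks probe.
    """
    B, T, _ = x.shape
    H = w_in.shape[1]
    V = np.empty((B, T, H))
    V_prev = np.zeros((B, H))
    spike_sum = np.zeros((B, H))
    for t in range(T):
        gate = V_prev < vth
        V_t = np.maximum(x[:, t, :] @ w_in + lam * V_prev * gate, 0.0)
        V[:, t, :] = V_t
        if smoothed:
            spike_sum += _sigmoid(beta * (V_t - vth))
        else:
            spike_sum += V_t >= vth
        V_prev = V_t
    rate = spike_sum / T
    scores = rate @ w_out
    return scores, rate, V


def _backward(x, V, w_in, w_out, lam, beta, vth, dscores, rate,
              reset_surrogate=False):
    """BPTT through the recurrence; spike derivative via the surrogate."""
    B, T, _ = x.shape
    g_w_out = rate.T @ dscores
    grate = dscores @ w_out.T
    gy = grate / T  # same for every step
    g_w_in = np.zeros_like(w_in)
    gcarry = np.zeros((B, w_in.shape[1]))
    for t in range(T - 1, -1, -1):
        V_t = V[:, t, :]
        gV = gy * surrogate_grad(V_t, beta, vth) + gcarry
        gpre = gV * (V_t > 0)
        g_w_in += x[:, t, :].T @ gpre
        if t > 0:
            V_p = V[:, t - 1, :]
            gate = V_p < vth
            d_carry = lam * gate
            if reset_surrogate:
                # also differentiate gate = theta2(vth - V_p) via sigmoid
                d_carry = d_carry - lam * V_p * surrogate_grad(V_p, beta, vth)
            gcarry = gpre * d_carry
    return g_w_in, g_w_out


def loss_and_grads(x, targets, w_in, w_out, lam, beta, vth=1.0,
                   smoothed=False, reset_surrogate=False):
    """MSE loss, its gradients w.r.t. both weight matrices, and the scores.

    ``x`` is the binary input tensor (samples, steps, channels) as float;
    ``targets`` the one-hot label matrix. ``smoothed=True`` makes the loss
    the exactly-differentiable sigmoid-readout variant used in gradient
    checks; the default is the hard forward with surrogate backward.
    """
    scores, rate, V = _forward(x, w_in, w_out, lam, beta, vth, smoothed)
    diff = scores - targets
    loss = float(np.mean(diff**2))
    dscores = 2.0 * diff / diff.size
    g_w_in, g_w_out = _backward(x, V, w_in, w_out, lam, beta, vth, dscores,
                                rate, reset_surrogate)
    return loss, g_w_in, g_w_out, scores


class _Adam:
    """Minimal Adam state for a list of parameter arrays."""

    def __init__(self, params, lr, b1, b2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _one_hot(labels, n_classes):
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def train(dataset: ImageDataset, config: TrainConfig,
          scheme: DecayInitScheme, fold_id: int | None = None,
          encode_seed: int | None = None) -> TrainedModel:
    """Train one SNN on the full given dataset.

    The dataset is Poisson-encoded once (seed derived from ``config.seed``
    unless ``encode_seed`` is given) and the same spike trains are reused
    across epochs. Decay times are assigned by ``scheme`` and are excluded
    from the trainable set. Fully deterministic given the seeds.

    Raises
    ------
    TrainingError
        If the loss becomes non-finite (with epoch/batch context).
    """
    n_classes = dataset.n_classes
    if n_classes < 2:
        raise ValidationError("dataset must contain at least two classes")
    ss = np.random.SeedSequence(config.seed)
    init_seed, enc_seed, shuffle_seed = (s.generate_state(1)[0]
                                         for s in ss.spawn(3))
    if encode_seed is not None:
        enc_seed = encode_seed
    rng = np.random.default_rng(init_seed)

    t_decay = init_decay(scheme, config.hidden_size)
    spikes = poisson_encode(dataset, n_steps=config.n_steps, seed=int(enc_seed),
                            dt=config.dt)
    x_all = spikes.spikes
    targets_all = _one_hot(dataset.labels, n_classes)
    n_channels = spikes.n_channels

    w_in = _glorot(rng, n_channels, config.hidden_size)
    w_out = _glorot(rng, config.hidden_size, n_classes)
    lam = np.where(np.isinf(t_decay), 1.0, 1.0 - config.dt / t_decay)

    opt = _Adam([w_in, w_out], config.learning_rate, config.adam_beta1,
                config.adam_beta2, config.adam_eps)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    history = []
    n = dataset.n_samples
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = x_all[idx].astype(np.float64)
            targets = targets_all[idx]
            loss, g_in, g_out, scores = loss_and_grads(
                x, targets, w_in, w_out, lam, config.surrogate_beta,
                reset_surrogate=config.reset_surrogate)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss {loss} at epoch {epoch}, "
                    f"batch starting {start}", epoch=epoch,
                    batch=start // config.batch_size)
            opt.step([w_in, w_out], [g_in, g_out])
            epoch_loss += loss * len(idx)
            epoch_correct += int(
                (scores.argmax(axis=1) == dataset.labels[idx]).sum())
        history.append({"epoch": epoch, "loss": epoch_loss / n,
                        "accuracy": epoch_correct / n})

    params = LIFParams(w_input=w_in, t_decay=t_decay, dt=config.dt,
                       n_steps=config.n_steps)
    return TrainedModel(lif_params=params, w_out=w_out,
                        training_history=history, fold_id=fold_id,
                        scheme=scheme)


def forward_scores(model: TrainedModel, spikes: SpikeTrainBatch,
                   neuron_mask: np.ndarray | None = None):
    """Simulate the hidden layer and read out class scores.

    ``neuron_mask`` (bool per neuron) forces masked-out neurons' output
    spikes to zero before the readout — the ablation mechanism.

    Returns (scores, trace).
    """
    trace = simulate_layer(spikes, model.lif_params)
    hidden = trace.y
    if neuron_mask is not None:
        hidden = hidden * neuron_mask.astype(np.uint8)[None, None, :]
    scores = readout(SpikeTrainBatch(hidden, dt=spikes.dt), model.w_out)
    return scores, trace


def compute_metrics(labels: np.ndarray, scores: np.ndarray) -> Metrics:
    """Accuracy, macro F1 and macro one-vs-rest ROC AUC from class scores.

    AUC is averaged over the classes present in ``labels``; classes whose
    one-vs-rest split is degenerate are skipped.
    """
    preds = scores.argmax(axis=1)
    acc = accuracy_score(labels, preds)
    f1 = f1_score(labels, preds, average="macro", zero_division=0)
    aucs = []
    for k in range(scores.shape[1]):
        mask = labels == k
        if mask.any() and not mask.all():
            aucs.append(roc_auc_score(mask, scores[:, k]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    return Metrics(accuracy=float(acc), macro_f1=float(f1), auc=auc)


def evaluate(model: TrainedModel, dataset: ImageDataset,
             n_steps: int | None = None, seed: int = 0,
             neuron_mask: np.ndarray | None = None) -> Metrics:
    """Encode with a fresh seed, forward-simulate and score the model."""
    n_steps = n_steps or model.lif_params.n_steps
    spikes = poisson_encode(dataset, n_steps=n_steps, seed=seed,
                            dt=model.lif_params.dt)
    scores, _ = forward_scores(model, spikes, neuron_mask=neuron_mask)
    return compute_metrics(dataset.labels, scores)


def crossvalidate(dataset: ImageDataset, config: TrainConfig,
                  scheme: DecayInitScheme):
    """Stratified, seeded k-fold cross-validation.

    Returns a list of ``(TrainedModel, Metrics, test_indices)`` per fold and
    a summary dict with mean and SD of every metric.
    """
    if config.k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    _, counts = np.unique(dataset.labels, return_counts=True)
    if counts.min() < config.k_folds:
        raise ValidationError(
            f"every class needs >= k_folds={config.k_folds} members "
            f"(smallest class has {counts.min()})")
    skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                          random_state=config.seed)
    results = []
    for fold, (tr_idx, te_idx) in enumerate(
            skf.split(dataset.pixels, dataset.labels)):
        fold_seed = np.random.SeedSequence([config.seed, fold])
        tr_seed, ev_seed = (int(s.generate_state(1)[0])
                            for s in fold_seed.spawn(2))
        fold_config = TrainConfig(**{**asdict(config), "seed": tr_seed})
        model = train(subset(dataset, tr_idx), fold_config, scheme,
                      fold_id=fold)
        metrics = evaluate(model, subset(dataset, te_idx), seed=ev_seed)
        results.append((model, metrics, te_idx))
    summary = {}
    for name in ("accuracy", "macro_f1", "auc"):
        vals = [getattr(m, name) for _, m, _ in results]
        summary[f"{name}_mean"] = float(np.mean(vals))
        summary[f"{name}_sd"] = float(np.std(vals))
    return results, summary


# ---------------------------------------------------------------------------
# Model persistence (JSON for scalars, HDF5 for matrices)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, json_path, h5_path) -> None:
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("w_input", data=model.lif_params.w_input)
        f.create_dataset("t_decay", data=model.lif_params.t_decay)
        f.create_dataset("w_out", data=model.w_out)
    record = {
        "v_thresh": model.lif_params.v_thresh,
        "dt": model.lif_params.dt,
        "n_steps": model.lif_params.n_steps,
        "fold_id": model.fold_id,
        "training_history": model.training_history,
        "scheme": asdict(model.scheme) if model.scheme else None,
    }
    with open(json_path, "w") as f:
        json.dump(record, f, indent=2, sort_keys=True)


def load_model(json_path, h5_path) -> TrainedModel:
    with open(json_path) as f:
        record = json.load(f)
    with h5py.File(h5_path, "r") as f:
        w_in = f["w_input"][...]
        t_decay = f["t_decay"][...]
        w_out = f["w_out"][...]
    params = LIFParams(w_input=w_in, t_decay=t_decay,
                       v_thresh=record["v_thresh"], dt=record["dt"],
                       n_steps=record["n_steps"])
    scheme = None
    if record.get("scheme"):
        s = dict(record["scheme"])
        s["decay_range"] = tuple(s["decay_range"])
        scheme = DecayInitScheme(**s)
    return TrainedModel(lif_params=params, w_out=w_out,
                        training_history=record["training_history"],
                        fold_id=record["fold_id"], scheme=scheme)
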