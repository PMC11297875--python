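"""Synthetic labeled grayscale image datasets.

Generates class-discriminable images with controllable mean brightness on the
[0, 255] intensity scale and controllable pixel-intensity histogram shape:
``near_binary`` (pixels concentrated at {0, peak}, stroke-image-like) or
``graded`` (intensities spread over the value range, photo-like). Each class is a fixed
random template; samples are the template plus truncated Gaussian pixel noise.

Intensities are stored on [0, 255] throughout and are normalized to spike
probabilities exactly once, at the encoder boundary
(:func:`spikemode.encoding.poisson_encode`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

from .errors import UnachievableError, ValidationError

INTENSITY_MODES = ("near_binary", "graded")

#: Default brightness-matching tolerance on the [0, 255] scale.
DEFAULT_BRIGHTNESS_TOL = 0.045


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for a synthetic dataset.

    Parameters
    ----------
    n_samples : int
        Total number of images; distributed over classes as evenly as possible.
    image_side : int
        Images are ``image_side x image_side`` pixels.
    n_classes : int
        Number of distinct class templates (>= 2).
    target_mean_brightness : float
        Desired dataset-wide mean pixel intensity, strictly inside (0, 255).
    intensity_mode : str
        ``"near_binary"`` or ``"graded"``.
    noise_sd : float
        Standard deviation of per-pixel additive Gaussian noise (truncated by
        clipping to [0, 255]).
    seed : int
        Seed for all randomness; generation is bit-reproducible.
    """

    n_samples: int
    image_side: int
    n_classes: int
    target_mean_brightness: float = 70.0
    intensity_mode: str = "near_binary"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if not 0.0 < self.target_mean_brightness < 255.0:
            raise ValidationError(
                "target_mean_brightness must be in (0, 255), got "
                f"{self.target_mean_brightness}"
            )
        if self.intensity_mode not in INTENSITY_MODES:
            raise ValidationError(
                f"intensity_mode must be one of {INTENSITY_MODES}, "
                f"got {self.intensity_mode!r}"
            )
        if self.n_samples < self.n_classes:
            raise ValidationError("need at least one sample per class")
        if self.image_side < 2:
            raise ValidationError("image_side must be >= 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class ImageDataset:
    """Labeled grayscale images.

    Attributes
    ----------
    pixels : ndarray, shape (n_samples, side, side)
        Intensities on [0, 255], float64.
    labels : ndarray of int, shape (n_samples,)
        Class index per sample, in ``[0, n_classes)``.
    meta : dict
        Provenance record (spec fields, transformations applied).
    """

    pixels: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.pixels.ndim != 3:
            raise ValidationError("pixels must be (n_samples, rows, cols)")
        if self.labels.shape != (self.pixels.shape[0],):
            raise ValidationError("labels must have one entry per sample")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValidationError("pixel intensities must lie in [0, 255]")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[1] * self.pixels.shape[2]

    def mean_brightness(self) -> float:
        """Dataset-wide mean intensity on the [0, 255] scale."""
        return float(self.pixels.mean())


def _class_templates(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """One template image per class, each with mean ~ target brightness.

    Templates are thresholded (near_binary) or rank-mapped (graded) smoothed
    random fields, so classes differ in spatial structure while sharing
    brightness statistics.
    """
    side = spec.image_side
    target = spec.target_mean_brightness
    templates = np.empty((spec.n_classes, side, side))
    for k in range(spec.n_classes):
        f = ndimage.gaussian_filter(rng.standard_normal((side, side)),
                                    sigma=max(1.0, side / 8.0))
        if spec.intensity_mode == "near_binary":
            # on-fraction chosen so the peak value stays below 255
            frac = float(np.clip(target / 200.0, target / 255.0 * 1.001, 0.95))
            thresh = np.quantile(f, 1.0 - frac)
            mask = f >= thresh
            n_on = int(mask.sum())
            peak = min(255.0, target * mask.size / max(n_on, 1))
            templates[k] = peak * mask
        else:
            # rank-transform to uniform, then power-map so the mean matches:
            # E[255 * u^gamma] = 255 / (gamma + 1) = target
            ranks = f.ravel().argsort().argsort()
            u = (ranks + 0.5) / f.size
            gamma = 255.0 / target - 1.0
            templates[k] = (255.0 * u**gamma).reshape(side, side)
    return templates


def make_dataset(spec: DatasetSpec) -> ImageDataset:
    """Generate a labeled dataset from a :class:`DatasetSpec`.

    Labels cycle through the classes (``label = i % n_classes``) so class
    counts differ by at most one. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    templates = _class_templates(spec, rng)
    labels = np.arange(spec.n_samples, dtype=np.int64) % spec.n_classes
    pixels = templates[labels]
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=pixels.shape)
        pixels = np.clip(pixels + noise, 0.0, 255.0)
    else:
        pixels = pixels.copy()
    meta = {
        "n_samples": spec.n_samples,
        "image_side": spec.image_side,
        "n_classes": spec.n_classes,
        "target_mean_brightness": spec.target_mean_brightness,
        "intensity_mode": spec.intensity_mode,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return ImageDataset(pixels=pixels, labels=labels, meta=meta)


def adjust_brightness(ds: ImageDataset, target_mean: float,
                      tol: float = DEFAULT_BRIGHTNESS_TOL) -> ImageDataset:
    """Rescale intensities so the dataset mean matches ``target_mean``.

    The transform is multiplicative with clipping to [0, 255]; the scale
    factor is found by bisection (<= 60 iterations) so the post-clip mean is
    within ``tol`` of the target. ``tol`` defaults to 0.045 on the [0, 255]
    scale, the matching tolerance used throughout the analysis.

    Raises
    ------
    ValidationError
        If ``target_mean`` is outside [0, 255].
    UnachievableError
        If no scale factor can reach the target (all-zero data, or target
        above the fully-saturated mean).
    """
    if not 0.0 <= target_mean <= 255.0:
        raise ValidationError(f"target_mean must be in [0, 255], got {target_mean}")
    pixels = ds.pixels
    current = float(pixels.mean())
    if current == target_mean:
        out = ImageDataset(pixels.copy(), ds.labels.copy(), dict(ds.meta))
        out.meta["brightness_scale"] = 1.0
        return out
    if target_mean == 0.0:
        scaled = np.zeros_like(pixels)
        return _adjusted(ds, scaled, 0.0)
    if current == 0.0:
        raise UnachievableError(
            f"cannot reach mean {target_mean} from an all-zero dataset")
    max_mean = 255.0 * float((pixels > 0).mean())
    if target_mean > max_mean - tol:
        raise UnachievableError(
            f"target mean {target_mean} exceeds the saturated maximum "
            f"{max_mean:.3f} for this dataset")

    def post_clip_mean(s: float) -> float:
        return float(np.clip(s * pixels, 0.0, 255.0).mean())

    lo, hi = 0.0, 1.0
    while post_clip_mean(hi) < target_mean:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - guarded by max_mean check
            raise UnachievableError("bisection bracket expansion failed")
    scale = hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = post_clip_mean(mid)
        if abs(m - target_mean) <= tol:
            scale = mid
            break
        if m < target_mean:
            lo = mid
        else:
            hi = mid
        scale = mid
    achieved = post_clip_mean(scale)
    if abs(achieved - target_mean) > tol:
        raise UnachievableError(
            f"bisection reached mean {achieved:.4f}, outside tol {tol} of "
            f"{target_mean}")
    return _adjusted(ds, np.clip(scale * pixels, 0.0, 255.0), scale)


def _adjusted(ds: ImageDataset, pixels: np.ndarray, scale: float) -> ImageDataset:
    meta = dict(ds.meta)
    meta["brightness_scale"] = scale
    meta["target_mean_brightness"] = float(pixels.mean())
    return ImageDataset(pixels, ds.labels.copy(), meta)


def make_spike_fixture(pattern, n_steps: int, n_channels: int, dt: float = 5.0):
    """Build a single-sample spike train from an explicit event list.

    ``pattern`` is an iterable of ``(time_step, channel)`` pairs; duplicate
    events are idempotent (the train stays binary). Intended for constructing
    hand-crafted input trains for single-neuron demonstrations and tests.
    """
    from .encoding import SpikeTrainBatch

    spikes = np.zeros((1, n_steps, n_channels), dtype=np.uint8)
    for t, c in pattern:
        t, c = int(t), int(c)
        if not (0 <= t < n_steps and 0 <= c < n_channels):
            raise ValidationError(
                f"event ({t}, {c}) outside bounds ({n_steps} steps, "
                f"{n_channels} channels)")
        spikes[0, t, c] = 1
    return SpikeTrainBatch(spikes=spikes, dt=dt)


# ---------------------------------------------------------------------------
# Container I/O: HDF5 (pixels + labels + spec attrs) and CSV label manifest.
# Any user-supplied dataset in the same container is accepted by the loader.
# ---------------------------------------------------------------------------

def save_dataset(ds: ImageDataset, path) -> None:
    """Write the dataset to HDF5 (`pixels`, `labels` datasets, meta as attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=ds.pixels)
        f.create_dataset("labels", data=ds.labels)
        for key, val in ds.meta.items():
            if isinstance(val, (int, float, str, np.integer, np.floating)):
                f.attrs[key] = val


def load_dataset(path) -> ImageDataset:
    """Load a dataset from the HDF5 container written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        pixels = f["pixels"][...]
        labels = f["labels"][...]
        meta = {k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in f.attrs.items()}
    return ImageDataset(pixels=pixels, labels=labels, meta=meta)


def save_label_manifest(ds: ImageDataset, path) -> None:
    """Write a `sample,label` CSV manifest."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["sample", "label"])
        for i, lab in enumerate(ds.labels):
            writer.writerow([i, int(lab)])


def subset(ds: ImageDataset, indices) -> ImageDataset:
    """View of the dataset restricted to ``indices`` (copying arrays)."""
    idx = np.asarray(indices)
    return ImageDataset(ds.pixels[idx].copy(), ds.labels[idx].copy(),
                        dict(ds.meta))
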