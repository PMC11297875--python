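# spikemode

Operation-mode analysis of leaky-integrate-and-fire (LIF) spiking neural
networks: when does a neuron act as a **coincidence detector** (short
membrane decay time, spikes only on near-simultaneous input) and when as an
**integrator** (long decay time, accumulates input over long intervals)?

The package provides the full pipeline:

1. **`synthetic_data`** — labeled grayscale image generation with
   controllable mean brightness (on [0, 255]) and intensity-histogram shape
   (near-binary vs. graded), plus brightness matching by bisection and
   hand-crafted spike-train fixtures. HDF5 + CSV containers; any
   user-supplied dataset in the same container is accepted.
2. **`encoding`** — Poisson rate coding: every pixel becomes an independent
   per-time-step Bernoulli spike probability `intensity / 255`.
3. **`lif_network`** — discrete-time LIF layer dynamics with full state
   recording (`V_t = ReLU[w·x_t + (1 − Δt/t_decay)·V_{t−1}·gate]`,
   threshold 1, reset via the gate) and a spike-count readout.
4. **`training`** — surrogate-gradient backpropagation through time
   implemented in NumPy (binary forward pass, logistic-derivative surrogate
   in the backward pass), MSE loss, Adam, stratified five-fold
   cross-validation, and decay-time initializers (`constant` /
   `binned_uniform`: 32 equidistant bins over [15, 480] ms, 15 ms apart,
   4 neurons each). Decay times are never trainable.
5. **`attribution`** — the two operation-mode measures. For every hidden
   output spike, input spikes are backtracked with weight and decay effects
   (`c = w·λ^d`): the *number of contributing input spikes* and the
   *effective integration interval*. A zero-anchored window variant
   decomposes the recorded membrane potential exactly (conservation checked
   to 1e-8 relative).
6. **`mode_analysis`** — origin-constrained line fits of the measure
   scatter per decay time, the slope-vs-decay-time curve, and offset
   powerlaw fits `s(t) = a·t^b + c` with multi-start nonlinear least
   squares.
7. **`ablation`** — cumulative decay-ordered neuron ablation (ascending =
   coincidence detectors first, descending = integrators first) with
   shared-seed re-evaluation, and brightness sweeps of the
   ascending/descending gap.
8. **`experiment` / `cli`** — YAML-configured stage chaining with a single
   master seed, per-stage subdirectories, canonical checksums and a
   manifest.

## CLI

```bash
spikemode run-all --config examples/config.yaml --out runs/demo
# or stage by stage (stages communicate through files in --out):
spikemode generate-data --config examples/config.yaml --out runs/demo
spikemode train        --config examples/config.yaml --out runs/demo
spikemode measure      --config examples/config.yaml --out runs/demo
spikemode analyze      --config examples/config.yaml --out runs/demo
spikemode ablate       --config examples/config.yaml --out runs/demo
```

`--seed` overrides the config's master seed; every stage seed is derived
from it. Outputs: `data/dataset.h5`, `models/fold_*.json|h5` +
`metrics.csv`, `measures/measures.csv`, `analysis/slopes.csv` +
`powerlaw.json`, `ablation/ablation.csv` + `gap.json`, and a
`manifest.json` with canonical checksums (re-running a config reproduces
identical checksums; `spikemode.experiment.load_results` verifies them).

## Library example

```python
import spikemode as sm

ds = sm.make_dataset(sm.DatasetSpec(n_samples=2000, image_side=12,
                                    n_classes=4,
                                    target_mean_brightness=15.0,
                                    noise_sd=4.0, seed=11))
model = sm.train(ds, sm.TrainConfig(), sm.DecayInitScheme(mode="binned_uniform"))
points = sm.measure_model(model, ds, seed=7, max_samples=150)
curve = sm.slope_curve(points)
fit = sm.powerlaw_fit(curve)
print(fit.a, fit.b, fit.c)
```
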