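import numpy as np
import pytest
from scipy.stats import spearmanr

from spikemode.attribution import (MeasurePoint, aggregate_by_decay,
                                   attribute_spike, find_window_start,
                                   measure_model, measure_spikes,
                                   measures_frame)
from spikemode.encoding import SpikeTrainBatch
from spikemode.errors import ConservationError, ValidationError
from spikemode.lif_network import LIFParams, simulate_layer
from spikemode.synthetic_data import make_spike_fixture


def single_neuron(w, t_decay, n_steps=20):
    w = np.asarray(w, dtype=float).reshape(-1, 1)
    return LIFParams(w_input=w, t_decay=np.array([float(t_decay)]),
                     n_steps=n_steps)


class TestFindWindowStart:
    def test_first_spike_anchors_at_simulation_start(self):
        params = single_neuron([0.4], 480.0)
        spikes = make_spike_fixture([(t, 0) for t in range(4)], 10, 1)
        trace = simulate_layer(spikes, params)
        out_step = int(np.flatnonzero(trace.y[0, :, 0])[0])
        assert find_window_start(trace, 0, 0, out_step) == -1

    def test_spike_after_reset_anchors_at_previous_spike(self):
        params = single_neuron([1.5], 480.0)
        spikes = make_spike_fixture([(2, 0), (3, 0)], 10, 1)
        trace = simulate_layer(spikes, params)
        assert trace.y[0, 2, 0] == 1 and trace.y[0, 3, 0] == 1
        assert find_window_start(trace, 0, 0, 3) == 2

    def test_relu_clamp_anchors_window(self):
        # excitation, then an inhibitory volley clamping V to zero at step 3,
        # then excitation to a spike: window starts at the clamp step
        params = LIFParams(w_input=np.array([[0.5], [-2.0]]),
                           t_decay=np.array([480.0]), n_steps=10)
        events = [(0, 0), (1, 0), (3, 1), (4, 0), (5, 0), (6, 0)]
        spikes = make_spike_fixture(events, 10, 2)
        trace = simulate_layer(spikes, params)
        assert trace.V[0, 3, 0] == 0.0
        out_step = int(np.flatnonzero(trace.y[0, :, 0])[0])
        assert out_step > 3
        assert find_window_start(trace, 0, 0, out_step) == 3

    def test_non_spike_rejected(self):
        params = single_neuron([0.1], 60.0)
        spikes = make_spike_fixture([(0, 0)], 5, 1)
        trace = simulate_layer(spikes, params)
        with pytest.raises(ValidationError):
            find_window_start(trace, 0, 0, 2)


class TestAttributeSpike:
    def test_single_strong_spike(self):
        params = single_neuron([1.5], 60.0)
        spikes = make_spike_fixture([(4, 0)], 10, 1)
        trace = simulate_layer(spikes, params)
        att = attribute_spike(trace, spikes, params, 0, 0, 4)
        assert att.n_contributing == 1
        assert att.integration_interval == 0.0
        assert att.conserved_potential == pytest.approx(1.5)

    def test_two_spike_accumulation(self):
        # lam = 0.9 (t_decay = 50 ms at dt = 5): V = 0.6*0.9 + 0.6 = 1.14
        params = single_neuron([0.6], 50.0)
        spikes = make_spike_fixture([(3, 0), (4, 0)], 10, 1)
        trace = simulate_layer(spikes, params)
        assert trace.y[0, 4, 0] == 1
        att = attribute_spike(trace, spikes, params, 0, 0, 4)
        assert att.n_contributing == 2
        assert att.integration_interval == pytest.approx(5.0)
        assert att.conserved_potential == pytest.approx(1.14)
        assert trace.V[0, 4, 0] == pytest.approx(1.14)

    def test_conservation_on_random_instances(self, random_simulation):
        spikes, trace, params = random_simulation
        checked = 0
        for s in range(spikes.n_samples):
            for h in range(params.n_neurons):
                for t in np.flatnonzero(trace.y[s, :, h]):
                    att = attribute_spike(trace, spikes, params, s, h, int(t))
                    rel = abs(att.conserved_potential - trace.V[s, t, h]) \
                        / max(abs(trace.V[s, t, h]), 1.0)
                    assert rel <= 1e-9
                    checked += 1
        assert checked >= 200

    def test_inhibitory_spikes_in_sum_but_not_counted(self):
        params = LIFParams(w_input=np.array([[0.8], [-0.2]]),
                           t_decay=np.array([480.0]), n_steps=10)
        spikes = make_spike_fixture([(0, 0), (1, 1), (2, 0)], 10, 2)
        trace = simulate_layer(spikes, params)
        out_step = int(np.flatnonzero(trace.y[0, :, 0])[0])
        att = attribute_spike(trace, spikes, params, 0, 0, out_step)
        channels = [j for j, _, _ in att.contributions]
        assert 1 in channels  # inhibitory event present in the decomposition
        assert att.n_contributing == 2  # but only the two excitatory count

    def test_corrupted_trace_raises_conservation_error(self):
        params = single_neuron([1.5], 60.0)
        spikes = make_spike_fixture([(4, 0)], 10, 1)
        trace = simulate_layer(spikes, params)
        trace.V[0, 4, 0] += 1e-3
        with pytest.raises(ConservationError):
            attribute_spike(trace, spikes, params, 0, 0, 4)

    def test_window_invariants(self, random_simulation):
        spikes, trace, params = random_simulation
        for s in range(3):
            for h in range(params.n_neurons):
                for t in np.flatnonzero(trace.y[s, :, h])[:5]:
                    att = attribute_spike(trace, spikes, params, s, h, int(t))
                    assert att.window_start < att.out_step
                    steps = [m for _, m, _ in att.contributions]
                    assert all(att.window_start < m <= att.out_step
                               for m in steps)
                    n_window_spikes = len(att.contributions)
                    assert att.n_contributing <= n_window_spikes
                    assert att.integration_interval <= \
                        (att.out_step - att.window_start) * trace.dt


class TestFastPathEquivalence:
    @pytest.mark.parametrize("window", ["zero_anchored", "horizon"])
    def test_measure_spikes_matches_attribute_spike(self, random_simulation,
                                                    window):
        spikes, trace, params = random_simulation
        fast = measure_spikes(spikes, trace, params, window=window)
        for h in range(params.n_neurons):
            slow_counts, slow_intervals = [], []
            for s in range(spikes.n_samples):
                for t in np.flatnonzero(trace.y[s, :, h]):
                    att = attribute_spike(trace, spikes, params, s, h, int(t),
                                          window=window)
                    slow_counts.append(att.n_contributing)
                    slow_intervals.append(att.integration_interval)
            if not slow_counts:
                assert fast[h] is None
                continue
            counts, intervals = fast[h]
            assert np.array_equal(counts, slow_counts)
            assert np.array_equal(intervals, slow_intervals)


@pytest.fixture(scope="module")
def decay_sweep():
    """Fixed Poisson input and fixed weight statistics across a decay sweep
    of 32 neurons covering [15, 480] ms."""
    gen = np.random.default_rng(0)
    n_channels, n_neurons = 60, 32
    t_decay = np.linspace(15.0, 480.0, n_neurons)
    w = np.abs(gen.normal(0.2, 0.05, size=(n_channels, n_neurons)))
    params = LIFParams(w_input=w, t_decay=t_decay, n_steps=100)
    spikes = SpikeTrainBatch(
        (gen.random((40, 100, n_channels)) < 0.06).astype(np.uint8))
    trace = simulate_layer(spikes, params)
    return spikes, trace, params


class TestMeasures:
    def test_memoryless_limit_zero_intervals(self):
        params = LIFParams(w_input=np.full((4, 2), 0.6),
                           t_decay=np.array([5.0, 5.0]), n_steps=30)
        gen = np.random.default_rng(3)
        spikes = SpikeTrainBatch((gen.random((10, 30, 4)) < 0.5).astype(np.uint8))
        trace = simulate_layer(spikes, params)
        for res in measure_spikes(spikes, trace, params):
            assert res is not None
            _, intervals = res
            assert (intervals == 0.0).all()

    def test_sweep_both_measures_increase_with_decay(self, decay_sweep):
        spikes, trace, params = decay_sweep
        res = measure_spikes(spikes, trace, params)
        t_decay, counts, intervals = [], [], []
        for h, r in enumerate(res):
            assert r is not None
            t_decay.append(params.t_decay[h])
            counts.append(r[0].mean())
            intervals.append(r[1].mean())
        assert spearmanr(t_decay, counts).statistic >= 0.9
        assert spearmanr(t_decay, intervals).statistic >= 0.9

    def test_sweep_saturates_for_high_decay(self, decay_sweep):
        spikes, trace, params = decay_sweep
        res = measure_spikes(spikes, trace, params)
        counts = np.array([r[0].mean() for r in res])
        intervals = np.array([r[1].mean() for r in res])
        # difference between the top two decay values is smaller than
        # between the bottom two on matched input
        assert abs(counts[-1] - counts[-2]) < abs(counts[1] - counts[0])
        assert abs(intervals[-1] - intervals[-2]) < abs(intervals[1] - intervals[0])

    def test_silent_neuron_has_no_point(self, tiny_dataset):
        from spikemode.training import TrainedModel
        w = np.zeros((tiny_dataset.n_pixels, 2))
        w[:, 1] = 0.3
        params = LIFParams(w_input=w, t_decay=np.array([15.0, 480.0]),
                           n_steps=30)
        model = TrainedModel(lif_params=params, w_out=np.zeros((2, 4)))
        points = measure_model(model, tiny_dataset, seed=0, max_samples=10)
        assert all(p.neuron == 1 for p in points)

    def test_measure_model_deterministic(self, tiny_binned_model, tiny_dataset):
        a = measure_model(tiny_binned_model, tiny_dataset, seed=4,
                          max_samples=20)
        b = measure_model(tiny_binned_model, tiny_dataset, seed=4,
                          max_samples=20)
        assert measures_frame(a).equals(measures_frame(b))

    def test_measure_model_tags_decay_times(self, tiny_binned_model,
                                            tiny_dataset):
        points = measure_model(tiny_binned_model, tiny_dataset, seed=4,
                               max_samples=20)
        t_decay = tiny_binned_model.lif_params.t_decay
        for p in points:
            assert p.decay_time == t_decay[p.neuron]
            assert p.n_spikes_observed >= 1

    def test_aggregate_by_decay(self):
        points = [
            MeasurePoint(15.0, 10.0, 20.0, neuron=0, n_spikes_observed=5),
            MeasurePoint(15.0, 20.0, 40.0, neuron=1, n_spikes_observed=5),
            MeasurePoint(480.0, 50.0, 100.0, neuron=2, n_spikes_observed=2),
        ]
        agg = aggregate_by_decay(points)
        assert len(agg) == 2
        row = agg[agg.decay_time_ms == 15.0].iloc[0]
        assert row.mean_n_contributing == 15.0
        assert row.mean_interval_ms == 30.0
        assert row.n_neurons == 2

    def test_invalid_window_rejected(self, random_simulation):
        spikes, trace, params = random_simulation
        with pytest.raises(ValidationError):
            measure_spikes(spikes, trace, params, window="flux")
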