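"""Spiking encoder: filter shape, nonlinearity, spike generation, latencies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingsense.encoding import (
    EncodingParams, encode_strain_field, filter_strain, firing_probability,
    first_spike_times, generate_spikes, make_filter,
)


@pytest.fixture(scope="module")
def params():
    return EncodingParams(n_trials=20)


class TestFilter:
    def test_peak_is_one_at_lag_tau(self, params):
        filt = make_filter(params)
        i = int(round(params.tau / params.bin))
        assert filt.taps[i] == pytest.approx(1.0, abs=1e-12)
        assert filt.lags[i] == pytest.approx(params.tau)

    def test_value_at_zero_lag(self, params):
        # cos(5 rad) * exp(-25/16)
        filt = make_filter(params)
        expected = np.cos(5.0) * np.exp(-25.0 / 16.0)
        assert filt.taps[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0595, abs=2e-4)

    def test_bounded_by_one(self, params):
        filt = make_filter(params)
        assert np.all(np.abs(filt.taps) <= 1.0)

    def test_support_length(self, params):
        filt = make_filter(params)
        assert filt.lags[-1] == pytest.approx(params.tau + 4 * params.delta)


class TestFilterStrain:
    def test_zero_strain_gives_zero(self, params):
        filt = make_filter(params)
        out = filter_strain(np.zeros(500), filt)
        assert np.all(out == 0.0)

    def test_impulse_reproduces_kernel(self, params):
        filt = make_filter(params)
        x = np.zeros(500)
        x[30] = 1.0
        out = filter_strain(x, filt)
        n = filt.taps.size
        assert np.allclose(out[30:30 + n], filt.taps, atol=1e-10)
        assert np.allclose(out[:30], 0.0, atol=1e-12)   # causality

    def test_linearity(self, params):
        filt = make_filter(params)
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 400))
        lhs = filter_strain(3.0 * x - 0.5 * y, filt)
        rhs = 3.0 * filter_strain(x, filt) - 0.5 * filter_strain(y, filt)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_too_short_strain_rejected(self, params):
        filt = make_filter(params)
        with pytest.raises(ValueError, match="shorter than the filter"):
            filter_strain(np.zeros(10), filt)


class TestNonlinearity:
    def test_half_maximum_at_threshold(self, params):
        assert firing_probability(np.array([params.beta]), params)[0] == 0.5

    def test_saturation_limits(self, params):
        assert firing_probability(np.array([1e3]), params)[0] == pytest.approx(1.0)
        assert firing_probability(np.array([-1e3]), params)[0] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(-1e-3, 1e-3), st.floats(1e-8, 1e-3))
    def test_strictly_increasing(self, g, dg):
        p = EncodingParams()
        lo, hi = firing_probability(np.array([g, g + dg]), p)
        assert hi >= lo
        if 0 < lo < 1 and 0 < hi < 1:
            assert hi > lo


class TestSpikeGeneration:
    def test_zero_probability_never_spikes(self, params, rng):
        assert generate_spikes(np.zeros(600), params, rng).size == 0

    def test_certain_bin_spikes_every_trial(self, params):
        prob = np.zeros(400)
        prob[123] = 1.0
        for seed in range(5):
            spikes = generate_spikes(prob, params, np.random.default_rng(seed))
            assert spikes.tolist() == [123]

    def test_refractory_suppresses_close_spikes(self, params):
        # two certain bins 5 ms apart: only the first may fire
        prob = np.zeros(400)
        prob[100] = 1.0
        prob[150] = 1.0            # 5 ms later at 0.1 ms bins
        spikes = generate_spikes(prob, params, np.random.default_rng(0))
        assert spikes.tolist() == [100]

    def test_refractory_allows_spacing_beyond_15ms(self, params):
        prob = np.zeros(500)
        prob[[100, 250, 400]] = 1.0   # exactly 15 ms apart
        spikes = generate_spikes(prob, params, np.random.default_rng(0))
        assert spikes.tolist() == [100, 250, 400]

    def test_rate_bounded_by_refractory(self, params, rng):
        # 40 ms of certain firing admits at most ceil(400/150) = 3 spikes
        prob = np.ones(400)
        spikes = generate_spikes(prob, params, rng)
        assert spikes.size == 3
        assert np.all(np.diff(spikes) >= params.refractory_bins)


class TestFirstSpikeTimes:
    def test_earliest_in_window(self):
        spikes = np.array([123, 310])
        assert first_spike_times(spikes, (0, 400), 0.1) == pytest.approx(12.4)

    def test_no_spike_encodes_zero(self):
        assert first_spike_times(np.array([], dtype=int), (0, 400), 0.1) == 0.0
        assert first_spike_times(np.array([450]), (0, 400), 0.1) == 0.0

    def test_boundary_belongs_to_later_wingbeat(self):
        spikes = np.array([400])
        assert first_spike_times(spikes, (0, 400), 0.1) == 0.0
        assert first_spike_times(spikes, (400, 800), 0.1) == pytest.approx(0.1)


class TestEncodeStrainField:
    def test_reproducible_for_fixed_seed(self, grid_pair):
        _, flap, _ = grid_pair
        p = EncodingParams(n_trials=10)
        a = encode_strain_field(flap, p, rng=42)
        b = encode_strain_field(flap, p, rng=42)
        assert np.array_equal(a.first_spike, b.first_spike)

    def test_different_seeds_differ(self, grid_pair):
        _, flap, _ = grid_pair
        p = EncodingParams(n_trials=10)
        a = encode_strain_field(flap, p, rng=1)
        b = encode_strain_field(flap, p, rng=2)
        assert not np.array_equal(a.first_spike, b.first_spike)

    def test_latencies_quantized_and_in_range(self, grid_pair):
        _, flap, _ = grid_pair
        p = EncodingParams(n_trials=10)
        sd = encode_strain_field(flap, p, rng=0)
        fs = sd.first_spike
        assert np.all(fs >= 0)
        assert np.all(fs <= sd.wingbeat_period + 1e-9)
        snapped = np.round(fs / p.bin) * p.bin
        assert np.allclose(fs, snapped, atol=1e-9)
        assert sd.wingbeat_period == pytest.approx(40.0)

    def test_typical_spike_count_logged(self, grid_pair, capsys):
        """Soft check: with the default threshold most sensors fire
        1-2 spikes per wingbeat (logged, not asserted)."""
        _, flap, _ = grid_pair
        p = EncodingParams(n_trials=5)
        sd = encode_strain_field(flap, p, rng=0)
        frac = (sd.first_spike > 0).mean()
        print(f"fraction of (trial, node) pairs with a spike: {frac:.2f}")
        assert 0.0 <= frac <= 1.0


class TestParamValidation:
    def test_bin_exceeding_refractory_rejected(self):
        with pytest.raises(ValueError):
            EncodingParams(bin=20.0, refractory=15.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            EncodingParams(beta=0.0)
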