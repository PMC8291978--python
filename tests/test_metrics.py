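import warnings

import numpy as np
import pytest

from mfgc.metrics import (MetricParams, first_spike_delay, gain_rheobase,
                          hill_fit, spike_synchronization,
                          van_rossum_distance)
from mfgc.stimulus import SpikeTrain


def hill(x, fmax, xhalf, n):
    return fmax / (1.0 + (xhalf / x) ** n)


class TestHillFit:
    def test_noiseless_parameter_recovery(self):
        x = np.linspace(5.0, 1000.0, 20)
        y = hill(x, 100.0, 50.0, 2.0)
        fit = hill_fit(x, y)
        assert fit.f_max == pytest.approx(100.0, rel=1e-3)
        assert fit.x_half == pytest.approx(50.0, rel=1e-3)
        assert fit.exponent == pytest.approx(2.0, rel=1e-3)

    def test_half_max_at_x_half(self):
        x = np.linspace(5.0, 1000.0, 20)
        fit = hill_fit(x, hill(x, 200.0, 80.0, 1.5))
        assert fit.predict(fit.x_half) == pytest.approx(fit.f_max / 2.0,
                                                        rel=1e-9)
        assert fit.offset == fit.x_half

    def test_gain_invariant_to_point_order(self, rng):
        x = np.linspace(10.0, 900.0, 15)
        y = hill(x, 150.0, 120.0, 1.8)
        perm = rng.permutation(x.size)
        a = hill_fit(x, y)
        b = hill_fit(x[perm], y[perm])
        assert a.gain == pytest.approx(b.gain, rel=1e-9)

    def test_all_zero_outputs_degenerate(self):
        x = np.linspace(10.0, 100.0, 6)
        with pytest.raises(ValueError):
            hill_fit(x, np.zeros_like(x))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hill_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestGainRheobase:
    def test_piecewise_linear_fixture(self):
        """f = max(0, 0.5 (I - 10)) sampled at 5 pA steps: first nonzero
        sample at 15 pA, suprathreshold slope 0.5 Hz/pA."""
        import pandas as pd
        I = np.arange(0.0, 45.0, 5.0)
        f = np.maximum(0.0, 0.5 * (I - 10.0))
        out = gain_rheobase(pd.DataFrame({"current_pA": I,
                                          "frequency_Hz": f}))
        assert out["rheobase"] == 15.0
        assert out["gain"] == pytest.approx(0.5, rel=1e-9)

    def test_silent_curve_flagged(self):
        import pandas as pd
        out = gain_rheobase(pd.DataFrame({"current_pA": [0.0, 5.0],
                                          "frequency_Hz": [0.0, 0.0]}))
        assert out["rheobase"] is None and out["gain"] is None


class TestFirstSpikeDelay:
    def test_no_spikes_undefined(self, train_factory):
        assert first_spike_delay(0.0, train_factory([])) is None

    def test_five_ms_delay(self, train_factory):
        assert first_spike_delay(0.1, train_factory([0.105])) == \
            pytest.approx(5.0)

    def test_never_negative(self, train_factory, rng):
        spikes = train_factory(np.sort(rng.uniform(0, 1, 20)))
        for onset in (0.0, 0.3, 0.9):
            d = first_spike_delay(onset, spikes)
            assert d is None or d >= 0.0


class TestVanRossum:
    def test_identical_trains_zero(self, train_factory):
        a = train_factory([0.1, 0.2, 0.5])
        assert van_rossum_distance(a, a) == 0.0

    def test_single_spike_vs_empty(self, train_factory):
        """Analytic value sqrt((1/tau) * integral exp(-2t/tau)) =
        sqrt(1/2) for a spike far from the train end."""
        a = train_factory([0.1])
        b = train_factory([])
        d = van_rossum_distance(a, b)
        assert d == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_distant_spikes_limit(self, train_factory):
        a = train_factory([0.1])
        b = train_factory([0.6])  # separated by 50 kernel time constants
        assert van_rossum_distance(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_exact(self, train_factory, rng):
        a = train_factory(np.sort(rng.uniform(0, 1, 15)))
        b = train_factory(np.sort(rng.uniform(0, 1, 10)))
        assert van_rossum_distance(a, b) == van_rossum_distance(b, a)

    def test_triangle_inequality_random_triplets(self, train_factory, rng):
        for _ in range(100):
            trains = [train_factory(np.sort(rng.uniform(0, 1, rng.integers(0, 12))))
                      for _ in range(3)]
            d_ab = van_rossum_distance(trains[0], trains[1])
            d_bc = van_rossum_distance(trains[1], trains[2])
            d_ac = van_rossum_distance(trains[0], trains[2])
            assert d_ac <= d_ab + d_bc + 1e-12

    def test_squared_option(self, train_factory):
        a = train_factory([0.1])
        b = train_factory([])
        assert van_rossum_distance(a, b, squared=True) == \
            pytest.approx(0.5, abs=1e-9)


class TestSpikeSynchronization:
    def test_identical_trains(self, train_factory):
        a = train_factory([0.1, 0.4, 0.7])
        assert spike_synchronization(a, a) == 1.0

    def test_interleaved_beyond_windows(self, train_factory):
        """Interleaved bursts: every window is at most half the 2 ms
        within-burst ISI, while the nearest cross-train spike is ~0.1 s
        away, so no spike has a coincident partner."""
        a = train_factory([0.100, 0.102, 0.104, 0.300, 0.302, 0.304])
        b = train_factory([0.200, 0.202, 0.204])
        assert spike_synchronization(a, b) == 0.0

    def test_half_coincident_four_spike_fixture(self, train_factory):
        """Hand-computed windows: first pair coincident (|dt| = 1 ms well
        inside the window), second spikes isolated (3 s gap vs window 1)."""
        a = train_factory([1.0, 5.0], duration=10.0)
        b = train_factory([1.001, 8.0], duration=10.0)
        assert spike_synchronization(a, b) == pytest.approx(0.5)

    def test_joint_shift_invariance(self, train_factory, rng):
        base_a = np.sort(rng.uniform(0.1, 0.5, 8))
        base_b = np.sort(rng.uniform(0.1, 0.5, 6))
        a0 = train_factory(base_a)
        b0 = train_factory(base_b)
        shift = 0.3
        a1 = train_factory(base_a + shift)
        b1 = train_factory(base_b + shift)
        assert spike_synchronization(a0, b0) == \
            pytest.approx(spike_synchronization(a1, b1))

    def test_empty_pair_defined_as_one_with_warning(self, train_factory):
        with pytest.warns(UserWarning):
            v = spike_synchronization(train_factory([]), train_factory([]))
        assert v == 1.0

    def test_one_empty_is_zero(self, train_factory):
        assert spike_synchronization(train_factory([]),
                                     train_factory([0.5])) == 0.0

    def test_bounded(self, train_factory, rng):
        for _ in range(20):
            a = train_factory(np.sort(rng.uniform(0, 1, rng.integers(1, 30))))
            b = train_factory(np.sort(rng.uniform(0, 1, rng.integers(1, 30))))
            assert 0.0 <= spike_synchronization(a, b) <= 1.0


def test_metric_params_validation():
    with pytest.raises(ValueError):
        MetricParams(van_rossum_tau=0.0)
    with pytest.raises(ValueError):
        MetricParams(hill_gain_band=(0.6, 0.02))


# property-based checks (derandomized)
from hypothesis import given, settings, strategies as st


@st.composite
def spike_trains(draw, duration=1.0, max_spikes=15):
    n = draw(st.integers(min_value=0, max_value=max_spikes))
    times = sorted(draw(st.lists(
        st.floats(min_value=1e-6, max_value=duration - 1e-6,
                  allow_nan=False), min_size=n, max_size=n, unique=True)))
    return SpikeTrain(np.asarray(times), duration)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(a=spike_trains(), b=spike_trains())
def test_van_rossum_is_symmetric_and_nonnegative(a, b):
    d_ab = van_rossum_distance(a, b)
    assert d_ab >= 0.0
    assert d_ab == van_rossum_distance(b, a)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(a=spike_trains(max_spikes=10), b=spike_trains(max_spikes=10))
def test_spike_synchronization_bounded_and_symmetric(a, b):
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        v = spike_synchronization(a, b)
        assert 0.0 <= v <= 1.0
        assert v == spike_synchronization(b, a)
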