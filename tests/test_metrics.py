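"""Burst metrics against constructed spike trains and synthetic traces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstlab.fixtures import (
    SpikeFixtureSpec,
    TraceFixtureSpec,
    generate_spike_fixture,
    generate_trace_fixture,
)
from burstlab.metrics import (
    InsufficientCyclesError,
    SpikeTrain,
    detect_spikes,
    segment_bursts,
    spikes_per_burst_fit,
    temporal_stats,
    wave_stats,
)


def train(times, refractory=0.01):
    return SpikeTrain(np.asarray(times, dtype=float), refractory=refractory)


class TestSegmentation:
    def test_constructed_two_burst_train(self):
        seg = segment_bursts(train([0.0, 0.1, 0.2, 5.0, 5.1, 5.2]), isi_gap=1.0)
        assert seg.n_bursts == 2
        assert [b.duration for b in seg.bursts] == pytest.approx([0.2, 0.2])
        assert seg.bursts[1].t_first - seg.bursts[0].t_last == pytest.approx(4.8)

    def test_tonic_train_is_one_burst(self):
        t = np.arange(0.0, 10.0, 0.2)
        seg = segment_bursts(train(t), isi_gap=1.0)
        assert seg.n_bursts == 1
        assert seg.bursts[0].n_spikes == t.size

    def test_empty_train(self):
        seg = segment_bursts(train([]), isi_gap=1.0)
        assert seg.n_bursts == 0

    def test_idempotent_resegmentation(self):
        spikes = generate_spike_fixture(SpikeFixtureSpec(n_bursts=5))
        seg1 = segment_bursts(spikes, 1.0)
        seg2 = segment_bursts(spikes, 1.0)
        assert seg1.bursts == seg2.bursts

    def test_refractory_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.0, 0.001]), refractory=0.01)


class TestTemporalStats:
    def test_constructed_train_stats(self):
        # three bursts so the middle cycle is complete on both sides
        seg = segment_bursts(
            train([0.0, 0.1, 0.2, 5.0, 5.1, 5.2, 10.0, 10.1, 10.2]), isi_gap=1.0,
            record_start=-2.0, record_end=12.0,
        )
        st_ = temporal_stats(seg)
        assert st_.mean_period == pytest.approx(5.0)
        assert st_.mean_bd == pytest.approx(0.2)
        assert st_.mean_ibi == pytest.approx(4.8)
        assert st_.mean_duty == pytest.approx(4.0)

    def test_period_additivity_identity(self):
        spikes = generate_spike_fixture(SpikeFixtureSpec(n_bursts=6, jitter=0.02), seed=1)
        st_ = temporal_stats(segment_bursts(spikes, 1.0, record_start=-5.0, record_end=1e9))
        np.testing.assert_allclose(
            st_.periods, st_.burst_durations + st_.interburst_intervals, rtol=0, atol=0
        )

    def test_insufficient_cycles_raises(self):
        seg = segment_bursts(train([0.0, 0.1]), isi_gap=1.0)
        with pytest.raises(InsufficientCyclesError):
            temporal_stats(seg)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_duty_invariant_under_time_rescaling(self, scale):
        base = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2, 10.0, 10.1, 10.2])
        kw = dict(record_start=-2.0, record_end=12.0)
        st_1 = temporal_stats(segment_bursts(train(base), 1.0, **kw))
        st_2 = temporal_stats(
            segment_bursts(train(base * scale, refractory=0.01 * scale), 1.0 * scale,
                           record_start=-2.0 * scale, record_end=12.0 * scale)
        )
        assert st_2.mean_duty == pytest.approx(st_1.mean_duty, rel=1e-12)


class TestDetectSpikes:
    def test_constant_subthreshold_trace_is_empty(self):
        tr = generate_trace_fixture(train([]), TraceFixtureSpec())
        assert len(detect_spikes(tr)) == 0

    def test_fixture_spikes_recovered_within_one_sample(self):
        spec = TraceFixtureSpec(dt=1e-3)
        declared = train([1.0, 1.4, 1.8, 6.0, 6.4])
        tr = generate_trace_fixture(declared, spec)
        got = detect_spikes(tr).times
        assert got.size == 5
        np.testing.assert_allclose(got, declared.times, atol=2 * spec.dt)


class TestWaveStats:
    @staticmethod
    def _staggered(n_cells=5, period=15.0, lag=2.0, n_bursts=8, bd=1.5, spb=4):
        """Posterior-to-anterior wave: last cell leads, each more anterior
        cell delayed by ``lag``."""
        trains = []
        for i in range(n_cells):
            delay = (n_cells - 1 - i) * lag
            spec = SpikeFixtureSpec(
                n_bursts=n_bursts, spikes_per_burst=spb, burst_duration=bd,
                interburst_interval=period - bd, t_start=delay,
            )
            trains.append(generate_spike_fixture(spec))
        return trains

    def test_identical_cells_have_zero_lags(self):
        trains = self._staggered(lag=0.0)
        ws = wave_stats(trains)
        np.testing.assert_allclose(ws.neighbor_phases, 0.0, atol=1e-9)

    def test_known_lag_recovered(self):
        ws = wave_stats(self._staggered(period=15.0, lag=1.95))
        assert ws.mean_neighbor_phase == pytest.approx(100 * 1.95 / 15.0, rel=1e-9)
        assert ws.wave_formed
        assert ws.formation_cycles == 0
        # phase lags relative to the reference accumulate along the chain
        assert ws.reference_phases[0] == pytest.approx(4 * 100 * 1.95 / 15.0, rel=1e-9)

    def test_shift_by_one_period_preserves_phase(self):
        trains = self._staggered(period=15.0, lag=1.5)
        ws1 = wave_stats(trains)
        shifted = list(trains)
        shifted[1] = SpikeTrain(trains[1].times + 15.0, refractory=trains[1].refractory)
        ws2 = wave_stats(shifted)
        assert ws2.neighbor_phases[0] == pytest.approx(ws1.neighbor_phases[0], abs=1e-9)


class TestSpikesPerBurstFit:
    def test_exact_collinear_points(self):
        periods = np.array([15.0, 30.0, 45.0, 60.0])
        counts = 0.4 * periods + 1.0
        slope, intercept, r2 = spikes_per_burst_fit(periods, counts)
        assert slope == pytest.approx(0.4, rel=1e-12)
        assert intercept == pytest.approx(1.0, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(5)
        periods = np.linspace(15.0, 85.0, 10)
        sigma = 0.5
        counts = 0.4 * periods + 1.0 + rng.normal(0, sigma, periods.size)
        slope, _, _ = spikes_per_burst_fit(periods, counts)
        # 3-sigma CI of the OLS slope estimator
        se = sigma / np.sqrt(np.sum((periods - periods.mean()) ** 2))
        assert abs(slope - 0.4) < 3 * se

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError):
            spikes_per_burst_fit([10.0, 10.0, 10.0], [1.0, 2.0, 3.0])
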