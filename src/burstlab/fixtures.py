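"""Deterministic synthetic spike trains, voltage traces and law samples.

These generators make the metrics and fitting machinery testable without
the integrator: the declared statistics (burst duration, interburst
interval, duty cycle, law coefficients) hold exactly before noise, and a
fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import SpikeTrain
from .simulate import Trace

__all__ = [
    "SpikeFixtureSpec",
    "TraceFixtureSpec",
    "LawFixtureSpec",
    "generate_spike_fixture",
    "generate_trace_fixture",
    "generate_law_fixture",
]


@dataclass(frozen=True)
class SpikeFixtureSpec:
    """Template of a periodic bursting spike train."""

    n_bursts: int = 4
    spikes_per_burst: int = 5
    burst_duration: float = 1.0
    interburst_interval: float = 9.0
    t_start: float = 0.0
    jitter: float = 0.0  # s, uniform spike-time jitter (never reorders spikes)

    def __post_init__(self) -> None:
        if self.burst_duration <= 0 or self.interburst_interval <= 0:
            raise ValueError("burst duration and interburst interval must be positive")
        if self.spikes_per_burst < 2:
            raise ValueError("need at least 2 spikes per burst to define its duration")
        isi = self.burst_duration / (self.spikes_per_burst - 1)
        if self.jitter >= 0.5 * isi:
            raise ValueError("jitter must be below half the intra-burst ISI")
        if self.burst_duration >= self.period:
            raise ValueError("burst duration must be below the cycle period")

    @property
    def period(self) -> float:
        return self.burst_duration + self.interburst_interval

    @property
    def duty_cycle(self) -> float:
        return 100.0 * self.burst_duration / self.period


def generate_spike_fixture(spec: SpikeFixtureSpec, seed: int | None = None) -> SpikeTrain:
    """Spike train with exactly the declared BD/IBI/period (pre-jitter)."""
    isi = spec.burst_duration / (spec.spikes_per_burst - 1)
    times = []
    for b in range(spec.n_bursts):
        onset = spec.t_start + b * spec.period
        times.extend(onset + k * isi for k in range(spec.spikes_per_burst))
    times = np.asarray(times)
    if spec.jitter > 0:
        rng = np.random.default_rng(seed)
        inner = np.ones(times.size, dtype=bool)
        times = times + spec.jitter * rng.uniform(-1, 1, times.size) * inner
    return SpikeTrain(times, refractory=min(0.01, 0.5 * isi))


@dataclass(frozen=True)
class TraceFixtureSpec:
    """Voltage-trace template: stereotyped spike waveforms on a baseline.

    Waveforms are triangular and placed so that the upward crossing of
    ``threshold`` falls exactly on the declared spike time.
    """

    baseline: float = -0.045
    spike_peak: float = 0.005
    spike_width: float = 0.02  # s, full width of the triangular waveform
    threshold: float = -0.01  # V, detection threshold the fixture is aligned to
    dt: float = 1e-3
    noise_sigma: float = 0.0  # V


def generate_trace_fixture(
    spikes: SpikeTrain, spec: TraceFixtureSpec, seed: int | None = None,
    t_pad: float = 1.0,
) -> Trace:
    """Synthetic voltage trace whose upward threshold crossings reproduce the
    given spike times to within one sample step."""
    t0 = spikes.times[0] - t_pad if len(spikes) else 0.0
    t1 = (spikes.times[-1] + t_pad) if len(spikes) else 1.0
    t = np.arange(t0, t1, spec.dt)
    v = np.full(t.size, spec.baseline)
    half = 0.5 * spec.spike_width
    # on the rising flank, threshold is reached this long after ramp onset
    rise = half * (spec.threshold - spec.baseline) / (spec.spike_peak - spec.baseline)
    for s in spikes.times:
        peak_t = s + (half - rise)
        mask = np.abs(t - peak_t) < half
        v[mask] = np.maximum(
            v[mask],
            spec.spike_peak - (spec.spike_peak - spec.baseline) * np.abs(t[mask] - peak_t) / half,
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, spec.noise_sigma, v.size)
    states = np.zeros((t.size, 4))
    states[:, 0] = v
    return Trace(times=t, states=states, n_cells=1, spikes=[],
                 metadata={"fixture": True})


@dataclass(frozen=True)
class LawFixtureSpec:
    """Sampler of an inverse-square-root law with multiplicative noise.

    ``form`` is "BD_law" (T = a/sqrt(c - |theta|) + b, samples at
    |theta| = c - offsets) or "IBI_law" (T = a/sqrt(theta_bif - theta) + b,
    samples at theta = theta_bif - offsets).
    """

    form: str
    a: float
    b: float
    critical: float  # c or theta_bif
    offsets: tuple  # positive distances from the critical value, volts
    noise_sigma: float = 0.0  # relative (multiplicative)

    def __post_init__(self) -> None:
        if self.form not in ("BD_law", "IBI_law"):
            raise ValueError("form must be 'BD_law' or 'IBI_law'")
        if any(o <= 0 for o in self.offsets):
            raise ValueError("offsets must be positive")


def generate_law_fixture(spec: LawFixtureSpec, seed: int | None = None):
    """(theta, duration) samples drawn from the law; exact at zero noise."""
    off = np.asarray(spec.offsets, dtype=float)
    durations = spec.a / np.sqrt(off) + spec.b
    if spec.form == "BD_law":
        theta = -(spec.critical - off)  # thetas are negative for this branch
    else:
        theta = spec.critical - off
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        durations = durations * (1.0 + spec.noise_sigma * rng.standard_normal(off.size))
    return theta, durations
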