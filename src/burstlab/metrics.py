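"""Burst metrics: spike detection, burst segmentation, temporal statistics,
pulse-response measurements, and metachronal-wave statistics.

Definitions follow the standard conventions for bursting traces: burst
duration is first spike to last spike of a burst, interburst interval is
last spike of a burst to first spike of the next, cycle period is first
spike to first spike, duty cycle is burst duration over period (percent).
Spikes are split into bursts wherever an interspike interval reaches the
configured gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import DEFAULT_ISI_GAP, PulseSpec, Trace

__all__ = [
    "SpikeTrain",
    "Burst",
    "BurstSegmentation",
    "TemporalStats",
    "WaveStats",
    "detect_spikes",
    "segment_bursts",
    "temporal_stats",
    "latency_to_spike",
    "pulse_burst_duration",
    "wave_stats",
    "spikes_per_burst_fit",
]

DEFAULT_THRESHOLD = -0.01  # V
DEFAULT_REFRACTORY = 0.01  # s


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times with the detection settings used."""

    times: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    refractory: float = DEFAULT_REFRACTORY

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size > 1:
            d = np.diff(t)
            if np.any(d <= 0):
                raise ValueError("spike times must be strictly increasing")
            if np.any(d < self.refractory - 1e-12):
                raise ValueError("consecutive spikes closer than the refractory period")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Burst:
    t_first: float
    t_last: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.t_last - self.t_first


@dataclass(frozen=True)
class BurstSegmentation:
    """Spikes grouped into bursts by an interspike-interval gap."""

    bursts: tuple
    isi_gap: float
    record_start: float
    record_end: float

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def complete_bursts(self) -> tuple:
        """Bursts not clipped by the record edges.

        The first burst is kept only if the record shows a silent gap before
        it; the last one only if a gap follows it.  These edge bursts cannot
        contribute unbiased durations, so means exclude them.
        """
        out = []
        for i, b in enumerate(self.bursts):
            if i == 0 and b.t_first - self.record_start < self.isi_gap:
                continue
            if i == len(self.bursts) - 1 and self.record_end - b.t_last < self.isi_gap:
                continue
            out.append(b)
        return tuple(out)


@dataclass(frozen=True)
class TemporalStats:
    """Per-cycle and mean burst statistics.  ``period[i] = bd[i] + ibi[i]`` exactly."""

    burst_durations: np.ndarray
    interburst_intervals: np.ndarray
    periods: np.ndarray
    duty_cycles: np.ndarray  # percent
    spikes_per_burst: np.ndarray

    @property
    def n_cycles(self) -> int:
        return int(self.periods.size)

    @property
    def mean_bd(self) -> float:
        return float(np.mean(self.burst_durations))

    @property
    def mean_ibi(self) -> float:
        return float(np.mean(self.interburst_intervals))

    @property
    def mean_period(self) -> float:
        return float(np.mean(self.periods))

    @property
    def mean_duty(self) -> float:
        return float(np.mean(self.duty_cycles))

    @property
    def mean_spikes_per_burst(self) -> float:
        return float(np.mean(self.spikes_per_burst))


class InsufficientCyclesError(ValueError):
    """Fewer complete bursts than needed for the requested statistic."""


def detect_spikes(
    trace: Trace,
    threshold: float = DEFAULT_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    cell: int = 0,
    use_events: bool = True,
) -> SpikeTrain:
    """Upward threshold crossings of the voltage of one cell.

    If the trace carries solver-event spike times at the same threshold they
    are used directly (they are far more accurate than sample
    interpolation); otherwise crossings are located by linear interpolation
    between samples.  Crossings within the refractory period of an accepted
    spike are ignored.
    """
    if (
        use_events
        and trace.spikes
        and cell < len(trace.spikes)
        and trace.metadata.get("spike_threshold") == threshold
    ):
        raw = np.asarray(trace.spikes[cell], dtype=float)
    else:
        v = trace.v(cell)
        t = trace.times
        below = v[:-1] < threshold
        above = v[1:] >= threshold
        idx = np.nonzero(below & above)[0]
        frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
        raw = t[idx] + frac * (t[idx + 1] - t[idx])
    kept: list[float] = []
    for s in raw:
        if not kept or s - kept[-1] >= refractory:
            kept.append(float(s))
    return SpikeTrain(np.asarray(kept), threshold, refractory)


def segment_bursts(spikes: SpikeTrain, isi_gap: float = DEFAULT_ISI_GAP,
                   record_start: float | None = None, record_end: float | None = None) -> BurstSegmentation:
    """Split a spike train into bursts wherever an ISI is >= ``isi_gap``."""
    t = spikes.times
    if record_start is None:
        record_start = float(t[0]) if t.size else 0.0
    if record_end is None:
        record_end = float(t[-1]) if t.size else 0.0
    if t.size == 0:
        return BurstSegmentation((), isi_gap, record_start, record_end)
    splits = np.nonzero(np.diff(t) >= isi_gap)[0]
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [t.size - 1]])
    bursts = tuple(Burst(float(t[a]), float(t[b]), int(b - a + 1)) for a, b in zip(starts, ends))
    return BurstSegmentation(bursts, isi_gap, record_start, record_end)


def temporal_stats(seg: BurstSegmentation) -> TemporalStats:
    """Per-cycle burst duration, interburst interval, period and duty cycle.

    A cycle runs from the first spike of one complete burst to the first
    spike of the next burst, so ``n_cycles = n_complete_bursts - 1`` when the
    following burst exists.
    """
    complete = seg.complete_bursts()
    # cycles are anchored on complete bursts followed by any burst
    all_bursts = seg.bursts
    bds, ibis, periods, duties, counts = [], [], [], [], []
    for b in complete:
        i = all_bursts.index(b)
        if i + 1 >= len(all_bursts):
            continue
        nxt = all_bursts[i + 1]
        bd = b.duration
        ibi = nxt.t_first - b.t_last
        bds.append(bd)
        ibis.append(ibi)
        periods.append(bd + ibi)
        duties.append(100.0 * bd / (bd + ibi))
        counts.append(b.n_spikes)
    if len(periods) < 1:
        raise InsufficientCyclesError(
            f"need at least 2 complete bursts, found {len(complete)} "
            f"(of {seg.n_bursts} total)"
        )
    return TemporalStats(
        np.asarray(bds), np.asarray(ibis), np.asarray(periods),
        np.asarray(duties), np.asarray(counts),
    )


def latency_to_spike(trace: Trace, pulse_offset: float | None = None,
                     threshold: float = DEFAULT_THRESHOLD) -> float:
    """Time from the pulse offset to the first subsequent spike.

    ``pulse_offset`` defaults to the value recorded by the pulse protocol in
    the trace metadata.  Raises ``ValueError`` when no spike follows.
    """
    if pulse_offset is None:
        pulse_offset = trace.metadata.get("pulse_offset")
        if pulse_offset is None:
            raise ValueError("trace has no recorded pulse; pass pulse_offset explicitly")
    spikes = detect_spikes(trace, threshold=threshold).times
    after = spikes[spikes > pulse_offset]
    if after.size == 0:
        raise ValueError("no spike after the pulse within the record")
    return float(after[0] - pulse_offset)


def pulse_burst_duration(trace: Trace, pulse_offset: float | None = None,
                         isi_gap: float = DEFAULT_ISI_GAP,
                         threshold: float = DEFAULT_THRESHOLD) -> float:
    """First-to-last spike time of the burst elicited by a pulse.

    The elicited burst is the first burst whose spikes all follow the pulse.
    Raises ``ValueError`` when the pulse elicited no spikes.
    """
    if pulse_offset is None:
        pulse_offset = trace.metadata.get("pulse_offset")
        if pulse_offset is None:
            raise ValueError("trace has no recorded pulse; pass pulse_offset explicitly")
    spikes = detect_spikes(trace, threshold=threshold)
    after = SpikeTrain(spikes.times[spikes.times > pulse_offset], spikes.threshold, spikes.refractory)
    if len(after) == 0:
        raise ValueError("pulse elicited no spikes")
    seg = segment_bursts(after, isi_gap)
    return seg.bursts[0].duration


@dataclass(frozen=True)
class WaveStats:
    """Metachronal-wave summary for a chain.

    ``neighbor_phases`` holds, per anterior/posterior neighbor pair, the
    mean onset lag of the anterior cell behind its posterior neighbor as a
    percentage of the reference cell's period.  ``formation_cycles`` counts
    reference-cell cycles before the wave pattern is stable.
    """

    periods: np.ndarray  # per cell, s
    duty_cycles: np.ndarray  # per cell, %
    neighbor_phases: np.ndarray  # per pair (i, i+1), %
    reference_phases: np.ndarray  # per cell, % relative to the reference cell
    formation_cycles: int
    wave_formed: bool

    @property
    def mean_neighbor_phase(self) -> float:
        return float(np.mean(self.neighbor_phases))


def _burst_onsets(spikes: SpikeTrain, isi_gap: float) -> np.ndarray:
    seg = segment_bursts(spikes, isi_gap)
    return np.asarray([b.t_first for b in seg.bursts])


def wave_stats(
    trains: list[SpikeTrain],
    reference_cell: int = -1,
    isi_gap: float = DEFAULT_ISI_GAP,
    formation_band: float = 0.2,
    min_cycles: int = 3,
) -> WaveStats:
    """Phase structure of a (posterior-reference) chain of bursters.

    ``trains`` is ordered anterior to posterior; the reference cell defaults
    to the last (most posterior).  Per-cycle neighbor lags are
    ``100 * ((onset_i - onset_{i+1}) mod P) / P`` with ``P`` the reference
    period.  The wave counts as formed at the earliest reference cycle after
    which onsets stay ordered posterior-to-anterior and every neighbor lag
    is within ``formation_band`` (relative) of its final-cycle value.
    """
    n = len(trains)
    ref = reference_cell % n
    onsets = [_burst_onsets(tr, isi_gap) for tr in trains]
    ref_onsets = onsets[ref]
    if ref_onsets.size < min_cycles + 1:
        raise ValueError("reference cell has too few bursts for wave statistics")
    period = float(np.mean(np.diff(ref_onsets)))

    # align each cell's onsets to reference cycles: first onset at/after the
    # reference onset (wave travels away from the reference)
    n_cycles = ref_onsets.size - 1
    onset_matrix = np.full((n_cycles, n), np.nan)
    for i in range(n):
        for c in range(n_cycles):
            t0, t1 = ref_onsets[c], ref_onsets[c + 1]
            cand = onsets[i][(onsets[i] >= t0 - 1e-9) & (onsets[i] < t1 - 1e-9)]
            if cand.size:
                onset_matrix[c, i] = cand[0]

    lags = np.full((n_cycles, n - 1), np.nan)  # pair k = (cell k, cell k+1)
    for k in range(n - 1):
        lags[:, k] = 100.0 * np.mod(onset_matrix[:, k] - onset_matrix[:, k + 1], period) / period

    # wave formation: find earliest cycle from which onsets stay ordered
    # posterior-to-anterior and every lag sits in its final-cycle band
    raw_diff = onset_matrix[:, :-1] - onset_matrix[:, 1:]
    final = lags[-1]
    formed_from = None
    for c in range(n_cycles):
        window = lags[c:]
        if np.any(np.isnan(window)):
            continue
        ordered = np.all(raw_diff[c:] > 0.0)
        within = np.all(np.abs(window - final[None, :]) <= formation_band * np.abs(final[None, :]))
        if ordered and within:
            formed_from = c
            break
    wave_formed = formed_from is not None
    use = slice(formed_from if wave_formed else 0, None)

    per_cell_period, per_cell_duty = [], []
    for tr in trains:
        seg = segment_bursts(tr, isi_gap)
        st = temporal_stats(seg)
        per_cell_period.append(st.mean_period)
        per_cell_duty.append(st.mean_duty)

    mean_lags = np.nanmean(lags[use], axis=0)
    ref_phase = np.nanmean(
        100.0 * np.mod(onset_matrix[use] - onset_matrix[use, ref][:, None], period) / period,
        axis=0,
    )
    return WaveStats(
        periods=np.asarray(per_cell_period),
        duty_cycles=np.asarray(per_cell_duty),
        neighbor_phases=mean_lags,
        reference_phases=ref_phase,
        formation_cycles=int(formed_from) if wave_formed else n_cycles,
        wave_formed=wave_formed,
    )


def spikes_per_burst_fit(periods, spike_counts):
    """Ordinary least-squares line of spikes-per-burst against cycle period.

    Returns ``(slope, intercept, r_squared)``.
    """
    x = np.asarray(periods, dtype=float)
    y = np.asarray(spike_counts, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 (period, spike count) pairs")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate abscissa: all periods identical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)
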