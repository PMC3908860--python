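# burstlab

Simulation and bifurcation analysis of a reduced conductance-based
bursting interneuron, for computational neuroscientists studying how a
pair of regulated half-activation voltages controls the timing of
bursting, and how that cellular control scales a crawling-type motor
pattern in a small central pattern generator.

## The science

The model cell (leech-heartbeat interneuron lineage, under a
pharmacological reduction) keeps four currents: fast Na⁺, a slow
non-inactivating K⁺ current `I_K2` (activation `m_K2`, τ = 2 s — the slow
variable), a hyperpolarization-activated current `I_h`, and leak:

    C dV/dt = −I_Na − I_K2 − I_h − I_leak + I_pol + I_ext

Two parameters are regulated: the half-activation voltages θ_K2 and θ_h
of the K2 and h gates.  In the (θ_K2, θ_h) plane, a saddle-node curve of
equilibria (a SNIC: bursting↔silence) and a saddle-node curve of periodic
orbits (a blue-sky catastrophe: bursting↔tonic spiking) intersect at a
codimension-2 point that organizes four regimes: tonic spiking, bursting,
silence, and bistability of spiking and silence.  Near the curves the
passage times obey inverse-square-root laws,

    BD  = a / √(c − |θ_K2|) + b        (burst duration, blue-sky side)
    IBI = a / √(θ_bif − θ_h) + b       (interburst interval / latency, SNIC side)

so coregulating (θ_K2, θ_h) along an isoline of duty cycle scales the
burst period over a wide range while preserving the waveform fractions —
the cellular mechanism behind a period-scalable metachronal wave in a
chain of five inhibitory-coupled bursters (body segments 3–7 of a
crawling larva).

What the package provides, by module:

- `burstlab.model` — the vector field, gating functions, steady-state
  current; calibrated default parameters (see `docs/methods.md`).
- `burstlab.simulate` — high-order adaptive integration (DOP853) with
  event-accurate spike times, attractor settling, current-pulse
  protocols, network integration.
- `burstlab.metrics` — spike detection, burst segmentation, burst
  duration / interburst interval / period / duty cycle, pulse-response
  latency, metachronal-wave phase statistics.
- `burstlab.regimes` — regime classification and maps, boundary
  bisection, inverse-square-root law fits, scaling-exponent estimation,
  duty-cycle isolines.
- `burstlab.slowfast` — slow-fast decomposition (fast subsystem =
  V, h_Na, m_h; slow = m_K2), orbit averaging, saddle-node location for
  equilibria and periodic orbits, codimension-2 intersection.
- `burstlab.chain` — the five-cell inhibitory chain and wave experiments.
- `burstlab.fixtures` / `burstlab.io` / `burstlab.cli` — synthetic test
  fixtures, serialization, and the `burstlab` command-line tool.

## Worked example

```python
import numpy as np
from burstlab import (NeuronParams, run_to_attractor, detect_spikes,
                      segment_bursts, temporal_stats, locate_sn_equilibria)

# endogenous bursting at a reference point of the bursting region
p = NeuronParams(theta_k2=-0.0075, theta_h=0.038)
trace = run_to_attractor(p, t_transient=150.0)
stats = temporal_stats(segment_bursts(detect_spikes(trace)))
print(f"burst duration {stats.mean_bd:.2f} s, interburst {stats.mean_ibi:.2f} s, "
      f"duty {stats.mean_duty:.1f} %")

# the saddle-node of equilibria bounding the silent regime
fold = locate_sn_equilibria(p, theta_k2=-0.010)
print(f"SNIC fold at theta_K2=-0.010: theta_h* = {fold.theta_h:.10f} V")
```

prints (calibrated defaults):

    burst duration 2.80 s, interburst 3.17 s, duty 46.9 %
    SNIC fold at theta_K2=-0.010: theta_h* = 0.0413523801 V

The burst lasts a few seconds because θ_K2 sits 3 mV from the blue-sky
fold; moving θ_K2 toward −0.0105 V lengthens bursts without bound, and
moving θ_h toward the fold value above lengthens the interburst interval
the same way.  The same machinery drives the five-cell chain:

    burstlab chain --theta-k2 0.0059 --theta-h 0.040736 --cycles 8

reports the network period of the posterior (segment-7) cell, per-cell
duty cycles, and the mean segment-to-segment phase lag of the wave.

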