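# Methods

## The model

`burstlab` simulates a reduced conductance-based model of a bursting
interneuron of the leech-heartbeat lineage, in the pharmacological
reduction in which Ca²⁺ currents, synaptic currents and most K⁺ currents
are blocked.  Four currents remain:

- a fast Na⁺ current `I_Na = g_Na · m∞³(V) · h · (V − E_Na)` with
  instantaneous cubic activation (Boltzmann slope 150 V⁻¹, half-activation
  −30.5 mV) and inactivation `h` (slope −500 V⁻¹, half −32.5 mV, time
  constant `τ_hNa`);
- a slow, non-inactivating K⁺ current `I_K2 = g_K2 · m_K2² · (V − E_K)`
  with slope 83 V⁻¹ and τ = 2 s; `m_K2` is the slow variable of the
  burster;
- a hyperpolarization-activated current `I_h = g_h · m_h² · (V − E_h)`
  whose steady state is the double-exponential sigmoid
  `m∞_h = 1/(1 + 2·exp(k₁ x) + exp(k₂ x))` with `x = V + θ_h`
  (the form used for this current throughout the lineage's h-current
  literature), relaxing with time constant `τ_mh(V)`;
- an ohmic leak, plus a constant polarizing current `I_pol`.

Membrane equation: `C dV/dt = −I_Na − I_K2 − I_h − I_leak + I_pol + I_ext`,
with `g_Na, g_K2, g_h, g_leak = 105, 30, 4, 8` nS, `E_Na, E_K, E_h,
E_leak = 45, −70, −21, −46` mV and `C = 2` nF.  Units are volts, seconds,
nA, nS and nF throughout (nS·V = nA, nA/nF·s = V); voltages are never
expressed in millivolts in code.

The two regulated parameters are the half-activation voltages of `m_K2`
and `m_h`.  They enter the exponents as `(V + θ_K2)` and `(V + θ_h)`, so
the physiological half-activation voltages are `−θ_K2` (≈ +6…+11 mV) and
`−θ_h` (≈ −38…−42 mV).

The shape of `m∞_h` matters structurally: the shallow `k₁` component
forms the activation foot around the rest voltage, where the saddle-node
of equilibria (SNIC) lives, while the steep `k₂` component switches the
current off during interspike dips, which is what makes the fold of
periodic orbits nearly independent of θ_h (the published two-parameter
diagram shows that curve as essentially vertical).  A single-Boltzmann
gate steep enough to do the second job cannot reproduce the fold-curve
geometry that pins the first, and vice versa; the double-exponential form
does both.

## Calibration of the under-determined constants

The reference parameterization prints conductances, reversal potentials,
capacitance and the slow time constant, but not the polarizing current,
the h-gate slopes, or the Na-inactivation time constant.  With `k₂ = 500`
fixed at the canonical steep slope, the remaining three are pinned by
published anchor values:

| constant | value | anchor |
|---|---|---|
| `I_pol` | −0.0060040 nA | fold of equilibria at θ_K2 = −0.010 V lies at θ_h = 0.0413523801025906 V |
| `k₁` | 180.743 V⁻¹ | the duty-cycle coregulation path lies on the bursting side of the SNIC curve, grazing it: the fold at θ_K2 = +0.0059 V sits 5·10⁻⁶ V above the path point θ_h = 0.040736 V |
| `τ_hNa` | 0.163303 s | fold of periodic orbits at θ_h = 0.0415 V lies at θ_K2 = −0.010505 V (dynamical bisection on sustained spiking vs burst termination) |

The first two equations involve only the steady-state current, so they
are solved exactly and independently of every time constant; the third is
then a one-dimensional solve.  `scripts/calibrate_model.py` reproduces
the shipped numbers.  Three observations corroborate the structure:

- the calibrated `k₁` lands on 180.7 V⁻¹ — the canonical shallow slope of
  the literature form — and `|I_pol|` on 0.0060 nA, the predecessor
  model's canonical polarizing current, although neither value was
  imposed;
- a further published fold location (θ_K2 = −0.009 V →
  θ_h = 0.0413430845706376 V), *not* used in the calibration, is
  reproduced to 1.7·10⁻⁸ V;
- the freely fitted fold magnitude of the burst-duration law at
  θ_h = 0.040 comes out at 0.01055, within 5·10⁻⁵ V of the published
  0.0105051 — i.e. the fold-of-orbits curve is near-vertical, as
  published.

Two further constants could not be pinned by anchors and were set once:

- **τ_mh.** The literature-style rule at its published scale (0.7–2.4 s)
  makes the interburst trajectory lag the h-gate steady state so strongly
  that it bypasses the saddle-node ghost: the interburst interval
  saturates instead of diverging, and the inverse-square-root law at the
  SNIC boundary is unobservable at any practical parameter offset.  The
  shipped rule keeps the voltage-dependent shape at one tenth the scale,
  `τ_mh(V) = 0.07 + 0.17/(1+exp(−100(V + 0.073)))` s, which restores a
  clean −1/2 scaling regime for offsets of 10⁻⁶–10⁻⁴ V.
- **Na kinetics at this capacitance.** With the predecessor's
  τ_hNa = 0.0405 s the depolarized equilibrium is linearly stable at
  C = 2 nF and the model sits in depolarization block; the calibrated
  value (0.163 s ≈ 4× the predecessor's, the capacitance ratio) restores
  spiking.

Residual, documented mismatches of the re-derived parameterization: the
near-SNIC law prefactor is ≈ 0.054 s·V^½ against the published 0.00688
(its quasi-static value is set by the knee curvature that the fold-curve
anchors fix, so it cannot be matched simultaneously); absolute burst
durations run ~2× short of the published tables (the slow-drive traversal
of the spiking manifold is faster than in the reference model), which
propagates into the duty cycles and periods of the coregulation-path
instantiations.  Every monotonicity and scaling property holds.

## Numerics

- **Integration.** scipy's DOP853 (8th-order Dormand–Prince, adaptive)
  with rtol 10⁻⁹, atol 10⁻¹² and max step 5 ms; the step cap guarantees no
  suprathreshold excursion is stepped over (spikes here are ≳100 ms wide).
  Spike times are solver events (upward crossing of −10 mV), accurate to
  solver tolerance; under 100× tolerance refinement spike times move by
  < 10⁻⁴ s per 100 s of trajectory.  Current pulses are integration-segment
  boundaries, so discontinuous forcing never degrades the order.
- **Burst metrics.** Spike threshold −10 mV with 10 ms refractory; burst
  segmentation at an interspike-interval gap of 1.4 s.  The gap sits
  between this parameterization's longest intra-burst interval (~1.05 s —
  spikes are slow at C = 2 nF) and its shortest interburst interval
  (~1.9 s).  Cycle period = first spike to first spike; duty cycle =
  100·BD/period; partial cycles at record edges are excluded from means.
- **Fold of equilibria.** Two-equation system (steady-state current and
  its V-derivative both zero) solved by a scan-bracketed Newton iteration;
  residuals below 10⁻¹⁰ nA (the derivative residual is limited by
  finite-difference noise).
- **Fold of periodic orbits.** Two methods: (i) averaging — the
  frozen-`m_K2` fast subsystem is continued in `m_K2`, each orbit's slow
  nullcline value `⟨m∞_K2(V)⟩` is trapezoid-averaged over one period
  (Poincaré section V = −30 mV upward, closure tolerance 10⁻⁸), and the
  fold is where `min_m [⟨m∞_K2⟩(m) − m] = 0`; (ii) dynamical bisection on
  sustained spiking versus burst termination, probing from two entry
  points on the manifold (m_K2 = 0.05 and 0.15) because the tonic orbit's
  basin is bounded above in the slow variable.  The averaging estimate is
  biased by a few 10⁻⁴ V (it is first-order in the fast/slow time-scale
  ratio, which is ~0.2 here, not small); (ii) defines the boundary that
  regime classification and the law fits see and is the one used for
  calibration.
- **Law fits.** Trust-region least squares (`scipy.optimize.least_squares`,
  trf) with tolerances 10⁻⁹.  The burst-duration law `T = a/√(c−|θ|) + b`
  fits (a, b, c); the interburst/latency law `T = a/√(θ_bif−θ) + b` fits
  (a, b) with θ_bif fixed at the independently located fold.  Parameter
  recovery is within 5% at 1% multiplicative noise (tested).
- **Pulse protocols.**  The silent protocol settles to rest, applies a
  rectangular pulse, and records until ‖rhs‖ < 10⁻⁸ sustained for 5 s.
  The spiking protocol locks the pulse onset to the most recent spike +
  50 ms (the published protocol does not state the phase; locking makes
  latencies reproducible) and records until five consecutive interspike
  intervals match the attractor period to 0.1%.  Latency is measured from
  pulse offset.  In this parameterization the rebound threshold for
  triggering a burst from rest is near (−0.3 nA, 1 s): the fast `τ_mh`
  lets the rebound decay before the phase point clears the rest basin, so
  the published (−0.1 nA, 30 ms) pulse does not trigger.

## The chain

Five identical cells (segments 3–7, anterior to posterior) coupled by
fast graded inhibitory synapses: activation `s` relaxes with τ = 20 ms
toward `1/(1+exp(−1000(V_pre + 0.0305)))`, and the current onto cell i is
`Σ_j w(j→i) · s_j · (V_i − E_syn)` with `E_syn = −62.5 mV`.  Published
weight magnitudes are not available, only their ordering (nearest
posterior strongest, anterior weakest), so the default scheme is
geometric: `w(j→i) = g_p · 0.5^(j−i−1)` for posterior j, `w(i−1→i) =
0.1·g_p`, with `g_p = 8` nS calibrated once so the fastest coregulated
instantiation forms its wave within two posterior-cell cycles (at 8 nS it
forms within one).  Initial conditions put every cell at the state of the
isolated cell at the voltage minimum between spikes 2 and 3 of a burst
(bursts of two spikes fall back to their last interspike minimum), with
odd-numbered segments displaced by +10⁻⁴ V.

The wave's network period tracks the isolated-cell period to 0.05% at
the fastest instantiation, but degrades to a few percent for the slower
ones: those cells graze the SNIC so closely that the weak anterior
synapse onto the posterior cell perturbs its ghost passage with
inverse-square-root leverage.  The published sub-0.1% tracking therefore
holds here only at the fastest instantiation.

## What the synthetic fixtures emulate

The fixture generators produce periodic burst trains with exactly
declared durations, triangular spike waveforms aligned so threshold
crossings reproduce declared spike times, and law samples with
multiplicative noise.  They exercise the metric and fitting code without
the integrator.  They do not emulate intraburst spike-frequency
adaptation, waveform variability, or channel noise, so passing metric
tests demonstrates correctness of the measurement definitions, not
robustness to biological variability.

## Problem sizes used in tests and the acceptance script

Attractor statistics use ≥150 s of settling and up to 20 recorded cycles;
the regime-map tests use coarse grids and individual points rather than
the full published 114×39 sweep; chain experiments run 8 posterior-cell
cycles; scaling checks use the three fastest coregulation entries; the
scaling-exponent windows are offsets of 10⁻⁶–10⁻⁴ V (SNIC side) and
2.5·10⁻⁴–9·10⁻³ V (orbit-fold side).  These sizes keep every quantity
stable to well inside its stated tolerance while keeping runs to minutes.

## Known limitations

- Constants that the reference shows only in typeset images are
  re-derived through anchor calibration; quantities far from the anchors
  (absolute burst durations, path-instantiation periods and duty cycles)
  carry the structural mismatch described above.
- Period-doubling cascades, chaotic large-amplitude regimes, homoclinic
  and saddle-saddle continuation are out of scope.
- The averaging route to the orbit fold is a first-order approximation
  here, several 10⁻⁴ V from the dynamical boundary; use it for speed and
  the dynamical method for location.
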