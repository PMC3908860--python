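"""Regime classification over the (theta_K2, theta_h) plane, boundary
localization, inverse-square-root law fits, and the duty-cycle-preserving
coregulation path.

Near the two saddle-node borders the passage time through the bifurcation
ghost obeys inverse-square-root laws: burst duration follows
``T = a / sqrt(c - |theta_K2|) + b`` toward the fold of periodic orbits,
and interburst interval / latency follows ``T = a / sqrt(theta_bif -
theta_h) + b`` toward the fold of equilibria.  Fitting these laws to
simulated durations, inverting them, and refining on simulated statistics
yields parameter paths of constant duty cycle across a wide period range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .metrics import (
    DEFAULT_ISI_GAP,
    InsufficientCyclesError,
    detect_spikes,
    segment_bursts,
    temporal_stats,
)
from .model import NeuronParams
from .simulate import SolverConfig, rest_like_state, run_to_attractor, spiking_like_state

__all__ = [
    "RegimeGrid",
    "FitResult",
    "CoregulationPath",
    "classify_regime",
    "map_regimes",
    "find_boundary",
    "bd_law",
    "ibi_law",
    "fit_bd_law",
    "fit_ibi_law",
    "estimate_scaling_exponent",
    "find_duty_isoline",
]

REGIMES = ("silence", "tonic", "bursting", "bistable_tonic_silence", "undecided")


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def _run_label(params, state0, solver, t_transient, isi_gap, min_cycles=3):
    """Label one trajectory: 'silence' | 'tonic' | 'bursting' with stats."""
    tr = run_to_attractor(params, state0, t_transient=t_transient, solver=solver,
                          min_cycles=min_cycles, isi_gap=isi_gap)
    spikes = detect_spikes(tr)
    if len(spikes) == 0:
        return "silence", None
    seg = segment_bursts(spikes, isi_gap)
    record = tr.times[-1] - tr.times[0]
    if seg.n_bursts == 1 and seg.bursts[0].duration > 0.8 * record:
        return "tonic", None
    if seg.n_bursts >= 2:
        try:
            return "bursting", temporal_stats(seg)
        except InsufficientCyclesError:
            return "bursting", None
    return "undecided", None


def classify_regime(
    params: NeuronParams,
    solver: SolverConfig | None = None,
    t_transient: float = 100.0,
    isi_gap: float = DEFAULT_ISI_GAP,
) -> tuple[str, object]:
    """Regime label from two runs (rest-like and spiking-like initial states).

    Both silent -> silence; both tonic -> tonic; bursting from either ->
    bursting; one silent and one tonic -> bistable_tonic_silence.  Returns
    ``(label, stats)`` where stats are the bursting temporal statistics when
    available.
    """
    solver = solver or SolverConfig()
    l_rest, s_rest = _run_label(params, rest_like_state(params), solver, t_transient, isi_gap)
    l_spk, s_spk = _run_label(params, spiking_like_state(params), solver, t_transient, isi_gap)
    stats = s_rest or s_spk
    if "bursting" in (l_rest, l_spk):
        return "bursting", stats
    if l_rest == l_spk:
        return l_rest, stats
    if {l_rest, l_spk} == {"silence", "tonic"}:
        return "bistable_tonic_silence", None
    return "undecided", None


@dataclass(frozen=True)
class RegimeGrid:
    """Per-point regime labels and duty cycles over a rectangular parameter grid."""

    theta_k2_axis: np.ndarray
    theta_h_axis: np.ndarray
    labels: np.ndarray  # (n_k2, n_h) of str
    duty: np.ndarray  # (n_k2, n_h), NaN where not bursting

    def __post_init__(self) -> None:
        for ax in (self.theta_k2_axis, self.theta_h_axis):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be strictly increasing")


def map_regimes(
    params: NeuronParams,
    theta_k2_axis,
    theta_h_axis,
    solver: SolverConfig | None = None,
    t_transient: float = 100.0,
    isi_gap: float = DEFAULT_ISI_GAP,
) -> RegimeGrid:
    """Classify every point of a (theta_K2, theta_h) grid."""
    tk = np.atleast_1d(np.asarray(theta_k2_axis, dtype=float))
    th = np.atleast_1d(np.asarray(theta_h_axis, dtype=float))
    labels = np.empty((tk.size, th.size), dtype=object)
    duty = np.full((tk.size, th.size), np.nan)
    for i, a in enumerate(tk):
        for j, b in enumerate(th):
            lab, stats = classify_regime(
                params.replace(theta_k2=a, theta_h=b), solver, t_transient, isi_gap
            )
            labels[i, j] = lab
            if stats is not None:
                duty[i, j] = stats.mean_duty
    return RegimeGrid(tk, th, labels, duty)


def find_boundary(
    params: NeuronParams,
    axis: str,
    interval: tuple[float, float],
    labels: tuple[str, str],
    fixed: dict | None = None,
    tol: float = 1e-7,
    solver: SolverConfig | None = None,
    t_transient: float = 100.0,
) -> float:
    """Bisect a regime boundary along ``axis`` ("theta_k2" or "theta_h").

    ``labels`` gives the expected labels at the interval ends, which are
    verified before bisection.
    """
    if axis not in ("theta_k2", "theta_h"):
        raise ValueError("axis must be 'theta_k2' or 'theta_h'")
    fixed = fixed or {}
    base = params.replace(**fixed)

    def lab(x: float) -> str:
        return classify_regime(base.replace(**{axis: x}), solver, t_transient)[0]

    a, b = interval
    la, lb = lab(a), lab(b)
    if (la, lb) != tuple(labels):
        raise ValueError(f"bracket labels ({la}, {lb}) do not match expected {labels}")
    while abs(b - a) > tol:
        mid = 0.5 * (a + b)
        if lab(mid) == la:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


# --------------------------------------------------------------------------
# inverse-square-root laws
# --------------------------------------------------------------------------

def bd_law(theta, a, b, c):
    """Burst-duration law ``T = a / sqrt(c - |theta|) + b`` (theta in volts)."""
    return a / np.sqrt(c - np.abs(theta)) + b


def ibi_law(theta, a, b, theta_bif):
    """Interburst/latency law ``T = a / sqrt(theta_bif - theta) + b``."""
    return a / np.sqrt(theta_bif - theta) + b


@dataclass(frozen=True)
class FitResult:
    """Coefficients of an inverse-square-root law fit plus diagnostics."""

    form: str  # "BD_law" | "IBI_law"
    a: float
    b: float
    c: float | None = None  # fitted fold magnitude (BD law only)
    theta_bif: float | None = None  # fixed fold position (IBI law only)
    residual_norm: float = np.nan
    n_points: int = 0

    def __call__(self, theta):
        if self.form == "BD_law":
            return bd_law(theta, self.a, self.b, self.c)
        return ibi_law(theta, self.a, self.b, self.theta_bif)


def fit_bd_law(theta, duration, p0=None, tol: float = 1e-9) -> FitResult:
    """Trust-region least-squares fit of the burst-duration law with
    (a, b, c) free; ``c`` must exceed every sampled |theta|."""
    theta = np.asarray(theta, dtype=float)
    duration = np.asarray(duration, dtype=float)
    if theta.size < 4:
        raise ValueError("need at least 4 points to fit (a, b, c)")
    at = np.abs(theta)
    if p0 is None:
        c0 = at.max() + 0.1 * np.ptp(at) + 1e-6
        a0 = (duration.max() - duration.min()) * np.sqrt(c0 - at.max()) or 1.0
        p0 = (a0, float(duration.min()), c0)

    def res(x):
        a, b, c = x
        if c <= at.max():
            return 1e6 * np.ones_like(duration)
        return bd_law(theta, a, b, c) - duration

    sol = least_squares(res, x0=p0, method="trf", xtol=tol, ftol=tol, gtol=tol,
                        x_scale=[1.0, 1.0, 1e-3])
    if not sol.success:
        raise RuntimeError(f"BD-law fit did not converge: {sol.message}")
    a, b, c = sol.x
    return FitResult("BD_law", float(a), float(b), c=float(c),
                     residual_norm=float(np.linalg.norm(sol.fun)), n_points=theta.size)


def fit_ibi_law(theta, duration, theta_bif: float, p0=None, tol: float = 1e-9) -> FitResult:
    """Least-squares fit of the interburst/latency law with (a, b) free and
    the fold position ``theta_bif`` fixed (it is determined independently by
    the saddle-node location)."""
    theta = np.asarray(theta, dtype=float)
    duration = np.asarray(duration, dtype=float)
    if np.any(theta >= theta_bif):
        raise ValueError("theta_bif must exceed every sampled theta")
    if p0 is None:
        a0 = (duration.max() - duration.min()) * np.sqrt(theta_bif - theta.max()) or 1.0
        p0 = (a0, float(duration.min()))

    def res(x):
        a, b = x
        return ibi_law(theta, a, b, theta_bif) - duration

    sol = least_squares(res, x0=p0, method="trf", xtol=tol, ftol=tol, gtol=tol)
    if not sol.success:
        raise RuntimeError(f"IBI-law fit did not converge: {sol.message}")
    a, b = sol.x
    return FitResult("IBI_law", float(a), float(b), theta_bif=float(theta_bif),
                     residual_norm=float(np.linalg.norm(sol.fun)), n_points=theta.size)


def estimate_scaling_exponent(offsets, durations, baseline: float) -> float:
    """Slope of ``log(T - baseline)`` against ``log(offset)``.

    ``offsets`` are distances of the control parameter from its bifurcation
    value (positive, ideally spanning two or more decades); an exact
    inverse-square-root law gives slope -0.5.
    """
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(durations, dtype=float) - baseline
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("offsets and baseline-corrected durations must be positive")
    lx = np.log(x)
    if np.ptp(lx) < np.log(10):
        raise ValueError("offsets must span at least one decade")
    slope = np.polyfit(lx, np.log(y), 1)[0]
    return float(slope)


# --------------------------------------------------------------------------
# duty-cycle coregulation path
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoregulationPath:
    """Parameter path achieving a target duty cycle across a period range."""

    target_duty: float  # percent
    tolerance: float  # percent, |duty - target| bound per entry
    entries: tuple  # of dicts: theta_k2, theta_h, period, duty, converged


def _measure(params, solver, isi_gap, t_transient, min_cycles=3):
    tr = run_to_attractor(params, t_transient=t_transient, solver=solver,
                          min_cycles=min_cycles, isi_gap=isi_gap)
    st = temporal_stats(segment_bursts(detect_spikes(tr), isi_gap))
    return st.mean_bd, st.mean_ibi


def find_duty_isoline(
    params: NeuronParams,
    bd_fit: FitResult,
    ibi_fit: FitResult,
    target_duty: float,
    period_targets,
    tolerance: float = 0.1,
    solver: SolverConfig | None = None,
    isi_gap: float = DEFAULT_ISI_GAP,
    t_transient: float = 100.0,
    max_iter: int = 8,
    measure=None,
) -> CoregulationPath:
    """Solve for (theta_K2, theta_h) pairs with duty = ``target_duty`` (%)
    at each requested cycle period.

    The fitted laws are inverted for an initial guess (burst duration is
    controlled by theta_K2, interburst interval by theta_h); a damped
    secant iteration on the measured statistics then refines each entry
    until the duty cycle is within ``tolerance`` (percentage points) of the
    target and the period within 0.5% of its target.  ``measure`` may
    replace the simulator with any callable ``(params) -> (bd, ibi)``.
    """
    solver = solver or SolverConfig()
    if measure is None:
        def measure(p):
            return _measure(p, solver, isi_gap, t_transient)
    frac = target_duty / 100.0
    entries = []
    for period in period_targets:
        bd_t, ibi_t = frac * period, (1.0 - frac) * period
        # invert the laws for the initial guess
        tk = -(bd_fit.c - (bd_fit.a / (bd_t - bd_fit.b)) ** 2)
        th = ibi_fit.theta_bif - (ibi_fit.a / (ibi_t - ibi_fit.b)) ** 2
        converged = False
        # finite-difference steps for the 2x2 secant Jacobian
        d_tk, d_th = 2e-5, 2e-6
        bd = ibi = np.nan
        for _ in range(max_iter):
            p = params.replace(theta_k2=tk, theta_h=th)
            bd, ibi = measure(p)
            duty = 100.0 * bd / (bd + ibi)
            if abs(duty - target_duty) <= tolerance and abs(bd + ibi - period) <= 0.005 * period:
                converged = True
                break
            bd_k, ibi_k = measure(params.replace(theta_k2=tk + d_tk, theta_h=th))
            bd_h, ibi_h = measure(params.replace(theta_k2=tk, theta_h=th + d_th))
            jac = np.array([
                [(bd_k - bd) / d_tk, (bd_h - bd) / d_th],
                [(ibi_k - ibi) / d_tk, (ibi_h - ibi) / d_th],
            ])
            try:
                step = np.linalg.solve(jac, [bd_t - bd, ibi_t - ibi])
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, [-5e-4, -5e-5], [5e-4, 5e-5])
            tk, th = tk + step[0], th + step[1]
        entries.append({
            "theta_k2": float(tk), "theta_h": float(th),
            "period": float(bd + ibi), "duty": float(100.0 * bd / (bd + ibi)),
            "converged": bool(converged),
        })
    return CoregulationPath(target_duty, tolerance, tuple(entries))
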