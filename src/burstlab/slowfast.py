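"""Slow-fast decomposition and saddle-node bifurcation location.

The slow variable is the K2 activation ``m_K2`` (time constant 2 s); the
fast subsystem is (V, h_Na, m_h).  Freezing ``m_K2`` as a parameter yields
the manifolds of slow motion: a branch of fast-subsystem equilibria (the
silent phase) and a branch of fast-subsystem limit cycles (the spiking
phase).  Averaging the slow nullcline over each orbit (Pontryagin-Rodygin
averaging) reduces the slow dynamics on the spiking manifold to
``dm/dt = (<m_inf_K2(V)> - m)/tau``; tangency of ``<m_inf_K2>(m)`` with the
identity locates the saddle-node of full-system periodic orbits, and the
fold of the equilibrium branch against the h half-activation parameter
locates the saddle-node of equilibria.  Their intersection in the
(theta_K2, theta_h) plane is the organizing codimension-2 point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from . import _kernels
from .model import NeuronParams, gate_steady_state, steady_state_current, steady_state_current_dv

__all__ = [
    "FastBranch",
    "OrbitPoint",
    "OrbitBranch",
    "BifurcationPoint",
    "fast_equilibria",
    "fast_orbit",
    "orbit_averages",
    "orbit_branch",
    "locate_sn_equilibria",
    "locate_sn_orbits",
    "locate_codim2",
]

POINCARE_V = -0.03  # default section V = POINCARE_V, dV/dt > 0
RESIDUAL_TOL = 1e-10


# --------------------------------------------------------------------------
# fast-subsystem equilibria
# --------------------------------------------------------------------------

def _fast_current(v, params: NeuronParams, m_k2: float):
    """Stationary membrane current of the fast subsystem with m_K2 frozen."""
    v = np.asarray(v, dtype=float)
    m_na = gate_steady_state(v, params.m_na)
    h_na = gate_steady_state(v, params.h_na)
    m_h = params.m_h_inf(v)
    i = (
        params.g_na * m_na**3 * h_na * (v - params.e_na)
        + params.g_k2 * m_k2**2 * (v - params.e_k)
        + params.g_h * m_h**2 * (v - params.e_h)
        + params.g_leak * (v - params.e_leak)
        - params.i_pol
    )
    return i if i.ndim else float(i)


def _fast_jacobian(params: NeuronParams, m_k2: float, y: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    p = params.pack()
    f0 = _kernels.fast_rhs(y.copy(), p, m_k2, np.empty(3)).copy()
    jac = np.empty((3, 3))
    for j in range(3):
        yp = y.copy()
        yp[j] += eps
        jac[:, j] = (_kernels.fast_rhs(yp, p, m_k2, np.empty(3)) - f0) / eps
    return jac


def _roots_on_grid(f, v_grid: np.ndarray) -> list[float]:
    vals = f(v_grid)
    out = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        out.append(brentq(f, v_grid[i], v_grid[i + 1], xtol=1e-14))
    for i in np.nonzero(vals == 0.0)[0]:
        out.append(float(v_grid[i]))
    return sorted(out)


@dataclass(frozen=True)
class FastBranch:
    """Equilibria of the frozen-m_K2 fast subsystem over a grid of m values."""

    m_values: np.ndarray
    equilibria: tuple  # per m: tuple of (V, stable) pairs
    folds: tuple  # m values where the equilibrium count changes

    def count(self, i: int) -> int:
        return len(self.equilibria[i])


def fast_equilibria(
    params: NeuronParams,
    m_values,
    v_window: tuple[float, float] = (-0.07, 0.02),
    n_scan: int = 2000,
) -> FastBranch:
    """All fast-subsystem equilibria for each frozen m_K2 value.

    Roots of the stationary current are found by a sign scan plus Brent
    refinement; stability comes from the eigenvalues of the 3x3 fast
    Jacobian.  Folds (m values where the root count changes) are refined by
    bisection on m.
    """
    m_values = np.asarray(m_values, dtype=float)
    if np.any((m_values < 0) | (m_values > 1)):
        raise ValueError("m_K2 values must lie in [0, 1]")
    v_grid = np.linspace(*v_window, n_scan)

    def eq_at(m: float):
        roots = _roots_on_grid(lambda v: _fast_current(v, params, m), v_grid)
        out = []
        for v in roots:
            y = np.array([
                v,
                gate_steady_state(v, params.h_na),
                params.m_h_inf(v),
            ])
            lam = np.linalg.eigvals(_fast_jacobian(params, m, y))
            out.append((float(v), bool(np.all(lam.real < 0))))
        return tuple(out)

    eqs = [eq_at(m) for m in m_values]
    folds = []
    for i in range(len(m_values) - 1):
        if len(eqs[i]) != len(eqs[i + 1]):
            a, b = m_values[i], m_values[i + 1]
            na = len(eqs[i])
            while b - a > 1e-10:
                mid = 0.5 * (a + b)
                if len(eq_at(mid)) == na:
                    a = mid
                else:
                    b = mid
            folds.append(0.5 * (a + b))
    return FastBranch(m_values, tuple(eqs), tuple(folds))


# --------------------------------------------------------------------------
# fast-subsystem orbits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OrbitPoint:
    """One fast-subsystem limit cycle at a frozen m_K2 value."""

    m_k2: float
    period: float
    times: np.ndarray  # one period, starting on the Poincare section
    states: np.ndarray  # (n, 3): V, h_Na, m_h
    v_max: float
    v_min: float
    closure: float  # |state(T) - state(0)|

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 0]


class NoOscillationError(RuntimeError):
    """The fast subsystem settles to an equilibrium at this m_K2 (branch endpoint)."""


def fast_orbit(
    params: NeuronParams,
    m_k2: float,
    y0: np.ndarray | None = None,
    t_settle: float = 40.0,
    section_v: float | None = None,
    closure_tol: float = 1e-8,
    max_rounds: int = 6,
    rtol: float = 1e-10,
) -> OrbitPoint:
    """Settle the frozen-m_K2 fast subsystem onto its limit cycle.

    The orbit is anchored on a Poincare section (upward crossing of
    ``section_v``, defaulting to the midrange voltage if the standard
    section is not crossed) and accepted once the return mismatch is below
    ``closure_tol``; one period is then sampled densely.
    """
    p = params.pack()

    def fun(t, y):
        return _kernels.fast_rhs(y, p, m_k2, np.empty(3))

    if y0 is None:
        y0 = np.array([0.0, 0.5, 0.05])
    sol = solve_ivp(fun, (0.0, t_settle), y0, method="DOP853",
                    rtol=rtol, atol=1e-12, max_step=5e-3)
    y = sol.y[:, -1]
    tail = sol.y[0, sol.t > sol.t[-1] - min(10.0, 0.5 * t_settle)]
    amp = float(tail.max() - tail.min())
    if amp < 1e-4:
        raise NoOscillationError(f"fast subsystem stationary at m_K2={m_k2}")
    sec = section_v if section_v is not None else (
        POINCARE_V if tail.max() > POINCARE_V > tail.min() else 0.5 * (tail.max() + tail.min())
    )

    def ev(t, yy):
        return yy[0] - sec

    ev.direction = 1.0

    closure = np.inf
    for _ in range(max_rounds):
        sol = solve_ivp(fun, (0.0, 20.0), y, method="DOP853", rtol=rtol,
                        atol=1e-12, max_step=5e-3, events=[ev], dense_output=True)
        tev = sol.t_events[0]
        if tev.size < 3:
            y = sol.y[:, -1]
            continue
        y_a = sol.sol(tev[-2])
        y_b = sol.sol(tev[-1])
        closure = float(np.linalg.norm(y_b - y_a))
        if closure < closure_tol:
            t0, t1 = tev[-2], tev[-1]
            ts = np.linspace(t0, t1, 2001)
            states = sol.sol(ts).T
            return OrbitPoint(
                m_k2=float(m_k2),
                period=float(t1 - t0),
                times=ts - t0,
                states=states,
                v_max=float(states[:, 0].max()),
                v_min=float(states[:, 0].min()),
                closure=closure,
            )
        y = sol.y[:, -1]
    raise NoOscillationError(
        f"fast orbit did not close to {closure_tol} at m_K2={m_k2} (last mismatch {closure:.2e})"
    )


def orbit_averages(orbit: OrbitPoint, params: NeuronParams) -> tuple[float, float]:
    """Trapezoidal time averages of (V, m_inf_K2(V)) over exactly one period."""
    v = orbit.states[:, 0]
    minf = gate_steady_state(v, params.m_k2)
    T = orbit.times[-1] - orbit.times[0]
    avg_v = float(np.trapezoid(v, orbit.times) / T)
    avg_m = float(np.trapezoid(minf, orbit.times) / T)
    return avg_v, avg_m


@dataclass(frozen=True)
class OrbitBranch:
    """Spiking manifold: fast-subsystem orbits over a range of frozen m_K2."""

    m_values: np.ndarray
    periods: np.ndarray
    v_max: np.ndarray
    v_min: np.ndarray
    avg_v: np.ndarray
    avg_minf: np.ndarray  # orbit-averaged slow nullcline <m_inf_K2(V)>
    m_end: float  # last m at which an orbit was found (branch endpoint probe)

    @property
    def drive(self) -> np.ndarray:
        """Averaged slow drive g(m) = <m_inf_K2> - m; zeros are full-system orbits."""
        return self.avg_minf - self.m_values


def orbit_branch(
    params: NeuronParams,
    m_values,
    t_settle_first: float = 40.0,
    t_settle_next: float = 8.0,
    closure_tol: float = 1e-8,
    rtol: float = 1e-10,
) -> OrbitBranch:
    """Continue the spiking manifold over increasing m_K2 by warm-starting
    each orbit from the previous one; stops at the fold where oscillation
    dies."""
    m_values = np.sort(np.asarray(m_values, dtype=float))
    rows = []
    y0 = None
    m_end = float(m_values[0])
    for i, m in enumerate(m_values):
        try:
            orb = fast_orbit(
                params, m, y0=y0,
                t_settle=t_settle_first if i == 0 else t_settle_next,
                closure_tol=closure_tol, rtol=rtol,
            )
        except NoOscillationError:
            if i == 0:
                raise
            break
        avg_v, avg_m = orbit_averages(orb, params)
        rows.append((m, orb.period, orb.v_max, orb.v_min, avg_v, avg_m))
        y0 = orb.states[0].copy()
        m_end = float(m)
    if not rows:
        raise NoOscillationError("no oscillatory point on the requested m range")
    arr = np.array(rows)
    return OrbitBranch(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4], arr[:, 5], m_end)


# --------------------------------------------------------------------------
# bifurcation points
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationPoint:
    kind: str  # "SN_equilibria" | "SN_orbits" | "codim2"
    theta_k2: float
    theta_h: float
    aux: dict = field(default_factory=dict)


def locate_sn_equilibria(
    params: NeuronParams,
    theta_k2: float | None = None,
    theta_h_window: tuple[float, float] = (0.030, 0.060),
    v_window: tuple[float, float] = (-0.060, -0.034),
    tol: float = 1e-10,
) -> BifurcationPoint:
    """Saddle-node of full-system equilibria at fixed theta_K2.

    Solves ``I_ss(V; theta_h) = 0`` and ``dI_ss/dV = 0`` simultaneously for
    (V*, theta_h*).  The initial guess brackets the knee of the steady-state
    current by a scan, after which a damped Newton iteration (scipy root)
    refines to ``tol`` on the residuals.
    """
    p = params if theta_k2 is None else params.replace(theta_k2=theta_k2)

    # initial guess: theta_h where the knee maximum crosses zero
    def knee(theta_h):
        vg = np.linspace(*v_window, 400)
        i = steady_state_current(vg, p, theta_h)
        k = int(np.argmax(i))
        return float(i[k]), float(vg[k])

    lo, hi = theta_h_window
    f_lo, f_hi = knee(lo)[0], knee(hi)[0]
    if not (f_lo < 0 < f_hi):
        raise ValueError(
            f"no saddle-node of equilibria bracketed for theta_h in {theta_h_window}"
        )
    th0 = brentq(lambda t: knee(t)[0], lo, hi, xtol=1e-10)
    v0 = knee(th0)[1]

    def residuals(x):
        v, th = x
        return [
            steady_state_current(v, p, th),
            steady_state_current_dv(v, p, th),
        ]

    sol = root(residuals, x0=[v0, th0], method="hybr")
    v_star, th_star = sol.x
    res = np.abs(residuals(sol.x))
    # the derivative residual is limited by finite-difference noise (~1e-10
    # of the nA/V scale), so it gets a correspondingly looser bound
    if res[0] > tol or res[1] > max(tol, 1e-8):
        raise RuntimeError(f"fold refinement failed: residuals {res}")
    return BifurcationPoint(
        "SN_equilibria",
        theta_k2=float(p.theta_k2),
        theta_h=float(th_star),
        aux={"v_star": float(v_star), "residuals": tuple(float(r) for r in res)},
    )


def _min_drive(params: NeuronParams, theta_k2: float, theta_h: float,
               m_grid: np.ndarray, **branch_kw) -> tuple[float, float]:
    """Minimum over the spiking branch of the averaged slow drive g(m)."""
    p = params.replace(theta_k2=theta_k2, theta_h=theta_h)
    br = orbit_branch(p, m_grid, **branch_kw)
    k = int(np.argmin(br.drive))
    return float(br.drive[k]), float(br.m_values[k])


def locate_sn_orbits(
    params: NeuronParams,
    theta_h: float | None = None,
    theta_k2_window: tuple[float, float] = (-0.016, -0.008),
    method: str = "averaging",
    m_grid: np.ndarray | None = None,
    xtol: float = 1e-7,
    cross_check_tol: float = 1e-4,
    dyn_t_max: float = 400.0,
    branch_kw: dict | None = None,
) -> BifurcationPoint:
    """Saddle-node of full-system periodic orbits (tonic-spiking fold) at
    fixed theta_h.

    method "averaging": the fold is where the averaged slow drive
    ``g(m) = <m_inf_K2>(m) - m`` becomes tangent to zero from above
    (min g = 0) along the spiking manifold.  method "dynamical": bisection
    on the qualitative outcome of the full system started on the spiking
    manifold (sustained spiking vs burst termination).  method "both" runs
    the two and insists they agree within ``cross_check_tol`` volts.
    """
    p = params if theta_h is None else params.replace(theta_h=theta_h)
    th = p.theta_h
    if m_grid is None:
        m_grid = np.linspace(0.0, 0.30, 31)
    branch_kw = branch_kw or {}
    lo, hi = theta_k2_window

    def by_averaging():
        f_lo, _ = _min_drive(params, lo, th, m_grid, **branch_kw)
        f_hi, _ = _min_drive(params, hi, th, m_grid, **branch_kw)
        if not (f_lo < 0 < f_hi):
            raise ValueError(
                f"fold of orbits not bracketed: min drive {f_lo:.4f} at {lo}, {f_hi:.4f} at {hi}"
            )
        tk = brentq(lambda t: _min_drive(params, t, th, m_grid, **branch_kw)[0], lo, hi, xtol=xtol)
        g, m_t = _min_drive(params, tk, th, m_grid, **branch_kw)
        return float(tk), {"min_drive": g, "m_tangency": m_t}

    def by_dynamics():
        from .model import NeuronState
        from .simulate import SolverConfig, integrate

        solver = SolverConfig(rtol=1e-9, time_limit=dyn_t_max + 1)

        def persists_from(pp, m0: float) -> bool:
            y = NeuronState(0.0, 0.5, m0, 0.05)
            t_done, chunk = 0.0, 50.0
            prev_mean_m = None
            while t_done < dyn_t_max:
                tr = integrate(pp, y, (0.0, chunk), solver)
                sp = tr.spikes[0]
                if sp.size == 0 or (chunk - sp[-1]) > 2.0:
                    return False  # burst terminated: fell off the spiking manifold
                mean_m = float(np.trapezoid(tr.states[:, 2], tr.times) / chunk)
                if prev_mean_m is not None and abs(mean_m - prev_mean_m) < 1e-6:
                    return True  # slow variable converged on the manifold
                prev_mean_m = mean_m
                y = tr.last_state()
                t_done += chunk
            return True

        def spiking_persists(theta_k2: float) -> bool:
            # the tonic orbit's slow equilibrium sits at low m_K2 and its
            # basin is bounded above, so probe from below and from mid-branch
            pp = params.replace(theta_k2=theta_k2, theta_h=th)
            return persists_from(pp, 0.05) or persists_from(pp, 0.15)

        a, b = lo, hi
        pa, pb = spiking_persists(a), spiking_persists(b)
        if not pa or pb:
            raise ValueError(
                f"dynamical bisection bracket invalid: spiking persists at "
                f"{a}: {pa}, at {b}: {pb}"
            )
        while b - a > xtol:
            mid = 0.5 * (a + b)
            if spiking_persists(mid):
                a = mid
            else:
                b = mid
        return 0.5 * (a + b), {}

    if method == "averaging":
        tk, aux = by_averaging()
    elif method == "dynamical":
        tk, aux = by_dynamics()
    elif method == "both":
        tk_a, aux = by_averaging()
        tk_d, _ = by_dynamics()
        if abs(tk_a - tk_d) > cross_check_tol:
            raise RuntimeError(
                f"averaging ({tk_a}) and dynamical ({tk_d}) fold locations disagree "
                f"beyond {cross_check_tol} V"
            )
        tk = tk_a
        aux = dict(aux, dynamical=tk_d)
    else:
        raise ValueError("method must be 'averaging', 'dynamical' or 'both'")
    return BifurcationPoint("SN_orbits", theta_k2=float(tk), theta_h=float(th), aux=aux)


def locate_codim2(
    params: NeuronParams,
    theta_k2_points: np.ndarray | None = None,
    theta_h_points: np.ndarray | None = None,
    poly_order: int = 2,
    sn_orbit_kw: dict | None = None,
) -> BifurcationPoint:
    """Intersection of the SN-equilibria and SN-orbit curves.

    Traces ``theta_h*(theta_K2)`` and ``theta_K2*(theta_h)`` on a handful of
    points each, fits each curve with a low-order polynomial, and intersects
    them; the SN-orbit curve is nearly vertical and the SN-equilibria curve
    nearly horizontal, so the intersection is well conditioned.
    """
    if theta_k2_points is None:
        theta_k2_points = np.linspace(-0.0115, -0.0095, 5)
    if theta_h_points is None:
        theta_h_points = np.linspace(0.0405, 0.0425, 5)
    sn_orbit_kw = sn_orbit_kw or {}

    eq_th = np.array([
        locate_sn_equilibria(params, tk).theta_h for tk in theta_k2_points
    ])
    orb_tk = np.array([
        locate_sn_orbits(params, th, **sn_orbit_kw).theta_k2 for th in theta_h_points
    ])
    # theta_h*(theta_k2) and theta_k2*(theta_h), both as polynomials
    c_eq = np.polyfit(theta_k2_points, eq_th, min(poly_order, len(theta_k2_points) - 1))
    c_orb = np.polyfit(theta_h_points, orb_tk, min(poly_order, len(theta_h_points) - 1))

    tk = float(np.mean(orb_tk))
    for _ in range(100):
        th = float(np.polyval(c_eq, tk))
        tk_new = float(np.polyval(c_orb, th))
        if abs(tk_new - tk) < 1e-14:
            tk = tk_new
            break
        tk = tk_new
    th = float(np.polyval(c_eq, tk))
    resid = abs(float(np.polyval(c_orb, th)) - tk)
    return BifurcationPoint(
        "codim2", theta_k2=tk, theta_h=th,
        aux={
            "eq_curve": (tuple(theta_k2_points), tuple(eq_th)),
            "orbit_curve": (tuple(theta_h_points), tuple(orb_tk)),
            "fixed_point_residual": resid,
        },
    )
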