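"""Monod growth kinetics and culture mass balances for shaken-flask batches.

The state of one culture is (X, V, c_N): biomass [g/L], working volume [L]
and nitrate [g/L]. Growth follows a double Monod law in the volume-averaged
light intensity and the nitrate concentration,

    mu = mu_max * I_avg / (K_I + I_avg) * c_N / (K_N + c_N),

with a first-order death term mu_d. The balances are

    dX/dt   = (mu - mu_d) X - (F_M / V) X
    dV/dt   = F_M - F_S
    dc_N/dt = -Y_NX mu X - F_M c_N / V + F_M c_N_feed / V.

Daily sampling withdraws a small volume and replaces it with fresh medium; by
default this is modelled as an impulsive dilution event at each recorded
sampling time (the continuous F_M/F_S rate formulation is kept as an option).
Light on/off switches and sampling events are hard integrator breakpoints.

Two integration paths are provided: the default segment-wise LSODA with dense
output (rtol 1e-8, atol 1e-10) used for data generation and reporting, and a
fixed-step RK4 path (JIT-compiled when numba is available) used inside the
parameter-estimation loops where hundreds of thousands of trajectories are
needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .radiative import FlaskGeometry, LightSetting, RadiativeParams, incident_intensity

try:  # pragma: no cover - exercised implicitly by every fast-path test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


__all__ = [
    "KineticParams",
    "CultureState",
    "SamplingSchedule",
    "growth_rate",
    "ode_rhs",
    "apply_sampling_event",
    "simulate",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; names the offending interval."""


@dataclass(frozen=True)
class KineticParams:
    """Growth and uptake parameters.

    mu_max, mu_d in 1/h; K_I in umol/(m2 s); K_N in g/L (note: literature
    half-saturation constants for nitrate are often printed in mg/L — this
    package stores g/L throughout); Y_NX in g nitrate per g biomass.
    """

    mu_max: float = 0.135
    mu_d: float = 0.002
    K_I: float = 96.0
    K_N: float = 1.49e-4
    Y_NX: float = 0.245

    def __post_init__(self) -> None:
        for name in ("mu_max", "mu_d", "K_I", "K_N", "Y_NX"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.mu_d > self.mu_max:
            raise ValueError(
                f"death rate mu_d ({self.mu_d}) must not exceed mu_max ({self.mu_max})"
            )


@dataclass(frozen=True)
class CultureState:
    X: float
    V: float
    c_N: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.X < 0:
            raise ValueError(f"biomass X must be >= 0, got {self.X}")
        if self.V <= 0:
            raise ValueError(f"volume V must be > 0, got {self.V}")
        if self.c_N < 0:
            raise ValueError(f"nitrate c_N must be >= 0, got {self.c_N}")


@dataclass(frozen=True)
class SamplingSchedule:
    """Sample-and-replace protocol.

    ``impulsive`` mode removes ``V_sample`` litres and replaces them with
    fresh medium instantaneously at each time in ``sample_times``;
    ``continuous`` mode uses the constant rates F_M (feed) and F_S (sampling)
    of the balance equations instead. In the batch-with-sampling design
    F_M == F_S so the volume stays constant.
    """

    mode: str = "impulsive"
    sample_times: tuple[float, ...] = ()
    V_sample: float = 0.0075
    F_M: float = 0.0
    F_S: float = 0.0
    c_N_feed: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("impulsive", "continuous"):
            raise ValueError(f"mode must be 'impulsive' or 'continuous', got {self.mode!r}")
        if self.V_sample < 0 or self.F_M < 0 or self.F_S < 0 or self.c_N_feed < 0:
            raise ValueError("V_sample, F_M, F_S and c_N_feed must be >= 0")
        object.__setattr__(self, "sample_times", tuple(float(t) for t in self.sample_times))


def growth_rate(I_avg, c_N, params: KineticParams):
    """Specific growth rate mu [1/h] from the double Monod law."""
    I_avg = np.asarray(I_avg, dtype=float)
    c_N = np.asarray(c_N, dtype=float)
    if np.any(I_avg < 0) or np.any(c_N < 0):
        raise ValueError("I_avg and c_N must be >= 0")
    out = params.mu_max * I_avg / (params.K_I + I_avg) * c_N / (params.K_N + c_N)
    return float(out) if out.ndim == 0 else out


def ode_rhs(
    state: CultureState,
    t: float,
    setting: LightSetting,
    kp: KineticParams,
    rp: RadiativeParams,
    sched: SamplingSchedule,
    geometry: FlaskGeometry | None = None,
) -> tuple[float, float, float]:
    """Instantaneous derivatives (dX/dt, dV/dt, dc_N/dt) of the balances."""
    geometry = geometry or FlaskGeometry()
    from .radiative import scheduled_average_intensity

    F_M = sched.F_M if sched.mode == "continuous" else 0.0
    F_S = sched.F_S if sched.mode == "continuous" else 0.0
    I_avg = scheduled_average_intensity(t, setting.I_S, setting.L, state.X, rp, geometry.h)
    cN = max(state.c_N, 0.0)
    mu = kp.mu_max * I_avg / (kp.K_I + I_avg) * cN / (kp.K_N + cN) if cN > 0 else 0.0
    dX = (mu - kp.mu_d) * state.X - F_M / state.V * state.X
    dV = F_M - F_S
    dcN = -kp.Y_NX * mu * state.X - F_M * state.c_N / state.V + F_M * sched.c_N_feed / state.V
    return dX, dV, dcN


def apply_sampling_event(state: CultureState, V_sample: float, c_N_feed: float) -> CultureState:
    """Withdraw ``V_sample`` of culture and replace it with fresh medium.

    Volume is unchanged; biomass is diluted by (V - V_sample)/V and nitrate
    mixes toward the feed concentration.
    """
    if not 0.0 <= V_sample < state.V:
        raise ValueError(f"V_sample must satisfy 0 <= V_sample < V, got {V_sample} vs V={state.V}")
    keep = (state.V - V_sample) / state.V
    return CultureState(
        X=state.X * keep,
        V=state.V,
        c_N=state.c_N * keep + c_N_feed * V_sample / state.V,
        t=state.t,
    )


# ---------------------------------------------------------------------------
# Integration plan: breakpoints at light switches, sampling events and output
# times. Within each interval the light indicator is constant.
# ---------------------------------------------------------------------------

def _build_plan(t0, t1, L, sample_times, t_grid):
    """Return (t_nodes, lit, is_sample, out_idx) for [t0, t1].

    t_nodes includes t0, t1, every light switch, sampling event and output
    time (merged at 1e-9 h). lit[i] is the light state on (t_nodes[i],
    t_nodes[i+1]); is_sample flags dilution events; out_idx maps nodes to
    positions in t_grid (-1 otherwise). Outputs at a sampling node are
    recorded *before* the dilution.
    """
    pts = [float(t0), float(t1)]
    if 0.0 < L < 24.0:
        k0, k1 = int(math.floor(t0 / 24.0)), int(math.floor(t1 / 24.0)) + 1
        for k in range(k0, k1 + 1):
            for s in (24.0 * k, 24.0 * k + L):
                if t0 < s < t1:
                    pts.append(s)
    samples = [float(s) for s in sample_times if t0 <= s < t1]
    pts.extend(samples)
    pts.extend(float(t) for t in t_grid)
    t_nodes = np.unique(np.round(np.asarray(pts, dtype=float), 9))
    t_nodes = t_nodes[(t_nodes >= t0 - 1e-9) & (t_nodes <= t1 + 1e-9)]

    is_sample = np.zeros(t_nodes.shape, dtype=np.bool_)
    for s in samples:
        i = int(np.searchsorted(t_nodes, round(s, 9)))
        is_sample[i] = True
    out_idx = np.full(t_nodes.shape, -1, dtype=np.int64)
    for j, t in enumerate(t_grid):
        i = int(np.searchsorted(t_nodes, round(float(t), 9)))
        out_idx[i] = j
    mid = 0.5 * (t_nodes[:-1] + t_nodes[1:])
    lit = (mid - 24.0 * np.floor(mid / 24.0)) < L if 0.0 < L else np.zeros(mid.shape, bool)
    if L >= 24.0:
        lit = np.ones(mid.shape, bool)
    return t_nodes, lit.astype(np.bool_), is_sample, out_idx


@njit(cache=True)
def _rk4_path(
    t_nodes, lit, is_sample, out_idx, n_out,
    X0, V0, cN0,
    I0, eps, hgeo,
    mu_max, mu_d, K_I, K_N, Y_NX,
    V_sample, cN_feed, F_M, F_S,
    dt_max,
):  # pragma: no cover - compiled
    X_out = np.empty(n_out)
    V_out = np.empty(n_out)
    N_out = np.empty(n_out)
    X, V, cN = X0, V0, cN0
    n_nodes = t_nodes.shape[0]
    for i in range(n_nodes):
        oi = out_idx[i]
        if oi >= 0:
            X_out[oi] = X
            V_out[oi] = V
            N_out[oi] = cN
        if is_sample[i] and V_sample > 0.0:
            keep = (V - V_sample) / V
            X = X * keep
            cN = cN * keep + cN_feed * V_sample / V
        if i == n_nodes - 1:
            break
        ta = t_nodes[i]
        tb = t_nodes[i + 1]
        on = lit[i]
        t = ta
        while t < tb - 1e-12:
            dt = dt_max
            if Y_NX > 0.0 and cN < 0.02:
                dt = dt_max / 16.0  # resolve the sharp nitrate cut-off
            if t + dt > tb:
                dt = tb - t
            # classic RK4 on (X, V, cN)
            k1x, k1v, k1n = _rhs_fast(X, V, cN, on, I0, eps, hgeo,
                                      mu_max, mu_d, K_I, K_N, Y_NX, F_M, F_S, cN_feed)
            X2 = X + 0.5 * dt * k1x
            V2 = V + 0.5 * dt * k1v
            N2 = cN + 0.5 * dt * k1n
            k2x, k2v, k2n = _rhs_fast(X2, V2, N2, on, I0, eps, hgeo,
                                      mu_max, mu_d, K_I, K_N, Y_NX, F_M, F_S, cN_feed)
            X3 = X + 0.5 * dt * k2x
            V3 = V + 0.5 * dt * k2v
            N3 = cN + 0.5 * dt * k2n
            k3x, k3v, k3n = _rhs_fast(X3, V3, N3, on, I0, eps, hgeo,
                                      mu_max, mu_d, K_I, K_N, Y_NX, F_M, F_S, cN_feed)
            X4 = X + dt * k3x
            V4 = V + dt * k3v
            N4 = cN + dt * k3n
            k4x, k4v, k4n = _rhs_fast(X4, V4, N4, on, I0, eps, hgeo,
                                      mu_max, mu_d, K_I, K_N, Y_NX, F_M, F_S, cN_feed)
            X = X + dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            V = V + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            cN = cN + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
            if X < 0.0:
                X = 0.0
            if cN < 0.0:
                cN = 0.0
            t = t + dt
    return X_out, V_out, N_out


@njit(cache=True)
def _rhs_fast(X, V, cN, lit, I0, eps, hgeo,
              mu_max, mu_d, K_I, K_N, Y_NX, F_M, F_S, cN_feed):  # pragma: no cover
    if lit:
        u = eps * X * hgeo
        if u < 1e-8:
            I_avg = I0 * (1.0 - 0.5 * u)
        else:
            I_avg = I0 * (1.0 - math.exp(-u)) / u
    else:
        I_avg = 0.0
    cNe = cN if cN > 0.0 else 0.0
    if cNe > 0.0:
        mu = mu_max * I_avg / (K_I + I_avg) * cNe / (K_N + cNe)
    else:
        mu = 0.0
    dX = (mu - mu_d) * X - F_M / V * X
    dV = F_M - F_S
    dcN = -Y_NX * mu * X - F_M * cN / V + F_M * cN_feed / V
    return dX, dV, dcN


def _simulate_plan_rk4(plan, initial, rp_scalar, kp: KineticParams, sched, geometry, dt_max=0.25):
    """Run the fast path on a prebuilt plan; returns (X, V, cN) arrays."""
    t_nodes, lit, is_sample, out_idx, n_out = plan
    I0, eps = rp_scalar
    F_M = sched.F_M if sched.mode == "continuous" else 0.0
    F_S = sched.F_S if sched.mode == "continuous" else 0.0
    V_sample = sched.V_sample if sched.mode == "impulsive" else 0.0
    return _rk4_path(
        t_nodes, lit, is_sample, out_idx, n_out,
        float(initial[0]), float(initial[1]), float(initial[2]),
        float(I0), float(eps), float(geometry.h),
        kp.mu_max, kp.mu_d, kp.K_I, kp.K_N, kp.Y_NX,
        float(V_sample), float(sched.c_N_feed), float(F_M), float(F_S),
        float(dt_max),
    )


def _simulate_lsoda(initial, rp_scalar, kp, sched, geometry, setting_L, t_grid, rtol, atol):
    """Event-segmented LSODA with dense output evaluated at t_grid.

    Integration segments run between physical events only (light switches,
    sampling events); output times are read off the dense interpolant, so the
    trajectory is exactly invariant under refinement of the output grid. A
    terminal event detects nitrate exhaustion; without feed the remainder of
    the segment is pure first-order biomass decay and is evaluated in closed
    form (re-arming the zero-crossing event on an identically-zero nitrate
    trajectory would stall the integrator).
    """
    I0, eps = rp_scalar
    F_M = sched.F_M if sched.mode == "continuous" else 0.0
    F_S = sched.F_S if sched.mode == "continuous" else 0.0
    V_sample = sched.V_sample if sched.mode == "impulsive" else 0.0
    sample_times = sched.sample_times if sched.mode == "impulsive" else ()
    h = geometry.h
    t_grid = np.asarray(t_grid, dtype=float)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])

    # event nodes only (no output times): light switches and sampling events
    t_nodes, lit, is_sample, _, = _build_plan(t0, t1, setting_L, sample_times, [t0, t1])

    def rhs(t, y, on):
        X, V, cN = y
        return _rhs_fast(X, V, max(cN, 0.0), on, I0, eps, h,
                         kp.mu_max, kp.mu_d, kp.K_I, kp.K_N, kp.Y_NX, F_M, F_S, sched.c_N_feed)

    def nitrate_zero(t, y, on):
        return y[2]

    nitrate_zero.terminal = True
    nitrate_zero.direction = -1

    X_out = np.empty(t_grid.size)
    V_out = np.empty(t_grid.size)
    N_out = np.empty(t_grid.size)

    def record(idx, chunks, y_end):
        """Evaluate buffered dense chunks at the output times in this segment."""
        for j in idx:
            t = t_grid[j]
            val = None
            for kind, ta, tb, payload in chunks:
                if ta - 1e-9 <= t <= tb + 1e-9:
                    if kind == "sol":
                        val = payload.sol(t)
                    else:  # starved closed-form decay
                        X_e, V_e = payload
                        val = np.array([X_e * math.exp(-kp.mu_d * (t - ta)), V_e, 0.0])
                    break
            if val is None:  # t coincides with the segment end
                val = y_end
            X_out[j] = max(float(val[0]), 0.0)
            V_out[j] = float(val[1])
            N_out[j] = max(float(val[2]), 0.0)

    y = np.array([initial[0], initial[1], initial[2]], dtype=float)
    for i in range(t_nodes.shape[0]):
        node_t = t_nodes[i]
        exact = np.nonzero(np.abs(t_grid - node_t) <= 1e-9)[0]
        for j in exact:  # outputs at the node itself: pre-sampling state
            X_out[j], V_out[j], N_out[j] = max(y[0], 0.0), y[1], max(y[2], 0.0)
        if is_sample[i] and V_sample > 0.0:
            keep = (y[1] - V_sample) / y[1]
            y = np.array([y[0] * keep, y[1], y[2] * keep + sched.c_N_feed * V_sample / y[1]])
        if i == t_nodes.shape[0] - 1:
            break
        ta, tb = t_nodes[i], t_nodes[i + 1]
        interior = np.nonzero((t_grid > ta + 1e-9) & (t_grid < tb - 1e-9))[0]
        if tb - ta <= 1e-12:
            continue
        on = bool(lit[i])
        chunks = []
        t_start, y_start = ta, y
        while True:
            sol = solve_ivp(
                rhs, (t_start, tb), y_start, method="LSODA", rtol=rtol, atol=atol,
                dense_output=True, events=nitrate_zero, args=(on,),
            )
            if not sol.success:
                raise SimulationError(
                    f"integration failed on [{t_start:.6g}, {tb:.6g}] h: {sol.message}"
                )
            chunks.append(("sol", t_start, sol.t[-1], sol))
            if sol.t[-1] >= tb - 1e-12:
                y = sol.y[:, -1].copy()
                y[0] = max(y[0], 0.0)
                y[2] = max(y[2], 0.0)
                break
            t_e = sol.t[-1]
            y_e = sol.y[:, -1].copy()
            y_e[2] = 0.0
            if F_M == 0.0:
                X_e = max(y_e[0], 0.0)
                chunks.append(("decay", t_e, tb, (X_e, y_e[1])))
                y = np.array([X_e * math.exp(-kp.mu_d * (tb - t_e)), y_e[1], 0.0])
                break
            # with continuous feed nitrate recovers; resume without the event
            sol = solve_ivp(
                rhs, (t_e, tb), y_e, method="LSODA", rtol=rtol, atol=atol,
                dense_output=True, args=(on,),
            )
            if not sol.success:
                raise SimulationError(
                    f"integration failed on [{t_e:.6g}, {tb:.6g}] h: {sol.message}"
                )
            chunks.append(("sol", t_e, tb, sol))
            y = sol.y[:, -1].copy()
            y[0] = max(y[0], 0.0)
            y[2] = max(y[2], 0.0)
            break
        record(interior, chunks, y)
    return X_out, V_out, N_out


def simulate(
    initial: CultureState,
    setting: LightSetting,
    kp: KineticParams,
    rp: RadiativeParams,
    geometry: FlaskGeometry,
    sched: SamplingSchedule,
    t_grid,
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dt_max: float = 0.25,
) -> pd.DataFrame:
    """Integrate one cultivation and report the state at ``t_grid``.

    Breakpoints are placed at every light on/off switch and every sampling
    event; values reported at a sampling time are the pre-dilution state (the
    measured sample). ``method`` is ``"lsoda"`` (adaptive, default) or
    ``"rk4"`` (fixed-step fast path, dt <= ``dt_max`` hours).

    Returns a DataFrame with columns time_h, biomass_g_per_L, volume_L,
    nitrate_g_per_L.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a nonempty 1-D array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < initial.t - 1e-12:
        raise ValueError("t_grid must start at or after the initial state time")

    I0 = incident_intensity(setting.I_S, rp)
    eps = rp.epsilon
    y0 = (initial.X, initial.V, initial.c_N)
    if method == "rk4":
        sample_times = sched.sample_times if sched.mode == "impulsive" else ()
        plan_nodes = _build_plan(initial.t, float(t_grid[-1]), setting.L, sample_times, t_grid)
        plan = (*plan_nodes, t_grid.size)
        X, V, N = _simulate_plan_rk4(plan, y0, (I0, eps), kp, sched, geometry, dt_max)
    elif method == "lsoda":
        X, V, N = _simulate_lsoda(y0, (I0, eps), kp, sched, geometry, setting.L,
                                  t_grid, rtol, atol)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {
            "time_h": t_grid,
            "biomass_g_per_L": np.maximum(X, 0.0),
            "volume_L": V,
            "nitrate_g_per_L": np.maximum(N, 0.0),
        }
    )
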