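"""Deterministic core of the P-C-S senescence model.

A cultured fibroblast population is split into three compartments:

* ``P`` — proliferating cells, dividing at the constant rate ``r`` (per day);
* ``C`` — reversibly cell-cycle-arrested cells, entered from P at rate
  ``f1 * Fhat`` and left back to P at rate ``f2``;
* ``S`` — irreversibly arrested (senescent) cells, entered from C at rate
  ``f3``; there is no back reaction out of S.

The P->C flux is gated by the cellular stress response ``F(t)``, a bistable
variable with Ludwig-type saturating positive feedback and linear decay::

    dF/dt = gamma(t) + a * F^2 / (b^2 + F^2) - c * F

driven additively by the stress input gamma(t).  ``Fhat = F / K`` normalizes
the response by its characteristic scale ``K`` so that ``f1`` is a plain rate;
``Fhat`` is deliberately not capped — under sustained accumulating stress the
response keeps growing and eventually overwhelms proliferation, which is what
produces the replicative-senescence plateau.

The state equations (mass exchange is conservative, so the total only changes
through division)::

    dP/dt = r*P - f1*Fhat*P + f2*C
    dC/dt =       f1*Fhat*P - f2*C - f3*C
    dS/dt =                          f3*C
    d(P+C+S)/dt = r*P

Growth is reported as population doublings, PD(t) = log2(total(t)/total(0)).
A population whose proliferating pool falls below one cell cannot recover:
:func:`simulate` monitors the event ``P < 1`` and permanently switches the
division term off once it fires (state transitions keep running, so S still
accumulates while PD stays flat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .stress import StressProtocol

__all__ = [
    "LN2",
    "FShape",
    "default_f_shape",
    "ModelParameters",
    "CellStateVector",
    "SimulationResult",
    "SimulationError",
    "constant_growth_rhs",
    "stress_response_rhs",
    "pcs_rhs",
    "simulate",
    "simulate_constant_growth",
    "state_fractions",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FShape:
    """Kinetic constants (a, b, c) of the stress-response right-hand side.

    ``a`` is the maximal positive-feedback production (units/day), ``b`` the
    half-saturation level of the feedback (same units as F), and ``c`` the
    linear decay rate (per day).  The ratio ``rho = a / (c*b)`` controls the
    fixed-point structure at gamma=0: for rho < 1.54 the response is globally
    monostable, for 1.54 < rho < 2 it is bistable over an interior window of
    gamma (two saddle-node folds at gamma > 0, hysteresis, and a slow
    relaxation back to F=0 once the stress is removed), and for rho >= 2 the
    high state persists even at gamma=0.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"FShape.{name} must be finite and > 0, got {v!r}")


def default_f_shape(K: float = 1.0) -> FShape:
    """Default response kinetics scaled to the response ceiling ``K``.

    ``a = 1.9*K``, ``b = 0.5*K``, ``c = 2.0``/day, i.e. rho = 1.9: bistable
    over an interior gamma window with fast up-switching and slow recovery.
    """
    return FShape(a=1.9 * K, b=0.5 * K, c=2.0)


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic rates of the P-C-S-F system (rates per day, K dimensionless)."""

    r: float
    f1: float
    f2: float
    f3: float
    K: float = 1.0
    f_shape: FShape | None = None

    def __post_init__(self) -> None:
        for name in ("r", "f1", "f2", "f3"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"ModelParameters.{name} must be finite and >= 0, got {v!r}")
        if not (math.isfinite(self.K) and self.K > 0):
            raise ValueError(f"ModelParameters.K must be finite and > 0, got {self.K!r}")
        if self.f_shape is None:
            object.__setattr__(self, "f_shape", default_f_shape(self.K))

    def with_(self, **kw) -> "ModelParameters":
        """Copy with selected fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class CellStateVector:
    """Instantaneous state: cell counts P, C, S and response level F."""

    P: float
    C: float = 0.0
    S: float = 0.0
    F: float = 0.0

    def __post_init__(self) -> None:
        for name in ("P", "C", "S", "F"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"CellStateVector.{name} must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.P + self.C + self.S

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.C, self.S, self.F], dtype=float)


class SimulationError(RuntimeError):
    """Solver failure; carries the final successfully reached time."""

    def __init__(self, message: str, t_reached: float):
        super().__init__(f"{message} (last successful time t={t_reached:.6g} d)")
        self.t_reached = t_reached


@dataclass(frozen=True)
class SimulationResult:
    """A trajectory sampled on a time grid, with PD relative to t=0."""

    times: np.ndarray
    P: np.ndarray
    C: np.ndarray
    S: np.ndarray
    F: np.ndarray
    pd: np.ndarray
    terminated: bool = False
    t_extinction: float | None = None

    @property
    def total(self) -> np.ndarray:
        return self.P + self.C + self.S


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def constant_growth_rhs(state: CellStateVector, params: ModelParameters) -> float:
    """dP/dt of the pure exponential-growth model, r * P."""
    return params.r * state.P


def stress_response_rhs(F: float, gamma_now: float, K: float, f_shape: FShape) -> float:
    """dF/dt = gamma + a F^2/(b^2 + F^2) - c F (``K`` enters via the defaults only)."""
    a, b, c = f_shape.a, f_shape.b, f_shape.c
    return gamma_now + a * F * F / (b * b + F * F) - c * F


def pcs_rhs(
    state: CellStateVector,
    params: ModelParameters,
    gamma_now: float,
) -> tuple[float, float, float, float]:
    """Time derivatives (dP, dC, dS, dF) of the full system.

    Raises ``ValueError`` on negative state components or stress (contract
    violation).  The f-fluxes cancel pairwise so dP + dC + dS = r * P.
    """
    if gamma_now < 0:
        raise ValueError(f"gamma_now must be >= 0, got {gamma_now!r}")
    P, C, F = state.P, state.C, state.F  # dataclass already enforces >= 0
    fhat = F / params.K
    flux_pc = params.f1 * fhat * P
    dP = params.r * P - flux_pc + params.f2 * C
    dC = flux_pc - (params.f2 + params.f3) * C
    dS = params.f3 * C
    dF = stress_response_rhs(F, gamma_now, params.K, params.f_shape)
    return (dP, dC, dS, dF)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _segment_gamma(protocol: StressProtocol, t0: float, t1: float):
    """Within (t0, t1) the protocol is smooth; return a cheap gamma(t)."""
    if protocol.kind == "linear":
        alpha, beta = protocol.alpha, protocol.beta
        return lambda t: alpha + beta * t
    g = protocol.gamma_at(0.5 * (t0 + t1))
    return lambda t: g


def simulate(
    params: ModelParameters,
    protocol: StressProtocol,
    initial: CellStateVector | None = None,
    t_end: float | None = None,
    grid: Sequence[float] | np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    extinction_threshold: float = 1.0,
    fixed_fhat: float | None = None,
) -> SimulationResult:
    """Integrate the P-C-S-F system under a stress protocol.

    Parameters
    ----------
    params, protocol:
        Kinetics and stress input.
    initial:
        Starting state; defaults to 1e5 proliferating cells with C=S=F=0
        (F starts at the unstressed low fixed point, which is 0).
    t_end, grid:
        Sampling times in days.  If ``grid`` is omitted, 201 uniform points on
        [0, t_end] are used; if ``t_end`` is omitted it is taken from the grid.
    extinction_threshold:
        Absolute P count below which proliferation terminates permanently
        (growth-termination criterion "cell concentration below one").
    fixed_fhat:
        If given, hold the normalized response at this constant value instead
        of F/K (used for the constant-saturated-stress fate analysis).

    Integration restarts at every protocol discontinuity so that short
    irradiation pulses are resolved exactly.
    """
    if grid is None:
        if t_end is None:
            raise ValueError("provide t_end and/or grid")
        grid = np.linspace(0.0, float(t_end), 201)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a non-empty 1-D array")
    if grid[0] < 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-negative and strictly increasing")
    if t_end is None:
        t_end = float(grid[-1])
    if t_end <= 0 or t_end < grid[-1]:
        raise ValueError("t_end must be positive and cover the grid")

    if initial is None:
        initial = CellStateVector(P=1e5)
    total0 = initial.total
    if total0 <= 0:
        raise ValueError("initial total cell count must be positive")

    r, f1, f2, f3, K = params.r, params.f1, params.f2, params.f3, params.K
    a, b, c = params.f_shape.a, params.f_shape.b, params.f_shape.c

    breaks = sorted({0.0, t_end, *protocol.breakpoints(t_end)})
    out = np.empty((4, grid.size))
    out.fill(np.nan)
    if grid[0] == 0.0:
        out[:, 0] = initial.as_array()

    prolif = initial.P >= extinction_threshold
    terminated = not prolif
    t_extinction = 0.0 if terminated else None
    y = initial.as_array()

    def make_rhs(gamma_fn, prolif_on: bool):
        grow = r if prolif_on else 0.0

        def rhs(t, yv):
            P, C, S, F = yv
            fhat = fixed_fhat if fixed_fhat is not None else F / K
            flux_pc = f1 * fhat * P
            return (
                grow * P - flux_pc + f2 * C,
                flux_pc - (f2 + f3) * C,
                f3 * C,
                gamma_fn(t) + a * F * F / (b * b + F * F) - c * F,
            )

        return rhs

    def extinct(t, yv):
        return yv[0] - extinction_threshold

    extinct.terminal = True
    extinct.direction = -1

    # abort hopeless trajectories before floating-point overflow corrupts the
    # solver state (reachable only for extreme trial parameters during fits)
    def blowup(t, yv):
        return (yv[0] + yv[1] + yv[2]) - 1e30

    blowup.terminal = True
    blowup.direction = 1

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        gamma_fn = _segment_gamma(protocol, t0, t1)
        t_cur = t0
        while t_cur < t1 - 1e-14 * max(1.0, t1):
            mask = (grid > t_cur) & (grid <= t1)
            t_eval = grid[mask]
            events = [extinct, blowup] if prolif else [blowup]
            sol = solve_ivp(
                make_rhs(gamma_fn, prolif),
                (t_cur, t1),
                y,
                method=method,
                t_eval=t_eval if t_eval.size else None,
                events=events,
                rtol=rtol,
                atol=atol,
            )
            sol_t = np.atleast_1d(np.asarray(sol.t, dtype=float))
            if sol.status == -1:
                t_last = sol_t[-1] if sol_t.size else t_cur
                raise SimulationError(f"ODE solver failed: {sol.message}", t_last)
            if t_eval.size and sol_t.size:
                idx = np.nonzero(mask)[0][: sol_t.size]
                out[:, idx] = np.asarray(sol.y)[:, : sol_t.size]
            if sol.status == 1:  # a terminal event fired
                if prolif and sol.t_events[0].size:
                    te = float(sol.t_events[0][0])
                    y = sol.y_events[0][0].copy()
                    prolif = False
                    terminated = True
                    t_extinction = te
                    t_cur = te
                else:
                    te = float(sol.t_events[-1][0])
                    raise SimulationError("population exceeded 1e30 cells", te)
            else:
                if sol_t.size and sol_t[-1] >= t1 - 1e-12:
                    y = sol.y[:, -1].copy()
                else:
                    # grid has no point at t1; integrate silently to the break
                    tail = solve_ivp(
                        make_rhs(gamma_fn, prolif),
                        (t_cur if not t_eval.size else float(sol_t[-1]), t1),
                        y if not t_eval.size else sol.y[:, -1].copy(),
                        method=method,
                        events=events,
                        rtol=rtol,
                        atol=atol,
                    )
                    if tail.status == -1:
                        raise SimulationError(
                            f"ODE solver failed: {tail.message}",
                            tail.t[-1] if tail.t.size else t_cur,
                        )
                    if tail.status == 1:
                        if prolif and tail.t_events[0].size:
                            te = float(tail.t_events[0][0])
                            y = tail.y_events[0][0].copy()
                            prolif = False
                            terminated = True
                            t_extinction = te
                            t_cur = te
                            continue
                        te = float(tail.t_events[-1][0])
                        raise SimulationError("population exceeded 1e30 cells", te)
                    y = tail.y[:, -1].copy()
                t_cur = t1

    if np.any(np.isnan(out)):
        raise SimulationError("internal sampling error: unassigned grid points", t_end)

    P, C, S, F = out
    total = P + C + S
    if np.any(total <= 0):
        raise SimulationError("population total became non-positive", t_end)
    pd = np.log2(total / total0)
    if grid[0] == 0.0:
        pd[0] = 0.0
    return SimulationResult(
        times=grid, P=P, C=C, S=S, F=F, pd=pd,
        terminated=terminated, t_extinction=t_extinction,
    )


def simulate_constant_growth(
    r: float,
    P0: float = 1.0,
    times: Sequence[float] | np.ndarray | None = None,
    t_end: float | None = None,
) -> SimulationResult:
    """Closed-form trajectory of the constant-growth model P(t) = P0 e^{rt}.

    PD versus time is exactly linear with slope r/ln 2.
    """
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r!r}")
    if P0 <= 0:
        raise ValueError(f"P0 must be > 0, got {P0!r}")
    if times is None:
        if t_end is None:
            raise ValueError("provide times and/or t_end")
        times = np.linspace(0.0, float(t_end), 101)
    times = np.asarray(times, dtype=float)
    P = P0 * np.exp(r * times)
    zeros = np.zeros_like(times)
    return SimulationResult(
        times=times, P=P, C=zeros, S=zeros, F=zeros,
        pd=r * times / LN2, terminated=False, t_extinction=None,
    )


def state_fractions(result: SimulationResult) -> dict[str, np.ndarray]:
    """Per-time fractions of the population in P, C, S and C+S.

    The P, C, S fractions sum to 1 at every time; raises if the total is not
    strictly positive anywhere on the grid.
    """
    total = result.total
    if np.any(total <= 0):
        raise ValueError("population total must be > 0 at all requested times")
    fr = {
        "P": result.P / total,
        "C": result.C / total,
        "S": result.S / total,
    }
    fr["C+S"] = fr["C"] + fr["S"]
    return fr
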