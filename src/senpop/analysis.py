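"""Model analyses: fate threshold, bifurcation structure, sensitivity, markers.

Four questions about the fitted model are answered here:

1. *Will a population under constant saturated stress keep growing?*
   Analytically, with the response held at Fhat = 1 the (P, C) subsystem is
   linear and the population grows iff r > f1*f3/(f2+f3)
   (:func:`classify_fate`).
2. *Is the stress response really switch-like?*  :func:`bifurcation_scan`
   locates the fixed points of the F dynamics per stress level and the
   saddle-node folds where they collide; :func:`hysteresis_sweep` follows the
   response quasi-statically up and down a stress ramp.
3. *Which parameters dominate the growth curve?*  :func:`sensitivity` runs
   one-at-a-time perturbations and ranks parameters by the PD-curve
   displacement they cause.
4. *Is a biomarker a quantitative readout of a model state?*
   :func:`marker_comparison` pairs marker-positive fractions with the model's
   state fractions (p21 <-> C+S, SA-b-Gal <-> S) and reports residuals; a
   small RMSE relative to the counting-noise floor marks a good marker.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    CellStateVector,
    ModelParameters,
    SimulationResult,
    simulate,
    state_fractions,
    stress_response_rhs,
)
from .stress import StressProtocol

__all__ = [
    "FateClassification",
    "BifurcationDiagram",
    "SensitivityReport",
    "MarkerComparison",
    "classify_fate",
    "arrest_eigenvalue",
    "bifurcation_scan",
    "hysteresis_sweep",
    "sensitivity",
    "marker_comparison",
    "DEFAULT_MARKER_MAP",
]

#: which model state fraction each quantitative marker reads out;
#: p16 and SAHF are treated as qualitative and deliberately not mapped
DEFAULT_MARKER_MAP = {"p21": "C+S", "SA-b-Gal": "S"}


# ---------------------------------------------------------------------------
# fate threshold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FateClassification:
    """Constant-saturated-stress fate: threshold rate and verdict."""

    r_crit: float
    grows: bool
    degenerate: bool = False


def arrest_eigenvalue(params: ModelParameters, fhat: float = 1.0) -> float:
    """Dominant eigenvalue of the (P, C) subsystem at a constant response.

    The subsystem matrix is [[r - f1*Fhat, f2], [f1*Fhat, -(f2+f3)]]; its
    dominant eigenvalue is the asymptotic exponential growth rate.
    """
    f1e = params.f1 * fhat
    A = np.array([[params.r - f1e, params.f2], [f1e, -(params.f2 + params.f3)]])
    return float(np.max(np.real(np.linalg.eigvals(A))))


def classify_fate(params: ModelParameters) -> FateClassification:
    """Growth-versus-arrest verdict under constant saturated stress.

    r_crit = f1*f3/(f2+f3); the population grows iff r > r_crit strictly.
    The degenerate case f2 + f3 = 0 (with f1 > 0) leaves no route out of C,
    so the threshold collapses to f1 itself and is flagged.
    """
    if params.f2 + params.f3 == 0.0:
        if params.f1 > 0.0:
            return FateClassification(r_crit=params.f1, grows=params.r > params.f1,
                                      degenerate=True)
        return FateClassification(r_crit=0.0, grows=params.r > 0.0, degenerate=True)
    r_crit = params.f1 * params.f3 / (params.f2 + params.f3)
    return FateClassification(r_crit=r_crit, grows=params.r > r_crit)


# ---------------------------------------------------------------------------
# bifurcation structure of F
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationDiagram:
    """Fixed points of the F dynamics across a stress grid.

    ``fixed_points[i]`` is a tuple of (F*, stable) pairs for
    ``gamma_grid[i]``; ``fold_points`` are the stress levels at which the
    fixed-point count changes (saddle-node bifurcations).
    """

    gamma_grid: np.ndarray
    fixed_points: tuple
    fold_points: tuple


def _f_fixed_points(params: ModelParameters, gamma: float) -> list[tuple[float, bool]]:
    shape = params.f_shape
    a, b, c = shape.a, shape.b, shape.c

    def h(F):
        return stress_response_rhs(F, gamma, params.K, shape)

    def hprime(F):
        return a * 2.0 * F * b * b / (b * b + F * F) ** 2 - c

    out: list[tuple[float, bool]] = []
    if gamma == 0.0:
        out.append((0.0, hprime(0.0) < 0))
    f_max = (gamma + a) / c * 1.2 + 5.0 * b
    grid = np.linspace(0.0, f_max, 4001)
    vals = h(grid)
    for lo, hi, vlo, vhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if vlo == 0.0 and lo > 0.0:
            out.append((float(lo), hprime(lo) < 0))
        elif vlo * vhi < 0.0:
            root = brentq(h, lo, hi, xtol=1e-13, rtol=1e-14)
            out.append((float(root), hprime(root) < 0))
    # dedupe near-identical roots
    dedup: list[tuple[float, bool]] = []
    for F, st in sorted(out):
        if not dedup or abs(F - dedup[-1][0]) > 1e-9 * max(1.0, f_max):
            dedup.append((F, st))
    return dedup


def bifurcation_scan(
    params: ModelParameters,
    gamma_grid: Sequence[float] | np.ndarray,
) -> BifurcationDiagram:
    """Fixed points and saddle-node folds of the F dynamics over a stress grid.

    Roots of dF/dt = 0 are bracketed on a dense F grid and polished with
    Brent's method; stability is the sign of d(dF/dt)/dF; folds are located
    by bisection on each grid interval where the fixed-point count changes.
    """
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if gamma_grid.ndim != 1 or np.any(np.diff(gamma_grid) < 0):
        raise ValueError("gamma_grid must be a sorted 1-D array")
    if np.any(gamma_grid < 0):
        raise ValueError("stress levels must be >= 0")

    per_gamma = [tuple(_f_fixed_points(params, g)) for g in gamma_grid]
    if any(len(fp) == 0 for fp in per_gamma):
        raise RuntimeError("no fixed points found: the F form violates its contract")

    folds: list[float] = []
    counts = [len(fp) for fp in per_gamma]
    for g0, g1, c0, c1 in zip(gamma_grid[:-1], gamma_grid[1:], counts[:-1], counts[1:]):
        if c0 == c1:
            continue
        lo, hi, n_lo = g0, g1, c0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if len(_f_fixed_points(params, mid)) == n_lo:
                lo = mid
            else:
                hi = mid
        folds.append(0.5 * (lo + hi))
    return BifurcationDiagram(
        gamma_grid=gamma_grid,
        fixed_points=tuple(per_gamma),
        fold_points=tuple(folds),
    )


def hysteresis_sweep(
    params: ModelParameters,
    gamma_max: float,
    n: int = 400,
) -> dict:
    """Quasi-static up-then-down sweep of the stress level.

    At each stress value the response relaxes to the stable fixed point
    nearest its previous position; an abrupt jump of the tracked branch marks
    the switch.  Returns the up- and down-switch stress levels, the swept
    branches, and the area enclosed by the loop (zero iff no hysteresis).
    """
    gammas = np.linspace(0.0, gamma_max, n)

    def track(gamma_seq):
        F_cur = 0.0
        branch = []
        for g in gamma_seq:
            stable = [F for F, st in _f_fixed_points(params, g) if st]
            if not stable:
                raise RuntimeError(f"no stable fixed point at gamma={g}")
            F_cur = min(stable, key=lambda F: abs(F - F_cur))
            branch.append(F_cur)
        return np.asarray(branch)

    up = track(gammas)
    down = track(gammas[::-1])[::-1]
    jump = 0.5 * (params.f_shape.b + params.f_shape.a / params.f_shape.c)

    def switch_gamma(branch, seq):
        steps = np.abs(np.diff(branch))
        i = int(np.argmax(steps))
        return float(0.5 * (seq[i] + seq[i + 1])) if steps[i] > 0.05 * jump else None

    return {
        "gamma": gammas,
        "F_up": up,
        "F_down": down,
        "gamma_up_switch": switch_gamma(up, gammas),
        "gamma_down_switch": switch_gamma(down, gammas),
        "loop_area": float(np.trapezoid(np.abs(up - down), gammas)),
    }


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityReport:
    """One-at-a-time sensitivity of the PD curve and terminal composition."""

    perturbation: float
    entries: dict
    ranking: tuple
    failures: tuple = ()


def sensitivity(
    params: ModelParameters,
    protocol: StressProtocol,
    *,
    perturbation: float = 0.10,
    grid: Sequence[float] | np.ndarray,
    initial: CellStateVector | None = None,
    include: Iterable[str] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SensitivityReport:
    """Perturb each parameter by +-``perturbation`` and measure the response.

    For every parameter the report holds the RMS displacement of the PD curve
    over the grid and the largest absolute change of the terminal P/C/S
    fractions, both averaged over the + and - perturbation.  ``ranking``
    orders parameters by PD displacement, largest first.  alpha and beta are
    included only for linear (accumulating-stress) protocols.
    """
    if initial is None:
        initial = CellStateVector(P=1e5)
    if include is None:
        include = ["r", "f1", "f2", "f3", "K"]
        if protocol.kind == "linear":
            include += ["alpha", "beta"]
    include = list(include)

    base = simulate(params, protocol, initial, grid=grid, rtol=rtol, atol=atol)
    base_frac = state_fractions(base)

    def perturbed_run(name: str, factor: float) -> SimulationResult:
        if name in ("alpha", "beta"):
            prot = replace(protocol, **{name: getattr(protocol, name) * factor})
            return simulate(params, prot, initial, grid=grid, rtol=rtol, atol=atol)
        pars = params.with_(**{name: getattr(params, name) * factor})
        return simulate(pars, protocol, initial, grid=grid, rtol=rtol, atol=atol)

    entries: dict = {}
    failures: list[tuple[str, str]] = []
    for name in include:
        deltas_pd, deltas_frac = [], []
        try:
            for factor in (1.0 + perturbation, 1.0 - perturbation):
                res = perturbed_run(name, factor)
                deltas_pd.append(float(np.sqrt(np.mean((res.pd - base.pd) ** 2))))
                frac = state_fractions(res)
                deltas_frac.append(max(
                    abs(frac[k][-1] - base_frac[k][-1]) for k in ("P", "C", "S")
                ))
        except Exception as exc:
            failures.append((name, str(exc)))
            continue
        entries[name] = {
            "delta_pd_rms": float(np.mean(deltas_pd)),
            "delta_terminal_fraction": float(np.mean(deltas_frac)),
        }
    ranking = tuple(sorted(entries, key=lambda n: entries[n]["delta_pd_rms"],
                           reverse=True))
    return SensitivityReport(
        perturbation=perturbation,
        entries=entries,
        ranking=ranking,
        failures=tuple(failures),
    )


# ---------------------------------------------------------------------------
# marker comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerComparison:
    """Per-marker residuals between measured fractions and model fractions."""

    per_marker: dict

    def rmse(self, marker: str) -> float:
        return self.per_marker[marker]["rmse"]


def marker_comparison(
    result: SimulationResult,
    markers: Sequence,
    marker_map: dict | None = None,
) -> MarkerComparison:
    """Pair marker-positive fractions with the mapped model state fractions.

    ``markers`` is a sequence of objects with ``marker``, ``times`` and
    ``fraction_positive`` attributes (see
    :class:`senpop.synthetic_data.MarkerSeries`).  Marker times must lie
    within the simulated horizon; unknown marker names are an error so that a
    typo cannot silently be scored against the wrong state.
    """
    mapping = DEFAULT_MARKER_MAP if marker_map is None else marker_map
    fractions = state_fractions(result)
    out: dict = {}
    for series in markers:
        name = series.marker
        if name not in mapping:
            raise ValueError(
                f"marker {name!r} has no state mapping; known: {sorted(mapping)}"
            )
        state = mapping[name]
        times = np.asarray(series.times, dtype=float)
        if times.min() < result.times.min() - 1e-9 or times.max() > result.times.max() + 1e-9:
            raise ValueError(f"marker {name!r} times fall outside the simulated horizon")
        model = np.interp(times, result.times, fractions[state])
        resid = np.asarray(series.fraction_positive, dtype=float) - model
        out[name] = {
            "state": state,
            "times": times,
            "model_fraction": model,
            "residuals": resid,
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
        }
    return MarkerComparison(per_marker=out)
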