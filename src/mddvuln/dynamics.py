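"""Compartmental dynamics of MDD vulnerability and parameter sweeps.

The rescaled system in the fractions (x, y, z) = (V1, V2, M)/N is

    dx/dt = a*mu - mu*x + eps*x*y - alpha*x
    dy/dt = b*mu - mu*y - eps*x*y + alpha*x - delta*y*z + beta*z
    dz/dt = c*mu - mu*z + delta*y*z - beta*z

with the conservation law d(x+y+z)/dt = mu*((a+b+c) - (x+y+z)): the total
fraction relaxes to a+b+c at rate mu, so the unit simplex is invariant
exactly when the entry probabilities sum to 1.  The raw (count) system is
the same with source terms scaled by N and the bilinear contact terms by
1/N.

Time is measured in days throughout, matching the per-day parameter units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .estimation import ModelParameters, StateFractions

__all__ = [
    "SolverError",
    "Trajectory",
    "raw_derivatives",
    "derivatives",
    "normalized_entry",
    "integrate",
    "sweep",
]

#: Default solver tolerances (adaptive, stiff-capable LSODA).
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10
#: Infinity-norm of the vector field below which a state counts as steady.
STEADY_TOL = 1e-8
#: Horizon-doubling schedule for adaptive steady-state search (days).
T_END_START = 512.0
T_END_CAP = 2.0**21


class SolverError(RuntimeError):
    """The ODE integrator failed to produce a trajectory."""


@dataclass
class Trajectory:
    """Time course of the rescaled compartment fractions."""

    times: np.ndarray  # days, strictly increasing
    states: np.ndarray  # shape (len(times), 3), columns x, y, z
    params: ModelParameters
    solver_meta: dict = field(default_factory=dict)

    @property
    def terminal(self) -> np.ndarray:
        return self.states[-1]

    @property
    def terminal_residual(self) -> float:
        """Infinity-norm of the vector field at the final state."""
        return float(
            np.max(np.abs(derivatives(tuple(self.states[-1]), self.params)))
        )

    @property
    def converged(self) -> bool:
        return self.terminal_residual < self.solver_meta.get("steady_tol", STEADY_TOL)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.states[:, 0],
             "y": self.states[:, 1], "z": self.states[:, 2]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------


def raw_derivatives(
    counts: Sequence[float], p: ModelParameters, n: float
) -> tuple[float, float, float]:
    """Right-hand sides (dV1/dt, dV2/dt, dM/dt) of the count-level system."""
    if n <= 0:
        raise ValueError(f"total population N must be positive, got {n}")
    v1, v2, m = counts
    dv1 = p.a * p.mu * n - p.mu * v1 + p.epsilon * v1 * v2 / n - p.alpha * v1
    dv2 = (
        p.b * p.mu * n - p.mu * v2 - p.delta * v2 * m / n
        - p.epsilon * v1 * v2 / n + p.alpha * v1 + p.beta * m
    )
    dm = p.c * p.mu * n - p.mu * m + p.delta * v2 * m / n - p.beta * m
    return (dv1, dv2, dm)


def derivatives(
    s: Sequence[float] | StateFractions, p: ModelParameters
) -> tuple[float, float, float]:
    """Right-hand sides (dx/dt, dy/dt, dz/dt) of the rescaled system."""
    if isinstance(s, StateFractions):
        x, y, z = s.as_tuple()
    else:
        x, y, z = s
    dx = p.a * p.mu - p.mu * x + p.epsilon * x * y - p.alpha * x
    dy = (
        p.b * p.mu - p.mu * y - p.epsilon * x * y + p.alpha * x
        - p.delta * y * z + p.beta * z
    )
    dz = p.c * p.mu - p.mu * z + p.delta * y * z - p.beta * z
    return (dx, dy, dz)


def normalized_entry(p: ModelParameters) -> ModelParameters:
    """Rescale (a, b, c) to sum to 1, keeping their proportions.

    The equilibrium cubic is derived under x+y+z = 1, which requires entry
    probabilities summing to 1; the cohort estimates sum to ~0.80, so
    analyses that rely on the simplex assumption use this normalization.
    """
    total = p.a + p.b + p.c
    if total <= 0:
        raise ValueError("entry probabilities sum to zero; cannot normalize")
    return p.replace(a=p.a / total, b=p.b / total, c=p.c / total)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _solve(p, init, t_end, dt_out, rtol, atol):
    n_out = max(int(np.ceil(t_end / dt_out)), 2)
    t_eval = np.linspace(0.0, t_end, n_out + 1)
    sol = solve_ivp(
        lambda _t, s: derivatives(s, p),
        (0.0, t_end),
        np.asarray(init, dtype=float),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"integration failed at t_end={t_end}: {sol.message}")
    return sol


def integrate(
    p: ModelParameters,
    init: StateFractions | Sequence[float],
    t_end: float | None = None,
    dt_out: float = 1.0,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    steady_tol: float = STEADY_TOL,
    normalize_entry: bool = False,
) -> Trajectory:
    """Integrate the rescaled system from ``init`` for ``t_end`` days.

    When ``t_end`` is None the horizon is chosen adaptively: starting from
    512 days it doubles until the terminal vector-field infinity-norm drops
    below ``steady_tol`` (steady state) or the cap of ~2.1e6 days is hit.
    """
    if isinstance(init, StateFractions):
        init = init.as_tuple()
    init = tuple(float(v) for v in init)
    if any(v < 0 for v in init):
        raise ValueError(f"initial state must be nonnegative, got {init}")
    if normalize_entry:
        p = normalized_entry(p)

    if t_end is not None:
        if t_end <= 0:
            raise ValueError(f"t_end must be positive, got {t_end}")
        horizons = [float(t_end)]
    else:
        horizons = []
        h = T_END_START
        while h <= T_END_CAP:
            horizons.append(h)
            h *= 2

    sol = None
    for h in horizons:
        sol = _solve(p, init, h, dt_out, rtol, atol)
        resid = np.max(np.abs(derivatives(sol.y[:, -1], p)))
        if t_end is not None or resid < steady_tol:
            break

    traj = Trajectory(
        times=sol.t,
        states=sol.y.T.copy(),
        params=p,
        solver_meta={
            "method": "LSODA", "rtol": rtol, "atol": atol,
            "steady_tol": steady_tol, "t_end": float(sol.t[-1]),
            "nfev": int(sol.nfev),
        },
    )
    return traj


def sweep(
    p: ModelParameters,
    param_name: str,
    grid: Sequence[float],
    init: StateFractions | Sequence[float],
    t_end: float | None = None,
    **integrate_kwargs,
) -> pd.DataFrame:
    """Terminal fractions as one model parameter varies over a grid.

    Each grid point re-integrates from the same initial state and horizon.
    Solver failures are recorded (``converged`` False, NaN terminals) and the
    sweep continues.
    """
    if param_name not in ("delta", "epsilon", "alpha", "beta"):
        raise ValueError(f"cannot sweep parameter {param_name!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid is empty")
    if any(v < 0 for v in grid):
        raise ValueError("sweep grid values must be nonnegative")
    rows = []
    for value in grid:
        pv = p.replace(**{param_name: float(value)})
        try:
            traj = integrate(pv, init, t_end=t_end, **integrate_kwargs)
            xe, ye, ze = traj.terminal
            rows.append(
                {"param": param_name, "value": value, "x_end": xe, "y_end": ye,
                 "z_end": ze, "converged": traj.converged}
            )
        except SolverError:
            rows.append(
                {"param": param_name, "value": value, "x_end": np.nan,
                 "y_end": np.nan, "z_end": np.nan, "converged": False}
            )
    return pd.DataFrame(rows)
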