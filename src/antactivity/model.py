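"""The A/I/R compartmental model and its numerical integration.

The colony is described by the counts of active ``A(t)``, inactive ``I(t)``
and refractory ``R(t)`` individuals, evolving as

.. math::

    \\dot A &= (\\langle k\\rangle/N)\\,(\\beta_0 A I - \\gamma_0 A^2) \\\\
    \\dot I &= \\delta R - (\\langle k\\rangle/N)\\,\\beta_0 A I \\\\
    \\dot R &= -\\delta R + (\\langle k\\rangle/N)\\,\\gamma_0 A^2

The three right-hand sides sum to zero, so ``A + I + R = N`` is conserved,
and any non-negative initial condition stays non-negative.  States are
real-valued (mean-field); the integer-agent counterpart lives in
:mod:`antactivity.abm`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParams, ParameterError

__all__ = [
    "ColonyState",
    "Trajectory",
    "IntegrationError",
    "ode_rhs",
    "simulate",
    "conservation_residual",
]

logger = logging.getLogger(__name__)


class IntegrationError(RuntimeError):
    """The adaptive integrator failed to produce an accepted solution."""


@dataclasses.dataclass(frozen=True)
class ColonyState:
    """Counts in the three compartments at one instant (real-valued)."""

    A: float
    I: float
    R: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.A, self.I, self.R) < 0:
            raise ParameterError(
                f"compartment counts must be non-negative, got "
                f"(A={self.A}, I={self.I}, R={self.R})"
            )

    @property
    def total(self) -> float:
        return self.A + self.I + self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.I, self.R], dtype=float)


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """A solution of the model on a strictly increasing time grid.

    ``states`` has shape ``(len(times), 3)`` with columns ``A, I, R``.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or states.shape != (times.size, 3):
            raise ValueError("times must be 1-D and states (len(times), 3)")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def A(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def I(self) -> np.ndarray:  # noqa: E743 - compartment name
        return self.states[:, 1]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 2]

    def final_state(self) -> ColonyState:
        A, I, R = np.clip(self.states[-1], 0.0, None)
        return ColonyState(A=A, I=I, R=R, t=float(self.times[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "A": self.A, "I": self.I, "R": self.R}
        )

    def to_csv(self, path: str | Path, write_params: bool = True) -> None:
        """Write ``t,A,I,R`` CSV plus a JSON sidecar with the parameters."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if write_params:
            sidecar = path.with_suffix(path.suffix + ".params.json")
            sidecar.write_text(json.dumps(self.params.to_dict(), indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, params: ModelParams | None = None) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        if params is None:
            sidecar = path.with_suffix(path.suffix + ".params.json")
            params = ModelParams.from_mapping(json.loads(sidecar.read_text()))
        return cls(
            times=df["t"].to_numpy(),
            states=df[["A", "I", "R"]].to_numpy(),
            params=params,
        )


def _rhs(y: np.ndarray, params: ModelParams) -> np.ndarray:
    # Unvalidated kernel shared with the integrator (which may probe states
    # a hair outside the simplex).
    A, I, R = y
    kappa = params.kappa
    dA = kappa * (params.beta0 * A * I - params.gamma0 * A * A)
    dR = -params.delta * R + kappa * params.gamma0 * A * A
    dI = -dA - dR
    return np.array([dA, dI, dR])


def ode_rhs(state: ColonyState | Sequence[float], params: ModelParams) -> np.ndarray:
    """Instantaneous rates ``(dA/dt, dI/dt, dR/dt)`` at ``state`` (1/s).

    ``dI/dt`` is computed as the negative of the other two components, so
    the triple sums to zero identically in exact arithmetic (and to within
    one rounding of the largest term in floats).
    """
    y = state.as_array() if isinstance(state, ColonyState) else np.asarray(state, dtype=float)
    if y.shape != (3,):
        raise ParameterError(f"state must have three components, got shape {y.shape}")
    if np.min(y) < 0:
        raise ParameterError(f"compartment counts must be non-negative, got {y}")
    return _rhs(y, params)


def _time_grid(t0: float, t_end: float, n_points: int, grid: str) -> np.ndarray:
    if grid == "linear":
        return np.linspace(t0, t_end, n_points)
    if grid == "geometric":
        # Log-spaced grids suit log-time plots; keep t0 as the first point.
        start = max(t0, t_end * 1e-6)
        pts = np.geomspace(start, t_end, n_points - 1 if t0 < start else n_points)
        return np.concatenate([[t0], pts]) if t0 < start else pts
    raise ParameterError(f"unknown grid {grid!r} (use 'linear' or 'geometric')")


def simulate(
    params: ModelParams,
    initial: ColonyState | None = None,
    t_end: float = 60.0,
    n_points: int = 500,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-12,
    grid: str = "linear",
    method: str = "RK45",
) -> Trajectory:
    """Integrate the model with an adaptive Runge-Kutta scheme.

    The default initial condition is the nearly-all-active colony
    ``(A, I, R) = (N - 1, 1, 0)`` used throughout the reference analysis.
    ``A0 = 0`` is legal but leaves the activation dynamics frozen (only
    R -> I proceeds); it is logged as a warning rather than rejected.
    """
    if initial is None:
        initial = ColonyState(A=params.N - 1, I=1.0, R=0.0)
    if t_end <= 0:
        raise ParameterError(f"t_end must be positive, got {t_end}")
    if abs(initial.total - params.N) > 1e-6 * params.N:
        raise ParameterError(
            f"initial state sums to {initial.total}, expected N={params.N}"
        )
    if initial.A == 0:
        logger.warning(
            "A0 = 0: activity can never start; only the R -> I relaxation evolves"
        )

    t_eval = _time_grid(initial.t, initial.t + t_end, n_points, grid)
    sol = solve_ivp(
        lambda _t, y: _rhs(y, params),
        (initial.t, initial.t + t_end),
        initial.as_array(),
        method=method,
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message} (t reached {sol.t[-1] if sol.t.size else 'none'})"
        )
    return Trajectory(times=sol.t, states=sol.y.T, params=params)


def conservation_residual(traj: Trajectory) -> float:
    """``max |A + I + R - N|`` over the grid; < 1e-6 N at default tolerances."""
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    return float(np.max(np.abs(traj.states.sum(axis=1) - traj.params.N)))
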