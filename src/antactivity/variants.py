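"""Ablation models: the negative controls for hypometric scaling.

Two reduced models show that *both* ingredients of the full model are needed
for sublinear activity scaling:

* **No refractory state** — active ants inactivate directly (A + A -> I + A)
  and can be re-activated immediately.  The endemic equilibrium is
  ``A* = beta0/(beta0 + gamma0) * N``: exactly proportional to ``N``
  (isometric) for every ``alpha``.
* **No reverse social contagion** — inactivation is spontaneous at constant
  rate ``mu`` instead of socially driven.  For ``mu < beta0 <k>`` the
  positive equilibrium is ``A* = N delta (beta0 <k> - mu) /
  (beta0 <k> (delta + mu))``, again asymptotically proportional to ``N``;
  for ``mu >= beta0 <k>`` only the trivial equilibrium exists (reported as
  an infeasibility value, not an exception, so parameter sweeps can cross
  it).
"""

from __future__ import annotations

import dataclasses
import numbers
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import ColonyState, IntegrationError, Trajectory
from .params import ModelParams, ParameterError, mean_degree

__all__ = [
    "NoRefractoryParams",
    "NoReverseParams",
    "VariantEquilibrium",
    "no_refractory_rhs",
    "no_refractory_equilibrium",
    "no_reverse_rhs",
    "no_reverse_equilibrium",
    "simulate_no_refractory",
    "simulate_no_reverse",
]


def _check_positive(name: str, value) -> None:
    if not (isinstance(value, numbers.Real) and value > 0):
        raise ParameterError(f"{name} must be a positive real number, got {value!r}")


@dataclasses.dataclass(frozen=True)
class NoRefractoryParams:
    """Parameters of the two-compartment model without a refractory state."""

    beta0: float
    gamma0: float
    E0: float
    alpha: float
    N: int

    def __post_init__(self) -> None:
        for name in ("beta0", "gamma0", "E0"):
            _check_positive(name, getattr(self, name))
        if not 1.0 <= self.alpha <= 2.0:
            raise ParameterError(f"alpha must lie in [1, 2], got {self.alpha}")
        if not (isinstance(self.N, numbers.Integral) and self.N >= 2):
            raise ParameterError(f"N must be an integer >= 2, got {self.N!r}")

    @property
    def k_mean(self) -> float:
        return mean_degree(self.E0, self.alpha, self.N)


@dataclasses.dataclass(frozen=True)
class NoReverseParams:
    """Parameters of the model with spontaneous (asocial) inactivation."""

    beta0: float
    delta: float
    mu: float  # spontaneous active-to-refractory rate (1/s)
    E0: float
    alpha: float
    N: int

    def __post_init__(self) -> None:
        for name in ("beta0", "delta", "mu", "E0"):
            _check_positive(name, getattr(self, name))
        if not 1.0 <= self.alpha <= 2.0:
            raise ParameterError(f"alpha must lie in [1, 2], got {self.alpha}")
        if not (isinstance(self.N, numbers.Integral) and self.N >= 2):
            raise ParameterError(f"N must be an integer >= 2, got {self.N!r}")

    @property
    def k_mean(self) -> float:
        return mean_degree(self.E0, self.alpha, self.N)


@dataclasses.dataclass(frozen=True)
class VariantEquilibrium:
    """Equilibrium of an ablation model; ``feasible=False`` marks the case
    where only the trivial equilibrium exists (``mu >= beta0 <k>``)."""

    A_star: float
    I_star: float
    R_star: float
    feasible: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.A_star, self.I_star, self.R_star])


def no_refractory_rhs(A: float, I: float, params: NoRefractoryParams) -> tuple[float, float]:
    """Rates ``(dA/dt, dI/dt)``; the pair sums to zero exactly."""
    if A < 0 or I < 0:
        raise ParameterError(f"counts must be non-negative, got (A={A}, I={I})")
    kappa = params.k_mean / params.N
    dA = kappa * (params.beta0 * A * I - params.gamma0 * A * A)
    return dA, -dA


def no_refractory_equilibrium(params: NoRefractoryParams) -> VariantEquilibrium:
    """``(A*, I*) = (beta0, gamma0) / (beta0 + gamma0) * N`` — isometric."""
    total = params.beta0 + params.gamma0
    A = params.beta0 / total * params.N
    return VariantEquilibrium(A_star=A, I_star=params.N - A, R_star=0.0)


def no_reverse_rhs(
    A: float, I: float, R: float, params: NoReverseParams
) -> tuple[float, float, float]:
    """Rates ``(dA/dt, dI/dt, dR/dt)``; components sum to zero exactly."""
    if min(A, I, R) < 0:
        raise ParameterError(f"counts must be non-negative, got (A={A}, I={I}, R={R})")
    kappa = params.k_mean / params.N
    dA = kappa * params.beta0 * A * I - params.mu * A
    dR = -params.delta * R + params.mu * A
    return dA, -dA - dR, dR


def no_reverse_equilibrium(params: NoReverseParams) -> VariantEquilibrium:
    """Positive equilibrium for ``mu < beta0 <k>``; infeasible marker otherwise.

    ``A* = N delta (beta0 <k> - mu) / (beta0 <k> (delta + mu))``,
    ``I* = mu N / (beta0 <k>)``, ``R* = (mu/delta) A*``.  For ``alpha = 1``
    this is exactly ``A* = [delta/(delta+mu)] [(2 beta0 E0 - mu)/(2 beta0 E0)] N``;
    dropping the ``mu/(2 beta0 E0)`` factor gives the crude large-colony
    reading ``A* ~ delta/(delta+mu) N``.  Either way ``A*`` is proportional
    to ``N`` up to a factor that tends to 1: isometric scaling.
    """
    bk = params.beta0 * params.k_mean
    if params.mu >= bk:
        return VariantEquilibrium(0.0, float(params.N), 0.0, feasible=False)
    A = params.N * params.delta * (bk - params.mu) / (bk * (params.delta + params.mu))
    I = params.mu * params.N / bk
    R = params.mu / params.delta * A
    return VariantEquilibrium(A_star=A, I_star=I, R_star=R)


def _integrate(fun, y0, t_end, n_points, rel_tol, abs_tol):
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(fun, (0.0, t_end), y0, method="RK45", t_eval=t_eval,
                    rtol=rel_tol, atol=abs_tol)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    return sol


def simulate_no_refractory(
    params: NoRefractoryParams,
    initial: Sequence[float] | None = None,
    t_end: float = 60.0,
    n_points: int = 500,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-12,
) -> Trajectory:
    """Integrate the no-refractory model; ``R`` is zero-filled in the output
    so the shared :class:`~antactivity.model.Trajectory` plumbing applies."""
    A0, I0 = (params.N - 1.0, 1.0) if initial is None else initial
    sol = _integrate(
        lambda _t, y: np.asarray(no_refractory_rhs(max(y[0], 0.0), max(y[1], 0.0), params)),
        [A0, I0], t_end, n_points, rel_tol, abs_tol,
    )
    states = np.column_stack([sol.y[0], sol.y[1], np.zeros_like(sol.t)])
    shim = ModelParams(
        beta0=params.beta0, gamma0=params.gamma0, delta=1.0,
        E0=params.E0, alpha=params.alpha, N=params.N,
    )
    return Trajectory(times=sol.t, states=states, params=shim)


def simulate_no_reverse(
    params: NoReverseParams,
    initial: Sequence[float] | None = None,
    t_end: float = 60.0,
    n_points: int = 500,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-12,
) -> Trajectory:
    """Integrate the spontaneous-inactivation model."""
    y0 = (params.N - 1.0, 1.0, 0.0) if initial is None else tuple(initial)
    sol = _integrate(
        lambda _t, y: np.asarray(no_reverse_rhs(*np.clip(y, 0.0, None), params)),
        list(y0), t_end, n_points, rel_tol, abs_tol,
    )
    shim = ModelParams(
        beta0=params.beta0, gamma0=params.mu, delta=params.delta,
        E0=params.E0, alpha=params.alpha, N=params.N,
    )
    return Trajectory(times=sol.t, states=sol.y.T, params=shim)
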