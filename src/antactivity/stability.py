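"""Stability diagnostics: Jacobian spectra, Routh-Hurwitz, Lyapunov function.

The conservation constraint ``A + I + R = N`` shows up as a structural zero
eigenvalue at every equilibrium.  At the trivial equilibrium the remaining
eigenvalues are ``{-delta, beta0 <k>}`` — the positive one makes the
all-inactive state unstable.  At the positive equilibrium the characteristic
polynomial factors as ``p(s) = -s (a0 s**2 + a1 s + a2)`` with ``a0 = 1`` and
``a1, a2 > 0`` for every admissible parameter set, so by Routh-Hurwitz the
two nonzero eigenvalues have strictly negative real parts (marginal
stability).  Global stability is certified by a Goh-Lotka-Volterra-type
Lyapunov function on the reduced ``(A, R)`` system.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .equilibria import Equilibrium, nontrivial_equilibrium
from .model import ColonyState
from .params import ModelParams, ParameterError

__all__ = [
    "StabilityReport",
    "jacobian",
    "routh_hurwitz",
    "rh_roots",
    "stability_report",
    "lyapunov_value",
    "lyapunov_rate",
]

#: An eigenvalue is treated as the structural (conservation) zero when its
#: magnitude is below this factor times the fastest rate in the model.
ZERO_EIGENVALUE_RTOL = 1e-9


@dataclasses.dataclass(frozen=True)
class StabilityReport:
    """Jacobian, spectrum and Routh-Hurwitz data at an equilibrium."""

    jacobian: np.ndarray
    eigenvalues: np.ndarray
    rh_coeffs: tuple[float, float, float]
    verdict: str  # "unstable" | "marginally_stable"


def _state_array(state) -> np.ndarray:
    if isinstance(state, ColonyState):
        return state.as_array()
    if isinstance(state, Equilibrium):
        return state.as_array()
    return np.asarray(state, dtype=float)


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Jacobian of the right-hand side at ``state`` (columns: d/dA, d/dI, d/dR)."""
    A, I, _R = _state_array(state)
    kappa = params.kappa
    b0, g0, d = params.beta0, params.gamma0, params.delta
    return np.array(
        [
            [kappa * (b0 * I - 2.0 * g0 * A), kappa * b0 * A, 0.0],
            [-kappa * b0 * I, -kappa * b0 * A, d],
            [2.0 * kappa * g0 * A, 0.0, -d],
        ]
    )


def routh_hurwitz(params: ModelParams) -> tuple[float, float, float]:
    """Coefficients ``(a0, a1, a2)`` of the quadratic factor at the positive
    equilibrium: ``p(s) = -s (a0 s**2 + a1 s + a2)``.

    Closed forms follow from the characteristic polynomial of the analytic
    Jacobian, using ``beta0 I* = gamma0 A*``:

    ``a1 = kappa (beta0 + gamma0) A* + delta`` (minus the trace) and
    ``a2 = 2 kappa**2 beta0 gamma0 A***2 + delta kappa (beta0 + gamma0) A*``
    (sum of the principal 2x2 minors).  Both are manifestly positive, hence
    the stability of the quadratic factor.
    """
    eq = nontrivial_equilibrium(params)
    kappa = params.kappa
    A = eq.A_star
    bg = params.beta0 + params.gamma0
    a1 = kappa * bg * A + params.delta
    a2 = (
        2.0 * kappa ** 2 * params.beta0 * params.gamma0 * A ** 2
        + params.delta * kappa * bg * A
    )
    return (1.0, float(a1), float(a2))


def rh_roots(params: ModelParams) -> np.ndarray:
    """Roots of the Routh-Hurwitz quadratic (the two nonzero eigenvalues)."""
    _a0, a1, a2 = routh_hurwitz(params)
    disc = a1 * a1 - 4.0 * a2
    if disc >= 0:
        # Stable quadratic formula: avoid cancellation in the small root.
        q = -0.5 * (a1 + np.sqrt(disc))
        return np.sort_complex(np.array([q, a2 / q], dtype=complex))
    root = complex(-0.5 * a1, 0.5 * np.sqrt(-disc))
    return np.sort_complex(np.array([root.conjugate(), root]))


def stability_report(params: ModelParams, kind: str = "nontrivial") -> StabilityReport:
    """Spectrum and verdict at the trivial or nontrivial equilibrium."""
    if kind == "trivial":
        state = np.array([0.0, float(params.N), 0.0])
    elif kind == "nontrivial":
        state = nontrivial_equilibrium(params).as_array()
    else:
        raise ParameterError(f"kind must be 'trivial' or 'nontrivial', got {kind!r}")
    J = jacobian(state, params)
    eigenvalues = np.linalg.eigvals(J)
    scale = max(params.beta0, params.gamma0, params.delta) * max(params.k_mean, 1.0)
    nonzero = eigenvalues[np.abs(eigenvalues) >= ZERO_EIGENVALUE_RTOL * scale]
    verdict = (
        "unstable" if np.any(nonzero.real > 0) else "marginally_stable"
    )
    return StabilityReport(
        jacobian=J,
        eigenvalues=eigenvalues,
        rh_coeffs=routh_hurwitz(params),
        verdict=verdict,
    )


def _lyapunov_reference(params: ModelParams) -> tuple[float, float]:
    eq = nontrivial_equilibrium(params)
    return eq.A_star, eq.R_star


def lyapunov_value(A, R, params: ModelParams):
    """Goh-type Lyapunov function ``V(A, R)`` of the reduced system.

    ``V = (R - R*)**2 / (2 N**2)
    + gamma0 / (2 N**2 beta0) * [A**2 - A***2 - A***2 ln(A**2 / A***2)]``.

    Positive definite on ``(0, N] x [0, N]`` with its zero at ``(A*, R*)``.
    ``A <= 0`` is outside the domain (the logarithm is undefined there).
    """
    A = np.asarray(A, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(A <= 0):
        raise ParameterError("lyapunov_value requires A > 0")
    if np.any(R < 0):
        raise ParameterError("lyapunov_value requires R >= 0")
    As, Rs = _lyapunov_reference(params)
    N2 = float(params.N) ** 2
    quad = (R - Rs) ** 2 / (2.0 * N2)
    goh = (
        params.gamma0
        / (2.0 * N2 * params.beta0)
        * (A ** 2 - As ** 2 - As ** 2 * np.log(A ** 2 / As ** 2))
    )
    value = quad + goh
    return float(value) if value.ndim == 0 else value


def lyapunov_rate(A, R, params: ModelParams):
    """Orbital derivative of ``V`` along the flow (1/s); ``<= 0`` everywhere.

    ``dV/dt = -delta (R - R*)**2 / N**2
    - (<k>/N**3)(gamma0 + gamma0**2/beta0)(A - A*)(A**2 - A***2)``,
    vanishing only at ``(A*, R*)``.
    """
    A = np.asarray(A, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(A <= 0):
        raise ParameterError("lyapunov_rate requires A > 0")
    As, Rs = _lyapunov_reference(params)
    N = float(params.N)
    term_R = -params.delta / N ** 2 * (R - Rs) ** 2
    term_A = (
        -params.k_mean
        / N ** 3
        * (params.gamma0 + params.gamma0 ** 2 / params.beta0)
        * (A - As)
        * (A ** 2 - As ** 2)
    )
    value = term_R + term_A
    return float(value) if value.ndim == 0 else value
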