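"""Closed-form equilibria and steady-state scaling of the A/I/R model.

Setting the right-hand sides to zero yields two fixed points: the trivial
all-inactive state ``(0, N, 0)`` and a unique positive equilibrium, the
positive root of

.. math::

    \\frac{\\gamma_0 \\langle k\\rangle}{\\delta N} (A^*)^2
    + (1 + \\gamma_0/\\beta_0) A^* - N = 0,

expressed via the auxiliary function
``phi(x, y) = sqrt((1 + x)**2 + y) - (1 + x)``.  For ``alpha > 1`` and
``N >> 1`` the positive equilibrium follows the hypometric power law
``A* ~ sqrt(delta / (2 gamma0 E0)) * N**((3 - alpha)/2)`` — the model's
Kleiber-like prediction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import ModelParams, ParameterError

__all__ = [
    "Equilibrium",
    "phi",
    "trivial_equilibrium",
    "nontrivial_equilibrium",
    "asymptotic_equilibrium",
    "asymptotic_validity_ratio",
    "scaling_exponent",
    "fit_scaling_exponent",
]


@dataclasses.dataclass(frozen=True)
class Equilibrium:
    """A labelled steady-state triple.

    ``kind`` is ``"trivial"``, ``"nontrivial"`` or ``"asymptotic"``; the
    first two sum exactly to ``N``, the asymptotic one only approximately
    (its ``R*`` component is the leading-order ``N`` itself).
    """

    A_star: float
    I_star: float
    R_star: float
    kind: str
    params: ModelParams

    def as_array(self) -> np.ndarray:
        return np.array([self.A_star, self.I_star, self.R_star])

    def to_dict(self) -> dict:
        return {
            "A_star": self.A_star,
            "I_star": self.I_star,
            "R_star": self.R_star,
            "kind": self.kind,
        }


def phi(x, y):
    """``sqrt((1 + x)**2 + y) - (1 + x)`` for ``x, y >= 0``.

    Computed in the rationalized form ``y / (sqrt((1+x)**2 + y) + (1+x))``,
    which avoids cancellation for small ``y``.  Non-negative, zero iff
    ``y = 0``, increasing in ``y`` and decreasing in ``x``.  Accepts scalars
    or arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ParameterError("phi requires x >= 0 and y >= 0")
    value = y / (np.sqrt((1.0 + x) ** 2 + y) + (1.0 + x))
    return float(value) if value.ndim == 0 else value


def trivial_equilibrium(params: ModelParams) -> Equilibrium:
    """The all-inactive fixed point ``(0, N, 0)`` (unstable)."""
    return Equilibrium(0.0, float(params.N), 0.0, "trivial", params)


def nontrivial_equilibrium(params: ModelParams) -> Equilibrium:
    """The unique positive fixed point (globally, marginally stable).

    ``A* = delta N / (2 gamma0 <k>) * phi(gamma0/beta0, 4 gamma0 <k>/delta)``,
    with ``I* = (gamma0/beta0) A*`` and ``R* = (phi/2) A*``.
    """
    x = params.gamma0 / params.beta0
    y = 4.0 * params.gamma0 * params.k_mean / params.delta
    f = phi(x, y)
    A = params.delta * params.N / (2.0 * params.gamma0 * params.k_mean) * f
    I = x * A
    R = 0.5 * f * A
    return Equilibrium(A, I, R, "nontrivial", params)


def asymptotic_equilibrium(params: ModelParams) -> Equilibrium:
    """Large-``N`` power-law limit of the positive equilibrium (``alpha > 1``).

    ``A* ~ sqrt(delta/(2 gamma0 E0)) N**((3-alpha)/2)``,
    ``I* = (gamma0/beta0) A*``, ``R* ~ N``.  Undefined for ``alpha = 1``
    (the isometric case has no such asymptote).
    """
    if params.alpha <= 1.0:
        raise ParameterError(
            "asymptotic equilibrium requires alpha > 1 (alpha = 1 scales isometrically)"
        )
    exponent = scaling_exponent(params.alpha)
    A = np.sqrt(params.delta / (2.0 * params.gamma0 * params.E0)) * params.N ** exponent
    I = (
        np.sqrt(params.delta * params.gamma0 / (2.0 * params.E0))
        / params.beta0
        * params.N ** exponent
    )
    return Equilibrium(float(A), float(I), float(params.N), "asymptotic", params)


def asymptotic_validity_ratio(params: ModelParams) -> float:
    """``(4 gamma0 <k>/delta) / (1 + gamma0/beta0)**2``.

    The power-law limit is accurate when this ratio is large; it grows with
    ``N`` for ``alpha > 1`` and shrinks as ``beta0 -> 0``.
    """
    y = 4.0 * params.gamma0 * params.k_mean / params.delta
    return float(y / (1.0 + params.gamma0 / params.beta0) ** 2)


def scaling_exponent(alpha: float) -> float:
    """Steady-state exponent ``(3 - alpha)/2`` of ``A*`` versus ``N``.

    ``alpha = 1`` gives isometry (exponent 1); ``alpha = 3/2`` the
    Kleiber-like 3/4; ``alpha = 2`` the strongest regulation, 1/2.
    """
    if not 1.0 <= alpha <= 2.0:
        raise ParameterError(f"alpha must lie in [1, 2], got {alpha}")
    return (3.0 - alpha) / 2.0


def fit_scaling_exponent(sizes, values) -> tuple[float, float]:
    """Ordinary least squares of ``log(value)`` on ``log(N)``.

    Returns ``(slope, intercept)`` with the intercept on the natural-log
    scale (``value = exp(intercept) * N**slope`` for an exact power law).
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if sizes.shape != values.shape or sizes.ndim != 1:
        raise ParameterError("sizes and values must be 1-D arrays of equal length")
    if np.unique(sizes).size < 3:
        raise ParameterError("need at least 3 distinct sizes for a power-law fit")
    if np.any(values <= 0) or np.any(sizes <= 0):
        raise ParameterError("power-law fit requires strictly positive sizes and values")
    slope, intercept = np.polyfit(np.log(sizes), np.log(values), 1)
    return float(slope), float(intercept)
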