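"""Agent-based Monte Carlo model on switching Erdős–Rényi networks.

The stochastic counterpart of the mean-field model: ``N`` agents, each in
state A, I or R, evolve in discrete time with step ``dt``.  At every step a
fresh Erdős–Rényi graph with link probability ``p = <k>/N`` is drawn
(memoryless switching — the full-mixing limit), and all agents update
synchronously from the time-``t`` snapshot:

* an inactive agent with ``m`` active neighbours activates with probability
  ``1 - (1 - beta0 dt)**m``;
* an active agent with ``m`` active neighbours becomes refractory with
  probability ``1 - (1 - gamma0 dt)**m``;
* a refractory agent becomes inactive with probability ``delta dt``.

Each active neighbour is an independent Bernoulli channel with per-step
probability ``rate * dt``; this reproduces the bilinear/quadratic mean-field
terms to first order in ``dt``.  A ``linear`` combination rule
(``min(m r dt, 1)``) is available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .model import Trajectory
from .params import ModelParams, ParameterError

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "REFRACTORY",
    "AbmConfig",
    "EnsembleSummary",
    "draw_network",
    "active_neighbor_counts",
    "step",
    "run",
    "ensemble",
    "compare_to_ode",
]

logger = logging.getLogger(__name__)

ACTIVE, INACTIVE, REFRACTORY = 0, 1, 2


@dataclasses.dataclass(frozen=True)
class AbmConfig:
    """Discrete-time simulation settings.

    The default initial condition is the all-active-but-one colony used by
    the reference simulations; per-step probabilities ``rate * dt`` must not
    exceed 1.
    """

    params: ModelParams
    dt: float = 0.0667
    n_steps: int = 150
    n_realizations: int = 10
    seed: int = 0
    initial: tuple[int, int, int] | None = None  # (A, I, R) counts
    combine: str = "binomial"  # or "linear"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        for name in ("beta0", "gamma0", "delta"):
            p = getattr(self.params, name) * self.dt
            if p > 1.0:
                raise ParameterError(
                    f"per-step probability {name}*dt = {p:.3g} exceeds 1; reduce dt"
                )
        if self.combine not in ("binomial", "linear"):
            raise ParameterError(f"combine must be 'binomial' or 'linear', got {self.combine!r}")
        if self.initial is not None:
            A, I, R = self.initial
            if min(A, I, R) < 0 or A + I + R != self.params.N:
                raise ParameterError(
                    f"initial counts {self.initial} must be non-negative and sum to N"
                )

    def initial_states(self) -> np.ndarray:
        if self.initial is None:
            A, I, R = self.params.N - 1, 1, 0
        else:
            A, I, R = self.initial
        return np.repeat(
            np.array([ACTIVE, INACTIVE, REFRACTORY], dtype=np.uint8), [A, I, R]
        )


@dataclasses.dataclass(frozen=True)
class EnsembleSummary:
    """Per-step mean and standard deviation of the three counts."""

    times: np.ndarray
    mean: np.ndarray  # (n_steps + 1, 3)
    sd: np.ndarray  # (n_steps + 1, 3)
    n_realizations: int


def draw_network(N: int, k_mean: float, rng: np.random.Generator) -> np.ndarray:
    """Sample an Erdős–Rényi edge list with link probability ``p = k_mean/N``.

    Returns an ``(E, 2)`` int array of undirected edges (``u < v``).  Every
    one of the ``N(N-1)/2`` pairs is included independently; ``p > 1`` is
    clipped to the complete graph with a logged warning.
    """
    if N < 2:
        raise ParameterError(f"N must be >= 2, got {N}")
    if k_mean < 0:
        raise ParameterError(f"k_mean must be non-negative, got {k_mean}")
    p = k_mean / N
    if p > 1.0:
        logger.warning("link probability %.3g > 1; clipping to complete graph", p)
        p = 1.0
    n_pairs = N * (N - 1) // 2
    if p == 0.0:
        return np.empty((0, 2), dtype=np.int64)
    n_edges = rng.binomial(n_pairs, p)
    if n_edges == 0:
        return np.empty((0, 2), dtype=np.int64)
    idx = rng.choice(n_pairs, size=n_edges, replace=False)
    # Decode linear index of the strict upper triangle: row u, then offset.
    # Pair (u, v), u < v, has index u*N - u*(u+3)/2 + v - 1.
    u = (
        N
        - 2
        - np.floor(np.sqrt(4.0 * N * (N - 1) - 8.0 * idx - 7.0) / 2.0 - 0.5)
    ).astype(np.int64)
    v = idx + u * (u + 3) // 2 - u * N + 1
    return np.column_stack([u, v])


def active_neighbor_counts(states: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Number of active neighbours of every agent under ``edges``."""
    N = states.size
    m = np.zeros(N, dtype=np.int64)
    if edges.size == 0:
        return m
    u, v = edges[:, 0], edges[:, 1]
    act = states == ACTIVE
    np.add.at(m, u, act[v])
    np.add.at(m, v, act[u])
    return m


def _channel_prob(rate_dt: float, m: np.ndarray, combine: str) -> np.ndarray:
    if combine == "binomial":
        return -np.expm1(m * np.log1p(-rate_dt)) if rate_dt < 1.0 else (m > 0).astype(float)
    return np.minimum(m * rate_dt, 1.0)


def step(
    states: np.ndarray,
    edges: np.ndarray,
    probs: tuple[float, float, float],
    rng: np.random.Generator,
    combine: str = "binomial",
) -> np.ndarray:
    """One synchronous update from the time-``t`` snapshot.

    ``probs = (beta0*dt, gamma0*dt, delta*dt)``, each in [0, 1].  Total
    population is conserved exactly (every agent maps to exactly one state).
    """
    beta_dt, gamma_dt, delta_dt = probs
    for name, p in zip(("beta0*dt", "gamma0*dt", "delta*dt"), probs):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} = {p} outside [0, 1]")
    m = active_neighbor_counts(states, edges)
    u = rng.random(states.size)
    out = states.copy()
    inactive = states == INACTIVE
    out[inactive & (u < _channel_prob(beta_dt, m, combine))] = ACTIVE
    active = states == ACTIVE
    out[active & (u < _channel_prob(gamma_dt, m, combine))] = REFRACTORY
    refractory = states == REFRACTORY
    out[refractory & (u < delta_dt)] = INACTIVE
    return out


def _counts(states: np.ndarray) -> np.ndarray:
    return np.bincount(states, minlength=3)


def run(
    config: AbmConfig,
    rng: np.random.Generator | None = None,
    record_frames: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """One realization: ``(n_steps + 1, 3)`` integer counts of (A, I, R).

    The interaction network is redrawn at every step.  With
    ``record_frames=True`` also returns the per-step edge lists and the
    ``(n_steps + 1, N)`` per-agent state history (used by the synthetic
    fixtures).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.params
    probs = (p.beta0 * config.dt, p.gamma0 * config.dt, p.delta * config.dt)
    states = config.initial_states()
    counts = np.empty((config.n_steps + 1, 3), dtype=np.int64)
    counts[0] = _counts(states)
    edge_frames: list[np.ndarray] = []
    state_frames = (
        np.empty((config.n_steps + 1, p.N), dtype=np.uint8) if record_frames else None
    )
    if record_frames:
        state_frames[0] = states
    for k in range(config.n_steps):
        edges = draw_network(p.N, p.k_mean, rng)
        if record_frames:
            edge_frames.append(edges)
        states = step(states, edges, probs, rng, config.combine)
        counts[k + 1] = _counts(states)
        if record_frames:
            state_frames[k + 1] = states
    if record_frames:
        return counts, edge_frames, state_frames
    return counts


def ensemble(config: AbmConfig, n_realizations: int | None = None,
             base_seed: int | None = None) -> EnsembleSummary:
    """Mean and sd of the count series over independent seeded realizations.

    Streams are spawned from ``base_seed`` (default: ``config.seed``) via
    ``SeedSequence``, so results are reproducible bit-for-bit.
    """
    n = config.n_realizations if n_realizations is None else n_realizations
    if n < 1:
        raise ParameterError(f"need at least one realization, got {n}")
    seed = config.seed if base_seed is None else base_seed
    streams = np.random.SeedSequence(seed).spawn(n)
    all_counts = np.stack(
        [run(config, np.random.default_rng(s)) for s in streams]
    ).astype(float)
    times = np.arange(config.n_steps + 1) * config.dt
    return EnsembleSummary(
        times=times,
        mean=all_counts.mean(axis=0),
        sd=all_counts.std(axis=0, ddof=0),
        n_realizations=n,
    )


def compare_to_ode(summary: EnsembleSummary, traj: Trajectory) -> float:
    """``max |ensemble mean - ODE| / N`` over steps and compartments.

    The trajectory must be sampled on the summary's grid (``k * dt``).
    """
    if summary.times.shape != traj.times.shape or not np.allclose(
        summary.times, traj.times, rtol=0, atol=1e-9
    ):
        raise ValueError("time grids of the ensemble and the trajectory differ")
    return float(np.max(np.abs(summary.mean - traj.states)) / traj.params.N)
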