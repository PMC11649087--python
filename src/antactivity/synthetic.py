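"""Synthetic fixtures with the statistical structure the calibration assumes.

The original colony videos are not publicly deposited, so every pipeline
stage is exercised on generated data instead.  Two generators cover the two
halves of the pipeline:

* **Network fixtures** — per-frame Erdős–Rényi contact networks with mean
  degree ``2 E0 N**(alpha-1)``, agent states evolved by the agent-based
  update, activity labels equal to the planted A-states.  These test the
  ``E0/alpha`` fit, the ``q`` fit and the event-counting rates, because the
  planted degree law is exact by construction.
* **Track fixtures** — planar positions in a square arena: active ants take
  a uniformly oriented step of at least one pixel, inactive/refractory ants
  jitter below the pixel threshold, walls reflect.  States evolve on the
  *proximity* graph (6 mm radius), so the contact structure arises from the
  geometry; these test activity scoring and network construction, not the
  degree law (a prescribed degree law cannot in general be realized by a
  unit-disk graph).

The spatial defaults copy the video geometry (16 colonies of 40-360
workers, 450 frames at 0.0667 s, 248 mm arena, 6 mm contact radius).
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import abm
from .calibration import ColonyMeta, ColonyNetworkData, TrackTable
from .equilibria import nontrivial_equilibrium
from .params import CALIBRATED_RATES, ModelParams, ParameterError

__all__ = [
    "FixtureSpec",
    "PrintedCounts",
    "generate_network_fixture",
    "generate_track_fixture",
    "printed_counts_fixture",
]


def _default_sizes() -> tuple[int, ...]:
    return tuple(int(n) for n in np.linspace(40, 360, 16))


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Generator settings; defaults emulate the calibration dataset."""

    beta0: float = 10.0 * CALIBRATED_RATES["gamma0"]
    gamma0: float = CALIBRATED_RATES["gamma0"]
    delta: float = CALIBRATED_RATES["delta"]
    E0: float = CALIBRATED_RATES["E0"]
    alpha: float = CALIBRATED_RATES["alpha"]
    colony_sizes: tuple[int, ...] = dataclasses.field(default_factory=_default_sizes)
    n_frames: int = 450
    burn_in: int = 100
    dt: float = 0.0667
    pixel_mm: float = 0.5
    arena_mm: float = 248.0
    contact_radius_mm: float = 6.0
    active_step_px: tuple[float, float] = (1.0, 4.0)  # uniform, in pixels
    jitter_px: float = 0.15  # Gaussian sd for non-active ants, in pixels
    initial: str = "equilibrium"  # or "mostly_active" / "all_inactive"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.jitter_px < 1.0 <= self.active_step_px[0]:
            raise ParameterError(
                "need jitter < 1 pixel <= minimum active step for threshold separation"
            )
        if self.n_frames < 2 or self.burn_in < 0:
            raise ParameterError("need n_frames >= 2 and burn_in >= 0")

    def model_params(self, N: int) -> ModelParams:
        return ModelParams(
            beta0=self.beta0, gamma0=self.gamma0, delta=self.delta,
            E0=self.E0, alpha=self.alpha, N=int(N),
        )


class PrintedCounts(NamedTuple):
    """The worked-example event counts reported for the real videos."""

    n_interaction_frames: int
    n_inactivation_events: int
    dt: float


def printed_counts_fixture() -> PrintedCounts:
    """Counts behind the reported reverse-contagion probability: 800 / 9861
    at a 0.0667 s frame interval."""
    return PrintedCounts(n_interaction_frames=9861, n_inactivation_events=800,
                         dt=0.0667)


def _initial_states(spec: FixtureSpec, params: ModelParams,
                    rng: np.random.Generator) -> np.ndarray:
    N = params.N
    if spec.initial == "mostly_active":
        counts = (N - 1, 1, 0)
    elif spec.initial == "all_inactive":
        counts = (0, N, 0)
    elif spec.initial == "equilibrium":
        eq = nontrivial_equilibrium(params)
        a = int(round(eq.A_star))
        i = int(round(eq.I_star))
        a, i = max(a, 1), max(i, 1)
        counts = (a, i, N - a - i)
        if counts[2] < 0:
            counts = (a, N - a, 0)
    else:
        raise ParameterError(f"unknown initial condition {spec.initial!r}")
    states = np.repeat(
        np.array([abm.ACTIVE, abm.INACTIVE, abm.REFRACTORY], dtype=np.uint8), counts
    )
    rng.shuffle(states)
    return states


def _evolve_recorded(spec, params, rng, networks_from):
    """Burn in, then record (edges, states) frames; the contact graph for
    the dynamics is supplied by ``networks_from(positions?)``."""
    probs = (params.beta0 * spec.dt, params.gamma0 * spec.dt, params.delta * spec.dt)
    if max(probs) > 1.0:
        raise ParameterError("per-step probability exceeds 1; reduce dt")
    states = _initial_states(spec, params, rng)
    for _ in range(spec.burn_in):
        states = abm.step(states, networks_from(), probs, rng)
    edges, history = [], [states.copy()]
    for _ in range(spec.n_frames - 1):
        e = networks_from()
        states = abm.step(states, e, probs, rng)
        edges.append(e)
        history.append(states.copy())
    # Edge list for the last recorded frame (dynamics no longer need it,
    # but the calibration formats expect one network per frame).
    edges.append(networks_from())
    return edges, np.stack(history)


def generate_network_fixture(
    spec: FixtureSpec,
) -> tuple[dict[str, ColonyNetworkData], dict[str, np.ndarray]]:
    """Per-colony switching-network data plus the planted state history.

    Returns ``(dataset, history)`` where ``dataset`` feeds
    :func:`antactivity.calibration.calibrate` directly (activity label =
    planted A-state, every frame scored) and ``history[colony]`` is the
    ``(n_frames, N)`` agent-state array.
    """
    root = np.random.SeedSequence(spec.seed)
    dataset: dict[str, ColonyNetworkData] = {}
    history: dict[str, np.ndarray] = {}
    for child, N in zip(root.spawn(len(spec.colony_sizes)), spec.colony_sizes):
        rng = np.random.default_rng(child)
        params = spec.model_params(N)
        edges, states = _evolve_recorded(
            spec, params, rng, lambda: abm.draw_network(N, params.k_mean, rng)
        )
        colony = f"N{N:04d}"
        active = states == abm.ACTIVE
        dataset[colony] = ColonyNetworkData(
            colony=colony, n=N, edges=edges, active=active,
            scored=np.ones_like(active),
        )
        history[colony] = states
    return dataset, history


def _proximity_edges(xy: np.ndarray, radius: float) -> np.ndarray:
    from scipy.spatial import cKDTree

    pairs = cKDTree(xy).query_pairs(r=radius, output_type="ndarray")
    pairs.sort(axis=1)
    return pairs.astype(np.int64)


def generate_track_fixture(
    spec: FixtureSpec,
) -> tuple[TrackTable, dict[str, np.ndarray]]:
    """Planar tracks whose movement encodes the planted states.

    Active ants move ``uniform(active_step_px) * pixel_mm`` in a uniform
    direction; others get isotropic Gaussian jitter of ``jitter_px`` pixels,
    so the one-pixel scoring rule recovers the planted labels exactly up to
    reflection clipping at the walls.  The contact graph driving the state
    dynamics is the 6 mm proximity graph of the current positions.
    """
    root = np.random.SeedSequence(spec.seed + 1)
    frames_out = []
    history: dict[str, np.ndarray] = {}
    meta: dict[str, ColonyMeta] = {}
    for child, N in zip(root.spawn(len(spec.colony_sizes)), spec.colony_sizes):
        rng = np.random.default_rng(child)
        params = spec.model_params(N)
        probs = (params.beta0 * spec.dt, params.gamma0 * spec.dt,
                 params.delta * spec.dt)
        xy = rng.uniform(0.0, spec.arena_mm, size=(N, 2))
        states = _initial_states(spec, params, rng)
        colony = f"N{N:04d}"
        positions = np.empty((spec.n_frames, N, 2))
        planted = np.empty((spec.n_frames, N), dtype=np.uint8)
        for f in range(spec.n_frames):
            positions[f] = xy
            planted[f] = states
            edges = _proximity_edges(xy, spec.contact_radius_mm)
            new_states = abm.step(states, edges, probs, rng)
            # Displacement over (f -> f+1) encodes the state at f+1: the
            # scoring rule marks an ant active at f+1 if it moved since f.
            will_be_active = new_states == abm.ACTIVE
            step_len = np.where(
                will_be_active,
                rng.uniform(*spec.active_step_px, size=N) * spec.pixel_mm,
                np.abs(rng.normal(0.0, spec.jitter_px * spec.pixel_mm, size=N)),
            )
            theta = rng.uniform(0.0, 2.0 * np.pi, size=N)
            xy = xy + step_len[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
            # Reflective walls (the arena is an enclosure).
            xy = np.abs(xy)
            xy = spec.arena_mm - np.abs(spec.arena_mm - xy)
            states = new_states
        frame_idx = np.repeat(np.arange(spec.n_frames), N)
        ant_idx = np.tile(np.arange(N), spec.n_frames)
        frames_out.append(
            pd.DataFrame(
                {
                    "colony": colony,
                    "frame": frame_idx,
                    "ant": ant_idx,
                    "x_mm": positions.reshape(-1, 2)[:, 0],
                    "y_mm": positions.reshape(-1, 2)[:, 1],
                }
            )
        )
        history[colony] = planted
        meta[colony] = ColonyMeta(
            colony=colony, n_nominal=N, dt=spec.dt,
            pixel_mm=spec.pixel_mm, arena_mm=spec.arena_mm,
        )
    tracks = TrackTable(df=pd.concat(frames_out, ignore_index=True), meta=meta)
    return tracks, history
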