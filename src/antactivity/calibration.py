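"""Estimating model rates from per-frame tracks or contact networks.

The pipeline mirrors how the model was calibrated on harvester-ant colony
videos (16 colonies, N = 40–360, 30 s at an effective frame interval of
0.0667 s, 248 x 248 mm arena):

1. **Proximity networks** — two ants are in contact in a frame when their
   Euclidean distance is at most 6 mm (one body length; ties count).
2. **Instantaneous activity** — an ant is active at frame ``f`` if it moved
   at least one pixel since frame ``f - 1`` (frame 0 is unscored).
3. **Network scaling** — the per-colony mean edge count ``E`` is fitted
   against ``N`` on log-log axes: ``E = E0 * N**alpha``.
4. **Reverse-contagion extent** — ``y = 2 A**2 E / N**2`` (A = per-frame
   mean active count) is fitted through the origin; at the steady state the
   model gives ``y = (delta/gamma0)(N - (1 + gamma0/beta0) A*)``, so the
   slope identifies ``q = delta/gamma0`` (exactly so in the ``N >> 1``
   limit, where the fit on ``N`` and the fit on ``N - A`` coincide).
5. **gamma0** — the per-interaction probability of reverse social contagion
   is the count of deactivation events divided by the count of active-active
   interaction observations; dividing by the frame interval gives the rate.
6. **delta = q * gamma0.**

``beta0`` is deliberately never reported: with inactive and refractory ants
indistinguishable in video, the observable activation probability is
independent of ``beta0``, so the data cannot identify it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .params import ParameterError

__all__ = [
    "CalibrationError",
    "ColonyMeta",
    "TrackTable",
    "ColonyNetworkData",
    "NetworkScalingFit",
    "CalibrationResult",
    "build_proximity_networks",
    "score_activity",
    "attach_activity",
    "colony_summaries",
    "fit_network_scaling",
    "reverse_contagion_slope",
    "count_reverse_contagion_events",
    "estimate_gamma0",
    "estimate_delta",
    "calibrate",
    "calibrate_tracks",
    "write_network_dataset",
    "read_network_dataset",
    "write_track_table",
    "read_track_table",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_RADIUS_MM = 6.0
DEFAULT_FRAME_INTERVAL_S = 0.0667  # 75 fps source, one of every five frames


class CalibrationError(RuntimeError):
    """A calibration stage failed; the message names the stage."""


@dataclasses.dataclass(frozen=True)
class ColonyMeta:
    """Per-colony acquisition metadata."""

    colony: str
    n_nominal: int
    dt: float = DEFAULT_FRAME_INTERVAL_S
    pixel_mm: float = 0.5
    arena_mm: float = 248.0


@dataclasses.dataclass(frozen=True)
class TrackTable:
    """Per-frame positions: DataFrame with columns
    ``colony, frame, ant, x_mm, y_mm`` plus per-colony metadata."""

    df: pd.DataFrame
    meta: dict[str, ColonyMeta]

    REQUIRED = ("colony", "frame", "ant", "x_mm", "y_mm")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ParameterError(f"track table missing columns {sorted(missing)}")

    def colonies(self) -> list[str]:
        return sorted(self.df["colony"].astype(str).unique())


@dataclasses.dataclass
class ColonyNetworkData:
    """Per-frame contact networks and activity flags for one colony.

    ``edges[f]`` is an ``(E_f, 2)`` int array over ant indices ``0..n-1``;
    ``active`` and ``scored`` are ``(n_frames, n)`` booleans — a flag is
    meaningful only where ``scored`` is True (frame 0 of a track table is
    never scored).
    """

    colony: str
    n: int
    edges: list[np.ndarray]
    active: np.ndarray
    scored: np.ndarray

    def __post_init__(self) -> None:
        T = len(self.edges)
        if self.active.shape != (T, self.n) or self.scored.shape != (T, self.n):
            raise ParameterError(
                f"colony {self.colony}: activity arrays must be ({T}, {self.n})"
            )
        for f, e in enumerate(self.edges):
            if e.size and (np.any(e[:, 0] == e[:, 1]) or e.max() >= self.n):
                raise ParameterError(
                    f"colony {self.colony}, frame {f}: bad edge list (self-edge or id out of range)"
                )

    @property
    def n_frames(self) -> int:
        return len(self.edges)

    def mean_edges(self) -> float:
        return float(np.mean([e.shape[0] for e in self.edges]))

    def mean_active(self, per_frame: bool = True) -> float:
        """Active count per scored frame (default) or the raw flag total."""
        scored_frames = np.flatnonzero(self.scored.any(axis=1))
        total = float(self.active[self.scored].sum())
        if not per_frame:
            return total
        if scored_frames.size == 0:
            return 0.0
        return total / scored_frames.size


# ---------------------------------------------------------------------------
# Stage 1-2: geometry -> networks and activity flags
# ---------------------------------------------------------------------------

def _colony_frames(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Sorted frames, sorted ant ids, and a pivotable copy for one colony."""
    frames = np.sort(df["frame"].unique())
    ants = np.sort(df["ant"].unique())
    return frames, ants, df


def build_proximity_networks(
    tracks: TrackTable, radius: float = DEFAULT_CONTACT_RADIUS_MM
) -> dict[str, ColonyNetworkData]:
    """Per-frame contact networks: edge iff distance <= ``radius`` (mm).

    Rows with missing coordinates are skipped (count logged).  Activity
    flags are left unscored; use :func:`attach_activity` or
    :func:`calibrate_tracks` for the full chain.
    """
    n_missing = int(tracks.df[["x_mm", "y_mm"]].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("skipping %d rows with missing coordinates", n_missing)
    df = tracks.df.dropna(subset=["x_mm", "y_mm"])
    out: dict[str, ColonyNetworkData] = {}
    for colony, cdf in df.groupby("colony", sort=True):
        colony = str(colony)
        frames, ants, _ = _colony_frames(cdf)
        index = {a: i for i, a in enumerate(ants)}
        edges: list[np.ndarray] = []
        for frame in frames:
            fdf = cdf[cdf["frame"] == frame]
            ids = fdf["ant"].map(index).to_numpy()
            xy = fdf[["x_mm", "y_mm"]].to_numpy()
            if ids.size < 2:
                edges.append(np.empty((0, 2), dtype=np.int64))
                continue
            pairs = cKDTree(xy).query_pairs(r=radius, output_type="ndarray")
            e = ids[pairs]
            e.sort(axis=1)
            edges.append(e.astype(np.int64))
        T, n = frames.size, ants.size
        out[colony] = ColonyNetworkData(
            colony=colony,
            n=n,
            edges=edges,
            active=np.zeros((T, n), dtype=bool),
            scored=np.zeros((T, n), dtype=bool),
        )
    return out


def score_activity(
    tracks: TrackTable, pixel_mm: float | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-frame activity flags from the one-pixel displacement rule.

    Returns ``{colony: (active, scored)}`` arrays of shape
    ``(n_frames, n_ants)``; an ant is active at frame ``f`` when its
    displacement from ``f - 1`` is at least one pixel.  Frame 0 (and any
    frame without a predecessor position) is unscored.  Single-frame tracks
    are unusable and raise.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for colony, cdf in tracks.df.groupby("colony", sort=True):
        colony = str(colony)
        px = pixel_mm if pixel_mm is not None else tracks.meta[colony].pixel_mm
        frames, ants, _ = _colony_frames(cdf)
        if frames.size < 2:
            raise CalibrationError(
                f"stage activity-scoring: colony {colony} has a single frame"
            )
        x = cdf.pivot_table(index="frame", columns="ant", values="x_mm").reindex(
            index=frames, columns=ants
        )
        y = cdf.pivot_table(index="frame", columns="ant", values="y_mm").reindex(
            index=frames, columns=ants
        )
        disp = np.hypot(x.diff().to_numpy(), y.diff().to_numpy())
        scored = ~np.isnan(disp)
        scored[0] = False
        active = np.zeros_like(scored)
        active[scored] = disp[scored] >= px
        out[colony] = (active, scored)
    return out


def attach_activity(
    networks: dict[str, ColonyNetworkData],
    activity: dict[str, tuple[np.ndarray, np.ndarray]],
) -> dict[str, ColonyNetworkData]:
    for colony, data in networks.items():
        active, scored = activity[colony]
        data.active = active
        data.scored = scored
        data.__post_init__()
    return networks


# ---------------------------------------------------------------------------
# Stage 3-4: scaling fits
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NetworkScalingFit:
    E0: float
    alpha: float
    r_squared: float
    in_range: bool  # alpha within the model's admissible [1, 2]


def fit_network_scaling(sizes, mean_edge_counts) -> NetworkScalingFit:
    """OLS of ``log E`` on ``log N``: ``E0 = exp(intercept)``, ``alpha = slope``.

    Colonies with zero edges are excluded with a warning; an out-of-range
    exponent is flagged rather than raised.
    """
    sizes = np.asarray(sizes, dtype=float)
    E = np.asarray(mean_edge_counts, dtype=float)
    keep = E > 0
    if not np.all(keep):
        logger.warning("excluding %d zero-edge colonies from the scaling fit",
                       int((~keep).sum()))
    sizes, E = sizes[keep], E[keep]
    if np.unique(sizes).size < 3:
        raise CalibrationError(
            "stage network-scaling: need >= 3 colonies with distinct sizes and edges"
        )
    logN, logE = np.log(sizes), np.log(E)
    slope, intercept = np.polyfit(logN, logE, 1)
    fitted = intercept + slope * logN
    ss_res = float(np.sum((logE - fitted) ** 2))
    ss_tot = float(np.sum((logE - logE.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    in_range = 1.0 <= slope <= 2.0
    if not in_range:
        logger.warning("fitted alpha = %.3f lies outside [1, 2]", slope)
    return NetworkScalingFit(E0=float(np.exp(intercept)), alpha=float(slope),
                             r_squared=r2, in_range=in_range)


def reverse_contagion_slope(sizes, mean_edge_counts, active_counts,
                            regressor: str = "origin") -> float:
    """Slope ``q`` of the reverse-contagion extent ``y = 2 A**2 E / N**2``.

    ``regressor`` selects the design:

    * ``"origin"`` — through-origin least squares of ``y`` on ``N`` (the
      historical procedure; identifies ``q = delta/gamma0`` for ``N >> 1``);
    * ``"ols"`` — OLS with intercept on ``N`` (sensitivity check);
    * ``"finite_size"`` — through-origin on ``N - A``, which removes the
      leading finite-size bias using the exact steady-state identity
      ``y = (delta/gamma0)(N - (1 + gamma0/beta0) A*)``.
    """
    N = np.asarray(sizes, dtype=float)
    E = np.asarray(mean_edge_counts, dtype=float)
    A = np.asarray(active_counts, dtype=float)
    y = 2.0 * A ** 2 * E / N ** 2
    if np.all(y == 0):
        logger.warning("reverse-contagion extent is identically zero (no active ants)")
        return 0.0
    if regressor == "origin":
        return float(np.dot(y, N) / np.dot(N, N))
    if regressor == "ols":
        return float(np.polyfit(N, y, 1)[0])
    if regressor == "finite_size":
        x = N - A
        if np.any(x <= 0):
            raise CalibrationError(
                "stage q-fit: N - A must be positive for the finite-size regressor"
            )
        return float(np.dot(y, x) / np.dot(x, x))
    raise CalibrationError(f"stage q-fit: unknown regressor {regressor!r}")


# ---------------------------------------------------------------------------
# Stage 5-6: event counting and rates
# ---------------------------------------------------------------------------

def count_reverse_contagion_events(
    dataset: Iterable[ColonyNetworkData] | ColonyNetworkData,
    unit: str = "interaction",
) -> tuple[int, int]:
    """Count ``(interaction observations, deactivation events)``.

    For every pair of consecutive frames the edges whose endpoints are both
    active (and scored at both frames) are the interaction observations;
    an event is an active ant that is no longer active in the next frame.
    ``unit`` picks the counting dialect:

    * ``"interaction"`` (default) — denominator counts *directed*
      active-active contacts (one per active ant per active partner);
      numerator counts each deactivating ant once.  Under the model each
      active partner is an independent deactivation channel of probability
      ``gamma0 * dt``, so the ratio estimates that probability without a
      multiplicity bias.
    * ``"edge"`` — denominator counts undirected active-active edges;
      numerator counts edges with at least one endpoint deactivating
      (the per-edge event probability is ~``2 gamma0 dt`` under the model).
    * ``"ant"`` — denominator counts active ants with at least one active
      contact; numerator counts those deactivating.
    """
    if isinstance(dataset, ColonyNetworkData):
        dataset = [dataset]
    if unit not in ("interaction", "edge", "ant"):
        raise CalibrationError(f"stage event-counting: unknown unit {unit!r}")
    denom = 0
    num = 0
    for data in dataset:
        for f in range(data.n_frames - 1):
            e = data.edges[f]
            usable = data.scored[f] & data.scored[f + 1]
            act = data.active[f] & usable
            if e.size == 0 or not act.any():
                continue
            both = act[e[:, 0]] & act[e[:, 1]]
            e_aa = e[both]
            if e_aa.size == 0:
                continue
            m = np.zeros(data.n, dtype=np.int64)
            np.add.at(m, e_aa[:, 0], 1)
            np.add.at(m, e_aa[:, 1], 1)
            contacted = m > 0
            deactivated = contacted & ~data.active[f + 1]
            if unit == "interaction":
                denom += int(m.sum())
                num += int(deactivated.sum())
            elif unit == "edge":
                denom += int(e_aa.shape[0])
                lost = ~data.active[f + 1]
                num += int((lost[e_aa[:, 0]] | lost[e_aa[:, 1]]).sum())
            else:  # per-ant
                denom += int(contacted.sum())
                num += int(deactivated.sum())
    return denom, num


def estimate_gamma0(
    n_interaction_frames: int, n_inactivation_events: int, dt: float
) -> tuple[float, float]:
    """``(probability, gamma0)`` from the two event counts.

    ``probability = events / interactions`` and ``gamma0 = probability/dt``.
    """
    if dt <= 0:
        raise CalibrationError(f"stage gamma0: dt must be positive, got {dt}")
    if n_interaction_frames < 0 or n_inactivation_events < 0:
        raise CalibrationError("stage gamma0: counts must be non-negative")
    if n_inactivation_events > n_interaction_frames:
        raise CalibrationError("stage gamma0: events cannot exceed interactions")
    if n_interaction_frames == 0:
        raise CalibrationError(
            "stage gamma0: no active-active interactions observed; estimate undefined"
        )
    probability = n_inactivation_events / n_interaction_frames
    return probability, probability / dt


def estimate_delta(q: float, gamma0: float) -> float:
    """``delta = q * gamma0`` (q is the fitted slope, i.e. delta/gamma0)."""
    if q <= 0 or gamma0 <= 0:
        raise CalibrationError(
            f"stage delta: q and gamma0 must be positive, got q={q}, gamma0={gamma0}"
        )
    return q * gamma0


# ---------------------------------------------------------------------------
# The full chain
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    """Fitted parameters plus diagnostics.  ``delta == q * gamma0`` by
    construction; ``beta0`` is absent by design (not identifiable)."""

    E0: float
    alpha: float
    q: float
    gamma0: float
    delta: float
    probability: float
    n_interaction_frames: int
    n_inactivation_events: int
    r_squared: float
    per_colony: pd.DataFrame
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "E0": self.E0,
            "alpha": self.alpha,
            "q": self.q,
            "gamma0": self.gamma0,
            "delta": self.delta,
            "probability": self.probability,
            "n_interaction_frames": self.n_interaction_frames,
            "n_inactivation_events": self.n_inactivation_events,
            "r_squared": self.r_squared,
            "per_colony": self.per_colony.to_dict(orient="records"),
            "flags": list(self.flags),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def colony_summaries(dataset: Mapping[str, ColonyNetworkData]) -> pd.DataFrame:
    """Per-colony ``(N, mean edges E, mean active count A)`` table."""
    rows = [
        {
            "colony": c,
            "N": d.n,
            "E": d.mean_edges(),
            "A": d.mean_active(),
        }
        for c, d in sorted(dataset.items())
    ]
    return pd.DataFrame(rows)


def calibrate(
    dataset: Mapping[str, ColonyNetworkData],
    dt: float = DEFAULT_FRAME_INTERVAL_S,
    q_regressor: str = "finite_size",
    event_unit: str = "interaction",
) -> CalibrationResult:
    """Run the full chain on per-colony contact networks with activity flags.

    Needs at least 3 colonies (the log-log fit is degenerate otherwise).
    Degenerate stages (no active ants) are flagged, not raised, so that the
    structural estimates remain available.
    """
    if len(dataset) < 3:
        raise CalibrationError(
            f"stage network-scaling: need >= 3 colonies, got {len(dataset)}"
        )
    summary = colony_summaries(dataset)
    flags: list[str] = []
    scaling = fit_network_scaling(summary["N"], summary["E"])
    if not scaling.in_range:
        flags.append(f"alpha={scaling.alpha:.3f} outside [1, 2]")

    q = reverse_contagion_slope(summary["N"], summary["E"], summary["A"],
                                regressor=q_regressor)
    if q == 0.0:
        flags.append("q degenerate (no active ants)")

    denom, num = count_reverse_contagion_events(dataset.values(), unit=event_unit)
    if denom == 0:
        flags.append("gamma0 degenerate (no active-active interactions)")
        probability, gamma0, delta = float("nan"), float("nan"), float("nan")
    else:
        probability, gamma0 = estimate_gamma0(denom, num, dt)
        delta = estimate_delta(q, gamma0) if q > 0 and gamma0 > 0 else float("nan")
        if not np.isfinite(delta):
            flags.append("delta degenerate (q or gamma0 unavailable)")

    return CalibrationResult(
        E0=scaling.E0,
        alpha=scaling.alpha,
        q=q,
        gamma0=gamma0,
        delta=delta,
        probability=probability,
        n_interaction_frames=denom,
        n_inactivation_events=num,
        r_squared=scaling.r_squared,
        per_colony=summary,
        flags=tuple(flags),
    )


def calibrate_tracks(
    tracks: TrackTable,
    radius: float = DEFAULT_CONTACT_RADIUS_MM,
    pixel_mm: float | None = None,
    dt: float | None = None,
    q_regressor: str = "finite_size",
    event_unit: str = "interaction",
) -> CalibrationResult:
    """Full chain from raw tracks: networks -> activity -> fits -> rates."""
    networks = build_proximity_networks(tracks, radius=radius)
    activity = score_activity(tracks, pixel_mm=pixel_mm)
    dataset = attach_activity(networks, activity)
    if dt is None:
        dts = {m.dt for m in tracks.meta.values()}
        if len(dts) != 1:
            raise CalibrationError(
                f"stage event-counting: colonies disagree on dt ({sorted(dts)}); pass dt explicitly"
            )
        dt = dts.pop()
    return calibrate(dataset, dt=dt, q_regressor=q_regressor, event_unit=event_unit)


# ---------------------------------------------------------------------------
# Plain-text IO (edge lists, activity CSVs, YAML metadata)
# ---------------------------------------------------------------------------

def write_network_dataset(dataset: Mapping[str, ColonyNetworkData], directory: str | Path) -> None:
    """Write per-colony directories with ``frame_K.edges`` files (``u v``
    pairs, 0-based), an ``activity.csv`` (``frame,ant,active,scored``) and a
    ``meta.yaml``."""
    directory = Path(directory)
    for colony, data in dataset.items():
        cdir = directory / f"colony_{colony}"
        cdir.mkdir(parents=True, exist_ok=True)
        for f, e in enumerate(data.edges):
            lines = "".join(f"{u} {v}\n" for u, v in e)
            (cdir / f"frame_{f:05d}.edges").write_text(lines)
        frames, ants = np.nonzero(np.ones_like(data.active))
        pd.DataFrame(
            {
                "frame": frames,
                "ant": ants,
                "active": data.active[frames, ants].astype(int),
                "scored": data.scored[frames, ants].astype(int),
            }
        ).to_csv(cdir / "activity.csv", index=False)
        (cdir / "meta.yaml").write_text(
            yaml.safe_dump({"colony": colony, "n": int(data.n),
                            "n_frames": int(data.n_frames)})
        )


def read_network_dataset(directory: str | Path) -> dict[str, ColonyNetworkData]:
    directory = Path(directory)
    out: dict[str, ColonyNetworkData] = {}
    for cdir in sorted(directory.glob("colony_*")):
        meta = yaml.safe_load((cdir / "meta.yaml").read_text())
        n, T = int(meta["n"]), int(meta["n_frames"])
        edges = []
        for f in range(T):
            text = (cdir / f"frame_{f:05d}.edges").read_text().split()
            arr = np.array(text, dtype=np.int64).reshape(-1, 2) if text else np.empty((0, 2), dtype=np.int64)
            edges.append(arr)
        act_df = pd.read_csv(cdir / "activity.csv")
        active = np.zeros((T, n), dtype=bool)
        scored = np.zeros((T, n), dtype=bool)
        active[act_df["frame"], act_df["ant"]] = act_df["active"].astype(bool)
        scored[act_df["frame"], act_df["ant"]] = act_df["scored"].astype(bool)
        out[str(meta["colony"])] = ColonyNetworkData(
            colony=str(meta["colony"]), n=n, edges=edges, active=active, scored=scored
        )
    return out


def write_track_table(tracks: TrackTable, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tracks.df.to_csv(directory / "tracks.csv", index=False)
    meta = {c: dataclasses.asdict(m) for c, m in tracks.meta.items()}
    (directory / "metadata.yaml").write_text(yaml.safe_dump(meta))


def read_track_table(directory: str | Path) -> TrackTable:
    directory = Path(directory)
    df = pd.read_csv(directory / "tracks.csv")
    raw = yaml.safe_load((directory / "metadata.yaml").read_text())
    meta = {str(c): ColonyMeta(**m) for c, m in raw.items()}
    return TrackTable(df=df, meta=meta)
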