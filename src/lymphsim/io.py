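"""Configuration files, RNG management, CSV round trips and fixtures.

Configs are YAML, one key per :class:`~lymphsim.params.SimParams` field.
Track and event tables are plain CSV (comma separator, ``.`` decimal,
header row, unit-suffixed column names).  The fixture generators produce
the synthetic inputs every statistic can be validated on without any
external data: free-diffusion and worm-like-chain track tables with known
parameters, duration histograms drawn from a known five-parameter model,
and a track with a planted kinematic-interaction window.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import engine
from .params import ConfigurationError, SimParams

__all__ = [
    "load_config", "save_config", "spawn_rngs", "gaussian_rng",
    "write_tracks", "read_tracks", "write_events", "read_events",
    "free_diffusion_tracks", "wlc_tracks", "positions_to_frame", "synthetic_duration_events",
    "planted_interaction_tracks",
]

_FIELDS = {f.name for f in dataclasses.fields(SimParams)}


def load_config(path) -> SimParams:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    if "box" in raw:
        raw["box"] = tuple(raw["box"])
    if raw.get("dc_positions") is not None:
        raw["dc_positions"] = np.asarray(raw["dc_positions"], float)
    return SimParams(**raw)


def save_config(params: SimParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# RNG management
# ---------------------------------------------------------------------------

def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams from one master seed.

    Each component of a pipeline gets its own stream so that changing the
    number of draws in one never perturbs another.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gaussian_rng(seed: int) -> np.random.Generator:
    """Reproducible generator for standard-normal streams."""
    return np.random.default_rng(np.random.SeedSequence(seed))


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"track_id", "t_s", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table missing column(s): {sorted(missing)}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"nk_id", "dc_id", "t_start_s", "t_end_s", "duration_s", "censored"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table missing column(s): {sorted(missing)}")
    df["censored"] = df["censored"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def positions_to_frame(pos: np.ndarray, dt: float) -> pd.DataFrame:
    """(T, n, 3) position array -> long-format track table."""
    T, n, _ = pos.shape
    step = np.repeat(np.arange(T), n)
    return pd.DataFrame({
        "track_id": np.tile(np.arange(n), T),
        "step": step,
        "t_s": step * dt,
        "x_um": pos[:, :, 0].ravel(),
        "y_um": pos[:, :, 1].ravel(),
        "z_um": pos[:, :, 2].ravel(),
    })


def free_diffusion_tracks(d0: float = 1.0, n_cells: int = 50,
                          n_steps: int = 2000, dt: float = 1.0,
                          seed: int = 0) -> pd.DataFrame:
    """Pure Brownian tracks with a known diffusion coefficient."""
    pos = engine.run_free_diffusion(n_cells, n_steps, d0, dt, seed, isotropic=True)
    return positions_to_frame(pos, dt)


def wlc_tracks(d0: float = 1.0, sigma_theta: float = 0.3, n_cells: int = 50,
               n_steps: int = 2000, dt: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Worm-like-chain tracks with known persistence sigma_theta."""
    pos = engine.run_free_diffusion(n_cells, n_steps, d0, dt, seed,
                                    isotropic=False, sigma_theta=sigma_theta)
    return positions_to_frame(pos, dt)


def synthetic_duration_events(A: float = 800.0, t1: float = 70.0,
                              B: float = 78.0, t0: float = 450.0,
                              sigma: float = 250.0, bin_width: float = 40.0,
                              seed: int = 0) -> pd.DataFrame:
    """Event table whose duration histogram follows the two-component model.

    Bin counts are Poisson draws around A exp(-t/t1) + B exp(-(t-t0)^2 /
    (2 sigma^2)); each count is materialized as that many events at the
    bin centre, so re-histogramming at the same width recovers the draw.
    """
    rng = np.random.default_rng(seed)
    t_max = max(6.0 * t1, t0 + 4.0 * sigma)
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    mids = 0.5 * (edges[:-1] + edges[1:])
    lam = A * np.exp(-mids / t1) + B * np.exp(-((mids - t0) ** 2) / (2 * sigma**2))
    counts = rng.poisson(lam)
    durations = np.repeat(mids, counts)
    n = len(durations)
    return pd.DataFrame({
        "nk_id": np.arange(n), "dc_id": np.zeros(n, int),
        "t_start_s": np.zeros(n), "t_end_s": durations,
        "duration_s": durations, "censored": np.zeros(n, bool),
    })


def planted_interaction_tracks(dc_pos: Sequence[float] = (0.0, 0.0, 0.0),
                               dt: float = 1.0) -> tuple[pd.DataFrame, np.ndarray,
                                                         tuple[float, float]]:
    """Two deterministic tracks, one with a planted interaction window.

    Track 0 travels fast in a straight line 60 um from the DC (never
    qualifies).  Track 1 approaches the DC, then spirals inward with
    shrinking steps — slow, converging and with a strictly decreasing
    windowed confinement ratio — before leaving again.  Returns
    ``(tracks, dc_positions, (t_lo, t_hi))`` where the window brackets the
    qualifying frames.
    """
    dc = np.asarray(dc_pos, float)
    # fast far track: speed 2 um/s along x at y = 60
    T = 60
    t = np.arange(T) * dt
    far = np.stack([2.0 * t, np.full(T, 60.0), np.zeros(T)], axis=1) + dc
    # slow near track: radial approach then inward spiral with decay
    theta = 0.25 * np.arange(T)
    radius = np.concatenate([np.linspace(30, 12, 20), 12 * 0.93 ** np.arange(T - 20)])
    near = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                     np.zeros(T)], axis=1) + dc
    frames = []
    for tid, x in ((0, far), (1, near)):
        frames.append(pd.DataFrame({
            "track_id": tid, "step": np.arange(T), "t_s": t,
            "x_um": x[:, 0], "y_um": x[:, 1], "z_um": x[:, 2]}))
    tracks = pd.concat(frames, ignore_index=True)
    return tracks, dc[None, :], (20.0 * dt, (T - 1) * dt)
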