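"""Kinematic and interaction statistics of 3D cell tracks.

Operates on long-format track tables (columns ``track_id, step, t_s, x_um,
y_um, z_um``) and on interaction-event tables, the two carriers every other
module produces.  Implements the full statistics battery used to compare
simulations against two-photon microscopy tracking data: mean squared
displacement, velocity and turning-angle autocorrelation, the
interaction-duration histogram with its exponential-plus-Gaussian
two-component fit, the percent-interacting-vs-chi sigmoid, confinement
ratio, 3D speed, trajectory length, rebinning to a coarser acquisition
interval, and a purely kinematic interaction detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "msd", "fit_diffusion_coefficient", "velocity_autocorr", "angle_autocorr",
    "duration_histogram", "DurationFit", "fit_duration_distribution",
    "ChiSweepResult", "chi_sweep_stats", "confinement_ratio", "speed_3d",
    "trajectory_length", "rebin_tracks", "detect_interactions_kinematic",
]

_COORDS = ["x_um", "y_um", "z_um"]


def _iter_tracks(tracks: pd.DataFrame):
    for tid, g in tracks.groupby("track_id", sort=False):
        yield tid, g.sort_values("t_s")


def _positions(track: pd.DataFrame) -> np.ndarray:
    return track[_COORDS].to_numpy(float)


# ---------------------------------------------------------------------------
# MSD and autocorrelations
# ---------------------------------------------------------------------------

def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one trajectory (T, d) for lags 0..T-1 via FFT."""
    T = len(x)
    s2 = np.square(x).sum(axis=1)
    # autocorrelation of each coordinate via FFT
    nfft = 1 << (2 * T - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:T].sum(axis=1).real
    sumsq = np.concatenate([[0.0], np.cumsum(s2)])
    # S1(lag) = sum_{t} (|x_t|^2 + |x_{t+lag}|^2) over valid t
    n_valid = T - np.arange(T)
    s1 = (sumsq[T] - sumsq[np.arange(T)]) + (sumsq[T - np.arange(T)] - sumsq[0])
    return np.maximum(s1 / n_valid - 2.0 * acf / n_valid, 0.0)


def msd(tracks: pd.DataFrame, max_lag: int) -> pd.DataFrame:
    """Ensemble- and time-averaged mean squared displacement.

    Returns a frame with columns ``lag`` (in samples), ``dt_s`` (in
    seconds) and ``msd_um2``.  Tracks shorter than two samples are
    skipped; an empty table is an error.
    """
    if len(tracks) == 0:
        raise ValueError("empty track table")
    acc: Optional[np.ndarray] = None
    wts: Optional[np.ndarray] = None
    dt = None
    for _, g in _iter_tracks(tracks):
        if len(g) < 2:
            continue
        x = _positions(g)
        t = g["t_s"].to_numpy(float)
        if dt is None:
            dt = t[1] - t[0]
        m = _msd_fft_single(x)
        L = min(len(m), max_lag + 1)
        w = (len(x) - np.arange(L)).astype(float)
        if acc is None:
            acc = np.zeros(max_lag + 1)
            wts = np.zeros(max_lag + 1)
        acc[:L] += m[:L] * w
        wts[:L] += w
    if acc is None:
        raise ValueError("no track has at least two samples")
    valid = wts > 0
    lags = np.arange(max_lag + 1)[valid]
    return pd.DataFrame({"lag": lags, "dt_s": lags * (dt or 1.0),
                         "msd_um2": acc[valid] / wts[valid]})


def fit_diffusion_coefficient(msd_curve: pd.DataFrame,
                              lag_range: Tuple[int, int] = (1, 100)) -> float:
    """Recover D [um^2/s] from the MSD slope: <dr^2> = 6 D t, line through origin."""
    sel = (msd_curve["lag"] >= lag_range[0]) & (msd_curve["lag"] <= lag_range[1])
    t = msd_curve.loc[sel, "dt_s"].to_numpy(float)
    y = msd_curve.loc[sel, "msd_um2"].to_numpy(float)
    slope = float(np.dot(t, y) / np.dot(t, t))
    return slope / 6.0


def _normalized_autocorr(series: List[np.ndarray], max_lag: int) -> np.ndarray:
    """Ensemble-averaged autocorrelation of vector series, normalized to 1 at lag 0."""
    num = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1)
    for v in series:
        T = len(v)
        for lag in range(min(max_lag + 1, T)):
            num[lag] += float((v[:T - lag] * v[lag:]).sum())
            cnt[lag] += (T - lag) * 0 + (T - lag)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = num / cnt
    return c / c[0]


def velocity_autocorr(tracks: pd.DataFrame, max_lag: int) -> pd.DataFrame:
    """Normalized velocity autocorrelation <v(t).v(t+lag)> / <v^2>."""
    series = []
    for _, g in _iter_tracks(tracks):
        if len(g) < 2:
            continue
        x = _positions(g)
        t = g["t_s"].to_numpy(float)
        v = np.diff(x, axis=0) / np.diff(t)[:, None]
        series.append(v)
    if not series:
        raise ValueError("no track has at least two samples")
    c = _normalized_autocorr(series, max_lag)
    return pd.DataFrame({"lag": np.arange(len(c)), "vacf": c})


def angle_autocorr(tracks: pd.DataFrame, max_lag: int) -> pd.DataFrame:
    """Mean cosine between step directions separated by ``lag`` steps.

    For free worm-like-chain motion the lag-L value decays geometrically
    as exp(-sigma_theta^2 / 2)^L.
    """
    sums = np.zeros(max_lag + 1)
    cnts = np.zeros(max_lag + 1)
    for _, g in _iter_tracks(tracks):
        if len(g) < 3:
            continue
        steps = np.diff(_positions(g), axis=0)
        norm = np.linalg.norm(steps, axis=1)
        ok = norm > 0
        u = steps[ok] / norm[ok, None]
        T = len(u)
        for lag in range(min(max_lag + 1, T)):
            sums[lag] += float((u[:T - lag] * u[lag:]).sum(axis=1).sum())
            cnts[lag] += T - lag
    if cnts[0] == 0:
        raise ValueError("no track has at least two steps")
    valid = cnts > 0
    return pd.DataFrame({"lag": np.arange(max_lag + 1)[valid],
                         "cos_theta": sums[valid] / cnts[valid]})


# ---------------------------------------------------------------------------
# interaction durations
# ---------------------------------------------------------------------------

def completed_durations(events: pd.DataFrame, include_censored: bool = False) -> np.ndarray:
    """Durations [s] of events, excluding censored ones by default."""
    ev = events if include_censored else events[~events["censored"]]
    return ev["duration_s"].dropna().to_numpy(float)


def duration_histogram(events: pd.DataFrame, bin_width: float = 40.0,
                       include_censored: bool = False) -> pd.DataFrame:
    """Histogram of interaction durations with fixed-width bins."""
    d = completed_durations(events, include_censored)
    if len(d) == 0:
        raise ValueError("no uncensored events")
    n_bins = int(math.ceil(d.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({"t_lo_s": edges[:-1], "t_hi_s": edges[1:],
                         "t_mid_s": 0.5 * (edges[:-1] + edges[1:]),
                         "count": counts})


def fraction_below(events: pd.DataFrame, threshold: float,
                   include_censored: bool = False) -> float:
    """Exact fraction of event durations below ``threshold`` seconds."""
    d = completed_durations(events, include_censored)
    if len(d) == 0:
        raise ValueError("no uncensored events")
    return float((d < threshold).mean())


@dataclass(frozen=True)
class DurationFit:
    """Two-component fit of the duration histogram.

    count(t) = A exp(-t / t1) + B exp(-(t - t0)^2 / (2 sigma^2)):
    a fast exponential decay (brief encounters) plus a Gaussian bump
    (the long-duration component released as the source discharges).
    """

    A: float
    t1: float
    B: float
    t0: float
    sigma: float
    A_err: float
    t1_err: float
    B_err: float
    t0_err: float
    sigma_err: float

    def as_tuple(self) -> Tuple[float, float, float, float, float]:
        return (self.A, self.t1, self.B, self.t0, self.sigma)


def _duration_model(t, A, t1, B, t0, sigma):
    return A * np.exp(-t / t1) + B * np.exp(-((t - t0) ** 2) / (2.0 * sigma**2))


def fit_duration_distribution(hist: pd.DataFrame) -> DurationFit:
    """Nonlinear least-squares fit of the two-component duration model.

    Initial values are data driven: the exponential from the first bins,
    the Gaussian from the counts beyond three exponential lifetimes.
    Raises ``RuntimeError`` with diagnostics on non-convergence.
    """
    t = hist["t_mid_s"].to_numpy(float)
    y = hist["count"].to_numpy(float)
    if (y > 0).sum() < 8:
        raise ValueError("histogram needs at least 8 non-empty bins")
    A0 = max(y.max(), 1.0)
    # crude exponential time from the first decade of decay
    above = t[y > A0 / np.e]
    t1_0 = max(above.max(), t[1]) if len(above) else t[len(t) // 4]
    tail = t > 3.0 * t1_0
    if tail.any() and y[tail].sum() > 0:
        t0_0 = float(np.average(t[tail], weights=y[tail] + 1e-9))
        sigma_0 = max(float(np.sqrt(np.average((t[tail] - t0_0) ** 2,
                                               weights=y[tail] + 1e-9))), t[1])
        B0 = max(y[tail].max(), 1.0)
    else:
        t0_0, sigma_0, B0 = t.max() / 2.0, t.max() / 4.0, A0 / 10.0
    p0 = [A0, t1_0, B0, t0_0, sigma_0]
    bounds = ([0.0, 1e-6, 0.0, 0.0, 1e-6],
              [np.inf, np.inf, np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(_duration_model, t, y, p0=p0, bounds=bounds,
                               maxfev=20000)
    except Exception as exc:  # non-convergence or degenerate jacobian
        raise RuntimeError(f"duration fit failed (p0={p0}): {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return DurationFit(*popt, *perr)


# ---------------------------------------------------------------------------
# chi sweep
# ---------------------------------------------------------------------------

def _sigmoid(x, a, b, x0, w):
    return a - b / (1.0 + np.exp((x - x0) / w))


@dataclass
class ChiSweepResult:
    """Percent of interacting NK cells vs the chemotactic parameter."""

    table: pd.DataFrame                      # chi, pct_all, pct_long
    sigmoid_all: Optional[Tuple[float, float, float, float]]
    sigmoid_long: Optional[Tuple[float, float, float, float]]


def chi_sweep_stats(runs: Dict[float, Tuple[pd.DataFrame, int]],
                    t_th: float = 600.0) -> ChiSweepResult:
    """Summarize per-chi event lists into percent-interacting curves.

    ``runs`` maps chi to ``(events_frame, n_cells_total)``.  A cell counts
    as interacting if it has at least one completed event, and as
    long-interacting if at least one event exceeds ``t_th``.  A sigmoid
    a - b / (1 + exp((chi - chi0)/w)) is fitted to each curve when
    possible; raw percentages are always returned.
    """
    if len(runs) < 3:
        raise ValueError("need at least 3 chi values")
    rows = []
    for chi in sorted(runs):
        ev, n_cells = runs[chi]
        done = ev[~ev["censored"]] if len(ev) else ev
        pct_all = 100.0 * done["nk_id"].nunique() / n_cells
        long_ev = done[done["duration_s"] > t_th] if len(done) else done
        pct_long = 100.0 * long_ev["nk_id"].nunique() / n_cells
        rows.append({"chi": chi, "pct_all": pct_all, "pct_long": pct_long})
    table = pd.DataFrame(rows)

    def _fit(y):
        x = table["chi"].to_numpy(float)
        yv = np.asarray(y, float)
        p0 = [yv.max(), max(yv.max() - yv.min(), 1e-3), float(np.median(x)), 0.1]
        try:
            popt, _ = curve_fit(_sigmoid, x, yv, p0=p0,
                                bounds=([0, 0, -1, 1e-3], [200, 200, 2, 10]),
                                maxfev=20000)
            return tuple(popt)
        except Exception:
            return None

    return ChiSweepResult(table=table,
                          sigmoid_all=_fit(table["pct_all"]),
                          sigmoid_long=_fit(table["pct_long"]))


# ---------------------------------------------------------------------------
# per-track geometry
# ---------------------------------------------------------------------------

def confinement_ratio(track: pd.DataFrame) -> float:
    """Net displacement over path length, in [0, 1]; NaN for < 2 points."""
    x = _positions(track.sort_values("t_s"))
    if len(x) < 2:
        return float("nan")
    path = float(np.linalg.norm(np.diff(x, axis=0), axis=1).sum())
    if path == 0.0:
        return 1.0
    return float(np.linalg.norm(x[-1] - x[0]) / path)


def speed_3d(track: pd.DataFrame) -> np.ndarray:
    """Instantaneous 3D speeds |dr|/dt per step [um/s]; empty for < 2 points."""
    g = track.sort_values("t_s")
    x = _positions(g)
    if len(x) < 2:
        return np.empty(0)
    t = g["t_s"].to_numpy(float)
    return np.linalg.norm(np.diff(x, axis=0), axis=1) / np.diff(t)


def trajectory_length(track: pd.DataFrame) -> float:
    """Total path length [um]; NaN for < 2 points."""
    x = _positions(track.sort_values("t_s"))
    if len(x) < 2:
        return float("nan")
    return float(np.linalg.norm(np.diff(x, axis=0), axis=1).sum())


def rebin_tracks(tracks: pd.DataFrame, stride: int) -> pd.DataFrame:
    """Keep every ``stride``-th sample of each track (coarser acquisition)."""
    if stride < 1 or int(stride) != stride:
        raise ValueError("stride must be a positive integer")
    if stride == 1:
        return tracks.copy()
    parts = []
    for _, g in _iter_tracks(tracks):
        parts.append(g.iloc[::stride])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# kinematic interaction detector
# ---------------------------------------------------------------------------

def detect_interactions_kinematic(tracks: pd.DataFrame, dc_positions: np.ndarray,
                                  distance_threshold: float = 25.0,
                                  window: int = 5,
                                  speed_threshold: Optional[float] = None,
                                  ) -> pd.DataFrame:
    """Detect putative interactions from track kinematics alone.

    A frame belongs to a putative interaction when simultaneously
    (1) the distance to the nearest DC is below ``distance_threshold``,
    (2) the confinement ratio, computed on a sliding window of ``window``
        frames, is decreasing between consecutive windows, and
    (3) the instantaneous speed is below ``speed_threshold`` (by default
        the mean instantaneous speed of all cells over all frames).
    Maximal contiguous runs of qualifying frames become events.

    Returns a frame with columns ``nk_id, dc_id, t_start_s, t_end_s,
    duration_s``.
    """
    dc_positions = np.atleast_2d(np.asarray(dc_positions, float))
    if speed_threshold is None:
        speeds = [speed_3d(g) for _, g in _iter_tracks(tracks)]
        allspeed = np.concatenate([s for s in speeds if len(s)]) if speeds else np.empty(0)
        if len(allspeed) == 0:
            return _empty_events()
        speed_threshold = float(allspeed.mean())
    rows = []
    for tid, g in _iter_tracks(tracks):
        if len(g) < window + 2:
            continue
        x = _positions(g)
        t = g["t_s"].to_numpy(float)
        d = np.linalg.norm(x[:, None, :] - dc_positions[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        near = d.min(axis=1) < distance_threshold
        v = np.linalg.norm(np.diff(x, axis=0), axis=1) / np.diff(t)
        slow = np.concatenate([[False], v < speed_threshold])
        # sliding-window confinement ratio ending at each frame
        n = len(x)
        cr = np.full(n, np.nan)
        for i in range(window - 1, n):
            seg = x[i - window + 1:i + 1]
            path = np.linalg.norm(np.diff(seg, axis=0), axis=1).sum()
            cr[i] = 1.0 if path == 0 else np.linalg.norm(seg[-1] - seg[0]) / path
        decreasing = np.concatenate([[False], np.diff(cr) < 0]) & ~np.isnan(cr)
        ok = near & slow & decreasing
        # maximal contiguous runs
        idx = np.flatnonzero(ok)
        if len(idx) == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        for seg_idx in np.split(idx, splits + 1):
            if len(seg_idx) < 2:
                continue
            k = int(np.bincount(nearest[seg_idx]).argmax())
            rows.append({"nk_id": tid, "dc_id": k,
                         "t_start_s": t[seg_idx[0]], "t_end_s": t[seg_idx[-1]],
                         "duration_s": t[seg_idx[-1]] - t[seg_idx[0]]})
    if not rows:
        return _empty_events()
    return pd.DataFrame(rows)


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "nk_id": np.array([], dtype=int), "dc_id": np.array([], dtype=int),
        "t_start_s": np.array([], dtype=float),
        "t_end_s": np.array([], dtype=float),
        "duration_s": np.array([], dtype=float),
    })
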