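"""Single-particle track linking and motility analysis.

Two mean-square-displacement variants are provided. The ``cumulative``
variant is the cumulative sum of squared increments of the
distance-from-origin,

    MSD(n) = sum_{i=1..n} (d_i - d_{i-1})^2,   d_i = |p_i - p_0|,

which is non-decreasing by construction and grows linearly even for
straight-line motion. The ``standard`` variant is the conventional
time-averaged MSD over all pairs at each lag, which obeys textbook
diffusion theory (ensemble mean 4 D k Δt + 4 σ_loc² for 2D Brownian motion)
and is the one used for diffusion-coefficient calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Trajectory",
    "MSDCurve",
    "MotilityCall",
    "StateSegment",
    "link_tracks",
    "msd_cumulative",
    "msd_standard",
    "estimate_D",
    "detect_plateau",
    "classify_motility",
    "segment_states",
]

MIN_TRACK_LENGTH = 5  # frames; tracks shorter than this carry too little signal


@dataclass(frozen=True)
class Trajectory:
    """One particle's 2D positions (µm) at a fixed frame interval, no gaps."""

    track_id: str
    frame_interval: float
    positions: np.ndarray  # (N, 2), µm
    start_frame: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if pos.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 positions")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Track duration in seconds (N-1 intervals)."""
        return (len(self) - 1) * self.frame_interval


@dataclass(frozen=True)
class MSDCurve:
    """MSD values at lag times ``lag_s``; ``variant`` is 'cumulative' or 'standard'."""

    variant: str
    lag_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag_s, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if self.variant not in ("cumulative", "standard"):
            raise ValueError("variant must be 'cumulative' or 'standard'")
        if lag.shape != val.shape or lag.ndim != 1:
            raise ValueError("lag_s and values must be matching 1-D arrays")
        if np.any(np.diff(lag) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(val < -1e-12):
            raise ValueError("MSD values must be non-negative")
        object.__setattr__(self, "lag_s", lag)
        object.__setattr__(self, "values", np.maximum(val, 0.0))


@dataclass(frozen=True)
class MotilityCall:
    """Per-track motility summary: D, the fitted lag window, plateau and class."""

    D: float
    fit_lags: int
    plateau_time: float | None
    motion_class: str  # diffusive | confined | stationary
    r_squared: float = float("nan")


@dataclass(frozen=True)
class StateSegment:
    """A maximal run of frames sharing one motility class."""

    motion_class: str
    start_frame: int
    end_frame: int  # inclusive
    start_s: float = field(default=0.0)
    end_s: float = field(default=0.0)


# ---------------------------------------------------------------------------
# linking

def link_tracks(
    spots_per_frame: list[list],
    max_displacement: float,
    frame_interval: float,
    min_length: int = MIN_TRACK_LENGTH,
) -> list[Trajectory]:
    """Link per-frame detections into gapless trajectories.

    Greedy nearest-neighbour assignment frame to frame: candidate pairs within
    ``max_displacement`` are accepted in order of increasing distance, one-to-one.
    Unmatched spots open new tracks; a missing detection terminates a track
    (no gap closing). Tracks shorter than ``min_length`` frames are dropped.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    active: list[list[tuple[float, float]]] = []   # position history of open tracks
    active_start: list[int] = []
    finished: list[tuple[int, list[tuple[float, float]]]] = []

    prev_positions: np.ndarray | None = None
    prev_track_idx: list[int] = []

    for frame, spots in enumerate(spots_per_frame):
        coords = np.array([(s.x, s.y) for s in spots], dtype=float).reshape(-1, 2)
        if len(spots) != len({(s.x, s.y) for s in spots}):
            warnings.warn(f"duplicate spot coordinates in frame {frame}; ties broken by spot order")
        assigned_spot = np.full(len(coords), -1, dtype=int)  # -> active track index
        if prev_positions is not None and len(prev_positions) and len(coords):
            d = np.linalg.norm(prev_positions[:, None, :] - coords[None, :, :], axis=2)
            pairs = [(d[i, j], i, j) for i in range(d.shape[0]) for j in range(d.shape[1])
                     if d[i, j] <= max_displacement]
            pairs.sort(key=lambda p: (p[0], p[1], p[2]))
            used_prev: set[int] = set()
            for dist, i, j in pairs:
                if i in used_prev or assigned_spot[j] >= 0:
                    continue
                used_prev.add(i)
                assigned_spot[j] = prev_track_idx[i]

        # close tracks that got no continuation
        continued = set(assigned_spot[assigned_spot >= 0].tolist())
        still_open: list[int] = []
        for ti in range(len(active)):
            if ti in continued:
                still_open.append(ti)
            else:
                finished.append((active_start[ti], active[ti]))
        remap = {ti: k for k, ti in enumerate(still_open)}
        active = [active[ti] for ti in still_open]
        active_start = [active_start[ti] for ti in still_open]

        next_prev_idx: list[int] = []
        next_prev_pos: list[tuple[float, float]] = []
        for j, spot in enumerate(spots):
            ti = assigned_spot[j]
            if ti >= 0:
                k = remap[ti]
                active[k].append((spot.x, spot.y))
            else:
                active.append([(spot.x, spot.y)])
                active_start.append(frame)
                k = len(active) - 1
            next_prev_idx.append(k)
            next_prev_pos.append((spot.x, spot.y))
        prev_positions = np.array(next_prev_pos, dtype=float).reshape(-1, 2)
        prev_track_idx = next_prev_idx

    finished.extend(zip(active_start, active))
    finished.sort(key=lambda t: t[0])
    out = []
    for k, (start, poslist) in enumerate(finished):
        if len(poslist) < min_length:
            continue
        out.append(Trajectory(track_id=str(len(out)), frame_interval=frame_interval,
                              positions=np.array(poslist), start_frame=start))
    return out


# ---------------------------------------------------------------------------
# MSD

def msd_cumulative(traj: Trajectory) -> MSDCurve:
    """Cumulative-radial-increment MSD.

    With ``d_i`` the distance of position *i* from the first position,
    ``MSD(n) = sum_{i=1..n} (d_i - d_{i-1})^2``, reported at lag ``n Δt``.
    The nominal sum from i = 0 would reference an undefined position at
    i = -1; the sum therefore starts at i = 1.
    """
    d = np.linalg.norm(traj.positions - traj.positions[0], axis=1)
    incr2 = np.diff(d) ** 2
    values = np.cumsum(incr2)
    lags = np.arange(1, len(traj)) * traj.frame_interval
    return MSDCurve("cumulative", lags, values)


def msd_standard(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Conventional time-averaged MSD, lags up to ``max_lag_fraction (N-1)`` (min 4)."""
    n = len(traj)
    max_lag = max(4, int(np.floor(max_lag_fraction * (n - 1))))
    max_lag = min(max_lag, n - 1)
    values = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        disp = traj.positions[k:] - traj.positions[:-k]
        values[k - 1] = np.mean(np.sum(disp**2, axis=1))
    lags = np.arange(1, max_lag + 1) * traj.frame_interval
    return MSDCurve("standard", lags, values)


def estimate_D(curve: MSDCurve, n_fit_lags: int = 4) -> tuple[float, dict]:
    """Diffusion coefficient from the initial linear phase of an MSD curve.

    A least-squares line with free intercept is fit through the first
    ``n_fit_lags`` points. For the standard variant ``D = slope / 4`` (2D
    diffusion; the intercept absorbs localization noise). For the cumulative
    variant ``D = slope`` directly, matching the convention the cumulative
    curve is reported with.
    Negative slopes are clipped to ``D = 0``.
    """
    if len(curve.lag_s) < n_fit_lags:
        raise ValueError(f"curve has {len(curve.lag_s)} points; need >= {n_fit_lags}")
    t = curve.lag_s[:n_fit_lags]
    y = curve.values[:n_fit_lags]
    if np.allclose(y, y[0]):
        slope, intercept, r2 = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(t, y)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    D = slope if curve.variant == "cumulative" else slope / 4.0
    D = max(float(D), 0.0)
    return D, {"slope": float(slope), "intercept": float(intercept),
               "r_squared": float(r2), "n_fit_lags": int(n_fit_lags)}


def detect_plateau(
    curve: MSDCurve,
    plateau_slope_frac: float = 0.15,
    window: int = 3,
    min_sustained: int = 2,
    sustain_windows: int = 12,
) -> float | None:
    """First lag time where the MSD flattens, or ``None``.

    The initial slope is the secant from the origin (MSD(0) = 0) to the first
    point. Local slopes are taken over sliding ``window``-point fits; a
    plateau is declared at the first window whose slope drops below
    ``plateau_slope_frac`` × the initial slope and stays below for the next
    ``sustain_windows`` windows (or to the end of the curve), with at least
    ``min_sustained`` qualifying windows. A non-positive initial slope is
    degenerate: the plateau is the first lag.
    """
    t, y = curve.lag_s, curve.values
    if len(t) < max(6, window + 1):
        raise ValueError("need at least 6 lag points for plateau detection")
    n_win = len(t) - window + 1
    slopes = np.empty(n_win)
    for i in range(n_win):
        tt, yy = t[i:i + window], y[i:i + window]
        slopes[i] = np.polyfit(tt, yy, 1)[0]
    initial = y[0] / t[0]
    if initial <= 0:
        return float(t[0])
    below = slopes < plateau_slope_frac * initial
    for i in range(n_win):
        m = min(n_win - i, max(min_sustained, sustain_windows))
        if m >= min_sustained and below[i:i + m].all():
            return float(t[i])
    return None


def classify_motility(
    D: float,
    plateau_time: float | None,
    d_stationary: float = 0.01,
    plateau_level: float | None = None,
    msd_stationary: float = 0.01,
    max_lag_s: float | None = None,
) -> str:
    """Three-way motility call from D (µm²/s) and an optional MSD plateau.

    When the long-lag MSD *level* (mean MSD over the upper half of the lag
    range, µm²) is known the call is level-first: a track whose MSD sits at
    the localization floor (``level <= msd_stationary``) is stationary; an
    elevated track is confined when its MSD flattens — an early plateau
    (within the first half of the lag range when ``max_lag_s`` is given) or a
    near-zero initial slope (``D <= d_stationary``) — and diffusive
    otherwise. Without a level the simple rule applies: stationary if
    ``D <= d_stationary``, else confined iff a plateau was detected, else
    diffusive.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if plateau_level is not None:
        if plateau_level <= msd_stationary:
            return "stationary"
        early = plateau_time is not None and (
            max_lag_s is None or plateau_time <= 0.5 * max_lag_s)
        if early or D <= d_stationary:
            return "confined"
        return "diffusive"
    if D <= d_stationary:
        return "stationary"
    if plateau_time is not None:
        return "confined"
    return "diffusive"


def analyze_track(
    traj: Trajectory,
    n_fit_lags: int = 4,
    max_lag_fraction: float = 0.5,
    d_stationary: float = 0.01,
    plateau_slope_frac: float = 0.15,
    msd_stationary: float = 0.01,
) -> MotilityCall:
    """Standard-MSD motility call for one trajectory.

    The MSD is taken out to half the track length (longer than the
    conventional quarter) so that a confinement plateau a few multiples of
    the equilibration time into the track still falls inside the curve.
    """
    curve = msd_standard(traj, max_lag_fraction)
    D, diag = estimate_D(curve, min(n_fit_lags, len(curve.lag_s)))
    try:
        plateau = detect_plateau(curve, plateau_slope_frac)
    except ValueError:
        plateau = None
    level = float(np.mean(curve.values[len(curve.values) // 2:]))
    cls = classify_motility(D, plateau, d_stationary, level, msd_stationary,
                            max_lag_s=float(curve.lag_s[-1]))
    if cls != "confined":
        plateau = None
    return MotilityCall(D=D, fit_lags=diag["n_fit_lags"], plateau_time=plateau,
                        motion_class=cls, r_squared=diag["r_squared"])


def segment_states(
    traj: Trajectory,
    window: int = 10,
    step: int = 1,
    n_fit_lags: int = 4,
    d_stationary: float = 0.01,
) -> list[StateSegment]:
    """Within-track motility-state segmentation by a rolling window.

    A standard MSD is computed in each ``window``-frame window (step ``step``),
    the window's D is estimated from its initial slope and thresholded into a
    class, adjacent same-class windows are merged, and runs shorter than
    ``window`` frames are absorbed into the preceding segment. Change points
    sit at the midpoint of the first window of the new class.
    """
    n = len(traj)
    if n < 2 * window:
        raise ValueError(f"trajectory too short: {n} frames < 2 x window ({window})")
    starts = list(range(0, n - window + 1, step))
    classes = []
    for s in starts:
        sub = Trajectory("w", traj.frame_interval, traj.positions[s:s + window])
        curve = msd_standard(sub, 1.0)  # short windows: use all lags available
        D, _ = estimate_D(curve, min(n_fit_lags, len(curve.lag_s)))
        classes.append("stationary" if D <= d_stationary else "diffusive")

    # runs of identical window class: [class, first window index, last window index]
    runs: list[list] = []
    for i, c in enumerate(classes):
        if runs and runs[-1][0] == c:
            runs[-1][2] = i
        else:
            runs.append([c, i, i])

    # a run of m step-1 windows corresponds to an m-frame segment between
    # change points; absorb runs shorter than `window` into a neighbour
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for idx in range(len(runs)):
            c, i0, i1 = runs[idx]
            if i1 - i0 + 1 >= window:
                continue
            if idx > 0:
                runs[idx - 1][2] = i1
            else:
                runs[idx + 1][1] = i0
            del runs[idx]
            j = 0
            while j < len(runs) - 1:  # re-merge adjacent same-class runs
                if runs[j][0] == runs[j + 1][0]:
                    runs[j][2] = runs[j + 1][2]
                    del runs[j + 1]
                else:
                    j += 1
            changed = True
            break

    segments: list[StateSegment] = []
    dt = traj.frame_interval
    for k, (c, i0, i1) in enumerate(runs):
        # change point: midpoint of the first window of the new class
        start_frame = 0 if k == 0 else starts[i0] + window // 2
        end_frame = (n - 1) if k == len(runs) - 1 else (starts[runs[k + 1][1]] + window // 2 - 1)
        segments.append(StateSegment(motion_class=c, start_frame=start_frame, end_frame=end_frame,
                                     start_s=start_frame * dt, end_s=end_frame * dt))
    return segments
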