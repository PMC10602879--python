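"""Readers, writers and run configuration for the foci/tracking pipeline.

All physical coordinates are reported as ``(x, y, z)`` in micrometres with the
origin at the corner of voxel ``(0, 0, 0)``; the centre of voxel ``(k, j, i)``
(z, y, x index order) sits at ``((i + 0.5) dx, (j + 0.5) dy, (k + 0.5) dz)``.
Image arrays are stored ``(channel, z, y, x)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack3D",
    "SpotRecord",
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_tracks",
    "write_tracks",
    "write_foci_table",
    "read_foci_table",
    "write_summary",
    "read_summary",
]


@dataclass(frozen=True)
class ImageStack3D:
    """A multichannel 3D intensity stack with physical voxel size.

    Parameters
    ----------
    voxels
        4-D array ordered ``(channel, z, y, x)``; non-negative, finite.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, all positive.
    channel_names
        One unique label per channel.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 4:
            raise ValueError(f"voxels must be 4-D (channel, z, y, x), got ndim={vox.ndim}")
        if any(s <= 0 for s in vox.shape[1:]):
            raise ValueError("all spatial dimensions must be > 0")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel intensities must be finite")
        if np.any(vox < 0):
            raise ValueError("voxel intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values (dz, dy, dx), got {self.voxel_size}")
        names = tuple(str(n) for n in self.channel_names)
        if len(names) != vox.shape[0]:
            raise ValueError(f"{vox.shape[0]} channels but {len(names)} channel names")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "channel_names", names)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        return self.voxels[self.channel_index(name_or_index)]

    def channel_index(self, name_or_index: str | int) -> int:
        if isinstance(name_or_index, (int, np.integer)):
            idx = int(name_or_index)
            if not 0 <= idx < self.voxels.shape[0]:
                raise KeyError(f"channel index {idx} out of range")
            return idx
        try:
            return self.channel_names.index(str(name_or_index))
        except ValueError:
            raise KeyError(f"unknown channel {name_or_index!r}; have {self.channel_names}") from None


@dataclass(frozen=True)
class SpotRecord:
    """A single per-frame detection prior to track linking."""

    frame: int
    t: float
    x: float
    y: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


def _default_detection() -> dict:
    return {
        "sigma_um": 0.15,       # expected focus sigma, isotropic, µm
        "k_mad": 5.0,           # peak threshold in robust sigmas of the LoG response
        "grow_frac": 0.5,       # region-growing cutoff, fraction of peak above background
        "min_volume_um3": 4.0,  # nucleus size filter
        "max_volume_um3": 150.0,
        "watershed_split": False,
    }


def _default_zonation() -> dict:
    return {"convention": "equal_area"}  # or "equal_volume"


def _default_coloc() -> dict:
    return {"n_shuffles": 100, "alpha": 0.05, "distance_tolerance_um": 0.0}


def _default_spt() -> dict:
    return {
        "max_displacement_um": 1.0,
        "min_length": 5,
        "n_fit_lags": 4,
        "max_lag_fraction": 0.25,
        "d_stationary": 0.01,       # µm²/s
        "plateau_slope_frac": 0.15,
        "window": 10,
        "position_scale": 1.0,      # multiply CSV positions by this to get µm
    }


def _default_qpcr() -> dict:
    return {"error_mode": "corrected"}  # or "legacy"


@dataclass
class RunConfig:
    """Per-module parameter blocks plus the master seed.

    Any block may be partially overridden; unknown keys raise.
    """

    seed: int = 0
    detection: dict = field(default_factory=_default_detection)
    zonation: dict = field(default_factory=_default_zonation)
    coloc: dict = field(default_factory=_default_coloc)
    spt: dict = field(default_factory=_default_spt)
    qpcr: dict = field(default_factory=_default_qpcr)

    def __post_init__(self) -> None:
        self.seed = int(self.seed)
        for name, default_fn in (
            ("detection", _default_detection),
            ("zonation", _default_zonation),
            ("coloc", _default_coloc),
            ("spt", _default_spt),
            ("qpcr", _default_qpcr),
        ):
            block = dict(default_fn())
            given = getattr(self, name) or {}
            unknown = set(given) - set(block)
            if unknown:
                raise ValueError(f"unknown {name} parameters: {sorted(unknown)}")
            block.update(given)
            setattr(self, name, block)
        self._validate()

    def _validate(self) -> None:
        det, zon, col, spt_, qp = self.detection, self.zonation, self.coloc, self.spt, self.qpcr
        if det["sigma_um"] <= 0:
            raise ValueError("detection.sigma_um must be > 0")
        if det["k_mad"] <= 0:
            raise ValueError("detection.k_mad must be > 0")
        if not 0 < det["grow_frac"] < 1:
            raise ValueError("detection.grow_frac must be in (0, 1)")
        if zon["convention"] not in ("equal_area", "equal_volume"):
            raise ValueError("zonation.convention must be equal_area or equal_volume")
        if col["n_shuffles"] < 19:
            raise ValueError("coloc.n_shuffles must be >= 19")
        if not 0 < col["alpha"] < 1:
            raise ValueError("coloc.alpha must be in (0, 1)")
        if spt_["min_length"] < 2:
            raise ValueError("spt.min_length must be >= 2")
        if spt_["max_displacement_um"] <= 0:
            raise ValueError("spt.max_displacement_um must be > 0")
        if qp["error_mode"] not in ("corrected", "legacy"):
            raise ValueError("qpcr.error_mode must be corrected or legacy")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# image stacks

def read_stack(
    path: str | Path,
    voxel_size: Sequence[float],
    channel_names: Sequence[str] | None = None,
) -> ImageStack3D:
    """Read a TIFF z-stack into an :class:`ImageStack3D`.

    Accepts single-channel ``(z, y, x)`` and multichannel ``(z, c, y, x)``
    (ImageJ hyperstack order) or ``(c, z, y, x)`` files. Axis metadata is used
    when present; otherwise the smaller of the two leading axes is taken as
    the channel axis.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            axes = tif.series[0].axes if tif.series else ""
    except Exception as exc:
        raise ValueError(f"unreadable TIFF: {path}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 2:  # single plane -> one z slice
        arr = arr[None, :, :]
    if arr.ndim == 3:
        arr = arr[None, ...]  # one channel
        axes = ""
    elif arr.ndim == 4:
        if axes in ("ZCYX",):
            arr = np.moveaxis(arr, 1, 0)
        elif axes in ("CZYX",):
            pass
        elif arr.shape[0] > arr.shape[1]:
            # heuristics: channel count is the smaller leading axis
            arr = np.moveaxis(arr, 1, 0)
    else:
        raise ValueError(f"cannot interpret a {arr.ndim}-D TIFF as (z, y, x) or (c, z, y, x)")

    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(arr.shape[0])]
    return ImageStack3D(arr.astype(np.float64), tuple(voxel_size), tuple(channel_names))


def write_stack(path: str | Path, stack: ImageStack3D) -> None:
    """Write a stack as a CZYX TIFF, preserving the float intensities exactly."""
    tifffile.imwrite(
        Path(path),
        stack.voxels,
        metadata={"axes": "CZYX", "channel_names": list(stack.channel_names)},
    )


# ---------------------------------------------------------------------------
# track tables

_TRACK_COLUMNS = {
    "track_id": ("track_id", "TRACK_ID", "track"),
    "frame": ("frame", "FRAME"),
    "x": ("x_um", "x", "POSITION_X"),
    "y": ("y_um", "y", "POSITION_Y"),
    "intensity": ("intensity", "MEAN_INTENSITY", "TOTAL_INTENSITY"),
}


def _resolve_column(df: pd.DataFrame, key: str, required: bool) -> str | None:
    for cand in _TRACK_COLUMNS[key]:
        if cand in df.columns:
            return cand
    if required:
        raise ValueError(f"track CSV is missing a {key!r} column (one of {_TRACK_COLUMNS[key]})")
    return None


def read_tracks(path: str | Path, frame_interval: float, position_scale: float = 1.0) -> list:
    """Read a TrackMate-style CSV into a list of :class:`~terrafoci.spt.Trajectory`.

    Rows are grouped by track id and sorted by frame. A gap in the frame
    sequence splits the trajectory at the gap (no gap closing); fragment ids
    get a ``#k`` suffix. ``position_scale`` converts pixel coordinates to µm.
    """
    from .spt import Trajectory

    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    df = pd.read_csv(path)
    if df.empty:
        return []
    id_col = _resolve_column(df, "track_id", True)
    fr_col = _resolve_column(df, "frame", True)
    x_col = _resolve_column(df, "x", True)
    y_col = _resolve_column(df, "y", True)
    if df.duplicated(subset=[id_col, fr_col]).any():
        raise ValueError("duplicate (track, frame) rows in track CSV")

    out: list[Trajectory] = []
    for tid, grp in df.groupby(id_col, sort=True):
        grp = grp.sort_values(fr_col)
        frames = grp[fr_col].to_numpy(dtype=int)
        pos = np.column_stack([grp[x_col].to_numpy(float), grp[y_col].to_numpy(float)])
        pos = pos * float(position_scale)
        # split at gaps
        breaks = np.flatnonzero(np.diff(frames) != 1) + 1
        pieces = np.split(np.arange(len(frames)), breaks)
        for k, idx in enumerate(pieces):
            frag_id = str(tid) if len(pieces) == 1 else f"{tid}#{k}"
            if len(idx) < 2:
                continue
            out.append(Trajectory(track_id=frag_id, frame_interval=float(frame_interval),
                                  positions=pos[idx], start_frame=int(frames[idx[0]])))
    return out


def write_tracks(path: str | Path, trajectories: Sequence) -> None:
    """Write trajectories as CSV with columns track_id, frame, t_s, x_um, y_um, intensity."""
    rows = []
    for tr in trajectories:
        for i, (x, y) in enumerate(tr.positions):
            frame = tr.start_frame + i
            rows.append((tr.track_id, frame, frame * tr.frame_interval, x, y, 0.0))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_um", "y_um", "intensity"])
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# foci tables and run summaries

FOCI_COLUMNS = [
    "focus_id", "nucleus_id", "channel", "x_um", "y_um", "z_um",
    "volume_um3", "integrated_density", "average_intensity", "background",
    "compartment", "d_center_um", "d_edge_um", "rho", "zone", "clamped",
]


def write_foci_table(path: str | Path, foci: Sequence) -> None:
    """Write measured foci as a CSV with the fixed :data:`FOCI_COLUMNS` header."""
    rows = []
    for f in foci:
        rows.append({
            "focus_id": f.focus_id,
            "nucleus_id": "" if f.nucleus_id is None else f.nucleus_id,
            "channel": f.channel,
            "x_um": f.centroid[0], "y_um": f.centroid[1], "z_um": f.centroid[2],
            "volume_um3": f.volume,
            "integrated_density": f.integrated_density,
            "average_intensity": f.average_intensity,
            "background": f.background,
            "compartment": f.compartment,
            "d_center_um": "" if f.d_center is None else f.d_center,
            "d_edge_um": "" if f.d_edge is None else f.d_edge,
            "rho": "" if f.rho is None else f.rho,
            "zone": "" if f.zone is None else f.zone,
            "clamped": f.clamped,
        })
    df = pd.DataFrame(rows, columns=FOCI_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_foci_table(path: str | Path) -> list:
    """Read a foci CSV written by :func:`write_foci_table`."""
    from .foci3d import Focus

    df = pd.read_csv(path)
    missing = set(FOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"foci CSV missing columns: {sorted(missing)}")
    foci = []
    for row in df.itertuples(index=False):
        foci.append(Focus(
            focus_id=int(row.focus_id),
            nucleus_id=None if pd.isna(row.nucleus_id) else int(row.nucleus_id),
            channel=str(row.channel),
            centroid=(float(row.x_um), float(row.y_um), float(row.z_um)),
            volume=float(row.volume_um3),
            integrated_density=float(row.integrated_density),
            average_intensity=float(row.average_intensity),
            background=float(row.background),
            compartment=str(row.compartment),
            d_center=None if pd.isna(row.d_center_um) else float(row.d_center_um),
            d_edge=None if pd.isna(row.d_edge_um) else float(row.d_edge_um),
            rho=None if pd.isna(row.rho) else float(row.rho),
            zone=None if pd.isna(row.zone) else int(row.zone),
            clamped=bool(row.clamped),
        ))
    return foci


def write_summary(path: str | Path, summary: dict) -> None:
    """Write a run summary as deterministic, sorted-key JSON."""
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")


def read_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
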