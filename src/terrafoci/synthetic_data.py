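"""Ground-truth generators for every pipeline stage.

The generators emulate the statistical structure of the real inputs: fixed
gonad nuclei imaged as DAPI-stained spheres of 2–3 µm radius, RNA-FISH focus
channels containing 0–6 diffraction-limited foci per nucleus (plus an
optional telomere-marker channel with ~12 foci), live-imaging trajectories
sampled at 200–600 ms for up to 30 s in four motility regimes, and qPCR Ct
replicate tables with known relative expression. Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ImageStack3D
from .spt import Trajectory

__all__ = [
    "GroundTruthFocus",
    "MotionModel",
    "generate_nuclei_stack",
    "simulate_trajectory",
    "simulate_ensemble",
    "generate_ct_table",
    "EQUAL_AREA_BOUNDS",
    "EQUAL_VOLUME_BOUNDS",
]

# Radial zone boundaries on the normalized radius rho = d_center / r.
# Equal-area: three annuli of equal area in a 2D projection of the radius;
# equal-volume: three shells of equal volume.
EQUAL_AREA_BOUNDS = (math.sqrt(1.0 / 3.0), math.sqrt(2.0 / 3.0))
EQUAL_VOLUME_BOUNDS = ((1.0 / 3.0) ** (1.0 / 3.0), (2.0 / 3.0) ** (1.0 / 3.0))


@dataclass(frozen=True)
class GroundTruthFocus:
    """Truth record for one rendered focus."""

    focus_id: int
    nucleus_id: int | None
    channel: str
    center: tuple[float, float, float]  # (x, y, z) µm
    sigma: float                        # isotropic Gaussian sigma, µm
    amplitude: float
    compartment: str                    # nuclear | cytoplasmic
    zone: int | None = None
    partner_id: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    def analytic_mass(self) -> float:
        """Total rendered intensity of the focus: A (2π)^{3/2} σ³ / voxel volume
        is obtained per-stack; this returns the continuous integral A (2π)^{3/2} σ³ (µm³)."""
        return self.amplitude * (2.0 * math.pi) ** 1.5 * self.sigma**3


@dataclass(frozen=True)
class GroundTruthNucleus:
    nucleus_id: int
    center: tuple[float, float, float]  # (x, y, z) µm
    radius: float                       # µm


@dataclass(frozen=True)
class MotionModel:
    """Simulation-side motion regime for one particle.

    kind 'brownian' uses D; 'confined' adds a reflecting circular boundary of
    radius R about the start point; 'stationary' is a fixed point; 'switching'
    concatenates segments (each a MotionModel, duration seconds) continuously.
    Localization noise sigma_loc (µm) is added to every reported position.
    """

    kind: str
    D: float = 0.0
    R: float = 0.0
    sigma_loc: float = 0.0
    segments: tuple = ()  # ((MotionModel, duration_s), ...) for 'switching'

    def __post_init__(self) -> None:
        if self.kind not in ("brownian", "confined", "stationary", "switching"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.D < 0 or self.sigma_loc < 0:
            raise ValueError("D and sigma_loc must be >= 0")
        if self.kind == "confined" and self.R <= 0:
            raise ValueError("confined motion needs R > 0")
        if self.kind == "switching" and not self.segments:
            raise ValueError("switching motion needs segments")


# ---------------------------------------------------------------------------
# image stacks

def _sample_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n

def _sample_radius_in_shell(rng: np.random.Generator, a: float, b: float) -> float:
    """Radius uniform-in-volume within the shell [a, b] of the unit ball."""
    u = rng.uniform()
    return (a**3 + (b**3 - a**3) * u) ** (1.0 / 3.0)


def _sample_focus_position(
    rng: np.random.Generator,
    radius: float,
    zone_probs: tuple[float, float, float] | None,
    zone_bounds: tuple[float, float],
    margin: float,
) -> tuple[np.ndarray, int]:
    """Point inside a sphere of given radius (relative to its centre).

    With ``zone_probs`` the radial zone (1 = peripheral annulus, 3 = core) is
    drawn first and the radius uniformly-in-volume within that shell; without,
    the point is uniform in the sphere. ``margin`` keeps the focus centre away
    from the nuclear edge so the rendered blob stays inside the nucleus.
    """
    b1, b2 = zone_bounds
    rmax = max(1e-6, 1.0 - margin / radius)
    if zone_probs is None:
        rho = _sample_radius_in_shell(rng, 0.0, rmax)
    else:
        p = np.asarray(zone_probs, dtype=float)
        if p.min() < 0 or not math.isclose(p.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("zone_probs must be non-negative and sum to 1")
        zone = rng.choice(3, p=p) + 1
        shells = {1: (b2, rmax), 2: (b1, b2), 3: (0.0, b1)}
        lo, hi = shells[zone]
        hi = min(hi, rmax)
        lo = min(lo, hi)
        rho = _sample_radius_in_shell(rng, lo, hi)
    rho_val = rho
    zone = 1 if rho_val > b2 else (2 if rho_val > b1 else 3)
    return _sample_direction(rng) * rho_val * radius, zone


def generate_nuclei_stack(
    n_nuclei: int,
    shape: tuple[int, int, int] = (40, 160, 160),
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1),
    radius_range: tuple[float, float] = (2.0, 3.0),
    foci_per_channel: dict | None = None,
    noise_sd: float = 10.0,
    background: float = 100.0,
    dna_amplitude: float = 150.0,
    poisson_noise: bool = False,
    seed: int | np.random.Generator = 0,
    max_placement_tries: int = 200,
    return_clean: bool = False,
):
    """Render a multichannel 3D stack of spherical nuclei with Gaussian foci.

    Parameters
    ----------
    foci_per_channel
        Mapping ``channel name -> spec dict`` with keys: ``n`` (foci per
        nucleus; int, or (lo, hi) for a uniform draw per nucleus),
        ``sigma_um`` (default 0.15), ``amplitude`` (peak above background;
        default ``8 * noise_sd``, i.e. SNR 8), ``zone_probs`` (optional
        placement bias over zones (1, 2, 3)), ``compartment``
        ('nuclear', default, or 'cytoplasmic'). The DNA channel named
        ``"dna"`` is always first.
    noise_sd, background
        Gaussian read noise sd and constant offset; negative values are
        clipped at zero. With ``poisson_noise`` the noiseless image is
        additionally Poisson-resampled.

    Returns the stack, the nucleus truth list and the focus truth list;
    with ``return_clean`` additionally the noise-free stack (background
    included) as a fourth element.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    foci_per_channel = foci_per_channel or {}
    dz, dy, dx = voxel_size
    extent = np.array([shape[2] * dx, shape[1] * dy, shape[0] * dz])  # (x, y, z) µm

    # non-overlapping sphere placement by rejection
    nuclei: list[GroundTruthNucleus] = []
    for nid in range(1, n_nuclei + 1):
        placed = False
        for _ in range(max_placement_tries):
            r = rng.uniform(*radius_range)
            lo = np.array([r, r, r]) * 1.02
            hi = extent - lo
            if np.any(hi <= lo):
                continue
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - np.array(n.center)) > r + n.radius + 0.8 for n in nuclei):
                nuclei.append(GroundTruthNucleus(nid, tuple(c), r))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {nid} without overlap after {max_placement_tries} tries")

    channel_names = ["dna"] + [c for c in foci_per_channel if c != "dna"]
    clean = np.zeros((len(channel_names),) + tuple(shape), dtype=np.float64)

    # voxel-centre coordinate grids in µm
    zc = (np.arange(shape[0]) + 0.5) * dz
    yc = (np.arange(shape[1]) + 0.5) * dy
    xc = (np.arange(shape[2]) + 0.5) * dx

    # DNA channel: soft-edged filled spheres
    edge = 2.0 * min(dy, dx)  # sigmoid edge width, µm
    for nuc in nuclei:
        cx, cy, cz = nuc.center
        dist = np.sqrt((zc[:, None, None] - cz) ** 2 +
                       (yc[None, :, None] - cy) ** 2 +
                       (xc[None, None, :] - cx) ** 2)
        clean[0] += dna_amplitude / (1.0 + np.exp((dist - nuc.radius) / edge))

    # focus channels: isotropic 3D Gaussians
    truth: list[GroundTruthFocus] = []
    fid = 0
    for ch_i, ch in enumerate(channel_names):
        spec = foci_per_channel.get(ch)
        if spec is None:
            continue
        n_spec = spec.get("n", 0)
        sigma = float(spec.get("sigma_um", 0.15))
        amplitude = float(spec.get("amplitude", 8.0 * noise_sd))
        zone_probs = spec.get("zone_probs")
        compartment = spec.get("compartment", "nuclear")
        for nuc in nuclei:
            n_foci = (int(rng.integers(n_spec[0], n_spec[1] + 1))
                      if isinstance(n_spec, (tuple, list)) else int(n_spec))
            for _ in range(n_foci):
                if compartment == "nuclear":
                    offset, zone = _sample_focus_position(
                        rng, nuc.radius, zone_probs, EQUAL_AREA_BOUNDS, margin=3.0 * sigma)
                    center = np.array(nuc.center) + offset
                    nucleus_id: int | None = nuc.nucleus_id
                else:
                    # cytoplasmic: a ring just outside the nucleus
                    direction = _sample_direction(rng)
                    center = np.array(nuc.center) + direction * (nuc.radius + rng.uniform(0.5, 1.0))
                    center = np.clip(center, 3 * sigma, extent - 3 * sigma)
                    nucleus_id, zone = None, None
                fid += 1
                truth.append(GroundTruthFocus(
                    focus_id=fid, nucleus_id=nucleus_id, channel=ch,
                    center=tuple(center), sigma=sigma, amplitude=amplitude,
                    compartment=compartment, zone=zone))
                _render_gaussian(clean[ch_i], center, sigma, amplitude, (zc, yc, xc))

    clean = clean + background
    noisy = clean
    if poisson_noise:
        noisy = rng.poisson(np.maximum(noisy, 0.0)).astype(np.float64)
    if noise_sd > 0:
        noisy = noisy + rng.normal(0.0, noise_sd, size=noisy.shape)
    noisy = np.maximum(noisy, 0.0)
    stack = ImageStack3D(noisy, voxel_size, tuple(channel_names))
    if return_clean:
        clean_stack = ImageStack3D(clean, voxel_size, tuple(channel_names))
        return stack, nuclei, truth, clean_stack
    return stack, nuclei, truth


def _render_gaussian(img: np.ndarray, center_xyz: np.ndarray, sigma: float,
                     amplitude: float, grids: tuple) -> None:
    """Add an isotropic 3D Gaussian to ``img`` (z, y, x), cropped at 5 sigma."""
    zc, yc, xc = grids
    cx, cy, cz = center_xyz
    zi = np.flatnonzero(np.abs(zc - cz) <= 5 * sigma)
    yi = np.flatnonzero(np.abs(yc - cy) <= 5 * sigma)
    xi = np.flatnonzero(np.abs(xc - cx) <= 5 * sigma)
    if not (len(zi) and len(yi) and len(xi)):
        return
    gz = np.exp(-0.5 * ((zc[zi] - cz) / sigma) ** 2)
    gy = np.exp(-0.5 * ((yc[yi] - cy) / sigma) ** 2)
    gx = np.exp(-0.5 * ((xc[xi] - cx) / sigma) ** 2)
    img[np.ix_(zi, yi, xi)] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


# ---------------------------------------------------------------------------
# trajectories

def simulate_trajectory(
    model: MotionModel,
    frame_interval: float,
    n_frames: int,
    seed: int | np.random.Generator = 0,
    start: tuple[float, float] = (0.0, 0.0),
    track_id: str = "sim",
) -> Trajectory:
    """Simulate one 2D trajectory under a motion model.

    Brownian motion uses independent per-axis Gaussian increments of variance
    ``2 D Δt``. Confined motion proposes Brownian steps and reflects them at a
    circle of radius R about the starting point. Stationary particles do not
    move. Switching models concatenate their segments continuously, rounding
    each duration to whole frames. Localization noise is added to the true
    positions at the end.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if model.kind == "switching":
        total = sum(dur for _, dur in model.segments)
        expected = (n_frames - 1) * frame_interval
        if not math.isclose(total, expected, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError(
                f"switching segment durations sum to {total} s but the trajectory lasts {expected} s")
        pos = [np.asarray(start, dtype=float)]
        for sub, dur in model.segments:
            steps = round(dur / frame_interval)
            if steps == 0:
                continue
            seg = _simulate_true(sub, frame_interval, steps + 1, rng, pos[-1])
            pos.extend(seg[1:])
        true_pos = np.array(pos[:n_frames])
    else:
        true_pos = _simulate_true(model, frame_interval, n_frames, rng, np.asarray(start, float))

    noisy = true_pos + rng.normal(0.0, model.sigma_loc, size=true_pos.shape) \
        if model.sigma_loc > 0 else true_pos
    return Trajectory(track_id=track_id, frame_interval=frame_interval, positions=noisy)


def _simulate_true(model: MotionModel, dt: float, n: int, rng: np.random.Generator,
                   start: np.ndarray) -> np.ndarray:
    if model.kind == "stationary":
        return np.tile(start, (n, 1))
    step_sd = math.sqrt(2.0 * model.D * dt)
    steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
    if model.kind == "brownian" or model.kind == "switching":
        return start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    # confined: reflect radially at |p - start| = R
    pos = np.empty((n, 2))
    pos[0] = start
    for i in range(1, n):
        p = pos[i - 1] + steps[i - 1]
        d = np.linalg.norm(p - start)
        while d > model.R:
            p = start + (p - start) / d * (2.0 * model.R - d)
            d = abs(2.0 * model.R - d)
        pos[i] = p
    return pos


def simulate_ensemble(
    model: MotionModel,
    frame_interval: float,
    n_frames: int,
    n_tracks: int,
    seed: int | np.random.Generator = 0,
) -> list[Trajectory]:
    """Simulate ``n_tracks`` independent trajectories from one model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        simulate_trajectory(model, frame_interval, n_frames, rng, track_id=str(i))
        for i in range(n_tracks)
    ]


# ---------------------------------------------------------------------------
# qPCR Ct tables

def generate_ct_table(
    expression: dict[str, float],
    target_primer: str = "telo",
    housekeeping_primers: tuple[str, ...] = ("arp-6", "tba-1"),
    efficiency: float = 1.0,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    baseline_ct: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct replicate table with known relative expression.

    ``expression`` maps sample (strain) name to the true target expression
    relative to the housekeeping level. With amplification efficiency E
    (1.0 = perfect doubling), Ct = baseline − log(expr) / log(1 + E), plus
    Gaussian replicate noise. Housekeeping primers amplify at the baseline.

    Returns a tidy DataFrame with columns
    ``sample, primer, role, replicate, ct``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if efficiency <= 0:
        raise ValueError("efficiency must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sample in sorted(expression):
        expr = expression[sample]
        if expr <= 0:
            raise ValueError(f"expression for {sample!r} must be > 0")
        ct_target = baseline_ct - math.log(expr) / math.log(1.0 + efficiency)
        for primer, role, ct0 in (
            [(target_primer, "target", ct_target)]
            + [(hk, "housekeeping", baseline_ct) for hk in housekeeping_primers]
        ):
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append((sample, primer, role, rep, ct0 + noise))
    return pd.DataFrame(rows, columns=["sample", "primer", "role", "replicate", "ct"])
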