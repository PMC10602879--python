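"""Object-based colocalization between two focus channels with a shuffle null.

Within each nucleus, every channel-A focus is greedily matched to its nearest
channel-B focus (one-to-one). A pair is *colocalized* when the centre
distance is at most the sum of the two equal-volume object radii (objects
touching or overlapping, plus an optional tolerance). Significance comes
from a shuffle null: channel-A centres are re-placed uniformly at random
inside their nucleus mask, sizes preserved and channel B fixed, and the
pair's p-value is the add-one rank of the observed nearest-B distance among
the shuffled ones. Only significant colocalization counts as telomeric when
channel B marks telomeres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .foci3d import Focus, NucleusModel

__all__ = [
    "ColocPair",
    "match_objects",
    "shuffle_null",
    "classify_telomeric",
    "signal_correlation",
]


@dataclass(frozen=True)
class ColocPair:
    """A matched A–B focus pair within one nucleus."""

    focus_a: int
    focus_b: int | None
    nucleus_id: int
    center_distance: float        # µm; inf when the nucleus has no B focus
    colocalized: bool
    p_shuffle: float | None = None
    significant: bool = False

    def __post_init__(self) -> None:
        if self.significant and not self.colocalized:
            raise ValueError("significant implies colocalized")


def _pair_distance_limit(fa: Focus, fb: Focus, tolerance: float) -> float:
    return fa.equivalent_radius + fb.equivalent_radius + tolerance


def match_objects(
    foci_a: list[Focus],
    foci_b: list[Focus],
    tolerance: float = 0.0,
) -> list[ColocPair]:
    """Greedy one-to-one nearest-neighbour matching of A to B foci per nucleus.

    Candidate pairs are sorted by centre distance (ties broken by smaller B
    focus id, then A id) and accepted one-to-one. Every A focus yields a
    ColocPair; A foci in nuclei without any B focus get ``focus_b=None`` and
    an infinite distance. Foci without a nucleus assignment are skipped.
    """
    for f in foci_a + foci_b:
        if f.volume <= 0:
            raise ValueError(f"focus {f.focus_id} is unmeasured (volume <= 0)")
    a_by_nuc: dict[int, list[Focus]] = {}
    b_by_nuc: dict[int, list[Focus]] = {}
    for f in foci_a:
        if f.nucleus_id is not None:
            a_by_nuc.setdefault(f.nucleus_id, []).append(f)
    for f in foci_b:
        if f.nucleus_id is not None:
            b_by_nuc.setdefault(f.nucleus_id, []).append(f)

    pairs: list[ColocPair] = []
    for nid, a_list in sorted(a_by_nuc.items()):
        b_list = b_by_nuc.get(nid, [])
        cand = []
        for fa in a_list:
            for fb in b_list:
                d = math.dist(fa.centroid, fb.centroid)
                cand.append((d, fb.focus_id, fa.focus_id, fa, fb))
        cand.sort(key=lambda t: (t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, _, _, fa, fb in cand:
            if fa.focus_id in used_a or fb.focus_id in used_b:
                continue
            used_a.add(fa.focus_id)
            used_b.add(fb.focus_id)
            pairs.append(ColocPair(
                focus_a=fa.focus_id, focus_b=fb.focus_id, nucleus_id=nid,
                center_distance=d,
                colocalized=d <= _pair_distance_limit(fa, fb, tolerance)))
        for fa in a_list:
            if fa.focus_id not in used_a:
                pairs.append(ColocPair(
                    focus_a=fa.focus_id, focus_b=None, nucleus_id=nid,
                    center_distance=math.inf, colocalized=False))
    pairs.sort(key=lambda p: p.focus_a)
    return pairs


def _uniform_points_in_mask(
    mask: np.ndarray, voxel_size: tuple[float, float, float],
    n: int, rng: np.random.Generator,
) -> np.ndarray:
    """n points (x, y, z µm) uniform over a voxel mask, jittered within voxels."""
    dz, dy, dx = voxel_size
    zz, yy, xx = np.nonzero(mask)
    if len(zz) == 0:
        raise ValueError("empty nucleus mask")
    idx = rng.integers(0, len(zz), size=n)
    u = rng.uniform(0.0, 1.0, size=(n, 3))
    x = (xx[idx] + u[:, 0]) * dx
    y = (yy[idx] + u[:, 1]) * dy
    z = (zz[idx] + u[:, 2]) * dz
    return np.column_stack([x, y, z])


def _uniform_points_in_sphere(
    center: tuple[float, float, float], radius: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return np.asarray(center) + v * r


def shuffle_null(
    foci_a: list[Focus],
    foci_b: list[Focus],
    nuclei: list[NucleusModel],
    voxel_size: tuple[float, float, float] | None = None,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    tolerance: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[ColocPair]:
    """Shuffle-null significance for the observed A–B matches.

    For each shuffle, the channel-A centres of a nucleus are re-placed
    uniformly at random inside that nucleus (its voxel mask when present,
    else its fitted sphere), keeping per-nucleus counts and sizes; channel B
    stays fixed. For each A focus the nearest-B distance is recorded, and

        p = (1 + #{shuffles with nearest-B distance <= observed}) / (n_shuffles + 1).

    A pair is significant iff it is colocalized and p <= alpha.
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = match_objects(foci_a, foci_b, tolerance)
    by_id_nuc = {n.nucleus_id: n for n in nuclei}
    obs_by_a = {p.focus_a: p for p in observed}

    a_by_nuc: dict[int, list[Focus]] = {}
    b_pos_by_nuc: dict[int, np.ndarray] = {}
    for f in foci_a:
        if f.nucleus_id is not None:
            a_by_nuc.setdefault(f.nucleus_id, []).append(f)
    for f in foci_b:
        if f.nucleus_id is not None:
            b_pos_by_nuc.setdefault(f.nucleus_id, []).append(f.centroid)  # type: ignore[arg-type]
    b_pos_by_nuc = {k: np.asarray(v) for k, v in b_pos_by_nuc.items()}

    exceed: dict[int, int] = {f.focus_id: 0 for nid in a_by_nuc for f in a_by_nuc[nid]}
    for nid, a_list in sorted(a_by_nuc.items()):
        nuc = by_id_nuc.get(nid)
        if nuc is None:
            raise ValueError(f"no nucleus model for nucleus {nid}")
        b_pos = b_pos_by_nuc.get(nid)
        if b_pos is None or len(b_pos) == 0:
            continue  # nearest-B distance undefined; p stays None
        n_a = len(a_list)
        for _ in range(n_shuffles):
            if nuc.mask is not None and voxel_size is not None:
                pts = _uniform_points_in_mask(nuc.mask, voxel_size, n_a, rng)
            else:
                pts = _uniform_points_in_sphere(nuc.centroid, nuc.radius, n_a, rng)
            dmin = np.min(np.linalg.norm(pts[:, None, :] - b_pos[None, :, :], axis=2), axis=1)
            for fa, d in zip(a_list, dmin):
                if d <= obs_by_a[fa.focus_id].center_distance:
                    exceed[fa.focus_id] += 1

    out: list[ColocPair] = []
    for p in observed:
        if p.focus_b is None:
            out.append(p)
            continue
        pval = (1 + exceed[p.focus_a]) / (n_shuffles + 1)
        out.append(ColocPair(
            focus_a=p.focus_a, focus_b=p.focus_b, nucleus_id=p.nucleus_id,
            center_distance=p.center_distance, colocalized=p.colocalized,
            p_shuffle=pval, significant=bool(p.colocalized and pval <= alpha)))
    return out


def classify_telomeric(
    foci_a: list[Focus],
    pairs: list[ColocPair],
) -> tuple[dict[int, str], dict[str, float]]:
    """Label each channel-A focus telomeric or extratelomeric.

    A focus is *telomeric* iff its pair is a significant colocalization with
    the telomere-marker channel. Returns the per-focus labels and summary
    percentages over all channel-A foci.
    """
    sig = {p.focus_a for p in pairs if p.significant}
    labels = {f.focus_id: ("telomeric" if f.focus_id in sig else "extratelomeric")
              for f in foci_a}
    n = len(labels)
    n_tel = sum(1 for v in labels.values() if v == "telomeric")
    summary = {
        "n_foci": float(n),
        "pct_telomeric": 100.0 * n_tel / n if n else 0.0,
        "pct_extratelomeric": 100.0 * (n - n_tel) / n if n else 0.0,
    }
    return labels, summary


def signal_correlation(
    foci_a: list[Focus],
    foci_b: list[Focus],
    pairs: list[ColocPair],
    metric_a: str = "integrated_density",
    metric_b: str = "integrated_density",
) -> dict:
    """Spearman rank correlation of a metric across significant pairs.

    Metrics are ``volume``, ``integrated_density`` or ``average_intensity``.
    Needs at least 3 significant pairs; a zero-variance metric yields an
    ``undefined`` result flag instead of a coefficient.
    """
    valid = ("volume", "integrated_density", "average_intensity")
    if metric_a not in valid or metric_b not in valid:
        raise ValueError(f"metrics must be one of {valid}")
    a_by_id = {f.focus_id: f for f in foci_a}
    b_by_id = {f.focus_id: f for f in foci_b}
    sig = [p for p in pairs if p.significant]
    if len(sig) < 3:
        raise ValueError(f"need >= 3 significant pairs, have {len(sig)}")
    xa = np.array([getattr(a_by_id[p.focus_a], metric_a) for p in sig])
    xb = np.array([getattr(b_by_id[p.focus_b], metric_b) for p in sig])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return {"rho": None, "n": len(sig), "undefined": True}
    rho = stats.spearmanr(xa, xb).statistic
    return {"rho": float(rho), "n": len(sig), "undefined": False}
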