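"""Per-fiber FA thresholding and the visualized ratio (VR).

The quantity of interest is, for each streamline, the largest fractional
anisotropy threshold (on a 0.01 grid) at which the fiber would still be
tracked with at least the fiber length threshold (FLT, default 30 mm):
``fa_max``.  The subject-level maximum over fibers is ``FAT_max``, and each
fiber's visualized ratio is

    VR = fa_max / FAT_max * 100  (percent).

Two independent routes compute ``fa_max``:

* :func:`famax_by_sweep` — direct per-fiber sweep: the largest grid threshold
  ``t`` such that some contiguous run of points with FA >= t has arc length
  >= FLT.
* :func:`famax_by_retracking` — the literal procedure: rerun a deterministic
  principal-direction tracker at every grid threshold and record the largest
  threshold at which each seed still yields a surviving streamline.  This is
  slow and serves as the oracle for the sweep on synthetic phantoms.

Thresholds are held internally as integer hundredths so grid values never
drift in floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .io import VolumeGrid

__all__ = [
    "GRID_STEP",
    "FiberRecord",
    "SubjectTractogram",
    "segment_lengths",
    "fiber_length",
    "famax_by_sweep",
    "annotate_famax",
    "compute_vr",
    "select_fibers",
    "seeds_from_fa",
    "track_at_threshold",
    "famax_by_retracking",
]

GRID_STEP = 0.01
_EPS = 1e-9


@dataclass
class FiberRecord:
    """One streamline with its per-point FA samples and VR annotations."""

    points: np.ndarray  # (N, 3) world mm
    fa: np.ndarray  # (N,)
    fa_max: float | None = None  # on the 0.01 grid, None if fiber < FLT
    vr: float | None = None  # percent in [0, 100]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if len(self.fa) != len(self.points):
            raise ValueError("fa must have one value per point")

    @property
    def length(self) -> float:
        return fiber_length(self.points)


@dataclass
class SubjectTractogram:
    """A subject's fibers plus the derived FAT_max."""

    subject_id: str
    fibers: list[FiberRecord] = field(default_factory=list)

    @property
    def fat_max(self) -> float | None:
        vals = [f.fa_max for f in self.fibers if f.fa_max is not None]
        if not vals:
            return None
        return max(vals)


def segment_lengths(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(np.asarray(points, dtype=float), axis=0), axis=1)


def fiber_length(points: np.ndarray) -> float:
    return float(segment_lengths(points).sum())


def _has_qualifying_run(fa: np.ndarray, cum: np.ndarray, thr: float, flt_mm: float) -> bool:
    """True if some contiguous run of points with FA >= thr spans >= flt_mm.

    ``cum`` is the prefix arc length at each point; a run's span is the
    difference of prefix lengths at its last and first point.
    """
    mask = fa >= thr - _EPS
    if not mask.any():
        return False
    idx = np.flatnonzero(mask)
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = idx[np.concatenate(([0], brk + 1))]
    ends = idx[np.concatenate((brk, [len(idx) - 1]))]
    return bool(np.any(cum[ends] - cum[starts] >= flt_mm - _EPS))


def famax_by_sweep(
    fiber: FiberRecord, flt_mm: float = 30.0, grid_step: float = GRID_STEP
) -> float | None:
    """Largest grid threshold at which the fiber still spans the FLT.

    Returns the largest multiple of ``grid_step`` ``t`` such that a contiguous
    run of points with FA >= t has arc length >= ``flt_mm``; ``None`` if even
    t = 0 fails (fiber shorter than the FLT).  The qualification predicate is
    monotone in ``t``, so a binary search over the integer grid suffices and
    the result matches a brute-force scan of every grid value.
    """
    fa = fiber.fa
    cum = np.concatenate(([0.0], np.cumsum(segment_lengths(fiber.points))))
    if not _has_qualifying_run(fa, cum, 0.0, flt_mm):
        return None
    hi = int(math.floor(float(fa.max()) / grid_step + _EPS))  # above this no point qualifies
    lo = 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _has_qualifying_run(fa, cum, mid * grid_step, flt_mm):
            lo = mid
        else:
            hi = mid - 1
    return round(lo * grid_step, 10)


def annotate_famax(
    tractogram: SubjectTractogram, flt_mm: float = 30.0, grid_step: float = GRID_STEP
) -> SubjectTractogram:
    """Fill ``fa_max`` for every fiber (in place) and return the tractogram."""
    for fib in tractogram.fibers:
        fib.fa_max = famax_by_sweep(fib, flt_mm=flt_mm, grid_step=grid_step)
    return tractogram


def compute_vr(tractogram: SubjectTractogram) -> SubjectTractogram:
    """Fill ``vr`` = fa_max / FAT_max * 100 for every fiber with a fa_max.

    The fiber attaining FAT_max gets VR = 100 exactly.  A degenerate subject
    (FAT_max absent or zero) raises.
    """
    fat_max = tractogram.fat_max
    if fat_max is None or fat_max <= 0:
        raise ValueError(
            f"subject {tractogram.subject_id}: FAT_max is {fat_max!r}; "
            "no fiber survives the length threshold at a positive FA threshold"
        )
    for fib in tractogram.fibers:
        if fib.fa_max is None:
            fib.vr = None
        else:
            fib.vr = float(fib.fa_max / fat_max * 100.0)
    return tractogram


def select_fibers(tractogram: SubjectTractogram, vr_threshold: float) -> list[FiberRecord]:
    """Fibers with VR >= threshold (inclusive), order preserved.

    Inclusive comparison keeps the FAT_max-defining fiber (VR = 100) at every
    threshold and makes boundary behaviour deterministic.
    """
    return [
        f
        for f in tractogram.fibers
        if f.vr is not None and f.vr >= vr_threshold - _EPS
    ]


# ---------------------------------------------------------------------------
# Minimal deterministic tracker (phantom-scale)


def seeds_from_fa(fa_volume: VolumeGrid, min_fa: float = 0.0) -> np.ndarray:
    """World-mm voxel centers with FA above ``min_fa`` (tracking seeds)."""
    vox = np.argwhere(fa_volume.data > min_fa)
    return fa_volume.voxel_to_world(vox)


def _directions_at(direction_field: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Nearest-voxel direction lookup; out-of-grid positions get the zero vector."""
    idx = np.rint(vox).astype(int)
    shape = np.asarray(direction_field.shape[:3])
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros((len(vox), 3))
    if inside.any():
        v = idx[inside]
        out[inside] = direction_field[v[:, 0], v[:, 1], v[:, 2]]
    return out


def _fa_at(fa_volume: VolumeGrid, points: np.ndarray) -> np.ndarray:
    vox = fa_volume.world_to_voxel(points)
    return map_coordinates(
        fa_volume.data.astype(float), vox.T, order=1, mode="constant", cval=0.0
    )


def _march(
    direction_field: np.ndarray,
    fa_volume: VolumeGrid,
    seeds: np.ndarray,
    sign: float,
    fat: float,
    step_mm: float,
    cos_max_angle: float,
    max_steps: int,
) -> list[list[np.ndarray]]:
    """Follow the principal direction from every seed in one orientation.

    Returns, per seed, the list of points *after* the seed.  Stops at: zero
    direction, turning angle above the limit, interpolated FA below ``fat``,
    or the volume edge.  Fully vectorized over seeds.
    """
    n = len(seeds)
    pos = seeds.copy()
    vox = fa_volume.world_to_voxel(pos)
    prev_dir = sign * _directions_at(direction_field, vox)
    norms = np.linalg.norm(prev_dir, axis=1)
    active = norms > _EPS
    prev_dir[active] = prev_dir[active] / norms[active, None]
    chains: list[list[np.ndarray]] = [[] for _ in range(n)]
    for _ in range(max_steps):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        vox = fa_volume.world_to_voxel(pos[ai])
        d = _directions_at(direction_field, vox)
        dn = np.linalg.norm(d, axis=1)
        ok = dn > _EPS
        d[ok] = d[ok] / dn[ok, None]
        # keep orientation consistent with the previous step
        flip = (d * prev_dir[ai]).sum(axis=1) < 0
        d[flip] = -d[flip]
        cosang = (d * prev_dir[ai]).sum(axis=1)
        ok &= cosang >= cos_max_angle - _EPS
        new_pos = pos[ai] + step_mm * d
        fa_new = _fa_at(fa_volume, new_pos)
        ok &= fa_new >= fat - _EPS
        for j, seed_idx in enumerate(ai):
            if ok[j]:
                chains[seed_idx].append(new_pos[j])
        pos[ai[ok]] = new_pos[ok]
        prev_dir[ai[ok]] = d[ok]
        active[ai[~ok]] = False
    return chains


def track_at_threshold(
    direction_field: np.ndarray,
    fa_volume: VolumeGrid,
    fat: float,
    flt_mm: float = 30.0,
    step_mm: float = 1.0,
    seeds: np.ndarray | None = None,
    max_angle_deg: float = 60.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Deterministic fixed-step principal-direction tracking at one FA threshold.

    Parameters
    ----------
    direction_field : ndarray (X, Y, Z, 3)
        Unit principal directions in world space on the same grid as
        ``fa_volume``; the zero vector marks voxels with no direction.
    fat : float
        FA stopping threshold: tracking halts where interpolated FA < fat.
    seeds : ndarray (N, 3), optional
        World-mm seed points; defaults to every voxel center with FA > 0.

    Returns
    -------
    streamlines, seed_indices
        Streamlines of length >= ``flt_mm`` (each traced in both orientations
        from its seed) and the index of the originating seed for each.
    """
    if not 0.0 <= fat <= 1.0:
        raise ValueError("fat must be in [0, 1]")
    if flt_mm <= 0:
        raise ValueError("flt_mm must be positive")
    if seeds is None:
        seeds = seeds_from_fa(fa_volume)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if len(seeds) == 0:
        return [], np.array([], dtype=int)
    keep0 = _fa_at(fa_volume, seeds) >= fat - _EPS
    diag = float(np.linalg.norm(np.asarray(fa_volume.shape) * np.sqrt(
        (fa_volume.affine[:3, :3] ** 2).sum(axis=0))))
    max_steps = int(diag / step_mm) + 2
    cos_max = math.cos(math.radians(max_angle_deg))
    idx0 = np.flatnonzero(keep0)
    fwd = _march(direction_field, fa_volume, seeds[idx0], +1.0, fat, step_mm, cos_max, max_steps)
    bwd = _march(direction_field, fa_volume, seeds[idx0], -1.0, fat, step_mm, cos_max, max_steps)
    streamlines: list[np.ndarray] = []
    seed_indices: list[int] = []
    for j, seed_idx in enumerate(idx0):
        pts = bwd[j][::-1] + [seeds[seed_idx]] + fwd[j]
        chain = np.asarray(pts)
        if len(chain) >= 2 and fiber_length(chain) >= flt_mm - _EPS:
            streamlines.append(chain)
            seed_indices.append(int(seed_idx))
    return streamlines, np.asarray(seed_indices, dtype=int)


def famax_by_retracking(
    direction_field: np.ndarray,
    fa_volume: VolumeGrid,
    seeds: np.ndarray,
    flt_mm: float = 30.0,
    grid_step: float = GRID_STEP,
    step_mm: float = 1.0,
    max_angle_deg: float = 60.0,
) -> np.ndarray:
    """Per-seed fa_max by literally re-tracking at every grid threshold.

    Runs :func:`track_at_threshold` at t = 0, step, 2*step, ... and records,
    per seed, the largest threshold at which that seed still yields a
    surviving streamline.  NaN marks seeds that never survive.  Test oracle;
    O(grid levels) full tracking passes.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    out = np.full(len(seeds), np.nan)
    n_levels = int(round(1.0 / grid_step)) + 1
    for level in range(n_levels):
        fat = round(level * grid_step, 10)
        _, surv = track_at_threshold(
            direction_field, fa_volume, fat, flt_mm=flt_mm, step_mm=step_mm,
            seeds=seeds, max_angle_deg=max_angle_deg,
        )
        if len(surv) == 0:
            break
        out[surv] = fat
    return out
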