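"""Synthetic phantoms and cohorts with the structure the analysis assumes.

The generator emulates, at desk scale, the study conditions of an nTMS /
tractography language-network comparison:

* a bilateral block parcellation with ``n_regions`` labeled regions, half per
  hemisphere (default 90, i.e. 45 + 45, mirroring an AAL-style template);
* straight fiber bundles between region pairs realized as FA tubes in a
  phantom volume, with per-bundle peak FA spread below a single anchor bundle
  at 0.53 so that per-subject FAT_max lands near 0.53 +/- 0.065;
* per-subject streamline sets: jittered copies of bundle centerlines with FA
  sampled from the phantom and scaled by a subject factor;
* a two-group cohort (NA = no aphasia, GIA = glioma-induced aphasia,
  default 30 + 30): GIA subjects lose each left intra-hemispheric bundle
  independently with probability ``1 - left_deficit``; tumor sizes are drawn
  per group (defaults 2.4 +/- 2.6 vs 4.7 +/- 4.3 cm^3, truncated at 0);
  the ordinal aphasia level (0-5) is driven by the deficit-induced bundle
  drops plus noise, so under the null (``left_deficit = 1``) it is pure
  noise and downstream tests stay calibrated, while under an effect it is
  negatively linked to realized left connectivity by construction;
* POS/NEG stimulation-region sets over left-hemisphere regions only, POS
  rarer than NEG (target means ~8.4 vs ~16.6 regions), with two designated
  "contrast" regions whose POS probability is elevated in the GIA group.

Every random draw descends from one root seed through named substreams, so a
fixed seed yields a bit-identical cohort and per-subject results do not
depend on cohort ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import VolumeGrid, sample_fa_along
from .regions import Parcellation, StimulationMap
from .tracking import FiberRecord

__all__ = [
    "BundleSpec",
    "Bundle",
    "Phantom",
    "SyntheticConfig",
    "CohortData",
    "default_config",
    "small_config",
    "null_config",
    "make_parcellation",
    "default_bundles",
    "make_phantom",
    "make_streamlines",
    "make_cohort",
    "apply_lesion",
]

logger = logging.getLogger(__name__)

GROUPS = ("NA", "GIA")

# substream tags for named seeding
_SS_BUNDLES, _SS_PHANTOM, _SS_SUBJECT = 1, 2, 10


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class BundleSpec:
    """One ground-truth bundle: a region pair with fiber count and FA profile.

    ``bow_mm`` arcs the centerline out of the hemisphere slab along x (signed;
    0 = straight chord), which both separates bundles in space and lets short
    chords reach the fiber length threshold, like association fibers curving
    through white matter rather than running point to point.
    """

    region_a: int
    region_b: int
    n_fibers: int = 8
    peak_fa: float = 0.5
    fa_jitter: float = 0.02
    bow_mm: float = 0.0


@dataclass
class Bundle:
    spec: BundleSpec
    centerline: np.ndarray  # (K, 3) world mm

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())


@dataclass
class Phantom:
    fa: VolumeGrid
    directions: np.ndarray  # (X, Y, Z, 3) unit tangents, zero outside tubes
    bundles: list[Bundle]


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    seed: int = 0
    n_per_group: int = 30
    n_regions: int = 90
    block_shape: tuple[int, int, int] = (4, 4, 4)
    voxel_size_mm: float = 2.0
    hemisphere_gap_vox: int = 20
    grid_shape: tuple[int, int, int] | None = None  # None -> derived from blocks

    # bundle wiring
    bundles: tuple[BundleSpec, ...] | None = None  # None -> default wiring
    n_intra_per_hemisphere: int = 12
    n_inter: int = 4
    n_hubs: int = 6  # bundles wire the complete graph over this many spread-out regions
    min_bundle_length_mm: float = 36.0
    fibers_per_bundle: tuple[int, int] = (6, 11)  # inclusive-exclusive draw range
    peak_fa_min: float = 0.16
    peak_fa_max: float = 0.53
    fa_jitter: float = 0.02
    tube_radius_mm: float = 3.0

    # per-subject streamline generation
    fiber_point_spacing_mm: float = 2.0
    fiber_jitter_mm: float = 0.6
    fatmax_scale_sd: float = 0.12  # ~0.065 / 0.53 relative spread of FAT_max

    # group structure
    base_keep: float = 0.92  # every subject keeps each bundle with this prob
    left_deficit: float = 0.75  # GIA keeps each left intra bundle with this prob
    tumor_mean: dict[str, float] = field(default_factory=lambda: {"NA": 2.4, "GIA": 4.7})
    tumor_sd: dict[str, float] = field(default_factory=lambda: {"NA": 2.6, "GIA": 4.3})
    n_aphasia_levels: int = 5
    aphasia_signal_weight: float = 1.5  # deficit-drop z-score weight vs unit noise

    # stimulation-region assignment probabilities (left hemisphere only)
    pos_prob_high: float = 0.75
    pos_prob_low: float = 0.07
    n_pos_high: int = 8
    neg_prob_high: float = 0.90
    neg_prob_low: float = 0.18
    n_neg_high: int = 12
    contrast_pos_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"NA": (0.133, 0.433), "GIA": (0.400, 0.700)}
    )

    def __post_init__(self) -> None:
        if self.n_regions % 2:
            raise ValueError("n_regions must be even (half per hemisphere)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        probs = [self.base_keep, self.left_deficit, self.pos_prob_high,
                 self.pos_prob_low, self.neg_prob_high, self.neg_prob_low]
        probs += [p for pair in self.contrast_pos_probs.values() for p in pair]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.left_deficit <= 1.0:
            raise ValueError("left_deficit must be in (0, 1]")


def default_config(seed: int = 0, n_per_group: int = 30) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, n_per_group=n_per_group)


def small_config(seed: int = 0, n_per_group: int = 30) -> SyntheticConfig:
    """Reduced configuration for replicate studies (calibration/power loops)."""
    return SyntheticConfig(
        seed=seed,
        n_per_group=n_per_group,
        n_regions=20,
        voxel_size_mm=3.0,
        hemisphere_gap_vox=14,
        min_bundle_length_mm=34.0,
        tube_radius_mm=3.5,
        n_intra_per_hemisphere=5,
        n_inter=2,
        n_hubs=4,
        fibers_per_bundle=(6, 10),
        n_pos_high=4,
        n_neg_high=6,
    )


def null_config(base: SyntheticConfig | None = None, seed: int = 0,
                n_per_group: int = 30) -> SyntheticConfig:
    """No-effect configuration: no left deficit, exchangeable tumor sizes and
    POS probabilities, aphasia level pure noise."""
    if base is None:
        base = small_config(seed=seed, n_per_group=n_per_group)
    return replace(
        base,
        seed=seed,
        left_deficit=1.0,
        tumor_mean={"NA": base.tumor_mean["NA"], "GIA": base.tumor_mean["NA"]},
        tumor_sd={"NA": base.tumor_sd["NA"], "GIA": base.tumor_sd["NA"]},
        contrast_pos_probs={"NA": (0.2, 0.4), "GIA": (0.2, 0.4)},
    )


# ---------------------------------------------------------------------------
# Parcellation


def make_parcellation(config: SyntheticConfig) -> Parcellation:
    """Blockwise bilateral parcellation: ``n_regions`` contiguous labeled
    blocks, exactly half with centroid left of the midline."""
    m = config.n_regions // 2
    bx, by, bz = config.block_shape
    gz = max(1, int(np.floor(np.sqrt(m))))
    gy = int(np.ceil(m / gz))
    need = (2 * (bx + 1) + config.hemisphere_gap_vox, gy * by + 2, gz * bz + 2)
    if config.grid_shape is None:
        nx, ny, nz = need
    else:
        nx, ny, nz = config.grid_shape
        if nx < need[0] or ny < need[1] or nz < need[2]:
            raise ValueError(
                f"grid {config.grid_shape} too small to pack {config.n_regions} "
                f"blocks of {config.block_shape}; need at least {need}"
            )
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    rows = []
    for side, hemi in enumerate("LR"):
        x0 = 1 if hemi == "L" else nx - 1 - bx
        for local in range(m):
            region_id = local + 1 + side * m
            iy, iz = local % gy, local // gy
            y0, z0 = 1 + iy * by, 1 + iz * bz
            labels[x0:x0 + bx, y0:y0 + by, z0:z0 + bz] = region_id
            rows.append({"id": region_id, "name": f"{hemi}{local + 1:02d}",
                         "hemisphere": hemi})
    table = pd.DataFrame(rows)
    return Parcellation(labels=VolumeGrid(data=labels, affine=affine), table=table)


def region_centroids(parcellation: Parcellation) -> dict[int, np.ndarray]:
    """World-mm centroid of every labeled region."""
    data = parcellation.labels.data
    out: dict[int, np.ndarray] = {}
    for region_id in parcellation.node_ids:
        vox = np.argwhere(data == region_id)
        out[int(region_id)] = parcellation.labels.voxel_to_world(vox).mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Bundle wiring and phantom


def default_bundles(config: SyntheticConfig, parcellation: Parcellation,
                    rng: np.random.Generator | None = None) -> tuple[BundleSpec, ...]:
    """Deterministic (seeded) default wiring.

    Intra-hemispheric bundles are drawn from the complete graph over
    ``n_hubs`` hub regions spread evenly across each hemisphere (a dense
    language-network core — the clustering gives the networks nonzero local
    efficiency); the right hemisphere mirrors the left.  Each intra bundle
    bows into the interhemispheric gap at its own depth so the FA tubes stay
    spatially separated outside the hub blocks.  Interhemispheric bundles
    connect mirrored hub pairs; the first of them anchors the FA spectrum at
    ``peak_fa_max`` so the subject-level FAT_max does not depend on which
    left bundles a subject retains.
    """
    if rng is None:
        rng = _rng(config.seed, _SS_BUNDLES)
    m = config.n_regions // 2
    k = min(config.n_hubs, m)
    hubs = [int(s) + 1 for s in np.unique(np.round(np.linspace(0, m - 1, k)).astype(int))]
    pairs = [(a, b) for i, a in enumerate(hubs) for b in hubs[i + 1:]]
    if len(pairs) < config.n_intra_per_hemisphere:
        raise ValueError(
            f"{len(pairs)} hub pairs available but n_intra_per_hemisphere="
            f"{config.n_intra_per_hemisphere}; increase n_hubs"
        )
    pick = sorted(int(i) for i in
                  rng.choice(len(pairs), size=config.n_intra_per_hemisphere, replace=False))
    lo, hi = config.fibers_per_bundle
    gap_mm = config.hemisphere_gap_vox * config.voxel_size_mm
    lanes = np.linspace(6.0, 0.45 * gap_mm, config.n_intra_per_hemisphere)
    specs: list[BundleSpec] = []
    # interhemispheric first: the anchor bundle must never be group-droppable
    inter_hubs = rng.choice(hubs, size=min(config.n_inter, len(hubs)), replace=False)
    for j, a in enumerate(sorted(int(r) for r in inter_hubs)):
        peak = config.peak_fa_max if j == 0 else float(
            rng.uniform(config.peak_fa_min, config.peak_fa_max))
        specs.append(BundleSpec(a, a + m, int(rng.integers(lo, hi)), round(peak, 3),
                                config.fa_jitter, 0.0))
    for lane, idx in zip(lanes, pick):
        a, b = pairs[idx]
        for base, sign in ((0, +1.0), (m, -1.0)):  # left bundle + mirrored right twin
            peak = float(rng.uniform(config.peak_fa_min, config.peak_fa_max))
            specs.append(BundleSpec(a + base, b + base, int(rng.integers(lo, hi)),
                                    round(peak, 3), config.fa_jitter,
                                    sign * round(float(lane), 2)))
    return tuple(specs)


def _bundle_centerline(
    p0: np.ndarray,
    p1: np.ndarray,
    bow_mm: float,
    spacing_mm: float,
    min_length_mm: float = 0.0,
) -> np.ndarray:
    """Quadratic-Bezier centerline bowing along x, resampled at even arc spacing.

    The bow is deepened if needed until the arc length reaches
    ``min_length_mm`` (so every bundle can clear the fiber length threshold).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    h = float(bow_mm)
    for _ in range(64):
        ctrl = 0.5 * (p0 + p1) + np.array([2.0 * h, 0.0, 0.0])
        t = np.linspace(0.0, 1.0, 256)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = float(seg.sum())
        if arc >= min_length_mm:
            break
        h = (abs(h) + 4.0) * (1.0 if h >= 0 else -1.0)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(arc / spacing_mm)) + 1)
    s = np.linspace(0.0, arc, n)
    return np.column_stack([np.interp(s, cum, pts[:, d]) for d in range(3)])


def make_phantom(
    config: SyntheticConfig,
    parcellation: Parcellation,
    bundles: tuple[BundleSpec, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> Phantom:
    """Realize bundles as FA tubes with tangent direction fields.

    Inside a tube FA = peak +/- jitter; outside every tube FA is 0 and the
    direction field is the zero vector (which also terminates the tracker).
    Overlapping tubes are allowed; the later bundle overwrites and a warning
    is logged.
    """
    if bundles is None:
        bundles = config.bundles or default_bundles(config, parcellation)
    if rng is None:
        rng = _rng(config.seed, _SS_PHANTOM)
    vol = parcellation.labels
    centroids = region_centroids(parcellation)
    fa = np.zeros(vol.shape, dtype=float)
    directions = np.zeros(vol.shape + (3,), dtype=float)
    all_vox = np.argwhere(np.ones(vol.shape, dtype=bool))
    voxel_centers = vol.voxel_to_world(all_vox)
    radius = config.tube_radius_mm
    overlap = 0
    out_bundles: list[Bundle | None] = [None] * len(bundles)
    # rasterize in ascending peak-FA order: where tubes cross, the higher-FA
    # tube keeps its identity and low-FA tubes get harmless high spikes
    for b_idx in np.argsort([spec.peak_fa for spec in bundles], kind="stable"):
        spec = bundles[b_idx]
        if spec.region_a not in centroids or spec.region_b not in centroids:
            raise ValueError(f"bundle references unknown region: {spec}")
        p0, p1 = centroids[spec.region_a], centroids[spec.region_b]
        dense = _bundle_centerline(p0, p1, spec.bow_mm, 1.0, config.min_bundle_length_mm)
        tree = cKDTree(dense)
        box = np.all((voxel_centers >= dense.min(axis=0) - radius)
                     & (voxel_centers <= dense.max(axis=0) + radius), axis=1)
        dist, nearest = tree.query(voxel_centers[box])
        inside = dist <= radius
        idx = all_vox[box][inside]
        overlap += int((fa[idx[:, 0], idx[:, 1], idx[:, 2]] > 0).sum())
        fa[idx[:, 0], idx[:, 1], idx[:, 2]] = np.clip(
            spec.peak_fa + rng.normal(0.0, spec.fa_jitter, size=len(idx)), 0.01, 1.0
        )
        tangents = np.gradient(dense, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        directions[idx[:, 0], idx[:, 1], idx[:, 2]] = tangents[nearest[inside]]
        out_bundles[b_idx] = Bundle(
            spec=spec,
            centerline=_bundle_centerline(p0, p1, spec.bow_mm,
                                          config.fiber_point_spacing_mm,
                                          config.min_bundle_length_mm),
        )
    if overlap:
        logger.warning("phantom tubes overlap in %d voxel(s); higher-FA bundles win",
                       overlap)
    return Phantom(fa=VolumeGrid(data=fa, affine=vol.affine.copy()),
                   directions=directions, bundles=out_bundles)  # type: ignore[arg-type]


def apply_lesion(fa_volume: VolumeGrid, center_mm, radius_mm: float) -> VolumeGrid:
    """Zero FA inside a sphere (stress-tests tracking around a lesion)."""
    vox = np.argwhere(np.ones(fa_volume.shape, dtype=bool))
    world = fa_volume.voxel_to_world(vox)
    inside = np.linalg.norm(world - np.asarray(center_mm, dtype=float), axis=1) <= radius_mm
    data = fa_volume.data.copy()
    sel = vox[inside]
    data[sel[:, 0], sel[:, 1], sel[:, 2]] = 0.0
    return VolumeGrid(data=data, affine=fa_volume.affine.copy())


# ---------------------------------------------------------------------------
# Streamlines and cohorts


def make_streamlines(
    phantom: Phantom,
    bundles: list[Bundle],
    rng: np.random.Generator,
    n_fibers: list[int] | None = None,
    fa_scale: float = 1.0,
    jitter_mm: float = 0.6,
) -> list[FiberRecord]:
    """Jittered copies of bundle centerlines with phantom-sampled per-point FA.

    Each fiber is the centerline plus a constant perpendicular offset and
    small per-point noise; FA is trilinearly sampled from the phantom and
    multiplied by the subject factor ``fa_scale``.
    """
    all_points: list[np.ndarray] = []
    for b_idx, bundle in enumerate(bundles):
        k = bundle.spec.n_fibers if n_fibers is None else n_fibers[b_idx]
        if k <= 0:
            continue
        line = bundle.centerline
        tangent = line[-1] - line[0]
        tangent = tangent / np.linalg.norm(tangent)
        for _ in range(k):
            offset = rng.normal(0.0, jitter_mm, size=3)
            offset -= (offset @ tangent) * tangent  # keep endpoints in their blocks
            all_points.append(line + offset
                              + rng.normal(0.0, 0.15 * jitter_mm, size=line.shape))
    if not all_points:
        return []
    fa_flat = np.clip(
        sample_fa_along(np.concatenate(all_points), phantom.fa) * fa_scale, 0.0, 1.0)
    fibers: list[FiberRecord] = []
    start = 0
    for pts in all_points:
        fibers.append(FiberRecord(points=pts, fa=fa_flat[start:start + len(pts)]))
        start += len(pts)
    return fibers


@dataclass
class CohortData:
    """A generated cohort: records plus per-subject fibers and region sets."""

    config: SyntheticConfig
    parcellation: Parcellation
    phantom: Phantom
    records: pd.DataFrame  # subject_id, group, tumor_size_cm3, aphasia_level, n_pos, n_neg
    fibers: dict[str, list[FiberRecord]]
    stim_maps: dict[str, StimulationMap]
    ground_truth: dict[str, dict]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


def _region_probs(config: SyntheticConfig, left_ids: np.ndarray,
                  wired_left: list[int], group: str) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-region POS/NEG membership probabilities for one group."""
    pos = np.full(len(left_ids), config.pos_prob_low)
    neg = np.full(len(left_ids), config.neg_prob_low)
    order = wired_left + [int(r) for r in left_ids if int(r) not in wired_left]
    index = {int(r): i for i, r in enumerate(left_ids)}
    pos_high = order[: config.n_pos_high]
    neg_high = order[: config.n_neg_high]
    for r in pos_high:
        pos[index[r]] = config.pos_prob_high
    for r in neg_high:
        neg[index[r]] = config.neg_prob_high
    contrast = order[config.n_pos_high: config.n_pos_high + 2]
    for r, p in zip(contrast, config.contrast_pos_probs[group]):
        pos[index[r]] = p
    return pos, neg, contrast


def make_cohort(config: SyntheticConfig) -> CohortData:
    """Generate the full two-group cohort (records, fibers, stimulation sets).

    Fixed seed => bit-identical output; per-subject substreams are keyed by
    subject index, so one subject's data does not depend on cohort size or
    ordering.
    """
    parcellation = make_parcellation(config)
    bundle_specs = config.bundles or default_bundles(config, parcellation)
    phantom = make_phantom(config, parcellation, bundle_specs)
    bundles = phantom.bundles
    m = config.n_regions // 2
    left_ids = parcellation.left_ids
    left_intra = np.array([
        b.spec.region_a <= m and b.spec.region_b <= m for b in bundles
    ])
    n_left_bundles = int(left_intra.sum())
    wired_left = sorted({b.spec.region_a for b in bundles if b.spec.region_a <= m}
                        | {b.spec.region_b for b in bundles if b.spec.region_b <= m})

    n_total = 2 * config.n_per_group
    rows, fibers_by_subject, maps_by_subject, truth = [], {}, {}, {}
    latents = np.zeros(n_total)
    p_drop = 1.0 - config.left_deficit
    for i in range(n_total):
        group = GROUPS[0] if i < config.n_per_group else GROUPS[1]
        sid = f"S{i + 1:03d}"
        rng = _rng(config.seed, _SS_SUBJECT, i)
        fa_scale = float(np.clip(1.0 + rng.normal(0.0, config.fatmax_scale_sd), 0.6, 1.4))
        keep = rng.random(len(bundles)) < config.base_keep
        u_deficit = rng.random(len(bundles))  # drawn for every subject: same stream shape
        n_deficit_drops = 0
        if group == "GIA" and p_drop > 0:
            drop = left_intra & (u_deficit < p_drop)
            n_deficit_drops = int(drop.sum())
            keep &= ~drop
        n_fibers = [int(rng.poisson(b.spec.n_fibers)) if keep[j] else 0
                    for j, b in enumerate(bundles)]
        fibers_by_subject[sid] = make_streamlines(
            phantom, bundles, rng, n_fibers=n_fibers, fa_scale=fa_scale,
            jitter_mm=config.fiber_jitter_mm,
        )
        tumor = _truncated_normal(rng, config.tumor_mean[group], config.tumor_sd[group])
        # latent aphasia severity: standardized deficit-drop count + noise
        if group == "GIA":
            if p_drop > 0 and n_left_bundles > 0:
                z = (n_deficit_drops - n_left_bundles * p_drop) / np.sqrt(
                    n_left_bundles * p_drop * (1 - p_drop))
            else:
                z = 0.0
            latents[i] = config.aphasia_signal_weight * z + rng.normal(0.0, 1.0)
        pos_p, neg_p, contrast = _region_probs(config, left_ids, wired_left, group)
        pos_set = frozenset(int(r) for r in left_ids[rng.random(len(left_ids)) < pos_p])
        neg_set = frozenset(int(r) for r in left_ids[rng.random(len(left_ids)) < neg_p])
        maps_by_subject[sid] = StimulationMap(subject_id=sid, pos_regions=pos_set,
                                              neg_regions=neg_set)
        truth[sid] = {
            "kept_bundles": np.flatnonzero(keep).tolist(),
            "n_deficit_drops": n_deficit_drops,
            "fa_scale": fa_scale,
            "contrast_regions": contrast,
        }
        rows.append({"subject_id": sid, "group": group, "tumor_size_cm3": tumor,
                     "aphasia_level": 0, "n_pos": len(pos_set), "n_neg": len(neg_set)})

    records = pd.DataFrame(rows)
    # GIA aphasia levels by within-group latent quantile: monotone in the
    # deficit-driven severity, uniform over 1..n_levels, pure noise under null
    gia_idx = np.arange(config.n_per_group, n_total)
    order = gia_idx[np.argsort(latents[gia_idx], kind="stable")]
    n_gia = len(gia_idx)
    for rank, subj_i in enumerate(order):
        level = 1 + (rank * config.n_aphasia_levels) // n_gia
        records.loc[subj_i, "aphasia_level"] = level
    records["aphasia_level"] = records["aphasia_level"].astype(int)

    return CohortData(config=config, parcellation=parcellation, phantom=phantom,
                      records=records, fibers=fibers_by_subject,
                      stim_maps=maps_by_subject, ground_truth=truth)


def stimulation_points_for(
    cohort: CohortData, subject_id: str, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Materialize a subject's region sets as world-mm stimulation points.

    One point per mapped region, placed at the region centroid with a small
    jitter; used when writing file-based cohort inputs so the file pipeline
    reconstructs the same POS/NEG sets through voxel assignment.
    """
    if rng is None:
        rng = _rng(cohort.config.seed, 3, int(subject_id.lstrip("S")))
    centroids = region_centroids(cohort.parcellation)
    stim = cohort.stim_maps[subject_id]
    rows = []
    for polarity, regions in (("POS", stim.pos_regions), ("NEG", stim.neg_regions)):
        for r in sorted(regions):
            xyz = centroids[r] + rng.normal(0.0, 0.5, size=3)
            rows.append({"subject_id": subject_id, "x": xyz[0], "y": xyz[1],
                         "z": xyz[2], "polarity": polarity})
    return pd.DataFrame(rows, columns=["subject_id", "x", "y", "z", "polarity"])
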