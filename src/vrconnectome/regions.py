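"""Parcellation nodes and nTMS stimulation-site mapping.

A parcellation is an integer label volume plus a region table (id, name,
hemisphere).  Stimulation sites arrive as world-mm points flagged POS
(naming error under stimulation) or NEG; each point is assigned to the
region whose voxel contains it, falling back to the nearest labeled voxel
center within a search radius — cortical sites often sit just outside the
labeled gray matter after registration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import VolumeGrid, ValidationError, labels_at

__all__ = [
    "Parcellation",
    "StimulationMap",
    "assign_point",
    "assign_points",
    "build_stimulation_map",
    "intragroup_proportions",
]

logger = logging.getLogger(__name__)

UNASSIGNED = 0


@dataclass
class Parcellation:
    """Label volume + region table defining the network nodes."""

    labels: VolumeGrid
    table: pd.DataFrame  # columns: id, name, hemisphere (L|R)

    def __post_init__(self) -> None:
        self.labels.validate_labels()
        required = {"id", "name", "hemisphere"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"region table needs columns {sorted(required)}")
        ids = self.table["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("region ids must be unique")
        if (ids < 1).any():
            raise ValidationError("region ids must be >= 1")
        if not set(self.table["hemisphere"]).issubset({"L", "R"}):
            raise ValidationError("hemisphere must be 'L' or 'R'")
        present = np.unique(self.labels.data)
        present = present[present != 0]
        unknown = np.setdiff1d(present, ids)
        if unknown.size:
            raise ValidationError(f"voxel labels {unknown.tolist()} missing from region table")
        self._tree: cKDTree | None = None
        self._tree_labels: np.ndarray | None = None
        self._node_ids = np.sort(ids)
        self._hemi_ids = {
            h: np.sort(self.table.loc[self.table["hemisphere"] == h, "id"].to_numpy())
            for h in ("L", "R")
        }

    @property
    def node_ids(self) -> np.ndarray:
        return self._node_ids

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        return self._hemi_ids[hemisphere]

    @property
    def left_ids(self) -> np.ndarray:
        return self._hemi_ids["L"]

    @property
    def right_ids(self) -> np.ndarray:
        return self._hemi_ids["R"]

    def _kdtree(self) -> tuple[cKDTree, np.ndarray]:
        if self._tree is None:
            vox = np.argwhere(self.labels.data != 0)
            world = self.labels.voxel_to_world(vox)
            self._tree = cKDTree(world)
            self._tree_labels = self.labels.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        return self._tree, self._tree_labels  # type: ignore[return-value]


def assign_point(
    point_mm: np.ndarray, parcellation: Parcellation, search_radius_mm: float = 5.0
) -> int:
    """Region id for one world-mm point, or 0 (unassigned).

    The containing voxel's label wins; if background, the nearest labeled
    voxel center within ``search_radius_mm`` (distance ties broken by the
    smallest region id); otherwise unassigned.
    """
    return int(assign_points(np.asarray(point_mm, dtype=float)[None, :],
                             parcellation, search_radius_mm)[0])


def assign_points(
    points_mm: np.ndarray, parcellation: Parcellation, search_radius_mm: float = 5.0
) -> np.ndarray:
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if not np.all(np.isfinite(points_mm)):
        raise ValidationError("stimulation points must be finite")
    out = labels_at(points_mm, parcellation.labels).astype(int)
    if search_radius_mm <= 0:
        return out
    miss = np.flatnonzero(out == UNASSIGNED)
    if miss.size == 0:
        return out
    tree, tree_labels = parcellation._kdtree()
    for i in miss:
        idx = tree.query_ball_point(points_mm[i], r=search_radius_mm)
        if not idx:
            continue
        cand = np.asarray(idx)
        dists = np.linalg.norm(tree.data[cand] - points_mm[i], axis=1)
        dmin = dists.min()
        nearest = cand[dists <= dmin + 1e-9]
        out[i] = int(tree_labels[nearest].min())  # smallest id wins ties
    return out


@dataclass
class StimulationMap:
    """Per-subject POS/NEG region sets derived from stimulation points."""

    subject_id: str
    pos_regions: frozenset[int] = field(default_factory=frozenset)
    neg_regions: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_pos(self) -> int:
        return len(self.pos_regions)

    @property
    def n_neg(self) -> int:
        return len(self.neg_regions)


def build_stimulation_map(
    points: pd.DataFrame,
    parcellation: Parcellation,
    search_radius_mm: float = 5.0,
    pos_precedence: bool = False,
    subject_id: str | None = None,
) -> StimulationMap:
    """Assign a subject's stimulation points to regions and collect the sets.

    A region is positively mapped iff at least one POS point assigns to it
    (likewise NEG); by default a region may appear in both sets, with
    ``pos_precedence`` removing POS regions from the NEG set.  Unassigned
    points are dropped with a logged count.
    """
    if subject_id is None:
        subject_id = str(points["subject_id"].iloc[0]) if len(points) else ""
    if len(points) == 0:
        return StimulationMap(subject_id=subject_id)
    coords = points[["x", "y", "z"]].to_numpy(dtype=float)
    labels = assign_points(coords, parcellation, search_radius_mm)
    dropped = int((labels == UNASSIGNED).sum())
    if dropped:
        logger.info("subject %s: %d stimulation point(s) unassigned, dropped",
                    subject_id, dropped)
    pol = points["polarity"].to_numpy()
    pos = frozenset(int(r) for r in labels[(pol == "POS") & (labels != UNASSIGNED)])
    neg = frozenset(int(r) for r in labels[(pol == "NEG") & (labels != UNASSIGNED)])
    if pos_precedence:
        neg = neg - pos
    return StimulationMap(subject_id=subject_id, pos_regions=pos, neg_regions=neg)


def intragroup_proportions(
    maps: list[StimulationMap],
    groups: list[str],
    highlight_min_count: int = 20,
) -> pd.DataFrame:
    """Per-region, per-group proportion of subjects positively/negatively mapped.

    Returns a tidy table (region, group, polarity, count, proportion,
    highlighted) where ``highlighted`` flags regions mapped in at least
    ``highlight_min_count`` subjects of that group.
    """
    if len(maps) != len(groups):
        raise ValueError("one group label per stimulation map required")
    rows = []
    group_names = sorted(set(groups))
    for g in group_names:
        members = [m for m, gg in zip(maps, groups) if gg == g]
        if not members:
            continue
        n = len(members)
        regions = sorted(set().union(*(m.pos_regions | m.neg_regions for m in members)))
        for region in regions:
            for polarity, attr in (("POS", "pos_regions"), ("NEG", "neg_regions")):
                count = sum(1 for m in members if region in getattr(m, attr))
                rows.append({
                    "region": region,
                    "group": g,
                    "polarity": polarity,
                    "count": count,
                    "proportion": count / n,
                    "highlighted": count >= highlight_min_count,
                })
    return pd.DataFrame(rows, columns=["region", "group", "polarity", "count",
                                       "proportion", "highlighted"])
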