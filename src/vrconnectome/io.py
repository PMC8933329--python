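"""On-disk formats and coordinate conventions.

Every cross-module exchange of spatial data is in world millimetres (RAS).
Voxel indices are 0-based; world -> voxel goes through the inverse affine,
with nearest-voxel rounding for label lookup and trilinear interpolation for
FA sampling.  Volumes are NIfTI-1, streamlines TRK/TCK, tables CSV, matrix
exports CSV or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

__all__ = [
    "FormatError",
    "ValidationError",
    "VolumeGrid",
    "read_volume",
    "write_volume",
    "read_streamlines",
    "write_streamlines",
    "sample_fa_along",
    "labels_at",
    "read_points",
    "write_points",
    "read_cohort_table",
    "write_cohort_table",
    "write_matrix",
    "read_matrix",
    "matrix_to_json",
    "write_matrix_json",
    "write_metrics_table",
    "read_metrics_table",
]

POLARITIES = ("POS", "NEG")


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant (e.g. FA outside [0, 1])."""


@dataclass
class VolumeGrid:
    """A 3-D scalar or integer-label volume on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Scalar FA values in [0, 1] or non-negative integer labels
        (0 = background).
    affine : ndarray, shape (4, 4)
        Voxel-to-world (RAS, mm) map; must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        self._inv_affine: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def inv_affine(self) -> np.ndarray:
        if self._inv_affine is None:
            self._inv_affine = np.linalg.inv(self.affine)
        return self._inv_affine

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = self.inv_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(voxels, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def validate_fa(self) -> "VolumeGrid":
        """Check FA range; raises listing the first offending voxel index."""
        bad = np.argwhere((self.data < 0) | (self.data > 1))
        if bad.size:
            raise ValidationError(
                f"FA outside [0, 1] at voxel index {tuple(int(i) for i in bad[0])} "
                f"(value {float(self.data[tuple(bad[0])]):g})"
            )
        return self

    def validate_labels(self) -> "VolumeGrid":
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError(f"label volume must be integer, got {self.data.dtype}")
        if self.data.min() < 0:
            bad = np.argwhere(self.data < 0)[0]
            raise ValidationError(f"negative label at voxel index {tuple(int(i) for i in bad)}")
        return self


def read_volume(path: str | Path, kind: str | None = None) -> VolumeGrid:
    """Read a NIfTI-1 volume.

    ``kind`` may be ``"fa"`` (enforces FA in [0, 1]) or ``"label"`` (enforces
    3-D integer data).  The affine is the header's best transform; data
    orientation is left untouched.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if kind == "label":
        if data.ndim != 3:
            raise FormatError(f"label volume must be 3-D, got {data.ndim}-D: {path}")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValidationError(f"non-integer labels in {path}")
            data = rounded.astype(np.int32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    vol = VolumeGrid(data=data, affine=np.asarray(img.affine))
    if kind == "fa":
        vol.validate_fa()
    elif kind == "label":
        vol.validate_labels()
    return vol


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    data = vol.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16 if data.max() < 2**15 else np.int32)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# Streamlines


def read_streamlines(path: str | Path) -> list[np.ndarray]:
    """Read a TRK/TCK tractogram as a list of (N_i, 3) world-mm point chains.

    TRK voxel-space coordinates are mapped to world mm via the header
    transform.  Chains with fewer than two points are dropped.  An empty file
    yields an empty list.
    """
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise FormatError(f"cannot parse tractogram {path}: {exc}") from exc
    return [np.asarray(s, dtype=float) for s in tf.streamlines if len(s) >= 2]


def write_streamlines(
    streamlines: list[np.ndarray],
    path: str | Path,
    reference: VolumeGrid | None = None,
) -> None:
    """Write world-mm streamlines to TRK or TCK (chosen by extension).

    For TRK a ``reference`` volume supplies the header geometry; without one
    an identity-affine header is written.
    """
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix.lower() == ".tck":
        nib.streamlines.save(tractogram, str(path))
        return
    header = {}
    if reference is not None:
        header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = reference.affine.astype(np.float32)
        header[nib.streamlines.trk.Field.VOXEL_SIZES] = np.sqrt(
            (reference.affine[:3, :3] ** 2).sum(axis=0)
        ).astype(np.float32)
        header[nib.streamlines.trk.Field.DIMENSIONS] = np.asarray(reference.shape, dtype=np.int16)
    nib.streamlines.save(tractogram, str(path), header=header)


def sample_fa_along(streamline: np.ndarray, fa_volume: VolumeGrid) -> np.ndarray:
    """Trilinearly sample FA at each streamline point; out of bounds -> 0."""
    vox = fa_volume.world_to_voxel(streamline)
    return map_coordinates(
        fa_volume.data.astype(float), vox.T, order=1, mode="constant", cval=0.0
    )


def labels_at(points_mm: np.ndarray, label_volume: VolumeGrid) -> np.ndarray:
    """Nearest-voxel label lookup; points outside the grid get label 0."""
    vox = np.rint(label_volume.world_to_voxel(points_mm)).astype(int)
    shape = np.asarray(label_volume.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(len(vox), dtype=label_volume.data.dtype)
    if inside.any():
        v = vox[inside]
        out[inside] = label_volume.data[v[:, 0], v[:, 1], v[:, 2]]
    return out


# ---------------------------------------------------------------------------
# Point / cohort tables

_POINT_COLS = ["subject_id", "x", "y", "z", "polarity"]


def read_points(path: str | Path) -> pd.DataFrame:
    """Read a stimulation-point table (subject_id, x, y, z [mm], polarity)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _POINT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"point table {path} missing columns {missing}")
    df = df[_POINT_COLS].copy()
    bad = ~df["polarity"].isin(POLARITIES)
    if bad.any():
        raise ValidationError(
            f"invalid polarity value {df.loc[bad, 'polarity'].iloc[0]!r} in {path}"
        )
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError(f"non-finite coordinates in {path}")
    return df


def write_points(df: pd.DataFrame, path: str | Path) -> None:
    df[_POINT_COLS].to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the no-aphasia group label "NA" must not become NaN
    df = pd.read_csv(path, dtype={"subject_id": str},
                     keep_default_na=False, na_values=[""])
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"cohort table {path} missing column {col!r}")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrices and metric tables


def write_matrix(matrix: np.ndarray, node_ids, path: str | Path) -> None:
    """Write a square matrix as CSV: header row of node ids, one row per node."""
    df = pd.DataFrame(np.asarray(matrix), index=list(node_ids), columns=list(node_ids))
    df.to_csv(path, index=True, index_label="node")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path, index_col=0)
    node_ids = [int(c) for c in df.columns]
    return df.to_numpy(), node_ids


def matrix_to_json(matrix: np.ndarray, node_ids) -> str:
    payload = {
        "node_ids": [int(i) for i in node_ids],
        "matrix": np.asarray(matrix).tolist(),
    }
    return json.dumps(payload)


def write_matrix_json(matrix: np.ndarray, node_ids, path: str | Path) -> None:
    Path(path).write_text(matrix_to_json(matrix, node_ids))


def write_metrics_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})
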