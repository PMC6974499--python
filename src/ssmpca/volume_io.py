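"""Reading, writing and vectorizing neuroimaging volumes.

Scans are NIfTI volumes of nonnegative tracer-uptake intensities, all
assumed already spatially normalized to a common grid (same shape and
affine).  A cohort is held in memory as a :class:`VolumeSet`: a dense
subject x voxel matrix plus the boolean brain mask that defines which
grid voxels the matrix columns refer to.

Voxel linearization is row-major (C order) over the 3D grid, so masks,
weight maps and patterns are portable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DegenerateMaskError, DimensionError

#: tolerance for deciding two affines describe the same space
AFFINE_ATOL = 1e-4

#: labels accepted in the ``group`` metadata column
VALID_GROUPS = ("control", "patient", "other")


@dataclass
class VolumeSet:
    """A cohort of vectorized scans with per-subject metadata.

    Parameters
    ----------
    data
        ``(n_subjects, n_voxels)`` matrix of intensities; column ``j``
        is the ``j``-th True voxel of ``mask`` in C order.
    mask
        Boolean 3D grid marking which voxels the columns represent.
    affine
        4x4 voxel-to-world transform shared by all subjects.
    subject_ids, group_labels, camera_labels
        Per-subject metadata; groups must be control/patient/other.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]
    group_labels: np.ndarray
    camera_labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        self.camera_labels = np.asarray(self.camera_labels, dtype=object)
        self.subject_ids = list(self.subject_ids)
        n = self.data.shape[0]
        if not (len(self.subject_ids) == len(self.group_labels) == len(self.camera_labels) == n):
            raise DimensionError(
                f"metadata lengths must equal the {n} data rows"
            )
        if self.mask.ndim != 3:
            raise DimensionError("mask must be a 3D grid")
        if self.data.ndim != 2 or self.data.shape[1] != int(self.mask.sum()):
            raise DimensionError(
                f"data has {self.data.shape[1]} columns but mask selects "
                f"{int(self.mask.sum())} voxels"
            )
        if self.affine.shape != (4, 4):
            raise DimensionError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contain non-finite values")
        bad = set(self.group_labels) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)

    def subset(self, rows: Sequence[int], subject_ids: Sequence[str] | None = None) -> "VolumeSet":
        """Row-indexed copy (with replacement allowed, for resampling)."""
        rows = np.asarray(rows, dtype=int)
        ids = list(subject_ids) if subject_ids is not None else [
            self.subject_ids[i] for i in rows
        ]
        return replace(
            self,
            data=self.data[rows],
            subject_ids=ids,
            group_labels=self.group_labels[rows],
            camera_labels=self.camera_labels[rows],
        )


@dataclass
class VOIAtlas:
    """Labeled integer volume naming anatomical regions (0 = background)."""

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionError("atlas labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels).tolist())
        missing = [lab for lab in self.names if lab not in present]
        if missing:
            raise ValueError(f"named labels absent from grid: {missing}")


def _read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def load_volume_set(paths: Sequence[str | Path], metadata: pd.DataFrame) -> VolumeSet:
    """Load scans into a :class:`VolumeSet` with an all-true mask.

    ``metadata`` needs columns ``subject_id``, ``group``, ``camera``;
    if it has a ``path`` column, rows are matched to ``paths`` by file
    name, otherwise rows must align with ``paths`` one-to-one.
    """
    required = {"subject_id", "group", "camera"}
    if not required.issubset(metadata.columns):
        raise KeyError(f"metadata must have columns {sorted(required)}")
    paths = [Path(p) for p in paths]
    if "path" in metadata.columns:
        by_path = {Path(p).name: row for p, (_, row) in zip(metadata["path"], metadata.iterrows())}
        try:
            rows = [by_path[p.name] for p in paths]
        except KeyError as exc:
            raise KeyError(f"metadata has no row for volume {exc.args[0]!r}") from None
    else:
        if len(metadata) != len(paths):
            raise KeyError(
                f"metadata has {len(metadata)} rows for {len(paths)} volumes"
            )
        rows = [row for _, row in metadata.iterrows()]

    volumes, affine0, shape0 = [], None, None
    for p in paths:
        vol, aff = _read_volume(p)
        if vol.ndim != 3:
            raise DimensionError(f"{p.name}: expected a 3D volume, got {vol.ndim}D")
        if shape0 is None:
            shape0, affine0 = vol.shape, aff
        else:
            if vol.shape != shape0:
                raise DimensionError(
                    f"{p.name}: shape {vol.shape} differs from {shape0}"
                )
            if not np.allclose(aff, affine0, atol=AFFINE_ATOL):
                raise DimensionError(f"{p.name}: affine differs beyond tolerance")
        if not np.all(np.isfinite(vol)):
            raise ValueError(f"{p.name}: non-finite voxel values")
        volumes.append(vol.ravel(order="C"))

    mask = np.ones(shape0, dtype=bool)
    return VolumeSet(
        data=np.vstack(volumes),
        mask=mask,
        affine=affine0,
        subject_ids=[str(r["subject_id"]) for r in rows],
        group_labels=np.array([str(r["group"]) for r in rows], dtype=object),
        camera_labels=np.array([str(r["camera"]) for r in rows], dtype=object),
    )


def volume_set_from_array(
    volumes: np.ndarray,
    affine: np.ndarray | None = None,
    subject_ids: Sequence[str] | None = None,
    group_labels: Sequence[str] | None = None,
    camera_labels: Sequence[str] | None = None,
) -> VolumeSet:
    """Build an unmasked VolumeSet from a ``(n, X, Y, Z)`` intensity array."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise DimensionError("expected a (n_subjects, X, Y, Z) array")
    n = volumes.shape[0]
    grid = volumes.shape[1:]
    return VolumeSet(
        data=volumes.reshape(n, -1, order="C").copy(),
        mask=np.ones(grid, dtype=bool),
        affine=np.eye(4) if affine is None else affine,
        subject_ids=list(subject_ids) if subject_ids is not None else [f"s{i:03d}" for i in range(n)],
        group_labels=np.array(
            list(group_labels) if group_labels is not None else ["control"] * n, dtype=object
        ),
        camera_labels=np.array(
            list(camera_labels) if camera_labels is not None else ["cam0"] * n, dtype=object
        ),
    )


def compute_brain_mask(vs: VolumeSet, threshold_fraction: float = 0.35) -> np.ndarray:
    """Intersection mask of per-subject relative-threshold masks.

    A voxel is kept iff, for every subject, its intensity exceeds
    ``threshold_fraction`` times that subject's maximum intensity — the
    usual convention for removing out-of-brain voxels from uptake
    images before the log transform.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if not vs.mask.all():
        raise ValueError("compute_brain_mask expects an unmasked VolumeSet")
    maxima = vs.data.max(axis=1, keepdims=True)
    keep = np.all(vs.data > threshold_fraction * maxima, axis=0)
    mask = keep.reshape(vs.grid_shape, order="C")
    if not mask.any():
        raise DegenerateMaskError(
            f"threshold_fraction={threshold_fraction} removes every voxel"
        )
    return mask


def apply_mask(vs: VolumeSet, mask: np.ndarray) -> VolumeSet:
    """Restrict data columns to ``mask`` voxels (must be a subset of the current mask)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vs.grid_shape:
        raise DimensionError(
            f"mask shape {mask.shape} does not match grid {vs.grid_shape}"
        )
    cur = vs.mask.ravel(order="C")
    new = mask.ravel(order="C")
    if np.any(new & ~cur):
        raise DimensionError("new mask selects voxels outside the current mask")
    if not new.any():
        raise DegenerateMaskError("mask selects zero voxels")
    sel = new[cur]
    return replace(vs, data=vs.data[:, sel], mask=mask)


def unmask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter per-voxel values back onto the 3D grid, zero outside the mask."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape[-1] != int(mask.sum()):
        raise DimensionError(
            f"{values.shape[-1]} values for {int(mask.sum())} mask voxels"
        )
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask] = values
    return vol


def export_weight_map(
    weights: np.ndarray, mask: np.ndarray, affine: np.ndarray, path: str | Path
) -> Path:
    """Write per-voxel weights as a NIfTI volume (zeros outside the mask)."""
    vol = unmask(weights, mask)
    nib.Nifti1Image(vol, np.asarray(affine, dtype=float)).to_filename(str(path))
    return Path(path)


def load_weight_map(path: str | Path, mask: np.ndarray) -> np.ndarray:
    """Read back the in-mask values of an exported weight map."""
    vol, _ = _read_volume(path)
    mask = np.asarray(mask, dtype=bool)
    if vol.shape != mask.shape:
        raise DimensionError("weight map grid does not match mask grid")
    return vol[mask]


def load_atlas(path: str | Path, names: Mapping[int, str] | pd.DataFrame) -> VOIAtlas:
    """Load a labeled NIfTI atlas; ``names`` maps label -> region name.

    A DataFrame with columns ``label`` and ``name`` is also accepted
    (the on-disk ``labels.tsv`` convention).
    """
    vol, _ = _read_volume(path)
    labels = np.rint(vol).astype(int)
    if isinstance(names, pd.DataFrame):
        names = {int(r["label"]): str(r["name"]) for _, r in names.iterrows()}
    return VOIAtlas(labels=labels, names=dict(names))


def save_atlas(atlas: VOIAtlas, affine: np.ndarray, path: str | Path, labels_path: str | Path) -> None:
    nib.Nifti1Image(atlas.labels.astype(np.int16), np.asarray(affine, dtype=float)).to_filename(str(path))
    pd.DataFrame(
        {"label": list(atlas.names), "name": [atlas.names[k] for k in atlas.names]}
    ).to_csv(labels_path, sep="\t", index=False)
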