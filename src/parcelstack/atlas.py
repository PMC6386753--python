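"""Parcellation atlases in three dialects and their ROI designs.

An atlas assigns voxels to regions of interest (ROIs) in one of three
dialects:

``labels``
    a single integer volume; 0 is background and every positive integer
    is one ROI (a hard, non-overlapping parcellation, e.g. anatomical
    atlases or bootstrap cluster atlases);
``maps``
    a 4D stack of continuous spatial weight maps, one per ROI (possibly
    overlapping networks, e.g. ICA/dictionary-learning components);
``spheres``
    a table of world-space seed coordinates; each ROI is the set of
    voxels whose centres lie within a fixed radius of the seed.

Conventions (fixed for this package): coordinates are world-space mm in
the image's affine frame, voxel indices are 0-based, and the background
label is exactly 0.

``resolve_design`` binds an atlas to a concrete analysis grid + mask,
resampling when grids differ (nearest-neighbour for label volumes, to
preserve label identity; trilinear for map stacks, to preserve continuous
weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nilearn import image as nl_image

from .exceptions import AtlasFormatError, DegenerateRoiError

DIALECTS = ("labels", "maps", "spheres")


@dataclass
class Atlas:
    """One parcellation in one of the three dialects.

    ``payload`` is a 3D integer label volume (labels), a 4D weight stack
    with one volume per ROI (maps), or an (n_rois, 3) array of seed
    coordinates in mm (spheres, with ``radius_mm`` set).
    """

    name: str
    dialect: str
    payload: np.ndarray
    affine: np.ndarray | None
    roi_names: list[str]
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "spheres":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise ValueError("spheres dialect requires radius_mm > 0")
        if self.n_rois < 1:
            raise AtlasFormatError(f"atlas {self.name!r} has no ROIs")
        if len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length must equal n_rois")

    @property
    def n_rois(self) -> int:
        if self.dialect == "labels":
            labels = np.unique(self.payload)
            return int((labels > 0).sum())
        if self.dialect == "maps":
            return self.payload.shape[3]
        return self.payload.shape[0]

    @property
    def labels_present(self) -> np.ndarray:
        """Sorted positive labels (labels dialect only)."""
        labels = np.unique(self.payload)
        return labels[labels > 0]


@dataclass
class RoiDesign:
    """An atlas resolved against a concrete grid and analysis mask.

    For labels/spheres, ``members[k]`` holds flat voxel indices (C order
    over the full grid) of ROI k. For maps, ``weights`` is an
    (n_rois, n_mask_voxels) matrix over the in-mask voxels listed in
    ``mask_indices``.
    """

    atlas: Atlas
    mask: np.ndarray
    members: list[np.ndarray] | None = None
    weights: np.ndarray | None = None
    mask_indices: np.ndarray | None = None
    roi_names: list[str] = field(default_factory=list)

    @property
    def dialect(self) -> str:
        return self.atlas.dialect

    @property
    def n_rois(self) -> int:
        return self.atlas.n_rois


def _default_names(n: int) -> list[str]:
    return [f"roi_{k}" for k in range(1, n + 1)]


def load_atlas(
    path_or_table,
    dialect: str,
    name: str | None = None,
    radius_mm: float | None = None,
    roi_names: list[str] | None = None,
) -> Atlas:
    """Load an atlas file in the declared dialect.

    ``labels``/``maps`` accept a NIfTI path or image; ``spheres`` accepts
    a TSV path (columns ``x y z`` and optionally ``name``) or a DataFrame,
    and requires ``radius_mm``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if name is None:
        name = Path(str(path_or_table)).stem if isinstance(
            path_or_table, (str, Path)
        ) else "atlas"

    if dialect == "spheres":
        if radius_mm is None:
            raise ValueError("spheres dialect requires radius_mm")
        if isinstance(path_or_table, pd.DataFrame):
            table = path_or_table
        else:
            table = pd.read_csv(path_or_table, sep="\t")
        if table.empty:
            raise AtlasFormatError("seed table is empty")
        missing = [c for c in ("x", "y", "z") if c not in table.columns]
        if missing:
            raise AtlasFormatError(f"seed table lacks columns {missing}")
        seeds = table[["x", "y", "z"]].to_numpy(dtype=float)
        names = (
            [str(v) for v in table["name"]]
            if "name" in table.columns
            else _default_names(len(table))
        )
        return Atlas(name, "spheres", seeds, None, roi_names or names,
                     radius_mm=radius_mm)

    img = (
        path_or_table
        if isinstance(path_or_table, nib.spatialimages.SpatialImage)
        else nib.load(str(path_or_table))
    )
    data = np.asarray(img.dataobj)
    if dialect == "labels":
        if data.ndim != 3:
            raise AtlasFormatError("label atlas must be a 3D volume")
        if np.any(data < 0):
            raise AtlasFormatError("label volume contains negative values")
        data = np.rint(data).astype(int)
        n = int((np.unique(data) > 0).sum())
        if n == 0:
            raise AtlasFormatError("label volume has no positive labels")
        names = roi_names or _default_names(n)
        return Atlas(name, "labels", data, np.asarray(img.affine), names)

    if data.ndim != 4:
        raise AtlasFormatError("map atlas must be a 4D stack")
    zero = [k for k in range(data.shape[3]) if not np.any(data[..., k])]
    if zero:
        raise DegenerateRoiError(f"map(s) {zero} are all zero")
    names = roi_names or _default_names(data.shape[3])
    return Atlas(name, "maps", np.asarray(data, dtype=float),
                 np.asarray(img.affine), names)


def _resample_payload(atlas: Atlas, mask_shape, target_affine) -> np.ndarray:
    """Bring a labels/maps payload onto the analysis grid if needed."""
    same_grid = (
        atlas.payload.shape[:3] == tuple(mask_shape)
        and atlas.affine is not None
        and np.allclose(atlas.affine, target_affine)
    )
    if same_grid:
        return atlas.payload
    interp = "nearest" if atlas.dialect == "labels" else "linear"
    src = nib.Nifti1Image(
        np.asarray(atlas.payload, dtype=float), atlas.affine
    )
    resampled = nl_image.resample_img(
        src,
        target_affine=np.asarray(target_affine),
        target_shape=tuple(mask_shape),
        interpolation=interp,
        force_resample=True,
        copy_header=True,
    )
    out = np.asarray(resampled.dataobj)
    if atlas.dialect == "labels":
        out = np.rint(out).astype(int)
    return out


def resolve_design(
    atlas: Atlas, mask: np.ndarray, affine: np.ndarray
) -> RoiDesign:
    """Resolve an atlas to voxel memberships on an analysis grid.

    Every ROI must keep at least one in-mask voxel (for maps: nonzero
    in-mask weight mass), otherwise a :class:`DegenerateRoiError` naming
    the ROI is raised. Deterministic: identical inputs give identical
    memberships.
    """
    mask = np.asarray(mask, dtype=bool)
    affine = np.asarray(affine, dtype=float)
    flat_mask = mask.ravel()

    if atlas.dialect == "spheres":
        ii, jj, kk = np.nonzero(mask)
        vox = np.column_stack([ii, jj, kk]).astype(float)
        world = vox @ affine[:3, :3].T + affine[:3, 3]
        members = []
        for r, seed in enumerate(atlas.payload):
            dist2 = ((world - seed) ** 2).sum(axis=1)
            sel = dist2 <= atlas.radius_mm**2
            if not sel.any():
                raise DegenerateRoiError(
                    f"sphere ROI {atlas.roi_names[r]!r} has no in-mask voxels"
                )
            members.append(
                np.ravel_multi_index(
                    (ii[sel], jj[sel], kk[sel]), mask.shape
                )
            )
        return RoiDesign(atlas, mask, members=members,
                         roi_names=list(atlas.roi_names))

    payload = _resample_payload(atlas, mask.shape, affine)

    if atlas.dialect == "labels":
        flat_labels = payload.ravel()
        members = []
        for r, lab in enumerate(atlas.labels_present):
            idx = np.flatnonzero((flat_labels == lab) & flat_mask)
            if idx.size == 0:
                raise DegenerateRoiError(
                    f"label ROI {atlas.roi_names[r]!r} (label {lab}) "
                    "has no in-mask voxels"
                )
            members.append(idx)
        return RoiDesign(atlas, mask, members=members,
                         roi_names=list(atlas.roi_names))

    mask_indices = np.flatnonzero(flat_mask)
    weights = payload.reshape(-1, payload.shape[3])[mask_indices].T.copy()
    for r in range(weights.shape[0]):
        if not np.any(weights[r]):
            raise DegenerateRoiError(
                f"map ROI {atlas.roi_names[r]!r} has zero in-mask weight"
            )
    return RoiDesign(atlas, mask, weights=weights, mask_indices=mask_indices,
                     roi_names=list(atlas.roi_names))
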