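"""Volumetric spatial utilities: hemisphere flipping, lesion overlap maps,
loading-threshold masks, and Dice similarity.

Masks live on the image's native 0-based voxel grid; world coordinates are
reached only through the affine.  Flipping about the midsagittal plane
mirrors the data along the left-right voxel axis (identified from the
affine) and leaves the affine untouched, so world coordinates are reflected
about x = 0 of the voxel axis; applying the flip twice restores the input
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeMask",
    "flip_midsagittal",
    "lr_axis",
    "lesion_overlap",
    "top_fraction_mask",
    "dice",
]


@dataclass
class VolumeMask:
    """A binary voxel set with its spatial frame."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_label: str = "study"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if np.linalg.matrix_rank(self.affine) < 4:
            raise ValueError("affine must be invertible")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_image(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_image(cls, img: nib.Nifti1Image, space_label: str = "study") -> "VolumeMask":
        return cls(np.asanyarray(img.dataobj) > 0, img.affine, space_label)


def lr_axis(affine: np.ndarray) -> int:
    """Voxel axis most aligned with the world left-right (x) direction."""
    codes = nib.orientations.aff2axcodes(affine)
    for ax, code in enumerate(codes[:3]):
        if code in ("L", "R"):
            return ax
    raise ValueError("affine orientation is ambiguous: no left-right axis")


def flip_midsagittal(volume: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Mirror a 3D or 4D volume about the midsagittal plane.

    The left-right axis is read from the affine; data are reversed along
    it.  Intended for moving a lesioned hemisphere to a common side before
    group analysis.
    """
    volume = np.asarray(volume)
    if volume.ndim not in (3, 4):
        raise ValueError("expected a 3D or 4D volume")
    return np.flip(volume, axis=lr_axis(affine))


def lesion_overlap(masks: list[VolumeMask]) -> np.ndarray:
    """Voxelwise count of subjects lesioned at each voxel.

    All masks must share shape and affine; the maximum count equals the
    number of patients whose lesions coincide there.
    """
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].data.shape
    aff = masks[0].affine
    total = np.zeros(shape, dtype=np.int32)
    for m in masks:
        if m.data.shape != shape or not np.allclose(m.affine, aff):
            raise ValueError("mask shape/affine mismatch")
        total += m.data.astype(np.int32)
    return total


def top_fraction_mask(
    loadings: np.ndarray,
    fraction: float,
    sign: str = "absolute",
    affine: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> VolumeMask:
    """Mask of the most extreme ``fraction`` of voxels of a loading map.

    ``sign`` selects the tail: ``"positive"`` keeps the highest positive
    loadings, ``"negative"`` the most negative, ``"absolute"`` the largest
    magnitudes.  The mask holds exactly ``ceil(fraction * n_valid)``
    voxels; ties are broken by voxel index order (C order, lowest index
    wins).  ``valid`` restricts the candidate set (e.g. to in-brain
    voxels).  Asking for a signed tail that has too few voxels of that
    sign raises ``ValueError``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    loadings = np.asarray(loadings, dtype=float)
    if valid is None:
        valid = np.ones(loadings.shape, dtype=bool)
    vals = loadings[valid]
    if vals.size == 0:
        raise ValueError("no valid voxels")
    if np.ptp(vals) == 0:
        raise ValueError("all-constant loading map: extreme fraction undefined")

    if sign == "positive":
        key = loadings
    elif sign == "negative":
        key = -loadings
    elif sign == "absolute":
        key = np.abs(loadings)
    else:
        raise ValueError(f"unknown sign rule: {sign!r}")

    n_keep = int(np.ceil(fraction * vals.size))
    flat_idx = np.flatnonzero(valid.ravel())
    if sign in ("positive", "negative"):
        eligible = flat_idx[key.ravel()[flat_idx] > 0]
        if eligible.size < n_keep:
            raise ValueError(
                f"only {eligible.size} voxels have {sign} loadings; "
                f"{n_keep} requested")
        flat_idx = eligible
    order = np.lexsort((flat_idx, -key.ravel()[flat_idx]))  # value desc, index asc
    chosen = flat_idx[order[:n_keep]]
    mask = np.zeros(loadings.size, dtype=bool)
    mask[chosen] = True
    return VolumeMask(mask.reshape(loadings.shape),
                      np.eye(4) if affine is None else affine)


def dice(a: VolumeMask | np.ndarray, b: VolumeMask | np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|), in [0, 1]."""
    da = a.data if isinstance(a, VolumeMask) else np.asarray(a).astype(bool)
    db = b.data if isinstance(b, VolumeMask) else np.asarray(b).astype(bool)
    if da.shape != db.shape:
        raise ValueError("mask shape mismatch")
    if isinstance(a, VolumeMask) and isinstance(b, VolumeMask):
        if not np.allclose(a.affine, b.affine):
            raise ValueError("mask affine mismatch")
    na, nb = int(da.sum()), int(db.sum())
    if na + nb == 0:
        raise ValueError("both masks empty: Dice undefined")
    return 2.0 * int((da & db).sum()) / (na + nb)
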