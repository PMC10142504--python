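"""Lesion segmentation, contralateral reference ROI, grid reslicing.

The contrast-enhancing lesion is segmented semi-automatically on the
pre/post-contrast T1 pair: an enhancement map E = (post - pre) / pre is
thresholded at mean(E over NAWM) + k * SD(E over NAWM) and the 6-connected
component containing a user seed is kept. The normal-appearing
white-matter (NAWM) reference ROI is obtained by mirroring across the
grid midsagittal plane, excluding any lesion overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dti import ScalarMap

__all__ = [
    "LesionMask",
    "ReferenceROI",
    "reslice_to_reference",
    "segment_enhancing",
    "mirror_contralateral",
    "sphere_roi",
]

MIN_COMPONENT_VOXELS = 5
MIN_REFERENCE_VOXELS = 50


class NoEnhancementError(ValueError):
    """No voxel exceeds the enhancement threshold."""


class NoLesionAtSeedError(ValueError):
    """The seed voxel is not part of any supra-threshold component."""


class ReferenceTooSmallError(ValueError):
    """Mirrored reference ROI below the minimum voxel count."""


@dataclass
class LesionMask:
    mask: np.ndarray
    seed: tuple[int, int, int]
    threshold: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ReferenceROI:
    mask: np.ndarray
    laterality: str = "contralateral"

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def reslice_to_reference(
    source: ScalarMap,
    reference_shape: tuple[int, int, int],
    reference_affine: np.ndarray,
    order: str = "trilinear",
) -> ScalarMap:
    """Resample a map onto a reference grid through both NIfTI affines.

    ``order`` is 'nearest' (masks) or 'trilinear' (continuous maps).
    Inputs are assumed co-registered in world space; only the resampling
    between voxel grids is performed here.
    """
    if order not in ("nearest", "trilinear"):
        raise ValueError("order must be 'nearest' or 'trilinear'")
    src_affine = np.asarray(source.affine, dtype=float)
    ref_affine = np.asarray(reference_affine, dtype=float)
    if abs(np.linalg.det(src_affine)) < 1e-12:
        raise ValueError("singular source affine")

    # ref voxel -> world -> source voxel
    composite = np.linalg.inv(src_affine) @ ref_affine
    ii, jj, kk = np.meshgrid(
        *[np.arange(n, dtype=float) for n in reference_shape], indexing="ij"
    )
    coords = np.stack([ii, jj, kk, np.ones_like(ii)])
    src_coords = np.tensordot(composite, coords, axes=1)[:3]
    resampled = ndimage.map_coordinates(
        source.values,
        src_coords,
        order=0 if order == "nearest" else 1,
        mode="nearest",
    )
    return ScalarMap(name=source.name, values=resampled, affine=ref_affine)


def enhancement_map(
    post_t1: np.ndarray, pre_t1: np.ndarray, eps_frac: float = 1e-6
) -> np.ndarray:
    """Relative enhancement E = (post - pre) / max(pre, eps).

    eps is a small fraction of the pre-contrast median, guarding division
    while leaving E invariant to joint affine intensity rescaling.
    """
    pre = np.asarray(pre_t1, dtype=float)
    post = np.asarray(post_t1, dtype=float)
    eps = eps_frac * max(float(np.median(np.abs(pre))), 1e-300)
    return (post - pre) / np.maximum(pre, eps)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def segment_enhancing(
    post_t1: ScalarMap,
    pre_t1: ScalarMap,
    seed: tuple[int, int, int],
    nawm: np.ndarray,
    k: float = 3.0,
    min_voxels: int = MIN_COMPONENT_VOXELS,
) -> LesionMask:
    """Threshold-based semi-automatic segmentation of the enhancing lesion.

    The threshold is mean + k*SD of the enhancement map over the NAWM ROI;
    the lesion is the 6-connected supra-threshold component containing the
    seed, rejected if smaller than ``min_voxels``.
    """
    e = enhancement_map(post_t1.values, pre_t1.values)
    seed = tuple(int(c) for c in seed)
    if any(c < 0 or c >= n for c, n in zip(seed, e.shape)):
        raise ValueError("seed outside grid")
    nawm = np.asarray(nawm, dtype=bool)
    thresh = float(e[nawm].mean() + k * e[nawm].std())

    supra = e > thresh
    if not supra.any():
        raise NoEnhancementError("no voxel above the enhancement threshold")
    labels, _ = ndimage.label(supra, structure=_STRUCT6)
    seed_label = labels[seed]
    if seed_label == 0:
        raise NoLesionAtSeedError("seed voxel is below the enhancement threshold")
    mask = labels == seed_label
    if mask.sum() < min_voxels:
        raise NoLesionAtSeedError(
            f"component at seed has {int(mask.sum())} voxels (< {min_voxels})"
        )
    return LesionMask(mask=mask, seed=seed, threshold=thresh)


def mirror_contralateral(
    roi: np.ndarray,
    lesion: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    axis: int = 0,
    min_voxels: int = MIN_REFERENCE_VOXELS,
) -> ReferenceROI:
    """Mirror an ROI across the grid midplane to build the NAWM reference.

    Voxel i on the mirror axis maps to N-1-i. Voxels overlapping the
    lesion or falling outside the brain mask are removed.
    """
    roi = np.asarray(roi, dtype=bool)
    mirrored = np.flip(roi, axis=axis).copy()
    if lesion is not None:
        mirrored &= ~np.asarray(lesion, dtype=bool)
    if brain_mask is not None:
        mirrored &= np.asarray(brain_mask, dtype=bool)
    if mirrored.sum() < min_voxels:
        raise ReferenceTooSmallError(
            f"mirrored reference has {int(mirrored.sum())} voxels (< {min_voxels})"
        )
    return ReferenceROI(mask=mirrored)


def sphere_roi(
    shape: tuple[int, int, int], center: tuple[float, float, float], radius: float
) -> np.ndarray:
    """Boolean spherical ROI in voxel coordinates (isotropic radius)."""
    grids = np.ogrid[[slice(0, n) for n in shape]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2
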