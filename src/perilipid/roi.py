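"""Region-of-interest construction: tumour rim, whole breast, adipose filter.

The peri-tumoural region is the three-dimensional shell of voxels whose
Euclidean distance (in physical units, anisotropic voxel spacing respected)
to the nearest tumour voxel is at most 15 mm — with 3.75 mm in-plane voxels
that reaches exactly 4 voxels in plane.  The whole breast keeps adipose and
fibroglandular tissue only: chest wall, subcutaneous fat, background and
(in participants) the tumour are removed.  Histogram analysis uses only
adipose voxels whose fat fraction exceeds 60% of the total signal (strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import ndimage

from .phantom import LABELS

__all__ = [
    "RoiSet",
    "EmptyRegionError",
    "make_rim",
    "make_whole_breast",
    "adipose_filter",
    "build_roi_set",
]


class EmptyRegionError(ValueError):
    """Raised when a region contains no voxels (e.g. no delineable tumour,
    or no voxel survives the adipose filter)."""


@dataclass
class RoiSet:
    """Boolean masks on one grid plus the parameters that built them."""

    tumour: np.ndarray
    rim: np.ndarray
    whole_breast: np.ndarray
    adipose_rim: np.ndarray
    adipose_whole_breast: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    provenance: dict[str, Any]


def make_rim(tumour_mask: np.ndarray, voxel_spacing_mm,
             thickness_mm: float = 15.0) -> np.ndarray:
    """Peri-tumoural rim: voxels within ``thickness_mm`` of the tumour.

    Distance is Euclidean from voxel centre to the nearest tumour voxel
    centre, computed with the anisotropic voxel spacing; the tumour itself
    is excluded.  Raises :class:`EmptyRegionError` on an empty tumour mask
    (a region that cannot be delineated has no rim).
    """
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    spacing = np.asarray(voxel_spacing_mm, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacings must be positive")
    if not tumour_mask.any():
        raise EmptyRegionError("tumour mask is empty; cannot define a rim")
    if thickness_mm <= 0:
        return np.zeros_like(tumour_mask)
    dist = ndimage.distance_transform_edt(~tumour_mask, sampling=spacing)
    return (dist > 0) & (dist <= thickness_mm)


def make_whole_breast(labels: np.ndarray, control: bool = False) -> np.ndarray:
    """Whole-breast mask: adipose plus fibroglandular tissue only.

    Chest wall, subcutaneous fat and background are always excluded; the
    tumour is excluded by construction since it carries its own label.
    ``control=True`` asserts a tumour-free breast (WB-C) and raises if a
    tumour label is present; ``control=False`` is the participant mask
    (WB-P), which retains peri-tumoural tissue.
    """
    labels = np.asarray(labels)
    known = np.isin(labels, list(LABELS.values()))
    if not known.all():
        bad = np.unique(labels[~known])
        raise ValueError(f"unknown label codes {bad.tolist()}")
    if control and np.any(labels == LABELS["tumour"]):
        raise ValueError("control mode requested but a tumour label is present")
    return np.isin(labels, [LABELS["adipose"], LABELS["fibroglandular"]])


def adipose_filter(fat_fraction_map: np.ndarray, region_mask: np.ndarray,
                   threshold: float = 0.60):
    """Select adipose voxels: fat fraction strictly above ``threshold``.

    Returns ``(mask, values)`` where ``mask`` marks the surviving voxels and
    ``values`` is the fat-fraction values at those voxels in scan (C) order.
    Raises :class:`EmptyRegionError` if no voxel survives, so downstream
    statistics can skip the region explicitly.
    """
    fat_fraction_map = np.asarray(fat_fraction_map, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if fat_fraction_map.shape != region_mask.shape:
        raise ValueError("fat-fraction map and region mask grids differ")
    with np.errstate(invalid="ignore"):
        mask = region_mask & (fat_fraction_map > threshold)
    if not mask.any():
        raise EmptyRegionError(
            f"no voxel exceeds fat fraction {threshold} in the region")
    return mask, fat_fraction_map[mask]


def build_roi_set(labels: np.ndarray, fat_fraction_map: np.ndarray,
                  voxel_spacing_mm, rim_mm: float = 15.0,
                  fat_threshold: float = 0.60,
                  valid_mask: np.ndarray | None = None) -> RoiSet:
    """Assemble the study's regions for one participant phantom/scan.

    For a tumour-free label volume (a control) the rim masks are empty and
    ``whole_breast`` is the WB-C region.  ``valid_mask`` (e.g. converged fit
    voxels) further restricts the adipose selections.
    """
    labels = np.asarray(labels)
    tumour = labels == LABELS["tumour"]
    spacing = tuple(float(s) for s in np.asarray(voxel_spacing_mm))
    wb = make_whole_breast(labels, control=not tumour.any())
    if tumour.any():
        rim = make_rim(tumour, spacing, rim_mm)
        rim &= labels > 0          # rim is tissue, not background/air
    else:
        rim = np.zeros_like(tumour)

    def _adipose(region):
        if not region.any():
            return np.zeros_like(region)
        try:
            mask, _ = adipose_filter(fat_fraction_map, region, fat_threshold)
        except EmptyRegionError:
            return np.zeros_like(region)
        if valid_mask is not None:
            mask = mask & valid_mask
        return mask

    # the adipose filter operates on breast tissue inside each region
    rim_tissue = rim & np.isin(labels, [LABELS["adipose"],
                                        LABELS["fibroglandular"]])
    return RoiSet(
        tumour=tumour,
        rim=rim,
        whole_breast=wb,
        adipose_rim=_adipose(rim_tissue),
        adipose_whole_breast=_adipose(wb),
        voxel_spacing_mm=spacing,
        provenance={"rim_mm": rim_mm, "fat_threshold": fat_threshold},
    )
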