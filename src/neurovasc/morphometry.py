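"""Pixel- and surface-ratio quantification of vascular immunofluorescence.

The measures are simple, auditable pixel ratios on binary or
instance-labeled masks:

* mural-cell **coverage** — desmin-positive pixels over lectin-positive
  (vessel) pixels;
* mural-cell **detachment** — pixels in cells not in contact with any
  other cell, over all cell pixels;
* per-class pixel fractions (e.g. dedifferentiating cells; the
  morphological classification itself is an input);
* parenchymal **plaque load** — amyloid-positive pixels over ROI area,
  after discarding components below a minimum area (~100 um^2, the
  smallest plaques preserved by thresholding);
* **vascular amyloid load** — amyloid surface area as a percent of the
  vessel surface area (surfaces from 3D segmentation enter as scalars).

Connectivity is 8-neighborhood throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "LabeledMask",
    "MorphometryResult",
    "threshold_by_background",
    "coverage_fraction",
    "detachment_fraction",
    "class_pixel_fraction",
    "plaque_load",
    "vascular_amyloid_load",
]

#: reference area (um^2) for the background pixel-density thresholding rule
BACKGROUND_REFERENCE_AREA_UM2 = 150.0


@dataclass(frozen=True)
class LabeledMask:
    """A 2-D mask: 0 = background, 1 = foreground (binary) or instance labels."""

    pixels: np.ndarray
    pixel_size: float  # um per pixel
    stain_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            if np.issubdtype(px.dtype, np.bool_):
                px = px.astype(np.uint8)
            else:
                raise ValueError("pixels must be integer labeled (0 = background)")
        if px.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "pixels", px)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class MorphometryResult:
    measure: str
    value: float
    numerator_pixels: int
    denominator_pixels: int
    parameters: Mapping[str, object]


def threshold_by_background(
    image: np.ndarray,
    background: np.ndarray,
    pixel_size: float,
    target_density: float = 10.0,
) -> tuple[LabeledMask, float]:
    """Binarize an intensity image by its background suprathreshold density.

    Finds the smallest intensity threshold at which the background region
    contains at most ``target_density`` suprathreshold (strictly greater)
    pixels per 150 um^2, and applies it to the whole image.  Returns the
    binary mask and the chosen threshold.
    """
    image = np.asarray(image, dtype=float)
    background = np.asarray(background, dtype=bool)
    if image.shape != background.shape:
        raise ValueError("image and background region must share a shape")
    bg = image[background]
    if bg.size == 0:
        raise ValueError("background region is empty")
    if target_density < 0:
        raise ValueError("target_density must be non-negative")
    bg_area = bg.size * pixel_size**2
    allowed = target_density * bg_area / BACKGROUND_REFERENCE_AREA_UM2
    if allowed < 1.0 and np.all(bg == bg.max()) and bg.size > 1:
        raise ValueError("background is saturated; density target unattainable")
    # count(bg > t) is non-increasing in t: the smallest admissible t is the
    # k-th largest background value, k = floor(allowed)
    k = int(np.floor(allowed))
    srt = np.sort(bg)[::-1]
    thresh = float(srt[k]) if k < bg.size else float(srt[-1]) - 1.0
    mask = (image > thresh).astype(np.uint8)
    return LabeledMask(mask, pixel_size, "thresholded"), thresh


def _binary(mask: LabeledMask) -> np.ndarray:
    return mask.pixels > 0


def coverage_fraction(signal_mask: LabeledMask, reference_mask: LabeledMask) -> MorphometryResult:
    """Signal-positive pixels over reference-positive pixels (e.g. desmin/lectin)."""
    if signal_mask.pixels.shape != reference_mask.pixels.shape:
        raise ValueError("masks must share a shape")
    num = int(_binary(signal_mask).sum())
    den = int(_binary(reference_mask).sum())
    if den == 0:
        raise ValueError("reference mask is empty")
    return MorphometryResult(
        measure="coverage_fraction", value=num / den,
        numerator_pixels=num, denominator_pixels=den,
        parameters={"signal": signal_mask.stain_label,
                    "reference": reference_mask.stain_label},
    )


def detachment_fraction(instance_mask: LabeledMask, contact_distance: int = 1) -> MorphometryResult:
    """Pixel fraction of instances not in contact with any other instance.

    Two instances are in contact when any pair of their pixels lies within
    ``contact_distance`` in the chebyshev metric (1 = 8-connectivity touch).
    A single-instance mask returns 1.0 with a warning, since contact is
    impossible.
    """
    if contact_distance < 1:
        raise ValueError("contact_distance must be >= 1")
    labels = instance_mask.pixels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("mask contains no instances")
    total = int((labels > 0).sum())
    if ids.size == 1:
        warnings.warn("single instance: detachment is trivially 1.0", stacklevel=2)
        return MorphometryResult("detachment_fraction", 1.0, total, total,
                                 {"contact_distance": contact_distance})
    struct = np.ones((2 * contact_distance + 1,) * 2, dtype=bool)
    objects = ndimage.find_objects(labels)
    detached_px = 0
    for lab in ids:
        sl = objects[lab - 1]
        pad = contact_distance
        rows = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0]))
        cols = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1]))
        window = labels[rows, cols]
        own = window == lab
        halo = ndimage.binary_dilation(own, structure=struct) & ~own
        if not np.any(window[halo] > 0):
            detached_px += int(own.sum())
    return MorphometryResult(
        measure="detachment_fraction", value=detached_px / total,
        numerator_pixels=detached_px, denominator_pixels=total,
        parameters={"contact_distance": contact_distance},
    )


def class_pixel_fraction(instance_mask: LabeledMask,
                         class_flags: Mapping[int, bool]) -> MorphometryResult:
    """Pixel fraction of flagged instances (e.g. dedifferentiating cells)."""
    labels = instance_mask.pixels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("mask contains no instances")
    missing = [int(i) for i in ids if int(i) not in class_flags]
    if missing:
        raise ValueError(f"missing class flags for instances {missing}")
    flagged = [int(i) for i in ids if class_flags[int(i)]]
    num = int(np.isin(labels, flagged).sum())
    den = int((labels > 0).sum())
    return MorphometryResult(
        measure="class_pixel_fraction", value=num / den,
        numerator_pixels=num, denominator_pixels=den,
        parameters={"n_flagged": len(flagged), "n_instances": int(ids.size)},
    )


def plaque_load(
    plaque_mask: LabeledMask,
    roi_mask: LabeledMask,
    min_plaque_area: float = 100.0,
) -> tuple[MorphometryResult, int]:
    """Percent of an ROI covered by plaques, discarding components below
    ``min_plaque_area`` (um^2; default preserves ~100 um^2, the smallest
    plaques kept by the thresholding).  Returns (result, plaque count)."""
    if plaque_mask.pixels.shape != roi_mask.pixels.shape:
        raise ValueError("masks must share a shape")
    if min_plaque_area < 0:
        raise ValueError("min_plaque_area must be non-negative")
    roi = _binary(roi_mask)
    roi_px = int(roi.sum())
    if roi_px == 0:
        raise ValueError("ROI is empty")
    inside = _binary(plaque_mask) & roi
    labeled = measure.label(inside, connectivity=2)  # 8-connectivity
    min_px = min_plaque_area / plaque_mask.pixel_size**2
    surviving_px = 0
    count = 0
    for region in measure.regionprops(labeled):
        if region.area >= min_px:
            surviving_px += int(region.area)
            count += 1
    result = MorphometryResult(
        measure="plaque_load_percent", value=100.0 * surviving_px / roi_px,
        numerator_pixels=surviving_px, denominator_pixels=roi_px,
        parameters={"min_plaque_area_um2": min_plaque_area,
                    "pixel_size": plaque_mask.pixel_size},
    )
    return result, count


def vascular_amyloid_load(amyloid_surface: float, vessel_surface: float) -> float:
    """Amyloid surface area as a percent of the vessel surface area."""
    if vessel_surface <= 0:
        raise ValueError("vessel surface must be positive")
    if amyloid_surface < 0:
        raise ValueError("amyloid surface must be non-negative")
    if amyloid_surface > vessel_surface:
        raise ValueError("amyloid surface exceeds vessel surface: inconsistent segmentation")
    return 100.0 * amyloid_surface / vessel_surface
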