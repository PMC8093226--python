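"""Resolution normalization and lumen segmentation.

Analysis runs at 1 um/px; images at other resolutions are bilinearly
resampled first.  The segmenter interface is pluggable: the default is a
classical pipeline thresholding low-stain/high-luminance pixels (gland
lumens appear near-white and unstained on H&E) followed by
opening-by-reconstruction, hole filling and an area filter; a truth-mask
bypass converts precomputed label masks straight to polygons.
"""

from __future__ import annotations

import logging

import numpy as np
from shapely.geometry import Point, Polygon
from skimage import measure, morphology
from skimage.color import rgb2gray
from skimage.filters import gaussian, threshold_otsu
from skimage.transform import resize

from .io_core import (
    AnnotationPolygon,
    LumenSet,
    RegionImage,
    ValidationError,
)
from .graph_texture_features import region_mask

logger = logging.getLogger("histotyping")

ANALYSIS_MPP = 1.0
DEFAULT_MIN_AREA_UM2 = 40.0


def rescale_to_analysis_resolution(img: RegionImage) -> RegionImage:
    """Bilinearly resample an image to exactly 1.0 um/px.

    An image already at 1.0 um/px is returned with identical pixels.
    """
    if not img.microns_per_pixel > 0:
        raise ValidationError("microns_per_pixel must be > 0")
    if img.microns_per_pixel == ANALYSIS_MPP:
        return img
    h, w = img.shape_px
    out_h = max(32, int(round(h * img.microns_per_pixel / ANALYSIS_MPP)))
    out_w = max(32, int(round(w * img.microns_per_pixel / ANALYSIS_MPP)))
    resampled = resize(
        img.pixels.astype(float), (out_h, out_w, 3), order=1,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return RegionImage(
        np.clip(resampled, 0, 255).astype(np.uint8),
        microns_per_pixel=ANALYSIS_MPP,
        region_id=img.region_id,
        site=img.site,
    )


def segment_lumens(
    img: RegionImage,
    region: AnnotationPolygon,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    opening_radius_px: int = 2,
) -> np.ndarray:
    """Classical lumen segmentation: label mask at 1 um/px.

    Lumens are the unstained (low-chroma) bright class: Otsu thresholds on
    in-region chroma and luminance select low-stain/high-luminance pixels,
    followed by opening-by-reconstruction (speckle removal without boundary
    rounding), hole filling, an area filter, and removal of components
    whose centroid falls outside the region.  Deterministic for fixed
    input.
    """
    if abs(img.microns_per_pixel - ANALYSIS_MPP) > 1e-9:
        raise ValidationError("segment_lumens requires a 1 um/px image")
    h, w = img.shape_px
    mask = region_mask(img, region)
    if mask.sum() < 0.01 * h * w:
        logger.warning("annotation covers < 1%% of the image; returning empty mask")
        return np.zeros((h, w), dtype=np.uint16)
    rgb = img.pixels.astype(float) / 255.0
    gray = gaussian(rgb2gray(rgb), sigma=1.0)  # suppress pixel noise
    # stain density: lumens are unstained (near-achromatic white) while
    # stroma carries eosin/hematoxylin, so chroma separates them robustly
    # even under brightness texture
    chroma = gaussian(rgb.max(axis=-1) - rgb.min(axis=-1), sigma=1.0)
    gvals, cvals = gray[mask], chroma[mask]
    if gvals.max() - gvals.min() < 1e-6:
        return np.zeros((h, w), dtype=np.uint16)
    thr_c = threshold_otsu(cvals)
    lo, hi = cvals[cvals < thr_c], cvals[cvals >= thr_c]
    # guard: a lumen-free region has unimodal chroma; require a real
    # unstained class well separated from the stained stroma
    if lo.size == 0 or hi.size == 0 or hi.mean() - lo.mean() < 0.08:
        return np.zeros((h, w), dtype=np.uint16)
    thr_g = threshold_otsu(gvals)
    binary = (chroma < thr_c) & (gray > thr_g) & mask
    # opening-by-reconstruction: the opening removes speckle but the
    # surviving components keep their original (unrounded) boundaries
    opened = morphology.opening(binary, morphology.disk(opening_radius_px))
    binary = morphology.reconstruction(opened, binary).astype(bool)
    binary = morphology.remove_small_holes(binary, max_size=10_000)
    labeled = measure.label(binary, connectivity=2)
    out = np.zeros((h, w), dtype=np.uint16)
    next_label = 1
    poly = region.polygon
    for prop in measure.regionprops(labeled):
        if prop.area < min_area_um2:  # 1 px = 1 um^2 at analysis resolution
            continue
        cy, cx = prop.centroid
        cx_um, cy_um = (cx + 0.5) * ANALYSIS_MPP, (cy + 0.5) * ANALYSIS_MPP
        if not poly.contains(Point(cx_um, cy_um)):
            continue
        out[labeled == prop.label] = next_label
        next_label += 1
    return out


def mask_to_lumens(
    mask: np.ndarray,
    region: AnnotationPolygon,
    mpp: float = ANALYSIS_MPP,
    source: str = "mask",
) -> LumenSet:
    """Vectorize a label mask to one polygon per label (contour tracing).

    Components are assigned to the region by the centroid-in-polygon rule;
    labels with fewer than 4 boundary pixels are dropped with a log entry.
    Holes are not traced (outer contour only).
    """
    mask = np.asarray(mask)
    poly = region.polygon
    lumens: list[Polygon] = []
    for label in np.unique(mask):
        if label == 0:
            continue
        comp = mask == label
        if comp.sum() < 4:
            logger.info("label %d has < 4 pixels; dropped", label)
            continue
        padded = np.pad(comp.astype(float), 3)
        # subpixel boundary: contour the smoothed indicator field at its
        # half level, which suppresses the marching-squares staircase
        padded = gaussian(padded, sigma=0.8)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            logger.info("label %d has no traceable contour; dropped", label)
            continue
        contour = max(contours, key=len) - 3.0  # undo padding
        if len(contour) < 4:
            logger.info("label %d contour too short; dropped", label)
            continue
        if np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        # (i, j) -> (x, y) um with pixel-center convention
        xy = np.column_stack(
            [(contour[:, 1] + 0.5) * mpp, (contour[:, 0] + 0.5) * mpp]
        )
        lumen = Polygon(xy)
        if not lumen.is_valid:
            lumen = lumen.buffer(0)
            if lumen.geom_type == "MultiPolygon":
                lumen = max(lumen.geoms, key=lambda g: g.area)
        if lumen.is_empty or lumen.area <= 0:
            continue
        if not poly.contains(lumen.centroid):
            continue
        lumens.append(lumen)
    return LumenSet(region=region, lumens=lumens, source=source)


def segment_region(
    img: RegionImage,
    region: AnnotationPolygon,
    segmenter: str = "classical",
    truth_mask: np.ndarray | None = None,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> LumenSet:
    """End-to-end segmentation: image -> LumenSet.

    ``segmenter`` is "classical" (default) or "mask" (truth-mask bypass,
    requires ``truth_mask``).
    """
    img = rescale_to_analysis_resolution(img)
    if segmenter == "mask":
        if truth_mask is None:
            raise ValidationError("mask segmenter requires a truth mask")
        return mask_to_lumens(truth_mask, region, source="mask")
    if segmenter != "classical":
        raise ValidationError(f"unknown segmenter {segmenter!r}")
    label_mask = segment_lumens(img, region, min_area_um2=min_area_um2)
    return mask_to_lumens(label_mask, region, source="segmenter")
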