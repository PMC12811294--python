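"""Nucleus/cell-body detection and seeded-watershed single-cell segmentation.

The segmentation route follows the classical high-content recipe:
background subtraction, Gaussian blur + threshold + size/roundness
exclusion for seeds, an enhanced-contrast composite built by exact
histogram equalization of two channels summed pixelwise, and a seeded
watershed that partitions the composite's foreground into one region
per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import rankdata
from skimage import measure, morphology
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed as _sk_watershed

from .frames import Frame


class SeedError(ValueError):
    """Watershed seeds fall outside the foreground."""


@dataclass
class DetectionParams:
    """Blob-detection parameters; physical units so they transfer across
    magnifications."""

    sigma_um: float = 2.0
    #: "otsu", "background" (median + k·MAD, robust to class-imbalanced
    #: brightness), or a fixed intensity value
    threshold: str | float = "otsu"
    background_k: float = 8.0
    min_area_um2: float = 20.0
    max_area_um2: float = 400.0
    min_roundness: float | None = 0.5  # None disables the roundness filter

    def validate(self) -> None:
        if self.sigma_um <= 0:
            raise ValueError("sigma_um must be > 0")
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ValueError("need 0 < min_area_um2 < max_area_um2")
        if isinstance(self.threshold, str) and self.threshold not in ("otsu", "background"):
            raise ValueError(f"unknown threshold method {self.threshold!r}")


#: presets: somata keep the roundness filter; nuclei are smaller and the
#: roundness filter is off; debris allows very small fragments
SOMA_PARAMS = DetectionParams()
NUCLEUS_PARAMS = DetectionParams(sigma_um=1.0, min_area_um2=4.0, max_area_um2=150.0,
                                 min_roundness=None)
ANY_OBJECT_PARAMS = DetectionParams(sigma_um=2.0, threshold="background",
                                    min_area_um2=3.0, max_area_um2=2500.0,
                                    min_roundness=None)


def subtract_background(frame: Frame, radius_um: float) -> Frame:
    """Remove large-scale background by grey-opening with a disk footprint.

    The opening with a disk of the given radius estimates a background
    that no object smaller than the disk can contribute to (the
    rolling-ball idea); the estimate is subtracted and the result
    clipped at zero, so peaks of objects smaller than ~radius/2 are
    preserved.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    r_px = max(int(round(radius_um / frame.pixel_size_um)), 1)
    footprint = morphology.disk(r_px, decomposition="sequence")
    background = morphology.opening(frame.data, footprint)
    return frame.with_data(np.clip(frame.data - background, 0, None))


def detect_blobs(frame: Frame, params: DetectionParams) -> np.ndarray:
    """Detect bright blobs: Gaussian blur, threshold, size/roundness exclusion.

    Returns a label mask with consecutive labels 1..K in top-left scan
    order. Roundness is the isoperimetric ratio 4πA/P² on the pixel
    boundary; objects outside the area bounds or below ``min_roundness``
    are excluded.
    """
    params.validate()
    px = frame.pixel_size_um
    blurred = gaussian(frame.data, sigma=params.sigma_um / px, preserve_range=True)
    if np.ptp(blurred) == 0:
        return np.zeros(frame.shape, dtype=np.int32)
    if params.threshold == "otsu":
        thr = threshold_otsu(blurred)
    elif params.threshold == "background":
        med = np.median(blurred)
        mad = np.median(np.abs(blurred - med))
        thr = med + params.background_k * max(mad, 1e-12)
    else:
        thr = float(params.threshold)
    fg = blurred > thr
    labels = measure.label(fg, connectivity=1)
    out = np.zeros_like(labels, dtype=np.int32)
    k = 0
    for region in measure.regionprops(labels):
        area_um2 = region.area * px**2
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue
        if params.min_roundness is not None:
            perim = region.perimeter
            roundness = 4 * math.pi * region.area / perim**2 if perim > 0 else 1.0
            if min(roundness, 1.0) < params.min_roundness:
                continue
        k += 1
        out[labels == region.label] = k
    return out


def roundness_of(mask: np.ndarray) -> float:
    """Isoperimetric roundness 4πA/P² of a binary mask, clipped to [0, 1]."""
    props = measure.regionprops(mask.astype(np.int32))
    if not props:
        raise ValueError("empty mask")
    r = props[0]
    if r.perimeter == 0:
        return 1.0
    return float(min(4 * math.pi * r.area / r.perimeter**2, 1.0))


def equalize(frame_or_array: Frame | np.ndarray) -> np.ndarray:
    """Exact rank-based histogram equalization to [0, 1].

    Ties get their average rank, so the map is deterministic and
    resolution-independent; on all-distinct values the output histogram
    is exactly uniform.
    """
    img = frame_or_array.data if isinstance(frame_or_array, Frame) else frame_or_array
    flat = np.asarray(img, dtype=float).ravel()
    ranks = rankdata(flat, method="average")
    return ((ranks - 0.5) / flat.size).reshape(img.shape)


def equalize_and_sum(chan_a: Frame, chan_b: Frame) -> Frame:
    """Enhanced-contrast composite: per-channel histogram equalization
    then pixelwise sum (range [0, 2]).

    Equalizing both channels before summing brings dim cytoplasmic and
    bright nuclear signal onto one scale, which makes whole-cell bodies
    visible for segmentation.
    """
    if chan_a.shape != chan_b.shape:
        raise ValueError(f"shape mismatch: {chan_a.shape} vs {chan_b.shape}")
    return chan_a.with_data(equalize(chan_a) + equalize(chan_b))


def watershed_cells(
    eq: Frame,
    seeds: np.ndarray,
    foreground: np.ndarray | None = None,
) -> np.ndarray:
    """Partition the composite's foreground into one region per seed.

    The watershed runs on the inverted composite (bright cells become
    basins), constrained to ``foreground`` (Otsu threshold of the
    composite when not given). Every seed must lie inside the
    foreground; regions are disjoint, cover the foreground, and each
    contains its seed.
    """
    img = eq.data
    if foreground is None:
        foreground = img > threshold_otsu(img)
    foreground = foreground.astype(bool)
    seed_ids = np.unique(seeds)
    seed_ids = seed_ids[seed_ids > 0]
    bad = [int(s) for s in seed_ids if not np.any((seeds == s) & foreground)]
    if bad:
        raise SeedError(f"seeds outside foreground: {bad}")
    return _sk_watershed(-img, markers=seeds, mask=foreground)


def crop_centered(frame: Frame, center: tuple[float, float], side_um: float) -> Frame:
    """Square crop of physical side ``side_um`` centered on ``center``
    (row, col px); out-of-field area is zero-padded."""
    if side_um <= 0:
        raise ValueError("side_um must be > 0")
    cy, cx = center
    if not (0 <= cy < frame.shape[0] and 0 <= cx < frame.shape[1]):
        raise ValueError(f"center {center} outside frame {frame.shape}")
    side_px = int(round(side_um / frame.pixel_size_um))
    out = np.zeros((side_px, side_px))
    y0 = int(round(cy)) - side_px // 2
    x0 = int(round(cx)) - side_px // 2
    ys = slice(max(y0, 0), min(y0 + side_px, frame.shape[0]))
    xs = slice(max(x0, 0), min(x0 + side_px, frame.shape[1]))
    out[ys.start - y0 : ys.stop - y0, xs.start - x0 : xs.stop - x0] = frame.data[ys, xs]
    return frame.with_data(out)


def _robust_foreground(frame: Frame, sigma_um: float, k: float = 8.0) -> np.ndarray:
    """Blur then threshold at median + k·MAD of the blurred image."""
    blurred = gaussian(frame.data, sigma=sigma_um / frame.pixel_size_um,
                       preserve_range=True)
    med = np.median(blurred)
    mad = np.median(np.abs(blurred - med))
    return blurred > med + k * max(mad, 1e-12)


def soma_from_region(
    cyto: Frame,
    region: np.ndarray,
    nucleus: np.ndarray | None = None,
    core_fraction: float = 0.7,
    reference_radius_um: float = 5.0,
) -> np.ndarray:
    """Cell body within one watershed region, by adaptive thresholding
    referenced to the intensity around the cell's own nucleus.

    The threshold is ``core_fraction`` of the 95th intensity percentile
    over a small disk around the nucleus centroid — a local reference
    that a bright neurite from a neighboring cell crossing the region's
    periphery cannot corrupt. Bright compact somata separate from their
    dimmer neurites; uniformly dim flat cells keep their whole extent;
    fragmented debris keeps each fragment. An empty result falls back to
    the whole region.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return region
    if nucleus is not None and np.asarray(nucleus).any():
        cy, cx = ndi.center_of_mass(np.asarray(nucleus, dtype=bool))
        r_px = reference_radius_um / cyto.pixel_size_um
        yy, xx = np.mgrid[: region.shape[0], : region.shape[1]]
        ref = region & ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2)
        if not ref.any():
            ref = region
    else:
        ref = region
    thr = core_fraction * np.percentile(cyto.data[ref], 95)
    body = region & (cyto.data >= thr)
    return body if body.any() else region


def segment_culture(
    cyto: Frame,
    nuclei: Frame,
    nucleus_params: DetectionParams = NUCLEUS_PARAMS,
    core_fraction: float = 0.7,
) -> dict[str, np.ndarray]:
    """Nucleus-seeded single-cell segmentation of one culture field.

    Nuclei detected on the nuclear channel seed a watershed on the
    equalized composite, constrained to the cytoplasm-channel foreground
    (robust background threshold; the composite's rank-flattened
    histogram carries no threshold information of its own). Each
    resulting cell region then yields a body mask by per-region adaptive
    thresholding. Returns ``soma``, ``nuclei`` and ``cells`` label masks.
    """
    nuc = detect_blobs(nuclei, nucleus_params)
    eq = equalize_and_sum(cyto, nuclei)
    fg = _robust_foreground(cyto, 0.7) | _robust_foreground(nuclei, 0.7) | (nuc > 0)
    cells = watershed_cells(eq, nuc, fg)
    soma = np.zeros_like(cells)
    for cid in np.unique(cells):
        if cid == 0:
            continue
        body = soma_from_region(cyto, cells == cid, nucleus=nuc == cid,
                                core_fraction=core_fraction)
        soma[body] = cid
    return {"soma": soma, "nuclei": nuc, "cells": cells}
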