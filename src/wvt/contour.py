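"""DAPI-cytoarchitecture contour recognition and minimum imaging-region planning.

During block-face tomography every freshly cut layer is counterstained and a
low-resolution coronal preview is available while the microtome sections the
next slice.  Rather than imaging a fixed cuboid covering the brain's maximum
cross-section, the contour of the tissue in the current layer is recognized
by a mathematical-morphology pipeline and the next layer's acquisition is
restricted to the smallest mosaic-grid rectangle that safely covers it.

The mosaic lattice is anchored to fixed stage coordinates for the whole
dataset, so per-layer regions are index ranges on one lattice and the stack
self-registers without any post-hoc alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as _sk_measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import InputError, PlanningError


@dataclass
class ContourParams:
    """Knobs of the morphology pipeline, all at recognition resolution.

    ``fragment_distance_limit_um`` realizes the distance-based rejection of
    sectioning debris: any component other than the largest whose centroid
    lies farther from the largest component's centroid than that component's
    bounding radius plus this limit is dropped.
    """

    median_kernel: int = 3
    threshold_method: str = "otsu"  # or "fixed"
    fixed_value: float = 0.0
    opening_radius: int = 3
    fragment_distance_limit_um: float = 500.0
    min_fragment_area_px: int = 64
    min_tissue_area_px: int = 500
    recognition_pixel_size_um: float = 1.68

    def __post_init__(self):
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise InputError("median_kernel must be odd and >= 1")
        if self.opening_radius < 0:
            raise InputError("opening_radius must be >= 0")
        if self.recognition_pixel_size_um <= 0:
            raise InputError("recognition pixel size must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise InputError(f"unknown threshold method {self.threshold_method!r}")


@dataclass
class BrainContour:
    """Recognized tissue region of one coronal layer.

    ``rect_um`` is the circumscribed rectangle ``(xmin, ymin, xmax, ymax)``
    in μm in the sample/stage frame (image origin at ``origin_um``).
    ``empty`` flags layers where nothing survived the pipeline; the planner
    then reuses the previous layer's region.
    """

    mask: np.ndarray
    boundary: np.ndarray  # (N, 2) array of (row, col) pixel coordinates, closed
    rect_um: tuple[float, float, float, float]
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    empty: bool = False

    @classmethod
    def empty_contour(cls, shape: tuple[int, int], pixel_size_um: float,
                      origin_um: tuple[float, float] = (0.0, 0.0)) -> "BrainContour":
        return cls(mask=np.zeros(shape, dtype=bool), boundary=np.empty((0, 2)),
                   rect_um=(0.0, 0.0, 0.0, 0.0), pixel_size_um=pixel_size_um,
                   origin_um=origin_um, empty=True)


@dataclass(frozen=True)
class MosaicSpec:
    """The fixed stage lattice of overlapping fields of view.

    FOV centers sit at ``origin + i*stride`` per axis with
    ``stride = fov_side − overlap``; the origin never moves within a dataset.
    """

    fov_side_um: float = 576.0
    overlap_um: float = 5.0
    origin_um: tuple[float, float] = (0.0, 0.0)  # (x, y) of FOV (0, 0) center

    def __post_init__(self):
        if not (0 <= self.overlap_um < self.fov_side_um):
            raise InputError("need 0 <= overlap < fov_side")

    @property
    def stride_um(self) -> float:
        return self.fov_side_um - self.overlap_um


@dataclass(frozen=True)
class ImagingRegion:
    """A planned acquisition area: a contiguous span of lattice columns/rows.

    ``rect_um`` is the margin-expanded target rectangle the grid must cover;
    the grid span (inclusive indices on the dataset's fixed lattice) is the
    smallest cover of it.
    """

    rect_um: tuple[float, float, float, float]
    col0: int
    col1: int
    row0: int
    row1: int

    @property
    def n_cols(self) -> int:
        return self.col1 - self.col0 + 1

    @property
    def n_rows(self) -> int:
        return self.row1 - self.row0 + 1

    @property
    def n_mosaics(self) -> int:
        return self.n_cols * self.n_rows

    def covered_rect_um(self, spec: MosaicSpec) -> tuple[float, float, float, float]:
        """The stage-space rectangle actually swept by the grid span."""
        half = spec.fov_side_um / 2.0
        ox, oy = spec.origin_um
        return (ox + self.col0 * spec.stride_um - half,
                oy + self.row0 * spec.stride_um - half,
                ox + self.col1 * spec.stride_um + half,
                oy + self.row1 * spec.stride_um + half)

    def to_dict(self) -> dict:
        return {"rect_um": list(self.rect_um), "col0": self.col0, "col1": self.col1,
                "row0": self.row0, "row1": self.row1, "n_mosaics": self.n_mosaics}


def recognize_contour(
    dapi_image: np.ndarray,
    params: ContourParams | None = None,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> BrainContour:
    """Recognize the tissue contour in a single-channel coronal preview.

    Pipeline: median filter → threshold (Otsu by default) → morphological
    opening → connected-component filtering (area and distance-from-tissue
    rules drop sectioning fragments and embedding-agent borders) → hole
    filling (ventricles of any size) → boundary of the largest survivor.
    """
    params = params or ContourParams()
    img = np.asarray(dapi_image, dtype=float)
    if img.ndim != 2:
        raise InputError("contour recognition expects a 2-D single-channel image")

    smoothed = ndimage.median_filter(img, size=params.median_kernel)

    if params.threshold_method == "otsu":
        if float(np.ptp(smoothed)) == 0.0:
            return BrainContour.empty_contour(img.shape, params.recognition_pixel_size_um, origin_um)
        thresh = threshold_otsu(smoothed)
    else:
        thresh = params.fixed_value
    binary = smoothed > thresh
    if not binary.any() or binary.all():
        return BrainContour.empty_contour(img.shape, params.recognition_pixel_size_um, origin_um)

    if params.opening_radius > 0:
        binary = ndimage.binary_opening(binary, structure=disk(params.opening_radius))
    if not binary.any():
        return BrainContour.empty_contour(img.shape, params.recognition_pixel_size_um, origin_um)

    labels, n = ndimage.label(binary)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    centroids = np.array(ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1)))
    main = int(np.argmax(areas)) + 1
    if areas[main - 1] < params.min_tissue_area_px:
        # nothing tissue-sized in the field: noise-only layer
        return BrainContour.empty_contour(img.shape, params.recognition_pixel_size_um, origin_um)

    # bounding radius of the main component, used by the distance rule
    main_pts = np.argwhere(labels == main)
    main_centroid = centroids[main - 1]
    bound_radius_px = float(np.sqrt(((main_pts - main_centroid) ** 2).sum(axis=1)).max())
    limit_px = bound_radius_px + params.fragment_distance_limit_um / params.recognition_pixel_size_um

    keep = np.zeros(n + 1, dtype=bool)
    keep[main] = True
    for lbl in range(1, n + 1):
        if lbl == main:
            continue
        if areas[lbl - 1] < params.min_fragment_area_px:
            continue
        dist = float(np.hypot(*(centroids[lbl - 1] - main_centroid)))
        if dist <= limit_px:
            keep[lbl] = True
    mask = keep[labels]
    mask = ndimage.binary_fill_holes(mask)

    # keep only the largest connected survivor as the brain
    labels2, n2 = ndimage.label(mask)
    if n2 > 1:
        areas2 = ndimage.sum_labels(np.ones_like(labels2), labels2, index=np.arange(1, n2 + 1))
        mask = labels2 == (int(np.argmax(areas2)) + 1)

    contours = _sk_measure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len) if contours else np.empty((0, 2))

    rows, cols = np.nonzero(mask)
    px = params.recognition_pixel_size_um
    rect_um = (origin_um[0] + cols.min() * px, origin_um[1] + rows.min() * px,
               origin_um[0] + (cols.max() + 1) * px, origin_um[1] + (rows.max() + 1) * px)
    return BrainContour(mask=mask, boundary=boundary, rect_um=rect_um,
                        pixel_size_um=px, origin_um=origin_um)


def _span_indices(lo: float, hi: float, origin: float, spec: MosaicSpec) -> tuple[int, int]:
    """Smallest inclusive lattice index range whose FOV union covers [lo, hi]."""
    half = spec.fov_side_um / 2.0
    stride = spec.stride_um
    i0 = math.floor((lo - origin + half) / stride + 1e-9)
    i1 = math.ceil((hi - origin - half) / stride - 1e-9)
    return i0, max(i0, i1)


def plan_region(
    contour: BrainContour,
    spec: MosaicSpec,
    margin_um: float = 288.0,
    stage_limits_um: tuple[float, float, float, float] | None = None,
) -> ImagingRegion:
    """Plan the minimum mosaic grid for the next layer.

    The target rectangle is the contour's circumscribed rectangle expanded by
    ``margin_um`` (default half a FOV) on all four sides — the safety band
    that absorbs layer-to-layer contour change and slight under-segmentation.
    The grid span is the smallest run of lattice columns/rows covering it.
    """
    if margin_um < 0:
        raise InputError("margin must be non-negative")
    if contour.empty:
        raise PlanningError("cannot plan from an empty contour")
    xmin, ymin, xmax, ymax = contour.rect_um
    rect = (xmin - margin_um, ymin - margin_um, xmax + margin_um, ymax + margin_um)
    if stage_limits_um is not None:
        lx0, ly0, lx1, ly1 = stage_limits_um
        if rect[0] < lx0 or rect[1] < ly0 or rect[2] > lx1 or rect[3] > ly1:
            raise PlanningError(
                f"planned rectangle {rect} exceeds stage travel limits {stage_limits_um}")
    col0, col1 = _span_indices(rect[0], rect[2], spec.origin_um[0], spec)
    row0, row1 = _span_indices(rect[1], rect[3], spec.origin_um[1], spec)
    return ImagingRegion(rect_um=rect, col0=col0, col1=col1, row0=row0, row1=row1)


def region_from_rect(rect_um: tuple[float, float, float, float], spec: MosaicSpec) -> ImagingRegion:
    """Smallest lattice cover of an arbitrary stage-space rectangle (no margin)."""
    col0, col1 = _span_indices(rect_um[0], rect_um[2], spec.origin_um[0], spec)
    row0, row1 = _span_indices(rect_um[1], rect_um[3], spec.origin_um[1], spec)
    return ImagingRegion(rect_um=tuple(rect_um), col0=col0, col1=col1, row0=row0, row1=row1)


@dataclass
class WholeBrainPlan:
    """Per-layer planned regions plus the fixed-region alternative."""

    regions: list[ImagingRegion]
    fixed_region: ImagingRegion
    contours: list[BrainContour] = field(repr=False, default_factory=list)
    skipped_layers: list[int] = field(default_factory=list)

    @property
    def mosaics_per_layer(self) -> list[int]:
        return [r.n_mosaics for r in self.regions]

    @property
    def total_with_recognition(self) -> int:
        return sum(self.mosaics_per_layer)

    @property
    def total_without_recognition(self) -> int:
        return self.fixed_region.n_mosaics * len(self.regions)


def plan_whole_brain(
    layers: Sequence[np.ndarray],
    spec: MosaicSpec,
    params: ContourParams | None = None,
    margin_um: float = 288.0,
    first_region: ImagingRegion | None = None,
    stage_limits_um: tuple[float, float, float, float] | None = None,
) -> WholeBrainPlan:
    """Plan every layer of a brain from its ordered coronal previews.

    The region for layer k+1 derives from the recognized contour of layer k
    (the preview only exists once the layer is cut); layer 1 uses a
    configured full-coverage region (by default, the whole preview frame).
    A layer with an empty contour is skipped and the previous region reused.
    The fixed-region alternative — one grid sized to the maximum
    cross-section, repeated every layer — is computed for comparison.
    """
    params = params or ContourParams()
    if len(layers) == 0:
        raise InputError("need at least one layer")
    px = params.recognition_pixel_size_um

    contours: list[BrainContour] = []
    for layer in layers:
        contours.append(recognize_contour(layer, params))

    h, w = np.shape(layers[0])
    if first_region is None:
        first_region = region_from_rect((0.0, 0.0, w * px, h * px), spec)

    regions: list[ImagingRegion] = [first_region]
    skipped: list[int] = []
    for k in range(1, len(layers)):
        prev = contours[k - 1]
        if prev.empty:
            skipped.append(k)
            regions.append(regions[-1])
            continue
        try:
            regions.append(plan_region(prev, spec, margin_um, stage_limits_um))
        except PlanningError:
            import logging
            logging.getLogger(__name__).warning(
                "layer %d: planned region exceeds stage limits; clipping", k)
            clipped = _clip_plan(prev, spec, margin_um, stage_limits_um)
            regions.append(clipped)

    # fixed region: maximum cross-section over all recognized layers
    rects = [c.rect_um for c in contours if not c.empty]
    if rects:
        union = (min(r[0] for r in rects) - margin_um, min(r[1] for r in rects) - margin_um,
                 max(r[2] for r in rects) + margin_um, max(r[3] for r in rects) + margin_um)
        fixed = region_from_rect(union, spec)
    else:
        fixed = first_region
    return WholeBrainPlan(regions=regions, fixed_region=fixed,
                          contours=contours, skipped_layers=skipped)


def _clip_plan(contour, spec, margin_um, limits):
    xmin, ymin, xmax, ymax = contour.rect_um
    rect = [xmin - margin_um, ymin - margin_um, xmax + margin_um, ymax + margin_um]
    rect[0] = max(rect[0], limits[0])
    rect[1] = max(rect[1], limits[1])
    rect[2] = min(rect[2], limits[2])
    rect[3] = min(rect[3], limits[3])
    return region_from_rect(tuple(rect), spec)


def stitch_layer(
    tiles: Mapping[tuple[int, int], np.ndarray],
    spec: MosaicSpec,
    pixel_size_um: float = 0.32,
) -> np.ndarray:
    """Stitch a grid of reconstructed tiles into one coronal image.

    Tiles are keyed by ``(row, col)`` lattice indices and placed at their
    lattice positions; inside overlap strips, intensities are feathered with
    a linear ramp so constant tiles stitch to a constant and seams carry no
    double edge.  Missing tiles are zero-filled.
    """
    if not tiles:
        raise InputError("no tiles to stitch")
    shapes = {np.shape(t) for t in tiles.values()}
    if len(shapes) != 1:
        raise InputError("all tiles must share one shape")
    (th, tw), = shapes
    stride_px = int(round(spec.stride_um / pixel_size_um))
    overlap_px = tw - stride_px
    if overlap_px < 0:
        raise InputError("tile smaller than lattice stride")

    rows = sorted({k[0] for k in tiles})
    cols = sorted({k[1] for k in tiles})
    r0, c0 = rows[0], cols[0]
    out_h = (rows[-1] - r0) * stride_px + th
    out_w = (cols[-1] - c0) * stride_px + tw

    def _ramp(n: int) -> np.ndarray:
        r = np.ones(n)
        if overlap_px > 0:
            edge = np.linspace(1.0 / (overlap_px + 1), 1.0, overlap_px)
            r[:overlap_px] = edge
            r[-overlap_px:] = edge[::-1]
        return r

    weight2d = np.outer(_ramp(th), _ramp(tw))

    acc = np.zeros((out_h, out_w))
    wacc = np.zeros((out_h, out_w))
    for (r, c), tile in tiles.items():
        y = (r - r0) * stride_px
        x = (c - c0) * stride_px
        acc[y:y + th, x:x + tw] += np.asarray(tile, dtype=float) * weight2d
        wacc[y:y + th, x:x + tw] += weight2d
    with np.errstate(invalid="ignore"):
        out = np.where(wacc > 0, acc / np.maximum(wacc, 1e-30), 0.0)
    return out
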