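"""Imaging-plane geometry of the three channels and bead-based resolution measurement.

The instrument illuminates the block face with structured light whose blue
focal plane sits several micrometres deeper than the green/red planes because
of axial chromatic aberration in the illumination path.  Nuclear counterstain
applied to the freshly cut surface only penetrates the top few micrometres, so
the choice of detection-plane depths per channel decides whether
cytoarchitecture and fluorescent labels can be acquired simultaneously and
crosstalk-free.  This module encodes that plane arithmetic and the empirical
point-source resolution measurement (Gaussian FWHM of sub-diffraction beads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import InputError, MeasurementError

Channel = Literal["blue", "green", "red"]
PlaneMode = Literal["conjugated", "optimized"]

#: FWHM of a Gaussian of unit standard deviation.
GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Depth below the cut surface past which nuclear-counterstain signal has
#: decayed to the noise floor (μm).  Detection planes of the non-blue channels
#: are parked at this depth to avoid spectral crosstalk.
CROSSTALK_FREE_DEPTH_UM = 4.0


@dataclass
class OpticalGeometry:
    """Axial plane layout of the three detection channels.

    All depths are in μm below the sample (block-face) surface; positive is
    deeper into the sample.

    Parameters
    ----------
    axial_chromatic_separation:
        Measured axial distance between the blue and green/red illumination
        focal planes (μm).
    gdp_offset_below_surface:
        Depth of the green (and red) detection plane below the surface (μm).
    bdp_offset_below_surface:
        Depth of the blue detection plane; ``None`` until filled in by
        :func:`compute_detection_planes`.
    crosstalk_free_depth:
        Depth at which nuclear-stain crosstalk reaches the noise floor (μm).
    fov_side:
        Lateral side of one mosaic field of view (μm).
    pixel_size_lateral:
        Lateral sample-space pixel size (μm).
    z_step:
        Axial sampling step (μm).
    out_of_sample:
        Set when a computed detection plane lands above the block face
        (negative depth); flagged rather than raised because the instrument
        can still acquire such a plane — it simply sees no sample.
    """

    axial_chromatic_separation: float = 10.0
    gdp_offset_below_surface: float = 4.0
    bdp_offset_below_surface: float | None = None
    crosstalk_free_depth: float = CROSSTALK_FREE_DEPTH_UM
    fov_side: float = 576.0
    pixel_size_lateral: float = 0.32
    z_step: float = 2.0
    out_of_sample: bool = False

    def __post_init__(self):
        for name in ("axial_chromatic_separation", "gdp_offset_below_surface",
                     "crosstalk_free_depth", "fov_side", "pixel_size_lateral", "z_step"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def image_width_pixels(self) -> int:
        """Tile width consistent with ``fov_side = width × pixel_size``."""
        return int(round(self.fov_side / self.pixel_size_lateral))


def compute_detection_planes(geometry: OpticalGeometry, mode: PlaneMode) -> OpticalGeometry:
    """Fill in the blue detection-plane depth for a given imaging scheme.

    In the ``conjugated`` scheme every detection plane is conjugate to its
    channel's illumination plane, so the blue detection plane sits one full
    chromatic separation below the green one.  In the ``optimized`` scheme the
    blue camera is moved so its detection plane sits at the sample surface —
    i.e. one crosstalk-free depth *above* the green detection plane — where
    the nuclear counterstain is strongest.

    Returns a new :class:`OpticalGeometry` with ``bdp_offset_below_surface``
    set.  A negative resulting depth (plane above the block face) is flagged
    via ``out_of_sample`` rather than raised.
    """
    gdp = geometry.gdp_offset_below_surface
    if mode == "conjugated":
        bdp = gdp + geometry.axial_chromatic_separation
    elif mode == "optimized":
        bdp = gdp - geometry.crosstalk_free_depth
    else:
        raise InputError(f"unknown detection-plane mode: {mode!r}")
    return replace(geometry, bdp_offset_below_surface=bdp, out_of_sample=bdp < 0)


@dataclass
class ResolutionMeasurement:
    """Aggregate bead-resolution measurement for one channel (mean ± s.e.m.)."""

    channel: Channel
    lateral_fwhm: float
    axial_fwhm: float
    n_beads: int
    sem_lateral: float
    sem_axial: float

    def __post_init__(self):
        if self.lateral_fwhm <= 0 or self.axial_fwhm <= 0:
            raise InputError("FWHM must be positive")
        if self.sem_lateral < 0 or self.sem_axial < 0:
            raise InputError("s.e.m. must be non-negative")
        if self.n_beads < 1:
            raise InputError("need at least one bead")


def _gaussian(x, amplitude, center, sigma, offset):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_fwhm(coords_um: Sequence[float], intensity: Sequence[float]) -> float:
    """Least-squares Gaussian fit of a 1-D intensity profile; returns FWHM in μm.

    The model has amplitude, center, width and a constant offset, so the
    result is invariant under additive background and multiplicative scaling.

    Raises
    ------
    MeasurementError
        If the profile is too short, flat, or the fit does not converge.
    """
    x = np.asarray(coords_um, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("coords and intensity must be 1-D arrays of equal length")
    if x.size < 5:
        raise MeasurementError("need at least 5 samples for a Gaussian fit")
    span = float(np.ptp(y))
    if span <= 0 or not np.isfinite(span):
        raise MeasurementError("flat profile: no peak to fit")

    offset0 = float(np.min(y))
    amp0 = span
    center0 = float(x[np.argmax(y)])
    # second-moment width estimate of the background-subtracted profile
    w = np.clip(y - offset0, 0, None)
    if w.sum() > 0:
        sigma0 = float(np.sqrt(np.sum(w * (x - center0) ** 2) / w.sum()))
    else:  # pragma: no cover - span>0 implies w.sum()>0
        sigma0 = float(np.ptp(x)) / 4
    sigma0 = max(sigma0, float(np.min(np.diff(np.sort(x)))) / 2)

    try:
        import warnings
        with warnings.catch_warnings():
            # zero-residual fits legitimately have a singular covariance
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gaussian, x, y, p0=(amp0, center0, sigma0, offset0), maxfev=10000
            )
    except RuntimeError as exc:
        raise MeasurementError(f"Gaussian fit did not converge: {exc}") from exc
    amplitude, _, sigma, _ = popt
    if amplitude <= 0 or not np.isfinite(sigma):
        raise MeasurementError("fit converged to a non-peak solution")
    return GAUSSIAN_FWHM_FACTOR * abs(float(sigma))


def _quadratic_subpixel(values: np.ndarray, idx: int) -> float:
    """Sub-pixel peak location by quadratic interpolation around ``idx``."""
    if idx <= 0 or idx >= values.size - 1:
        return float(idx)
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def _find_bead_peaks(stack: np.ndarray, voxel_size: Sequence[float],
                     min_separation_um: float) -> list[tuple[int, int, int]]:
    """Local maxima above background, with an isolation filter.

    A bead is kept only if no other local maximum lies within
    ``min_separation_um`` (3D distance in μm); merged/crowded objects are
    excluded from aggregation.
    """
    background = float(np.median(stack))
    spread = float(np.std(stack))
    threshold = background + max(4.0 * spread, 1e-12)

    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (stack == ndimage.maximum_filter(stack, footprint=footprint)) & (stack > threshold)
    peaks = np.argwhere(local_max)
    if peaks.size == 0:
        raise MeasurementError("no bead found above background")

    scale = np.array([voxel_size[2], voxel_size[1], voxel_size[0]], dtype=float)  # stack is (z,y,x)
    coords_um = peaks * scale
    keep = []
    for i in range(len(peaks)):
        d = np.sqrt(((coords_um - coords_um[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        if np.min(d) > min_separation_um:
            keep.append(tuple(int(v) for v in peaks[i]))
    if not keep:
        raise MeasurementError("no isolated bead found (all within the separation limit)")
    return keep


def measure_bead_resolution(
    bead_stack: np.ndarray,
    voxel_size: Sequence[float] = (0.32, 0.32, 0.2),
    channel: Channel = "green",
    nominal_fwhm_um: float = 0.5,
    isolation_factor: float = 3.0,
) -> ResolutionMeasurement:
    """Measure lateral/axial FWHM from a 3-D bead stack (axes ``(z, y, x)``).

    For each isolated bead, a lateral line profile along x and an axial
    profile along z are taken through the intensity maximum (axial profile at
    the quadratically interpolated lateral peak, rounded to the nearest
    voxel), each fitted with :func:`fit_fwhm`.  Per-bead values are
    aggregated as mean ± s.e.m.

    ``voxel_size`` is ``(x, y, z)`` in μm.
    """
    stack = np.asarray(bead_stack, dtype=float)
    if stack.ndim != 3:
        raise InputError("bead stack must be 3-D (z, y, x)")
    peaks = _find_bead_peaks(stack, voxel_size, isolation_factor * nominal_fwhm_um)

    dx, dy, dz = (float(v) for v in voxel_size)
    nz, ny, nx = stack.shape
    laterals, axials = [], []
    for (z, y, x) in peaks:
        half_lat = max(int(round(4 * nominal_fwhm_um / dx)), 4)
        half_ax = max(int(round(4 * nominal_fwhm_um * 4 / dz)), 4)
        x0, x1 = max(0, x - half_lat), min(nx, x + half_lat + 1)
        z0, z1 = max(0, z - half_ax), min(nz, z + half_ax + 1)
        lat_profile = stack[z, y, x0:x1]
        # refine the lateral peak before cutting the axial profile
        xi = int(round(_quadratic_subpixel(stack[z, y, :], x)))
        xi = min(max(xi, 0), nx - 1)
        ax_profile = stack[z0:z1, y, xi]
        try:
            laterals.append(fit_fwhm(np.arange(x0, x1) * dx, lat_profile))
            axials.append(fit_fwhm(np.arange(z0, z1) * dz, ax_profile))
        except MeasurementError:
            continue  # bead at edge or too noisy: drop from aggregation
    if not laterals:
        raise MeasurementError("no bead yielded a convergent FWHM fit")

    lat = np.array(laterals)
    ax = np.array(axials)
    n = lat.size
    sem = lambda v: float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ResolutionMeasurement(
        channel=channel,
        lateral_fwhm=float(lat.mean()),
        axial_fwhm=float(ax.mean()),
        n_beads=int(n),
        sem_lateral=sem(lat),
        sem_axial=sem(ax),
    )
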