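"""Synthetic phantoms exercising every pipeline stage, with exact ground truth.

The generators emulate the imaging targets of block-face whole-brain
tomography at desk scale: coronal sections with irregular superellipse
outlines, ventricle-like holes and sectioning fragments; nuclear counterstain
confined to the top few μm of the cut face; sinusoidal structured-illumination
triplets (the DMD's binary fringes are low-pass filtered by the objective, so
only the sinusoidal fundamental reaches the sample); per-channel similarity
misalignments; sub-diffraction bead fields; and sparse green/red soma
populations with a planted co-location fraction.

Every generator is deterministic under its seed and returns the ground truth
alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .quantify import AtlasVolume, ColocatedPairs, Soma, SomaSet
from .reconstruction import PhaseTriplet
from .registration import SimilarityTransform2D, apply_transform

# ---------------------------------------------------------------------------
# structured illumination


def dapi_depth_attenuation(depth_um: float | np.ndarray,
                           confinement_um: float = 4.0) -> np.ndarray | float:
    """Nuclear-counterstain intensity vs depth below the cut surface.

    Real-time staining only penetrates a few μm in the sectioning time
    window; the signal decays steeply and reaches the noise floor at
    ``confinement_um``.  Modeled as exponential decay with a 1/3-confinement
    length scale (≈5% residual at the confinement depth).
    """
    return np.exp(-np.asarray(depth_um, dtype=float) / (confinement_um / 3.0))


def modulate_sim(
    scene: np.ndarray,
    period_um: float,
    phase: float,
    modulation_depth: float = 1.0,
    pixel_size_um: float = 0.32,
    out_of_focus: np.ndarray | float = 0.0,
    curvature: float = 0.0,
) -> np.ndarray:
    """One raw image of a fringe-illuminated scene.

    raw = scene · (1 + m·cos(2πx/period + φ)) / 2
          + out_of_focus · (1 + m_bg(r)·cos(2πx/period + φ))

    ``out_of_focus`` (scalar or image) stands in for light from outside the
    sectioning depth; ideally it carries no fringe contrast and cancels in
    the demodulation.  ``curvature`` (1/μm²) emulates field curvature of the
    illumination plane: the out-of-focus layer picks up residual fringe
    contrast growing quadratically with field radius,
    ``m_bg(r) = min(1, curvature·r²)·m``, so the demodulated background
    residual is strongest at the field edge, zero on the optical axis.
    """
    if not (0.0 <= modulation_depth <= 1.0):
        raise InputError("modulation depth must be in [0, 1]")
    if period_um <= 2.0 * pixel_size_um:
        raise InputError("fringe period at or below Nyquist would alias")
    scene = np.asarray(scene, dtype=float)
    h, w = scene.shape
    x = np.arange(w) * pixel_size_um
    y = np.arange(h) * pixel_size_um
    xx, yy = np.meshgrid(x, y)
    carrier = np.cos(2.0 * math.pi * xx / period_um + phase)
    raw = scene * (1.0 + modulation_depth * carrier) / 2.0
    if curvature:
        cx, cy = x[-1] / 2.0, y[-1] / 2.0
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        m_bg = np.minimum(1.0, curvature * r2) * modulation_depth
        raw = raw + np.asarray(out_of_focus, dtype=float) * (1.0 + m_bg * carrier)
    else:
        raw = raw + out_of_focus
    return raw


def make_phase_triplet(
    scene: np.ndarray,
    period_um: float = 17.5,
    modulation_depth: float = 1.0,
    pixel_size_um: float = 0.32,
    out_of_focus: np.ndarray | float = 0.0,
    curvature: float = 0.0,
    channel: str = "green",
    phase0: float = 0.0,
) -> PhaseTriplet:
    """Three π/2-stepped raws of one scene (phases φ₀, φ₀+π/2, φ₀+π)."""
    raws = [modulate_sim(scene, period_um, phase0 + k * math.pi / 2.0,
                         modulation_depth, pixel_size_um, out_of_focus, curvature)
            for k in range(3)]
    return PhaseTriplet(raw0=raws[0], raw1=raws[1], raw2=raws[2], channel=channel)


# ---------------------------------------------------------------------------
# calibration targets


def make_ring_target(
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.32,
    ring_period_um: float = 8.0,
    n_spokes: int = 6,
    seed: int | None = None,
) -> np.ndarray:
    """Concentric-ring calibration target with faint radial spokes.

    The rings provide dense structure out to the corners for correlation;
    the spokes break the rotational symmetry so in-plane rotation is
    observable.  Values in [0, 1]; a touch of seeded noise avoids perfectly
    flat windows.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy) * pixel_size_um
    theta = np.arctan2(yy - cy, xx - cx)
    img = 0.5 * (1.0 + np.cos(2.0 * math.pi * r / ring_period_um))
    if n_spokes:
        img *= 1.0 + 0.2 * np.cos(n_spokes * theta)
    img *= np.exp(-((r / (0.9 * r.max())) ** 4))  # soft vignette, keeps corners lit
    if seed is not None:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, 0.002, size=img.shape)
    return img


def inject_misalignment(
    tiles: dict[str, np.ndarray],
    transforms: dict[str, SimilarityTransform2D],
    envelope: tuple[float, float, float] = (10.0, 1.0, 0.01),
) -> tuple[dict[str, np.ndarray], dict]:
    """Warp per-channel tiles by known transforms; returns tiles + ground truth.

    ``envelope`` is (max |shift| px, max |rotation| deg, max |scale−1|); a
    transform outside it is applied anyway but noted in the ground truth,
    since the estimator's recovery guarantee only holds inside.
    """
    warped: dict[str, np.ndarray] = {}
    truth: dict = {"transforms": {}, "out_of_envelope": []}
    for ch, img in tiles.items():
        t = transforms.get(ch)
        if t is None or t.is_identity:
            warped[ch] = np.asarray(img, dtype=float).copy()
        else:
            warped[ch] = apply_transform(img, t)
        if t is not None:
            truth["transforms"][ch] = t.to_dict()
            shift_px = max(abs(t.dx_um), abs(t.dy_um)) / t.pixel_size_um
            if (shift_px > envelope[0] or abs(t.rotation_deg) > envelope[1]
                    or abs(t.scale - 1.0) > envelope[2]):
                truth["out_of_envelope"].append(ch)
    return warped, truth


def random_similarity(rng: np.random.Generator,
                      max_shift_px: float = 10.0,
                      max_rotation_deg: float = 1.0,
                      max_scale_dev: float = 0.01,
                      pixel_size_um: float = 0.32) -> SimilarityTransform2D:
    """A random transform uniform inside the stated recovery envelope."""
    return SimilarityTransform2D(
        dx_um=float(rng.uniform(-max_shift_px, max_shift_px)) * pixel_size_um,
        dy_um=float(rng.uniform(-max_shift_px, max_shift_px)) * pixel_size_um,
        rotation_deg=float(rng.uniform(-max_rotation_deg, max_rotation_deg)),
        scale=float(1.0 + rng.uniform(-max_scale_dev, max_scale_dev)),
        pixel_size_um=pixel_size_um,
    )


# ---------------------------------------------------------------------------
# bead fields


def make_bead_field(
    n_beads: int = 10,
    shape: tuple[int, int, int] = (64, 256, 256),
    sigma_um: tuple[float, float] = (0.20, 1.0),  # (lateral, axial)
    voxel_size_um: tuple[float, float, float] = (0.32, 0.32, 0.2),
    min_separation_factor: float = 3.0,
    amplitude: float = 10000.0,
    read_noise: float = 0.0,
    shot_noise: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Gaussian point emitters on a dark background, well separated.

    Beads are rejection-sampled so every pair is at least
    ``min_separation_factor × lateral FWHM`` apart (same isolation rule the
    measurement applies).  Returns the stack (z, y, x) and the planted
    (x, y, z) voxel-coordinate centers.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dx, dy, dz = voxel_size_um
    sig_lat, sig_ax = sigma_um
    fwhm_lat = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sig_lat
    min_sep = min_separation_factor * fwhm_lat * 2.0  # generous: 2× the filter radius

    margin_xy = int(math.ceil(5 * sig_lat / dx)) + 2
    margin_z = int(math.ceil(5 * sig_ax / dz)) + 2
    if 2 * margin_xy >= nx or 2 * margin_z >= nz:
        raise InputError("stack too small for the requested PSF")

    centers: list[tuple[float, float, float]] = []
    attempts = 0
    while len(centers) < n_beads:
        attempts += 1
        if attempts > 1000 * max(n_beads, 1):
            raise InputError("cannot place beads at the requested separation")
        cx = rng.uniform(margin_xy, nx - 1 - margin_xy)
        cy = rng.uniform(margin_xy, ny - 1 - margin_xy)
        cz = rng.uniform(margin_z, nz - 1 - margin_z)
        ok = True
        for (px_, py_, pz_) in centers:
            d = math.sqrt(((cx - px_) * dx) ** 2 + ((cy - py_) * dy) ** 2
                          + ((cz - pz_) * dz) ** 2)
            if d < min_sep:
                ok = False
                break
        if ok:
            centers.append((cx, cy, cz))

    stack = np.zeros(shape, dtype=float)
    zz = np.arange(nz)[:, None, None] * dz
    yy = np.arange(ny)[None, :, None] * dy
    xx = np.arange(nx)[None, None, :] * dx
    for (cx, cy, cz) in centers:
        stack += amplitude * np.exp(
            -0.5 * (((xx - cx * dx) / sig_lat) ** 2
                    + ((yy - cy * dy) / sig_lat) ** 2
                    + ((zz - cz * dz) / sig_ax) ** 2))
    if shot_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if read_noise > 0:
        stack = stack + rng.normal(0.0, read_noise, size=stack.shape)
    return stack, centers


# ---------------------------------------------------------------------------
# coronal sections and whole phantom brains


@dataclass
class CoronalTruth:
    """Ground truth of one generated coronal section."""

    tissue_mask: np.ndarray
    ventricle_mask: np.ndarray
    fragment_masks: list[np.ndarray] = field(default_factory=list)


def _superellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                       semi_axes: tuple[float, float], exponent: float = 2.5,
                       rotation_deg: float = 0.0) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    th = math.radians(rotation_deg)
    u = (xx - center[1]) * math.cos(th) + (yy - center[0]) * math.sin(th)
    v = -(xx - center[1]) * math.sin(th) + (yy - center[0]) * math.cos(th)
    a, b = semi_axes
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (np.abs(u) / a) ** exponent + (np.abs(v) / b) ** exponent
    return val <= 1.0


def make_coronal_section(
    shape: tuple[int, int] = (700, 1000),
    pixel_size_um: float = 1.68,
    semi_axes_um: tuple[float, float] = (650.0, 450.0),
    exponent: float = 2.5,
    ventricle_frac: float = 0.18,
    n_fragments: int = 3,
    fragment_radius_px: tuple[int, int] = (10, 26),
    nuclei_density_per_mm2: float = 1500.0,
    tissue_level: float = 400.0,
    background_level: float = 100.0,
    noise_sigma: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, CoronalTruth]:
    """One nuclear-counterstain coronal preview with planted artifacts.

    Tissue is a wobbled superellipse; a ventricle-like hole is carved near
    the center; ``n_fragments`` sectioning-debris blobs are scattered outside
    the tissue; nuclei appear as bright dots over a diffuse tissue level;
    Gaussian read noise is added everywhere.  The returned truth contains the
    *filled* tissue mask (ventricle included, as the contour stage defines
    tissue) and the individual fragment masks.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    a_px = semi_axes_um[0] / pixel_size_um
    b_px = semi_axes_um[1] / pixel_size_um
    center = (h / 2.0 + rng.uniform(-0.05, 0.05) * h,
              w / 2.0 + rng.uniform(-0.05, 0.05) * w)
    tissue = _superellipse_mask(shape, center, (a_px, b_px), exponent,
                                rotation_deg=float(rng.uniform(-10, 10)))

    ventricle = np.zeros(shape, dtype=bool)
    if ventricle_frac > 0:
        ventricle = _superellipse_mask(
            shape,
            (center[0] + rng.uniform(-0.1, 0.1) * b_px,
             center[1] + rng.uniform(-0.1, 0.1) * a_px),
            (ventricle_frac * a_px, ventricle_frac * b_px * 0.7),
            2.0, rotation_deg=float(rng.uniform(0, 180)))
        ventricle &= tissue

    img = np.full(shape, background_level, dtype=float)
    visible = tissue & ~ventricle
    img[visible] = tissue_level

    # nuclei as bright dots on the tissue
    area_mm2 = visible.sum() * (pixel_size_um / 1000.0) ** 2
    n_nuclei = rng.poisson(nuclei_density_per_mm2 * area_mm2)
    if n_nuclei > 0:
        ys, xs = np.nonzero(visible)
        pick = rng.integers(0, len(ys), size=n_nuclei)
        img[ys[pick], xs[pick]] += rng.uniform(200, 600, size=n_nuclei)

    fragments: list[np.ndarray] = []
    outside = ~tissue
    ys, xs = np.nonzero(outside)
    placed = 0
    guard = 0
    if len(ys) == 0:
        n_fragments = 0  # tissue fills the frame: nowhere to scatter debris
    while placed < n_fragments and guard < 200:
        guard += 1
        i = rng.integers(0, len(ys))
        fy, fx = float(ys[i]), float(xs[i])
        rad = float(rng.integers(*fragment_radius_px))
        # keep fragments clear of the tissue and of the image border
        if fy < rad + 2 or fy > h - rad - 3 or fx < rad + 2 or fx > w - rad - 3:
            continue
        frag = _superellipse_mask(shape, (fy, fx), (rad, rad * rng.uniform(0.5, 1.0)),
                                  2.0, rotation_deg=float(rng.uniform(0, 180)))
        if (frag & tissue).any():
            continue
        img[frag] = tissue_level * rng.uniform(0.8, 1.2)
        fragments.append(frag)
        placed += 1

    img += rng.normal(0.0, noise_sigma, size=shape)
    return img, CoronalTruth(tissue_mask=tissue, ventricle_mask=ventricle,
                             fragment_masks=fragments)


@dataclass
class PhantomSpec:
    """Study conditions of one synthetic phantom brain.

    The anterior–posterior taper is a half-sine: the cross-section grows to a
    maximum mid-brain and shrinks again, like a real coronal series.
    """

    n_layers: int = 6
    shape: tuple[int, int] = (700, 1000)
    recognition_pixel_size_um: float = 1.68
    max_semi_axes_um: tuple[float, float] = (650.0, 450.0)
    min_axis_fraction: float = 0.45
    superellipse_exponent: float = 2.5
    ventricle_frac: float = 0.18
    n_fragments: int = 3
    nuclei_density_per_mm2: float = 1500.0
    noise_sigma: float = 20.0
    n_green_somas: int = 10000
    n_red_somas: int = 9000
    coloc_fraction: float = 0.0022
    coloc_max_dist_um: float = 0.8
    soma_min_separation_um: float = 5.0
    atlas_regions: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise InputError("coloc_fraction must be in [0, 1]")
        if self.n_layers < 1:
            raise InputError("need at least one layer")
        if min(self.n_green_somas, self.n_red_somas) < 0:
            raise InputError("soma counts must be non-negative")


@dataclass
class Phantom:
    """Generated phantom brain with full ground truth."""

    spec: PhantomSpec
    dapi_layers: list[np.ndarray]
    truths: list[CoronalTruth]
    green: SomaSet
    red: SomaSet
    true_pairs: ColocatedPairs
    atlas: AtlasVolume


def _axis_profile(spec: PhantomSpec) -> list[float]:
    """Per-layer size factor: half-sine taper from min → max → min."""
    n = spec.n_layers
    if n == 1:
        return [1.0]
    lo = spec.min_axis_fraction
    return [lo + (1.0 - lo) * math.sin(math.pi * (k + 0.5) / n) for k in range(n)]


def make_soma_populations(
    n_green: int,
    n_red: int,
    coloc_fraction: float,
    bounds_um: tuple[float, float, float],
    coloc_max_dist_um: float = 0.8,
    min_separation_um: float = 5.0,
    region_probs: np.ndarray | None = None,
    atlas: AtlasVolume | None = None,
    seed: int = 0,
) -> tuple[SomaSet, SomaSet, ColocatedPairs]:
    """Green/red soma coordinate sets with a planted co-location fraction.

    A ``coloc_fraction`` of the green somas is duplicated into the red
    channel within ``coloc_max_dist_um``; all other somas (within and across
    channels) keep at least ``min_separation_um`` apart, so the planted pairs
    are exactly the mutual-NN pairs below 1 μm.  If ``region_probs`` and
    ``atlas`` are given, green somas are placed region by region with those
    probabilities (rejection sampling on the label volume).
    """
    rng = np.random.default_rng(seed)
    bx, by, bz = bounds_um
    n_pairs = int(round(coloc_fraction * n_green))

    def _sample_point() -> np.ndarray:
        return np.array([rng.uniform(0, bx), rng.uniform(0, by), rng.uniform(0, bz)])

    def _sample_in_region(target_label: int) -> np.ndarray:
        for _ in range(10000):
            p = _sample_point()
            if atlas.label_at(*p) == target_label:
                return p
        raise InputError(f"cannot place soma in region {target_label}")

    region_labels = None
    if region_probs is not None:
        if atlas is None:
            raise InputError("region placement needs an atlas")
        region_labels = sorted(set(atlas.hierarchy) )
        region_probs = np.asarray(region_probs, dtype=float)
        region_probs = region_probs / region_probs.sum()

    # spatial hash on a min_separation-sized grid keeps placement O(n)
    cell = max(min_separation_um, 1e-6)
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _far_enough(p: np.ndarray) -> bool:
        ci = tuple(int(v // cell) for v in p)
        for oz in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for ox in (-1, 0, 1):
                    for q in grid.get((ci[0] + ox, ci[1] + oy, ci[2] + oz), ()):
                        if float(np.sum((p - q) ** 2)) < min_separation_um ** 2:
                            return False
        return True

    def _register(p: np.ndarray) -> None:
        grid.setdefault(tuple(int(v // cell) for v in p), []).append(p)

    def _place(region_idx: int | None = None) -> np.ndarray:
        for _ in range(10000):
            if region_idx is not None:
                p = _sample_in_region(region_labels[region_idx])
            else:
                p = _sample_point()
            if not _far_enough(p):
                continue
            _register(p)
            return p
        raise InputError("soma placement failed: volume too crowded")

    green_coords = []
    for i in range(n_green):
        ridx = None
        if region_labels is not None:
            ridx = int(rng.choice(len(region_labels), p=region_probs))
        green_coords.append(_place(ridx))

    red_coords: list[np.ndarray] = []
    pair_list: list[tuple[int, int, float]] = []
    # first n_pairs green somas get a red twin within the co-location distance
    for i in range(n_pairs):
        offset = rng.normal(size=3)
        offset *= rng.uniform(0.1, coloc_max_dist_um) / np.linalg.norm(offset)
        twin = green_coords[i] + offset
        red_coords.append(twin)
        pair_list.append((i + 1, len(red_coords), float(np.linalg.norm(offset))))
    for i in range(n_red - n_pairs):
        red_coords.append(_place())

    green = SomaSet(
        somas=[Soma(id=i + 1, x=c[0], y=c[1], z=c[2], channel="green")
               for i, c in enumerate(green_coords)],
        channel="green")
    red = SomaSet(
        somas=[Soma(id=i + 1, x=c[0], y=c[1], z=c[2], channel="red")
               for i, c in enumerate(red_coords)],
        channel="red")
    return green, red, ColocatedPairs(pairs=pair_list)


def make_atlas(
    shape: tuple[int, int, int] = (64, 128, 128),
    voxel_size_um: tuple[float, float, float] = (10.0, 10.0, 10.0),
    n_regions: int = 3,
    n_parents: int = 2,
) -> AtlasVolume:
    """Synthetic pre-aligned label volume: ``n_regions`` slabs along x.

    Sub-region k (label k+1) occupies an equal x-slab; parents wrap the
    sub-regions round-robin, giving a two-level hierarchy for rollup tests.
    This is a stand-in for a real reference atlas, generated in the data
    frame (no deformation registration involved).
    """
    nz, ny, nx = shape
    labels = np.zeros(shape, dtype=np.int32)
    edges = np.linspace(0, nx, n_regions + 1).astype(int)
    hierarchy: dict[int, dict] = {}
    for k in range(n_regions):
        labels[:, :, edges[k]:edges[k + 1]] = k + 1
        parent = 100 + (k % n_parents)
        hierarchy[k + 1] = {"name": f"sub_{k + 1}", "parent_id": parent,
                            "parent_name": f"parent_{parent}"}
    return AtlasVolume(labels=labels, voxel_size_um=voxel_size_um, hierarchy=hierarchy)


def render_soma_volume(
    coords_um: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 2.0),
    sigma_um: float = 4.0,
    amplitude: float = 1000.0,
    snr: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Render somas as 3-D Gaussian blobs with Gaussian read noise at a given SNR."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dx, dy, dz = voxel_size_um
    vol = np.zeros(shape, dtype=float)
    rad_vox = (int(math.ceil(3 * sigma_um / dz)), int(math.ceil(3 * sigma_um / dy)),
               int(math.ceil(3 * sigma_um / dx)))
    for (x, y, z) in np.asarray(coords_um, dtype=float):
        k, j, i = z / dz, y / dy, x / dx
        k0, k1 = max(0, int(k) - rad_vox[0]), min(nz, int(k) + rad_vox[0] + 1)
        j0, j1 = max(0, int(j) - rad_vox[1]), min(ny, int(j) + rad_vox[1] + 1)
        i0, i1 = max(0, int(i) - rad_vox[2]), min(nx, int(i) + rad_vox[2] + 1)
        zz = (np.arange(k0, k1) * dz - z)[:, None, None]
        yy = (np.arange(j0, j1) * dy - y)[None, :, None]
        xx = (np.arange(i0, i1) * dx - x)[None, None, :]
        vol[k0:k1, j0:j1, i0:i1] += amplitude * np.exp(
            -0.5 * (zz ** 2 + yy ** 2 + xx ** 2) / sigma_um ** 2)
    if snr > 0:
        vol = vol + rng.normal(0.0, amplitude / snr, size=shape)
    return vol


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a whole phantom brain: DAPI layers, soma populations, atlas.

    All randomness derives from ``spec.seed``; the same spec yields
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    layer_seeds = rng.integers(0, 2 ** 31 - 1, size=spec.n_layers)

    layers, truths = [], []
    for k, factor in enumerate(_axis_profile(spec)):
        semi = (spec.max_semi_axes_um[0] * factor, spec.max_semi_axes_um[1] * factor)
        img, truth = make_coronal_section(
            shape=spec.shape,
            pixel_size_um=spec.recognition_pixel_size_um,
            semi_axes_um=semi,
            exponent=spec.superellipse_exponent,
            ventricle_frac=spec.ventricle_frac,
            n_fragments=spec.n_fragments,
            nuclei_density_per_mm2=spec.nuclei_density_per_mm2,
            noise_sigma=spec.noise_sigma,
            seed=int(layer_seeds[k]),
        )
        layers.append(img)
        truths.append(truth)

    atlas = make_atlas(n_regions=spec.atlas_regions)
    bounds = (atlas.labels.shape[2] * atlas.voxel_size_um[0],
              atlas.labels.shape[1] * atlas.voxel_size_um[1],
              atlas.labels.shape[0] * atlas.voxel_size_um[2])
    green, red, pairs = make_soma_populations(
        spec.n_green_somas, spec.n_red_somas, spec.coloc_fraction,
        bounds_um=bounds, coloc_max_dist_um=spec.coloc_max_dist_um,
        min_separation_um=spec.soma_min_separation_um,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
    return Phantom(spec=spec, dapi_layers=layers, truths=truths,
                   green=green, red=red, true_pairs=pairs, atlas=atlas)
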