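"""Lateral chromatic co-registration between detection channels.

The three cameras view the sample through a shared objective but separate
emission paths, so images of the same structure differ by a small lateral
similarity transform (shift, rotation, isotropic scale) per channel.  The
green channel is the fixed reference; transforms are fitted once on a
structured calibration target by maximizing the normalized cross-correlation
and then applied to every tile of a dataset.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform as _SkSimilarity
from skimage.transform import warp as _sk_warp

from .errors import InputError, RegistrationError

log = logging.getLogger(__name__)


@dataclass
class SimilarityTransform2D:
    """Lateral correction for one channel: translate, rotate, scale about the image center.

    ``dx_um``/``dy_um`` translate along image x (columns) / y (rows) in μm;
    rotation is in degrees (positive rotates +x toward +y, i.e. clockwise on
    screen with row-down display); scale is isotropic and dimensionless.
    The identity is ``dx=dy=rotation=0, scale=1``.
    """

    dx_um: float = 0.0
    dy_um: float = 0.0
    rotation_deg: float = 0.0
    scale: float = 1.0
    channel: str | None = None
    reference_channel: str = "green"
    pixel_size_um: float = 0.32
    correlation: float | None = None
    fitted_on: str | None = None

    def __post_init__(self):
        if self.scale <= 0:
            raise InputError("scale must be positive")

    @property
    def is_identity(self) -> bool:
        return (self.dx_um == 0.0 and self.dy_um == 0.0
                and self.rotation_deg == 0.0 and self.scale == 1.0)

    # -- pixel-space matrix machinery -------------------------------------
    def pixel_matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3×3 homogeneous matrix mapping moving→fixed pixel coords (x, y).

        Rotation/scale pivot at the image center (the channels share an
        optical axis), translation in pixels appended last.
        """
        h, w = shape[:2]
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        s, th = self.scale, math.radians(self.rotation_deg)
        tx, ty = self.dx_um / self.pixel_size_um, self.dy_um / self.pixel_size_um
        rot = _SkSimilarity(scale=s, rotation=th)
        shift_in = _SkSimilarity(translation=(-cx, -cy))
        shift_out = _SkSimilarity(translation=(cx + tx, cy + ty))
        return shift_out.params @ rot.params @ shift_in.params

    @classmethod
    def from_pixel_matrix(cls, matrix: np.ndarray, shape: tuple[int, int],
                          pixel_size_um: float = 0.32, **kw) -> "SimilarityTransform2D":
        """Recover (dx, dy, rotation, scale) from a center-pivot pixel matrix."""
        h, w = shape[:2]
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        lin = matrix[:2, :2]
        scale = float(np.sqrt(abs(np.linalg.det(lin))))
        rot = math.degrees(math.atan2(lin[1, 0], lin[0, 0]))
        b = matrix[:2, 2]
        d = b - c + lin @ c
        return cls(dx_um=float(d[0]) * pixel_size_um, dy_um=float(d[1]) * pixel_size_um,
                   rotation_deg=rot, scale=scale, pixel_size_um=pixel_size_um, **kw)

    def compose(self, other: "SimilarityTransform2D", shape: tuple[int, int]) -> "SimilarityTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        m = self.pixel_matrix(shape) @ other.pixel_matrix(shape)
        return SimilarityTransform2D.from_pixel_matrix(
            m, shape, pixel_size_um=self.pixel_size_um,
            channel=self.channel, reference_channel=self.reference_channel)

    def inverse(self, shape: tuple[int, int]) -> "SimilarityTransform2D":
        m = np.linalg.inv(self.pixel_matrix(shape))
        return SimilarityTransform2D.from_pixel_matrix(
            m, shape, pixel_size_um=self.pixel_size_um,
            channel=self.channel, reference_channel=self.reference_channel)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "reference_channel": self.reference_channel,
            "dx_um": self.dx_um, "dy_um": self.dy_um,
            "rotation_deg": self.rotation_deg, "scale": self.scale,
            "pixel_size_um": self.pixel_size_um,
            "correlation": self.correlation,
            "fitted_on": self.fitted_on,
        }

    def save(self, path: str | Path) -> None:
        d = self.to_dict()
        if d["fitted_on"] is None:
            d["fitted_on"] = _dt.date.today().isoformat()
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityTransform2D":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ColocationErrorReport:
    """Per-probe residual displacement between two channels, in μm."""

    probe_points: list[tuple[int, int]]
    residuals_um: list[float]
    max_center: float
    max_corner: float
    skipped: list[tuple[int, int]] = field(default_factory=list)

    @property
    def max_residual(self) -> float:
        return max(self.residuals_um) if self.residuals_um else float("nan")


def apply_transform(image: np.ndarray, t: SimilarityTransform2D,
                    order: int = 1, return_mask: bool = False):
    """Resample ``image`` under ``t`` (moving→fixed) about the image center.

    Bilinear interpolation by default (``order=3`` for bicubic);
    out-of-bounds pixels are filled with 0.  The identity transform bypasses
    interpolation and returns an exact copy.  With ``return_mask=True`` also
    returns the in-bounds validity mask.
    """
    img = np.asarray(image)
    if not all(np.isfinite(v) for v in (t.dx_um, t.dy_um, t.rotation_deg, t.scale)):
        raise InputError("transform parameters must be finite")
    if t.is_identity:
        out = img.astype(float, copy=True)
        mask = np.ones(img.shape, dtype=bool)
    else:
        tf = _SkSimilarity(matrix=t.pixel_matrix(img.shape))
        out = _sk_warp(img.astype(float), inverse_map=tf.inverse, order=order,
                       cval=0.0, preserve_range=True)
        mask = _sk_warp(np.ones(img.shape), inverse_map=tf.inverse, order=0,
                        cval=0.0, preserve_range=True) > 0.5
    if return_mask:
        return out, mask
    return out


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalized cross-correlation of two images over a validity mask."""
    av = a[mask].astype(float)
    bv = b[mask].astype(float)
    av -= av.mean()
    bv -= bv.mean()
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def _warp_ncc(fixed: np.ndarray, moving: np.ndarray,
              params: Sequence[float], pixel_size_um: float) -> float:
    dx, dy, rot, scale = params
    t = SimilarityTransform2D(dx_um=dx * pixel_size_um, dy_um=dy * pixel_size_um,
                              rotation_deg=rot, scale=scale, pixel_size_um=pixel_size_um)
    warped, mask = apply_transform(moving, t, return_mask=True)
    if mask.sum() < 0.25 * mask.size:
        return -1.0
    return _ncc(fixed, warped, mask)


def estimate_transform(
    fixed: np.ndarray,
    moving: np.ndarray,
    pixel_size_um: float = 0.32,
    rotation_bound_deg: float = 1.0,
    scale_bound: float = 0.01,
    correlation_floor: float = 0.2,
    channel: str | None = None,
) -> SimilarityTransform2D:
    """Fit the similarity transform aligning ``moving`` onto ``fixed``.

    Strategy (derivative-free, robust on the smooth correlation surface of a
    structured calibration target): a coarse grid over rotation × scale with
    the translation at each node solved by sub-pixel phase correlation,
    followed by Nelder–Mead refinement of all four parameters on the
    correlation objective.

    Raises
    ------
    RegistrationError
        If either image is structureless or the achieved correlation stays
        below ``correlation_floor``.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise InputError("fixed and moving images must share shape")
    if float(np.std(moving)) == 0.0 or float(np.std(fixed)) == 0.0:
        raise RegistrationError("image has no structure (constant intensity)")

    # --- coarse grid: rotation × scale, translation by phase correlation ---
    best = None
    rotations = np.linspace(-rotation_bound_deg, rotation_bound_deg, 5)
    scales = 1.0 + np.linspace(-scale_bound, scale_bound, 5)
    for rot in rotations:
        for s in scales:
            t_rs = SimilarityTransform2D(rotation_deg=float(rot), scale=float(s),
                                         pixel_size_um=pixel_size_um)
            prewarped = apply_transform(moving, t_rs)
            shift, _, _ = phase_cross_correlation(fixed, prewarped,
                                                  upsample_factor=10, normalization=None)
            dy, dx = float(shift[0]), float(shift[1])
            params = (dx, dy, float(rot), float(s))
            # residual translation composes with the rotation/scale prewarp
            score = _warp_ncc(fixed, moving, _compose_params(params, t_rs, fixed.shape,
                                                             pixel_size_um), pixel_size_um)
            cand = (_compose_params(params, t_rs, fixed.shape, pixel_size_um), score)
            if best is None or cand[1] > best[1]:
                best = cand
    grid_params, grid_score = best

    # --- local refinement ------------------------------------------------
    res = optimize.minimize(
        lambda p: -_warp_ncc(fixed, moving, p, pixel_size_um),
        x0=np.asarray(grid_params, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400,
                 "initial_simplex": _initial_simplex(grid_params)},
    )
    params, score = (res.x, -res.fun) if -res.fun >= grid_score else (grid_params, grid_score)

    if score < correlation_floor:
        raise RegistrationError(
            f"registration failed: correlation {score:.3f} below floor {correlation_floor}")
    dx, dy, rot, s = (float(v) for v in params)
    return SimilarityTransform2D(
        dx_um=dx * pixel_size_um, dy_um=dy * pixel_size_um,
        rotation_deg=rot, scale=s, channel=channel,
        pixel_size_um=pixel_size_um, correlation=score,
        fitted_on=_dt.date.today().isoformat(),
    )


def _compose_params(params, t_rs, shape, pixel_size_um):
    """Compose a pure translation (after a rotation/scale prewarp) into one parameter vector."""
    dx, dy, _, _ = params
    t_shift = SimilarityTransform2D(dx_um=dx * pixel_size_um, dy_um=dy * pixel_size_um,
                                    pixel_size_um=pixel_size_um)
    t_full = t_shift.compose(t_rs, shape)
    return (t_full.dx_um / pixel_size_um, t_full.dy_um / pixel_size_um,
            t_full.rotation_deg, t_full.scale)


def _initial_simplex(p0):
    steps = (0.5, 0.5, 0.05, 0.001)
    simplex = [np.asarray(p0, dtype=float)]
    for i, step in enumerate(steps):
        v = np.asarray(p0, dtype=float).copy()
        v[i] += step
        simplex.append(v)
    return np.array(simplex)


def default_probe_points(shape: tuple[int, int], window: int = 128) -> list[tuple[int, int]]:
    """Center and four corners of the field, inset by half a probe window."""
    h, w = shape[:2]
    m = window // 2
    return [(h // 2, w // 2), (m, m), (m, w - 1 - m), (h - 1 - m, m), (h - 1 - m, w - 1 - m)]


def measure_colocation_error(
    img_a: np.ndarray,
    img_b: np.ndarray,
    probe_points: Sequence[tuple[int, int]] | None = None,
    window: int = 128,
    pixel_size_um: float = 0.32,
) -> ColocationErrorReport:
    """Residual channel displacement at probe points, by windowed phase correlation.

    Probe points are ``(row, col)`` pixel coordinates; the default probes the
    field center and four corners.  Each probe's local displacement between
    the two channels is the sub-pixel cross-correlation peak offset of a
    ``window``-sized crop, converted to μm.  Structureless windows are
    skipped with a warning.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("images must share shape")
    if probe_points is None:
        probe_points = default_probe_points(a.shape, window)
    h, w = a.shape
    half = window // 2
    residuals, used, skipped = [], [], []
    for (r, c) in probe_points:
        r0, r1 = max(0, r - half), min(h, r + half)
        c0, c1 = max(0, c - half), min(w, c + half)
        ca, cb = a[r0:r1, c0:c1], b[r0:r1, c0:c1]
        if float(np.std(ca)) == 0.0 or float(np.std(cb)) == 0.0:
            log.warning("probe (%d, %d) skipped: flat window", r, c)
            skipped.append((r, c))
            continue
        # Hann apodization suppresses spectral leakage from the window edges,
        # which otherwise biases the sub-pixel peak on quasi-periodic content
        taper = np.outer(np.hanning(ca.shape[0]), np.hanning(ca.shape[1]))
        shift, _, _ = phase_cross_correlation(ca * taper, cb * taper,
                                              upsample_factor=100)
        residuals.append(float(np.hypot(shift[0], shift[1])) * pixel_size_um)
        used.append((r, c))
    center = (h // 2, w // 2)
    center_res, corner_res = [], []
    for pt, res in zip(used, residuals):
        if abs(pt[0] - center[0]) <= half and abs(pt[1] - center[1]) <= half:
            center_res.append(res)
        else:
            corner_res.append(res)
    return ColocationErrorReport(
        probe_points=list(used),
        residuals_um=residuals,
        max_center=max(center_res) if center_res else float("nan"),
        max_corner=max(corner_res) if corner_res else float("nan"),
        skipped=skipped,
    )
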