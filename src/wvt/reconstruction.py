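"""Three-phase optical-sectioning (SIM) and wide-field (WF) tile reconstruction.

Each field of view is acquired three times per channel under a sinusoidal
fringe pattern stepped by π/2 (nominal phases 0, π/2, π).  Writing the raws as

    I_k = A + B·cos(φ + k·π/2),  k = 0, 1, 2

the in-focus, fringe-modulated component B is recovered pixelwise by

    I_sim = ½·√((I0 − I2)² + (2·I1 − I0 − I2)²)

since I0 − I2 = 2B·cosφ and 2I1 − I0 − I2 = −2B·sinφ.  Unmodulated
(out-of-focus) light contributes only to A and cancels exactly, which is what
gives SIM its optical sectioning.  The wide-field image is the plain
superposition I0 + I1 + I2 and keeps all light; it is the mode of choice for
the blue channel in the optimized scheme, where the detection plane is
deliberately decoupled from the blue illumination plane and the fringes carry
almost no modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .errors import InputError

Channel = Literal["blue", "green", "red"]
Mode = Literal["SIM", "WF"]

#: Reconstruction mode per channel in the optimized multicolor scheme:
#: optical sectioning for the fluorescent labels, wide-field for the
#: surface-confined nuclear counterstain.
DEFAULT_SCHEME: dict[str, str] = {"blue": "WF", "green": "SIM", "red": "SIM"}

#: Saturation value of the 16-bit cameras.
SATURATION_LEVEL = 65535


@dataclass
class PhaseTriplet:
    """Three same-shaped raw images of one field of view, phases 0, π/2, π."""

    raw0: np.ndarray
    raw1: np.ndarray
    raw2: np.ndarray
    channel: Channel = "green"
    fov_index: tuple[int, int] = (0, 0)

    def __post_init__(self):
        shapes = {np.shape(self.raw0), np.shape(self.raw1), np.shape(self.raw2)}
        if len(shapes) != 1:
            raise InputError(f"phase raws must share one shape, got {sorted(shapes)}")
        if np.ndim(self.raw0) != 2:
            raise InputError("phase raws must be 2-D images")

    @property
    def raws(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.raw0, self.raw1, self.raw2

    def saturation_mask(self) -> np.ndarray:
        """True where any raw hit the camera's full well (propagated, not repaired)."""
        mask = np.zeros(np.shape(self.raw0), dtype=bool)
        for raw in self.raws:
            if np.issubdtype(np.asarray(raw).dtype, np.integer):
                mask |= np.asarray(raw) >= SATURATION_LEVEL
        return mask


@dataclass
class ReconstructedTile:
    """A reconstructed single-FOV image with its provenance."""

    pixels: np.ndarray
    mode: Mode
    channel: Channel
    fov_index: tuple[int, int] = (0, 0)
    pixel_size: float = 0.32
    saturation_mask: np.ndarray | None = field(default=None, repr=False)


def reconstruct_sim(t: PhaseTriplet, pixel_size: float = 0.32) -> ReconstructedTile:
    """Demodulate a π/2-stepped phase triplet into an optically sectioned tile.

    Output is non-negative by construction and invariant to any constant
    added to all three raws (the out-of-focus/DC term cancels).
    """
    i0, i1, i2 = (np.asarray(r, dtype=float) for r in t.raws)
    pixels = 0.5 * np.sqrt((i0 - i2) ** 2 + (2.0 * i1 - i0 - i2) ** 2)
    return ReconstructedTile(pixels=pixels, mode="SIM", channel=t.channel,
                             fov_index=t.fov_index, pixel_size=pixel_size,
                             saturation_mask=t.saturation_mask())


def reconstruct_wf(t: PhaseTriplet, pixel_size: float = 0.32, mean: bool = False) -> ReconstructedTile:
    """Superpose the three phase raws into a wide-field tile.

    The sum (default) preserves photon-count semantics; ``mean=True`` divides
    by 3 for display.  Stored at float precision, so no integer overflow.
    """
    i0, i1, i2 = (np.asarray(r, dtype=float) for r in t.raws)
    pixels = i0 + i1 + i2
    if mean:
        pixels = pixels / 3.0
    return ReconstructedTile(pixels=pixels, mode="WF", channel=t.channel,
                             fov_index=t.fov_index, pixel_size=pixel_size,
                             saturation_mask=t.saturation_mask())


def reconstruct_fov(
    t: PhaseTriplet,
    scheme: Mapping[str, str] | None = None,
    pixel_size: float = 0.32,
) -> ReconstructedTile:
    """Reconstruct one FOV with the mode assigned to its channel.

    The default scheme maps green/red to SIM and blue to WF.  Explicit
    overrides are honored (a blue→SIM override is legitimate for, e.g., the
    conjugated scheme) with a warning logged.
    """
    scheme = dict(DEFAULT_SCHEME if scheme is None else scheme)
    if t.channel not in scheme:
        raise InputError(f"scheme assigns no mode to channel {t.channel!r}")
    mode = scheme[t.channel]
    if mode not in ("SIM", "WF"):
        raise InputError(f"unknown reconstruction mode {mode!r}")
    if mode != DEFAULT_SCHEME.get(t.channel):
        import logging
        logging.getLogger(__name__).warning(
            "channel %s reconstructed as %s (default is %s)",
            t.channel, mode, DEFAULT_SCHEME.get(t.channel))
    if mode == "SIM":
        return reconstruct_sim(t, pixel_size=pixel_size)
    return reconstruct_wf(t, pixel_size=pixel_size)
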