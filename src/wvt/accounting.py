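"""Acquisition accounting: mosaic counts, data volume, imaging time, hardware wear.

All sizes use binary units (1 MB = 2^20 bytes, 1 TB = 2^40 bytes), which is
how the acquisition software reports them; decimal units are available via
``binary=False``.  One stored image per mosaic per channel is counted — the
three phase raws are reconstructed on the fly and only the reconstruction is
written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InputError

MIB = 2 ** 20
TIB = 2 ** 40


@dataclass
class AcquisitionAccounting:
    """Bookkeeping constants of one acquisition run."""

    mosaics_per_channel: int
    n_channels: int = 3
    phases_per_mosaic: int = 3
    tile_shape: tuple[int, int] = (1800, 1800)
    bit_depth: int = 16
    per_mosaic_time_ms: float = 342.5
    layers: int | None = None

    def __post_init__(self):
        if min(self.mosaics_per_channel, self.n_channels, self.phases_per_mosaic,
               self.tile_shape[0], self.tile_shape[1], self.bit_depth) < 0:
            raise InputError("accounting quantities must be non-negative")
        if self.per_mosaic_time_ms < 0:
            raise InputError("per-mosaic time must be non-negative")

    @property
    def tile_bytes(self) -> int:
        return self.tile_shape[0] * self.tile_shape[1] * self.bit_depth // 8


def tile_size_mb(tile_shape: tuple[int, int] = (1800, 1800), bit_depth: int = 16,
                 binary: bool = True) -> float:
    """Size of one stored mosaic image in MB, rounded to 2 decimals."""
    if tile_shape[0] <= 0 or tile_shape[1] <= 0 or bit_depth <= 0:
        raise InputError("tile dimensions and bit depth must be positive")
    unit = MIB if binary else 10 ** 6
    return round(tile_shape[0] * tile_shape[1] * (bit_depth // 8) / unit, 2)


def dataset_size_tb(mosaics_per_channel: int, n_channels: int = 3,
                    tile_shape: tuple[int, int] = (1800, 1800), bit_depth: int = 16,
                    binary: bool = True) -> float:
    """Raw dataset size in TB across all channels (unrounded; round for display)."""
    if mosaics_per_channel < 0 or n_channels < 0:
        raise InputError("counts must be non-negative")
    tile_bytes = tile_shape[0] * tile_shape[1] * (bit_depth // 8)
    unit = TIB if binary else 10 ** 12
    return mosaics_per_channel * n_channels * tile_bytes / unit


def imaging_time_h(mosaics_per_channel: int, per_mosaic_time_ms: float = 342.5) -> float:
    """Whole-acquisition imaging time in hours (channels acquire simultaneously,
    so the per-channel mosaic count is the number of stage dwell positions)."""
    if mosaics_per_channel < 0 or per_mosaic_time_ms < 0:
        raise InputError("inputs must be non-negative")
    return mosaics_per_channel * per_mosaic_time_ms / 3.6e6


def exposure_reduction(mosaics_without: int, mosaics_with: int,
                       phases_per_mosaic: int = 3) -> int:
    """Camera exposures / DMD flips saved by contour recognition: phases × Δmosaics."""
    if mosaics_without < mosaics_with:
        raise InputError("mosaic count with recognition cannot exceed the fixed-region count")
    return phases_per_mosaic * (mosaics_without - mosaics_with)


def summarize_plan(plan, acct: AcquisitionAccounting | None = None) -> dict:
    """Acquisition report for a whole-brain plan (see ``contour.WholeBrainPlan``).

    The mosaic reduction is reported under both aggregations — ratio of
    totals and mean of per-layer ratios — because they differ whenever layer
    sizes vary.
    """
    per_layer_with = plan.mosaics_per_layer
    n_layers = len(per_layer_with)
    per_layer_without = [plan.fixed_region.n_mosaics] * n_layers
    total_with = sum(per_layer_with)
    total_without = sum(per_layer_without)

    if acct is None:
        acct = AcquisitionAccounting(mosaics_per_channel=total_with, layers=n_layers)

    ratio_of_totals = (100.0 * (1 - total_with / total_without)) if total_without else 0.0
    per_layer_ratios = [100.0 * (1 - w / wo) if wo else 0.0
                        for w, wo in zip(per_layer_with, per_layer_without)]
    mean_of_ratios = sum(per_layer_ratios) / n_layers if n_layers else 0.0

    tile_mb = tile_size_mb(acct.tile_shape, acct.bit_depth)
    return {
        "layers": n_layers,
        "per_layer_mosaics_with_recognition": per_layer_with,
        "per_layer_mosaics_without_recognition": per_layer_without,
        "total_mosaics_with_recognition": total_with,
        "total_mosaics_without_recognition": total_without,
        "reduction_pct_ratio_of_totals": round(ratio_of_totals, 1),
        "reduction_pct_mean_of_layer_ratios": round(mean_of_ratios, 1),
        "tile_size_mb": tile_mb,
        "dataset_size_tb_with_recognition": round(
            dataset_size_tb(total_with, acct.n_channels, acct.tile_shape, acct.bit_depth), 3),
        "dataset_size_tb_without_recognition": round(
            dataset_size_tb(total_without, acct.n_channels, acct.tile_shape, acct.bit_depth), 3),
        "imaging_time_h_with_recognition": round(
            imaging_time_h(total_with, acct.per_mosaic_time_ms), 1),
        "imaging_time_h_without_recognition": round(
            imaging_time_h(total_without, acct.per_mosaic_time_ms), 1),
        "exposure_reduction": exposure_reduction(total_without, total_with,
                                                 acct.phases_per_mosaic),
    }


def brain_report(mosaics_without: int, mosaics_with: int,
                 acct: AcquisitionAccounting | None = None) -> dict:
    """Report from bare per-channel mosaic counts (no plan object needed)."""
    if acct is None:
        acct = AcquisitionAccounting(mosaics_per_channel=mosaics_with)
    return {
        "mosaics_per_channel_without": mosaics_without,
        "mosaics_per_channel_with": mosaics_with,
        "tile_size_mb": tile_size_mb(acct.tile_shape, acct.bit_depth),
        "dataset_size_tb_without": round(dataset_size_tb(
            mosaics_without, acct.n_channels, acct.tile_shape, acct.bit_depth), 1),
        "dataset_size_tb_with": round(dataset_size_tb(
            mosaics_with, acct.n_channels, acct.tile_shape, acct.bit_depth), 1),
        "imaging_time_h_without": round(imaging_time_h(mosaics_without, acct.per_mosaic_time_ms), 1),
        "imaging_time_h_with": round(imaging_time_h(mosaics_with, acct.per_mosaic_time_ms), 1),
        "exposure_reduction": exposure_reduction(mosaics_without, mosaics_with,
                                                 acct.phases_per_mosaic),
        "reduction_pct_ratio_of_totals": round(
            100.0 * (1 - mosaics_with / mosaics_without), 1) if mosaics_without else 0.0,
    }
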