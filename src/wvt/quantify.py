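"""Soma detection, triple-channel co-location, and atlas-region quantification.

Somas detected independently in the green and red channels are declared
co-located — i.e. one doubly labeled neuron — when their 3-D distance is
strictly below 1 μm, using mutual-nearest-neighbor matching so no soma can
pair twice.  Counts are rolled up onto an integer-labeled atlas volume with a
two-level region hierarchy and aggregated across brains as mean ± s.e.m. of
per-brain proportions.

The blob detector here is deliberately simple plumbing (blockwise
Laplacian-of-Gaussian with halo deduplication): the scientific content of
this module is the co-location rule and the region bookkeeping, not soma
segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InputError

#: Strict 3-D distance bound for calling two detections one neuron (μm).
COLOCATION_THRESHOLD_UM = 1.0

#: Block edge used when a dataset exceeds workstation memory (voxels).
DEFAULT_BLOCK_SHAPE = (512, 512, 512)


@dataclass
class Soma:
    """One detected cell body, coordinates in μm in the dataset frame."""

    id: int
    x: float
    y: float
    z: float
    channel: str = "green"
    intensity: float = 0.0
    radius: float = 3.0


@dataclass
class SomaSet:
    """All somas of one channel of one brain; lossless to/from SWC."""

    somas: list[Soma] = field(default_factory=list)
    brain_id: str = ""
    channel: str = "green"
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 2.0)

    def __post_init__(self):
        ids = [s.id for s in self.somas]
        if len(ids) != len(set(ids)):
            raise InputError("soma ids must be unique within a set")
        self.somas.sort(key=lambda s: s.id)

    def __len__(self) -> int:
        return len(self.somas)

    def coords(self) -> np.ndarray:
        """(N, 3) array of (x, y, z) μm coordinates."""
        if not self.somas:
            return np.empty((0, 3))
        return np.array([[s.x, s.y, s.z] for s in self.somas], dtype=float)


@dataclass
class ColocatedPairs:
    """Matched (green, red) soma pairs; each id appears at most once."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    threshold_um: float = COLOCATION_THRESHOLD_UM

    def __post_init__(self):
        g = [p[0] for p in self.pairs]
        r = [p[1] for p in self.pairs]
        if len(g) != len(set(g)) or len(r) != len(set(r)):
            raise InputError("a soma id may appear in at most one pair")
        for _, _, d in self.pairs:
            if not d < self.threshold_um:
                raise InputError("all pair distances must be strictly below the threshold")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AtlasVolume:
    """Integer label volume (axes ``(z, y, x)``) with a region hierarchy.

    ``hierarchy`` maps each nonzero sub-region label to
    ``{"name": ..., "parent_id": ..., "parent_name": ...}``; label 0 is
    background/outside-tissue.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    hierarchy: dict[int, dict]

    def __post_init__(self):
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.hierarchy)
        if missing:
            raise InputError(f"labels without hierarchy entries: {sorted(missing)}")

    def label_at(self, x: float, y: float, z: float) -> int:
        """Label of the voxel containing a μm point (floor-to-voxel convention)."""
        dx, dy, dz = self.voxel_size_um
        i, j, k = int(math.floor(z / dz)), int(math.floor(y / dy)), int(math.floor(x / dx))
        nz, ny, nx = self.labels.shape
        if not (0 <= i < nz and 0 <= j < ny and 0 <= k < nx):
            return 0
        return int(self.labels[i, j, k])


@dataclass
class RegionReport:
    """Per-region soma counts/proportions, optionally aggregated across brains."""

    table: pd.DataFrame
    level: Literal["region", "subregion"] = "subregion"
    n_brains: int = 1
    n_somas: int = 0
    single_brain_sem_flag: bool = False


def detect_somas(
    volume: np.ndarray,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 2.0),
    block_shape: tuple[int, int, int] = DEFAULT_BLOCK_SHAPE,
    halo: int = 16,
    sigma_um: float = 4.0,
    threshold: float = 0.3,
    merge_radius_um: float = 3.0,
    channel: str = "green",
    brain_id: str = "",
) -> SomaSet:
    """Blockwise single-scale Laplacian-of-Gaussian soma detection.

    The volume (axes ``(z, y, x)``) is processed in ``block_shape`` blocks
    with a ``halo``-voxel overlap so somas straddling a block boundary are
    seen whole by at least one block; detections landing in a halo are
    deduplicated by a ``merge_radius_um`` merge (brightest wins).
    ``sigma_um`` is the (isotropic, in μm) soma scale; per-axis filter sigmas
    absorb the voxel anisotropy.  Candidate voxels are scale-normalized LoG
    local maxima above ``threshold`` × the volume's global peak response
    (for a matched Gaussian blob the peak response ≈ its amplitude).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise InputError("expected a 3-D volume (z, y, x)")
    if vol.size == 0 or float(vol.max()) <= 0:
        return SomaSet(somas=[], brain_id=brain_id, channel=channel,
                       voxel_size_um=voxel_size_um)
    dx, dy, dz = voxel_size_um
    sigma_vox = (sigma_um / dz, sigma_um / dy, sigma_um / dx)  # (z, y, x)
    abs_threshold = threshold * float(vol.max())
    min_dist_vox = tuple(max(1, int(round(sigma_um / v))) for v in (dz, dy, dx))
    footprint = np.ones(tuple(2 * m + 1 for m in min_dist_vox), dtype=bool)

    nz, ny, nx = vol.shape
    bz, by, bx = block_shape
    detections: list[tuple[float, float, float, float]] = []  # x, y, z, response
    for z0 in range(0, nz, bz):
        for y0 in range(0, ny, by):
            for x0 in range(0, nx, bx):
                z1, y1, x1 = min(nz, z0 + bz), min(ny, y0 + by), min(nx, x0 + bx)
                hz0, hy0, hx0 = max(0, z0 - halo), max(0, y0 - halo), max(0, x0 - halo)
                hz1, hy1, hx1 = min(nz, z1 + halo), min(ny, y1 + halo), min(nx, x1 + halo)
                block = vol[hz0:hz1, hy0:hy1, hx0:hx1]
                if float(block.max()) < abs_threshold / 2:
                    continue
                resp = -ndimage.gaussian_laplace(block, sigma=sigma_vox) * sigma_um ** 2
                local_max = (resp == ndimage.maximum_filter(resp, footprint=footprint))
                cand = np.argwhere(local_max & (resp > abs_threshold))
                for (cz, cy, cx) in cand:
                    gz, gy, gx = cz + hz0, cy + hy0, cx + hx0
                    # attribute halo detections to their owning block only
                    if not (z0 <= gz < z1 and y0 <= gy < y1 and x0 <= gx < x1):
                        continue
                    detections.append((gx * dx, gy * dy, gz * dz,
                                       float(resp[cz, cy, cx])))
    # merge near-duplicates (block seams, double maxima): brightest wins
    somas: list[Soma] = []
    if detections:
        detections.sort(key=lambda d: -d[3])
        pts = np.array([d[:3] for d in detections])
        tree = cKDTree(pts)
        suppressed = np.zeros(len(detections), dtype=bool)
        kept: list[tuple[float, float, float, float]] = []
        for i, det in enumerate(detections):
            if suppressed[i]:
                continue
            kept.append(det)
            for j in tree.query_ball_point(pts[i], merge_radius_um):
                if j != i:
                    suppressed[j] = True
        kept.sort(key=lambda d: (d[2], d[1], d[0]))
        somas = [Soma(id=i + 1, x=d[0], y=d[1], z=d[2], channel=channel, intensity=d[3])
                 for i, d in enumerate(kept)]
    return SomaSet(somas=somas, brain_id=brain_id, channel=channel,
                   voxel_size_um=voxel_size_um)


def colocate(green: SomaSet, red: SomaSet,
             threshold_um: float = COLOCATION_THRESHOLD_UM) -> ColocatedPairs:
    """Mutual-nearest-neighbor matching with a strict distance cutoff.

    A (green, red) pair is emitted iff each soma is the other's nearest
    neighbor in the opposite channel and their 3-D Euclidean distance is
    strictly less than ``threshold_um``.
    """
    gc, rc = green.coords(), red.coords()
    if len(gc) == 0 or len(rc) == 0:
        return ColocatedPairs(pairs=[], threshold_um=threshold_um)
    gtree, rtree = cKDTree(gc), cKDTree(rc)
    d_gr, nn_gr = rtree.query(gc)  # for each green: nearest red
    d_rg, nn_rg = gtree.query(rc)  # for each red: nearest green
    pairs = []
    for gi, (d, ri) in enumerate(zip(d_gr, nn_gr)):
        if d < threshold_um and nn_rg[ri] == gi:
            pairs.append((green.somas[gi].id, red.somas[int(ri)].id, float(d)))
    return ColocatedPairs(pairs=pairs, threshold_um=threshold_um)


def count_by_region(
    somas: SomaSet,
    atlas: AtlasVolume,
    level: Literal["region", "subregion"] = "subregion",
) -> RegionReport:
    """Assign each soma to its containing atlas voxel and roll up counts.

    Somas falling on background (label 0) or outside the atlas are counted
    in an ``unassigned`` bin (id 0) with a warning.  Proportions are
    percentages of the total soma count (including unassigned).
    """
    import logging
    rows: dict[int, int] = {}
    unassigned = 0
    for s in somas.somas:
        lbl = atlas.label_at(s.x, s.y, s.z)
        if lbl == 0:
            unassigned += 1
            continue
        if level == "region":
            lbl = int(atlas.hierarchy[lbl]["parent_id"])
        rows[lbl] = rows.get(lbl, 0) + 1
    if unassigned:
        logging.getLogger(__name__).warning(
            "%d soma(s) in background voxels counted as unassigned", unassigned)

    total = len(somas)
    names = _region_names(atlas, level)
    records = []
    for rid in sorted(set(rows) | set(names)):
        count = rows.get(rid, 0)
        records.append({
            "region_id": rid,
            "region_name": names.get(rid, f"region_{rid}"),
            "level": level,
            "count": count,
            "proportion_pct": 100.0 * count / total if total else float("nan"),
        })
    if unassigned:
        records.append({"region_id": 0, "region_name": "unassigned", "level": level,
                        "count": unassigned,
                        "proportion_pct": 100.0 * unassigned / total})
    table = pd.DataFrame.from_records(
        records, columns=["region_id", "region_name", "level", "count", "proportion_pct"])
    return RegionReport(table=table, level=level, n_brains=1, n_somas=total)


def _region_names(atlas: AtlasVolume, level: str) -> dict[int, str]:
    if level == "subregion":
        return {rid: str(e.get("name", f"region_{rid}")) for rid, e in atlas.hierarchy.items()}
    out: dict[int, str] = {}
    for e in atlas.hierarchy.values():
        out[int(e["parent_id"])] = str(e.get("parent_name", f"region_{e['parent_id']}"))
    return out


def aggregate_brains(reports: Sequence[RegionReport]) -> RegionReport:
    """Cross-brain mean ± s.e.m. of per-region proportions.

    Regions missing from a brain count as 0% for that brain.  With a single
    brain the s.e.m. is reported as 0 and flagged.
    """
    if not reports:
        raise InputError("need at least one report")
    level = reports[0].level
    if any(r.level != level for r in reports):
        raise InputError("reports must share a hierarchy level")
    all_ids = sorted({rid for r in reports for rid in r.table["region_id"]})
    names: dict[int, str] = {}
    for r in reports:
        for rid, name in zip(r.table["region_id"], r.table["region_name"]):
            names.setdefault(int(rid), str(name))
    n = len(reports)
    records = []
    for rid in all_ids:
        props = []
        counts = []
        for r in reports:
            sel = r.table[r.table["region_id"] == rid]
            props.append(float(sel["proportion_pct"].iloc[0]) if len(sel) else 0.0)
            counts.append(int(sel["count"].iloc[0]) if len(sel) else 0)
        props_arr = np.asarray(props)
        sem = float(np.std(props_arr, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        records.append({
            "region_id": rid, "region_name": names[rid], "level": level,
            "count": int(np.sum(counts)),
            "proportion_pct": float(props_arr.mean()),
            "mean_pct": float(props_arr.mean()),
            "sem_pct": sem,
        })
    table = pd.DataFrame.from_records(records, columns=[
        "region_id", "region_name", "level", "count", "proportion_pct", "mean_pct", "sem_pct"])
    return RegionReport(table=table, level=level, n_brains=n,
                        n_somas=sum(r.n_somas for r in reports),
                        single_brain_sem_flag=(n == 1))


def coloc_proportions(pairs: ColocatedPairs, green: SomaSet, red: SomaSet
                      ) -> tuple[float, float]:
    """Co-located fraction as a percentage of each channel's soma count.

    Empty input sets yield NaN for the corresponding proportion (undefined,
    not zero).
    """
    n = len(pairs)
    pct_g = 100.0 * n / len(green) if len(green) else float("nan")
    pct_r = 100.0 * n / len(red) if len(red) else float("nan")
    return pct_g, pct_r
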