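"""Readers/writers for the formats the pipeline exchanges: TIFF, SWC, JSON sidecars.

TIFF images are 16-bit grayscale (single or multi-page); acquisition metadata
(pixel size, channel, reconstruction mode) travels in a JSON sidecar next to
the image, since plain TIFF tags are routinely stripped by downstream tools.
SWC files hold soma point sets as standard 7-column records with parent −1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, SwcParseError
from .quantify import Soma, SomaSet


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_tiff(path: str | Path, image: np.ndarray,
               metadata: dict | None = None) -> None:
    """Write a 2-D image or 3-D stack as (multi-page) grayscale TIFF.

    Integer images are written as-is (16-bit expected); float images are
    written as float32.  Metadata, if given, goes to a JSON sidecar.
    """
    arr = np.asarray(image)
    if arr.ndim not in (2, 3):
        raise FormatError("only 2-D images or 3-D stacks are supported")
    if np.issubdtype(arr.dtype, np.integer):
        if arr.dtype != np.uint16:
            if arr.min() < 0 or arr.max() > 65535:
                raise FormatError("integer image does not fit 16-bit range")
            arr = arr.astype(np.uint16)
    elif np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    else:
        raise FormatError(f"unsupported dtype {arr.dtype}")
    tifffile.imwrite(str(path), arr)
    if metadata is not None:
        sidecar_path(path).write_text(json.dumps(metadata, indent=2) + "\n")


def read_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF (+ sidecar metadata if present).

    Multi-page stacks come back as (pages, h, w).  RGB or other
    multi-sample images are rejected.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise FormatError("color (multi-sample) TIFF is not supported; expected grayscale")
    if arr.ndim not in (2, 3):
        raise FormatError(f"unsupported TIFF dimensionality {arr.ndim}")
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return arr, meta


def write_swc(path: str | Path, somas: SomaSet, comments: list[str] | None = None) -> None:
    """Write a soma set as 7-column SWC (id type x y z radius parent), parent −1."""
    lines = [f"# channel {somas.channel}", f"# brain {somas.brain_id}"]
    for c in comments or []:
        lines.append(c if c.startswith("#") else f"# {c}")
    for s in somas.somas:
        lines.append(f"{s.id} 1 {s.x:.6f} {s.y:.6f} {s.z:.6f} {s.radius:.6f} -1")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path, channel: str = "green", brain_id: str = "") -> SomaSet:
    """Parse an SWC file into a SomaSet; comments tolerated, malformed rows rejected.

    Channel/brain are taken from leading ``# channel``/``# brain`` comments
    when present.
    """
    somas: list[Soma] = []
    comments: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line)
            body = line.lstrip("#").strip()
            if body.startswith("channel "):
                channel = body.split(None, 1)[1]
            elif body.startswith("brain "):
                brain_id = body.split(None, 1)[1]
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SwcParseError(
                f"line {lineno}: expected 7 columns, got {len(fields)}", lineno)
        try:
            sid, stype = int(fields[0]), int(fields[1])
            x, y, z, radius = (float(v) for v in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: {exc}", lineno) from exc
        del stype, parent
        somas.append(Soma(id=sid, x=x, y=y, z=z, radius=radius, channel=channel))
    return SomaSet(somas=somas, channel=channel, brain_id=brain_id)


def write_region_report(path: str | Path, report) -> None:
    """Region report → CSV with the standard column set."""
    report.table.to_csv(path, index=False)


def write_regions_jsonl(path: str | Path, regions) -> None:
    """Planned imaging regions → JSON lines, one record per layer."""
    with open(path, "w") as fh:
        for k, region in enumerate(regions):
            rec = {"layer": k, **region.to_dict()}
            fh.write(json.dumps(rec) + "\n")
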