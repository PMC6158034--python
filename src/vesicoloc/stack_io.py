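"""Reading and writing multi-channel z-stacks and result tables.

The interchange image format is OME-TIFF with ``PhysicalSizeX/Y/Z``
metadata; plain TIFFs are accepted when voxel sizes are supplied
explicitly.  Result tables are CSV (per vesicle) and JSON (per cell).
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import CHANNELS

log = logging.getLogger("vesicoloc")

_UNIT_TO_NM = {"nm": 1.0, "µm": 1e3, "um": 1e3, "micron": 1e3, "mm": 1e6, "m": 1e9}


@dataclass
class VoxelGrid:
    """One channel's 3D intensity volume plus its voxel dimensions.

    ``data`` is indexed ``(z, y, x)``; voxel sizes are nm.  This is the
    unit every imaging operation consumes.
    """

    data: np.ndarray
    voxel_xy_nm: float
    voxel_z_nm: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VoxelGrid data must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VoxelGrid data must be finite")
        if self.voxel_xy_nm <= 0 or self.voxel_z_nm <= 0:
            raise ValueError("voxel sizes must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_sizes_nm(self) -> np.ndarray:
        return np.array([self.voxel_z_nm, self.voxel_xy_nm, self.voxel_xy_nm])

    def index_to_nm(self, index: Sequence[float]) -> np.ndarray:
        """Convert a (z, y, x) voxel index (may be fractional) to nm."""
        return np.asarray(index, dtype=float) * self.voxel_sizes_nm()

    def nm_to_index(self, pos_nm: Sequence[float]) -> np.ndarray:
        return np.asarray(pos_nm, dtype=float) / self.voxel_sizes_nm()


def write_stack(path: str | Path, grids: Sequence[VoxelGrid]) -> Path:
    """Write channels as a single OME-TIFF with physical-size metadata."""
    path = Path(path)
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError("all channels must share one shape")
    data = np.stack([g.data for g in grids]).astype(np.float32)  # (C, Z, Y, X)
    g0 = grids[0]
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": g0.voxel_xy_nm,
            "PhysicalSizeXUnit": "nm",
            "PhysicalSizeY": g0.voxel_xy_nm,
            "PhysicalSizeYUnit": "nm",
            "PhysicalSizeZ": g0.voxel_z_nm,
            "PhysicalSizeZUnit": "nm",
            "Channel": {"Name": [g.channel_name for g in grids]},
        },
    )
    return path


def _parse_ome_sizes(ome_xml: str) -> tuple[float | None, float | None, list[str]]:
    """Extract (xy_nm, z_nm, channel names) from OME-XML; None if absent."""
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pix is None:
        return None, None, []

    def _get(attr: str) -> float | None:
        val = pix.get(f"PhysicalSize{attr}")
        if val is None:
            return None
        unit = pix.get(f"PhysicalSize{attr}Unit", "µm")
        return float(val) * _UNIT_TO_NM.get(unit, 1e3)

    names = [
        c.get("Name", "") or ""
        for c in pix.findall("ome:Channel" if ns else "Channel", ns)
    ]
    return _get("X"), _get("Z"), names


def read_stack(
    path: str | Path,
    voxel_xy_nm: float | None = None,
    voxel_z_nm: float | None = None,
    require_triplex: bool = True,
) -> list[VoxelGrid]:
    """Read an OME-TIFF (or plain TIFF with explicit voxel sizes).

    Voxel sizes come from the OME metadata unless overridden.  With
    ``require_triplex`` the file must hold exactly three channels.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_xml = tif.ome_metadata

    names: list[str] = []
    if ome_xml:
        xy, z, names = _parse_ome_sizes(ome_xml)
        voxel_xy_nm = voxel_xy_nm if voxel_xy_nm is not None else xy
        voxel_z_nm = voxel_z_nm if voxel_z_nm is not None else z
    if voxel_xy_nm is None:
        raise ValueError(
            f"{path}: missing PhysicalSizeX/Y metadata; pass voxel_xy_nm explicitly"
        )
    if voxel_z_nm is None:
        raise ValueError(
            f"{path}: missing PhysicalSizeZ metadata; pass voxel_z_nm explicitly"
        )

    data = np.asarray(data)
    if data.ndim == 3:  # single channel
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a (C, Z, Y, X) or (Z, Y, X) stack")
    if require_triplex and data.shape[0] != 3:
        raise ValueError(
            f"{path}: expected 3 channels for the triplex pipeline, got {data.shape[0]}"
        )
    if not names or len(names) != data.shape[0]:
        names = list(CHANNELS[: data.shape[0]]) if data.shape[0] == 3 else [
            f"ch{i}" for i in range(data.shape[0])
        ]
    return [
        VoxelGrid(ch, voxel_xy_nm=voxel_xy_nm, voxel_z_nm=voxel_z_nm, channel_name=nm)
        for ch, nm in zip(data, names)
    ]


# ---------------------------------------------------------------------------
# result tables

def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten VesicleRecords into a tidy per-vesicle table."""
    rows = []
    for r in records:
        row: dict = {"vesicle_id": r.vesicle_id}
        for i, ch in enumerate(CHANNELS):
            pos = r.positions_nm[i]
            row[f"z_nm_{ch}"] = pos[0]
            row[f"y_nm_{ch}"] = pos[1]
            row[f"x_nm_{ch}"] = pos[2]
            row[f"intensity_{ch}"] = r.norm_intensity[i]
            row[f"call_{ch}"] = r.call[i]
        row["prefilter_pass"] = r.prefilter_pass
        row["category"] = r.category
        rows.append(row)
    cols = ["vesicle_id"]
    for ch in CHANNELS:
        cols += [f"z_nm_{ch}", f"y_nm_{ch}", f"x_nm_{ch}", f"intensity_{ch}", f"call_{ch}"]
    cols += ["prefilter_pass", "category"]
    return pd.DataFrame(rows, columns=cols)


def write_results(records: Sequence, summary, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-vesicle CSV and per-cell JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "vesicles.csv"
    json_path = out_dir / "cell_summary.json"
    records_to_frame(records).to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(summary.to_dict(), indent=2))
    log.info("wrote %s and %s", csv_path, json_path)
    return {"vesicles": csv_path, "summary": json_path}


def read_results(out_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    out_dir = Path(out_dir)
    frame = pd.read_csv(out_dir / "vesicles.csv")
    summary = json.loads((out_dir / "cell_summary.json").read_text())
    return frame, summary
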