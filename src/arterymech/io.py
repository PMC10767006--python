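"""Readers and writers for the package's on-disk formats.

Myograph data travel as tidy CSV (one row per pressure sample, with an
``axial_stretch`` column separating the sweeps) plus a YAML sidecar holding
the traced ring geometry.  Image stacks travel as multi-page TIFF with a
YAML sidecar for pixel size and z-spacing when TIFF metadata is absent.
Analysis outputs are tidy CSV (states, histograms) and JSON (specimen
summaries), each embedding the configuration hash that produced it.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .mechanics import (
    BiaxialDataset,
    InflationRecord,
    StressStrainCurve,
    UnloadedGeometry,
)
from .orientation import DepthOrientationMap, FiberImageStack, OrientationHistogram

MYOGRAPH_COLUMNS = [
    "axial_stretch", "pressure_mmhg", "outer_diameter_mm", "axial_force_mN",
]


# ---------------------------------------------------------------------------
# Myograph CSV + geometry sidecar
# ---------------------------------------------------------------------------

def write_myograph_csv(path: str | Path, records: list[InflationRecord]) -> None:
    frames = []
    for rec in records:
        frames.append(
            pd.DataFrame(
                {
                    "axial_stretch": rec.axial_stretch,
                    "pressure_mmhg": rec.pressures,
                    "outer_diameter_mm": rec.outer_diameters,
                    "axial_force_mN": rec.axial_forces,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_myograph_csv(
    path: str | Path, discard_preconditioning: bool = True
) -> list[InflationRecord]:
    """Read inflation sweeps from a tidy myograph CSV.

    Each distinct ``axial_stretch`` value forms one record.  Rows marked
    with a truthy ``preconditioning`` column (the 0–140 mmHg ×3 conditioning
    sweeps) are discarded by default: they are a protocol fact, not data.
    """
    df = pd.read_csv(path)
    missing = [c for c in MYOGRAPH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"myograph CSV {path} lacks columns {missing}")
    if discard_preconditioning and "preconditioning" in df.columns:
        df = df[~df["preconditioning"].astype(bool)]
    records = []
    for lz, block in df.groupby("axial_stretch", sort=True):
        block = block.sort_values("pressure_mmhg")
        samples = tuple(
            (float(p), float(d), float(f))
            for p, d, f in zip(
                block["pressure_mmhg"],
                block["outer_diameter_mm"],
                block["axial_force_mN"],
            )
        )
        records.append(InflationRecord(axial_stretch=float(lz), samples=samples))
    return records


def write_geometry_yaml(path: str | Path, geometry: UnloadedGeometry) -> None:
    payload = {
        "outer_diameter_mm": geometry.outer_diameter,
        "inner_diameter_mm": geometry.inner_diameter,
    }
    Path(path).write_text(yaml.safe_dump(payload))


def read_geometry_yaml(path: str | Path) -> UnloadedGeometry:
    """Read ring geometry from a sidecar; accepts traced circumferences
    (``*_circumference_mm``) or diameters (``*_diameter_mm``)."""
    payload = yaml.safe_load(Path(path).read_text())
    if "outer_diameter_mm" in payload:
        return UnloadedGeometry(
            float(payload["outer_diameter_mm"]), float(payload["inner_diameter_mm"])
        )
    if "outer_circumference_mm" in payload:
        return UnloadedGeometry(
            float(payload["outer_circumference_mm"]) / math.pi,
            float(payload["inner_circumference_mm"]) / math.pi,
        )
    raise ValueError(
        f"geometry sidecar {path} needs *_diameter_mm or *_circumference_mm keys"
    )


# ---------------------------------------------------------------------------
# Analysis outputs
# ---------------------------------------------------------------------------

def states_to_frame(curve: StressStrainCurve) -> pd.DataFrame:
    """Tidy DataFrame of the deformed states of one sweep."""
    return pd.DataFrame(
        {
            "pressure_mmhg": [s.pressure for s in curve.states],
            "outer_diameter_mm": [s.outer_diameter for s in curve.states],
            "inner_diameter_mm": [s.inner_diameter for s in curve.states],
            "wall_thickness_mm": [s.wall_thickness for s in curve.states],
            "circ_stretch": [s.circ_stretch for s in curve.states],
            "axial_stretch": [s.axial_stretch for s in curve.states],
            "circ_stress_kpa": [s.circ_stress for s in curve.states],
            "axial_stress_kpa": [s.axial_stress for s in curve.states],
        }
    )


def histogram_to_frame(hist: OrientationHistogram) -> pd.DataFrame:
    return pd.DataFrame(
        {"angle_deg": hist.bin_centers, "fraction": hist.weights}
    )


def depth_map_to_frame(dmap: DepthOrientationMap) -> pd.DataFrame:
    """Long-form (depth, angle, fraction) table of a depth-orientation map."""
    depth, angle = np.meshgrid(dmap.depths_um, dmap.bin_centers, indexing="ij")
    return pd.DataFrame(
        {
            "depth_um": depth.ravel(),
            "angle_deg": angle.ravel(),
            "fraction": dmap.fractions.ravel(),
        }
    )


def write_summary_json(path: str | Path, payload: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def fibers_to_frame(fibers_per_slice: dict[int, list]) -> pd.DataFrame:
    """Per-fiber table (slice, fiber id, arc length μm, Ps) from traced
    polylines keyed by slice index."""
    from .straightness import straightness

    rows = []
    for slice_idx, fibers in fibers_per_slice.items():
        for fid, poly in enumerate(fibers):
            rows.append(
                {
                    "slice": slice_idx,
                    "fiber_id": fid,
                    "length_um": poly.arc_length,
                    "ps": straightness(poly),
                }
            )
    return pd.DataFrame(rows)


def ps_histograms_to_frame(summary) -> pd.DataFrame:
    """Long-form per-slice Ps histogram table from a StackPsSummary."""
    rows = []
    for rec in summary.records:
        centers = 0.5 * (rec.bin_edges[:-1] + rec.bin_edges[1:])
        for c, n in zip(centers, rec.counts):
            rows.append({"slice": rec.depth_index, "ps_bin": c, "count": int(n)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TIFF stacks + sidecar
# ---------------------------------------------------------------------------

def write_stack_tiff(
    path: str | Path,
    stack: FiberImageStack,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write a stack as multi-page TIFF (float32) plus a YAML sidecar with
    the physical calibration and acquisition state."""
    tifffile.imwrite(Path(path), stack.voxels.astype(np.float32))
    if sidecar_path is not None:
        Path(sidecar_path).write_text(
            yaml.safe_dump(
                {
                    "pixel_size_um": stack.pixel_size_um,
                    "z_spacing_um": stack.z_spacing_um,
                    "channel": stack.channel,
                    "pressure_mmhg": stack.pressure_mmhg,
                    "axial_stretch": stack.axial_stretch,
                }
            )
        )


def read_stack_tiff(
    path: str | Path, sidecar_path: str | Path | None = None
) -> FiberImageStack:
    """Read a (multi-page) TIFF stack; calibration from the YAML sidecar."""
    voxels = np.asarray(tifffile.imread(Path(path)), dtype=float)
    if voxels.ndim == 2:
        voxels = voxels[None, :, :]
    meta: dict[str, Any] = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        meta = yaml.safe_load(Path(sidecar_path).read_text()) or {}
    return FiberImageStack(
        voxels=voxels,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        z_spacing_um=float(meta.get("z_spacing_um", 1.0)),
        channel=str(meta.get("channel", "collagen")),
        pressure_mmhg=float(meta.get("pressure_mmhg", 0.0)),
        axial_stretch=float(meta.get("axial_stretch", 1.0)),
    )
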