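"""Plate-to-volume geometry: anchor 2D section plates inside a 3D volume.

An :class:`AnchoringSpec` places one rectangular plate in the voxel space of
a reference volume using the o/u/v parametrisation of the QuickNII tool
family: ``o`` is the position of the plate's upper-left corner, ``u`` and
``v`` are the full-width and full-height in-plane edge vectors.  Pixel
``(i, j)`` (column, row) maps to the continuous voxel coordinate

    o + ((i + 0.5) / width) * u + ((j + 0.5) / height) * v

(pixel-centre convention).  Voxel centres sit at integer coordinates and a
continuous coordinate is resolved to a voxel by per-axis round-half-up, so
the axis-aligned spec with ``o = (-0.5, -0.5, k)``, ``u = (nx, 0, 0)``,
``v = (0, ny, 0)`` reproduces slice ``volume[:, :, k]`` exactly.  Labels are
never interpolated.

Plate images throughout this package are arrays indexed ``[i, j]`` =
(column, row), i.e. shape ``(width, height)``, matching the (x, y) voxel
axis order; the PNG helpers in :mod:`atlasoverlap.overlap` transpose to the
row-major layout image files use.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_model import LabelVolume

__all__ = [
    "AnchoringSpec",
    "SectionSeries",
    "GeometryError",
    "AnchoringParseError",
    "pixel_to_voxel",
    "plate_to_voxel",
    "extract_plate",
    "axis_aligned_spec",
    "read_anchoring",
    "write_anchoring",
]


class GeometryError(ValueError):
    """Degenerate plate geometry (e.g. collinear edge vectors)."""


class AnchoringParseError(ValueError):
    """An anchoring file is missing required plate attributes."""


@dataclass
class AnchoringSpec:
    """Placement of one plate in volume voxel space (o/u/v convention)."""

    plate_id: str
    o: np.ndarray
    u: np.ndarray
    v: np.ndarray
    width: int
    height: int

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name, vec in (("o", self.o), ("u", self.u), ("v", self.v)):
            if vec.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plate dimensions must be positive")
        if np.linalg.norm(np.cross(self.u, self.v)) == 0.0:
            raise GeometryError("u and v are linearly dependent")


@dataclass
class SectionSeries:
    """Ordered rostral-to-caudal plate series with per-plate Bregma levels.

    Bregma (mm) is the stereotaxic rostrocaudal coordinate, positive rostral,
    so it must decrease strictly along the series.  ``thickness_mm`` is the
    physical section thickness (default 40 um); it feeds the sampling-ratio
    arithmetic only and plays no role in plane sampling, which treats plates
    as infinitesimal.
    """

    plates: list[tuple[AnchoringSpec, float]] = field(default_factory=list)
    thickness_mm: float = 0.04

    def __post_init__(self) -> None:
        if not self.thickness_mm > 0:
            raise ValueError("thickness_mm must be positive")
        bregmas = [b for _, b in self.plates]
        for earlier, later in zip(bregmas, bregmas[1:]):
            if not later < earlier:
                raise ValueError("bregma_mm must be strictly decreasing rostral to caudal")

    def __len__(self) -> int:
        return len(self.plates)


def plate_to_voxel(spec: AnchoringSpec, x, y) -> np.ndarray:
    """Continuous plate coordinates (x, y) in [0, w] x [0, h] -> voxel coords.

    Vectorised: x and y may be arrays; the result has their broadcast shape
    plus a trailing axis of length 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (
        spec.o
        + (x / spec.width)[..., None] * spec.u
        + (y / spec.height)[..., None] * spec.v
    )


def pixel_to_voxel(spec: AnchoringSpec, i: int, j: int) -> np.ndarray:
    """Map plate pixel (column i, row j) to its centre's voxel coordinate."""
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(i >= spec.width) or np.any(j < 0) or np.any(j >= spec.height):
        raise ValueError(f"pixel out of range for {spec.width}x{spec.height} plate")
    return plate_to_voxel(spec, i + 0.5, j + 0.5)


def sample_labels(volume: LabelVolume, coords: np.ndarray) -> np.ndarray:
    """Nearest-voxel label lookup at continuous coordinates (..., 3).

    Per-axis round-half-up; coordinates outside the volume yield background 0.
    """
    idx = np.floor(coords + 0.5).astype(np.int64)
    dims = np.asarray(volume.labels.shape)
    inside = np.all((idx >= 0) & (idx < dims), axis=-1)
    out = np.zeros(coords.shape[:-1], dtype=volume.labels.dtype)
    if np.any(inside):
        ii = idx[inside]
        out[inside] = volume.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def extract_plate(volume: LabelVolume, spec: AnchoringSpec) -> np.ndarray:
    """Resample a "custom-cut" 2D label image from the volume along a spec.

    Output is indexed [i, j] with shape (width, height); each pixel carries
    the label of the nearest voxel at its centre, 0 outside the volume.
    """
    ii, jj = np.meshgrid(
        np.arange(spec.width), np.arange(spec.height), indexing="ij"
    )
    coords = plate_to_voxel(spec, ii + 0.5, jj + 0.5)
    return sample_labels(volume, coords)


def axis_aligned_spec(
    volume: LabelVolume, axis: int = 2, index: int = 0, plate_id: str | None = None
) -> AnchoringSpec:
    """Identity spec whose extraction reproduces ``volume`` slice ``index`` on ``axis``."""
    dims = volume.labels.shape
    in_plane = [a for a in range(3) if a != axis]
    o = np.full(3, -0.5)
    o[axis] = float(index)
    u = np.zeros(3)
    u[in_plane[0]] = dims[in_plane[0]]
    v = np.zeros(3)
    v[in_plane[1]] = dims[in_plane[1]]
    return AnchoringSpec(
        plate_id=plate_id or f"slice-{'xyz'[axis]}{index}",
        o=o,
        u=u,
        v=v,
        width=dims[in_plane[0]],
        height=dims[in_plane[1]],
    )


# ---------------------------------------------------------------------------
# Anchoring file IO: QuickNII-compatible XML attribute names and an
# equivalent JSON dialect.

_REQUIRED = ("ox", "oy", "oz", "ux", "uy", "uz", "vx", "vy", "vz", "width", "height")


def _spec_from_attrs(plate_id: str, attrs: dict) -> AnchoringSpec:
    missing = [k for k in _REQUIRED if k not in attrs]
    if missing:
        raise AnchoringParseError(f"plate {plate_id!r}: missing attributes {missing}")
    return AnchoringSpec(
        plate_id=plate_id,
        o=[float(attrs["ox"]), float(attrs["oy"]), float(attrs["oz"])],
        u=[float(attrs["ux"]), float(attrs["uy"]), float(attrs["uz"])],
        v=[float(attrs["vx"]), float(attrs["vy"]), float(attrs["vz"])],
        width=int(attrs["width"]),
        height=int(attrs["height"]),
    )


def read_anchoring(path: str | Path) -> SectionSeries:
    """Read a section series from anchoring XML (``<series><slice .../>``)
    or the equivalent JSON dialect, preserving plate order."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        plates = []
        for p in doc["plates"]:
            attrs = {
                "ox": p["o"][0], "oy": p["o"][1], "oz": p["o"][2],
                "ux": p["u"][0], "uy": p["u"][1], "uz": p["u"][2],
                "vx": p["v"][0], "vy": p["v"][1], "vz": p["v"][2],
                "width": p["width"], "height": p["height"],
            }
            missing = [k for k in ("o", "u", "v") if k not in p]
            if missing:
                raise AnchoringParseError(f"plate {p.get('id', '?')!r}: missing {missing}")
            plates.append((_spec_from_attrs(str(p["id"]), attrs), float(p["bregma_mm"])))
        return SectionSeries(plates=plates, thickness_mm=float(doc.get("thickness_mm", 0.04)))
    root = ET.parse(str(path)).getroot()
    plates = []
    for el in root.findall("slice"):
        plate_id = el.get("id", f"slice-{len(plates)}")
        spec = _spec_from_attrs(plate_id, dict(el.attrib))
        if "bregma" not in el.attrib:
            raise AnchoringParseError(f"plate {plate_id!r}: missing bregma attribute")
        plates.append((spec, float(el.get("bregma"))))
    thickness = float(root.get("thickness", 0.04))
    return SectionSeries(plates=plates, thickness_mm=thickness)


def write_anchoring(series: SectionSeries, path: str | Path) -> None:
    """Write a section series as anchoring XML or JSON (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "thickness_mm": series.thickness_mm,
            "plates": [
                {
                    "id": s.plate_id,
                    "width": s.width,
                    "height": s.height,
                    "bregma_mm": b,
                    "o": list(s.o),
                    "u": list(s.u),
                    "v": list(s.v),
                }
                for s, b in series.plates
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    root = ET.Element("series", thickness=repr(series.thickness_mm))
    for spec, bregma in series.plates:
        ET.SubElement(
            root,
            "slice",
            id=spec.plate_id,
            width=str(spec.width),
            height=str(spec.height),
            bregma=repr(float(bregma)),
            ox=repr(float(spec.o[0])), oy=repr(float(spec.o[1])), oz=repr(float(spec.o[2])),
            ux=repr(float(spec.u[0])), uy=repr(float(spec.u[1])), uz=repr(float(spec.u[2])),
            vx=repr(float(spec.v[0])), vy=repr(float(spec.v[1])), vz=repr(float(spec.v[2])),
        )
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)
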