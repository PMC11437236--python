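"""Core parcellation data types and readers/writers.

A parcellation ("annotation" or "label volume") assigns every voxel of a 3D
grid to a named brain region.  The region vocabulary of one atlas version --
ids, terms, colours, and an optional parent hierarchy -- is a
:class:`Terminology`.  Volumes travel as NIfTI-1 files; terminologies as
ITK-SNAP label-description files (whitespace-separated columns
``ID R G B A VIS MSH "LABEL"``, ``#`` comments).

Conventions fixed here and relied on throughout the package:

* background is label 0 everywhere and is never a terminology entry;
  "unlabelled tissue" and "outside brain" are not distinguished;
* the volume axis order is (x = mediolateral, y = dorsoventral,
  z = rostrocaudal); readers record orientation metadata (the NIfTI affine)
  but never reorient or resample data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "TermEntry",
    "Terminology",
    "LabelVolume",
    "FormatError",
    "read_label_volume",
    "write_label_volume",
    "read_label_descriptions",
    "write_label_descriptions",
    "region_voxel_counts",
    "generic_terminology",
]


class FormatError(ValueError):
    """A file's content violates the expected format."""


@dataclass(frozen=True)
class TermEntry:
    """One region of a terminology."""

    region_id: int
    name: str
    abbreviation: str
    color: tuple[int, int, int]
    parent_id: int | None = None


@dataclass
class Terminology:
    """Region vocabulary of one atlas version.

    Invariants enforced on construction: unique region ids, unique colours
    (colour-coded plates must decode unambiguously), acyclic parent links,
    and no entry for the reserved background id 0.
    """

    entries: list[TermEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.region_id for e in self.entries]
        if any(i <= 0 for i in ids):
            raise ValueError("region ids must be positive; 0 is reserved for background")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids in terminology")
        colors = [e.color for e in self.entries]
        if len(set(colors)) != len(colors):
            raise ValueError("duplicate colours in terminology")
        by_id = {e.region_id: e for e in self.entries}
        for e in self.entries:
            if e.parent_id is not None and e.parent_id not in by_id:
                raise ValueError(f"entry {e.region_id} has unknown parent {e.parent_id}")
        # cycle check by walking each parent chain
        for e in self.entries:
            seen = set()
            node: int | None = e.region_id
            while node is not None:
                if node in seen:
                    raise ValueError("parent links form a cycle")
                seen.add(node)
                node = by_id[node].parent_id

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TermEntry]:
        return iter(self.entries)

    def by_id(self) -> dict[int, TermEntry]:
        return {e.region_id: e for e in self.entries}

    def by_color(self) -> dict[tuple[int, int, int], int]:
        return {e.color: e.region_id for e in self.entries}

    def ids(self) -> set[int]:
        return {e.region_id for e in self.entries}


@dataclass
class LabelVolume:
    """3D integer parcellation grid with voxel size and terminology.

    ``labels`` is indexed ``[x, y, z]``; voxel centres sit at integer
    coordinates in the volume's own voxel space.  ``affine`` is recorded
    orientation metadata and is never applied.
    """

    labels: np.ndarray
    voxel_size_um: float
    terminology: Terminology
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"label volume must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be integers")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        present = set(np.unique(self.labels).tolist()) - {0}
        known = self.terminology.ids()
        if not present <= known:
            raise ValueError(f"labels missing from terminology: {sorted(present - known)}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]


def region_voxel_counts(volume: LabelVolume) -> dict[int, int]:
    """Voxel count per region, background excluded.

    The counts conserve volume: their sum plus the background count equals
    nx*ny*nz.
    """
    values, counts = np.unique(volume.labels, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts) if v != 0}


def _distinct_color(i: int, taken: set[tuple[int, int, int]]) -> tuple[int, int, int]:
    # deterministic, collision-free colour assignment for generated terminologies
    c = ((37 * i + 11) % 256, (101 * i + 53) % 256, (197 * i + 29) % 256)
    while c in taken or c == (255, 255, 255):
        c = ((c[0] + 1) % 256, c[1], (c[2] + 7) % 256)
    return c


def generic_terminology(region_ids, prefix: str = "region") -> Terminology:
    """Placeholder terminology (distinct colours, no hierarchy) for given ids."""
    entries: list[TermEntry] = []
    taken: set[tuple[int, int, int]] = set()
    for rid in sorted(int(r) for r in region_ids if int(r) != 0):
        color = _distinct_color(rid, taken)
        taken.add(color)
        entries.append(TermEntry(rid, f"{prefix} {rid}", f"{prefix[:1].upper()}{rid}", color))
    return Terminology(entries)


def read_label_volume(path: str | Path, terminology: Terminology | None = None) -> LabelVolume:
    """Read a NIfTI label volume.

    The data must be a single-channel integer 3D grid (integral-valued float
    storage is accepted and cast).  The voxel size comes from the header
    zooms; header spatial units of mm or micron are honoured, unknown units
    are assumed to be mm.  No resampling or reorientation is applied.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        if np.issubdtype(data.dtype, np.floating) and np.all(data == np.round(data)):
            data = data.astype(np.int32)
        else:
            raise FormatError("volume data is not integer-valued")
    zooms = img.header.get_zooms()[:3]
    unit = img.header.get_xyzt_units()[0]
    factor = {"micron": 1.0, "mm": 1000.0, "meter": 1e6}.get(unit, 1000.0)
    voxel_size_um = float(zooms[0]) * factor
    if terminology is None:
        terminology = generic_terminology(np.unique(data))
    return LabelVolume(
        labels=np.ascontiguousarray(data),
        voxel_size_um=voxel_size_um,
        terminology=terminology,
        affine=np.asarray(img.affine),
    )


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a NIfTI-1 label volume (mm units, diagonal affine)."""
    vox_mm = volume.voxel_size_um / 1000.0
    affine = volume.affine if volume.affine is not None else np.diag([vox_mm] * 3 + [1.0])
    img = nib.Nifti1Image(volume.labels.astype(np.int32), affine)
    img.header.set_zooms((vox_mm,) * 3)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))


_LABEL_ROW = re.compile(
    r"^\s*(\d+)\s+(\d+)\s+(\d+)\s+(\d+)\s+([\d.]+)\s+(\d+)\s+(\d+)\s+\"(.*)\"\s*$"
)


def read_label_descriptions(path: str | Path) -> Terminology:
    """Parse an ITK-SNAP label-description file into a :class:`Terminology`.

    One entry per non-background row; quoted labels may contain spaces.  The
    alpha and visibility columns are parsed but ignored.  The format carries
    no abbreviation or parent column, so abbreviations default to the name
    and parents to none.
    """
    entries: list[TermEntry] = []
    seen_ids: set[int] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _LABEL_ROW.match(line)
        if m is None:
            raise FormatError(f"{path}: malformed label row at line {lineno}: {line!r}")
        rid = int(m.group(1))
        if rid in seen_ids:
            raise ValueError(f"{path}: duplicate region id {rid} at line {lineno}")
        seen_ids.add(rid)
        if rid == 0:
            continue  # background row is conventional, never an entry
        name = m.group(8)
        entries.append(
            TermEntry(
                region_id=rid,
                name=name,
                abbreviation=name,
                color=(int(m.group(2)), int(m.group(3)), int(m.group(4))),
            )
        )
    return Terminology(entries)


def write_label_descriptions(terminology: Terminology, path: str | Path) -> None:
    """Write an ITK-SNAP label-description file (round-trips through the reader)."""
    lines = [
        "# ITK-SNAP label description file",
        "# Columns: ID R G B A VIS MSH LABEL",
        '0 0 0 0 0 0 0 "Clear Label"',
    ]
    for e in sorted(terminology.entries, key=lambda e: e.region_id):
        r, g, b = e.color
        lines.append(f'{e.region_id} {r} {g} {b} 1 1 1 "{e.name}"')
    Path(path).write_text("\n".join(lines) + "\n")
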