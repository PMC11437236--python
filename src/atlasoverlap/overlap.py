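"""Per-section overlap counting between a query annotation and a reference cut.

For one section, the query atlas contributes a 2D label image (its regions,
the "objects") and the reference atlas contributes the matching custom-cut
label image resampled from its 3D volume.  :func:`count_overlap` tallies the
joint label distribution: for every query region q present on the section,
how many of its pixels fall in each reference region r.  Query pixels lying
outside the reference brain land on reference id 0 and stay in the tally,
because section proportions downstream are normalised by the *total* object
pixels of the section (configurable via ``include_reference_background``).

Connected-component ("object splitting") outputs of quantifier tools are out
of scope here: only aggregate counts are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .anchoring import AnchoringSpec
from .atlas_model import LabelVolume, Terminology
from .refinement import MarkerSet, extract_refined_plate

__all__ = [
    "SectionOverlapReport",
    "AnnotationPlate",
    "ColourDecodeError",
    "count_overlap",
    "decode_colour_plate",
    "encode_colour_plate",
    "read_plate_png",
    "write_plate_png",
    "quantify_series",
    "reports_to_frame",
    "frame_to_reports",
]

BACKGROUND_COLOUR = (255, 255, 255)


class ColourDecodeError(ValueError):
    """A plate contains colours absent from the terminology."""


@dataclass
class SectionOverlapReport:
    """Joint pixel counts (query region x reference region) for one section.

    ``query_totals[q]`` is the section's total object-pixel count for query
    region q and always equals the sum of ``counts[q, .]`` (conservation).
    """

    plate_id: str
    bregma_mm: float
    counts: dict[tuple[int, int], int]
    query_totals: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        totals: dict[int, int] = {}
        for (q, r), c in self.counts.items():
            if q == 0:
                raise ValueError("query background (0) cannot appear as an object")
            if c < 0:
                raise ValueError("counts must be non-negative")
            totals[q] = totals.get(q, 0) + c
        if self.query_totals:
            if self.query_totals != totals:
                raise ValueError("query_totals inconsistent with counts")
        else:
            self.query_totals = totals

    def query_regions(self) -> set[int]:
        return set(self.query_totals)


def count_overlap(
    annotation: np.ndarray,
    reference: np.ndarray,
    plate_id: str = "",
    bregma_mm: float = 0.0,
    include_reference_background: bool = True,
) -> SectionOverlapReport:
    """Tally, per query region, where its pixels fall in the reference image.

    ``counts[q, r]`` = number of pixels with annotation q != 0 and reference
    r.  Background annotation pixels are not objects and are ignored.  With
    ``include_reference_background=False``, query pixels on reference
    background are dropped from the tally (and hence from section totals).
    """
    annotation = np.asarray(annotation)
    reference = np.asarray(reference)
    if annotation.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: annotation {annotation.shape} vs reference {reference.shape}"
        )
    mask = annotation != 0
    if not include_reference_background:
        mask &= reference != 0
    q = annotation[mask].astype(np.int64)
    r = reference[mask].astype(np.int64)
    pairs, counts = np.unique(np.stack([q, r]), axis=1, return_counts=True)
    return SectionOverlapReport(
        plate_id=plate_id,
        bregma_mm=bregma_mm,
        counts={(int(a), int(b)): int(c) for (a, b), c in zip(pairs.T, counts)},
    )


def decode_colour_plate(
    image: np.ndarray,
    terminology: Terminology,
    background_colour: tuple[int, int, int] = BACKGROUND_COLOUR,
) -> np.ndarray:
    """Decode an RGB-coded plate (shape (w, h, 3)) to a 2D label image.

    Colour matching is exact: plates must be saved without anti-aliasing.
    Unknown colours raise :class:`ColourDecodeError` listing each offending
    RGB value with its pixel count, which catches anti-aliased edges early.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (w, h, 3)")
    packed = (
        image[..., 0].astype(np.int64) << 16
    ) | (image[..., 1].astype(np.int64) << 8) | image[..., 2].astype(np.int64)
    lut = {(c[0] << 16) | (c[1] << 8) | c[2]: rid for c, rid in terminology.by_color().items()}
    bg = (background_colour[0] << 16) | (background_colour[1] << 8) | background_colour[2]
    lut[bg] = 0
    values, counts = np.unique(packed, return_counts=True)
    unknown = [(int(v), int(c)) for v, c in zip(values, counts) if int(v) not in lut]
    if unknown:
        desc = ", ".join(
            f"RGB({v >> 16},{(v >> 8) & 255},{v & 255}) x{c}" for v, c in unknown
        )
        raise ColourDecodeError(f"unknown colours in plate: {desc}")
    out = np.zeros(packed.shape, dtype=np.int32)
    for v, rid in lut.items():
        if rid != 0:
            out[packed == v] = rid
    return out


def encode_colour_plate(
    labels: np.ndarray,
    terminology: Terminology,
    background_colour: tuple[int, int, int] = BACKGROUND_COLOUR,
) -> np.ndarray:
    """Inverse of :func:`decode_colour_plate`: label image -> exact RGB image."""
    labels = np.asarray(labels)
    out = np.empty(labels.shape + (3,), dtype=np.uint8)
    out[...] = np.asarray(background_colour, dtype=np.uint8)
    by_id = terminology.by_id()
    for rid in np.unique(labels):
        if rid == 0:
            continue
        out[labels == rid] = np.asarray(by_id[int(rid)].color, dtype=np.uint8)
    return out


def write_plate_png(image: np.ndarray, path: str | Path) -> None:
    """Write a plate array ([i, j] indexed, optionally RGB) as a PNG file."""
    image = np.asarray(image)
    rowmajor = image.swapaxes(0, 1)  # (w, h[, 3]) -> (h, w[, 3])
    if rowmajor.ndim == 2:
        rowmajor = rowmajor.astype(np.uint16 if rowmajor.max() > 255 else np.uint8)
    iio.imwrite(str(path), rowmajor)


def read_plate_png(path: str | Path) -> np.ndarray:
    """Read a PNG plate back into the package's [i, j] (column, row) layout."""
    rowmajor = iio.imread(str(path))
    if rowmajor.ndim == 3 and rowmajor.shape[-1] == 4:
        rowmajor = rowmajor[..., :3]
    return np.asarray(rowmajor).swapaxes(0, 1)


@dataclass
class AnnotationPlate:
    """One query-atlas section: label image + anchoring + optional markers."""

    plate_id: str
    bregma_mm: float
    labels: np.ndarray
    spec: AnchoringSpec
    markers: MarkerSet = field(default_factory=MarkerSet)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.spec.width, self.spec.height):
            raise ValueError("plate labels must have shape (width, height) of its spec")


def quantify_series(
    reference: LabelVolume,
    plates: list[AnnotationPlate],
    include_reference_background: bool = True,
) -> list[SectionOverlapReport]:
    """Run the quantifier over a plate series against a 3D reference volume.

    Each plate's reference cut is extracted along its anchoring (with marker
    refinement when present) and tallied against its annotation image.
    """
    reports = []
    for plate in plates:
        ref_img = extract_refined_plate(reference, plate.spec, plate.markers)
        reports.append(
            count_overlap(
                plate.labels,
                ref_img,
                plate_id=plate.plate_id,
                bregma_mm=plate.bregma_mm,
                include_reference_background=include_reference_background,
            )
        )
    return reports


def reports_to_frame(reports: list[SectionOverlapReport]) -> pd.DataFrame:
    """Compile section-wise reports into one table, section number as a column.

    Sections are numbered 1..n in rostral-to-caudal (decreasing Bregma) order.
    """
    ordered = sorted(reports, key=lambda r: -r.bregma_mm)
    rows = []
    for number, rep in enumerate(ordered, start=1):
        for (q, r), c in sorted(rep.counts.items()):
            rows.append(
                {
                    "section_number": number,
                    "plate_id": rep.plate_id,
                    "bregma_mm": rep.bregma_mm,
                    "query_region_id": q,
                    "reference_region_id": r,
                    "pixel_count": c,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "section_number",
            "plate_id",
            "bregma_mm",
            "query_region_id",
            "reference_region_id",
            "pixel_count",
        ],
    )


def frame_to_reports(frame: pd.DataFrame) -> list[SectionOverlapReport]:
    """Rebuild section reports from a compiled table (inverse of reports_to_frame)."""
    reports = []
    for (_, plate_id, bregma), grp in frame.groupby(
        ["section_number", "plate_id", "bregma_mm"], sort=True
    ):
        counts = {
            (int(row.query_region_id), int(row.reference_region_id)): int(row.pixel_count)
            for row in grp.itertuples()
        }
        reports.append(
            SectionOverlapReport(plate_id=str(plate_id), bregma_mm=float(bregma), counts=counts)
        )
    return reports
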