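"""Overlap statistics: section proportions, segment pooling, sampling ratios.

The section-wise overlap proportion of a query region q with a reference
region r is OP_reg / sum(OPs): the object pixels of q landing in r divided
by all object pixels of q on that section.  Sections containing q are then
grouped into rostral, middle and caudal thirds (any remainder goes to the
middle segment) and pooled; pooling is pixel-weighted, i.e. a ratio of
summed counts, not an unweighted mean of per-section proportions
(``method="mean"`` gives the unweighted alternative).

Sampling ratios describe how densely a printed stereotaxic atlas samples a
region: from the rostral and caudal Bregma ends, the estimated number of
40-um sections spanning the region is ``round_half_up(extent / thickness)``
and the ratio is the percentage of those sections that carry annotations.
Rounding is half-up (away from zero) for both counts and percentages;
percentages are reported at integer precision to match printed tables,
with the raw fraction retained on the record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .overlap import SectionOverlapReport

__all__ = [
    "Segment",
    "SegmentSummary",
    "SamplingRecord",
    "EmptyRegionError",
    "round_half_up",
    "section_proportions",
    "split_segments",
    "pooled_proportions",
    "sampling_ratio",
    "summarize_for_charts",
]

Segment = Literal["rostral", "middle", "caudal", "all"]
SEGMENTS: tuple[Segment, ...] = ("rostral", "middle", "caudal", "all")


class EmptyRegionError(KeyError):
    """The query region has no object pixels on this section."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (0.5 -> 1).

    Values are snapped to 9 decimals first so binary float noise around an
    exact half (e.g. 161.99999999999997) cannot flip the result.
    """
    x = round(x, 9)
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SegmentSummary:
    """Reference-region composition of one query region within one segment."""

    segment: Segment
    query_region_id: int
    fractions: dict[int, float]
    n_sections: int = 0
    total_pixels: int = 0

    def __post_init__(self) -> None:
        if self.fractions:
            s = sum(self.fractions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"fractions sum to {s}, expected 1")


@dataclass
class SamplingRecord:
    """Section-sampling arithmetic for one region of a printed atlas."""

    abbreviation: str
    rostral_mm: float
    caudal_mm: float
    n_sampled: int
    thickness_mm: float = 0.04
    total_length_mm: float = field(init=False)
    total_sections: int = field(init=False)
    ratio_pct: int = field(init=False)
    ratio_raw: float = field(init=False)
    oversampled: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not self.rostral_mm > self.caudal_mm:
            raise ValueError("rostral end must be rostral to (greater than) caudal end")
        if self.n_sampled < 1:
            raise ValueError("n_sampled must be at least 1")
        if not self.thickness_mm > 0:
            raise ValueError("thickness_mm must be positive")
        self.total_length_mm = self.rostral_mm - self.caudal_mm
        self.total_sections = round_half_up(self.total_length_mm / self.thickness_mm)
        # more sampled plates than estimated sections flags a likely table
        # typo upstream; the record is kept, not rejected
        self.oversampled = self.n_sampled > self.total_sections
        self.ratio_raw = 100.0 * self.n_sampled / self.total_sections
        self.ratio_pct = round_half_up(self.ratio_raw)


def sampling_ratio(
    rostral_mm: float,
    caudal_mm: float,
    n_sampled: int,
    thickness_mm: float = 0.04,
    abbreviation: str = "",
) -> SamplingRecord:
    """Estimate total sections and the sampled-section percentage for a region."""
    return SamplingRecord(
        abbreviation=abbreviation,
        rostral_mm=rostral_mm,
        caudal_mm=caudal_mm,
        n_sampled=n_sampled,
        thickness_mm=thickness_mm,
    )


def section_proportions(report: SectionOverlapReport, q: int) -> dict[int, float]:
    """Section-wise overlap proportions OP_reg / sum(OPs) for query region q."""
    total = report.query_totals.get(q, 0)
    if total <= 0:
        raise EmptyRegionError(f"query region {q} has no pixels on plate {report.plate_id!r}")
    return {r: c / total for (qq, r), c in sorted(report.counts.items()) if qq == q}


def split_segments(n_sections: int) -> tuple[int, int, int]:
    """Partition n sections (ordered by decreasing Bregma) into thirds.

    Rostral and caudal segments take floor(n/3) each; any remainder is
    allocated to the middle segment.
    """
    if n_sections < 1:
        raise ValueError("need at least one section")
    k = n_sections // 3
    return k, n_sections - 2 * k, k


def pooled_proportions(
    reports: Iterable[SectionOverlapReport],
    q: int,
    method: Literal["pixel", "mean"] = "pixel",
) -> dict[Segment, SegmentSummary]:
    """Pool section-wise overlap of query region q into segments and overall.

    Only sections where q has object pixels enter its rostral/middle/caudal
    partition; they are ordered by decreasing Bregma before splitting.  The
    default pixel pooling computes sum(counts)/sum(totals) per segment;
    ``method="mean"`` averages per-section proportions unweighted instead.
    """
    with_q = sorted(
        (r for r in reports if r.query_totals.get(q, 0) > 0),
        key=lambda r: -r.bregma_mm,
    )
    if not with_q:
        raise EmptyRegionError(f"query region {q} appears on no section")
    n_r, n_m, n_c = split_segments(len(with_q))
    groups: dict[Segment, list[SectionOverlapReport]] = {
        "rostral": with_q[:n_r],
        "middle": with_q[n_r : n_r + n_m],
        "caudal": with_q[n_r + n_m :],
        "all": with_q,
    }
    out: dict[Segment, SegmentSummary] = {}
    for segment, group in groups.items():
        if not group:
            out[segment] = SegmentSummary(segment, q, {}, 0, 0)
            continue
        total = sum(rep.query_totals[q] for rep in group)
        if method == "pixel":
            sums: dict[int, float] = {}
            for rep in group:
                for (qq, r), c in rep.counts.items():
                    if qq == q:
                        sums[r] = sums.get(r, 0) + c
            fractions = {r: c / total for r, c in sorted(sums.items())}
        elif method == "mean":
            acc: dict[int, float] = {}
            for rep in group:
                for r, f in section_proportions(rep, q).items():
                    acc[r] = acc.get(r, 0.0) + f
            fractions = {r: f / len(group) for r, f in sorted(acc.items())}
        else:
            raise ValueError(f"unknown pooling method {method!r}")
        out[segment] = SegmentSummary(segment, q, fractions, len(group), total)
    return out


def summarize_for_charts(
    summaries: Iterable[SegmentSummary],
    display_threshold: float = 1e-4,
    other_id: int = -1,
) -> pd.DataFrame:
    """Flatten segment summaries into deterministic pie-chart rows.

    Rows are ordered by descending fraction (ties broken by region id);
    reference regions below ``display_threshold`` (default 0.01%) are
    collapsed into a single "other" row carrying ``other_id``.
    """
    rows = []
    for summary in summaries:
        kept = [
            (r, f) for r, f in summary.fractions.items() if f >= display_threshold
        ]
        kept.sort(key=lambda rf: (-rf[1], rf[0]))
        tail = sum(f for r, f in summary.fractions.items() if f < display_threshold)
        for r, f in kept:
            rows.append(
                {
                    "query_region_id": summary.query_region_id,
                    "segment": summary.segment,
                    "reference_region_id": r,
                    "fraction": f,
                }
            )
        if tail > 0:
            rows.append(
                {
                    "query_region_id": summary.query_region_id,
                    "segment": summary.segment,
                    "reference_region_id": other_id,
                    "fraction": tail,
                }
            )
    return pd.DataFrame(
        rows, columns=["query_region_id", "segment", "reference_region_id", "fraction"]
    )
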