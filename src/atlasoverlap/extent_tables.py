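"""Published region-extent tables for two printed stereotaxic rat atlases.

Printed stereotaxic atlases do not annotate regions on every 40-um section;
they sample a subset of plates.  These tables record, for each basal
ganglia region, the rostral and caudal Bregma ends of the region, the
number of atlas plates that carry its annotation, and the values the
published survey printed for the derived quantities (total sections and
sample ratio), which :func:`atlasoverlap.stats.sampling_ratio` recomputes.

Data-provenance note.  In the published survey a few cells are internally
inconsistent.  Three rows of the *The Rat Brain in Stereotaxic Coordinates*
v6 table (CPu, IPAC, PN) print a Bregma end that contradicts the row's
mutually consistent length/total/ratio triple; for those rows the canonical
end stored here is the length-consistent value and the raw printed end is
kept in ``printed_rostral_mm``/``printed_caudal_mm`` with an explanatory
note.  In the *Brain Maps* v3 table the VTA and STN total-length cells are
swapped relative to their own Bregma ends while totals and ratios agree
with the ends; the ends are canonical there and the swapped length is
noted.  The survey's printed 19% average for *Brain Maps* v3 does not equal
the mean of its printed per-row ratios (15.5 -> 16); this module reports
only recomputed means.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stats import SamplingRecord, round_half_up, sampling_ratio

__all__ = [
    "RegionExtent",
    "ExtentTable",
    "RAT_STEREOTAXIC_V6",
    "BRAIN_MAPS_V3",
    "sampling_table",
    "mean_ratio_pct",
]


@dataclass(frozen=True)
class RegionExtent:
    """One region's extent row: canonical Bregma ends + sampled plate count."""

    group: str
    abbreviation: str
    rostral_mm: float
    caudal_mm: float
    n_sampled: int
    published_total_sections: int
    published_ratio_pct: int
    printed_rostral_mm: float | None = None
    printed_caudal_mm: float | None = None
    note: str = ""


@dataclass(frozen=True)
class ExtentTable:
    atlas_name: str
    version_label: str
    thickness_mm: float
    rows: tuple[RegionExtent, ...]


RAT_STEREOTAXIC_V6 = ExtentTable(
    atlas_name="The Rat Brain in Stereotaxic Coordinates",
    version_label="6",
    thickness_mm=0.04,
    rows=(
        RegionExtent("STR", "AcbC", 3.00, 0.48, 19, 63, 30),
        RegionExtent("STR", "AcbSh", 3.24, 0.48, 20, 69, 29),
        RegionExtent(
            "STR", "CPu", 2.76, -3.72, 55, 162, 34,
            printed_caudal_mm=-3.96,
            note="published caudal end -3.96 contradicts the published length 6.48 "
            "(= 162 x 0.04); the length-consistent end is canonical",
        ),
        RegionExtent(
            "STR", "IPAC", 0.60, -0.48, 9, 27, 33,
            printed_caudal_mm=-1.44,
            note="published caudal end -1.44 contradicts the published length 1.08 "
            "and ratio 33%; the length-consistent end is canonical",
        ),
        RegionExtent("STR", "IPACL", -0.24, -1.20, 9, 24, 38),
        RegionExtent("STR", "IPACM", -0.24, -1.20, 9, 24, 38),
        RegionExtent("STR", "LAcbSh", 2.16, 0.84, 12, 33, 36),
        RegionExtent("STR", "LSS", 2.28, -0.60, 24, 72, 33),
        RegionExtent("PAL", "GP", -0.24, -3.12, 25, 72, 35),
        RegionExtent("PAL", "EP", -1.92, -2.76, 8, 21, 38),
        RegionExtent("PAL", "VP", 3.00, -1.08, 32, 102, 31),
        RegionExtent("SN", "SNCD", -4.56, -6.60, 18, 51, 35),
        RegionExtent("SN", "SNCM", -5.76, -6.60, 8, 21, 38),
        RegionExtent("SN", "SNCV", -5.76, -6.60, 8, 21, 38),
        RegionExtent("SN", "SNL", -4.56, -6.48, 17, 48, 35),
        RegionExtent("SN", "SNR", -4.36, -6.72, 21, 59, 36),
        RegionExtent("VTA", "PBP", -4.56, -6.48, 17, 48, 35),
        RegionExtent("VTA", "PIF", -5.52, -6.60, 10, 27, 37),
        RegionExtent(
            "VTA", "PN", -5.16, -6.48, 12, 33, 36,
            printed_rostral_mm=-5.2,
            note="published rostral end -5.2 contradicts the published length 1.32; "
            "the length-consistent end is canonical",
        ),
        RegionExtent("VTA", "VTA", -6.72, -6.84, 2, 3, 67),
        RegionExtent("VTA", "VTAR", -4.68, -5.04, 4, 9, 44),
        RegionExtent("STN", "STh", -3.12, -4.20, 10, 27, 37),
    ),
)

BRAIN_MAPS_V3 = ExtentTable(
    atlas_name="Brain Maps: Structure of the Rat Brain",
    version_label="3",
    thickness_mm=0.04,
    rows=(
        RegionExtent("STR", "CP", 2.15, -3.70, 22, 146, 15),
        RegionExtent("STR", "ACB", 2.80, 0.45, 7, 59, 12),
        RegionExtent("STR", "FS", 1.20, -0.83, 10, 51, 20),
        RegionExtent("PAL", "GPe", -0.26, -2.85, 11, 65, 17),
        RegionExtent("PAL", "GPi", -1.08, -2.45, 6, 34, 18),
        RegionExtent("PAL", "SI", 2.15, -2.85, 20, 125, 16),
        RegionExtent("SN", "SNc", -4.60, -6.50, 6, 48, 13),
        RegionExtent("SN", "SNr", -4.45, -6.65, 8, 55, 15),
        RegionExtent(
            "VTA", "VTA", -4.45, -7.10, 8, 66, 12,
            note="published total-length cell (0.95) is swapped with STN's; ends, "
            "total sections and ratio are mutually consistent and canonical",
        ),
        RegionExtent(
            "STN", "STN", -3.25, -4.20, 4, 24, 17,
            note="published total-length cell (2.65) is swapped with VTA's; ends, "
            "total sections and ratio are mutually consistent and canonical",
        ),
    ),
)


def sampling_table(table: ExtentTable) -> pd.DataFrame:
    """Recompute every row's sampling arithmetic from its Bregma ends.

    Returns one row per region with the recomputed total sections and ratio
    next to the published values, so discrepancies are visible at a glance.
    """
    records: list[SamplingRecord] = [
        sampling_ratio(
            row.rostral_mm,
            row.caudal_mm,
            row.n_sampled,
            thickness_mm=table.thickness_mm,
            abbreviation=row.abbreviation,
        )
        for row in table.rows
    ]
    return pd.DataFrame(
        {
            "group": [r.group for r in table.rows],
            "abbreviation": [r.abbreviation for r in table.rows],
            "rostral_mm": [r.rostral_mm for r in table.rows],
            "caudal_mm": [r.caudal_mm for r in table.rows],
            "total_length_mm": [rec.total_length_mm for rec in records],
            "n_sampled": [r.n_sampled for r in table.rows],
            "total_sections": [rec.total_sections for rec in records],
            "ratio_pct": [rec.ratio_pct for rec in records],
            "published_total_sections": [r.published_total_sections for r in table.rows],
            "published_ratio_pct": [r.published_ratio_pct for r in table.rows],
            "note": [r.note for r in table.rows],
        }
    )


def mean_ratio_pct(table: ExtentTable) -> int:
    """Mean of the recomputed per-row integer ratios, rounded half-up."""
    frame = sampling_table(table)
    return round_half_up(float(frame["ratio_pct"].mean()))
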