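"""Synthetic paired parcellations with exact ground truth.

The real analysis compares copyrighted atlas material that cannot ship with
code, so every pipeline stage here is exercised on generated stand-ins: a
3D reference parcellation of a toy anatomy (superellipsoid blobs over
background), a query parcellation of the *same* anatomy with controlled
discrepancies (translation, dilation, merge, split), a coronal plate series
cut from the query at configurable spacing, tilt and nonlinear deformation,
and the exact 3D joint voxel counts the pipeline estimates from the plates.

All randomness flows from the scenario seed.  The default geometry mimics
the real setting scaled down about 8x per axis: a 128 x 64 x 64 grid at a
nominal 39 um voxel size stands in for a 1024 x 512 x 512 reference volume.
Bregma is an affine function of z (stored on the scenario, never inferred):
``bregma_mm(z) = (bregma_zero_frac * nz - z) * voxel_size_mm``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .anchoring import AnchoringSpec, SectionSeries, write_anchoring
from .atlas_model import (
    LabelVolume,
    Terminology,
    TermEntry,
    write_label_descriptions,
    write_label_volume,
)
from .overlap import AnnotationPlate, SectionOverlapReport, encode_colour_plate, quantify_series, write_plate_png
from .refinement import MarkerSet, extract_refined_plate, write_markers
from .stats import pooled_proportions

__all__ = [
    "GenerationError",
    "PerturbationPlan",
    "PlatePlan",
    "SyntheticScenario",
    "Ellipsoid",
    "SyntheticReference",
    "SyntheticQuery",
    "SyntheticSeries",
    "make_reference_volume",
    "make_query_atlas",
    "cut_plate_series",
    "oracle_overlap_3d",
    "run_scenario",
    "recovery_scenario",
    "write_scenario",
]


class GenerationError(RuntimeError):
    """The scenario cannot be realised (e.g. blobs do not fit the volume)."""


@dataclass(frozen=True)
class PerturbationPlan:
    """Controlled discrepancies applied when deriving the query parcellation.

    ``translation_voxels`` shifts the listed regions (``None`` = all) by a
    whole-voxel offset; ``dilation_radius`` grows the listed regions by that
    many binary-dilation iterations (they overwrite their neighbours);
    ``merge`` pairs (a, b) relabel b as a; ``split`` ids are divided at
    their mid-plane along z into the original id and a new one.
    """

    translation_voxels: tuple[int, int, int] = (0, 0, 0)
    translated_regions: tuple[int, ...] | None = None
    dilation_radius: int = 0
    dilated_regions: tuple[int, ...] = ()
    merge: tuple[tuple[int, int], ...] = ()
    split: tuple[int, ...] = ()

    @property
    def is_identity(self) -> bool:
        return (
            self.translation_voxels == (0, 0, 0) or self.translated_regions == ()
        ) and self.dilation_radius == 0 and not self.merge and not self.split


@dataclass(frozen=True)
class PlatePlan:
    """How the coronal plate series is cut from the query volume."""

    spacing_mm: float = 0.039
    thickness_mm: float = 0.04
    sampled_fraction: float = 1.0
    tilt_dv_deg: float = 0.0
    tilt_ml_deg: float = 0.0
    deformation_amplitude_px: float = 0.0
    deformation_grid: tuple[int, int] = (3, 3)
    pixels_per_voxel: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.sampled_fraction <= 1.0:
            raise ValueError("sampled_fraction must be in (0, 1]")
        if self.spacing_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("spacing_mm and thickness_mm must be positive")


@dataclass(frozen=True)
class SyntheticScenario:
    """One fully specified synthetic study, reproducible from its seed."""

    seed: int = 0
    dims: tuple[int, int, int] = (128, 64, 64)
    voxel_size_um: float = 39.0
    n_regions: int = 8
    perturbation: PerturbationPlan = field(default_factory=PerturbationPlan)
    plate_plan: PlatePlan = field(default_factory=PlatePlan)
    bregma_zero_frac: float = 0.3

    def bregma_at(self, z: float) -> float:
        """Bregma coordinate (mm, positive rostral) of coronal level z."""
        return (self.bregma_zero_frac * self.dims[2] - z) * self.voxel_size_um / 1000.0


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def analytic_volume(self) -> float:
        a, b, c = self.radii
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class SyntheticReference:
    volume: LabelVolume
    blobs: dict[int, Ellipsoid]


@dataclass
class SyntheticQuery:
    volume: LabelVolume
    truth_counts: dict[tuple[int, int], int]


@dataclass
class SyntheticSeries:
    plates: list[AnnotationPlate]
    series: SectionSeries
    markers: dict[str, MarkerSet]


def _region_colors(n: int) -> list[tuple[int, int, int]]:
    taken = {(255, 255, 255)}
    out = []
    for i in range(1, n + 1):
        c = ((53 * i + 19) % 256, (131 * i + 67) % 256, (223 * i + 41) % 256)
        while c in taken:
            c = ((c[0] + 3) % 256, c[1], (c[2] + 11) % 256)
        taken.add(c)
        out.append(c)
    return out


def _terminology_for(region_ids: list[int], blobs: dict[int, Ellipsoid], nz: int) -> Terminology:
    """Terminology with a small two-group parent hierarchy (by z position)."""
    colors = _region_colors(len(region_ids) + 2)
    rostral_parent = max(region_ids, default=0) + 101
    caudal_parent = rostral_parent + 1
    entries = [
        TermEntry(rostral_parent, "rostral group", "RG", colors[-2]),
        TermEntry(caudal_parent, "caudal group", "CG", colors[-1]),
    ]
    for color, rid in zip(colors, region_ids):
        cz = blobs[rid].center[2] if rid in blobs else nz / 2
        parent = rostral_parent if cz < nz / 2 else caudal_parent
        entries.append(TermEntry(rid, f"region {rid}", f"R{rid}", color, parent_id=parent))
    return Terminology(entries)


def make_reference_volume(scenario: SyntheticScenario) -> SyntheticReference:
    """Deterministically generate the reference parcellation for a scenario.

    Regions are ellipsoids drawn fully inside the volume (so their painted
    voxel counts track the analytic ellipsoid volume); later region ids
    overwrite earlier ones where they overlap, like nested anatomy.
    """
    rng = np.random.default_rng(scenario.seed)
    nx, ny, nz = scenario.dims
    labels = np.zeros(scenario.dims, dtype=np.int32)
    blobs: dict[int, Ellipsoid] = {}
    budget = 0.0
    for rid in range(1, scenario.n_regions + 1):
        radii = (
            rng.uniform(0.06, 0.11) * nx,
            rng.uniform(0.12, 0.22) * ny,
            rng.uniform(0.19, 0.31) * nz,
        )
        lo = [r + 1.5 for r in radii]
        hi = [d - r - 2.5 for d, r in zip(scenario.dims, radii)]
        if any(l >= h for l, h in zip(lo, hi)):
            raise GenerationError(f"region {rid} does not fit inside dims {scenario.dims}")
        center = tuple(rng.uniform(l, h) for l, h in zip(lo, hi))
        blobs[rid] = Ellipsoid(center, radii)
        budget += blobs[rid].analytic_volume()
    if budget > 0.7 * nx * ny * nz:
        raise GenerationError("overcrowded scenario: blobs exceed 70% of the volume")
    x, y, z = np.ogrid[:nx, :ny, :nz]
    for rid, blob in blobs.items():
        (cx, cy, cz), (rx, ry, rz) = blob.center, blob.radii
        mask = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0
        labels[mask] = rid
    terminology = _terminology_for(list(blobs), blobs, nz)
    volume = LabelVolume(labels, scenario.voxel_size_um, terminology)
    return SyntheticReference(volume, blobs)


def _shift(mask: np.ndarray, t: tuple[int, int, int]) -> np.ndarray:
    """Shift a boolean mask by whole voxels, zero-padded (no wrap-around)."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for axis, d in enumerate(t):
        n = mask.shape[axis]
        if abs(d) >= n:
            return out
        src.append(slice(max(0, -d), n - max(0, d)))
        dst.append(slice(max(0, d), n - max(0, -d)))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def make_query_atlas(
    reference: SyntheticReference, scenario: SyntheticScenario
) -> SyntheticQuery:
    """Derive the query parcellation by applying the perturbation plan.

    With a zero plan the query equals the reference and the ground-truth
    joint counts are diagonal.  Ground truth is recorded by the naive 3D
    oracle, independent of the plate pipeline.
    """
    plan = scenario.perturbation
    ref_labels = reference.volume.labels
    ids = sorted(reference.blobs)
    query = np.zeros_like(ref_labels)
    translated = set(ids if plan.translated_regions is None else plan.translated_regions)
    for rid in ids:
        mask = ref_labels == rid
        if rid in translated and plan.translation_voxels != (0, 0, 0):
            mask = _shift(mask, plan.translation_voxels)
        query[mask] = rid
    if plan.dilation_radius > 0:
        for rid in plan.dilated_regions:
            grown = ndimage.binary_dilation(query == rid, iterations=plan.dilation_radius)
            query[grown] = rid
    for a, b in plan.merge:
        query[query == b] = a
    next_id = max(ids, default=0) + 1
    split_names: dict[int, int] = {}
    for rid in plan.split:
        mask = query == rid
        if not mask.any():
            continue
        zs = np.nonzero(mask)[2]
        zmid = 0.5 * (zs.min() + zs.max())
        caudal = mask & (np.arange(query.shape[2])[None, None, :] > zmid)
        query[caudal] = next_id
        split_names[rid] = next_id
        next_id += 1

    present = sorted(set(np.unique(query).tolist()) - {0})
    terminology = _terminology_for(present, reference.blobs, scenario.dims[2])
    volume = LabelVolume(query, scenario.voxel_size_um, terminology)
    truth = oracle_overlap_3d(volume, reference.volume)
    return SyntheticQuery(volume, truth)


def _rotation(tilt_ml_deg: float, tilt_dv_deg: float) -> np.ndarray:
    """Section tilt: mediolateral angle about the y axis, dorsoventral about x."""
    t = np.deg2rad(tilt_ml_deg)
    p = np.deg2rad(tilt_dv_deg)
    r_y = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])
    r_x = np.array([[1, 0, 0], [0, np.cos(p), -np.sin(p)], [0, np.sin(p), np.cos(p)]])
    return r_x @ r_y


def cut_plate_series(
    query_volume: LabelVolume, scenario: SyntheticScenario
) -> SyntheticSeries:
    """Cut the coronal plate series (annotation images + anchoring + markers).

    Planes are placed every ``spacing_mm`` along z, tilted per the plan, and
    every plate is kept or dropped so that a fraction ``sampled_fraction``
    of the full series survives, evenly spread.  With a deformation
    amplitude, each plate is cut through a smooth piecewise-affine warp and
    the exact markers reproducing that warp are emitted, so refinement can
    restore the undeformed sampling.
    """
    plan = scenario.plate_plan
    rng = np.random.default_rng(scenario.seed + 1_000_003)
    nx, ny, nz = scenario.dims
    voxel_mm = scenario.voxel_size_um / 1000.0
    spacing_vox = plan.spacing_mm / voxel_mm
    width = nx * plan.pixels_per_voxel
    height = ny * plan.pixels_per_voxel
    rot = _rotation(plan.tilt_ml_deg, plan.tilt_dv_deg)

    n_full = int(np.floor((nz - 1) / spacing_vox)) + 1
    kept = [
        k
        for k in range(n_full)
        if np.floor((k + 1) * plan.sampled_fraction) > np.floor(k * plan.sampled_fraction)
    ]

    plates: list[AnnotationPlate] = []
    series_plates: list[tuple[AnchoringSpec, float]] = []
    markers: dict[str, MarkerSet] = {}
    for k in kept:
        z = k * spacing_vox
        o = np.array([-0.5, -0.5, z])
        u = np.array([float(nx), 0.0, 0.0])
        v = np.array([0.0, float(ny), 0.0])
        centre = o + 0.5 * u + 0.5 * v
        u = rot @ u
        v = rot @ v
        o = centre - 0.5 * u - 0.5 * v
        spec = AnchoringSpec(f"plate-{k:03d}", o, u, v, width, height)
        if plan.deformation_amplitude_px > 0:
            gx, gy = plan.deformation_grid
            pairs = []
            for fx in (np.arange(1, gx + 1)) / (gx + 1):
                for fy in (np.arange(1, gy + 1)) / (gy + 1):
                    src = (float(fx * width), float(fy * height))
                    d = rng.uniform(-plan.deformation_amplitude_px, plan.deformation_amplitude_px, 2)
                    pairs.append((src, (src[0] + float(d[0]), src[1] + float(d[1]))))
            plate_markers = MarkerSet(pairs)
        else:
            plate_markers = MarkerSet()
        labels = extract_refined_plate(query_volume, spec, plate_markers)
        bregma = scenario.bregma_at(z)
        plates.append(AnnotationPlate(spec.plate_id, bregma, labels, spec, plate_markers))
        series_plates.append((spec, bregma))
        markers[spec.plate_id] = plate_markers
    return SyntheticSeries(
        plates=plates,
        series=SectionSeries(series_plates, thickness_mm=plan.thickness_mm),
        markers=markers,
    )


def oracle_overlap_3d(
    volume_a: LabelVolume | np.ndarray, volume_b: LabelVolume | np.ndarray
) -> dict[tuple[int, int], int]:
    """Exact 3D joint voxel counts by a deliberately naive per-voxel tally.

    This is the independent ground-truth oracle: it walks every voxel pair
    once with a plain counter and shares no code with the plate pipeline.
    """
    a = (volume_a.labels if isinstance(volume_a, LabelVolume) else np.asarray(volume_a)).ravel()
    b = (volume_b.labels if isinstance(volume_b, LabelVolume) else np.asarray(volume_b)).ravel()
    if a.shape != b.shape:
        raise ValueError("volumes must share dimensions")
    tally: Counter = Counter(zip(a.tolist(), b.tolist()))
    return {(int(q), int(r)): int(c) for (q, r), c in sorted(tally.items())}


@dataclass
class ScenarioResult:
    """Everything one synthetic study produced, pipeline and truth side."""

    scenario: SyntheticScenario
    reference: SyntheticReference
    query: SyntheticQuery
    cut: SyntheticSeries
    reports: list[SectionOverlapReport]

    def truth_fractions(self, q: int) -> dict[int, float]:
        counts = {r: c for (qq, r), c in self.query.truth_counts.items() if qq == q and qq != 0}
        total = sum(counts.values())
        return {r: c / total for r, c in counts.items()}

    def pipeline_fractions(self, q: int) -> dict[int, float]:
        return pooled_proportions(self.reports, q)["all"].fractions

    def recovery_errors_pp(self, q: int) -> dict[int, float]:
        """Per reference region: |pipeline - truth| in percentage points."""
        truth = self.truth_fractions(q)
        pipe = self.pipeline_fractions(q)
        return {
            r: 100.0 * abs(pipe.get(r, 0.0) - truth.get(r, 0.0))
            for r in set(truth) | set(pipe)
        }

    def plates_spanned(self, q: int) -> int:
        """Sections of the *full* (unsampled) series the query region spans."""
        mask = self.query.volume.labels == q
        if not mask.any():
            return 0
        zs = np.nonzero(mask)[2]
        voxel_mm = self.scenario.voxel_size_um / 1000.0
        spacing_vox = self.scenario.plate_plan.spacing_mm / voxel_mm
        return int((zs.max() - zs.min() + 1) / spacing_vox)


def run_scenario(scenario: SyntheticScenario) -> ScenarioResult:
    """Generate a scenario end to end and run the plate pipeline on it."""
    reference = make_reference_volume(scenario)
    query = make_query_atlas(reference, scenario)
    cut = cut_plate_series(query.volume, scenario)
    reports = quantify_series(reference.volume, cut.plates)
    return ScenarioResult(scenario, reference, query, cut, reports)


def recovery_scenario(seed: int) -> SyntheticScenario:
    """The standard sparse-sampling recovery study condition.

    Eight regions; half of them shifted by (1, 0, 2) voxels, one dilated,
    one pair merged and one region split, emulating real inter-atlas
    boundary discrepancies; coronal plates at one-voxel spacing with a
    4-degree mediolateral tilt and ~30% of plates kept, matching the
    sampling range of printed stereotaxic atlases.
    """
    return SyntheticScenario(
        seed=seed,
        perturbation=PerturbationPlan(
            translation_voxels=(1, 0, 2),
            translated_regions=(1, 2, 3, 4),
            dilation_radius=1,
            dilated_regions=(5,),
            merge=((6, 7),),
            split=(8,),
        ),
        plate_plan=PlatePlan(sampled_fraction=0.3, tilt_ml_deg=4.0),
    )


def write_scenario(scenario: SyntheticScenario, path: str | Path) -> dict[str, Path]:
    """Emit a complete scenario directory in the formats the pipeline reads.

    Writes reference and query NIfTI volumes with label-description files,
    the anchoring series as XML and JSON, the per-plate marker JSON, and
    each annotation plate as a losslessly colour-coded PNG.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    result = run_scenario(scenario)
    paths: dict[str, Path] = {}

    paths["reference_volume"] = path / "reference_atlas.nii.gz"
    write_label_volume(result.reference.volume, paths["reference_volume"])
    paths["reference_labels"] = path / "reference_atlas.label"
    write_label_descriptions(result.reference.volume.terminology, paths["reference_labels"])
    paths["query_volume"] = path / "query_atlas.nii.gz"
    write_label_volume(result.query.volume, paths["query_volume"])
    paths["query_labels"] = path / "query_atlas.label"
    write_label_descriptions(result.query.volume.terminology, paths["query_labels"])
    paths["anchoring_xml"] = path / "anchoring.xml"
    write_anchoring(result.cut.series, paths["anchoring_xml"])
    paths["anchoring_json"] = path / "anchoring.json"
    write_anchoring(result.cut.series, paths["anchoring_json"])
    paths["markers"] = path / "markers.json"
    write_markers(result.cut.markers, paths["markers"])
    plate_dir = path / "plates"
    plate_dir.mkdir(exist_ok=True)
    for plate in result.cut.plates:
        rgb = encode_colour_plate(plate.labels, result.query.volume.terminology)
        write_plate_png(rgb, plate_dir / f"{plate.plate_id}.png")
    paths["plates"] = plate_dir
    return paths
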