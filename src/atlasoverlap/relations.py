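"""Relational metadata: atlases, regions, and region-to-region relations.

Mirrors the three-table relational design used to catalogue how regions
correspond across atlas versions ("Nomenclatures", "Regions",
"Topological_relations"), stored portably as a directory of CSV files.
Qualitative relation types between a region A of one atlas and a region B
of another follow the five-value vocabulary *identical*, *part_of*,
*includes*, *overlapping*, *non_overlapping* (the last reserved for regions
that share a term but do not spatially overlap).

:func:`classify_relation` is an advisory heuristic that derives a
qualitative type from the two directed overlap fractions; published
qualitative calls of this kind are typically made by expert inspection, so
every automated call should be emitted alongside the raw fractions.

:func:`to_openminds` emits SANDS-style JSON metadata documents (BrainAtlas,
BrainAtlasVersion, ParcellationTerminologyVersion,
ParcellationEntityVersion with embedded qualitative/quantitative relation
assessments); field names follow the cited schema vocabulary, with
qualitative types mapped to isIdenticalTo / isSubsetOf / isSupersetOf /
hasIntersectionWith.  @context handling and versioned-IRI minting are out
of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

from .schemas import load_schema, validate

__all__ = [
    "CHANGE_STATUSES",
    "QUALITATIVE_TYPES",
    "NomenclatureRecord",
    "RegionRecord",
    "RelationRecord",
    "RelationalDatabase",
    "IntegrityError",
    "classify_relation",
    "invert_qualitative",
    "expand_bidirectional",
    "to_openminds",
    "validate_openminds",
    "store_relational",
    "load_relational",
]

CHANGE_STATUSES = ("new", "unchanged", "minor", "major", "replaced")
QUALITATIVE_TYPES = ("identical", "part_of", "includes", "overlapping", "non_overlapping")

_INVERSE = {
    "identical": "identical",
    "part_of": "includes",
    "includes": "part_of",
    "overlapping": "overlapping",
    "non_overlapping": "non_overlapping",
}

_OPENMINDS_VOCAB = {
    "identical": "isIdenticalTo",
    "part_of": "isSubsetOf",
    "includes": "isSupersetOf",
    "overlapping": "hasIntersectionWith",
}


class IntegrityError(ValueError):
    """Referential-integrity violation in the three-table dataset."""


@dataclass(frozen=True)
class NomenclatureRecord:
    """One atlas version (a nomenclature)."""

    atlas_name: str
    version_label: str
    publication_year: int | None = None
    reference_data_id: str | None = None

    @property
    def key(self) -> str:
        return f"{self.atlas_name}@{self.version_label}"


@dataclass(frozen=True)
class RegionRecord:
    """One region of one nomenclature, with optional extent and change status."""

    nomenclature_ref: str
    term: str
    abbreviation: str
    rostral_bregma_mm: float | None = None
    caudal_bregma_mm: float | None = None
    n_sections: int | None = None
    change_status: str = "new"
    change_note: str = ""

    def __post_init__(self) -> None:
        if self.change_status not in CHANGE_STATUSES:
            raise ValueError(
                f"change_status must be one of {CHANGE_STATUSES}, got {self.change_status!r}"
            )

    @property
    def key(self) -> str:
        return f"{self.nomenclature_ref}/{self.abbreviation}"


@dataclass(frozen=True)
class RelationRecord:
    """Directed relation between region A and region B of different atlases."""

    region_a_ref: str
    region_b_ref: str
    qualitative: str
    overlap_pct_a_in_b: float | None = None
    comparability_score: int | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        if self.qualitative not in QUALITATIVE_TYPES:
            raise ValueError(f"unknown qualitative type {self.qualitative!r}")
        if self.overlap_pct_a_in_b is not None:
            if not 0.0 <= self.overlap_pct_a_in_b <= 100.0:
                raise ValueError("overlap_pct_a_in_b must be within [0, 100]")
            if self.qualitative == "non_overlapping" and self.overlap_pct_a_in_b != 0.0:
                raise ValueError("non_overlapping requires zero overlap")


@dataclass
class RelationalDatabase:
    """The three tables, with referential integrity checked on demand."""

    nomenclatures: list[NomenclatureRecord] = field(default_factory=list)
    regions: list[RegionRecord] = field(default_factory=list)
    relations: list[RelationRecord] = field(default_factory=list)

    def check_integrity(self) -> None:
        nom_keys = [n.key for n in self.nomenclatures]
        if len(set(nom_keys)) != len(nom_keys):
            raise IntegrityError("duplicate (atlas_name, version_label) nomenclature")
        region_keys: set[str] = set()
        for r in self.regions:
            if r.nomenclature_ref not in set(nom_keys):
                raise IntegrityError(f"region {r.key!r} references unknown nomenclature")
            if r.key in region_keys:
                raise IntegrityError(f"duplicate abbreviation {r.abbreviation!r} in {r.nomenclature_ref!r}")
            region_keys.add(r.key)
        for rel in self.relations:
            for ref in (rel.region_a_ref, rel.region_b_ref):
                if ref not in region_keys:
                    raise IntegrityError(f"relation references unknown region {ref!r}")


def classify_relation(
    f_ab: float,
    f_ba: float,
    tau_identity: float = 0.95,
    tau_floor: float = 1e-4,
) -> str:
    """Heuristic qualitative type from the two directed overlap fractions.

    ``f_ab`` is the fraction of region A inside region B and ``f_ba`` the
    converse.  Both above ``tau_identity`` means *identical*; only
    ``f_ab`` means A is *part_of* B; only ``f_ba`` means A *includes* B;
    anything above ``tau_floor`` is *overlapping*; else *non_overlapping*.
    Advisory: emit the raw fractions alongside any automated call.
    """
    for name, f in (("f_ab", f_ab), ("f_ba", f_ba)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be within [0, 1], got {f}")
    if f_ab >= tau_identity and f_ba >= tau_identity:
        return "identical"
    if f_ab >= tau_identity:
        return "part_of"
    if f_ba >= tau_identity:
        return "includes"
    if max(f_ab, f_ba) >= tau_floor:
        return "overlapping"
    return "non_overlapping"


def invert_qualitative(qualitative: str) -> str:
    return _INVERSE[qualitative]


def expand_bidirectional(records: Iterable[RelationRecord]) -> list[RelationRecord]:
    """Close a relation set under inversion (every part_of gains its includes).

    Existing inverse records are checked for consistency; missing ones are
    added with the directed overlap left unknown.  Output order is
    deterministic (sorted by region references).  The operation is
    idempotent.
    """
    by_pair: dict[tuple[str, str], RelationRecord] = {}
    for rec in records:
        key = (rec.region_a_ref, rec.region_b_ref)
        if key in by_pair and by_pair[key].qualitative != rec.qualitative:
            raise IntegrityError(f"conflicting duplicate relation for {key}")
        by_pair.setdefault(key, rec)
    for key, rec in list(by_pair.items()):
        inv_key = (rec.region_b_ref, rec.region_a_ref)
        expected = invert_qualitative(rec.qualitative)
        if inv_key in by_pair:
            if by_pair[inv_key].qualitative != expected:
                raise IntegrityError(
                    f"inverse of {key} is {by_pair[inv_key].qualitative!r}, expected {expected!r}"
                )
            continue
        by_pair[inv_key] = RelationRecord(
            region_a_ref=inv_key[0],
            region_b_ref=inv_key[1],
            qualitative=expected,
            comment="mirrored from the opposite relation",
        )
    return [by_pair[k] for k in sorted(by_pair)]


def to_openminds(
    atlases: Iterable[NomenclatureRecord],
    regions: Iterable[RegionRecord],
    relations: Iterable[RelationRecord],
    quantitative_threshold_pct: float = 0.01,
    annotation_files: Mapping[str, str] | None = None,
) -> list[dict]:
    """Emit SANDS-style metadata documents for atlases, regions and relations.

    One BrainAtlas per atlas name, one BrainAtlasVersion plus
    ParcellationTerminologyVersion per version, one ParcellationEntityVersion
    per region with embedded relation assessments.  Quantitative assessments
    below ``quantitative_threshold_pct`` (default 0.01%) are dropped;
    non_overlapping pairs carry no metadata vocabulary term and are likewise
    omitted from qualitative assessments.  ``annotation_files`` maps a
    nomenclature key to its label-volume file; AtlasAnnotation documents
    link a file only for atlases that have one.
    """
    atlases = list(atlases)
    regions = list(regions)
    relations = list(relations)
    RelationalDatabase(atlases, regions, relations).check_integrity()
    annotation_files = dict(annotation_files or {})

    docs: list[dict] = []
    by_name: dict[str, list[NomenclatureRecord]] = {}
    for nom in atlases:
        by_name.setdefault(nom.atlas_name, []).append(nom)

    region_ids = {r.key: f"region/{r.key}" for r in regions}
    qual_by_region: dict[str, list[dict]] = {}
    quant_by_region: dict[str, list[dict]] = {}
    for rel in relations:
        if rel.qualitative != "non_overlapping":
            qual_by_region.setdefault(rel.region_a_ref, []).append(
                {
                    "inRelationTo": {"@id": region_ids[rel.region_b_ref]},
                    "qualitativeOverlap": _OPENMINDS_VOCAB[rel.qualitative],
                    "criteria": rel.comment or "expert visual comparison of co-registered atlases",
                }
            )
        if (
            rel.overlap_pct_a_in_b is not None
            and rel.overlap_pct_a_in_b >= quantitative_threshold_pct
        ):
            quant_by_region.setdefault(rel.region_a_ref, []).append(
                {
                    "inRelationTo": {"@id": region_ids[rel.region_b_ref]},
                    "quantitativeOverlap": {
                        "value": rel.overlap_pct_a_in_b,
                        "unit": "percent",
                    },
                    "criteria": "pixel overlap of co-registered annotations",
                }
            )

    for atlas_name in sorted(by_name):
        versions = by_name[atlas_name]
        docs.append(
            {
                "@type": "BrainAtlas",
                "@id": f"atlas/{atlas_name}",
                "shortName": atlas_name,
                "hasVersion": [{"@id": f"atlas/{nom.key}"} for nom in versions],
            }
        )
        for nom in versions:
            term_id = f"terminology/{nom.key}"
            docs.append(
                {
                    "@type": "BrainAtlasVersion",
                    "@id": f"atlas/{nom.key}",
                    "shortName": nom.atlas_name,
                    "versionIdentifier": nom.version_label,
                    "publicationYear": nom.publication_year,
                    "usedReferenceData": nom.reference_data_id,
                    "hasTerminologyVersion": {"@id": term_id},
                }
            )
            nom_regions = [r for r in regions if r.nomenclature_ref == nom.key]
            docs.append(
                {
                    "@type": "ParcellationTerminologyVersion",
                    "@id": term_id,
                    "hasEntityVersion": [{"@id": region_ids[r.key]} for r in nom_regions],
                }
            )
            for r in nom_regions:
                doc = {
                    "@type": "ParcellationEntityVersion",
                    "@id": region_ids[r.key],
                    "name": r.term,
                    "abbreviation": r.abbreviation,
                    "versionInnovation": r.change_note or None,
                }
                annotation = {
                    "@type": "AtlasAnnotation",
                    "internalIdentifier": r.abbreviation,
                }
                if nom.key in annotation_files:
                    annotation["annotationFile"] = annotation_files[nom.key]
                doc["hasAnnotation"] = annotation
                if r.key in qual_by_region:
                    doc["qualitativeRelationAssessment"] = qual_by_region[r.key]
                if r.key in quant_by_region:
                    doc["quantitativeRelationAssessment"] = quant_by_region[r.key]
                docs.append(doc)
    return docs


def validate_openminds(docs: list[dict]) -> None:
    """Validate emitted documents against the shipped JSON schema."""
    schema = load_schema()
    validate(docs, {"type": "array", "items": {"type": "object"}})
    for k, doc in enumerate(docs):
        dtype = doc.get("@type")
        if dtype not in schema["$defs"]:
            raise ValueError(f"document {k} has unknown @type {dtype!r}")
        validate(doc, {"$ref": f"#/$defs/{dtype}"}, root=schema, path=f"/{k}")


# ---------------------------------------------------------------------------
# Three-table CSV storage

_TABLES = {
    "nomenclatures.csv": NomenclatureRecord,
    "regions.csv": RegionRecord,
    "relations.csv": RelationRecord,
}


def _to_cell(value) -> str:
    return "" if value is None else str(value)


def _from_cell(text: str, kind):
    if text == "":
        return None
    if kind in (int, "int | None", int | None):
        return int(text)
    if kind in (float, "float | None", float | None):
        return float(text)
    return text


def store_relational(db: RelationalDatabase, path: str | Path) -> None:
    """Write the three tables as CSV files in a directory (lossless)."""
    db.check_integrity()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for filename, cls in _TABLES.items():
        rows = {
            NomenclatureRecord: db.nomenclatures,
            RegionRecord: db.regions,
            RelationRecord: db.relations,
        }[cls]
        names = [f.name for f in fields(cls)]
        with open(path / filename, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(names)
            for rec in rows:
                writer.writerow([_to_cell(getattr(rec, n)) for n in names])


def load_relational(path: str | Path) -> RelationalDatabase:
    """Read the three-table dataset back, validating foreign keys."""
    path = Path(path)
    loaded: dict[str, list] = {}
    for filename, cls in _TABLES.items():
        specs = {f.name: f.type for f in fields(cls)}
        records = []
        with open(path / filename, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header != list(specs):
                raise IntegrityError(f"{filename}: unexpected columns {header}")
            for row in reader:
                kwargs = {}
                for name, text in zip(header, row):
                    t = specs[name]
                    if t in ("int | None",):
                        kwargs[name] = _from_cell(text, int)
                    elif t in ("float | None",):
                        kwargs[name] = _from_cell(text, float)
                    elif t in ("str | None",):
                        kwargs[name] = text if text != "" else None
                    else:
                        kwargs[name] = text
                records.append(cls(**kwargs))
        loaded[filename] = records
    db = RelationalDatabase(
        nomenclatures=loaded["nomenclatures.csv"],
        regions=loaded["regions.csv"],
        relations=loaded["relations.csv"],
    )
    db.check_integrity()
    return db
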