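import pytest
from hypothesis import given, settings, strategies as st

from atlasoverlap.relations import (
    IntegrityError,
    NomenclatureRecord,
    RegionRecord,
    RelationRecord,
    RelationalDatabase,
    classify_relation,
    expand_bidirectional,
    invert_qualitative,
    load_relational,
    store_relational,
    to_openminds,
    validate_openminds,
)
from atlasoverlap.schemas import SchemaValidationError, load_schema, validate


def fixture_database():
    noms = [
        NomenclatureRecord("Waxholm Space rat brain atlas", "4", 2023, "MRI/DTI v1.01"),
        NomenclatureRecord("Brain Maps", "3", 2004, "plates v1"),
        NomenclatureRecord("Brain Maps", "4", 2018, "plates v1"),
    ]
    regions = [
        RegionRecord("Waxholm Space rat brain atlas@4", "nucleus accumbens, core", "NAc-c"),
        RegionRecord("Waxholm Space rat brain atlas@4", "nucleus accumbens, shell", "NAc-sh"),
        RegionRecord("Brain Maps@3", "Nucleus accumbens", "ACB", 2.80, 0.45, 7, "unchanged"),
        RegionRecord("Brain Maps@3", "Caudoputamen", "CP", 2.15, -3.70, 22, "minor"),
        RegionRecord("Brain Maps@4", "Accumbens nucleus", "ACB", change_status="minor"),
    ]
    relations = [
        RelationRecord(
            "Brain Maps@3/ACB",
            "Waxholm Space rat brain atlas@4/NAc-c",
            "includes",
            overlap_pct_a_in_b=55.0,
        ),
        RelationRecord(
            "Brain Maps@3/CP",
            "Waxholm Space rat brain atlas@4/NAc-sh",
            "overlapping",
            overlap_pct_a_in_b=2.5,
        ),
    ]
    return RelationalDatabase(noms, regions, relations)


class TestClassifyRelation:
    @pytest.mark.parametrize(
        "f_ab,f_ba,expected",
        [
            (1.0, 1.0, "identical"),
            (1.0, 0.5, "part_of"),
            (0.5, 1.0, "includes"),
            (0.4, 0.3, "overlapping"),
            (0.0, 0.0, "non_overlapping"),
            (5e-5, 0.0, "non_overlapping"),
        ],
    )
    def test_examples(self, f_ab, f_ba, expected):
        assert classify_relation(f_ab, f_ba) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_relation(1.2, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_antisymmetry(self, f_ab, f_ba):
        assert classify_relation(f_ba, f_ab) == invert_qualitative(classify_relation(f_ab, f_ba))


class TestExpandBidirectional:
    def test_includes_gains_part_of(self):
        # e.g. "atlas B nucleus accumbens includes atlas W nucleus accumbens, core"
        rec = RelationRecord("bm3/ACB", "whs4/NAc-c", "includes")
        out = expand_bidirectional([rec])
        assert len(out) == 2
        mirrored = [r for r in out if r.region_a_ref == "whs4/NAc-c"][0]
        assert mirrored.qualitative == "part_of"
        assert mirrored.region_b_ref == "bm3/ACB"

    def test_symmetric_input_unchanged(self):
        recs = [
            RelationRecord("a/x", "b/y", "overlapping"),
            RelationRecord("b/y", "a/x", "overlapping"),
        ]
        assert expand_bidirectional(recs) == sorted(
            recs, key=lambda r: (r.region_a_ref, r.region_b_ref)
        )

    def test_idempotent_involution(self):
        recs = [
            RelationRecord("a/x", "b/y", "includes"),
            RelationRecord("a/x", "c/z", "identical"),
            RelationRecord("b/y", "c/w", "overlapping"),
        ]
        once = expand_bidirectional(recs)
        twice = expand_bidirectional(once)
        assert once == twice
        pairs = {(r.region_a_ref, r.region_b_ref) for r in once}
        assert pairs == {(b, a) for a, b in pairs}

    def test_conflicting_inverse_rejected(self):
        recs = [
            RelationRecord("a/x", "b/y", "includes"),
            RelationRecord("b/y", "a/x", "identical"),
        ]
        with pytest.raises(IntegrityError, match="inverse"):
            expand_bidirectional(recs)


class TestRecordInvariants:
    def test_nonoverlapping_requires_zero_overlap(self):
        with pytest.raises(ValueError, match="zero overlap"):
            RelationRecord("a/x", "b/y", "non_overlapping", overlap_pct_a_in_b=1.0)

    def test_overlap_pct_bounded(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            RelationRecord("a/x", "b/y", "overlapping", overlap_pct_a_in_b=101.0)

    def test_change_status_vocabulary(self):
        with pytest.raises(ValueError, match="change_status"):
            RegionRecord("n@1", "term", "T", change_status="tweaked")


class TestOpenMinds:
    def test_document_inventory_small_graph(self):
        nom = NomenclatureRecord("atlas-x", "1")
        regions = [RegionRecord("atlas-x@1", "area a", "A"), RegionRecord("atlas-x@1", "area b", "B")]
        rels = [RelationRecord("atlas-x@1/A", "atlas-x@1/B", "identical", overlap_pct_a_in_b=99.0)]
        docs = to_openminds([nom], regions, rels)
        by_type = {}
        for d in docs:
            by_type.setdefault(d["@type"], []).append(d)
        assert len(by_type["BrainAtlas"]) == 1
        assert len(by_type["BrainAtlasVersion"]) == 1
        assert len(by_type["ParcellationTerminologyVersion"]) == 1
        assert len(by_type["ParcellationEntityVersion"]) == 2
        entity_a = [d for d in by_type["ParcellationEntityVersion"] if d["abbreviation"] == "A"][0]
        assert entity_a["qualitativeRelationAssessment"][0]["qualitativeOverlap"] == "isIdenticalTo"
        assert entity_a["qualitativeRelationAssessment"][0]["inRelationTo"]["@id"] == "region/atlas-x@1/B"

    def test_quantitative_inclusion_threshold(self):
        nom = NomenclatureRecord("atlas-x", "1")
        regions = [RegionRecord("atlas-x@1", "a", "A"), RegionRecord("atlas-x@1", "b", "B"),
                   RegionRecord("atlas-x@1", "c", "C")]
        rels = [
            RelationRecord("atlas-x@1/A", "atlas-x@1/B", "overlapping", overlap_pct_a_in_b=0.009),
            RelationRecord("atlas-x@1/A", "atlas-x@1/C", "overlapping", overlap_pct_a_in_b=0.01),
        ]
        docs = to_openminds([nom], regions, rels)
        entity_a = [d for d in docs if d.get("abbreviation") == "A"][0]
        quant = entity_a["quantitativeRelationAssessment"]
        assert len(quant) == 1
        assert quant[0]["inRelationTo"]["@id"].endswith("/C")

    def test_vocabulary_mapping(self):
        mapping = {
            "identical": "isIdenticalTo",
            "part_of": "isSubsetOf",
            "includes": "isSupersetOf",
            "overlapping": "hasIntersectionWith",
        }
        nom = NomenclatureRecord("atlas-x", "1")
        regions = [RegionRecord("atlas-x@1", "a", "A"), RegionRecord("atlas-x@1", "b", "B")]
        for qualitative, term in mapping.items():
            rels = [RelationRecord("atlas-x@1/A", "atlas-x@1/B", qualitative)]
            docs = to_openminds([nom], regions, rels)
            entity_a = [d for d in docs if d.get("abbreviation") == "A"][0]
            assert entity_a["qualitativeRelationAssessment"][0]["qualitativeOverlap"] == term

    def test_dangling_reference_rejected(self):
        nom = NomenclatureRecord("atlas-x", "1")
        regions = [RegionRecord("atlas-x@1", "a", "A")]
        rels = [RelationRecord("atlas-x@1/A", "atlas-x@1/GONE", "overlapping")]
        with pytest.raises(IntegrityError, match="unknown region"):
            to_openminds([nom], regions, rels)

    def test_annotation_file_only_when_available(self):
        db = fixture_database()
        docs = to_openminds(
            db.nomenclatures, db.regions, db.relations,
            annotation_files={"Waxholm Space rat brain atlas@4": "atlas_v4.nii.gz"},
        )
        for d in docs:
            if d.get("@type") != "ParcellationEntityVersion":
                continue
            has_file = "annotationFile" in d["hasAnnotation"]
            assert has_file == d["@id"].startswith("region/Waxholm")

    def test_fixture_graph_validates_against_schema(self):
        db = fixture_database()
        docs = to_openminds(db.nomenclatures, db.regions, db.relations)
        validate_openminds(docs)  # raises on violation

    def test_schema_rejects_bad_vocabulary(self):
        schema = load_schema()
        bad = {
            "inRelationTo": {"@id": "region/x"},
            "qualitativeOverlap": "touches",
        }
        with pytest.raises(SchemaValidationError, match="touches"):
            validate(bad, {"$ref": "#/$defs/qualitativeRelationAssessment"}, root=schema)


class TestRelationalStore:
    def test_empty_round_trip(self, tmp_path):
        db = RelationalDatabase()
        store_relational(db, tmp_path / "db")
        assert load_relational(tmp_path / "db") == db

    def test_fixture_round_trip_lossless(self, tmp_path):
        db = fixture_database()
        store_relational(db, tmp_path / "db")
        back = load_relational(tmp_path / "db")
        assert back.nomenclatures == db.nomenclatures
        assert back.regions == db.regions
        assert back.relations == db.relations

    def test_duplicate_abbreviation_rejected(self, tmp_path):
        db = fixture_database()
        db.regions.append(RegionRecord("Brain Maps@3", "another", "ACB"))
        with pytest.raises(IntegrityError, match="duplicate abbreviation"):
            store_relational(db, tmp_path / "db")

    def test_orphan_relation_rejected(self, tmp_path):
        db = fixture_database()
        store_relational(db, tmp_path / "db")
        with open(tmp_path / "db" / "relations.csv", "a", newline="") as fh:
            fh.write("ghost/X,ghost/Y,overlapping,,,\n")
        with pytest.raises(IntegrityError, match="unknown region"):
            load_relational(tmp_path / "db")
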