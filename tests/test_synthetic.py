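import numpy as np
import pytest

from atlasoverlap.overlap import count_overlap, quantify_series
from atlasoverlap.stats import pooled_proportions
from atlasoverlap.synthetic import (
    GenerationError,
    PerturbationPlan,
    PlatePlan,
    SyntheticScenario,
    cut_plate_series,
    make_query_atlas,
    make_reference_volume,
    oracle_overlap_3d,
    run_scenario,
)

SMALL = dict(dims=(48, 32, 32), n_regions=3)


class TestReferenceGeneration:
    def test_seed_determinism(self):
        a = make_reference_volume(SyntheticScenario(seed=5, **SMALL))
        b = make_reference_volume(SyntheticScenario(seed=5, **SMALL))
        np.testing.assert_array_equal(a.volume.labels, b.volume.labels)
        assert a.blobs == b.blobs

    def test_no_regions_all_background(self):
        ref = make_reference_volume(SyntheticScenario(seed=1, dims=(16, 16, 16), n_regions=0))
        assert not ref.volume.labels.any()

    def test_single_ellipsoid_matches_analytic_volume(self):
        ref = make_reference_volume(SyntheticScenario(seed=2, dims=(64, 48, 48), n_regions=1))
        count = int(np.sum(ref.volume.labels == 1))
        analytic = ref.blobs[1].analytic_volume()
        assert abs(count - analytic) / analytic < 0.02

    def test_overcrowded_scenario_rejected(self):
        with pytest.raises(GenerationError):
            make_reference_volume(SyntheticScenario(seed=0, dims=(10, 10, 10), n_regions=60))

    def test_regions_have_parent_hierarchy(self):
        ref = make_reference_volume(SyntheticScenario(seed=3, **SMALL))
        by_id = ref.volume.terminology.by_id()
        for rid in ref.blobs:
            assert by_id[rid].parent_id is not None
            assert by_id[rid].parent_id in by_id


class TestQueryAtlas:
    def test_zero_perturbation_is_identity(self):
        scenario = SyntheticScenario(seed=4, **SMALL)
        ref = make_reference_volume(scenario)
        query = make_query_atlas(ref, scenario)
        np.testing.assert_array_equal(query.volume.labels, ref.volume.labels)
        assert all(q == r for (q, r) in query.truth_counts if q != 0 and r != 0)

    def test_pure_translation_matches_set_intersection(self):
        scenario = SyntheticScenario(
            seed=6,
            **SMALL,
            perturbation=PerturbationPlan(translation_voxels=(0, 0, 3), translated_regions=(1,)),
        )
        ref = make_reference_volume(scenario)
        query = make_query_atlas(ref, scenario)
        # independent recount: shift region 1's voxel set directly
        mask1 = ref.volume.labels == 1
        shifted = np.zeros_like(mask1)
        shifted[:, :, 3:] = mask1[:, :, :-3]
        # region 1 was painted first, so later regions overwrite it
        for rid in (2, 3):
            shifted &= ref.volume.labels != rid
        for r in range(4):
            expected = int(np.sum(shifted & (ref.volume.labels == r)))
            assert query.truth_counts.get((1, r), 0) == expected

    def test_split_conserves_region(self):
        scenario = SyntheticScenario(seed=7, **SMALL, perturbation=PerturbationPlan(split=(2,)))
        ref = make_reference_volume(scenario)
        query = make_query_atlas(ref, scenario)
        new_id = max(ref.blobs) + 1
        union = (query.volume.labels == 2) | (query.volume.labels == new_id)
        np.testing.assert_array_equal(union, ref.volume.labels == 2)

    def test_merge_relabels(self):
        scenario = SyntheticScenario(seed=8, **SMALL, perturbation=PerturbationPlan(merge=((1, 2),)))
        ref = make_reference_volume(scenario)
        query = make_query_atlas(ref, scenario)
        assert 2 not in set(np.unique(query.volume.labels).tolist())


class TestOracleOverlap3D:
    def test_identical_volumes_diagonal(self, small_volume):
        counts = oracle_overlap_3d(small_volume, small_volume)
        assert all(q == r for q, r in counts)

    def test_disjoint_labels_no_cross_terms(self):
        a = np.zeros((4, 4, 4), dtype=int)
        b = np.zeros((4, 4, 4), dtype=int)
        a[:2] = 1
        b[2:] = 2
        counts = oracle_overlap_3d(a, b)
        assert counts.get((1, 2), 0) == 0

    def test_matches_set_intersection_recount(self, rng):
        a = rng.integers(0, 4, size=(8, 7, 6))
        b = rng.integers(0, 4, size=(8, 7, 6))
        counts = oracle_overlap_3d(a, b)
        for q in range(4):
            for r in range(4):
                expected = int(np.sum((a == q) & (b == r)))
                assert counts.get((q, r), 0) == expected


class TestPlateSeries:
    def test_full_sampling_no_tilt_equals_slices(self):
        scenario = SyntheticScenario(seed=9, **SMALL)
        ref = make_reference_volume(scenario)
        query = make_query_atlas(ref, scenario)
        cut = cut_plate_series(query.volume, scenario)
        assert len(cut.plates) == scenario.dims[2]
        for k, plate in enumerate(cut.plates):
            np.testing.assert_array_equal(plate.labels, query.volume.labels[:, :, k])

    def test_plate_count_follows_sampling_fraction(self):
        scenario = SyntheticScenario(
            seed=9, **SMALL, plate_plan=PlatePlan(sampled_fraction=0.25)
        )
        ref = make_reference_volume(scenario)
        query = make_query_atlas(ref, scenario)
        cut = cut_plate_series(query.volume, scenario)
        assert len(cut.plates) == int(np.floor(scenario.dims[2] * 0.25))

    def test_bregma_strictly_decreasing(self):
        scenario = SyntheticScenario(seed=9, **SMALL)
        ref = make_reference_volume(scenario)
        query = make_query_atlas(ref, scenario)
        bregmas = [b for _, b in cut_plate_series(query.volume, scenario).series.plates]
        assert all(b2 < b1 for b1, b2 in zip(bregmas, bregmas[1:]))


class TestScenarioExport:
    def test_written_scenario_round_trips_through_readers(self, tmp_path):
        from atlasoverlap.anchoring import read_anchoring
        from atlasoverlap.atlas_model import read_label_descriptions, read_label_volume
        from atlasoverlap.overlap import decode_colour_plate, read_plate_png
        from atlasoverlap.refinement import read_markers
        from atlasoverlap.synthetic import write_scenario

        scenario = SyntheticScenario(
            seed=13, dims=(32, 24, 16), n_regions=2,
            plate_plan=PlatePlan(sampled_fraction=0.5, deformation_amplitude_px=1.0),
        )
        paths = write_scenario(scenario, tmp_path / "scene")
        term = read_label_descriptions(paths["query_labels"])
        query = read_label_volume(paths["query_volume"], terminology=term)
        expected_query = make_query_atlas(make_reference_volume(scenario), scenario)
        np.testing.assert_array_equal(query.labels, expected_query.volume.labels)
        series = read_anchoring(paths["anchoring_xml"])
        markers = read_markers(paths["markers"])
        cut = cut_plate_series(expected_query.volume, scenario)
        assert len(series) == len(cut.plates) == len(markers)
        for plate in cut.plates:
            png = read_plate_png(tmp_path / "scene" / "plates" / f"{plate.plate_id}.png")
            np.testing.assert_array_equal(
                decode_colour_plate(png, expected_query.volume.terminology), plate.labels
            )


class TestPipelineAgainstOracle:
    def test_full_sampling_recovers_truth_exactly(self):
        result = run_scenario(SyntheticScenario(seed=10, **SMALL))
        for q in sorted({q for q, _ in result.query.truth_counts if q != 0}):
            truth = result.truth_fractions(q)
            pipe = result.pipeline_fractions(q)
            assert pipe == pytest.approx(truth, abs=1e-12)

    def test_deformed_plates_with_inverse_markers_restore_counts(self):
        base = SyntheticScenario(seed=11, **SMALL)
        deformed = SyntheticScenario(
            seed=11, **SMALL,
            plate_plan=PlatePlan(deformation_amplitude_px=2.0),
        )
        ref = make_reference_volume(base)
        query = make_query_atlas(ref, base)
        undeformed_cut = cut_plate_series(query.volume, base)
        deformed_cut = cut_plate_series(query.volume, deformed)
        undeformed_reports = quantify_series(ref.volume, undeformed_cut.plates)
        deformed_reports = quantify_series(ref.volume, deformed_cut.plates)
        from scipy import ndimage

        for rep_u, rep_d, plate in zip(undeformed_reports, deformed_reports, undeformed_cut.plates):
            # allowed discrepancy: a 1-pixel band around in-plane boundaries
            # of either image (annotation and reference change together)
            edges = ndimage.morphological_gradient(plate.labels, size=3) > 0
            band = int(edges.sum())
            for key in set(rep_u.counts) | set(rep_d.counts):
                diff = abs(rep_u.counts.get(key, 0) - rep_d.counts.get(key, 0))
                assert diff <= band

    def test_sparse_sampling_recovers_within_tolerance(self):
        scenario = SyntheticScenario(
            seed=12,
            **SMALL,
            perturbation=PerturbationPlan(translation_voxels=(1, 0, 1), translated_regions=(1,)),
            plate_plan=PlatePlan(sampled_fraction=0.33),
        )
        result = run_scenario(scenario)
        for q in sorted({q for q, _ in result.query.truth_counts if q != 0}):
            if result.plates_spanned(q) < 15:
                continue
            assert max(result.recovery_errors_pp(q).values()) < 5.0
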