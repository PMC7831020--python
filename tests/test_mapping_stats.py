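import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from bmmap import (
    CohortSpec,
    ContingencyTable,
    GridSpec,
    LesionMask,
    adiffi_map,
    extract_clusters,
    fdr_adjust,
    fisher_exact_two_sided,
    frequency_map,
    relative_metastatic_risk,
    simulate_cohort,
    weighted_spec,
)
from bmmap.lesion_metrics import LesionRecord, label_components, lesion_records
from bmmap.mapping_stats import DIRECTION_NONE

from oracles import fisher_two_sided_enumeration


def _mask(coords, shape=(6, 6, 6), pid="P"):
    data = np.zeros(shape, dtype=np.uint8)
    for c in coords:
        data[c] = 1
    return LesionMask(grid=GridSpec(shape=shape), data=data, patient_id=pid)


class TestFrequencyMap:
    def test_single_mask_counts_equal_mask(self):
        m = _mask([(1, 1, 1), (2, 2, 2)])
        fmap = frequency_map([m])
        assert np.array_equal(fmap.counts, m.data)

    def test_overlapping_masks_add(self):
        m1 = _mask([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0)])
        m2 = _mask([(3, 0, 0), (4, 0, 0), (5, 0, 0), (5, 1, 0), (5, 2, 0)])
        fmap = frequency_map([m1, m2])
        assert fmap.counts.max() == 2
        assert fmap.counts.sum() == 10

    def test_identical_masks_stack_to_n(self):
        masks = [_mask([(2, 2, 2)], pid=f"P{i}") for i in range(7)]
        fmap = frequency_map(masks)
        assert fmap.counts[2, 2, 2] == 7
        assert fmap.counts.sum() == 7

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            frequency_map([])

    def test_grid_mismatch_rejected(self):
        from bmmap import GridMismatchError

        with pytest.raises(GridMismatchError):
            frequency_map([_mask([(0, 0, 0)]), _mask([(0, 0, 0)], shape=(5, 5, 5))])


class TestFisherExact:
    def test_degenerate_row_gives_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 5, 5)) == 1.0

    def test_fully_separated_three_vs_three(self):
        # 4 tables share margins (3,3|3,3); the two extremes each carry 1/20
        assert fisher_exact_two_sided(ContingencyTable(3, 0, 0, 3)) == pytest.approx(0.1)

    def test_balanced_two_by_two_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_enumeration_and_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d), abs=1e-12)
        _, p_ref = scipy_fisher([[a, b], [c, d]])
        assert p == pytest.approx(p_ref, abs=1e-9)


class TestAdiffi:
    def test_identical_groups_are_null_everywhere(self):
        masks = [_mask([(1, 1, 1), (2, 2, 2)], pid=f"P{i}") for i in range(4)]
        pmap = adiffi_map(masks, masks)
        assert np.all(pmap.p == 1.0)
        assert np.all(pmap.direction == DIRECTION_NONE)

    def test_complete_separation_three_vs_three(self):
        hit = [_mask([(2, 2, 2)], pid=f"A{i}") for i in range(3)]
        miss = [_mask([(4, 4, 4)], pid=f"B{i}") for i in range(3)]
        pmap = adiffi_map(hit, miss)
        assert pmap.p[2, 2, 2] == pytest.approx(0.1)
        assert pmap.direction[2, 2, 2] == 1
        assert pmap.direction[4, 4, 4] == -1
        # untouched voxel
        assert pmap.p[0, 0, 0] == 1.0
        assert pmap.direction[0, 0, 0] == DIRECTION_NONE

    def test_swap_symmetry(self, rng):
        ga = [
            LesionMask(grid=GridSpec(shape=(6, 6, 6)),
                       data=(rng.random((6, 6, 6)) < 0.2))
            for _ in range(5)
        ]
        gb = [
            LesionMask(grid=GridSpec(shape=(6, 6, 6)),
                       data=(rng.random((6, 6, 6)) < 0.4))
            for _ in range(7)
        ]
        p1 = adiffi_map(ga, gb)
        p2 = adiffi_map(gb, ga)
        assert np.allclose(p1.p, p2.p)
        assert np.array_equal(p1.direction, -p2.direction)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            adiffi_map([], [_mask([(0, 0, 0)])])


class TestClusters:
    @staticmethod
    def _pmap_from(p, direction):
        from bmmap.mapping_stats import PValueMap

        return PValueMap(
            grid=GridSpec(shape=p.shape), p=p, direction=direction, n_a=5, n_b=5
        )

    def test_no_significant_voxels_gives_empty_table(self):
        p = np.ones((6, 6, 6))
        cl = extract_clusters(self._pmap_from(p, np.zeros_like(p, dtype=np.int8)))
        assert len(cl) == 0

    def test_single_voxel_cluster(self):
        p = np.ones((6, 6, 6))
        d = np.zeros((6, 6, 6), dtype=np.int8)
        p[2, 2, 2] = 0.01
        d[2, 2, 2] = 1
        cl = extract_clusters(self._pmap_from(p, d), alpha=0.05, min_size=1)
        assert len(cl) == 1
        assert cl.iloc[0]["size"] == 1 and cl.iloc[0].direction == "A"

    def test_adjacent_same_direction_voxels_merge(self):
        p = np.ones((6, 6, 6))
        d = np.zeros((6, 6, 6), dtype=np.int8)
        for v in ((2, 2, 2), (2, 2, 3)):
            p[v] = 0.01
            d[v] = 1
        cl = extract_clusters(self._pmap_from(p, d))
        assert len(cl) == 1 and cl.iloc[0]["size"] == 2

    def test_opposite_directions_never_merge(self):
        p = np.ones((6, 6, 6))
        d = np.zeros((6, 6, 6), dtype=np.int8)
        p[2, 2, 2] = p[2, 2, 3] = 0.01
        d[2, 2, 2], d[2, 2, 3] = 1, -1
        cl = extract_clusters(self._pmap_from(p, d))
        assert len(cl) == 2
        assert set(cl.direction) == {"A", "B"}

    def test_min_size_filters(self):
        p = np.ones((6, 6, 6))
        d = np.zeros((6, 6, 6), dtype=np.int8)
        p[2, 2, 2] = 0.01
        d[2, 2, 2] = 1
        cl = extract_clusters(self._pmap_from(p, d), min_size=2)
        assert len(cl) == 0

    def test_monotone_thresholding(self, rng):
        p = rng.random((8, 8, 8))
        d = np.where(rng.random((8, 8, 8)) < 0.5, 1, -1).astype(np.int8)
        pmap = self._pmap_from(p, d)
        strict = extract_clusters(pmap, alpha=0.01)
        loose = extract_clusters(pmap, alpha=0.10)
        # every voxel significant at the stricter level is significant at the looser
        assert int(strict["size"].sum()) <= int(loose["size"].sum())

    def test_invalid_alpha_rejected(self):
        p = np.ones((4, 4, 4))
        with pytest.raises(ValueError):
            extract_clusters(self._pmap_from(p, np.zeros_like(p, dtype=np.int8)),
                             alpha=1.5)


class TestRelativeMetastaticRisk:
    @staticmethod
    def _two_region_atlas(v1, v2):
        from bmmap import Region, RegionAtlas

        labels = np.zeros((10, 10, 10), int)
        labels.ravel()[:v1] = 1
        labels.ravel()[v1 : v1 + v2] = 2
        return RegionAtlas(
            grid=GridSpec(shape=(10, 10, 10), voxel_volume=1.0),
            labels=labels,
            regions=(
                Region(1, "r1", "left", "supratentorial"),
                Region(2, "r2", "right", "supratentorial"),
            ),
        )

    @staticmethod
    def _patients_hitting(region_counts):
        records = {}
        pid = 0
        for rid, n in region_counts.items():
            for _ in range(n):
                records[f"P{pid}"] = [
                    LesionRecord(f"P{pid}", 1, 1, 1.0, (0, 0, 0), rid, "left",
                                 "supratentorial")
                ]
                pid += 1
        return records

    def test_two_region_hand_example(self):
        # N = (10, 10), V = (1, 4), N_p = 100 -> RMR = (1.6, 0.4)
        atlas = self._two_region_atlas(1, 4)
        table = relative_metastatic_risk(
            self._patients_hitting({1: 10, 2: 10}), atlas, n_patients=100
        )
        by_region = table.set_index("region_id")
        assert by_region.loc[1, "per_volume_risk"] == pytest.approx(0.1)
        assert by_region.loc[2, "per_volume_risk"] == pytest.approx(0.025)
        assert by_region.loc[1, "rmr"] == pytest.approx(1.6)
        assert by_region.loc[2, "rmr"] == pytest.approx(0.4)

    def test_uniform_per_volume_risk_is_flat(self):
        atlas = self._two_region_atlas(2, 4)
        table = relative_metastatic_risk(
            self._patients_hitting({1: 5, 2: 10}), atlas, n_patients=50
        )
        assert np.allclose(table["rmr"], 1.0)

    def test_untouched_region_has_zero_rmr(self):
        atlas = self._two_region_atlas(2, 4)
        table = relative_metastatic_risk(
            self._patients_hitting({1: 5}), atlas, n_patients=50
        )
        assert table.set_index("region_id").loc[2, "rmr"] == 0.0

    def test_patient_counted_once_per_region(self):
        atlas = self._two_region_atlas(2, 4)
        records = {
            "P0": [
                LesionRecord("P0", 1, 1, 1.0, (0, 0, 0), 1, "left", "supratentorial"),
                LesionRecord("P0", 2, 1, 1.0, (0, 0, 1), 1, "left", "supratentorial"),
            ]
        }
        table = relative_metastatic_risk(records, atlas, n_patients=10)
        assert table.set_index("region_id").loc[1, "n_patients_with_bm"] == 1

    def test_mean_rmr_is_one_on_random_cohorts(self, small_atlas):
        for seed in range(5):
            spec = CohortSpec(n_patients=25, seed=seed)
            _, masks = simulate_cohort(spec, small_atlas)
            by_patient = {
                m.patient_id: lesion_records(label_components(m), small_atlas,
                                             patient_id=m.patient_id)
                for m in masks
            }
            table = relative_metastatic_risk(by_patient, small_atlas,
                                             n_patients=len(masks))
            assert table["rmr"].mean() == pytest.approx(1.0, abs=1e-9)


class TestPlantedEffect:
    def test_adiffi_recovers_infratentorial_enrichment(self, toy_atlas):
        # group A places lesions in infratentorial regions with 4x weight
        spec_a = weighted_spec(CohortSpec(n_patients=100, seed=11), toy_atlas,
                               infratentorial_factor=4.0)
        spec_b = weighted_spec(CohortSpec(n_patients=100, seed=12), toy_atlas,
                               infratentorial_factor=1.0)
        _, masks_a = simulate_cohort(spec_a, toy_atlas)
        _, masks_b = simulate_cohort(spec_b, toy_atlas)
        pmap = adiffi_map(masks_a, masks_b)
        clusters = extract_clusters(pmap, alpha=0.05, min_size=1, atlas=toy_atlas)
        a_clusters = clusters[clusters.direction == "A"]
        assert len(a_clusters) > 0
        largest = a_clusters.sort_values("size", ascending=False).iloc[0]
        assert largest.infratentorial_fraction > 0.5


def test_fdr_adjustment_only_raises_pvalues(rng):
    ga = [
        LesionMask(grid=GridSpec(shape=(6, 6, 6)), data=(rng.random((6, 6, 6)) < 0.3))
        for _ in range(6)
    ]
    gb = [
        LesionMask(grid=GridSpec(shape=(6, 6, 6)), data=(rng.random((6, 6, 6)) < 0.1))
        for _ in range(6)
    ]
    pmap = adiffi_map(ga, gb)
    adjusted = fdr_adjust(pmap)
    tested = pmap.direction != DIRECTION_NONE
    assert np.all(adjusted.p[tested] >= pmap.p[tested] - 1e-12)
    assert np.array_equal(adjusted.direction, pmap.direction)
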