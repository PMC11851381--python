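"""Shape voxelization, region atlas, defect injection, dataset composition."""

import numpy as np
import pytest

from craniorec.defects import (
    REGIONS,
    SHAPES,
    DefectSpec,
    RegionAtlas,
    build_dataset,
    enumerate_cases,
    inject_defect,
    make_shape_mask,
    realize_case,
    sample_defect_center,
)
from craniorec.errors import InputError
from craniorec.volio import BinaryVolume


class TestShapeLatticeCounts:
    """Frozen lattice-point counts for unit-spacing reference shapes."""

    @pytest.mark.parametrize(
        "spec, expected",
        [
            (DefectSpec("sphere", radius_mm=2, center=(5, 5, 5)), 33),
            (DefectSpec("cube", edges_mm=(3, 3, 3), center=(5, 5, 5)), 27),
            (DefectSpec("cylinder", radius_mm=1, height_mm=3, center=(5, 5, 5)), 15),
            (
                DefectSpec(
                    "triangular_prism", base_mm=4, tri_height_mm=4,
                    extrusion_mm=2, center=(5, 5, 5), axis=(0, 0, 1),
                ),
                30,
            ),
        ],
        ids=["sphere_r2", "cube_3", "cylinder_r1h3", "prism_4x4x2"],
    )
    def test_counts(self, unit_grid, spec, expected):
        assert make_shape_mask(spec, unit_grid).count() == expected

    def test_sphere_membership_oracle(self, unit_grid):
        """Voxel membership equals the analytic x^2+y^2+z^2 <= r^2 rule."""
        spec = DefectSpec("sphere", radius_mm=3.2, center=(5, 5, 5))
        mask = make_shape_mask(spec, unit_grid)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = tuple(rng.integers(0, 11, size=3))
            inside = sum((c - 5) ** 2 for c in p) <= 3.2**2
            assert bool(mask.voxels[p]) == inside

    def test_cube_membership_oracle(self, unit_grid):
        spec = DefectSpec("cube", edges_mm=(5, 3, 7), center=(5, 5, 5))
        mask = make_shape_mask(spec, unit_grid)
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.integers(0, 11, size=3)
            d = np.abs(p - 5)
            inside = d[0] <= 2.5 and d[1] <= 1.5 and d[2] <= 3.5
            assert bool(mask.voxels[tuple(p)]) == inside

    def test_spacing_scales_shapes(self):
        like = BinaryVolume(np.zeros((11, 11, 11), dtype=np.uint8),
                            spacing=(2, 2, 2))
        spec = DefectSpec("sphere", radius_mm=4, center=(5, 5, 5))
        # radius 4 mm at 2 mm spacing = radius 2 voxels -> same 33 lattice points
        assert make_shape_mask(spec, like).count() == 33

    def test_center_outside_grid_rejected(self, unit_grid):
        with pytest.raises(InputError):
            make_shape_mask(DefectSpec("sphere", radius_mm=1, center=(20, 5, 5)),
                            unit_grid)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(InputError):
            DefectSpec("sphere", radius_mm=0.0)


class TestRegionSampling:
    def test_determinism(self, phantom64):
        a = sample_defect_center(phantom64, "top", seed=5)
        b = sample_defect_center(phantom64, "top", seed=5)
        assert a == b

    def test_top_centers_above_elevation_floor(self, phantom64):
        atlas = RegionAtlas()
        sp = np.asarray(phantom64.spacing)
        centroid = (np.argwhere(phantom64.voxels > 0) * sp).mean(axis=0)
        for seed in range(20):
            c = np.asarray(sample_defect_center(phantom64, "top", atlas, seed)) * sp
            d = c - centroid
            elev = np.degrees(np.arctan2(d[2], np.hypot(d[0], d[1])))
            assert elev > atlas.top_elevation_deg

    def test_left_centers_on_positive_x_side(self, phantom64):
        sp = np.asarray(phantom64.spacing)
        centroid = (np.argwhere(phantom64.voxels > 0) * sp).mean(axis=0)
        for seed in range(200):
            c = sample_defect_center(phantom64, "left", seed=seed)
            assert c[0] * sp[0] > centroid[0]

    def test_centers_are_shell_voxels(self, phantom64):
        for region in REGIONS:
            c = sample_defect_center(phantom64, region, seed=1)
            assert phantom64.voxels[c] == 1

    def test_unknown_region_rejected(self, phantom64):
        with pytest.raises(InputError):
            sample_defect_center(phantom64, "bottom")

    def test_atlas_classify_partitions_upper_shell(self, phantom64):
        """Every outer-surface voxel above the floor gets exactly one label."""
        atlas = RegionAtlas()
        sp = np.asarray(phantom64.spacing)
        centroid = (np.argwhere(phantom64.voxels > 0) * sp).mean(axis=0)
        from craniorec.defects import _surface_voxels

        labels = set()
        for v in np.argwhere(_surface_voxels(phantom64.voxels)):
            lab = atlas.classify(v * sp - centroid)
            assert lab in REGIONS or lab is None
            labels.add(lab)
        assert set(REGIONS) <= labels


class TestInjectDefect:
    def test_voxel_count_conservation(self, phantom64):
        spec = DefectSpec("sphere", region="top", radius_mm=10,
                          center=sample_defect_center(phantom64, "top", seed=2))
        pair = inject_defect(phantom64, spec)
        assert pair.defected.count() + pair.implant_gt.count() == phantom64.count()
        assert not (pair.defected.voxels & pair.implant_gt.voxels).any()
        union = pair.defected.voxels | pair.implant_gt.voxels
        assert np.array_equal(union, phantom64.voxels)

    def test_disjoint_mask_flags_pair(self, phantom64):
        # tiny sphere at the grid corner: far from the shell
        spec = DefectSpec("sphere", radius_mm=2.0, center=(1, 1, 1))
        with pytest.warns(UserWarning, match="overlap"):
            pair = inject_defect(phantom64, spec)
        assert not pair.usable
        assert pair.implant_gt.count() == 0
        assert np.array_equal(pair.defected.voxels, phantom64.voxels)

    def test_total_removal(self, phantom64):
        spec = DefectSpec("sphere", radius_mm=1000.0, center=(32, 32, 16))
        pair = inject_defect(phantom64, spec)
        assert pair.defected.count() == 0
        assert np.array_equal(pair.implant_gt.voxels, phantom64.voxels)

    @pytest.mark.parametrize("shape", SHAPES)
    def test_realize_case_all_shapes_usable(self, phantom64, shape):
        pair = realize_case(phantom64, "top", shape, seed=17)
        assert pair.usable
        assert pair.implant_gt.count() > 0


class TestEnumerateCases:
    def test_full_plan_is_20(self):
        assert len(enumerate_cases()) == 20

    def test_stable_order_regions_then_shapes(self):
        cases = enumerate_cases(regions=("a", "b"), shapes=("s1", "s2"))
        assert cases == [("a", "s1"), ("a", "s2"), ("b", "s1"), ("b", "s2")]

    def test_empty_shapes(self):
        assert enumerate_cases(shapes=()) == []


class TestBuildDataset:
    def _cohort(self, n, tag):
        return {f"{tag}{i:03d}": None for i in range(n)}

    def test_full_plan_counts(self):
        manifest = build_dataset(self._cohort(360, "tr"), self._cohort(36, "te"))
        assert manifest.n_train == 1440  # 72 x 4 x 5
        assert manifest.n_test == 720  # 36 x 4 x 5
        assert len(manifest) == 2160

    def test_small_plan_counts(self):
        manifest = build_dataset(
            self._cohort(5, "tr"), self._cohort(2, "te"),
            shapes=("sphere", "cube"),
        )
        # 1 skull/region x 2 shapes x 5 regions
        assert manifest.n_train == 10
        assert manifest.n_test == 2 * 2 * 5

    def test_indivisible_cohort_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            manifest = build_dataset(self._cohort(7, "tr"), self._cohort(1, "te"))
        assert manifest.n_train == 5 * 4 // 5 * 5  # 5 skulls x 4 shapes

    def test_each_train_skull_single_region_all_shapes(self):
        manifest = build_dataset(self._cohort(10, "tr"), self._cohort(1, "te"))
        train = manifest.rows[manifest.rows["split"] == "train"]
        per_skull = train.groupby("skull_id")
        for _, grp in per_skull:
            assert grp["region"].nunique() == 1
            assert sorted(grp["shape"]) == sorted(SHAPES)

    def test_test_skulls_get_all_20_cases(self):
        manifest = build_dataset(self._cohort(5, "tr"), self._cohort(2, "te"))
        test = manifest.rows[manifest.rows["split"] == "test"]
        for _, grp in test.groupby("skull_id"):
            assert len(grp) == 20

    def test_case_seeds_reproducible_and_distinct(self):
        m1 = build_dataset(self._cohort(5, "tr"), self._cohort(1, "te"), seed=9)
        m2 = build_dataset(self._cohort(5, "tr"), self._cohort(1, "te"), seed=9)
        assert m1.rows["case_seed"].tolist() == m2.rows["case_seed"].tolist()
        assert m1.rows["case_seed"].nunique() == len(m1.rows)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            build_dataset({}, self._cohort(1, "te"))
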