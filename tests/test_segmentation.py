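import numpy as np
import pytest

from hsiderm.hsio import BinaryMask, CubeState, HSCube
from hsiderm.labeling import sam_angle
from hsiderm.library import ReferenceLibrary
from hsiderm.metrics import confusion, jaccard
from hsiderm.segmentation import (
    AssignMethod,
    ClusterMap,
    SegmentationConfig,
    TwoClassMap,
    assign_per_centroid,
    assign_per_pixel,
    kmeans_cluster,
    postprocess_map,
    segment_psl,
)

WL = np.linspace(450, 950, 10)
SKIN_SPEC = np.linspace(0.2, 0.9, 10)
LESION_SPEC = np.linspace(0.9, 0.2, 10)


def _library():
    return ReferenceLibrary(
        entries=[
            ("skin_1", "skin", SKIN_SPEC),
            ("skin_2", "skin", SKIN_SPEC * 0.8 + 0.05),
            ("benign", "benign", LESION_SPEC),
            ("malignant", "malignant", LESION_SPEC * 0.9 + 0.02),
        ],
        wavelengths_nm=WL,
    )


def _two_region_cube():
    values = np.empty((8, 8, 10))
    values[:] = SKIN_SPEC
    values[2:6, 2:6] = LESION_SPEC
    return HSCube(values, WL, CubeState.PREPROCESSED)


class TestKmeansCluster:
    def test_k1_centroid_is_global_mean(self, rng):
        cube = HSCube(rng.random((5, 5, 10)), WL, CubeState.PREPROCESSED)
        cm = kmeans_cluster(cube, K=1, seed=0)
        np.testing.assert_allclose(cm.centroids[0], cube.pixels().mean(axis=0), rtol=1e-6)

    def test_two_regions_recovered_exactly(self):
        cm = kmeans_cluster(_two_region_cube(), K=2, seed=0)
        region = np.zeros((8, 8), dtype=bool)
        region[2:6, 2:6] = True
        # cluster indices are arbitrary; the partition must match
        assert (
            np.array_equal(cm.assignments == 0, region)
            or np.array_equal(cm.assignments == 1, region)
        )

    def test_deterministic_given_seed(self, rng):
        cube = HSCube(rng.random((6, 6, 10)), WL, CubeState.PREPROCESSED)
        a = kmeans_cluster(cube, K=3, seed=7)
        b = kmeans_cluster(cube, K=3, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_centroids_sorted_by_mean_reflectance(self, rng):
        cube = HSCube(rng.random((6, 6, 10)), WL, CubeState.PREPROCESSED)
        cm = kmeans_cluster(cube, K=4, seed=1)
        means = cm.centroids.mean(axis=1)
        assert np.all(np.diff(means) >= 0)

    def test_k_exceeding_pixels_rejected(self, rng):
        cube = HSCube(rng.random((2, 2, 10)), WL, CubeState.PREPROCESSED)
        with pytest.raises(ValueError):
            kmeans_cluster(cube, K=5, seed=0)


def _manual_clusters(assignments, centroids):
    return ClusterMap(
        assignments=np.asarray(assignments),
        centroids=np.asarray(centroids, dtype=float),
        K=len(centroids),
        seed=0,
    )


class TestAssignPerCentroid:
    def test_centroid_equal_to_skin_entry_is_skin(self):
        cm = _manual_clusters(np.zeros((2, 2), int), [SKIN_SPEC])
        out = assign_per_centroid(cm, _library())
        assert not out.values.any()

    def test_centroid_equal_to_benign_entry_is_psl(self):
        cm = _manual_clusters(np.zeros((2, 2), int), [LESION_SPEC])
        assert assign_per_centroid(cm, _library()).values.all()

    def test_nearest_entry_wins_by_sam(self):
        lib = _library()
        # build a centroid closer (in angle) to malignant than to any skin entry
        centroid = lib.spectra[3] + 0.02
        angles = [sam_angle(centroid, s) for s in lib.spectra]
        assert np.argmin(angles) == 3
        cm = _manual_clusters(np.zeros((1, 1), int), [centroid])
        assert assign_per_centroid(cm, lib).values.all()

    def test_empty_library_rejected(self):
        cm = _manual_clusters(np.zeros((1, 1), int), [SKIN_SPEC])
        with pytest.raises(ValueError):
            assign_per_centroid(cm, ReferenceLibrary(entries=[], wavelengths_nm=WL))


class TestAssignPerPixel:
    def test_pixels_equal_to_skin_entry_give_skin(self):
        cube = HSCube(np.tile(SKIN_SPEC, (3, 3, 1)), WL, CubeState.PREPROCESSED)
        cm = _manual_clusters(np.zeros((3, 3), int), [SKIN_SPEC])
        assert not assign_per_pixel(cube, cm, _library()).values.any()

    def test_equals_per_centroid_on_pure_clusters(self):
        cube = _two_region_cube()
        cm = kmeans_cluster(cube, K=2, seed=0)
        # every pixel equals its centroid by construction of the cube
        per_pix = assign_per_pixel(cube, cm, _library())
        per_cen = assign_per_centroid(cm, _library())
        np.testing.assert_array_equal(per_pix.values, per_cen.values)

    def test_hand_computed_sam_sums_decide(self):
        lib = _library()
        pix = np.vstack([LESION_SPEC * 1.1, LESION_SPEC * 0.95, LESION_SPEC + 0.05])
        sums = [sum(sam_angle(p, entry) for p in pix) for entry in lib.spectra]
        assert np.argmin(sums) >= 2  # a lesion entry wins
        cube = HSCube(pix.reshape(1, 3, 10), WL, CubeState.PREPROCESSED)
        cm = _manual_clusters(np.zeros((1, 3), int), [pix.mean(axis=0)])
        assert assign_per_pixel(cube, cm, lib).values.all()

    def test_empty_cluster_skipped(self):
        cube = HSCube(np.tile(SKIN_SPEC, (2, 2, 1)), WL, CubeState.PREPROCESSED)
        cm = _manual_clusters(np.zeros((2, 2), int), [SKIN_SPEC, LESION_SPEC])
        out = assign_per_pixel(cube, cm, _library())  # cluster 1 has no pixels
        assert not out.values.any()


class TestPostprocess:
    def _map(self, values):
        return TwoClassMap(values=np.asarray(values, bool), method=AssignMethod.PER_PIXEL)

    def test_all_skin_unchanged(self):
        out = postprocess_map(self._map(np.zeros((7, 7))), SegmentationConfig())
        assert not out.values.any()
        assert out.postprocessed

    def test_interior_hole_filled_by_closing(self):
        grid = np.zeros((9, 9), bool)
        grid[2:7, 2:7] = True
        grid[4, 4] = False
        out = postprocess_map(self._map(grid), SegmentationConfig())
        assert out.values[4, 4]

    def test_isolated_pixel_removed(self):
        grid = np.zeros((7, 7), bool)
        grid[3, 3] = True
        out = postprocess_map(self._map(grid), SegmentationConfig(min_component_px=4))
        assert not out.values.any()

    def test_composite_idempotent_on_random_maps(self, rng):
        cfg = SegmentationConfig()
        for _ in range(10):
            grid = rng.random((20, 20)) > 0.6
            once = postprocess_map(self._map(grid), cfg)
            twice = postprocess_map(self._map(once.values), cfg)
            np.testing.assert_array_equal(twice.values, once.values)

    def test_double_postprocess_flag_rejected(self):
        out = postprocess_map(self._map(np.zeros((5, 5))), SegmentationConfig())
        with pytest.raises(ValueError):
            postprocess_map(out, SegmentationConfig())


class TestSegmentPsl:
    def test_synthetic_lesion_scene_high_jaccard(self, cohort, reference_library):
        from hsiderm.preprocess import preprocess_chain

        scenes, _ = cohort
        scene = scenes[0]
        pre = preprocess_chain(scene.raw, scene.refs)
        out = segment_psl(pre, reference_library)
        j = jaccard(confusion(BinaryMask(out.values), scene.ground_truth))
        assert j >= 0.9

    def test_pure_skin_cube_yields_zero_psl(self, reference_library):
        from hsiderm.preprocess import preprocess_chain
        from hsiderm.synthetic import SceneConfig, make_scene

        scene = make_scene(SceneConfig(lesion_class="none", skin_type=1, seed=21))
        pre = preprocess_chain(scene.raw, scene.refs)
        assert segment_psl(pre, reference_library).n_psl == 0

    def test_deterministic_given_seed(self, cohort, reference_library):
        from hsiderm.preprocess import preprocess_chain

        scenes, _ = cohort
        pre = preprocess_chain(scenes[1].raw, scenes[1].refs)
        cfg = SegmentationConfig(seed=3)
        a = segment_psl(pre, reference_library, cfg)
        b = segment_psl(pre, reference_library, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_requires_preprocessed_cube(self, rng, reference_library):
        cube = HSCube(rng.random((5, 5, 116)), np.linspace(450, 950, 116), CubeState.RAW)
        with pytest.raises(ValueError):
            segment_psl(cube, reference_library)
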