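"""AFM morphometrics: smoothing, segmentation, skeleton lengths, volumes,
mixture decomposition, clusters and binding density."""
import numpy as np
import pandas as pd
import pytest

from nanoquant import afm
from nanoquant.datatypes import AFMImage, DNAMask, GrainTable
from nanoquant.simulate import AFMConfig, sample_volume_mixture, simulate_afm_image

PX = 2.0  # nm/pixel used throughout


def _mask_from(arr):
    return DNAMask(mask=np.asarray(arr, dtype=bool), z_low_nm=0.1, z_high_nm=2.0)


class TestPreprocess:
    def test_constant_image_is_fixed_point(self):
        img = AFMImage(np.full((64, 64), 0.7), PX)
        out, _ = afm.preprocess_height_map(img)
        assert np.allclose(out.heights, 0.7)

    def test_impulse_response_matches_kernel_oracle(self):
        """One pass on a unit impulse reproduces the truncated separable kernel."""
        h = np.zeros((33, 33))
        h[16, 16] = 1.0
        img = AFMImage(h, PX)
        out, used = afm.preprocess_height_map(img, min_iter=1, max_iter=1)
        sigma_px = 2.0 / PX
        radius_px = int(round((5.0 / 2.0) / PX))
        k = afm.gaussian_kernel_1d(sigma_px, radius_px)
        expected = np.outer(k, k)
        got = out.heights[16 - radius_px : 16 + radius_px + 1, 16 - radius_px : 16 + radius_px + 1]
        assert used == 1
        assert np.allclose(got, expected, atol=1e-12)
        assert out.heights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_clean_image_stops_at_min_iterations(self):
        img, _ = simulate_afm_image(
            AFMConfig(seed=0, straight=True, dna_contour_nm=400, shape=(300, 300), roughness_nm=0.0)
        )
        _, used = afm.preprocess_height_map(img)
        assert used == 3

    def test_subpixel_window_rejected(self):
        img = AFMImage(np.zeros((8, 8)), pixel_size_nm=10.0)
        with pytest.raises(ValueError):
            afm.preprocess_height_map(img, window_nm=5.0)


class TestSegmentation:
    def test_clean_rod_all_dna_no_grains(self):
        img, _ = simulate_afm_image(
            AFMConfig(seed=0, straight=True, dna_contour_nm=400, shape=(300, 300), roughness_nm=0.0)
        )
        mask, grains = afm.segment_dna_and_proteins(img)
        assert mask.mask.sum() > 100
        assert len(grains) == 0
        heights = img.heights[mask.mask]
        assert np.all((heights > 0.1) & (heights < 2.0))

    def test_rod_plus_blob_splits_into_mask_and_grain(self):
        img, man = simulate_afm_image(
            AFMConfig(
                seed=1, straight=True, dna_contour_nm=400, shape=(300, 300),
                n_bound_dimers=1, roughness_nm=0.0,
            )
        )
        mask, grains = afm.segment_dna_and_proteins(img)
        assert len(grains) == 1
        blob = next(o for o in man.truth["objects"] if o["class"] == "bound_dimer")
        r, c = int(blob["y_nm"] / PX), int(blob["x_nm"] / PX)
        assert grains.labels[r, c] > 0
        assert not mask.mask[r, c]

    def test_empty_image_empty_outputs(self):
        mask, grains = afm.segment_dna_and_proteins(AFMImage(np.zeros((32, 32)), PX))
        assert not mask.mask.any()
        assert len(grains) == 0

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            afm.segment_dna_and_proteins(AFMImage(np.zeros((8, 8)), PX), z_low_nm=2.0, z_high_nm=0.1)


class TestSkeletonLength:
    def test_horizontal_rod_hand_count(self):
        """101 collinear pixels = 100 axial steps = 200 nm at 2 nm/px."""
        m = np.zeros((20, 120), bool)
        m[10, 5:106] = True
        sk = afm.skeleton_dna_length(_mask_from(m), PX)
        assert sk.total_length_nm == pytest.approx(200.0)
        assert len(sk.path_lengths_nm) == 1

    def test_diagonal_rod_step_count(self):
        """101 diagonal pixels = 100 sqrt(2) steps."""
        m = np.zeros((120, 120), bool)
        idx = np.arange(5, 106)
        m[idx, idx] = True
        sk = afm.skeleton_dna_length(_mask_from(m), PX)
        assert sk.total_length_nm == pytest.approx(100 * 2 * np.sqrt(2.0), rel=1e-9)

    def test_empty_mask_zero_length(self):
        sk = afm.skeleton_dna_length(_mask_from(np.zeros((16, 16))), PX)
        assert sk.total_length_nm == 0.0

    def test_rotation_changes_quasi_euclidean_length_under_3_percent(self):
        straight = np.zeros((120, 120), bool)
        straight[60, 10:111] = True
        diag = np.zeros((120, 120), bool)
        idx = np.arange(10, 111)
        diag[idx, idx] = True
        l_axial = afm.skeleton_dna_length(_mask_from(straight), PX).total_length_nm
        l_diag = afm.skeleton_dna_length(_mask_from(diag), PX).total_length_nm
        # same pixel count; diagonal true length is sqrt(2) longer, and the
        # quasi-Euclidean metric measures exactly that
        assert l_diag / l_axial == pytest.approx(np.sqrt(2.0), rel=0.03)

    def test_rendered_rod_end_to_end_within_two_percent(self):
        img, man = simulate_afm_image(
            AFMConfig(seed=0, straight=True, dna_contour_nm=600, shape=(400, 400), roughness_nm=0.0)
        )
        sm, _ = afm.preprocess_height_map(img)
        mask, _ = afm.segment_dna_and_proteins(sm)
        sk = afm.skeleton_dna_length(mask, img.pixel_size_nm)
        assert sk.total_length_nm == pytest.approx(600.0, rel=0.02)


class TestGrainVolumes:
    def test_single_pixel_arithmetic(self):
        heights = np.zeros((8, 8))
        heights[4, 4] = 2.0
        labels = np.zeros((8, 8), int)
        labels[4, 4] = 1
        table = pd.DataFrame([{c: 0 for c in GrainTable.COLUMNS} | {"grain_id": 1}])
        gt = GrainTable(table=table, labels=labels)
        out = afm.measure_grain_volumes(AFMImage(heights, PX), gt, dilation_nm=0.0)
        assert out.table["volume_nm3"].iloc[0] == pytest.approx(8.0)

    def test_rendered_blob_within_two_percent_of_analytic(self):
        img, man = simulate_afm_image(
            AFMConfig(seed=2, dna_contour_nm=0, n_dna=0, n_dimers=1, roughness_nm=0.0, shape=(200, 200))
        )
        _, grains = afm.segment_dna_and_proteins(img)
        out = afm.measure_grain_volumes(img, grains)
        truth = man.truth["objects"][0]["volume_nm3"]
        assert out.table["volume_nm3"].iloc[0] == pytest.approx(truth, rel=0.02)

    def test_volume_invariant_under_translation_and_rotation(self):
        img, _ = simulate_afm_image(
            AFMConfig(seed=3, dna_contour_nm=0, n_dna=0, n_dimers=1, roughness_nm=0.0, shape=(200, 200))
        )

        def measure(heights):
            im = AFMImage(heights, PX)
            _, grains = afm.segment_dna_and_proteins(im)
            return afm.measure_grain_volumes(im, grains).table["volume_nm3"].iloc[0]

        v0 = measure(img.heights)
        assert measure(np.rot90(img.heights)) == pytest.approx(v0, rel=1e-9)
        assert measure(np.roll(img.heights, (13, -7), axis=(0, 1))) == pytest.approx(v0, rel=1e-9)

    def test_empty_grain_set_unchanged(self):
        gt = GrainTable.empty((8, 8))
        out = afm.measure_grain_volumes(AFMImage(np.zeros((8, 8)), PX), gt)
        assert len(out) == 0


class TestVolumeMixture:
    def test_seventy_thirty_recovery_within_five_points(self):
        vols, man = sample_volume_mixture(1000, 0.7, seed=0)
        fit = afm.fit_volume_mixture(vols)
        assert fit.weights[1] == pytest.approx(man.truth["dimer_fraction"], abs=0.05)

    def test_recovery_stable_across_seeds(self):
        devs = []
        for seed in range(10):
            vols, man = sample_volume_mixture(1000, 0.7, seed=seed)
            fit = afm.fit_volume_mixture(vols)
            devs.append(abs(fit.weights[1] - man.truth["dimer_fraction"]))
        assert max(devs) < 0.05

    def test_well_separated_means_within_three_percent(self):
        vols, _ = sample_volume_mixture(1000, 0.5, seed=1)
        fit = afm.fit_volume_mixture(vols)
        assert fit.means[0] == pytest.approx(250.0, rel=0.03)
        assert fit.means[1] == pytest.approx(500.0, rel=0.03)

    def test_identical_volumes_warn_unimodal(self):
        fit = afm.fit_volume_mixture(np.full(100, 400.0))
        assert fit.unimodal_warning

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            afm.fit_volume_mixture(np.arange(10.0))


class TestClusterDetection:
    def test_seven_sigma_false_positive_rate(self, rng):
        """Monte Carlo n=1e6: single-dimer volumes essentially never exceed
        the 7-sigma threshold (>99.9% confidence)."""
        vols = rng.normal(500.0, 75.0, 1_000_000)
        threshold = 500.0 + 7.0 * 75.0
        assert (vols > threshold).mean() < 0.001

    def test_cluster_count_arithmetic(self):
        labels = np.zeros((4, 4), int)
        table = pd.DataFrame(
            [{c: 0 for c in GrainTable.COLUMNS} | {"grain_id": 1, "volume_nm3": 5000.0}]
        )
        rep = afm.detect_clusters_and_count(GrainTable(table, labels), 500.0, 50.0)
        assert rep.protein_counts[0] == pytest.approx(10.0)
        assert rep.protein_counts_rounded[0] == 10

    def test_all_grains_below_threshold(self):
        labels = np.zeros((4, 4), int)
        table = pd.DataFrame(
            [{c: 0 for c in GrainTable.COLUMNS} | {"grain_id": i, "volume_nm3": v}
             for i, v in enumerate([480.0, 520.0], start=1)]
        )
        rep = afm.detect_clusters_and_count(GrainTable(table, labels), 500.0, 50.0, monomer_mean_nm3=250.0)
        assert len(rep.cluster_ids) == 0
        assert set(table["class"]) <= {"monomer", "dimer", "cluster", "unassigned"}


class TestBoundBlobs:
    @pytest.fixture(scope="class")
    @staticmethod
    def decorated():
        cfg = AFMConfig(
            seed=7, dna_contour_nm=1500, shape=(500, 500), n_bound_dimers=5,
            cluster_volumes_nm3=(5000.0,), roughness_nm=0.05,
        )
        return simulate_afm_image(cfg)

    def test_five_on_dna_dimers_found(self, decorated):
        img, _ = decorated
        sm, _ = afm.preprocess_height_map(img)
        mask, _ = afm.segment_dna_and_proteins(sm)
        blobs = afm.detect_bound_blobs(img, mask)
        assert len(blobs) == 5

    def test_off_dna_blob_excluded(self):
        img, _ = simulate_afm_image(
            AFMConfig(seed=8, straight=True, dna_contour_nm=400, shape=(300, 300),
                      n_dimers=1, roughness_nm=0.0)
        )
        mask, _ = afm.segment_dna_and_proteins(img)
        blobs = afm.detect_bound_blobs(img, mask)
        assert len(blobs) == 0

    def test_small_blob_excluded_by_size(self):
        heights = np.zeros((100, 100))
        yy, xx = np.mgrid[:100, :100]
        heights += 3.0 * np.exp(-((yy - 50.0) ** 2 + (xx - 50.0) ** 2) / (2 * 1.0**2))
        heights[48:53, :] = np.maximum(heights[48:53, :], 1.0)  # DNA through the blob
        mask = _mask_from((heights > 0.1) & (heights < 2.0))
        blobs = afm.detect_bound_blobs(AFMImage(heights, PX), mask)
        assert len(blobs) == 0  # footprint ~4-6 nm across


class TestBindingDensity:
    def _blob_table(self, n):
        table = pd.DataFrame(
            [{c: 0 for c in GrainTable.COLUMNS} | {"grain_id": i} for i in range(1, n + 1)]
        )
        return GrainTable(table, np.zeros((4, 4), int))

    def _skeletons(self, length_nm):
        from nanoquant.datatypes import SkeletonSet

        return SkeletonSet(
            skeleton=np.zeros((4, 4), bool), path_labels=np.zeros((4, 4), int),
            path_lengths_nm=np.array([length_nm]), pixel_size_nm=PX,
        )

    def test_blob_only_arithmetic(self):
        d = afm.binding_density(self._blob_table(5), None, self._skeletons(1000.0))
        assert d["per_100nm"] == pytest.approx(0.5)
        assert d["per_kbp"] == pytest.approx(0.5 * 3.4)

    def test_cluster_counts_included(self):
        from nanoquant.datatypes import ClusterReport

        rep = ClusterReport(
            cluster_threshold_nm3=1000.0, cluster_ids=np.array([1]),
            cluster_volumes_nm3=np.array([5000.0]), protein_counts=np.array([10.0]),
            protein_counts_rounded=np.array([10]),
        )
        d = afm.binding_density(self._blob_table(0), rep, self._skeletons(1000.0))
        assert d["per_100nm"] == pytest.approx(1.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            afm.binding_density(self._blob_table(1), None, self._skeletons(0.0))

    def test_generator_field_recovered_within_ten_percent(self):
        img, man = simulate_afm_image(
            AFMConfig(seed=13, dna_contour_nm=1500, shape=(500, 500),
                      n_bound_dimers=5, cluster_volumes_nm3=(5000.0,), roughness_nm=0.05)
        )
        sm, _ = afm.preprocess_height_map(img)
        mask, _ = afm.segment_dna_and_proteins(sm)
        sk = afm.skeleton_dna_length(mask, img.pixel_size_nm)
        blobs = afm.detect_bound_blobs(img, mask)
        grains = afm.measure_grain_volumes(img, afm.segment_dna_and_proteins(img)[1])
        rep = afm.detect_clusters_and_count(grains, 500.0, 75.0)
        d = afm.binding_density(blobs, rep, sk)
        truth = (5 + 10) / sk.total_length_nm * 100.0  # 5 dimers + 10-dimer cluster
        assert d["per_100nm"] == pytest.approx(truth, rel=0.10)
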