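"""Depth binning, laminar/differential profiles, clusters, ANOVA, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminarpy.synthetic_cortex import LABEL_GM, LABEL_WM
from laminarpy.bold_simulator import (BlockDesign, NeuralDepthProfile,
                                      simulate_session)
from laminarpy import depth_mapping as dm
from laminarpy import laminar_analysis as la
from laminarpy.glm_stats import PermutationSpec


class TestBinByDepth:
    def test_even_split(self):
        rng = np.random.default_rng(0)
        a = la.bin_by_depth(rng.uniform(0, 1, 100), 5)
        assert np.bincount(a).tolist() == [20, 20, 20, 20, 20]

    def test_remainder_goes_to_deeper_bins(self):
        a = la.bin_by_depth(np.linspace(0, 1, 7), 5)
        assert np.bincount(a).tolist() == [2, 2, 1, 1, 1]

    def test_bins_ordered_by_depth(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 1, 83)
        a = la.bin_by_depth(d, 5)
        for b in range(4):
            assert d[a == b].max() <= d[a == b + 1].min()

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            la.bin_by_depth(np.array([0.1, 0.5]), 5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(5, 400), k=st.integers(2, 8), seed=st.integers(0, 99))
    def test_partition_properties(self, n, k, seed):
        if n < k:
            return
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 1, n)
        a = la.bin_by_depth(d, k)
        counts = np.bincount(a, minlength=k)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1
        for b in range(k - 1):
            assert d[a == b].max() <= d[a == b + 1].min()


@pytest.fixture(scope="module")
def profiled_session(flat_slab, block_design):
    _, pair, tissue, truth = flat_slab
    depthmap = dm.matched_faces_depth(pair, tissue)
    vox = np.argwhere(tissue.labels == LABEL_GM)
    roi = la.ClusterROI(voxels=vox,
                        wm_voxels=la.adjacent_wm_voxels(vox, tissue.labels))
    return tissue, truth, depthmap, roi


class TestLaminarProfile:
    def test_constant_truth_flat_profile(self, profiled_session,
                                         block_design):
        tissue, truth, depthmap, roi = profiled_session
        prof = NeuralDepthProfile(amplitude={"intact": 1.0,
                                             "scrambled": 1.0})
        sess = simulate_session(truth, prof, block_design,
                                noise_std_pct=0.0, psf_fwhm_mm=0.0,
                                labels=tissue.labels)
        lp = la.laminar_profile(sess.data, depthmap, roi, block_design)
        for c in ("intact", "scrambled"):
            assert np.allclose(lp.amplitude[c], 1.0, atol=1e-8)
        assert abs(lp.wm_amplitude["intact"]) < 1e-8

    def test_middle_bump_recovered_noiselessly(self, profiled_session,
                                               block_design):
        tissue, truth, depthmap, roi = profiled_session
        prof = NeuralDepthProfile(amplitude={
            "intact": 1.0,
            "scrambled": NeuralDepthProfile.middle_bump(1.0, 0.5)})
        sess = simulate_session(truth, prof, block_design,
                                noise_std_pct=0.0, psf_fwhm_mm=0.0,
                                labels=tissue.labels)
        lp = la.laminar_profile(sess.data, depthmap, roi, block_design)
        diff = la.differential_profile(lp)
        assert diff.extremum_bin == 2
        assert np.allclose(lp.amplitude["intact"], 1.0, atol=1e-8)

    def test_bin_counts_equally_populated(self, profiled_session,
                                          block_design):
        tissue, truth, depthmap, roi = profiled_session
        prof = NeuralDepthProfile(amplitude={"intact": 1.0,
                                             "scrambled": 1.0})
        sess = simulate_session(truth, prof, block_design,
                                noise_std_pct=0.0, psf_fwhm_mm=0.0,
                                labels=tissue.labels)
        lp = la.laminar_profile(sess.data, depthmap, roi, block_design)
        assert lp.voxel_count.max() - lp.voxel_count.min() <= 1

    def test_missing_wm_reference_degrades_gracefully(self,
                                                      profiled_session,
                                                      block_design):
        tissue, truth, depthmap, roi = profiled_session
        prof = NeuralDepthProfile(amplitude={"intact": 1.0,
                                             "scrambled": 1.0})
        sess = simulate_session(truth, prof, block_design,
                                noise_std_pct=0.0, psf_fwhm_mm=0.0,
                                labels=tissue.labels)
        bare = la.ClusterROI(voxels=roi.voxels,
                             wm_voxels=np.empty((0, 3), int))
        lp = la.laminar_profile(sess.data, depthmap, bare, block_design)
        assert np.isnan(lp.wm_amplitude["intact"])
        flagged = la.roi_eligibility(bare, lp, "intact", "scrambled")
        assert flagged.flags["wm_stable"]


class TestClusters:
    def test_blob_size_and_connectivity_rules(self):
        p = np.full((20, 20, 20), 1.0)
        # one 150-voxel blob
        p[2:8, 2:7, 2:7] = 1e-5
        assert len(la.label_clusters(p, min_voxels=100)) == 1
        # shrink below 100 voxels
        p = np.full((20, 20, 20), 1.0)
        p[2:6, 2:7, 2:7] = 1e-5          # 99 voxels? 4*5*5 = 100 -> use 99
        p[2, 2, 2] = 1.0
        assert len(la.label_clusters(p, min_voxels=100)) == 0
        # two blobs separated by a subthreshold gap
        p = np.full((24, 24, 24), 1.0)
        p[1:6, 1:11, 1:11] = 1e-5
        p[8:13, 1:11, 1:11] = 1e-5
        assert len(la.label_clusters(p, min_voxels=100)) == 2

    def test_diagonal_contact_not_connected(self):
        p = np.full((12, 12, 12), 1.0)
        p[2:5, 2:5, 2:5] = 1e-5
        p[5:8, 5:8, 5:8] = 1e-5          # touches only at a corner
        clusters = la.label_clusters(p, min_voxels=10)
        assert len(clusters) == 2

    def test_detect_clusters_on_simulated_activation(self, profiled_session,
                                                     block_design):
        tissue, truth, depthmap, roi = profiled_session
        prof = NeuralDepthProfile(amplitude={"intact": 1.0,
                                             "scrambled": 1.0})
        sess = simulate_session(truth, prof, block_design,
                                noise_std_pct=0.3, psf_fwhm_mm=0.6,
                                labels=tissue.labels, seed=5)
        rois = la.detect_clusters(sess.data, block_design, 0.7,
                                  tissue.labels, truth,
                                  perm=PermutationSpec(1000, seed=2))
        assert len(rois) == 1
        assert rois[0].size >= 100
        assert len(rois[0].wm_voxels) > 0
        assert 0 <= rois[0].retinotopic_tag[0] <= 2

    def test_adjacent_wm_shell_is_wm_only(self, profiled_session):
        tissue, _, _, roi = profiled_session
        assert len(roi.wm_voxels) > 0
        labs = tissue.labels[roi.wm_voxels[:, 0], roi.wm_voxels[:, 1],
                             roi.wm_voxels[:, 2]]
        assert np.all(labs == LABEL_WM)


class TestEligibility:
    def _profile(self, wm_a, wm_b, counts):
        k = len(counts)
        return la.LaminarProfile(
            k=k, conditions=("intact", "scrambled"),
            mean_depth=np.linspace(0.1, 0.9, k),
            voxel_count=np.asarray(counts),
            amplitude={"intact": np.ones(k), "scrambled": np.ones(k)},
            se={"intact": np.full(k, 0.05), "scrambled": np.full(k, 0.05)},
            wm_amplitude={"intact": wm_a, "scrambled": wm_b},
            wm_se={"intact": 0.02, "scrambled": 0.02})

    def test_stable_roi_eligible(self):
        roi = la.ClusterROI(voxels=np.zeros((350, 3), int),
                            wm_voxels=np.zeros((10, 3), int),
                            stimulus_presence=0.4)
        prof = self._profile(0.10, 0.05, [70] * 5)
        assert la.roi_eligibility(roi, prof, "intact", "scrambled").eligible

    def test_unstable_wm_baseline_excluded(self):
        roi = la.ClusterROI(voxels=np.zeros((350, 3), int),
                            wm_voxels=np.zeros((10, 3), int),
                            stimulus_presence=0.4)
        prof = self._profile(0.30, 0.05, [70] * 5)   # delta 0.25% > 0.16%
        assert not la.roi_eligibility(roi, prof, "intact",
                                      "scrambled").eligible

    def test_small_bins_excluded(self):
        roi = la.ClusterROI(voxels=np.zeros((150, 3), int),
                            wm_voxels=np.zeros((10, 3), int),
                            stimulus_presence=0.4)
        prof = self._profile(0.05, 0.05, [30] * 5)   # < 40 voxels per bin
        assert not la.roi_eligibility(roi, prof, "intact",
                                      "scrambled").eligible

    def test_low_stimulus_presence_excluded(self):
        roi = la.ClusterROI(voxels=np.zeros((350, 3), int),
                            wm_voxels=np.zeros((10, 3), int),
                            stimulus_presence=0.2)
        prof = self._profile(0.05, 0.05, [70] * 5)
        assert not la.roi_eligibility(roi, prof, "intact",
                                      "scrambled").eligible

    def test_data_driven_threshold_overrides_constant(self):
        roi = la.ClusterROI(voxels=np.zeros((350, 3), int),
                            wm_voxels=np.zeros((10, 3), int),
                            stimulus_presence=0.4)
        prof = self._profile(0.30, 0.05, [70] * 5)
        out = la.roi_eligibility(roi, prof, "intact", "scrambled",
                                 mean_se_across_rois=0.2)  # 2x0.2 = 0.4%
        assert out.flags["wm_stable"]


class TestDifferentialProfile:
    def test_identical_conditions_zero(self):
        k = 5
        prof = la.LaminarProfile(
            k=k, conditions=("intact", "scrambled"),
            mean_depth=np.linspace(0.1, 0.9, k), voxel_count=np.full(k, 50),
            amplitude={"intact": np.ones(k), "scrambled": np.ones(k)},
            se={"intact": np.full(k, 0.1), "scrambled": np.full(k, 0.1)})
        d = la.differential_profile(prof)
        assert np.allclose(d.difference, 0.0)
        assert np.allclose(d.se, 0.1 * np.sqrt(2))

    def test_middle_excess_arithmetic(self):
        k = 5
        prof = la.LaminarProfile(
            k=k, conditions=("intact", "scrambled"),
            mean_depth=np.linspace(0.1, 0.9, k), voxel_count=np.full(k, 50),
            amplitude={"intact": np.ones(k),
                       "scrambled": np.array([1, 1, 2, 1, 1.0])},
            se={"intact": np.zeros(k), "scrambled": np.zeros(k)})
        d = la.differential_profile(prof)
        assert np.allclose(d.difference, [0, 0, -1, 0, 0])

    def test_condition_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        k = 5
        prof = la.LaminarProfile(
            k=k, conditions=("intact", "scrambled"),
            mean_depth=np.linspace(0.1, 0.9, k), voxel_count=np.full(k, 50),
            amplitude={"intact": rng.normal(1, 0.3, k),
                       "scrambled": rng.normal(1, 0.3, k)},
            se={"intact": rng.uniform(0.01, 0.1, k),
                "scrambled": rng.uniform(0.01, 0.1, k)})
        fwd = la.differential_profile(prof, "intact", "scrambled")
        rev = la.differential_profile(prof, "scrambled", "intact")
        assert np.allclose(fwd.difference, -rev.difference)
        assert np.allclose(fwd.se, rev.se)

    def test_missing_condition_rejected(self):
        prof = la.LaminarProfile(
            k=2, conditions=("intact",), mean_depth=np.array([0.2, 0.8]),
            voxel_count=np.array([5, 5]),
            amplitude={"intact": np.ones(2)}, se={"intact": np.ones(2)})
        with pytest.raises(ValueError):
            la.differential_profile(prof)


def _anova_bruteforce(values):
    """F from explicit between/within sums of squares."""
    v = np.asarray(values, float)
    r, k = v.shape
    grand = v.mean()
    ss_between = r * np.sum((v.mean(axis=0) - grand) ** 2)
    ss_within = np.sum((v - v.mean(axis=0)) ** 2)
    ms_b = ss_between / (k - 1)
    ms_w = ss_within / (k * (r - 1))
    return ms_b / ms_w


class TestDepthAnova:
    @pytest.mark.parametrize("r,expected_den", [(7, 30), (4, 15), (3, 10)])
    def test_degrees_of_freedom(self, r, expected_den):
        rng = np.random.default_rng(r)
        res = la.depth_anova(rng.normal(size=(r, 5)))
        assert (res.df_num, res.df_den) == (4, expected_den)

    def test_no_depth_effect_gives_zero_f(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=4)
        res = la.depth_anova(np.tile(col[:, None], (1, 5)))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_sums_of_squares(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            r = rng.integers(2, 9)
            k = rng.integers(2, 7)
            v = rng.normal(size=(r, k))
            res = la.depth_anova(v)
            assert abs(res.F - _anova_bruteforce(v)) < 1e-10

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            la.depth_anova(np.ones((1, 5)))


class TestPairedT:
    def test_identical_pairs_are_null(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(6, 5))
        out = la.paired_t_by_depth(a, a.copy())
        assert np.allclose(out["t"], 0.0)
        assert np.all(out["p_corrected"] == 1.0)

    def test_bonferroni_factor_is_twice_bins(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(6, 5))
        out = la.paired_t_by_depth(a, a + 0.1)
        assert out["n_comparisons"] == 10

    def test_superficial_effect_detected_in_top_bin(self):
        rng = np.random.default_rng(14)
        hits, clean = 0, 0
        for _ in range(100):
            m = 1.0 + 0.1 * rng.standard_normal((8, 5))
            p = m.copy()
            p[:, 4] += 0.4
            p += 0.1 * rng.standard_normal((8, 5))
            out = la.paired_t_by_depth(p, m)
            sig = out["significant_05"]
            if sig[4]:
                hits += 1
                if not sig[:4].any():
                    clean += 1
        assert hits >= 90
        assert clean >= 90


class TestLatencyByDepth:
    def test_constant_latency_demeans_to_zero(self, profiled_session):
        tissue, truth, depthmap, roi = profiled_session
        design = BlockDesign()
        prof = NeuralDepthProfile(amplitude={"stimulus": 1.0},
                                  latency={"stimulus": 1.0})
        sess = simulate_session(truth, prof, design, noise_std_pct=0.0,
                                psf_fwhm_mm=0.0, labels=tissue.labels)
        lat_prof, _ = la.latency_by_depth([sess], depthmap, roi)
        assert np.allclose(lat_prof.demeaned_s, 0.0, atol=1e-6)

    def test_gradient_recovered_on_curved_phantom(self, curved_phantom):
        # continuous depth sampling: 0.1 s per bin across five bins
        cfg, pair, tissue, truth = curved_phantom
        depthmap = dm.matched_faces_depth(pair, tissue)
        design = BlockDesign()
        prof = NeuralDepthProfile(
            amplitude={"stimulus": 1.0},
            latency={"stimulus": NeuralDepthProfile.linear(0.5, 0.0)})
        sess = simulate_session(truth, prof, design, noise_std_pct=0.0,
                                psf_fwhm_mm=0.0, labels=tissue.labels)
        vox = np.argwhere(depthmap.gm_labeled)
        roi = la.ClusterROI(voxels=vox, wm_voxels=np.empty((0, 3), int))
        lat_prof, _ = la.latency_by_depth([sess], depthmap, roi)
        lat = lat_prof.latency_s[0]
        assert np.all(np.diff(lat) < 0)
        assert lat[0] - lat[-1] == pytest.approx(0.4, abs=0.05)

    def test_gradient_anova_power_across_subjects(self, profiled_session):
        tissue, truth, depthmap, roi = profiled_session
        design = BlockDesign()
        prof = NeuralDepthProfile(
            amplitude={"stimulus": 1.0},
            latency={"stimulus": NeuralDepthProfile.linear(0.5, 0.0)})
        rejections = 0
        n_reps = 20
        for rep in range(n_reps):
            sessions = [simulate_session(truth, prof, design,
                                         noise_std_pct=0.5, psf_fwhm_mm=0.0,
                                         labels=tissue.labels,
                                         seed=rep * 10 + s)
                        for s in range(5)]
            _, anova = la.latency_by_depth(sessions, depthmap, roi)
            if anova.p_value < 0.05:
                rejections += 1
        assert rejections / n_reps > 0.8

    def test_anova_df_matches_five_subjects(self, profiled_session):
        tissue, truth, depthmap, roi = profiled_session
        design = BlockDesign()
        prof = NeuralDepthProfile(
            amplitude={"stimulus": 1.0},
            latency={"stimulus": NeuralDepthProfile.linear(0.2, 0.0)})
        sessions = [simulate_session(truth, prof, design, noise_std_pct=0.2,
                                     psf_fwhm_mm=0.0, labels=tissue.labels,
                                     seed=s) for s in range(5)]
        _, anova = la.latency_by_depth(sessions, depthmap, roi)
        assert (anova.df_num, anova.df_den) == (4, 20)
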