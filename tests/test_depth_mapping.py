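"""Depth metrics against analytic geometry and exhaustive oracles."""

import itertools

import numpy as np
import pytest
import trimesh

from laminarpy.synthetic_cortex import (LABEL_GM, LABEL_WM, Mesh,
                                        PhantomConfig, SurfacePair,
                                        TissueVolume, make_ribbon_phantom,
                                        voxelize)
from laminarpy import depth_mapping as dm


def _brute_force_matched_faces(pair, tissue):
    """Independent O(segments x voxels) recomputation of matched-faces depth.

    Uses the slab-method segment/box intersection instead of grid traversal.
    """
    vs = tissue.voxel_size_mm
    shape = tissue.labels.shape
    sum_d = np.zeros(shape)
    sum_l = np.zeros(shape)
    cnt = np.zeros(shape, dtype=int)
    gm_idx = np.argwhere(tissue.labels == LABEL_GM)
    lo = gm_idx * vs
    hi = lo + vs
    for wm_pt, gm_pt in pair.segments:
        d = gm_pt - wm_pt
        L = np.linalg.norm(d)
        u = d / L
        # slab intersection of the segment with each GM voxel box
        t0 = np.zeros(len(gm_idx))
        t1 = np.ones(len(gm_idx))
        ok = np.ones(len(gm_idx), dtype=bool)
        for ax in range(3):
            if abs(d[ax]) < 1e-15:
                ok &= (wm_pt[ax] >= lo[:, ax]) & (wm_pt[ax] <= hi[:, ax])
            else:
                ta = (lo[:, ax] - wm_pt[ax]) / d[ax]
                tb = (hi[:, ax] - wm_pt[ax]) / d[ax]
                t0 = np.maximum(t0, np.minimum(ta, tb))
                t1 = np.minimum(t1, np.maximum(ta, tb))
        ok &= (t1 - t0) > 1e-12   # positive path length inside the cube
        for (i, j, k) in gm_idx[ok]:
            center = (np.array([i, j, k]) + 0.5) * vs
            proj = np.clip(np.dot(center - wm_pt, u), 0.0, L)
            sum_d[i, j, k] += proj
            sum_l[i, j, k] += L
            cnt[i, j, k] += 1
    abs_depth = np.full(shape, np.nan)
    thick = np.full(shape, np.nan)
    hit = cnt > 0
    abs_depth[hit] = sum_d[hit] / cnt[hit]
    thick[hit] = sum_l[hit] / cnt[hit]
    rel = np.full(shape, np.nan)
    rel[hit] = np.clip(abs_depth[hit] / thick[hit], 0, 1)
    return abs_depth, rel, thick, cnt


class TestMatchedFaces:
    def test_flat_slab_planar_depths_exact(self, flat_slab):
        _, pair, tissue, truth = flat_slab
        d = dm.matched_faces_depth(pair, tissue)
        gm = d.gm_labeled
        z = tissue.voxel_centers()[..., 2]
        assert np.allclose(d.abs_depth[gm], z[gm] - 2.5, atol=1e-9)
        assert np.allclose(d.rel_depth[gm], (z[gm] - 2.5) / 2.5, atol=1e-9)
        assert np.allclose(d.thickness[gm], 2.5, atol=1e-9)

    def test_matches_exhaustive_segment_voxel_oracle(self,
                                                     small_curved_phantom):
        _, pair, tissue, _ = small_curved_phantom
        d = dm.matched_faces_depth(pair, tissue)
        abs_o, rel_o, thick_o, cnt_o = _brute_force_matched_faces(pair,
                                                                  tissue)
        assert np.array_equal(d.n_segments, cnt_o)
        hit = cnt_o > 0
        assert np.allclose(d.abs_depth[hit], abs_o[hit], atol=1e-12)
        assert np.allclose(d.rel_depth[hit], rel_o[hit], atol=1e-12)
        assert np.allclose(d.thickness[hit], thick_o[hit], atol=1e-12)

    def test_recovers_ground_truth_depth(self, curved_phantom):
        _, pair, tissue, truth = curved_phantom
        d = dm.matched_faces_depth(pair, tissue)
        gm = d.gm_labeled
        rms = np.sqrt(np.mean((d.rel_depth[gm] - truth.rel_depth[gm]) ** 2))
        assert rms < 0.08

    def test_coarse_mesh_with_no_traversals_raises(self):
        cfg = PhantomConfig(fov_mm=(10, 10, 8), fold_amplitude_mm=0.0,
                            mesh_edge_mm=0.7)
        pair = make_ribbon_phantom(cfg)
        # a grid so much finer than any mesh could traverse is impractical;
        # instead shift segments outside the sampled volume
        far = SurfacePair(
            Mesh(pair.wm.vertices + np.array([100.0, 0, 0]), pair.wm.faces),
            Mesh(pair.gm.vertices + np.array([100.0, 0, 0]), pair.gm.faces),
        )
        tissue, _ = voxelize(pair, cfg)
        with pytest.raises(ValueError, match="refine"):
            dm.matched_faces_depth(far, tissue)

    def test_mesh_refinement_stabilises_thickness(self):
        # doubling mesh resolution moves per-voxel thickness by < 1%
        kw = dict(fov_mm=(10, 10, 8), fold_amplitude_mm=1.0,
                  fold_wavelength_mm=14.0)
        maps = []
        for edge in (0.7, 0.35):
            cfg = PhantomConfig(mesh_edge_mm=edge, **kw)
            pair = make_ribbon_phantom(cfg)
            tissue, _ = voxelize(pair, cfg)
            maps.append(dm.matched_faces_depth(pair, tissue))
        both = maps[0].gm_labeled & maps[1].gm_labeled
        rel = np.abs(maps[0].thickness[both] - maps[1].thickness[both]) \
            / maps[1].thickness[both]
        assert np.median(rel) < 0.01


class TestMetricConcordance:
    def test_flat_slab_metrics_identical(self, flat_slab):
        _, pair, tissue, _ = flat_slab
        d1 = dm.matched_faces_depth(pair, tissue)
        d2 = dm.wm_normal_depth(pair, tissue)
        d3 = dm.nearest_gm_depth(pair, tissue)
        common = d1.gm_labeled & d2.gm_labeled & d3.gm_labeled
        assert common.sum() > 0
        for a, b in itertools.combinations((d1, d2, d3), 2):
            assert np.allclose(a.rel_depth[common], b.rel_depth[common],
                               atol=1e-9)

    def test_curved_phantom_relative_depth_agrees(self, curved_phantom):
        _, pair, tissue, _ = curved_phantom
        d1 = dm.matched_faces_depth(pair, tissue)
        d2 = dm.wm_normal_depth(pair, tissue)
        d3 = dm.nearest_gm_depth(pair, tissue)
        common = d1.gm_labeled & d2.gm_labeled & d3.gm_labeled
        for a, b in itertools.combinations((d1, d2, d3), 2):
            rms = np.sqrt(np.mean(
                (a.rel_depth[common] - b.rel_depth[common]) ** 2))
            assert rms < 0.05

    def test_every_gm_voxel_labeled_by_each_metric(self, curved_phantom):
        _, pair, tissue, _ = curved_phantom
        gm = tissue.labels == LABEL_GM
        for fn in (dm.matched_faces_depth, dm.wm_normal_depth,
                   dm.nearest_gm_depth):
            d = fn(pair, tissue)
            assert np.all(d.gm_labeled[gm])

    def test_concentric_spheres_relative_depth_agrees(self):
        # analytic oracle: depth between spheres r=8 and r=10.5 is (r-8)/2.5
        wm_tm = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        gm_tm = trimesh.creation.icosphere(subdivisions=3, radius=10.5)
        center = np.array([12.0, 12.0, 12.0])
        pair = SurfacePair(Mesh(wm_tm.vertices + center, wm_tm.faces),
                           Mesh(gm_tm.vertices + center, gm_tm.faces))
        vs = 0.7
        n = int(np.ceil(24.0 / vs))
        idx = np.indices((n, n, n)).reshape(3, -1).T
        centers = (idx + 0.5) * vs
        r = np.linalg.norm(centers - center, axis=1)
        labels = np.full(n ** 3, 0, dtype=np.int16)
        labels[r < 8.0] = LABEL_WM
        labels[(r >= 8.0) & (r <= 10.5)] = LABEL_GM
        tissue = TissueVolume(labels.reshape(n, n, n), vs)
        truth_rel = np.full(n ** 3, np.nan)
        gm_sel = labels == LABEL_GM
        truth_rel[gm_sel] = (r[gm_sel] - 8.0) / 2.5
        truth_rel = truth_rel.reshape(n, n, n)

        d1 = dm.matched_faces_depth(pair, tissue)
        d2 = dm.wm_normal_depth(pair, tissue)
        d3 = dm.nearest_gm_depth(pair, tissue)
        common = d1.gm_labeled & d2.gm_labeled & d3.gm_labeled
        assert common.sum() > 500
        for a, b in itertools.combinations((d1, d2, d3), 2):
            rms = np.sqrt(np.mean(
                (a.rel_depth[common] - b.rel_depth[common]) ** 2))
            assert rms < 0.05
        rms_truth = np.sqrt(np.mean(
            (d1.rel_depth[common] - truth_rel[common]) ** 2))
        assert rms_truth < 0.05


class TestQC:
    def test_thickness_rule_boundaries(self, flat_slab):
        _, pair, tissue, _ = flat_slab
        d = dm.matched_faces_depth(pair, tissue)
        passed = dm.qc_filter(d, 4.0)
        assert np.all(passed.qc_pass[d.gm_labeled])       # 2.5 mm passes

        thick = dm.DepthMap(**{**d.__dict__})
        thick.thickness = np.where(np.isfinite(d.thickness), 5.0, np.nan)
        assert not np.any(dm.qc_filter(thick, 4.0).qc_pass[d.gm_labeled])

        border = dm.DepthMap(**{**d.__dict__})
        border.thickness = np.where(np.isfinite(d.thickness), 4.0, np.nan)
        # exactly 4 mm fails: the rule is strictly 'less than'
        assert not np.any(dm.qc_filter(border, 4.0).qc_pass[d.gm_labeled])

    def test_qc_report_counts(self, flat_slab):
        _, pair, tissue, _ = flat_slab
        d = dm.matched_faces_depth(pair, tissue)
        rep = dm.qc_report(d)
        assert rep.n_gm_voxels == int(np.sum(tissue.labels == LABEL_GM))
        assert rep.n_gm_labeled == int(np.sum(d.gm_labeled))
        assert rep.frac_thickness_fail == 0.0
        assert abs(rep.thickness_mean_mm - 2.5) < 1e-9
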