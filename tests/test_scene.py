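"""Synthetic field scenes: layout, ground truth and raster properties."""

import numpy as np
import pandas as pd
import pytest

from alfapnc.raster import zonal_mean
from alfapnc.scene import (N_LEVELS, STAGE_PNC, SceneParams, compute_pnc,
                           generate_dataset, generate_layout, generate_stage,
                           layout_from_geojson, layout_to_geojson,
                           planted_tfv_table)


@pytest.mark.parametrize("lnc,ldm,snc,sdm,expected", [
    (3.0, 2.0, 1.0, 2.0, 2.0),      # equal masses -> plain average
    (2.75, 5.0, 2.75, 1.0, 2.75),   # equal concentrations -> masses cancel
    (4.16, 3.0, 2.0, 0.0, 4.16),    # zero stem mass -> leaf value
])
def test_compute_pnc_is_mass_weighted_mean(lnc, ldm, snc, sdm, expected):
    assert compute_pnc(lnc, ldm, snc, sdm) == pytest.approx(expected)


def test_compute_pnc_bounded_by_components(rng):
    for _ in range(100):
        lnc, snc = rng.uniform(0, 6, 2)
        ldm, sdm = rng.uniform(0.1, 50, 2)
        v = compute_pnc(lnc, ldm, snc, sdm)
        assert min(lnc, snc) - 1e-12 <= v <= max(lnc, snc) + 1e-12


def test_compute_pnc_rejects_zero_total_mass():
    with pytest.raises(ValueError):
        compute_pnc(3.0, 0.0, 2.0, 0.0)


class TestLayout:
    def test_randomized_block_structure(self, layout):
        assert len(layout.plots) == 16
        levels = [p.n_level for p in layout.plots]
        assert all(levels.count(lv) == 4 for lv in N_LEVELS)
        for block in range(1, 5):
            in_block = sorted(p.n_level for p in layout.plots if p.block == block)
            assert in_block == sorted(N_LEVELS)

    def test_plots_disjoint_and_frames_inside(self, layout):
        rects = [p.rect for p in layout.plots]
        for i, a in enumerate(rects):
            for b in rects[i + 1:]:
                assert a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]
        for p in layout.plots:
            for fr in layout.sampling_frames[p.plot_id]:
                assert p.rect[0] <= fr[0] and fr[2] <= p.rect[2]
                assert p.rect[1] <= fr[1] and fr[3] <= p.rect[3]

    def test_48_sampling_frames_and_determinism(self):
        a = generate_layout(0)
        b = generate_layout(0)
        assert sum(len(v) for v in a.sampling_frames.values()) == 48
        assert a == b
        assert generate_layout(1) != a

    def test_geojson_roundtrip(self, layout, tmp_path):
        path = tmp_path / "layout.geojson"
        layout_to_geojson(layout, path)
        back = layout_from_geojson(path)
        assert back.plots == layout.plots
        assert back.sampling_frames == layout.sampling_frames


class TestGenerateStage:
    def test_noise_free_scene_constant_within_plots(self, layout):
        params = SceneParams.for_stage(
            "branching", seed=5, noise_sd=0.0, texture_amplitude=0.0,
            row_amplitude=0.0,
        )
        stack, _ = generate_stage(layout, params)
        for p in layout.plots:
            r0, c0, r1, c1 = p.rect
            for band in stack.data:
                patch = band[r0:r1, c0:c1]
                assert patch.max() == patch.min()

    def test_pnc_identity_holds_exactly(self, branching_stage):
        gt = branching_stage.ground_truth
        for rec in gt.itertuples():
            assert rec.PNC == compute_pnc(rec.LNC, rec.LDM, rec.SNC, rec.SDM)

    def test_sample_pnc_mean_near_stage_target(self):
        mean, sd, lo, hi = STAGE_PNC["branching"]
        ds = generate_dataset({"stages": ["branching"]}, seed=1)
        pnc = ds["branching"].samples["PNC"]
        assert len(pnc) == 48
        se = sd / np.sqrt(16)  # 16 independent plot draws
        assert abs(pnc.mean() - mean) < 2 * se
        assert (pnc >= lo).all() and (pnc <= hi).all()

    def test_nir_reflectance_tracks_pnc(self, layout, branching_stage):
        stack = branching_stage.stack
        gt = branching_stage.ground_truth.set_index("plot_id")
        nir, pnc = [], []
        for roi in branching_stage.layout.plot_rois():
            nir.append(zonal_mean(stack, roi)["NIR"])
            pnc.append(gt.loc[roi.plot_id, "PNC"])
        assert np.corrcoef(nir, pnc)[0, 1] > 0

    def test_expected_pnc_monotone_in_nitrogen_level(self):
        by_level = {lv: [] for lv in N_LEVELS}
        for seed in range(10):
            ds = generate_dataset({"stages": ["branching"]}, seed=seed)
            sd = ds["branching"]
            merged = sd.samples.groupby("n_level")["PNC"].mean()
            for lv in N_LEVELS:
                by_level[lv].append(merged[lv])
        means = [np.mean(by_level[lv]) for lv in N_LEVELS]
        assert means == sorted(means)

    def test_byte_identical_under_same_seed(self, layout):
        params = SceneParams.for_stage("budding", seed=9)
        s1, r1 = generate_stage(layout, params)
        s2, r2 = generate_stage(layout, params)
        assert np.array_equal(s1.data, s2.data)
        assert r1 == r2


class TestGenerateDataset:
    def test_three_stages_yield_144_rows(self):
        ds = generate_dataset(seed=0)
        assert sum(len(sd.samples) for sd in ds.values()) == 144
        for sd in ds.values():
            assert len(sd.samples) == 48
            assert len(sd.ground_truth) == 16

    def test_single_stage_and_determinism(self):
        a = generate_dataset({"stages": ["budding"]}, seed=7)
        b = generate_dataset({"stages": ["budding"]}, seed=7)
        assert len(a["budding"].samples) == 48
        pd.testing.assert_frame_equal(a["budding"].samples, b["budding"].samples)
        assert np.array_equal(a["budding"].stack.data, b["budding"].stack.data)

    def test_invalid_stage_count_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset({"stages": []}, seed=0)


def test_planted_table_shape_and_positivity():
    df, (family, t1, t2) = planted_tfv_table(3)
    assert df.shape == (48, 49)
    tfv_cols = [c for c in df.columns if c != "PNC"]
    assert len(tfv_cols) == 48
    assert (df[tfv_cols] > 0).all().all()
    assert {t1, t2} <= set(tfv_cols)
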