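"""GLCM texture features: quantization, matrices, windowed extraction.

The windowed engine is checked against an independent brute-force
pair-enumeration oracle (pure Python, dict-based) and, for a single
window, against scikit-image's co-occurrence implementation.
"""

import math

import numpy as np
import pytest

from alfapnc.glcm import (DIRECTION_OFFSETS, EmptyInputError, FEATURES,
                          GLCMParams, glcm_features, glcm_matrix, quantize,
                          texture_image, tfv_names, tfv_table)
from alfapnc.raster import BAND_NAMES, BandStack, ROI

# ---------------------------------------------------------------------------
# independent oracle: explicit pair enumeration with python dicts


def oracle_window_features(q, r, c, window, distance, directions):
    half = window // 2
    H, W = q.shape
    rlo, rhi = max(r - half, 0), min(r + half, H - 1)
    clo, chi = max(c - half, 0), min(c + half, W - 1)
    sums = dict.fromkeys(FEATURES, 0.0)
    ndir = 0
    for d in directions:
        dy, dx = DIRECTION_OFFSETS[d]
        dy, dx = dy * distance, dx * distance
        counts = {}
        for i in range(rlo, rhi + 1):
            for j in range(clo, chi + 1):
                i2, j2 = i + dy, j + dx
                if rlo <= i2 <= rhi and clo <= j2 <= chi:
                    a, b = int(q[i, j]), int(q[i2, j2])
                    if a < 0 or b < 0:
                        continue
                    counts[(a, b)] = counts.get((a, b), 0) + 1
                    counts[(b, a)] = counts.get((b, a), 0) + 1
        if not counts:
            continue
        total = sum(counts.values())
        P = {k: v / total for k, v in counts.items()}
        mu = sum(i * p for (i, j), p in P.items())
        var = sum((i - mu) ** 2 * p for (i, j), p in P.items())
        cov = sum((i - mu) * (j - mu) * p for (i, j), p in P.items())
        feats = {
            "mean": mu,
            "var": var,
            "hom": sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items()),
            "con": sum((i - j) ** 2 * p for (i, j), p in P.items()),
            "diss": sum(abs(i - j) * p for (i, j), p in P.items()),
            "ent": -sum(p * math.log(p) for p in P.values()),
            "corr": cov / var if var > 0 else 1.0,
            "sm": sum(p * p for p in P.values()),
        }
        for k, v in feats.items():
            sums[k] += v
        ndir += 1
    if ndir == 0:
        return dict.fromkeys(FEATURES, float("nan"))
    return {k: v / ndir for k, v in sums.items()}


class TestQuantize:
    def test_endpoints_map_to_extreme_levels(self):
        q = quantize(np.array([[0.0, 1.0]]), 64)
        assert set(q.ravel()) == {0, 63}

    def test_constant_raster_maps_to_zero(self):
        q = quantize(np.full((5, 5), 0.37), 64)
        assert (q == 0).all()

    def test_uniform_ramp_covers_all_levels(self):
        ramp = np.linspace(0.0, 1.0, 64).reshape(8, 8)
        q = quantize(ramp, 64)
        assert sorted(set(q.ravel().tolist())) == list(range(64))

    def test_masked_pixels_and_empty_input(self):
        band = np.array([[0.1, np.nan], [0.9, 0.5]])
        q = quantize(band, 4)
        assert q[0, 1] == -1 and (q[q >= 0] >= 0).all()
        with pytest.raises(EmptyInputError):
            quantize(np.full((3, 3), np.nan), 4)


class TestMatrix:
    def test_constant_window_single_entry(self):
        P = glcm_matrix(np.full((4, 4), 7, dtype=int), 0, levels=8)
        assert P[7, 7] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal_pairs(self):
        q = np.array([[0, 1], [1, 0]])
        P = glcm_matrix(q, 0, levels=2)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    def test_normalized_and_symmetric_on_random_windows(self, rng):
        for _ in range(20):
            q = rng.integers(0, 6, (5, 5))
            d = int(rng.choice([0, 45, 90, 135]))
            P = glcm_matrix(q, d, levels=6)
            assert P.sum() == pytest.approx(1.0)
            assert np.allclose(P, P.T)


class TestFeatures:
    def test_constant_window_degenerate_values(self):
        P = glcm_matrix(np.full((3, 3), 2, dtype=int), 0, levels=4)
        f = glcm_features(P)
        assert f["con"] == f["diss"] == f["var"] == 0.0
        assert f["ent"] == 0.0
        assert f["sm"] == f["hom"] == 1.0
        assert f["corr"] == 1.0

    def test_checkerboard_hand_computed_values(self):
        P = glcm_matrix(np.array([[0, 1], [1, 0]]), 0, levels=2)
        f = glcm_features(P)
        assert f["mean"] == pytest.approx(0.5)
        assert f["var"] == pytest.approx(0.25)
        assert f["con"] == pytest.approx(1.0)
        assert f["diss"] == pytest.approx(1.0)
        assert f["ent"] == pytest.approx(math.log(2))
        assert f["sm"] == pytest.approx(0.5)
        assert f["hom"] == pytest.approx(0.5)
        assert f["corr"] == pytest.approx(-1.0)

    def test_uniform_matrix_closed_forms(self):
        for L in (2, 4, 8):
            P = np.full((L, L), 1.0 / L**2)
            f = glcm_features(P)
            assert f["ent"] == pytest.approx(2 * math.log(L))
            assert f["sm"] == pytest.approx(1.0 / L**2)


class TestWindowedEngine:
    def test_matches_brute_force_oracle(self, rng):
        params = GLCMParams(window=5, levels=8, distance=1)
        for _ in range(10):
            h, w = rng.integers(6, 14, 2)
            img = rng.integers(0, 8, (h, w)).astype(float) / 7.0
            feats = texture_image(img, params)
            q = quantize(img, params.levels)
            for r in range(h):
                for c in range(w):
                    want = oracle_window_features(
                        q, r, c, params.window, params.distance, params.directions
                    )
                    for k in FEATURES:
                        assert feats[k][r, c] == pytest.approx(want[k], abs=1e-10)

    def test_matches_scikit_image_on_full_window(self, rng):
        from skimage.feature import graycomatrix, graycoprops

        q = rng.integers(0, 16, (9, 9))
        # skimage measures angles with the row axis flipped, so its pi/4
        # matches this package's 135 deg offset (symmetric GLCM makes the
        # sign of the offset irrelevant)
        angles = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        for d, ang in angles.items():
            P_sk = graycomatrix(q.astype(np.uint8), [1], [ang], levels=16,
                                symmetric=True, normed=True)[:, :, 0, 0]
            P = glcm_matrix(q, d, levels=16)
            assert np.allclose(P, P_sk, atol=1e-12)
            f = glcm_features(P)
            for ours, theirs in [("con", "contrast"), ("diss", "dissimilarity"),
                                 ("hom", "homogeneity"), ("sm", "ASM"),
                                 ("corr", "correlation")]:
                ref = graycoprops(P_sk[:, :, None, None], theirs)[0, 0]
                assert f[ours] == pytest.approx(ref, abs=1e-10)

    def test_rotation_leaves_direction_average_unchanged(self, rng):
        params = GLCMParams(window=5, levels=8)
        img = rng.random((12, 12))
        feats = texture_image(img, params)
        feats_rot = texture_image(np.rot90(img).copy(), params)
        for k in FEATURES:
            assert np.allclose(feats_rot[k], np.rot90(feats[k]), atol=1e-10)

    def test_feature_range_invariants(self, rng):
        params = GLCMParams(window=5, levels=16)
        img = rng.random((15, 15))
        f = texture_image(img, params)
        assert ((f["hom"] > 0) & (f["hom"] <= 1 + 1e-12)).all()
        assert ((f["sm"] > 0) & (f["sm"] <= 1 + 1e-12)).all()
        assert (f["ent"] >= 0).all()
        for k in ("con", "diss", "var"):
            assert (f[k] >= 0).all()
        assert ((f["corr"] >= -1 - 1e-9) & (f["corr"] <= 1 + 1e-9)).all()

    def test_contrast_equals_dissimilarity_at_two_levels(self, rng):
        params = GLCMParams(window=5, levels=2)
        img = rng.integers(0, 2, (10, 10)).astype(float)
        f = texture_image(img, params)
        assert np.allclose(f["con"], f["diss"], atol=1e-12)

    def test_band_smaller_than_window_rejected(self, rng):
        with pytest.raises(ValueError):
            texture_image(rng.random((5, 5)), GLCMParams(window=9))


class TestTFVTable:
    def test_exactly_48_named_columns(self, branching_stage, branching_features):
        cols = [c for c in branching_features.columns if c in tfv_names()]
        assert cols == tfv_names()
        assert len(cols) == 48
        assert cols[0] == "B_mean" and cols[-1] == "NIR_sm"

    def test_constant_stack_gives_degenerate_texture(self):
        stack = BandStack(np.full((6, 16, 16), 0.4, dtype=np.float32))
        rois = [ROI.from_rect("a", (4, 4, 12, 12))]
        t = tfv_table(stack, rois, GLCMParams(window=5, levels=8))
        for b in BAND_NAMES:
            for feat, want in [("con", 0.0), ("diss", 0.0), ("ent", 0.0),
                               ("sm", 1.0), ("hom", 1.0), ("corr", 1.0)]:
                assert t[f"{b}_{feat}"].iloc[0] == pytest.approx(want)

    def test_single_pixel_roi_equals_direct_window_computation(self, rng):
        params = GLCMParams(window=9, levels=8)
        data = rng.random((6, 11, 11), dtype=np.float32)
        stack = BandStack(data)
        roi = ROI.from_rect("c", (5, 5, 6, 6))  # center pixel only
        t = tfv_table(stack, [roi], params)
        band = stack.band("G")
        q = quantize(band, params.levels)
        window = q[1:10, 1:10]
        acc = dict.fromkeys(FEATURES, 0.0)
        for d in params.directions:
            f = glcm_features(glcm_matrix(window, d, levels=params.levels))
            for k in FEATURES:
                acc[k] += f[k] / 4
        for k in FEATURES:
            assert t[f"G_{k}"].iloc[0] == pytest.approx(acc[k], abs=1e-10)


@pytest.mark.parametrize("kw", [
    {"window": 4}, {"window": 1}, {"levels": 1}, {"distance": 0},
    {"directions": (30,)},
])
def test_invalid_params_rejected(kw):
    with pytest.raises(ValueError):
        GLCMParams(**kw)
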