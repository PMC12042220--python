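import numpy as np
import pytest
from scipy import ndimage

from monorelief import _grid
from monorelief.errors import ValidationError
from monorelief.intrinsic import (DecompositionConfig, TexturePairSet,
                                  decompose, retinex_weight, scale_indicator,
                                  texture_pairs)
from monorelief.raster_io import RadianceImage, RegionMask, to_log

from conftest import pearson


# ---------------------------------------------------------------------------
# independent dense oracle: assemble the decomposition system with explicit
# Python loops (no shared code with the package's vectorised assembly) and
# solve it densely with numpy.linalg.lstsq


def dense_decompose_logS(image: RadianceImage, mask: RegionMask,
                         cfg: DecompositionConfig, eps_floor=1e-4):
    lg = np.log(np.maximum(image.pixels, eps_floor))
    H, W, C = lg.shape
    inside = mask.inside
    var = {}
    for r in range(H):
        for c in range(W):
            if inside[r, c]:
                var[(r, c)] = len(var)
    n = len(var)

    # per-pixel pooled gradient magnitude -> omega
    omega = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            mag = 0.0
            for ch in range(C):
                gx = lg[r, c + 1, ch] - lg[r, c, ch] if c + 1 < W else 0.0
                gy = lg[r + 1, c, ch] - lg[r, c, ch] if r + 1 < H else 0.0
                mag = max(mag, np.hypot(gx, gy))
            omega[r, c] = 0.0 if mag > cfg.retinex_threshold_t else cfg.retinex_smooth_weight

    rows, rhs = [], []
    srx = np.sqrt(cfg.lambda_rx)
    for r in range(H):
        for c in range(W):
            if not inside[r, c]:
                continue
            for (r2, c2) in ((r, c + 1), (r + 1, c)):
                if r2 >= H or c2 >= W or not inside[r2, c2]:
                    continue
                w = omega[r, c]
                for ch in range(C):
                    row = np.zeros(n)
                    row[var[(r2, c2)]] = srx * (1.0 - w)
                    row[var[(r, c)]] = -srx * (1.0 - w)
                    rows.append(row)
                    rhs.append(-srx * w * (lg[r2, c2, ch] - lg[r, c, ch]))

    brightness = image.pixels.max(axis=2)
    peak = brightness[inside].max()
    for r in range(H):
        for c in range(W):
            if inside[r, c] and brightness[r, c] >= cfg.brightness_quantile * peak:
                row = np.zeros(n)
                row[var[(r, c)]] = np.sqrt(cfg.lambda_sc)
                rows.append(row)
                rhs.append(0.0)

    A = np.array(rows)
    b = np.array(rhs)
    s, *_ = np.linalg.lstsq(A, b, rcond=None)
    out = np.zeros((H, W))
    for (r, c), i in var.items():
        out[r, c] = s[i]
    return out


class TestRetinexWeight:
    def test_values_are_zero_or_hundred(self):
        rng = np.random.default_rng(0)
        img = RadianceImage(rng.uniform(0.05, 1.0, (16, 16, 3)))
        w = retinex_weight(to_log(img), t=0.1)
        assert set(np.unique(w)) <= {0.0, 100.0}

    def test_large_gradient_gets_zero(self):
        px = np.full((8, 8, 1), 0.2)
        px[:, 4:] = 0.8  # log step ~1.39 > t
        w = retinex_weight(to_log(RadianceImage(px)), t=0.1)
        assert np.all(w[:, 3] == 0.0)

    def test_zero_gradient_gets_hundred(self):
        w = retinex_weight(to_log(RadianceImage(np.full((8, 8, 1), 0.5))), t=0.1)
        assert np.all(w == 100.0)

    def test_constant_image_all_hundred(self):
        for t in (1e-6, 0.1, 10.0):
            w = retinex_weight(to_log(RadianceImage(np.full((8, 8, 3), 0.3))), t=t)
            assert np.all(w == 100.0)

    def test_nonpositive_threshold_rejected(self):
        lg = to_log(RadianceImage(np.full((8, 8, 1), 0.5)))
        with pytest.raises(ValidationError):
            retinex_weight(lg, t=0.0)


class TestScaleIndicator:
    def test_above_and_below_threshold(self):
        px = np.full((8, 8, 1), 0.5)
        px[0, 0] = 1.0
        px[0, 1] = 0.96
        px[0, 2] = 0.90
        b = scale_indicator(RadianceImage(px), 0.95)
        assert b[0, 0] == 1 and b[0, 1] == 1 and b[0, 2] == 0

    def test_uniform_image_all_ones(self):
        b = scale_indicator(RadianceImage(np.full((8, 8, 3), 0.42)), 0.95)
        assert np.all(b == 1)

    def test_ramp_count_matches_direct_rule(self):
        ramp = np.tile(np.linspace(0.01, 1.0, 100), (8, 1))[:, :, None]
        img = RadianceImage(ramp)
        b = scale_indicator(img, 0.95)
        expected = int((ramp.max(axis=2) >= 0.95 * ramp.max()).sum())
        assert int(b.sum()) == expected
        assert expected == 8 * 6  # 6 columns of the 100-step ramp reach 0.95


def _textured_patch(rng, amp=0.04):
    return amp * rng.standard_normal((5, 5))


class TestTexturePairs:
    def test_identical_patches_paired(self):
        rng = np.random.default_rng(4)
        px = np.full((24, 24), 0.5)
        tex = _textured_patch(rng)  # sub-threshold contrast texture
        px[4:9, 4:9] += tex
        px[4:9, 15:20] += tex
        img = RadianceImage(px[:, :, None])
        mask = RegionMask(np.ones((24, 24), dtype=bool))
        cfg = DecompositionConfig(texture_stride=1, texture_corr_min=0.95,
                                  retinex_threshold_t=0.5)
        ps = texture_pairs(to_log(img), mask, cfg)
        a = 6 * 24 + 6
        b = 6 * 24 + 17
        assert (min(a, b), max(a, b), 1.0) in ps.pairs

    def test_noise_with_corr_one_is_empty(self):
        rng = np.random.default_rng(5)
        px = np.clip(0.5 + 0.03 * rng.standard_normal((24, 24, 1)), 0.05, 1)
        mask = RegionMask(np.ones((24, 24), dtype=bool))
        cfg = DecompositionConfig(texture_corr_min=1.0, texture_stride=1)
        ps = texture_pairs(to_log(RadianceImage(px)), mask, cfg)
        assert len(ps) == 0

    def test_checkerboard_against_bruteforce(self):
        # low-contrast checkerboard: textured but below the Retinex edge
        # threshold, so the texture term (not Retinex) must handle it
        size, tile = 32, 2
        yy, xx = np.mgrid[0:size, 0:size]
        phase = ((yy // tile) + (xx // tile)) % 2
        px = np.where(phase, 0.52, 0.48)[:, :, None]
        img = RadianceImage(px)
        mask = RegionMask(np.ones((size, size), dtype=bool))
        cfg = DecompositionConfig(texture_stride=2, texture_corr_min=0.9,
                                  retinex_threshold_t=0.5)
        lg = to_log(img)
        ps = texture_pairs(lg, mask, cfg)
        assert len(ps) > 0
        # brute-force oracle: every reported pair must have mean-subtracted
        # normalised patch correlation >= threshold
        gray = lg.log_pixels[:, :, 0]
        for a, b, w in ps.pairs:
            ar, ac = divmod(a, size)
            br, bc = divmod(b, size)
            pa = gray[ar - 2:ar + 3, ac - 2:ac + 3].ravel()
            pb = gray[br - 2:br + 3, bc - 2:bc + 3].ravel()
            pa = pa - pa.mean()
            pb = pb - pb.mean()
            corr = pa @ pb / (np.linalg.norm(pa) * np.linalg.norm(pb))
            assert corr >= cfg.texture_corr_min - 1e-12
            assert w == 1.0
            # same-phase centres only
            assert phase[ar, ac] == phase[br, bc]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        px = np.clip(0.5 + 0.05 * rng.standard_normal((32, 32, 1)), 0.05, 1)
        img = RadianceImage(px)
        mask = RegionMask(np.ones((32, 32), dtype=bool))
        cfg = DecompositionConfig(texture_corr_min=0.5, texture_stride=1,
                                  texture_max_candidates=50, rng_seed=11)
        p1 = texture_pairs(to_log(img), mask, cfg)
        p2 = texture_pairs(to_log(img), mask, cfg)
        assert p1.pairs == p2.pairs

    def test_no_self_pairs_and_inside_mask(self):
        scene_px = np.clip(0.5 + 0.05 * np.random.default_rng(7)
                           .standard_normal((32, 32, 1)), 0.05, 1)
        img = RadianceImage(scene_px)
        inside = np.zeros((32, 32), dtype=bool)
        inside[4:28, 4:28] = True
        mask = RegionMask(inside)
        cfg = DecompositionConfig(texture_corr_min=0.4, texture_stride=1)
        ps = texture_pairs(to_log(img), mask, cfg)
        for a, b, w in ps.pairs:
            assert a != b and w > 0
            assert inside[divmod(a, 32)] and inside[divmod(b, 32)]


class TestDecompose:
    def test_uniform_image(self, full_mask_8):
        img = RadianceImage(np.full((8, 8, 3), 0.5))
        R, S, diag = decompose(img, full_mask_8)
        assert np.allclose(S.values, 1.0, atol=1e-6)
        assert np.allclose(R.values, 0.5, atol=1e-6)

    def test_dense_oracle_equivalence_8x8(self, full_mask_8):
        rng = np.random.default_rng(8)
        base = np.clip(0.4 + 0.02 * rng.standard_normal((8, 8, 3)), 0.05, 1)
        base[:, 4:] *= 1.8  # one reflectance edge
        img = RadianceImage(np.clip(base, 0.0, 1.0))
        cfg = DecompositionConfig(lambda_tx=0.0, solver_tol=1e-12)
        R, S, diag = decompose(img, full_mask_8, cfg)
        expected = dense_decompose_logS(img, full_mask_8, cfg)
        assert np.abs(np.log(S.values) - expected).max() <= 1e-6

    def test_dense_oracle_equivalence_irregular_mask_12x12(self):
        rng = np.random.default_rng(9)
        px = np.clip(0.3 + 0.1 * rng.standard_normal((12, 12, 1)), 0.05, 1)
        img = RadianceImage(px)
        yy, xx = np.mgrid[0:12, 0:12]
        mask = RegionMask((yy - 5.5) ** 2 + (xx - 5.5) ** 2 <= 30)
        cfg = DecompositionConfig(lambda_tx=0.0, solver_tol=1e-12)
        R, S, diag = decompose(img, mask, cfg)
        expected = dense_decompose_logS(img, mask, cfg)
        m = mask.inside
        assert np.abs(np.log(S.values[m]) - expected[m]).max() <= 1e-6

    def test_reconstruction_identity(self, full_mask_16):
        rng = np.random.default_rng(10)
        px = np.clip(rng.uniform(0.1, 0.9, (16, 16, 3)), 0.05, 1)
        img = RadianceImage(px)
        cfg = DecompositionConfig()
        R, S, diag = decompose(img, full_mask_16, cfg)
        log_err = np.abs(np.log(R.values) + np.log(S.values)[:, :, None]
                         - np.log(np.maximum(px, 1e-4)))
        assert log_err.max() <= 10 * cfg.solver_tol

    def test_mondrian_smooth_shading_recovery(self):
        from monorelief.synthetic import make_reflectance, make_shading_field

        size = 64
        Rtrue = make_reflectance("mondrian", size, {"n_patches": 6}, seed=0)
        Strue = make_shading_field(size, "blobs", seed=0)
        img = RadianceImage(np.clip(Rtrue * Strue[:, :, None], 0, 1))
        mask = RegionMask(np.ones((size, size), dtype=bool))
        R, S, diag = decompose(img, mask)
        m = mask.inside
        assert pearson(np.log(S.values[m]), np.log(Strue[m])) >= 0.9

    def test_recovered_edges_near_true_borders(self):
        from monorelief.synthetic import make_reflectance, make_shading_field

        size = 64
        Rtrue = make_reflectance("mondrian", size, {"n_patches": 6}, seed=0)
        Strue = make_shading_field(size, "blobs", seed=0)
        img = RadianceImage(np.clip(Rtrue * Strue[:, :, None], 0, 1))
        mask = RegionMask(np.ones((size, size), dtype=bool))
        cfg = DecompositionConfig()
        R, S, diag = decompose(img, mask, cfg)

        def pooled_grad_mag(arr3):
            mag = np.zeros(arr3.shape[:2])
            for c in range(arr3.shape[2]):
                gx, gy = _grid.forward_gradient(arr3[:, :, c])
                mag = np.maximum(mag, np.hypot(gx, gy))
            return mag

        rec = pooled_grad_mag(np.log(np.maximum(R.values, 1e-6)))
        true = pooled_grad_mag(np.log(Rtrue))
        strong = rec > cfg.retinex_threshold_t
        near_border = ndimage.binary_dilation(true > 1e-9, iterations=1)
        frac = (strong & near_border).sum() / max(strong.sum(), 1)
        assert frac >= 0.9

    def test_global_scaling_leaves_shading_fixed(self, full_mask_16):
        # differences of log I and the relative brightness threshold are both
        # scale-invariant, so log S is unchanged and R carries the scale
        rng = np.random.default_rng(12)
        px = np.clip(rng.uniform(0.1, 0.5, (16, 16, 3)), 0.05, 0.5)
        cfg = DecompositionConfig(lambda_tx=0.0, solver_tol=1e-12)
        R1, S1, _ = decompose(RadianceImage(px), full_mask_16, cfg)
        R2, S2, _ = decompose(RadianceImage(1.7 * px), full_mask_16, cfg)
        assert np.abs(S1.values - S2.values).max() <= 1e-6
        assert np.abs(R2.values - 1.7 * R1.values).max() <= 1e-6

    def test_all_black_region_rejected(self):
        px = np.full((8, 8, 1), 0.5)
        px[0:3, 0:3] = 0.0
        inside = np.zeros((8, 8), dtype=bool)
        inside[0:3, 0:3] = True
        with pytest.raises(ValidationError, match="black"):
            decompose(RadianceImage(px), RegionMask(inside))

    def test_deterministic(self, full_mask_16):
        rng = np.random.default_rng(13)
        px = np.clip(rng.uniform(0.1, 0.9, (16, 16, 3)), 0.05, 1)
        img = RadianceImage(px)
        R1, S1, d1 = decompose(img, full_mask_16)
        R2, S2, d2 = decompose(img, full_mask_16)
        assert np.array_equal(S1.values, S2.values)
        assert np.array_equal(R1.values, R2.values)
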