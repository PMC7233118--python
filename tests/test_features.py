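"""Feature extraction: discretization, LoG bank, FOS, GLCM/GLSZM vs oracles, ICC."""

import numpy as np
import pytest
from scipy import stats

from noderad import (
    ExtractionConfig,
    discretize,
    extract_features,
    feature_agreement_icc,
    feature_names,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glszm_features,
    glszm_matrix,
    log_filter,
)
from noderad.features import FOS_NAMES, GLCM_NAMES, GLSZM_NAMES


# ---------------------------------------------------------------------------
# oracles


def glcm_oracle(levels, mask, offsets, ng):
    """Brute-force pair enumeration: O(N * offsets) double loop."""
    acc = np.zeros((ng, ng))
    total = 0
    h, w = levels.shape
    for dy, dx in offsets:
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                    a, b = levels[y, x] - 1, levels[y2, x2] - 1
                    acc[a, b] += 1
                    acc[b, a] += 1
                    total += 2
    return acc / total


def glszm_oracle(levels, mask):
    """Brute-force flood fill over 8-connected equal-level zones."""
    h, w = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                lvl = levels[y, x]
                stack, size = [(y, x)], 0
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if (
                                0 <= ny < h
                                and 0 <= nx < w
                                and mask[ny, nx]
                                and not seen[ny, nx]
                                and levels[ny, nx] == lvl
                            ):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                zones.append((lvl, size))
    ng = max(l for l, _ in zones)
    ms = max(s for _, s in zones)
    mat = np.zeros((ng, ms), dtype=np.int64)
    for l, s in zones:
        mat[l - 1, s - 1] += 1
    return mat


# ---------------------------------------------------------------------------


class TestDiscretize:
    def test_right_closed_top_bin(self):
        assert list(discretize(np.array([0.0, 0.5, 1.0]), 2)) == [1, 1, 2]

    def test_constant_maps_to_level_one(self):
        assert set(discretize(np.full(9, 3.3), 32)) == {1}

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty ROI"):
            discretize(np.array([]), 8)

    def test_uniform_values_fill_bins_uniformly(self, rng):
        v = rng.random(10_000)
        levels = discretize(v, 32)
        counts = np.bincount(levels, minlength=33)[1:]
        chi2 = ((counts - v.size / 32) ** 2 / (v.size / 32)).sum()
        assert stats.chi2.sf(chi2, 31) > 1e-4


class TestLogFilter:
    def test_constant_image_gives_zero_response(self):
        out = log_filter(np.full((32, 32), 7.0), 2.0)
        assert np.max(np.abs(out)) < 1e-8

    def test_isolated_bright_pixel_is_extremum(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = log_filter(img, 2.0)
        assert np.unravel_index(np.argmax(np.abs(out)), out.shape) == (16, 16)

    def test_scale_space_optimum_near_blob_scale(self):
        # centered Gaussian blob of scale s: |response| maximal at sigma ~ s
        s = 3.0
        yy, xx = np.mgrid[0:65, 0:65] - 32.0
        blob = np.exp(-(xx**2 + yy**2) / (2 * s**2))
        grid = np.arange(1.0, 6.1, 0.25)
        responses = [np.abs(log_filter(blob, sg))[32, 32] for sg in grid]
        assert abs(grid[int(np.argmax(responses))] - s) <= 0.5


class TestFirstOrder:
    def test_symmetric_triplet(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0]))
        assert f["Mean"] == 2.0
        assert abs(f["SD"] - 0.816496580927726) < 1e-12
        assert f["Skewness"] == 0.0

    def test_constant_input_conventions(self):
        f = first_order_features(np.full(20, 5.0))
        assert f["Variance"] == 0.0 and f["Entropy"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_normal_sample_moments_in_sampling_bounds(self, rng):
        v = rng.standard_normal(1000)
        f = first_order_features(v)
        assert abs(f["Skewness"]) < 0.25
        assert abs(f["Kurtosis"]) < 0.5

    def test_matches_scipy_moments(self, rng):
        v = rng.gamma(2.0, 1.5, size=400)
        f = first_order_features(v)
        assert np.isclose(f["Skewness"], stats.skew(v, bias=True))
        assert np.isclose(f["Kurtosis"], stats.kurtosis(v, fisher=True, bias=True))


class TestGLCM:
    def test_two_row_image_direct_enumeration(self):
        levels = np.array([[1, 1], [2, 2]])
        m = glcm_matrix(levels, np.ones((2, 2), bool), offsets=[(0, 1)], n_gray_levels=2)
        assert np.allclose(m.matrix, [[0.5, 0.0], [0.0, 0.5]])

    def test_checkerboard_mass_off_diagonal(self):
        levels = np.indices((6, 6)).sum(axis=0) % 2 + 1
        m = glcm_matrix(levels, np.ones((6, 6), bool), offsets=[(0, 1)], n_gray_levels=2)
        assert m.matrix[0, 0] == 0 and m.matrix[1, 1] == 0
        assert np.isclose(m.matrix[0, 1] + m.matrix[1, 0], 1.0)

    def test_matches_bruteforce_oracle_on_random_images(self, rng):
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
        for _ in range(30):
            levels = rng.integers(1, 7, (16, 16))
            mask = rng.random((16, 16)) < 0.8
            if mask.sum() < 4:
                continue
            got = glcm_matrix(levels, mask, offsets=offsets, n_gray_levels=6)
            exp = glcm_oracle(levels, mask, offsets, 6)
            assert np.array_equal(got.matrix, exp)

    def test_normalization_sums_to_one(self, rng):
        levels = rng.integers(1, 9, (20, 20))
        m = glcm_matrix(levels, np.ones((20, 20), bool), n_gray_levels=8)
        assert abs(m.matrix.sum() - 1.0) < 1e-9

    def test_degenerate_single_pixel_roi(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="degenerate"):
            glcm_matrix(np.ones((5, 5), int), mask)


class TestGLCMFeatures:
    def test_diagonal_matrix(self):
        from noderad.features import TextureMatrix

        m = TextureMatrix("GLCM", np.array([[0.5, 0.0], [0.0, 0.5]]), True)
        f = glcm_features(m)
        assert f["contrast"] == 0.0 and abs(f["cshade"]) < 1e-12

    def test_point_mass(self):
        from noderad.features import TextureMatrix

        p = np.zeros((4, 4))
        p[1, 1] = 1.0
        f = glcm_features(TextureMatrix("GLCM", p, True))
        assert f["entropy"] == 0.0 and f["asm"] == 1.0 and f["max_prob"] == 1.0

    def test_random_matrix_matches_direct_summation(self, rng):
        """Independent formula evaluation with explicit loops, 1e-10."""
        raw = rng.random((8, 8))
        p = raw + raw.T
        p /= p.sum()
        from noderad.features import TextureMatrix

        f = glcm_features(TextureMatrix("GLCM", p, True))
        mu_i = sum(i * p[i - 1, j - 1] for i in range(1, 9) for j in range(1, 9))
        mu_j = mu_i
        contrast = sum(
            (i - j) ** 2 * p[i - 1, j - 1] for i in range(1, 9) for j in range(1, 9)
        )
        cshade = sum(
            (i + j - mu_i - mu_j) ** 3 * p[i - 1, j - 1]
            for i in range(1, 9)
            for j in range(1, 9)
        )
        autoc = sum(i * j * p[i - 1, j - 1] for i in range(1, 9) for j in range(1, 9))
        homog = sum(
            p[i - 1, j - 1] / (1 + abs(i - j)) for i in range(1, 9) for j in range(1, 9)
        )
        assert abs(f["contrast"] - contrast) < 1e-10
        assert abs(f["cshade"] - cshade) < 1e-10
        assert abs(f["autocorrelation"] - autoc) < 1e-10
        assert abs(f["homogeneity"] - homog) < 1e-10
        assert abs(f["joint_average"] - mu_i) < 1e-10


class TestGLSZM:
    def test_uniform_roi_single_zone(self):
        m = glszm_matrix(np.ones((4, 4), int), np.ones((4, 4), bool))
        assert m.matrix.shape == (1, 16)
        assert m.matrix[0, 15] == 1 and m.matrix.sum() == 1

    def test_checkerboard_levels_form_one_zone_each(self):
        # 8-connectivity joins diagonal same-level cells
        levels = np.indices((4, 4)).sum(axis=0) % 2 + 1
        m = glszm_matrix(levels, np.ones((4, 4), bool))
        assert m.matrix[0, 7] == 1 and m.matrix[1, 7] == 1 and m.matrix.sum() == 2

    def test_matches_floodfill_oracle_on_random_images(self, rng):
        for _ in range(30):
            levels = rng.integers(1, 5, (16, 16))
            mask = rng.random((16, 16)) < 0.75
            if not mask.any():
                continue
            got = glszm_matrix(levels, mask).matrix
            exp = glszm_oracle(levels, mask)
            assert got.shape == exp.shape and np.array_equal(got, exp)

    def test_zone_counts_conserve_mask_pixels(self, rng):
        levels = rng.integers(1, 6, (20, 20))
        mask = rng.random((20, 20)) < 0.6
        mat = glszm_matrix(levels, mask).matrix
        sizes = np.arange(1, mat.shape[1] + 1)
        assert (mat * sizes).sum() == mask.sum()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            glszm_matrix(np.ones((4, 4), int), np.zeros((4, 4), bool))


class TestGLSZMFeatures:
    def test_single_zone_matrix(self):
        from noderad.features import TextureMatrix

        mat = np.zeros((1, 16), dtype=np.int64)
        mat[0, 15] = 1  # one zone of 16 pixels at level 1
        f = glszm_features(TextureMatrix("GLSZM", mat, False))
        assert f["ZP"] == 1 / 16
        assert f["SZE"] == 1 / 16**2 and f["LZE"] == 16**2

    def test_all_singleton_low_level_zones(self):
        from noderad.features import TextureMatrix

        mat = np.zeros((1, 1), dtype=np.int64)
        mat[0, 0] = 5  # 5 zones, size 1, level 1
        f = glszm_features(TextureMatrix("GLSZM", mat, False))
        assert f["LZLGE"] == 1.0

    def test_random_matrix_matches_direct_summation(self, rng):
        from noderad.features import TextureMatrix

        mat = rng.integers(0, 4, (6, 9))
        mat[2, 3] += 1  # guarantee a zone
        f = glszm_features(TextureMatrix("GLSZM", mat, False))
        nz = mat.sum()
        lzlge = sum(
            mat[i - 1, s - 1] * s**2 / i**2 for i in range(1, 7) for s in range(1, 10)
        ) / nz
        sze = sum(mat[i - 1, s - 1] / s**2 for i in range(1, 7) for s in range(1, 10)) / nz
        zp = nz / sum(mat[i - 1, s - 1] * s for i in range(1, 7) for s in range(1, 10))
        assert abs(f["LZLGE"] - lzlge) < 1e-10
        assert abs(f["SZE"] - sze) < 1e-10
        assert abs(f["ZP"] - zp) < 1e-10


class TestExtraction:
    def test_per_sequence_count_is_264_and_total_1056(self, small_cohort):
        _, samples, _ = small_cohort
        cfg = ExtractionConfig()
        assert cfg.n_features_per_sequence == 264
        names = feature_names(cfg)
        assert len(names) == 1056 and len(set(names)) == 1056
        vec = extract_features(samples[0], cfg)
        assert len(vec) == 1056
        per_seq = sum(1 for n in names if n.startswith("T2w:"))
        assert per_seq == 264

    def test_deterministic(self, small_cohort):
        _, samples, _ = small_cohort
        v1 = extract_features(samples[1])
        v2 = extract_features(samples[1])
        assert v1 == v2

    def test_missing_sequence_names_it(self, small_cohort):
        import copy

        _, samples, _ = small_cohort
        s = copy.copy(samples[0])
        s.images = {k: v for k, v in s.images.items() if k != "ADC"}
        with pytest.raises(ValueError, match="ADC"):
            extract_features(s)

    def test_translation_invariance(self, rng):
        """Shifting image and mask together leaves every feature unchanged
        (mask kept away from the border by more than the LoG support)."""
        from noderad.synthetic import MRISample, ClinicalRecord, SEQUENCES

        size = 64
        base = rng.standard_normal((size, size))
        yy, xx = np.mgrid[0:size, 0:size]
        mask = ((yy - 26) ** 2 + (xx - 26) ** 2) <= 36
        shift = 5

        def make(img, msk):
            return MRISample(
                patient_id="x",
                images={s: img for s in SEQUENCES},
                masks={s: msk for s in SEQUENCES},
                clinical=None,
                label=0,
            )

        v1 = extract_features(make(base, mask))
        v2 = extract_features(make(np.roll(base, (shift, shift), (0, 1)),
                                   np.roll(mask, (shift, shift), (0, 1))))
        a = np.array(list(v1.values()))
        b = np.array(list(v2.values()))
        assert np.allclose(a, b, rtol=1e-9, atol=1e-9)

    def test_outside_mask_relabeling_invariance(self, rng):
        """Texture features depend only on in-mask pixels (orig channel)."""
        from noderad.features import _channel_features

        img = rng.random((32, 32))
        mask = np.zeros((32, 32), bool)
        mask[8:20, 8:20] = True
        cfg = ExtractionConfig()
        f1 = _channel_features(img, mask, cfg)
        img2 = img.copy()
        img2[~mask] = rng.random((~mask).sum()) * 100
        f2 = _channel_features(img2, mask, cfg)
        assert np.allclose(f1, f2)

    def test_monotone_rescaling_leaves_texture_unchanged(self, rng):
        from noderad.features import _channel_features

        img = rng.random((32, 32))
        mask = np.zeros((32, 32), bool)
        mask[6:26, 6:26] = True
        cfg = ExtractionConfig()
        f1 = _channel_features(img, mask, cfg)
        f2 = _channel_features(3.7 * img + 11.0, mask, cfg)
        names = FOS_NAMES + GLCM_NAMES + GLSZM_NAMES
        texture = {
            n: (a, b)
            for n, a, b in zip(names, f1, f2)
            if n in GLCM_NAMES or n in GLSZM_NAMES
        }
        for n, (a, b) in texture.items():
            assert np.isclose(a, b, rtol=1e-9), n


class TestICC:
    def _tables(self, rng, noise_sd):
        import pandas as pd

        base = rng.standard_normal((40, 6)) * 3.0
        t1 = pd.DataFrame(base, columns=[f"f{i}" for i in range(6)])
        t2 = t1 + rng.standard_normal(t1.shape) * noise_sd
        return t1, t2

    def test_identical_tables_give_one(self, rng):
        t1, t2 = self._tables(rng, 0.0)
        icc = feature_agreement_icc(t1, t1)
        assert np.allclose(icc.values, 1.0)

    def test_large_noise_drives_icc_to_zero(self, rng):
        t1, t2 = self._tables(rng, 30.0)
        icc = feature_agreement_icc(t1, t2)
        assert np.all(np.abs(icc.values) < 0.35)

    def test_noise_one_ninth_of_signal_gives_point_nine(self, rng):
        # closed form: ICC = sigma_s^2 / (sigma_s^2 + sigma_e^2) = 9/10
        import pandas as pd

        base = rng.standard_normal(3000)[:, None] * 3.0
        noise_sd = 1.0  # signal var 9, noise var 1
        t1 = pd.DataFrame(base + rng.standard_normal(base.shape) * noise_sd, columns=["f"])
        t2 = pd.DataFrame(base + rng.standard_normal(base.shape) * noise_sd, columns=["f"])
        icc = feature_agreement_icc(t1, t2)
        assert abs(icc["f"] - 0.9) < 0.03

    def test_constant_feature_reported_missing(self, rng):
        import pandas as pd

        t = pd.DataFrame({"f": np.ones(10)})
        assert np.isnan(feature_agreement_icc(t, t)["f"])

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        t1, t2 = self._tables(rng, 1.0)
        ours = feature_agreement_icc(t1, t2)
        for col in t1.columns:
            long = pd.DataFrame(
                {
                    "subject": list(range(len(t1))) * 2,
                    "rater": ["a"] * len(t1) + ["b"] * len(t1),
                    "score": np.concatenate([t1[col], t2[col]]),
                }
            )
            ref = pingouin.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score"
            )
            icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
            assert abs(ours[col] - icc2) < 1e-8
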