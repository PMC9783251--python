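"""Quality indices: values, identities, naive-loop oracles, cross-checks."""

import numpy as np
import pytest
from scipy import stats
from skimage.metrics import structural_similarity

from perfcolor.colormaps import apply_colormap, wcm_transfer
from perfcolor.metrics import (
    MetricReport,
    SSIMParams,
    anova_oneway,
    gray_to_rgb,
    metric_report,
    mse,
    ncd,
    psnr,
    rgb_to_lab,
    ssim_image,
    ssim_window,
)

# ---------------------------------------------------------------- oracles


def naive_mse(x, y):
    total = 0.0
    m, n, c = x.shape
    for i in range(m):
        for j in range(n):
            for k in range(c):
                total += (x[i, j, k] - y[i, j, k]) ** 2
    return total / (m * n * c)


def naive_ssim(x, y, w, c1, c2):
    """Double loop over all fully contained windows, population moments."""
    scores = []
    for ch in range(x.shape[-1]):
        a, b = x[..., ch], y[..., ch]
        vals = []
        for i in range(x.shape[0] - w + 1):
            for j in range(x.shape[1] - w + 1):
                wa = a[i : i + w, j : j + w]
                wb = b[i : i + w, j : j + w]
                ma, mb = wa.mean(), wb.mean()
                va, vb = wa.var(), wb.var()
                cov = ((wa - ma) * (wb - mb)).mean()
                vals.append(
                    (2 * ma * mb + c1)
                    * (2 * cov + c2)
                    / ((ma**2 + mb**2 + c1) * (va + vb + c2))
                )
        scores.append(np.mean(vals))
    return float(np.mean(scores))


# ---------------------------------------------------------------- MSE / PSNR


class TestMse:
    def test_identical_images_score_zero(self, random_gray):
        rgb = gray_to_rgb(random_gray)
        assert mse(rgb, rgb) == 0.0

    @pytest.mark.parametrize(
        "a, b, expected",
        [((0, 0, 0), (1, 1, 1), 1.0), ((0, 0, 0), (1, 0, 0), 1 / 3)],
    )
    def test_single_pixel_hand_values(self, a, b, expected):
        x = np.array(a, dtype=float).reshape(1, 1, 3)
        y = np.array(b, dtype=float).reshape(1, 1, 3)
        assert mse(x, y) == pytest.approx(expected)
        assert mse(y, x) == pytest.approx(expected)  # symmetry

    def test_vectorized_agrees_with_naive_loop(self, rng):
        x = rng.uniform(size=(16, 16, 3))
        y = rng.uniform(size=(16, 16, 3))
        assert mse(x, y) == pytest.approx(naive_mse(x, y), abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse(np.zeros((2, 2, 3)), np.zeros((3, 2, 3)))


class TestPsnr:
    @pytest.mark.parametrize(
        "mse_value, expected_db",
        [(0.3234, 4.9026), (0.3256, 4.8732), (0.0938, 10.2779)],
    )
    def test_published_mse_to_psnr_pairs(self, mse_value, expected_db):
        assert psnr(mse_value, imax=1.0) == pytest.approx(expected_db, abs=0.01)

    def test_unit_mse_is_zero_db_and_zero_mse_is_infinite(self):
        assert psnr(1.0) == 0.0
        assert psnr(0.0) == float("inf")

    def test_negative_mse_rejected(self):
        with pytest.raises(ValueError):
            psnr(-0.1)


# ---------------------------------------------------------------- Lab / NCD


class TestLab:
    def test_black_white_and_mid_gray(self):
        lab = rgb_to_lab(np.array([[[0, 0, 0], [1, 1, 1], [0.5, 0.5, 0.5]]], float))
        np.testing.assert_allclose(lab[0, 0], (0, 0, 0), atol=1e-6)
        assert lab[0, 1, 0] == pytest.approx(100.0, abs=1e-3)
        assert abs(lab[0, 1, 1]) < 0.01 and abs(lab[0, 1, 2]) < 0.01
        assert 0 < lab[0, 2, 0] < 100
        assert abs(lab[0, 2, 1]) < 0.01 and abs(lab[0, 2, 2]) < 0.01

    def test_srgb_red_against_published_reference_values(self):
        # canonical sRGB/D65 red: L*=53.24, a*=80.09, b*=67.20
        lab = rgb_to_lab(np.array([[[1.0, 0.0, 0.0]]]))
        np.testing.assert_allclose(lab[0, 0], (53.2408, 80.0925, 67.2032), atol=0.01)

    def test_out_of_range_channels_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            rgb_to_lab(np.full((2, 2, 3), 1.5))


class TestNcd:
    def test_replicated_gray_scores_zero(self, random_gray):
        assert ncd(random_gray, gray_to_rgb(random_gray)) == 0.0

    @pytest.mark.parametrize("form", ["printed", "classic"])
    def test_tiling_invariance(self, form, random_gray):
        colored = apply_colormap(random_gray, "scm")
        once = ncd(random_gray, colored, form=form)
        tiled = ncd(
            np.tile(random_gray, (2, 2)), np.tile(colored, (2, 2, 1)), form=form
        )
        assert tiled == pytest.approx(once, rel=1e-12)

    def test_gray_versus_pure_red_positive_finite(self):
        gray = np.full((8, 8), 0.5)
        red = np.zeros((8, 8, 3))
        red[..., 0] = 1.0
        value = ncd(gray, red)
        assert np.isfinite(value) and value > 0
        # independent hand check from published Lab triples:
        # gray 0.5 -> (53.389, 0, 0); sRGB red -> (53.241, 80.093, 67.203)
        diff = np.array([53.389 - 53.2408, -80.0925, -67.2032])
        ref = np.array([53.2408, 80.0925, 67.2032])
        expected = (diff @ diff) / (ref @ ref)
        assert value == pytest.approx(expected, rel=1e-3)

    def test_classic_form_differs_from_printed_on_structured_images(self, random_gray):
        colored = apply_colormap(2 * random_gray - 1, "jcm", value_range="signed")
        assert ncd(random_gray, colored, "printed") != pytest.approx(
            ncd(random_gray, colored, "classic")
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ncd(np.zeros((4, 4)), np.zeros((4, 4, 3)))


# ---------------------------------------------------------------- SSIM


class TestSsim:
    def test_identical_windows_score_one(self, rng):
        x = rng.uniform(size=(8, 8))
        assert ssim_window(x, x) == pytest.approx(1.0)

    def test_constant_windows_luminance_term_only(self):
        params = SSIMParams(dynamic_range=1.0)
        c1, _ = params.constants()
        got = ssim_window(np.zeros((8, 8)), np.ones((8, 8)), params)
        assert got == pytest.approx(c1 / (1 + c1))

    def test_sign_flip_gives_negative_score(self, rng):
        x = rng.uniform(-0.5, 0.5, size=(8, 8))
        x -= x.mean()
        assert ssim_window(x, -x) < 0

    def test_identical_images_score_one(self, random_gray):
        rgb = gray_to_rgb(random_gray)
        assert ssim_image(rgb, rgb) == pytest.approx(1.0)

    def test_vectorized_agrees_with_naive_loop(self, rng):
        x = rng.uniform(size=(16, 16, 3))
        y = np.clip(x + 0.1 * rng.standard_normal(x.shape), 0, 1)
        params = SSIMParams(window_size=8)
        c1, c2 = params.constants()
        assert ssim_image(x, y, params) == pytest.approx(
            naive_ssim(x, y, 8, c1, c2), abs=1e-10
        )

    def test_agrees_with_skimage_reference(self, rng):
        # matched settings: uniform 7x7 window, population covariance
        x = rng.uniform(size=(32, 32))
        y = np.clip(x + 0.05 * rng.standard_normal(x.shape), 0, 1)
        ours = ssim_image(x, y, SSIMParams(window_size=7))
        theirs = structural_similarity(
            x, y, win_size=7, data_range=1.0, gaussian_weights=False,
            use_sample_covariance=False,
        )
        assert ours == pytest.approx(theirs, abs=1e-7)

    def test_channel_permutation_matters_only_for_chromatic_pairs(self, random_gray, rng):
        # per-channel averaging: permuting one side of a chromatic pair
        # re-pairs unlike channels; with a gray (replicated) side any
        # permutation of the other side is score-invariant by symmetry
        ref = apply_colormap(random_gray, "hcm")
        test = np.clip(ref + 0.05 * rng.standard_normal(ref.shape), 0, 1)
        assert ssim_image(ref, test[..., [2, 0, 1]]) != pytest.approx(
            ssim_image(ref, test)
        )
        gray_ref = gray_to_rgb(random_gray)
        assert ssim_image(gray_ref, test[..., [2, 0, 1]]) == pytest.approx(
            ssim_image(gray_ref, test)
        )

    def test_more_noise_scores_lower(self, clean_phantom, rng):
        ref = gray_to_rgb(clean_phantom)
        low = gray_to_rgb(
            np.clip(clean_phantom + 0.05 * rng.standard_normal((64, 64)), 0, 1)
        )
        high = gray_to_rgb(
            np.clip(clean_phantom + 0.10 * rng.standard_normal((64, 64)), 0, 1)
        )
        assert ssim_image(ref, high) < ssim_image(ref, low) < 1.0

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim_image(np.zeros((4, 4)), np.zeros((4, 4)), SSIMParams(window_size=8))


# ---------------------------------------------------------------- report / ANOVA


class TestMetricReport:
    def test_constant_image_rows_are_finite(self):
        rows = metric_report(np.full((16, 16), 0.5), ["scm"])
        (row,) = rows
        assert isinstance(row, MetricReport)
        assert np.isfinite([row.mse, row.psnr_db, row.ncd, row.ssim]).all()

    def test_rows_follow_requested_order(self, random_gray):
        rows = metric_report(random_gray, ["jcm", "wcm", "scm"])
        assert [r.map_name for r in rows] == ["jcm", "wcm", "scm"]

    def test_psnr_column_is_log_of_mse_column(self, random_gray):
        for row in metric_report(random_gray):
            assert row.psnr_db == pytest.approx(10 * np.log10(1 / row.mse))

    def test_wcm_row_against_per_pixel_transfer_loop(self, rng):
        gray = rng.uniform(size=(8, 8))
        (row,) = metric_report(gray, ["wcm"])
        total = 0.0
        for i in range(8):
            for j in range(8):
                rgb = wcm_transfer(np.array(gray[i, j]))
                total += float(np.sum((rgb - gray[i, j]) ** 2))
        assert row.mse == pytest.approx(total / (3 * 64), abs=1e-12)

    def test_unknown_map_rejected(self, random_gray):
        with pytest.raises(ValueError, match="unknown color map"):
            metric_report(random_gray, ["wcm", "nope"])


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        f, p = anova_oneway([[1.0, 2.0, 3.0]] * 3)
        assert f == 0.0 and p == 1.0

    def test_perfect_separation_gives_infinite_f(self):
        f, p = anova_oneway([[0.0, 0.0], [1.0, 1.0]])
        assert f == float("inf") and p == 0.0

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(loc, 1.0, size=9) for loc in (0.0, 0.5, 1.5)]
        f, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_fixed_table_sums_of_squares(self):
        # 3 groups of 5; hand-computed sums of squares
        g = [[1, 2, 3, 4, 5], [2, 3, 4, 5, 6], [4, 5, 6, 7, 8]]
        means = [3.0, 4.0, 6.0]
        grand = 13.0 / 3.0
        ssb = 5 * sum((m - grand) ** 2 for m in means)
        ssw = sum(sum((x - m) ** 2 for x in grp) for grp, m in zip(g, means))
        expected_f = (ssb / 2) / (ssw / 12)
        f, p = anova_oneway(g)
        assert f == pytest.approx(expected_f)
        assert 0 < p < 1

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            anova_oneway([[1.0, 2.0]])
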