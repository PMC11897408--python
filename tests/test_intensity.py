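"""Intensity measurement, background ROI, line scans, foci detection."""

import numpy as np
import pytest
from scipy import stats as sps

from decondenseq.intensity import (
    FociConfig,
    corrected_intensity,
    detect_foci,
    line_scan,
    mean_on_mask,
    sample_background,
)
from decondenseq.synthetic import MassParams, TwoChannelParams, \
    make_two_channel_cell


def cell_fixture(n_foci=0, seed=0, noise=0.0, **kw):
    params = TwoChannelParams(n_foci=n_foci, seed=seed, marker_noise_sd=noise,
                              **kw)
    return make_two_channel_cell(params), params


class TestMeanOnMask:
    def test_constant_image(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True
        assert mean_on_mask(np.full((10, 10), 7.0), mask) == 7.0

    def test_rim_band_exact(self):
        (_, marker, truth), params = cell_fixture()
        assert mean_on_mask(marker, truth.info["rim_mask"]) == \
            params.rim_intensity

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.random((30, 30)) * 100
        mask = rng.random((30, 30)) < 0.3
        total = n = 0
        for r in range(30):
            for c in range(30):
                if mask[r, c]:
                    total += img[r, c]
                    n += 1
        assert mean_on_mask(img, mask) == pytest.approx(total / n, abs=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            mean_on_mask(np.ones((5, 5)), np.zeros((5, 5), dtype=bool))

    def test_linear_in_scaling(self):
        rng = np.random.default_rng(6)
        img = rng.random((20, 20))
        mask = rng.random((20, 20)) < 0.5
        assert mean_on_mask(img * 3.0, mask) == pytest.approx(
            3.0 * mean_on_mask(img, mask)
        )


class TestBackgroundSampling:
    def test_uniform_cytoplasm_any_seed(self):
        (_, marker, truth), params = cell_fixture()
        for seed in (0, 1, 2):
            _, bg = sample_background(
                marker, truth.info["chromatin_mask"], truth.info["cell_mask"],
                radius_px=8, seed=seed,
                exclusion_dilation_px=params.rim_width_px + 1,
            )
            assert bg == params.cytoplasm_intensity

    def test_seed_reproducible(self):
        (_, marker, truth), params = cell_fixture(noise=5.0, seed=3)
        args = (marker, truth.info["chromatin_mask"], truth.info["cell_mask"])
        r1 = sample_background(*args, radius_px=8, seed=42)
        r2 = sample_background(*args, radius_px=8, seed=42)
        assert r1 == r2

    def test_gradient_bounded_by_cytoplasm_range(self):
        (_, marker, truth), params = cell_fixture()
        grad = marker.data + np.linspace(0, 10, marker.data.shape[1])[None, :]
        cyto = truth.info["cytoplasm_mask"]
        _, bg = sample_background(
            grad, truth.info["chromatin_mask"], truth.info["cell_mask"],
            radius_px=8, seed=0, exclusion_dilation_px=params.rim_width_px + 1,
        )
        assert grad[cyto].min() <= bg <= grad[cyto].max()

    def test_impossible_radius_raises(self):
        (_, marker, truth), _ = cell_fixture()
        with pytest.raises(RuntimeError, match="smaller radius"):
            sample_background(
                marker, truth.info["chromatin_mask"], truth.info["cell_mask"],
                radius_px=90, seed=0, max_retries=50,
            )

    def test_roi_centers_uniform_over_admissible_region(self):
        """Chi-squared goodness of fit of ROI centers against uniformity."""
        (_, marker, truth), params = cell_fixture()
        chrom = truth.info["chromatin_mask"].astype(bool)
        cell = truth.info["cell_mask"]
        radius = 6
        centers = [
            sample_background(marker, chrom, cell, radius_px=radius, seed=s,
                              exclusion_dilation_px=params.rim_width_px + 1)[0]
            for s in range(4000)
        ]
        # admissible centers: cytoplasm pixels whose whole disk fits
        from scipy import ndimage
        from skimage.morphology import disk

        cyto = cell & ~ndimage.binary_dilation(
            chrom, structure=disk(params.rim_width_px + 1)
        )
        fits = ndimage.binary_erosion(cyto, structure=disk(radius))
        # coarse spatial bins; expected count proportional to admissible area
        nbins = 6
        h, w = cyto.shape
        obs = np.zeros((nbins, nbins))
        exp = np.zeros((nbins, nbins))
        for (r, c) in centers:
            obs[r * nbins // h, c * nbins // w] += 1
        rr, cc = np.nonzero(fits)
        for r, c in zip(rr, cc):
            exp[r * nbins // h, c * nbins // w] += 1
        keep = exp > 0
        exp = exp[keep] / exp[keep].sum() * len(centers)
        chi2 = float(((obs[keep] - exp) ** 2 / exp).sum())
        p = sps.chi2.sf(chi2, df=keep.sum() - 1)
        assert p > 0.01


class TestCorrectedIntensity:
    def test_exact_on_noise_free_cell(self):
        (_, marker, truth), params = cell_fixture()
        meas = corrected_intensity(
            marker, truth.info["chromatin_mask"], truth.info["cell_mask"],
            seed=1, exclusion_dilation_px=params.rim_width_px + 1,
        )
        assert meas.on_mask_mean == params.rim_intensity
        assert meas.background_mean == params.cytoplasm_intensity
        assert meas.corrected == params.rim_intensity - params.cytoplasm_intensity
        assert not meas.negative_corrected

    def test_linearity_under_intensity_scaling(self):
        (_, marker, truth), params = cell_fixture()
        kw = dict(seed=9, exclusion_dilation_px=params.rim_width_px + 1)
        m1 = corrected_intensity(marker, truth.info["chromatin_mask"],
                                 truth.info["cell_mask"], **kw)
        m2 = corrected_intensity(marker.data * 2.0,
                                 truth.info["chromatin_mask"],
                                 truth.info["cell_mask"], **kw)
        assert m2.corrected == pytest.approx(2.0 * m1.corrected)

    def test_zero_marker_flagged_negative(self):
        (_, marker, truth), params = cell_fixture()
        zero = np.zeros_like(marker.data)
        # force a nonzero background by adding cytoplasm signal only
        zero[truth.info["cytoplasm_mask"]] = 10.0
        meas = corrected_intensity(
            zero, truth.info["chromatin_mask"], truth.info["cell_mask"],
            seed=2, exclusion_dilation_px=params.rim_width_px + 1,
        )
        assert meas.corrected < 0
        assert meas.negative_corrected


class TestLineScan:
    def test_constant_image(self):
        prof = line_scan(np.full((40, 40), 50.0), (5, 5), (30, 30))
        assert prof.values.shape == (200,)
        assert prof.values == pytest.approx(np.full(200, 50.0), abs=1e-10)

    def test_horizontal_ramp_closed_form(self):
        img = np.tile(np.arange(200.0), (20, 1))
        prof = line_scan(img, (10, 0), (10, 199))
        expected = np.linspace(0, 199, 200)
        assert prof.values == pytest.approx(expected, abs=1e-9)

    def test_out_of_frame_endpoint_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            line_scan(np.zeros((10, 10)), (0, 0), (5, 20))

    def test_peaks_at_rim_crossings(self):
        (_, marker, truth), params = cell_fixture(
            chromatin_marker_intensity=60.0
        )
        nr, nc = marker.data.shape
        cy = (nr - 1) // 2
        prof = line_scan(marker, (cy, 10), (cy, nc - 11))
        vals = prof.values
        mid = vals[90:110].mean()  # over the chromatin body
        assert vals.max() == params.rim_intensity
        # two rim crossings flank the chromatin: peak exceeds both sides
        assert vals.max() > mid
        assert vals.max() > vals[:40].max()


class TestFociDetection:
    def test_no_foci_fixture(self):
        (_, marker, truth), _ = cell_fixture(n_foci=0)
        res = detect_foci(marker, truth.info["chromatin_mask"],
                          truth.info["cell_mask"])
        assert res.foci == []
        assert not res.big_foci_present

    def test_three_bright_foci_counted(self):
        (_, marker, truth), _ = cell_fixture(n_foci=3, seed=4,
                                             focus_intensity=150.0)
        res = detect_foci(marker, truth.info["chromatin_mask"],
                          truth.info["cell_mask"])
        assert len(res.foci) == 3
        assert res.big_foci_present

    def test_rim_blob_not_counted(self):
        (_, marker, truth), params = cell_fixture(n_foci=0)
        bright = marker.data.copy()
        bright[truth.info["rim_mask"]] = 500.0  # bright, but excluded region
        res = detect_foci(bright, truth.info["chromatin_mask"],
                          truth.info["cell_mask"],
                          FociConfig(exclusion_dilation_px=params.rim_width_px
                                     + 1))
        assert res.foci == []

    def test_small_foci_below_min_area_ignored(self):
        (_, marker, truth), _ = cell_fixture(n_foci=0)
        img = marker.data.copy()
        cyto = truth.info["cytoplasm_mask"]
        rr, cc = np.nonzero(cyto)
        img[rr[0], cc[0]] = 400.0  # single hot pixel: area 1 < min_area 4
        res = detect_foci(img, truth.info["chromatin_mask"],
                          truth.info["cell_mask"])
        assert res.foci == []

    def test_empty_cytoplasm_raises(self):
        (_, marker, truth), _ = cell_fixture()
        with pytest.raises(ValueError, match="empty"):
            detect_foci(marker, np.ones_like(truth.info["chromatin_mask"]),
                        truth.info["cell_mask"])
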