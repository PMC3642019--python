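"""Angiographic scoring, ROI sampling and FWHM diameter measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from vesselct import (
    DiameterMeasurement,
    LineProfile,
    SamplingScheme,
    angiographic_score,
    extract_profile,
    format_diameter_um,
    measure_diameter,
    min_detectable_diameter,
    sample_rois,
    score_group,
)
from conftest import make_tube_tree, project_clean


class TestAngiographicScore:
    @pytest.mark.parametrize("ones,total,expected", [
        (0, 40000, 0.0),
        (40000, 40000, 1.0),
        (1200, 40000, 0.03),
    ])
    def test_counting_ratio(self, ones, total, expected):
        mask = np.zeros(total, np.uint8).reshape(200, -1)
        mask.ravel()[:ones] = 1
        assert angiographic_score(mask) == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_score_equals_fraction_exactly(self, seed, density):
        """Score recovery is exact: it is a pure counting ratio."""
        rng = np.random.default_rng(seed)
        mask = (rng.random((50, 80)) < density).astype(np.uint8)
        assert angiographic_score(mask) == mask.sum() / mask.size

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            angiographic_score(np.zeros((0, 10), np.uint8))


class TestSampleRois:
    def _projections(self):
        tree = make_tube_tree(90.0, height_um=2000.0)
        return project_clean(tree, 200, n_rows=120)

    def test_default_scheme_gives_27(self):
        samples = sample_rois(self._projections(), roi_size=(40, 40), seed=0)
        assert len(samples) == 27
        assert {s.angle_deg for s in samples} == {0.0, 90.0, 179.0}
        assert {s.film_idx for s in samples} == {0, 1, 2}
        assert {s.area_idx for s in samples} == {0, 1, 2}

    def test_minimal_scheme_gives_one(self):
        scheme = SamplingScheme(angles_deg=(90.0,), films_per_angle=1,
                                areas_per_film=1)
        samples = sample_rois(self._projections(), scheme, roi_size=(40, 40),
                              seed=0)
        assert len(samples) == 1

    def test_same_seed_same_placements(self):
        a = sample_rois(self._projections(), roi_size=(40, 40), seed=7)
        b = sample_rois(self._projections(), roi_size=(40, 40), seed=7)
        assert [s.roi.origin for s in a] == [s.roi.origin for s in b]

    def test_non_overlapping_within_film(self):
        samples = sample_rois(self._projections(), roi_size=(40, 40), seed=3)
        by_film = {}
        for s in samples:
            by_film.setdefault((s.angle_deg, s.film_idx), []).append(s.roi.origin)
        for placements in by_film.values():
            for i, (r1, c1) in enumerate(placements):
                for r2, c2 in placements[i + 1:]:
                    assert abs(r1 - r2) >= 40 or abs(c1 - c2) >= 40

    def test_infeasible_placement_reports_capacity(self):
        with pytest.raises(ValueError, match="at most"):
            sample_rois(self._projections(), roi_size=(100, 100), seed=0)


class TestScoreGroup:
    def test_constant_scores(self):
        mean, sd, n = score_group([0.2] * 27)
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.0, abs=1e-15)
        assert n == 27

    def test_two_scores_closed_form(self):
        mean, sd, n = score_group([0.1, 0.3])
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(np.sqrt(2) * 0.1)
        assert n == 2

    def test_too_few_scores(self):
        with pytest.raises(ValueError, match="at least 2"):
            score_group([0.5])


class TestExtractProfile:
    def test_constant_image_constant_profile(self):
        prof = extract_profile(np.full((20, 30), 2.5), (10, 2), (10, 27))
        assert np.allclose(prof.values, 2.5)
        assert len(prof.values) == 26

    def test_reversed_endpoints_reverse_values(self):
        img = np.tile(np.arange(30.0), (20, 1))
        fwd = extract_profile(img, (5, 2), (5, 27))
        rev = extract_profile(img, (5, 27), (5, 2))
        np.testing.assert_allclose(rev.values, fwd.values[::-1])

    def test_cylinder_projection_chord(self, cylinder_projections):
        img = -np.log(cylinder_projections.images[0]
                      / cylinder_projections.background[0])
        prof = extract_profile(img, (1, 0), (1, 127))
        x = (np.arange(128) - 63.5) * 9.0
        chord = 1e-3 * 2 * np.sqrt(np.maximum(180.0**2 - x**2, 0.0))
        assert np.sqrt(np.mean((prof.values - chord) ** 2)) <= 0.02 * chord.max()

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            extract_profile(np.zeros((10, 10)), (3, 3), (3, 3))


class TestMeasureDiameter:
    def test_rectangular_dip_width_five(self):
        x = np.arange(40.0)
        vals = np.where((x >= 10) & (x < 15), 0.7, 1.0)
        m = measure_diameter(LineProfile(x, vals, (0, 1)))
        assert m.pixel_count == pytest.approx(5.0)
        assert m.diameter_um == pytest.approx(45.0)

    def test_gaussian_dip_fwhm(self):
        x = np.arange(60.0)
        sigma = 2.0
        vals = 1.0 - 0.3 * np.exp(-((x - 30) ** 2) / (2 * sigma**2))
        m = measure_diameter(LineProfile(x, vals, (0, 1)))
        assert m.pixel_count == pytest.approx(2.355 * sigma, rel=0.03)

    def test_pixel_count_to_micrometres(self):
        m = DiameterMeasurement(7.8, 9.0)
        assert m.diameter_um == pytest.approx(70.2)
        assert format_diameter_um(m) == 70.0

    def test_no_vessel_rejected(self):
        rng = np.random.default_rng(0)
        x = np.arange(50.0)
        prof = LineProfile(x, 1.0 + rng.normal(0, 0.01, 50), (0, 1))
        with pytest.raises(ValueError, match="no vessel"):
            measure_diameter(prof, noise_floor=0.05)

    @pytest.mark.parametrize("d_px", [3, 5, 8, 12, 18, 25])
    def test_tube_cross_sections_recovered(self, d_px):
        """Partial-volume tube cross-sections: within 1 px over 20 seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 72
            c = (n - 1) / 2 + rng.uniform(-0.5, 0.5)
            yy, xx = np.indices((n, n))
            rr = np.hypot(yy - (n - 1) / 2, xx - c)
            img = np.clip(d_px / 2 - rr + 0.5, 0.0, 1.0)
            img = ndimage.gaussian_filter(img, 0.6)
            img += rng.normal(0, 0.02, img.shape)
            prof = extract_profile(img, ((n - 1) / 2, 0.0), ((n - 1) / 2, n - 1.0))
            m = measure_diameter(prof, polarity="bright")
            assert abs(m.pixel_count - d_px) <= 1.0


class TestMinDetectableDiameter:
    def test_noiseless_detects_smallest(self):
        sweep = [18.0, 36.0, 72.0]
        assert min_detectable_diameter(sweep, cnr=np.inf,
                                       mode="absorption") == 18.0
        assert min_detectable_diameter(sweep, cnr=np.inf, mode="phase") == 18.0

    def test_sweep_floor_returned(self):
        assert min_detectable_diameter([90.0, 180.0], cnr=np.inf) == 90.0

    def test_unsorted_sweep_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            min_detectable_diameter([72.0, 18.0])

    def test_undetectable_returns_inf(self):
        with pytest.warns(UserWarning, match="inf"):
            out = min_detectable_diameter([18.0], cnr=0.2, seed=0)
        assert out == np.inf

    def test_phase_at_most_absorption(self):
        """Edge enhancement never raises the detectability floor."""
        sweep = [18.0, 27.0, 36.0, 54.0, 72.0]
        for seed in (0, 1, 2):
            a = min_detectable_diameter(sweep, cnr=5.0, seed=seed,
                                        mode="absorption")
            p = min_detectable_diameter(sweep, cnr=5.0, seed=seed, mode="phase")
            assert p <= a
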