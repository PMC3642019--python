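"""Normalization, sinogram assembly, axis estimation and FBP."""

import warnings

import numpy as np
import pytest

from vesselct import (
    FlatFieldModel,
    Sinogram,
    assemble_sinogram,
    equalize_background,
    estimate_axis,
    fbp,
    normalize,
    reconstruct_volume,
)
from vesselct.phantom import VesselSegment, VesselTree
from conftest import disk_truth, make_tube_tree, project_clean


# ---------------------------------------------------------------------------
# Independent brute-force FBP oracle (explicit per-pixel loops)
# ---------------------------------------------------------------------------

def fbp_oracle(sino_data, angles_deg):
    """Direct back-projection of discretely ramp-filtered rows.

    Same filter (band-limited Ram-Lak kernel) and linear interpolation as
    the implementation, but computed with explicit per-pixel loops and an
    independently written frequency response.
    """
    n_angles, n = sino_data.shape
    n_pad = max(64, int(2 ** np.ceil(np.log2(2 * n))))
    # band-limited ramp from its real-space kernel (textbook form)
    m = np.concatenate((np.arange(1, n_pad / 2 + 1, 2, dtype=int),
                        np.arange(n_pad / 2 - 1, 0, -2, dtype=int)))
    h = np.zeros(n_pad)
    h[0] = 0.25
    h[1::2] = -1.0 / (np.pi * m) ** 2
    resp = 2.0 * np.real(np.fft.fft(h))
    filtered = np.empty((n_angles, n))
    for i in range(n_angles):
        spec = np.fft.fft(sino_data[i], n=n_pad) * resp
        filtered[i] = np.real(np.fft.ifft(spec))[:n]
    c = (n - 1) / 2.0
    out = np.zeros((n, n))
    for iy in range(n):
        for ix in range(n):
            x, y = ix - c, iy - c
            acc = 0.0
            for i, ang in enumerate(angles_deg):
                th = np.deg2rad(ang)
                t = x * np.cos(th) + y * np.sin(th) + c
                k = int(np.floor(t))
                if 0 <= k < n - 1:
                    frac = t - k
                    acc += (1 - frac) * filtered[i, k] + frac * filtered[i, k + 1]
                elif k == n - 1 and t == k:
                    acc += filtered[i, k]
            out[iy, ix] = acc
    return out * np.pi / (2.0 * n_angles)


def centered_sinogram(tree, n_cols, angles=None):
    ps = project_clean(tree, n_cols, angles=angles)
    sino = assemble_sinogram(normalize(ps), 1)
    sino.axis_offset = 0.0
    return sino


class TestNormalize:
    def test_equal_intensity_gives_zero(self):
        from vesselct.phantom import VoxelPhantom, project

        flat_only = project(VoxelPhantom(np.zeros((3, 16, 16)), 9.0),
                            angles_deg=[0.0, 90.0])
        out = normalize(flat_only)
        np.testing.assert_allclose(out.images, 0.0, atol=1e-12)

    def test_log_definition(self):
        from vesselct.phantom import ProjectionSet
        flat = np.ones((2, 4))
        img = np.ones((1, 2, 4))
        img[0, 0, 1] = np.exp(-1.0)
        ps = ProjectionSet(img, [0.0], flat)
        out = normalize(ps)
        assert out.images[0, 0, 1] == pytest.approx(1.0)
        assert out.images[0, 0, 0] == pytest.approx(0.0)

    def test_cylinder_profile_matches_chord(self, cylinder_projections):
        out = normalize(cylinder_projections)
        x = (np.arange(128) - 63.5) * 9.0
        chord = 1e-3 * 2 * np.sqrt(np.maximum(180.0**2 - x**2, 0.0))
        rms = np.sqrt(np.mean((out.images[0, 1] - chord) ** 2))
        assert rms <= 0.02 * chord.max()

    def test_nonpositive_pixels_replaced_and_counted(self):
        from vesselct.phantom import ProjectionSet
        flat = np.ones((3, 5))
        img = np.full((1, 3, 5), 0.5)
        img[0, 1, 2] = 0.0
        ps = ProjectionSet(img, [0.0], flat)
        out = normalize(ps)
        assert np.isfinite(out.images).all()
        assert out.meta["n_nonpositive_replaced"] == 1
        # replaced by the smallest positive neighbour (0.5)
        assert out.images[0, 1, 2] == pytest.approx(-np.log(0.5))

    def test_double_normalization_rejected(self, cylinder_projections):
        out = normalize(cylinder_projections)
        with pytest.raises(ValueError, match="already normalized"):
            normalize(out)


class TestAssembleSinogram:
    def test_shape_and_roundtrip(self, cylinder_projections):
        norm = normalize(cylinder_projections)
        sino = assemble_sinogram(norm, 2)
        assert sino.data.shape == (180, 128)
        np.testing.assert_array_equal(sino.data, norm.images[:, 2, :])

    def test_constant_projections_give_constant_sinogram(self):
        from vesselct.phantom import ProjectionSet
        flat = np.ones((3, 8))
        ps = ProjectionSet(np.full((5, 3, 8), 0.5), np.arange(5.0), flat)
        sino = assemble_sinogram(normalize(ps), 1)
        assert np.allclose(sino.data, np.log(2.0))

    def test_out_of_range_row(self, cylinder_projections):
        norm = normalize(cylinder_projections)
        with pytest.raises(ValueError, match="outside detector rows"):
            assemble_sinogram(norm, 99)

    def test_unnormalized_rejected(self, cylinder_projections):
        with pytest.raises(ValueError, match="normalize"):
            assemble_sinogram(cylinder_projections, 0)


class TestEstimateAxis:
    @staticmethod
    def _asym_tree():
        segs = [
            VesselSegment([0, 0, 0], [0, 0, 900], 20 * 9.0, 0),
            VesselSegment([8 * 9.0, 3 * 9.0, 0], [8 * 9.0, 3 * 9.0, 900],
                          4 * 9.0, 0),
        ]
        return VesselTree(segs, contrast_per_um=1e-3)

    def test_centered_offset_zero(self):
        sino = assemble_sinogram(
            normalize(project_clean(self._asym_tree(), 96)), 1)
        assert abs(estimate_axis(sino)) <= 0.1

    @pytest.mark.parametrize("shift", [-5.0, -1.5, 0.0, 2.7, 3.0, 5.0])
    def test_induced_shift_recovered(self, shift):
        ps = project_clean(self._asym_tree(), 96, axis_offset_px=shift)
        sino = assemble_sinogram(normalize(ps), 1)
        est = estimate_axis(sino)
        assert abs(est - shift) <= 0.2
        assert sino.axis_offset == est

    def test_all_zero_sinogram_rejected(self):
        sino = Sinogram(np.zeros((180, 32)), np.arange(180.0))
        with pytest.raises(ValueError, match="no signal"):
            estimate_axis(sino)


class TestFbp:
    def test_zero_sinogram_gives_zero_slice(self):
        sino = Sinogram(np.zeros((180, 32)), np.arange(180.0))
        sino.axis_offset = 0.0
        assert not fbp(sino).any()

    def test_point_impulse_localized(self):
        tree = make_tube_tree(5.0, x_um=12 * 9.0, y_um=-7 * 9.0, contrast=0.1)
        sino = centered_sinogram(tree, 64)
        rec = fbp(sino)
        iy, ix = np.unravel_index(rec.argmax(), rec.shape)
        c = (64 - 1) / 2
        assert abs(ix - c - 12) <= 1.0
        assert abs(iy - c - (-7)) <= 1.0

    def test_cylinder_nrmse(self, cylinder_tree):
        sino = centered_sinogram(cylinder_tree, 128)
        rec = fbp(sino)
        truth = disk_truth(128, 20.0, value=1e-3 * 9.0)
        support = truth > 0
        nrmse = np.sqrt(np.mean((rec - truth)[support] ** 2)) / truth[support].mean()
        assert nrmse < 0.10

    def test_linearity(self, cylinder_tree):
        sino = centered_sinogram(cylinder_tree, 64)
        rec = fbp(sino)
        scaled = Sinogram(3.0 * sino.data, sino.angles_deg)
        scaled.axis_offset = 0.0
        assert np.abs(fbp(scaled) - 3.0 * rec).max() <= 1e-6 * np.abs(rec).max()

    def test_matches_bruteforce_oracle(self):
        """Vectorized FBP == direct filtered back-projection, 1e-6 relative."""
        tree = VesselTree(
            [VesselSegment([30, -40, 0], [30, -40, 900], 80.0, 0),
             VesselSegment([-90, 60, 0], [-90, 60, 900], 50.0, 0)],
            contrast_per_um=1e-3,
        )
        sino = centered_sinogram(tree, 64, angles=np.arange(0, 180, 4.0))
        rec = fbp(sino)
        oracle = fbp_oracle(sino.data, sino.angles_deg)
        rel = np.sqrt(np.mean((rec - oracle) ** 2)) / np.sqrt(np.mean(oracle**2))
        assert rel <= 1e-6

    def test_close_to_reference_iradon(self, cylinder_tree):
        """Sanity cross-check against an independent FBP implementation."""
        from skimage.transform import iradon

        sino = centered_sinogram(cylinder_tree, 128)
        rec = fbp(sino)
        ref = iradon(sino.data.T, theta=sino.angles_deg, filter_name="ramp",
                     circle=True, output_size=128)
        scale = 1e-3 * 9.0
        assert np.sqrt(np.mean((rec - ref) ** 2)) <= 0.15 * scale

    def test_fidelity_improves_with_angle_count(self):
        """Streak artifacts shrink as the angular sampling densifies."""
        tree = make_tube_tree(40 * 9.0, x_um=20 * 9.0, y_um=-10 * 9.0)
        truth = disk_truth(128, 40.0, cx_px=20, cy_px=-10, value=1e-3 * 9.0)
        denom = np.sqrt(np.mean(truth**2))
        errs = []
        for n_ang in (45, 90, 180):
            sino = centered_sinogram(tree, 128,
                                     angles=np.arange(0, 180, 180 / n_ang))
            rec = fbp(sino)
            errs.append(np.sqrt(np.mean((rec - truth) ** 2)) / denom)
        assert errs[0] > errs[1] > errs[2]

    def test_unknown_filter_rejected(self):
        sino = Sinogram(np.zeros((4, 8)), [0, 45, 90, 135])
        with pytest.raises(ValueError, match="ramlak"):
            fbp(sino, filter_name="butterworth")

    def test_axis_offset_applied(self, cylinder_tree):
        """Reconstruction with the estimated offset re-centres the object."""
        ps = project_clean(cylinder_tree, 96, axis_offset_px=4.0)
        sino = assemble_sinogram(normalize(ps), 1)
        estimate_axis(sino)
        rec = fbp(sino)
        truth = disk_truth(96, 20.0, value=1e-3 * 9.0)
        support = truth > 0
        nrmse = np.sqrt(np.mean((rec - truth)[support] ** 2)) / truth[support].mean()
        assert nrmse < 0.12


class TestEqualizeBackground:
    def test_shift_invariance(self, cylinder_tree):
        sino = centered_sinogram(cylinder_tree, 64)
        rec = fbp(sino)
        a, _ = equalize_background(rec)
        b, _ = equalize_background(rec + 0.3)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_constant_slice_warns_identity(self):
        with pytest.warns(UserWarning, match="constant slice"):
            out, _ = equalize_background(np.full((32, 32), 1.7))
        np.testing.assert_array_equal(out, np.full((32, 32), 1.7))

    def test_flat_field_invariance(self, cylinder_tree):
        """Two acquisitions with different beam profiles equalize alike."""
        recs = []
        for flat in (FlatFieldModel(),
                     FlatFieldModel(tilt_x=-0.08, curve_x=0.05, tilt_z=0.03)):
            ps = project_clean(cylinder_tree, 96, flat=flat)
            sino = assemble_sinogram(normalize(ps), 1)
            sino.axis_offset = 0.0
            rec, _ = equalize_background(fbp(sino))
            recs.append(rec)
        gray_range = np.ptp(recs[0])
        # compare background annulus means
        n = 96
        yy, xx = np.indices((n, n))
        r = np.hypot(yy - 47.5, xx - 47.5)
        annulus = (r > 30) & (r < 42)
        diff = abs(recs[0][annulus].mean() - recs[1][annulus].mean())
        assert diff <= 0.02 * gray_range


class TestReconstructVolume:
    def test_row_selection_and_provenance(self, cylinder_tree):
        ps = project_clean(cylinder_tree, 64, n_rows=6)
        vol = reconstruct_volume(ps, rows=[1, 4])
        assert vol.slices.shape == (2, 64, 64)
        assert vol.rows == [1, 4]
        assert "mode=absorption" in vol.provenance
        assert len(vol.timings_s) == 2

    def test_all_rows_by_default(self, cylinder_tree):
        ps = project_clean(cylinder_tree, 32, n_rows=5, angles=np.arange(0, 180, 6.0))
        vol = reconstruct_volume(ps)
        assert vol.slices.shape[0] == 5

    def test_lumens_brighter_than_background(self):
        """Vessel cross-sections reconstruct bright in >= 95% of lumen pixels."""
        from vesselct import BranchingSpec, build_vessel_tree, voxelize

        spec = BranchingSpec([180.0, 120.0, 80.0], lengths_um=[700, 500, 400],
                             branch_angle_deg=50.0)
        tree = build_vessel_tree(spec, seed=3, contrast_per_um=2e-3)
        n = 256
        lo, hi = tree.bounding_box()
        z_rows = 3
        z0 = 0.5 * (lo[2] + hi[2]) - z_rows / 2 * 9.0
        phantom = voxelize(
            tree, 9.0, (z_rows, n, n),
            origin=np.array([-(n - 1) / 2 * 9.0, -(n - 1) / 2 * 9.0, z0]),
        )
        from vesselct import project
        ps = project(tree, angles_deg=np.arange(180.0),
                     flat=np.ones((z_rows, n)), detector_shape=(z_rows, n),
                     z0_um=z0)
        vol = reconstruct_volume(ps, rows=[1])
        sl = vol.slices[0]
        lumen = phantom.grid[1] > 0
        assert lumen.sum() > 100
        frac = (sl[lumen] > vol.background_gray).mean()
        assert frac >= 0.95
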