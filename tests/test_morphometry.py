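import numpy as np
import pytest

from ntpipe import morphometry as mm
from ntpipe.optics import OpticsModel
from ntpipe.render import render_scene
from ntpipe.scene import CONTACT_CELL_CELL, CONTACT_SUBSTRATE, Tube, VolumeScene


class TestPathLength:
    @pytest.mark.parametrize(
        "points,expect",
        [
            ([[0, 0, 0], [14.85, 0, 0]], 14.85),
            ([[0, 0, 0], [1, 0, 0], [1, 1, 0]], 2.0),
        ],
    )
    def test_closed_form_polylines(self, points, expect):
        assert mm.path_length(np.asarray(points, float)) == pytest.approx(expect)

    def test_quarter_circle_matches_pi_r_over_2(self):
        theta = np.linspace(0, np.pi / 2, 100)
        pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)])
        assert mm.path_length(pts) == pytest.approx(np.pi * 10 / 2, rel=1e-3)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mm.path_length(np.array([[1.0, 2.0, 3.0]]))

    def test_rigid_motion_invariance(self):
        """Arc length is invariant under rotation + translation."""
        rng = np.random.default_rng(0)
        pts = rng.random((20, 3)) * 10
        ang = 0.7
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        moved = pts @ R.T + np.array([3.0, -2.0, 1.0])
        assert mm.path_length(moved) == pytest.approx(mm.path_length(pts), rel=1e-12)


class TestTracePath:
    def test_straight_tube_traced_within_one_voxel(self, straight_tube_volume):
        vol, a, b = straight_tube_volume
        path = mm.trace_path(vol, a, b)
        dev = np.hypot(path.points[:, 1] - a[1], path.points[:, 2] - a[2])
        assert np.sqrt(np.mean(dev**2)) < 0.105  # 1 lateral voxel RMS
        assert path.length_um == pytest.approx(10.0, rel=0.02)

    def test_coincident_seeds_rejected(self, straight_tube_volume):
        vol, a, _ = straight_tube_volume
        with pytest.raises(ValueError, match="zero-length"):
            mm.trace_path(vol, a, a)

    def test_no_ridge_raises(self, optics):
        scene = VolumeScene(
            tubes=[Tube(points=[[1, 1, 1], [4, 1, 1]], intensity=0.0)],
            bounds=((0, 5), (0, 2), (0, 2)),
        )
        vol = render_scene(scene, optics)
        with pytest.raises(ValueError, match="no ridge"):
            mm.trace_path(vol, [1, 1, 1], [4, 1, 1])

    def test_l_shaped_tube_length_within_2_percent(self, optics):
        corner = np.array([[1, 1, 1.25], [6, 1, 1.25], [6, 6, 1.25]], float)
        scene = VolumeScene(
            tubes=[Tube(points=corner, diameter_nm=100.0)],
            bounds=((0, 8), (0, 8), (0, 2.5)),
        )
        vol = render_scene(scene, optics)
        path = mm.trace_path(vol, corner[0], corner[-1])
        assert path.length_um == pytest.approx(10.0, rel=0.02)

    def test_rotated_tube_length_stable(self, optics):
        """Traced length of the same tube is rotation-invariant within 2%
        after re-rendering at another in-plane orientation."""
        lengths = {}
        for ang_deg in (0.0, 30.0):
            ang = np.radians(ang_deg)
            a = np.array([2.0, 2.0, 1.25])
            b = a + 8.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
            scene = VolumeScene(
                tubes=[Tube(points=np.stack([a, b]), diameter_nm=100.0)],
                bounds=((0, 12), (0, 8), (0, 2.5)),
            )
            vol = render_scene(scene, optics)
            lengths[ang_deg] = mm.trace_path(vol, a, b).length_um
        assert lengths[30.0] == pytest.approx(lengths[0.0], rel=0.02)


class TestTransverseProfileAndFit:
    def test_profile_unimodal_and_symmetric(self, straight_tube_volume):
        vol, a, b = straight_tube_volume
        path = mm.trace_path(vol, a, b)
        prof = mm.transverse_profile(vol, path, 5.0)
        y = prof.intensities
        assert y.argmax() == pytest.approx(len(y) // 2, abs=1)
        sym_err = np.abs(y - y[::-1]).max() / y.max()
        assert sym_err < 0.05

    def test_uniform_volume_gives_flat_profile_and_fit_rejection(self):
        from ntpipe.deskew import Volume

        vol = Volume(voxels=np.full((10, 20, 20), 3.0), spacing=(0.3, 0.105, 0.105))
        path = mm.NanotubePath(points=np.array([[0.3, 1.0, 1.5], [1.8, 1.0, 1.5]]))
        prof = mm.transverse_profile(vol, path, 0.7, half_width_um=0.6)
        assert np.allclose(prof.intensities, 3.0)
        with pytest.raises(ValueError, match="unimodal"):
            mm.fit_fwhm(prof)

    def test_station_outside_path_rejected(self, straight_tube_volume):
        vol, a, b = straight_tube_volume
        path = mm.NanotubePath(points=np.stack([a, b]))
        with pytest.raises(ValueError, match="station"):
            mm.transverse_profile(vol, path, 99.0)

    def test_gaussian_fwhm_closed_form(self):
        """A noise-free Gaussian profile with sigma = 195.36 nm fits to
        FWHM = 2.3548 * sigma = 460.0 nm."""
        x = np.arange(-1.5, 1.5, 0.105)
        prof = mm.TransverseProfile(0.0, x, np.exp(-0.5 * (x / 0.19536) ** 2))
        fit = mm.fit_fwhm(prof)
        assert fit.fwhm_nm == pytest.approx(460.0, abs=0.5)
        assert fit.r_squared > 0.999

    def test_constant_offset_does_not_change_fwhm(self):
        x = np.arange(-1.5, 1.5, 0.105)
        y = 5.0 * np.exp(-0.5 * (x / 0.2) ** 2)
        f0 = mm.fit_fwhm(mm.TransverseProfile(0.0, x, y)).fwhm_nm
        f1 = mm.fit_fwhm(mm.TransverseProfile(0.0, x, y + 100.0)).fwhm_nm
        assert f1 == pytest.approx(f0, rel=1e-6)

    def test_multi_peak_profile_rejected(self):
        x = np.arange(-1.5, 1.5, 0.105)
        y = np.exp(-0.5 * ((x - 0.6) / 0.15) ** 2) + np.exp(-0.5 * ((x + 0.6) / 0.15) ** 2)
        with pytest.raises(ValueError, match="unimodal"):
            mm.fit_fwhm(mm.TransverseProfile(0.0, x, y))

    def test_sub_resolution_tube_measures_psf_width(self, straight_tube_volume):
        """A 100 nm tube imaged at 460 nm PSF measures within 2% of the
        PSF-predicted width (the convolution limit)."""
        vol, a, b = straight_tube_volume
        path = mm.trace_path(vol, a, b)
        fit = mm.fit_fwhm(mm.transverse_profile(vol, path, 5.0))
        assert fit.fwhm_nm == pytest.approx(465.0, rel=0.02)


class TestContactAndSummary:
    def _path(self, za, zb):
        return mm.NanotubePath(points=np.array([[0, 0, za], [5, 0, zb]], float))

    def test_endpoint_on_substrate(self):
        assert mm.classify_contact(self._path(0.0, 4.0), substrate_z=0.0) == CONTACT_SUBSTRATE

    def test_both_endpoints_elevated(self):
        assert mm.classify_contact(self._path(5.0, 5.0), substrate_z=0.0) == CONTACT_CELL_CELL

    def test_boundary_is_inclusive(self):
        assert (
            mm.classify_contact(self._path(0.5, 4.0), substrate_z=0.0, z_tol_um=0.5)
            == CONTACT_SUBSTRATE
        )

    def test_summary_mean_and_sd(self):
        paths = [self._path(2, 2), self._path(2, 2)]
        paths[0].points[1, 0] = 10.0
        paths[1].points[1, 0] = 20.0
        s = mm.summarize(paths)
        assert s.length_mean_um == pytest.approx(15.0)
        assert s.length_sd_um == pytest.approx(7.0711, abs=1e-3)
        assert s.hist_counts.sum() == s.n_paths == 2

    def test_single_path_sd_missing(self):
        s = mm.summarize([self._path(2, 2)])
        assert s.length_sd_um is None and s.length_sem_um is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            mm.summarize([])

    def test_simulated_cohort_recovers_generator_mean(self):
        """Sample mean over 98 draws from the cultured-cell length
        distribution lies within 2 s.e.m. of the generator mean."""
        from ntpipe.pipeline import draw_tube_lengths

        rng = np.random.default_rng(42)
        lengths = draw_tube_lengths(14.85, 6.3, 98, rng)
        paths = []
        for L in lengths:
            p = self._path(2, 2)
            p.points[1, 0] = L
            paths.append(p)
        s = mm.summarize(paths)
        sem = 6.3 / np.sqrt(98)
        # truncation at zero lifts the true mean slightly above 14.85
        assert abs(s.length_mean_um - 15.01) < 2 * sem
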