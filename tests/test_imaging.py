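"""Illumination correction, localization, photometry, trace QC."""

import numpy as np
import pytest

from hexkin import imaging as im
from hexkin import synthetic as syn


def photon_movie(data, dt=0.15):
    return im.Movie(np.asarray(data, dtype=float), dt, "photons")


class TestIllumination:
    def test_flat_movie_gives_flat_profile(self):
        m = photon_movie(np.full((5, 40, 40), 7.0))
        prof = im.estimate_illumination(m)
        np.testing.assert_allclose(prof.profile, 7.0)

    def test_profile_tracks_true_shape(self):
        # the field must be large relative to the smoothing kernel, or the
        # reflective boundary flattens the estimate near the edges
        spec = syn.IlluminationSpec(sigma=120.0)
        true = spec.profile((256, 256))
        rng = np.random.default_rng(0)
        stack = 5.0 * true[None] + rng.normal(0, 0.5, (40, 256, 256))
        prof = im.estimate_illumination(photon_movie(stack))
        r = np.corrcoef(prof.profile.ravel(), true.ravel())[0, 1]
        assert r > 0.99

    def test_smoothing_reduces_variance(self):
        rng = np.random.default_rng(1)
        stack = 5.0 + rng.normal(0, 1.0, (20, 64, 64))
        prof = im.estimate_illumination(photon_movie(stack))
        assert prof.profile.var() <= stack.mean(axis=0).var()

    def test_nonpositive_profile_errors(self):
        m = photon_movie(np.full((3, 16, 16), -1.0))
        with pytest.raises(ValueError):
            im.estimate_illumination(m)


class TestCorrection:
    def test_unit_profile_is_identity(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(1, 10, (4, 16, 16))
        prof = im.IlluminationProfile(np.ones((16, 16)))
        phot, _ = im.correct_movie(photon_movie(data), prof, temporal_sigma=0)
        np.testing.assert_allclose(phot.data, data)

    def test_movie_equal_to_profile_flattens_to_one(self):
        prof_img = syn.IlluminationSpec(sigma=60.0).profile((48, 48))
        movie = photon_movie(np.repeat(prof_img[None], 4, axis=0))
        prof = im.IlluminationProfile(prof_img)
        phot, _ = im.correct_movie(movie, prof, temporal_sigma=0,
                                   renormalize=False)
        np.testing.assert_allclose(phot.data, 1.0)

    def test_center_and_corner_spots_equalized(self):
        # two identical spots under a Gaussian profile agree within 2%
        # after correction, using the fitted per-particle baselines
        spec = syn.IlluminationSpec(sigma=120.0)
        H = W = 256
        prof_true = spec.profile((H, W))
        spot_c = syn.psf_image((H, W), 128.0, 128.0, 200.0, 1.5)
        spot_e = syn.psf_image((H, W), 80.0, 80.0, 200.0, 1.5)
        rng = np.random.default_rng(4)
        frame = (5.0 + spot_c + spot_e) * prof_true
        stack = frame[None] + rng.normal(0, 0.1, (30, H, W))
        movie = photon_movie(stack)
        prof = im.estimate_illumination(movie)
        phot, det = im.correct_movie(movie, prof)
        locs = im.locate_particles(det)
        assert len(locs) == 2
        f = sorted(im.extract_trace(phot, p).photons.mean() for p in locs)
        assert (f[1] - f[0]) / f[1] < 0.02


class TestLocalization:
    def make_spot_movie(self, x, y, photons=400.0, n_frames=20, noise=0.05,
                        shape=(64, 64), extra=(), background=1.0):
        rng = np.random.default_rng(5)
        frame = np.full(shape, background)
        frame += syn.psf_image(shape, x, y, photons, 1.5)
        for (ex, ey, ep) in extra:
            frame += syn.psf_image(shape, ex, ey, ep, 1.5)
        stack = frame[None] + rng.normal(0, noise, (n_frames, *shape))
        return photon_movie(stack)

    def test_subpixel_accuracy_high_snr(self):
        m = self.make_spot_movie(20.3, 14.7)
        locs = im.locate_particles(m)
        assert len(locs) == 1
        assert abs(locs[0].x - 20.3) < 0.1
        assert abs(locs[0].y - 14.7) < 0.1

    def test_close_pair_merges_into_one_detection(self):
        m = self.make_spot_movie(30.0, 30.0, extra=[(34.0, 30.0, 400.0)])
        locs = im.locate_particles(m, separation=6)
        assert len(locs) <= 1

    def test_dim_spot_below_minmass_not_detected(self):
        # minmass = 0.4 * mean of the averaged movie: a 3-photon spot on a
        # 40-photon background integrates far below that
        m = self.make_spot_movie(30.0, 30.0, photons=3.0, background=40.0)
        locs = im.locate_particles(m)
        assert locs == []

    def test_no_candidates_returns_empty_list(self):
        m = photon_movie(np.full((5, 32, 32), 2.0))
        assert im.locate_particles(m) == []

    def test_localization_bias_small_on_brightness_ladder(self,
                                                          photometry_experiment):
        locations, _, truth, _ = photometry_experiment
        est = np.array([(p.x, p.y) for p in locations])
        from scipy.spatial.distance import cdist

        d = cdist(est, truth)
        nearest = d.min(axis=1)
        assert np.median(nearest) < 0.15
        matched = d.argmin(axis=1)
        bias = est - truth[matched]
        assert np.all(np.abs(bias.mean(axis=0)) < 0.05)


class TestPhotometry:
    def test_background_only_roi_near_zero(self):
        rng = np.random.default_rng(6)
        stack = 2.0 + rng.normal(0, 0.3, (200, 32, 32))
        p = im.ParticleLocation(x=16, y=16, amplitude=0.1, sigma_x=1.5,
                                sigma_y=1.5, baseline=2.0, mass=1.0,
                                roundness=1.0)
        tr = im.extract_trace(photon_movie(stack), p)
        se = tr.photons.std() / np.sqrt(len(tr.photons))
        assert abs(tr.photons.mean()) < 3 * se

    def test_mass_in_disk_matches_gaussian_closed_form(self):
        # 1000-photon spot, sigma 1.5 px, ROI radius 4.5 px:
        # enclosed mass 1000 * (1 - exp(-r^2 / 2 sigma^2)) ~ 989 photons
        frame = syn.psf_image((41, 41), 20.0, 20.0, 1000.0, 1.5)
        p = im.ParticleLocation(x=20, y=20, amplitude=1.0, sigma_x=1.5,
                                sigma_y=1.5, baseline=0.0, mass=1000.0,
                                roundness=1.0)
        tr = im.extract_trace(photon_movie(frame[None]), p)
        expected = 1000.0 * (1 - np.exp(-4.5**2 / (2 * 1.5**2)))
        assert tr.photons[0] == pytest.approx(expected, rel=0.005)

    def test_doubling_amplitude_doubles_signal(self):
        frame = syn.psf_image((41, 41), 20.0, 20.0, 500.0, 1.5) + 3.0
        frame2 = syn.psf_image((41, 41), 20.0, 20.0, 1000.0, 1.5) + 3.0
        p = im.ParticleLocation(x=20, y=20, amplitude=1.0, sigma_x=1.5,
                                sigma_y=1.5, baseline=3.0, mass=1.0,
                                roundness=1.0)
        f1 = im.extract_trace(photon_movie(frame[None]), p).photons[0]
        f2 = im.extract_trace(photon_movie(frame2[None]), p).photons[0]
        assert f2 == pytest.approx(2 * f1, rel=1e-9)

    def test_roi_uses_69_pixels(self):
        dy, dx = im.roi_mask(4.5)
        assert len(dy) == 69

    def test_clipped_roi_rejected(self):
        p = im.ParticleLocation(x=2, y=16, amplitude=1.0, sigma_x=1.5,
                                sigma_y=1.5, baseline=0.0, mass=1.0,
                                roundness=1.0)
        with pytest.raises(ValueError):
            im.extract_trace(photon_movie(np.zeros((3, 32, 32))), p)


def _trace(photons):
    p = im.ParticleLocation(x=16, y=16, amplitude=1.0, sigma_x=1.5,
                            sigma_y=1.5, baseline=0.0, mass=1.0, roundness=1.0)
    return im.PhotonTrace(particle=p, photons=np.asarray(photons, float))


class TestTraceQC:
    def test_aggregate_threshold_boundary(self):
        over = _trace(np.full(50, 100.0))
        over.photons[10] = 520.0
        under = _trace(np.full(50, 100.0))
        under.photons[10] = 499.0
        kept = im.qc_traces([over, under])
        assert len(kept) == 1
        assert kept[0].photons[10] == 499.0

    def test_fixture_with_planted_aggregates(self):
        rng = np.random.default_rng(7)
        traces = [_trace(46 + rng.normal(0, 14, 100)) for _ in range(7)]
        for _ in range(3):
            t = _trace(46 + rng.normal(0, 14, 100))
            t.photons[rng.integers(100)] = 600.0
            traces.append(t)
        assert len(im.qc_traces(traces)) == 7

    def test_optional_smoothing_applied(self):
        rng = np.random.default_rng(8)
        t = _trace(46 + rng.normal(0, 14, 200))
        sm, = im.qc_traces([t], smoothing_sigma=5.0)
        assert sm.photons.std() < t.photons.std()


class TestBleachBlinkQC:
    def test_dim_trace_bleached_in_first_block(self):
        rep = im.bleach_blink_qc([_trace(np.full(1200, 20.0))])
        assert bool(rep.iloc[0]["bleached"])
        assert rep.iloc[0]["first_bleached_block"] == 0

    def test_steady_monomer_clean(self):
        # bounded noise keeps every deviation under 3 SD by construction
        rng = np.random.default_rng(9)
        rep = im.bleach_blink_qc([_trace(46 + rng.uniform(-2, 2, 1200))])
        assert not rep.iloc[0]["bleached"]
        assert rep.iloc[0]["n_blink_frames_dark"] == 0
        assert rep.iloc[0]["n_blink_frames_abs"] == 0

    def test_planted_dark_excursion_flagged(self):
        rng = np.random.default_rng(10)
        x = 46 + rng.normal(0, 2.0, 1200)
        x[500:510] -= 60.0  # far beyond 3 sigma, negative
        rep = im.bleach_blink_qc([_trace(x)])
        flagged = set(rep.iloc[0]["blink_frames"])
        assert set(range(500, 510)) <= flagged
        assert len(flagged) <= 14  # a few extra tail frames at most

    def test_short_trace_flagged_not_fatal(self):
        rep = im.bleach_blink_qc([_trace(np.full(120, 46.0))])
        assert bool(rep.iloc[0]["short_trace"])
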