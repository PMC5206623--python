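"""Movie rendering, spot detection, channel registration, trace extraction."""

import math

import numpy as np
import pytest

import alexfret as af
from alexfret import extract as ex
from alexfret.render import Optics, psf_image, render_movie, sample_positions


@pytest.fixture(scope="module")
def rendered_scene():
    """20 molecules, noise-free traces rendered with camera noise + shifted channel."""
    cfg = af.preset("L662-N", seed=5, n_molecules=20, n_cycles=60,
                    background={"donor": 0.0, "acceptor": 0.0}, shot_noise=False,
                    bleach_tau_D=math.inf, bleach_tau_A=math.inf)
    traces = af.simulate_traces(cfg)
    optics = Optics(field=(128, 128), channel_shift=(1.5, -0.8),
                    background_per_px=2.0)
    pos = sample_positions(20, optics, np.random.default_rng(5), margin=12)
    donor, acceptor = render_movie(
        traces, pos, optics,
        camera=af.CameraModel(excess_noise=1.4, read_noise_sd=3.0), seed=5)
    return traces, pos, optics, donor, acceptor


class TestDemultiplex:
    @pytest.mark.parametrize("phase,first", [(0, 0), (1, 1)])
    def test_parity_split(self, phase, first):
        stack = np.arange(10)[:, None, None] * np.ones((1, 4, 4))
        dex, aex = ex.demultiplex_alex(stack, phase)
        assert list(dex[:, 0, 0]) == list(range(first, 10, 2))
        assert list(aex[:, 0, 0]) == list(range(1 - first, 10, 2))

    def test_odd_length(self):
        stack = np.zeros((9, 4, 4))
        dex, aex = ex.demultiplex_alex(stack, 0)
        assert len(dex) == 5 and len(aex) == 4

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            ex.demultiplex_alex(np.zeros((1, 4, 4)), 0)


class TestPsfRendering:
    def test_gaussian_mass_in_box(self):
        """Pixel sum over a 7x7 box matches the analytic Gaussian integral."""
        from scipy.special import erf
        img = psf_image(20.0, 20.0, 1000.0, 1.2, (64, 64))
        box = img[17:24, 17:24].sum()
        frac_1d = erf(3.5 / (1.2 * np.sqrt(2)))
        assert box == pytest.approx(1000.0 * frac_1d ** 2, rel=1e-6)

    def test_total_mass_conserved(self):
        img = psf_image(32.0, 30.5, 777.0, 1.2, (64, 64))
        assert img.sum() == pytest.approx(777.0, rel=1e-6)

    def test_zero_molecules_background_only(self):
        optics = Optics(field=(32, 32), background_per_px=5.0)
        donor, acc = render_movie([], np.zeros((0, 2)), optics,
                                  camera=af.CameraModel(excess_noise=1.0,
                                                        read_noise_sd=0.0),
                                  seed=0, n_cycles=5)
        assert donor.shape[1:] == (32, 32)
        assert abs(donor.mean() - 5.0) < 0.2

    def test_position_outside_field_raises(self):
        cfg = af.preset("H589-N", n_molecules=1, n_cycles=4, shot_noise=False)
        traces = af.simulate_traces(cfg)
        with pytest.raises(ValueError, match="outside field"):
            render_movie(traces, np.array([[200.0, 10.0]]), Optics(field=(64, 64)))


class TestDetectSpots:
    def test_all_spots_found_within_half_pixel(self, rendered_scene):
        traces, pos, optics, donor, _ = rendered_scene
        dex, _ = ex.demultiplex_alex(donor, 0)
        spots = ex.detect_spots(dex[:10].mean(axis=0))
        visible = [p for t, p in zip(traces, pos)
                   if t.truth.species != "acceptor_only"]
        assert len(spots) == len(visible)
        for p in visible:
            d = min(np.hypot(s.x - p[0], s.y - p[1]) for s in spots)
            assert d < 0.5

    def test_flat_image_returns_empty(self):
        assert ex.detect_spots(np.full((32, 32), 7.0)) == []

    def test_noise_only_false_positives_bounded(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 3, (128, 128))
        spots = ex.detect_spots(img, threshold=5.0)
        # 5-sigma threshold on ~16k pixels: expect << 1 Gaussian-tail hit
        assert len(spots) <= 2

    def test_detection_deterministic(self, rendered_scene):
        _, _, _, donor, _ = rendered_scene
        dex, _ = ex.demultiplex_alex(donor, 0)
        img = dex[:10].mean(axis=0)
        a = ex.detect_spots(img)
        b = ex.detect_spots(img)
        assert [(s.x, s.y) for s in a] == [(s.x, s.y) for s in b]


class TestRegistration:
    def _spots(self, pts, channel="donor"):
        return [ex.Spot(x=float(x), y=float(y), channel=channel, peak_intensity=1.0)
                for x, y in pts]

    def test_translation_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(10, 100, (12, 2))
        tf = ex.register_channels(self._spots(pts), self._spots(pts + [3.0, -2.0]))
        assert np.allclose(tf.b, [3.0, -2.0], atol=0.1)
        assert np.allclose(tf.A, np.eye(2), atol=1e-6)

    def test_identity_fixture(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(10, 100, (8, 2))
        tf = ex.register_channels(self._spots(pts), self._spots(pts))
        assert np.allclose(tf.A, np.eye(2), atol=1e-9)
        assert np.allclose(tf.b, 0.0, atol=1e-9)
        assert tf.residual_rms < 1e-9

    def test_small_rotation_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(10, 100, (15, 2))
        theta = np.deg2rad(0.5)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        ctr = pts.mean(axis=0)
        moved = (pts - ctr) @ R.T + ctr
        tf = ex.register_channels(self._spots(pts), self._spots(moved))
        angle = np.rad2deg(np.arctan2(tf.A[1, 0], tf.A[0, 0]))
        assert angle == pytest.approx(0.5, abs=0.05)

    def test_collinear_points_raise(self):
        pts = [(10.0, 10.0), (20.0, 20.0), (30.0, 30.0), (40.0, 40.0)]
        with pytest.raises(ValueError, match="collinear"):
            ex.register_channels(self._spots(pts), self._spots(pts))


class TestExtractTraces:
    def test_round_trip_recovers_intensities(self, rendered_scene):
        traces, pos, optics, donor, acceptor = rendered_scene
        dex_d, _ = ex.demultiplex_alex(donor, 0)
        dex_a, _ = ex.demultiplex_alex(acceptor, 0)
        dspots = ex.detect_spots(dex_d[:10].mean(axis=0), channel="donor")
        aspots = ex.detect_spots(dex_a[:10].mean(axis=0), channel="acceptor")
        tf = ex.register_channels(dspots, aspots)
        spos = np.array([[s.x, s.y] for s in dspots])
        etr, excl = ex.extract_traces(donor, acceptor, spos, tf,
                                      psf_sigma=optics.psf_sigma)
        assert len(etr) >= 10
        for t in etr:
            x, y = spos[t.molecule_id]
            i = int(np.argmin(((pos - [x, y]) ** 2).sum(1)))
            for got, want in [(t.F_DD_raw, traces[i].F_DD_raw),
                              (t.F_DA_raw, traces[i].F_DA_raw),
                              (t.F_AA_raw, traces[i].F_AA_raw)]:
                if want.mean() > 100:
                    assert got.mean() == pytest.approx(want.mean(), rel=0.05)

    def test_background_constant_invariance(self, rendered_scene):
        """Adding a constant to every pixel leaves extracted signals unchanged."""
        _, pos, _, donor, acceptor = rendered_scene
        spos = pos[:3]
        a, _ = ex.extract_traces(donor, acceptor, spos)
        b, _ = ex.extract_traces(donor + 123.0, acceptor + 123.0, spos)
        for ta, tb in zip(a, b):
            assert np.allclose(ta.F_DD_raw, tb.F_DD_raw, atol=1e-6)
            assert np.allclose(ta.F_AA_raw, tb.F_AA_raw, atol=1e-6)

    def test_close_pair_excluded(self):
        stack = np.zeros((10, 64, 64))
        pts = np.array([[30.0, 30.0], [33.0, 30.0], [50.0, 50.0]])
        traces, excl = ex.extract_traces(stack, stack, pts)
        assert excl == [0, 1]
        assert [t.molecule_id for t in traces] == [2]

    def test_edge_aperture_excluded(self):
        stack = np.zeros((10, 64, 64))
        traces, excl = ex.extract_traces(stack, stack, np.array([[3.0, 30.0]]))
        assert excl == [0] and traces == []

    def test_bad_annulus_raises(self):
        stack = np.zeros((10, 64, 64))
        with pytest.raises(ValueError, match="annulus"):
            ex.extract_traces(stack, stack, np.array([[30.0, 30.0]]),
                              aperture_radius=3.0, annulus=(2.0, 8.0))
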