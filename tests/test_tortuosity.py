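"""Spline fitting, curvature, arc length and the tortuosity index."""

import numpy as np
import pytest

import plusquant as pq
from conftest import rasterized_segment


def analytic_control_points(spec: pq.SyntheticVesselSpec, spacing: float = 10.0) -> np.ndarray:
    """Noise-free control points sampled from an analytic curve."""
    u = np.linspace(0, 1, 4000)
    pos, _, _ = spec.evaluate(u)
    d = np.hypot(*np.diff(pos, axis=0).T)
    s = np.concatenate([[0], np.cumsum(d)])
    idx = np.unique(np.searchsorted(s, np.arange(0, s[-1], spacing)))
    return pos[np.concatenate([idx, [len(pos) - 1]])]


def sinusoid_spec(amplitude, wavelength=120.0, length=400.0):
    return pq.SyntheticVesselSpec(
        "sinusoid",
        {
            "start": (100, 30),
            "orientation_deg": 90,
            "length": length,
            "amplitude": amplitude,
            "wavelength": wavelength,
        },
        width=9,
    )


class TestDownsample:
    def test_straight_path_spacing_arithmetic(self):
        coords = np.column_stack([np.full(101, 10), np.arange(101)])
        pts = pq.downsample_path(pq.CenterlinePath(coords), spacing=10)
        assert len(pts) == 11
        assert tuple(pts[0]) == (10, 0) and tuple(pts[-1]) == (10, 100)

    def test_oversized_spacing_shrinks_to_four_points(self):
        coords = np.column_stack([np.full(10, 5), np.arange(10)])
        pts = pq.downsample_path(pq.CenterlinePath(coords), spacing=100)
        assert len(pts) == 4

    def test_points_subset_of_input(self):
        _, path, _ = rasterized_segment(
            "sinusoid",
            {"start": (100, 30), "orientation_deg": 90, "length": 300, "amplitude": 8, "wavelength": 100},
            width=9,
        )
        pts = pq.downsample_path(path, 10)
        path_set = set(map(tuple, path.coords))
        assert all(tuple(p) in path_set for p in pts)


class TestFitSpline:
    def test_collinear_points_zero_curvature(self):
        pts = np.column_stack([np.arange(0, 200, 10.0), np.arange(0, 100, 5.0)])
        prof = pq.curvature_profile(pq.fit_spline(pts))
        assert prof.kappa.max() < 1e-6

    def test_circle_constant_curvature(self):
        # points every ~10 px on a circle of radius 50 -> kappa = 0.02 within 2%
        theta = np.arange(0, 1.5 * np.pi, 10.0 / 50.0)
        pts = np.column_stack([100 + 50 * np.cos(theta), 100 + 50 * np.sin(theta)])
        prof = pq.curvature_profile(pq.fit_spline(pts))
        t0, tn = prof.t[0], prof.t[-1]
        interior = (prof.t > t0 + 0.1 * (tn - t0)) & (prof.t < tn - 0.1 * (tn - t0))
        assert np.abs(prof.kappa[interior] - 0.02).max() < 0.02 * 0.02

    def test_interpolates_control_points(self):
        spec = sinusoid_spec(10)
        pts = analytic_control_points(spec)
        spline = pq.fit_spline(pts)
        recon = spline.evaluate(spline.t)
        assert np.abs(recon - pts).max() < 1e-9

    def test_duplicate_consecutive_points_rejected(self):
        pts = np.array([[0, 0], [1, 1], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(ValueError, match="duplicate"):
            pq.fit_spline(pts)


class TestCurvatureProfile:
    def test_straight_segment_zero(self):
        pts = np.column_stack([np.full(20, 7.0), np.arange(0, 200, 10.0)])
        prof = pq.curvature_profile(pq.fit_spline(pts))
        assert np.all(prof.kappa <= 1e-6)

    def test_sinusoid_matches_closed_form(self):
        # y = A sin(2 pi x / lambda): kappa has the closed form
        # A w^2 |sin(w x)| / (1 + A^2 w^2 cos^2(w x))^(3/2), w = 2 pi / lambda
        A, wavelength = 10.0, 100.0
        xs = np.arange(0, 401, 5.0)
        pts = np.column_stack([xs, A * np.sin(2 * np.pi * xs / wavelength)])
        spline = pq.fit_spline(pts)
        prof = pq.curvature_profile(spline, n_samples=300)
        x_of_t = spline.evaluate(prof.t)[:, 0]
        w = 2 * np.pi / wavelength
        closed = A * w**2 * np.abs(np.sin(w * x_of_t)) / (1 + A**2 * w**2 * np.cos(w * x_of_t) ** 2) ** 1.5
        interior = (x_of_t > 30) & (x_of_t < 370) & (closed > 0.25 * closed.max())
        rel = np.abs(prof.kappa[interior] - closed[interior]) / closed[interior]
        assert rel.max() < 0.05

    def test_kappa_nonnegative_everywhere(self):
        for amp in [0.0, 5.0, 20.0]:
            pts = analytic_control_points(sinusoid_spec(amp))
            prof = pq.curvature_profile(pq.fit_spline(pts))
            assert (prof.kappa >= 0).all()


class TestArcLength:
    def test_straight_segment(self):
        pts = np.column_stack([np.full(11, 3.0), np.arange(0, 101, 10.0)])
        assert pq.arc_length(pq.fit_spline(pts)) == pytest.approx(100.0, abs=0.5)

    def test_quarter_circle(self):
        theta = np.linspace(0, np.pi / 2, 15)
        pts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta)])
        assert pq.arc_length(pq.fit_spline(pts)) == pytest.approx(25 * np.pi, abs=1.0)

    def test_arc_at_least_chord(self):
        for amp in [0, 3, 8, 15]:
            pts = analytic_control_points(sinusoid_spec(amp))
            spline = pq.fit_spline(pts)
            chord = np.hypot(*(pts[-1] - pts[0]))
            assert pq.arc_length(spline) >= chord - 1e-6


class TestTortuosity:
    def test_perfectly_linear_segment_is_zero(self):
        # the defining limit of the squared-derivative-curvature index
        coords = np.column_stack([np.full(200, 50), np.arange(20, 220)])
        pts = pq.downsample_path(pq.CenterlinePath(coords), 10)
        T = pq.tortuosity(pq.fit_spline(pts)).T
        assert abs(T) < 1e-6

    def test_constant_curvature_arc_is_zero(self):
        theta = np.linspace(0, 1.5 * np.pi, 40)
        pts = np.column_stack([256 + 100 * np.cos(theta), 256 + 100 * np.sin(theta)])
        assert pq.tortuosity(pq.fit_spline(pts)).T < 1e-8

    def test_sinusoid_amplitudes_match_quadrature_oracle(self):
        # Eq-level check on clean analytic control points: the noise filter is
        # off because there is no rasterization noise to suppress
        Ts = {}
        for A in [5.0, 15.0]:
            spec = sinusoid_spec(A)
            spline = pq.fit_spline(analytic_control_points(spec))
            Ts[A] = pq.tortuosity(spline, savgol_window_px=0).T
            oracle = pq.curve_truth(spec).T
            assert Ts[A] == pytest.approx(oracle, rel=0.10)
        assert Ts[15.0] > Ts[5.0]

    def test_too_few_samples_rejected(self):
        pts = analytic_control_points(sinusoid_spec(5))
        with pytest.raises(ValueError, match="10"):
            pq.tortuosity(pq.fit_spline(pts), n_samples=8)

    def test_reversal_invariance(self):
        from scipy.ndimage import gaussian_filter

        mask, path, _ = rasterized_segment(
            "sinusoid",
            {"start": (100, 30), "orientation_deg": 90, "length": 400, "amplitude": 10, "wavelength": 120},
            width=9,
        )
        field = gaussian_filter(pq.mask_distance_transform(mask), 1.5)

        def estimate(p):
            pts = pq.refine_centerline(pq.downsample_path(p), field)
            return pq.tortuosity(pq.fit_spline(pts)).T

        fwd = estimate(path)
        rev = estimate(pq.CenterlinePath(path.coords[::-1]))
        assert rev == pytest.approx(fwd, rel=0.05)

    def test_rasterized_amplitude_ladder_monotone(self):
        # end-to-end through skeletonization: T strictly increases with the
        # generating amplitude, and mid/high amplitudes agree with the
        # analytic-curve quadrature oracle within the pixelation bound
        from scipy.ndimage import gaussian_filter

        Ts, truths = [], []
        for A in [2, 5, 10, 15, 20]:
            spec = sinusoid_spec(A)
            mask, truth = pq.rasterize_vessel(spec, (512, 512))
            paths = pq.extract_segments(pq.prune_spurs(pq.skeletonize_mask(mask)))
            field = gaussian_filter(pq.mask_distance_transform(mask), 1.5)
            pts = pq.refine_centerline(pq.downsample_path(paths[0]), field)
            Ts.append(pq.tortuosity(pq.fit_spline(pts)).T)
            truths.append(truth.T)
        assert all(a < b for a, b in zip(Ts, Ts[1:]))
        for T, truth_T in list(zip(Ts, truths))[1:]:  # A in {5, 10, 15, 20}
            assert T == pytest.approx(truth_T, rel=0.25)


class TestTortuosityFeatures:
    def _seg(self, sid, T, in_5dd=True):
        return pq.SegmentTortuosity(segment_id=sid, T=T, L_c=100.0, in_5dd=in_5dd)

    def _profile(self, kappas):
        return pq.CurvatureProfile(t=np.linspace(0, 99, len(kappas)), kappa=np.asarray(kappas))

    def test_top5_mean(self):
        segs = [self._seg(i, float(i + 1)) for i in range(7)]
        profs = [self._profile(np.full(20, 0.01))] * 7
        f1, _, _ = pq.tortuosity_features(segs, profs)
        assert f1 == pytest.approx(5.0)

    def test_five_identical_segments(self):
        segs = [self._seg(i, 3.25) for i in range(5)]
        profs = [self._profile(np.full(20, 0.01))] * 5
        f1, f2, _ = pq.tortuosity_features(segs, profs)
        assert f1 == pytest.approx(3.25)
        assert f2 == pytest.approx(3.25)

    def test_top_percent_curvature_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        kappas = rng.exponential(0.01, size=1000)
        segs = [self._seg(0, 1.0)]
        profs = [self._profile(kappas)]
        _, _, f3 = pq.tortuosity_features(segs, profs)
        assert f3 == pytest.approx(np.sort(kappas)[-10:].mean())

    def test_no_zone_segment_flags_f2_missing(self):
        segs = [self._seg(0, 1.0, in_5dd=False)]
        profs = [self._profile(np.full(20, 0.01))]
        _, f2, _ = pq.tortuosity_features(segs, profs)
        assert f2 is None

    def test_f3_at_least_mean_kappa(self):
        rng = np.random.default_rng(7)
        profs = [self._profile(rng.random(200) * 0.05) for _ in range(3)]
        segs = [self._seg(i, 1.0) for i in range(3)]
        _, _, f3 = pq.tortuosity_features(segs, profs)
        assert f3 >= np.concatenate([p.kappa for p in profs]).mean()
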