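"""Standardized-frame construction and coordinate transforms."""

import numpy as np
import pytest
from scipy import optimize

import laminagc as L
from laminagc.errors import DegenerateGeometryError, OrientationError
from laminagc.frame import image_to_polar, polar_to_image, standardize_landmarks

from conftest import make_bundle, random_bundles


def _bundle_from_lines(r3, t3, r4, t3p, t4=(1.0, 0.0)):
    from laminagc import BundleAnnotation, EllipseROI, Point2D

    def ell(p):
        return EllipseROI(center=Point2D(*p), major_axis=2.0, minor_axis=1.4,
                          major_angle=0.0)

    heels = {3: Point2D(*r3), 4: Point2D(*r4)}
    return BundleAnnotation(bundle_id="lines", heels=heels,
                            targets={"T3": ell(t3), "T3p": ell(t3p),
                                     "T4": ell(t4)})


class TestComputeCenter:
    def test_perpendicular_lines_meet_at_origin(self):
        b = _bundle_from_lines(r3=(0, 1), t3=(0, -1), r4=(1, 1), t3p=(-1, -1))
        c = L.compute_center(b)
        assert c.x == pytest.approx(0.0, abs=1e-12)
        assert c.y == pytest.approx(0.0, abs=1e-12)

    def test_parallel_lines_are_degenerate(self):
        b = _bundle_from_lines(r3=(0, 0), t3=(2, 0), r4=(0, 1), t3p=(2, 1))
        with pytest.raises(DegenerateGeometryError):
            L.compute_center(b)

    def test_matches_least_squares_oracle(self):
        """C minimizes the summed squared distance to both defining lines
        (numeric minimization as the independent oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            r3, t3, r4, t3p = rng.uniform(-10, 10, size=(4, 2))
            d1, d2 = t3 - r3, t3p - r4
            cross2 = lambda a, b: a[0] * b[1] - a[1] * b[0]
            n1 = np.linalg.norm(d1) * np.linalg.norm(d2)
            if n1 == 0 or abs(cross2(d1, d2)) / n1 < 1e-3:
                continue

            def cost(p):
                e1 = cross2(d1, p - r3) / np.linalg.norm(d1)
                e2 = cross2(d2, p - r4) / np.linalg.norm(d2)
                return e1 ** 2 + e2 ** 2

            res = optimize.minimize(cost, x0=(r3 + r4) / 2, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-20})
            c = L.compute_center(_bundle_from_lines(r3, t3, r4, t3p))
            assert np.linalg.norm(np.array([c.x, c.y]) - res.x) < 1e-5


class TestBuildFrame:
    def test_symmetric_toy_bundle(self):
        b = make_bundle(unit_length=7.0, wedge_t3_deg=15.0, wedge_t3p_deg=15.0)
        f = L.build_frame(b)
        assert f.unit_length == pytest.approx(7.0, abs=1e-9)
        assert f.wedge_t3 == pytest.approx(np.deg2rad(15), abs=1e-9)
        assert f.wedge_t3p == pytest.approx(np.deg2rad(15), abs=1e-9)

    def test_landmark_mapping_is_exact(self):
        rng = np.random.default_rng(7)
        for b in random_bundles(50, rng):
            f = L.build_frame(b)
            for label, theta in (("T3", 1.0), ("T4", 0.0), ("T3p", -1.0)):
                q = L.to_standard(b.targets[label].center, f)
                assert q.theta == pytest.approx(theta, abs=1e-9)
            assert L.to_standard(b.targets["T4"].center, f).r == pytest.approx(
                1.0, abs=1e-9)

    def test_mirror_invariance(self):
        b = make_bundle(wedge_t3_deg=14.0, wedge_t3p_deg=12.0, axis_deg=30)
        m = make_bundle(wedge_t3_deg=14.0, wedge_t3p_deg=12.0, axis_deg=30,
                        mirror=True)
        fb, fm = L.build_frame(b), L.build_frame(m)
        assert fb.chirality == -fm.chirality
        for label in ("T3", "T4", "T3p"):
            qb = L.to_standard(b.targets[label].center, fb)
            qm = L.to_standard(m.targets[label].center, fm)
            assert qb.r == pytest.approx(qm.r, abs=1e-9)
            assert qb.theta == pytest.approx(qm.theta, abs=1e-9)

    def test_similarity_invariance(self):
        """Global translation+rotation+uniform scaling leaves (r, theta) of
        any probe point unchanged."""
        rng = np.random.default_rng(3)
        b = make_bundle(wedge_t3_deg=16.0, wedge_t3p_deg=11.0)
        f = L.build_frame(b)
        probe = np.array([3.0, -2.0])
        q0 = image_to_polar(probe, f)
        for _ in range(20):
            s = rng.uniform(0.3, 3.0)
            ang = rng.uniform(0, 2 * np.pi)
            t = rng.uniform(-30, 30, 2)
            R = np.array([[np.cos(ang), -np.sin(ang)],
                          [np.sin(ang), np.cos(ang)]])

            def xf(p):
                return tuple(s * (R @ np.asarray(p)) + t)

            from laminagc import BundleAnnotation, EllipseROI, Point2D
            b2 = BundleAnnotation(
                bundle_id="sim",
                heels={i: Point2D(*xf(p)) for i, p in b.heels.items()},
                targets={k: EllipseROI(center=Point2D(*xf(e.center)),
                                       major_axis=s * e.major_axis,
                                       minor_axis=s * e.minor_axis,
                                       major_angle=e.major_angle)
                         for k, e in b.targets.items()})
            f2 = L.build_frame(b2)
            q1 = image_to_polar(s * (R @ probe) + t, f2)
            assert np.allclose(q0, q1, atol=1e-9)

    def test_targets_same_side_is_orientation_error(self):
        b = make_bundle()
        b.targets["T3p"] = b.targets["T3"]
        with pytest.raises(OrientationError):
            L.build_frame(b)


class TestTransforms:
    def test_t4_maps_to_unit_zero(self, symmetric_bundle):
        f = L.build_frame(symmetric_bundle)
        q = L.to_standard(symmetric_bundle.targets["T4"].center, f)
        assert (q.r, q.theta) == pytest.approx((1.0, 0.0), abs=1e-9)

    def test_wedge_bisector_point(self):
        """A point on the bisector of the (T3, C, T4) wedge at distance
        2*|C-T4| has standardized coordinates (2, 0.5) by explicit angle
        arithmetic."""
        b = make_bundle(unit_length=7.0, wedge_t3_deg=16.0, axis_deg=25.0)
        f = L.build_frame(b)
        ang = np.deg2rad(25.0 + 8.0)  # axis + half the T3 wedge
        p = L.Point2D(14.0 * np.cos(ang), 14.0 * np.sin(ang))
        q = L.to_standard(p, f)
        assert q.r == pytest.approx(2.0, abs=1e-9)
        assert q.theta == pytest.approx(0.5, abs=1e-9)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(11)
        for b in random_bundles(20, rng):
            f = L.build_frame(b)
            r = rng.uniform(0.0, 3.8, 50)
            th = rng.uniform(-3.0, 3.0, 50)
            xy = polar_to_image(r, th, f)
            r2, th2 = image_to_polar(xy, f)
            assert np.allclose(r, r2, atol=1e-9)
            # theta of r=0 points is defined as 0
            keep = r > 1e-12
            assert np.allclose(th[keep], th2[keep], atol=1e-9)

    def test_center_maps_to_origin_and_back(self, symmetric_bundle):
        f = L.build_frame(symmetric_bundle)
        q = L.to_standard(f.center, f)
        assert q.r == 0.0 and q.theta == 0.0
        p = L.from_standard(L.StandardPolarPoint(0.0, 1.7), f)
        assert np.allclose([p.x, p.y], [f.center.x, f.center.y], atol=1e-12)


class TestAlignment:
    def test_t4_lands_on_x_axis(self, symmetric_bundle):
        f = L.build_frame(symmetric_bundle)
        t = L.align_raw(symmetric_bundle, f).set_index("label")
        assert t.loc["T4", "x"] == pytest.approx(f.unit_length, abs=1e-9)
        assert t.loc["T4", "y"] == pytest.approx(0.0, abs=1e-9)
        assert t.loc["T3", "y"] > 0  # chirality convention

    def test_zero_noise_lattice_aligns_identically(self, noise_free_config):
        truth, anns = L.simulate_lattice(noise_free_config, seed=5)
        tables = [L.align_raw(a).set_index("label")[["x", "y"]] for a in anns]
        for t in tables[1:]:
            assert np.allclose(t.to_numpy(), tables[0].to_numpy(), atol=1e-9)

    def test_centroid_error_shrinks_with_sample_size(self):
        """Monte-Carlo: centroids of noisy aligned landmarks approach the
        noise-free template as n grows."""
        import dataclasses
        base = L.SyntheticConfig(n_bundles=150, warp_amplitude=0.0,
                                 c_t4_sd_um=0.0, wedge_t3_sd_deg=0.0,
                                 wedge_t3p_sd_deg=0.0, orientation_sd_deg=0.0,
                                 landmark_noise_sd=0.3)
        clean = dataclasses.replace(base, n_bundles=1, landmark_noise_sd=0.0)
        _, ref_ann = L.simulate_lattice(clean, seed=0)
        ref = L.align_raw(ref_ann[0]).set_index("label")[["x", "y"]]
        _, anns = L.simulate_lattice(base, seed=1)

        def centroid_err(subset):
            c = L.centroid_summary(subset, space="raw_aligned")
            c = c.set_index("label")[["x_mean", "y_mean"]]
            common = ref.index.intersection(c.index)
            return np.abs(c.loc[common].to_numpy()
                          - ref.loc[common].to_numpy()).mean()

        assert centroid_err(anns[:150]) < centroid_err(anns[:10])

    def test_single_bundle_centroid_is_itself(self, symmetric_bundle):
        c = L.centroid_summary([symmetric_bundle], space="raw_aligned")
        t = L.align_raw(symmetric_bundle)
        merged = c.merge(t, on="label")
        assert np.allclose(merged["x_mean"], merged["x"], atol=1e-9)
        assert np.allclose(merged["y_mean"], merged["y"], atol=1e-9)

    def test_standardized_t3_centroid_has_unit_angle(self):
        rng = np.random.default_rng(13)
        bundles = random_bundles(10, rng)
        c = L.centroid_summary(bundles, space="standardized")
        t3 = c[c.label == "T3"]
        assert np.allclose(t3["theta_mean"], 1.0, atol=1e-9)
        # per-bundle theta(T3) is exactly +1, so the variance is zero
        thetas = [standardize_landmarks(b).set_index("label").loc["T3", "theta"]
                  for b in bundles]
        assert np.std(thetas) < 1e-12
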