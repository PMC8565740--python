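"""Shared fixtures: hand-built bundle geometries independent of the
package's own frame code, and small synthetic configurations."""

import numpy as np
import pytest

from laminagc import BundleAnnotation, EllipseROI, Point2D, SyntheticConfig
from laminagc.synthetic import RenderConfig


def make_bundle(unit_length=7.0, wedge_t3_deg=15.0, wedge_t3p_deg=15.0,
                center=(0.0, 0.0), axis_deg=0.0, mirror=False,
                t3_radius=None, t3p_radius=None, heel_dist=2.0,
                bundle_id="b0", **extra) -> BundleAnnotation:
    """Construct a bundle directly from the frame's defining geometry.

    Places C at ``center`` with C->T4 along ``axis_deg``; T3 sits at
    +wedge_t3 and T3' at -wedge_t3p from the axis (flipped when ``mirror``),
    and the R3/R4 heels sit on the lines (T3, C) and (T3', C) beyond C, which
    is what makes C the intersection of those lines.
    """
    c = np.asarray(center, dtype=float)
    a = np.deg2rad(axis_deg)
    sign = -1.0 if mirror else 1.0

    def at(angle_deg, radius):
        ang = a + sign * np.deg2rad(angle_deg)
        return c + radius * np.array([np.cos(ang), np.sin(ang)])

    t3_radius = t3_radius if t3_radius is not None else 1.05 * unit_length
    t3p_radius = t3p_radius if t3p_radius is not None else 1.02 * unit_length
    t4 = at(0.0, unit_length)
    t3 = at(wedge_t3_deg, t3_radius)
    t3p = at(-wedge_t3p_deg, t3p_radius)
    r3 = at(wedge_t3_deg, -heel_dist)      # beyond C on the T3 line
    r4 = at(-wedge_t3p_deg, -heel_dist)    # beyond C on the T3' line
    r2 = r3 + np.array([-1.2, -1.6])
    r5 = r4 + np.array([-1.2, 1.6])
    r1 = r2 + np.array([-1.6, -1.0])
    r6 = r5 + np.array([-1.6, 1.0])

    def ell(p):
        return EllipseROI(center=Point2D(*p), major_axis=2.0,
                          minor_axis=1.4, major_angle=0.0)

    return BundleAnnotation(
        bundle_id=bundle_id,
        heels={i: Point2D(*p) for i, p in
               zip(range(1, 7), (r1, r2, r3, r4, r5, r6))},
        targets={"T3": ell(t3), "T4": ell(t4), "T3p": ell(t3p)},
        **extra,
    )


@pytest.fixture
def symmetric_bundle():
    """Wedges both 15 deg, |C-T4| = 7 um."""
    return make_bundle()


@pytest.fixture
def quiet_render():
    """Noise-free rendering parameters."""
    return RenderConfig(photon_scale=None, read_noise_sd=0.0)


@pytest.fixture
def noise_free_config(quiet_render):
    """All geometric and kinetic variability switched off."""
    return SyntheticConfig(
        n_bundles=4, warp_amplitude=0.0, landmark_noise_sd=0.0,
        c_t4_sd_um=0.0, wedge_t3_sd_deg=0.0, wedge_t3p_sd_deg=0.0,
        orientation_sd_deg=0.0, angle_noise_sd=0.0, length_noise_sd=0.0,
        render=quiet_render)


def random_bundles(n, rng, **overrides):
    """Random non-degenerate bundles via the test-local constructor."""
    out = []
    for k in range(n):
        out.append(make_bundle(
            unit_length=rng.uniform(4.0, 10.0),
            wedge_t3_deg=rng.uniform(8.0, 30.0),
            wedge_t3p_deg=rng.uniform(8.0, 30.0),
            center=rng.uniform(-50, 50, size=2),
            axis_deg=rng.uniform(0, 360),
            mirror=bool(rng.integers(2)),
            bundle_id=f"r{k}",
            **overrides,
        ))
    return out
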