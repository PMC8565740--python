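"""Bundle-local standardized polar coordinates.

Each lamina bundle defines its own frame from five landmarks: the R3 and R4
heel points and the centres of the target ellipses T3, T4 and T3'.  The frame
centre C is the intersection of line(R3 heel, T3 centre) with
line(R4 heel, T3' centre).  Radii are expressed in units of |C-T4| and angles
in "wedge units": the angular coordinate is scaled separately on each side of
the C->T4 axis so that T3 sits at theta = +1 and T3' at theta = -1.  The map
is therefore piecewise linear in angle with a slope break at theta = 0 (the
two wedges generally differ: about 14.8 deg on the T3 side and 13.3 deg on the
T3' side in wild type); beyond +-1 each side's scale extends linearly.

A per-bundle chirality sign makes the frame mirror-invariant: reflected
specimens produce identical (r, theta) without any preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotations import BundleAnnotation, Point2D
from .errors import DegenerateGeometryError, OrientationError

#: Below this sine of the inter-line angle the two defining lines are treated
#: as parallel and the bundle is rejected.
PARALLEL_SIN_TOL = 1e-6


class StandardPolarPoint(NamedTuple):
    """Radius in units of |C-T4|; angle in wedge units (+1 at T3, -1 at T3')."""

    r: float
    theta: float


@dataclass(frozen=True)
class StandardFrame:
    """A bundle's standardized frame.

    ``axis_angle`` is the direction of C->T4 in image coordinates (radians,
    atan2 convention on y-down axes).  ``chirality`` is +1 when rotating from
    C->T4 toward C->T3 is in the positive atan2 sense of the image axes, -1
    otherwise; it is applied so that theta(T3) = +1 for every bundle.
    """

    center: Point2D
    unit_length: float
    wedge_t3: float
    wedge_t3p: float
    axis_angle: float
    chirality: int
    bundle_id: str = ""


def _cross(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def compute_center(bundle: BundleAnnotation) -> Point2D:
    """Intersection of line(R3 heel, T3 centre) and line(R4 heel, T3' centre),
    solved as a 2x2 linear system."""
    bundle.require(heels=(3, 4), targets=("T3", "T3p"))
    p1 = bundle.heels[3].asarray()
    d1 = bundle.targets["T3"].center.asarray() - p1
    p2 = bundle.heels[4].asarray()
    d2 = bundle.targets["T3p"].center.asarray() - p2
    n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        raise DegenerateGeometryError(
            f"bundle {bundle.bundle_id}: heel coincides with its target centre",
            bundle_id=bundle.bundle_id)
    sin_angle = abs(_cross(d1 / n1, d2 / n2))
    if sin_angle < PARALLEL_SIN_TOL:
        raise DegenerateGeometryError(
            f"bundle {bundle.bundle_id}: defining lines are (near-)parallel "
            f"(|sin| = {sin_angle:.2e})", bundle_id=bundle.bundle_id)
    # p1 + t*d1 = p2 + s*d2
    A = np.column_stack([d1, -d2])
    t, _ = np.linalg.solve(A, p2 - p1)
    c = p1 + t * d1
    return Point2D(float(c[0]), float(c[1]))


def _signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle from u to v in the atan2 sense of the raw axes."""
    return float(np.arctan2(_cross(u, v), float(u @ v)))


def build_frame(bundle: BundleAnnotation) -> StandardFrame:
    """Construct the standardized frame from a bundle's landmarks.

    Wedge angles are measured at C between the C->T4 axis and the target
    ellipse centres (the centres, not boundary points, anchor all geometry).
    """
    bundle.require(heels=(3, 4), targets=("T3", "T4", "T3p"))
    c = compute_center(bundle).asarray()
    t4 = bundle.targets["T4"].center.asarray() - c
    unit_length = float(np.linalg.norm(t4))
    if unit_length < 1e-6:
        raise DegenerateGeometryError(
            f"bundle {bundle.bundle_id}: |C-T4| = {unit_length:.2e} um is "
            f"degenerate", bundle_id=bundle.bundle_id)
    u = t4 / unit_length
    t3 = bundle.targets["T3"].center.asarray() - c
    t3p = bundle.targets["T3p"].center.asarray() - c
    a3 = _signed_angle(u, t3)
    a3p = _signed_angle(u, t3p)
    if a3 == 0.0 or a3p == 0.0 or np.sign(a3) == np.sign(a3p):
        raise OrientationError(
            f"bundle {bundle.bundle_id}: T3 and T3' do not straddle the "
            f"C->T4 axis")
    chirality = 1 if a3 > 0 else -1
    return StandardFrame(
        center=Point2D(float(c[0]), float(c[1])),
        unit_length=unit_length,
        wedge_t3=abs(a3),
        wedge_t3p=abs(a3p),
        axis_angle=float(np.arctan2(u[1], u[0])),
        chirality=chirality,
        bundle_id=bundle.bundle_id,
    )


def image_to_polar(points: np.ndarray, frame: StandardFrame
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized image->standardized transform.

    Parameters
    ----------
    points : (..., 2) array of image coordinates in micrometres.

    Returns
    -------
    (r, theta) arrays.  Points exactly at C map to (0, 0).
    """
    pts = np.asarray(points, dtype=float)
    d = pts - frame.center.asarray()
    r = np.linalg.norm(d, axis=-1) / frame.unit_length
    phi_img = np.arctan2(d[..., 1], d[..., 0]) - frame.axis_angle
    phi = frame.chirality * (np.mod(phi_img + np.pi, 2 * np.pi) - np.pi)
    theta = np.where(phi >= 0, phi / frame.wedge_t3, phi / frame.wedge_t3p)
    theta = np.where(r == 0, 0.0, theta)
    return r, theta


def polar_to_image(r: np.ndarray, theta: np.ndarray, frame: StandardFrame
                   ) -> np.ndarray:
    """Inverse of :func:`image_to_polar`; returns (..., 2) image um."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.where(theta >= 0, theta * frame.wedge_t3, theta * frame.wedge_t3p)
    ang = frame.axis_angle + frame.chirality * phi
    xy = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return frame.center.asarray() + (r * frame.unit_length)[..., None] * xy


def to_standard(p: Point2D, frame: StandardFrame) -> StandardPolarPoint:
    """Map one image point into the standardized polar frame."""
    r, theta = image_to_polar(np.asarray(p, dtype=float), frame)
    return StandardPolarPoint(float(r), float(theta))


def from_standard(q: StandardPolarPoint, frame: StandardFrame) -> Point2D:
    """Map a standardized polar point back to image micrometres."""
    xy = polar_to_image(np.array(q.r), np.array(q.theta), frame)
    return Point2D(float(xy[0]), float(xy[1]))


def _landmarks(bundle: BundleAnnotation) -> dict[str, np.ndarray]:
    out = {f"R{i}": p.asarray() for i, p in sorted(bundle.heels.items())}
    out.update({lbl: e.center.asarray() for lbl, e in sorted(bundle.targets.items())})
    return out


def align_raw(bundle: BundleAnnotation, frame: StandardFrame | None = None
              ) -> pd.DataFrame:
    """Rigidly align a bundle's raw landmarks: C to the origin, C->T4 along
    +x, and the chirality flip applied so T3 has positive y.

    Returns a table with columns ``label, x, y`` (micrometres).
    """
    if frame is None:
        frame = build_frame(bundle)
    ca, sa = np.cos(-frame.axis_angle), np.sin(-frame.axis_angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    rows = []
    for label, p in _landmarks(bundle).items():
        q = rot @ (p - frame.center.asarray())
        rows.append({"label": label, "x": q[0], "y": frame.chirality * q[1]})
    df = pd.DataFrame(rows)
    df.insert(0, "bundle_id", bundle.bundle_id)
    df.insert(0, "specimen_id", bundle.specimen_id)
    return df


def standardize_landmarks(bundle: BundleAnnotation,
                          frame: StandardFrame | None = None) -> pd.DataFrame:
    """Landmark table in standardized coordinates (columns ``label, r, theta``)."""
    if frame is None:
        frame = build_frame(bundle)
    rows = []
    for label, p in _landmarks(bundle).items():
        r, theta = image_to_polar(p, frame)
        rows.append({"label": label, "r": float(r), "theta": float(theta)})
    df = pd.DataFrame(rows)
    df.insert(0, "bundle_id", bundle.bundle_id)
    df.insert(0, "specimen_id", bundle.specimen_id)
    return df


def centroid_summary(bundles: Iterable[BundleAnnotation],
                     space: str = "raw_aligned",
                     group_by: str = "specimen_id") -> pd.DataFrame:
    """Per-landmark centroids across bundles, grouped by specimen or time.

    ``space`` is ``raw_aligned`` (mean x/y of rigidly aligned landmarks, um)
    or ``standardized`` (mean r/theta).  Empty groups are simply absent.
    """
    if space not in ("raw_aligned", "standardized"):
        raise ValueError(f"unknown space {space!r}")
    tables = []
    for b in bundles:
        try:
            frame = build_frame(b)
        except (DegenerateGeometryError, OrientationError) as exc:
            import warnings

            warnings.warn(f"centroid_summary: skipping bundle: {exc}", stacklevel=2)
            continue
        t = (align_raw(b, frame) if space == "raw_aligned"
             else standardize_landmarks(b, frame))
        t["time_hrs_apf"] = b.time_hrs_apf
        tables.append(t)
    if not tables:
        return pd.DataFrame()
    full = pd.concat(tables, ignore_index=True)
    value_cols = ["x", "y"] if space == "raw_aligned" else ["r", "theta"]
    out = (full.groupby([group_by, "label"], sort=True)[value_cols]
           .agg(["mean", "count"]))
    out.columns = [f"{c}_{s}" if s == "mean" else "n"
                   for c, s in out.columns]
    out = out.loc[:, ~out.columns.duplicated()]
    return out.reset_index()
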