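"""Growth-cone morphometry on standardized density maps.

A growth cone's "front" is read off its density map: the map is binarized at a
fraction of its 99.5th-percentile intensity, each theta-column's maximal
suprathreshold radius forms an extent profile, and

* ``rel_length`` is the largest extent (the longest leading filopodium);
* ``rel_angle`` is the intensity-weighted mean theta of suprathreshold nodes
  in the leading edge (radius >= 80% of ``rel_length``), except for split
  morphology — two or more extent peaks reaching >= 90% of the maximum,
  separated by at least ``min_peak_separation`` wedge units — where the angle
  is the mean of the peak angles.

Because the threshold is relative, detection is invariant to overall intensity
scaling.  Growth cones sitting in regions too dense to isolate a front are
flagged ambiguous (by the fraction of suprathreshold columns within
theta in [-1.5, 1.5]) and excluded from statistics downstream.

Cell-type labels follow the reporter logic: R4 membranes carry strong GFP,
so a front is labelled R4 when its GFP intensity is at least half the RFP
intensity in the same neighbourhood, and R3 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .annotations import EllipseROI
from .density import DensityMap
from .errors import EmptyFrontError
from .frame import StandardFrame, image_to_polar

DEFAULT_THRESHOLD_FRACTION = 0.2
DEFAULT_MIN_PEAK_SEPARATION = 0.3  # wedge units
LEADING_EDGE_FRACTION = 0.8
PEAK_QUALIFY_FRACTION = 0.9
DENSE_COLUMN_FRACTION = 0.6
STRONG_GFP_RATIO = 0.5


@dataclass
class FrontEstimate:
    """Front of one growth cone in standardized units."""

    rel_length: float
    rel_angle: float
    peak_angles: list[float] = field(default_factory=list)
    split: bool = False
    ambiguous: bool = False


@dataclass
class GrowthConeMeasurement:
    """One cell's measured front plus identifying labels.

    ``position`` is the heel position within the bundle (3 or 4);
    ``cell_type`` is the reporter-derived identity (may differ from position
    in fate-transformed bundles).
    """

    bundle_id: str
    specimen_id: str
    position: int
    cell_type: str
    genotype: str
    time_hrs_apf: float
    front: FrontEstimate

    @property
    def flags(self) -> str:
        parts = []
        if self.front.split:
            parts.append("split")
        if self.front.ambiguous:
            parts.append("ambiguous")
        return "|".join(parts)


def _suprathreshold(dm: DensityMap, threshold_fraction: float
                    ) -> tuple[np.ndarray, float]:
    vals = np.where(dm.mask, 0.0, dm.values)
    ref = np.percentile(vals[~dm.mask], 99.5) if (~dm.mask).any() else 0.0
    threshold = threshold_fraction * ref
    supra = (vals >= threshold) & (vals > 0)
    return supra, threshold


def _extent_profile(supra: np.ndarray, r_values: np.ndarray) -> np.ndarray:
    """Per-theta-column maximal suprathreshold radius (0 where empty)."""
    any_col = supra.any(axis=0)
    # highest suprathreshold row index per column
    idx = supra.shape[0] - 1 - np.argmax(supra[::-1], axis=0)
    return np.where(any_col, r_values[idx], 0.0)


def _weighted_mean_angle(dm: DensityMap, weights: np.ndarray,
                         cols: slice = slice(None)) -> float:
    """Intensity-weighted mean angle of the weighted nodes, in wedge units.

    When the map carries its frame's wedge scale factors the averaging is
    done in physical angle (with per-column angular widths as additional
    weights) and converted back; otherwise a wedge-unit mean is taken.
    Averaging raw wedge units would bias the angle toward the narrow-wedge
    side whenever the two wedges differ, since a Cartesian-symmetric blob
    subtends more wedge units there.
    """
    theta = dm.grid.theta_values[cols]
    if dm.wedge_t3 is None or dm.wedge_t3p is None:
        return float((weights * theta[None, :]).sum() / weights.sum())
    scale = np.where(theta >= 0, dm.wedge_t3, dm.wedge_t3p)
    phi = theta * scale
    w = weights * scale[None, :]
    mean_phi = float((w * phi[None, :]).sum() / w.sum())
    return mean_phi / (dm.wedge_t3 if mean_phi >= 0 else dm.wedge_t3p)


def detect_front(dm: DensityMap,
                 threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                 min_peak_separation: float = DEFAULT_MIN_PEAK_SEPARATION,
                 ) -> FrontEstimate:
    """Estimate front length and angle from one density map."""
    supra, _ = _suprathreshold(dm, threshold_fraction)
    if not supra.any():
        raise EmptyFrontError(f"bundle {dm.bundle_id} ({dm.channel}): no "
                              f"suprathreshold node")
    r_values = dm.grid.r_values
    theta_values = dm.grid.theta_values
    extent = _extent_profile(supra, r_values)
    rel_length = float(extent.max())

    peaks = _find_extent_peaks(extent, dm.grid.theta_step, min_peak_separation)
    qualified = [p for p in peaks if extent[p] >= PEAK_QUALIFY_FRACTION * rel_length]
    peak_angles = [float(theta_values[p]) for p in qualified]

    if len(qualified) >= 2:
        split = True
        rel_angle = float(np.mean(peak_angles))
    else:
        # leading edge = suprathreshold nodes in the outer 20% of the
        # growth cone, restricted to the angular neighbourhood of the
        # dominant extent peak so the shaft of an oblique cone (which
        # crosses the radial band at unrelated angles) cannot drag the mean
        split = False
        peak_col = qualified[0] if qualified else int(np.argmax(extent))
        halfw = max(1, int(round(min_peak_separation / dm.grid.theta_step)))
        cols = slice(max(0, peak_col - halfw),
                     min(len(theta_values), peak_col + halfw + 1))
        rr = r_values[:, None]
        leading = supra[:, cols] & (rr >= LEADING_EDGE_FRACTION * rel_length)
        w = np.where(leading, np.where(dm.mask, 0.0, dm.values)[:, cols], 0.0)
        rel_angle = _weighted_mean_angle(dm, w, cols)

    # Dense-region exclusion: a front is indistinguishable when signal
    # reaches the outer half of the growth cone across most of the central
    # angular band.  Columns are qualified by extent (not mere presence)
    # because every map carries signal near the centre, where all angular
    # columns converge on the heel region.
    in_band = (theta_values >= -1.5) & (theta_values <= 1.5)
    dense = ((extent[in_band] >= 0.5 * rel_length).mean()
             > DENSE_COLUMN_FRACTION)
    return FrontEstimate(rel_length=rel_length, rel_angle=rel_angle,
                         peak_angles=peak_angles, split=split,
                         ambiguous=bool(dense))


def _find_extent_peaks(extent: np.ndarray, theta_step: float,
                       min_peak_separation: float) -> list[int]:
    """Local maxima of the extent profile (plateau-aware, endpoint-aware)."""
    distance = max(1, int(round(min_peak_separation / theta_step)))
    padded = np.concatenate([[-1.0], extent, [-1.0]])  # let endpoints peak
    peaks, props = _signal.find_peaks(padded, distance=distance, height=0.0,
                                      prominence=0.0)
    # a secondary filopodium must stand clear of the valley by a fifth of
    # its own extent, otherwise shallow noise bumps on one broad tip read
    # as a second one
    peaks = [int(p) - 1 for p, prom in zip(peaks, props["prominences"])
             if prom >= 0.2 * extent[int(p) - 1]]
    # ensure the global maximum is represented (flat plateaus and profiles
    # rejected wholesale by the prominence filter)
    argmax = int(np.argmax(extent))
    if not peaks or max(extent[p] for p in peaks) < extent[argmax]:
        peaks.append(argmax)
    return sorted(peaks)


def _front_intensity(dm: DensityMap, r: float, theta: float,
                     halfwidth: int = 2) -> float:
    """Mean intensity in a small node neighbourhood around (r, theta)."""
    i = int(round((r - dm.grid.r_min) / dm.grid.r_step))
    j = int(round((theta - dm.grid.theta_min) / dm.grid.theta_step))
    n_r, n_t = dm.grid.shape
    i0, i1 = max(0, i - halfwidth), min(n_r, i + halfwidth + 1)
    j0, j1 = max(0, j - halfwidth), min(n_t, j + halfwidth + 1)
    patch = np.where(dm.mask, 0.0, dm.values)[i0:i1, j0:j1]
    return float(patch.mean()) if patch.size else 0.0


def _per_peak_fronts(dm: DensityMap, fe: FrontEstimate,
                     threshold_fraction: float) -> list[FrontEstimate]:
    """Split a multi-peak front into one estimate per qualifying peak."""
    supra, _ = _suprathreshold(dm, threshold_fraction)
    r_values = dm.grid.r_values
    theta_values = dm.grid.theta_values
    extent = _extent_profile(supra, r_values)
    out = []
    half = max(1, int(round(DEFAULT_MIN_PEAK_SEPARATION / dm.grid.theta_step / 2)))
    for ang in fe.peak_angles:
        j = int(round((ang - dm.grid.theta_min) / dm.grid.theta_step))
        j0, j1 = max(0, j - half), min(len(theta_values), j + half + 1)
        length = float(extent[j0:j1].max())
        cols = slice(j0, j1)
        leading = supra[:, cols] & (r_values[:, None]
                                    >= LEADING_EDGE_FRACTION * length)
        w = np.where(leading, np.where(dm.mask, 0.0, dm.values)[:, cols], 0.0)
        angle = (_weighted_mean_angle(dm, w, cols)
                 if w.sum() > 0 else float(ang))
        out.append(FrontEstimate(rel_length=length, rel_angle=angle,
                                 peak_angles=[float(ang)], split=False,
                                 ambiguous=fe.ambiguous))
    return out


def label_cell_type(front: FrontEstimate, dm_gfp: DensityMap | None,
                    dm_rfp: DensityMap | None,
                    strong_gfp_ratio: float = STRONG_GFP_RATIO) -> str:
    """R4 when strong GFP is present at the front, R3 otherwise."""
    g = (_front_intensity(dm_gfp, front.rel_length, front.rel_angle)
         if dm_gfp is not None else 0.0)
    r = (_front_intensity(dm_rfp, front.rel_length, front.rel_angle)
         if dm_rfp is not None else 0.0)
    if r <= 0:
        return "R4" if g > 0 else "R3"
    return "R4" if g >= strong_gfp_ratio * r else "R3"


def measure_bundle(dm_gfp: DensityMap | None, dm_rfp: DensityMap | None,
                   meta: Mapping,
                   threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                   strong_gfp_ratio: float = STRONG_GFP_RATIO,
                   ) -> list[GrowthConeMeasurement]:
    """Measure every labelled growth cone of one bundle.

    R4 cells (strong GFP) are measured from the GFP map; R3 cells from the
    RFP map, keeping only RFP fronts without strong GFP so doubly-labelled
    R4s are not counted twice.  A fate-transformed bundle therefore yields
    two same-type measurements, both read from one channel (its two fronts
    appear as split morphology and are measured per peak).  Heel positions
    3 and 4 are assigned by descending front angle: the T3-side front is
    position 3.

    ``meta`` must carry ``bundle_id, specimen_id, genotype, time_hrs_apf``.
    An empty-front channel contributes no measurements but does not abort the
    bundle.
    """
    fronts: list[tuple[FrontEstimate, str]] = []  # (front, channel)
    for dm, chan in ((dm_gfp, "GFP"), (dm_rfp, "RFP")):
        if dm is None:
            continue
        try:
            fe = detect_front(dm, threshold_fraction)
        except EmptyFrontError:
            continue
        if fe.split and len(fe.peak_angles) >= 2:
            cand = _per_peak_fronts(dm, fe, threshold_fraction)
        else:
            cand = [fe]
        for f in cand:
            fronts.append((f, chan))

    kept: list[FrontEstimate] = []
    types: list[str] = []
    for fe, chan in fronts:
        ctype = label_cell_type(fe, dm_gfp, dm_rfp, strong_gfp_ratio)
        if chan == "GFP":
            if ctype != "R4":
                continue  # GFP front without strong GFP is noise
            kept.append(fe)
            types.append("R4")
        else:  # RFP
            if ctype == "R4" and dm_gfp is not None:
                continue  # same cell already measured from GFP
            kept.append(fe)
            types.append("R3" if ctype == "R3" else "R4")

    positions: dict[int, int] = {}
    if len(kept) == 1:
        # a lone cell takes its wild-type position
        positions[0] = 3 if types[0] == "R3" else 4
    else:
        order = np.argsort([-f.rel_angle for f in kept], kind="stable")
        for rank, k in enumerate(order):
            positions[int(k)] = 3 if rank == 0 else 4
    out = []
    for k, (fe, ctype) in enumerate(zip(kept, types)):
        out.append(GrowthConeMeasurement(
            bundle_id=str(meta["bundle_id"]),
            specimen_id=str(meta.get("specimen_id", "")),
            position=positions.get(k, 3),
            cell_type=ctype,
            genotype=str(meta.get("genotype", "wild_type")),
            time_hrs_apf=float(meta.get("time_hrs_apf", np.nan)),
            front=fe,
        ))
    return out


def classify_targeting(m: GrowthConeMeasurement, frame: StandardFrame,
                       targets: Mapping[str, EllipseROI],
                       n_boundary: int = 64) -> str:
    """Label of the target ellipse containing the front, else ``other``.

    Each ellipse boundary is mapped point-by-point into standardized
    coordinates and containment is tested against the resulting polygon in
    the (r, theta) plane.
    """
    from shapely.geometry import Point, Polygon

    pt = Point(m.front.rel_length, m.front.rel_angle)
    order = [t for t in ("T3", "T4", "T3p") if t in targets]
    order += [t for t in targets if t not in order]
    for label in order:
        boundary = targets[label].boundary(n_boundary)
        r, theta = image_to_polar(boundary, frame)
        poly = Polygon(np.column_stack([r, theta]))
        if poly.contains(pt) or poly.touches(pt):
            return label
    return "other"


def measurements_to_frame(measurements: Sequence[GrowthConeMeasurement]):
    """Flatten measurements into the measurements-table schema."""
    import pandas as pd

    rows = [{
        "specimen_id": m.specimen_id,
        "bundle_id": m.bundle_id,
        "cell_type": m.cell_type,
        "position": m.position,
        "genotype": m.genotype,
        "time_hrs_apf": m.time_hrs_apf,
        "rel_length": m.front.rel_length,
        "rel_angle": m.front.rel_angle,
        "flags": m.flags,
    } for m in measurements]
    return pd.DataFrame(rows, columns=list(
        ("specimen_id", "bundle_id", "cell_type", "position", "genotype",
         "time_hrs_apf", "rel_length", "rel_angle", "flags")))
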