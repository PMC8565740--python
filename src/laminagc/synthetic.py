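"""Synthetic lamina specimens with known ground truth.

Generates everything the measurement pipeline consumes — heel/target
annotations, growth-cone trajectories and rendered multi-channel z-stacks —
from a parametric model of the lamina plexus:

* bundles sit on a hexagonal lattice and share a canonical landmark template
  (heel trapezoid plus target grid) whose population parameters default to
  the wild-type calibration: |C-T4| = 7.1 +- 1.5 um, T3-side wedge
  14.8 +- 4.0 deg, T3'-side wedge 13.3 +- 3.8 deg;
* a smooth sinusoidal warp field distorts the whole lattice (specimen-level
  "local warping"), and independent Gaussian jitter perturbs individual
  landmarks;
* growth cones extend radially at cell-type-specific speeds (R3 faster than
  R4, both reaching their target radius by 28 hrs), with symmetric
  pre-arrival angles that snap to the target angle on arrival;
* fate-transformation modes (two R3s or two R4s per bundle) reassign
  targets with configurable penetrance, mirroring sev>Fz / sev>Nic
  perturbations;
* image stacks render each growth cone as an anisotropic Gaussian ridge from
  heel to front (brightest at the front), heels as blobs (24B10 channel) and
  target ellipses as rings (FasII channel), with a Gaussian PSF,
  Poisson-Gaussian noise, and a z-profile that makes filopodium extent peak
  at a selectable slice.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotations import BundleAnnotation, EllipseROI, ImageStack, Point2D
from .errors import DegenerateGeometryError, LaminaError, OrientationError
from .frame import build_frame, polar_to_image

#: canonical target angles in wedge units
TARGET_THETA = {"T3": 1.0, "T4": 0.0, "T3p": -1.0}

GENOTYPE_FOR_MODE = {"wild_type": "wild_type", "two_R3": "sev_Fz",
                     "two_R4": "sev_Nic"}


@dataclass(frozen=True)
class RenderConfig:
    """Raster parameters for synthetic stacks (lengths in micrometres)."""

    pixel_size: float = 0.15
    z_step: float = 0.125
    n_slices: int = 9
    filopodium_width: float = 0.4
    psf_sd: float = 0.12
    photon_scale: float | None = 200.0
    read_noise_sd: float = 0.01
    z_sigma_slices: float = 2.0
    peak_slice: int | None = None  # None -> middle slice
    crop_factor: float = 1.5       # crop half-size as multiple of |C-T4|


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic lamina.

    Population geometry defaults reproduce the wild-type calibration values;
    kinetic defaults satisfy the qualitative constraints (R3 faster than R4,
    both arriving by 28 hrs APF after onset at 18 hrs) since no absolute
    speeds are published.
    """

    n_bundles: int = 100
    lattice_pitch: float = 10.0
    # population geometry (means and SDs of the per-bundle draws)
    c_t4_um: float = 7.1
    c_t4_sd_um: float = 1.5
    wedge_t3_deg: float = 14.8
    wedge_t3_sd_deg: float = 4.0
    wedge_t3p_deg: float = 13.3
    wedge_t3p_sd_deg: float = 3.8
    orientation_sd_deg: float = 5.0
    # template shape (relative to |C-T4|)
    t3_rel_radius: float = 1.15
    t3p_rel_radius: float = 1.10
    heel_rel_radius: float = 0.28
    ellipse_major_um: float = 2.0
    ellipse_minor_um: float = 1.4
    # specimen-level distortion and landmark jitter
    warp_amplitude: float = 0.5
    warp_wavelength: float = 40.0
    landmark_noise_sd: float = 0.1
    # kinetics
    speed: dict = field(default_factory=lambda: {"R3": 0.115, "R4": 0.10})
    t_onset: float = 18.0
    pre_arrival_angle: float = 0.5
    angle_noise_sd: float = 0.08
    length_noise_sd: float = 0.05
    times: tuple = (22.0, 24.0, 26.0, 28.0, 30.0, 32.0, 34.0, 36.0)
    # perturbation
    fate_mode: str = "wild_type"
    fate_penetrance: float = 1.0
    render: RenderConfig = field(default_factory=RenderConfig)

    def __post_init__(self):
        if self.fate_mode not in GENOTYPE_FOR_MODE:
            raise ValueError(f"unknown fate_mode {self.fate_mode!r}")
        if not 0 <= self.fate_penetrance <= 1:
            raise ValueError("fate_penetrance must be in [0, 1]")
        if any(v <= 0 for v in self.speed.values()):
            raise ValueError("speeds must be positive")


@dataclass
class CellTruth:
    identity: str          # R3 or R4
    final_target: str      # T3, T4 or T3p
    r_target: float
    theta_target: float
    speed: float


@dataclass
class BundleTruth:
    bundle_id: str
    center: np.ndarray
    length: float          # drawn |C-T4|
    wedge_t3: float        # radians
    wedge_t3p: float
    orientation: float
    landmarks_pre: dict[str, np.ndarray]
    landmarks: dict[str, np.ndarray]
    altered: bool = False
    cells: dict[int, CellTruth] = field(default_factory=dict)
    trajectories: dict[float, dict[int, tuple[float, float]]] = field(
        default_factory=dict)
    crop_origin: np.ndarray | None = None


@dataclass
class GroundTruth:
    """Everything needed to score downstream estimates without re-deriving."""

    config: SyntheticConfig
    seed: int
    bundles: dict[str, BundleTruth] = field(default_factory=dict)
    generating_weights: tuple[float, float] | None = None


def _hex_centers(n: int, pitch: float) -> np.ndarray:
    """First n points of a hexagonal lattice, row-major around the origin."""
    side = int(np.ceil(np.sqrt(n)))
    pts = []
    for row in range(side + 1):
        for col in range(side + 1):
            x = pitch * (col + 0.5 * (row % 2))
            y = pitch * (np.sqrt(3) / 2) * row
            pts.append((x, y))
            if len(pts) >= n:
                return np.asarray(pts)
    return np.asarray(pts[:n])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _template(length: float, w3: float, w3p: float, cfg: SyntheticConfig
              ) -> dict[str, np.ndarray]:
    """Landmarks in bundle-local coordinates (C at origin, C->T4 along +x).

    R3 sits on the line through C and T3 (and R4 on the line through C and
    T3'), which is exactly how the frame centre is defined, so the template
    reproduces its own drawn parameters when re-measured.
    """
    t4 = np.array([length, 0.0])
    t3 = cfg.t3_rel_radius * length * np.array([np.cos(w3), np.sin(w3)])
    t3p = cfg.t3p_rel_radius * length * np.array([np.cos(w3p), -np.sin(w3p)])
    r3 = -cfg.heel_rel_radius * length * _unit(t3)
    r4 = -cfg.heel_rel_radius * length * _unit(t3p)
    r2 = r3 + length * np.array([-0.17, -0.23])
    r5 = r4 + length * np.array([-0.17, 0.23])
    r1 = r2 + length * np.array([-0.22, -0.14])
    r6 = r5 + length * np.array([-0.22, 0.14])
    t0 = np.array([-0.30 * length, 0.0])
    return {"R1": r1, "R2": r2, "R3": r3, "R4": r4, "R5": r5, "R6": r6,
            "T0": t0, "T3": t3, "T4": t4, "T3p": t3p}


def _warp_field(rng: np.random.Generator, cfg: SyntheticConfig):
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    amp, lam = cfg.warp_amplitude, cfg.warp_wavelength

    def warp(p: np.ndarray) -> np.ndarray:
        if amp == 0:
            return p
        dx = amp * np.sin(2 * np.pi * p[..., 1] / lam + ph1)
        dy = amp * np.sin(2 * np.pi * p[..., 0] / lam + ph2)
        return p + np.stack([dx, dy], axis=-1)

    return warp


def _annotation_from_landmarks(bid: str, lms: dict[str, np.ndarray],
                               cfg: SyntheticConfig, genotype: str,
                               specimen_id: str) -> BundleAnnotation:
    heels = {i: Point2D(*lms[f"R{i}"]) for i in range(1, 7)}
    targets = {}
    for label in ("T0", "T3", "T4", "T3p"):
        center = lms[label]
        d = center - 0.5 * (lms["R3"] + lms["R4"])
        angle = np.degrees(np.arctan2(d[1], d[0])) % 180.0
        targets[label] = EllipseROI(
            center=Point2D(*center), major_axis=cfg.ellipse_major_um,
            minor_axis=cfg.ellipse_minor_um, major_angle=float(angle))
    return BundleAnnotation(
        bundle_id=bid, heels=heels, targets=targets, genotype=genotype,
        specimen_id=specimen_id, pixel_size=cfg.render.pixel_size)


def simulate_lattice(cfg: SyntheticConfig, seed: int = 0,
                     specimen_id: str = "sim0"
                     ) -> tuple[GroundTruth, list[BundleAnnotation]]:
    """Place per-bundle templates on a warped hexagonal lattice.

    Per bundle, |C-T4|, the two wedge angles and the in-plane orientation are
    drawn around their population means; landmark jitter is added on top.
    A bundle whose realized landmarks fail frame construction is redrawn up
    to 10 times.
    """
    rng = np.random.default_rng(seed)
    warp = _warp_field(rng, cfg)
    centers = _hex_centers(cfg.n_bundles, cfg.lattice_pitch)
    genotype = GENOTYPE_FOR_MODE[cfg.fate_mode]
    truth = GroundTruth(config=cfg, seed=seed)
    annotations = []
    for k, center in enumerate(centers):
        bid = f"b{k:04d}"
        for attempt in range(10):
            length = max(0.5, rng.normal(cfg.c_t4_um, cfg.c_t4_sd_um))
            # truncate below 7 deg: bundles with near-collapsed wedges are
            # not annotatable and never enter real measurement sets
            w3 = np.deg2rad(np.clip(
                rng.normal(cfg.wedge_t3_deg, cfg.wedge_t3_sd_deg), 7.0, 60.0))
            w3p = np.deg2rad(np.clip(
                rng.normal(cfg.wedge_t3p_deg, cfg.wedge_t3p_sd_deg), 7.0, 60.0))
            orient = np.deg2rad(rng.normal(0.0, cfg.orientation_sd_deg))
            local = _template(length, w3, w3p, cfg)
            ca, sa = np.cos(orient), np.sin(orient)
            rot = np.array([[ca, -sa], [sa, ca]])
            pre = {lbl: center + rot @ p for lbl, p in local.items()}
            post = {lbl: warp(p[None])[0]
                    + rng.normal(0.0, cfg.landmark_noise_sd, size=2)
                    for lbl, p in pre.items()}
            ann = _annotation_from_landmarks(bid, post, cfg, genotype,
                                             specimen_id)
            try:
                build_frame(ann)
            except (DegenerateGeometryError, OrientationError):
                continue
            break
        else:
            raise LaminaError(f"bundle {bid}: could not realize a "
                              f"non-degenerate geometry in 10 attempts")
        truth.bundles[bid] = BundleTruth(
            bundle_id=bid, center=np.asarray(center, float), length=length,
            wedge_t3=float(w3), wedge_t3p=float(w3p), orientation=float(orient),
            landmarks_pre=pre, landmarks=post)
        annotations.append(ann)
    return truth, annotations


def _assign_cells(bt: BundleTruth, cfg: SyntheticConfig,
                  rng: np.random.Generator) -> None:
    altered = (cfg.fate_mode != "wild_type"
               and rng.random() < cfg.fate_penetrance)
    bt.altered = bool(altered)
    if not altered:
        plan = {3: ("R3", "T3"), 4: ("R4", "T4")}
    elif cfg.fate_mode == "two_R4":
        # the R3-position cell is fate-transformed to R4; both target T4
        plan = {3: ("R4", "T4"), 4: ("R4", "T4")}
    else:  # two_R3
        plan = {3: ("R3", "T3"), 4: ("R3", "T3p")}
    r_rel = {"T3": cfg.t3_rel_radius, "T4": 1.0, "T3p": cfg.t3p_rel_radius}
    for pos, (identity, target) in plan.items():
        bt.cells[pos] = CellTruth(
            identity=identity, final_target=target, r_target=r_rel[target],
            theta_target=TARGET_THETA[target], speed=cfg.speed[identity])


def simulate_kinetics(truth: GroundTruth, cfg: SyntheticConfig | None = None,
                      seed: int | None = None) -> GroundTruth:
    """Attach per-cell trajectories (rel_length(t), rel_angle(t)) to truth.

    Length grows linearly from extension onset and saturates at the target
    radius; the angle is symmetric about the axis before arrival (positive
    for position 3, negative for position 4) and equals the target's angle
    afterwards.  Noise is independent Gaussian per time point.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    for bt in truth.bundles.values():
        _assign_cells(bt, cfg, rng)
        for t in cfg.times:
            row = {}
            for pos, cell in bt.cells.items():
                nominal = cell.speed * (t - cfg.t_onset)
                arrived = nominal >= cell.r_target
                length = min(nominal, cell.r_target) + rng.normal(
                    0.0, cfg.length_noise_sd)
                if arrived:
                    angle = cell.theta_target
                else:
                    angle = (1.0 if pos == 3 else -1.0) * cfg.pre_arrival_angle
                angle = angle + rng.normal(0.0, cfg.angle_noise_sd)
                row[pos] = (float(max(length, 0.02)), float(angle))
            bt.trajectories[float(t)] = row
    return truth


def _ridge(xx: np.ndarray, yy: np.ndarray, a: np.ndarray, b: np.ndarray,
           sigma: float) -> np.ndarray:
    """Gaussian ridge along segment a->b, brightest near b (the front).

    The cross-section is Gaussian with SD ``sigma`` but the tip is capped
    three times harder axially, so the detectable leading edge of the
    rendered filopodium sits at ``b`` instead of a PSF-halo beyond it.
    """
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        d2 = (xx - a[0]) ** 2 + (yy - a[1]) ** 2
        return np.exp(-d2 / (2 * sigma ** 2))
    length = np.sqrt(denom)
    t = ((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / denom
    tc = np.clip(t, 0.0, 1.0)
    lat2 = (xx - (a[0] + t * ab[0])) ** 2 + (yy - (a[1] + t * ab[1])) ** 2
    over = np.clip(t - 1.0, 0.0, None) * length
    under = np.clip(-t, 0.0, None) * length
    return ((0.3 + 0.7 * tc) * np.exp(-lat2 / (2 * sigma ** 2))
            * np.exp(-over ** 2 / (2 * (sigma / 3) ** 2))
            * np.exp(-under ** 2 / (2 * sigma ** 2)))


def _blob(xx, yy, p, sigma):
    return np.exp(-((xx - p[0]) ** 2 + (yy - p[1]) ** 2) / (2 * sigma ** 2))


def _ellipse_ring(xx, yy, ell: EllipseROI, width: float = 0.25) -> np.ndarray:
    phi = np.deg2rad(ell.major_angle)
    dx, dy = xx - ell.center.x, yy - ell.center.y
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    a, b = 0.5 * ell.major_axis, 0.5 * ell.minor_axis
    q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    return np.exp(-((q - 1.0) * min(a, b)) ** 2 / (2 * width ** 2))


def render_bundle(truth: GroundTruth, ann: BundleAnnotation, time: float,
                  cfg: SyntheticConfig | None = None,
                  channels: tuple[str, ...] = ("FasII", "24B10", "GFP", "RFP"),
                  rng: np.random.Generator | None = None
                  ) -> tuple[ImageStack, np.ndarray]:
    """Render one bundle's crop at one time point.

    Returns the stack and the crop origin (global um of pixel (0, 0)); the
    annotation must be shifted by that origin (:func:`localize_annotation`)
    before building frames against the stack.
    """
    cfg = cfg or truth.config
    rc = cfg.render
    bt = truth.bundles[ann.bundle_id]
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    frame = build_frame(ann)
    half = rc.crop_factor * frame.unit_length
    origin = frame.center.asarray() - half
    npix = int(np.ceil(2 * half / rc.pixel_size))
    if npix < 8:
        raise LaminaError("rendering raster too small to contain landmarks")
    coords = origin[0] + rc.pixel_size * np.arange(npix)
    ycoords = origin[1] + rc.pixel_size * np.arange(npix)
    xx, yy = np.meshgrid(coords, ycoords)  # (y, x) grids in global um

    k = rc.peak_slice if rc.peak_slice is not None else rc.n_slices // 2
    zg = np.exp(-((np.arange(rc.n_slices) - k) ** 2)
                / (2 * rc.z_sigma_slices ** 2))

    traj = bt.trajectories.get(float(time))
    if traj is None:
        raise KeyError(f"no trajectory for time {time}; run simulate_kinetics")
    sigma_w = rc.filopodium_width / 2.0

    base = {c: np.zeros((npix, npix)) for c in channels}
    if "FasII" in channels:
        for ell in ann.targets.values():
            base["FasII"] += _ellipse_ring(xx, yy, ell)
    if "24B10" in channels:
        for p in ann.heels.values():
            base["24B10"] += _blob(xx, yy, p.asarray(), 0.4)

    planes = np.zeros((len(channels), rc.n_slices, npix, npix))
    for ci, chan in enumerate(channels):
        for z in range(rc.n_slices):
            g = zg[z]
            img = (0.2 + 0.8 * g) * base[chan] if chan in (
                "FasII", "24B10") else np.zeros((npix, npix))
            if chan in ("GFP", "RFP"):
                for pos, cell in bt.cells.items():
                    want = "GFP" if cell.identity == "R4" else "RFP"
                    if want != chan:
                        continue
                    length, angle = traj[pos]
                    heel = ann.heels[pos].asarray()
                    front = polar_to_image(np.array(length), np.array(angle),
                                           frame)
                    # brightness (not footprint) falls off away from the
                    # peak slice; against the stack-wide detection threshold
                    # this makes the measured extent peak exactly at k
                    img = img + (0.2 + 0.8 * g) * _ridge(
                        xx, yy, heel, front, sigma_w)
            if rc.psf_sd > 0:
                img = ndimage.gaussian_filter(img, rc.psf_sd / rc.pixel_size)
            if rc.photon_scale:
                img = rng.poisson(np.clip(img, 0, None)
                                  * rc.photon_scale) / rc.photon_scale
                img = img + rng.normal(0.0, rc.read_noise_sd, img.shape)
            planes[ci, z] = np.clip(img, 0.0, None)
    bt.crop_origin = origin
    stack = ImageStack(voxels=planes, channel_names=tuple(channels),
                       z_step=rc.z_step, pixel_size=rc.pixel_size)
    return stack, origin


def localize_annotation(ann: BundleAnnotation, origin: np.ndarray
                        ) -> BundleAnnotation:
    """Copy of an annotation with all coordinates shifted into crop space."""
    heels = {i: Point2D(p.x - origin[0], p.y - origin[1])
             for i, p in ann.heels.items()}
    targets = {
        lbl: EllipseROI(center=Point2D(e.center.x - origin[0],
                                       e.center.y - origin[1]),
                        major_axis=e.major_axis, minor_axis=e.minor_axis,
                        major_angle=e.major_angle)
        for lbl, e in ann.targets.items()}
    return dataclasses.replace(ann, heels=heels, targets=targets)


def make_repulsion_dataset(cfg: SyntheticConfig, alpha: float, beta: float,
                           angular_noise_sd_deg: float, n: int,
                           cell_type: str = "R3", seed: int = 0,
                           times: tuple = (22.0, 24.0, 26.0)) -> list:
    """Repulsion-model inputs whose measured directions are generated by the
    weighted vector-sum model plus Gaussian angular noise."""
    from .repulsion import RepulsionInput, repulsion_vectors

    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rng = np.random.default_rng(seed)
    lat_cfg = dataclasses.replace(cfg, n_bundles=n)
    truth, anns = simulate_lattice(lat_cfg, seed=seed)
    out = []
    for i, ann in enumerate(anns):
        frame = build_frame(ann)
        v1, v2 = repulsion_vectors(ann, cell_type, frame)
        vp = alpha * v1 + beta * v2
        phi = np.arctan2(vp[1], vp[0]) + rng.normal(
            0.0, np.deg2rad(angular_noise_sd_deg))
        measured = phi / (frame.wedge_t3 if phi >= 0 else frame.wedge_t3p)
        out.append(RepulsionInput(
            v1=v1, v2=v2, measured_angle=float(measured),
            bundle_id=ann.bundle_id, time_hrs_apf=times[i % len(times)],
            cell_type=cell_type, wedge_t3=frame.wedge_t3,
            wedge_t3p=frame.wedge_t3p,
            measured_magnitude=float(np.linalg.norm(vp))))
    return out
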