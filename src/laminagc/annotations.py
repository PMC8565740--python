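"""Annotation and image I/O.

Reads and writes the three flat-file schemas produced by ROI annotation of
lamina confocal stacks (heel points, target ellipses, bundle->target mapping),
multi-channel TIFF z-stacks, per-cell measurement tables, and the Excel
workbook layout used for archival numerical data.

Coordinate conventions
----------------------
All in-memory coordinates are micrometres in image convention: ``x`` increases
rightward, ``y`` increases *downward*.  Annotation CSVs may carry pixel
coordinates instead; a per-row ``units`` column (``um`` or ``px``) selects, and
pixel rows are converted using the bundle's pixel size.  Ellipse angles are
degrees counter-clockwise from +x in image coordinates and are normalized to
[0, 180) on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    AnnotationParseError,
    CalibrationError,
    ConsistencyError,
    DimensionError,
    SchemaError,
)

#: Canonical channel labels, in storage order.
CHANNELS = ("FasII", "24B10", "GFP", "RFP")

#: Recognised target labels.  ``T3p`` is the mirror-symmetric target of
#: fate-transformed R3 cells (written T3' in prose).
TARGET_LABELS = ("T0", "T1", "T2", "T3", "T4", "T5", "T6", "T3p")

HEELS_COLUMNS = ("bundle_id", "rcell", "x", "y")
TARGETS_COLUMNS = ("bundle_id", "target", "cx", "cy", "major", "minor", "angle_deg")
MAPPING_COLUMNS = ("bundle_id", "target")

MEASUREMENT_COLUMNS = (
    "specimen_id",
    "bundle_id",
    "cell_type",
    "position",
    "genotype",
    "time_hrs_apf",
    "rel_length",
    "rel_angle",
    "flags",
)


class Point2D(NamedTuple):
    """A point in the image plane (micrometres; y increases downward)."""

    x: float
    y: float

    def asarray(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class EllipseROI:
    """Target ellipse: centre, full axis lengths (um) and major-axis angle
    in degrees from +x (image convention), normalized to [0, 180)."""

    center: Point2D
    major_axis: float
    minor_axis: float
    major_angle: float

    def __post_init__(self):
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError(
                f"ellipse axes must satisfy major >= minor > 0, got "
                f"{self.major_axis}, {self.minor_axis}"
            )

    def boundary(self, n: int = 64) -> np.ndarray:
        """``n`` points on the ellipse boundary, (n, 2) in image um."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = 0.5 * self.major_axis, 0.5 * self.minor_axis
        phi = np.deg2rad(self.major_angle)
        x = a * np.cos(t)
        y = b * np.sin(t)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        return (rot @ np.vstack([x, y])).T + self.center.asarray()


@dataclass
class BundleAnnotation:
    """One bundle's raw landmarks: six heel points (R-cell index 1..6) and
    target ellipses (at minimum T3, T4, T3p for frame construction)."""

    bundle_id: str
    heels: dict[int, Point2D]
    targets: dict[str, EllipseROI]
    genotype: str = "wild_type"
    time_hrs_apf: float = np.nan
    specimen_id: str = "specimen0"
    pixel_size: float = np.nan
    target_provenance: dict[str, str] = field(default_factory=dict)

    def require(self, heels: Sequence[int] = (), targets: Sequence[str] = ()) -> None:
        missing_h = [i for i in heels if i not in self.heels]
        missing_t = [t for t in targets if t not in self.targets]
        if missing_h or missing_t:
            raise ConsistencyError(
                f"bundle {self.bundle_id}: missing heels {missing_h}, "
                f"targets {missing_t}"
            )


@dataclass
class ImageStack:
    """Multi-channel confocal z-stack: voxels are (channel, z, y, x)."""

    voxels: np.ndarray
    channel_names: tuple[str, ...]
    z_step: float
    pixel_size: float

    def __post_init__(self):
        if self.voxels.ndim != 4:
            raise DimensionError(f"expected 4-D voxels, got {self.voxels.ndim}-D")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise DimensionError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if not (self.z_step > 0 and self.pixel_size > 0):
            raise CalibrationError("z_step and pixel_size must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("negative intensities")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channel_names:
            raise KeyError(f"channel {name!r} not in {self.channel_names}")
        return self.voxels[self.channel_names.index(name)]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], what: str) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        bad = vals.isna() & out[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise AnnotationParseError(
                f"{what}: non-numeric value {out[c].iloc[row]!r} in column "
                f"{c!r} at row {row + 2}"  # +2: header line + 1-based
            )
        out[c] = vals
    return out


def _to_um(df: pd.DataFrame, coord_cols: Sequence[str], pixel_size: float,
           what: str) -> pd.DataFrame:
    """Convert pixel-unit rows to micrometres in place (units column optional,
    default um)."""
    out = df.copy()
    units = out["units"] if "units" in out.columns else pd.Series("um", index=out.index)
    units = units.fillna("um").astype(str).str.lower()
    bad = ~units.isin(["um", "px"])
    if bad.any():
        raise AnnotationParseError(f"{what}: unknown units {sorted(units[bad].unique())}")
    px = units == "px"
    if px.any():
        scale = out["pixel_size"] if "pixel_size" in out.columns else pd.Series(
            pixel_size, index=out.index)
        scale = pd.to_numeric(scale, errors="coerce").fillna(pixel_size)
        if np.any(~(scale[px] > 0)):
            raise CalibrationError(
                f"{what}: pixel-unit rows present but no positive pixel size")
        for c in coord_cols:
            out.loc[px, c] = out.loc[px, c] * scale[px]
    return out


def read_annotations(
    heels_path,
    targets_path,
    mapping_path=None,
    *,
    pixel_size: float = np.nan,
    genotype: str = "wild_type",
    time_hrs_apf: float = np.nan,
    specimen_id: str = "specimen0",
) -> list[BundleAnnotation]:
    """Read heel/target/mapping CSVs into one :class:`BundleAnnotation` per
    bundle id.

    Optional per-row ``genotype``, ``time_hrs_apf``, ``specimen_id`` and
    ``pixel_size`` columns in the heels table override the keyword defaults.
    Bundles missing the frame-critical heels (3, 4) or targets (T3, T4, T3p)
    are returned with a warning; frame construction rejects them later.
    """
    heels = pd.read_csv(heels_path)
    targets = pd.read_csv(targets_path)
    _check_columns(heels, HEELS_COLUMNS, "heels table")
    _check_columns(targets, TARGETS_COLUMNS, "targets table")
    heels = _numeric(heels, ["rcell", "x", "y"], "heels table")
    targets = _numeric(
        targets, ["cx", "cy", "major", "minor", "angle_deg"], "targets table")
    heels = _to_um(heels, ["x", "y"], pixel_size, "heels table")
    targets = _to_um(targets, ["cx", "cy", "major", "minor"], pixel_size,
                     "targets table")

    mapping = None
    if mapping_path is not None:
        mapping = pd.read_csv(mapping_path)
        _check_columns(mapping, MAPPING_COLUMNS, "mapping table")
        known = set(heels["bundle_id"].astype(str))
        orphan = set(mapping["bundle_id"].astype(str)) - known
        if orphan:
            raise ConsistencyError(
                f"mapping references bundle(s) absent from heels: {sorted(orphan)}")

    bundles: list[BundleAnnotation] = []
    for bid, hrows in heels.groupby("bundle_id", sort=False):
        bid = str(bid)
        heel_map: dict[int, Point2D] = {}
        meta = hrows.iloc[0]
        for _, row in hrows.iterrows():
            idx = int(row["rcell"])
            if not 1 <= idx <= 6:
                raise AnnotationParseError(
                    f"heels table: R-cell index {idx} out of range 1..6 "
                    f"(bundle {bid})")
            heel_map[idx] = Point2D(float(row["x"]), float(row["y"]))
        target_map: dict[str, EllipseROI] = {}
        trows = targets[targets["bundle_id"].astype(str) == bid]
        for _, row in trows.iterrows():
            label = str(row["target"])
            if label not in TARGET_LABELS:
                raise AnnotationParseError(
                    f"targets table: unknown target label {label!r} (bundle {bid})")
            target_map[label] = EllipseROI(
                center=Point2D(float(row["cx"]), float(row["cy"])),
                major_axis=float(row["major"]),
                minor_axis=float(row["minor"]),
                major_angle=float(row["angle_deg"]) % 180.0,
            )
        prov: dict[str, str] = {}
        if mapping is not None:
            mrows = mapping[mapping["bundle_id"].astype(str) == bid]
            for _, row in mrows.iterrows():
                if "neighbor_bundle_id" in mrows.columns and pd.notna(
                        row.get("neighbor_bundle_id")):
                    prov[str(row["target"])] = str(row["neighbor_bundle_id"])
        ann = BundleAnnotation(
            bundle_id=bid,
            heels=heel_map,
            targets=target_map,
            genotype=str(meta["genotype"]) if "genotype" in hrows.columns else genotype,
            time_hrs_apf=float(meta["time_hrs_apf"])
            if "time_hrs_apf" in hrows.columns else time_hrs_apf,
            specimen_id=str(meta["specimen_id"])
            if "specimen_id" in hrows.columns else specimen_id,
            pixel_size=float(meta["pixel_size"])
            if "pixel_size" in hrows.columns else pixel_size,
            target_provenance=prov,
        )
        missing_h = [i for i in (3, 4) if i not in heel_map]
        missing_t = [t for t in ("T3", "T4", "T3p") if t not in target_map]
        if missing_h or missing_t:
            warnings.warn(
                f"bundle {bid}: frame-critical landmark(s) missing "
                f"(heels {missing_h}, targets {missing_t}); frame construction "
                f"will reject this bundle",
                stacklevel=2,
            )
        bundles.append(ann)
    return bundles


def write_annotations(bundles: Sequence[BundleAnnotation], heels_path,
                      targets_path, mapping_path=None) -> None:
    """Serialize annotations back to the CSV schemas (micrometre units)."""
    hrows, trows, mrows = [], [], []
    for b in bundles:
        for idx in sorted(b.heels):
            p = b.heels[idx]
            hrows.append({
                "bundle_id": b.bundle_id, "rcell": idx, "x": p.x, "y": p.y,
                "units": "um", "genotype": b.genotype,
                "time_hrs_apf": b.time_hrs_apf, "specimen_id": b.specimen_id,
                "pixel_size": b.pixel_size,
            })
        for label in sorted(b.targets):
            e = b.targets[label]
            trows.append({
                "bundle_id": b.bundle_id, "target": label,
                "cx": e.center.x, "cy": e.center.y,
                "major": e.major_axis, "minor": e.minor_axis,
                "angle_deg": e.major_angle, "units": "um",
            })
        for label, neighbor in sorted(b.target_provenance.items()):
            mrows.append({"bundle_id": b.bundle_id, "target": label,
                          "neighbor_bundle_id": neighbor})
    pd.DataFrame(hrows).to_csv(heels_path, index=False)
    pd.DataFrame(trows).to_csv(targets_path, index=False)
    if mapping_path is not None:
        pd.DataFrame(mrows, columns=list(MAPPING_COLUMNS) + ["neighbor_bundle_id"]
                     ).to_csv(mapping_path, index=False)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF with a JSON description tag carrying
    channel names and calibration."""
    meta = {
        "channel_names": list(stack.channel_names),
        "z_step_um": stack.z_step,
        "pixel_size_um": stack.pixel_size,
    }
    tifffile.imwrite(path, stack.voxels, photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path, *, config: Mapping | None = None) -> ImageStack:
    """Read a multi-channel TIFF stack written by :func:`write_stack` or an
    equivalent export.

    ``config`` supplies ``channel_names``, ``z_step_um`` and ``pixel_size_um``
    when the TIFF description tag does not carry them.
    """
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if config:
        meta = {**meta, **config}
    if voxels.ndim == 3:
        # single channel stored as (z, y, x)
        voxels = voxels[None]
    if voxels.ndim != 4:
        raise DimensionError(f"expected 3-D or 4-D TIFF, got {voxels.ndim}-D")
    names = tuple(meta.get("channel_names", CHANNELS[: voxels.shape[0]]))
    if voxels.shape[0] != len(names):
        raise DimensionError(
            f"stack has {voxels.shape[0]} channels but {len(names)} names declared")
    if "pixel_size_um" not in meta:
        raise CalibrationError(f"{path}: no pixel size in TIFF tags or config")
    return ImageStack(
        voxels=np.asarray(voxels, dtype=float),
        channel_names=names,
        z_step=float(meta.get("z_step_um", 0.125)),
        pixel_size=float(meta["pixel_size_um"]),
    )


def write_measurements(df: pd.DataFrame, path) -> None:
    _check_columns(df, MEASUREMENT_COLUMNS, "measurements table")
    df.loc[:, MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, MEASUREMENT_COLUMNS, "measurements table")
    return df


def read_annotation_workbook(path, *, heels_sheet="heels",
                             targets_sheet="targets", mapping_sheet=None,
                             **kwargs) -> list[BundleAnnotation]:
    """Read annotations from an Excel workbook whose sheets mirror the CSV
    schemas (one sheet per table).  Used for archival numerical-data
    workbooks."""
    import tempfile, os

    try:
        sheets = pd.read_excel(path, sheet_name=None)
    except ValueError as exc:
        raise SchemaError(f"cannot read workbook {path}: {exc}") from exc
    for name in (heels_sheet, targets_sheet):
        if name not in sheets:
            raise SchemaError(
                f"workbook {path}: missing sheet {name!r} "
                f"(has {sorted(sheets)})")
    with tempfile.TemporaryDirectory() as td:
        hp = os.path.join(td, "heels.csv")
        tp = os.path.join(td, "targets.csv")
        mp = None
        sheets[heels_sheet].to_csv(hp, index=False)
        sheets[targets_sheet].to_csv(tp, index=False)
        if mapping_sheet and mapping_sheet in sheets:
            mp = os.path.join(td, "mapping.csv")
            sheets[mapping_sheet].to_csv(mp, index=False)
        return read_annotations(hp, tp, mp, **kwargs)
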