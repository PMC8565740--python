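"""Density maps: image channels resampled onto the standardized polar grid.

The fixed grid spans r in [0, 3.8] and theta in [-3, 3], both at 0.05 steps
(77 x 121 nodes).  Each node is mapped back to image pixels through the
bundle's frame and sampled with bilinear (piecewise-linear) interpolation,
which preserves constant images exactly and is exact on affine intensity
fields.  Nodes falling outside the image get value 0 and are flagged in an
out-of-bounds mask so downstream front detection can ignore them.

Per-bundle maps average a window of z-slices (41 by default) centred on the
slice showing the longest growth cone; the window is clipped at stack
boundaries rather than padded, and the number of slices actually averaged is
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotations import ImageStack
from .errors import CalibrationError, EmptySignalError
from .frame import StandardFrame, polar_to_image

#: Fraction of the 99.5th-percentile intensity used as the detection
#: threshold throughout (front detection and reference-slice selection).
DEFAULT_THRESHOLD_FRACTION = 0.2


@dataclass(frozen=True)
class PolarGridSpec:
    """The standardized resampling grid (dimensionless units)."""

    r_min: float = 0.0
    r_max: float = 3.8
    r_step: float = 0.05
    theta_min: float = -3.0
    theta_max: float = 3.0
    theta_step: float = 0.05

    def __post_init__(self):
        if not (self.r_step > 0 and self.theta_step > 0):
            raise ValueError("grid steps must be positive")
        if not (self.r_max > self.r_min and self.theta_max > self.theta_min):
            raise ValueError("grid ranges must be well-ordered")

    @property
    def r_values(self) -> np.ndarray:
        n = int(round((self.r_max - self.r_min) / self.r_step)) + 1
        return self.r_min + self.r_step * np.arange(n)

    @property
    def theta_values(self) -> np.ndarray:
        n = int(round((self.theta_max - self.theta_min) / self.theta_step)) + 1
        return self.theta_min + self.theta_step * np.arange(n)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.r_values), len(self.theta_values)


@dataclass
class DensityMap:
    """A channel resampled onto the polar grid.

    ``values`` is (n_r, n_theta); ``mask`` is True where the node fell outside
    the source image.
    """

    values: np.ndarray
    channel: str
    bundle_id: str
    n_slices: int = 1
    grid: PolarGridSpec = field(default_factory=PolarGridSpec)
    mask: np.ndarray | None = None
    #: wedge scale factors of the generating frame (radians per wedge unit);
    #: kept so angular statistics can be computed in physical angle.
    wedge_t3: float | None = None
    wedge_t3p: float | None = None

    def __post_init__(self):
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def grid_pixel_coords(frame: StandardFrame, grid: PolarGridSpec,
                      pixel_size: float) -> np.ndarray:
    """Pixel-space sampling coordinates for every grid node.

    Returns a (2, n_r, n_theta) array ordered (row, col) for
    ``scipy.ndimage.map_coordinates``.
    """
    if not pixel_size > 0:
        raise CalibrationError(f"pixel_size must be positive, got {pixel_size}")
    rr, tt = np.meshgrid(grid.r_values, grid.theta_values, indexing="ij")
    xy = polar_to_image(rr, tt, frame) / pixel_size
    return np.stack([xy[..., 1], xy[..., 0]])  # (row=y, col=x)


def _sample(slice2d: np.ndarray, coords: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    vals = ndimage.map_coordinates(np.asarray(slice2d, dtype=float), coords,
                                   order=1, mode="constant", cval=0.0)
    ny, nx = slice2d.shape
    oob = ((coords[0] < 0) | (coords[0] > ny - 1)
           | (coords[1] < 0) | (coords[1] > nx - 1))
    vals[oob] = 0.0
    return np.clip(vals, 0.0, None), oob


def resample_slice(slice2d: np.ndarray, frame: StandardFrame,
                   grid: PolarGridSpec | None = None, *,
                   pixel_size: float, channel: str = "",
                   bundle_id: str | None = None) -> DensityMap:
    """Resample one 2-D image slice onto the standardized polar grid."""
    grid = grid or PolarGridSpec()
    coords = grid_pixel_coords(frame, grid, pixel_size)
    vals, oob = _sample(slice2d, coords)
    return DensityMap(values=vals, channel=channel,
                      bundle_id=bundle_id or frame.bundle_id, grid=grid,
                      mask=oob, wedge_t3=frame.wedge_t3,
                      wedge_t3p=frame.wedge_t3p)


def _resample_all(stack: ImageStack, channel: str, frame: StandardFrame,
                  grid: PolarGridSpec) -> tuple[np.ndarray, np.ndarray]:
    coords = grid_pixel_coords(frame, grid, stack.pixel_size)
    planes = stack.channel(channel)
    maps = np.empty((planes.shape[0],) + grid.shape)
    oob = None
    for z in range(planes.shape[0]):
        maps[z], oob = _sample(planes[z], coords)
    return maps, oob


def _extent_and_mass(values: np.ndarray, mask: np.ndarray, threshold: float,
                     r_values: np.ndarray) -> tuple[float, float]:
    supra = (values >= threshold) & (values > 0) & ~mask
    if not supra.any():
        return -np.inf, 0.0
    extent = float(r_values[np.where(supra.any(axis=1))[0].max()])
    return extent, float(values[supra].sum())


def select_reference_slice(stack: ImageStack, channel: str,
                           frame: StandardFrame,
                           grid: PolarGridSpec | None = None,
                           threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                           _maps=None) -> int:
    """Index of the z-slice showing the longest growth cone.

    The growth-cone extent of each slice is the largest radius among
    suprathreshold grid nodes; the threshold is ``threshold_fraction`` times
    the stack-wide 99.5th-percentile resampled intensity, so dim slices do not
    win on noise.  Extent ties (the grid quantizes extent to one radial step)
    are broken by total suprathreshold intensity, then by lowest index.
    """
    grid = grid or PolarGridSpec()
    if _maps is None:
        maps, oob = _resample_all(stack, channel, frame, grid)
    else:
        maps, oob = _maps
    inb = ~oob
    if not inb.any() or not np.any(maps[:, inb] > 0):
        raise EmptySignalError(
            f"channel {channel}: no signal in any slice of bundle "
            f"{frame.bundle_id}")
    threshold = threshold_fraction * np.percentile(maps[:, inb], 99.5)
    if threshold <= 0:
        raise EmptySignalError(
            f"channel {channel}: no signal in any slice of bundle "
            f"{frame.bundle_id}")
    stats = [_extent_and_mass(m, oob, threshold, grid.r_values) for m in maps]
    extents = np.array([s[0] for s in stats])
    masses = np.array([s[1] for s in stats])
    if not np.isfinite(extents).any():
        raise EmptySignalError(
            f"channel {channel}: no suprathreshold node in any slice of "
            f"bundle {frame.bundle_id}")
    best = extents == extents.max()
    candidates = np.flatnonzero(best)
    return int(candidates[np.argmax(masses[candidates])])


def bundle_density(stack: ImageStack, channel: str, frame: StandardFrame,
                   grid: PolarGridSpec | None = None, window: int = 41,
                   threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
                   ) -> DensityMap:
    """Mean density map over a z-window centred on the reference slice.

    ``window`` must be odd; at stack boundaries the window shrinks (no
    padding) and ``n_slices`` records the count actually averaged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    grid = grid or PolarGridSpec()
    maps, oob = _resample_all(stack, channel, frame, grid)
    ref = select_reference_slice(stack, channel, frame, grid,
                                 threshold_fraction, _maps=(maps, oob))
    half = window // 2
    lo = max(0, ref - half)
    hi = min(maps.shape[0], ref + half + 1)
    return DensityMap(values=maps[lo:hi].mean(axis=0), channel=channel,
                      bundle_id=frame.bundle_id, n_slices=hi - lo, grid=grid,
                      mask=oob, wedge_t3=frame.wedge_t3,
                      wedge_t3p=frame.wedge_t3p)
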