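"""Sensor-space images: flatten the sensor array into 2D and rasterize.

Per subject and condition the channels x time average is converted into a
64 x 64 pixel (3 x 3 mm) by time volume: sensor positions are projected
onto the tangent plane at the vertex (azimuthal equidistant), amplitudes
are linearly interpolated over the pixel grid inside the sensor convex
hull, and the volume is smoothed with a separable Gaussian kernel
(default FWHM 8 mm x 8 mm x 8 ms).  Pixels outside the hull are invalid
and excluded from all downstream statistics rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay

from .layout import SensorLayout

__all__ = [
    "ScalpImage",
    "project_sensors",
    "SensorRasterizer",
    "rasterize",
    "smooth",
    "temporal_mask",
]

GRID_N = 64
PIXEL_MM = 3.0
FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


def grid_axes(n: int = GRID_N, pixel_mm: float = PIXEL_MM) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in mm; the projection origin sits at index n//2."""
    coords = (np.arange(n) - n // 2) * pixel_mm
    return coords, coords


@dataclass
class ScalpImage:
    """64 x 64 x T image volume with axis metadata and validity mask."""

    values: np.ndarray  # (nx, ny, T); NaN outside the validity mask
    x_mm: np.ndarray
    y_mm: np.ndarray
    time_ms: np.ndarray
    validity_mask: np.ndarray  # (nx, ny) boolean, time-independent
    pixel_mm: float = PIXEL_MM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.x_mm.size, self.y_mm.size, self.time_ms.size):
            raise ValueError("values shape does not match axes")
        if self.validity_mask.shape != v.shape[:2]:
            raise ValueError("validity mask shape does not match grid")
        if not np.all(np.isfinite(v[self.validity_mask])):
            raise ValueError("values must be finite on the validity mask")
        self.values = v

    @property
    def time_step_ms(self) -> float:
        return float(np.diff(self.time_ms).mean()) if self.time_ms.size > 1 else np.nan


def project_sensors(layout: SensorLayout) -> np.ndarray:
    """Azimuthal-equidistant projection of sensors about the vertex, in mm.

    A sensor at polar angle theta (from +z) and azimuth phi maps to the
    tangent-plane point at radius r * theta in direction phi, preserving
    great-circle distance from the vertex.
    """
    pos = layout.positions_3d
    r = np.linalg.norm(pos, axis=1)
    theta = np.arccos(np.clip(pos[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    rho_mm = r * theta * 1000.0
    xy = np.column_stack([rho_mm * np.cos(phi), rho_mm * np.sin(phi)])
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate layout: projected sensors are collinear")
    return xy


class SensorRasterizer:
    """Precomputed piecewise-linear interpolation from sensors to the grid.

    Barycentric weights over the Delaunay triangulation of the projected
    sensors are assembled once; each frame is then a single matrix
    product, and the full pipeline is deterministic.
    """

    def __init__(
        self,
        layout: SensorLayout,
        grid_n: int = GRID_N,
        pixel_mm: float = PIXEL_MM,
    ) -> None:
        if layout.n_channels < 3:
            raise ValueError("need at least 3 sensors to interpolate")
        self.layout = layout
        self.pixel_mm = pixel_mm
        self.positions_2d = project_sensors(layout)
        self.x_mm, self.y_mm = grid_axes(grid_n, pixel_mm)
        gx, gy = np.meshgrid(self.x_mm, self.y_mm, indexing="ij")
        pix = np.column_stack([gx.ravel(), gy.ravel()])

        tri = Delaunay(self.positions_2d)
        simplex = tri.find_simplex(pix)
        inside = simplex >= 0
        self.validity_mask = inside.reshape(grid_n, grid_n)

        n_pix = pix.shape[0]
        weights = np.zeros((n_pix, layout.n_channels))
        sidx = simplex[inside]
        transform = tri.transform[sidx]  # (m, 3, 2)
        delta = pix[inside] - transform[:, 2, :]
        bary = np.einsum("mij,mj->mi", transform[:, :2, :], delta)
        bary = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
        verts = tri.simplices[sidx]  # (m, 3) sensor indices
        rows = np.flatnonzero(inside)
        for corner in range(3):
            weights[rows, verts[:, corner]] += bary[:, corner]
        self._weights = weights
        self.grid_n = grid_n

    def rasterize(self, values_at_sensors: np.ndarray) -> np.ndarray:
        """Interpolate sensor values -> (nx, ny[, T]) image, NaN outside hull."""
        v = np.asarray(values_at_sensors, dtype=float)
        single = v.ndim == 1
        if single:
            v = v[:, None]
        img = self._weights @ v  # (n_pix, T)
        img = img.reshape(self.grid_n, self.grid_n, -1)
        img[~self.validity_mask] = np.nan
        return img[..., 0] if single else img

    def volume(self, data: np.ndarray, time_ms: np.ndarray) -> ScalpImage:
        """channels x samples -> ScalpImage."""
        if data.shape[0] != self.layout.n_channels:
            raise ValueError("data channel count does not match layout")
        return ScalpImage(
            values=self.rasterize(data),
            x_mm=self.x_mm,
            y_mm=self.y_mm,
            time_ms=np.asarray(time_ms, dtype=float),
            validity_mask=self.validity_mask,
            pixel_mm=self.pixel_mm,
        )


def rasterize(
    values_at_sensors: np.ndarray,
    layout: SensorLayout,
    grid_n: int = GRID_N,
    pixel_mm: float = PIXEL_MM,
) -> np.ndarray:
    """One-shot linear interpolation of a single frame (convenience)."""
    rast = SensorRasterizer(layout, grid_n, pixel_mm)
    return rast.rasterize(values_at_sensors)


def smooth(
    volume: ScalpImage, fwhm: tuple[float, float, float] = (8.0, 8.0, 8.0)
) -> ScalpImage:
    """Separable Gaussian smoothing (FWHM in mm, mm, ms), mask-renormalized.

    At the hull boundary the kernel is renormalized over valid pixels so
    constants are preserved and no mass leaks into the invalid exterior.
    """
    if any(f <= 0 for f in fwhm):
        raise ValueError("FWHM must be positive on every axis")
    dt = volume.time_step_ms
    sig = (
        fwhm[0] / FWHM_TO_SD / volume.pixel_mm,
        fwhm[1] / FWHM_TO_SD / volume.pixel_mm,
        fwhm[2] / FWHM_TO_SD / dt if volume.time_ms.size > 1 else 0.0,
    )
    mask3 = np.broadcast_to(
        volume.validity_mask[..., None], volume.values.shape
    ).astype(float)
    filled = np.where(np.isfinite(volume.values), volume.values, 0.0)
    num = ndimage.gaussian_filter(filled, sig, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(mask3, sig, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~volume.validity_mask] = np.nan
    return replace(volume, values=out)


def temporal_mask(volume: ScalpImage, window_ms: tuple[float, float]) -> ScalpImage:
    """Restrict the volume to frames with window[0] <= t <= window[1]."""
    lo, hi = window_ms
    if lo > hi:
        raise ValueError(f"empty temporal window {window_ms}")
    keep = (volume.time_ms >= lo) & (volume.time_ms <= hi)
    if not keep.any():
        raise ValueError(f"temporal window {window_ms} contains no frames")
    return replace(
        volume, values=volume.values[..., keep], time_ms=volume.time_ms[keep]
    )
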