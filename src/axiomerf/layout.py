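"""Sensor layouts on a head-centered sphere.

Positions live in meters in a right-handed head frame: +x anterior,
+y left, +z superior, origin at the head center.  MEG layouts emulate a
whole-head axial-gradiometer array (a spherical cap of ~275 sensors);
the EEG layout places the 11 electrodes of a sparse 10-20 montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorLayout",
    "meg_cap_layout",
    "eeg_sparse_1020_layout",
    "dipole_topography",
    "gaussian_topography",
]


@dataclass(frozen=True)
class SensorLayout:
    """Named sensor positions on (or near) a head-centered sphere."""

    channel_ids: tuple[str, ...]
    positions_3d: np.ndarray  # (n_channels, 3), meters
    channel_type: str = "axial_gradiometer"  # or "eeg"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_3d, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions_3d must have shape (n_channels, 3)")
        if pos.shape[0] != len(self.channel_ids):
            raise ValueError("channel_ids and positions_3d disagree in length")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        radii = np.linalg.norm(pos, axis=1)
        if np.any(radii <= 0):
            raise ValueError("all sensor radii must be positive")
        uniq = {tuple(np.round(p, 9)) for p in pos}
        if len(uniq) != pos.shape[0]:
            raise ValueError("sensor positions must be unique")
        object.__setattr__(self, "positions_3d", pos)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"channel {channel_id!r} not in layout") from None


def meg_cap_layout(
    n_channels: int = 275,
    radius_m: float = 0.09,
    max_polar_angle: float = 1.05,
) -> SensorLayout:
    """Quasi-uniform spherical cap of axial gradiometers.

    Sensors are placed on a Fibonacci spiral over polar angles
    [0, ``max_polar_angle``] so that the flattened array fits the 64 x 64
    (3 mm pixel) image grid used downstream.
    """
    k = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    # uniform in cos(theta) between cos(max) and 1 -> even area coverage
    cos_t = 1.0 - (1.0 - np.cos(max_polar_angle)) * (k + 0.5) / n_channels
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = k * golden
    pos = radius_m * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    ids = tuple(f"MEG{i:03d}" for i in range(n_channels))
    return SensorLayout(ids, pos, "axial_gradiometer")


# approximate spherical angles (polar from vertex, azimuth from +x/anterior,
# +y left) for the sparse 10-20 montage used for concurrent EEG
_EEG_1020_ANGLES: dict[str, tuple[float, float]] = {
    "AF7": (0.72, 0.63),
    "AF8": (0.72, -0.63),
    "AFz": (0.63, 0.0),
    "Fz": (0.40, 0.0),
    "Cz": (0.0, 0.0),
    "Pz": (0.40, np.pi),
    "P3": (0.63, 2.44),
    "P4": (0.63, -2.44),
    "M1": (1.45, 1.92),
    "M2": (1.45, -1.92),
    "VEOG": (1.25, 0.17),
}


def eeg_sparse_1020_layout(radius_m: float = 0.09) -> SensorLayout:
    """Eleven-electrode 10-20 montage (plus a vertical EOG channel)."""
    ids, pos = [], []
    for name, (theta, phi) in _EEG_1020_ANGLES.items():
        ids.append(name)
        pos.append(
            [
                radius_m * np.sin(theta) * np.cos(phi),
                radius_m * np.sin(theta) * np.sin(phi),
                radius_m * np.cos(theta),
            ]
        )
    return SensorLayout(tuple(ids), np.asarray(pos), "eeg")


def dipole_topography(
    layout: SensorLayout,
    dipole_pos_m: np.ndarray,
    dipole_moment: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """Radial field component of an ideal current dipole at each sensor.

    A point equivalent-current dipole with moment ``q`` at ``p`` produces,
    at sensor position ``r`` on the helmet, the magnetic field of the
    Biot-Savart point source; axial gradiometers are emulated by the radial
    projection, which yields the bilateral two-lobed pattern characteristic
    of a tangential cortical source.  The same weights serve as an idealized
    potential pattern for EEG fixtures.
    """
    pos = layout.positions_3d
    p = np.asarray(dipole_pos_m, dtype=float)
    q = np.asarray(dipole_moment, dtype=float)
    d = pos - p[None, :]
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < 1e-6):
        raise ValueError("dipole coincides with a sensor position")
    b = np.cross(q[None, :], d) / dist[:, None] ** 3
    radial = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    w = np.sum(b * radial, axis=1)
    if normalize:
        peak = np.max(np.abs(w))
        if peak > 0:
            w = w / peak
    return w


def gaussian_topography(
    layout: SensorLayout, center_channel: str, sigma_rad: float = 0.5
) -> np.ndarray:
    """Unimodal scalp pattern: Gaussian in great-circle angle from a channel.

    Convenient for EEG fixtures where a component should load maximally on
    a named electrode (e.g. a fronto-central negativity at Cz).
    """
    pos = layout.positions_3d
    unit = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    c = unit[layout.index(center_channel)]
    angle = np.arccos(np.clip(unit @ c, -1.0, 1.0))
    return np.exp(-0.5 * (angle / sigma_rad) ** 2)
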