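"""Scan geometry and point-spread-function descriptions.

All lengths are in micrometres and all times in seconds. The pixel dwell
time is the lag between two consecutive pixels of a scan line (``dx / v``
for scanner speed ``v``), not the photon integration time; for a linear
scanner it is a single scalar, for a non-linear (e.g. resonant or
sinusoidal galvo) scanner it is a per-column profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = ["ScanGeometry", "PSFModel"]


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan sampling grid.

    Parameters
    ----------
    nx, ny:
        Pixels per line and lines per frame.
    dx:
        Pixel size in µm (square pixels).
    dwell:
        Pixel dwell time in seconds; a scalar for constant-speed scanners
        or a length-``nx`` per-column profile for non-linear scanners.
    line_retrace, frame_retrace:
        Extra dead time (s) appended after each line / frame.
    """

    nx: int
    ny: int
    dx: float
    dwell: Union[float, np.ndarray]
    line_retrace: float = 0.0
    frame_retrace: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")
        if not self.dx > 0:
            raise ValueError("pixel size dx must be > 0")
        dwell = np.atleast_1d(np.asarray(self.dwell, dtype=float))
        if dwell.ndim != 1:
            raise ValueError("dwell must be a scalar or 1-D per-column profile")
        if dwell.size not in (1, self.nx):
            raise ValueError(
                f"dwell profile has length {dwell.size}, expected 1 or nx={self.nx}"
            )
        if not np.all(dwell > 0):
            raise ValueError("all dwell times must be > 0")
        if self.line_retrace < 0 or self.frame_retrace < 0:
            raise ValueError("retrace times must be >= 0")

    # -- derived quantities -------------------------------------------------
    @property
    def dwell_profile(self) -> np.ndarray:
        """Per-column dwell times, always length ``nx``."""
        dwell = np.atleast_1d(np.asarray(self.dwell, dtype=float))
        if dwell.size == 1:
            return np.full(self.nx, dwell[0])
        return dwell.copy()

    @property
    def has_constant_dwell(self) -> bool:
        dwell = self.dwell_profile
        return bool(np.all(dwell == dwell[0]))

    @property
    def dwell_scalar(self) -> float:
        """The constant dwell time; raises for non-linear profiles."""
        if not self.has_constant_dwell:
            raise ValueError("geometry has a non-constant dwell profile")
        return float(self.dwell_profile[0])

    @property
    def line_time(self) -> float:
        """Time per scanned line, including line retrace."""
        return float(self.dwell_profile.sum() + self.line_retrace)

    @property
    def frame_time(self) -> float:
        """Time per frame, including all retraces."""
        return float(self.ny * self.line_time + self.frame_retrace)

    @property
    def extent(self) -> tuple[float, float]:
        """(x, y) size of the scanned field in µm."""
        return (self.nx * self.dx, self.ny * self.dx)


@dataclass(frozen=True)
class PSFModel:
    """3-D Gaussian observation volume.

    ``w0`` is the lateral 1/e² waist (µm) and ``wz_ratio`` the axial-to-
    lateral aspect ratio w_z/w_0 (about 3 for a confocal PSF).
    """

    w0: float
    wz_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not self.w0 > 0:
            raise ValueError("w0 must be > 0")
        if not self.wz_ratio > 0:
            raise ValueError("wz_ratio must be > 0")

    @property
    def wz(self) -> float:
        return self.w0 * self.wz_ratio
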