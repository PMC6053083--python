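"""Brownian-motion raster-scan simulator.

Generates synthetic image series of point emitters undergoing 3-D free
diffusion while a confocal spot raster-scans the field, pixel by pixel.
Each pixel (frame k, line y, column x) is sampled at the absolute time

    t = k * T_frame + y * T_line + sum_{c<x} dwell(c)

and between two consecutive samples every molecule takes an independent
Gaussian step with per-axis variance ``2 * D * dt`` (motion within a
single dwell interval is neglected; the dwell time acts as a sampling
interval). The expected signal of a pixel is

    sum_molecules  B * dwell(x) * exp(-2 r^2 / w0^2 - 2 z^2 / wz^2)

with ``r`` the lateral distance of the molecule from the pixel centre and
``z`` its axial offset from the focal plane; with shot noise enabled the
recorded value is Poisson-distributed around that expectation.

Molecules live in a periodic box extending beyond the scanned field
(2 µm laterally and +-3 wz axially by default) so that the concentration
is conserved; the convention mirrors standard FCS simulators. When the
diffusion coefficient is a per-pixel zone map, each molecule steps with
the D of the zone containing its current lateral position (molecules
outside the mapped field use the nearest zone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from numba import njit

from .geometry import PSFModel, ScanGeometry

__all__ = [
    "SimConfig",
    "RasterStack",
    "simulate_stack",
    "make_zone_map",
    "make_dwell_profile",
    "molecules_for_concentration",
    "DEFAULT_CONCENTRATION",
]

# Default molecule concentration (µm^-3): 2500 molecules distributed over
# the simulation box belonging to the reference acquisition (256 x 256
# pixels of 20 nm with the default box padding). Used whenever a
# SimConfig does not pin the molecule count explicitly.
DEFAULT_CONCENTRATION = 2500.0 / ((256 * 0.02 + 2 * 2.0) ** 2 * (2 * 3 * 3.0 * 0.16))


@dataclass
class SimConfig:
    """Physical parameters of one simulated acquisition.

    ``d_map`` is either a scalar diffusion coefficient (µm² s⁻¹) or a
    per-pixel ground-truth map with shape ``(ny, nx)``. ``brightness`` is
    the detected count rate per molecule at the PSF centre (counts/s).
    """

    n_molecules: int
    brightness: float
    d_map: Union[float, np.ndarray]
    n_frames: int
    seed: int = 0
    noise: bool = True
    box_margin: float = 2.0      # lateral padding beyond the field, µm
    half_depth: Optional[float] = None  # axial half-depth, µm; default 3*wz
    initial_positions: Optional[np.ndarray] = None  # (n, 3), for testing

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not np.all(np.asarray(self.d_map, dtype=float) > 0):
            raise ValueError("all diffusion coefficients must be > 0")
        if self.box_margin < 0:
            raise ValueError("box_margin must be >= 0")


@dataclass
class RasterStack:
    """N frames of raster-scanned intensities plus acquisition metadata."""

    data: np.ndarray                 # (n_frames, ny, nx), counts
    geometry: ScanGeometry
    psf: Optional[PSFModel] = None
    ground_truth: Optional[Union[float, np.ndarray]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (n_frames, ny, nx)")
        if self.data.shape[1:] != (self.geometry.ny, self.geometry.nx):
            raise ValueError(
                f"data shape {self.data.shape[1:]} does not match geometry "
                f"({self.geometry.ny}, {self.geometry.nx})"
            )
        # raw acquisitions are non-negative; background-subtracted
        # fluctuation stacks (meta["preprocessed"]) may dip below zero
        if (self.data.size and not self.meta.get("preprocessed")
                and np.nanmin(self.data) < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def molecules_for_concentration(
    geometry: ScanGeometry,
    psf: PSFModel,
    concentration: float = DEFAULT_CONCENTRATION,
    box_margin: float = 2.0,
    half_depth: Optional[float] = None,
) -> int:
    """Molecule count giving ``concentration`` (µm^-3) in the periodic box."""
    if half_depth is None:
        half_depth = 3.0 * psf.wz
    lx = geometry.nx * geometry.dx + 2 * box_margin
    ly = geometry.ny * geometry.dx + 2 * box_margin
    volume = lx * ly * 2 * half_depth
    return max(1, int(round(concentration * volume)))


@njit(cache=True, fastmath=True)
def _scan_kernel(n_frames, ny, nx, dwell, line_retrace, frame_retrace, dx,
                 pos, box_lo, box_size, d_scalar, d_map, use_map,
                 brightness, w0, wz, rng, out):  # pragma: no cover
    n_mol = pos.shape[0]
    inv_w02 = 2.0 / (w0 * w0)
    inv_wz2 = 2.0 / (wz * wz)
    r2cut = (4.0 * w0) ** 2
    zcut = 4.0 * wz
    inv_dx = 1.0 / dx
    x_lo = box_lo[0]
    y_lo = box_lo[1]
    z_lo = box_lo[2]
    x_hi = x_lo + box_size[0]
    y_hi = y_lo + box_size[1]
    z_hi = z_lo + box_size[2]
    for k in range(n_frames):
        for y in range(ny):
            yc = y * dx
            for x in range(nx):
                if k == 0 and y == 0 and x == 0:
                    dt = 0.0
                elif x > 0:
                    dt = dwell[x - 1]
                elif y > 0:
                    dt = dwell[nx - 1] + line_retrace
                else:
                    dt = dwell[nx - 1] + line_retrace + frame_retrace
                xc = x * dx
                em = 0.0
                if dt > 0.0:
                    sig_const = math.sqrt(2.0 * d_scalar * dt)
                    for i in range(n_mol):
                        if use_map:
                            ix = int(math.floor(pos[i, 0] * inv_dx + 0.5))
                            iy = int(math.floor(pos[i, 1] * inv_dx + 0.5))
                            if ix < 0:
                                ix = 0
                            elif ix >= nx:
                                ix = nx - 1
                            if iy < 0:
                                iy = 0
                            elif iy >= ny:
                                iy = ny - 1
                            sig = math.sqrt(2.0 * d_map[iy, ix] * dt)
                        else:
                            sig = sig_const
                        px = pos[i, 0] + sig * rng.standard_normal()
                        py = pos[i, 1] + sig * rng.standard_normal()
                        pz = pos[i, 2] + sig * rng.standard_normal()
                        # periodic wrap (single Brownian steps are far
                        # smaller than the box, one correction suffices)
                        if px < x_lo:
                            px += box_size[0]
                        elif px >= x_hi:
                            px -= box_size[0]
                        if py < y_lo:
                            py += box_size[1]
                        elif py >= y_hi:
                            py -= box_size[1]
                        if pz < z_lo:
                            pz += box_size[2]
                        elif pz >= z_hi:
                            pz -= box_size[2]
                        pos[i, 0] = px
                        pos[i, 1] = py
                        pos[i, 2] = pz
                        dxr = px - xc
                        dyr = py - yc
                        rr = dxr * dxr + dyr * dyr
                        if rr < r2cut and -zcut < pz < zcut:
                            em += math.exp(-rr * inv_w02 - pz * pz * inv_wz2)
                else:
                    for i in range(n_mol):
                        dxr = pos[i, 0] - xc
                        dyr = pos[i, 1] - yc
                        rr = dxr * dxr + dyr * dyr
                        pz = pos[i, 2]
                        if rr < r2cut and -zcut < pz < zcut:
                            em += math.exp(-rr * inv_w02 - pz * pz * inv_wz2)
                out[k, y, x] = brightness * dwell[x] * em


def simulate_stack(
    config: SimConfig, geometry: ScanGeometry, psf: PSFModel
) -> RasterStack:
    """Run a raster-scan acquisition over Brownian molecules.

    Returns a :class:`RasterStack` whose ``meta`` records the seed, the
    simulation box and the molecule count, and whose ``ground_truth``
    holds the configured diffusion map.
    """
    dwell = geometry.dwell_profile
    d_arr = np.asarray(config.d_map, dtype=float)
    use_map = d_arr.ndim > 0
    if use_map:
        if d_arr.shape != (geometry.ny, geometry.nx):
            raise ValueError(
                f"d_map shape {d_arr.shape} does not match field "
                f"({geometry.ny}, {geometry.nx})"
            )
        d_map = np.ascontiguousarray(d_arr)
        d_scalar = 0.0
    else:
        d_map = np.zeros((1, 1))
        d_scalar = float(d_arr)

    half_depth = config.half_depth
    if half_depth is None:
        half_depth = 3.0 * psf.wz
    margin = config.box_margin
    # pixel centres span [0, (n-1)*dx]; the box must strictly contain the
    # field plus margin
    box_lo = np.array([-margin, -margin, -half_depth])
    box_hi = np.array(
        [(geometry.nx - 1) * geometry.dx + margin,
         (geometry.ny - 1) * geometry.dx + margin,
         half_depth]
    )
    box_size = box_hi - box_lo
    if np.any(box_size <= 0):
        raise ValueError("simulation box has non-positive extent")

    rng = np.random.default_rng(config.seed)
    if config.initial_positions is not None:
        pos = np.array(config.initial_positions, dtype=float)
        if pos.shape != (config.n_molecules, 3):
            raise ValueError("initial_positions must have shape (n_molecules, 3)")
    else:
        pos = box_lo + rng.random((config.n_molecules, 3)) * box_size
    pos = np.ascontiguousarray(pos)

    out = np.empty((config.n_frames, geometry.ny, geometry.nx), dtype=np.float64)
    _scan_kernel(
        config.n_frames, geometry.ny, geometry.nx, dwell,
        float(geometry.line_retrace), float(geometry.frame_retrace),
        float(geometry.dx), pos, box_lo, box_size, d_scalar, d_map,
        use_map, float(config.brightness), float(psf.w0), float(psf.wz),
        rng, out,
    )
    if config.noise:
        # shot noise: the kernel returns expectations, the detector
        # records Poisson counts
        out = rng.poisson(out).astype(np.float64)
    meta = {
        "seed": int(config.seed),
        "n_molecules": int(config.n_molecules),
        "brightness": float(config.brightness),
        "noise": bool(config.noise),
        "box_lo": box_lo.tolist(),
        "box_hi": box_hi.tolist(),
    }
    ground_truth = d_map.copy() if use_map else d_scalar
    return RasterStack(out, geometry, psf, ground_truth, meta)


def make_zone_map(
    nx: int, ny: int, zone_widths, d_values, axis: str = "y"
) -> np.ndarray:
    """Piecewise-constant diffusion map of stacked zones.

    Zones are stacked along ``axis`` ("y": horizontal bands, the layout
    of the three-zone benchmark; "x": vertical bands). ``zone_widths``
    must sum to the field size along that axis.
    """
    widths = [int(w) for w in zone_widths]
    values = [float(v) for v in d_values]
    if len(widths) != len(values):
        raise ValueError("zone_widths and d_values must have equal length")
    if any(v <= 0 for v in values):
        raise ValueError("all diffusion coefficients must be > 0")
    size = ny if axis == "y" else nx
    if sum(widths) != size:
        raise ValueError(
            f"zone widths sum to {sum(widths)}, expected {size} along {axis}"
        )
    profile = np.repeat(values, widths)
    if axis == "y":
        return np.tile(profile[:, None], (1, nx))
    return np.tile(profile[None, :], (ny, 1))


def make_dwell_profile(nx: int, kind: str, params: dict) -> np.ndarray:
    """Per-column dwell-time profile for a (possibly non-linear) scanner.

    Kinds:

    - ``"constant"``: params ``{"tau": value}``.
    - ``"polynomial"``: params ``{"coeffs": [...]}`` evaluated over the
      normalized coordinate u in [-1, 1] (highest order first).
    - ``"edge_slowdown"``: params ``{"tau_min", "tau_max"}``; dwell is
      minimal at mid-line and rises sinusoidally toward both borders,
      emulating galvo turnaround.
    """
    if nx < 1:
        raise ValueError("nx must be >= 1")
    u = np.linspace(-1.0, 1.0, nx) if nx > 1 else np.zeros(1)
    if kind == "constant":
        profile = np.full(nx, float(params["tau"]))
    elif kind == "polynomial":
        profile = np.polyval(np.asarray(params["coeffs"], dtype=float), u)
    elif kind in ("edge_slowdown", "sinusoidal-edge-slowdown"):
        tau_min = float(params["tau_min"])
        tau_max = float(params["tau_max"])
        profile = tau_min + (tau_max - tau_min) * np.sin(u * np.pi / 2) ** 2
    else:
        raise ValueError(f"unknown dwell profile kind: {kind!r}")
    if not np.all(profile > 0):
        raise ValueError("dwell profile must be strictly positive everywhere")
    return profile
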