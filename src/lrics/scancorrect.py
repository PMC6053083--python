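"""Characterization and correction of non-constant scanner speed.

On scanners whose speed varies along a line (resonant or sinusoidal
galvos) the pixel dwell time τ — the lag between consecutive pixels,
δx/v — is a function of the column x. Local correlation analysis only
requires the speed to be constant over one mask, so the phase map of a
*uniform* sample of known diffusion coefficient directly exposes the
dwell-time profile: averaging the phase map along y, smoothing the
profile with a low-order polynomial, inverting it through the φ(K_t)
calibration, and scaling with the known D gives

    τ(x) = K_t(x) · w0² / (4 D).

The 2-D dwell map is the profile copied along y (the scanner speed does
not depend on the line). Feeding this map into the phase → D inversion
removes the border bias that a constant-dwell assumption produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import CalibrationCurve, CalibrationError, DiffusionMap, phase_to_d
from .phasor import PhaseMap

__all__ = ["DwellTimeProfile", "estimate_dwell_profile", "corrected_diffusion_map"]


@dataclass
class DwellTimeProfile:
    """Per-column dwell times estimated from a calibration sample."""

    tau_x: np.ndarray            # length nx, NaN at invalid border columns
    poly_coeffs: np.ndarray      # polynomial fitted to the y-averaged phase
    valid_cols: np.ndarray       # bool, length nx
    d_known: float
    meta: dict = field(default_factory=dict)

    def dwell_map(self, ny: int) -> np.ndarray:
        """2-D dwell-time map: the profile copied along the y axis."""
        return np.tile(self.tau_x[None, :], (ny, 1))


def estimate_dwell_profile(
    pmap: PhaseMap,
    cal: CalibrationCurve,
    d_known: float,
    w0: float,
    poly_degree: int = 4,
) -> DwellTimeProfile:
    """Estimate τ(x) from the phase map of a uniform known-D sample.

    The phase image is averaged along y over the valid rows, fitted with
    a polynomial of ``poly_degree`` over the valid columns, inverted
    through the calibration to K_t(x), and scaled by the known D. An
    error is raised if the smoothed profile leaves the invertible phase
    range of the calibration.
    """
    if d_known <= 0:
        raise ValueError("d_known must be > 0")
    if cal.m != pmap.m:
        raise CalibrationError(
            f"calibration mask m={cal.m} does not match phase map m={pmap.m}"
        )
    phi = np.where(pmap.valid, pmap.phi, np.nan)
    nx = phi.shape[1]
    col_n = np.sum(pmap.valid & np.isfinite(pmap.phi), axis=0)
    col_phi = np.where(col_n > 0,
                       np.nansum(phi, axis=0) / np.maximum(col_n, 1), np.nan)
    valid_cols = (col_n > 0) & np.isfinite(col_phi)
    if valid_cols.sum() <= poly_degree:
        raise ValueError("too few valid columns for the polynomial degree")

    x = np.arange(nx, dtype=float)
    series = np.polynomial.Polynomial.fit(
        x[valid_cols], col_phi[valid_cols], deg=poly_degree
    )
    phi_smooth = series(x)
    kt = cal.kt_of_phi(phi_smooth)
    if np.any(~np.isfinite(kt[valid_cols])):
        raise CalibrationError(
            "smoothed phase profile leaves the invertible range of the "
            "calibration; check d_known and the calibration K_t range"
        )
    tau = kt * w0**2 / (4.0 * d_known)
    tau = np.where(valid_cols, tau, np.nan)
    return DwellTimeProfile(
        tau_x=tau,
        poly_coeffs=series.convert().coef,
        valid_cols=valid_cols,
        d_known=float(d_known),
        meta={"poly_degree": int(poly_degree),
              "calibration": f"ks={cal.ks},m={cal.m}"},
    )


def corrected_diffusion_map(
    pmap: PhaseMap,
    cal: CalibrationCurve,
    profile: DwellTimeProfile,
    w0: float,
    *,
    clamp: bool = False,
) -> DiffusionMap:
    """Phase → D inversion using the per-column dwell-time profile.

    Identical to :func:`lrics.calibration.phase_to_d` with a scalar
    dwell when the profile is flat; with a non-trivial profile it
    removes the border bias of the uncorrected map.
    """
    if profile.tau_x.size != pmap.phi.shape[1]:
        raise ValueError(
            f"profile length {profile.tau_x.size} does not match map width "
            f"{pmap.phi.shape[1]}"
        )
    tau = profile.tau_x.copy()
    # NaN dwell (border columns) invalidates those pixels downstream,
    # but phase_to_d requires positive dwell values; substitute a
    # placeholder and mask afterwards
    invalid_cols = ~np.isfinite(tau) | (tau <= 0)
    tau[invalid_cols] = np.nanmax(tau) if np.any(np.isfinite(tau)) else 1.0
    dmap = phase_to_d(pmap, cal, tau, w0, clamp=clamp,
                      calibration_id=profile.meta.get("calibration"))
    dmap.d[:, invalid_cols] = np.nan
    dmap.valid[:, invalid_cols] = False
    dmap.provenance["dwell"] = "profile"
    dmap.provenance["d_known"] = profile.d_known
    return dmap
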