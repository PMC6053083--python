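"""Phasor transform of local ACFs and phase maps.

Each L-point local ACF is summarized by its normalized first harmonic

    g = Σ_ξ G(ξ) cos(2πξ/L) / Σ_ξ G(ξ)
    s = Σ_ξ G(ξ) sin(2πξ/L) / Σ_ξ G(ξ)
    φ = atan2(s, g)

i.e. the k = 1 coefficient of the L-point DFT (cosine → real part,
sine → negative imaginary part), normalized by the k = 0 coefficient.
The phase φ is an offset- and amplitude-free descriptor of how fast the
ACF decays: slowly decaying ACFs (slow diffusion) give larger phases,
fast decays give smaller ones. A pixel whose zeroth harmonic vanishes
has an undefined phase and is flagged, not thrown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import PSFModel, ScanGeometry
from .localacf import LocalACFField

__all__ = ["PhaseMap", "phasor_transform", "phase_map", "phase_error",
           "phase_std"]

# Sign convention (fixed): s = -Im(DFT_1)/DFT_0, which makes slower
# decay -> larger positive phase.
PHASOR_CONVENTION = "dft-k1; g=Re/F0, s=-Im/F0"

_EPS = 1e-300


@dataclass
class PhaseMap:
    """Per-pixel phasor phase of the local ACFs."""

    phi: np.ndarray              # radians, NaN where undefined
    g: np.ndarray
    s: np.ndarray
    m: int
    valid: np.ndarray            # bool, phase defined here
    geometry: Optional[ScanGeometry] = None
    psf: Optional[PSFModel] = None
    mask_kind: str = "square"

    @property
    def L(self) -> int:
        return (self.m + 1) // 2


def phasor_transform(acf: np.ndarray):
    """First-harmonic phasor coordinates of L-point ACF(s).

    ``acf`` may be a single 1-D sequence or an array whose last axis is
    the lag axis (the zero-lag point is expected to be replaced
    already). Returns ``(g, s)`` with NaN where the zeroth harmonic is
    zero or the input is not finite.
    """
    acf = np.asarray(acf, dtype=np.float64)
    f = np.fft.fft(acf, axis=-1)
    f0 = f[..., 0].real
    f1 = f[..., 1]
    bad = ~np.isfinite(f0) | (np.abs(f0) < _EPS) | ~np.isfinite(f1.real)
    denom = np.where(bad, 1.0, f0)
    g = np.where(bad, np.nan, f1.real / denom)
    s = np.where(bad, np.nan, -f1.imag / denom)
    return g, s


def phase_map(field: LocalACFField) -> PhaseMap:
    """Apply the phasor transform at every valid pixel of a field."""
    g, s = phasor_transform(field.values)
    phi = np.arctan2(s, g)
    phi = np.where(np.isnan(g) | np.isnan(s), np.nan, phi)
    valid = field.valid & np.isfinite(phi)
    mask_kind = "line" if field.values.shape[0] == 1 else "square"
    if field.geometry is not None and field.geometry.ny == 1:
        mask_kind = "line"
    return PhaseMap(phi, g, s, field.m, valid, field.geometry, field.psf,
                    mask_kind=mask_kind)


def phase_std(pmap: PhaseMap) -> float:
    """Absolute phase error σ_φ: standard deviation over the phase image."""
    vals = pmap.phi[pmap.valid]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("phase map has no valid pixels")
    return float(np.std(vals))


def phase_error(pmap: PhaseMap) -> float:
    """Relative phase error σ_φ / ⟨φ⟩ over the valid region.

    Meaningful for spatially uniform samples, where the spread of the
    phase image is pure noise.
    """
    vals = pmap.phi[pmap.valid]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("phase map has no valid pixels")
    mean = np.mean(vals)
    if mean == 0:
        raise ValueError("mean phase is zero; relative error undefined")
    return float(np.std(vals) / abs(mean))
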