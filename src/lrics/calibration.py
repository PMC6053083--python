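"""Simulation-built calibration curves φ(K_t) and phase → D inversion.

The shape of a local ACF — and therefore its phasor phase — depends only
on the spatial sampling K_s = δx/w0, the temporal sampling
K_t = 4Dτ/w0² = τ/τ_D, the mask size m and the ACF convention. For
fixed (K_s, m) a series of uniform-diffusion simulations spanning the
working K_t range therefore defines a smooth, monotone calibration
φ(K_t), which is fitted with a three-parameter exponential decay

    φ(K_t) = a · exp(-K_t / b) + c

and inverted analytically to turn measured phases into diffusion
coefficients: K_t = -b ln((φ - c)/a), D = K_t w0² / (4τ). The dwell
time may be a per-pixel map, which is what makes correction of
non-linear scanners possible.

Calibration simulations use high molecular brightness (3 MHz by
default) and many frames so that calibration noise is negligible
compared to measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .geometry import PSFModel, ScanGeometry
from .localacf import ACF_CONVENTION, local_acf_map
from .phasor import PhaseMap, phase_map
from .preprocess import subtract_global_mean
from .sim import DEFAULT_CONCENTRATION, SimConfig, molecules_for_concentration, simulate_stack

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "DiffusionMap",
    "kt_from_d",
    "d_from_kt",
    "build_calibration",
    "phase_to_d",
]

DEFAULT_D_GRID = tuple(np.linspace(4.0, 36.0, 9))  # µm² s⁻¹ working range


class CalibrationError(RuntimeError):
    """Raised when a calibration cannot be built or does not apply."""


def kt_from_d(d, dwell, w0: float):
    """Temporal sampling constant K_t = 4 D τ / w0²."""
    return 4.0 * np.asarray(d, dtype=np.float64) * dwell / w0**2


def d_from_kt(kt, dwell, w0: float):
    """Inverse of :func:`kt_from_d`: D = K_t w0² / (4 τ)."""
    return np.asarray(kt, dtype=np.float64) * w0**2 / (4.0 * dwell)


@dataclass
class CalibrationCurve:
    """Fitted φ(K_t) relationship for fixed (K_s, m, mask kind)."""

    ks: float
    m: int
    samples: list            # dicts: d_sim, kt, phi_mean, phi_std
    a: float
    b: float
    c: float
    wz_ratio: float = 3.0
    mask_kind: str = "square"
    acf_convention: str = ACF_CONVENTION
    fit_rss: float = float("nan")
    provenance: dict = dataclass_field(default_factory=dict)

    def phi_of_kt(self, kt):
        """Evaluate the fitted curve."""
        return self.a * np.exp(-np.asarray(kt, dtype=np.float64) / self.b) + self.c

    @property
    def kt_range(self) -> tuple[float, float]:
        kts = [s["kt"] for s in self.samples]
        return (min(kts), max(kts))

    @property
    def phi_range(self) -> tuple[float, float]:
        """Invertible phase interval (open at the asymptote c)."""
        return (self.c, self.a + self.c) if self.a > 0 else (self.a + self.c, self.c)

    def kt_of_phi(self, phi, clamp: bool = False):
        """Analytic inverse K_t(φ); NaN where φ is outside the range.

        With ``clamp=True`` out-of-range phases are clipped to the
        phases of the sampled K_t endpoints instead of being flagged.
        """
        phi = np.asarray(phi, dtype=np.float64)
        if clamp:
            lo, hi = self.kt_range
            phi_hi, phi_lo = self.phi_of_kt(lo), self.phi_of_kt(hi)
            phi = np.clip(phi, min(phi_lo, phi_hi), max(phi_lo, phi_hi))
        with np.errstate(invalid="ignore", divide="ignore"):
            arg = (phi - self.c) / self.a
            kt = np.where(arg > 0, -self.b * np.log(np.maximum(arg, 1e-300)), np.nan)
        kt = np.where(kt < 0, np.nan, kt)
        return kt

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "lrics.calibration/1",
            "ks": self.ks, "m": self.m, "wz_ratio": self.wz_ratio,
            "mask_kind": self.mask_kind, "acf_convention": self.acf_convention,
            "fit": {"form": "a*exp(-kt/b)+c", "a": self.a, "b": self.b,
                    "c": self.c, "rss": self.fit_rss},
            "samples": self.samples,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        fit = d["fit"]
        return cls(
            ks=d["ks"], m=d["m"], samples=d["samples"],
            a=fit["a"], b=fit["b"], c=fit["c"],
            wz_ratio=d.get("wz_ratio", 3.0),
            mask_kind=d.get("mask_kind", "square"),
            acf_convention=d.get("acf_convention", ACF_CONVENTION),
            fit_rss=fit.get("rss", float("nan")),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def validate_monotone(samples: list) -> None:
    """Reject calibration samples whose mean phase does not decrease
    with K_t beyond its sampling noise."""
    for lo, hi in zip(samples[:-1], samples[1:]):
        slack = 3.0 * (lo["phi_std"] + hi["phi_std"]) / np.sqrt(
            max(lo.get("n_pixels", 1), 1))
        if hi["phi_mean"] >= lo["phi_mean"] + slack:
            raise CalibrationError(
                "calibration samples are not monotone decreasing in K_t: "
                f"phi({lo['kt']:.4f})={lo['phi_mean']:.4f} vs "
                f"phi({hi['kt']:.4f})={hi['phi_mean']:.4f}"
            )


def fit_exponential_decay(kt: np.ndarray, phi: np.ndarray):
    """Fit φ = a·exp(-kt/b) + c by least squares; returns (a, b, c, rss)."""
    kt = np.asarray(kt, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    span = phi.max() - phi.min()
    p0 = (max(span, 1e-6), max((kt.max() - kt.min()) / 2.0, 1e-6),
          phi.min() - 0.05 * span)
    popt, _ = optimize.curve_fit(
        lambda x, a, b, c: a * np.exp(-x / b) + c, kt, phi, p0=p0, maxfev=20000
    )
    rss = float(np.sum((phi - (popt[0] * np.exp(-kt / popt[1]) + popt[2])) ** 2))
    return float(popt[0]), float(popt[1]), float(popt[2]), rss


def build_calibration(
    ks: float = 0.125,
    m: int = 25,
    d_values: Sequence[float] = DEFAULT_D_GRID,
    *,
    dx: float = 0.02,
    dwell: float = 50e-6,
    wz_ratio: float = 3.0,
    nx: int = 64,
    ny: int = 64,
    n_frames: int = 250,
    brightness: float = 3e6,
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int = 12345,
    mask_kind: str = "square",
) -> CalibrationCurve:
    """Build a φ(K_t) calibration from uniform-diffusion simulations.

    One simulation per diffusion coefficient in ``d_values`` (the
    default grid spans the 4-36 µm² s⁻¹ working range) is run at fixed
    K_s = δx/w0, the mean phase of each map is recorded against its
    K_t, and the samples are fitted with an exponential decay. The
    samples must be monotone decreasing beyond their noise, otherwise
    the calibration is rejected.

    ``mask_kind="line"`` calibrates 1×m masks on repeated line scans
    (``ny`` is then the number of lines per simulated acquisition).
    """
    w0 = dx / ks
    psf = PSFModel(w0, wz_ratio)
    if mask_kind == "line":
        geometry = ScanGeometry(nx, 1, dx, dwell)
        n_frames_eff = ny * n_frames  # repeated lines play the role of frames
    elif mask_kind == "square":
        geometry = ScanGeometry(nx, ny, dx, dwell)
        n_frames_eff = n_frames
    else:
        raise ValueError("mask_kind must be 'square' or 'line'")
    n_mol = molecules_for_concentration(geometry, psf, concentration)

    samples = []
    for idx, d in enumerate(sorted(float(v) for v in d_values)):
        cfg = SimConfig(
            n_molecules=n_mol, brightness=brightness, d_map=d,
            n_frames=n_frames_eff, seed=seed + idx, noise=True,
        )
        stack = subtract_global_mean(simulate_stack(cfg, geometry, psf))
        pmap = phase_map(local_acf_map(stack, m))
        phis = pmap.phi[pmap.valid]
        n_pix = phis.size
        if n_pix == 0:
            raise CalibrationError(f"no valid phases for D={d}")
        samples.append({
            "d_sim": d,
            "kt": float(kt_from_d(d, dwell, w0)),
            "phi_mean": float(np.mean(phis)),
            "phi_std": float(np.std(phis)),
            "n_pixels": int(n_pix),
        })

    samples.sort(key=lambda s: s["kt"])
    validate_monotone(samples)

    kt = np.array([s["kt"] for s in samples])
    phi = np.array([s["phi_mean"] for s in samples])
    a, b, c, rss = fit_exponential_decay(kt, phi)
    provenance = {
        "seed": seed, "dx": dx, "dwell": dwell, "w0": w0,
        "nx": nx, "ny": ny, "n_frames": n_frames,
        "brightness": brightness, "n_molecules": n_mol,
        "concentration": concentration,
    }
    return CalibrationCurve(
        ks=ks, m=m, samples=samples, a=a, b=b, c=c, wz_ratio=wz_ratio,
        mask_kind=mask_kind, fit_rss=rss, provenance=provenance,
    )


@dataclass
class DiffusionMap:
    """Per-pixel diffusion coefficients in µm² s⁻¹."""

    d: np.ndarray
    valid: np.ndarray            # D defined here
    m: int
    out_of_range: np.ndarray = None  # phase defined but outside calibration
    provenance: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.out_of_range is None:
            self.out_of_range = np.zeros_like(self.valid)


def phase_to_d(
    pmap: PhaseMap,
    cal: CalibrationCurve,
    dwell: Union[float, np.ndarray],
    w0: float,
    *,
    clamp: bool = False,
    calibration_id: Optional[str] = None,
) -> DiffusionMap:
    """Invert a phase map into a diffusion map through a calibration.

    ``dwell`` may be a scalar, a per-column profile (nx,), or a full
    per-pixel map (ny, nx) — the latter two are what scanner-speed
    correction uses. Phases outside the invertible range of the fit are
    flagged NaN unless ``clamp`` is set.
    """
    if cal.m != pmap.m:
        raise CalibrationError(
            f"calibration mask m={cal.m} does not match phase map m={pmap.m}"
        )
    if cal.mask_kind != pmap.mask_kind:
        raise CalibrationError(
            f"calibration mask kind {cal.mask_kind!r} does not match "
            f"phase map {pmap.mask_kind!r}"
        )
    if pmap.geometry is not None and pmap.psf is not None:
        ks_map = pmap.geometry.dx / pmap.psf.w0
        if abs(ks_map - cal.ks) > 1e-9:
            raise CalibrationError(
                f"calibration K_s={cal.ks} does not match acquisition "
                f"K_s={ks_map}"
            )
    dwell_arr = np.asarray(dwell, dtype=np.float64)
    if dwell_arr.ndim == 1:
        dwell_arr = dwell_arr[None, :]
    if np.any(dwell_arr <= 0):
        raise ValueError("dwell times must be > 0")
    kt = cal.kt_of_phi(pmap.phi, clamp=clamp)
    d = d_from_kt(kt, dwell_arr, w0)
    d = np.where(pmap.valid, d, np.nan)
    provenance = {
        "calibration": calibration_id or f"ks={cal.ks},m={cal.m},{cal.mask_kind}",
        "clamped": bool(clamp),
        "dwell": "map" if np.asarray(dwell).ndim else float(dwell),
        "w0": float(w0),
    }
    valid = pmap.valid & np.isfinite(d)
    out_of_range = pmap.valid & ~np.isfinite(d)
    return DiffusionMap(d, valid, pmap.m, out_of_range, provenance)
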