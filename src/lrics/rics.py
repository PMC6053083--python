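"""Whole-image ("global") RICS: spatial ACF and one-component model fit.

The spatial autocorrelation of a raster-scanned image mixes spatial and
temporal information because consecutive pixels along a line are also
consecutive in time (separated by the dwell time τ). For 3-D free
diffusion and a Gaussian observation volume, the x-axis ACF is

    G(ξ) = G(0) · exp(-(|ξ| K_s)² / (1 + K_t(ξ)))
                · (1 + K_t(ξ))^-1 · (1 + (w0/wz)² K_t(ξ))^-1/2

with K_s = δx/w0 the spatial sampling constant and
K_t(ξ) = 4 D τ |ξ| / w0² the temporal sampling constant evaluated at the
elapsed time τ·|ξ| of the lag (K_t = τ/τ_D per pixel step, τ_D = w0²/4D).
Fitting G(ξ) for ξ ≥ 1 yields the average diffusion coefficient of the
imaged field; the ξ = 0 point carries the uncorrelated shot-noise spike
and is excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .geometry import PSFModel, ScanGeometry
from .sim import RasterStack

__all__ = [
    "ACF2D",
    "ACF1D",
    "RICSFitResult",
    "global_acf",
    "acf_x_profile",
    "rics_model_1d",
    "fit_rics_1d",
]


@dataclass
class ACF2D:
    """Frame-averaged spatial ACF over lags (ξ, η), centred at (0, 0)."""

    values: np.ndarray       # (2*max_lag+1, 2*max_lag+1), index [η, ξ]
    max_lag: int
    n_frames: int

    def at(self, xi: int, eta: int) -> float:
        return float(self.values[eta + self.max_lag, xi + self.max_lag])


@dataclass
class ACF1D:
    """x-axis ACF G(ξ, 0) over ξ = 0..max_lag."""

    values: np.ndarray
    n_frames: int

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.values.size)


@dataclass
class RICSFitResult:
    g0: float
    d: float                    # µm² s⁻¹
    ks: float
    residuals: np.ndarray
    cov: Optional[np.ndarray]   # covariance of (g0, d)
    success: bool
    message: str = ""

    @property
    def d_err(self) -> float:
        if self.cov is None:
            return float("nan")
        return float(np.sqrt(self.cov[1, 1]))


def global_acf(stack: RasterStack, max_lag: int) -> ACF2D:
    """Per-frame normalized spatial ACF, averaged over frames.

    Computed with zero-padded FFT correlation (no circular wrap) and
    normalized per lag by the number of overlapping pixel pairs; each
    frame is normalized by its own squared mean before averaging.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    n, ny, nx = data.shape
    if max_lag >= min(nx, ny):
        raise ValueError("max_lag must be smaller than the image size")
    fy, fx = 2 * ny, 2 * nx  # zero padding to avoid wrap-around
    ones = np.ones((ny, nx))
    counts = np.fft.irfft2(np.abs(np.fft.rfft2(ones, s=(fy, fx))) ** 2, s=(fy, fx))
    counts = np.round(counts).astype(np.int64)
    acc = np.zeros((fy, fx))
    for k in range(n):
        frame = data[k]
        mean = frame.mean()
        if not abs(mean) > 0:
            raise ValueError(f"frame {k} has zero mean; cannot normalize the ACF")
        corr = np.fft.irfft2(np.abs(np.fft.rfft2(frame, s=(fy, fx))) ** 2, s=(fy, fx))
        with np.errstate(invalid="ignore", divide="ignore"):
            g = corr / (counts * mean * mean) - 1.0
        acc += np.where(counts > 0, g, 0.0)
    acc /= n
    # re-centre: lag index 0 -> centre
    acc = np.fft.fftshift(acc)
    c_y, c_x = fy // 2, fx // 2
    sl = acc[c_y - max_lag:c_y + max_lag + 1, c_x - max_lag:c_x + max_lag + 1]
    return ACF2D(sl.copy(), max_lag, n)


def acf_x_profile(acf: ACF2D) -> ACF1D:
    """Reduce a 2-D ACF to the x-axis profile G(ξ, 0), ξ = 0..max_lag.

    Positive and negative ξ branches are averaged (the ACF is symmetric
    under lag negation up to estimation noise).
    """
    row = acf.values[acf.max_lag]
    centre = acf.max_lag
    pos = row[centre:]
    neg = row[centre::-1]
    return ACF1D((pos + neg) / 2.0, acf.n_frames)


def rics_model_1d(
    xi, g0: float, d: float, geometry: ScanGeometry, psf: PSFModel
) -> np.ndarray:
    """One-component 3-D diffusion RICS model along the scan axis."""
    if d <= 0:
        raise ValueError("d must be > 0")
    xi = np.abs(np.asarray(xi, dtype=np.float64))
    tau = geometry.dwell_scalar
    ks = geometry.dx / psf.w0
    kt = 4.0 * d * tau * xi / psf.w0**2
    ratio2 = (psf.w0 / psf.wz) ** 2
    scan = np.exp(-((xi * ks) ** 2) / (1.0 + kt))
    diff = (1.0 + kt) ** -1.0 * (1.0 + ratio2 * kt) ** -0.5
    return g0 * scan * diff


def fit_rics_1d(
    acf: ACF1D,
    geometry: ScanGeometry,
    psf: PSFModel,
    init: Optional[tuple[float, float]] = None,
    include_zero_lag: bool = False,
) -> RICSFitResult:
    """Least-squares fit of (G(0), D) to the one-component RICS model.

    The zero-lag point is excluded by default (shot-noise spike). Raises
    no silent failures: a non-converged fit is reported through
    ``success``/``message`` with diagnostics.
    """
    values = np.asarray(acf.values, dtype=np.float64)
    if values.size < 5:
        raise ValueError("need at least 5 lags to fit the RICS model")
    lags = np.arange(values.size)
    if not include_zero_lag:
        lags, values = lags[1:], values[1:]
    ks = geometry.dx / psf.w0

    if init is None:
        g0_init = float(values[0])
        # initial D from the lag where the ACF has decayed to half of
        # its first point: τ_D ≈ elapsed time at the half-decay lag
        below = np.nonzero(values < 0.5 * g0_init)[0]
        xi_half = float(lags[below[0]]) if below.size else float(lags[-1])
        tau = geometry.dwell_scalar
        d_init = psf.w0**2 / (4.0 * tau * max(xi_half, 1.0))
        init = (max(g0_init, 1e-12), d_init)

    def model(x, g0, d):
        return rics_model_1d(x, g0, d, geometry, psf)

    try:
        popt, pcov = optimize.curve_fit(
            model, lags, values, p0=init,
            bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=10000,
        )
        success = np.all(np.isfinite(popt))
        message = ""
    except RuntimeError as exc:  # non-convergence
        popt = np.array(init)
        pcov = None
        success = False
        message = f"RICS fit did not converge: {exc}"
    residuals = values - model(lags, *popt)
    return RICSFitResult(
        g0=float(popt[0]), d=float(popt[1]), ks=float(ks),
        residuals=residuals, cov=pcov, success=bool(success), message=message,
    )
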