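"""Per-pixel local spatial ACFs on m×m masks — the core of L-RICS.

For every pixel (i, j), the m×m sub-image centred on it is
autocorrelated per frame,

    G_m^{ij}(ξ, η) = (1/N) Σ_k [ <I_k^{ij}(x, y) I_k^{ij}(x+ξ, y+η)>
                                 / <I_k^{ij}>² - 1 ],

with the averages taken over the sub-image (circular indexing, i.e. the
plain FFT autocorrelation of the mask — the same convention must be used
for calibration and analysis, see ACF_CONVENTION). The 2-D ACF is
reduced to 1-D by keeping the η = 0 row; only the first L = (m+1)/2 lags
are informative for an odd mask. The ξ = 0 point contains the white
(shot) noise autocorrelation and is replaced by the ξ = 1 value before
any phasor analysis.

The batched implementation computes all masks of a frame at once with
sliding-window (integral-image) sums; it is exactly equivalent to the
per-pixel FFT route (see :func:`local_acf_at`), which is kept as the
readable reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .geometry import PSFModel, ScanGeometry
from .sim import RasterStack

__all__ = ["LocalACFField", "local_acf_map", "local_acf_running", "local_acf_at",
           "ACF_CONVENTION"]

# Fixed package-wide convention: local mask ACFs are circular (no zero
# padding). Calibration curves record it and refuse to mix conventions.
ACF_CONVENTION = "circular"


@dataclass
class LocalACFField:
    """1-D local ACFs (ξ = 0..L-1) for every valid pixel of the field.

    ``values`` has shape (ny, nx, L) and is NaN outside the valid region
    (pixels at least ⌊m/2⌋ from the left/right borders and, for masks
    taller than one line, from the top/bottom borders).
    """

    values: np.ndarray
    m: int
    n_frames: int
    valid: np.ndarray            # (ny, nx) bool
    geometry: Optional[ScanGeometry] = None
    psf: Optional[PSFModel] = None
    zero_lag_replaced: bool = True

    @property
    def L(self) -> int:
        return (self.m + 1) // 2


def _check_mask(m: int) -> int:
    if m % 2 == 0 or m < 5:
        raise ValueError("mask size m must be odd and >= 5")
    return (m + 1) // 2


def _integral(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(a, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def _box(s: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sums of all h×w windows of the array behind integral image ``s``."""
    return s[h:, w:] - s[:-h, w:] - s[h:, :-w] + s[:-h, :-w]


def _frame_local_acf(frame: np.ndarray, m: int, h: int, L: int):
    """Numerator row η=0 (circular in ξ) and mask means for one frame.

    Returns ``(g, bad)`` where ``g`` has shape (ny-h+1, nx-m+1, L) and
    ``bad`` marks masks with non-positive mean.
    """
    ny, nx = frame.shape
    area = h * m
    s_i = _integral(frame)
    mean = _box(s_i, h, m) / area
    bad = ~(mean > 0)
    safe_mean = np.where(bad, 1.0, mean)
    g = np.empty((ny - h + 1, nx - m + 1, L), dtype=np.float64)
    for xi in range(L):
        # split the circular sum into the in-window part (offset ξ) and
        # the wrapped part (offset ξ - m)
        a = frame[:, : nx - xi] * frame[:, xi:]
        num = _box(_integral(a), h, m - xi)
        if xi > 0:
            b = frame[:, m - xi:] * frame[:, : nx - m + xi]
            num = num + _box(_integral(b), h, xi)
        g[:, :, xi] = (num / area) / (safe_mean * safe_mean) - 1.0
    return g, bad


def _window_height(m: int, ny: int) -> int:
    if ny == 1:
        return 1  # line scans: 1×m masks along the line
    if ny < m:
        raise ValueError(f"image height {ny} is smaller than the mask size {m}")
    return m


def local_acf_running(
    stack: RasterStack,
    m: int,
    checkpoints: Iterable[int],
    replace_zero_lag: bool = True,
) -> dict[int, LocalACFField]:
    """Local ACF fields averaged over the first N frames, for several N.

    Frames are accumulated once; a snapshot of the running average is
    taken at every requested checkpoint. Useful for noise-versus-N
    studies without re-simulating.
    """
    L = _check_mask(m)
    data = np.asarray(stack.data, dtype=np.float64)
    n, ny, nx = data.shape
    checkpoints = sorted(set(int(c) for c in checkpoints))
    if not checkpoints or checkpoints[0] < 1 or checkpoints[-1] > n:
        raise ValueError(f"checkpoints must lie in [1, n_frames={n}]")
    h = _window_height(m, ny)
    half, hh = m // 2, h // 2
    if nx - m + 1 <= 0:
        raise ValueError("valid region is empty for this mask size")

    acc = np.zeros((ny - h + 1, nx - m + 1, L), dtype=np.float64)
    any_bad = np.zeros((ny - h + 1, nx - m + 1), dtype=bool)
    out: dict[int, LocalACFField] = {}
    for k in range(checkpoints[-1]):
        g, bad = _frame_local_acf(data[k], m, h, L)
        acc += g
        any_bad |= bad
        if (k + 1) in checkpoints:
            mean_acf = acc / (k + 1)
            mean_acf = np.where(any_bad[:, :, None], np.nan, mean_acf)
            if replace_zero_lag and L > 1:
                mean_acf = mean_acf.copy()
                mean_acf[:, :, 0] = mean_acf[:, :, 1]
            values = np.full((ny, nx, L), np.nan)
            values[hh:ny - hh, half:nx - half] = mean_acf
            valid = np.zeros((ny, nx), dtype=bool)
            valid[hh:ny - hh, half:nx - half] = ~any_bad
            out[k + 1] = LocalACFField(
                values, m, k + 1, valid, stack.geometry, stack.psf,
                zero_lag_replaced=bool(replace_zero_lag and L > 1),
            )
    return out


def local_acf_map(
    stack: RasterStack, m: int, replace_zero_lag: bool = True
) -> LocalACFField:
    """Local ACF field averaged over all frames of the stack."""
    n = stack.data.shape[0]
    return local_acf_running(stack, m, [n], replace_zero_lag)[n]


def local_acf_at(
    stack: RasterStack, i: int, j: int, m: int, replace_zero_lag: bool = False
) -> np.ndarray:
    """Single-pixel local ACF via per-frame 2-D FFT of the sub-image.

    Reference route for the batched computation; both must agree to
    floating tolerance. ``(i, j)`` indexes (row, column) of the mask
    centre and must lie in the valid region.
    """
    L = _check_mask(m)
    data = np.asarray(stack.data, dtype=np.float64)
    n, ny, nx = data.shape
    h = _window_height(m, ny)
    half, hh = m // 2, h // 2
    if not (hh <= i < ny - hh and half <= j < nx - half):
        raise ValueError(f"pixel ({i}, {j}) is outside the valid region")
    acc = np.zeros(L)
    area = h * m
    for k in range(n):
        sub = data[k, i - hh:i + hh + 1, j - half:j + half + 1]
        mean = sub.mean()
        if not mean > 0:
            return np.full(L, np.nan)
        f = np.fft.fft2(sub)
        corr = np.fft.ifft2(np.abs(f) ** 2).real / area  # circular autocorr
        acc += corr[0, :L] / mean**2 - 1.0
    acf = acc / n
    if replace_zero_lag and L > 1:
        acf[0] = acf[1]
    return acf
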