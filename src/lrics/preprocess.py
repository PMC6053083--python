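"""Background / immobile-component removal before correlation analysis.

Correlation functions are computed on intensity *fluctuations*; slow
drifts (photobleaching, cell movement) and immobile structures must be
removed first. Two standard schemes are provided: subtraction of a
per-pixel moving average over time (for experimental data) and
subtraction of the per-pixel temporal mean (for stationary simulated
data). In both cases the grand mean of the subtracted component is added
back as a constant offset so that the downstream normalization by the
squared mean stays well defined and the overall mean is preserved.
"""

from __future__ import annotations

import numpy as np

from .sim import RasterStack

__all__ = ["subtract_moving_average", "subtract_global_mean", "apply_background"]


def _repack(stack: RasterStack, data: np.ndarray, method: str) -> RasterStack:
    meta = dict(stack.meta)
    meta["preprocessed"] = method
    return RasterStack(data, stack.geometry, stack.psf, stack.ground_truth, meta)


def subtract_global_mean(stack: RasterStack) -> RasterStack:
    """Subtract each pixel's temporal mean; restore the grand mean.

    Removes immobile structure exactly; appropriate for simulations and
    stationary samples. Idempotent.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    pixel_mean = data.mean(axis=0, keepdims=True)
    grand_mean = data.mean()
    return _repack(stack, data - pixel_mean + grand_mean, "global_mean")


def subtract_moving_average(stack: RasterStack, window: int) -> RasterStack:
    """Subtract a temporal moving average, restoring the grand mean.

    Each pixel's time trace has a centred length-``window`` running mean
    subtracted; near the first/last frames the window is shifted to stay
    inside the series (keeping its full length, so ``window == n_frames``
    degenerates exactly to :func:`subtract_global_mean`). The mean of
    the subtracted component is added back as a constant, preserving
    the overall mean exactly.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    n = data.shape[0]
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, n_frames={n}], got {window}")
    # centred start indices, clamped so the window stays inside [0, n)
    t = np.arange(n)
    start = np.clip(t - (window - 1) // 2, 0, n - window)
    csum = np.cumsum(data, axis=0, dtype=np.float64)
    csum = np.concatenate([np.zeros_like(csum[:1]), csum], axis=0)
    running = (csum[start + window] - csum[start]) / window
    # add back the mean of the subtracted component, so the overall
    # mean is preserved exactly
    return _repack(stack, data - running + running.mean(), "moving_average")


def apply_background(
    stack: RasterStack, method: str = "global_mean", window: int = 10
) -> RasterStack:
    """Dispatch helper used by the pipeline and the CLI."""
    if method == "none":
        return stack
    if method == "global_mean":
        return subtract_global_mean(stack)
    if method == "moving_average":
        return subtract_moving_average(stack, window)
    raise ValueError(f"unknown background method: {method!r}")
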