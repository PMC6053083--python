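"""High-level entry points chaining the analysis stages.

These helpers wire background subtraction → local ACF → phasor →
(optionally) calibration inversion, which is the path the CLI and most
scripts take. The individual stages remain available for custom use.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .calibration import CalibrationCurve, DiffusionMap, phase_to_d
from .localacf import local_acf_map, local_acf_running
from .phasor import PhaseMap, phase_map
from .preprocess import apply_background
from .sim import RasterStack

__all__ = ["compute_phase_map", "compute_phase_maps_vs_n", "compute_diffusion_map"]


def compute_phase_map(
    stack: RasterStack,
    m: int,
    *,
    background: str = "global_mean",
    window: int = 10,
) -> PhaseMap:
    """Background-subtract a stack and compute its m-mask phase map."""
    pre = apply_background(stack, background, window)
    return phase_map(local_acf_map(pre, m))


def compute_phase_maps_vs_n(
    stack: RasterStack,
    m: int,
    checkpoints,
    *,
    background: str = "global_mean",
    window: int = 10,
) -> dict[int, PhaseMap]:
    """Phase maps from the first N frames for each N in ``checkpoints``."""
    pre = apply_background(stack, background, window)
    fields = local_acf_running(pre, m, checkpoints)
    return {n: phase_map(f) for n, f in fields.items()}


def compute_diffusion_map(
    stack: RasterStack,
    m: int,
    cal: CalibrationCurve,
    *,
    dwell: Optional[Union[float, np.ndarray]] = None,
    background: str = "global_mean",
    window: int = 10,
    clamp: bool = False,
) -> DiffusionMap:
    """Full L-RICS pipeline: stack → phase map → diffusion map."""
    pmap = compute_phase_map(stack, m, background=background, window=window)
    if dwell is None:
        dwell = stack.geometry.dwell_scalar
    if stack.psf is None:
        raise ValueError("stack has no PSF metadata; w0 is required")
    return phase_to_d(pmap, cal, dwell, stack.psf.w0, clamp=clamp)
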