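"""Shared fixtures.

All stacks are generated programmatically with fixed seeds. The heavy
session fixtures (calibration curve, benchmark stacks) are shared
between the module tests and the acceptance suite to keep the total
runtime bounded; their problem sizes are scaled-down versions of the
reference acquisitions, at the same molecule concentration, brightness
and sampling constants.
"""

from __future__ import annotations

import numpy as np
import pytest

from lrics import (
    DEFAULT_CONCENTRATION,
    PSFModel,
    ScanGeometry,
    SimConfig,
    make_dwell_profile,
    make_zone_map,
    molecules_for_concentration,
    simulate_stack,
)
from lrics.calibration import build_calibration

# reference acquisition constants: 20 nm pixels, 50 µs dwell, w0 = 160 nm
DX = 0.02
DWELL = 50e-6
W0 = 0.16
KS = DX / W0  # = 1/8
BRIGHT_LOW = 24e3   # "GFP-like" brightness, counts/s
BRIGHT_HIGH = 3e6   # calibration-grade brightness


@pytest.fixture(scope="session")
def psf() -> PSFModel:
    return PSFModel(W0, 3.0)


@pytest.fixture(scope="session")
def calibration_m25(psf):
    """φ(K_t) calibration for m=25, K_s=1/8 over D = 4..36 µm²/s."""
    return build_calibration(
        ks=KS, m=25, dx=DX, dwell=DWELL, nx=64, ny=64, n_frames=150,
        brightness=BRIGHT_HIGH, seed=100,
    )


@pytest.fixture(scope="session")
def uniform_stacks(psf):
    """Two uniform D=24 µm²/s acquisitions at GFP-like brightness.

    96×96 px, 100 frames each; used for the phase-noise scaling and
    local-ACF statistics checks.
    """
    geo = ScanGeometry(96, 96, DX, DWELL)
    n_mol = molecules_for_concentration(geo, psf)
    stacks = []
    for seed in (201, 202):
        cfg = SimConfig(n_mol, BRIGHT_LOW, 24.0, n_frames=100, seed=seed)
        stacks.append(simulate_stack(cfg, geo, psf))
    return stacks


@pytest.fixture(scope="session")
def zone_stack(psf):
    """Three-zone acquisition (D = 12/18/24 µm²/s bands along y)."""
    nx, ny = 192, 96
    geo = ScanGeometry(nx, ny, DX, DWELL)
    zmap = make_zone_map(nx, ny, [32, 32, 32], [12.0, 18.0, 24.0])
    n_mol = molecules_for_concentration(geo, psf)
    cfg = SimConfig(n_mol, BRIGHT_LOW, zmap, n_frames=250, seed=42)
    return simulate_stack(cfg, geo, psf)


@pytest.fixture(scope="session")
def scan_stack(psf):
    """Uniform D=30.6 sample scanned with a 12→18 µs edge-slowdown
    dwell profile at calibration-grade brightness (hardware
    characterization uses a bright dye sample)."""
    nx, ny = 128, 128
    profile = make_dwell_profile(
        nx, "edge_slowdown", {"tau_min": 12e-6, "tau_max": 18e-6}
    )
    geo = ScanGeometry(nx, ny, DX, profile)
    n_mol = molecules_for_concentration(geo, psf)
    cfg = SimConfig(n_mol, BRIGHT_HIGH, 30.6, n_frames=250, seed=41)
    return simulate_stack(cfg, geo, psf), profile


# line scans target abundant fluorophores (every 1-px-high mask must
# hold signal in every line), so the line benchmarks run at 10x the
# default concentration — matched between calibration and measurement
LINE_CONCENTRATION = 10 * DEFAULT_CONCENTRATION


@pytest.fixture(scope="session")
def line_calibration(psf):
    """φ(K_t) calibration for 1×25 line masks."""
    return build_calibration(
        ks=KS, m=25, dx=DX, dwell=DWELL, nx=48, ny=40, n_frames=50,
        brightness=BRIGHT_HIGH, seed=300, mask_kind="line",
        concentration=LINE_CONCENTRATION,
        d_values=(4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0),
    )


def make_line_stack(psf, d_map, n_lines, seed, nx=64, brightness=BRIGHT_HIGH):
    """Repeated single-line acquisition over the given D map (1, nx)."""
    geo = ScanGeometry(nx, 1, DX, DWELL)
    n_mol = molecules_for_concentration(geo, psf, LINE_CONCENTRATION)
    cfg = SimConfig(n_mol, brightness, d_map, n_frames=n_lines, seed=seed)
    return simulate_stack(cfg, geo, psf)
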