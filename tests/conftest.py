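"""Shared fixtures: synthetic stacks and reconstructed spectra.

Expensive renders are session-scoped so the whole suite pays for them once.
"""

import logging

import numpy as np
import pytest

from wbshear.correlate import compute_g2, frequency_bounds, select_roi_from_drp
from wbshear.datatypes import AnalysisROI, InversionConstants, MeasurementContext
from wbshear.reconstruct import spectrum_from_g2
from wbshear.simulate import DynamicsModel, RenderConfig, render_speckle

logging.getLogger("wbshear").setLevel(logging.ERROR)

WATER_ETA = 1e-3  # Pa.s
BEAD_RADIUS = 1.5e-6  # m, 3-um-diameter polystyrene tracer


@pytest.fixture(scope="session")
def newtonian_model():
    return DynamicsModel(
        kind="newtonian", radius=BEAD_RADIUS, temperature=295.0, eta=WATER_ETA
    )


@pytest.fixture(scope="session")
def ctx_bead():
    return MeasurementContext(radius=BEAD_RADIUS, temperature=295.0)


@pytest.fixture(scope="session")
def small_newtonian_stack(newtonian_model):
    """3000-frame 64x64 Newtonian stack with a DRP envelope (DLS synthesis)."""
    cfg = RenderConfig(
        n_frames=3000,
        frame_rate=10000.0,
        shape=(64, 64),
        drp_radius=24e-6,
        seed=2,
        gamma=2.0 / 3.0,
        zeta=1.0,
    )
    return render_speckle(newtonian_model, cfg), cfg


@pytest.fixture(scope="session")
def small_curve(small_newtonian_stack):
    stack, _cfg = small_newtonian_stack
    roi = select_roi_from_drp(stack)
    return compute_g2(stack, roi), roi


@pytest.fixture(scope="session")
def newtonian_pipeline(newtonian_model, ctx_bead):
    """Full-pipeline reconstruction of a diffusing-bead stack.

    12,000 frames at 10 kHz over 96x96 px; the speckle decorrelation is
    synthesized with the single-scattering constants (2/3, 1) and inverted
    with the same constants.
    """
    cfg = RenderConfig(
        n_frames=12000,
        frame_rate=10000.0,
        shape=(96, 96),
        drp_radius=33e-6,
        seed=21,
        gamma=2.0 / 3.0,
        zeta=1.0,
    )
    stack = render_speckle(newtonian_model, cfg)
    roi = select_roi_from_drp(stack)
    curve = compute_g2(stack, roi)
    band = frequency_bounds(stack.frame_rate, stack.duration)
    spec = spectrum_from_g2(
        curve, InversionConstants(2.0 / 3.0, 1.0), ctx_bead, omega_band=band
    )
    return {"stack": stack, "roi": roi, "curve": curve, "spectrum": spec, "cfg": cfg}


def full_frame_circular_roi(shape, radius_px, pitch=1.5e-6):
    """Helper: circular ROI centered in the frame, bypassing DRP detection."""
    rr = (np.arange(shape[0]) - shape[0] // 2)[:, None]
    cc = (np.arange(shape[1]) - shape[1] // 2)[None, :]
    mask = rr ** 2 + cc ** 2 <= radius_px ** 2
    return AnalysisROI(
        center=(shape[0] // 2, shape[1] // 2),
        diameter=2.0 * radius_px * pitch,
        mask=mask,
    )
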