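"""File I/O: TIFF speckle stacks with JSON sidecars, CSV curves and spectra."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CorrelationCurve, SpeckleStack, ViscoelasticSpectrum

__all__ = [
    "write_stack",
    "read_stack",
    "write_correlation_csv",
    "read_correlation_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_stack(stack: SpeckleStack, path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensity, photometric="minisblack")
    meta = {
        "frame_rate_hz": stack.frame_rate,
        "pixel_pitch_um": stack.pixel_pitch * 1e6,
        "wavelength_nm": stack.wavelength * 1e9,
        "bit_depth": stack.bit_depth,
        "n_frames": int(stack.n_frames),
        **{k: v for k, v in stack.meta.items() if _json_safe(v)},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _json_safe(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None)))


def read_stack(path) -> SpeckleStack:
    """Read a multi-page TIFF stack and its JSON sidecar."""
    path = Path(path)
    intensity = tifffile.imread(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return SpeckleStack(
        intensity=intensity,
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_pitch=float(meta["pixel_pitch_um"]) * 1e-6,
        wavelength=float(meta["wavelength_nm"]) * 1e-9,
        bit_depth=int(meta.get("bit_depth", 12)),
        meta={"source_path": str(path), **meta},
    )


def write_correlation_csv(curve: CorrelationCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "lag_s": curve.t,
            "g2": curve.g2,
            "g2_raw": curve.g2_raw,
            "n_pairs": curve.n_pairs,
        }
    ).to_csv(path, index=False)
    return path


def read_correlation_csv(path, n_pixels: int = 0) -> CorrelationCurve:
    df = pd.read_csv(path)
    return CorrelationCurve(
        t=df["lag_s"].to_numpy(),
        g2=df["g2"].to_numpy(),
        g2_raw=df["g2_raw"].to_numpy(),
        n_pixels=n_pixels,
        n_pairs=df["n_pairs"].to_numpy(),
    )


def write_spectrum_csv(spec: ViscoelasticSpectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "omega_rad_s": spec.omega,
            "alpha": spec.alpha,
            "G1_Pa": spec.G1,
            "G2_Pa": spec.G2,
            "Gmag_Pa": spec.Gmag,
            "active_dynamics": (
                spec.active_dynamics
                if spec.active_dynamics is not None
                else np.zeros(spec.omega.size, dtype=bool)
            ),
        }
    ).to_csv(path, index=False)
    return path


def read_spectrum_csv(path) -> ViscoelasticSpectrum:
    df = pd.read_csv(path)
    return ViscoelasticSpectrum(
        omega=df["omega_rad_s"].to_numpy(),
        alpha=df["alpha"].to_numpy(),
        G1=df["G1_Pa"].to_numpy(),
        G2=df["G2_Pa"].to_numpy(),
        Gmag=df["Gmag_Pa"].to_numpy(),
        active_dynamics=df["active_dynamics"].to_numpy(dtype=bool),
    )
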