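"""2D laser-scanning: per-location spectra assembled into hyperspectral maps.

A sample is translated on a regular grid (default step 25 um); at each
location the full per-point pipeline runs (DRP -> ROI -> g2 -> MSD ->
G*(omega)).  Per-frequency G'(omega) and G"(omega) images are assembled
into a :class:`HyperspectralMap`, optionally upsampled for display by
Fourier zero-padding (factor 7 by default, mean-preserving), and exported
to HDF5 with 16-bit image previews on a shared log scale.

Failed locations (saturated stacks, no speckle contrast, DRP outside the
field of view, ...) become masked cells, not aborts; analysis output keeps
the mask, only the display transform infills by nearest neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample

from .correlate import compute_g2, frequency_bounds, select_roi_from_drp
from .datatypes import (
    InversionConstants,
    MeasurementContext,
    SpeckleStack,
    ViscoelasticSpectrum,
)
from .optics import LookupTable, fit_optical_properties, lookup_constants, radial_profile
from .reconstruct import spectrum_from_g2

__all__ = [
    "ScanGrid",
    "HyperspectralMap",
    "process_scan",
    "assemble_maps",
    "upsample_map",
    "export_maps",
    "DISPLAY_OMEGAS",
]

log = logging.getLogger(__name__)

DISPLAY_OMEGAS = tuple(10.0 ** e for e in range(1, 6))  # 10^1 .. 10^5 rad/s


@dataclass
class ScanGrid:
    """Per-location pipeline results on a regular rectangular scan grid."""

    shape: tuple                      # (n_rows, n_cols)
    step: float = 25e-6               # m
    spectra: dict = field(default_factory=dict)     # (i, j) -> ViscoelasticSpectrum
    constants: dict = field(default_factory=dict)   # (i, j) -> InversionConstants
    failures: dict = field(default_factory=dict)    # (i, j) -> reason string
    sources: dict = field(default_factory=dict)     # (i, j) -> stack provenance

    def stage_position(self, i: int, j: int) -> tuple:
        """Stage (x, y) in meters; x runs along columns, origin top-left."""
        return (j * self.step, i * self.step)


@dataclass
class HyperspectralMap:
    """G' and G" images (Pa) at a list of probe frequencies."""

    omegas: np.ndarray
    G1: np.ndarray        # (n_omega, rows, cols)
    G2: np.ndarray
    mask: np.ndarray      # (rows, cols) True where the cell failed
    step: float
    upsample_factor: int = 1
    meta: dict = field(default_factory=dict)


def process_scan(
    stacks: dict,
    ctx: MeasurementContext,
    consts: InversionConstants | None = None,
    lut: LookupTable | None = None,
    step: float = 25e-6,
    max_failure_fraction: float = 0.5,
) -> ScanGrid:
    """Run the per-location pipeline over a grid of speckle stacks.

    Parameters
    ----------
    stacks
        ``{(i, j): SpeckleStack}`` on a regular grid.
    consts, lut
        Either fixed inversion constants for all locations, or a lookup
        table; with a table, each location's DRP is fitted by diffusion
        theory to pick per-location (gamma, zeta).

    Raises
    ------
    RuntimeError
        If more than ``max_failure_fraction`` of the cells fail.
    """
    if consts is None and lut is None:
        raise ValueError("provide fixed inversion constants or a lookup table")
    keys = list(stacks)
    rows = max(k[0] for k in keys) + 1
    cols = max(k[1] for k in keys) + 1
    rates = [stacks[k].frame_rate for k in keys]
    if (max(rates) - min(rates)) / max(rates) > 0.01:
        log.info("per-location frame rates differ by more than 1%%; using each")

    grid = ScanGrid(shape=(rows, cols), step=step)
    for key in keys:
        stack = stacks[key]
        grid.sources[key] = stack.meta.get("source_path", f"stack_{key[0]}_{key[1]}")
        try:
            roi = select_roi_from_drp(stack)
            if lut is not None:
                rho, prof = radial_profile(stack, center=roi.center)
                props = fit_optical_properties(rho, prof, n=ctx.n)
                c = lookup_constants(lut, props)
            else:
                c = consts
            curve = compute_g2(stack, roi)
            band = frequency_bounds(stack.frame_rate, stack.duration)
            spec = spectrum_from_g2(curve, c, ctx, omega_band=band)
            grid.spectra[key] = spec
            grid.constants[key] = c
        except (ValueError, RuntimeError) as exc:
            grid.failures[key] = str(exc)
            log.warning("scan cell %s failed: %s", key, exc)

    n_cells = rows * cols
    if len(grid.failures) > max_failure_fraction * n_cells:
        causes = {}
        for msg in grid.failures.values():
            causes[msg] = causes.get(msg, 0) + 1
        raise RuntimeError(f"{len(grid.failures)}/{n_cells} scan cells failed: {causes}")
    return grid


def _sample_spectrum(spec: ViscoelasticSpectrum, omega: float) -> tuple:
    """Log-interpolate (G', G") at a probe frequency; NaN outside the band."""
    if not (spec.omega[0] <= omega <= spec.omega[-1]):
        return np.nan, np.nan
    lw = np.log10(spec.omega)
    lq = np.log10(omega)
    g1 = 10.0 ** np.interp(lq, lw, np.log10(np.maximum(spec.G1, 1e-300)))
    g2 = 10.0 ** np.interp(lq, lw, np.log10(np.maximum(spec.G2, 1e-300)))
    return float(g1), float(g2)


def assemble_maps(
    grid: ScanGrid, omegas=DISPLAY_OMEGAS, upsample_factor: int = 1
) -> HyperspectralMap:
    """Compile per-location spectra into per-frequency G'/G" images.

    Cells that failed, or whose spectrum does not cover a probe frequency,
    are masked.  ``upsample_factor`` > 1 applies the Fourier zero-padding
    display transform to each image.
    """
    omegas = np.asarray(list(omegas), dtype=float)
    rows, cols = grid.shape
    G1 = np.full((omegas.size, rows, cols), np.nan)
    G2 = np.full_like(G1, np.nan)
    for (i, j), spec in grid.spectra.items():
        for q, w in enumerate(omegas):
            G1[q, i, j], G2[q, i, j] = _sample_spectrum(spec, w)
    mask = np.all(np.isnan(G1), axis=0)

    if upsample_factor > 1:
        G1u = np.stack([upsample_map(G1[q], upsample_factor) for q in range(omegas.size)])
        G2u = np.stack([upsample_map(G2[q], upsample_factor) for q in range(omegas.size)])
        G1, G2 = G1u, G2u
        mask = np.repeat(np.repeat(mask, upsample_factor, 0), upsample_factor, 1)

    return HyperspectralMap(
        omegas=omegas,
        G1=G1,
        G2=G2,
        mask=mask,
        step=grid.step / upsample_factor,
        upsample_factor=upsample_factor,
        meta={
            "grid_shape": grid.shape,
            "coordinate_convention": "row-major, origin top-left, stage x = columns",
            "sources": {f"{i},{j}": s for (i, j), s in grid.sources.items()},
        },
    )


def _nearest_fill(img: np.ndarray) -> np.ndarray:
    """Replace NaNs by the nearest finite value (display infill only)."""
    from scipy.ndimage import distance_transform_edt

    bad = ~np.isfinite(img)
    if not bad.any():
        return img
    if bad.all():
        raise ValueError("cannot infill a fully masked map")
    _, idx = distance_transform_edt(bad, return_indices=True)
    return img[tuple(idx)]


def upsample_map(map2d: np.ndarray, factor: int) -> np.ndarray:
    """Fourier zero-padding upsampling of a 2D map, mean-preserving.

    The map is 2D-DFT'd, symmetrically zero-padded to ``factor`` times the
    size (with Hermitian-consistent splitting of the Nyquist row/column for
    even sizes, handled by the FFT resampler), inverse transformed, and the
    real part rescaled so the spatial mean is preserved exactly.  Masked
    (NaN) cells are infilled by nearest neighbor before the transform.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    map2d = np.asarray(map2d, dtype=float)
    if factor == 1:
        return map2d.copy()
    filled = _nearest_fill(map2d)
    up = resample(filled, filled.shape[0] * factor, axis=0)
    up = resample(up, map2d.shape[1] * factor, axis=1)
    mean0 = filled.mean()
    mean1 = up.mean()
    if mean1 != 0:
        up *= mean0 / mean1
    else:
        up += mean0
    return up


def export_maps(hmap: HyperspectralMap, out_dir) -> dict:
    """Export a hyperspectral map: HDF5 archive plus 16-bit PNG previews.

    Previews share one log color scale across all frequencies and both
    moduli, so a frame sequence over omega can be assembled into a movie.
    Returns ``{"h5": path, "previews": [paths...]}``.
    """
    import pathlib

    import h5py
    import imageio.v3 as iio

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if hmap.omegas.size == 0:
        raise ValueError("empty map")

    finite = np.concatenate(
        [hmap.G1[np.isfinite(hmap.G1)], hmap.G2[np.isfinite(hmap.G2)]]
    )
    finite = finite[finite > 0]
    if finite.size == 0:
        raise ValueError("no finite positive moduli to export")
    lo, hi = float(finite.min()), float(finite.max())

    h5_path = out_dir / "maps.h5"
    with h5py.File(h5_path, "w") as f:
        f.attrs["units"] = "Pa"
        f.attrs["upsample_factor"] = hmap.upsample_factor
        f.attrs["step_m"] = hmap.step
        f.attrs["clim_pa"] = (lo, hi)
        f.attrs["coordinate_convention"] = hmap.meta.get("coordinate_convention", "")
        f.create_dataset("omegas_rad_s", data=hmap.omegas)
        f.create_dataset("mask", data=hmap.mask)
        for q, w in enumerate(hmap.omegas):
            grp = f.create_group(f"omega_{q:03d}")
            grp.attrs["omega_rad_s"] = w
            grp.create_dataset("G1_Pa", data=hmap.G1[q])
            grp.create_dataset("G2_Pa", data=hmap.G2[q])

    previews = []
    log_lo, log_hi = np.log10(lo), np.log10(max(hi, lo * (1 + 1e-12)))
    span = max(log_hi - log_lo, 1e-12)
    for q, w in enumerate(hmap.omegas):
        for name, img in (("G1", hmap.G1[q]), ("G2", hmap.G2[q])):
            scaled = (np.log10(np.clip(img, lo, hi)) - log_lo) / span
            scaled = np.where(np.isfinite(scaled), scaled, 0.0)
            png = out_dir / f"{name}_omega{q:03d}_{w:.3g}rad_s.png"
            iio.imwrite(png, (scaled * 65535).astype(np.uint16))
            previews.append(png)
    return {"h5": h5_path, "previews": previews}
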