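"""Ensemble intensity autocorrelation of speckle time series.

The analysis region is a circle concentric with the illumination center,
extending to the 1/e radius of the diffuse reflectance profile (DRP,
the temporal mean image).  Within that region the contrast-normalized
intensity autocorrelation is

    g2(t) = (g2_raw(t) - 1) / (g2_raw(0) - 1) + 1,
    g2_raw(t) = <I(t0 + t) I(t0)> / (<I(t0)> <I(t0 + t)>),

the ensemble running over all ROI pixels and all frame pairs separated by
lag t.  The normalization forces g2(0) = 2 regardless of the raw speckle
contrast, so partially developed speckle maps onto the same decorrelation
scale.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter

from .datatypes import AnalysisROI, CorrelationCurve, SpeckleStack

__all__ = [
    "select_roi_from_drp",
    "compute_g2",
    "frequency_bounds",
    "default_lag_grid",
]


def estimate_envelope(drp: np.ndarray, median_px: int = 5,
                      blur_px: float = 3.0) -> np.ndarray:
    """Robust smooth illumination envelope from a temporal-mean image.

    Median filtering suppresses single-grain maxima and the Gaussian blur
    averages over several speckle grains — essential for gel-like samples
    whose temporal mean retains frozen speckle grain structure.
    """
    return gaussian_filter(median_filter(drp, size=median_px), sigma=blur_px)


def select_roi_from_drp(stack: SpeckleStack, smooth_px: int = 5) -> AnalysisROI:
    """Select the circular analysis ROI from the diffuse reflectance profile.

    The DRP is the temporal mean of all frames; its peak (after grain-scale
    smoothing, see :func:`estimate_envelope`) defines the illumination
    center, and the ROI radius is where the azimuthally averaged profile
    first falls to 1/e of its peak.

    Raises
    ------
    ValueError
        If the profile never falls below 1/e inside the field of view.
    """
    drp = stack.intensity.mean(axis=0)
    # the Gaussian-blurred image locates the center robustly even when the
    # temporal mean retains frozen speckle grains
    smoothed = estimate_envelope(drp, median_px=smooth_px)
    center = np.unravel_index(np.argmax(smoothed), smoothed.shape)

    rho, prof, counts = _azimuthal_average(
        median_filter(drp, size=smooth_px), center, return_counts=True
    )
    if np.any(prof <= 0) or prof.size < 8:
        raise ValueError("DRP not contained in field of view")
    # peak from a count-weighted log-linear fit of the inner profile: the
    # single-pixel central annuli are too grain-noisy to read directly, and
    # any smoothing flattens the central cusp and biases the peak low
    n_fit = max(8, int(np.searchsorted(rho, rho[-1] / 4)))
    w = np.sqrt(counts[:n_fit].astype(float))
    coef = np.polyfit(rho[:n_fit], np.log(prof[:n_fit]), 1, w=w)
    peak = float(np.exp(coef[1]))
    if peak <= 0:
        raise ValueError("DRP not contained in field of view")

    prof = _smooth_profile(prof, counts)  # crossing read on the smoothed decay
    below = np.nonzero(prof <= peak / np.e)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError("DRP not contained in field of view")
    j = below[0]
    # linear interpolation of the 1/e crossing between annuli
    f0, f1 = prof[j - 1], prof[j]
    frac = (peak / np.e - f0) / (f1 - f0)
    radius_px = max(float(rho[j - 1] + frac * (rho[j] - rho[j - 1])), 1.0)

    rr = (np.arange(drp.shape[0]) - center[0])[:, None]
    cc = (np.arange(drp.shape[1]) - center[1])[None, :]
    mask = rr ** 2 + cc ** 2 <= radius_px ** 2
    return AnalysisROI(
        center=(int(center[0]), int(center[1])),
        diameter=2.0 * radius_px * stack.pixel_pitch,
        mask=mask,
    )


def _azimuthal_average(img: np.ndarray, center, return_counts: bool = False) -> tuple:
    """Azimuthal average in 1-pixel annular bins around ``center``."""
    rr = (np.arange(img.shape[0]) - center[0])[:, None]
    cc = (np.arange(img.shape[1]) - center[1])[None, :]
    rho = np.hypot(rr, cc).ravel()
    bins = np.rint(rho).astype(int)
    counts = np.bincount(bins)
    sums = np.bincount(bins, weights=img.ravel())
    nonzero = counts > 0
    rho_out = np.arange(len(counts))[nonzero].astype(float)
    prof = sums[nonzero] / counts[nonzero]
    if return_counts:
        return rho_out, prof, counts[nonzero]
    return rho_out, prof


def _smooth_profile(prof: np.ndarray, counts: np.ndarray, window: int = 7) -> np.ndarray:
    """Count-weighted moving average of a radial profile.

    Inner annuli hold only a handful of speckle grains, so the raw profile
    is grain-noisy there; smoothing over neighboring annuli (weighted by
    pixel counts) suppresses that noise without distorting the smooth DRP.
    """
    half = window // 2
    out = np.empty_like(prof)
    n = prof.size
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = counts[lo:hi].astype(float)
        out[i] = np.dot(w, prof[lo:hi]) / w.sum()
    return out


def default_lag_grid(
    n_frames: int, max_lag: int | None = None, per_decade: int = 30
) -> np.ndarray:
    """Pseudo-logarithmic frame-lag grid: every lag up to 64, then log-spaced.

    The log tail uses ``per_decade`` points per decade to match the spectral
    resampling downstream.  Lags are unique integers < ``max_lag``
    (default: a quarter of the stack).
    """
    if max_lag is None:
        max_lag = max(n_frames // 4, 2)
    max_lag = min(max_lag, n_frames - 1)
    lin = np.arange(1, min(64, max_lag) + 1)
    if max_lag > 64:
        n_log = int(np.ceil(per_decade * np.log10(max_lag / 64.0)))
        logs = np.unique(
            np.rint(np.logspace(np.log10(64), np.log10(max_lag), n_log + 1)).astype(int)
        )
        lags = np.unique(np.concatenate([lin, logs]))
    else:
        lags = lin
    return lags[lags >= 1]


def compute_g2(
    stack: SpeckleStack,
    roi: AnalysisROI,
    lags: np.ndarray | None = None,
    max_pairs_per_lag: int = 2_000_000,
) -> CorrelationCurve:
    """Contrast-normalized ensemble intensity autocorrelation.

    Parameters
    ----------
    lags
        Frame lags (integers >= 1).  Defaults to :func:`default_lag_grid`.
    max_pairs_per_lag
        Upper bound on (pixel x frame-pair) samples per lag; longer stacks
        are strided uniformly over start frames, which leaves the estimator
        unbiased while bounding runtime.

    Raises
    ------
    ValueError
        If the zero-lag contrast ``g2_raw(0) - 1`` is not positive
        ("speckle contrast below floor"), or a lag exceeds the stack.
    """
    if lags is None:
        lags = default_lag_grid(stack.n_frames)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags >= stack.n_frames):
        raise ValueError("all lags must be shorter than the acquisition")
    if np.any(lags < 1):
        raise ValueError("lags must be >= 1 frame")

    # Flatten the smooth illumination envelope (azimuthally averaged DRP
    # around the ROI center) out of each pixel before forming the spatial
    # ensemble: without this the nonuniform DRP biases the estimator
    # baseline above 1.  The azimuthal average spans many speckle grains,
    # so per-grain static speckle survives the flattening — essential for
    # gel-like samples whose speckle never fully decorrelates (the spatial
    # ensemble, not per-pixel time averaging, captures the frozen
    # component).
    drp = estimate_envelope(stack.intensity.mean(axis=0))
    rho_bins, prof, counts = _azimuthal_average(drp, roi.center, return_counts=True)
    prof = _smooth_profile(prof, counts)
    rr = (np.arange(drp.shape[0]) - roi.center[0])[:, None]
    cc = (np.arange(drp.shape[1]) - roi.center[1])[None, :]
    rho_map = np.hypot(rr, cc)[roi.mask]
    env = np.interp(rho_map, rho_bins, prof)
    if np.any(env <= 0):
        raise ValueError("speckle contrast below floor")

    pix = stack.intensity[:, roi.mask].astype(np.float64) / env[None, :]
    n_frames, n_pix = pix.shape

    mean_all = float(pix.mean())
    g2_raw0 = float(np.mean(pix * pix)) / mean_all ** 2
    if g2_raw0 - 1.0 <= 0:
        raise ValueError("speckle contrast below floor")

    g2_raw = np.empty(lags.size + 1)
    n_pairs = np.empty(lags.size + 1, dtype=np.int64)
    g2_raw[0] = g2_raw0
    n_pairs[0] = n_frames * n_pix

    for i, lag in enumerate(lags, start=1):
        n_start = n_frames - lag
        stride = max(1, int(np.ceil(n_start * n_pix / max_pairs_per_lag)))
        a = pix[:n_start:stride]
        b = pix[lag:lag + n_start:stride]
        num = float(np.mean(a * b))
        den = float(a.mean()) * float(b.mean())
        g2_raw[i] = num / den
        n_pairs[i] = a.shape[0] * n_pix

    t = np.concatenate([[0.0], lags / stack.frame_rate])
    g2 = (g2_raw - 1.0) / (g2_raw0 - 1.0) + 1.0
    return CorrelationCurve(t=t, g2=g2, g2_raw=g2_raw, n_pixels=n_pix, n_pairs=n_pairs)


def frequency_bounds(frame_rate: float, duration: float) -> tuple:
    """Accessible band (omega_min, omega_max) = (1/tau, Fs).

    The upper bound follows the printed convention of comparing omega in
    rad/s directly with the frame rate in frames/s; an alternative
    ``2 pi Fs`` convention can be applied by the caller.
    """
    if frame_rate <= 0 or duration <= 0:
        raise ValueError("frame_rate and duration must be positive")
    omega_min = 1.0 / duration
    omega_max = float(frame_rate)
    if omega_min >= omega_max:
        raise ValueError("empty frequency band: duration too short for frame rate")
    return omega_min, omega_max
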