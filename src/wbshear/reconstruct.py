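"""From intensity autocorrelation to wideband viscoelastic spectra.

Three stages:

1. :func:`invert_g2_to_msd` — algebraic inversion of the empirical
   DWS-style relation ``g2(t) - 1 = exp(-2 gamma (k^2 <dr^2(t)>)^zeta)``:

       MSD(t) = [-ln(g2(t) - 1) / (2 gamma)]^(1/zeta) / k^2.

   Lags where the speckle has fully decorrelated (g2 - 1 at the noise
   floor) are masked, never extrapolated.

2. :func:`compute_alpha` — the MSD is resampled linearly in log space onto
   an omega grid with 30 points per decade at t = 1/omega; the local
   power-law exponent alpha(omega) is the least-squares log-log slope over
   a centered rolling window of 7 points, then smoothed by a 15-point
   moving average.

3. :func:`gser_reconstruct` — the algebraic generalized Stokes-Einstein
   relation

       G*(omega) = kB T / (pi a <dr^2(1/omega)> Gamma[1 + alpha(omega)])
                   * exp(i pi alpha(omega) / 2),

   valid under thermal equilibrium; alpha = 0 is a purely elastic solid
   (G* = G'), alpha = 1 a purely viscous fluid (G* = i G"), and alpha = 0.5
   the G' = G" crossover.  G' and G" are each smoothed by a second 15-point
   moving average and |G*| recomputed from the smoothed components.

Pre-clip alpha > 1 signals actively driven (non-thermal) dynamics; it is
clipped to 1 for the GSER but flagged per frequency.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gamma as gamma_fn

from .datatypes import (
    CorrelationCurve,
    InversionConstants,
    MeasurementContext,
    MSDCurve,
    ViscoelasticSpectrum,
)

__all__ = [
    "invert_g2_to_msd",
    "compute_alpha",
    "gser_reconstruct",
    "moving_average",
    "spectrum_from_g2",
    "spectrum_from_msd",
]

log = logging.getLogger(__name__)

POINTS_PER_DECADE = 30
SLOPE_WINDOW = 7
SMOOTH_WINDOW = 15
# Conservative decorrelation floor: the log transform amplifies g2 noise by
# 1/(beta |ln beta|), so points below ~10x the tail noise (or 0.02 absolute)
# contribute large spurious curvature to the MSD at the band edge.
DECORRELATION_FLOOR = 0.02
FLOOR_NOISE_MULTIPLIER = 5.0


def invert_g2_to_msd(
    curve: CorrelationCurve,
    consts: InversionConstants,
    ctx: MeasurementContext,
    floor: float | None = None,
) -> MSDCurve:
    """Invert g2(t) to the mean square displacement.

    ``floor`` is the decorrelation floor on ``g2 - 1``; by default
    ``max(0.02, 5 x tail noise SD)``, the tail SD estimated from the last
    decade of lags when they sit below 0.05.  Points below the floor, and
    points with ``g2 - 1 > 1`` (noise above perfect correlation), are
    masked.
    """
    if consts.gamma <= 0 or consts.zeta <= 0:
        raise ValueError("gamma and zeta must be positive")
    beta = curve.g2 - 1.0

    if floor is None:
        floor = DECORRELATION_FLOOR
        tail = beta[curve.t > curve.t.max() / 10.0]
        tail = tail[np.abs(tail) < 0.05]
        if tail.size >= 4:
            floor = max(floor, FLOOR_NOISE_MULTIPLIER * float(tail.std()))

    valid = (beta > floor) & (beta <= 1.0)
    valid[0] = True  # zero lag: MSD = 0 by construction
    # decorrelation is monotone in lag: once g2 - 1 first drops to the
    # floor, all later lags are fully decorrelated even if noise spikes
    # back above it
    crossed = np.nonzero(~valid & (curve.t > 0))[0]
    if crossed.size:
        valid[crossed[0]:] = False

    x = np.full_like(beta, np.nan)
    safe = beta > 0
    x[safe] = -np.log(beta[safe]) / (2.0 * consts.gamma)
    msd = np.zeros_like(beta)
    pos = safe & (x > 0)
    msd[pos] = np.power(x[pos], 1.0 / consts.zeta) / ctx.k ** 2
    valid &= ~np.isnan(x)
    return MSDCurve(t=curve.t.copy(), msd=msd, valid=valid)


def moving_average(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with symmetric shrink at the edges.

    Near the boundaries the window shrinks symmetrically (no padding), so
    no values are fabricated beyond the band limits.
    """
    y = np.asarray(y, dtype=float)
    half = window // 2
    out = np.empty_like(y)
    n = y.size
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = y[i - h:i + h + 1].mean()
    return out


def _rolling_loglog_slope(logt: np.ndarray, logy: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of logy vs logt over a centered rolling window.

    Returned only where the full centered window fits (``len - window + 1``
    values): a shrunken edge window would regress on 2-3 points of the
    noisiest data near the decorrelation floor and dominate the band-edge
    error.
    """
    half = window // 2
    n = logt.size
    out = np.empty(n - 2 * half)
    for i in range(half, n - half):
        xt = logt[i - half:i + half + 1]
        yt = logy[i - half:i + half + 1]
        xm = xt - xt.mean()
        out[i - half] = np.dot(xm, yt - yt.mean()) / np.dot(xm, xm)
    return out


def compute_alpha(
    msd: MSDCurve,
    omega_band: tuple | None = None,
    points_per_decade: int = POINTS_PER_DECADE,
    slope_window: int = SLOPE_WINDOW,
    smooth_window: int = SMOOTH_WINDOW,
) -> tuple:
    """Resample the MSD and compute the smoothed log-log slope alpha(omega).

    Returns ``(omega, alpha, msd_omega)`` where ``msd_omega`` is the MSD
    interpolated at t = 1/omega.  ``omega_band`` restricts the grid (e.g.
    to the acquisition band (1/tau, Fs)); the grid is additionally limited
    to the lag range covered by valid MSD points.

    Raises
    ------
    ValueError
        If fewer than ``slope_window`` valid points or less than one decade
        of valid lag coverage is available.
    """
    m = msd.valid & (msd.t > 0) & (msd.msd > 0)
    t = msd.t[m]
    y = msd.msd[m]
    if t.size < slope_window:
        raise ValueError("need at least 7 valid MSD points")
    if t.max() / t.min() < 10.0:
        raise ValueError("valid MSD must span at least one decade in lag")

    w_lo, w_hi = 1.0 / t.max(), 1.0 / t.min()
    if omega_band is not None:
        w_lo, w_hi = max(w_lo, omega_band[0]), min(w_hi, omega_band[1])
    if w_lo >= w_hi:
        raise ValueError("empty omega band after intersecting MSD coverage")

    n_pts = int(np.floor(points_per_decade * np.log10(w_hi / w_lo))) + 1
    if n_pts < slope_window + 2:
        raise ValueError("omega band too narrow for the rolling slope window")
    omega = np.logspace(np.log10(w_lo), np.log10(w_hi), n_pts)
    logt_grid = np.log10(1.0 / omega)[::-1]  # ascending in t

    order = np.argsort(t)
    logt, logy = np.log10(t[order]), np.log10(y[order])
    logm = np.interp(logt_grid, logt, logy)

    # the slope exists only where the full centered window fits; the grid
    # is trimmed by window//2 points at each band edge accordingly
    half = slope_window // 2
    slope = _rolling_loglog_slope(logt_grid, logm, slope_window)
    alpha_t = moving_average(slope, smooth_window)

    msd_omega = 10.0 ** logm[half:-half][::-1]  # ascending omega order
    alpha = alpha_t[::-1]
    omega = omega[half:-half]
    return omega, alpha, msd_omega


def gser_reconstruct(
    omega: np.ndarray,
    alpha: np.ndarray,
    msd_omega: np.ndarray,
    ctx: MeasurementContext,
    smooth_window: int = SMOOTH_WINDOW,
    smooth: bool = True,
) -> ViscoelasticSpectrum:
    """Algebraic GSER: complex modulus from MSD amplitude and exponent.

    ``msd_omega`` is the MSD at t = 1/omega (m^2).  alpha is clipped to
    [0, 1]; pre-clip values above 1 raise the per-frequency
    ``active_dynamics`` flag (thermal-equilibrium violation).
    """
    if ctx.radius <= 0 or ctx.temperature <= 0:
        raise ValueError("radius and temperature must be positive")
    omega = np.asarray(omega, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    msd_omega = np.asarray(msd_omega, dtype=float)
    if np.any(msd_omega <= 0):
        raise ValueError("MSD must be positive at all evaluated frequencies")

    active = alpha > 1.0
    if np.any(active):
        # marginal exceedances are expected estimator noise at alpha ~ 1;
        # only a substantial excursion is worth surfacing loudly
        msg = (
            "alpha exceeds 1 at %d of %d frequencies: possible actively driven dynamics"
        )
        if np.max(alpha) > 1.05:
            log.warning(msg, int(active.sum()), alpha.size)
        else:
            log.debug(msg, int(active.sum()), alpha.size)
    a_cl = np.clip(alpha, 0.0, 1.0)

    mag = ctx.kBT / (np.pi * ctx.radius * msd_omega * gamma_fn(1.0 + a_cl))
    phase = np.pi * a_cl / 2.0
    g1_raw = mag * np.cos(phase)
    g2_raw = mag * np.sin(phase)

    if smooth:
        # the moving average runs in the log domain (geometric mean): on the
        # log-spaced omega grid an arithmetic window would inflate a pure
        # power law by a constant factor (+5.5% at slope 1 for 15 points),
        # while the geometric window is exact for power laws
        with np.errstate(divide="ignore"):
            g1 = 10.0 ** moving_average(np.log10(g1_raw), smooth_window)
            g2 = 10.0 ** moving_average(np.log10(g2_raw), smooth_window)
    else:
        g1, g2 = g1_raw.copy(), g2_raw.copy()
    gmag = np.hypot(g1, g2)

    return ViscoelasticSpectrum(
        omega=omega,
        alpha=a_cl,
        G1=g1,
        G2=g2,
        Gmag=gmag,
        G1_raw=g1_raw,
        G2_raw=g2_raw,
        active_dynamics=active,
    )


def spectrum_from_msd(
    msd: MSDCurve,
    ctx: MeasurementContext,
    omega_band: tuple | None = None,
    smooth: bool = True,
) -> ViscoelasticSpectrum:
    """alpha + GSER in one call, starting from an MSD curve."""
    omega, alpha, msd_omega = compute_alpha(msd, omega_band=omega_band)
    return gser_reconstruct(omega, alpha, msd_omega, ctx, smooth=smooth)


def spectrum_from_g2(
    curve: CorrelationCurve,
    consts: InversionConstants,
    ctx: MeasurementContext,
    omega_band: tuple | None = None,
    smooth: bool = True,
) -> ViscoelasticSpectrum:
    """Full reconstruction g2 -> MSD -> alpha -> G*(omega)."""
    msd = invert_g2_to_msd(curve, consts, ctx)
    return spectrum_from_msd(msd, ctx, omega_band=omega_band, smooth=smooth)
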