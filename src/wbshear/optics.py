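"""Sample optical properties and the (gamma, zeta) inversion-constant lookup.

The radial diffuse reflectance profile (DRP) of the focused illumination,
obtained by temporally averaging the speckle time series, is fitted to the
steady-state semi-infinite diffusion-theory dipole solution (extrapolated
boundary condition) to estimate the reduced scattering ``mus'`` and
absorption ``mua`` of the sample.

For a given set of optical properties, Monte Carlo photon transport in a
semi-infinite medium (Henyey-Greenstein phase function, continuous
absorption weighting, detection of 180-degree backscattered photons within
a collection radius and numerical aperture) yields the field correlation

    g1(X) = < W exp(-(X/3) Y) > / < W >,      X = k^2 <dr^2>,

with Y the accumulated dimensionless momentum transfer ``sum(1 - cos
theta_i)`` and W the absorption weight of each detected photon.  Fitting
``g2 - 1 = |g1|^2`` to ``exp(-2 gamma X^zeta)`` over its decay range gives
the inversion constants.  In the single-scattering (DLS) limit they reduce
to (2/3, 1); in the diffusive (DWS backscattering) limit zeta approaches
0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .correlate import _azimuthal_average
from .datatypes import InversionConstants, OpticalProperties, SpeckleStack

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not args else wrap(args[0])

__all__ = [
    "radial_profile",
    "diffusion_reflectance",
    "fit_optical_properties",
    "MonteCarloConfig",
    "run_photon_mc",
    "fit_gamma_zeta",
    "constants_from_mc",
    "dls_limit_constants",
    "LookupTable",
    "build_lookup",
    "lookup_constants",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# radial DRP and diffusion-theory fit
# --------------------------------------------------------------------------

def radial_profile(stack: SpeckleStack, center: tuple | None = None) -> tuple:
    """Azimuthally averaged temporal-mean intensity in 1-pixel annuli.

    Returns ``(rho, profile)`` with ``rho`` in meters.  ``center`` defaults
    to the image center.
    """
    drp = stack.intensity.mean(axis=0)
    if center is None:
        center = ((drp.shape[0] - 1) / 2.0, (drp.shape[1] - 1) / 2.0)
    if not (0 <= center[0] < drp.shape[0] and 0 <= center[1] < drp.shape[1]):
        raise ValueError("center outside image")
    rho_px, prof = _azimuthal_average(drp, center)
    return rho_px * stack.pixel_pitch, prof


def _boundary_parameter(n: float) -> float:
    """Internal-reflection parameter A(n) (Groenhuis polynomial fit)."""
    rd = -1.440 / n ** 2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + rd) / (1.0 - rd)


def diffusion_reflectance(
    rho: np.ndarray, mus_prime: float, mua: float, n: float = 1.36
) -> np.ndarray:
    """Steady-state diffuse reflectance of a semi-infinite medium.

    Dipole solution with extrapolated boundary: an isotropic source at depth
    ``z0 = 1/(mus' + mua)`` and its negative image above the extrapolated
    boundary at ``z = -2 zb``, ``zb = 2 A D``.
    """
    rho = np.asarray(rho, dtype=float)
    mut = mus_prime + mua
    D = 1.0 / (3.0 * mut)
    mueff = np.sqrt(3.0 * mua * mut)
    z0 = 1.0 / mut
    zb = 2.0 * _boundary_parameter(n) * D
    r1 = np.sqrt(z0 ** 2 + rho ** 2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho ** 2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1 ** 2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2 ** 2
    return (term1 + term2) / (4.0 * np.pi)


def fit_optical_properties(
    rho: np.ndarray,
    profile: np.ndarray,
    n: float = 1.36,
    mus_prime_init: float = 1000.0,
    mua_init: float = 10.0,
) -> OpticalProperties:
    """Fit the radial DRP to diffusion theory; free mus', mua and amplitude.

    The fit is least-squares on the log reflectance (multiplicative noise
    model).  Units: rho in m, mus'/mua in 1/m.  Raises on non-convergence.
    """
    rho = np.asarray(rho, dtype=float)
    profile = np.asarray(profile, dtype=float)
    ok = (profile > 0) & (rho > 0)
    if ok.sum() < 5:
        raise ValueError("too few positive profile points to fit")
    rho, profile = rho[ok], profile[ok]
    logp = np.log(profile)

    def resid(theta):
        lmus, lmua, lamp = theta
        model = diffusion_reflectance(rho, np.exp(lmus), np.exp(lmua), n=n)
        return np.log(np.maximum(model, 1e-300)) + lamp - logp

    amp0 = logp[0] - np.log(
        max(diffusion_reflectance(rho[:1], mus_prime_init, mua_init, n=n)[0], 1e-300)
    )
    res = least_squares(
        resid,
        x0=[np.log(mus_prime_init), np.log(mua_init), amp0],
        method="lm",
        max_nfev=2000,
    )
    if not res.success:
        raise RuntimeError(
            f"diffusion-theory DRP fit did not converge (cost {res.cost:.3e})"
        )
    mus_fit, mua_fit = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return OpticalProperties(mus_prime=mus_fit, mua=mua_fit, n=n)


# --------------------------------------------------------------------------
# Monte Carlo photon transport
# --------------------------------------------------------------------------

@dataclass
class MonteCarloConfig:
    """Photon-transport settings for the (gamma, zeta) lookup.

    ``det_radius`` is the surface collection radius around the source;
    ``None`` collects every NA-passing exit regardless of radius.  By
    optical reciprocity, ensemble-averaging g2 over an analysis region under
    focused illumination is equivalent to wide illumination with point
    detection — the classic DWS backscattering geometry — so unrestricted
    collection is the default; a finite radius reproduces aperture-limited
    collection.  ``na`` is the collection numerical aperture (0.15 from a
    9-mm aperture at 30-mm focal length).  Russian roulette terminates
    low-weight photons unbiasedly; set ``rr_threshold = 0`` to disable it
    when exact per-photon weight bookkeeping is required.
    """

    n_photons: int = 1_000_000
    det_radius: Optional[float] = None   # m; None -> collect all NA-passing exits
    na: float = 0.15
    max_events: int = 100_000
    rr_threshold: float = 1e-4
    rr_survive: float = 0.1
    seed: int = 0
    x_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-5, 1.5, 80)
    )


@njit(cache=True)
def _mc_kernel(mus, mua, g, n_photons, det_radius, cos_max, max_events,
               rr_threshold, rr_survive, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    ys = np.empty(n_photons)
    ws = np.empty(n_photons)
    n_det = 0
    w_detected = 0.0
    w_escaped = 0.0
    w_absorbed = 0.0
    w_killed = 0.0
    w_gained = 0.0
    w_lost = 0.0
    # absorption is applied once per photon as exp(-mua * total path), so
    # the in-flight weight factor tracks only Russian-roulette boosts
    s_roulette = 1e300
    if rr_threshold > 0.0 and mua > 0.0:
        s_roulette = -np.log(rr_threshold) / mua
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        boost = 1.0
        gained_p = 0.0
        s_tot = 0.0
        s_mark = s_roulette
        ymom = 0.0
        alive = True
        for _ev in range(max_events):
            s = -np.log(np.random.random()) / mus
            zn = z + uz * s
            if zn < 0.0:
                # crossed the surface: exit over the partial path
                s_surf = -z / uz
                s_tot += s_surf
                w = boost * np.exp(-mua * s_tot)
                w_absorbed += 1.0 + gained_p - w
                xe = x + ux * s_surf
                ye = y + uy * s_surf
                if xe * xe + ye * ye <= det_radius * det_radius and -uz >= cos_max:
                    ys[n_det] = ymom
                    ws[n_det] = w
                    n_det += 1
                    w_detected += w
                else:
                    w_escaped += w
                alive = False
                break
            s_tot += s
            x += ux * s
            y += uy * s
            z = zn
            # Henyey-Greenstein deflection
            if g > 1e-6:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                ct = 2.0 * np.random.random() - 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            ymom += 1.0 - ct
            st = np.sqrt(1.0 - ct * ct)
            # azimuth by rejection sampling on the unit circle (no trig)
            while True:
                v1 = 2.0 * np.random.random() - 1.0
                v2 = 2.0 * np.random.random() - 1.0
                r2 = v1 * v1 + v2 * v2
                if 1e-12 < r2 <= 1.0:
                    break
            rn = np.sqrt(r2)
            cp = v1 / rn
            sp = v2 / rn
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz >= 0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                uxn = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uyn = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uzn = -st * cp * den + uz * ct
                norm = np.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                ux = uxn / norm
                uy = uyn / norm
                uz = uzn / norm
            if s_tot > s_mark:
                # in-flight weight boost*exp(-mua*s_tot) fell below threshold
                w_here = boost * np.exp(-mua * s_tot)
                if np.random.random() < rr_survive:
                    dg = w_here * (1.0 / rr_survive - 1.0)
                    w_gained += dg
                    gained_p += dg
                    boost /= rr_survive
                    s_mark = s_tot + s_roulette
                else:
                    w_killed += w_here
                    w_absorbed += 1.0 + gained_p - w_here
                    alive = False
                    break
        else:
            alive = False
            w = boost * np.exp(-mua * s_tot)
            w_absorbed += 1.0 + gained_p - w
            w_lost += w
        if alive:
            w = boost * np.exp(-mua * s_tot)
            w_absorbed += 1.0 + gained_p - w
            w_lost += w
    return (ys[:n_det], ws[:n_det], w_detected, w_escaped, w_absorbed,
            w_killed, w_gained, w_lost)


def run_photon_mc(props: OpticalProperties, cfg: MonteCarloConfig) -> dict:
    """Run backscattering photon transport for one set of optical properties.

    Returns a dict with per-detected-photon momentum-transfer sums ``Y`` and
    weights ``W``, plus a weight ledger whose entries balance the launched
    weight exactly (``detected + escaped + absorbed + killed - gained +
    lost = launched``).
    """
    mus = props.mus_prime / (1.0 - props.g) if props.g > 0 else props.mus_prime
    det_radius = cfg.det_radius if cfg.det_radius is not None else 1e6 * props.lstar
    sin_max = min(cfg.na / props.n, 1.0)
    cos_max = np.sqrt(1.0 - sin_max ** 2)
    out = _mc_kernel(
        mus, props.mua, props.g, int(cfg.n_photons), det_radius, cos_max,
        int(cfg.max_events), cfg.rr_threshold, cfg.rr_survive,
        int(cfg.seed) % (2 ** 31 - 1),
    )
    ys, ws, det, esc, absd, killed, gained, lost = out
    return {
        "Y": np.asarray(ys),
        "W": np.asarray(ws),
        "launched": float(cfg.n_photons),
        "detected": det,
        "escaped": esc,
        "absorbed": absd,
        "killed": killed,
        "gained": gained,
        "lost": lost,
    }


def mc_g1(mc: dict, x_grid: np.ndarray) -> np.ndarray:
    """Field correlation g1(X) from detected-photon momentum transfer."""
    Y = mc["Y"]
    W = mc["W"]
    if Y.size == 0:
        raise RuntimeError("no detected photons")
    wsum = W.sum()
    return np.array([np.dot(W, np.exp(-(x / 3.0) * Y)) / wsum for x in x_grid])


def fit_gamma_zeta(
    x_grid: np.ndarray, g2m1: np.ndarray, lo: float = 0.01, hi: float = 0.95
) -> tuple:
    """Fit ``g2 - 1 = exp(-2 gamma X^zeta)`` over its decay range.

    The fit is linear in log space: ``log(-ln(g2-1)/2) = log gamma +
    zeta log X``, restricted to points with ``g2 - 1`` in [lo, hi] (noise
    floor and flat head excluded).  Returns ``(gamma, zeta)``.
    """
    g2m1 = np.asarray(g2m1, dtype=float)
    sel = (g2m1 >= lo) & (g2m1 <= hi)
    if sel.sum() < 3:
        raise ValueError("too few points in the fit range [0.01, 0.95]")
    lx = np.log(x_grid[sel])
    ly = np.log(-np.log(g2m1[sel]) / 2.0)
    zeta, lgamma = np.polyfit(lx, ly, 1)
    return float(np.exp(lgamma)), float(zeta)


GAMMA_BRACKET = (2.0 / 3.0, 5.0 / 3.0)
ZETA_BRACKET = (0.5, 1.0)


def constants_from_mc(
    props: OpticalProperties,
    cfg: MonteCarloConfig,
    min_detected: int = 1000,
    clamp: bool = False,
) -> InversionConstants:
    """(gamma, zeta) for given optical properties via Monte Carlo transport.

    With ``clamp=True`` the fit is clamped into the DLS/DWS bracket
    (2/3 <= gamma <= 5/3, 0.5 <= zeta <= 1).  The unpolarized transport
    simulated here yields gamma near the classic ~2.1 diffusive
    backscattering coefficient, above the 5/3 of polarization-resolved
    detection; clamping restores the bracket the inversion assumes.
    """
    mc = run_photon_mc(props, cfg)
    if mc["Y"].size < min_detected:
        raise RuntimeError(
            f"only {mc['Y'].size} detected photons (< {min_detected}); "
            "increase n_photons or the detection radius"
        )
    g1 = mc_g1(mc, cfg.x_grid)
    gamma, zeta = fit_gamma_zeta(cfg.x_grid, g1 ** 2)
    if clamp:
        gc = float(np.clip(gamma, *GAMMA_BRACKET))
        zc = float(np.clip(zeta, *ZETA_BRACKET))
        if gc != gamma or zc != zeta:
            log.info(
                "clamped (gamma, zeta) = (%.3f, %.3f) -> (%.3f, %.3f)",
                gamma, zeta, gc, zc,
            )
        gamma, zeta = gc, zc
    return InversionConstants(gamma=gamma, zeta=zeta, provenance="lookup")


def dls_limit_constants(x_grid: np.ndarray | None = None) -> InversionConstants:
    """Single-scattering (dilute) limit via the analytic DLS reduction.

    At 180-degree backscatter the scattering vector is q = 2k, so
    ``g1 = exp(-q^2 MSD / 6) = exp(-(2/3) k^2 MSD)`` and ``g2 - 1 =
    exp(-2 (2/3) X)``: running the same (gamma, zeta) fit on this closed
    form recovers (2/3, 1) numerically.
    """
    if x_grid is None:
        x_grid = np.logspace(-4, 1, 60)
    g2m1 = np.exp(-2.0 * (2.0 / 3.0) * x_grid)
    gamma, zeta = fit_gamma_zeta(x_grid, g2m1)
    return InversionConstants(gamma=gamma, zeta=zeta, provenance="dls_limit")


# --------------------------------------------------------------------------
# lookup table
# --------------------------------------------------------------------------

@dataclass
class LookupTable:
    """(gamma, zeta) on a (mus', mua) grid, interpolated in log coordinates."""

    mus_prime: np.ndarray     # 1/m, ascending
    mua: np.ndarray           # 1/m, ascending
    gamma: np.ndarray         # (len(mus_prime), len(mua))
    zeta: np.ndarray
    meta: dict = field(default_factory=dict)

    MUA_EPS = 1e-2  # 1/m, regularizes log(mua) at mua ~ 0

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("mus_prime", data=self.mus_prime)
            f.create_dataset("mua", data=self.mua)
            f.create_dataset("gamma", data=self.gamma)
            f.create_dataset("zeta", data=self.zeta)
            for k, v in self.meta.items():
                if v is not None:
                    f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "LookupTable":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                mus_prime=f["mus_prime"][:],
                mua=f["mua"][:],
                gamma=f["gamma"][:],
                zeta=f["zeta"][:],
                meta=dict(f.attrs),
            )


def build_lookup(
    mus_prime_grid: np.ndarray,
    mua_grid: np.ndarray,
    cfg: MonteCarloConfig | None = None,
    g: float = 0.9,
    n: float = 1.36,
    clamp: bool = True,
) -> LookupTable:
    """Monte Carlo (gamma, zeta) lookup over a grid of optical properties.

    Each grid node runs an independent, seeded photon-transport simulation;
    nodes with fewer than 10^3 detected photons raise.  By default node
    values are clamped into the DLS/DWS bracket (see
    :func:`constants_from_mc`).
    """
    cfg = cfg or MonteCarloConfig()
    mus_prime_grid = np.asarray(mus_prime_grid, dtype=float)
    mua_grid = np.asarray(mua_grid, dtype=float)
    if mus_prime_grid.size == 0 or mua_grid.size == 0:
        raise ValueError("empty lookup grid")
    if cfg.n_photons < 1e5:
        raise ValueError("lookup requires at least 1e5 photons per node")

    gam = np.empty((mus_prime_grid.size, mua_grid.size))
    zet = np.empty_like(gam)
    for i, musp in enumerate(mus_prime_grid):
        for j, mua in enumerate(mua_grid):
            props = OpticalProperties(mus_prime=musp, mua=mua, g=g, n=n)
            node_cfg = MonteCarloConfig(
                n_photons=cfg.n_photons,
                det_radius=cfg.det_radius,
                na=cfg.na,
                max_events=cfg.max_events,
                rr_threshold=cfg.rr_threshold,
                rr_survive=cfg.rr_survive,
                seed=cfg.seed + 7919 * i + 104729 * j,
                x_grid=cfg.x_grid,
            )
            consts = constants_from_mc(props, node_cfg, clamp=clamp)
            gam[i, j] = consts.gamma
            zet[i, j] = consts.zeta
    return LookupTable(
        mus_prime=mus_prime_grid,
        mua=mua_grid,
        gamma=gam,
        zeta=zet,
        meta={
            "g": g, "n": n, "na": cfg.na, "n_photons": cfg.n_photons,
            "seed": cfg.seed,
            "det_radius": cfg.det_radius if cfg.det_radius is not None else -1.0,
        },
    )


def lookup_constants(table: LookupTable, props: OpticalProperties) -> InversionConstants:
    """Bilinear interpolation of (gamma, zeta) in (log mus', log(mua + eps)).

    Queries outside the table hull are clamped to the boundary with a
    warning.
    """
    if table.gamma.size == 0:
        raise ValueError("empty lookup table")
    lx = np.log(table.mus_prime)
    ly = np.log(table.mua + LookupTable.MUA_EPS)
    qx = np.log(props.mus_prime)
    qy = np.log(props.mua + LookupTable.MUA_EPS)
    if not (lx[0] <= qx <= lx[-1]) or not (ly[0] <= qy <= ly[-1]):
        log.warning("lookup query outside table hull; clamping to boundary")
        qx = np.clip(qx, lx[0], lx[-1])
        qy = np.clip(qy, ly[0], ly[-1])

    def interp2(z):
        if lx.size == 1 and ly.size == 1:
            return float(z[0, 0])
        if lx.size == 1:
            return float(np.interp(qy, ly, z[0]))
        if ly.size == 1:
            return float(np.interp(qx, lx, z[:, 0]))
        i = int(np.clip(np.searchsorted(lx, qx) - 1, 0, lx.size - 2))
        j = int(np.clip(np.searchsorted(ly, qy) - 1, 0, ly.size - 2))
        tx = (qx - lx[i]) / (lx[i + 1] - lx[i])
        ty = (qy - ly[j]) / (ly[j + 1] - ly[j])
        return float(
            z[i, j] * (1 - tx) * (1 - ty)
            + z[i + 1, j] * tx * (1 - ty)
            + z[i, j + 1] * (1 - tx) * ty
            + z[i + 1, j + 1] * tx * ty
        )

    return InversionConstants(
        gamma=interp2(table.gamma), zeta=interp2(table.zeta), provenance="lookup"
    )
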