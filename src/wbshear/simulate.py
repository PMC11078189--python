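"""Synthetic scatterer dynamics and backscattered speckle rendering.

Ground truth for the whole pipeline: a :class:`DynamicsModel` prescribes the
scatterers' mean square displacement (Newtonian diffusion, harmonically
trapped Ornstein-Uhlenbeck motion, or a power-law MSD realized as fractional
Brownian motion), and :func:`render_speckle` turns it into a speckle
intensity time series whose temporal decorrelation follows the empirical
inversion relation ``g2 - 1 = exp(-2 gamma (k^2 MSD)^zeta)`` for a chosen
(gamma, zeta).

Two rendering backends are provided:

``gaussian_field``
    Per-pixel circular complex Gaussian process with exactly the target field
    autocorrelation ``g1(t) = exp(-gamma (k^2 MSD(t))^zeta)``, synthesized by
    circulant spectral factorization, band-limited to the configured speckle
    grain size and shaped by a diffuse-reflectance envelope.  Fast and with
    exact control of the target correlation; the default.

``phasor_sum``
    Coherent sum of per-particle phasors ``exp(i q . r_j(t))`` with ``q = 2k``
    (180-degree backscatter), using simulated trajectories.  Slower; kept for
    physics cross-validation against the Gaussian-field route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import BOLTZMANN, SpeckleStack

__all__ = [
    "DynamicsModel",
    "RenderConfig",
    "simulate_trajectories",
    "render_speckle",
]

log = logging.getLogger(__name__)


@dataclass
class DynamicsModel:
    """Scatterer dynamics with a closed-form ensemble MSD.

    Parameters
    ----------
    kind
        ``newtonian`` (free diffusion in a fluid of viscosity ``eta``),
        ``trapped`` (harmonic trap of stiffness ``kappa`` in a bath of
        viscosity ``bath_eta``), or ``powerlaw`` (``MSD(t) = C t**p``).
    radius
        Particle radius a, m.
    temperature
        Bath temperature T, K.
    """

    kind: str
    radius: float
    temperature: float = 295.0
    eta: Optional[float] = None        # Pa.s, newtonian
    kappa: Optional[float] = None      # N/m, trapped
    bath_eta: float = 1e-3             # Pa.s, trapped relaxation bath
    p: Optional[float] = None          # powerlaw exponent
    C: Optional[float] = None          # m^2 at t = 1 s, powerlaw amplitude

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.temperature <= 0:
            raise ValueError("radius and temperature must be positive")
        if self.kind == "newtonian":
            if self.eta is None or self.eta <= 0:
                raise ValueError("newtonian model needs eta > 0")
        elif self.kind == "trapped":
            if self.kappa is None or self.kappa <= 0:
                raise ValueError("trapped model needs kappa > 0")
            if self.bath_eta <= 0:
                raise ValueError("bath viscosity must be positive")
        elif self.kind == "powerlaw":
            if self.p is None or not (0 < self.p <= 1):
                raise ValueError("powerlaw model needs 0 < p <= 1")
            if self.C is None or self.C <= 0:
                raise ValueError("powerlaw model needs C > 0")
        else:
            raise ValueError(f"unsupported dynamics kind: {self.kind!r}")

    @property
    def kBT(self) -> float:
        return BOLTZMANN * self.temperature

    @property
    def diffusivity(self) -> float:
        """Stokes-Einstein diffusivity D = kB T / (6 pi a eta), m^2/s."""
        if self.kind != "newtonian":
            raise ValueError("diffusivity defined for the newtonian model")
        return self.kBT / (6.0 * np.pi * self.radius * self.eta)

    @property
    def trap_relaxation_time(self) -> float:
        """OU relaxation time tau_r = 6 pi a eta_bath / kappa, s."""
        if self.kind != "trapped":
            raise ValueError("relaxation time defined for the trapped model")
        return 6.0 * np.pi * self.radius * self.bath_eta / self.kappa

    @property
    def plateau_modulus(self) -> float:
        """Equivalent elastic plateau G0 = kappa / (6 pi a), Pa."""
        if self.kind != "trapped":
            raise ValueError("plateau modulus defined for the trapped model")
        return self.kappa / (6.0 * np.pi * self.radius)

    def msd(self, t: np.ndarray) -> np.ndarray:
        """Closed-form 3D ensemble MSD at lag times ``t`` (s), in m^2."""
        t = np.asarray(t, dtype=float)
        if self.kind == "newtonian":
            return 6.0 * self.diffusivity * t
        if self.kind == "trapped":
            # plateau = kB T / (pi a G0) = 6 kB T / kappa
            plateau = self.kBT / (np.pi * self.radius * self.plateau_modulus)
            return plateau * -np.expm1(-t / self.trap_relaxation_time)
        return self.C * t ** self.p


@dataclass
class RenderConfig:
    """Configuration of the speckle renderer.

    ``grain_size`` is the FWHM of the spatial intensity autocorrelation in
    pixels (>= 2 for Nyquist-sampled fully developed speckle; 3.5 mirrors a
    3.5 pixel/speckle optical design).  ``drp_radius`` is the 1/e radius of
    the exponential diffuse-reflectance envelope at the sample, in meters.
    ``photon_budget`` sets the mean photoelectron count at the envelope peak
    for Poisson shot noise; ``None`` disables shot noise (the default, so
    statistical oracles see pure speckle statistics).
    """

    backend: str = "gaussian_field"
    n_frames: int = 2000
    frame_rate: float = 1000.0
    shape: tuple = (64, 64)
    pixel_pitch: float = 1.5e-6
    grain_size: float = 3.5
    wavelength: float = 637e-9
    n_medium: float = 1.33
    drp_radius: Optional[float] = None   # None -> flat envelope
    photon_budget: Optional[float] = None
    bit_depth: int = 12
    peak_fill: float = 0.15              # envelope-peak mean as fraction of full scale
    n_particles: int = 300               # phasor_sum backend only
    seed: int = 0
    gamma: float = 2.0 / 3.0
    zeta: float = 1.0

    def __post_init__(self) -> None:
        if self.backend not in ("gaussian_field", "phasor_sum"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.grain_size < 2:
            raise ValueError("grain size must be >= 2 pixels (Nyquist)")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_rate <= 0 or self.pixel_pitch <= 0:
            raise ValueError("frame_rate and pixel_pitch must be positive")
        if not (1 <= self.bit_depth <= 16):
            raise ValueError("bit_depth must be within [1, 16]")

    @property
    def k(self) -> float:
        """Wave number in the medium, 1/m."""
        return 2.0 * np.pi * self.n_medium / self.wavelength


def simulate_trajectories(
    model: DynamicsModel,
    n_particles: int,
    dt: float,
    n_steps: int,
    seed: int = 0,
) -> np.ndarray:
    """Simulate 3D particle trajectories for the given dynamics model.

    Returns positions of shape ``(n_particles, n_steps, 3)`` in meters,
    starting from the origin (newtonian/powerlaw) or from the stationary
    trap distribution (trapped).  The empirical ensemble MSD matches the
    model's closed form within sampling error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)

    if model.kind == "newtonian":
        sigma = np.sqrt(2.0 * model.diffusivity * dt)
        steps = rng.normal(0.0, sigma, size=(n_particles, n_steps - 1, 3))
        pos = np.zeros((n_particles, n_steps, 3))
        np.cumsum(steps, axis=1, out=pos[:, 1:, :])
        return pos

    if model.kind == "trapped":
        tau = model.trap_relaxation_time
        var = model.kBT / model.kappa           # per-axis stationary variance
        rho = np.exp(-dt / tau)
        innov = np.sqrt(var * (1.0 - rho * rho))
        pos = np.empty((n_particles, n_steps, 3))
        pos[:, 0, :] = rng.normal(0.0, np.sqrt(var), size=(n_particles, 3))
        for i in range(1, n_steps):
            pos[:, i, :] = rho * pos[:, i - 1, :] + innov * rng.normal(
                size=(n_particles, 3)
            )
        return pos

    # powerlaw: fBm with Hurst H = p/2 per axis so MSD ~ t^(2H) = t^p
    H = model.p / 2.0
    amp = np.sqrt(model.C / 3.0)  # per-axis MSD = (C/3) t^p
    incr = _fbm_increments(rng, H, n_particles * 3, n_steps - 1, dt)
    incr = incr.reshape(n_particles, 3, n_steps - 1).transpose(0, 2, 1)
    pos = np.zeros((n_particles, n_steps, 3))
    np.cumsum(amp * incr, axis=1, out=pos[:, 1:, :])
    return pos


def _fbm_increments(rng, H: float, n_series: int, n: int, dt: float) -> np.ndarray:
    """Fractional Gaussian noise via circulant embedding (Davies-Harte).

    Returns ``(n_series, n)`` increments with Var(sum of first m) = (m dt)^(2H).
    """
    if abs(H - 0.5) < 1e-12:
        return rng.normal(0.0, dt ** H, size=(n_series, n))
    k = np.arange(n + 1, dtype=float)
    # autocovariance of unit-spaced fGn, then scale by dt^(2H)
    g = 0.5 * ((k + 1) ** (2 * H) + np.abs(k - 1) ** (2 * H) - 2 * k ** (2 * H))
    g *= dt ** (2 * H)
    m = 2 * n
    c = np.concatenate([g[:n], g[n:0:-1]])  # length 2n circulant row
    lam = np.fft.fft(c).real
    lam = np.clip(lam, 0.0, None)
    z = rng.normal(size=(n_series, m)) + 1j * rng.normal(size=(n_series, m))
    w = np.fft.fft(np.sqrt(lam / m) * z, axis=1)
    return w.real[:, :n]  # real part carries exactly the target covariance


def target_g1(model: DynamicsModel, cfg: RenderConfig, t: np.ndarray) -> np.ndarray:
    """Target field autocorrelation ``exp(-gamma (k^2 MSD(t))^zeta)``."""
    x = cfg.k ** 2 * model.msd(np.abs(t))
    return np.exp(-cfg.gamma * np.power(x, cfg.zeta, where=x > 0, out=np.zeros_like(x)))


def render_speckle(model: DynamicsModel, cfg: RenderConfig) -> SpeckleStack:
    """Render a synthetic backscattered speckle stack for the given dynamics.

    See the module docstring for the two backends.  Output intensities are
    quantized to ``cfg.bit_depth`` with the envelope-peak mean placed at
    ``cfg.peak_fill`` of full scale; a warning is logged if more than 1% of
    samples saturate.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.backend == "gaussian_field":
        intensity = _render_gaussian_field(model, cfg, rng)
    else:
        intensity = _render_phasor_sum(model, cfg, rng)

    env = _drp_envelope(cfg).astype(np.float32)
    full_scale = float(2 ** cfg.bit_depth - 1)
    # unit-mean speckle at the envelope peak -> peak_fill of full scale
    scale = cfg.peak_fill * full_scale
    quantized = np.empty(intensity.shape, dtype=np.uint16)
    n_sat = 0
    chunk = 512
    for start in range(0, intensity.shape[0], chunk):
        stop = min(start + chunk, intensity.shape[0])
        blk = intensity[start:stop] * env[None, :, :]
        if cfg.photon_budget is not None:
            counts = rng.poisson(blk.astype(np.float64) * cfg.photon_budget)
            counts = counts * (scale / cfg.photon_budget)
        else:
            counts = blk * scale
        counts = np.rint(counts)
        n_sat += int(np.count_nonzero(counts > full_scale))
        quantized[start:stop] = np.clip(counts, 0, full_scale).astype(np.uint16)
    sat = n_sat / quantized.size
    if sat > 0.01:
        log.warning("saturation fraction %.2f%% exceeds 1%%", 100 * sat)

    meta = {
        "backend": cfg.backend,
        "seed": cfg.seed,
        "model_kind": model.kind,
        "gamma": cfg.gamma,
        "zeta": cfg.zeta,
        "grain_size_px": cfg.grain_size,
        "drp_radius_m": cfg.drp_radius,
        "saturation_fraction": sat,
    }
    return SpeckleStack(
        intensity=quantized,
        frame_rate=cfg.frame_rate,
        pixel_pitch=cfg.pixel_pitch,
        wavelength=cfg.wavelength,
        bit_depth=cfg.bit_depth,
        meta=meta,
    )


def _drp_envelope(cfg: RenderConfig) -> np.ndarray:
    """Exponential diffuse-reflectance envelope exp(-rho/rho0), peak 1."""
    rows, cols = cfg.shape
    if cfg.drp_radius is None:
        return np.ones((rows, cols))
    r = (np.arange(rows) - rows / 2.0)[:, None]
    c = (np.arange(cols) - cols / 2.0)[None, :]
    rho = np.hypot(r, c) * cfg.pixel_pitch
    return np.exp(-rho / cfg.drp_radius)


def _grain_filter_mask(cfg: RenderConfig) -> np.ndarray:
    """Gaussian spatial band-limit giving the configured grain FWHM.

    For a white complex field filtered by H(k) = exp(-|k|^2 / (2 sk^2)),
    the intensity autocorrelation is exp(-sk^2 rho^2 / 2), whose FWHM is
    2 sqrt(2 ln 2) / sk; we invert that for sk.
    """
    rows, cols = cfg.shape
    sk = 2.0 * np.sqrt(2.0 * np.log(2.0)) / cfg.grain_size  # rad/pixel
    kr = 2 * np.pi * np.fft.fftfreq(rows)[:, None]
    kc = 2 * np.pi * np.fft.fftfreq(cols)[None, :]
    return np.exp(-(kr ** 2 + kc ** 2) / (2.0 * sk ** 2))


def _spectral_amplitudes(g1: np.ndarray, n_frames: int) -> np.ndarray:
    """Circulant factorization of the target temporal autocovariance.

    ``g1`` holds the target autocorrelation at lags 0..N (length N + 1).
    Builds its length-2N symmetric circulant embedding and returns sqrt of
    the (clipped) eigenvalue spectrum.  A complex Gaussian process
    synthesized from these amplitudes has autocorrelation g1 exactly, up to
    the clipping of negative eigenvalues, whose fraction is logged.
    """
    m = 2 * n_frames
    row = np.concatenate([g1[: n_frames + 1], g1[n_frames - 1:0:-1]])
    lam = np.fft.fft(row).real
    neg = float(-lam[lam < 0].sum() / max(lam[lam > 0].sum(), 1e-300))
    if neg > 1e-6:
        log.info("clipped %.2e negative spectral mass in temporal factorization", neg)
    return np.sqrt(np.clip(lam, 0.0, None) / m)


def _render_gaussian_field(model, cfg: RenderConfig, rng) -> np.ndarray:
    """Unit-mean intensity frames from a band-limited complex Gaussian field.

    The field is synthesized directly on the active spatial-frequency modes
    (the grain-size band limit leaves only a few hundred of them), each mode
    carrying an independent temporal process with the target autocorrelation.
    """
    rows, cols = cfg.shape
    n = cfg.n_frames
    t = np.arange(n + 1) / cfg.frame_rate
    g1 = target_g1(model, cfg, t)
    amps = _spectral_amplitudes(g1, n)  # length 2n

    # modes below 1e-2 amplitude carry < 1e-4 of the filter power; dropping
    # them bounds memory without visibly altering the grain statistics
    hmask = _grain_filter_mask(cfg)
    active = np.argwhere(hmask > 1e-2)
    weights = hmask[active[:, 0], active[:, 1]]
    n_modes = active.shape[0]
    wnorm = weights / np.sqrt(np.sum(weights ** 2))

    m = 2 * n
    # temporal synthesis per active mode: x_t = FFT(amps * z)_t, t < n;
    # z components scaled so each mode has unit complex variance
    modes = np.empty((n_modes, n), dtype=np.complex64)
    blk = 256
    for b0 in range(0, n_modes, blk):
        b1 = min(b0 + blk, n_modes)
        z = rng.standard_normal((b1 - b0, m)) + 1j * rng.standard_normal((b1 - b0, m))
        z *= np.sqrt(0.5)
        synth = np.fft.fft(amps[None, :] * z, axis=1)[:, :n]
        # amps give unit variance per mode; weight by the spatial filter
        # (normalized to unit total field variance)
        synth *= wnorm[b0:b1, None]
        modes[b0:b1] = synth.astype(np.complex64)

    intensity = np.empty((n, rows, cols), dtype=np.float32)
    chunk = max(1, int(8e6 // (rows * cols)))
    spec = np.zeros((chunk, rows, cols), dtype=complex)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        spec[: stop - start] = 0.0
        spec[: stop - start, active[:, 0], active[:, 1]] = modes[:, start:stop].T
        # orthonormal FFT keeps per-pixel variance equal to sum of mode powers
        fld = np.fft.ifft2(spec[: stop - start], norm="ortho") * np.sqrt(rows * cols)
        intensity[start:stop] = (np.abs(fld) ** 2).astype(np.float32)
    return intensity


def _render_phasor_sum(model, cfg: RenderConfig, rng) -> np.ndarray:
    """Unit-mean intensity from coherent per-particle phasors, q = 2k.

    Each particle couples to every pixel through a fixed random complex
    amplitude (spatially band-limited to the grain size); the temporal phase
    is q.z_j(t) for 180-degree backscatter along z.
    """
    rows, cols = cfg.shape
    n_particles = cfg.n_particles
    dt = 1.0 / cfg.frame_rate
    traj = simulate_trajectories(
        model, n_particles, dt, cfg.n_frames, seed=int(rng.integers(2 ** 31 - 1))
    )
    q = 2.0 * cfg.k
    phasors = np.exp(1j * q * traj[:, :, 2])  # (particles, frames)

    # per-particle speckle coupling field, band-limited to the grain size
    hmask = _grain_filter_mask(cfg)
    white = rng.standard_normal((n_particles, rows, cols)) + 1j * rng.standard_normal(
        (n_particles, rows, cols)
    )
    coup = np.fft.ifft2(np.fft.fft2(white, axes=(1, 2)) * hmask[None], axes=(1, 2))
    coup /= np.sqrt(np.mean(np.abs(coup) ** 2) * n_particles)

    field = np.tensordot(phasors.T, coup.reshape(n_particles, -1), axes=(1, 0))
    intensity = np.abs(field.reshape(cfg.n_frames, rows, cols)) ** 2
    return (intensity / intensity.mean()).astype(np.float32)
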