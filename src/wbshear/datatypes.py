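"""Core data containers shared across the pipeline.

The pipeline transforms a speckle intensity time series (:class:`SpeckleStack`)
into an ensemble intensity autocorrelation (:class:`CorrelationCurve`), a
mean-square-displacement curve (:class:`MSDCurve`) and finally a wideband
viscoelastic spectrum (:class:`ViscoelasticSpectrum`) with extracted
spectroscopic fingerprints (:class:`~wbshear.spectro.SpectroscopicParameters`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SpeckleStack",
    "AnalysisROI",
    "CorrelationCurve",
    "MSDCurve",
    "ViscoelasticSpectrum",
    "OpticalProperties",
    "InversionConstants",
    "MeasurementContext",
]

BOLTZMANN = 1.380649e-23  # J/K (exact, SI)


@dataclass
class SpeckleStack:
    """A speckle intensity time series with acquisition metadata.

    Attributes
    ----------
    intensity
        ``(frames, rows, cols)`` array of detector counts.
    frame_rate
        Acquisition frame rate Fs in frames/s.
    pixel_pitch
        Physical size of one pixel at the sample, m/pixel.
    wavelength
        Illumination wavelength in vacuum, m.
    bit_depth
        Sensor bit depth; intensities live in ``[0, 2**bit_depth - 1]``.
    meta
        Free-form provenance (simulation parameters, source path, ...).
    """

    intensity: np.ndarray
    frame_rate: float
    pixel_pitch: float
    wavelength: float
    bit_depth: int = 12
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (frames, rows, cols)")
        if self.intensity.shape[0] < 2:
            raise ValueError("stack needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def shape(self) -> tuple:
        return self.intensity.shape[1:]

    @property
    def duration(self) -> float:
        """Total acquisition duration tau = frames / Fs, in s."""
        return self.n_frames / self.frame_rate


@dataclass
class AnalysisROI:
    """Circular analysis region concentric with the illumination center.

    ``diameter`` is twice the 1/e radius of the diffuse reflectance profile,
    in meters; ``mask`` is the boolean pixel mask on the stack's image grid.
    """

    center: tuple
    diameter: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")
        if not np.any(self.mask):
            raise ValueError("ROI mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class CorrelationCurve:
    """Contrast-normalized ensemble intensity autocorrelation g2(t).

    ``t`` includes zero lag; ``g2[0] == 2`` exactly after contrast
    normalization.  ``g2_raw`` keeps the unnormalized estimator and
    ``n_pairs`` the number of (pixel x frame-pair) samples per lag.
    """

    t: np.ndarray
    g2: np.ndarray
    g2_raw: np.ndarray
    n_pixels: int
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.t.shape != self.g2.shape:
            raise ValueError("t and g2 must have matching shapes")


@dataclass
class MSDCurve:
    """Time-dependent mean square displacement with a validity mask.

    Points where the speckle has completely decorrelated (intensity
    correlation at the noise floor) are flagged invalid and excluded from
    all downstream fits rather than extrapolated.
    """

    t: np.ndarray
    msd: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def trimmed(self) -> "MSDCurve":
        """Return a copy restricted to valid points."""
        m = self.valid
        return MSDCurve(self.t[m], self.msd[m], np.ones(m.sum(), dtype=bool))


@dataclass
class ViscoelasticSpectrum:
    """Frequency-dependent complex shear modulus on a log-spaced grid.

    ``alpha`` is the local log-log slope of the MSD evaluated at t = 1/omega;
    ``G1``/``G2`` are the storage and loss moduli in Pa after smoothing, with
    the pre-smoothing components kept in ``G1_raw``/``G2_raw``.  The phase of
    G* is pi*alpha/2.  ``active_dynamics`` flags frequencies where the
    pre-clip alpha exceeded 1, the equilibrium-violation signature of
    actively driven motion.
    """

    omega: np.ndarray
    alpha: np.ndarray
    G1: np.ndarray
    G2: np.ndarray
    Gmag: np.ndarray
    G1_raw: Optional[np.ndarray] = None
    G2_raw: Optional[np.ndarray] = None
    active_dynamics: Optional[np.ndarray] = None

    @property
    def phase(self) -> np.ndarray:
        return np.pi * self.alpha / 2.0


@dataclass
class OpticalProperties:
    """Bulk optical properties of a turbid sample.

    ``mus_prime`` (reduced scattering) and ``mua`` (absorption) in 1/m,
    anisotropy ``g`` of the scattering phase function, refractive index ``n``.
    """

    mus_prime: float
    mua: float
    g: float = 0.9
    n: float = 1.36

    def __post_init__(self) -> None:
        if self.mus_prime <= 0:
            raise ValueError("mus_prime must be positive")
        if self.mua < 0:
            raise ValueError("mua must be non-negative")
        if not (0 <= self.g < 1):
            raise ValueError("anisotropy g must be in [0, 1)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def lstar(self) -> float:
        """Transport mean free path 1/(mus' + mua), m."""
        return 1.0 / (self.mus_prime + self.mua)


@dataclass
class InversionConstants:
    """Constants (gamma, zeta) of the empirical g2 -> MSD inversion.

    ``g2 - 1 = exp(-2 gamma (k^2 MSD)^zeta)``.  (2/3, 1) is the
    single-scattering (DLS) 180-degree-backscatter limit; (5/3, 0.5) the
    diffusing-wave (DWS) backscattering limit.  Within those limits the
    lookup-table values satisfy 2/3 <= gamma <= 5/3 and 0.5 <= zeta <= 1.
    """

    gamma: float
    zeta: float
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.zeta <= 0:
            raise ValueError("gamma and zeta must be positive")

    @classmethod
    def dls_limit(cls) -> "InversionConstants":
        return cls(2.0 / 3.0, 1.0, provenance="dls_limit")

    @classmethod
    def dws_limit(cls) -> "InversionConstants":
        return cls(5.0 / 3.0, 0.5, provenance="dws_limit")


@dataclass
class MeasurementContext:
    """Physical context needed by the inversion and the GSER.

    Attributes
    ----------
    radius
        Sphere-equivalent radius a of the dominant scatterers, m.  It only
        scales the magnitude of G*, not its frequency dependence.
    temperature
        Sample temperature T in K (room temperature default).
    wavelength
        Illumination wavelength in vacuum, m.
    n
        Refractive index of the medium; the wave number is k = 2 pi n / lambda.
    """

    radius: float
    temperature: float = 295.0
    wavelength: float = 637e-9
    n: float = 1.33

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.wavelength <= 0 or self.n < 1:
            raise ValueError("invalid optical parameters")

    @property
    def k(self) -> float:
        """Wave number in the medium, 1/m."""
        return 2.0 * np.pi * self.n / self.wavelength

    @property
    def kBT(self) -> float:
        return BOLTZMANN * self.temperature
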