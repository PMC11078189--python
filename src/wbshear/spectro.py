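"""Spectroscopic fingerprints of wideband viscoelastic spectra.

A wideband G*(omega) spectrum is segmented into regimes delimited by the
elastic plateaus (local minima of alpha, which coincide with local minima
of the loss modulus), and six parameter classes are extracted:

1. transition frequencies ``omega_T`` where alpha crosses 0.5 (G' = G"
   crossover; downward crossing = fluid-to-solid, upward = solid-to-fluid);
2. plateau frequencies ``omega_0`` at the alpha minima;
3. plateau moduli ``G0`` = G'(omega_0);
4. loss power-law exponents ``gamma`` = log-log slope of G" per
   inter-plateau regime;
5. the G" scaling transition frequency ``omega_gamma`` inside the first
   inter-plateau regime (inflection of the rolling log-log derivative),
   splitting it into IIIa/IIIb when the sub-slopes differ appreciably;
6. magnitude power-law exponents ``alpha`` = log-log slope of |G*| per
   regime.

Replicates are aggregated as mean +/- SD or median +/- median absolute
deviation, and groups compared by a two-sided Wilcoxon rank-sum
(Mann-Whitney U) test, exact for small samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu

from .datatypes import ViscoelasticSpectrum

__all__ = [
    "Crossing",
    "Plateau",
    "Regime",
    "SpectroscopicParameters",
    "extract_parameters",
    "aggregate_replicates",
    "compare_groups",
]

log = logging.getLogger(__name__)

PLATEAU_PROMINENCE = 0.02     # alpha dip depth distinguishing a plateau from ripple
PLATEAU_SEPARATION_DECADES = 0.5
SUBREGIME_SLOPE_SPLIT = 0.15  # min gamma difference for an IIIa/IIIb split


@dataclass
class Crossing:
    """An alpha = 0.5 crossing: G' = G" crossover frequency with direction."""

    omega: float
    direction: str  # "down" = fluid-to-solid, "up" = solid-to-fluid


@dataclass
class Plateau:
    """An elastic plateau: alpha local minimum with its G' plateau modulus."""

    omega0: float
    G0: float
    alpha_min: float


@dataclass
class Regime:
    """A frequency segment between plateaus (or band edges)."""

    label: str
    omega_lo: float
    omega_hi: float
    gamma: float = np.nan          # log-log slope of G"
    alpha_exp: float = np.nan      # log-log slope of |G*|
    omega_gamma: float = np.nan    # G" scaling transition inside the regime
    gamma_a: float = np.nan        # sub-slopes when split (IIIa / IIIb)
    gamma_b: float = np.nan

    @property
    def dominant(self) -> str:
        """Viscous if the loss slope is fluid-like (gamma >= 0.5)."""
        return "viscous" if (np.isnan(self.gamma) or self.gamma >= 0.5) else "elastic"


@dataclass
class SpectroscopicParameters:
    """All fingerprint values extracted from one spectrum."""

    crossings: list = field(default_factory=list)
    plateaus: list = field(default_factory=list)
    regimes: list = field(default_factory=list)

    def scalar_dict(self) -> dict:
        """Flat name -> value mapping for tabulation and aggregation."""
        out = {}
        for i, c in enumerate(self.crossings):
            out[f"omega_T_{i + 1}_{c.direction}"] = c.omega
        for i, p in enumerate(self.plateaus):
            out[f"omega0_{i + 1}"] = p.omega0
            out[f"G0_{i + 1}"] = p.G0
        for r in self.regimes:
            if not np.isnan(r.gamma):
                out[f"gamma_{r.label}"] = r.gamma
            if not np.isnan(r.alpha_exp):
                out[f"alpha_{r.label}"] = r.alpha_exp
            if not np.isnan(r.omega_gamma):
                out[f"omega_gamma_{r.label}"] = r.omega_gamma
            if not np.isnan(r.gamma_a):
                out[f"gamma_{r.label}a"] = r.gamma_a
                out[f"gamma_{r.label}b"] = r.gamma_b
        return out


def _loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x > 0) & (y > 0)
    if ok.sum() < 2:
        return float("nan")
    return float(np.polyfit(np.log10(x[ok]), np.log10(y[ok]), 1)[0])


def _interp_crossing(logw: np.ndarray, a: np.ndarray, i: int, level: float) -> float:
    """Log-linear interpolation of the level crossing between grid points."""
    f = (level - a[i]) / (a[i + 1] - a[i])
    return float(10.0 ** (logw[i] + f * (logw[i + 1] - logw[i])))


def extract_parameters(
    spec: ViscoelasticSpectrum,
    prominence: float = PLATEAU_PROMINENCE,
    min_separation_decades: float = PLATEAU_SEPARATION_DECADES,
    split_threshold: float = SUBREGIME_SLOPE_SPLIT,
) -> SpectroscopicParameters:
    """Extract the spectroscopic parameter set from a wideband spectrum.

    The spectrum must span at least two decades.  A spectrum with no alpha
    minima yields a single regime (no plateau entries) — that is a valid
    output, not an error.
    """
    w = np.asarray(spec.omega, dtype=float)
    a = np.asarray(spec.alpha, dtype=float)
    if w.size < 8 or w[-1] / w[0] < 100.0:
        raise ValueError("spectrum must cover at least 2 decades")
    logw = np.log10(w)
    pts_per_decade = (w.size - 1) / (logw[-1] - logw[0])

    # 1. alpha = 0.5 crossings, log-interpolated, with direction
    crossings = []
    d = a - 0.5
    sign_change = np.nonzero(np.diff(np.signbit(d)))[0]
    for i in sign_change:
        if d[i + 1] == d[i]:
            continue
        omega_t = _interp_crossing(logw, a, i, 0.5)
        crossings.append(
            Crossing(omega=omega_t, direction="down" if d[i] > d[i + 1] else "up")
        )

    # 2-3. plateaus: local minima of alpha with configured prominence and
    #      at least half a decade of separation
    distance = max(1, int(round(min_separation_decades * pts_per_decade)))
    peaks, _props = find_peaks(-a, prominence=prominence, distance=distance)
    plateaus = [
        Plateau(omega0=float(w[i]), G0=float(spec.G1[i]), alpha_min=float(a[i]))
        for i in peaks
    ]

    # regime boundaries: band edge, plateau frequencies, band edge
    bounds = [w[0]] + [p.omega0 for p in plateaus] + [w[-1]]
    regimes = []
    # ordinal labels: I before the first plateau, then inter-plateau scaling
    # regimes III, V, VII ... (plateaus themselves carry II, IV, VI)
    labels = ["I"] + [_roman(2 * i + 3) for i in range(len(plateaus))]
    for seg_idx, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        sel = (w >= lo) & (w <= hi)
        if sel.sum() < 2:
            continue
        reg = Regime(label=labels[seg_idx], omega_lo=float(lo), omega_hi=float(hi))
        reg.gamma = _loglog_slope(w[sel], spec.G2[sel])
        reg.alpha_exp = _loglog_slope(w[sel], spec.Gmag[sel])
        if seg_idx == 1 and sel.sum() >= 9:
            _locate_scaling_transition(reg, w[sel], spec.G2[sel], split_threshold)
        regimes.append(reg)

    return SpectroscopicParameters(
        crossings=crossings, plateaus=plateaus, regimes=regimes
    )


def _roman(n: int) -> str:
    numerals = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII",
                8: "VIII", 9: "IX"}
    return numerals.get(n, str(n))


def _locate_scaling_transition(
    reg: Regime, w: np.ndarray, g2: np.ndarray, split_threshold: float
) -> None:
    """Find omega_gamma inside a regime from the rolling log-log G" slope.

    omega_gamma sits at the inflection of the derivative: the maximum of
    the second difference magnitude of the rolling slope, localized at its
    sign change.  The regime is split into a/b sub-slopes when they differ
    by more than ``split_threshold``.
    """
    from .reconstruct import _rolling_loglog_slope

    lw = np.log10(w)
    lg = np.log10(np.maximum(g2, 1e-300))
    half = 3
    deriv = _rolling_loglog_slope(lw, lg, 2 * half + 1)  # deriv[k] <-> w[k + half]
    d2 = np.diff(deriv, 2)
    if d2.size < 3:
        return
    # inflection: extremum of the curvature of the derivative profile
    j = int(np.argmax(np.abs(d2))) + 1 + half
    omega_g = float(w[j])
    lo_sel = w <= omega_g
    hi_sel = w >= omega_g
    ga = _loglog_slope(w[lo_sel], g2[lo_sel])
    gb = _loglog_slope(w[hi_sel], g2[hi_sel])
    if np.isnan(ga) or np.isnan(gb):
        return
    if abs(gb - ga) > split_threshold:
        reg.omega_gamma = omega_g
        reg.gamma_a = ga
        reg.gamma_b = gb


def aggregate_replicates(params: list, method: str = "mean_sd") -> dict:
    """Aggregate parameter sets across replicates, matched by name.

    ``method`` is ``mean_sd`` (mean +/- standard deviation) or
    ``median_mad`` (median +/- median absolute deviation).  Returns
    ``{name: (center, dispersion, n)}``; parameters present in only some
    replicates are aggregated over the replicates that have them.
    """
    if not params:
        raise ValueError("no replicates to aggregate")
    if method not in ("mean_sd", "median_mad"):
        raise ValueError(f"unknown aggregation method {method!r}")
    tables = [
        p.scalar_dict() if isinstance(p, SpectroscopicParameters) else dict(p)
        for p in params
    ]
    names = sorted({k for t in tables for k in t})
    out = {}
    for name in names:
        vals = np.array([t[name] for t in tables if name in t], dtype=float)
        if method == "mean_sd":
            center, disp = float(vals.mean()), float(vals.std(ddof=0))
        else:
            med = float(np.median(vals))
            center, disp = med, float(np.median(np.abs(vals - med)))
        out[name] = (center, disp, int(vals.size))
    return out


def compare_groups(a, b, exact_max_n: int = 25) -> tuple:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test between two groups.

    Exact p-value for group sizes up to ``exact_max_n``, normal
    approximation with tie correction beyond.  Returns ``(p, significant)``
    with significance at the 0.05 level.  Degenerate all-tied groups give
    p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        log.warning("all observations tied; rank-sum p set to 1")
        return 1.0, False
    if max(a.size, b.size) <= exact_max_n and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return p, p < 0.05


def _has_ties(x: np.ndarray) -> bool:
    return np.unique(x).size < x.size
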