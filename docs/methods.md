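# Methods

## Scope and model

`wbshear` reconstructs wideband frequency-dependent shear moduli from laser
speckle intensity time series, the computational core of wideband speckle
rheological microscopy. Coherent light backscattered by a turbid,
thermally fluctuating sample forms a speckle pattern whose temporal
decorrelation encodes the mean square displacement (MSD) of the dominant
scatterers; under thermal equilibrium the MSD maps to the complex shear
modulus G*(ω) through the generalized Stokes–Einstein relation (GSER).
The chain is

1. **g₂(t)** — contrast-normalized ensemble intensity autocorrelation over
   a circular analysis region extending to the 1/e radius of the diffuse
   reflectance profile (DRP);
2. **MSD** — algebraic inversion of the empirical relation
   `g₂(t) − 1 = exp(−2γ [k² ⟨Δr²(t)⟩]^ζ)`, with `k = 2πn/λ` and constants
   (γ, ζ) interpolating between the single-scattering (DLS) limit (2/3, 1)
   and the diffusing-wave (DWS) backscattering limit (5/3, 0.5);
3. **α(ω)** — local log-log slope of the MSD at `t = 1/ω` (0 = elastic
   solid, 1 = viscous fluid, 0.5 = G′ = G″ crossover);
4. **G\*(ω)** — algebraic GSER
   `G*(ω) = kB T / (π a ⟨Δr²(1/ω)⟩ Γ[1+α(ω)]) · exp(iπα(ω)/2)`,
   where `a` is the sphere-equivalent scatterer radius (a pure magnitude
   scale) and T the sample temperature (default 295 K, configurable; only
   "room temperature" is physically implied);
5. **fingerprints** — regime segmentation and the six spectroscopic
   parameter classes (transition frequencies ω_T, plateau frequencies ω⁰,
   plateau moduli G⁰, loss power-law exponents γ, the G″ scaling
   transition ω_γ, magnitude power-law exponents α);
6. **maps** — per-location spectra on a 25-µm scan grid assembled into
   per-frequency G′/G″ images, Fourier-upsampled ×7 for display.

The spectral band is restricted to `1/τ < ω < Fs` (τ acquisition duration,
Fs frame rate). The inequality is applied with ω in rad/s against Fs in
frames/s, the printed convention; a 2πFs convention can be imposed by the
caller through the band argument.

## Estimator choices

**Ensemble and normalization.** The autocorrelation ensemble runs over all
ROI pixels and all frame pairs at each lag, with lags on a pseudo-log grid
(every frame lag to 64, then 30/decade) and frame pairs strided only to
bound the pair count (unbiased). Two refinements stabilize the textbook
estimator:

- *Envelope flattening.* Each pixel is divided by a smooth estimate of the
  illumination envelope (azimuthal average of the grain-smoothed temporal
  mean, count-weighted moving average over 7 annuli) before the ensemble
  is formed. Without this, the DRP's spatial nonuniformity leaves the
  normalized g₂ with a baseline offset of order +0.05–0.1 instead of
  decaying to 1.
- *Spatial (not per-pixel-temporal) means.* The normalization uses
  ensemble means rather than per-pixel temporal means. For gel-like
  samples the speckle never fully decorrelates; per-pixel temporal
  normalization would divide out exactly that frozen component and make
  every sample look like a fluid. The spatial ensemble retains it — the
  standard multi-speckle remedy for non-ergodic media.

The contrast normalization `g₂ = (g₂,raw − 1)/(g₂,raw(0) − 1) + 1` forces
g₂(0) = 2. Its statistical error is set by the number of independent
speckle grains in the ROI and is the dominant noise source for
plateau-type (frozen) samples.

**Decorrelation floor.** MSD points are masked (never extrapolated) where
`g₂ − 1 < max(0.02, 5 × tail noise SD)`, and everything beyond the first
floor crossing is masked as well, since decorrelation is monotone in lag.
The inversion amplifies g₂ noise by `1/(β |ln β|)` (β = g₂ − 1), so points
at ~3σ above the noise floor would carry O(30%) MSD errors that the
rolling slope converts into spurious α structure at the band edge; the
conservative floor keeps single-point MSD noise below ~10%.

**α(ω) schedule.** The MSD is resampled linearly in log-log onto a
30-points-per-decade ω grid at `t = 1/ω` (linear interpolation in
(log t, log MSD), exact for power-law segments); α is the OLS slope over a
centered rolling window of 7 points, computed only where the full window
fits (the grid loses 3 points per edge — a shrunken 2–3-point edge window
would regress on the noisiest near-floor data); α is then smoothed with a
15-point centered moving average whose window shrinks symmetrically at the
edges (no padding — padding would fabricate data beyond the band).

**GSER smoothing.** G′ and G″ are each smoothed by a second 15-point
moving average applied to log G′ and log G″ (geometric mean) and |G*| is
recomputed from the smoothed components. On a log-spaced grid an
*arithmetic* window multiplies a pure power law by a constant factor
(+5.5% at slope 1 for 15 points), which would bias every recovered
modulus; the geometric window is exact for power laws. α is smoothed
arithmetically (it is already a slope). α is clipped to [0, 1] after
smoothing, with a per-frequency `active_dynamics` flag raised when the
pre-clip α exceeds 1 — the thermal-equilibrium check, not a silent fix.

## Optical properties and the (γ, ζ) lookup

The radial DRP (azimuthal average of the temporal mean) is fitted in log
space to the steady-state semi-infinite diffusion dipole solution with
extrapolated boundary (free: μs′, μa, amplitude; internal-reflection
parameter A(n) from the Groenhuis polynomial). The fit expects radial
coverage from roughly one to several transport mean free paths.

(γ, ζ) for given optical properties come from Monte Carlo photon
transport in a semi-infinite medium: Henyey–Greenstein phase function
(default g = 0.9, tissue-typical; the phase function is not otherwise
constrained), continuous absorption weighting applied per-photon as
`exp(−μa · path)`, Russian roulette below weight 1e-4 with survival 0.1
(disable via `rr_threshold=0` for exact per-photon ledgers), and a
path-event cap (default 1e5; longer paths are tallied as `lost`). The cap
stiffens the fitted ζ by truncating the diffusive long-path tail — e.g.
~0.56 at 1e5 events vs ~0.54 at 3e5 in the deep-diffusive configuration —
so diffusive-limit work should raise it to 3e5. Detection accepts photons exiting the
surface within the collection NA (default 0.15, from a 9-mm aperture at
30-mm focal length). The collection *radius* is unrestricted by default:
by optical reciprocity, ensemble-averaging g₂ over an analysis region
under focused illumination is equivalent to wide illumination with point
detection — the classic DWS backscattering geometry. Restricting
collection to an ROI-scale radius (≤ l*) suppresses the diffusive s^(−3/2)
path-length tail and pushes ζ toward 1; a finite `det_radius` remains
available for studying aperture effects.

For each detected photon the dimensionless momentum transfer
`Y = Σ(1 − cos θᵢ)` and weight W are accumulated;
`g₁(X) = ⟨W exp(−(X/3)Y)⟩/⟨W⟩` over a sweep of `X = k²·MSD`, and
`g₂ − 1 = g₁²` is fitted to `exp(−2γX^ζ)` over the decay range
`g₂ − 1 ∈ [0.01, 0.95]` (noise floor and flat head excluded). The
single-scattering limit is realized analytically (at 180° backscatter
q = 2k gives `g₁ = exp(−(2/3)k²MSD)`, hence exactly (2/3, 1)); a
transport MC at near-zero optical thickness detects no multiply scattered
light. In the deep-diffusive limit the fitted ζ reaches 0.5; the fitted γ
comes out near the classic unpolarized diffusive backscattering
coefficient (~2), above 5/3 because the simulation does not model the
polarization-resolved detection that the 5/3 convention assumes
(polarization transport is out of scope). Lookup tables therefore clamp
(γ, ζ) into the DLS/DWS bracket [2/3, 5/3] × [0.5, 1] by default (logged);
the raw fit remains available. Tables are interpolated bilinearly in
(log μs′, log(μa + ε)) and persisted as HDF5.

## The synthetic speckle generator

The simulator provides ground truth, not a model of any specific
instrument. Scatterer dynamics with closed-form MSDs:

- **newtonian** — free diffusion, `MSD = 6Dt`, `D = kBT/(6πaη)`;
- **trapped** — per-axis Ornstein–Uhlenbeck motion in a harmonic trap κ,
  exact discretization, `MSD = (6kBT/κ)(1 − e^(−t/τr))`,
  `τr = 6πaη_bath/κ`; the equivalent plateau modulus is `G⁰ = κ/(6πa)`;
- **powerlaw** — fractional Brownian motion with Hurst H = p/2 per axis
  (circulant-embedding synthesis), `MSD = C·t^p`.

The default `gaussian_field` rendering backend synthesizes, per spatial
frequency mode inside a Gaussian band limit (grain FWHM default 3.5 px,
mirroring a 3.5 pixel/speckle optical design; ≥2 px enforced for Nyquist),
an independent stationary complex Gaussian process whose autocorrelation
is the target `g₁(t) = exp(−γ(k²MSD(t))^ζ)`, generated exactly by
circulant spectral factorization (negative eigenvalue mass is clipped and
logged). The inverse spatial FFT gives a field whose intensity is
fully developed speckle (exponential histogram, unit contrast) with the
prescribed temporal correlation; an exponential DRP envelope
`exp(−ρ/ρ₀)`, optional Poisson shot noise (photon budget; off by default
so statistical oracles see pure speckle statistics) and bit-depth
quantization complete the stack. Renders are bit-identical under a fixed
seed. The `phasor_sum` backend instead sums per-particle phasors
`exp(i·2k·z_j(t))` from simulated trajectories (≤ ~10³ particles) and is
kept as a physics cross-check of the Gaussian route against the
single-scattering closed form.

What the generator does *not* emulate: polarization, absorption spectra,
camera read noise beyond Poisson + quantization, depth-dependent speckle
decorrelation, or spatially heterogeneous optical properties within one
stack. Passing tests therefore demonstrate correctness of the
reconstruction chain under controlled dynamics, not robustness to every
property of real tissue data.

## Spectroscopic extraction

ω_T are log-interpolated α = 0.5 crossings with direction (downward =
fluid-to-solid; upward = the transition back to viscosity-dominant
behavior). Plateaus are local minima of the smoothed α with prominence
≥ 0.02 and ≥ half a decade of separation (both configurable; the
prominence suppresses residual smoothing ripple while resolving plateau
pairs about a decade apart). Regime boundaries are the band edges and the
plateau frequencies — the inter-plateau regressions for the loss exponent
γ and the magnitude exponent α run within those segments; where regime
boundaries are not otherwise defined this segmentation is a
reconstruction, noted as such. Inside the first inter-plateau regime,
ω_γ sits at the inflection of the rolling log-log derivative of G″, and
the regime is split into a/b sub-slopes only when they differ by > 0.15
(distinguishing exponent pairs like 0.4 vs 1.2 without splitting noise).
Replicates aggregate as mean ± SD or median ± MAD matched by parameter
name; groups are compared with a two-sided Wilcoxon rank-sum test, exact
for ≤ 25 per group without ties, normal approximation with tie correction
otherwise, significance at 0.05.

## Mapping

Scan cells that fail (no speckle contrast, DRP outside the field of view,
saturation) become masked cells; more than 50% failures aborts with a
cause summary. Maps store one G′ and one G″ image per probe frequency
(default decade values 10¹–10⁵ rad/s). Display upsampling is 2D Fourier
zero-padding (scipy's FFT resampler, which splits Nyquist bins
Hermitian-consistently) with the amplitude rescaled so the spatial mean is
preserved exactly; masked cells are infilled by nearest neighbor for the
transform only, and analysis output keeps the mask. The coordinate
convention (row-major, origin top-left, stage x along columns) is recorded
in the HDF5 metadata together with per-cell source provenance.

## Problem sizes and numerical tolerances

Acceptance-grade simulations use 20,000-frame stacks (96×96 px, DRP 1/e
radius 33 µm, ~190 speckle grains in the ROI) and 6×10⁵-photon transport
runs with a 3×10⁵ event cap (the diffusive-limit stretching exponent is
converged at that cap; see limitations); the test suite uses 12,000-frame
stacks and 2×10⁵-photon runs at the same cap, sizes at which the
recovered Newtonian exponent is stable to ±0.02 and the recovered
viscosity to ±3% across seeds. The trapped-network plateau
recovery uses three replicate stacks and compares the replicate mean,
mirroring how replicate spread is normally reported; its single-replicate
scatter (±25–40%) is dominated by speckle-contrast estimation noise,
which scales as the inverse square root of the ROI grain count. The
fibrin-plateau conditions use a = 5 nm so that the frozen-speckle
correlation plateau decays by a well-conditioned ~60% (at tissue-scale
probe radii the plateau decorrelation is only a few percent and the
inversion is noise-limited).

## Known limitations

- γ from the unpolarized MC exceeds the polarization-resolved 5/3
  convention; use the clamped lookup (default) for inversion consistency.
- The event cap biases the deep-diffusive ζ upward by ~0.02–0.04; raise
  `max_events` when the tail matters.
- The algebraic GSER is a local approximation; it degrades near sharp
  spectral features and the package deliberately does not implement the
  full Fourier-transform GSER or Kramers–Kronig enforcement.
- MSD validity masking assumes monotone decorrelation; oscillatory
  dynamics (e.g. flow) would violate it.
- The g₂ estimator's finite-window bias scales as τc/T; stacks shorter
  than ~100 decorrelation times will read slightly soft.
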