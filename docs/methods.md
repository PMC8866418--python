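# Methods

## Model overview

`dcswave` simulates a DCS measurement as a chain of physically explicit
stages. A transport Monte Carlo produces, for every detected photon, the
number of scattering events and the geometric pathlength in each tissue
layer. A wave model then treats each detected photon as one partial wave
whose field at the detector is

    E_ni(t) = S(k_i) · w_n · exp(i [φ_n + k_i L_n − k_i X_n(t)])

with φ_n ~ U[0, 2π) an initial phase, L_n the optical pathlength, w_n an
absorption amplitude weight, S(k_i) the source-spectrum amplitude of the
i-th discrete line, and X_n(t) the Brownian path-difference process. The
intensity is the incoherent sum over lines of the squared coherent photon
sum, I(t) = Σ_i |Σ_n E_ni(t)|²; the optical carrier e^{iωt} is dropped.
Poisson sampling of I(t) yields photon counts, and the linear lagged-product
estimator with a Siegert-model fit, g2 = 1 + β e^{−2τ/τc}, returns the
decay time.

## Transport

* Two-layer semi-infinite geometry; interface at 15 mm by default. Both
  layers share μs′ = 1 mm⁻¹ and μa = 0.01 mm⁻¹ in the study conditions;
  the layers differ only in their Brownian diffusion coefficient when an
  "activated" state is simulated.
* Isotropic scattering (g = 0) with step length ~ Exp(μs), μs ≡ μs′. In the
  diffusive regime this is statistically equivalent to forward-peaked
  scattering at equal reduced scattering coefficient, at much lower cost.
* Pencil beam normally incident at the origin; index-matched absorbing top
  boundary (a photon is terminated at its first crossing of z = 0). The
  matching analytic pathlength density therefore uses an extrapolated
  boundary with Reff = 0 (zb = 2D). `SemiInfiniteParams.reff` defaults to
  the conventional tissue–air value 0.493 for stand-alone theory use; all
  Monte Carlo comparisons pass `reff=0` explicitly.
* Absorption is not applied in transport. Detected photons later receive
  the intensity weight e^{−Σ μa,i L_i}; the field amplitude carries half
  that exponent by default (`absorption="intensity"`), keeping the photon
  intensity consistent with the e^{−μa L} factor in the pathlength density.
  A literal "field" mode (amplitude e^{−μa L}, i.e. intensity e^{−2 μa L})
  is available for comparison.
* A pathlength cutoff (default 2000 mm) bounds the cost of rare long
  random walks; at μa = 0.01 mm⁻¹ the discarded trajectories would carry
  intensity weights below e^{−20}.
* Step segments crossing the layer interface split their pathlength
  geometrically; a scattering event is attributed to the layer where it
  occurs.
* **Detector convention.** The surface detector is a disc at (ρ, 0). A
  published detector "size" of 2 mm is ambiguous; `DetectionGeometry`
  exposes `size_convention` with default **radius** (disc radius 2 mm).
  This choice reproduces a published detected-photon count at ρ = 20 mm
  (≈3.5×10⁴ per 10⁸ launches) to within ~15%, while the published
  flux-scaling table at the same nominal conditions implies counts ~3.5×
  larger that neither convention — nor diffusion theory, whose escape
  density our kernel matches — reproduces. Relative detected-count ratios
  across ρ = 10/20/30 mm agree with that table's flux column to within 6%.
  Absolute counts should therefore be trusted only up to the detector-area
  convention; every correlation-level result is independent of it.
* The kernel is a numba-compiled loop with an inline xoshiro256++
  generator (splitmix64-seeded) and trig-free isotropic direction
  sampling; a seeded run is bit-reproducible (~4×10⁷ scattering steps/s on
  one core).

## Instrument response and gating

The IRF is a tabulated density on a time grid, normalized by trapezoid and
shifted so its peak sits at t = 0 (global maximum, first occurrence on
ties). Per-photon delays are drawn by inverse-transform sampling with
linear interpolation of the CDF. Arrival time = transit time (v = c/n,
n = 1.33) + IRF delay. A gate keeps arrivals in the half-open window
[ts − tw/2, ts + tw/2), so adjacent gates partition photons. A synthetic
generator provides Gaussian and exponentially-modified-Gaussian profiles
(FWHM-calibrated by bisection) standing in for a measured IRF table; any
two-column time/intensity file can be loaded instead. Gate selection and
IRF delays are drawn once per measurement configuration, not per speckle
replicate.

## Spectrum and coherence

A Gaussian source spectrum S(k) = e^{−(k−k0)²/(2 kc²)} with kc = π/(2 lc)
is discretized into n_lines = 21 lines spanning ±3.5 kc (odd count keeps a
line exactly at k0); lc = ∞ collapses to a single line. Convergence was
checked by doubling the line count (β changes < 0.005). S(k_i) enters the
field as an amplitude, so the effective power spectrum is S².

Two β(lc) conventions coexist in the literature. The printed reference
envelope e^{−16[(L−L′)/(π lc)]²} decays ~1.3× faster in the exponent than
the envelope actually generated by the amplitude-weighted Gaussian
spectrum, |Σ S_i² e^{i k_i ΔL}|²/(Σ S_i²)² ≈ e^{−π²ΔL²/(8 lc²)}. The
quadrature references (`beta_of_coherence`, `gated_g2_theory`) therefore
default to the **self-consistent spectrum envelope** when a spectrum is
supplied — this is what simulation-vs-theory validation uses — and provide
the printed form under `envelope="printed"`.

**Wavevector.** `discretize_spectrum` defaults to the vacuum wavevector
k0 = 2π/λ and takes `medium_index` to apply the physically standard
in-medium wavevector k0 = 2πn/λ used in DCS analysis. All study conditions
use `medium_index=1.33`. With the vacuum convention every decay time below
would be larger by a factor n² ≈ 1.77.

## Dynamics

Scatterer motion is isotropic Brownian diffusion with per-axis increment
variance 2 D_B Δt (baseline D_B = 1×10⁻⁶ mm²/s; "activation" multiplies
the deep-layer D_B by 2.25). For each scattering event the direction
change Δn̂ = n̂_out − n̂_in has |Δn̂|² = 2(1 − cos θ) with cos θ ~ U(−1, 1)
(mean 2). The dynamic phase driver

    X_n(t) = Σ_s Δn̂_s · Δr_s(t)

is a Wiener process with variance rate 2 Σ_layers D_B Σ_s |Δn̂_s|². The
default **aggregated** mode draws X_n directly at that rate — exact in
distribution, since sums of independent Gaussian increments are Gaussian —
and is validated against the **explicit** per-scatterer 3-D walk by
two-sample tests. Brownian updates occur at the bin resolution Tb:
intensity is only observed per bin, and Wiener self-similarity makes
sub-bin resolution statistically redundant. Expectation over events
recovers the pathlength-resolved decay g1(L, τ) = e^{−2 μs′ D_B k0² L τ}.

## Correlation, fitting, noise

* Estimator: linear non-circular lagged products divided by the squared
  full-series mean. Intensity series include τ = 0; count series start at
  τ = Tb (the τ = 0 product is dominated by Poisson self-pairing).
* Fit: nonlinear least squares of 1 + β e^{−2τ/τc}, free β by default
  (fixed-β optional), uniform weights. The fit window runs until a 5-point
  moving average of (g2 − 1) first drops below 5% of a log-linear pre-fit
  β estimate, bounding noise-floor bias. Non-decaying curves, flat curves,
  and fits whose τc exceeds 50× the lag window raise a distinct `FitError`.
* The analytic correlator noise model σ(τ) for an exponential g2 − 1 with
  photon counting is implemented termwise; the simulated replicate std of
  (g2 − 1) at Tb = 1 μs, T = 10 ms, ⟨n⟩ = 0.1 matches it within 20% for
  τ ≤ 3 τc (500 replicates).

## Experiments

Replicates share photon records and redraw phases/directions/Brownian
paths (and Poisson counts) from substreams indexed by replicate number
only — baseline and activated ensembles from one master seed are therefore
**common-random-number paired**, which suppresses speckle noise in Δτc far
below the single-ensemble spread and makes small-replicate contrast
estimates usable. SNR = τc/std(τc) over replicates; CNR = Δτc/std(τc)
with the baseline std; specificity = Δτc (deep-layer activation) over
Δτc,h (homogeneous activation). Speckle-noise-limit experiments use the
intensity-based g2 (no counting step). The shot-noise decomposition draws
n_avg Poisson count series per intensity realization, fits the averaged
g2, and reports both the literal n_avg·std(τc,avg) scaling and a
variance-consistent reconstruction Var_shot = n_avg·(Var(τc,avg) −
Var_speckle); the two differ by the interpretation of an ambiguous printed
scaling, and only the variance-consistent form satisfies the additivity
check against a direct single-draw ensemble.

## Study conditions and problem sizes

Defaults mirror the published validation configuration: λ = 800 nm,
ρ = 20 mm, Tb = 1 μs, T = 10 ms, ⟨n⟩ = 0.1 (flux 10⁵ photons/s at the CW
reference), lc = 90 mm and tw = 0.2 ns for gated runs, gates at ts = 0.5,
1.5, 2.5 ns. The test suite scales Monte Carlo sizes to desk scale:
7.6×10⁷ launches (~3×10⁴ detected photons) for the pathlength
distribution, 10⁶-launch runs for detection fractions, 40–500 speckle
replicates per comparison, and photon subsets of 400–1400 per synthesis
(statistically a smaller detector; speckle statistics at ≥400 photons are
Gaussian to ≪1%). Gated simulation-vs-quadrature comparisons discretize
the lc = 90 mm spectrum into 11 lines — simulation and quadrature share
the discretized envelope exactly, so the comparison does not depend on
the line count — and the gate-delay trend ensembles (τc, SNR,
specificity vs ts) run in the fully coherent single-line limit, since
those trends are gating physics, independent of source bandwidth.

## Known limitations and discrepancies

* Absolute detected-photon counts depend on the unresolved detector-size
  convention (above); published absolute counts are not reproduced, while
  count *ratios* across separations are (within 6%).
* The CW decay time computed from first principles — and confirmed by two
  independent analytic routes (correlation-diffusion dipole and
  pathlength-mixture quadrature, which agree with the simulation to ~2%) —
  is ≈37–39 μs at the study conditions with the Siegert fit model and
  in-medium k0, vs a published calibration of ≈32 μs. A value of ≈32 μs
  arises only when g2 − 1 is fitted with a single exponent e^{−τ/τc}
  (vacuum k0), i.e. under a different fit convention; with the documented
  conventions the discrepancy is +15–20% and is reported, not absorbed.
* Dark counts, afterpulsing, dead time, polarization (β < 1 from multimode
  detection), convective/shear flow, anisotropic phase functions, Fresnel
  boundary reflections, and >2-layer or curved geometries are out of scope.
* Synthetic IRFs are smooth; measured IRFs with secondary peaks will
  broaden gated pathlength distributions in ways the Gaussian stand-in
  does not represent. Passing tests demonstrate internal consistency of
  the model chain and agreement with homogeneous semi-infinite theory;
  they do not certify predictions for structured heads or real
  instruments.
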