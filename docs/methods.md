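# Methods

This note documents the models implemented in `scpsizer`, the defaults
chosen where the design was genuinely open, and what the synthetic tests
do and do not demonstrate about real measurements.

## Physical model

Particles are treated as independent Brownian diffusers in a Newtonian
solvent.  The central relations are

* Stokes–Einstein: `D = kT / (6 π η R_h)` for a sphere of hydrodynamic
  radius `R_h`; `k = 1.380649e-23 J/K` exactly.
* 2-D projected free diffusion: `⟨d²(mΔt)⟩ = 4 D mΔt` for the squared
  displacement of a tracked particle between frames `m` lags apart.
* DLS: `g₂(t) = 1 + β|g₁(t)|²` (Siegert) with
  `g₁(t) = Σ_k w_k exp(−Γ_k t)`, `Γ = q²D`,
  `q = (4π n₀/λ₀) sin(θ/2)`.

`MediumConditions` defaults to water at 25 °C: T = 298.15 K,
η = 8.9 × 10⁻⁴ Pa·s (standard handbook value), n₀ = 1.33.  All three are
configurable; every internal computation is SI, files use nanometers and
seconds.

### Rod-shaped particles

Rigid rods use the Tirado–García de la Torre orientation-averaged
translational coefficient `D = kT (ln p + ν) / (3 π η L)` with aspect
ratio `p = L/d` and end correction `ν = 0.312 + 0.565/p − 0.100/p²`.
The end-correction fit is intended for `p ≳ 2`; below `p ≈ 1.4` the
value falls slightly under the equivalent-sphere lower bound and should
be read as an extrapolation (it stays within ~15 % of the equal-volume
sphere as `p → 1`).  A 400 × 20 nm rod maps to a sphere-equivalent
radius of ≈60 nm — between the 10 nm and 200 nm radii of its two
characteristic dimensions, which is exactly the ambiguity that makes
`R_h` a biased summary for non-globular particles.

### Obstructed (sub)diffusion

Motion hindered by a filament network is modelled as fractional
Brownian motion with Hurst exponent `H = α/2` per axis, scaled so the
projected 2-D MSD is exactly `4 K Δt^α` (`K` in m²·s^−α).  Increments
are stationary fractional Gaussian noise generated by a Cholesky factor
of the exact increment covariance (O(n²) per track length, computed once
per population).  Under the normal-diffusion analysis, the apparent
`D = MSD(mΔt)/(4mΔt) = K(mΔt)^{α−1}` decreases with lag, so the apparent
`R_h` grows with the fitting lag — the direction in which filament-rich
samples over-report particle size.

## Synthetic-data generator

`simulate_tracks` draws a Poisson number of particles per population
(mean = number density ÷ dilution factor × box volume), places them
uniformly in an open box that is 2× the side of the centred cubic
detection volume (default 15 pL), and evolves them in 3-D.
Localizations are the (x, y) projection plus Gaussian noise
(`localization_noise_sd`), emitted only while the particle is inside the
detection box and then only with `detection_probability` per frame;
tracks fragment on exit.  Fixed seeds reproduce output bit for bit.

`simulate_dls_g2` builds `g₁` as an intensity-weighted sum of
exponentials with Rayleigh weights `w ∝ number_density × R_h⁶`
(exponent configurable), applies the Siegert relation with coherence
factor β (default 0.8) and adds optional per-lag Gaussian noise.

What the generator does **not** emulate: interferogram/image formation
and the instrument's intensity threshold (detection is a Bernoulli event
on true positions), size-dependent detection efficiency, hydrodynamic
or direct particle–particle interactions, polydispersity within a mode,
number fluctuations in the scattering volume, multiple scattering, and
rod form factors in DLS (rod modes are rejected there).  Passing the
recovery tests therefore shows the *inference* chains are correct under
their stated assumptions, not that the instrument model is complete.

## Nanotracking inference

* Linking: distance-gated greedy nearest neighbour, processed in
  ascending distance with ties broken by smaller track id; bridgeable
  gaps up to `max_gap` frames.  In the dilute regime the instrument
  operates in (spacing ≫ gate > step scale) this is exact; no global
  assignment is attempted.
* Per-track estimator: unweighted least squares of MSD against lag over
  the first 4 lags with a **free intercept** (default).  The intercept
  absorbs the static localization-noise offset `4σ_loc²`, which would
  otherwise bias D high and `R_h` low; the bare lag-1 estimator
  `msd(Δt)/4Δt` is retained as an explicit mode for noise-free data.
  Negative slopes are returned as-is, flagged, and excluded from sample
  means (the exclusion count is reported).
* Per-sample summary: unweighted mean ± SD of per-track `R_h`; the SD is
  reported only when ≥ 40 particles were tracked.  Because per-track
  `R_h = 1/D̂` is convex in `D̂`, short tracks inflate the mean
  (≈ `R_h·Var(D̂)/D²`); the recovery demonstrations therefore use
  200-step tracks, where the residual bias (~3 nm at 100 nm) sits well
  inside the per-sample spread.  Track-length weighting is deliberately
  not applied, matching the unweighted per-particle presentation of
  nanotracking instruments.
* Number density: time-averaged per-frame detected count ÷ detection
  volume × dilution factor — robust to track fragmentation.
* Flags: `UDL` (fewer usable tracks than `udl_min_tracks`, default 5;
  the mean is withheld), `LP` (any track with `R_h` > 1 µm), `BA`
  (pass-through annotation for visually identified bacteria).

## DLS inversion

The decay spectrum solves
`min ‖Aw − g₁‖² + λ‖Lw‖², w ≥ 0`, with `A_jk = exp(−Γ_k t_j)` on a
log-spaced grid of `n_exponents ≤ 50` rates spanning 6 decades centred
on the geometric midpoint of the reciprocal lag window, and `L` the
second-difference operator (the smoothness penalty of the classic
CONTIN program).  Numerical choices:

* `g₁` is normalized by its maximum before solving, so peak positions
  are invariant to the instrumental amplitude.
* λ = "auto" picks the L-curve corner (maximum signed Menger curvature
  of consecutive (log residual, log penalty) triplets over a 21-point
  λ ladder from 10⁻⁸ to 10²), falling back to the smallest λ for
  degenerate (noiseless) curves.  A fixed numeric λ is available for
  reproducibility, and λ = 0 reduces to plain non-negative least
  squares.
* β, when not supplied, is estimated by a straight-line fit of
  `log(g₂ − 1)` over the first 5 lags extrapolated to t = 0.
* Negative Siegert radicands (noise below baseline) are clipped to zero
  and counted.
* Peaks are contiguous runs of weight above 10⁻⁴ of the maximum bin;
  each reports its intensity-weighted mean `R_h` and fraction
  (= summed weights); fractions below `min_fraction` (default 0.01) are
  dropped, at most 4 peaks are kept, and a peak beyond 10 µm carries a
  very-large flag.  Reports order peaks as smaller / main (highest
  fraction) / larger companions.

Exact numeric parity with the historical CONTIN program is not claimed:
its α-selection rule and grid are not published parameters of the
instrument software this mirrors.

## Comparison stage

Dilution-consistency ratios divide dilution-corrected quantities
measured at 1000× and 100× (ideal value 1; displayed half-up at 2
decimals, full precision retained).  Replicate error is the largest
absolute deviation from the mean of ≥ 2 repeats, also as a percentage
of the mean (undefined and flagged for zero mean).  Two size estimates
"agree within error" when |R_a − R_b| ≤ err_a + err_b; a tally operation
counts agreements over arbitrary pairs.  A small packaged TSV of
published liposome summary measurements (three preparations at two
dilutions) feeds the worked examples and the reproduction script.

## Problem sizes and tolerances

The demonstration runs use: ~650 particles in the 15 pL detection
volume, 201 frames at Δt = 10 ms (≥ 300 full-length tracks) for
nanotracking recovery; 120 log-spaced lags from 1 µs to 1 s and a
50-point rate grid for DLS (one grid bin = a factor 10^{6/49} ≈ 1.33 in
`R_h`, the natural resolution limit of the inversion); 10 seeded
repeats for the dilution-consistency demonstration.  Exact identities
(Stokes–Einstein round trip, Siegert reconstruction, ratio of equal
inputs) are tested at 10⁻¹² relative, within floating-point
representability — the Siegert inverse loses relative precision once
`β g₁²` falls below ~10⁻⁴ of the baseline, which the tests account for.

## Known limitations

* Linking is greedy; dense samples with inter-particle spacing
  comparable to the gate will mislink (the instrument regime is dilute
  by design).
* The per-track `1/D̂` convexity bias is not corrected; very short
  tracks should be filtered by the caller (`min_length`).
* The fBm generator's Cholesky factorization limits practical track
  lengths to a few thousand frames.
* DLS intensity weights use the Rayleigh `R_h⁶` law; Mie corrections
  for particles approaching the wavelength are out of scope.
* No size-dependent detection-efficiency correction is applied to
  number densities.
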