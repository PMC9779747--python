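# scpsizer

Sizing and counting of **small cellular particles** (SCPs: extracellular
vesicles, protein aggregates, lipoproteins, liposomes and other sub-micron
colloids harvested from biological material) from the two optical
measurements most commonly used on such samples:

* **Nanotracking** (interferometric light microscopy / nanoparticle
  tracking analysis): individual particles are localized frame by frame
  in a video, linked into trajectories, and sized from their Brownian
  motion.  The time-averaged mean squared displacement of a track grows
  as ⟨d²(Δt)⟩ = 4 D Δt; the Stokes–Einstein relation R_h = kT/(6πηD)
  converts the per-track diffusion coefficient D into a hydrodynamic
  radius.  Counting particles inside the instrument's fixed detection
  volume (≈15 pL) gives the number density — the quantity batch
  scattering methods cannot provide.
* **Dynamic light scattering (DLS)**: the intensity autocorrelation
  g₂(t) is converted to the field correlation through the Siegert
  relation g₂ = 1 + β|g₁|², and g₁(t) = Σ w exp(−Γt) is inverted by a
  CONTIN-style non-negative, smoothness-regularized inverse Laplace
  transform on a log-spaced grid of up to 50 decay rates.  Each rate
  maps to a radius via Γ = q²D with q = (4πn₀/λ₀)sin(θ/2), yielding the
  intensity-weighted I(R_h) distribution and its peak fractions I_i/I_tot.

Both chains assume freely diffusing spheres.  The package also ships a
synthetic-data generator that deliberately breaks that assumption in the
two ways seen in real isolates — rod-shaped particles, and subdiffusive
motion (MSD = 4KΔt^α, α < 1) caused by a filament network — so the size
and direction of the resulting bias can be studied quantitatively.
Cross-method bookkeeping (dilution-consistency ratios, replicate errors,
within-error agreement, study-style summary tables) rounds out the
pipeline.

The main entry points follow the statsmodels convention: a model object
built from data whose `fit()` returns a results object with estimates
and a `summary()`.

## Worked example

```python
from scpsizer import *

water = MediumConditions()                      # 298.15 K, 0.89 mPa s, n0 = 1.33
acq = AcquisitionSpec(frame_interval=0.01, n_frames=101, dilution_factor=50)
sample = PopulationMode(shape="sphere", rh=100e-9, number_density=1e12)

ts = simulate_tracks([sample], acq, water, seed=42)
res = IlmModel(ts, water).fit(min_length=50)
print(res.summary())

dls = DlsAcquisitionSpec(coherence_factor=0.8)
cf = simulate_dls_g2([sample], dls, water, seed=42)
print(DlsModel(cf, water).fit().summary())
```

prints

```
ILM nanotracking summary
  estimator: linear_fit (fit_lags=4)
  tracks used: 276   excluded (D <= 0): 0
  Rh (nm): 276  107 ± 26
  number density: 1.05e+12 /mL (dilution x50)
  flags: -

DLS decay-spectrum inversion
  lags: 120  grid points: 50
  q = 1.791e+07 1/m   beta = 0.800   reg = 1e-07   residual = 0.00887
  clipped lags (g2 < 1): 0
  peaks (ascending Rh):
    Rh =      100.8 nm   I/I_tot = 1.00
```

The nanotracking estimate (107 ± 26 nm over 276 tracks) recovers the
100 nm ground truth within the per-track statistical spread of
finite-length trajectories; the reported density (1.05 × 10¹² /mL after
the 50× dilution correction) matches the generating 10¹² /mL within the
Poisson counting error of ~330 particles in 15 pL.  The DLS inversion
finds a single population at 100.8 nm, i.e. within one grid bin of the
truth on the 50-point decay-rate grid.

A `scpsizer` console command exposes the same steps on files
(`simulate tracks`, `simulate dls`, `link`, `ilm`, `dls`, `report`);
run configurations are YAML, trajectory and correlogram files are
tab-separated text (see `docs/methods.md`).

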