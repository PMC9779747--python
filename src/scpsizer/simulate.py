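"""Synthetic Brownian-motion trajectories and DLS correlograms.

The generator produces the two raw-data types the inference stages
consume — per-frame particle localizations inside a finite detection
volume, and intensity autocorrelation curves g2(t) — with the
statistical structure those stages assume, plus the two mechanisms known
to bias sphere-model sizing of biological nanoparticle isolates:

* **non-spherical (rod-shaped) diffusers**, whose translational
  diffusion coefficient does not correspond to any single sphere radius;
* **obstructed (sub)diffusion**, MSD = 4 K t^alpha with alpha < 1,
  as produced by a filament network hindering particle motion, which
  inflates the apparent hydrodynamic radius under the normal-diffusion
  model.

Subdiffusion is realized as fractional Brownian motion with Hurst
exponent H = alpha/2 per axis, scaled so the observed 2-D MSD is exactly
4 K t^alpha.  Particles diffuse in 3-D through an open simulation box;
localizations are emitted (x, y only, plus Gaussian noise) while the
particle is inside a centred axis-aligned detection box of the stated
volume, with a per-frame detection probability.  Tracks fragment when a
particle leaves the detection volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .dls import CorrelationFunction, scattering_vector
from .physics import (
    MediumConditions,
    diffusion_coefficient_rod,
    diffusion_coefficient_sphere,
)
from .tracking import Track, TrackSet

__all__ = [
    "PopulationMode",
    "AcquisitionSpec",
    "DlsAcquisitionSpec",
    "simulate_tracks",
    "simulate_dls_g2",
]


@dataclass(frozen=True)
class PopulationMode:
    """One particle population: geometry, concentration and motion law.

    ``shape`` is "sphere" (set ``rh``) or "rod" (set ``rod_length`` and
    ``rod_diameter``).  ``number_density`` is in particles per mL of the
    undiluted sample.  ``alpha`` is the anomalous-diffusion exponent in
    (0, 1]; for ``alpha < 1`` the generalized coefficient ``K``
    (m^2 s^-alpha) replaces the Stokes--Einstein D and the 2-D MSD is
    4 K t^alpha.
    """

    shape: str = "sphere"
    rh: Optional[float] = None
    rod_length: Optional[float] = None
    rod_diameter: Optional[float] = None
    number_density: float = 0.0
    alpha: float = 1.0
    K: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "rod"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "sphere":
            if self.rh is None or self.rh <= 0:
                raise ValueError("sphere mode requires rh > 0")
            if self.rod_length is not None or self.rod_diameter is not None:
                raise ValueError("sphere mode must not set rod dimensions")
        else:
            if self.rh is not None:
                raise ValueError("rod mode must not set rh")
            if (
                self.rod_length is None
                or self.rod_diameter is None
                or not (self.rod_length > self.rod_diameter > 0)
            ):
                raise ValueError("rod mode requires rod_length > rod_diameter > 0")
        if self.number_density < 0:
            raise ValueError("number_density must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.alpha < 1 and (self.K is None or self.K <= 0):
            raise ValueError("subdiffusive mode (alpha < 1) requires K > 0")

    def diffusion_coefficient(self, medium: MediumConditions) -> float:
        """Normal-diffusion coefficient of this population (m^2/s)."""
        if self.shape == "sphere":
            return diffusion_coefficient_sphere(self.rh, medium)
        return diffusion_coefficient_rod(self.rod_length, self.rod_diameter, medium)

    def generalized_coefficient(self, medium: MediumConditions) -> float:
        """K in MSD_2D = 4 K t^alpha; equals D when alpha = 1."""
        if self.alpha < 1:
            return float(self.K)
        return self.diffusion_coefficient(medium)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Video acquisition and counting geometry for nanotracking.

    ``detection_volume`` is in liters (default 15 pL, the typical imaged
    volume of the instrument class modelled here); ``field_extent`` is
    the (x, y, z) extent in meters of the open simulation box enclosing
    it (default: twice the detection cube's side per axis).
    ``dilution_factor`` >= 1 is the dilution applied before measurement;
    number densities reported downstream are corrected by it.
    """

    frame_interval: float = 0.01
    n_frames: int = 100
    detection_volume: float = 15e-12
    field_extent: Optional[tuple[float, float, float]] = None
    localization_noise_sd: float = 0.0
    detection_probability: float = 1.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.detection_volume <= 0:
            raise ValueError("detection_volume must be > 0")
        if not (0 <= self.detection_probability <= 1):
            raise ValueError("detection_probability must be in [0, 1]")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.detection_volume * 1e-3 > np.prod(self.box_extent()) + 1e-30:
            raise ValueError("detection volume exceeds the simulation box")

    def detection_side(self) -> float:
        """Side (m) of the cubic detection box of the stated volume."""
        return (self.detection_volume * 1e-3) ** (1.0 / 3.0)

    def box_extent(self) -> np.ndarray:
        """(x, y, z) extent (m) of the open simulation box."""
        if self.field_extent is not None:
            return np.asarray(self.field_extent, dtype=float)
        return np.full(3, 2.0 * self.detection_side())


@dataclass(frozen=True)
class DlsAcquisitionSpec:
    """DLS optics and correlator settings.

    Defaults follow a 660 nm laser measured at 90 degrees.  ``noise_sd``
    is the relative sd of additive Gaussian noise per lag on g2.
    """

    wavelength: float = 660e-9
    angle: float = 90.0
    coherence_factor: float = 0.8
    lag_grid: Optional[np.ndarray] = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if not (0 < self.angle < 180):
            raise ValueError("angle must be in (0, 180) degrees")
        if not (0 < self.coherence_factor <= 1):
            raise ValueError("coherence_factor must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lags = self.lags()
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lag_grid must be positive and strictly increasing")

    def lags(self) -> np.ndarray:
        if self.lag_grid is None:
            return np.logspace(-6, 0, 120)
        return np.asarray(self.lag_grid, dtype=float)


def _fgn_cholesky(n_steps: int, hurst: float) -> np.ndarray:
    """Cholesky factor of the unit-variance fractional Gaussian noise covariance."""
    k = np.arange(n_steps, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    return cholesky(toeplitz(gamma), lower=True)


def _mode_steps(
    mode: PopulationMode,
    n_particles: int,
    n_steps: int,
    dt: float,
    medium: MediumConditions,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-axis displacement increments, shape (n_particles, n_steps, 3)."""
    z = rng.standard_normal((n_particles, n_steps, 3))
    if mode.alpha >= 1.0:
        sd = math.sqrt(2.0 * mode.generalized_coefficient(medium) * dt)
        return sd * z
    # fractional Gaussian noise: per-axis MSD(m dt) = 2 K (m dt)^alpha
    sd1 = math.sqrt(2.0 * mode.generalized_coefficient(medium) * dt**mode.alpha)
    L = _fgn_cholesky(n_steps, mode.alpha / 2.0)
    return sd1 * np.einsum("st,pta->psa", L, z)


def simulate_tracks(
    modes: Sequence[PopulationMode],
    acq: AcquisitionSpec = AcquisitionSpec(),
    medium: MediumConditions = MediumConditions(),
    seed: int = 0,
) -> TrackSet:
    """Simulate nanotracking video localizations and return ground-truth tracks.

    Particle counts per population are Poisson with mean
    ``number_density / dilution_factor x simulation-box volume``; initial
    positions are uniform in the box; motion is per-axis Brownian (or
    fractional Brownian for alpha < 1); localizations are the (x, y)
    projection plus Gaussian noise, emitted only while the particle is
    inside the detection box and then only with ``detection_probability``
    per frame.  A particle re-entering the detection box starts a new
    track (fragmentation on exit); runs with fewer than two localizations
    are counted as orphans.

    A fixed seed reproduces the output bit for bit.
    """
    if not modes:
        raise ValueError("at least one population mode is required")
    if all(m.number_density == 0 for m in modes):
        raise ValueError("at least one mode must have number_density > 0")
    rng = np.random.default_rng(seed)
    extent = acq.box_extent()
    box_volume = float(np.prod(extent))
    half_det = acq.detection_side() / 2.0
    n_steps = acq.n_frames - 1
    dt = acq.frame_interval

    tracks: list[Track] = []
    counts = np.zeros(acq.n_frames, dtype=np.int64)
    orphans = 0
    next_id = 0
    for mode in modes:
        conc_m3 = mode.number_density * 1e6 / acq.dilution_factor
        n_particles = int(rng.poisson(conc_m3 * box_volume))
        if n_particles == 0:
            continue
        start = (rng.random((n_particles, 3)) - 0.5) * extent
        steps = _mode_steps(mode, n_particles, n_steps, dt, medium, rng)
        pos = np.concatenate([start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
        inside = np.all(np.abs(pos) <= half_det, axis=2)
        detected = inside & (rng.random((n_particles, acq.n_frames)) <= acq.detection_probability)
        if acq.detection_probability == 0:
            detected[:] = False
        noise = (
            rng.standard_normal((n_particles, acq.n_frames, 2)) * acq.localization_noise_sd
            if acq.localization_noise_sd > 0
            else 0.0
        )
        observed = pos[:, :, :2] + noise
        counts += detected.sum(axis=0)
        for i in range(n_particles):
            det_i = detected[i]
            ins_i = inside[i]
            # segment boundaries: entries into the detection box
            entries = np.flatnonzero(ins_i & ~np.concatenate(([False], ins_i[:-1])))
            exits = np.flatnonzero(~ins_i & np.concatenate(([False], ins_i[:-1])))
            for s_idx, start_f in enumerate(entries):
                end_f = exits[s_idx] if s_idx < len(exits) else acq.n_frames
                seg_frames = np.flatnonzero(det_i[start_f:end_f]) + start_f
                if len(seg_frames) < 2:
                    orphans += len(seg_frames)
                    continue
                tracks.append(
                    Track(track_id=next_id, frames=seg_frames, positions=observed[i, seg_frames])
                )
                next_id += 1
    return TrackSet(
        tracks=tracks,
        acquisition=acq,
        provenance=f"simulate_tracks(seed={seed})",
        frame_localization_counts=counts,
        n_orphans=orphans,
    )


def simulate_dls_g2(
    modes: Sequence[PopulationMode],
    dls: DlsAcquisitionSpec = DlsAcquisitionSpec(),
    medium: MediumConditions = MediumConditions(),
    seed: int = 0,
    intensity_exponent: float = 6.0,
) -> CorrelationFunction:
    """Synthesize an intensity autocorrelation curve for a sphere mixture.

    The field correlation is the intensity-weighted mixture of
    exponentials ``g1(t) = sum_i w_i exp(-q^2 D_i t)`` with
    ``w_i ~ number_density_i * rh_i**intensity_exponent`` (Rayleigh
    scattering, exponent 6, by default), normalized to sum to 1;
    ``g2(t) = 1 + beta g1(t)^2`` plus zero-mean Gaussian noise of sd
    ``noise_sd`` per lag.  Rod-shaped modes are rejected: their field
    correlation is not a single-exponential decay.
    """
    if not modes:
        raise ValueError("at least one population mode is required")
    for m in modes:
        if m.shape != "sphere":
            raise ValueError("DLS synthesis supports spherical modes only")
    rng = np.random.default_rng(seed)
    lags = dls.lags()
    q = scattering_vector(medium, dls.wavelength, dls.angle)
    w = np.array([m.number_density * m.rh**intensity_exponent for m in modes], dtype=float)
    if w.sum() <= 0:
        raise ValueError("at least one mode must have number_density > 0")
    w /= w.sum()
    rates = np.array([q**2 * m.diffusion_coefficient(medium) for m in modes])
    g1 = (w[:, None] * np.exp(-rates[:, None] * lags[None, :])).sum(axis=0)
    g2 = 1.0 + dls.coherence_factor * g1**2
    if dls.noise_sd > 0:
        g2 = g2 + rng.standard_normal(len(lags)) * dls.noise_sd
    return CorrelationFunction(lags=lags, g2=g2, beta=dls.coherence_factor)
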