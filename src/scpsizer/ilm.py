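"""Nanotracking (ILM) inference: MSD -> D -> Rh, and per-sample counting.

Each tracked particle's mean squared displacement grows as
<d^2(m dt)> = 4 D m dt for free 2-D-projected Brownian motion; the
per-track diffusion coefficient feeds Stokes--Einstein to give a
per-track hydrodynamic radius.  A sample is summarized by the
unweighted mean +/- SD of the per-track radii (SD reported only when at
least 40 particles were tracked, matching the instrument's reporting
convention) and by the number density: the time-averaged per-frame
detected count divided by the detection volume, corrected for dilution.

Two estimators of D are provided: the lag-1 proportionality
(msd(dt)/4dt) and an unweighted straight-line fit over the first few
lags with a free intercept; the intercept absorbs the static
localization-noise offset 4 sigma_loc^2, so the fit mode is the default
in the presence of localization noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .physics import MediumConditions, rh_from_diffusion
from .tracking import Track, TrackSet, filter_tracks

__all__ = [
    "MsdCurve",
    "msd_curve",
    "diffusion_from_msd",
    "number_density",
    "IlmModel",
    "IlmResults",
    "ilm_summary",
]


@dataclass
class MsdCurve:
    """Time-averaged MSD of one track: lags (s), msd (m^2), pair counts."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if len(self.lags) == 0:
            raise ValueError("MSD curve is empty")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0) or np.any(self.n_pairs < 1):
            raise ValueError("msd must be >= 0 with n_pairs >= 1 at every reported lag")

    def __len__(self) -> int:
        return len(self.lags)


def msd_curve(track: Track, max_lag: int, frame_interval: float = 1.0) -> MsdCurve:
    """Time-averaged 2-D MSD over all overlapping pairs, lags 1..max_lag frames.

    Pairs are formed only between actually localized frames (gap-bridged
    frames contribute no pairs); lags with no pair are omitted from the
    curve.  ``max_lag`` must be smaller than the track length.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag >= len(track):
        raise ValueError(f"max_lag={max_lag} >= track length {len(track)}")
    frames = track.frames
    index_of = {int(f): i for i, f in enumerate(frames)}
    lags, msds, counts = [], [], []
    for m in range(1, max_lag + 1):
        sq = []
        for i, f in enumerate(frames):
            j = index_of.get(int(f) + m)
            if j is not None:
                d = track.positions[j] - track.positions[i]
                sq.append(d @ d)
        if sq:
            lags.append(m * frame_interval)
            msds.append(float(np.mean(sq)))
            counts.append(len(sq))
    return MsdCurve(lags=np.array(lags), msd=np.array(msds), n_pairs=np.array(counts))


def pooled_msd(ts: TrackSet, max_lag: int, frame_interval: float = 1.0, min_length: int = 2) -> MsdCurve:
    """Pair-count-weighted MSD pooled over all tracks of a TrackSet.

    Lags where no track contributes a pair are omitted.  Used for
    ensemble-level diagnostics (e.g. detecting subdiffusion from the
    lag dependence of the apparent diffusion coefficient).
    """
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for track in ts:
        if len(track) < min_length or len(track) < 2:
            continue
        curve = msd_curve(track, min(max_lag, len(track) - 1), frame_interval)
        idx = np.rint(curve.lags / frame_interval).astype(int) - 1
        sums[idx] += curve.msd * curve.n_pairs
        counts[idx] += curve.n_pairs
    have = counts > 0
    if not np.any(have):
        raise ValueError("no displacement pairs available")
    lags = (np.arange(1, max_lag + 1) * frame_interval)[have]
    return MsdCurve(lags=lags, msd=sums[have] / counts[have], n_pairs=counts[have])


def diffusion_from_msd(
    curve: MsdCurve,
    mode: str = "linear_fit",
    fit_lags: int = 4,
) -> tuple[float, float]:
    """Diffusion coefficient (m^2/s) and its standard error from an MSD curve.

    ``mode="lag1"``: D = msd(dt)/(4 dt) at the first reported lag, with
    the chi-squared standard error sqrt(2/n_pairs) relative.
    ``mode="linear_fit"``: D = slope/4 of an unweighted least-squares
    line over the first ``fit_lags`` lags with a free intercept (which
    absorbs the localization-noise offset).  Negative estimates are
    returned as-is for the caller to flag.
    """
    if mode == "lag1":
        D = float(curve.msd[0] / (4.0 * curve.lags[0]))
        se = abs(D) * math.sqrt(2.0 / curve.n_pairs[0])
        return D, se
    if mode != "linear_fit":
        raise ValueError(f"unknown mode {mode!r}")
    if len(curve) < fit_lags:
        raise ValueError(f"need {fit_lags} lags for linear_fit, curve has {len(curve)}")
    if fit_lags < 2:
        raise ValueError("linear_fit needs fit_lags >= 2")
    t = curve.lags[:fit_lags]
    y = curve.msd[:fit_lags]
    n = fit_lags
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    if n > 2:
        resid = y - (ybar + slope * (t - tbar))
        se_slope = math.sqrt(float(np.sum(resid**2)) / (n - 2) / sxx)
    else:
        se_slope = float("nan")
    return slope / 4.0, se_slope / 4.0


def number_density(n_particles: float, detection_volume: float, dilution_factor: float = 1.0) -> float:
    """Particles per mL: count / detection volume (liters), corrected for dilution."""
    if n_particles < 0:
        raise ValueError("particle count must be >= 0")
    if detection_volume <= 0:
        raise ValueError("detection_volume must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    volume_ml = detection_volume * 1e3
    return n_particles / volume_ml * dilution_factor


class IlmModel:
    """Per-sample sizing-and-counting model for a set of nanotracking tracks.

    Parameters
    ----------
    ts : TrackSet
        Linked tracks sharing one acquisition (the acquisition supplies
        the frame interval, detection volume and dilution factor).
    medium : MediumConditions
        Temperature and viscosity for Stokes--Einstein.
    dilution_factor, frame_interval, detection_volume :
        Overrides for values normally taken from ``ts.acquisition``.
    """

    def __init__(
        self,
        ts: TrackSet,
        medium: MediumConditions = MediumConditions(),
        dilution_factor: Optional[float] = None,
        frame_interval: Optional[float] = None,
        detection_volume: Optional[float] = None,
    ) -> None:
        self.ts = ts
        self.medium = medium
        acq = ts.acquisition
        self.frame_interval = frame_interval or getattr(acq, "frame_interval", None) or 1.0
        self.detection_volume = detection_volume or getattr(acq, "detection_volume", None) or 15e-12
        self.dilution_factor = dilution_factor or getattr(acq, "dilution_factor", None) or 1.0

    def fit(
        self,
        mode: str = "linear_fit",
        fit_lags: int = 4,
        min_length: Optional[int] = None,
        udl_min_tracks: int = 5,
        lp_rh_threshold: float = 1e-6,
        sd_min_tracks: int = 40,
        ba: bool = False,
    ) -> "IlmResults":
        """Estimate per-track Rh and per-sample summary statistics.

        Tracks shorter than ``min_length`` (default ``fit_lags + 1``)
        are dropped; tracks whose estimated D is not positive are
        excluded from the mean/SD but counted in ``n_excluded``.  Flags:
        UDL when fewer than ``udl_min_tracks`` tracks were usable (the
        mean is then withheld), LP when any track's Rh exceeds
        ``lp_rh_threshold`` (default 1 um), BA is a pass-through
        annotation.
        """
        if min_length is None:
            min_length = max(fit_lags + 1, 3) if mode == "linear_fit" else 2
        usable = filter_tracks(self.ts, min_length) if len(self.ts) else self.ts
        d_list, se_list, rh_list = [], [], []
        n_excluded = 0
        for track in usable:
            curve = msd_curve(track, min(fit_lags, len(track) - 1), self.frame_interval)
            eff_mode = mode
            if mode == "linear_fit" and len(curve) < max(fit_lags, 2):
                eff_mode = "lag1"  # gap-riddled track: too few lags for the fit
            D, se = diffusion_from_msd(curve, eff_mode, fit_lags)
            d_list.append(D)
            se_list.append(se)
            if D > 0:
                rh_list.append(rh_from_diffusion(D, self.medium))
            else:
                rh_list.append(np.nan)
                n_excluded += 1
        rh = np.asarray(rh_list, dtype=float)
        valid = rh[np.isfinite(rh)]
        n_tracked = int(len(valid))

        flags: set[str] = set()
        if ba:
            flags.add("BA")
        if n_tracked < udl_min_tracks:
            flags.add("UDL")
        if n_tracked and np.any(valid > lp_rh_threshold):
            flags.add("LP")
        mean_rh = float(valid.mean()) if n_tracked and "UDL" not in flags else None
        sd_rh = float(valid.std(ddof=1)) if n_tracked >= sd_min_tracks else None

        counts = self.ts.per_frame_counts(getattr(self.ts.acquisition, "n_frames", None))
        mean_count = float(counts.mean()) if len(counts) else 0.0
        density = number_density(mean_count, self.detection_volume, self.dilution_factor)

        return IlmResults(
            model=self,
            n_tracked=n_tracked,
            mean_rh=mean_rh,
            sd_rh=sd_rh,
            number_density=density,
            flags=flags,
            rh_per_track=rh,
            d_per_track=np.asarray(d_list),
            d_se_per_track=np.asarray(se_list),
            n_excluded=n_excluded,
            mode=mode,
            fit_lags=fit_lags,
        )


@dataclass
class IlmResults:
    """Per-sample nanotracking results: N tracked, Rh mean +/- SD, density, flags."""

    model: IlmModel
    n_tracked: int
    mean_rh: Optional[float]
    sd_rh: Optional[float]
    number_density: float
    flags: set = field(default_factory=set)
    rh_per_track: np.ndarray = field(default_factory=lambda: np.array([]))
    d_per_track: np.ndarray = field(default_factory=lambda: np.array([]))
    d_se_per_track: np.ndarray = field(default_factory=lambda: np.array([]))
    n_excluded: int = 0
    mode: str = "linear_fit"
    fit_lags: int = 4

    def rh_line(self) -> str:
        """'N  mean +/- SD' in nm, in the study-table style (e.g. '381  103 ± 27')."""
        if "UDL" in self.flags or self.mean_rh is None:
            return "UDL"
        mean_nm = self.mean_rh * 1e9
        if self.sd_rh is not None:
            return f"{self.n_tracked}  {mean_nm:.0f} ± {self.sd_rh * 1e9:.0f}"
        return f"{self.n_tracked}  {mean_nm:.0f}"

    def summary(self) -> str:
        lines = [
            "ILM nanotracking summary",
            f"  estimator: {self.mode} (fit_lags={self.fit_lags})",
            f"  tracks used: {self.n_tracked}   excluded (D <= 0): {self.n_excluded}",
            f"  Rh (nm): {self.rh_line()}",
            f"  number density: {self.number_density:.3g} /mL "
            f"(dilution x{self.model.dilution_factor:g})",
            f"  flags: {', '.join(sorted(self.flags)) if self.flags else '-'}",
        ]
        return "\n".join(lines)


def ilm_summary(ts: TrackSet, medium: MediumConditions = MediumConditions(), **fit_kwargs) -> IlmResults:
    """Convenience wrapper: ``IlmModel(ts, medium).fit(**fit_kwargs)``."""
    return IlmModel(ts, medium).fit(**fit_kwargs)
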