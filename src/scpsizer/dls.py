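"""Dynamic light scattering: Siegert relation, decay-spectrum inversion, I(Rh) peaks.

A DLS correlator measures the intensity autocorrelation g2(t).  The
Siegert relation g2 = 1 + beta |g1|^2 recovers the field correlation
g1(t), which for a polydisperse suspension of spheres is a Laplace
transform of the decay-rate spectrum w(Gamma):

    g1(t) = sum_k w_k exp(-Gamma_k t),   Gamma = q^2 D.

Recovering w from noisy g1 is an ill-posed inverse problem; following
the classic CONTIN approach it is solved as a non-negatively
constrained least squares with a second-difference (curvature)
smoothness penalty on a log-spaced Gamma grid of at most 50 points.
Each decay rate maps to a hydrodynamic radius through Gamma = q^2 D and
Stokes--Einstein, giving the intensity-weighted size distribution
I(Rh) whose contiguous peaks are reported with their intensity
fractions I_i / I_tot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import nnls

from .physics import MediumConditions

__all__ = [
    "CorrelationFunction",
    "DecaySpectrum",
    "SizeDistribution",
    "Peak",
    "scattering_vector",
    "estimate_beta",
    "g1_from_g2",
    "default_gamma_grid",
    "invert_decay_spectrum",
    "rh_from_gamma",
    "peaks_from_distribution",
    "DlsModel",
    "DlsResults",
]

#: DLS components slower than this radius (m) are flagged as very large.
VERY_LARGE_RH = 10e-6


@dataclass
class CorrelationFunction:
    """Measured intensity autocorrelation: lags (s), g2 values, coherence factor beta."""

    lags: np.ndarray
    g2: np.ndarray
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.lags.shape != self.g2.shape or self.lags.ndim != 1:
            raise ValueError("lags and g2 must be 1-D arrays of equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not (np.all(np.isfinite(self.lags)) and np.all(np.isfinite(self.g2))):
            raise ValueError("correlation data must be finite")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")


def scattering_vector(
    medium: MediumConditions = MediumConditions(),
    wavelength: float = 660e-9,
    angle: float = 90.0,
) -> float:
    """Scattering vector magnitude q = (4 pi n0 / lambda0) sin(theta/2), in 1/m.

    ``angle`` is the scattering angle in degrees, 0 < angle < 180.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    if not (0 < angle < 180):
        raise ValueError("scattering angle must be in (0, 180) degrees")
    return 4.0 * math.pi * medium.refractive_index / wavelength * math.sin(math.radians(angle) / 2.0)


def estimate_beta(cf: CorrelationFunction, n_lags: int = 5) -> float:
    """Estimate the coherence factor from the short-lag limit of g2 - 1.

    For any mixture of exponential decays, log(g2 - 1) is linear in t at
    short lags with intercept log(beta); a straight-line fit over the
    first ``n_lags`` lags with g2 > 1 is extrapolated to t = 0.
    """
    mask = cf.g2 > 1.0
    t = cf.lags[mask][:n_lags]
    y = np.log(cf.g2[mask][:n_lags] - 1.0)
    if len(t) < 2:
        raise ValueError("not enough lags with g2 > 1 to estimate beta")
    slope, intercept = np.polyfit(t, y, 1)
    return float(min(1.0, math.exp(intercept)))


def g1_from_g2(cf: CorrelationFunction, beta: Optional[float] = None) -> tuple[np.ndarray, int]:
    """Field correlation from the Siegert relation, g1 = sqrt((g2 - 1)/beta).

    Negative radicands (noise below the baseline) are clipped to zero;
    the number of clipped lags is returned alongside g1.
    """
    b = beta if beta is not None else cf.beta
    if b is None:
        b = estimate_beta(cf)
    if b <= 0:
        raise ValueError("beta must be positive")
    radicand = (cf.g2 - 1.0) / b
    clipped = int(np.sum(radicand < 0))
    return np.sqrt(np.clip(radicand, 0.0, None)), clipped


def default_gamma_grid(lags: np.ndarray, n_exponents: int = 50, gamma_span: float = 6.0) -> np.ndarray:
    """Log-spaced decay-rate grid centred on the lag window's reciprocal range.

    The grid of ``n_exponents`` points spans ``gamma_span`` decades
    around the geometric centre of [1/t_max, 1/t_min].
    """
    center = 1.0 / math.sqrt(lags[0] * lags[-1])
    half = gamma_span / 2.0
    return np.logspace(math.log10(center) - half, math.log10(center) + half, n_exponents)


def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def _solve_penalized_nnls(A: np.ndarray, g1: np.ndarray, L: np.ndarray, lam: float) -> np.ndarray:
    if lam > 0:
        A_aug = np.vstack([A, math.sqrt(lam) * L])
        b_aug = np.concatenate([g1, np.zeros(L.shape[0])])
    else:
        A_aug, b_aug = A, g1
    w, _ = nnls(A_aug, b_aug, maxiter=10 * A.shape[1] * 30)
    return w


def _lcurve_corner(lambdas: np.ndarray, rho: np.ndarray, eta: np.ndarray) -> float:
    """Pick the regularization strength at the corner of the L-curve.

    Uses the Menger curvature of consecutive triplets of
    (log residual, log penalty) points; falls back to the smallest
    lambda when the curve is degenerate (e.g. noiseless data).
    """
    eps = 1e-300
    x = np.log10(rho + eps)
    y = np.log10(eta + eps)
    best, best_curv = float(lambdas[0]), -np.inf
    for i in range(1, len(lambdas) - 1):
        p0 = np.array([x[i - 1], y[i - 1]])
        p1 = np.array([x[i], y[i]])
        p2 = np.array([x[i + 1], y[i + 1]])
        a = np.linalg.norm(p1 - p0)
        b = np.linalg.norm(p2 - p1)
        c = np.linalg.norm(p2 - p0)
        if min(a, b, c) < 1e-12:
            continue
        cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
        curv = 2.0 * cross / (a * b * c)  # signed: convex corners positive
        if curv > best_curv:
            best_curv = curv
            best = float(lambdas[i])
    return best


@dataclass
class DecaySpectrum:
    """Non-negative decay-rate spectrum w(Gamma), normalized to sum 1."""

    gamma_grid: np.ndarray
    weights: np.ndarray
    reg_strength: float
    residual: float

    def weighted_mean_gamma(self) -> float:
        return float(np.sum(self.gamma_grid * self.weights) / np.sum(self.weights))


def invert_decay_spectrum(
    g1: np.ndarray,
    lags: np.ndarray,
    n_exponents: int = 50,
    gamma_span: float = 6.0,
    reg_strength: Union[float, str] = "auto",
    gamma_grid: Optional[np.ndarray] = None,
) -> DecaySpectrum:
    """Regularized inverse Laplace transform of the field correlation.

    Solves ``min ||A w - g1||^2 + lam ||L w||^2, w >= 0`` where
    ``A_jk = exp(-Gamma_k t_j)`` on a log-spaced Gamma grid and L is the
    second-difference operator (CONTIN's smoothness penalty).  With
    ``reg_strength="auto"`` the strength is chosen by an L-curve corner
    heuristic over a log-spaced ladder; a numeric value fixes it.

    Returns the spectrum with weights normalized to sum 1.
    """
    g1 = np.asarray(g1, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if g1.shape != lags.shape:
        raise ValueError("g1 and lags must have the same shape")
    if not (2 <= n_exponents <= 50):
        raise ValueError("n_exponents must be in [2, 50]")
    if np.all(g1 == 0):
        raise ValueError("g1 is identically zero: no decay spectrum to recover")
    if len(lags) < 2 * n_exponents:
        import warnings

        warnings.warn(
            f"only {len(lags)} lag points for {n_exponents} exponents; "
            "inversion may be under-determined",
            stacklevel=2,
        )
    grid = gamma_grid if gamma_grid is not None else default_gamma_grid(lags, n_exponents, gamma_span)
    grid = np.asarray(grid, dtype=float)
    # scale-invariant inversion: peak positions must not depend on the
    # (instrumental) amplitude of g1
    scale = float(np.max(np.abs(g1)))
    g1 = g1 / scale
    A = np.exp(-np.outer(lags, grid))
    L = _second_difference(len(grid))

    if isinstance(reg_strength, str):
        if reg_strength != "auto":
            raise ValueError("reg_strength must be a number or 'auto'")
        lambdas = np.logspace(-8, 2, 21)
        rho = np.empty(len(lambdas))
        eta = np.empty(len(lambdas))
        sols = []
        for i, lam in enumerate(lambdas):
            w = _solve_penalized_nnls(A, g1, L, lam)
            sols.append(w)
            rho[i] = np.linalg.norm(A @ w - g1)
            eta[i] = np.linalg.norm(L @ w)
        lam = _lcurve_corner(lambdas, rho, eta)
        w = sols[int(np.argmin(np.abs(np.log(lambdas) - np.log(lam))))]
    else:
        lam = float(reg_strength)
        if lam < 0:
            raise ValueError("reg_strength must be >= 0")
        w = _solve_penalized_nnls(A, g1, L, lam)

    total = w.sum()
    if total <= 0:
        raise ValueError("non-negative solver returned an all-zero spectrum")
    residual = float(np.linalg.norm(A @ w - g1))
    return DecaySpectrum(gamma_grid=grid, weights=w / total, reg_strength=float(lam), residual=residual)


def rh_from_gamma(
    gamma: Union[float, np.ndarray],
    q: float,
    medium: MediumConditions = MediumConditions(),
) -> Union[float, np.ndarray]:
    """Hydrodynamic radius from a decay rate: D = Gamma/q^2, Rh = kT/(6 pi eta D)."""
    gamma_arr = np.asarray(gamma, dtype=float)
    if np.any(gamma_arr <= 0) or q <= 0:
        raise ValueError("gamma and q must be positive")
    D = gamma_arr / q**2
    rh = medium.kT / (6.0 * math.pi * medium.viscosity * D)
    return float(rh) if np.isscalar(gamma) else rh


@dataclass
class Peak:
    """One population in the I(Rh) distribution."""

    rh: float
    fraction: float
    very_large: bool = False


@dataclass
class SizeDistribution:
    """Intensity-weighted size distribution on an ascending log-spaced Rh grid."""

    rh_grid: np.ndarray
    weights: np.ndarray
    i_tot: Optional[float] = None
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rh_grid = np.asarray(self.rh_grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.rh_grid) <= 0):
            raise ValueError("rh_grid must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


def size_distribution_from_spectrum(
    spectrum: DecaySpectrum,
    q: float,
    medium: MediumConditions = MediumConditions(),
    i_tot: Optional[float] = None,
) -> SizeDistribution:
    """Map a decay-rate spectrum onto the hydrodynamic-radius axis (ascending Rh)."""
    rh = rh_from_gamma(spectrum.gamma_grid, q, medium)
    order = np.argsort(rh)
    return SizeDistribution(rh_grid=rh[order], weights=spectrum.weights[order], i_tot=i_tot)


def peaks_from_distribution(
    dist: SizeDistribution,
    min_fraction: float = 0.01,
    floor: float = 1e-4,
    max_peaks: int = 4,
) -> list[Peak]:
    """Extract contiguous peaks and their intensity fractions from I(Rh).

    Bins below ``floor`` times the maximum weight count as zero and
    separate peaks; peaks with fraction below ``min_fraction`` are
    dropped; at most ``max_peaks`` (largest fractions) are kept, sorted
    by ascending Rh.  A peak with mean Rh beyond 10 um carries the
    very-large flag.
    """
    w = dist.weights
    if w.max() <= 0:
        return []
    active = w >= floor * w.max()
    peaks: list[Peak] = []
    i = 0
    n = len(w)
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n and active[j]:
            j += 1
        frac = float(w[i:j].sum())
        if frac >= min_fraction:
            rh = float(np.sum(dist.rh_grid[i:j] * w[i:j]) / frac)
            peaks.append(Peak(rh=rh, fraction=frac, very_large=rh > VERY_LARGE_RH))
        i = j
    peaks.sort(key=lambda p: p.fraction, reverse=True)
    peaks = peaks[:max_peaks]
    peaks.sort(key=lambda p: p.rh)
    return peaks


class DlsModel:
    """Sizing model for one DLS correlogram.

    Parameters
    ----------
    cf : CorrelationFunction
        Measured g2(t); ``cf.beta`` is used when present, otherwise the
        coherence factor is estimated from the short-lag limit.
    medium : MediumConditions
        Solvent temperature, viscosity and refractive index.
    wavelength, angle : float
        Laser vacuum wavelength (m) and scattering angle (degrees).

    ``fit`` performs Siegert inversion, the regularized decay-spectrum
    inversion and peak extraction, returning a :class:`DlsResults`.
    """

    def __init__(
        self,
        cf: CorrelationFunction,
        medium: MediumConditions = MediumConditions(),
        wavelength: float = 660e-9,
        angle: float = 90.0,
    ) -> None:
        self.cf = cf
        self.medium = medium
        self.wavelength = wavelength
        self.angle = angle
        self.q = scattering_vector(medium, wavelength, angle)

    def fit(
        self,
        n_exponents: int = 50,
        gamma_span: float = 6.0,
        reg_strength: Union[float, str] = "auto",
        beta: Optional[float] = None,
        min_fraction: float = 0.01,
        i_tot: Optional[float] = None,
    ) -> "DlsResults":
        beta_used = beta if beta is not None else self.cf.beta
        if beta_used is None:
            beta_used = estimate_beta(self.cf)
        g1, n_clipped = g1_from_g2(self.cf, beta_used)
        spectrum = invert_decay_spectrum(
            g1, self.cf.lags, n_exponents=n_exponents, gamma_span=gamma_span, reg_strength=reg_strength
        )
        dist = size_distribution_from_spectrum(spectrum, self.q, self.medium, i_tot=i_tot)
        dist.peaks = peaks_from_distribution(dist, min_fraction=min_fraction)
        return DlsResults(
            model=self,
            beta=beta_used,
            g1=g1,
            n_clipped=n_clipped,
            spectrum=spectrum,
            distribution=dist,
        )


@dataclass
class DlsResults:
    """Fitted decay spectrum, I(Rh) distribution and extracted peaks."""

    model: DlsModel
    beta: float
    g1: np.ndarray
    n_clipped: int
    spectrum: DecaySpectrum
    distribution: SizeDistribution

    @property
    def peaks(self) -> list[Peak]:
        return self.distribution.peaks

    @property
    def main_peak(self) -> Optional[Peak]:
        """The highest-fraction peak (the 'main' population)."""
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p.fraction)

    def peak_columns(self) -> dict:
        """Small/main/large peak layout used by the study-style reports.

        The highest-fraction peak is the main one; the largest-fraction
        smaller and larger companions (if any) fill the flanking columns.
        """
        out = {
            "rh1_nm": None, "frac1": None,
            "rh2_nm": None, "frac2": None,
            "rh3_nm": None, "frac3": None,
            "lp_flag": any(p.very_large for p in self.peaks),
        }
        main = self.main_peak
        if main is None:
            return out
        out["rh2_nm"] = main.rh * 1e9
        out["frac2"] = main.fraction
        smaller = [p for p in self.peaks if p.rh < main.rh]
        larger = [p for p in self.peaks if p.rh > main.rh]
        if smaller:
            p = max(smaller, key=lambda p: p.fraction)
            out["rh1_nm"], out["frac1"] = p.rh * 1e9, p.fraction
        if larger:
            p = max(larger, key=lambda p: p.fraction)
            out["rh3_nm"], out["frac3"] = p.rh * 1e9, p.fraction
        return out

    def summary(self) -> str:
        lines = [
            "DLS decay-spectrum inversion",
            f"  lags: {len(self.model.cf.lags)}  grid points: {len(self.spectrum.gamma_grid)}",
            f"  q = {self.model.q:.4g} 1/m   beta = {self.beta:.3f}   "
            f"reg = {self.spectrum.reg_strength:.3g}   residual = {self.spectrum.residual:.3g}",
            f"  clipped lags (g2 < 1): {self.n_clipped}",
            "  peaks (ascending Rh):",
        ]
        for p in self.peaks:
            tag = "  [>10 um]" if p.very_large else ""
            lines.append(f"    Rh = {p.rh * 1e9:10.1f} nm   I/I_tot = {p.fraction:.2f}{tag}")
        if not self.peaks:
            lines.append("    (none)")
        return "\n".join(lines)

    def plot_distribution(self, ax=None):
        """Diagnostic plot of the intensity-weighted I(Rh) distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.distribution.rh_grid * 1e9, self.distribution.weights, "o-")
        ax.set_xlabel("Rh (nm)")
        ax.set_ylabel("intensity weight")
        return ax
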