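"""Medium description and translational diffusion coefficients.

Everything in this module is in SI units (meters, seconds, kelvin,
pascal-seconds).  The Stokes--Einstein relation

    D = k_B T / (6 pi eta R_h)

ties the translational diffusion coefficient of a sphere to its
hydrodynamic radius; both directions of the relation live here because
the nanotracking and light-scattering stages each use one of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23


@dataclass(frozen=True)
class MediumConditions:
    """Solvent conditions entering the Stokes--Einstein and q-vector formulas.

    Defaults are water at 25 degC: T = 298.15 K, eta = 8.9e-4 Pa s,
    refractive index n0 = 1.33.
    """

    temperature: float = 298.15
    viscosity: float = 8.9e-4
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.viscosity <= 0 or self.refractive_index <= 0:
            raise ValueError("temperature, viscosity and refractive_index must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_B T in joules."""
        return BOLTZMANN * self.temperature


def diffusion_coefficient_sphere(rh: float, medium: MediumConditions = MediumConditions()) -> float:
    """Stokes--Einstein diffusion coefficient of a sphere of hydrodynamic radius ``rh``.

    Parameters
    ----------
    rh : float
        Hydrodynamic radius in meters, > 0.
    medium : MediumConditions
        Temperature and viscosity of the suspending medium.

    Returns
    -------
    float
        Translational diffusion coefficient in m^2/s.
    """
    if rh <= 0:
        raise ValueError(f"hydrodynamic radius must be positive, got {rh}")
    return medium.kT / (6.0 * math.pi * medium.viscosity * rh)


def rh_from_diffusion(D: float, medium: MediumConditions = MediumConditions()) -> float:
    """Hydrodynamic radius (m) of the sphere with diffusion coefficient ``D`` (m^2/s)."""
    if D <= 0:
        raise ValueError(f"diffusion coefficient must be positive, got {D}")
    return medium.kT / (6.0 * math.pi * medium.viscosity * D)


def diffusion_coefficient_rod(
    length: float,
    diameter: float,
    medium: MediumConditions = MediumConditions(),
) -> float:
    """Translational diffusion coefficient of a rigid rod.

    Uses the Tirado--Garcia de la Torre slender-body result for the
    orientation-averaged translational coefficient,

        D = kT (ln p + nu) / (3 pi eta L),    p = L/d,
        nu = 0.312 + 0.565/p - 0.100/p**2,

    which is the standard choice for cylinders with aspect ratio p >~ 2.
    Below that the end-correction leaves its fitted domain and the value
    should be treated as an extrapolation (it stays within ~15% of the
    equal-volume sphere as p -> 1).

    Parameters
    ----------
    length, diameter : float
        Rod length and diameter in meters; ``length > diameter > 0``.

    Returns
    -------
    float
        Diffusion coefficient in m^2/s.
    """
    if diameter <= 0 or length <= diameter:
        raise ValueError("rod requires length > diameter > 0")
    p = length / diameter
    nu = 0.312 + 0.565 / p - 0.100 / p**2
    return medium.kT * (math.log(p) + nu) / (3.0 * math.pi * medium.viscosity * length)
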