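"""Fire-risk model: fuel accounting, soil-dryness trigger, flammable area.

A patch becomes fire-prone when the depth-averaged volumetric soil
moisture of the top ``z_F`` (default 30 cm) drops strictly below a
threshold anchored between the permanent wilting point and field
capacity:

    theta_crit = (1 - f) * theta_Wp + f * theta_Fc,       f = 0.02.

While dry, the fire disturbance rate is proportional to the fuel
carbon stock, ``lambda_F = I * C_Fuel`` with fire-intensity parameter
I = 0.5 m^2 kgC^-1 yr^-1; otherwise it is zero.  The flammable area
(percent of the patch per year) follows as

    alpha_F = 100 * (1 - exp(-lambda_F * dt)),            dt = 1 yr.

Understory fires dominate the system this represents, so fuels comprise
aboveground litter, aboveground coarse woody debris, and aboveground
biomass of grasses and seedlings (trees shorter than 2 m); canopy trees
are not fuels.  Fuel pools are inputs in kgC m^-2 — decomposition and
necromass dynamics are outside this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allometry import AllometrySet, CohortStack, agb_kg, default_allometry

__all__ = [
    "FlammabilityParams",
    "SoilState",
    "FuelInventory",
    "FlammabilityResult",
    "mean_soil_moisture",
    "dryness_threshold",
    "flammable_area",
    "fuel_from_cohorts",
]

#: Trees below this height (m) count as seedling fuel (strict <).
SEEDLING_HEIGHT = 2.0


@dataclass(frozen=True)
class FlammabilityParams:
    """Fire-model constants (defaults as used for Amazon forests)."""

    intensity: float = 0.5      # I, m^2 kgC^-1 yr^-1
    dryness_f: float = 0.02     # f, dimensionless, in (0, 1)
    z_fire: float = 0.30        # z_F, m
    dt: float = 1.0             # yr

    def __post_init__(self):
        if self.intensity <= 0 or self.z_fire <= 0 or self.dt <= 0:
            raise ValueError("I, z_F and dt must be positive")
        if not (0.0 < self.dryness_f < 1.0):
            raise ValueError("f must be in (0, 1)")


@dataclass(frozen=True)
class SoilState:
    """Layered soil-moisture state, top layer first.

    thickness[i] is layer i's vertical extent (m); theta[i] its
    volumetric water content (m^3 m^-3).
    """

    thickness: tuple[float, ...]
    theta: tuple[float, ...]
    theta_wp: float              # permanent wilting point
    theta_fc: float              # field capacity
    porosity: float = 0.50

    def __post_init__(self):
        if len(self.thickness) != len(self.theta):
            raise ValueError("thickness and theta must align")
        if not (0.0 <= self.theta_wp < self.theta_fc <= self.porosity <= 1.0):
            raise ValueError(
                "require 0 <= theta_Wp < theta_Fc <= porosity <= 1"
            )
        for th in self.theta:
            if not (0.0 <= th <= self.porosity + 1e-12):
                raise ValueError("theta must lie within [0, porosity]")

    @property
    def depth(self) -> float:
        return float(sum(self.thickness))


@dataclass(frozen=True)
class FuelInventory:
    """Understory fuel carbon pools (kgC m^-2)."""

    litter: float = 0.0
    cwd: float = 0.0                 # coarse woody debris
    grass_seedling_agb: float = 0.0  # grasses + trees of height < 2 m

    def __post_init__(self):
        for name in ("litter", "cwd", "grass_seedling_agb"):
            if getattr(self, name) < 0:
                raise ValueError(f"fuel pool {name} must be >= 0")

    @property
    def total(self) -> float:
        return self.litter + self.cwd + self.grass_seedling_agb


@dataclass(frozen=True)
class FlammabilityResult:
    lambda_f: float      # fire disturbance rate, yr^-1
    alpha_f: float       # flammable area, % yr^-1
    dry: bool
    mean_moisture: float
    threshold: float


def mean_soil_moisture(soil: SoilState, z_f: float) -> float:
    """Depth-averaged soil moisture over [0, z_f].

    A layer straddling z_f contributes only the part above it (linear
    weighting).  Raises if the layers do not cover z_f.
    """
    if soil.depth < z_f - 1e-12:
        raise ValueError(
            f"soil layers cover {soil.depth:.3f} m, shallower than z_F={z_f} m"
        )
    acc = 0.0
    top = 0.0
    for dz, th in zip(soil.thickness, soil.theta):
        bottom = top + dz
        overlap = max(0.0, min(bottom, z_f) - top)
        acc += th * overlap
        top = bottom
        if top >= z_f:
            break
    return acc / z_f


def dryness_threshold(soil: SoilState, f: float) -> float:
    """theta_crit = (1 - f) * theta_Wp + f * theta_Fc."""
    return (1.0 - f) * soil.theta_wp + f * soil.theta_fc


def flammable_area(fuel: FuelInventory, soil: SoilState,
                   params: FlammabilityParams = FlammabilityParams()
                   ) -> FlammabilityResult:
    """Fire disturbance rate and flammable area for one patch-state.

    The dry trigger uses a strict inequality: fire-prone conditions
    require the depth-mean moisture to fall strictly below theta_crit.
    """
    theta_bar = mean_soil_moisture(soil, params.z_fire)
    theta_crit = dryness_threshold(soil, params.dryness_f)
    dry = theta_bar < theta_crit
    lam = params.intensity * fuel.total if dry else 0.0
    alpha = 100.0 * (1.0 - np.exp(-lam * params.dt))
    return FlammabilityResult(lambda_f=lam, alpha_f=float(alpha), dry=dry,
                              mean_moisture=theta_bar, threshold=theta_crit)


def fuel_from_cohorts(stack: CohortStack, litter: float, cwd: float,
                      allom: AllometrySet | None = None) -> FuelInventory:
    """Build a fuel inventory from a cohort stack plus necromass pools.

    Sums AGB x density (kgC m^-2; cohort biomass is interpreted as
    carbon, no hidden conversion) over grass cohorts and tree cohorts
    strictly shorter than 2 m; canopy trees are excluded.  Litter and
    CWD pools are supplied, not simulated.
    """
    if litter < 0 or cwd < 0:
        raise ValueError("necromass pools must be >= 0")
    allom = allom or default_allometry()
    understory = 0.0
    for c in stack:
        if allom[c.pft].is_grass or c.height < SEEDLING_HEIGHT:
            understory += agb_kg(c.dbh, c.pft, allom) * c.density
    return FuelInventory(litter=litter, cwd=cwd,
                         grass_seedling_agb=understory)
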