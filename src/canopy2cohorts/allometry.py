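"""Individual-tree allometry and plot-level integration.

Converts stem diameter (DBH, cm) into height, leaf area, aboveground
biomass and basal area for a small registry of plant functional types
(PFTs), and integrates cohort stacks into the four plot-level properties
used throughout the initialization pipeline: aboveground biomass (AGB,
kg m**-2), basal area (cm**2 m**-2), stem number density (stems ha**-1)
and leaf area index (LAI, m**2 m**-2).

The height-diameter law is a saturating exponential

    H(D) = H_max * (1 - exp(-a * D**b))

which is strictly increasing in D and analytically invertible below
H_max.  Leaf area per individual follows a power law ``l0 * D**q`` and
aboveground biomass a Chave-form power law on the compound variable
``rho * D**2 * H``.  All coefficients are per-PFT and configurable; the
shipped defaults are plausible tropical values, not fitted constants,
and should be replaced with site-calibrated parameters for real use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "PFTAllometry",
    "AllometrySet",
    "PlotProperties",
    "Cohort",
    "CohortStack",
    "default_allometry",
    "height_from_dbh",
    "dbh_from_height",
    "stem_properties",
    "integrate_properties",
]


@dataclass(frozen=True)
class PFTAllometry:
    """Allometric coefficients for one plant functional type.

    Parameters
    ----------
    h_max : float
        Asymptotic height (m) of the saturating height-diameter law.
    h_a, h_b : float
        Rate and shape of the height law ``H = h_max*(1-exp(-h_a*D**h_b))``.
    leaf_l0, leaf_exp : float
        Leaf area per individual (m**2) = ``leaf_l0 * D**leaf_exp``.
    agb_c0, agb_c1 : float
        Aboveground biomass (kg) = ``agb_c0 * (rho * D**2 * H)**agb_c1``.
    wood_density : float
        Wood density rho (g cm**-3).
    is_grass : bool
        Grasses carry foliage only near the ground (< 2 m) and count as
        fuel regardless of height.
    """

    h_max: float
    h_a: float
    h_b: float
    leaf_l0: float
    leaf_exp: float
    agb_c0: float
    agb_c1: float
    wood_density: float
    is_grass: bool = False


#: Default PFT registry: three successional tropical tree types plus a C4
#: grass.  Early types are shorter, lighter-wooded and leafier per unit
#: diameter than late types.
_DEFAULT_PFTS: dict[str, PFTAllometry] = {
    "early": PFTAllometry(
        h_max=28.0, h_a=0.052, h_b=0.95,
        leaf_l0=0.90, leaf_exp=1.60,
        agb_c0=0.0673, agb_c1=0.976, wood_density=0.45,
    ),
    "mid": PFTAllometry(
        h_max=36.0, h_a=0.046, h_b=0.93,
        leaf_l0=0.75, leaf_exp=1.62,
        agb_c0=0.0673, agb_c1=0.976, wood_density=0.62,
    ),
    "late": PFTAllometry(
        h_max=44.0, h_a=0.040, h_b=0.92,
        leaf_l0=0.60, leaf_exp=1.65,
        agb_c0=0.0673, agb_c1=0.976, wood_density=0.78,
    ),
    "grass": PFTAllometry(
        h_max=2.4, h_a=0.90, h_b=1.0,
        leaf_l0=0.35, leaf_exp=1.20,
        agb_c0=0.08, agb_c1=0.60, wood_density=0.20,
        is_grass=True,
    ),
}


@dataclass(frozen=True)
class AllometrySet:
    """Registry of per-PFT allometric laws."""

    pfts: Mapping[str, PFTAllometry] = field(
        default_factory=lambda: dict(_DEFAULT_PFTS)
    )

    def __getitem__(self, pft: str) -> PFTAllometry:
        try:
            return self.pfts[pft]
        except KeyError:
            raise KeyError(
                f"unknown functional type {pft!r}; known: {sorted(self.pfts)}"
            ) from None

    def names(self) -> list[str]:
        return list(self.pfts)

    def tree_names(self) -> list[str]:
        return [k for k, v in self.pfts.items() if not v.is_grass]

    @classmethod
    def from_yaml(cls, path) -> "AllometrySet":
        """Load a registry from a YAML mapping ``{pft_name: {field: value}}``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(pfts={k: PFTAllometry(**v) for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        out = {
            k: {f: getattr(v, f) for f in PFTAllometry.__dataclass_fields__}
            for k, v in self.pfts.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=True)

    def with_pft(self, name: str, pft: PFTAllometry) -> "AllometrySet":
        new = dict(self.pfts)
        new[name] = pft
        return replace(self, pfts=new)


def default_allometry() -> AllometrySet:
    return AllometrySet()


def height_from_dbh(dbh, pft: str, allom: AllometrySet | None = None):
    """Height (m) from DBH (cm), saturating exponential law."""
    allom = allom or default_allometry()
    p = allom[pft]
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh < 0):
        raise ValueError("DBH must be non-negative")
    h = p.h_max * (1.0 - np.exp(-p.h_a * dbh**p.h_b))
    return float(h) if h.ndim == 0 else h


def dbh_from_height(height, pft: str, allom: AllometrySet | None = None):
    """Invert the height law.  Raises for heights at or above ``h_max``."""
    allom = allom or default_allometry()
    p = allom[pft]
    height = np.asarray(height, dtype=float)
    if np.any(height < 0):
        raise ValueError("height must be non-negative")
    if np.any(height >= p.h_max):
        raise ValueError(
            f"height >= h_max ({p.h_max} m) for pft {pft!r}: law not invertible"
        )
    d = (-np.log(1.0 - height / p.h_max) / p.h_a) ** (1.0 / p.h_b)
    return float(d) if d.ndim == 0 else d


def max_invertible_height(pft: str, allom: AllometrySet | None = None,
                          margin: float = 0.995) -> float:
    """Tallest height safely invertible for a PFT (a fraction of h_max)."""
    allom = allom or default_allometry()
    return allom[pft].h_max * margin


def basal_area_cm2(dbh) -> float | np.ndarray:
    """Stem basal area (cm**2) = pi * (DBH/2)**2, exact."""
    dbh = np.asarray(dbh, dtype=float)
    ba = math.pi * (dbh / 2.0) ** 2
    return float(ba) if ba.ndim == 0 else ba


def leaf_area_m2(dbh, pft: str, allom: AllometrySet | None = None):
    """Leaf area per individual (m**2) from the per-PFT power law."""
    allom = allom or default_allometry()
    p = allom[pft]
    dbh = np.asarray(dbh, dtype=float)
    la = p.leaf_l0 * dbh**p.leaf_exp
    return float(la) if la.ndim == 0 else la


def agb_kg(dbh, pft: str, allom: AllometrySet | None = None):
    """Aboveground biomass per individual (kg), Chave-form power law."""
    allom = allom or default_allometry()
    p = allom[pft]
    dbh = np.asarray(dbh, dtype=float)
    h = p.h_max * (1.0 - np.exp(-p.h_a * dbh**p.h_b))
    agb = p.agb_c0 * (p.wood_density * dbh**2 * h) ** p.agb_c1
    return float(agb) if agb.ndim == 0 else agb


def stem_properties(dbh: float, pft: str, allom: AllometrySet | None = None
                    ) -> tuple[float, float, float]:
    """Per-individual (leaf area m**2, AGB kg, basal area cm**2)."""
    allom = allom or default_allometry()
    if dbh <= 0:
        raise ValueError("DBH must be positive")
    return (
        leaf_area_m2(dbh, pft, allom),
        agb_kg(dbh, pft, allom),
        basal_area_cm2(dbh),
    )


@dataclass(frozen=True)
class PlotProperties:
    """The four scalar plot-level targets.

    agb in kg m**-2, basal_area in cm**2 m**-2, stem_density in
    stems ha**-1, lai in m**2 m**-2.  All non-negative.
    """

    agb: float
    basal_area: float
    stem_density: float
    lai: float

    def __post_init__(self):
        for name in ("agb", "basal_area", "stem_density", "lai"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "agb": self.agb,
            "basal_area": self.basal_area,
            "stem_density": self.stem_density,
            "lai": self.lai,
        }

    @staticmethod
    def zeros() -> "PlotProperties":
        return PlotProperties(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Cohort:
    """One cohort: plants of similar size and functional type.

    density is stems m**-2; lai is this cohort's contribution to the
    column LAI (m**2 m**-2).
    """

    dbh: float
    height: float
    pft: str
    density: float
    lai: float


@dataclass
class CohortStack:
    """Ordered cohorts for one column; the patch-level initial condition."""

    cohorts: list[Cohort]
    column_id: str = ""
    region: str = ""
    disturbance: str = ""

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self):
        return len(self.cohorts)

    @property
    def lai(self) -> float:
        return sum(c.lai for c in self.cohorts)


def integrate_properties(stack: CohortStack | Iterable[Cohort],
                         area_m2: float,
                         allom: AllometrySet | None = None,
                         census_dbh_min: float = 0.0) -> PlotProperties:
    """Integrate a cohort stack into plot-level properties.

    Each property is the density-weighted sum of per-individual
    allometric values; ``area_m2`` is only used to validate inputs since
    cohort densities are already per unit area.

    ``census_dbh_min`` (cm) restricts AGB, basal area and stem density
    to cohorts at or above an inventory census floor (grasses never
    count as stems), matching how inventory-calibrated targets are
    defined; LAI always integrates all foliage.  The default 0 counts
    everything.
    """
    allom = allom or default_allometry()
    if area_m2 <= 0:
        raise ValueError("column area must be positive")
    cohorts = list(stack)
    if not cohorts:
        return PlotProperties.zeros()
    agb = ba = lai = dens = 0.0
    for c in cohorts:
        if c.density < 0:
            raise ValueError("cohort density must be >= 0")
        la_i, agb_i, ba_i = stem_properties(c.dbh, c.pft, allom)
        lai += c.density * la_i
        if c.dbh >= census_dbh_min and not allom[c.pft].is_grass:
            agb += c.density * agb_i
            ba += c.density * ba_i
            dens += c.density
    return PlotProperties(
        agb=agb, basal_area=ba, stem_density=dens * 1e4, lai=lai
    )
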