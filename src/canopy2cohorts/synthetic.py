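"""Synthetic stands, lidar point clouds and climate series.

Emulates the statistical structure of the pipeline's real inputs so that
every stage is testable without field campaigns: 0.25-ha stem lists
across disturbance classes, discrete-return point clouds meeting a
minimum return density, and monthly precipitation/potential-ET series
with wet/dry seasonality.

The lidar simulator is deliberately minimal: flat ground at z = 0,
vertically uniform cylindrical crowns, and Beer-Lambert thinning of each
vertical pulse through the leaf-area-density (LAD) column above it.  Per
height bin the interception probability is ``1 - exp(-k * LAD * dz)``;
a pulse with no interception anywhere produces a ground return, so the
expected ground-return fraction under a uniform canopy equals the
Beer-Lambert gap fraction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .allometry import (
    AllometrySet,
    PlotProperties,
    basal_area_cm2,
    default_allometry,
    agb_kg,
    height_from_dbh,
    leaf_area_m2,
)

__all__ = [
    "DisturbanceClass",
    "SyntheticStandConfig",
    "SyntheticScene",
    "generate_stand",
    "simulate_point_cloud",
    "generate_climate",
    "stand_lad_profile",
]


class DisturbanceClass(str, Enum):
    """Degradation-history vocabulary: intact, logged and burned classes."""

    INT = "INT"   # intact
    RIL = "RIL"   # reduced-impact logging
    CL1 = "CL1"   # conventional logging, once
    CL2 = "CL2"   # conventional logging, twice
    LTH = "LTH"   # logged and thinned
    LB1 = "LB1"   # logged and burned once
    BN1 = "BN1"   # burned once
    BN2 = "BN2"   # burned twice
    BN3 = "BN3"   # burned three times
    BN6 = "BN6"   # burned six times


@dataclass(frozen=True)
class SyntheticStandConfig:
    """Configuration of one synthetic stand.

    DBH values are drawn i.i.d. from a truncated power law (Pareto) with
    lower bound ``dbh_min`` (10 cm, the inventory census floor) and an
    upper cap; the exponent controls how heavy the large-tree tail is.
    ``pft_mixture`` gives the probability that a stem belongs to each
    functional type and must sum to 1.
    """

    region_label: str = "SYN"
    disturbance_class: DisturbanceClass = DisturbanceClass.INT
    plot_area: float = 2500.0            # m**2 (0.25 ha; a 50 x 50 m column)
    stem_density: float = 520.0          # stems ha**-1 with DBH >= 10 cm
    dbh_min: float = 10.0                # cm
    dbh_max: float = 120.0               # cm
    dbh_pareto_exponent: float = 2.6     # tail exponent of the DBH law
    pft_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"early": 0.25, "mid": 0.45, "late": 0.30}
    )
    crown_radius_intercept: float = 0.6  # m; crown radius = i + s * DBH
    crown_radius_slope: float = 0.065    # m per cm DBH
    crown_depth_fraction: float = 0.45   # crown depth as fraction of height
    rng_seed: int = 0

    def __post_init__(self):
        if self.plot_area <= 0:
            raise ValueError("plot_area must be positive")
        if self.stem_density < 0:
            raise ValueError("stem_density must be >= 0")
        if self.dbh_min < 10.0 - 1e-9:
            raise ValueError("DBH draws must be >= 10 cm (census floor)")
        total = sum(self.pft_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pft_mixture must sum to 1, got {total}")


@dataclass
class SyntheticScene:
    """A stand, its simulated point cloud, and the allometric truth."""

    stems: pd.DataFrame          # x, y, dbh_cm, height_m, crown_radius_m, crown_depth_m, pft
    point_cloud: pd.DataFrame    # x, y, z, return_number, is_ground
    truth: PlotProperties
    config: SyntheticStandConfig


def _draw_truncated_pareto(rng: np.random.Generator, n: int, lo: float,
                           hi: float, alpha: float) -> np.ndarray:
    """Inverse-CDF draw from a power law with density ~ x**-alpha on [lo, hi]."""
    u = rng.random(n)
    a = 1.0 - alpha
    # CDF of x**-alpha on [lo, hi]:  (x^a - lo^a) / (hi^a - lo^a)
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def generate_stand(config: SyntheticStandConfig,
                   allom: AllometrySet | None = None
                   ) -> tuple[pd.DataFrame, PlotProperties]:
    """Draw a stem list and compute its allometric truth.

    Stems are placed uniformly at random; heights and crown dimensions
    come from the allometry module.  Truth is the exact sum of per-stem
    allometric quantities over the plot area.  A zero stem density gives
    an empty stand with zeroed truth.
    """
    allom = allom or default_allometry()
    rng = np.random.default_rng(config.rng_seed)
    side = float(np.sqrt(config.plot_area))
    n = int(round(config.stem_density * config.plot_area / 1e4))
    if n == 0:
        stems = pd.DataFrame(
            columns=["x", "y", "dbh_cm", "height_m",
                     "crown_radius_m", "crown_depth_m", "pft"]
        )
        return stems, PlotProperties.zeros()

    dbh = _draw_truncated_pareto(
        rng, n, config.dbh_min, config.dbh_max, config.dbh_pareto_exponent
    )
    pft_names = list(config.pft_mixture)
    probs = np.array([config.pft_mixture[k] for k in pft_names])
    pfts = rng.choice(pft_names, size=n, p=probs / probs.sum())
    height = np.array([height_from_dbh(d, p, allom) for d, p in zip(dbh, pfts)])
    stems = pd.DataFrame(
        {
            "x": rng.uniform(0, side, n),
            "y": rng.uniform(0, side, n),
            "dbh_cm": dbh,
            "height_m": height,
            "crown_radius_m": config.crown_radius_intercept
            + config.crown_radius_slope * dbh,
            "crown_depth_m": config.crown_depth_fraction * height,
            "pft": pfts,
        }
    )
    truth = _stand_truth(stems, config.plot_area, allom)
    return stems, truth


def _stand_truth(stems: pd.DataFrame, area: float,
                 allom: AllometrySet) -> PlotProperties:
    agb = ba = lai = 0.0
    for row in stems.itertuples():
        agb += agb_kg(row.dbh_cm, row.pft, allom)
        ba += basal_area_cm2(row.dbh_cm)
        lai += leaf_area_m2(row.dbh_cm, row.pft, allom)
    return PlotProperties(
        agb=agb / area,
        basal_area=ba / area,
        stem_density=len(stems) / area * 1e4,
        lai=lai / area,
    )


def stand_lad_profile(stems: pd.DataFrame, area: float, dz: float = 1.0,
                      z_max: float = 80.0,
                      allom: AllometrySet | None = None) -> np.ndarray:
    """True plot-mean LAD profile (m**2 m**-3) of a stand.

    Each crown spreads its leaf area uniformly over its vertical depth;
    the plot-mean LAD in a bin is the leaf area the bin holds divided by
    (plot area * dz).
    """
    allom = allom or default_allometry()
    n_bins = int(np.ceil(z_max / dz))
    lad = np.zeros(n_bins)
    for row in stems.itertuples():
        la = leaf_area_m2(row.dbh_cm, row.pft, allom)
        top = row.height_m
        bot = max(0.0, top - row.crown_depth_m)
        if top <= bot:
            continue
        dens = la / (top - bot)  # m**2 leaf per m of depth
        for i in range(n_bins):
            lo, hi = i * dz, (i + 1) * dz
            overlap = max(0.0, min(hi, top) - max(lo, bot))
            lad[i] += dens * overlap
    return lad / (area * dz)


def simulate_point_cloud(stems: pd.DataFrame, plot_area: float,
                         pulse_density: float = 4.0, rng_seed: int = 0,
                         k: float = 0.5, dz: float = 1.0, z_max: float = 80.0,
                         max_returns: int = 4,
                         allom: AllometrySet | None = None) -> pd.DataFrame:
    """Simulate a discrete-return point cloud over a square stand.

    Pulses are stratified per 1 x 1 m cell (``ceil(pulse_density)`` per
    cell, jittered within the cell) so the configured minimum return
    density holds over every cell.  Each pulse descends through the LAD
    column above its position; per bin it is intercepted with
    probability ``1 - exp(-k * LAD_local * dz)`` where LAD_local sums
    the crown leaf-area densities covering that (x, y).  Intercepted
    bins (top-down, up to ``max_returns``) become canopy returns at a
    uniform height within the bin; a pulse never intercepted becomes a
    single ground return at z = 0.
    """
    if pulse_density <= 0:
        raise ValueError("pulse_density must be positive")
    allom = allom or default_allometry()
    rng = np.random.default_rng(rng_seed)
    side = float(np.sqrt(plot_area))
    n_cells = int(np.ceil(side))
    per_cell = int(np.ceil(pulse_density))

    # pulse positions: jittered per 1 m cell
    cx, cy = np.meshgrid(np.arange(n_cells), np.arange(n_cells))
    base = np.column_stack([cx.ravel(), cy.ravel()]).astype(float)
    base = np.repeat(base, per_cell, axis=0)
    pos = base + rng.random(base.shape)
    pos = np.clip(pos, 0, side - 1e-9)
    n_pulses = len(pos)

    n_bins = int(np.ceil(z_max / dz))
    lad = np.zeros((n_pulses, n_bins))
    if len(stems):
        crown_la = np.array(
            [leaf_area_m2(r.dbh_cm, r.pft, allom) for r in stems.itertuples()]
        )
        for (row, la) in zip(stems.itertuples(), crown_la):
            r2 = row.crown_radius_m**2
            cover = (pos[:, 0] - row.x) ** 2 + (pos[:, 1] - row.y) ** 2 <= r2
            if not cover.any():
                continue
            top = row.height_m
            bot = max(0.0, top - row.crown_depth_m)
            if top <= bot:
                continue
            vol_dens = la / (np.pi * r2 * (top - bot))  # LAD inside the cylinder
            i0, i1 = int(bot // dz), min(n_bins - 1, int(np.ceil(top / dz)) - 1)
            for i in range(i0, i1 + 1):
                lo, hi = i * dz, (i + 1) * dz
                frac = max(0.0, min(hi, top) - max(lo, bot)) / dz
                if frac > 0:
                    lad[cover, i] += vol_dens * frac

    p_int = 1.0 - np.exp(-k * lad * dz)
    hits = rng.random((n_pulses, n_bins)) < p_int

    # order bins top-down and keep at most max_returns per pulse
    order = np.arange(n_bins)[::-1]
    hits_td = hits[:, order]
    cum = np.cumsum(hits_td, axis=1)
    keep = hits_td & (cum <= max_returns)

    pulse_idx, bin_td = np.nonzero(keep)
    bin_idx = order[bin_td]
    z = (bin_idx + rng.random(len(bin_idx))) * dz
    rn = cum[pulse_idx, bin_td]

    recs = {
        "x": pos[pulse_idx, 0],
        "y": pos[pulse_idx, 1],
        "z": z,
        "return_number": rn.astype(int),
        "is_ground": np.zeros(len(bin_idx), dtype=bool),
    }
    cloud = pd.DataFrame(recs)

    no_hit = ~hits.any(axis=1)
    if no_hit.any():
        ground = pd.DataFrame(
            {
                "x": pos[no_hit, 0],
                "y": pos[no_hit, 1],
                "z": np.zeros(no_hit.sum()),
                "return_number": np.ones(no_hit.sum(), dtype=int),
                "is_ground": np.ones(no_hit.sum(), dtype=bool),
            }
        )
        cloud = pd.concat([cloud, ground], ignore_index=True)
    return cloud.sort_values(["x", "y", "z"], ignore_index=True)


def generate_scene(config: SyntheticStandConfig, pulse_density: float = 4.0,
                   k: float = 0.5,
                   allom: AllometrySet | None = None) -> SyntheticScene:
    """Convenience: stand + point cloud + truth in one call."""
    allom = allom or default_allometry()
    stems, truth = generate_stand(config, allom)
    cloud = simulate_point_cloud(
        stems, config.plot_area, pulse_density,
        rng_seed=config.rng_seed + 1, k=k, allom=allom,
    )
    return SyntheticScene(stems=stems, point_cloud=cloud, truth=truth,
                          config=config)


def _seasonal_precip_means(annual_peak: float, dry_trough: float,
                           dry_months: int,
                           peak_month: float = 0.3) -> np.ndarray:
    """12 monthly mean precipitation values (mm/mo) with an exact number
    of months below the 100 mm dry-season threshold in the noise-free mean.

    The cycle is sinusoidal between a trough and a peak; the fractional
    ``peak_month`` phase keeps all 12 monthly values distinct so any dry
    season length is reachable.  Trough and (if needed) peak are scanned
    until exactly ``dry_months`` months fall below 100 mm.
    """
    if dry_months == 0:
        return np.full(12, max(annual_peak, 101.0))
    if dry_months >= 12:
        return np.full(12, min(dry_trough, 99.0))
    m = np.arange(12)
    shape = 0.5 * (1.0 + np.cos(2 * np.pi * (m - peak_month) / 12.0))
    # prefer the requested trough, then sweep the full range; widen the
    # peak sweep only if no trough realizes the requested count
    trough_grid = np.concatenate([[min(dry_trough, 99.0)],
                                  np.linspace(99.0, 1.0, 99)])
    for peak in np.linspace(annual_peak, 105.0, 44):
        for trough in trough_grid:
            means = trough + (peak - trough) * shape
            if int((means < 100.0).sum()) == dry_months:
                return means
    raise ValueError(
        f"cannot realize a {dry_months}-month dry season with peak {annual_peak}"
    )


def generate_climate(months: int, mean_precip_peak: float = 320.0,
                     dry_trough: float = 40.0, dry_season_months: int = 5,
                     pet_mean: float = 110.0, pet_amplitude: float = 25.0,
                     noise_sigma: float = 0.25,
                     rng_seed: int = 0) -> pd.DataFrame:
    """Monthly precipitation and potential-ET series with seasonality.

    Precipitation is a sinusoidal annual cycle (calibrated so exactly
    ``dry_season_months`` months of the noise-free mean fall below the
    100 mm/mo dry-season threshold) times lognormal multiplicative
    noise; PET has a smaller, phase-opposed sinusoidal cycle.  Both are
    strictly non-negative.  At least 12 months are required, since the
    drought metrics use a trailing 12-month window.
    """
    if months < 12:
        raise ValueError("need at least 12 months (trailing-window metrics)")
    rng = np.random.default_rng(rng_seed)
    p_means = _seasonal_precip_means(mean_precip_peak, dry_trough,
                                     dry_season_months)
    m = np.arange(months)
    precip_mean = p_means[m % 12]
    if noise_sigma > 0:
        noise = rng.lognormal(mean=-0.5 * noise_sigma**2, sigma=noise_sigma,
                              size=months)
    else:
        noise = np.ones(months)
    precip = precip_mean * noise
    # PET peaks in the dry season (anti-phase with rain)
    pet = pet_mean - pet_amplitude * np.cos(2 * np.pi * (m % 12) / 12.0)
    pet = np.maximum(pet, 0.0)
    return pd.DataFrame(
        {
            "year": 1 + m // 12,
            "month": 1 + m % 12,
            "precip_mm": precip,
            "pet_mm": pet,
            "precip_mean_mm": precip_mean,
        }
    )
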