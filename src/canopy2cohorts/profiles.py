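"""Point clouds to canopy leaf-area-density profiles.

Implements the first stage of the initialization: split point clouds
into 50 x 50 m columns, synthesize a pseudo-waveform from the discrete
returns of each column, invert it into an unscaled leaf-area-density
(LAD) profile with the MacArthur-Horn method, and compute the scalar
point-cloud metrics used as regression predictors.

MacArthur-Horn inversion: let ``S_i`` be the pulse energy reaching the
top of height bin *i* (counting energy from the canopy top down).  The
apparent LAD of the bin is ``ln(S_i / S_(i+1)) / dz`` — the log of the
gap-fraction ratio across the bin.  The result is proportional to the
true LAD with an unknown multiplicative constant (the extinction
coefficient), which is exactly what the later scaling-factor stage
corrects for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PointCloudColumn",
    "PseudoWaveform",
    "CanopyProfile",
    "CloudMetrics",
    "grid_columns",
    "pseudo_waveform",
    "macarthur_horn",
    "cloud_metrics",
]

#: Heights are binned at 1 m up to this cap; matches the 1 m terrain grid.
DEFAULT_DZ = 1.0
DEFAULT_Z_MAX = 80.0
#: Returns below this height count as ground energy (terrain noise floor).
GROUND_SEPARATION = 0.5


@dataclass
class PointCloudColumn:
    """Points of one grid column, heights normalized above ground."""

    column_id: str
    x_range: tuple[float, float]   # half-open [min, max)
    y_range: tuple[float, float]
    points: pd.DataFrame           # x, y, z, return_number, is_ground
    usable: bool = True

    def __len__(self):
        return len(self.points)


@dataclass
class PseudoWaveform:
    """Vertical energy distribution synthesized from discrete returns."""

    edges: np.ndarray        # bin edges, m, uniform dz
    energy: np.ndarray       # per-bin energy, >= 0
    ground_energy: float

    @property
    def total_energy(self) -> float:
        return float(self.energy.sum() + self.ground_energy)

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class CanopyProfile:
    """Height-binned leaf-area density, unscaled until a factor is applied."""

    edges: np.ndarray
    lad: np.ndarray
    scaled: bool = False
    scale_factor: float = 1.0
    column_id: str = ""

    @property
    def dz(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def lai(self) -> float:
        """Vertical integral of LAD (units of LAI once scaled)."""
        return float(np.sum(self.lad) * self.dz)

    def rescaled(self, factor: float) -> "CanopyProfile":
        return CanopyProfile(
            edges=self.edges, lad=self.lad * factor, scaled=True,
            scale_factor=self.scale_factor * factor, column_id=self.column_id,
        )


@dataclass
class CloudMetrics:
    """Scalar per-column metrics used as regression predictors."""

    column_id: str
    n_points: int
    mean_height: float
    quantiles: dict[str, float] = field(default_factory=dict)  # p10..p95
    cover_above_2m: float = 0.0
    skewness: float = 0.0
    kurtosis: float = 0.0
    ground_fraction: float = 0.0
    valid: bool = True

    def as_dict(self) -> dict[str, float]:
        d = {"mean_height": self.mean_height,
             "cover_above_2m": self.cover_above_2m,
             "skewness": self.skewness, "kurtosis": self.kurtosis,
             "ground_fraction": self.ground_fraction}
        d.update(self.quantiles)
        return d


def normalize_heights(points: pd.DataFrame) -> pd.DataFrame:
    """Subtract the local ground level inferred from class-ground returns.

    Requires an ``is_ground`` column with at least one ground return;
    raises otherwise (heights cannot be normalized).
    """
    if "is_ground" not in points.columns or not points["is_ground"].any():
        raise ValueError(
            "point cloud has no ground classification and no pre-normalized "
            "heights; cannot normalize"
        )
    ground_z = points.loc[points["is_ground"], "z"].median()
    out = points.copy()
    out["z"] = out["z"] - ground_z
    return out


def grid_columns(points: pd.DataFrame, cell_size: float = 50.0,
                 origin: tuple[float, float] = (0.0, 0.0),
                 min_points: int = 10,
                 heights_normalized: bool = True) -> list[PointCloudColumn]:
    """Partition a point cloud into half-open square columns.

    Every point lands in exactly one column (``[min, max)`` convention:
    a point exactly on an interior boundary goes to the higher-index
    cell).  Columns with fewer than ``min_points`` points are flagged
    unusable but still returned, so point counts are conserved.
    """
    if not heights_normalized:
        points = normalize_heights(points)
    elif "is_ground" not in points.columns:
        if (points["z"] < -0.5).any():
            raise ValueError(
                "points below -0.5 m without ground classification: "
                "heights do not look normalized"
            )
    x0, y0 = origin
    ix = np.floor((points["x"].to_numpy() - x0) / cell_size).astype(int)
    iy = np.floor((points["y"].to_numpy() - y0) / cell_size).astype(int)
    columns = []
    df = points.assign(_ix=ix, _iy=iy)
    for (cx, cy), grp in df.groupby(["_ix", "_iy"], sort=True):
        col = PointCloudColumn(
            column_id=f"c{cx}_{cy}",
            x_range=(x0 + cx * cell_size, x0 + (cx + 1) * cell_size),
            y_range=(y0 + cy * cell_size, y0 + (cy + 1) * cell_size),
            points=grp.drop(columns=["_ix", "_iy"]).reset_index(drop=True),
            usable=len(grp) >= min_points,
        )
        columns.append(col)
    return columns


def _gaussian_kernel(sigma: float, dz: float) -> np.ndarray:
    """Unit-sum Gaussian kernel truncated at 3 sigma on the dz grid."""
    if sigma <= 0:
        return np.array([1.0])
    half = max(1, int(np.ceil(3.0 * sigma / dz)))
    x = np.arange(-half, half + 1) * dz
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def pseudo_waveform(column: PointCloudColumn, dz: float = DEFAULT_DZ,
                    sigma: float = 0.5, z_max: float = DEFAULT_Z_MAX,
                    ground_separation: float = GROUND_SEPARATION
                    ) -> PseudoWaveform:
    """Histogram a column's returns into height bins and smooth.

    Returns below ``ground_separation`` contribute to ground energy.
    The canopy histogram is convolved with a truncated Gaussian; mass
    smoothed below the lowest bin edge is folded into ground energy and
    mass above the cap into the top bin, so total energy is conserved to
    round-off.
    """
    if len(column) == 0:
        raise ValueError("cannot build a waveform from an empty column")
    z = column.points["z"].to_numpy(dtype=float)
    z = np.clip(z, 0.0, z_max - 1e-9)
    is_ground = z < ground_separation
    if "is_ground" in column.points.columns:
        is_ground = is_ground | column.points["is_ground"].to_numpy(dtype=bool)
    edges = np.arange(0.0, z_max + dz / 2, dz)
    hist, _ = np.histogram(z[~is_ground], bins=edges)
    energy = hist.astype(float)
    ground = float(is_ground.sum())

    kernel = _gaussian_kernel(sigma, dz)
    if len(kernel) > 1:
        half = (len(kernel) - 1) // 2
        full = np.convolve(energy, kernel, mode="full")
        below = full[:half].sum()      # smoothed below z = 0 -> ground
        core = full[half:half + len(energy)].copy()
        above = full[half + len(energy):].sum()
        core[-1] += above              # fold overflow into the cap bin
        ground += below
        energy = core
    return PseudoWaveform(edges=edges, energy=energy, ground_energy=ground)


def macarthur_horn(waveform: PseudoWaveform,
                   transmittance_floor: float = 0.01) -> CanopyProfile:
    """Invert a pseudo-waveform into an unscaled LAD profile.

    Works from the canopy top downward: the energy reaching the top of
    bin *i* is total energy minus everything returned from above, and
    the bin's apparent LAD is ``ln(S_above / S_below) / dz``.  When a
    column returns no ground energy the cumulative transmittance is
    floored at ``transmittance_floor`` so the log stays finite (total
    apparent attenuation is then capped at ``ln(1/floor)``).
    """
    total = waveform.total_energy
    if total <= 0:
        raise ValueError("waveform has zero total energy")
    dz = float(waveform.edges[1] - waveform.edges[0])
    n = len(waveform.energy)
    floor = transmittance_floor * total
    lad = np.zeros(n)
    s_above = total
    for i in range(n - 1, -1, -1):   # top bin is index n-1
        s_below = s_above - waveform.energy[i]
        s_below_eff = max(s_below, floor)
        s_above_eff = max(s_above, s_below_eff)
        if s_above_eff > 0 and s_below_eff > 0:
            lad[i] = np.log(s_above_eff / s_below_eff) / dz
        s_above = s_below
    lad = np.maximum(lad, 0.0)
    return CanopyProfile(edges=waveform.edges.copy(), lad=lad, scaled=False)


_QUANTILES = (10, 25, 50, 75, 90, 95)


def cloud_metrics(column: PointCloudColumn, min_points: int = 10,
                  cover_threshold: float = 2.0) -> CloudMetrics:
    """Deterministic scalar metrics of one column's height distribution.

    Quantiles use linear interpolation on the sorted canopy heights.
    Skewness/kurtosis of a degenerate (constant-height) column are 0 by
    convention.  Columns with too few points are flagged invalid.
    """
    n = len(column)
    if n < min_points:
        return CloudMetrics(column_id=column.column_id, n_points=n,
                            mean_height=np.nan, valid=False)
    z = column.points["z"].to_numpy(dtype=float)
    ground = z < GROUND_SEPARATION
    if "is_ground" in column.points.columns:
        ground = ground | column.points["is_ground"].to_numpy(dtype=bool)
    qs = {f"p{q}": float(np.percentile(z, q)) for q in _QUANTILES}
    with np.errstate(invalid="ignore"):
        skew = float(stats.skew(z)) if np.ptp(z) > 0 else 0.0
        kurt = float(stats.kurtosis(z)) if np.ptp(z) > 0 else 0.0
    return CloudMetrics(
        column_id=column.column_id,
        n_points=n,
        mean_height=float(z.mean()),
        quantiles=qs,
        cover_above_2m=float((z > cover_threshold).mean()),
        skewness=0.0 if np.isnan(skew) else skew,
        kurtosis=0.0 if np.isnan(kurt) else kurt,
        ground_fraction=float(ground.mean()),
    )


def metrics_table(columns: list[PointCloudColumn], **kwargs) -> pd.DataFrame:
    """CloudMetrics for many columns as one DataFrame (row per column)."""
    rows = []
    for col in columns:
        m = cloud_metrics(col, **kwargs)
        if not m.valid:
            continue
        row = {"column_id": m.column_id, "n_points": m.n_points}
        row.update(m.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
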