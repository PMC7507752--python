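"""Canopy profiles to model-ready cohort stacks.

The later stages of the initialization: attribute functional-type
mixtures by Kolmogorov-Smirnov matching of vertical profiles against a
training library, split each profile into cohort layers around its local
maxima, convert layers into cohorts with the allometry module, optimize
a plot-specific scaling factor against regression-predicted plot
properties, collapse the plot factors into one global median factor, and
group finished columns into (region x disturbance-class) ensembles with
equal patch weights — no averaging or sampling of individual columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .allometry import (
    AllometrySet,
    Cohort,
    CohortStack,
    PlotProperties,
    default_allometry,
    dbh_from_height,
    integrate_properties,
    leaf_area_m2,
    max_invertible_height,
)
from .profiles import CanopyProfile

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingPlot",
    "TrainingLibrary",
    "ProfileMatch",
    "CohortLayer",
    "ScalingResult",
    "Ensemble",
    "ks_statistic",
    "match_profile",
    "split_layers",
    "layers_to_cohorts",
    "fit_scaling_factor",
    "global_scaling",
    "build_ensembles",
]

#: Grasses only hold foliage below this height (m); seedling/fuel boundary.
GRASS_HEIGHT_LIMIT = 2.0


@dataclass(frozen=True)
class TrainingPlot:
    """One training plot: its lidar profile and inventory PFT mixture."""

    plot_id: str
    profile: CanopyProfile
    pft_mixture: dict[str, float]
    region: str = ""
    disturbance: str = ""

    def __post_init__(self):
        total = sum(self.pft_mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"pft_mixture must sum to 1, got {total}")


@dataclass
class TrainingLibrary:
    plots: list[TrainingPlot]

    def __len__(self):
        return len(self.plots)

    def __iter__(self):
        return iter(self.plots)


@dataclass(frozen=True)
class ProfileMatch:
    plot_id: str
    ks_statistic: float
    pft_mixture: dict[str, float]


@dataclass(frozen=True)
class CohortLayer:
    """A contiguous run of profile bins around one retained maximum."""

    bottom: int          # first bin index (inclusive)
    top: int             # last bin index (inclusive)
    peak_bin: int
    peak_height: float   # m, bin midpoint of the peak
    leaf_area: float     # m**2 within the column


@dataclass(frozen=True)
class ScalingResult:
    factor: float
    objective: float
    relative_errors: dict[str, float]


@dataclass
class Ensemble:
    region: str
    disturbance: str
    members: list[CohortStack]

    @property
    def weights(self) -> np.ndarray:
        n = len(self.members)
        return np.full(n, 1.0 / n)


def _profile_cdf(profile: CanopyProfile, edges: np.ndarray) -> np.ndarray:
    """Normalized cumulative leaf area from the ground up, at ``edges[1:]``."""
    total = profile.lad.sum() * profile.dz
    if total <= 0:
        raise ValueError("profile has zero total leaf area")
    own_cdf = np.concatenate([[0.0], np.cumsum(profile.lad) * profile.dz]) / total
    return np.interp(edges[1:], profile.edges, own_cdf)


def ks_statistic(profile_a: CanopyProfile, profile_b: CanopyProfile) -> float:
    """Kolmogorov-Smirnov distance between two vertical leaf-area CDFs.

    CDFs accumulate leaf area from the ground up; profiles on different
    grids are linearly resampled onto the union of their bin edges.
    """
    if np.array_equal(profile_a.edges, profile_b.edges):
        edges = profile_a.edges
    else:
        edges = np.union1d(profile_a.edges, profile_b.edges)
    cdf_a = _profile_cdf(profile_a, edges)
    cdf_b = _profile_cdf(profile_b, edges)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def match_profile(profile: CanopyProfile,
                  library: TrainingLibrary) -> ProfileMatch:
    """Best-matching training plot: smallest KS distance, ties to the
    lexicographically lowest plot id (deterministic)."""
    if len(library) == 0:
        raise ValueError("training library is empty")
    best: TrainingPlot | None = None
    best_d = np.inf
    # iterate in plot-id order so exact ties resolve to the lowest id
    for plot in sorted(library, key=lambda p: p.plot_id):
        d = ks_statistic(profile, plot.profile)
        if d < best_d:
            best, best_d = plot, d
    assert best is not None
    return ProfileMatch(plot_id=best.plot_id, ks_statistic=best_d,
                        pft_mixture=dict(best.pft_mixture))


def _local_maxima(lad: np.ndarray, lo: int, hi: int) -> list[int]:
    """Indices of local maxima in lad[lo..hi] (strict; plateau -> leftmost)."""
    peaks = []
    i = lo
    while i <= hi:
        j = i
        while j < hi and lad[j + 1] == lad[i]:
            j += 1
        left_ok = i == lo or lad[i - 1] < lad[i]
        right_ok = j == hi or lad[j + 1] < lad[i]
        if left_ok and right_ok and lad[i] > 0:
            peaks.append(i)   # leftmost bin of a plateau wins
        i = j + 1
    return peaks


def split_layers(profile: CanopyProfile,
                 prominence_fraction: float = 0.05,
                 max_layer_depth: float | None = None) -> list[CohortLayer]:
    """Split a profile into cohort layers centred on retained maxima.

    Local maxima (plateaus: leftmost bin) survive a prominence filter:
    a peak is retained while its LAD exceeds the higher of its flanking
    valleys by at least ``prominence_fraction`` of the profile maximum;
    the weakest failing peak is merged into its taller neighbour and the
    filter re-applied.  Layer boundaries sit at the minimum-LAD bin
    between consecutive retained maxima (the valley bin joins the upper
    layer).  Layers partition the occupied support exactly, so layer
    leaf areas sum to the profile total.  An all-zero profile yields an
    empty list.

    ``max_layer_depth`` (m) optionally subdivides layers thicker than a
    plausible single crown into equal slabs, treating the slab edges as
    saddle points: on broad plateaus and shoulders a single layer would
    collapse trees of many sizes onto one cohort diameter.  The default
    (None) keeps pure peak-based splitting.
    """
    lad = profile.lad
    occupied = np.nonzero(lad > 0)[0]
    if len(occupied) == 0:
        return []
    lo, hi = int(occupied[0]), int(occupied[-1])
    peaks = _local_maxima(lad, lo, hi)
    if not peaks:
        peaks = [lo + int(np.argmax(lad[lo:hi + 1]))]

    thresh = prominence_fraction * lad.max()
    while len(peaks) > 1:
        # flanking valleys between consecutive peaks
        valleys = [
            min(lad[peaks[i]:peaks[i + 1] + 1])
            for i in range(len(peaks) - 1)
        ]
        prominences = []
        for i, p in enumerate(peaks):
            left = valleys[i - 1] if i > 0 else 0.0
            right = valleys[i] if i < len(valleys) else 0.0
            prominences.append(lad[p] - max(left, right))
        worst = int(np.argmin(prominences))
        if prominences[worst] >= thresh:
            break
        peaks.pop(worst)

    boundaries = []
    for i in range(len(peaks) - 1):
        seg = lad[peaks[i]:peaks[i + 1] + 1]
        boundaries.append(peaks[i] + int(np.argmin(seg)))

    dz = profile.dz
    z_mid = profile.z_mid
    layers = []
    starts = [lo] + boundaries
    ends = [b - 1 for b in boundaries] + [hi]
    for start, end, peak in zip(starts, ends, peaks):
        segments = [(start, end, peak, float(z_mid[peak]))]
        if max_layer_depth is not None:
            depth_bins = max(1, int(round(max_layer_depth / dz)))
            n_here = end - start + 1
            if n_here > depth_bins:
                n_sub = int(np.ceil(n_here / depth_bins))
                cuts = np.linspace(start, end + 1, n_sub + 1).astype(int)
                segments = []
                for a, b in zip(cuts[:-1], cuts[1:]):
                    if b <= a or lad[a:b].sum() <= 0:
                        continue
                    sub_peak = a + int(np.argmax(lad[a:b]))
                    # a saddle-bounded slab has no meaningful peak; its
                    # centre is the LAD-weighted mean height
                    h_rep = float(np.average(z_mid[a:b], weights=lad[a:b]))
                    segments.append((a, b - 1, sub_peak, h_rep))
        for s0, s1, pk, h_rep in segments:
            la = float(lad[s0:s1 + 1].sum() * dz)
            if la <= 0:
                continue
            layers.append(CohortLayer(
                bottom=s0, top=s1, peak_bin=pk,
                peak_height=h_rep, leaf_area=la,
            ))
    return layers


def layers_to_cohorts(layers: list[CohortLayer],
                      pft_mixture: dict[str, float],
                      area_m2: float,
                      allom: AllometrySet | None = None,
                      crown_offset_fraction: float = 0.0,
                      column_id: str = "", region: str = "",
                      disturbance: str = "") -> CohortStack:
    """Turn cohort layers into a cohort stack under a PFT mixture.

    Per layer and per functional type with positive mixture share: the
    cohort height is the layer's peak height, DBH inverts the height
    law, and stem density makes the cohort carry exactly its share of
    the layer leaf area.  Two rules modify shares per layer: grasses
    only take mass below the 2 m seedling boundary (their share is
    redistributed to trees above it), and a type whose height law
    saturates below the layer height passes its share to the tallest
    feasible type (logged).

    ``crown_offset_fraction`` corrects the leaf-height to tree-height
    inversion: the lidar profile measures where leaves sit, and a
    crown's leaf-area centroid lies below the tree top by roughly half
    the relative crown depth, so the cohort height is
    ``peak_height / (1 - crown_offset_fraction)``.  The default 0 keeps
    the identity mapping (cohort height = layer peak height).

    Layer leaf areas here are per unit column area times ``area_m2``;
    cohort LAI contributions therefore sum to the profile LAI exactly.
    """
    allom = allom or default_allometry()
    if not (0.0 <= crown_offset_fraction < 1.0):
        raise ValueError("crown_offset_fraction must be in [0, 1)")
    if not layers:
        return CohortStack([], column_id=column_id, region=region,
                           disturbance=disturbance)
    cohorts: list[Cohort] = []
    for li, layer in enumerate(layers):
        h = layer.peak_height / (1.0 - crown_offset_fraction)
        shares = {p: s for p, s in pft_mixture.items() if s > 0}
        # grasses hold no mass above the seedling boundary
        if h >= GRASS_HEIGHT_LIMIT:
            grass = [p for p in shares if allom[p].is_grass]
            moved = sum(shares.pop(p) for p in grass)
            if moved > 0:
                trees = {p: s for p, s in shares.items()}
                if not trees:
                    raise ValueError(
                        f"layer at {h:.1f} m has only grass in the mixture"
                    )
                tot = sum(trees.values())
                for p in trees:
                    shares[p] += moved * trees[p] / tot
        # reassign shares whose height law cannot reach this layer
        feasible = {p: s for p, s in shares.items()
                    if h < max_invertible_height(p, allom)}
        if not feasible:
            # layer taller than every type: cap at the tallest type's limit
            tallest = max(shares, key=lambda p: allom[p].h_max)
            h = max_invertible_height(tallest, allom) - 1e-9
            feasible = {tallest: 1.0}
            logger.info(
                "layer %d above all height laws; capped at %.1f m (%r)",
                li, h, tallest,
            )
        lost = 1.0 - sum(feasible.values()) / sum(shares.values())
        if len(feasible) < len(shares):
            tallest = max(feasible, key=lambda p: allom[p].h_max)
            moved = sum(s for p, s in shares.items() if p not in feasible)
            feasible[tallest] += moved
            logger.info(
                "layer %d at %.1f m: reassigned share %.3f to %r "
                "(height above other types' h_max)", li, h, moved, tallest,
            )
        del lost
        norm = sum(feasible.values())
        for pft, share in sorted(feasible.items()):
            la = layer.leaf_area * share / norm
            if la <= 0:
                continue
            dbh = dbh_from_height(h, pft, allom)
            l_i = leaf_area_m2(dbh, pft, allom)
            density = la / l_i / area_m2
            cohorts.append(Cohort(dbh=dbh, height=h, pft=pft,
                                  density=density, lai=la / area_m2))
    return CohortStack(cohorts, column_id=column_id, region=region,
                       disturbance=disturbance)


#: Properties entering the scaling objective (configurable subset).
SCALING_PROPERTIES = ("agb", "basal_area", "stem_density", "lai")


def profile_to_stack(profile: CanopyProfile, pft_mixture: dict[str, float],
                     area_m2: float, allom: AllometrySet | None = None,
                     prominence_fraction: float = 0.05,
                     max_layer_depth: float | None = None,
                     crown_offset_fraction: float = 0.0,
                     **stack_meta) -> CohortStack:
    """Full profile -> layers -> cohorts conversion for one column."""
    layers = split_layers(profile, prominence_fraction, max_layer_depth)
    # layers carry leaf area per column: lad integral * area
    layers = [
        CohortLayer(l.bottom, l.top, l.peak_bin, l.peak_height,
                    l.leaf_area * area_m2)
        for l in layers
    ]
    return layers_to_cohorts(layers, pft_mixture, area_m2, allom,
                             crown_offset_fraction, **stack_meta)


def fit_scaling_factor(profile: CanopyProfile,
                       pft_mixture: dict[str, float],
                       target: PlotProperties,
                       area_m2: float,
                       bounds: tuple[float, float] = (0.05, 20.0),
                       allom: AllometrySet | None = None,
                       properties: tuple[str, ...] = SCALING_PROPERTIES,
                       prominence_fraction: float = 0.05,
                       max_layer_depth: float | None = None,
                       crown_offset_fraction: float = 0.0,
                       census_dbh_min: float = 0.0) -> ScalingResult:
    """Plot-specific profile scaling factor.

    Minimizes the sum of squared relative differences between the four
    plot properties derived from the s-scaled profile and the regression
    targets, over s in ``bounds``.  Each objective evaluation re-derives
    the cohorts from the scaled profile.  A coarse log-spaced grid
    brackets the optimum before bounded Brent refinement (tolerance 1e-4
    in s), which also guards against multimodality from layer-splitting
    edge cases.
    """
    allom = allom or default_allometry()
    tvals = {k: getattr(target, k) for k in properties}
    if any(v <= 0 for v in tvals.values()):
        raise ValueError("all target properties must be positive")

    def objective(s: float) -> float:
        stack = profile_to_stack(profile.rescaled(s), pft_mixture, area_m2,
                                 allom, prominence_fraction, max_layer_depth,
                                 crown_offset_fraction)
        props = integrate_properties(stack, area_m2, allom, census_dbh_min)
        return float(sum(
            ((getattr(props, k) - tvals[k]) / tvals[k]) ** 2
            for k in properties
        ))

    grid = np.geomspace(bounds[0], bounds[1], 40)
    vals = np.array([objective(s) for s in grid])
    if not np.isfinite(vals).any():
        raise ValueError("scaling objective non-finite over the whole bracket")
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    s_best, f_best = float(res.x), float(res.fun)
    if vals[i] < f_best:      # keep the grid point if refinement regressed
        s_best, f_best = float(grid[i]), float(vals[i])

    stack = profile_to_stack(profile.rescaled(s_best), pft_mixture, area_m2,
                             allom, prominence_fraction, max_layer_depth,
                             crown_offset_fraction)
    props = integrate_properties(stack, area_m2, allom, census_dbh_min)
    rel = {k: (getattr(props, k) - tvals[k]) / tvals[k] for k in properties}
    return ScalingResult(factor=s_best, objective=f_best, relative_errors=rel)


def global_scaling(factors: list[float]) -> float:
    """Median of the plot-specific factors (even count: mean of the
    central pair); applied uniformly to all predicted profiles."""
    if not factors:
        raise ValueError("no scaling factors to aggregate")
    return float(np.median(factors))


def build_ensembles(stacks: list[CohortStack]) -> list[Ensemble]:
    """Group cohort stacks into (region, disturbance-class) ensembles.

    Every member keeps its full structure with equal patch weight
    ``1/N``; the ensemble represents the observed distribution of
    forest structures within the group.
    """
    groups: dict[tuple[str, str], list[CohortStack]] = {}
    for s in stacks:
        groups.setdefault((s.region, s.disturbance), []).append(s)
    return [
        Ensemble(region=r, disturbance=d, members=members)
        for (r, d), members in sorted(groups.items())
    ]
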