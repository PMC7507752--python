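"""End-to-end wiring: synthetic scenes -> profiles -> models -> cohorts.

Composes the stage modules into the full initialization:

1. grid the point cloud into 50 x 50 m columns, build pseudo-waveforms
   and unscaled LAD profiles, attribute a PFT mixture by KS matching
   against the training library;
2. predict the four plot properties from point-cloud metrics with the
   calibrated regression models;
3. optimize the plot-specific profile scaling factor against those
   targets;
4. take the median factor over all plots as the global factor, rescale
   every profile, and emit cohort stacks grouped into ensembles.

These helpers also provide the calibrate/predict callables used by the
cross-validation harness, and a synthetic training-set builder so the
whole chain runs without field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .allometry import (AllometrySet, CohortStack, PlotProperties,
                        default_allometry, integrate_properties)
from .cohorts import (TrainingLibrary, TrainingPlot, build_ensembles,
                      fit_scaling_factor, global_scaling, match_profile,
                      profile_to_stack)
from .plot_models import PropertyModel, fit_all_property_models
from .profiles import (CanopyProfile, PointCloudColumn, cloud_metrics,
                       macarthur_horn, pseudo_waveform)

__all__ = ["PipelineConfig", "column_profile", "build_training_set",
           "initialize_columns", "InitializationResult"]


@dataclass
class PipelineConfig:
    cell_size: float = 50.0
    dz: float = 1.0
    sigma: float = 0.5
    z_max: float = 80.0
    pulse_density: float = 4.0
    extinction_k: float = 0.5
    scaling_bounds: tuple[float, float] = (0.05, 20.0)
    prominence_fraction: float = 0.05
    #: subdivide layers thicker than a single crown (saddle handling)
    max_layer_depth: float | None = 5.0
    #: leaf-centroid-to-tree-top correction in the height inversion
    crown_offset_fraction: float = 0.2
    #: inventory census floor (cm) for AGB/BA/stem-density integration
    census_dbh_min: float = 10.0
    max_predictors: int = 2
    allometry: AllometrySet = field(default_factory=default_allometry)


def column_profile(column: PointCloudColumn,
                   cfg: PipelineConfig) -> CanopyProfile:
    """Pseudo-waveform + MacArthur-Horn profile for one column."""
    wf = pseudo_waveform(column, dz=cfg.dz, sigma=cfg.sigma, z_max=cfg.z_max)
    prof = macarthur_horn(wf)
    prof.column_id = column.column_id
    return prof


@dataclass
class TrainingSet:
    """Synthetic calibration data: metrics table + profile library."""

    table: pd.DataFrame               # metrics + four properties per plot
    library: TrainingLibrary
    truths: dict[str, PlotProperties]
    stands: dict[str, pd.DataFrame]


def _scene_to_column(scene, cfg: PipelineConfig,
                     column_id: str) -> PointCloudColumn:
    side = float(np.sqrt(scene.config.plot_area))
    return PointCloudColumn(
        column_id=column_id, x_range=(0.0, side), y_range=(0.0, side),
        points=scene.point_cloud,
    )


def build_training_set(n_plots: int, seed: int = 0,
                       cfg: PipelineConfig | None = None,
                       density_range: tuple[float, float] = (220.0, 750.0),
                       ) -> TrainingSet:
    """Simulate a library of training plots spanning a density gradient.

    Each plot is one 0.25-ha synthetic stand with its own stem density,
    DBH-tail exponent and PFT mixture, surveyed by the lidar simulator;
    the truth comes from the stand's allometric sums, the profile and
    metrics from its simulated point cloud.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    rows, plots, truths, stands = [], [], {}, {}
    for i in range(n_plots):
        dens = rng.uniform(*density_range)
        alpha = rng.uniform(2.2, 3.2)
        w = rng.dirichlet([2.0, 3.0, 2.5])
        mixture = {"early": w[0], "mid": w[1], "late": w[2]}
        config = synthetic.SyntheticStandConfig(
            stem_density=dens, dbh_pareto_exponent=alpha,
            pft_mixture=mixture,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene = synthetic.generate_scene(config, cfg.pulse_density,
                                         k=cfg.extinction_k,
                                         allom=cfg.allometry)
        pid = f"t{i:04d}"
        col = _scene_to_column(scene, cfg, pid)
        prof = column_profile(col, cfg)
        m = cloud_metrics(col)
        if not m.valid:
            continue
        row = {"plot_id": pid}
        row.update(m.as_dict())
        row.update(scene.truth.as_dict())
        rows.append(row)
        plots.append(TrainingPlot(plot_id=pid, profile=prof,
                                  pft_mixture=mixture))
        truths[pid] = scene.truth
        stands[pid] = scene.stems
    return TrainingSet(table=pd.DataFrame(rows),
                       library=TrainingLibrary(plots), truths=truths,
                       stands=stands)


@dataclass
class InitializationResult:
    stacks: list[CohortStack]
    ensembles: list
    global_factor: float
    plot_factors: dict[str, float]
    matches: dict[str, str]
    predicted: dict[str, PlotProperties]
    profiles: dict[str, CanopyProfile]


def initialize_columns(columns: list[PointCloudColumn],
                       models: dict[str, PropertyModel],
                       library: TrainingLibrary,
                       cfg: PipelineConfig | None = None,
                       region: str = "SYN",
                       disturbance: str = "INT") -> InitializationResult:
    """Run steps 1, 3 and 4 for a batch of columns.

    Per column: profile + KS-matched mixture, regression targets from
    the metrics, plot scaling factor; then the median factor rescales
    every profile and the finished stacks are grouped into ensembles.
    """
    cfg = cfg or PipelineConfig()
    area = cfg.cell_size**2
    profiles, mixtures, targets, factors, matches = {}, {}, {}, {}, {}
    for col in columns:
        if not col.usable:
            continue
        prof = column_profile(col, cfg)
        m = cloud_metrics(col)
        if not m.valid or prof.lai <= 0:
            continue
        match = match_profile(prof, library)
        preds = {k: mod.predict(m.as_dict())[0] for k, mod in models.items()}
        target = PlotProperties(**preds)
        res = fit_scaling_factor(
            prof, match.pft_mixture, target, area,
            bounds=cfg.scaling_bounds, allom=cfg.allometry,
            prominence_fraction=cfg.prominence_fraction,
            max_layer_depth=cfg.max_layer_depth,
            crown_offset_fraction=cfg.crown_offset_fraction,
            census_dbh_min=cfg.census_dbh_min,
        )
        profiles[col.column_id] = prof
        mixtures[col.column_id] = match.pft_mixture
        targets[col.column_id] = target
        factors[col.column_id] = res.factor
        matches[col.column_id] = match.plot_id

    if not factors:
        raise ValueError("no usable column produced a scaling factor")
    g = global_scaling(list(factors.values()))
    stacks = []
    for cid, prof in profiles.items():
        stack = profile_to_stack(
            prof.rescaled(g), mixtures[cid], area, cfg.allometry,
            cfg.prominence_fraction, cfg.max_layer_depth,
            cfg.crown_offset_fraction, column_id=cid, region=region,
            disturbance=disturbance,
        )
        stacks.append(stack)
    return InitializationResult(
        stacks=stacks, ensembles=build_ensembles(stacks), global_factor=g,
        plot_factors=factors, matches=matches, predicted=targets,
        profiles=profiles,
    )


def recover_synthetic_stands(n_stands: int = 30, n_training: int = 60,
                             seed: int = 0,
                             cfg: PipelineConfig | None = None,
                             return_result: bool = False):
    """Full synthetic round trip: truth vs recovered plot properties.

    Builds a training set, calibrates the regression models, generates
    ``n_stands`` fresh test stands, initializes them, and returns a
    table with the true and recovered total basal area (and the other
    three properties) per stand.  With ``return_result`` the
    InitializationResult (stacks, ensembles, factors) is returned too.
    """
    cfg = cfg or PipelineConfig()
    train = build_training_set(n_training, seed=seed, cfg=cfg)
    models = fit_all_property_models(train.table,
                                     max_predictors=cfg.max_predictors)
    rng = np.random.default_rng(seed + 1)
    rows = []
    columns, truths = [], {}
    for i in range(n_stands):
        config = synthetic.SyntheticStandConfig(
            stem_density=rng.uniform(220.0, 750.0),
            dbh_pareto_exponent=rng.uniform(2.2, 3.2),
            pft_mixture=dict(zip(("early", "mid", "late"),
                                 rng.dirichlet([2.0, 3.0, 2.5]))),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene = synthetic.generate_scene(config, cfg.pulse_density,
                                         k=cfg.extinction_k,
                                         allom=cfg.allometry)
        cid = f"s{i:04d}"
        columns.append(_scene_to_column(scene, cfg, cid))
        truths[cid] = scene.truth
    result = initialize_columns(columns, models, train.library, cfg)
    area = cfg.cell_size**2
    for stack in result.stacks:
        props = integrate_properties(stack, area, cfg.allometry,
                                     cfg.census_dbh_min)
        truth = truths[stack.column_id]
        rows.append({
            "column_id": stack.column_id,
            "ba_true": truth.basal_area, "ba_pred": props.basal_area,
            "agb_true": truth.agb, "agb_pred": props.agb,
            "lai_true": truth.lai, "lai_pred": props.lai,
            "dens_true": truth.stem_density, "dens_pred": props.stem_density,
            "scale_factor": result.plot_factors[stack.column_id],
            "global_factor": result.global_factor,
        })
    df = pd.DataFrame(rows)
    return (df, result) if return_result else df
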