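"""Hierarchical-bootstrap cross-validation and DBH-class evaluation.

Assesses the transferability of the initialization: regions are sampled
with replacement (so whole regions can drop out of a replicate), then
plots are sampled with replacement from the retained regions up to the
original training size.  Replicates that exclude a target region
calibrate the pipeline without any of its plots and predict them
out-of-region; the number of usable replicates is truncated to the
common minimum across regions so comparisons are balanced.  Predictions
are evaluated as basal area by DBH class (bias and RMSE), and a group
is only reported when it has at least 20 plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapPlan",
    "hierarchical_bootstrap",
    "out_of_region_predict",
    "evaluate_by_dbh_class",
    "region_exclusion_frequency",
    "DEFAULT_DBH_CLASSES",
]

#: Default DBH class edges (cm); last class is open-ended.
DEFAULT_DBH_CLASSES = ((10.0, 20.0), (20.0, 40.0), (40.0, 60.0),
                       (60.0, 100.0), (100.0, np.inf))

MIN_PLOTS_PER_GROUP = 20


@dataclass
class BootstrapPlan:
    """Resampling plan: per replicate, the drawn regions and plot ids."""

    replicates: list[dict]      # {"regions": [...], "plots": [...]}
    rng_seed: int
    n_replicates: int

    def excluding(self, region: str) -> list[int]:
        """Indices of replicates whose region draw excluded ``region``."""
        return [i for i, rep in enumerate(self.replicates)
                if region not in rep["regions"]]


def hierarchical_bootstrap(region_plots: Mapping[str, Sequence[str]],
                           n_replicates: int = 200,
                           seed: int = 0) -> BootstrapPlan:
    """Draw a two-level bootstrap plan over regions then plots.

    Each replicate draws R regions with replacement from the R unique
    regions, pools the plots of the drawn regions (with multiplicity),
    and draws plots with replacement from the pool until the replicate
    holds as many plots as the original training set.
    """
    regions = sorted(region_plots)
    if not regions or all(len(v) == 0 for v in region_plots.values()):
        raise ValueError("no regions/plots to resample")
    n_total = sum(len(v) for v in region_plots.values())
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        drawn = list(rng.choice(regions, size=len(regions), replace=True))
        pool = [p for r in drawn for p in region_plots[r]]
        plots = list(rng.choice(pool, size=n_total, replace=True))
        reps.append({"regions": drawn, "plots": plots})
    return BootstrapPlan(replicates=reps, rng_seed=seed,
                         n_replicates=n_replicates)


def region_exclusion_frequency(plan: BootstrapPlan, region: str) -> float:
    """Fraction of replicates that excluded a region entirely."""
    return len(plan.excluding(region)) / plan.n_replicates


def out_of_region_predict(
    plan: BootstrapPlan,
    region_plots: Mapping[str, Sequence[str]],
    target_region: str,
    calibrate: Callable[[list[str]], object],
    predict: Callable[[object, str], dict],
    max_replicates: int | None = None,
) -> pd.DataFrame:
    """Predict a held-out region from replicates that excluded it.

    ``calibrate(plot_ids) -> model`` fits the pipeline on a replicate's
    training plots; ``predict(model, plot_id) -> dict`` predicts one
    held-out plot.  The number of replicates used is the common minimum
    of qualifying replicates across all regions (so every region is
    predicted from equally many replicates), further capped by
    ``max_replicates``.  A leakage assertion guarantees no held-out plot
    ever enters a calibration set.
    """
    if target_region not in region_plots:
        raise ValueError(f"unknown region {target_region!r}")
    counts = {r: len(plan.excluding(r)) for r in region_plots}
    n_common = min(counts.values())
    if max_replicates is not None:
        n_common = min(n_common, max_replicates)
    idx = plan.excluding(target_region)
    if not idx:
        raise ValueError(
            f"no replicate excluded region {target_region!r}; "
            "increase n_replicates"
        )
    idx = idx[:n_common]
    held_out = set(region_plots[target_region])
    rows = []
    for i in idx:
        train = [p for p in plan.replicates[i]["plots"] if p not in held_out]
        # the region draw already excluded the target; assert no leakage
        assert not (set(plan.replicates[i]["plots"]) & held_out), \
            "held-out plots leaked into a calibration replicate"
        model = calibrate(train)
        for plot_id in region_plots[target_region]:
            rec = {"replicate": i, "plot_id": plot_id,
                   "region": target_region}
            rec.update(predict(model, plot_id))
            rows.append(rec)
    return pd.DataFrame(rows)


def _ba_by_class(stems: pd.DataFrame,
                 classes: Sequence[tuple[float, float]],
                 area_m2: float) -> np.ndarray:
    """Basal area (cm^2 m^-2) per DBH class from a stem table."""
    out = np.zeros(len(classes))
    dbh = stems["dbh_cm"].to_numpy(dtype=float)
    ba = np.pi * (dbh / 2.0) ** 2
    for i, (lo, hi) in enumerate(classes):
        sel = (dbh >= lo) & (dbh < hi)
        out[i] = ba[sel].sum() / area_m2
    return out


def cohort_ba_by_class(stack, classes: Sequence[tuple[float, float]]
                       ) -> np.ndarray:
    """Basal area (cm^2 m^-2) per DBH class from a cohort stack."""
    out = np.zeros(len(classes))
    for c in stack:
        ba = np.pi * (c.dbh / 2.0) ** 2 * c.density
        for i, (lo, hi) in enumerate(classes):
            if lo <= c.dbh < hi:
                out[i] += ba
                break
    return out


def evaluate_by_dbh_class(
    predicted: Mapping[str, np.ndarray],
    observed: Mapping[str, np.ndarray],
    classes: Sequence[tuple[float, float]] = DEFAULT_DBH_CLASSES,
    min_plots: int = MIN_PLOTS_PER_GROUP,
) -> pd.DataFrame:
    """Bias and RMSE of basal area by DBH class over matched plots.

    ``predicted`` and ``observed`` map plot id -> per-class basal-area
    vectors (cm^2 m^-2).  Groups (here: the whole matched set) with
    fewer than ``min_plots`` plots are excluded from the report;
    bias = mean(pred - obs), RMSE over plots, plus relative versions
    against the mean observation.
    """
    ids = sorted(set(predicted) & set(observed))
    if not ids:
        raise ValueError("no matched plot ids between prediction and truth")
    rows = []
    eligible = len(ids) >= min_plots
    for ci, (lo, hi) in enumerate(classes):
        pred = np.array([predicted[p][ci] for p in ids])
        obs = np.array([observed[p][ci] for p in ids])
        diff = pred - obs
        bias = float(diff.mean())
        rmse = float(np.sqrt(np.mean(diff**2)))
        denom = float(obs.mean())
        rows.append({
            "dbh_lo": lo, "dbh_hi": hi, "n_plots": len(ids),
            "bias": bias, "rmse": rmse,
            "rel_bias": bias / denom if denom > 0 else np.nan,
            "rel_rmse": rmse / denom if denom > 0 else np.nan,
            "eligible": eligible,
        })
    report = pd.DataFrame(rows)
    return report[report["eligible"]].reset_index(drop=True)
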