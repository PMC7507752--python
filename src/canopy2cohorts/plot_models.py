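"""Plot-property regression: subset selection with heteroskedastic errors.

Calibrates statistical models that predict the four plot-level
properties (AGB, basal area, stem density, LAI) from point-cloud
metrics.  The model family is a power law with multiplicative error,

    y = k * prod_j x_j^(a_j) * eps,

fitted on the log scale under a lognormal error whose log-sd varies
with the predicted magnitude: ``sd(ln y) = sigma0 * mu^(c - 1)``, so the
sd of y itself scales approximately as ``sigma0 * mu^c``.  The
heteroskedasticity exponent c is profiled on a fixed grid, predictor
subsets of size <= p are searched exhaustively, and the winner is the
candidate with the smallest BIC.  Fitting is deterministic given the
data (iteratively reweighted least squares on the log scale).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PropertyModel", "fit_property_model", "predict_property",
           "fit_all_property_models", "predict_properties",
           "save_models", "load_models"]

#: Heteroskedasticity exponents profiled during fitting.
C_GRID = tuple(np.arange(0.0, 2.0 + 1e-9, 0.25))

PROPERTY_NAMES = ("agb", "basal_area", "stem_density", "lai")


@dataclass
class PropertyModel:
    """A fitted power-law model for one plot property."""

    response: str
    predictors: list[str]
    intercept: float                       # k
    exponents: dict[str, float]            # a_j per predictor
    sigma0: float
    c: float                               # sd(y) ~ sigma0 * mu^c
    log_likelihood: float
    bic: float
    n: int
    #: training support per predictor; predictions clip into it, since a
    #: power law has no business extrapolating (and a zero metric under a
    #: negative exponent would blow up)
    ranges: dict[str, tuple[float, float]] | None = None

    def _clip(self, p: str, x):
        if self.ranges and p in self.ranges:
            lo, hi = self.ranges[p]
            return np.clip(x, lo, hi)
        return x

    def mu(self, metrics: dict[str, float] | pd.DataFrame) -> float | np.ndarray:
        """Median prediction k * prod x^a (before bias correction)."""
        if isinstance(metrics, pd.DataFrame):
            out = np.full(len(metrics), self.intercept)
            for p in self.predictors:
                out = out * self._clip(
                    p, metrics[p].to_numpy()) ** self.exponents[p]
            return out
        missing = [p for p in self.predictors if p not in metrics]
        if missing:
            raise KeyError(f"missing metric(s) for {self.response}: {missing}")
        out = self.intercept
        for p in self.predictors:
            out *= float(self._clip(p, metrics[p])) ** self.exponents[p]
        return out

    def predict(self, metrics) -> tuple[float | np.ndarray, float | np.ndarray]:
        """(mean prediction, heteroskedastic sd).

        The lognormal bias-correction factor exp(s^2/2), with
        ``s = sigma0 * mu^(c-1)`` the local log-sd, shifts the median
        prediction to the conditional mean.  sd is ``sigma0 * mu^c``.
        """
        mu = self.mu(metrics)
        s = self.sigma0 * np.asarray(mu) ** (self.c - 1.0)
        mean = mu * np.exp(0.5 * s**2)
        sd = self.sigma0 * np.asarray(mu) ** self.c
        if np.ndim(mean) == 0:
            return float(mean), float(sd)
        return mean, sd

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": self.predictors,
            "intercept": self.intercept,
            "exponents": self.exponents,
            "sigma0": self.sigma0,
            "c": self.c,
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n": self.n,
            "ranges": {k: list(v) for k, v in (self.ranges or {}).items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PropertyModel":
        d = dict(d)
        d["ranges"] = {k: tuple(v) for k, v in (d.get("ranges") or {}).items()}
        return cls(**d)


def _fit_subset(ln_y: np.ndarray, ln_x: np.ndarray, c: float,
                n_irls: int = 8) -> tuple[np.ndarray, float, float]:
    """ML fit of (ln k, a, sigma0) for one subset and c, via IRLS.

    With log-sd ``s_i = sigma0 * mu_i^(c-1)`` the weighted-LS weights
    are ``mu_i^(2(1-c))`` (sigma0 factors out of the normal equations).
    Returns (coefficients incl. intercept first, sigma0, log-likelihood).
    """
    n = len(ln_y)
    X = np.column_stack([np.ones(n), ln_x])
    beta, *_ = np.linalg.lstsq(X, ln_y, rcond=None)
    for _ in range(n_irls if c != 1.0 else 1):
        ln_mu = X @ beta
        w = np.exp(2.0 * (1.0 - c) * ln_mu)
        w = w / w.mean()
        Xw = X * np.sqrt(w)[:, None]
        beta_new, *_ = np.linalg.lstsq(Xw, ln_y * np.sqrt(w), rcond=None)
        if np.allclose(beta_new, beta, rtol=0, atol=1e-12):
            beta = beta_new
            break
        beta = beta_new
    ln_mu = X @ beta
    r = ln_y - ln_mu
    mu_pow = np.exp((c - 1.0) * ln_mu)
    sigma0_sq = float(np.mean((r / mu_pow) ** 2))
    sigma0 = float(np.sqrt(max(sigma0_sq, 1e-300)))
    s_i = sigma0 * mu_pow
    loglik = float(
        -0.5 * n * np.log(2 * np.pi)
        - np.sum(np.log(s_i))
        - 0.5 * np.sum((r / s_i) ** 2)
        # Jacobian of y -> ln y (density of y itself):
        - np.sum(ln_y)
    )
    return beta, sigma0, loglik


def fit_property_model(table: pd.DataFrame, response: str,
                       metric_columns: list[str] | None = None,
                       max_predictors: int = 3,
                       c_grid: tuple[float, ...] = C_GRID,
                       min_plots: int = 20) -> PropertyModel:
    """Fit the best power-law model for one property by subset selection.

    Exhaustively searches predictor subsets of size 1..max_predictors
    over the metric pool; for each subset the heteroskedasticity
    exponent c is profiled on ``c_grid``; the candidate with minimal BIC
    wins.  Constant or collinear predictors are dropped with a warning.
    Requires at least ``min_plots`` plots, all metrics and responses
    strictly positive.
    """
    if metric_columns is None:
        metric_columns = [c for c in table.columns
                          if c not in PROPERTY_NAMES
                          and c not in ("plot_id", "column_id", "n_points")]
    n = len(table)
    if n < min_plots:
        raise ValueError(f"need >= {min_plots} plots, got {n}")
    y = table[response].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError(f"response {response!r} must be strictly positive")

    usable = []
    for m in metric_columns:
        x = table[m].to_numpy(dtype=float)
        if np.any(x <= 0):
            logger.warning("dropping metric %r: non-positive values", m)
            continue
        if np.ptp(np.log(x)) < 1e-12:
            logger.warning("dropping metric %r: constant", m)
            continue
        usable.append(m)
    if not usable:
        raise ValueError("no usable (positive, non-constant) metrics")

    ln_y = np.log(y)
    ln_X = {m: np.log(table[m].to_numpy(dtype=float)) for m in usable}

    best = None
    for size in range(1, max_predictors + 1):
        for subset in itertools.combinations(usable, size):
            if n < size + 4:   # parameters + 2 rule (k, a_j, sigma0, c)
                continue
            mat = np.column_stack([ln_X[m] for m in subset])
            # collinearity guard within the subset
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(n), mat])
            ) < size + 1:
                continue
            for c in c_grid:
                beta, sigma0, loglik = _fit_subset(ln_y, mat, c)
                npar = size + 3    # ln k, a_j..., sigma0, c
                bic = -2.0 * loglik + npar * np.log(n)
                if best is None or bic < best[0] - 1e-12:
                    best = (bic, subset, c, beta, sigma0, loglik)
    if best is None:
        raise ValueError("no valid predictor subset could be fitted")
    bic, subset, c, beta, sigma0, loglik = best
    return PropertyModel(
        response=response,
        predictors=list(subset),
        intercept=float(np.exp(beta[0])),
        exponents={m: float(b) for m, b in zip(subset, beta[1:])},
        sigma0=sigma0,
        c=float(c),
        log_likelihood=loglik,
        bic=float(bic),
        n=n,
        ranges={m: (float(table[m].min()), float(table[m].max()))
                for m in subset},
    )


def fit_all_property_models(table: pd.DataFrame,
                            **kwargs) -> dict[str, PropertyModel]:
    """Fit all four property models from one training table."""
    return {
        prop: fit_property_model(table, prop, **kwargs)
        for prop in PROPERTY_NAMES
        if prop in table.columns
    }


def predict_property(model: PropertyModel, metrics) -> tuple[float, float]:
    return model.predict(metrics)


def predict_properties(models: dict[str, PropertyModel],
                       metrics: dict[str, float]) -> dict[str, tuple[float, float]]:
    """Point predictions + sds for every property from one metric vector."""
    return {name: m.predict(metrics) for name, m in models.items()}


def save_models(models: dict[str, PropertyModel], path) -> None:
    """Serialize fitted models to a documented JSON file (no binaries)."""
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=2,
                  sort_keys=True)


def load_models(path) -> dict[str, PropertyModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: PropertyModel.from_dict(d) for k, d in raw.items()}
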