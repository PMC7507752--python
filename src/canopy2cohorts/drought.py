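"""Drought analysis: Priestley-Taylor PET, MCWD, drought length, response curves.

Machinery for relating ecosystem responses to water stress:

* potential evapotranspiration by the Priestley-Taylor formula
  (alpha = 1.26 on the equilibrium evaporation term);
* monthly water deficit = PET - precipitation (positive = deficit);
* maximum cumulative water deficit (MCWD) over a trailing 12-month
  window, using the reset-to-zero running-sum convention: the
  cumulative deficit resets whenever rain exceeds PET enough to cancel
  the accumulated debt, and MCWD is the magnitude of the most negative
  cumulative value within the window;
* drought length: the longest run of consecutive months whose deficit
  exceeds 20 mm, classified as seasonal (< 12 mo), severe (12-36 mo) or
  extreme (> 36 mo);
* quantile-binned medians with 95% bands of 12-month running-mean
  responses along the MCWD axis;
* shifted-exponential / shifted-Weibull response-curve fits selected by
  BIC and accepted only when adjusted R^2 exceeds 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "priestley_taylor_pet",
    "water_deficit",
    "mcwd",
    "drought_length",
    "classify_drought",
    "running_mean_12",
    "bin_by_mcwd",
    "BinnedResponse",
    "ResponseCurveFit",
    "fit_response_curve",
]

#: Priestley-Taylor coefficient on the equilibrium evaporation term.
ALPHA_PT = 1.26
#: Psychrometric constant, kPa / degC (near-surface standard pressure).
GAMMA_PSY = 0.067
#: Latent heat of vaporization, J / kg.
LAMBDA_V = 2.45e6
#: Monthly deficit above this (mm) counts toward drought length.
DROUGHT_DEFICIT_MM = 20.0
#: Drought-length class boundaries (months).
SEVERE_MONTHS = 12
EXTREME_MONTHS = 36


def saturation_slope(temp_c):
    """Slope of the saturation vapour-pressure curve (kPa / degC)."""
    t = np.asarray(temp_c, dtype=float)
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return 4098.0 * es / (t + 237.3) ** 2


def priestley_taylor_pet(net_radiation, ground_heat_flux, temp_c,
                         alpha: float = ALPHA_PT):
    """Potential ET (mm day^-1) from net radiation and temperature.

    lambda*E = alpha * Delta/(Delta+gamma) * (R_n - G) in W m^-2,
    converted to water depth with the latent heat of vaporization and
    floored at zero.
    """
    rn = np.asarray(net_radiation, dtype=float)
    g = np.asarray(ground_heat_flux, dtype=float)
    delta = saturation_slope(temp_c)
    le = alpha * delta / (delta + GAMMA_PSY) * (rn - g)
    pet = np.maximum(le, 0.0) * 86400.0 / LAMBDA_V
    return float(pet) if pet.ndim == 0 else pet


def water_deficit(clim: pd.DataFrame) -> np.ndarray:
    """Monthly water deficit PET - P (mm; negative = surplus)."""
    if "precip_mm" not in clim.columns or "pet_mm" not in clim.columns:
        raise ValueError("climate table needs precip_mm and pet_mm columns")
    p = clim["precip_mm"].to_numpy(dtype=float)
    pet = clim["pet_mm"].to_numpy(dtype=float)
    if len(p) != len(pet):
        raise ValueError("precipitation and PET lengths differ")
    return pet - p


def cumulative_deficit(deficit: np.ndarray) -> np.ndarray:
    """Reset-to-zero running water balance (<= 0 by convention).

    CWD_m = min(0, CWD_(m-1) + P_m - PET_m); starts from zero.
    """
    cwd = np.zeros(len(deficit))
    acc = 0.0
    for i, d in enumerate(deficit):
        acc = min(0.0, acc - d)   # deficit is PET - P, balance is P - PET
        cwd[i] = acc
    return cwd


def mcwd(deficit: np.ndarray, window: int = 12,
         convention: str = "reset") -> np.ndarray:
    """Maximum cumulative water deficit per month (mm, magnitude).

    ``reset`` (default): magnitude of the most negative reset-to-zero
    cumulative balance within the trailing window.  ``window_sum``:
    sum of the positive monthly deficits within the window.  The first
    ``window - 1`` entries are NaN (undefined).
    """
    if window < 2:
        raise ValueError("window must be >= 2 months")
    deficit = np.asarray(deficit, dtype=float)
    n = len(deficit)
    if n < window:
        raise ValueError(f"need >= {window} months, got {n}")
    out = np.full(n, np.nan)
    if convention == "reset":
        cwd = cumulative_deficit(deficit)
        for m in range(window - 1, n):
            out[m] = -np.min(cwd[m - window + 1:m + 1])
    elif convention == "window_sum":
        pos = np.maximum(deficit, 0.0)
        for m in range(window - 1, n):
            out[m] = np.sum(pos[m - window + 1:m + 1])
    else:
        raise ValueError(f"unknown MCWD convention {convention!r}")
    return out


def drought_length(deficit: np.ndarray,
                   threshold: float = DROUGHT_DEFICIT_MM
                   ) -> tuple[int, np.ndarray]:
    """Longest run of months in deficit beyond the threshold.

    Returns (max run length, per-month current-run series).  The raw
    monthly difference is tested (surpluses are not clamped first).
    """
    deficit = np.asarray(deficit, dtype=float)
    if len(deficit) == 0:
        raise ValueError("empty deficit series")
    runs = np.zeros(len(deficit), dtype=int)
    cur = 0
    for i, d in enumerate(deficit):
        cur = cur + 1 if d > threshold else 0
        runs[i] = cur
    return int(runs.max()), runs


def classify_drought(length_months: int) -> str:
    """seasonal (< 12 mo), severe (12-36 mo), extreme (> 36 mo)."""
    if length_months < SEVERE_MONTHS:
        return "seasonal"
    if length_months <= EXTREME_MONTHS:
        return "severe"
    return "extreme"


def running_mean_12(series: np.ndarray) -> np.ndarray:
    """Trailing 12-month running mean; first 11 entries NaN."""
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(12).mean().to_numpy()


@dataclass(frozen=True)
class BinnedResponse:
    bin_index: int
    mcwd_lo: float
    mcwd_hi: float
    n: int
    median: float
    q025: float
    q975: float


def bin_by_mcwd(response: np.ndarray, mcwd_series: np.ndarray,
                n_bins: int = 40) -> list[BinnedResponse]:
    """Median + 95% band of a response along MCWD quantile bins.

    Months where either series is undefined are dropped; the remaining
    months are split into ``n_bins`` near-equal-count bins at empirical
    MCWD quantiles.
    """
    response = np.asarray(response, dtype=float)
    mcwd_series = np.asarray(mcwd_series, dtype=float)
    ok = np.isfinite(response) & np.isfinite(mcwd_series)
    if ok.sum() < n_bins:
        raise ValueError(
            f"only {int(ok.sum())} valid months for {n_bins} bins"
        )
    r, m = response[ok], mcwd_series[ok]
    try:
        codes = pd.qcut(m, n_bins, labels=False, duplicates="drop")
    except ValueError as exc:
        raise ValueError("cannot form MCWD quantile bins") from exc
    out = []
    for b in sorted(np.unique(codes)):
        sel = codes == b
        vals = r[sel]
        out.append(BinnedResponse(
            bin_index=int(b) + 1,
            mcwd_lo=float(m[sel].min()),
            mcwd_hi=float(m[sel].max()),
            n=int(sel.sum()),
            median=float(np.median(vals)),
            q025=float(np.quantile(vals, 0.025)),
            q975=float(np.quantile(vals, 0.975)),
        ))
    return out


# --- response-curve fits -------------------------------------------------

def shifted_exponential(x, y_inf, y0, tau):
    """y = y_inf - (y_inf - y0) * exp(-x / tau)."""
    return y_inf - (y_inf - y0) * np.exp(-x / tau)


def shifted_weibull(x, y_inf, y0, tau, k):
    """y = y_inf - (y_inf - y0) * exp(-(x / tau)^k); k = 1 nests the
    shifted exponential."""
    return y_inf - (y_inf - y0) * np.exp(-((x / tau) ** k))


_FAMILIES = {
    "shifted_exponential": (shifted_exponential, 3),
    "shifted_weibull": (shifted_weibull, 4),
}


@dataclass(frozen=True)
class ResponseCurveFit:
    family: str
    params: dict[str, float]
    bic: float
    r2_adj: float
    accepted: bool
    message: str = ""

    def predict(self, x):
        fn, _ = _FAMILIES[self.family]
        return fn(np.asarray(x, dtype=float), **self.params)


def _starts(x: np.ndarray, y: np.ndarray, family: str,
            n_starts: int, rng: np.random.Generator) -> list[list[float]]:
    """Multi-start initial guesses from data quantiles plus jitter."""
    y_lo, y_hi = np.quantile(y, [0.05, 0.95])
    x_scale = max(np.quantile(x, 0.5), 1e-6)
    base = [y_hi, y_lo, x_scale]
    if family == "shifted_weibull":
        base = base + [1.0]
    starts = [list(base)]
    for _ in range(n_starts - 1):
        jitter = rng.uniform(0.5, 1.8, size=len(base))
        s = [b * j if b != 0 else j - 1.0 for b, j in zip(base, jitter)]
        if family == "shifted_weibull":
            s[3] = float(np.clip(s[3], 0.3, 4.0))
        starts.append(s)
    return starts


def fit_response_curve(x, y, families: tuple[str, ...] = tuple(_FAMILIES),
                       n_starts: int = 5, seed: int = 0,
                       r2_threshold: float = 0.5) -> ResponseCurveFit:
    """Fit and select a response curve by nonlinear least squares.

    Both families are fitted with multi-start initialization (quantile
    heuristics, fixed seed); the most parsimonious is selected by BIC
    and accepted only when the adjusted R^2 exceeds the threshold.  If
    neither family converges a rejected fit with diagnostics is
    returned rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 points to fit a response curve")
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(x)
    best = None
    errors = []
    for family in families:
        fn, npar = _FAMILIES[family]
        pnames = ["y_inf", "y0", "tau"] + (["k"] if npar == 4 else [])
        for p0 in _starts(x, y, family, n_starts, rng):
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(fn, x, y, p0=p0, maxfev=20000)
            except (RuntimeError, ValueError) as exc:
                errors.append(f"{family}: {exc}")
                continue
            with np.errstate(all="ignore"):
                resid = y - fn(x, *popt)
                rss = float(np.nansum(resid**2))
            if not np.isfinite(rss):
                continue
            bic = n * np.log(max(rss, 1e-300) / n) + npar * np.log(n)
            if best is None or bic < best[0]:
                best = (bic, family, dict(zip(pnames, popt)), rss, npar)
    if best is None:
        return ResponseCurveFit(
            family=families[0], params={}, bic=np.inf, r2_adj=-np.inf,
            accepted=False, message="; ".join(errors[:3]) or "no convergence",
        )
    bic, family, params, rss, npar = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - npar - 1, 1)
    return ResponseCurveFit(
        family=family, params={k: float(v) for k, v in params.items()},
        bic=float(bic), r2_adj=float(r2_adj),
        accepted=bool(r2_adj > r2_threshold),
    )
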