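"""Time-series statistics for interval data.

Fluctuation-function scaling, maximum-likelihood power-law (Levy) and
shifted-exponential fits to increment magnitudes, Akaike-weight model
selection, and a log-binned G-test goodness of fit.

Both candidate models are continuous densities on x >= x_min, the standard
treatment of integer-valued interval data in the Levy-movement literature:

    power law:    p(x) = (mu - 1)/x_min * (x/x_min)^(-mu),   mu > 1
    exponential:  p(x) = lam * exp(-lam * (x - x_min)),      lam > 0

Their MLEs are closed-form:  mu_hat = 1 + n / sum(ln(x/x_min)),
lam_hat = 1 / mean(x - x_min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

POWER_LAW = "power_law"
EXPONENTIAL = "exponential"


@dataclass
class FluctuationResult:
    scales: np.ndarray
    f_values: np.ndarray
    alpha: float          # nan when the series is constant
    fit_range: tuple


@dataclass
class FitResult:
    model: str
    parameter: float      # mu for power_law, lam for exponential
    x_min: float
    log_likelihood: float
    n_obs: int
    aic: float


@dataclass
class ModelComparison:
    akaike_weights: dict   # model name -> weight in [0, 1], summing to 1
    g_statistic: float = np.nan
    df: int = 0
    p_value: float = np.nan

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def fluctuation_function(dt_series, scales=None, fit_range=None) -> FluctuationResult:
    """Root-mean-square fluctuation of the integrated interval series.

    The profile is the cumulative sum of the mean-subtracted series,
    Y_k = sum_{i<=k} (DT_i - <DT>).  For each window size n,

        F(n) = sqrt( mean_k (Y_{k+n} - Y_k)^2 ),

    and the scaling exponent alpha is the least-squares slope of
    log F(n) vs log n over ``fit_range`` (default n in [2, N/4]).  A flat
    F(n) (alpha near 0) means interval fluctuations do not build up across
    scales; alpha = 0.5 is the uncorrelated (white-noise) benchmark.
    """
    dt = np.asarray(dt_series, dtype=float)
    n_pts = len(dt)
    if scales is None:
        if n_pts < 8:
            raise ValueError(f"series too short for fluctuation analysis ({n_pts})")
        scales = np.arange(2, max(n_pts // 4, 3) + 1)
    scales = np.asarray(scales, dtype=int)
    if scales.max() >= n_pts:
        raise ValueError("largest scale must be < series length")
    profile = np.cumsum(dt - dt.mean())
    f_values = np.array([
        np.sqrt(np.mean((profile[n:] - profile[:-n]) ** 2)) for n in scales
    ])
    if fit_range is None:
        fit_range = (int(scales.min()), int(scales.max()))
    lo, hi = fit_range
    mask = (scales >= lo) & (scales <= hi) & (f_values > 0)
    if mask.sum() >= 3:
        alpha = float(np.polyfit(np.log(scales[mask]),
                                 np.log(f_values[mask]), 1)[0])
    else:
        alpha = float("nan")   # constant / degenerate series: F == 0
    return FluctuationResult(scales=scales, f_values=f_values,
                             alpha=alpha, fit_range=(lo, hi))


def _check_magnitudes(x, x_min):
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need at least 5 observations to fit (got {len(x)})")
    if x_min <= 0:
        raise ValueError("x_min must be > 0")
    if np.any(x < x_min):
        raise ValueError("all observations must be >= x_min")
    return x


def fit_power_law(magnitudes, x_min: float = 1.0) -> FitResult:
    """Continuous-Pareto MLE on magnitudes >= x_min."""
    x = _check_magnitudes(magnitudes, x_min)
    n = len(x)
    log_sum = np.sum(np.log(x / x_min))
    if log_sum == 0:
        raise ValueError("all observations equal x_min; exponent diverges")
    mu = 1.0 + n / log_sum
    loglik = n * np.log(mu - 1.0) - n * np.log(x_min) - mu * log_sum
    return FitResult(model=POWER_LAW, parameter=float(mu), x_min=x_min,
                     log_likelihood=float(loglik), n_obs=n,
                     aic=float(2.0 - 2.0 * loglik))


def fit_exponential(magnitudes, x_min: float = 1.0) -> FitResult:
    """Shifted-exponential MLE on magnitudes >= x_min."""
    x = _check_magnitudes(magnitudes, x_min)
    n = len(x)
    mean_excess = np.mean(x - x_min)
    if mean_excess == 0:
        raise ValueError("all observations equal x_min; rate diverges")
    lam = 1.0 / mean_excess
    loglik = n * np.log(lam) - lam * np.sum(x - x_min)
    return FitResult(model=EXPONENTIAL, parameter=float(lam), x_min=x_min,
                     log_likelihood=float(loglik), n_obs=n,
                     aic=float(2.0 - 2.0 * loglik))


def akaike_weights(fit_results) -> ModelComparison:
    """Relative AIC support w_i = exp(-d_i/2) / sum_j exp(-d_j/2)."""
    fits = list(fit_results)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits compare different data (n_obs = {sorted(n_obs)})")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    rel = np.exp(-delta / 2.0)
    w = rel / rel.sum()
    return ModelComparison(akaike_weights={f.model: float(wi)
                                           for f, wi in zip(fits, w)})


def _model_cdf(fit: FitResult, x):
    x = np.asarray(x, dtype=float)
    if fit.model == POWER_LAW:
        return 1.0 - (x / fit.x_min) ** (1.0 - fit.parameter)
    if fit.model == EXPONENTIAL:
        return 1.0 - np.exp(-fit.parameter * (x - fit.x_min))
    raise ValueError(f"unknown model {fit.model!r}")


def g_statistic(observed, expected) -> float:
    """Likelihood-ratio statistic G = 2 * sum O * ln(O/E) (O = 0 terms drop)."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    mask = o > 0
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def g_test_gof(magnitudes, fit: FitResult, n_bins: int = 8) -> ModelComparison:
    """Log-binned G-test of a fitted tail model.

    Counts are binned into ``n_bins`` log-spaced bins over
    [x_min, max(x)]; expected counts follow the fitted model's CDF
    renormalised over that range; bins expecting fewer than one count are
    merged into their right-hand neighbour (the last into its left).
    Degrees of freedom are n_bins - 1 - 1 (one fitted parameter).
    """
    x = _check_magnitudes(magnitudes, fit.x_min)
    n = len(x)
    top = x.max() * (1 + 1e-9)
    edges = np.geomspace(fit.x_min, top, n_bins + 1)
    observed, _ = np.histogram(x, bins=edges)
    cdf = _model_cdf(fit, edges)
    probs = np.diff(cdf) / (cdf[-1] - cdf[0])
    expected = n * probs

    obs, exp = list(observed), list(expected)
    i = 0
    while i < len(obs):
        if exp[i] < 1.0 and len(obs) > 1:
            j = i + 1 if i + 1 < len(obs) else i - 1
            obs[j] += obs[i]
            exp[j] += exp[i]
            del obs[i], exp[i]
            if j < i:
                i -= 1
        else:
            i += 1
    if len(obs) < 3:
        raise ValueError(f"only {len(obs)} bins after merging; need >= 3")

    g = g_statistic(obs, exp)
    df = len(obs) - 1 - 1
    p = float(sps.chi2.sf(g, df))
    weights = {fit.model: 1.0}
    return ModelComparison(akaike_weights=weights, g_statistic=g,
                           df=df, p_value=p)


def compare_tail_models(magnitudes, x_min: float = 1.0) -> dict:
    """Full model-selection protocol on pooled increment magnitudes.

    Fits both candidate tails, computes Akaike weights, and runs the
    goodness-of-fit G-test on the AIC-preferred model.  Returns a dict with
    both FitResults, the ModelComparison, and the preferred model name.
    """
    pl = fit_power_law(magnitudes, x_min)
    ex = fit_exponential(magnitudes, x_min)
    comparison = akaike_weights([pl, ex])
    preferred = max(comparison.akaike_weights, key=comparison.akaike_weights.get)
    best = pl if preferred == POWER_LAW else ex
    gof = g_test_gof(magnitudes, best)
    return {
        "power_law": pl,
        "exponential": ex,
        "akaike_weights": comparison.akaike_weights,
        "preferred": preferred,
        "gof": gof,
    }
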