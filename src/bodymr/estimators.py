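"""Two-sample MR causal-effect estimators.

Given k harmonized instruments with SNP-exposure effects ``beta_x`` (SE
``se_x``) and SNP-outcome effects ``beta_y`` (SE ``se_y``, log-OR scale
for a disease outcome), five estimators of the causal effect per 1-SD of
exposure are provided:

* Wald ratio (single SNP): beta_y / beta_x, first-order delta-method SE.
* IVW: precision-weighted no-intercept regression of beta_y on beta_x,
  weights 1/se_y^2; fixed-effect or multiplicative-random-effect SE (the
  latter inflates by max(1, sqrt(Q/(k-1))) and is the default).
* MR-Egger: the same regression with an intercept after orienting every
  instrument to beta_x >= 0; the intercept estimates average directional
  pleiotropy.
* Weighted median: weighted 50% quantile of the per-SNP Wald ratios,
  consistent when >= 50% of the weight comes from valid instruments.
* Weighted mode: mode of a Gaussian-kernel weighted density of the Wald
  ratios (modified-Silverman bandwidth), consistent when the largest group
  of instruments with equal ratios is valid.

Weighted-median/mode SEs come from a seeded parametric bootstrap.
All estimates carry 95% CIs and can be expressed as an OR per 1-SD.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import InputError, InsufficientInstrumentsError, UndefinedRatioError

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "to_odds_ratio",
    "estimate_all",
    "METHODS",
]

#: Normal 97.5% quantile used for every 95% CI in the package.
Z95 = 1.959964

METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


@dataclass
class MREstimate:
    """A causal estimate on the log-OR-per-SD scale, with OR translation."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    intercept: float | None = None          # Egger only
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    q: float | None = None                  # Cochran's Q at the IVW fit

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _finish(method: str, beta: float, se: float, k: int, **extra) -> MREstimate:
    beta, se = float(beta), float(se)
    est = MREstimate(
        method=method, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=_two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0),
        k=int(k), **extra)
    return to_odds_ratio(est)


def _arrays(bx, by, byse, bxse=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    byse = np.asarray(byse, dtype=float)
    if bxse is None:
        bxse = np.zeros_like(bx)
    else:
        bxse = np.asarray(bxse, dtype=float)
    if not (bx.shape == by.shape == byse.shape == bxse.shape):
        raise InputError("instrument arrays must share one length")
    if np.any(byse <= 0):
        raise InputError("all outcome SEs must be positive")
    return bx, by, byse, bxse


def from_frame(df: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Unpack a harmonized-instrument table into (bx, bxse, by, byse)."""
    return (df["beta_exposure"].to_numpy(float),
            df["se_exposure"].to_numpy(float),
            df["beta_outcome"].to_numpy(float),
            df["se_outcome"].to_numpy(float))


def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate beta_y / beta_x.

    SE is the first-order delta method se_y / |beta_x|; the contribution
    of the exposure SE is neglected (second-order term), consistent with
    the weighting used by the multi-SNP estimators.
    """
    if beta_x == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_x = 0")
    if se_y <= 0:
        raise InputError("se_y must be positive")
    return _finish("wald", beta_y / beta_x, se_y / abs(beta_x), k=1)


def ivw(bx, by, byse, *, model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate over k >= 1 instruments.

    beta = sum(bx*by/se_y^2) / sum(bx^2/se_y^2); the fixed-effect SE is
    (sum bx^2/se_y^2)^{-1/2} and the multiplicative random-effect SE
    inflates it by max(1, sqrt(Q/(k-1))).  With k = 1 this is exactly the
    Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise InputError(f"model must be 'fixed' or 'random', got {model!r}")
    bx, by, byse, _ = _arrays(bx, by, byse)
    k = bx.size
    if k == 0:
        raise InputError("empty instrument set")
    w = byse ** -2.0
    s2 = np.sum(bx ** 2 * w)
    beta = np.sum(bx * by * w) / s2
    se_fixed = s2 ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    se = se_fixed
    if model == "random" and k >= 2:
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    return _finish("ivw", beta, se, k=k, q=q)


def egger(bx, by, byse) -> MREstimate:
    """MR-Egger regression: WLS of beta_y on beta_x with intercept.

    Instruments are first oriented so beta_x >= 0 (jointly negating both
    betas where needed).  Weights are 1/se_y^2.  The slope is the causal
    estimate; the intercept estimates average directional pleiotropy.  SEs
    use a multiplicative random-effect scale bounded below by the
    fixed-effect value; p-values are two-sided normal.
    """
    bx, by, byse, _ = _arrays(bx, by, byse)
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs k >= 3, got {k}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=byse ** -2.0).fit()
    # statsmodels scales parameter covariances by the residual sigma^2;
    # bound the scale below by 1 (never report more than fixed-effect
    # precision), matching the random-effects IVW convention.
    sigma = np.sqrt(max(fit.scale, np.finfo(float).tiny))
    adj = max(1.0, sigma) / sigma
    inter, slope = fit.params
    inter_se, slope_se = fit.bse * adj
    return _finish("egger", slope, slope_se, k=k,
                   intercept=float(inter), intercept_se=float(inter_se),
                   intercept_pvalue=_two_sided_p(inter / inter_se)
                   if inter_se > 0 else 1.0)


def _ratio_weights(bx, by, byse):
    ratios = by / bx
    w = bx ** 2 / byse ** 2
    return ratios, w / w.sum()


def _weighted_median_point(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r, wt = ratios[order], w[order]
    s = np.cumsum(wt) - 0.5 * wt
    return float(np.interp(0.5, s, r))


def _weighted_quantile(r_sorted, w_sorted, q):
    s = np.cumsum(w_sorted) - 0.5 * w_sorted
    return float(np.interp(q, s, r_sorted))


def _mode_bandwidth(ratios: np.ndarray, w: np.ndarray, phi: float) -> float:
    mu = np.sum(w * ratios)
    sd = np.sqrt(np.sum(w * (ratios - mu) ** 2))
    order = np.argsort(ratios, kind="mergesort")
    iqr = (_weighted_quantile(ratios[order], w[order], 0.75)
           - _weighted_quantile(ratios[order], w[order], 0.25))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return float(phi * 0.9 * spread * ratios.size ** (-1 / 5))


_MODE_GRID = 512


def _weighted_mode_point(ratios: np.ndarray, w: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(ratios, w, phi)
    if h == 0:  # all ratios identical (or zero weighted spread)
        return float(ratios[np.argmax(w)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, _MODE_GRID)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def _parametric_boot(bx, bxse, by, byse, point_fn, n_boot, seed):
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, bxse)
        bys = rng.normal(by, byse)
        bxs[bxs == 0] = np.finfo(float).tiny  # ratios must stay defined
        ratios = bys / bxs
        w = bxs ** 2 / byse ** 2
        est[i] = point_fn(ratios, w / w.sum())
    return float(np.std(est, ddof=1))


def weighted_median(bx, by, byse, bxse=None, *, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimator over k >= 3 instruments.

    Wald ratios are ordered ascending with normalized weights
    w_j = bx_j^2/se_yj^2; the estimate interpolates the ratios at
    cumulative standardized weight 0.5.  The SE is the standard deviation
    of the estimate over ``n_boot`` parametric resamples of (bx, by) from
    their normal sampling distributions, seeded for reproducibility.
    """
    bx, by, byse, bxse = _arrays(bx, by, byse, bxse)
    if bx.size < 3:
        raise InsufficientInstrumentsError(f"weighted median needs k >= 3, got {bx.size}")
    if np.any(bx == 0):
        raise UndefinedRatioError("beta_x = 0 makes a Wald ratio undefined")
    ratios, w = _ratio_weights(bx, by, byse)
    beta = _weighted_median_point(ratios, w)
    se = _parametric_boot(bx, bxse, by, byse, _weighted_median_point, n_boot, seed)
    return _finish("weighted_median", beta, se, k=bx.size)


def weighted_mode(bx, by, byse, bxse=None, *, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimator over k >= 3 instruments.

    The estimate is the argmax of a Gaussian-kernel weighted density of
    the Wald ratios, bandwidth phi * 0.9 * min(weighted SD, weighted
    IQR/1.34) * k^{-1/5} (modified Silverman).  If the bandwidth is zero
    (all ratios identical) the common ratio is returned.  SE by seeded
    parametric bootstrap, as for the weighted median.
    """
    bx, by, byse, bxse = _arrays(bx, by, byse, bxse)
    if bx.size < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs k >= 3, got {bx.size}")
    if np.any(bx == 0):
        raise UndefinedRatioError("beta_x = 0 makes a Wald ratio undefined")
    ratios, w = _ratio_weights(bx, by, byse)
    beta = _weighted_mode_point(ratios, w, phi)
    se = _parametric_boot(bx, bxse, by, byse,
                          lambda r, wt: _weighted_mode_point(r, wt, phi),
                          n_boot, seed)
    return _finish("weighted_mode", beta, se, k=bx.size)


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Populate the OR-per-1-SD scale: OR = exp(beta), CI = exp(beta +/- z*se)."""
    return replace(est,
                   odds_ratio=float(np.exp(est.beta)),
                   or_ci_low=float(np.exp(est.beta - Z95 * est.se)),
                   or_ci_high=float(np.exp(est.beta + Z95 * est.se)))


def estimate_all(instruments: pd.DataFrame, *, ivw_model: str = "random",
                 phi: float = 1.0, n_boot: int = 1000, seed: int = 0,
                 methods: Sequence[str] = METHODS) -> dict[str, MREstimate]:
    """Run the requested multi-SNP estimators on a harmonized table."""
    bx, bxse, by, byse = from_frame(instruments)
    out: dict[str, MREstimate] = {}
    for m in methods:
        if m == "ivw":
            out[m] = ivw(bx, by, byse, model=ivw_model)
        elif m == "egger":
            out[m] = egger(bx, by, byse)
        elif m == "weighted_median":
            out[m] = weighted_median(bx, by, byse, bxse, n_boot=n_boot, seed=seed)
        elif m == "weighted_mode":
            out[m] = weighted_mode(bx, by, byse, bxse, phi=phi,
                                   n_boot=n_boot, seed=seed + 1)
        else:
            raise InputError(f"unknown method {m!r}")
    return out


def estimates_frame(estimates: dict[str, MREstimate]) -> pd.DataFrame:
    """Tabulate estimates (one row per method) for TSV export."""
    rows = []
    for m, e in estimates.items():
        rows.append({"method": m, "k": e.k, "beta": e.beta, "se": e.se,
                     "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.pvalue,
                     "OR": e.odds_ratio, "OR_low": e.or_ci_low,
                     "OR_high": e.or_ci_high})
    return pd.DataFrame(rows)
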