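"""Heterogeneity and horizontal-pleiotropy diagnostics.

Cochran's Q (with I^2 and H), the MR-Egger intercept test, an MR-PRESSO
style global/outlier test, leave-one-out analysis, and plot-ready data
tables (scatter, forest, leave-one-out, funnel).  All randomized
procedures are seeded and bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z95, from_frame, ivw
from .exceptions import InsufficientInstrumentsError

__all__ = [
    "HeterogeneityReport",
    "PressoResult",
    "heterogeneity",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "diagnostic_tables",
]


@dataclass
class HeterogeneityReport:
    """Cochran's Q over per-SNP Wald ratios at the IVW fit.

    I^2 = max(0, (Q - df)/Q) * 100 with the conventional 25/50/75%
    low/moderate/high boundaries; H = sqrt(Q/df).  The chi-square tail
    probability of Q serves as the p-value for both Q and H (they test the
    same homogeneity hypothesis).
    """

    q: float
    df: int
    p_q: float
    i2: float
    h: float
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        if self.i2 < 25:
            self.classification = "none"
        elif self.i2 < 50:
            self.classification = "low"
        elif self.i2 < 75:
            self.classification = "moderate"
        else:
            self.classification = "high"


def heterogeneity(bx, by, byse, beta_ivw: float | None = None) -> HeterogeneityReport:
    """Q = sum w_j (r_j - beta_ivw)^2, r_j the Wald ratios, w_j = bx^2/se_y^2.

    Algebraically equal to the weighted residual sum of squares of the
    no-intercept IVW regression.  Needs k >= 2.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    byse = np.asarray(byse, float)
    k = bx.size
    if k < 2:
        raise InsufficientInstrumentsError(f"heterogeneity needs k >= 2, got {k}")
    if beta_ivw is None:
        beta_ivw = ivw(bx, by, byse, model="fixed").beta
    w = bx ** 2 / byse ** 2
    r = by / bx
    q = float(np.sum(w * (r - beta_ivw) ** 2))
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    h = float(np.sqrt(q / df))
    return HeterogeneityReport(q=q, df=df, p_q=p_q, i2=i2, h=h)


def egger_intercept_test(egger_fit: MREstimate) -> tuple[float, float, float]:
    """Two-sided normal test of the MR-Egger intercept against zero.

    A non-zero intercept indicates average directional pleiotropy.
    Returns (intercept, se, p).
    """
    if egger_fit.intercept is None or egger_fit.intercept_se is None:
        raise InsufficientInstrumentsError("pass an MR-Egger fit (k >= 3)")
    inter, se = egger_fit.intercept, egger_fit.intercept_se
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(inter / se)))) if se > 0 else 1.0
    return inter, se, p


@dataclass
class PressoResult:
    """Global and per-SNP results of the pleiotropy residual-sum test."""

    rss_obs: float
    global_p: float
    outlier_p: pd.Series          # Bonferroni-adjusted, indexed by snp_id
    outliers: list[str]
    n_sim: int
    seed: int


def _loo_ivw_beta(bx, by, w):
    """Leave-one-out fixed-effect IVW betas, vectorized over the left-out SNP."""
    s1 = np.sum(bx * by * w, axis=-1, keepdims=True)
    s2 = np.sum(bx ** 2 * w, axis=-1, keepdims=True)
    return (s1 - bx * by * w) / (s2 - bx ** 2 * w)


def mr_presso(bx, by, byse, bxse, snp_ids=None, *, n_sim: int = 1000,
              seed: int = 0, outlier_alpha: float = 0.05) -> PressoResult:
    """Pleiotropy residual sum and outlier test (standardized-residual form).

    The observed residual sum RSS_obs = sum_j w_j (by_j - beta_(-j) bx_j)^2
    uses the leave-one-out IVW fit beta_(-j) so each SNP is judged against
    the others.  ``n_sim`` datasets are simulated under the no-pleiotropy
    null (by*_j ~ N(beta_(-j) bx_j, se_yj), bx*_j ~ N(bx_j, se_xj)) and

    * global p = (1 + #{RSS* >= RSS_obs}) / (n_sim + 1);
    * per-SNP outlier p = tail probability of SNP j's observed weighted
      squared residual in its simulated distribution, Bonferroni-adjusted
      by k; outliers have adjusted p < ``outlier_alpha``.

    The distortion test of the original publication is not implemented.
    Needs k >= 4.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    byse = np.asarray(byse, float)
    bxse = np.asarray(bxse, float)
    k = bx.size
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs k >= 4, got {k}")
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(k)]

    w = byse ** -2.0
    beta_loo = _loo_ivw_beta(bx[None, :], by[None, :], w[None, :])[0]
    d_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(d_obs.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, bxse, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, byse, size=(n_sim, k))
    beta_loo_sim = _loo_ivw_beta(bx_sim, by_sim, w[None, :])
    d_sim = w[None, :] * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = d_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    # Raw empirical tail probability (no continuity correction): with the
    # +1 correction the smallest reachable Bonferroni-adjusted p would be
    # k/(n_sim+1), which exceeds conventional alpha for large k and would
    # make the outlier test vacuous.
    p_raw = np.sum(d_sim >= d_obs[None, :], axis=0) / n_sim
    p_adj = np.minimum(1.0, p_raw * k)
    outlier_p = pd.Series(p_adj, index=list(snp_ids))
    outliers = [s for s, p in outlier_p.items() if p < outlier_alpha]
    return PressoResult(rss_obs=rss_obs, global_p=global_p, outlier_p=outlier_p,
                        outliers=outliers, n_sim=n_sim, seed=seed)


def leave_one_out(instruments: pd.DataFrame, *, ivw_model: str = "fixed",
                  ) -> pd.DataFrame:
    """Re-estimate IVW k times, each omitting one SNP.

    Returns one row per left-out SNP with the re-fit beta/se/CI and an
    ``influential`` flag set when the re-fit beta falls outside the
    full-set 95% CI.  The influence rule defaults to the fixed-effect CI:
    under the multiplicative random-effects model a single gross outlier
    inflates the full-set CI in proportion to its own displacement, so the
    rule could never fire on exactly the instruments it exists to catch.
    Needs k >= 3 (so every re-fit keeps >= 2 SNPs).
    """
    k = len(instruments)
    if k < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs k >= 3, got {k}")
    bx, bxse, by, byse = from_frame(instruments)
    full = ivw(bx, by, byse, model=ivw_model)
    rows = []
    for j in range(k):
        mask = np.arange(k) != j
        fit = ivw(bx[mask], by[mask], byse[mask], model=ivw_model)
        rows.append({
            "snp_id": instruments["snp_id"].iloc[j],
            "beta": fit.beta, "se": fit.se,
            "ci_low": fit.ci_low, "ci_high": fit.ci_high,
            "influential": not (full.ci_low <= fit.beta <= full.ci_high),
        })
    return pd.DataFrame(rows)


def diagnostic_tables(instruments: pd.DataFrame,
                      estimates: dict[str, MREstimate]) -> dict[str, pd.DataFrame]:
    """Plot-ready data tables: scatter, forest and funnel.

    * ``scatter``: per-SNP (bx, by) with SEs, plus one fitted-line row per
      method (slope, and intercept for MR-Egger) in ``scatter_fits``.
    * ``forest``: per-SNP Wald ratio with 95% CI and one combined row per
      multi-SNP method.
    * ``funnel``: per-SNP ratio against its precision 1/se(ratio); the
      ``funnel_asymmetry`` frame carries the precision-weighted slope of
      ratio on precision (near zero for symmetric data).
    """
    bx, bxse, by, byse = from_frame(instruments)
    snp = instruments["snp_id"]

    scatter = pd.DataFrame({"snp_id": snp, "beta_exposure": bx,
                            "se_exposure": bxse, "beta_outcome": by,
                            "se_outcome": byse})
    fits = pd.DataFrame([
        {"method": m, "slope": e.beta,
         "intercept": e.intercept if e.intercept is not None else 0.0}
        for m, e in estimates.items()])

    ratio = by / bx
    ratio_se = byse / np.abs(bx)
    rows = [{"snp_id": s, "ratio": r, "ci_low": r - Z95 * se,
             "ci_high": r + Z95 * se, "combined": False}
            for s, r, se in zip(snp, ratio, ratio_se)]
    for m, e in estimates.items():
        rows.append({"snp_id": f"All ({m})", "ratio": e.beta,
                     "ci_low": e.ci_low, "ci_high": e.ci_high, "combined": True})
    forest = pd.DataFrame(rows)

    precision = 1.0 / ratio_se
    funnel = pd.DataFrame({"snp_id": snp, "ratio": ratio, "precision": precision})
    X = np.column_stack([np.ones_like(precision), precision])
    wls = np.linalg.lstsq(X * precision[:, None], ratio * precision, rcond=None)[0]
    asym = pd.DataFrame([{"slope_ratio_on_precision": wls[1]}])

    return {"scatter": scatter, "scatter_fits": fits, "forest": forest,
            "funnel": funnel, "funnel_asymmetry": asym}
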