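"""The two-stage analysis workflow, end to end.

Stage "first": clump the exposure GWAS to index SNPs, screen out
confounder-linked and APOE-linked candidates, harmonize with the outcome
GWAS (substituting proxies for SNPs that are absent, ambiguous
palindromes, or mismatched), check instrument strength, run IVW and
MR-Egger with the full diagnostic battery, remove MR-PRESSO outliers and
then leave-one-out-influential SNPs, and re-estimate with all four
multi-SNP methods.

Stage "additional": identical, except that traits the first analysis
cleared of confounding (by default BMI and WHR) are dropped from the
confounder configuration, re-admitting the SNPs excluded for LD with
them.

Every removal is logged with a reason; the exclusion log and the final
instrument set together partition the candidate set (no silent drops).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import estimators as est
from . import instruments as ivs
from .exceptions import PipelineError
from .gwas_io import SummaryDataset, harmonize
from .instruments import LDMatrix

__all__ = ["AnalysisResult", "run_analysis", "results_table"]


@dataclass
class AnalysisResult:
    """Everything one pipeline run produces."""

    instruments: pd.DataFrame                 # final harmonized instrument table
    estimates: dict[str, est.MREstimate]      # final estimates per method
    first_pass: dict[str, est.MREstimate]     # IVW + Egger before outlier removal
    diagnostics: dict                         # heterogeneity/presso/loo/tables
    exclusion_log: pd.DataFrame               # snp_id, reason, partner, r2, stage
    harmonization: dict                       # category counts + lists
    strength: ivs.InstrumentStrength | None
    counts: list[tuple[str, int]]             # per-stage SNP bookkeeping
    stage: str
    provenance: pd.DataFrame                  # snp_id, provenance (index/proxy/re-admitted)


def run_analysis(exposure: SummaryDataset, outcome: SummaryDataset,
                 ld: LDMatrix, *,
                 confounders: Mapping[str, Sequence[str]] | None = None,
                 stage: str = "first",
                 readmit_confounders: Sequence[str] = ("BMI", "WHR"),
                 apoe_snps: Sequence[str] = ivs.APOE_SNPS,
                 apoe_region: tuple[str, int, int] | None = ivs.APOE_REGION,
                 apoe_r2: float = 0.1,
                 confounder_r2: float = 0.5,
                 p_threshold: float = 5e-8,
                 clump_r2: float = 0.001,
                 window_kb: float = 10_000,
                 palindrome_eaf_window: float = 0.08,
                 proxy_r2: float = 0.9,
                 ivw_model: str = "random",
                 n_boot: int = 1000,
                 presso_n_sim: int = 1000,
                 presso_alpha: float = 0.05,
                 methods: Sequence[str] = est.METHODS,
                 seed: int = 0) -> AnalysisResult:
    """Run the full two-sample MR workflow on one exposure-outcome pair.

    ``confounders`` maps a confounder trait name to its associated rsIDs;
    at stage "additional" the names in ``readmit_confounders`` are removed
    from that mapping before the LD screen, re-admitting their SNPs.

    Raises :class:`PipelineError` when filtering empties the instrument
    set; all other failures are logged, not fatal.
    """
    if stage not in ("first", "additional"):
        raise PipelineError(f"unknown stage {stage!r}", ["run_analysis"])
    trace = [f"stage={stage}"]
    counts: list[tuple[str, int]] = []
    excl_rows: list[dict] = []
    confounders = {k: list(v) for k, v in (confounders or {}).items()}
    readmit_lists: dict[str, list[str]] = {}
    if stage == "additional":
        for name in readmit_confounders:
            dropped_list = confounders.pop(name, None)
            if dropped_list:
                readmit_lists[name] = dropped_list

    positions = {**exposure.positions(), **ld.positions}

    # 1. clump -------------------------------------------------------------
    trace.append("clump")
    index_snps = ivs.clump(exposure, ld, p_threshold=p_threshold,
                           r2_threshold=clump_r2, window_kb=window_kb)
    counts.append(("index SNPs after clumping", len(index_snps)))
    if not index_snps:
        raise PipelineError("no genome-wide-significant index SNPs", trace)

    # 2. confounder / APOE screens ------------------------------------------
    trace.append("exclusions")
    retained = list(index_snps)
    for name, snps in confounders.items():
        retained, ex = ivs.exclude_by_ld(retained, snps, ld, confounder_r2,
                                         reason=f"confounder-LD:{name}")
        for e in ex:
            excl_rows.append({**e, "stage": "selection"})
    retained, ex = ivs.exclude_apoe(retained, ld, positions,
                                    apoe_snps=apoe_snps, r2_cutoff=apoe_r2,
                                    region=apoe_region)
    for e in ex:
        excl_rows.append({**e, "stage": "selection"})
    counts.append(("candidates after confounder/APOE screens", len(retained)))
    if not retained:
        raise PipelineError("all candidates excluded by confounder/APOE screens",
                            trace)

    # 3. harmonize + proxies -------------------------------------------------
    trace.append("harmonize")
    table, report = harmonize(exposure, outcome, retained,
                              palindrome_eaf_window=palindrome_eaf_window)
    provenance = {snp: "index" for snp in report.harmonized}
    for name, snps in readmit_lists.items():
        _, would_drop = ivs.exclude_by_ld(list(provenance), snps, ld,
                                          confounder_r2, reason=name)
        for e in would_drop:
            provenance[e["snp_id"]] = "re-admitted"

    conf_all = [s for snps in confounders.values() for s in snps]
    for reason, dropped in (("palindrome", report.ambiguous),
                            ("mismatch", report.mismatched),
                            ("absent", report.absent)):
        for snp in dropped:
            excl_rows.append({"snp_id": snp, "reason": reason,
                              "partner": None, "r2": np.nan,
                              "stage": "harmonization"})
            proxy = ivs.find_proxy(snp, exposure, outcome, ld,
                                   r2_min=proxy_r2,
                                   exclusion_snps=conf_all,
                                   exclusion_r2_cutoff=confounder_r2,
                                   palindrome_eaf_window=palindrome_eaf_window,
                                   apoe_snps=apoe_snps, apoe_r2_cutoff=apoe_r2)
            if proxy is not None and proxy not in provenance:
                ptab, prep = harmonize(exposure, outcome, [proxy],
                                       palindrome_eaf_window=palindrome_eaf_window)
                if len(ptab):
                    ptab.loc[:, "proxy_of"] = snp
                    table = pd.concat([table, ptab], ignore_index=True)
                    provenance[proxy] = "proxy"
    counts.append(("harmonized instruments (incl. proxies)", len(table)))
    if table.empty:
        raise PipelineError("no instruments survived harmonization", trace)

    # 4. instrument strength --------------------------------------------------
    trace.append("strength")
    strength = None
    exp_n = exposure.records["n"].dropna()
    n_exp = int(exp_n.median()) if len(exp_n) else 0
    if n_exp and table["eaf"].notna().any():
        strength = ivs.instrument_strength(table["beta_exposure"], table["eaf"],
                                           n=n_exp, k=len(table))
        if strength.weak:
            warnings.warn(f"weak instruments: F = {strength.f_stat:.2f} <= 10",
                          stacklevel=2)

    # 5. first-pass estimates + diagnostics -----------------------------------
    trace.append("first-pass")
    bx, bxse, by, byse = est.from_frame(table)
    first_pass = {"ivw": est.ivw(bx, by, byse, model=ivw_model)}
    dx: dict = {}
    if len(table) >= 3:
        first_pass["egger"] = est.egger(bx, by, byse)
        dx["egger_intercept"] = diag.egger_intercept_test(first_pass["egger"])
    if len(table) >= 2:
        dx["heterogeneity"] = diag.heterogeneity(bx, by, byse)

    # 6. outlier removal: MR-PRESSO first, then leave-one-out, one pass -------
    trace.append("outlier-removal")
    work = table
    if len(work) >= 4:
        presso = diag.mr_presso(*_cols(work), snp_ids=list(work["snp_id"]),
                                n_sim=presso_n_sim, seed=seed,
                                outlier_alpha=presso_alpha)
        dx["presso"] = presso
        if presso.outliers:
            for snp in presso.outliers:
                excl_rows.append({"snp_id": snp, "reason": "outlier",
                                  "partner": "mr-presso", "r2": np.nan,
                                  "stage": "sensitivity"})
            work = work[~work["snp_id"].isin(presso.outliers)].reset_index(drop=True)
    if len(work) >= 3:
        loo = diag.leave_one_out(work, ivw_model=ivw_model)
        dx["leave_one_out"] = loo
        bad = list(loo.loc[loo["influential"], "snp_id"])
        if bad:
            for snp in bad:
                excl_rows.append({"snp_id": snp, "reason": "outlier",
                                  "partner": "leave-one-out", "r2": np.nan,
                                  "stage": "sensitivity"})
            work = work[~work["snp_id"].isin(bad)].reset_index(drop=True)
    counts.append(("instruments after outlier removal", len(work)))
    if work.empty:
        raise PipelineError("outlier removal emptied the instrument set", trace)

    # 7. final estimates -------------------------------------------------------
    trace.append("final-estimates")
    usable = [m for m in methods if len(work) >= (3 if m != "ivw" else 1)]
    estimates = est.estimate_all(work, ivw_model=ivw_model, n_boot=n_boot,
                                 seed=seed, methods=usable)
    bxf, bxsef, byf, bysef = est.from_frame(work)
    if len(work) >= 2:
        dx["heterogeneity_final"] = diag.heterogeneity(bxf, byf, bysef)
    dx["tables"] = diag.diagnostic_tables(work, estimates)

    prov_df = pd.DataFrame(
        [{"snp_id": s, "provenance": provenance.get(s, "index")}
         for s in work["snp_id"]])
    log_cols = ["snp_id", "reason", "partner", "r2", "stage"]
    return AnalysisResult(
        instruments=work,
        estimates=estimates,
        first_pass=first_pass,
        diagnostics=dx,
        exclusion_log=pd.DataFrame(excl_rows, columns=log_cols),
        harmonization={"counts": report.counts(),
                       "ambiguous": report.ambiguous,
                       "mismatched": report.mismatched,
                       "absent": report.absent},
        strength=strength,
        counts=counts,
        stage=stage,
        provenance=prov_df,
    )


def _cols(df: pd.DataFrame):
    return (df["beta_exposure"].to_numpy(float),
            df["beta_outcome"].to_numpy(float),
            df["se_outcome"].to_numpy(float),
            df["se_exposure"].to_numpy(float))


def results_table(estimates_per_trait: Mapping[str, Mapping[str, est.MREstimate]]
                  ) -> pd.DataFrame:
    """OR summary table: one row per (trait, method), 2-decimal OR formatting."""
    rows = []
    for trait, methods in estimates_per_trait.items():
        for method, e in methods.items():
            rows.append({
                "trait": trait, "method": method, "k": e.k,
                "OR": round(e.odds_ratio, 2),
                "OR_95CI": f"{e.odds_ratio:.2f} ({e.or_ci_low:.2f}, {e.or_ci_high:.2f})",
                "p": e.pvalue,
            })
    return pd.DataFrame(rows, columns=["trait", "method", "k", "OR", "OR_95CI", "p"])
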