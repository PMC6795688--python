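"""Reading, writing and harmonising GWAS summary statistics.

A *summary dataset* holds one association record per SNP for one trait:
effect/other allele, effect-allele frequency (EAF), beta (log odds ratio
for binary traits), standard error, p-value and per-SNP sample size.
Consortium files name these columns differently, so reading goes through a
*dialect* — a mapping from canonical field names to file column names.
Two presets mimic the large anthropometric-trait and late-onset
Alzheimer's consortium layouts; the latter carries no EAF column, which is
why EAF is optional throughout.

Harmonisation aligns an exposure and an outcome dataset to a shared effect
allele per SNP, the precondition for every two-sample MR estimator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "DIALECTS",
    "SummaryDataset",
    "ParseReport",
    "HarmonizationReport",
    "CohortOverlapTable",
    "read_summary",
    "write_summary",
    "harmonize",
    "sample_overlap",
]

#: Canonical field -> column name, per supported dialect.  The "default"
#: dialect is what :func:`write_summary` emits.
DIALECTS: dict[str, dict[str, str]] = {
    "default": {
        "snp_id": "SNP", "chrom": "CHR", "pos": "POS",
        "effect_allele": "EA", "other_allele": "OA", "eaf": "EAF",
        "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N",
    },
    # GIANT-consortium-like anthropometric trait files.
    "giant": {
        "snp_id": "MarkerName", "chrom": "Chr", "pos": "Pos",
        "effect_allele": "A1", "other_allele": "A2",
        "eaf": "FreqAllele1HapMapCEU", "beta": "b", "se": "se",
        "pvalue": "p", "n": "N",
    },
    # IGAP-like disease files: log-OR scale, no EAF column.
    "igap": {
        "snp_id": "MarkerName", "chrom": "Chromosome", "pos": "Position",
        "effect_allele": "Effect_allele", "other_allele": "Non_Effect_allele",
        "beta": "Beta", "se": "SE", "pvalue": "Pvalue",
    },
}

_REQUIRED = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pvalue")
_OPTIONAL = ("eaf", "n")
_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: Fixed column order of the default on-disk layout.
DEFAULT_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


@dataclass
class ParseReport:
    """Bookkeeping from :func:`read_summary`: rows seen and rows dropped, by reason."""

    n_rows: int = 0
    n_valid: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def add_dropped(self, reason: str, count: int) -> None:
        if count:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(count)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SummaryDataset:
    """One GWAS summary-statistic table for one trait.

    ``records`` is a DataFrame with canonical columns (``snp_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
    ``pvalue``, ``n``); ``snp_id`` is unique.  ``beta`` is on the per-allele
    SD scale for continuous traits and the log-OR scale for binary traits.
    ``sd_per_unit`` records the phenotype SD in natural units (e.g. 4.69
    kg/m^2 for BMI) so "per 1-SD" results can be translated back.
    """

    trait: str
    trait_type: str  # "continuous" | "binary"
    records: pd.DataFrame
    sd_per_unit: float | None = None
    parse_report: ParseReport | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}")
        if self.records["snp_id"].duplicated().any():
            raise InputError(f"duplicate snp_id in dataset {self.trait!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in set(self.records["snp_id"])

    def get(self, snp_id: str) -> pd.Series:
        sub = self.records.loc[self.records["snp_id"] == snp_id]
        if sub.empty:
            raise KeyError(snp_id)
        return sub.iloc[0]

    def subset(self, snp_ids: Iterable[str]) -> "SummaryDataset":
        keep = set(snp_ids)
        return SummaryDataset(
            trait=self.trait, trait_type=self.trait_type,
            records=self.records[self.records["snp_id"].isin(keep)].reset_index(drop=True),
            sd_per_unit=self.sd_per_unit,
        )

    def positions(self) -> dict[str, tuple[str, int]]:
        """snp_id -> (chrom, pos) lookup for distance-aware operations."""
        return {
            r.snp_id: (str(r.chrom), int(r.pos))
            for r in self.records.itertuples()
        }


def _resolve_dialect(dialect: str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return dict(DIALECTS[dialect])
        except KeyError:
            raise ConfigurationError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}") from None
    return dict(dialect)


def read_summary(source, dialect: str | Mapping[str, str] = "default", *,
                 trait: str = "trait", trait_type: str = "continuous",
                 sd_per_unit: float | None = None) -> SummaryDataset:
    """Read a tab-separated summary-statistic table into a :class:`SummaryDataset`.

    Rows violating record invariants (non-ACGT or identical alleles,
    non-positive SE, EAF outside [0, 1], p-value outside (0, 1], duplicate
    rsID) are dropped and counted in ``dataset.parse_report`` rather than
    raising — consortium files routinely contain unusable rows.

    Raises
    ------
    ConfigurationError
        A required column named by the dialect is absent from the header.
    InputError
        No valid rows remain after filtering.
    """
    mapping = _resolve_dialect(dialect)
    df = pd.read_csv(source, sep="\t", dtype={mapping.get("chrom", "CHR"): str},
                     na_values=["NA", "na", ""], keep_default_na=True)

    missing = [mapping[f] for f in _REQUIRED if mapping.get(f) not in df.columns]
    if missing:
        raise ConfigurationError(f"required column(s) missing from header: {missing}")

    out = pd.DataFrame()
    for fld in _REQUIRED + _OPTIONAL:
        col = mapping.get(fld)
        out[fld] = df[col] if col in df.columns else np.nan

    report = ParseReport(n_rows=len(out))

    out["snp_id"] = out["snp_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    for allele_col in ("effect_allele", "other_allele"):
        out[allele_col] = out[allele_col].astype(str).str.upper()
    for num_col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        out[num_col] = pd.to_numeric(out[num_col], errors="coerce")

    ok_alleles = (out["effect_allele"].isin(_VALID_ALLELES)
                  & out["other_allele"].isin(_VALID_ALLELES)
                  & (out["effect_allele"] != out["other_allele"]))
    ok_se = out["se"] > 0
    ok_eaf = out["eaf"].isna() | ((out["eaf"] >= 0) & (out["eaf"] <= 1))
    ok_p = (out["pvalue"] > 0) & (out["pvalue"] <= 1)
    ok_core = out["beta"].notna() & out["pos"].notna()

    report.add_dropped("invalid_alleles", int((~ok_alleles).sum()))
    report.add_dropped("invalid_se", int((ok_alleles & ~ok_se.fillna(False)).sum()))
    report.add_dropped("invalid_eaf", int((ok_alleles & ok_se.fillna(False) & ~ok_eaf).sum()))
    report.add_dropped("invalid_pvalue",
                       int((ok_alleles & ok_se.fillna(False) & ok_eaf & ~ok_p.fillna(False)).sum()))
    keep = ok_alleles & ok_se.fillna(False) & ok_eaf & ok_p.fillna(False) & ok_core
    report.add_dropped("missing_fields",
                       int((ok_alleles & ok_se.fillna(False) & ok_eaf & ok_p.fillna(False) & ~ok_core).sum()))
    out = out[keep]

    dup = out["snp_id"].duplicated(keep="first")
    report.add_dropped("duplicate_snp", int(dup.sum()))
    out = out[~dup].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)

    report.n_valid = len(out)
    if report.n_valid == 0:
        raise InputError("no valid rows after filtering")

    return SummaryDataset(trait=trait, trait_type=trait_type, records=out,
                          sd_per_unit=sd_per_unit, parse_report=report)


def write_summary(dataset: SummaryDataset, sink) -> None:
    """Write a dataset as a tab-separated table in the default dialect.

    Column order is fixed (``SNP CHR POS EA OA EAF BETA SE P N``); missing
    EAF/N cells are written as ``NA``.  The output round-trips through
    :func:`read_summary` with the default dialect.
    """
    mapping = DIALECTS["default"]
    inv = {fld: col for fld, col in mapping.items()}
    df = dataset.records.rename(columns=inv)[DEFAULT_COLUMNS]
    df.to_csv(sink, sep="\t", index=False, na_rep="NA")


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC_PAIRS


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizationReport:
    """Per-category SNP lists from :func:`harmonize`.

    Every requested SNP lands in exactly one of: ``harmonized``,
    ``ambiguous`` (palindromic with EAF near 0.5 or missing), ``mismatched``
    (incompatible allele sets) or ``absent`` (missing from the outcome —
    a proxy is needed).
    """

    harmonized: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)
    mismatched: list[str] = field(default_factory=list)
    absent: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in
                ("harmonized", "ambiguous", "mismatched", "absent")}


def harmonize(exposure: SummaryDataset, outcome: SummaryDataset,
              snps: Iterable[str] | None = None, *,
              palindrome_eaf_window: float = 0.08,
              allow_strand_flip: bool = True,
              ) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align exposure and outcome effects to one effect allele per SNP.

    For each requested SNP present in both datasets:

    * same effect/other alleles -> copy the outcome effect;
    * swapped alleles -> negate the outcome beta and flip its EAF;
    * palindromic pair (A/T or C/G) with either EAF within
      ``0.5 +/- palindrome_eaf_window`` or missing -> "ambiguous", dropped;
    * palindromic but unambiguous -> aligned by EAF agreement (same side of
      0.5 keeps the outcome effect, opposite sides flip it);
    * otherwise -> "mismatched", dropped.  With ``allow_strand_flip`` the
      outcome alleles are first complemented when that makes them
      compatible (cannot apply to palindromic pairs).

    SNPs absent from the outcome are reported as needing a proxy.

    Returns a harmonized-instrument table (columns ``snp_id``,
    ``beta_exposure``, ``se_exposure``, ``beta_outcome``, ``se_outcome``,
    ``eaf``, ``proxy_of``) and the category report.
    """
    if snps is None:
        snps = list(exposure.records["snp_id"])
    else:
        snps = list(snps)
        missing_exp = set(snps) - set(exposure.records["snp_id"])
        if missing_exp:
            raise InputError(f"requested SNPs absent from exposure: {sorted(missing_exp)[:5]}")

    exp = exposure.records.set_index("snp_id")
    out = outcome.records.set_index("snp_id")
    report = HarmonizationReport()
    rows = []

    for snp in snps:
        e = exp.loc[snp]
        if snp not in out.index:
            report.absent.append(snp)
            continue
        o = out.loc[snp]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        o_beta, o_eaf = float(o["beta"]), o["eaf"]

        if _is_palindromic(e_ea, e_oa):
            if {o_ea, o_oa} != {e_ea, e_oa}:
                report.mismatched.append(snp)
                continue
            e_f, o_f = e["eaf"], o_eaf
            near_half = lambda f: (pd.isna(f)
                                   or abs(f - 0.5) <= palindrome_eaf_window)
            if near_half(e_f) or near_half(o_f):
                report.ambiguous.append(snp)
                continue
            # Align by frequency agreement: the outcome's effect allele is
            # the exposure's effect allele iff their EAFs sit on the same
            # side of 0.5 (strand flips swap the labels but not the
            # frequency of the underlying variant).
            same_side = (e_f - 0.5) * (o_f - 0.5) > 0
            if o_ea == e_ea:
                aligned_beta = o_beta if same_side else -o_beta
            else:  # labels swapped in the file
                aligned_beta = -o_beta if same_side else o_beta
        else:
            if allow_strand_flip and {o_ea, o_oa} & (_VALID_ALLELES - {e_ea, e_oa}):
                flipped = (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa])
                if set(flipped) == {e_ea, e_oa}:
                    o_ea, o_oa = flipped
            if (o_ea, o_oa) == (e_ea, e_oa):
                aligned_beta = o_beta
            elif (o_ea, o_oa) == (e_oa, e_ea):
                aligned_beta = -o_beta
                if not pd.isna(o_eaf):
                    o_eaf = 1.0 - o_eaf
            else:
                report.mismatched.append(snp)
                continue

        report.harmonized.append(snp)
        rows.append({
            "snp_id": snp,
            "beta_exposure": float(e["beta"]), "se_exposure": float(e["se"]),
            "beta_outcome": float(aligned_beta), "se_outcome": float(o["se"]),
            "eaf": float(e["eaf"]) if not pd.isna(e["eaf"]) else np.nan,
            "proxy_of": None,
        })

    cols = ["snp_id", "beta_exposure", "se_exposure", "beta_outcome",
            "se_outcome", "eaf", "proxy_of"]
    table = pd.DataFrame(rows, columns=cols)
    return table, report


@dataclass
class CohortOverlapTable:
    """Participant counts of potentially overlapping cohorts per dataset.

    ``counts``: DataFrame indexed by cohort name, one column per trait
    dataset.  ``totals``: Series of total participants per dataset.
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any() or (self.totals < 0).any():
            raise InputError("cohort counts and totals must be non-negative")


def sample_overlap(table: CohortOverlapTable) -> pd.Series:
    """Per-dataset overlap proportion, as a percentage rounded to 2 decimals.

    proportion = (sum of overlapping-cohort counts) / (total participants).
    """
    if (table.totals == 0).any():
        zero = table.totals.index[table.totals == 0].tolist()
        raise InputError(f"zero total participants for dataset(s): {zero}")
    pct = 100.0 * table.counts.sum(axis=0) / table.totals
    return pct.round(2)


def read_overlap_table(source) -> CohortOverlapTable:
    """Read a cohort-overlap table: tab-separated, first column cohort names,
    one column per dataset, with a final ``Total`` row of dataset sizes."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    if "Total" not in df.index:
        raise ConfigurationError("overlap table needs a 'Total' row")
    totals = df.loc["Total"]
    counts = df.drop(index="Total")
    return CohortOverlapTable(counts=counts, totals=totals)
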