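"""Instrument selection and validation.

Covers the IV-selection stages of a two-sample MR analysis: greedy LD
clumping of genome-wide-significant SNPs to an approximately independent
index set, exclusion of candidates in LD with confounder-associated or
APOE-region variants, proxy substitution for SNPs unusable in the outcome
dataset, and instrument-strength statistics (variance explained R^2 and
the F statistic, with the conventional F > 10 weak-instrument screen).

LD is consumed as input (a pairwise r^2 lookup), never computed from
genotypes here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .gwas_io import SummaryDataset, _is_palindromic

__all__ = [
    "LDMatrix",
    "InstrumentStrength",
    "clump",
    "exclude_by_ld",
    "exclude_apoe",
    "find_proxy",
    "instrument_strength",
]

#: Default APOE-region window (chromosome, start, end; single assumed build).
APOE_REGION = ("19", 45_000_000, 45_800_000)
APOE_SNPS = ("rs429358", "rs7412")


class LDMatrix:
    """Symmetric pairwise r^2 lookup.

    Absent pairs are treated as r^2 = 0 and the diagonal as 1.  Optionally
    carries (chrom, pos) per SNP for distance checks.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None,
                 positions: Mapping[str, tuple[str, int]] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, set[str]] = {}
        self.positions = dict(positions or {})
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputError(f"r^2 must lie in [0, 1], got {r2} for ({a}, {b})")
        if a == b:
            return
        self._r2[self._key(a, b)] = float(r2)
        self._neighbors.setdefault(a, set()).add(b)
        self._neighbors.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def neighbors(self, snp: str) -> set[str]:
        """SNPs with an explicit (possibly zero) r^2 entry against ``snp``."""
        return set(self._neighbors.get(snp, ()))

    @classmethod
    def from_long(cls, source, positions=None) -> "LDMatrix":
        """Load from a tab-separated long table with columns snp_a, snp_b, r2."""
        df = pd.read_csv(source, sep="\t")
        need = {"snp_a", "snp_b", "r2"}
        if not need <= set(df.columns):
            raise ConfigurationError(f"LD long format needs columns {sorted(need)}")
        return cls({(r.snp_a, r.snp_b): r.r2 for r in df.itertuples()},
                   positions=positions)

    @classmethod
    def from_square(cls, source, positions=None) -> "LDMatrix":
        """Load from a tab-separated square matrix with SNP ids as index/header."""
        df = pd.read_csv(source, sep="\t", index_col=0)
        m = cls(positions=positions)
        ids = list(df.index)
        arr = df.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise InputError("square LD matrix is not symmetric")
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if arr[i, j] != 0.0:
                    m.set(a, ids[j], arr[i, j])
        return m

    def to_long_frame(self) -> pd.DataFrame:
        rows = [{"snp_a": a, "snp_b": b, "r2": r2}
                for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def clump(dataset: SummaryDataset, ld: LDMatrix, *,
          p_threshold: float = 5e-8, r2_threshold: float = 0.001,
          window_kb: float = 10_000) -> list[str]:
    """Greedy LD clumping to an index-SNP set.

    SNPs below ``p_threshold`` are ranked by ascending p-value (rsID breaks
    ties, making the result independent of input row order).  The
    best-ranked remaining SNP is kept and every other remaining SNP on the
    same chromosome within ``window_kb`` whose r^2 with it is >=
    ``r2_threshold`` is removed; repeat until exhausted.

    A SNP is removed only when it is both within the window and above the
    r^2 threshold relative to an index SNP.
    """
    rec = dataset.records
    sig = rec[rec["pvalue"] < p_threshold]
    ranked = sig.sort_values(["pvalue", "snp_id"], kind="mergesort")
    remaining = list(ranked.itertuples())
    index_set: list[str] = []
    window_bp = window_kb * 1_000

    while remaining:
        best = remaining.pop(0)
        index_set.append(best.snp_id)
        kept = []
        for r in remaining:
            same_chr = str(r.chrom) == str(best.chrom)
            within = abs(int(r.pos) - int(best.pos)) <= window_bp
            linked = ld.r2(r.snp_id, best.snp_id) >= r2_threshold
            if not (same_chr and within and linked):
                kept.append(r)
        remaining = kept
    return index_set


def exclude_by_ld(candidates: Sequence[str], exclusion_snps: Sequence[str],
                  ld: LDMatrix, r2_cutoff: float, *,
                  reason: str = "confounder-LD",
                  ) -> tuple[list[str], list[dict]]:
    """Drop candidates in LD with any exclusion SNP at r^2 >= ``r2_cutoff``.

    Returns (retained ids, exclusion records).  Each exclusion record holds
    the candidate, the reason tag, the worst partner and its r^2.
    """
    if not (0.0 < r2_cutoff <= 1.0):
        raise ConfigurationError(f"r2_cutoff must lie in (0, 1], got {r2_cutoff}")
    retained, excluded = [], []
    excl = [s for s in exclusion_snps]
    for snp in candidates:
        worst_r2, worst_partner = 0.0, None
        for other in excl:
            if other == snp:
                continue
            r2 = ld.r2(snp, other)
            if r2 > worst_r2:
                worst_r2, worst_partner = r2, other
        if worst_partner is not None and worst_r2 >= r2_cutoff:
            excluded.append({"snp_id": snp, "reason": reason,
                             "partner": worst_partner, "r2": worst_r2})
        else:
            retained.append(snp)
    return retained, excluded


def exclude_apoe(candidates: Sequence[str], ld: LDMatrix,
                 positions: Mapping[str, tuple[str, int]] | None = None, *,
                 apoe_snps: Sequence[str] = APOE_SNPS,
                 r2_cutoff: float = 0.1,
                 region: tuple[str, int, int] | None = APOE_REGION,
                 ) -> tuple[list[str], list[dict]]:
    """Remove candidates linked to the APOE locus.

    A candidate is dropped when its r^2 with rs429358/rs7412 reaches
    ``r2_cutoff`` or, when positions are known, when it falls inside the
    configured APOE window.  APOE is by far the strongest genetic risk
    locus for late-onset Alzheimer's disease, so instruments must be
    demonstrably unlinked to it.
    """
    positions = dict(positions or ld.positions)
    retained, excluded = exclude_by_ld(candidates, apoe_snps, ld, r2_cutoff,
                                       reason="APOE")
    if region is not None:
        chrom, start, end = region
        still = []
        for snp in retained:
            cp = positions.get(snp)
            if cp is not None and str(cp[0]) == str(chrom) and start <= cp[1] <= end:
                excluded.append({"snp_id": snp, "reason": "APOE",
                                 "partner": "region", "r2": np.nan})
            else:
                still.append(snp)
        retained = still
    return retained, excluded


def find_proxy(target: str, exposure: SummaryDataset, outcome: SummaryDataset,
               ld: LDMatrix, *, r2_min: float = 0.9,
               exclusion_snps: Sequence[str] = (),
               exclusion_r2_cutoff: float = 0.5,
               palindrome_eaf_window: float = 0.08,
               apoe_snps: Sequence[str] = APOE_SNPS,
               apoe_r2_cutoff: float = 0.1) -> str | None:
    """Find a substitute SNP in high LD (r^2 > ``r2_min``) with ``target``.

    Candidates must be present in both datasets, not an ambiguous
    palindrome in the exposure, and pass the confounder-LD and APOE
    screens.  Ties break by higher r^2, then smaller exposure p-value,
    then lexicographic rsID.  Returns ``None`` when nothing qualifies.
    """
    exp_ids = set(exposure.records["snp_id"])
    out_ids = set(outcome.records["snp_id"])
    exp = exposure.records.set_index("snp_id")

    candidates = []
    for snp in ld.neighbors(target):
        r2 = ld.r2(target, snp)
        if r2 <= r2_min or snp == target:
            continue
        if snp not in exp_ids or snp not in out_ids:
            continue
        e = exp.loc[snp]
        if _is_palindromic(e["effect_allele"], e["other_allele"]):
            f = e["eaf"]
            if pd.isna(f) or abs(f - 0.5) <= palindrome_eaf_window:
                continue
        ok_conf, _ = exclude_by_ld([snp], exclusion_snps, ld, exclusion_r2_cutoff)
        if not ok_conf:
            continue
        ok_apoe, _ = exclude_by_ld([snp], apoe_snps, ld, apoe_r2_cutoff)
        if not ok_apoe:
            continue
        candidates.append((-r2, float(e["pvalue"]), snp))

    if not candidates:
        return None
    candidates.sort()
    return candidates[0][2]


@dataclass
class InstrumentStrength:
    """Variance explained and F statistic for an instrument set.

    R^2 = sum_j 2 f_j (1 - f_j) beta_j^2 for a standardized exposure;
    F = R^2 (n - k - 1) / (k (1 - R^2)).  ``weak`` flags F <= 10, the
    conventional weak-instrument threshold.
    """

    r2_total: float
    f_stat: float
    k: int
    n: int
    weak: bool = field(init=False)

    def __post_init__(self) -> None:
        self.weak = self.f_stat <= 10.0


def instrument_strength(betas: Sequence[float], eafs: Sequence[float],
                        n: int, k: int | None = None) -> InstrumentStrength:
    """Instrument R^2 and F from per-SNP standardized effects and EAFs.

    SNPs with missing EAF are excluded from R^2 with a warning (they still
    count toward ``k`` unless ``k`` is passed explicitly).
    """
    betas = np.asarray(betas, dtype=float)
    eafs = np.asarray(eafs, dtype=float)
    if betas.shape != eafs.shape:
        raise InputError("betas and eafs must have equal length")
    missing = np.isnan(eafs)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} instrument(s) lack EAF; "
                      "excluded from the R^2 sum", stacklevel=2)
    f = eafs[~missing]
    b = betas[~missing]
    r2 = float(np.sum(2.0 * f * (1.0 - f) * b ** 2))
    if k is None:
        k = len(betas)
    if k == 0 or r2 >= 1.0:
        raise InputError("need k >= 1 instruments and R^2 < 1")
    f_stat = r2 * (n - k - 1) / (k * (1.0 - r2)) if r2 > 0 else 0.0
    return InstrumentStrength(r2_total=r2, f_stat=float(f_stat), k=int(k), n=int(n))
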