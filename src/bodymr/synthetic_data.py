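"""Synthetic GWAS-summary-data generator with known ground truth.

Emulates the shape of the real inputs — a large continuous-trait exposure
GWAS (n ~ 322k) and a case-control outcome GWAS (17k cases / 37k
controls) — at instrument scale: k instrument SNPs whose true effects
explain a target fraction of exposure variance, optional null decoys,
block LD structure, and configurable pleiotropy / heterogeneity /
harmonization hazards (palindromic SNPs, swapped-allele representation).
Every draw is seeded, and the truth record makes each fixture
self-describing, so the whole pipeline is exercisable without downloads.

Generative model per instrument j:

* f_j ~ Uniform(0.05, 0.95); true beta_xj proportional to
  Uniform(0.8, 1.2), scaled so sum 2 f (1-f) beta_x^2 = target_r2 exactly
  (the narrow spread keeps every instrument genome-wide significant at the
  emulated sample sizes);
* se_xj = 1/sqrt(2 f (1-f) n_exposure) (unit-variance trait);
* observed beta_x ~ Normal(true beta_x, se_x);
* true beta_yj = true_beta * beta_xj + pleiotropy_j + Normal(0,
  heterogeneity_sd), with pleiotropy "directional" adding a constant c and
  "balanced" adding +/- delta alternately;
* se_yj = 1/sqrt(2 f (1-f) N K (1-K)) for the binary outcome (case
  fraction K), observed beta_y ~ Normal(true beta_y, se_y).

Decoy SNPs carry beta_x = 0 and are never genome-wide significant except
by chance.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .gwas_io import SummaryDataset, write_summary
from .instruments import LDMatrix

__all__ = ["TruthConfig", "Bundle", "generate_summary_pair",
           "generate_ld_matrix", "generate_bundle", "write_fixture_bundle"]

_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                          ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class TruthConfig:
    """Ground-truth parameterization of a synthetic summary-data pair."""

    k: int = 60
    target_r2: float = 0.0214
    n_exposure: int = 322_154
    n_cases: int = 17_008
    n_controls: int = 37_154
    true_beta: float = 0.0                # causal log-OR per SD exposure
    pleiotropy: str = "none"              # none | balanced | directional
    pleiotropy_value: float = 0.0
    heterogeneity_sd: float = 0.0
    ld_blocks: list[tuple[int, float]] | None = None  # (size, within-block r2)
    n_decoys: int = 5
    palindromic_fraction: float = 0.10
    swapped_fraction: float = 0.10
    confounder_ld: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("k must be >= 1")
        if not (0.0 < self.target_r2 < 1.0):
            raise InputError("target_r2 must lie in (0, 1)")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise InputError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        for _size, r2 in self.ld_blocks or []:
            if not (0.0 <= r2 <= 1.0):
                raise InputError("block r^2 must lie in [0, 1]")


@dataclass
class Bundle:
    """Everything one synthetic study needs, in memory."""

    exposure: SummaryDataset
    outcome: SummaryDataset
    ld: LDMatrix
    truth: dict
    confounder_snps: list[str]


def _blocks(cfg: TruthConfig) -> list[tuple[list[int], float]]:
    """Partition instrument indices 0..k-1 into LD blocks (singletons by default)."""
    if not cfg.ld_blocks:
        return [([j], 0.0) for j in range(cfg.k)]
    out, j = [], 0
    for size, r2 in cfg.ld_blocks:
        members = list(range(j, min(j + size, cfg.k)))
        if members:
            out.append((members, r2))
        j += size
    for rest in range(j, cfg.k):
        out.append(([rest], 0.0))
    return out


def _generate(cfg: TruthConfig) -> Bundle:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    k, nd = cfg.k, cfg.n_decoys
    total = k + nd + len(cfg.confounder_ld)

    ids = [f"rs{1000 + j}" for j in range(k)]
    decoy_ids = [f"rs{9000 + j}" for j in range(nd)]
    conf_ids = [f"rs{7000 + j}" for j in range(len(cfg.confounder_ld))]

    # --- layout: each block on its own distant locus --------------------
    blocks = _blocks(cfg)
    chroms, poss = {}, {}
    locus = 0
    for members, _r2 in blocks:
        chrom = str(1 + locus % 22)
        base = 1_000_000 + (locus // 22) * 50_000_000
        for off, j in enumerate(members):
            chroms[ids[j]], poss[ids[j]] = chrom, base + 5_000 * off
        locus += 1
    for d, snp in enumerate(decoy_ids):
        chroms[snp] = str(1 + (locus + d) % 22)
        poss[snp] = 1_000_000 + ((locus + d) // 22) * 50_000_000
    # confounder-linked SNPs sit right next to their instrument
    for c, (j, _r2) in enumerate(cfg.confounder_ld):
        snp = conf_ids[c]
        chroms[snp] = chroms[ids[j]]
        poss[snp] = poss[ids[j]] + 1_000

    # --- true effects ----------------------------------------------------
    # Per-SNP variance explained is made MAF-independent (beta proportional
    # to 1/sqrt(2f(1-f))), so every instrument clears genome-wide
    # significance at the emulated sample size; the Uniform(0.8, 1.2) shape
    # gives a modest spread of contributions.
    f = rng.uniform(0.05, 0.95, size=total)
    shape = rng.uniform(0.8, 1.2, size=k)
    var_weight = 2 * f[:k] * (1 - f[:k])
    scale2 = cfg.target_r2 / np.sum(shape ** 2)
    if scale2 <= 0 or not np.isfinite(scale2):
        raise InputError("infeasible target_r2 for this instrument count")
    beta_x_true = np.zeros(total)
    beta_x_true[:k] = (shape * np.sqrt(scale2 / var_weight)
                       * rng.choice([-1.0, 1.0], size=k))

    # Pleiotropy acts in the exposure-increasing-allele frame: "directional"
    # pushes the outcome the same way for every instrument once each is
    # oriented to a positive exposure effect (the frame MR-Egger fits in).
    orient = np.sign(beta_x_true)
    pleio = np.zeros(total)
    if cfg.pleiotropy == "directional":
        pleio[:k] = cfg.pleiotropy_value * orient[:k]
    elif cfg.pleiotropy == "balanced":
        pleio[:k] = (cfg.pleiotropy_value * orient[:k]
                     * np.where(np.arange(k) % 2 == 0, 1.0, -1.0))
    het = rng.normal(0.0, cfg.heterogeneity_sd, size=total) if cfg.heterogeneity_sd else 0.0
    beta_y_true = cfg.true_beta * beta_x_true + pleio + het

    # --- observed summary statistics -------------------------------------
    n_out = cfg.n_cases + cfg.n_controls
    K = cfg.n_cases / n_out
    se_x = 1.0 / np.sqrt(2 * f * (1 - f) * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(2 * f * (1 - f) * n_out * K * (1 - K))
    bx_obs = rng.normal(beta_x_true, se_x)
    by_obs = rng.normal(beta_y_true, se_y)

    from scipy.stats import norm
    p_x = np.clip(2 * norm.sf(np.abs(bx_obs / se_x)), 1e-300, 1.0)
    p_y = np.clip(2 * norm.sf(np.abs(by_obs / se_y)), 1e-300, 1.0)

    # --- alleles and harmonization hazards --------------------------------
    all_ids = ids + decoy_ids + conf_ids
    pal_mask = rng.random(total) < cfg.palindromic_fraction
    swap_mask = rng.random(total) < cfg.swapped_fraction
    ea, oa = [], []
    for i in range(total):
        pool = _PALINDROMIC_PAIRS if pal_mask[i] else _NON_PALINDROMIC_PAIRS
        a1, a2 = pool[rng.integers(len(pool))]
        ea.append(a1)
        oa.append(a2)

    def frame(beta, se, p, *, swap=False):
        rows = []
        for i, snp in enumerate(all_ids):
            e_a, o_a, b, fq = ea[i], oa[i], beta[i], f[i]
            if swap and swap_mask[i]:
                # same association, opposite allele labelling
                e_a, o_a, b, fq = o_a, e_a, -b, 1 - fq
            rows.append({"snp_id": snp, "chrom": chroms[snp], "pos": poss[snp],
                         "effect_allele": e_a, "other_allele": o_a, "eaf": fq,
                         "beta": b, "se": se[i], "pvalue": p[i]})
        return pd.DataFrame(rows)

    exp_df = frame(bx_obs, se_x, p_x)
    exp_df["n"] = cfg.n_exposure
    out_df = frame(by_obs, se_y, p_y, swap=True)
    out_df["n"] = n_out

    exposure = SummaryDataset(trait="exposure", trait_type="continuous",
                              records=exp_df, sd_per_unit=4.69)
    outcome = SummaryDataset(trait="outcome", trait_type="binary",
                             records=out_df)

    # --- LD ---------------------------------------------------------------
    positions = {snp: (chroms[snp], poss[snp]) for snp in all_ids}
    ld = LDMatrix(positions=positions)
    for members, r2 in blocks:
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                ld.set(ids[members[ai]], ids[members[bi]], r2)
    for c, (j, r2) in enumerate(cfg.confounder_ld):
        ld.set(conf_ids[c], ids[j], r2)

    truth = {
        "seed": cfg.seed,
        "config": {**asdict(cfg),
                   "ld_blocks": [list(b) for b in cfg.ld_blocks or []],
                   "confounder_ld": [list(c) for c in cfg.confounder_ld]},
        "instrument_ids": ids,
        "decoy_ids": decoy_ids,
        "confounder_ids": conf_ids,
        "true_beta": cfg.true_beta,
        "beta_x_true": beta_x_true[:k].tolist(),
        "beta_y_true": np.asarray(beta_y_true)[:k].tolist(),
        "eaf": f[:k].tolist(),
        "realized_r2": float(np.sum(2 * f[:k] * (1 - f[:k]) * beta_x_true[:k] ** 2)),
        "palindromic": [all_ids[i] for i in range(total) if pal_mask[i]],
        "swapped_in_outcome": [all_ids[i] for i in range(total) if swap_mask[i]],
    }
    return Bundle(exposure=exposure, outcome=outcome, ld=ld, truth=truth,
                  confounder_snps=conf_ids)


def generate_bundle(cfg: TruthConfig) -> Bundle:
    """Generate the full in-memory fixture bundle (deterministic in cfg)."""
    return _generate(cfg)


def generate_summary_pair(cfg: TruthConfig
                          ) -> tuple[SummaryDataset, SummaryDataset, dict]:
    """(exposure dataset, outcome dataset, truth record)."""
    b = _generate(cfg)
    return b.exposure, b.outcome, b.truth


def generate_ld_matrix(cfg: TruthConfig) -> LDMatrix:
    """The LD lookup consistent with :func:`generate_summary_pair` for ``cfg``."""
    return _generate(cfg).ld


def write_fixture_bundle(cfg: TruthConfig, directory) -> dict[str, Path]:
    """Write the bundle as plain-text files re-readable by the I/O layer.

    Emits the exposure table in both the default and GIANT-like dialects,
    the outcome table in both the default and IGAP-like dialects, the LD
    long table, the confounder rsID list and the truth record (JSON,
    including the seed).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    b = _generate(cfg)
    paths = {}

    paths["exposure"] = directory / "exposure.tsv"
    write_summary(b.exposure, paths["exposure"])
    paths["outcome"] = directory / "outcome.tsv"
    write_summary(b.outcome, paths["outcome"])

    # dialect variants
    from .gwas_io import DIALECTS
    def redialect(ds, dialect, path):
        mapping = DIALECTS[dialect]
        default = DIALECTS["default"]
        df = ds.records.rename(columns={fld: default[fld] for fld in default})
        df = df[[default[f] for f in default if default[f] in df.columns]]
        rename = {default[f]: mapping[f] for f in mapping}
        df = df[[default[f] for f in mapping]].rename(columns=rename)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    paths["exposure_giant"] = directory / "exposure.giant.tsv"
    redialect(b.exposure, "giant", paths["exposure_giant"])
    paths["outcome_igap"] = directory / "outcome.igap.tsv"
    redialect(b.outcome, "igap", paths["outcome_igap"])

    paths["ld"] = directory / "ld.tsv"
    b.ld.to_long_frame().to_csv(paths["ld"], sep="\t", index=False)

    paths["confounders"] = directory / "confounder_snps.txt"
    paths["confounders"].write_text("\n".join(b.confounder_snps) + "\n"
                                    if b.confounder_snps else "")

    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(json.dumps(b.truth, indent=1))
    return paths
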