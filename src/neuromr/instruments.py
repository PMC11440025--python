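"""Instrument (genetic IV) selection: p-value screen, LD clumping, strength filter.

The default pipeline mirrors standard two-sample MR practice: retain
genome-wide-significant SNPs (p < 5e-8), greedily clump to r² < 0.001 within
a ±10,000 kb window, then require per-SNP F = beta²/se² > 10.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, SummaryStatsTable

GENOME_WIDE_P = 5e-8
RELAXED_P = 5e-6


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than an estimator's arity requires."""


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure plus per-stage selection counts.

    ``f_stats`` and ``r2_explained`` are aligned with ``table.df`` rows;
    ``selection_log`` records counts removed at each filter stage.
    """

    exposure_name: str
    table: SummaryStatsTable
    f_stats: np.ndarray
    r2_explained: np.ndarray
    selection_log: dict[str, int] = field(default_factory=dict)
    p_threshold: float | None = None

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table.df["snp_id"])

    @property
    def n_snps(self) -> int:
        return len(self.table.df)


def select_by_pvalue(table: SummaryStatsTable, threshold: float) -> SummaryStatsTable:
    """Rows with p strictly below ``threshold``; input order preserved."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    df = table.df[table.df["pvalue"] < threshold].reset_index(drop=True)
    return SummaryStatsTable(table.trait_name, table.trait_type, df)


def ld_clump(
    table: SummaryStatsTable,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> SummaryStatsTable:
    """Greedy p-value-ranked LD clumping.

    Repeatedly take the remaining SNP with the smallest p-value as index and
    remove every other remaining SNP on the same chromosome within
    ``window_kb`` kilobases having r² >= ``r2_max`` with it. Ties on p are
    broken by snp_id so the result is independent of input row order. SNPs
    absent from ``ld`` are treated as uncorrelated.
    """
    df = table.df.sort_values(["pvalue", "snp_id"], kind="mergesort")
    order = list(df.index)
    snp = df["snp_id"].to_dict()
    chrom = df["chrom"].to_dict()
    pos = df["pos"].to_dict()
    window_bp = window_kb * 1000

    alive = dict.fromkeys(order, True)
    kept: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        for j in order:
            if alive[j] and chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp \
                    and ld.get(snp[i], snp[j]) >= r2_max:
                alive[j] = False

    keep_ids = {snp[i] for i in kept}
    out = table.df[table.df["snp_id"].isin(keep_ids)].reset_index(drop=True)
    return SummaryStatsTable(table.trait_name, table.trait_type, out)


def f_statistic(beta, se):
    """Per-SNP instrument-strength statistic F = beta² / se²."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    return beta**2 / se**2


def variance_explained(f, n):
    """Exposure variance explained by one SNP: R² = F / (F + N − 2).

    Inversion of the one-parameter relation F = R²(N−2)/(1−R²); monotone
    increasing in F at fixed N, and in [0, 1).
    """
    f = np.asarray(f, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("sample size must exceed 2")
    return f / (f + n - 2)


def build_instruments(
    table: SummaryStatsTable,
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    f_min: float = 10.0,
) -> InstrumentSet:
    """p-value screen -> LD clump -> F filter, with per-stage removal counts."""
    log: dict[str, int] = {"input": table.n_snps}
    sig = select_by_pvalue(table, p_threshold)
    log["removed_pvalue"] = table.n_snps - sig.n_snps
    clumped = ld_clump(sig, ld, r2_max=r2_max, window_kb=window_kb)
    log["removed_clump"] = sig.n_snps - clumped.n_snps

    f = f_statistic(clumped.df["beta"], clumped.df["se"]) if clumped.n_snps else np.array([])
    strong = clumped.df[f > f_min].reset_index(drop=True) if clumped.n_snps else clumped.df
    log["removed_weak"] = clumped.n_snps - len(strong)
    log["retained"] = len(strong)

    f_out = f_statistic(strong["beta"], strong["se"]) if len(strong) else np.array([])
    r2 = variance_explained(f_out, strong["n"]) if len(strong) else np.array([])
    out = SummaryStatsTable(table.trait_name, table.trait_type, strong)
    return InstrumentSet(table.trait_name, out, np.asarray(f_out), np.asarray(r2),
                         log, p_threshold=p_threshold)


def build_instruments_relaxed(
    table: SummaryStatsTable,
    ld: LDMatrix,
    min_instruments: int = 3,
    allow_relaxed: bool = True,
    **kwargs,
) -> InstrumentSet:
    """Genome-wide screen with fallback to the relaxed 5e-6 threshold.

    Used for mediator traits: if fewer than ``min_instruments`` survive at
    5e-8 and relaxation is allowed for the trait, re-select at 5e-6. The
    threshold actually used is recorded on the result.
    """
    strict = build_instruments(table, ld, p_threshold=GENOME_WIDE_P, **kwargs)
    if strict.n_snps >= min_instruments or not allow_relaxed:
        return strict
    relaxed = build_instruments(table, ld, p_threshold=RELAXED_P, **kwargs)
    relaxed.selection_log["relaxed_from"] = strict.n_snps
    return relaxed


def merge_instruments(
    sets: list[InstrumentSet],
    tables: list[SummaryStatsTable],
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> list[str]:
    """Merged instrument set for multivariable MR.

    Union of the per-exposure instrument SNPs, re-clumped jointly with the
    smallest p-value across exposures as the ranking key. Returns snp_ids.
    """
    rows = []
    for s in sets:
        rows.append(s.table.df[["snp_id", "chrom", "pos", "pvalue"]])
    pooled = pd.concat(rows, ignore_index=True)
    pooled = pooled.sort_values("pvalue").drop_duplicates("snp_id", keep="first")
    dummy = pooled.assign(
        effect_allele="A", other_allele="G", eaf=np.nan, beta=1.0, se=1.0, n=1000
    )
    from .sumstats import CANONICAL_COLUMNS

    tbl = SummaryStatsTable("merged", "continuous",
                            dummy[CANONICAL_COLUMNS].reset_index(drop=True))
    clumped = ld_clump(tbl, ld, r2_max=r2_max, window_kb=window_kb)
    return list(clumped.df["snp_id"])
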