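"""GWAS summary-statistics and LD containers with plain-text IO.

Effect sizes for binary traits are stored on the log-odds scale internally;
odds ratios appear only at the reporting boundary. Column mapping is explicit
(config-driven), never sniffed: GWAS header dialects vary too much for
sniffing to be safe.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]


class SumstatsError(ValueError):
    """Raised for malformed or empty summary-statistics input."""


@dataclass
class SummaryStatsTable:
    """Per-trait SNP-level association records.

    ``df`` holds one row per SNP with the canonical columns; ``snp_id`` is
    unique within the table. ``trait_type`` is ``"binary"`` (beta on the
    log-odds scale) or ``"continuous"``. ``drop_log`` counts rows removed
    during validation, keyed by reason.
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame
    drop_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        if self.df["snp_id"].duplicated().any():
            dup = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise SumstatsError(f"duplicate snp_id {dup!r} in {self.trait_name}")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStatsTable":
        """Rows for ``snp_ids``, in the given order; missing ids are skipped."""
        idx = self.df.set_index("snp_id")
        keep = [s for s in snp_ids if s in idx.index]
        out = idx.loc[keep].reset_index()[CANONICAL_COLUMNS]
        return SummaryStatsTable(self.trait_name, self.trait_type, out)

    def lookup(self) -> pd.DataFrame:
        return self.df.set_index("snp_id")


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating record invariants; count removals per reason."""
    log: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            log[reason] = log.get(reason, 0) + n
        return df[~mask]

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df = drop(~df["effect_allele"].isin(VALID_ALLELES)
              | ~df["other_allele"].isin(VALID_ALLELES), "non_acgt_allele")
    df = drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    df = drop(~(df["se"] > 0) | ~np.isfinite(df["se"]), "nonpositive_se")
    df = drop(~np.isfinite(df["beta"]), "missing_beta")
    df = drop(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue_out_of_range")
    df = drop(~(df["n"] > 0), "nonpositive_n")
    bad_eaf = df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0)
    df = drop(bad_eaf, "eaf_out_of_range")
    df = drop(df["snp_id"].duplicated(keep="first"), "duplicate_snp_id")
    return df, log


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str],
    trait_type: str,
    trait_name: str | None = None,
    sep: str | None = None,
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file with an explicit column map.

    ``column_map`` maps canonical field names to the file's column headers.
    The effect column is given either as ``"beta"`` or as ``"or"``; odds
    ratios are converted to log-odds on read. ``eaf`` may be omitted from the
    map, in which case frequencies are recorded as missing. Rows failing the
    record invariants are dropped and counted in ``drop_log``.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")

    effect_key = "or" if "or" in column_map else "beta"
    mandatory = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 effect_key, "se", "pvalue", "n"]
    missing = [k for k in mandatory if k not in column_map]
    if missing:
        raise SumstatsError(f"column_map missing mandatory keys: {missing}")
    absent = [column_map[k] for k in column_map if column_map[k] not in raw.columns]
    if absent:
        raise SumstatsError(f"columns not found in {path.name}: {absent}")

    df = pd.DataFrame({
        "snp_id": raw[column_map["snp_id"]].astype(str),
        "chrom": raw[column_map["chrom"]].astype(str),
        "pos": pd.to_numeric(raw[column_map["pos"]], errors="coerce"),
        "effect_allele": raw[column_map["effect_allele"]],
        "other_allele": raw[column_map["other_allele"]],
        "eaf": pd.to_numeric(raw[column_map["eaf"]], errors="coerce")
               if "eaf" in column_map else np.nan,
        "se": pd.to_numeric(raw[column_map["se"]], errors="coerce"),
        "pvalue": pd.to_numeric(raw[column_map["pvalue"]], errors="coerce"),
        "n": pd.to_numeric(raw[column_map["n"]], errors="coerce"),
    })
    eff = pd.to_numeric(raw[column_map[effect_key]], errors="coerce")
    df["beta"] = np.log(eff.where(eff > 0)) if effect_key == "or" else eff
    df = df[CANONICAL_COLUMNS]

    df, drop_log = _validate_rows(df)
    if drop_log:
        logger.info("read_sumstats(%s): dropped rows %s", path.name, drop_log)
    if df.empty:
        raise SumstatsError(f"no valid rows in {path}")
    df = df.astype({"pos": np.int64, "n": np.int64}).reset_index(drop=True)
    return SummaryStatsTable(trait_name or path.stem, trait_type, df, drop_log)


def write_sumstats(table: SummaryStatsTable, path: str | Path, sep: str = "\t") -> None:
    """Write the canonical columns; betas stay on the log-odds scale."""
    table.df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def or_ci_to_beta_se(
    or_value: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Invert a reported odds ratio and CI to (log-odds beta, se).

    beta = ln(OR); se = (ln(hi) - ln(lo)) / (2 z) with z the standard-normal
    quantile for ``level``. Requires ci_low < or_value < ci_high.
    """
    if min(or_value, ci_low, ci_high) <= 0:
        raise ValueError("odds ratio and CI bounds must be positive")
    if not (ci_low < or_value < ci_high):
        raise ValueError("need ci_low < or_value < ci_high")
    z = stats.norm.ppf(0.5 + level / 2)
    return math.log(or_value), (math.log(ci_high) - math.log(ci_low)) / (2 * z)


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of SNP ids.

    Symmetric, unit diagonal, entries in [0, 1]. SNPs absent from the matrix
    are treated as uncorrelated by consumers (reference-panel dropout).
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 shape does not match snp_ids")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("r2 entries must lie in [0, 1]")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        np.fill_diagonal(self.r2, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def get(self, a: str, b: str) -> float:
        """r² between two SNPs; 0 when either is absent, 1 when identical."""
        if a == b:
            return 1.0
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[str, str, float]], snp_ids: Sequence[str] | None = None
    ) -> "LDMatrix":
        """Build from (snp_a, snp_b, r2) triples; missing pairs default to 0."""
        ids: list[str] = list(snp_ids) if snp_ids is not None else []
        seen = set(ids)
        for a, b, _ in pairs:
            for s in (a, b):
                if s not in seen:
                    seen.add(s)
                    ids.append(s)
        mat = np.eye(len(ids))
        index = {s: i for i, s in enumerate(ids)}
        for a, b, r2 in pairs:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r2 {r2} outside [0,1] for pair ({a},{b})")
            mat[index[a], index[b]] = mat[index[b], index[a]] = r2
        return cls(ids, mat)


def read_ld(
    path: str | Path, format: str = "pairwise", snp_ids: Sequence[str] | None = None
) -> LDMatrix:
    """Read LD as pairwise triples (snp_a, snp_b, r2) or a square matrix.

    Pairwise files may be empty below the header; ``snp_ids`` then declares
    the universe and the result is identity-like. Square files carry SNP ids
    in the header row.
    """
    path = Path(path)
    if format == "pairwise":
        df = pd.read_csv(path, sep=r"\s+")
        pairs = [(str(a), str(b), float(r)) for a, b, r in
                 zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])]
        return LDMatrix.from_pairs(pairs, snp_ids=snp_ids)
    if format == "square":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        return LDMatrix(list(df.columns.astype(str)), df.to_numpy(dtype=float))
    raise ValueError(f"unknown LD format {format!r}")


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    """Write the square text form (tab-delimited, ids in header and index)."""
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", lineterminator="\n", float_format="%.17g"
    )
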