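"""Allele harmonization between exposure and outcome summary statistics.

Every estimator downstream consumes a :class:`HarmonizedInstruments` in which
all datasets refer to the same effect allele per SNP. Alignment resolves
effect/other allele swaps (sign flip) and opposite-strand reports (A<->T,
C<->G remap). Palindromic SNPs (A/T or C/G) carry no strand information in
their alleles; they are oriented by allele frequency when frequencies are
informative and dropped when the frequency is inside the ambiguity band or
missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import InstrumentSet, InsufficientInstrumentsError
from .sumstats import SummaryStatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default ambiguity band for palindromic allele frequencies (open interval)
PALINDROME_EAF_BAND = (0.42, 0.58)


class MvmrInfeasibleError(ValueError):
    """Too few jointly alignable SNPs for a multivariable fit."""


@dataclass
class HarmonizedInstruments:
    """Aligned effect/SE vectors for one outcome and one or more exposures.

    ``beta_x``/``se_x`` have shape (J,) for a single exposure or (J, K) for K
    exposures; ``beta_y``/``se_y`` are (J,). All rows share the exposure's
    effect allele after alignment. ``log`` records one action per candidate
    SNP: kept / sign-flipped / strand-flipped / dropped-palindromic /
    dropped-unmatched.
    """

    exposure_names: list[str]
    outcome_name: str
    snp_ids: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_x: np.ndarray | None = None
    eaf_y: np.ndarray | None = None
    log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        j = len(self.snp_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[0] != j:
                raise ValueError(f"{name} row count != number of SNPs")
        if np.any(self.se_y <= 0) or np.any(self.se_x <= 0):
            raise ValueError("standard errors must be positive")
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return 1 if self.beta_x.ndim == 1 else self.beta_x.shape[1]

    def drop(self, mask: np.ndarray) -> "HarmonizedInstruments":
        """Rows where ``mask`` is False are removed; log is carried over."""
        keep = np.asarray(mask, dtype=bool)
        return HarmonizedInstruments(
            self.exposure_names, self.outcome_name, self.snp_ids[keep],
            self.beta_x[keep], self.se_x[keep], self.beta_y[keep], self.se_y[keep],
            None if self.eaf_x is None else self.eaf_x[keep],
            None if self.eaf_y is None else self.eaf_y[keep],
            self.log,
        )

    def write_log(self, path: str | Path) -> None:
        self.log.to_csv(path, sep="\t", index=False, lineterminator="\n")


def is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _align_one(
    ea_x: str, oa_x: str, eaf_x: float,
    ea_y: str, oa_y: str, eaf_y: float,
    band: tuple[float, float],
) -> tuple[str, float, float] | tuple[str, None, None]:
    """Classify one SNP's outcome record against the exposure's alleles.

    Returns (action, sign, eaf_y_aligned); sign multiplies the outcome beta.
    Actions with sign None mean the SNP is dropped.
    """
    if is_palindromic(ea_x, oa_x):
        # letters cannot distinguish strands; orient by frequency
        if np.isnan(eaf_x) or np.isnan(eaf_y):
            return "dropped-palindromic", None, None
        lo, hi = band
        if lo < eaf_x < hi or lo < eaf_y < hi:
            return "dropped-palindromic", None, None
        if (ea_y, oa_y) == (ea_x, oa_x):
            sign, eaf_al, action = 1.0, eaf_y, "kept"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            sign, eaf_al, action = -1.0, 1.0 - eaf_y, "sign-flipped"
        else:
            return "dropped-unmatched", None, None
        # frequencies on opposite sides of 0.5 imply the other strand
        if (eaf_x - 0.5) * (eaf_al - 0.5) < 0:
            return "strand-flipped", -sign, 1.0 - eaf_al
        return action, sign, eaf_al

    if (ea_y, oa_y) == (ea_x, oa_x):
        return "kept", 1.0, eaf_y
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "sign-flipped", -1.0, 1.0 - eaf_y
    cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "strand-flipped", 1.0, eaf_y
    if (cea, coa) == (oa_x, ea_x):
        return "strand-flipped", -1.0, 1.0 - eaf_y
    return "dropped-unmatched", None, None


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    instruments: InstrumentSet | list[str],
    palindrome_eaf_band: tuple[float, float] = PALINDROME_EAF_BAND,
) -> HarmonizedInstruments:
    """Align outcome effects to the exposure's effect alleles per instrument.

    Instrument SNPs absent from the outcome, with irreconcilable allele
    pairs, or palindromic with ambiguous/missing frequency are dropped and
    logged; they are never silently kept. Setting the band to (0, 1) drops
    all palindromes outright.
    """
    snp_ids = instruments.snp_ids if isinstance(instruments, InstrumentSet) else list(instruments)
    ex = exposure.lookup()
    out = outcome.lookup()

    rows, actions = [], []
    for sid in snp_ids:
        if sid not in ex.index:
            actions.append((sid, "dropped-unmatched", "absent_from_exposure"))
            continue
        if sid not in out.index:
            actions.append((sid, "dropped-unmatched", "absent_from_outcome"))
            continue
        rx, ry = ex.loc[sid], out.loc[sid]
        action, sign, eaf_y = _align_one(
            rx["effect_allele"], rx["other_allele"], float(rx["eaf"]),
            ry["effect_allele"], ry["other_allele"], float(ry["eaf"]),
            palindrome_eaf_band,
        )
        if sign is None:
            actions.append((sid, action, "palindrome_ambiguous"
                            if action == "dropped-palindromic" else "allele_mismatch"))
            continue
        actions.append((sid, action, ""))
        rows.append((sid, rx["beta"], rx["se"], rx["eaf"],
                     sign * ry["beta"], ry["se"], eaf_y))

    log = pd.DataFrame(actions, columns=["snp_id", "action", "reason"])
    if not rows:
        raise InsufficientInstrumentsError(
            f"no harmonizable instruments for {exposure.trait_name} -> {outcome.trait_name}"
        )
    arr = pd.DataFrame(rows, columns=["snp_id", "bx", "sx", "fx", "by", "sy", "fy"])
    return HarmonizedInstruments(
        [exposure.trait_name], outcome.trait_name,
        arr["snp_id"].to_numpy(), arr["bx"].to_numpy(float), arr["sx"].to_numpy(float),
        arr["by"].to_numpy(float), arr["sy"].to_numpy(float),
        arr["fx"].to_numpy(float), arr["fy"].to_numpy(float), log,
    )


def harmonize_multi(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    merged_instruments: InstrumentSet | list[str],
    palindrome_eaf_band: tuple[float, float] = PALINDROME_EAF_BAND,
) -> HarmonizedInstruments:
    """Joint alignment of several exposures and one outcome.

    A SNP is kept only when present and alignable in every exposure and the
    outcome; the first exposure's effect allele is the reference. ``beta_x``
    becomes a (SNPs x exposures) matrix. Raises when fewer SNPs remain than
    exposures + 1 (the multivariable fit would be underdetermined).
    """
    if len(exposures) < 2:
        raise ValueError("harmonize_multi requires at least two exposures")
    snp_ids = (merged_instruments.snp_ids if isinstance(merged_instruments, InstrumentSet)
               else list(merged_instruments))

    per_exp = [harmonize(e, outcome, snp_ids, palindrome_eaf_band) for e in exposures]
    # the outcome row must harmonize identically against exposure 0's alleles,
    # so intersect on SNPs kept for every exposure
    kept_sets = [set(h.snp_ids) for h in per_exp]
    common = [s for s in snp_ids if all(s in ks for ks in kept_sets)]
    if len(common) < len(exposures) + 1:
        raise MvmrInfeasibleError(
            f"{len(common)} jointly alignable SNPs for {len(exposures)} exposures"
        )

    ref = per_exp[0]
    ref_idx = {s: i for i, s in enumerate(ref.snp_ids)}
    order = [ref_idx[s] for s in common]
    # exposure effects aligned to each file's own effect allele; re-express
    # all of them on exposure 0's allele via the shared outcome record
    beta_x = np.empty((len(common), len(exposures)))
    se_x = np.empty_like(beta_x)
    for k, h in enumerate(per_exp):
        idx = {s: i for i, s in enumerate(h.snp_ids)}
        rows = [idx[s] for s in common]
        # h.beta_y is the outcome beta aligned to exposure k's allele; the
        # relative sign vs the reference exposure's alignment recovers the
        # allele relation between exposure k and exposure 0
        sign = np.sign(h.beta_y[rows]) * np.sign(ref.beta_y[order])
        sign[sign == 0] = 1.0
        beta_x[:, k] = h.beta_x[rows] * sign
        se_x[:, k] = h.se_x[rows]

    log = pd.concat([h.log.assign(exposure=h.exposure_names[0]) for h in per_exp],
                    ignore_index=True)
    return HarmonizedInstruments(
        [e.trait_name for e in exposures], outcome.trait_name,
        np.asarray(common, dtype=object), beta_x, se_x,
        ref.beta_y[order], ref.se_y[order], None, ref.eaf_y[order], log,
    )
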