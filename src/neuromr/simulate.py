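"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical structure two-sample MR assumes:
per-SNP effect/SE pairs estimated in two non-overlapping samples, instrument
strength set by a target F, optional horizontal pleiotropy (balanced or
directional), LD blocks of near-duplicate SNPs, palindromic variants with
near-0.5 frequencies, and an optional exposure->mediator->outcome chain.

Effects are on standardized per-allele scales; the sampling variance of a
per-allele estimate is 1/(2 N p (1-p)) on that scale (used for binary
outcomes on the log-odds scale as well — adequate for method testing, not a
case-control likelihood simulation). Directional pleiotropy is aligned to
the exposure-increasing allele: allele labels are arbitrary, so a shift that
is "directional" in a biological sense must follow the orientation of the
true exposure effect, otherwise it averages out over random label choices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedInstruments
from .sumstats import CANONICAL_COLUMNS, LDMatrix, SummaryStatsTable

P_FLOOR = 1e-300  # p-values are clamped into (0, 1]

NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                        ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationTruth:
    """Known parameters a synthetic dataset encodes.

    Defaults follow the study conditions the package targets: exposure GWAS
    of ~350,000 individuals (UK-Biobank-scale neuroticism clusters), a
    binary outcome GWAS of ~200,000 (PTSD-scale case-control), ~50
    independent instruments, and a mean instrument F of about 80 (observed
    per-SNP F statistics in such analyses span roughly 20-170).
    """

    theta: float = 0.0
    theta_em: float | None = None
    theta_mo: float | None = None
    theta_direct: float | None = None
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    j_instruments: int = 50
    j_mediator: int = 30
    n_exposure: int = 350_000
    n_outcome: int = 200_000
    n_mediator: int = 50_000
    f_target: float = 80.0
    ld_block_spec: list[tuple[int, float]] = field(default_factory=list)
    palindrome_frac: float = 0.0
    n_null_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pleiotropy_frac", "palindrome_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.j_instruments < 1:
            raise ValueError("j_instruments must be at least 1")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")

    @property
    def mediation(self) -> bool:
        return self.theta_em is not None

    @property
    def total_effect(self) -> float:
        """theta, or direct + EM*MO in the mediation scenario."""
        if self.mediation:
            return self.theta_direct + self.theta_em * self.theta_mo
        return self.theta


@dataclass
class SyntheticDataset:
    """Generated tables plus the truth that produced them."""

    exposure: SummaryStatsTable
    outcome: SummaryStatsTable
    ld: LDMatrix
    truth: SimulationTruth
    mediator: SummaryStatsTable | None = None


def _se_per_allele(n: int | np.ndarray, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _draw_effects(truth: SimulationTruth, rng: np.random.Generator) -> dict:
    """Core instrument draw shared by the table and array generators."""
    j = truth.j_instruments
    eaf = rng.uniform(0.05, 0.95, j)
    n_pal = int(round(truth.palindrome_frac * j))
    pal = np.zeros(j, dtype=bool)
    if n_pal:
        pal[rng.choice(j, n_pal, replace=False)] = True
        eaf[pal] = rng.uniform(0.45, 0.55, n_pal)

    se_x = _se_per_allele(truth.n_exposure, eaf)
    se_y = _se_per_allele(truth.n_outcome, eaf)
    gamma = rng.normal(0.0, np.sqrt(max(truth.f_target - 1.0, 0.0)) * se_x)

    alpha = np.zeros(j)
    if truth.pleiotropy_frac > 0:
        invalid = rng.random(j) < truth.pleiotropy_frac
        raw = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, j)
        sign = np.where(gamma >= 0, 1.0, -1.0)  # exposure-increasing allele
        alpha = np.where(invalid, sign * raw, 0.0)

    beta_x = rng.normal(gamma, se_x)
    if truth.mediation:
        outcome_effect = truth.theta_direct * gamma + truth.theta_mo * truth.theta_em * gamma
    else:
        outcome_effect = truth.theta * gamma
    beta_y = rng.normal(outcome_effect + alpha, se_y)

    out = dict(eaf=eaf, palindromic=pal, gamma=gamma, alpha=alpha,
               beta_x=beta_x, se_x=se_x, beta_y=beta_y, se_y=se_y)
    if truth.mediation:
        se_m = _se_per_allele(truth.n_mediator, eaf)
        out["se_m"] = se_m
        out["beta_m"] = rng.normal(truth.theta_em * gamma, se_m)
        # mediator-specific instruments, independent of the exposure
        jm = truth.j_mediator
        eaf_m = rng.uniform(0.05, 0.95, jm)
        se_md = _se_per_allele(truth.n_mediator, eaf_m)
        delta = rng.normal(0.0, np.sqrt(max(truth.f_target - 1.0, 0.0)) * se_md)
        out["med_eaf"] = eaf_m
        out["med_delta"] = delta
        out["med_se_m"] = se_md
        out["med_beta_m"] = rng.normal(delta, se_md)
        se_yo = _se_per_allele(truth.n_outcome, eaf_m)
        out["med_se_y"] = se_yo
        out["med_beta_y"] = rng.normal(truth.theta_mo * delta, se_yo)
        se_xm = _se_per_allele(truth.n_exposure, eaf_m)
        out["med_se_x"] = se_xm
        out["med_beta_x"] = rng.normal(0.0, se_xm)
    return out


def generate_harmonized(truth: SimulationTruth,
                        seed: int | None = None) -> HarmonizedInstruments:
    """Exposure->outcome instruments as an already-harmonized set.

    Fast path for replicate studies (calibration, power): skips allele
    bookkeeping and table IO but draws from the identical effect model as
    :func:`generate`.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    d = _draw_effects(truth, rng)
    ids = np.array([f"rs{i + 1:06d}" for i in range(truth.j_instruments)], dtype=object)
    return HarmonizedInstruments(["exposure"], "outcome", ids,
                                 d["beta_x"], d["se_x"], d["beta_y"], d["se_y"],
                                 d["eaf"], d["eaf"])


def generate_mediation_harmonized(
    truth: SimulationTruth, seed: int | None = None
) -> tuple[HarmonizedInstruments, HarmonizedInstruments, HarmonizedInstruments]:
    """Harmonized sets for the three mediation links, sharing one draw.

    Returns (exposure->outcome, exposure->mediator, mediator->outcome); the
    first two use the exposure's instruments, the third the
    mediator-specific instruments. Fast path mirroring :func:`generate`'s
    effect model for replicate studies of the two-step procedure.
    """
    if not truth.mediation:
        raise ValueError("truth does not describe a mediation scenario")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    d = _draw_effects(truth, rng)
    ids = np.array([f"rs{i + 1:06d}" for i in range(truth.j_instruments)], dtype=object)
    m_ids = np.array([f"rs7{i + 1:05d}" for i in range(truth.j_mediator)], dtype=object)
    h_total = HarmonizedInstruments(["exposure"], "outcome", ids,
                                    d["beta_x"], d["se_x"], d["beta_y"], d["se_y"])
    h_em = HarmonizedInstruments(["exposure"], "mediator", ids,
                                 d["beta_x"], d["se_x"], d["beta_m"], d["se_m"])
    h_mo = HarmonizedInstruments(["mediator"], "outcome", m_ids,
                                 d["med_beta_m"], d["med_se_m"],
                                 d["med_beta_y"], d["med_se_y"])
    return h_total, h_em, h_mo


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2 * stats.norm.sf(np.abs(beta) / se), P_FLOOR, 1.0)


def _table(name: str, trait_type: str, ids, chrom, pos, ea, oa, eaf, beta, se,
           n: int) -> SummaryStatsTable:
    df = pd.DataFrame({
        "snp_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": _pvalues(np.asarray(beta), np.asarray(se)),
        "n": n,
    })[CANONICAL_COLUMNS]
    return SummaryStatsTable(name, trait_type, df.reset_index(drop=True))


def generate(truth: SimulationTruth) -> SyntheticDataset:
    """Full synthetic dataset: exposure/outcome (and mediator) tables + LD.

    Instruments sit far apart on alternating chromosomes; LD blocks add
    near-duplicate tag SNPs (effect scaled by sqrt(r²)) adjacent to randomly
    chosen index instruments, recorded in the LD matrix. Null filler SNPs
    (``n_null_snps``) carry no exposure effect. The outcome file reports each
    SNP in a random allele orientation (swapped and/or strand-complemented)
    so harmonization is exercised end to end.
    """
    rng = np.random.default_rng(truth.seed)
    d = _draw_effects(truth, rng)
    j = truth.j_instruments

    ids = [f"rs{i + 1:06d}" for i in range(j)]
    chrom = [str(i % 22 + 1) for i in range(j)]
    pos = [1_000_000 + (i // 22) * 25_000_000 for i in range(j)]
    pair_idx = rng.integers(0, len(NONPALINDROMIC_PAIRS), j)
    ea = [NONPALINDROMIC_PAIRS[k][0] for k in pair_idx]
    oa = [NONPALINDROMIC_PAIRS[k][1] for k in pair_idx]
    pal_pair = rng.integers(0, len(PALINDROMIC_PAIRS), j)
    for i in np.where(d["palindromic"])[0]:
        ea[i], oa[i] = PALINDROMIC_PAIRS[pal_pair[i]]

    rows = dict(ids=list(ids), chrom=list(chrom), pos=list(pos),
                ea=list(ea), oa=list(oa), eaf=list(d["eaf"]),
                bx=list(d["beta_x"]), sx=list(d["se_x"]),
                by=list(d["beta_y"]), sy=list(d["se_y"]))
    ld_pairs: list[tuple[str, str, float]] = []

    # LD blocks: tag SNPs clustered within 10 kb of a chosen index SNP
    tag_counter = 0
    for block_size, r2 in truth.ld_block_spec:
        idx = int(rng.integers(0, j))
        root = np.sqrt(r2)
        for t in range(block_size - 1):
            tag_counter += 1
            tid = f"rs9{tag_counter:05d}"
            gamma_tag = root * d["gamma"][idx]
            bx_t = rng.normal(gamma_tag, d["se_x"][idx])
            by_t = rng.normal(truth.total_effect * gamma_tag, d["se_y"][idx])
            rows["ids"].append(tid)
            rows["chrom"].append(chrom[idx])
            rows["pos"].append(pos[idx] + 1000 * (t + 1))
            rows["ea"].append(ea[idx]); rows["oa"].append(oa[idx])
            rows["eaf"].append(d["eaf"][idx])
            rows["bx"].append(bx_t); rows["sx"].append(d["se_x"][idx])
            rows["by"].append(by_t); rows["sy"].append(d["se_y"][idx])
            ld_pairs.append((ids[idx], tid, r2))
            for prev in range(t):
                ld_pairs.append((f"rs9{tag_counter - 1 - prev:05d}", tid, r2))

    # null filler SNPs with no exposure effect
    for k in range(truth.n_null_snps):
        nid = f"rs8{k + 1:05d}"
        eafn = rng.uniform(0.05, 0.95)
        sxn = _se_per_allele(truth.n_exposure, np.array(eafn))
        syn = _se_per_allele(truth.n_outcome, np.array(eafn))
        pr = NONPALINDROMIC_PAIRS[int(rng.integers(0, len(NONPALINDROMIC_PAIRS)))]
        rows["ids"].append(nid)
        rows["chrom"].append(str(k % 22 + 1))
        rows["pos"].append(500_000_000 + (k // 22) * 25_000_000)
        rows["ea"].append(pr[0]); rows["oa"].append(pr[1])
        rows["eaf"].append(eafn)
        rows["bx"].append(rng.normal(0.0, sxn)); rows["sx"].append(float(sxn))
        rows["by"].append(rng.normal(0.0, syn)); rows["sy"].append(float(syn))

    exposure = _table("exposure", "continuous", rows["ids"], rows["chrom"],
                      rows["pos"], rows["ea"], rows["oa"], rows["eaf"],
                      rows["bx"], rows["sx"], truth.n_exposure)

    # outcome file in random orientation: swap alleles and/or report the
    # complementary strand, which harmonization must undo
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    ea_y, oa_y, by_o, eaf_y = [], [], [], []
    for i in range(len(rows["ids"])):
        a, b, beta, f = rows["ea"][i], rows["oa"][i], rows["by"][i], rows["eaf"][i]
        if rng.random() < 0.5:
            a, b = comp[a], comp[b]
        if rng.random() < 0.5:
            a, b, beta, f = b, a, -beta, 1.0 - f
        ea_y.append(a); oa_y.append(b); by_o.append(beta); eaf_y.append(f)
    outcome = _table("outcome", "binary", rows["ids"], rows["chrom"], rows["pos"],
                     ea_y, oa_y, eaf_y, by_o, rows["sy"], truth.n_outcome)

    mediator = None
    if truth.mediation:
        m_ids = rows["ids"][:j] + [f"rs7{k + 1:05d}" for k in range(truth.j_mediator)]
        m_chrom = rows["chrom"][:j] + [str(k % 22 + 1) for k in range(truth.j_mediator)]
        m_pos = rows["pos"][:j] + [800_000_000 + (k // 22) * 25_000_000
                                   for k in range(truth.j_mediator)]
        m_pairs = [NONPALINDROMIC_PAIRS[int(rng.integers(0, len(NONPALINDROMIC_PAIRS)))]
                   for _ in range(truth.j_mediator)]
        m_ea = rows["ea"][:j] + [p[0] for p in m_pairs]
        m_oa = rows["oa"][:j] + [p[1] for p in m_pairs]
        m_eaf = rows["eaf"][:j] + list(d["med_eaf"])
        m_beta = list(d["beta_m"]) + list(d["med_beta_m"])
        m_se = list(d["se_m"]) + list(d["med_se_m"])
        mediator = _table("mediator", "binary", m_ids, m_chrom, m_pos,
                          m_ea, m_oa, m_eaf, m_beta, m_se, truth.n_mediator)
        # mediator instruments also appear in exposure (null) and outcome files
        ex2 = exposure.df.copy()
        out2 = outcome.df.copy()
        med_rows_x = _table("x", "continuous", m_ids[j:], m_chrom[j:], m_pos[j:],
                            m_ea, m_oa, d["med_eaf"], d["med_beta_x"],
                            d["med_se_x"], truth.n_exposure).df
        med_rows_y = _table("y", "binary", m_ids[j:], m_chrom[j:], m_pos[j:],
                            m_ea, m_oa, d["med_eaf"], d["med_beta_y"],
                            d["med_se_y"], truth.n_outcome).df
        exposure = SummaryStatsTable("exposure", "continuous",
                                     pd.concat([ex2, med_rows_x], ignore_index=True))
        outcome = SummaryStatsTable("outcome", "binary",
                                    pd.concat([out2, med_rows_y], ignore_index=True))

    ld = LDMatrix.from_pairs(ld_pairs, snp_ids=rows["ids"])
    return SyntheticDataset(exposure, outcome, ld, truth, mediator)


@dataclass
class GridStudy:
    """A study-shaped collection: several exposures crossed with outcomes.

    ``truth_effects`` maps (exposure, outcome) to the true total causal
    effect; ``mediation_chain`` names the planted
    exposure -> mediator -> final-outcome path with its coefficients.
    """

    exposures: dict[str, SummaryStatsTable]
    outcomes: dict[str, SummaryStatsTable]
    ld: LDMatrix
    truth_effects: dict[tuple[str, str], float]
    mediation_chain: tuple[str, str, str, float, float, float]
    seed: int


def generate_grid_study(seed: int = 0, n_exposures: int = 3,
                        n_outcomes: int = 10, j_per_exposure: int = 50,
                        f_target: float = 80.0) -> GridStudy:
    """Study-shaped synthetic data: a grid of exposures x outcomes.

    Emulates the layout of a neuroticism-cluster / psychiatric-disorder
    screen: 3 exposure GWAS, 10 outcome GWAS, a mostly-null truth matrix
    with a handful of real effects, and one planted mediation chain
    exposure_1 -> outcome_01 -> outcome_10 (EM 0.4, MO 0.25, direct 0.9,
    so 10% of the total effect is mediated). All tables share one SNP
    universe so merged multivariable instruments and mediator instruments
    resolve naturally.
    """
    rng = np.random.default_rng(seed)
    e_names = [f"exposure_{i + 1}" for i in range(n_exposures)]
    o_names = [f"outcome_{i + 1:02d}" for i in range(n_outcomes)]
    mediator, final = o_names[0], o_names[-1]
    th_em, th_mo, th_direct = 0.4, 0.25, 0.9

    truth: dict[tuple[str, str], float] = {(e, o): 0.0 for e in e_names for o in o_names}
    truth[(e_names[0], final)] = th_direct + th_em * th_mo
    truth[(e_names[0], mediator)] = th_em
    if n_exposures > 1:
        truth[(e_names[1], final)] = 0.5
        if n_outcomes > 2:
            truth[(e_names[1], o_names[2])] = 0.3
    if n_outcomes > 4:
        truth[(e_names[0], o_names[4])] = 0.25

    n_exp, n_out, n_med = 350_000, 200_000, 50_000
    j_med = 30

    # shared SNP universe: per-exposure instruments + mediator instruments
    blocks: dict[str, dict] = {}
    universe: list[dict] = []

    def add_snps(tag: str, count: int, n_owner: int) -> np.ndarray:
        eaf = rng.uniform(0.05, 0.95, count)
        se_own = _se_per_allele(n_owner, eaf)
        gam = rng.normal(0.0, np.sqrt(f_target - 1.0) * se_own)
        start = len(universe)
        for t in range(count):
            pr = NONPALINDROMIC_PAIRS[int(rng.integers(0, len(NONPALINDROMIC_PAIRS)))]
            universe.append(dict(snp_id=f"rs{start + t + 1:06d}",
                                 chrom=str((start + t) % 22 + 1),
                                 pos=1_000_000 + ((start + t) // 22) * 25_000_000,
                                 ea=pr[0], oa=pr[1], eaf=eaf[t]))
        blocks[tag] = dict(start=start, gamma=gam, eaf=eaf)
        return gam

    for e in e_names:
        add_snps(e, j_per_exposure, n_exp)
    add_snps(mediator, j_med, n_med)

    uni = pd.DataFrame(universe)
    j_total = len(uni)
    eaf_all = uni["eaf"].to_numpy()

    def owner_gamma(tag: str) -> np.ndarray:
        g = np.zeros(j_total)
        b = blocks[tag]
        g[b["start"]:b["start"] + len(b["gamma"])] = b["gamma"]
        return g

    def make_table(name: str, trait_type: str, n: int, true_effect: np.ndarray) -> SummaryStatsTable:
        se = _se_per_allele(n, eaf_all)
        beta = rng.normal(true_effect, se)
        return _table(name, trait_type, uni["snp_id"], uni["chrom"], uni["pos"],
                      uni["ea"], uni["oa"], eaf_all, beta, se, n)

    gammas = {e: owner_gamma(e) for e in e_names}
    delta_med = owner_gamma(mediator)

    exposures = {e: make_table(e, "continuous", n_exp, gammas[e]) for e in e_names}
    outcomes: dict[str, SummaryStatsTable] = {}
    for o in o_names:
        effect = np.zeros(j_total)
        for e in e_names:
            effect += truth[(e, o)] * gammas[e]
        if o == mediator:
            effect += delta_med  # its own instruments
            n_o = n_med
        elif o == final:
            effect += th_mo * delta_med  # mediator path into the final outcome
            n_o = n_out
        else:
            n_o = n_out
        outcomes[o] = make_table(o, "binary", n_o, effect)
    # the mediator trait's exposure-role table is its outcome table
    ld = LDMatrix.identity([])

    return GridStudy(exposures, outcomes, ld, truth,
                     (e_names[0], mediator, final, th_em, th_mo, th_direct), seed)
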