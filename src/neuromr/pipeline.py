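"""Full-study orchestration: UVMR grid, sensitivity gating, MVMR, mediation.

``run_study`` executes, for every exposure x outcome pair: instrument
selection -> harmonization -> three UVMR estimators -> sensitivity
diagnostics -> significance-tier assignment (Bonferroni at 0.05/m; a pair is
"dismissed" when the pleiotropy residual-sum global test fires). It then
fits multivariable IVW on every outcome with at least two nominally
significant exposures, and runs two-step mediation for every eligible
exposure/mediator/final-outcome triple. Per-pair failures are logged and do
not abort the grid; every stochastic step records its seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .estimators import MREstimate, ivw, run_uvmr
from .harmonize import (PALINDROME_EAF_BAND, HarmonizedInstruments,
                        harmonize, harmonize_multi)
from .instruments import (build_instruments, build_instruments_relaxed,
                          merge_instruments, InstrumentSet)
from .mvmr import (MediationResult, MvmrEstimate, PairResult, bonferroni,
                   mediation_eligibility, mvmr_ivw, two_step_mediation)
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import LDMatrix, SummaryStatsTable, read_ld, read_sumstats

logger = logging.getLogger(__name__)

GRID_COLUMNS = ["exposure", "outcome", "method", "n_snp", "beta", "se",
                "or", "ci_low", "ci_high", "pvalue", "presso_global_p",
                "egger_intercept_p", "q_p", "tier"]


@dataclass
class StudyParams:
    """All tunable analysis parameters with the standard defaults."""

    p_primary: float = 5e-8
    p_relaxed: float = 5e-6
    r2_max: float = 0.001
    window_kb: int = 10_000
    f_min: float = 10.0
    palindrome_band: tuple[float, float] = PALINDROME_EAF_BAND
    presso_n_sim: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    bonferroni_m: int | None = None
    seed: int = 0


@dataclass
class PairAnalysis:
    """Everything computed for one exposure -> outcome pair."""

    exposure: str
    outcome: str
    instruments: InstrumentSet
    harmonized: HarmonizedInstruments | None
    estimates: list[MREstimate]
    sensitivity: SensitivityReport | None
    tier: str
    error: str | None = None

    @property
    def ivw_estimate(self) -> MREstimate | None:
        for e in self.estimates:
            if e.method in ("ivw_mre", "ivw_fe", "wald"):
                return e
        return None


@dataclass
class StudyResult:
    """Grid, multivariable, and mediation outputs of one study run."""

    grid: pd.DataFrame
    pairs: dict[tuple[str, str], PairAnalysis]
    mvmr: dict[str, MvmrEstimate] = field(default_factory=dict)
    mediation: list[MediationResult] = field(default_factory=list)
    bonferroni_threshold: float = 0.05
    log: list[str] = field(default_factory=list)


def _tier(p: float, threshold: float, dismissed: bool, alpha: float) -> str:
    if dismissed:
        return "dismissed"
    if p < threshold:
        return "bonferroni"
    if p < alpha:
        return "nominal"
    return "null"


def _analyze_pair(
    e_name: str, e_table: SummaryStatsTable,
    o_name: str, o_table: SummaryStatsTable,
    ld: LDMatrix, params: StudyParams, threshold: float, seed: int,
    relaxed_fallback: bool = False,
) -> PairAnalysis:
    builder = build_instruments_relaxed if relaxed_fallback else build_instruments
    kwargs = dict(r2_max=params.r2_max, window_kb=params.window_kb, f_min=params.f_min)
    if relaxed_fallback:
        inst = builder(e_table, ld, **kwargs)
    else:
        inst = builder(e_table, ld, p_threshold=params.p_primary, **kwargs)
    if inst.n_snps == 0:
        return PairAnalysis(e_name, o_name, inst, None, [], None, "null",
                            error="no instruments survive selection")
    try:
        h = harmonize(e_table, o_table, inst, params.palindrome_band)
        ests = run_uvmr(h, seed=seed, n_boot=params.n_boot)
        sens = sensitivity_report(h, n_sim=params.presso_n_sim, seed=seed,
                                  alpha=params.alpha) if h.n_snp >= 2 else None
    except Exception as exc:  # per-pair failure must not abort the grid
        logger.warning("pair %s -> %s failed: %s", e_name, o_name, exc)
        return PairAnalysis(e_name, o_name, inst, None, [], None, "null",
                            error=str(exc))
    p_ivw = ests[0].pvalue
    dismissed = sens is not None and sens.dismissed
    return PairAnalysis(e_name, o_name, inst, h, ests, sens,
                        _tier(p_ivw, threshold, dismissed, params.alpha))


def _grid_rows(pa: PairAnalysis) -> list[dict]:
    rows = []
    sens = pa.sensitivity
    for est in pa.estimates:
        rows.append({
            "exposure": pa.exposure, "outcome": pa.outcome, "method": est.method,
            "n_snp": est.n_snp, "beta": est.beta, "se": est.se,
            "or": est.or_, "ci_low": est.or_low, "ci_high": est.or_high,
            "pvalue": est.pvalue,
            "presso_global_p": sens.presso.global_p if sens and sens.presso else float("nan"),
            "egger_intercept_p": sens.egger_intercept[2] if sens and sens.egger_intercept else float("nan"),
            "q_p": sens.q_ivw[2] if sens else float("nan"),
            "tier": pa.tier,
        })
    return rows


def run_study(
    exposures: dict[str, SummaryStatsTable],
    outcomes: dict[str, SummaryStatsTable],
    ld: LDMatrix,
    params: StudyParams | None = None,
    final_outcome: str | None = None,
) -> StudyResult:
    """Run the complete analysis over every exposure x outcome pair.

    ``final_outcome`` names the outcome for which mediation chains are
    assessed (each other outcome is a candidate mediator, instrumented with
    the relaxed-threshold fallback); omit it to skip mediation. MVMR runs on
    each outcome with >= 2 nominally significant, non-dismissed exposures.
    """
    params = params or StudyParams()
    m = params.bonferroni_m or (len(exposures) * len(outcomes))
    threshold, _, _ = bonferroni(1.0, m)
    result = StudyResult(grid=pd.DataFrame(), pairs={},
                         bonferroni_threshold=threshold)
    result.log.append(f"bonferroni m={m} threshold={threshold:.6g}")

    rows: list[dict] = []
    seed = params.seed
    for i, (e_name, e_table) in enumerate(exposures.items()):
        for k, (o_name, o_table) in enumerate(outcomes.items()):
            pair_seed = seed + 1000 * i + k
            pa = _analyze_pair(e_name, e_table, o_name, o_table, ld, params,
                               threshold, pair_seed)
            result.pairs[(e_name, o_name)] = pa
            rows.extend(_grid_rows(pa))
            result.log.append(
                f"{e_name}->{o_name}: {pa.instruments.n_snps} instruments "
                f"({pa.instruments.selection_log}), tier={pa.tier}"
                + (f", error={pa.error}" if pa.error else "")
            )
    result.grid = pd.DataFrame(rows, columns=GRID_COLUMNS)

    # MVMR per outcome with >= 2 nominally significant exposures
    for o_name, o_table in outcomes.items():
        sig = [e for e in exposures
               if (pa := result.pairs[(e, o_name)]).ivw_estimate is not None
               and pa.ivw_estimate.pvalue < params.alpha and pa.tier != "dismissed"]
        if len(sig) < 2:
            continue
        try:
            merged = merge_instruments([result.pairs[(e, o_name)].instruments for e in sig],
                                       [exposures[e] for e in sig], ld,
                                       r2_max=params.r2_max, window_kb=params.window_kb)
            h = harmonize_multi([exposures[e] for e in sig], o_table, merged,
                                params.palindrome_band)
            result.mvmr[o_name] = mvmr_ivw(h)
            result.log.append(f"mvmr[{o_name}]: exposures={sig}, n_snp={h.n_snp}")
        except Exception as exc:
            result.log.append(f"mvmr[{o_name}] failed: {exc}")

    if final_outcome is not None:
        result.mediation = _run_mediation(exposures, outcomes, ld, params,
                                          final_outcome, result)
    return result


def _run_mediation(exposures, outcomes, ld, params, final_outcome, result) -> list[MediationResult]:
    """Two-step mediation for every eligible triple into ``final_outcome``."""
    mediators = [o for o in outcomes if o != final_outcome]
    # mediator -> final-outcome links, instrumented with relaxed fallback
    mo_pairs: dict[str, PairAnalysis] = {}
    for j, m_name in enumerate(mediators):
        pa = _analyze_pair(m_name, outcomes[m_name], final_outcome,
                           outcomes[final_outcome], ld, params,
                           result.bonferroni_threshold,
                           params.seed + 900_000 + j, relaxed_fallback=True)
        mo_pairs[m_name] = pa
        result.pairs[(m_name, final_outcome)] = pa
        result.log.append(
            f"mediator {m_name}->{final_outcome}: {pa.instruments.n_snps} instruments "
            f"(p_threshold={pa.instruments.p_threshold}), tier={pa.tier}")

    links = []
    for (e, o), pa in result.pairs.items():
        if pa.ivw_estimate is not None:
            links.append(PairResult(e, o, pa.ivw_estimate.pvalue,
                                    dismissed=pa.tier == "dismissed"))
    triples = [(e, m, o) for (e, m, o) in mediation_eligibility(links, params.alpha)
               if o == final_outcome and e in exposures and m in mediators]

    out = []
    for t, (e, m_name, o) in enumerate(triples):
        total = result.pairs[(e, o)].ivw_estimate
        em = result.pairs[(e, m_name)].ivw_estimate
        mo = mo_pairs[m_name].ivw_estimate
        med = two_step_mediation(total, em, mo, seed=params.seed + 800_000 + t,
                                 labels=(e, m_name, o))
        out.append(med)
        result.log.append(
            f"mediation {e}->{m_name}->{o}: PM={med.proportion_mediated:.4f}")
    return out


# ---------------------------------------------------------------------------
# config-file entry point and report writing


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


DEFAULT_COLUMN_MAP = {k: k for k in
                      ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                       "eaf", "beta", "se", "pvalue", "n"]}


def run_study_from_config(path: str | Path) -> StudyResult:
    """Execute a study described by a flat YAML config and write reports.

    The config lists exposures/outcomes as (name, path, trait_type,
    optional column_map), the LD file, thresholds (defaulting to the
    standard ones), seeds and the output directory.
    """
    cfg = load_config(path)
    base = Path(path).parent

    def load(entry) -> SummaryStatsTable:
        cmap = entry.get("column_map", DEFAULT_COLUMN_MAP)
        return read_sumstats(base / entry["path"], cmap,
                             entry.get("trait_type", "binary"), entry["name"])

    exposures = {e["name"]: load(e) for e in cfg["exposures"]}
    outcomes = {o["name"]: load(o) for o in cfg["outcomes"]}
    if "ld" in cfg:
        ld = read_ld(base / cfg["ld"]["path"], cfg["ld"].get("format", "pairwise"))
    else:
        ld = LDMatrix.identity([])

    p = cfg.get("params", {})
    band = tuple(p.get("palindrome_band", PALINDROME_EAF_BAND))
    params = StudyParams(
        p_primary=float(p.get("p_primary", 5e-8)),
        p_relaxed=float(p.get("p_relaxed", 5e-6)),
        r2_max=float(p.get("r2_max", 0.001)),
        window_kb=int(p.get("window_kb", 10_000)),
        f_min=float(p.get("f_min", 10.0)),
        palindrome_band=band,
        presso_n_sim=int(p.get("presso_n_sim", 1000)),
        n_boot=int(p.get("n_boot", 1000)),
        bonferroni_m=p.get("bonferroni_m"),
        seed=int(p.get("seed", 0)),
    )
    result = run_study(exposures, outcomes, ld, params,
                       final_outcome=cfg.get("final_outcome"))
    if "out_dir" in cfg:
        write_reports(result, base / cfg["out_dir"])
    return result


def write_reports(result: StudyResult, out_dir: str | Path) -> None:
    """Write the grid, MVMR, mediation and sensitivity tables as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.grid.to_csv(out / "uvmr_grid.tsv", sep="\t", index=False,
                       lineterminator="\n")

    mv_rows = []
    for o_name, mv in result.mvmr.items():
        for k, e_name in enumerate(mv.exposure_names):
            est = mv.estimate_for(e_name)
            mv_rows.append({"outcome": o_name, "exposure": e_name,
                            "n_snp": mv.n_snp, "beta": est.beta, "se": est.se,
                            "or": est.or_, "ci_low": est.or_low,
                            "ci_high": est.or_high, "pvalue": est.pvalue})
    pd.DataFrame(mv_rows).to_csv(out / "mvmr.tsv", sep="\t", index=False,
                                 lineterminator="\n")

    med_rows = [{
        "exposure": m.exposure, "mediator": m.mediator, "outcome": m.outcome,
        "beta_total": m.beta_total, "beta_em": m.beta_em, "beta_mo": m.beta_mo,
        "beta_indirect": m.beta_indirect, "se_indirect": m.se_indirect,
        "proportion_mediated_pct": 100 * m.proportion_mediated,
        "pm_ci_low_pct": 100 * m.pm_ci[0], "pm_ci_high_pct": 100 * m.pm_ci[1],
        "seed": m.seed,
    } for m in result.mediation]
    pd.DataFrame(med_rows).to_csv(out / "mediation.tsv", sep="\t", index=False,
                                  lineterminator="\n")

    sens_dir = out / "sensitivity"
    sens_dir.mkdir(exist_ok=True)
    for (e, o), pa in result.pairs.items():
        if pa.sensitivity is None:
            continue
        s = pa.sensitivity
        stem = f"{e}__{o}"
        s.loo.to_csv(sens_dir / f"{stem}.loo.tsv", sep="\t", index=False,
                     lineterminator="\n")
        s.funnel.to_csv(sens_dir / f"{stem}.funnel.tsv", sep="\t", index=False,
                        lineterminator="\n")
        summary = {
            "q_ivw": s.q_ivw[0], "q_ivw_df": s.q_ivw[1], "q_ivw_p": s.q_ivw[2],
            "q_egger": s.q_egger[0] if s.q_egger else float("nan"),
            "q_egger_p": s.q_egger[2] if s.q_egger else float("nan"),
            "egger_intercept": s.egger_intercept[0] if s.egger_intercept else float("nan"),
            "egger_intercept_p": s.egger_intercept[2] if s.egger_intercept else float("nan"),
            "presso_global_p": s.presso.global_p if s.presso else float("nan"),
            "presso_outliers": ",".join(s.presso.outliers) if s.presso else "",
            "dismissed": s.dismissed,
        }
        pd.DataFrame([summary]).to_csv(sens_dir / f"{stem}.summary.tsv",
                                       sep="\t", index=False, lineterminator="\n")

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")
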