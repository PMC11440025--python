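"""Heterogeneity and horizontal-pleiotropy diagnostics.

Cochran's Q (at the IVW and Egger fits), the Egger intercept test,
leave-one-out re-estimation, funnel-plot data, and a simulation-based
residual-sum-of-squares test with per-SNP outlier identification and
outlier-corrected re-estimation (the MR-PRESSO procedure).

All empirical p-values use the add-one estimator (1 + #exceedances)/(n+1),
so they are never exactly zero; their lower bound is 1/(n_sim+1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, egger, ivw
from .harmonize import HarmonizedInstruments
from .instruments import InsufficientInstrumentsError


def cochran_q(h: HarmonizedInstruments, model: str = "ivw") -> tuple[float, int, float]:
    """Heterogeneity statistic Q = sum of w_j * residual_j² at the fitted model.

    Residuals come from the weighted no-intercept fit (``model="ivw"``, df
    J-1) or the weighted fit with intercept (``model="egger"``, df J-2);
    weights are 1/se_y². p is the upper chi-square tail.
    """
    j = h.n_snp
    w = 1.0 / h.se_y**2
    if model == "ivw":
        if j < 2:
            raise InsufficientInstrumentsError("Q (IVW) requires at least 2 SNPs")
        est = ivw(h, random_effects=False)
        resid = h.beta_y - est.beta * h.beta_x
        df = j - 1
    elif model == "egger":
        if j < 3:
            raise InsufficientInstrumentsError("Q (Egger) requires at least 3 SNPs")
        est = egger(h)
        flip = np.where(h.beta_x < 0, -1.0, 1.0)
        resid = h.beta_y * flip - est.intercept - est.beta * h.beta_x * flip
        df = j - 2
    else:
        raise ValueError(f"unknown model {model!r}")
    q = float(np.sum(w * resid**2))
    return q, df, float(stats.chi2.sf(q, df))


def _loo_components(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Leave-one-out IVW sums; returns (beta_loo, s_xx_loo, q_loo)."""
    s_xy, s_xx, s_yy = np.sum(w * bx * by), np.sum(w * bx**2), np.sum(w * by**2)
    xy = s_xy - w * bx * by
    xx = s_xx - w * bx**2
    yy = s_yy - w * by**2
    beta = xy / xx
    q = yy - 2 * beta * xy + beta**2 * xx
    return beta, xx, q


def leave_one_out(h: HarmonizedInstruments) -> pd.DataFrame:
    """IVW-MRE estimate excluding each SNP in turn.

    One row per excluded SNP (beta, se, p) plus ``sign_consistent``: whether
    the estimate keeps the full-set sign when that SNP is removed.
    """
    j = h.n_snp
    if j < 2:
        raise InsufficientInstrumentsError("leave-one-out requires at least 2 SNPs")
    w = 1.0 / h.se_y**2
    beta, xx, q = _loo_components(h.beta_x, h.beta_y, w)
    df = j - 2  # each subset has J-1 SNPs
    scale = np.maximum(1.0, np.sqrt(q / df)) if df > 0 else np.ones(j)
    se = scale / np.sqrt(xx)
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    full = ivw(h).beta
    return pd.DataFrame({
        "snp_id": h.snp_ids,
        "beta_excluding": beta,
        "se_excluding": se,
        "p_excluding": p,
        "sign_consistent": np.sign(beta) == np.sign(full),
    })


@dataclass
class PressoResult:
    """Global residual-sum test plus per-SNP outlier calls."""

    rss_observed: float
    global_p: float
    n_sim: int
    per_snp_p: pd.Series
    outliers: list[str]
    corrected_estimate: MREstimate | None
    seed: int


def mr_presso(
    h: HarmonizedInstruments,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Residual-sum-and-outlier test for horizontal pleiotropy.

    The observed statistic sums inverse-variance-weighted squared residuals
    of each SNP around its leave-one-out IVW prediction. Its null
    distribution is simulated by redrawing effects from normals centred on
    the instrument estimates and the leave-one-out predictions. Per-SNP
    empirical p-values are Bonferroni-adjusted by the SNP count; when
    outliers are found the IVW-MRE estimate on the remaining SNPs is
    reported as the corrected estimate.

    The global p uses the add-one estimator (never exactly zero, floor
    1/(n_sim+1)). The per-SNP outlier p is the raw exceedance proportion:
    with an add-one floor, the Bonferroni-adjusted p could never fall below
    n_snp/(n_sim+1), and a gross outlier would be undetectable whenever
    that exceeds ``outlier_alpha``.
    """
    j = h.n_snp
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 SNPs")
    bx, by = h.beta_x, h.beta_y
    w = 1.0 / h.se_y**2

    beta_loo, _, _ = _loo_components(bx, by, w)
    resid_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, h.se_x, size=(n_sim, j))
    by_star = rng.normal(beta_loo * bx, h.se_y, size=(n_sim, j))

    # identical computation on each simulated dataset, vectorized over sims
    s_xy = np.sum(w * bx_star * by_star, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_star**2, axis=1, keepdims=True)
    beta_loo_star = (s_xy - w * bx_star * by_star) / (s_xx - w * bx_star**2)
    resid_star = w * (by_star - beta_loo_star * bx_star) ** 2
    rss_star = np.sum(resid_star, axis=1)

    global_p = (1 + int(np.sum(rss_star >= rss_obs))) / (n_sim + 1)
    per_snp_p = np.sum(resid_star >= resid_obs, axis=0) / n_sim
    adjusted = np.minimum(1.0, per_snp_p * j)
    outlier_mask = adjusted < outlier_alpha
    outliers = [str(s) for s in h.snp_ids[outlier_mask]]

    corrected = None
    if outliers:
        kept = h.drop(~outlier_mask)
        if kept.n_snp >= 1:
            corrected = ivw(kept, random_effects=True)

    return PressoResult(
        rss_observed=rss_obs,
        global_p=float(global_p),
        n_sim=n_sim,
        per_snp_p=pd.Series(adjusted, index=list(h.snp_ids), name="adjusted_p"),
        outliers=outliers,
        corrected_estimate=corrected,
        seed=seed,
    )


def funnel_data(h: HarmonizedInstruments) -> pd.DataFrame:
    """Per-SNP (Wald ratio, precision) pairs for funnel-symmetry plotting."""
    if h.n_snp < 1:
        raise InsufficientInstrumentsError("funnel data requires at least 1 SNP")
    ratio = h.beta_y / h.beta_x
    ratio_se = h.se_y / np.abs(h.beta_x)
    return pd.DataFrame({"snp_id": h.snp_ids, "ratio": ratio,
                         "precision": 1.0 / ratio_se})


@dataclass
class SensitivityReport:
    """Bundle of all per-pair diagnostics with the dismissal flags.

    ``dismissed`` fires on the pleiotropy rule (global PRESSO p < alpha);
    the Egger intercept flag is recorded alongside as a secondary signal.
    """

    q_ivw: tuple[float, int, float]
    q_egger: tuple[float, int, float] | None
    egger_intercept: tuple[float, float, float] | None
    loo: pd.DataFrame
    funnel: pd.DataFrame
    presso: PressoResult | None
    alpha: float = 0.05

    @property
    def dismissed(self) -> bool:
        return self.presso is not None and self.presso.global_p < self.alpha

    @property
    def intercept_flag(self) -> bool:
        return self.egger_intercept is not None and self.egger_intercept[2] < self.alpha


def sensitivity_report(
    h: HarmonizedInstruments,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run every applicable diagnostic for one harmonized pair."""
    q_i = cochran_q(h, "ivw")
    q_e = cochran_q(h, "egger") if h.n_snp >= 3 else None
    if h.n_snp >= 3:
        e = egger(h)
        intercept = (e.intercept, e.intercept_se, e.intercept_p)
    else:
        intercept = None
    presso = mr_presso(h, n_sim=n_sim, seed=seed) if h.n_snp >= 4 else None
    return SensitivityReport(q_i, q_e, intercept, leave_one_out(h),
                             funnel_data(h), presso, alpha)
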