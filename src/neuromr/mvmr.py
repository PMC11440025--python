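"""Multivariable MR, two-step mediation MR, and multiplicity control.

Multivariable IVW regresses the outcome effects jointly on several
exposures' effect matrices, estimating each exposure's direct effect
conditional on the others. Two-step mediation multiplies the
exposure->mediator and mediator->outcome effects (product of coefficients)
and divides by the total effect to obtain the proportion mediated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .estimators import MREstimate
from .harmonize import HarmonizedInstruments


class CollinearExposuresError(ValueError):
    """Exposure effect matrix is rank deficient."""


class UndefinedProportionError(ValueError):
    """Proportion mediated undefined because the total effect is zero."""


@dataclass
class MvmrEstimate:
    """Joint IVW estimates: one direct effect per exposure."""

    exposure_names: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    n_snp: int
    scale_factor: float = 1.0

    def estimate_for(self, name: str) -> MREstimate:
        """One exposure's row repackaged as a univariable-style estimate."""
        k = self.exposure_names.index(name)
        return MREstimate.from_beta_se("mvmr_ivw", self.n_snp,
                                       float(self.betas[k]), float(self.ses[k]),
                                       scale_factor=self.scale_factor)


def mvmr_ivw(h: HarmonizedInstruments) -> MvmrEstimate:
    """Multivariable IVW: weighted no-intercept multiple regression.

    beta_y is regressed on the (SNPs x exposures) beta_x matrix with weights
    1/se_y²; per-exposure SEs are inflated by max(1, residual SD) and
    p-values are two-sided normal. A single-column matrix reduces exactly to
    univariable IVW with multiplicative random effects.
    """
    x = h.beta_x if h.beta_x.ndim == 2 else h.beta_x[:, None]
    j, k = x.shape
    if j <= k:
        raise CollinearExposuresError(f"{j} SNPs cannot identify {k} exposures")
    if np.linalg.matrix_rank(x) < k:
        raise CollinearExposuresError("exposure effect matrix is rank deficient")

    w = 1.0 / h.se_y**2
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * h.beta_y)
    betas = np.linalg.solve(xtwx, xtwy)
    cov_unit = np.linalg.inv(xtwx)

    resid = h.beta_y - x @ betas
    sigma2 = float(np.sum(w * resid**2)) / (j - k)
    scale = max(1.0, math.sqrt(sigma2))
    ses = np.sqrt(np.diag(cov_unit)) * scale
    pvals = 2 * stats.norm.sf(np.abs(betas) / ses)
    return MvmrEstimate(list(h.exposure_names), betas, ses, pvals, j, scale)


@dataclass
class MediationResult:
    """Two-step mediation decomposition for one exposure/mediator/outcome.

    ``beta_indirect`` is exactly ``beta_em * beta_mo`` (product of
    coefficients); ``proportion_mediated`` is indirect/total. The direct
    effect is reported as total - indirect (difference-derived). The CI of
    the proportion comes from seeded Monte-Carlo propagation of the three
    estimates, which respects the skew of the ratio when the total effect is
    imprecise.
    """

    exposure: str
    mediator: str
    outcome: str
    beta_total: float
    beta_em: float
    beta_mo: float
    beta_indirect: float
    se_indirect: float
    beta_direct: float
    proportion_mediated: float
    pm_ci: tuple[float, float]
    seed: int


def two_step_mediation(
    beta_total: MREstimate,
    beta_em: MREstimate,
    beta_mo: MREstimate,
    n_draws: int = 10_000,
    seed: int = 0,
    labels: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
) -> MediationResult:
    """Coefficient-product mediation with delta-method SE and MC proportion CI.

    indirect = beta_EM * beta_MO; se by the first-order delta method
    sqrt(beta_EM² se_MO² + beta_MO² se_EM²); proportion mediated =
    indirect / total. The Monte-Carlo CI redraws all three betas from
    normals with their SEs and takes the 2.5/97.5 percentiles of the ratio.
    """
    if beta_total.beta == 0:
        raise UndefinedProportionError("total effect is zero")
    indirect = beta_em.beta * beta_mo.beta
    se_ind = math.sqrt(beta_em.beta**2 * beta_mo.se**2
                       + beta_mo.beta**2 * beta_em.se**2)
    pm = indirect / beta_total.beta

    rng = np.random.default_rng(seed)
    em = rng.normal(beta_em.beta, beta_em.se, n_draws)
    mo = rng.normal(beta_mo.beta, beta_mo.se, n_draws)
    tot = rng.normal(beta_total.beta, beta_total.se, n_draws)
    draws = em * mo / tot
    lo, hi = np.percentile(draws, [2.5, 97.5])

    return MediationResult(
        exposure=labels[0], mediator=labels[1], outcome=labels[2],
        beta_total=beta_total.beta, beta_em=beta_em.beta, beta_mo=beta_mo.beta,
        beta_indirect=indirect, se_indirect=se_ind,
        beta_direct=beta_total.beta - indirect,
        proportion_mediated=pm, pm_ci=(float(lo), float(hi)), seed=seed,
    )


@dataclass
class PairResult:
    """Minimal record of one directed link for eligibility screening."""

    exposure: str
    outcome: str
    pvalue: float
    dismissed: bool = False


def mediation_eligibility(
    pairs: list[PairResult], alpha: float = 0.05
) -> list[tuple[str, str, str]]:
    """Triples (exposure, mediator, outcome) with all three links eligible.

    A triple qualifies when exposure->outcome, exposure->mediator and
    mediator->outcome links all exist, all have p < alpha, and none was
    dismissed by the pleiotropy rule.
    """
    by_key = {(p.exposure, p.outcome): p for p in pairs}
    names = {n for p in pairs for n in (p.exposure, p.outcome)}
    out = []
    for e, m, o in permutations(sorted(names), 3):
        links = [by_key.get((e, o)), by_key.get((e, m)), by_key.get((m, o))]
        if any(l is None for l in links):
            continue
        if all(l.pvalue < alpha and not l.dismissed for l in links):
            out.append((e, m, o))
    return out


def bonferroni(p: float, m: int) -> tuple[float, bool, bool]:
    """Family-wise threshold 0.05/m; (threshold, significant, nominal)."""
    if m < 1:
        raise ValueError("m must be at least 1")
    threshold = 0.05 / m
    return threshold, p < threshold, p < 0.05
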