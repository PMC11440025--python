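"""Univariable two-sample MR estimators.

All estimators consume a :class:`~neuromr.harmonize.HarmonizedInstruments`
with a single exposure and return an :class:`MREstimate`.

* ``ivw`` — inverse-variance-weighted regression of outcome on exposure
  effects through the origin; with multiplicative random effects (the
  default, and the primary estimator) the standard error is inflated by the
  residual overdispersion, truncated below at 1.
* ``egger`` — the same regression with an intercept; the slope is robust to
  directional pleiotropy under the InSIDE assumption and the intercept
  estimates the mean pleiotropic effect.
* ``weighted_median`` — the weighted median of per-SNP Wald ratios,
  consistent when at least half of the weight comes from valid instruments;
  its SE comes from a seeded parametric bootstrap.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstruments
from .instruments import InsufficientInstrumentsError


class DegenerateInstrumentError(ValueError):
    """Wald ratio requested for a SNP with zero exposure effect."""


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds (or SD) scale.

    ``beta`` is the causal effect per unit exposure; the odds-ratio scale
    (``or_``, ``or_low``, ``or_high``) is exp of the beta CI. Egger results
    additionally carry the intercept triple; ``scale_factor`` is the
    multiplicative random-effects / residual-SD inflation applied to ``se``
    (>= 1 by construction).
    """

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    scale_factor: float = 1.0
    seed: int | None = None

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    @classmethod
    def from_beta_se(cls, method: str, n_snp: int, beta: float, se: float,
                     df: int | None = None, **kw) -> "MREstimate":
        """Wald CI and two-sided p; normal by default, t when ``df`` given."""
        if df is None:
            crit = stats.norm.ppf(0.975)
            p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = stats.t.ppf(0.975, df)
            p = 2 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
        return cls(method, n_snp, float(beta), float(se),
                   float(beta - crit * se), float(beta + crit * se), float(p), **kw)


def _check_single_exposure(h: HarmonizedInstruments) -> None:
    if h.beta_x.ndim != 1:
        raise ValueError("univariable estimator called on multi-exposure data")


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal ratio beta_y/beta_x and its SE.

    First-order SE ignores exposure uncertainty (se_y/|beta_x|); the
    second-order option adds the delta-method exposure term.
    """
    if beta_x == 0:
        raise DegenerateInstrumentError("beta_x = 0: Wald ratio undefined")
    ratio = beta_y / beta_x
    if second_order:
        se = math.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    else:
        se = se_y / abs(beta_x)
    return ratio, se


def ivw(h: HarmonizedInstruments, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (the primary MR estimator).

    Weighted no-intercept regression of beta_y on beta_x with weights
    1/se_y². Under multiplicative random effects the fixed-effect SE is
    multiplied by max(1, sqrt(Q/(J-1))) with Q Cochran's heterogeneity
    statistic at the IVW estimate; a single SNP degrades to the Wald ratio.
    """
    _check_single_exposure(h)
    j = h.n_snp
    if j == 0:
        raise InsufficientInstrumentsError("IVW requires at least one SNP")
    if j == 1:
        ratio, se = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])
        return MREstimate.from_beta_se("wald", 1, ratio, se)

    w = 1.0 / h.se_y**2
    s_xx = float(np.sum(w * h.beta_x**2))
    beta = float(np.sum(w * h.beta_x * h.beta_y)) / s_xx
    se_fe = s_xx**-0.5
    scale = 1.0
    if random_effects:
        q = float(np.sum(w * (h.beta_y - beta * h.beta_x) ** 2))
        scale = max(1.0, math.sqrt(q / (j - 1)))
    method = "ivw_mre" if random_effects else "ivw_fe"
    return MREstimate.from_beta_se(method, j, beta, se_fe * scale, scale_factor=scale)


def egger(h: HarmonizedInstruments) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    SNPs are oriented so beta_x >= 0 (both betas flipped together, which
    leaves Wald ratios unchanged); the intercept then estimates directional
    pleiotropy on the exposure-increasing allele. SEs are inflated by
    max(1, residual SD); p-values use t with J-2 degrees of freedom.
    """
    _check_single_exposure(h)
    j = h.n_snp
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 SNPs")

    flip = np.where(h.beta_x < 0, -1.0, 1.0)
    bx, by = h.beta_x * flip, h.beta_y * flip
    w = 1.0 / h.se_y**2

    # weighted normal equations for [intercept, slope]
    sw, swx = float(np.sum(w)), float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy, swxy = float(np.sum(w * by)), float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise InsufficientInstrumentsError("degenerate design in Egger regression")
    alpha = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det

    resid = by - alpha - slope * bx
    sigma2 = float(np.sum(w * resid**2)) / (j - 2)
    scale = max(1.0, math.sqrt(sigma2))
    se_slope = math.sqrt(sw / det) * scale
    se_alpha = math.sqrt(swxx / det) * scale

    est = MREstimate.from_beta_se("egger", j, slope, se_slope, df=j - 2,
                                  scale_factor=scale)
    est.intercept = float(alpha)
    est.intercept_se = float(se_alpha)
    est.intercept_p = float(2 * stats.t.sf(abs(alpha) / se_alpha, j - 2)) \
        if se_alpha > 0 else 1.0
    return est


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weight crosses 1/2."""
    order = np.argsort(ratios, kind="mergesort")
    b, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, b))


def weighted_median(h: HarmonizedInstruments, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Per-SNP Wald ratios are weighted by inverse ratio variance (first-order
    SE); the bootstrap redraws beta_x and beta_y from normals with the
    observed SEs and takes the SD of the re-estimates. The seed is recorded
    in the result for bit-reproducibility.
    """
    _check_single_exposure(h)
    j = h.n_snp
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 SNPs")

    ratios = h.beta_y / h.beta_x
    ratio_se = h.se_y / np.abs(h.beta_x)
    est = _weighted_median(ratios, ratio_se**-2)

    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_x, h.se_x, size=(n_boot, j))
    by = rng.normal(h.beta_y, h.se_y, size=(n_boot, j))
    bx = np.where(bx == 0, np.finfo(float).tiny, bx)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        r = by[k] / bx[k]
        boot[k] = _weighted_median(r, (np.abs(bx[k]) / h.se_y) ** 2)
    se = float(np.std(boot, ddof=1))
    return MREstimate.from_beta_se("weighted_median", j, est, se, seed=seed)


def run_uvmr(h: HarmonizedInstruments, seed: int = 0,
             n_boot: int = 1000) -> list[MREstimate]:
    """IVW-MRE, MR-Egger and weighted-median estimates for one pair.

    Methods whose arity the instrument count cannot support are simply
    omitted (a single SNP yields only the Wald ratio; two SNPs only IVW).
    """
    out = [ivw(h, random_effects=True)]
    if h.n_snp >= 3:
        out.append(egger(h))
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
    return out


def consistent_direction(estimates: list[MREstimate]) -> bool:
    """True when every method's beta shares one sign."""
    signs = {np.sign(e.beta) for e in estimates}
    return len(signs - {0.0}) <= 1
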