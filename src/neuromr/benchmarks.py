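"""Replicate-study benchmarks of the estimators on generator truth.

Each function runs a seeded simulation study at a documented desk-scale
problem size and returns summary numbers: type-I error calibration of IVW
and the Egger intercept test under the null, weighted-median robustness to
directional pleiotropy, outlier-test power and size, and recovery of a
planted mediated proportion. These back both the test suite and the
reproduction script.
"""
from __future__ import annotations

import numpy as np

from .estimators import egger, ivw, weighted_median
from .mvmr import two_step_mediation
from .sensitivity import mr_presso
from .simulate import (SimulationTruth, generate_harmonized,
                       generate_mediation_harmonized)

#: robustness scenario: 40% invalid instruments with a directional
#: pleiotropic shift of about +1 on the Wald-ratio scale
ROBUSTNESS_TRUTH = dict(theta=0.5, pleiotropy_frac=0.4, pleiotropy_mean=0.03,
                        pleiotropy_sd=0.01, j_instruments=50)

#: mediation scenario: EM 0.4, MO 0.25, direct 0.9 => true PM = 0.10/1.00
MEDIATION_TRUTH = dict(theta_em=0.4, theta_mo=0.25, theta_direct=0.9,
                       j_instruments=50, j_mediator=30)


def null_calibration(n_reps: int = 1000, j: int = 50, seed: int = 0,
                     alpha: float = 0.05) -> dict[str, float]:
    """Rejection rates of IVW-MRE and the Egger intercept test at theta=0."""
    truth = SimulationTruth(theta=0.0, j_instruments=j)
    base = seed * 100_000
    rej_ivw = rej_int = 0
    for r in range(n_reps):
        h = generate_harmonized(truth, seed=base + r)
        if ivw(h).pvalue < alpha:
            rej_ivw += 1
        if egger(h).intercept_p < alpha:
            rej_int += 1
    return {"ivw_rejection_rate": rej_ivw / n_reps,
            "egger_intercept_rejection_rate": rej_int / n_reps,
            "n_reps": n_reps}


def wm_robustness(n_reps: int = 500, seed: int = 0,
                  n_boot: int = 50) -> dict[str, float]:
    """Mean bias of IVW vs weighted median under 40% directional pleiotropy."""
    truth = SimulationTruth(**ROBUSTNESS_TRUTH)
    base = seed * 100_000 + 20_000_000
    bias_ivw = np.empty(n_reps)
    bias_wm = np.empty(n_reps)
    for r in range(n_reps):
        h = generate_harmonized(truth, seed=base + r)
        bias_ivw[r] = ivw(h).beta - truth.theta
        bias_wm[r] = weighted_median(h, n_boot=n_boot, seed=r).beta - truth.theta
    return {"ivw_abs_bias": float(abs(bias_ivw.mean())),
            "wm_abs_bias": float(abs(bias_wm.mean())),
            "bias_ratio": float(abs(bias_wm.mean()) / abs(bias_ivw.mean())),
            "n_reps": n_reps}


def presso_power(n_reps: int = 200, n_sim: int = 500, j: int = 30,
                 displacement: float = 10.0, seed: int = 0) -> dict[str, float]:
    """Detection rate of one SNP displaced by ``displacement`` x se_y."""
    truth = SimulationTruth(theta=0.3, j_instruments=j)
    base = seed * 100_000 + 40_000_000
    detected = 0
    for r in range(n_reps):
        h = generate_harmonized(truth, seed=base + r)
        h.beta_y[0] += displacement * h.se_y[0]
        res = mr_presso(h, n_sim=n_sim, seed=r)
        if h.snp_ids[0] in res.outliers:
            detected += 1
    return {"detection_rate": detected / n_reps, "n_reps": n_reps}


def presso_type1(n_reps: int = 1000, n_sim: int = 500, j: int = 30,
                 seed: int = 0, alpha: float = 0.05) -> dict[str, float]:
    """Global-test rejection rate on clean (no-pleiotropy) data."""
    truth = SimulationTruth(theta=0.3, j_instruments=j)
    base = seed * 100_000 + 50_000_000
    rej = 0
    for r in range(n_reps):
        h = generate_harmonized(truth, seed=base + r)
        if mr_presso(h, n_sim=n_sim, seed=r).global_p < alpha:
            rej += 1
    return {"type1_rate": rej / n_reps, "n_reps": n_reps}


def mediation_recovery(n_reps: int = 200, seed: int = 0,
                       n_draws: int = 2000) -> dict[str, float]:
    """Mean estimated proportion mediated in the planted-chain scenario."""
    truth = SimulationTruth(**MEDIATION_TRUTH)
    base = seed * 100_000 + 60_000_000
    pms = np.empty(n_reps)
    for r in range(n_reps):
        ht, he, hm = generate_mediation_harmonized(truth, seed=base + r)
        med = two_step_mediation(ivw(ht), ivw(he), ivw(hm),
                                 n_draws=n_draws, seed=r)
        pms[r] = med.proportion_mediated
    true_pm = truth.theta_em * truth.theta_mo / truth.total_effect
    return {"mean_pm": float(pms.mean()), "true_pm": float(true_pm),
            "n_reps": n_reps}


def estimator_bias(n_reps: int = 500, theta: float = 0.3, j: int = 50,
                   f_target: float = 400.0, seed: int = 0) -> dict[str, float]:
    """Mean bias of the three estimators with strong, valid instruments."""
    truth = SimulationTruth(theta=theta, j_instruments=j, f_target=f_target)
    base = seed * 100_000 + 70_000_000
    b = {"ivw": [], "egger": [], "wm": []}
    for r in range(n_reps):
        h = generate_harmonized(truth, seed=base + r)
        b["ivw"].append(ivw(h).beta - theta)
        b["egger"].append(egger(h).beta - theta)
        b["wm"].append(weighted_median(h, n_boot=30, seed=r).beta - theta)
    return {k: float(np.mean(v)) for k, v in b.items()} | {"n_reps": n_reps}
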