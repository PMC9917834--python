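"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

The battery run on every MR analysis round: Cochran's Q about the IVW fit,
Rucker's Q about the Egger fit, the Egger intercept test, the MR-PRESSO
global / per-SNP outlier / distortion tests, and leave-one-out influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metabomr.errors import EstimationError
from metabomr.estimators import ivw_random_effects, mr_egger
from metabomr.instruments import HarmonizedIVSet


@dataclass
class QTest:
    statistic: float
    df: int
    p: float


@dataclass
class InterceptTest:
    estimate: float
    se: float
    p: float


@dataclass
class PressoResult:
    """MR-PRESSO global, per-SNP outlier, and distortion test outputs.

    ``outliers`` are Bonferroni-significant per-SNP tests; ``potential_outliers``
    are nominally significant ones that do not survive Bonferroni.
    ``distortion_p`` is None when there is nothing to remove.
    """

    available: bool
    global_rss: float = float("nan")
    global_p: float = float("nan")
    per_snp: pd.DataFrame | None = None  # snp_id, statistic, p, p_bonferroni
    outliers: list[str] = field(default_factory=list)
    potential_outliers: list[str] = field(default_factory=list)
    distortion_p: float | None = None


@dataclass
class SensitivityReport:
    q_ivw: QTest
    q_rucker: QTest | None
    egger_intercept: InterceptTest | None
    presso: PressoResult
    loo_table: pd.DataFrame
    influential_snps: list[str]


def cochran_q(ivs: HarmonizedIVSet) -> QTest:
    """Heterogeneity of Wald ratios about the fixed-effect IVW estimate.

    Q = sum_i w_i (r_i - beta_fixed)^2 with w_i = bx_i^2 / se_out_i^2,
    which equals the weighted RSS of by on bx through the origin;
    chi-square with k-1 df.
    """
    k = ivs.k
    if k < 2:
        raise EstimationError("Cochran's Q needs k >= 2")
    bx, _, by, se_y = ivs.arrays()
    w = 1.0 / se_y**2
    beta = np.sum(w * bx * by) / np.sum(w * bx * bx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    p = float(stats.chi2.sf(q, k - 1))
    return QTest(q, k - 1, p)


def rucker_q(ivs: HarmonizedIVSet) -> QTest:
    """Weighted residual sum of squares about the Egger fit; k-2 df."""
    k = ivs.k
    if k < 3:
        raise EstimationError("Rucker's Q needs k >= 3")
    egger = mr_egger(ivs)
    q = float(egger.extra["q_rucker"])
    p = float(stats.chi2.sf(q, k - 2))
    return QTest(q, k - 2, p)


def egger_intercept_test(ivs: HarmonizedIVSet) -> InterceptTest:
    """Directional-pleiotropy test: the Egger intercept and its t-test."""
    egger = mr_egger(ivs)
    return InterceptTest(
        egger.extra["intercept"],
        egger.extra["intercept_se"],
        egger.extra["intercept_p"],
    )


def _loo_betas(bx, by, w):
    """Leave-one-out fixed-effect IVW slopes, vectorized over the left-out SNP."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso_rss(ivs: HarmonizedIVSet) -> tuple[float, np.ndarray]:
    """Observed MR-PRESSO statistic: each SNP's outcome effect is predicted
    from the IVW fit of the other k-1 SNPs; the statistic is the weighted
    squared prediction error, summed for the global test."""
    bx, _, by, se_y = ivs.arrays()
    w = 1.0 / se_y**2
    beta_loo = _loo_betas(bx, by, w)
    per_snp = w * (by - beta_loo * bx) ** 2
    return float(np.sum(per_snp)), per_snp


def mr_presso(
    ivs: HarmonizedIVSet,
    n_sim: int = 1000,
    seed: int = 0,
    sig: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests (parametric null).

    The null distribution is built by redrawing, ``n_sim`` times, exposure
    effects from normal(bx, se_x) and outcome effects from
    normal(beta_loo_i * bx_i, se_out_i) — i.e. no pleiotropy — and
    recomputing the statistic. Empirical p-values use the (r+1)/(n+1) rule.
    """
    k = ivs.k
    if k < 4:
        return PressoResult(available=False)
    bx, se_x, by, se_y = ivs.arrays()
    w = 1.0 / se_y**2
    rss_obs, per_snp_obs = presso_rss(ivs)
    beta_loo = _loo_betas(bx, by, w)

    rng = np.random.default_rng(seed)
    bx_s = bx + rng.standard_normal((n_sim, k)) * se_x
    by_s = beta_loo * bx + rng.standard_normal((n_sim, k)) * se_y

    sxy = np.sum(w * bx_s * by_s, axis=1, keepdims=True)
    sxx = np.sum(w * bx_s * bx_s, axis=1, keepdims=True)
    beta_loo_s = (sxy - w * bx_s * by_s) / (sxx - w * bx_s * bx_s)
    per_snp_sim = w * (by_s - beta_loo_s * bx_s) ** 2
    rss_sim = np.sum(per_snp_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(per_snp_sim >= per_snp_obs, axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_snp * k)

    ids = np.asarray(ivs.snp_ids)
    outliers = sorted(ids[p_bonf < sig].tolist())
    potential = sorted(ids[(p_snp < sig) & (p_bonf >= sig)].tolist())
    per_snp_df = pd.DataFrame(
        {
            "snp_id": ids,
            "statistic": per_snp_obs,
            "p": p_snp,
            "p_bonferroni": p_bonf,
        }
    )

    distortion_p = None
    to_remove = outliers if outliers else potential
    if to_remove:
        distortion_p = _distortion_test(ivs, to_remove, n_sim, rng)
    return PressoResult(
        available=True,
        global_rss=rss_obs,
        global_p=global_p,
        per_snp=per_snp_df,
        outliers=outliers,
        potential_outliers=potential,
        distortion_p=distortion_p,
    )


def _distortion_test(
    ivs: HarmonizedIVSet, removed: list[str], n_sim: int, rng
) -> float:
    """Two-sided p for whether removing the flagged SNPs shifts the IVW
    estimate more than removing random same-size subsets does."""
    bx, _, by, se_y = ivs.arrays()
    w = 1.0 / se_y**2
    k = len(bx)
    beta_full = np.sum(w * bx * by) / np.sum(w * bx * bx)
    keep = ~np.isin(np.asarray(ivs.snp_ids), removed)
    if keep.sum() < 2:
        return float("nan")
    beta_wo = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(
        w[keep] * bx[keep] * bx[keep]
    )
    d_obs = beta_wo - beta_full
    n_out = int((~keep).sum())
    d_sim = np.empty(n_sim)
    for s in range(n_sim):
        drop = rng.choice(k, size=n_out, replace=False)
        mask = np.ones(k, dtype=bool)
        mask[drop] = False
        d_sim[s] = (
            np.sum(w[mask] * bx[mask] * by[mask])
            / np.sum(w[mask] * bx[mask] * bx[mask])
            - beta_full
        )
    return float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))


def leave_one_out(ivs: HarmonizedIVSet, alpha: float = 0.05):
    """Refit random-effects IVW k times, omitting one instrument each time.

    A SNP is flagged influential iff its omission flips the significance
    status of the IVW p-value at ``alpha`` relative to the full-set fit
    (in either direction).
    """
    k = ivs.k
    if k < 3:
        raise EstimationError("leave-one-out needs k >= 3")
    full = ivw_random_effects(ivs)
    full_sig = full.p < alpha
    rows = []
    influential = []
    for sid in ivs.snp_ids:
        sub = ivs.without([sid])
        res = ivw_random_effects(sub)
        rows.append(
            {
                "snp_id": sid,
                "beta_without": res.beta,
                "se_without": res.se,
                "p_without": res.p,
            }
        )
        if (res.p < alpha) != full_sig:
            influential.append(sid)
    return pd.DataFrame(rows), influential


def run_sensitivity(
    ivs: HarmonizedIVSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    sig: float = 0.05,
) -> SensitivityReport:
    """The full diagnostic battery for one instrument set."""
    q_ivw = cochran_q(ivs)
    q_rucker = rucker_q(ivs) if ivs.k >= 3 else None
    intercept = egger_intercept_test(ivs) if ivs.k >= 3 else None
    presso = mr_presso(ivs, n_sim=n_sim, seed=seed, sig=sig)
    if ivs.k >= 3:
        loo_table, influential = leave_one_out(ivs, alpha=alpha)
    else:
        loo_table, influential = pd.DataFrame(
            columns=["snp_id", "beta_without", "se_without", "p_without"]
        ), []
    return SensitivityReport(q_ivw, q_rucker, intercept, presso, loo_table, influential)


def sensitivity_row(report: SensitivityReport) -> dict:
    """One summary row per pair: heterogeneity, pleiotropy and outlier columns."""
    return {
        "cochran_q_p": report.q_ivw.p,
        "rucker_q_p": report.q_rucker.p if report.q_rucker else float("nan"),
        "egger_intercept_p": (
            report.egger_intercept.p if report.egger_intercept else float("nan")
        ),
        "distortion_outliers": len(report.presso.outliers)
        if report.presso.available
        else 0,
        "presso_global_p": report.presso.global_p
        if report.presso.available
        else float("nan"),
    }
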