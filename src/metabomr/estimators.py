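"""The five MR estimators plus the per-SNP Wald ratio primitive.

All estimators consume a :class:`~metabomr.instruments.HarmonizedIVSet` and
return an :class:`MRResult` with the causal estimate on the beta scale and
its exponentiated (odds-ratio) presentation.

Conventions:

* IVW and Egger use multiplicative random effects — the model-based SE is
  scaled by ``max(1, sqrt(Q / df))`` — the common convention for summary
  two-sample MR.
* Median and mode SEs come from a seeded parametric bootstrap that
  resamples both exposure and outcome effects from normal(estimate, SE).
* Mode estimators maximize a weighted normal-kernel density of the Wald
  ratios, bandwidth ``phi * 0.9 * min(sd, mad) * k^(-1/5)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from metabomr.errors import EstimationError
from metabomr.instruments import HarmonizedIVSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """One estimator's causal-effect estimate for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    p: float
    k: int
    extra: dict = field(default_factory=dict)
    ci_z: float = Z95  # quantile used for the CI (normal or t)

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - self.ci_z * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + self.ci_z * self.se))


def _ratios(ivs: HarmonizedIVSet):
    bx, se_x, by, se_y = ivs.arrays()
    if np.any(bx == 0):
        raise EstimationError("beta_exposure contains exact zeros; Wald undefined")
    r = by / bx
    se_r = se_y / np.abs(bx)
    return r, se_r


def wald_ratio(row) -> MRResult:
    """Single-SNP causal estimate by/bx with first-order SE se_y/|bx|."""
    bx = float(row["beta_exposure"])
    by = float(row["beta_outcome"])
    se_y = float(row["se_outcome"])
    if bx == 0:
        raise EstimationError("wald_ratio undefined for beta_exposure = 0")
    beta = by / bx
    se = se_y / abs(bx)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult("wald", beta, se, float(p), k=1)


def wald_ratio_second_order(row) -> MRResult:
    """Wald ratio with the second-order delta-method SE, which also
    propagates exposure-side uncertainty:
    se^2 = se_y^2/bx^2 + by^2 * se_x^2 / bx^4.
    """
    bx = float(row["beta_exposure"])
    by = float(row["beta_outcome"])
    se_x = float(row["se_exposure"])
    se_y = float(row["se_outcome"])
    if bx == 0:
        raise EstimationError("wald_ratio undefined for beta_exposure = 0")
    beta = by / bx
    se = np.sqrt(se_y**2 / bx**2 + by**2 * se_x**2 / bx**4)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult("wald", beta, float(se), float(p), k=1)


def ivw_fixed_effect_beta(ivs: HarmonizedIVSet) -> float:
    """Zero-intercept WLS slope with weights 1/se_out^2 (no dispersion)."""
    bx, _, by, se_y = ivs.arrays()
    w = 1.0 / se_y**2
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def ivw_random_effects(ivs: HarmonizedIVSet) -> MRResult:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Weighted regression of by on bx through the origin, weights 1/se_out^2;
    the model SE is scaled by ``max(1, sqrt(Q/(k-1)))``. With a single
    instrument this degenerates to the Wald ratio (with a warning).
    """
    k = ivs.k
    if k < 1:
        raise EstimationError("no instruments")
    if k == 1:
        warnings.warn("k=1: IVW falls back to the Wald ratio", stacklevel=2)
        res = wald_ratio(ivs.df.iloc[0])
        return MRResult("ivw_re", res.beta, res.se, res.p, k=1, extra={"q": 0.0})
    bx, _, by, se_y = ivs.arrays()
    w = 1.0 / se_y**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = max(1.0, np.sqrt(q / (k - 1)))
    se = se_fixed * scale
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult(
        "ivw_re",
        float(beta),
        float(se),
        float(p),
        k=k,
        extra={"q": q, "re_scale": float(scale)},
    )


def mr_egger(ivs: HarmonizedIVSet) -> MRResult:
    """Egger regression: WLS of by on bx with a free intercept.

    Rows are first oriented so all bx >= 0. The intercept estimates
    directional pleiotropy; SEs use multiplicative random effects with
    ``max(1, sqrt(Q'/(k-2)))`` and p-values come from t with k-2 df.
    """
    k = ivs.k
    if k < 3:
        raise EstimationError(f"MR-Egger needs k >= 3 instruments, got {k}")
    bx, _, by, se_y = ivs.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip
    w = 1.0 / se_y**2

    sw = np.sum(w)
    swx = np.sum(w * bx)
    swxx = np.sum(w * bx * bx)
    swy = np.sum(w * by)
    swxy = np.sum(w * bx * by)
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimationError("degenerate design in MR-Egger (constant bx)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    q_rucker = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q_rucker / (k - 2)))
    se_slope = np.sqrt(sw / det) * scale
    se_int = np.sqrt(swxx / det) * scale
    df = k - 2
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    return MRResult(
        "egger",
        float(slope),
        float(se_slope),
        float(p_slope),
        k=k,
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": float(p_int),
            "q_rucker": q_rucker,
            "re_scale": float(scale),
        },
        ci_z=float(stats.t.ppf(0.975, df)),
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50th weighted percentile of ratios ``r``."""
    order = np.argsort(r, kind="mergesort")
    r = r[order]
    w = w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    below = np.max(np.where(cum < 0.5)[0])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + (r[below + 1] - r[below]) * frac)


def weighted_median(
    ivs: HarmonizedIVSet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap SE."""
    k = ivs.k
    if k < 3:
        raise EstimationError(f"weighted median needs k >= 3 instruments, got {k}")
    r, se_r = _ratios(ivs)
    w = 1.0 / se_r**2
    beta = _weighted_median_point(r, w)
    se = _bootstrap_se(ivs, lambda rr, ww: _weighted_median_point(rr, ww), n_boot, seed)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return MRResult("weighted_median", beta, float(se), float(p), k=k)


def _bootstrap_se(ivs: HarmonizedIVSet, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample bx, by from normal(observed, SE),
    recompute ratios and inverse-variance weights, take the SD."""
    bx, se_x, by, se_y = ivs.arrays()
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = bx + rng.standard_normal(len(bx)) * se_x
        by_s = by + rng.standard_normal(len(by)) * se_y
        bx_s[bx_s == 0] = np.finfo(float).tiny
        rr = by_s / bx_s
        ww = (np.abs(bx_s) / se_y) ** 2
        ests[b] = point_fn(rr, ww)
    return float(np.std(ests, ddof=1))


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    sd = np.std(r, ddof=1)
    mad = stats.median_abs_deviation(r, scale="normal")
    s = 0.9 * min(sd, mad) * len(r) ** (-0.2)
    if s <= 0:  # all ratios identical (or MAD zero with tight sd)
        s = max(sd, 1e-8)
    return max(1e-8, s * phi)


def kernel_mode_point(
    r: np.ndarray, w: np.ndarray, h: float, n_grid: int = 512
) -> float:
    """Argmax of the weighted normal-kernel density over an evaluation grid
    spanning [min - 3h, max + 3h], refined by one parabolic step."""
    lo = np.min(r) - 3 * h
    hi = np.max(r) + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    dens = _kernel_density(grid, r, w, h)
    i = int(np.argmax(dens))
    if 0 < i < n_grid - 1:
        # parabolic refinement through the argmax and its neighbors
        y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            step = 0.5 * (y0 - y2) / denom
            return float(grid[i] + step * (grid[1] - grid[0]))
    return float(grid[i])


def _kernel_density(x: np.ndarray, r: np.ndarray, w: np.ndarray, h: float):
    wn = w / np.sum(w)
    z = (x[:, None] - r[None, :]) / h
    return np.exp(-0.5 * z**2) @ wn


def _mode_result(
    ivs: HarmonizedIVSet, method: str, weighted: bool, phi: float, n_boot: int, seed: int
) -> MRResult:
    k = ivs.k
    if k < 3:
        raise EstimationError(f"{method} needs k >= 3 instruments, got {k}")
    r, se_r = _ratios(ivs)

    def point(rr, ww):
        h = _mode_bandwidth(rr, phi)
        weights = ww if weighted else np.ones_like(rr)
        return kernel_mode_point(rr, weights, h)

    beta = point(r, 1.0 / se_r**2)
    se = _bootstrap_se(ivs, point, n_boot, seed)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return MRResult(method, float(beta), float(se), float(p), k=k)


def simple_mode(
    ivs: HarmonizedIVSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Unweighted mode of the smoothed Wald-ratio density."""
    return _mode_result(ivs, "simple_mode", False, phi, n_boot, seed)


def weighted_mode(
    ivs: HarmonizedIVSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Inverse-variance-weighted mode of the smoothed Wald-ratio density."""
    return _mode_result(ivs, "weighted_mode", True, phi, n_boot, seed)


def run_all_estimators(
    ivs: HarmonizedIVSet, n_boot: int = 1000, seed: int = 0, phi: float = 1.0
) -> dict[str, MRResult]:
    """All five estimators keyed by method name; methods whose instrument
    minimum is not met are silently absent from the result."""
    out: dict[str, MRResult] = {}
    if ivs.k >= 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["ivw_re"] = ivw_random_effects(ivs)
    if ivs.k >= 3:
        out["egger"] = mr_egger(ivs)
        out["weighted_median"] = weighted_median(ivs, n_boot, seed)
        out["simple_mode"] = simple_mode(ivs, phi, n_boot, seed)
        out["weighted_mode"] = weighted_mode(ivs, phi, n_boot, seed)
    return out


def results_table(results: dict[str, MRResult]):
    """Forest-plot-ready table: method, k, beta, se, OR, CI bounds, p."""
    import pandas as pd

    rows = [
        {
            "method": m,
            "k": r.k,
            "beta": r.beta,
            "se": r.se,
            "or": r.or_value,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
        }
        for m, r in results.items()
    ]
    return pd.DataFrame(rows)
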