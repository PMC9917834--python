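"""LD score regression: SNP heritability and bivariate genetic correlation.

Univariate: weighted regression of per-SNP chi-square on N*l/M with a free
intercept; the slope is the heritability estimate. Bivariate: regression of
z_x*z_y on sqrt(N_x*N_y)*l/M gives the genetic covariance, normalized by
the geometric mean of the heritabilities to give r_g. Weights combine the
1/l over-counting correction with the model-based heteroskedasticity term
and are iterated twice from an initial unweighted fit. Uncertainty comes
from a delete-one block jackknife over contiguous SNP blocks in genome
order, with the ratio r_g recomputed inside every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from metabomr.errors import EstimationError
from metabomr.sumstats_io import LDScoreTable, SummaryStatsTable


@dataclass
class H2Estimate:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    n_blocks_used: int


@dataclass
class RgEstimate:
    rg: float
    rg_se: float
    p: float
    gencov: float
    gencov_intercept: float
    h2_x: float
    h2_y: float
    n_blocks_used: int = 0


def chi2_stats(table: SummaryStatsTable) -> np.ndarray:
    """Per-SNP chi-square statistics, (beta/se)^2."""
    df = table.df
    z = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
    return z**2


# ---------------------------------------------------------------------------
# weighted regression helpers


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of the weighted least-squares line."""
    sw = np.sum(w)
    swx = np.sum(w * x)
    swxx = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0 or not np.isfinite(det):
        raise EstimationError("singular LDSC regression (constant LD scores?)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return float(intercept), float(slope)


def _iterated_weights(
    x: np.ndarray,
    y: np.ndarray,
    ell: np.ndarray,
    denom_fn: Callable[[float, float], np.ndarray],
    n_iter: int = 2,
) -> tuple[float, float, np.ndarray, list[tuple[float, float]]]:
    """Two-step iterated weighting starting from an unweighted fit.

    ``denom_fn(intercept, slope)`` returns the per-SNP variance term; the
    weight is 1 / (max(l,1) * denom). Also returns the per-iteration
    (intercept, slope) history so a companion regression can iterate its
    weights in lockstep.
    """
    w = np.ones_like(x)
    intercept, slope = _wls(x, y, w)
    history = [(intercept, slope)]
    for _ in range(n_iter):
        denom = np.maximum(denom_fn(intercept, slope), 1e-3)
        w = 1.0 / (np.maximum(ell, 1.0) * denom)
        intercept, slope = _wls(x, y, w)
        history.append((intercept, slope))
    return intercept, slope, w, history


def _model_term(intercept: float, slope: float, xv: np.ndarray) -> np.ndarray:
    """Per-SNP model mean used in the heteroskedasticity weights."""
    return max(intercept, 0.1) + float(np.clip(slope, 0.0, 1.0)) * xv


def _jackknife(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Delete-one-block (intercept, slope) replicates with fixed weights."""
    n = len(x)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    edges = np.unique(edges)
    starts = edges[:-1]
    g = len(starts)
    if g < 2:
        raise EstimationError("need at least 2 jackknife blocks")
    parts = {}
    for name, arr in (
        ("sw", w),
        ("swx", w * x),
        ("swxx", w * x * x),
        ("swy", w * y),
        ("swxy", w * x * y),
    ):
        parts[name] = np.add.reduceat(arr, starts)
    tot = {k: np.sum(v) for k, v in parts.items()}
    sw = tot["sw"] - parts["sw"]
    swx = tot["swx"] - parts["swx"]
    swxx = tot["swxx"] - parts["swxx"]
    swy = tot["swy"] - parts["swy"]
    swxy = tot["swxy"] - parts["swxy"]
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return intercept, slope, g


def _jackknife_se(replicates: np.ndarray) -> float:
    g = len(replicates)
    mean = np.mean(replicates)
    return float(np.sqrt((g - 1) / g * np.sum((replicates - mean) ** 2)))


def _merged(table: SummaryStatsTable, ld: LDScoreTable) -> pd.DataFrame:
    df = table.df.merge(ld.df, on="snp_id", how="inner")
    if df["n"].isna().any():
        raise EstimationError("per-SNP sample size N is required for LDSC")
    order = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return order


def fit_h2(
    table: SummaryStatsTable,
    ld: LDScoreTable,
    n_blocks: int = 200,
    n_weight_iters: int = 2,
) -> H2Estimate:
    """SNP heritability by LD score regression with a free intercept.

    With ``n_weight_iters=0`` this is a single unweighted least-squares
    pass (useful as an oracle target); the default iterates the combined
    heteroskedasticity/over-counting weights twice.
    """
    df = _merged(table, ld)
    if len(df) < 2 * n_blocks:
        raise EstimationError(
            f"too few overlapping SNPs ({len(df)}) for {n_blocks} jackknife blocks"
        )
    ell = df["ldscore"].to_numpy(float)
    n = df["n"].to_numpy(float)
    m = ld.m_total
    x = n * ell / m
    y = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) ** 2

    def denom(intercept: float, slope: float) -> np.ndarray:
        return _model_term(intercept, slope, x) ** 2

    if n_weight_iters == 0:
        w = np.ones_like(x)
        intercept, slope = _wls(x, y, w)
    else:
        intercept, slope, w, _ = _iterated_weights(x, y, ell, denom, n_weight_iters)

    int_reps, slope_reps, g = _jackknife(x, y, w, n_blocks)
    return H2Estimate(
        h2=slope,
        h2_se=_jackknife_se(slope_reps),
        intercept=intercept,
        intercept_se=_jackknife_se(int_reps),
        n_blocks_used=g,
    )


def fit_rg(
    x_table: SummaryStatsTable,
    y_table: SummaryStatsTable,
    ld: LDScoreTable,
    n_blocks: int = 200,
    overlap_intercept: float | None = None,
) -> RgEstimate:
    """Bivariate genetic correlation with block-jackknife uncertainty.

    ``overlap_intercept`` optionally pins the genetic-covariance intercept
    (e.g. at the known sample-overlap value) instead of estimating it.
    The jackknife recomputes the full ratio gencov/sqrt(h2_x*h2_y) within
    every delete-one-block replicate; the two-sided p is normal on
    rg/rg_se.
    """
    df = (
        x_table.df.merge(y_table.df, on="snp_id", suffixes=("_x", "_y"))
        .merge(ld.df, on="snp_id")
        .sort_values(["chrom_x", "pos_x"], kind="mergesort")
        .reset_index(drop=True)
    )
    if len(df) < 2 * n_blocks:
        raise EstimationError(
            f"too few shared SNPs ({len(df)}) for {n_blocks} jackknife blocks"
        )
    if df["n_x"].isna().any() or df["n_y"].isna().any():
        raise EstimationError("per-SNP sample size N is required for LDSC")

    ell = df["ldscore"].to_numpy(float)
    m = ld.m_total
    nx = df["n_x"].to_numpy(float)
    ny = df["n_y"].to_numpy(float)
    zx = df["beta_x"].to_numpy(float) / df["se_x"].to_numpy(float)
    zy = df["beta_y"].to_numpy(float) / df["se_y"].to_numpy(float)

    xvar_x = nx * ell / m
    xvar_y = ny * ell / m
    xvar_g = np.sqrt(nx * ny) * ell / m

    def denom_uni(xv):
        def fn(intercept, slope):
            return _model_term(intercept, slope, xv) ** 2

        return fn

    int_x, h2x, w_x, hist_x = _iterated_weights(xvar_x, zx**2, ell, denom_uni(xvar_x))
    int_y, h2y, w_y, hist_y = _iterated_weights(xvar_y, zy**2, ell, denom_uni(xvar_y))

    # the bivariate weights iterate in lockstep with the univariate fits:
    # iteration t uses the iteration t-1 estimates of all three regressions,
    # so fit_rg(x, x) reproduces the h2 fit exactly and rg(x, x) = 1
    yz = zx * zy
    iter_state = {"t": 0}

    def denom_biv(intercept, slope):
        t = iter_state["t"]
        iter_state["t"] += 1
        term_x = _model_term(*hist_x[min(t, len(hist_x) - 1)], xvar_x)
        term_y = _model_term(*hist_y[min(t, len(hist_y) - 1)], xvar_y)
        return term_x * term_y + (intercept + slope * xvar_g) ** 2

    if overlap_intercept is None:
        int_g, gencov, w_g, _ = _iterated_weights(xvar_g, yz, ell, denom_biv)
    else:
        int_g = float(overlap_intercept)
        w = np.ones_like(xvar_g)
        gencov = float(np.sum(w * xvar_g * (yz - int_g)) / np.sum(w * xvar_g**2))
        for _ in range(2):
            denom = np.maximum(denom_biv(int_g, gencov), 1e-3)
            w = 1.0 / (np.maximum(ell, 1.0) * denom)
            gencov = float(np.sum(w * xvar_g * (yz - int_g)) / np.sum(w * xvar_g**2))
        w_g = w

    if h2x <= 0 or h2y <= 0:
        raise EstimationError(
            f"rg undefined: nonpositive heritability estimate "
            f"(h2_x={h2x:.4g}, h2_y={h2y:.4g})"
        )
    rg = gencov / np.sqrt(h2x * h2y)

    # ratio jackknife: recompute h2_x, h2_y and gencov per replicate
    _, h2x_reps, g = _jackknife(xvar_x, zx**2, w_x, n_blocks)
    _, h2y_reps, _ = _jackknife(xvar_y, zy**2, w_y, n_blocks)
    if overlap_intercept is None:
        _, gencov_reps, _ = _jackknife(xvar_g, yz, w_g, n_blocks)
    else:
        gencov_reps = _jackknife_origin(xvar_g, yz - int_g, w_g, n_blocks)
    denom_reps = np.sqrt(np.maximum(h2x_reps * h2y_reps, 1e-12))
    rg_reps = gencov_reps / denom_reps
    rg_se = _jackknife_se(rg_reps)
    if rg_se <= 0:
        rg_se = float(np.finfo(float).tiny)
    p = float(2.0 * stats.norm.sf(abs(rg) / rg_se))
    return RgEstimate(
        rg=float(rg),
        rg_se=rg_se,
        p=max(p, np.finfo(float).tiny),
        gencov=float(gencov),
        gencov_intercept=float(int_g),
        h2_x=float(h2x),
        h2_y=float(h2y),
        n_blocks_used=g,
    )


def _jackknife_origin(x, y, w, n_blocks) -> np.ndarray:
    """Delete-one-block slope replicates for a through-origin fit."""
    n = len(x)
    edges = np.unique(np.linspace(0, n, n_blocks + 1).astype(int))
    starts = edges[:-1]
    sxy = np.add.reduceat(w * x * y, starts)
    sxx = np.add.reduceat(w * x * x, starts)
    return (np.sum(sxy) - sxy) / (np.sum(sxx) - sxx)


def rg_report(labels: list[str], estimates: list[RgEstimate]) -> pd.DataFrame:
    """Screen-report table: one row per metabolite with r_g and its p."""
    return pd.DataFrame(
        {
            "metabolite": labels,
            "rg": [e.rg for e in estimates],
            "rg_se": [e.rg_se for e in estimates],
            "p": [e.p for e in estimates],
        }
    )
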