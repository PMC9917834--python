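"""Synthetic GWAS summary statistics and MR instrument sets with known truth.

Two generators:

* :func:`simulate_gwas_pair` — a bivariate polygenic architecture over M
  SNPs arranged in equicorrelated LD blocks, emitting marginal effect
  estimates, standard errors and LD scores that satisfy the LD-score
  regression model (mean chi-square = 1 + N*h2*l/M).
* :func:`simulate_mr_dataset` — a harmonized instrument set with a chosen
  causal effect, pleiotropy regime and planted outliers.

Effect sizes are drawn on the standardized-genotype scale internally;
reported betas and SEs are on the per-allele scale using the binomial
genotype variance 2*maf*(1-maf). LD within a block is a single constant
r^2 (genotype correlation sqrt(r^2)); this is deliberately simpler than a
real LD map but sufficient to exercise LDSC and clumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metabomr.errors import ValidationError
from metabomr.instruments import HarmonizedIVSet
from metabomr.sumstats_io import LDMatrix, LDScoreTable, SummaryStatsTable

#: allele pairs whose strand cannot be resolved (A/T, C/G)
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]

#: floor applied to p-values so extreme z-scores never underflow to 0
_P_FLOOR = 1e-320

#: base-pair gap between consecutive LD blocks; > 10,000 kb so the default
#: clumping window never spans two blocks
_BLOCK_GAP_BP = 20_000_000


@dataclass
class ArchitectureSpec:
    """Parameters of a bivariate polygenic architecture."""

    n_snps: int = 20_000
    n_blocks: int = 400
    within_block_r2: float = 0.2
    h2_x: float = 0.3
    h2_y: float = 0.3
    rg: float = 0.0
    n_x: int = 50_000
    n_y: int = 50_000
    sample_overlap_frac: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_frac: float = 0.0
    effect_scale: str = "linear"  # labeling only: "linear" or "logodds"
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if not 1 <= self.n_blocks <= self.n_snps:
            raise ValidationError("n_blocks must be in [1, n_snps]")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValidationError("within_block_r2 must be in [0, 1]")
        for name in ("h2_x", "h2_y"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.rg <= 1.0:
            raise ValidationError("rg must be in [-1, 1]")
        for name in ("n_x", "n_y"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0.0 <= self.sample_overlap_frac <= 1.0:
            raise ValidationError("sample_overlap_frac must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.palindromic_frac <= 1.0:
            raise ValidationError("palindromic_frac must be in [0, 1]")
        if self.effect_scale not in ("linear", "logodds"):
            raise ValidationError("effect_scale must be 'linear' or 'logodds'")


@dataclass
class GwasTruth:
    """Ground truth behind one simulated GWAS pair."""

    h2_x: float
    h2_y: float
    rg: float
    beta_true_x: np.ndarray
    beta_true_y: np.ndarray
    block_of: np.ndarray  # block index per SNP
    effect_scale: str


@dataclass
class GwasSimResult:
    exposure: SummaryStatsTable
    outcome: SummaryStatsTable
    ldscores: LDScoreTable
    ld_matrix: LDMatrix | None
    truth: GwasTruth


def _block_sizes(n_snps: int, n_blocks: int) -> np.ndarray:
    """Split n_snps into contiguous blocks on a deterministic 0.5-1.5x ramp.

    Equal block sizes would give every SNP the same LD score, making the
    LD-score regression design singular; the ramp guarantees variation
    while keeping the generator deterministic.
    """
    if n_blocks >= n_snps:
        return np.ones(n_snps, dtype=int)
    weights = np.linspace(0.5, 1.5, n_blocks)
    raw = weights / weights.sum() * n_snps
    sizes = np.maximum(1, np.floor(raw).astype(int))
    deficit = n_snps - int(sizes.sum())
    if deficit > 0:
        frac = raw - np.floor(raw)
        order = np.argsort(-frac, kind="mergesort")
        sizes[order[:deficit]] += 1
    elif deficit < 0:
        order = np.argsort(-sizes, kind="mergesort")
        i = 0
        while deficit < 0:
            j = order[i % len(order)]
            if sizes[j] > 1:
                sizes[j] -= 1
                deficit += 1
            i += 1
    return sizes


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_frac: float):
    is_pal = rng.random(n) < palindromic_frac
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    ea = np.empty(n, dtype="U1")
    oa = np.empty(n, dtype="U1")
    for i in range(n):
        pair = (
            _PALINDROMIC_PAIRS[pal_idx[i]]
            if is_pal[i]
            else _NONPALINDROMIC_PAIRS[non_idx[i]]
        )
        ea[i], oa[i] = pair
    return ea, oa


def simulate_gwas_pair(
    spec: ArchitectureSpec, with_ld_matrix: bool = True
) -> GwasSimResult:
    """Generate a pair of GWAS summary-statistics tables with shared SNPs.

    Per-SNP standardized true effects are bivariate normal with variances
    h2/M and correlation rg. Marginal effects mix true effects through the
    block correlation matrix, so E[chi^2] = 1 + N*h2*l/M where l is the
    LD score (row sum of block r^2). Estimation noise has unit variance on
    the z scale, correlated between traits by ``sample_overlap_frac``.

    Set ``with_ld_matrix=False`` to skip materializing pairwise r^2 rows
    (cheaper for large M when only LDSC is exercised).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    sizes = _block_sizes(m, spec.n_blocks)
    block_of = np.repeat(np.arange(len(sizes)), sizes)

    # true standardized effects
    cov_xy = spec.rg * np.sqrt(spec.h2_x * spec.h2_y) / m
    cov = np.array([[spec.h2_x / m, cov_xy], [cov_xy, spec.h2_y / m]])
    # draw via Cholesky-like construction that tolerates h2 = 0
    z01 = rng.standard_normal((m, 2))
    sd_x = np.sqrt(cov[0, 0])
    sd_y = np.sqrt(cov[1, 1])
    bx = sd_x * z01[:, 0]
    if sd_x > 0 and sd_y > 0:
        rho = cov[0, 1] / (sd_x * sd_y)
        by = sd_y * (rho * z01[:, 0] + np.sqrt(max(0.0, 1 - rho**2)) * z01[:, 1])
    else:
        by = sd_y * z01[:, 1]

    # marginal effects through block equicorrelation r = sqrt(r2)
    r = np.sqrt(spec.within_block_r2)
    if r > 0:
        sums_x = np.bincount(block_of, weights=bx)
        sums_y = np.bincount(block_of, weights=by)
        marg_x = (1 - r) * bx + r * sums_x[block_of]
        marg_y = (1 - r) * by + r * sums_y[block_of]
    else:
        marg_x, marg_y = bx, by

    # estimation noise on the z scale; correlated across traits by overlap
    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    rho_e = spec.sample_overlap_frac
    eps_x = e1
    eps_y = rho_e * e1 + np.sqrt(1 - rho_e**2) * e2
    z_x = np.sqrt(spec.n_x) * marg_x + eps_x
    z_y = np.sqrt(spec.n_y) * marg_y + eps_y

    maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    geno_var = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(spec.n_x * geno_var)
    se_y = 1.0 / np.sqrt(spec.n_y * geno_var)

    ea, oa = _draw_alleles(rng, m, spec.palindromic_frac)
    within = np.concatenate([np.arange(s) for s in sizes])
    pos = block_of.astype(np.int64) * _BLOCK_GAP_BP + within * 1000 + 1
    snp_ids = np.array([f"rs{i + 1}" for i in range(m)])

    def _table(z, se, n, label):
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
        return SummaryStatsTable(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "chrom": "1",
                    "pos": pos,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": maf,
                    "beta": z * se,
                    "se": se,
                    "p": p,
                    "n": float(n),
                }
            ),
            trait_label=label,
        )

    exposure = _table(z_x, se_x, spec.n_x, "trait_x")
    outcome = _table(z_y, se_y, spec.n_y, "trait_y")

    ell = 1.0 + (sizes[block_of] - 1) * spec.within_block_r2
    ldscores = LDScoreTable(
        pd.DataFrame({"snp_id": snp_ids, "ldscore": ell}), m_total=m
    )

    ld_matrix = None
    if with_ld_matrix:
        ld_matrix = _block_ld_matrix(snp_ids, block_of, spec.within_block_r2)

    truth = GwasTruth(
        h2_x=spec.h2_x,
        h2_y=spec.h2_y,
        rg=spec.rg,
        beta_true_x=bx,
        beta_true_y=by,
        block_of=block_of,
        effect_scale=spec.effect_scale,
    )
    return GwasSimResult(exposure, outcome, ldscores, ld_matrix, truth)


def _block_ld_matrix(snp_ids, block_of, r2: float) -> LDMatrix:
    if r2 == 0.0:
        return LDMatrix.identity()
    rows_a, rows_b = [], []
    for b in np.unique(block_of):
        ids = snp_ids[block_of == b]
        if len(ids) < 2:
            continue
        iu = np.triu_indices(len(ids), k=1)
        rows_a.append(ids[iu[0]])
        rows_b.append(ids[iu[1]])
    if not rows_a:
        return LDMatrix.identity()
    a = np.concatenate(rows_a)
    b = np.concatenate(rows_b)
    return LDMatrix(pd.DataFrame({"snp_a": a, "snp_b": b, "r2": r2}))


@dataclass
class PanelSimResult:
    """One shared outcome plus a panel of exposures with chosen true rg."""

    outcome: SummaryStatsTable
    exposures: list[SummaryStatsTable]
    ldscores: LDScoreTable
    ld_matrix: LDMatrix | None
    true_rgs: list[float]


def simulate_screen_panel(
    spec: ArchitectureSpec,
    rgs: list[float],
    labels: list[str] | None = None,
    with_ld_matrix: bool = False,
) -> PanelSimResult:
    """A panel of exposure GWAS sharing one outcome GWAS.

    The outcome's true effects are drawn once; each exposure's true effects
    are drawn with the requested genetic correlation to the outcome
    (conditionally independent across exposures). ``spec.rg`` is ignored;
    per-exposure values come from ``rgs``. All tables share SNP ids,
    positions, alleles and frequencies.
    """
    spec.validate()
    for j, rg in enumerate(rgs):
        if not -1.0 <= rg <= 1.0:
            raise ValidationError(f"rgs[{j}] must be in [-1, 1]")
    if labels is None:
        labels = [f"metabolite_{j + 1}" for j in range(len(rgs))]
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    sizes = _block_sizes(m, spec.n_blocks)
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    geno_var = 2.0 * maf * (1.0 - maf)
    ea, oa = _draw_alleles(rng, m, spec.palindromic_frac)
    within = np.concatenate([np.arange(s) for s in sizes])
    pos = block_of.astype(np.int64) * _BLOCK_GAP_BP + within * 1000 + 1
    snp_ids = np.array([f"rs{i + 1}" for i in range(m)])
    r = np.sqrt(spec.within_block_r2)

    def _mix(t):
        if r == 0:
            return t
        sums = np.bincount(t_block_of := block_of, weights=t)
        return (1 - r) * t + r * sums[t_block_of]

    def _table(t_true, n, label):
        z = np.sqrt(n) * _mix(t_true) + rng.standard_normal(m)
        se = 1.0 / np.sqrt(n * geno_var)
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
        return SummaryStatsTable(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "chrom": "1",
                    "pos": pos,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": maf,
                    "beta": z * se,
                    "se": se,
                    "p": p,
                    "n": float(n),
                }
            ),
            trait_label=label,
        )

    t_y = rng.standard_normal(m) * np.sqrt(spec.h2_y / m)
    outcome = _table(t_y, spec.n_y, "outcome")
    exposures = []
    for label, rg in zip(labels, rgs):
        if spec.h2_y > 0:
            a = rg * np.sqrt(spec.h2_x / spec.h2_y)
        else:
            a = 0.0
        resid_sd = np.sqrt(max(0.0, spec.h2_x / m - a**2 * spec.h2_y / m))
        t_j = a * t_y + rng.standard_normal(m) * resid_sd
        exposures.append(_table(t_j, spec.n_x, label))

    ell = 1.0 + (sizes[block_of] - 1) * spec.within_block_r2
    ldscores = LDScoreTable(
        pd.DataFrame({"snp_id": snp_ids, "ldscore": ell}), m_total=m
    )
    ld_matrix = (
        _block_ld_matrix(snp_ids, block_of, spec.within_block_r2)
        if with_ld_matrix
        else None
    )
    return PanelSimResult(outcome, exposures, ldscores, ld_matrix, list(rgs))


# ---------------------------------------------------------------------------
# MR instrument-set generator


@dataclass
class MRSimSpec:
    """Parameters of a simulated harmonized instrument set."""

    k_instruments: int = 30
    beta_causal: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional | outlier
    pleiotropy_sd: float = 0.05
    n_outliers: int = 0
    outlier_shift: float = 0.5
    exposure_effect_range: tuple[float, float] = (0.1, 0.3)
    exposure_se_range: tuple[float, float] = (0.005, 0.015)
    outcome_se_range: tuple[float, float] = (0.03, 0.08)
    palindromic_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.k_instruments < 1:
            raise ValidationError("k_instruments must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ValidationError(
                "pleiotropy_mode must be one of none/balanced/directional/outlier"
            )
        if self.n_outliers < 0 or self.n_outliers >= self.k_instruments:
            raise ValidationError("n_outliers must satisfy 0 <= n < k_instruments")
        for name in ("exposure_effect_range", "exposure_se_range", "outcome_se_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < lo <= hi")
        if not 0.0 <= self.palindromic_frac <= 1.0:
            raise ValidationError("palindromic_frac must be in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be >= 0")


@dataclass
class MRTruth:
    """Ground truth behind one simulated instrument set."""

    beta_causal: float
    beta_exposure_true: np.ndarray
    pleiotropy: np.ndarray
    outlier_ids: list[str] = field(default_factory=list)
    palindromic_ids: list[str] = field(default_factory=list)


def simulate_mr_dataset(spec: MRSimSpec) -> tuple[HarmonizedIVSet, MRTruth]:
    """Generate a harmonized instrument set with known causal effect.

    True exposure effects are drawn away from zero (uniform magnitude in
    ``exposure_effect_range``, random sign); outcome effects are
    ``beta_causal * bx_true`` plus a pleiotropy term per mode plus noise.
    In outlier mode the first ``n_outliers`` instruments (post-shuffle)
    receive an additive ``outlier_shift`` on the outcome side.

    Palindromic draws (probability ``palindromic_frac``) are excluded from
    the returned set — a harmonized set never contains them — and recorded
    in the truth record, so the returned set may hold fewer than
    ``k_instruments`` rows.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = spec.k_instruments

    lo, hi = spec.exposure_effect_range
    bx_true = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
    se_x = rng.uniform(*spec.exposure_se_range, size=k)
    se_y = rng.uniform(*spec.outcome_se_range, size=k)
    bx_hat = bx_true + rng.standard_normal(k) * se_x

    pleio = np.zeros(k)
    outlier_idx = np.array([], dtype=int)
    if spec.pleiotropy_mode == "balanced":
        pleio = rng.standard_normal(k) * spec.pleiotropy_sd
    elif spec.pleiotropy_mode == "directional":
        pleio = spec.pleiotropy_sd + rng.standard_normal(k) * spec.pleiotropy_sd
    elif spec.pleiotropy_mode == "outlier":
        outlier_idx = rng.choice(k, size=spec.n_outliers, replace=False)
        pleio[outlier_idx] = spec.outlier_shift

    by_hat = spec.beta_causal * bx_true + pleio + rng.standard_normal(k) * se_y

    snp_ids = np.array([f"rs{i + 1:05d}" for i in range(k)])
    ea, oa = _draw_alleles(rng, k, spec.palindromic_frac)
    is_pal = np.array([{a, b} in ({"A", "T"}, {"C", "G"}) for a, b in zip(ea, oa)])

    p_x = np.clip(2.0 * stats.norm.sf(np.abs(bx_hat / se_x)), _P_FLOOR, 1.0)
    p_y = np.clip(2.0 * stats.norm.sf(np.abs(by_hat / se_y)), _P_FLOOR, 1.0)

    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "beta_exposure": bx_hat,
            "se_exposure": se_x,
            "p_exposure": p_x,
            "beta_outcome": by_hat,
            "se_outcome": se_y,
            "p_outcome": p_y,
            "effect_allele": ea,
            "other_allele": oa,
            "clump_seed": True,
            "flipped": False,
            "strand_flipped": False,
        }
    )
    keep = df.loc[~is_pal].reset_index(drop=True)
    ivs = HarmonizedIVSet(
        keep, exposure_label="sim_exposure", outcome_label="sim_outcome"
    )
    truth = MRTruth(
        beta_causal=spec.beta_causal,
        beta_exposure_true=bx_true,
        pleiotropy=pleio,
        outlier_ids=sorted(snp_ids[outlier_idx].tolist()),
        palindromic_ids=snp_ids[is_pal].tolist(),
    )
    return ivs, truth


def write_truth(truth: GwasTruth | MRTruth, path) -> None:
    """Write a ground-truth sidecar as delimited text."""
    if isinstance(truth, GwasTruth):
        pd.DataFrame(
            {
                "beta_true_x": truth.beta_true_x,
                "beta_true_y": truth.beta_true_y,
                "block": truth.block_of,
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(
            {
                "beta_exposure_true": truth.beta_exposure_true,
                "pleiotropy": truth.pleiotropy,
            }
        ).to_csv(path, sep="\t", index=False)
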