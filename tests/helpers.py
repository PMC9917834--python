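"""Shared test construction helpers."""

import numpy as np
import pandas as pd
from scipy import stats

from metabomr.instruments import HarmonizedIVSet


def make_ivs(bx, se_x, by, se_y, snp_ids=None, alleles=("A", "G")) -> HarmonizedIVSet:
    """Build a harmonized instrument set from raw effect arrays."""
    bx = np.asarray(bx, float)
    se_x = np.asarray(se_x, float)
    by = np.asarray(by, float)
    se_y = np.asarray(se_y, float)
    k = len(bx)
    if snp_ids is None:
        snp_ids = [f"rs{i + 1:04d}" for i in range(k)]
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "beta_exposure": bx,
            "se_exposure": se_x,
            "p_exposure": 2 * stats.norm.sf(np.abs(bx / se_x)),
            "beta_outcome": by,
            "se_outcome": se_y,
            "p_outcome": 2 * stats.norm.sf(np.abs(by / se_y)),
            "effect_allele": alleles[0],
            "other_allele": alleles[1],
            "clump_seed": True,
            "flipped": False,
            "strand_flipped": False,
        }
    )
    return HarmonizedIVSet(df, exposure_label="exposure", outcome_label="outcome")


def random_ivs(seed: int, k: int = 10) -> HarmonizedIVSet:
    """A random, well-conditioned instrument set for oracle comparisons."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.1, 0.4, k) * rng.choice([-1, 1], k)
    se_x = rng.uniform(0.005, 0.03, k)
    se_y = rng.uniform(0.02, 0.1, k)
    by = 0.1 * bx + rng.standard_normal(k) * se_y
    return make_ivs(bx, se_x, by, se_y)


def influential_fixture() -> HarmonizedIVSet:
    """Nine weak instruments with consistent ratios near 0.1 plus one
    high-precision instrument ('strong') that alone pushes the IVW fit
    across p = 0.05."""
    eps = np.array([0.001, -0.001] * 4 + [0.001])
    bx_weak = np.linspace(0.16, 0.24, 9)
    bx = np.concatenate([bx_weak, [0.3]])
    by = np.concatenate([0.1 * bx_weak + eps, [0.0305]])
    se_x = np.full(10, 0.01)
    se_y = np.array([0.05] * 9 + [0.01])
    ids = [f"weak{i}" for i in range(1, 10)] + ["strong"]
    return make_ivs(bx, se_x, by, se_y, snp_ids=ids)
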