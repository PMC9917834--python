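"""Instrument selection and harmonization for two-sample MR.

The screen applies, in order: exposure p-value threshold, greedy LD
clumping, outcome-association exclusion, confounder-blocklist exclusion,
palindromic-SNP removal, and allele harmonization. Every removal is
recorded in a ledger (snp_id, stage, reason).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metabomr.errors import ValidationError
from metabomr.sumstats_io import (
    ConfounderBlocklist,
    LDMatrix,
    SummaryStatsTable,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

IV_COLUMNS = [
    "snp_id",
    "beta_exposure",
    "se_exposure",
    "p_exposure",
    "beta_outcome",
    "se_outcome",
    "p_outcome",
    "effect_allele",
    "other_allele",
    "clump_seed",
    "flipped",
    "strand_flipped",
]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedIVSet:
    """Joined exposure/outcome effects on a common effect-allele orientation.

    The unit of all MR computation. Invariants: no palindromic rows;
    positive SEs; unique snp_ids.
    """

    df: pd.DataFrame
    exposure_label: str = ""
    outcome_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in IV_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"HarmonizedIVSet missing columns: {missing}")
        self.df = self.df[IV_COLUMNS].reset_index(drop=True)
        if len(self.df):
            if self.df["snp_id"].duplicated().any():
                raise ValidationError("snp_id not unique in instrument set")
            for col in ("se_exposure", "se_outcome"):
                if (self.df[col] <= 0).any():
                    raise ValidationError(f"{col} must be positive")
            pal = [
                is_palindromic(a, b)
                for a, b in zip(self.df["effect_allele"], self.df["other_allele"])
            ]
            if any(pal):
                raise ValidationError("harmonized set contains palindromic rows")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def k(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def without(self, snp_ids) -> "HarmonizedIVSet":
        drop = set(snp_ids)
        keep = ~self.df["snp_id"].isin(drop)
        return HarmonizedIVSet(
            self.df.loc[keep].copy(), self.exposure_label, self.outcome_label
        )

    def arrays(self):
        """(bx, se_x, by, se_y) as float arrays — the estimator inputs."""
        d = self.df
        return (
            d["beta_exposure"].to_numpy(float),
            d["se_exposure"].to_numpy(float),
            d["beta_outcome"].to_numpy(float),
            d["se_outcome"].to_numpy(float),
        )


@dataclass
class RemovalLedger:
    """Audit trail of every instrument removed and why."""

    rows: list[dict] = field(default_factory=list)

    def record(self, snp_id: str, stage: str, reason: str) -> None:
        self.rows.append({"snp_id": snp_id, "stage": stage, "reason": reason})

    def count(self, stage: str | None = None) -> int:
        if stage is None:
            return len(self.rows)
        return sum(1 for r in self.rows if r["stage"] == stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["snp_id", "stage", "reason"])


def select_instruments(
    exposure: SummaryStatsTable, p_thresh: float = 5e-6
) -> pd.DataFrame:
    """Rows of the exposure GWAS with p below the instrument threshold.

    An empty result is a legitimate "no instruments" outcome, not an error.
    """
    df = exposure.df
    return df.loc[df["p"] < p_thresh].copy().reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    ld_matrix: LDMatrix,
    r2_thresh: float = 0.001,
    window_kb: float = 10_000.0,
    ledger: RemovalLedger | None = None,
) -> pd.DataFrame:
    """Greedy p-value clumping.

    Candidates are visited in order of ascending p (ties broken by snp_id);
    each visited SNP either seeds a clump or is removed because it lies
    within ``window_kb`` of an already-selected seed on the same chromosome
    with r^2 >= ``r2_thresh``. Missing LD pairs count as r^2 = 0.
    """
    if candidates.empty:
        return candidates.copy()
    order = candidates.sort_values(
        ["p", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    ids = order["snp_id"].to_numpy()
    chroms = order["chrom"].to_numpy()
    pos = order["pos"].to_numpy(np.int64)
    selected: list[int] = []
    for i in range(len(order)):
        pruned = False
        for j in selected:
            if chroms[j] != chroms[i]:
                continue
            if abs(int(pos[j]) - int(pos[i])) / 1000.0 > window_kb:
                continue
            if ld_matrix.r2(ids[j], ids[i]) >= r2_thresh:
                pruned = True
                if ledger is not None:
                    ledger.record(ids[i], "clump", f"r2 with seed {ids[j]}")
                break
        if not pruned:
            selected.append(i)
    kept = order.iloc[selected].copy()
    kept["clump_seed"] = True
    return kept.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def exclude_outcome_associated(
    ivs: pd.DataFrame,
    outcome: SummaryStatsTable,
    p_thresh: float = 5e-6,
    ledger: RemovalLedger | None = None,
) -> pd.DataFrame:
    """Remove instruments associated with the outcome at ``p_thresh``."""
    out_p = outcome.df.set_index("snp_id")["p"]
    keep = []
    for _, row in ivs.iterrows():
        sid = row["snp_id"]
        if sid not in out_p.index:
            # proxy lookup is out of scope; drop with a log entry
            if ledger is not None:
                ledger.record(sid, "outcome_exclusion", "missing in outcome")
            logger.info("instrument %s missing in outcome table; dropped", sid)
            continue
        if out_p.loc[sid] < p_thresh:
            if ledger is not None:
                ledger.record(
                    sid, "outcome_exclusion", f"outcome p={out_p.loc[sid]:.3g}"
                )
            continue
        keep.append(row)
    if not keep:
        return ivs.iloc[0:0].copy()
    return pd.DataFrame(keep).reset_index(drop=True)


def exclude_confounders(
    ivs: pd.DataFrame,
    blocklist: ConfounderBlocklist,
    ledger: RemovalLedger | None = None,
) -> pd.DataFrame:
    """Remove instruments listed in the confounder blocklist."""
    listed = set(blocklist.df["snp_id"])
    keep = ~ivs["snp_id"].isin(listed)
    if ledger is not None:
        for sid in ivs.loc[~keep, "snp_id"]:
            traits = ",".join(sorted(set(blocklist.traits_for(sid)))) or "listed"
            ledger.record(sid, "confounder_exclusion", traits)
    return ivs.loc[keep].copy().reset_index(drop=True)


def drop_palindromic(
    ivs: pd.DataFrame, ledger: RemovalLedger | None = None
) -> pd.DataFrame:
    """Remove A/T and C/G instruments outright, regardless of frequency."""
    if len(ivs) == 0:
        return ivs.copy()
    pal = ivs.apply(
        lambda r: is_palindromic(r["effect_allele"], r["other_allele"]), axis=1
    )
    if ledger is not None:
        for sid in ivs.loc[pal, "snp_id"]:
            ledger.record(sid, "palindromic", "A/T or C/G alleles")
    return ivs.loc[~pal].copy().reset_index(drop=True)


def harmonize_alleles(
    exposure_rows: pd.DataFrame,
    outcome: SummaryStatsTable,
    exposure_label: str = "",
    outcome_label: str = "",
    ledger: RemovalLedger | None = None,
) -> HarmonizedIVSet:
    """Join exposure instruments with outcome records on one orientation.

    If the outcome's alleles are swapped relative to the exposure's, the
    outcome beta is negated; if they are the strand complement they are
    complemented first; rows that cannot be reconciled are dropped and
    logged.
    """
    out = outcome.df.set_index("snp_id")
    rows = []
    for _, row in exposure_rows.iterrows():
        sid = row["snp_id"]
        if sid not in out.index:
            if ledger is not None:
                ledger.record(sid, "harmonize", "missing in outcome")
            continue
        orow = out.loc[sid]
        ea, oa = row["effect_allele"], row["other_allele"]
        o_ea, o_oa = orow["effect_allele"], orow["other_allele"]
        flipped = False
        strand_flipped = False
        if (o_ea, o_oa) == (ea, oa):
            pass
        elif (o_ea, o_oa) == (oa, ea):
            flipped = True
        else:
            c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
            if (c_ea, c_oa) == (ea, oa):
                strand_flipped = True
            elif (c_ea, c_oa) == (oa, ea):
                strand_flipped = True
                flipped = True
            else:
                if ledger is not None:
                    ledger.record(
                        sid, "harmonize", f"irreconcilable alleles {o_ea}/{o_oa}"
                    )
                logger.info("instrument %s alleles irreconcilable; dropped", sid)
                continue
        beta_out = -orow["beta"] if flipped else orow["beta"]
        rows.append(
            {
                "snp_id": sid,
                "beta_exposure": row["beta"],
                "se_exposure": row["se"],
                "p_exposure": row["p"],
                "beta_outcome": beta_out,
                "se_outcome": orow["se"],
                "p_outcome": orow["p"],
                "effect_allele": ea,
                "other_allele": oa,
                "clump_seed": bool(row.get("clump_seed", True)),
                "flipped": flipped,
                "strand_flipped": strand_flipped,
            }
        )
    df = pd.DataFrame(rows, columns=IV_COLUMNS)
    return HarmonizedIVSet(df, exposure_label, outcome_label)


def build_instrument_set(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld_matrix: LDMatrix,
    blocklist: ConfounderBlocklist | None = None,
    exposure_p: float = 5e-6,
    outcome_p: float = 5e-6,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000.0,
) -> tuple[HarmonizedIVSet, RemovalLedger]:
    """The full five-step screen, in the fixed order:

    threshold -> clump -> outcome exclusion -> confounder exclusion ->
    palindromic drop -> harmonize.
    """
    ledger = RemovalLedger()
    candidates = select_instruments(exposure, exposure_p)
    step = clump(candidates, ld_matrix, clump_r2, clump_kb, ledger)
    step = exclude_outcome_associated(step, outcome, outcome_p, ledger)
    if blocklist is not None:
        step = exclude_confounders(step, blocklist, ledger)
    step = drop_palindromic(step, ledger)
    ivs = harmonize_alleles(
        step, outcome, exposure.trait_label, outcome.trait_label, ledger
    )
    return ivs, ledger
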