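"""Two-stage screen orchestration with iterative instrument refinement.

Stage one fits bivariate genetic correlations between the outcome trait
and every exposure in the panel; exposures passing the nominal p < 0.05
screen move to stage two, a multi-round MR analysis in which instruments
flagged by the diagnostic battery are removed round by round:

* if the MR-PRESSO global test is significant, the Bonferroni-significant
  outliers are removed (or, when there are none, the nominally significant
  "potential" outliers);
* otherwise, if leave-one-out flags influential instruments (their removal
  flips IVW significance), those are removed;
* otherwise the round is clean and refinement stops.

The verdict comes from the final round's random-effects IVW alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from metabomr.errors import EstimationError, MetaboMRError
from metabomr.estimators import MRResult, run_all_estimators
from metabomr.instruments import (
    HarmonizedIVSet,
    RemovalLedger,
    build_instrument_set,
)
from metabomr.ldsc import RgEstimate, fit_rg
from metabomr.sensitivity import SensitivityReport, run_sensitivity
from metabomr.sumstats_io import (
    ConfounderBlocklist,
    LDMatrix,
    LDScoreTable,
    SummaryStatsTable,
)

logger = logging.getLogger(__name__)

MIN_INSTRUMENTS = 3


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the two-stage screen in one place."""

    exposure_p: float = 5e-6
    outcome_p: float = 5e-6
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    alpha: float = 0.05  # verdict + leave-one-out significance level
    screen_alpha: float = 0.05  # stage-one rg selection threshold
    presso_sig: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    n_ldsc_blocks: int = 200
    max_rounds: int = 5
    seed: int = 0


@dataclass
class RefinementRound:
    round_index: int
    ivs_used: list[str]
    removed_before_round: list[str]
    removal_reason: str | None
    mr_results: dict[str, MRResult]
    sensitivity: SensitivityReport


@dataclass
class RefinementLog:
    rounds: list[RefinementRound]
    final_round_index: int
    verdict: str  # causal_positive | causal_negative | no_causal | not_evaluable
    stop_reason: str  # clean | max_rounds | too_few_instruments
    screen_ledger: RemovalLedger | None = None

    @property
    def final_round(self) -> RefinementRound:
        return self.rounds[-1]


@dataclass
class ScreenEntry:
    label: str
    rg: RgEstimate | None = None
    selected: bool = False
    refinement: RefinementLog | None = None
    error: str | None = None


@dataclass
class ScreenReport:
    entries: list[ScreenEntry] = field(default_factory=list)

    def selected_labels(self) -> list[str]:
        return [e.label for e in self.entries if e.selected]


def _verdict(ivw: MRResult, alpha: float) -> str:
    if ivw.p >= alpha:
        return "no_causal"
    return "causal_positive" if ivw.beta > 0 else "causal_negative"


def refine_ivs(ivs: HarmonizedIVSet, config: PipelineConfig) -> RefinementLog:
    """Iterative SNP-removal refinement on an already-harmonized set."""
    if ivs.k < MIN_INSTRUMENTS:
        raise EstimationError(
            f"refinement needs >= {MIN_INSTRUMENTS} instruments, got {ivs.k}"
        )
    rounds: list[RefinementRound] = []
    removed_before: list[str] = []
    reason: str | None = None
    current = ivs
    stop_reason = "max_rounds"
    for round_index in range(1, config.max_rounds + 1):
        mr_results = run_all_estimators(
            current, n_boot=config.n_boot, seed=config.seed
        )
        sens = run_sensitivity(
            current,
            n_sim=config.n_sim,
            seed=config.seed,
            alpha=config.alpha,
            sig=config.presso_sig,
        )
        rounds.append(
            RefinementRound(
                round_index=round_index,
                ivs_used=current.snp_ids,
                removed_before_round=removed_before,
                removal_reason=reason,
                mr_results=mr_results,
                sensitivity=sens,
            )
        )
        to_remove: list[str] = []
        if sens.presso.available and sens.presso.global_p < config.presso_sig:
            if sens.presso.outliers:
                to_remove, reason = sens.presso.outliers, "presso_outlier"
            elif sens.presso.potential_outliers:
                to_remove, reason = (
                    sens.presso.potential_outliers,
                    "presso_potential_outlier",
                )
        if not to_remove and sens.influential_snps:
            to_remove, reason = sens.influential_snps, "loo_influential"
        if not to_remove:
            stop_reason = "clean"
            break
        for sid in to_remove:
            logger.info("round %d: removing %s (%s)", round_index, sid, reason)
        nxt = current.without(to_remove)
        if nxt.k < MIN_INSTRUMENTS:
            stop_reason = "too_few_instruments"
            removed_before = to_remove
            break
        current = nxt
        removed_before = to_remove

    if stop_reason == "too_few_instruments":
        verdict = "not_evaluable"
    else:
        verdict = _verdict(rounds[-1].mr_results["ivw_re"], config.alpha)
    return RefinementLog(
        rounds=rounds,
        final_round_index=rounds[-1].round_index,
        verdict=verdict,
        stop_reason=stop_reason,
    )


def run_refinement(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld_matrix: LDMatrix,
    blocklist: ConfounderBlocklist | None,
    config: PipelineConfig,
) -> RefinementLog:
    """Instrument the exposure, harmonize against the outcome, and refine."""
    ivs, ledger = build_instrument_set(
        exposure,
        outcome,
        ld_matrix,
        blocklist,
        exposure_p=config.exposure_p,
        outcome_p=config.outcome_p,
        clump_r2=config.clump_r2,
        clump_kb=config.clump_kb,
    )
    log = refine_ivs(ivs, config)
    log.screen_ledger = ledger
    return log


def run_screen(
    outcome: SummaryStatsTable,
    exposures: list[SummaryStatsTable],
    ldscores: LDScoreTable,
    ld_matrix: LDMatrix,
    blocklist: ConfounderBlocklist | None,
    config: PipelineConfig,
) -> ScreenReport:
    """Full two-stage screen over a panel of exposures.

    Per-exposure failures are captured in the report and do not abort the
    remaining panel.
    """
    report = ScreenReport()
    for exposure in exposures:
        label = exposure.trait_label or f"exposure_{len(report.entries) + 1}"
        entry = ScreenEntry(label=label)
        try:
            entry.rg = fit_rg(exposure, outcome, ldscores, n_blocks=config.n_ldsc_blocks)
            entry.selected = entry.rg.p < config.screen_alpha
            if entry.selected:
                entry.refinement = run_refinement(
                    exposure, outcome, ld_matrix, blocklist, config
                )
        except MetaboMRError as exc:
            entry.error = str(exc)
            logger.warning("screen: %s failed: %s", label, exc)
        report.entries.append(entry)
    return report


def screen_table(report: ScreenReport):
    """Stage-one summary: one row per metabolite with r_g, p and selection."""
    import pandas as pd

    rows = []
    for e in report.entries:
        rows.append(
            {
                "metabolite": e.label,
                "rg": e.rg.rg if e.rg else float("nan"),
                "rg_p": e.rg.p if e.rg else float("nan"),
                "selected": e.selected,
                "verdict": e.refinement.verdict if e.refinement else "",
                "error": e.error or "",
            }
        )
    return pd.DataFrame(rows)
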