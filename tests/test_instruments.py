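import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomr.errors import ValidationError
from metabomr.instruments import (
    HarmonizedIVSet,
    RemovalLedger,
    build_instrument_set,
    clump,
    drop_palindromic,
    exclude_confounders,
    exclude_outcome_associated,
    harmonize_alleles,
    is_palindromic,
    select_instruments,
)
from metabomr.sumstats_io import ConfounderBlocklist, LDMatrix, SummaryStatsTable


def _sumstats(rows, label=""):
    df = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "p", "n",
        ],
    )
    return SummaryStatsTable(df, trait_label=label)


def _row(snp, pos=1000, ea="A", oa="G", beta=0.1, se=0.05, p=1e-7, chrom="1"):
    return (snp, chrom, pos, ea, oa, 0.3, beta, se, p, 10_000)


class TestSelect:
    def test_none_below_threshold(self):
        t = _sumstats([_row("rs1", p=0.5), _row("rs2", pos=2000, p=0.5)])
        assert len(select_instruments(t)) == 0

    def test_singleton(self):
        t = _sumstats([_row("rs1", p=1e-7), _row("rs2", pos=2000, p=0.5)])
        assert select_instruments(t)["snp_id"].tolist() == ["rs1"]

    def test_counts_on_fixture(self):
        rows = [
            _row(f"rs{i}", pos=1000 * (i + 1), p=(1e-7 if i < 4 else 1e-3))
            for i in range(10)
        ]
        assert len(select_instruments(_sumstats(rows))) == 4


class TestClump:
    def test_same_block_keeps_smallest_p(self):
        # 3 SNPs, pairwise r2=0.5, p ranks 1e-8 < 1e-7 < 1e-6 -> keep 1e-8 only
        t = _sumstats(
            [
                _row("rsA", pos=1000, p=1e-6),
                _row("rsB", pos=2000, p=1e-8),
                _row("rsC", pos=3000, p=1e-7),
            ]
        )
        ld = LDMatrix(
            pd.DataFrame(
                {
                    "snp_a": ["rsA", "rsA", "rsB"],
                    "snp_b": ["rsB", "rsC", "rsC"],
                    "r2": 0.5,
                }
            )
        )
        kept = clump(t.df, ld)
        assert kept["snp_id"].tolist() == ["rsB"]

    def test_brute_force_greedy_oracle(self):
        # independent enumeration of the greedy rule on a random instance
        rng = np.random.default_rng(3)
        n = 12
        rows = [
            _row(f"rs{i}", pos=int(rng.integers(1, 5_000_000)),
                 p=float(rng.uniform(1e-9, 1e-6)))
            for i in range(n)
        ]
        t = _sumstats(rows)
        pairs = []
        ids = [f"rs{i}" for i in range(n)]
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.4:
                pairs.append((a, b, float(rng.uniform(0, 1))))
        ld = LDMatrix(pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"]))

        kept = set(clump(t.df, ld, r2_thresh=0.1, window_kb=10_000)["snp_id"])

        # oracle: explicit greedy pass over p-sorted candidates
        order = sorted(rows, key=lambda r: (r[8], r[0]))
        chosen = []
        for r in order:
            ok = True
            for c in chosen:
                if abs(c[2] - r[2]) / 1000.0 <= 10_000 and ld.r2(c[0], r[0]) >= 0.1:
                    ok = False
                    break
            if ok:
                chosen.append(r)
        assert kept == {c[0] for c in chosen}

    def test_identity_ld_keeps_all(self):
        t = _sumstats([_row(f"rs{i}", pos=1000 * (i + 1)) for i in range(5)])
        kept = clump(t.df, LDMatrix.identity())
        assert len(kept) == 5

    def test_outside_window_both_kept(self):
        # 10,001 kb apart with r2=0.9: beyond the window, both survive
        t = _sumstats(
            [_row("rs1", pos=1), _row("rs2", pos=1 + 10_001_000)]
        )
        ld = LDMatrix(
            pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs2"], "r2": [0.9]})
        )
        assert len(clump(t.df, ld)) == 2


class TestExclusions:
    def _ivs_df(self):
        return _sumstats(
            [_row(f"rs{i}", pos=1000 * (i + 1)) for i in range(6)]
        ).df

    def test_outcome_associated_removed(self):
        ivs = self._ivs_df()
        outcome = _sumstats(
            [
                _row(f"rs{i}", pos=1000 * (i + 1),
                     p=(1e-7 if i < 2 else 1e-5))
                for i in range(6)
            ]
        )
        ledger = RemovalLedger()
        kept = exclude_outcome_associated(ivs, outcome, ledger=ledger)
        assert len(kept) == 4
        assert ledger.count("outcome_exclusion") == 2

    def test_missing_in_outcome_dropped_with_log(self):
        ivs = self._ivs_df()
        outcome = _sumstats([_row("rs0", pos=1000, p=0.5)])
        ledger = RemovalLedger()
        kept = exclude_outcome_associated(ivs, outcome, ledger=ledger)
        assert kept["snp_id"].tolist() == ["rs0"]
        reasons = {r["reason"] for r in ledger.rows}
        assert "missing in outcome" in reasons

    def test_confounders_empty_blocklist_identity(self):
        ivs = self._ivs_df()
        kept = exclude_confounders(ivs, ConfounderBlocklist.empty())
        assert kept["snp_id"].tolist() == ivs["snp_id"].tolist()

    def test_confounder_removed_once_despite_duplicates(self):
        ivs = self._ivs_df()
        bl = ConfounderBlocklist(
            pd.DataFrame(
                {"snp_id": ["rs2", "rs2"], "trait_label": ["smoking", "age"]}
            )
        )
        kept = exclude_confounders(ivs, bl)
        assert len(kept) == 5
        assert "rs2" not in set(kept["snp_id"])


class TestPalindromic:
    @pytest.mark.parametrize(
        "ea,oa,pal",
        [("A", "T", True), ("T", "A", True), ("C", "G", True),
         ("G", "C", True), ("A", "G", False), ("C", "T", False)],
    )
    def test_is_palindromic(self, ea, oa, pal):
        assert is_palindromic(ea, oa) is pal

    def test_fixture_23_with_4_palindromic(self):
        # mirrors the 23-candidate / 4-palindromic bookkeeping pattern
        rows = []
        for i in range(23):
            ea, oa = ("A", "T") if i < 4 else ("A", "C")
            rows.append(_row(f"rs{i}", pos=1000 * (i + 1), ea=ea, oa=oa))
        kept = drop_palindromic(_sumstats(rows).df)
        assert len(kept) == 19


class TestHarmonize:
    def _outcome(self, ea, oa, beta=0.3):
        return _sumstats([_row("rs1", ea=ea, oa=oa, beta=beta, p=0.5)], "out")

    def _exposure_rows(self):
        return _sumstats([_row("rs1", ea="A", oa="G", beta=0.1)]).df

    def test_swapped_alleles_negate_beta(self):
        ivs = harmonize_alleles(self._exposure_rows(), self._outcome("G", "A"))
        assert ivs.df.loc[0, "beta_outcome"] == pytest.approx(-0.3)
        assert bool(ivs.df.loc[0, "flipped"]) is True

    def test_strand_complement_same_order_unchanged(self):
        ivs = harmonize_alleles(self._exposure_rows(), self._outcome("T", "C"))
        assert ivs.df.loc[0, "beta_outcome"] == pytest.approx(0.3)
        assert bool(ivs.df.loc[0, "strand_flipped"]) is True

    def test_strand_complement_swapped_negates(self):
        ivs = harmonize_alleles(self._exposure_rows(), self._outcome("C", "T"))
        assert ivs.df.loc[0, "beta_outcome"] == pytest.approx(-0.3)

    def test_disjoint_alleles_dropped(self):
        ledger = RemovalLedger()
        ivs = harmonize_alleles(
            self._exposure_rows(), self._outcome("C", "A"), ledger=ledger
        )
        assert ivs.k == 0
        assert ledger.count("harmonize") == 1


class TestInvariants:
    def test_harmonized_set_rejects_palindromic(self):
        df = pd.DataFrame(
            {
                "snp_id": ["rs1"], "beta_exposure": [0.1], "se_exposure": [0.01],
                "p_exposure": [1e-8], "beta_outcome": [0.1], "se_outcome": [0.01],
                "p_outcome": [0.5], "effect_allele": ["A"], "other_allele": ["T"],
                "clump_seed": [True], "flipped": [False], "strand_flipped": [False],
            }
        )
        with pytest.raises(ValidationError, match="palindromic"):
            HarmonizedIVSet(df)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_row_filters_commute(self, seed):
        """Threshold, outcome exclusion, confounder exclusion and palindromic
        drop are row predicates: any application order gives the same set."""
        rng = np.random.default_rng(seed)
        n = 15
        rows = []
        for i in range(n):
            ea, oa = ("A", "T") if rng.random() < 0.3 else ("A", "C")
            rows.append(
                _row(f"rs{i}", pos=1000 * (i + 1), ea=ea, oa=oa,
                     p=float(rng.choice([1e-8, 1e-3])))
            )
        exposure = _sumstats(rows)
        outcome = _sumstats(
            [
                _row(f"rs{i}", pos=1000 * (i + 1),
                     p=float(rng.choice([1e-8, 0.5])))
                for i in range(n)
            ]
        )
        blocked = [f"rs{i}" for i in range(n) if rng.random() < 0.2]
        bl = ConfounderBlocklist(
            pd.DataFrame(
                {"snp_id": blocked, "trait_label": ["smoking"] * len(blocked)}
            )
        )

        filters = {
            "thresh": lambda df: df.loc[df["p"] < 5e-6].reset_index(drop=True),
            "outcome": lambda df: exclude_outcome_associated(df, outcome),
            "conf": lambda df: exclude_confounders(df, bl),
            "pal": drop_palindromic,
        }
        results = set()
        for order in itertools.permutations(filters):
            df = exposure.df
            for name in order:
                df = filters[name](df)
            results.add(tuple(sorted(df["snp_id"])))
        assert len(results) == 1

    def test_ledger_counts_sum(self):
        # candidates = kept + sum of removals by reason
        rows = []
        for i in range(12):
            ea, oa = ("C", "G") if i in (0, 1) else ("A", "C")
            p = 1e-8 if i < 10 else 0.5
            rows.append(_row(f"rs{i:02d}", pos=1000 * (i + 1), ea=ea, oa=oa, p=p))
        exposure = _sumstats(rows, "exp")
        out_rows = []
        for i in range(12):
            ea, oa = ("C", "G") if i in (0, 1) else ("A", "C")
            out_rows.append(
                _row(f"rs{i:02d}", pos=1000 * (i + 1), ea=ea, oa=oa,
                     p=(1e-8 if i == 5 else 0.5))
            )
        outcome = _sumstats(out_rows, "out")
        bl = ConfounderBlocklist(
            pd.DataFrame({"snp_id": ["rs03"], "trait_label": ["age"]})
        )
        ivs, ledger = build_instrument_set(
            exposure, outcome, LDMatrix.identity(), bl
        )
        candidates = len(select_instruments(exposure))
        assert candidates == 10
        assert ivs.k + ledger.count() == candidates
        assert ivs.k == 10 - 1 - 1 - 2  # outcome, blocklist, palindromic
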