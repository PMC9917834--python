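"""Read/write GWAS summary statistics, LD scores, LD matrices and blocklists.

All tables are delimited text (tab, comma or whitespace, auto-detected;
optionally gzip-compressed by file extension). Readers normalize common
header dialects into the internal column schema and enforce the table
invariants, dropping invalid rows with a logged count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metabomr.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column name -> accepted header synonyms (lower-cased match)
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "snp_id": ("snp_id", "snp", "rsid", "rs_id", "variant_id", "markername", "id"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "a1", "allele1", "ea", "alt"),
    "other_allele": ("other_allele", "a2", "allele2", "oa", "ref", "nea"),
    "eaf": ("eaf", "freq", "af", "effect_allele_frequency", "maf", "frq"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "or": ("or", "odds_ratio", "oddsratio"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "p": ("p", "pval", "p_value", "pvalue", "p_val"),
    "n": ("n", "samplesize", "sample_size", "neff", "n_total"),
}

MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "se", "p")

SUMSTATS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
]


@dataclass
class SummaryStatsTable:
    """Per-SNP GWAS association records for a single trait.

    Invariants: unique ``snp_id``; ``se > 0``; ``p`` in (0, 1]; alleles are
    single A/C/G/T bases and distinct within a row. ``eaf`` and ``n`` may be
    missing (NaN); ``n`` is required downstream only by LDSC.
    """

    df: pd.DataFrame
    trait_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"summary table missing columns: {missing}")
        self.df = self.df[SUMSTATS_COLUMNS].reset_index(drop=True)
        validate_sumstats_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["snp_id"]

    def subset(self, snp_ids) -> "SummaryStatsTable":
        keep = self.df["snp_id"].isin(set(snp_ids))
        return SummaryStatsTable(self.df.loc[keep].copy(), self.trait_label)


def validate_sumstats_frame(df: pd.DataFrame) -> None:
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValidationError(f"snp_id not unique (first duplicate: {dup!r})")
    if (df["se"] <= 0).any() or df["se"].isna().any():
        raise ValidationError("se must be positive for all rows")
    if (df["p"] <= 0).any() or (df["p"] > 1).any() or df["p"].isna().any():
        raise ValidationError("p must lie in (0, 1] for all rows")
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(VALID_ALLELES)
        if bad.any():
            raise ValidationError(f"{col} must be one of A/C/G/T")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValidationError("effect_allele and other_allele must be distinct")


@dataclass
class LDScoreTable:
    """Per-SNP LD scores plus the total SNP count ``m_total`` used as M.

    LD scores below 1 are permitted (adjusted estimators can produce them)
    but must be nonnegative.
    """

    df: pd.DataFrame  # columns: snp_id, ldscore
    m_total: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in ("snp_id", "ldscore") if c not in self.df.columns]
        if missing:
            raise ValidationError(f"LD score table missing columns: {missing}")
        self.df = self.df[["snp_id", "ldscore"]].reset_index(drop=True)
        if (self.df["ldscore"] < 0).any():
            raise ValidationError("ldscore must be nonnegative")
        if self.df["snp_id"].duplicated().any():
            raise ValidationError("snp_id not unique in LD score table")
        if self.m_total <= 0:
            self.m_total = len(self.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LDMatrix:
    """Sparse pairwise r-squared lookup, stored as symmetric long-form pairs.

    Pairs absent from the table are treated as r^2 = 0 by callers. The
    representation is per-LD-block in practice: only within-block pairs are
    materialized.
    """

    pairs: pd.DataFrame  # columns: snp_a, snp_b, r2 (one row per unordered pair)
    _lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("snp_a", "snp_b", "r2") if c not in self.pairs.columns]
        if missing:
            raise ValidationError(f"LD matrix table missing columns: {missing}")
        r2 = self.pairs["r2"].to_numpy(dtype=float)
        if (r2 < 0).any() or (r2 > 1).any():
            raise ValidationError("r2 must lie in [0, 1]")
        on_diag = self.pairs["snp_a"] == self.pairs["snp_b"]
        if on_diag.any() and not np.allclose(r2[on_diag.to_numpy()], 1.0):
            raise ValidationError("diagonal r2 entries must equal 1")
        lookup: dict[tuple[str, str], float] = {}
        for a, b, v in zip(self.pairs["snp_a"], self.pairs["snp_b"], r2):
            key = (a, b) if a <= b else (b, a)
            if key in lookup and abs(lookup[key] - v) > 1e-12:
                raise ValidationError(
                    f"asymmetric r2 for pair {key}: {lookup[key]} vs {v}"
                )
            lookup[key] = v
        self._lookup = lookup

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        key = (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)
        return self._lookup.get(key, 0.0)

    @classmethod
    def identity(cls) -> "LDMatrix":
        """An LD matrix with no off-diagonal entries (all pairs r^2 = 0)."""
        return cls(pd.DataFrame({"snp_a": [], "snp_b": [], "r2": []}))


@dataclass
class ConfounderBlocklist:
    """SNPs to exclude as instruments because a lookup tied them to a
    confounder trait. Local stand-in for a PhenoScanner snapshot."""

    df: pd.DataFrame  # columns: snp_id, trait_label

    def __post_init__(self) -> None:
        missing = [c for c in ("snp_id", "trait_label") if c not in self.df.columns]
        if missing:
            raise ValidationError(f"blocklist missing columns: {missing}")
        self.df = self.df[["snp_id", "trait_label"]].reset_index(drop=True)

    def traits_for(self, snp_id: str) -> list[str]:
        return self.df.loc[self.df["snp_id"] == snp_id, "trait_label"].tolist()

    def __contains__(self, snp_id: str) -> bool:
        return bool((self.df["snp_id"] == snp_id).any())

    @classmethod
    def empty(cls) -> "ConfounderBlocklist":
        return cls(pd.DataFrame({"snp_id": [], "trait_label": []}))


# ---------------------------------------------------------------------------
# readers / writers


def _read_delimited(path) -> pd.DataFrame:
    """Delimiter-sniffing read: tab, comma, or runs of whitespace."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def _map_columns(columns, column_map: dict | None) -> dict[str, str]:
    """Map file headers onto canonical names; explicit map wins."""
    resolved: dict[str, str] = {}
    lower = {c.lower(): c for c in columns}
    if column_map:
        for canonical, actual in column_map.items():
            if actual in columns:
                resolved[canonical] = actual
            elif actual.lower() in lower:
                resolved[canonical] = lower[actual.lower()]
    for canonical, synonyms in COLUMN_SYNONYMS.items():
        if canonical in resolved:
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[canonical] = lower[syn]
                break
    return resolved


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_label: str = "",
) -> SummaryStatsTable:
    """Read a GWAS summary-statistics file.

    Recognizes common header synonyms (SNP/rsid, A1/effect_allele, BETA/b,
    OR, SE, P/pval, EAF/freq, N). Odds ratios are converted to the log scale,
    with the file's SE taken as the SE of the log odds ratio. Rows violating
    the table invariants are dropped with a logged count.

    Parameters
    ----------
    column_map
        Optional explicit mapping from canonical names (``snp_id``, ``beta``,
        ``or``, ...) to the file's actual headers; overrides synonym lookup.
    """
    raw = _read_delimited(path)
    mapping = _map_columns(raw.columns, column_map)

    has_effect = "beta" in mapping or "or" in mapping
    missing = [c for c in MANDATORY if c not in mapping]
    if not has_effect:
        missing.append("beta|or")
    if missing:
        raise FormatError(
            f"{path}: cannot map mandatory columns {missing}; "
            f"headers found: {list(raw.columns)}"
        )

    df = pd.DataFrame()
    df["snp_id"] = raw[mapping["snp_id"]].astype(str)
    df["chrom"] = raw[mapping["chrom"]].astype(str)
    df["pos"] = pd.to_numeric(raw[mapping["pos"]], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = raw[mapping[col]].astype(str).str.upper().str.strip()
    df["eaf"] = (
        pd.to_numeric(raw[mapping["eaf"]], errors="coerce")
        if "eaf" in mapping
        else np.nan
    )
    if "beta" in mapping:
        df["beta"] = pd.to_numeric(raw[mapping["beta"]], errors="coerce")
    else:
        or_vals = pd.to_numeric(raw[mapping["or"]], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(or_vals.to_numpy(dtype=float))
    df["se"] = pd.to_numeric(raw[mapping["se"]], errors="coerce")
    df["p"] = pd.to_numeric(raw[mapping["p"]], errors="coerce")
    df["n"] = (
        pd.to_numeric(raw[mapping["n"]], errors="coerce") if "n" in mapping else np.nan
    )

    ok = (
        df["se"].gt(0)
        & df["p"].gt(0)
        & df["p"].le(1)
        & df["beta"].notna()
        & np.isfinite(df["beta"])
        & df["pos"].notna()
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & ~df["snp_id"].duplicated(keep="first")
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, n_dropped)
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    return SummaryStatsTable(df, trait_label=trait_label)


def write_sumstats(table: SummaryStatsTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


_M_RE = re.compile(r"#\s*M\s*=\s*(\d+)")


def read_ldscores(path) -> LDScoreTable:
    """Read per-SNP LD scores. Accepts LDSC-dialect headers (SNP, L2).

    The total SNP count M may be recorded in a leading ``# M=<int>`` comment
    line; otherwise it defaults to the number of rows.
    """
    m_total = 0
    with _open_text(path) as fh:
        first = fh.readline()
        m = _M_RE.match(first)
        if m:
            m_total = int(m.group(1))
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    lower = {c.lower(): c for c in df.columns}
    snp_col = next((lower[s] for s in ("snp_id", "snp", "rsid") if s in lower), None)
    ld_col = next(
        (lower[s] for s in ("ldscore", "l2", "ld", "ldscore_adj") if s in lower), None
    )
    if snp_col is None or ld_col is None:
        raise FormatError(f"{path}: need SNP and L2/ldscore columns")
    out = pd.DataFrame(
        {
            "snp_id": df[snp_col].astype(str),
            "ldscore": pd.to_numeric(df[ld_col], errors="coerce"),
        }
    )
    if out["ldscore"].isna().any():
        raise ValidationError("non-numeric ldscore values")
    return LDScoreTable(out, m_total=m_total)


def write_ldscores(table: LDScoreTable, path) -> None:
    with _open_text(path, "w") as fh:
        fh.write(f"# M={table.m_total}\n")
        table.df.to_csv(fh, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read a long-form pairwise r^2 table (snp_a, snp_b, r2).

    Symmetry is validated: if both orders of a pair appear they must agree;
    out-of-range or asymmetric entries raise ``ValidationError``.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    lower = {c.lower(): c for c in df.columns}
    cols = {}
    for canon, syns in (
        ("snp_a", ("snp_a", "snp1", "snp_i")),
        ("snp_b", ("snp_b", "snp2", "snp_j")),
        ("r2", ("r2", "rsq", "r_squared")),
    ):
        col = next((lower[s] for s in syns if s in lower), None)
        if col is None:
            raise FormatError(f"{path}: need columns snp_a, snp_b, r2")
        cols[canon] = col
    out = pd.DataFrame(
        {
            "snp_a": df[cols["snp_a"]].astype(str),
            "snp_b": df[cols["snp_b"]].astype(str),
            "r2": pd.to_numeric(df[cols["r2"]], errors="coerce"),
        }
    )
    if out["r2"].isna().any():
        raise ValidationError("non-numeric r2 values")
    return LDMatrix(out)


def write_ld_matrix(matrix: LDMatrix, path) -> None:
    matrix.pairs.to_csv(path, sep="\t", index=False)


def read_blocklist(path) -> ConfounderBlocklist:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    lower = {c.lower(): c for c in df.columns}
    snp_col = next((lower[s] for s in ("snp_id", "snp", "rsid") if s in lower), None)
    trait_col = next(
        (lower[s] for s in ("trait_label", "trait", "phenotype") if s in lower), None
    )
    if snp_col is None or trait_col is None:
        raise FormatError(f"{path}: need snp_id and trait_label columns")
    return ConfounderBlocklist(
        pd.DataFrame(
            {
                "snp_id": df[snp_col].astype(str),
                "trait_label": df[trait_col].astype(str),
            }
        )
    )


def write_blocklist(blocklist: ConfounderBlocklist, path) -> None:
    blocklist.df.to_csv(path, sep="\t", index=False)


def _open_text(path, mode: str = "r"):
    import gzip

    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)
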