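"""Reading, validating, and writing GWAS summary statistics and side inputs.

The canonical on-disk format is a tab-separated table with a header row and
columns ``snp_id, chr, pos, effect_allele, other_allele, eaf, beta, se,
pvalue, n``.  Positions are 1-based.  Missing values are written ``NA``;
``eaf`` and ``n`` may be missing, ``beta``/``se``/``pvalue`` may not.
Alleles are single bases from {A, C, G, T}: indel rows are dropped with a
warning, matching a SNP-only instrument pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for summary-statistic tables
CANONICAL_COLUMNS = [
    "snp_id", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

REQUIRED_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se"]


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected format."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits); ``se`` its standard error.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chr: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None


@dataclass
class TraitTable:
    """An ordered set of summary-statistic records for one trait.

    ``data`` holds the canonical columns; ``snp_id`` is unique and input
    order is preserved.  ``n_dropped`` counts rows removed during
    validation (invalid alleles, non-positive SE, out-of-range p, ...).
    """

    trait_name: str
    data: pd.DataFrame
    trait_type: str = "continuous"  # or "binary"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.data["snp_id"].duplicated().any():
            raise ValueError(f"duplicate snp_id in trait table {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> list[str]:
        return self.data["snp_id"].tolist()

    def subset(self, snp_ids: Iterable[str]) -> "TraitTable":
        """Rows whose snp_id is in ``snp_ids``, original order preserved."""
        keep = set(snp_ids)
        sub = self.data[self.data["snp_id"].isin(keep)].reset_index(drop=True)
        return TraitTable(self.trait_name, sub, self.trait_type)

    def records(self) -> list[SummaryStatRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(SummaryStatRecord(
                snp_id=row.snp_id, effect_allele=row.effect_allele,
                other_allele=row.other_allele, beta=row.beta, se=row.se,
                pvalue=row.pvalue,
                chr=None if pd.isna(row.chr) else str(row.chr),
                pos=None if pd.isna(row.pos) else int(row.pos),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            ))
        return out


@dataclass
class RunConfig:
    """Analysis thresholds and reproducibility settings.

    Defaults follow standard two-sample MR practice: genome-wide
    significance 5e-8 for instrument selection, LD clumping at r² = 0.001
    within a 10,000 kb window, palindromic SNPs dropped above an
    intermediate-frequency cutoff of 0.42.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    palindrome_eaf_limit: float = 0.42
    bootstrap_reps: int = 1000
    presso_sims: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if not 0 <= self.palindrome_eaf_limit <= 0.5:
            raise ValueError("palindrome_eaf_limit must be in [0, 0.5]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _validate_frame(df: pd.DataFrame, trait_name: str) -> tuple[pd.DataFrame, int]:
    n_in = len(df)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    numeric = {"eaf", "beta", "se", "pvalue", "n", "pos"}
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chr"] = df["chr"].astype("string")
    df["snp_id"] = df["snp_id"].astype(str)

    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & (df["n"].isna() | (df["n"] > 0))
        & ~df["snp_id"].duplicated(keep="first")
    )
    df = df[ok].reset_index(drop=True)
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s) of %d",
                       trait_name, n_dropped, n_in)
    return df, n_dropped


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    sep: str = "\t",
) -> TraitTable:
    """Read a delimited summary-statistic file into a validated TraitTable.

    Parameters
    ----------
    dialect
        Optional mapping from the file's column names to canonical names,
        e.g. ``{"BETA": "beta", "SE": "se"}``.  Canonical columns not
        covered by the mapping are matched by name.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA"],
                     keep_default_na=True)
    if df.shape[1] == 0 or (len(df) == 0 and df.shape[1] == 1):
        raise FormatError(f"{path}: empty input file")
    if dialect:
        df = df.rename(columns=dict(dialect))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    df, n_dropped = _validate_frame(df, trait_name or path.stem)
    return TraitTable(trait_name or path.stem, df, trait_type, n_dropped)


def write_summary_stats(table: TraitTable, path: str | Path) -> None:
    """Write a TraitTable as canonical TSV; round-trips through
    :func:`read_summary_stats` exactly (floats kept to 10 significant digits)."""
    df = table.data.copy()

    def fmt(x, integer=False):
        if pd.isna(x):
            return "NA"
        if integer and float(x) == int(x):
            return str(int(x))
        return format(float(x), ".10g")

    out = pd.DataFrame({
        "snp_id": df["snp_id"],
        "chr": df["chr"].map(lambda x: "NA" if pd.isna(x) else str(x)),
        "pos": df["pos"].map(lambda x: fmt(x, integer=True)),
        "effect_allele": df["effect_allele"],
        "other_allele": df["other_allele"],
        "eaf": df["eaf"].map(fmt),
        "beta": df["beta"].map(fmt),
        "se": df["se"].map(fmt),
        "pvalue": df["pvalue"].map(fmt),
        "n": df["n"].map(lambda x: fmt(x, integer=True)),
    })
    out.to_csv(path, sep="\t", index=False)


def table_from_arrays(
    trait_name: str,
    snp_id: Iterable[str],
    effect_allele: Iterable[str],
    other_allele: Iterable[str],
    beta: Iterable[float],
    se: Iterable[float],
    pvalue: Iterable[float],
    chr: Iterable | None = None,
    pos: Iterable | None = None,
    eaf: Iterable | None = None,
    n: Iterable | None = None,
    trait_type: str = "continuous",
) -> TraitTable:
    """Assemble a TraitTable from parallel arrays (validation applied)."""
    m = len(list(snp_id)) if not hasattr(snp_id, "__len__") else len(snp_id)
    df = pd.DataFrame({
        "snp_id": list(snp_id),
        "chr": list(chr) if chr is not None else [np.nan] * m,
        "pos": list(pos) if pos is not None else [np.nan] * m,
        "effect_allele": list(effect_allele),
        "other_allele": list(other_allele),
        "eaf": list(eaf) if eaf is not None else [np.nan] * m,
        "beta": list(beta),
        "se": list(se),
        "pvalue": list(pvalue),
        "n": list(n) if n is not None else [np.nan] * m,
    })
    df, n_dropped = _validate_frame(df, trait_name)
    return TraitTable(trait_name, df, trait_type, n_dropped)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: per line ``term<TAB>description<TAB>gene...``.

    Duplicate genes within a line are collapsed; a line with fewer than
    three fields raises a :class:`FormatError` naming the line.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            term = fields[0]
            sets[term] = {g for g in fields[2:] if g}
    return sets


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square r² matrix keyed by snp_id on both axes."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    if list(mat.index) != list(mat.columns):
        raise FormatError(f"{path}: LD matrix rows and columns disagree")
    return mat


def read_exclusion_list(path: str | Path) -> set[str]:
    """One snp_id per line; '#' starts a comment."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#")[0].strip()
            if token:
                out.add(token)
    return out


def read_eqtl_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a cis-eQTL association table (snp_id, gene, pvalue[, fdr])."""
    df = pd.read_csv(path, sep=sep)
    required = {"snp_id", "gene", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    df["snp_id"] = df["snp_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    return df
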