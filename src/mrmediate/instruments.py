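"""Instrument selection, LD clumping, allele harmonization, and strength.

The pipeline mirrors standard two-sample MR practice: keep genome-wide
significant SNPs, prune by LD (greedy, most significant first), remove
SNPs on a confounder exclusion list, align exposure and outcome effects
to a common effect allele, and grade instruments by variance explained
(R²) and F statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import TraitTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# provenance categories; every input SNP lands in exactly one
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_UNMATCHED = "dropped_unmatched"
DROPPED_EXCLUDED = "dropped_excluded"
DROPPED_CLUMPED = "dropped_clumped"


@dataclass
class HarmonizedSet:
    """Exposure(+mediator/extra-exposure) and outcome effects aligned to a
    common effect allele, one row per retained instrument.

    ``data`` columns: ``snp_id``, ``beta_<name>``/``se_<name>`` per exposure
    in ``exposures``, ``beta_outcome``/``se_outcome``, and ``eaf`` (exposure
    effect-allele frequency, NaN when unknown).  ``provenance`` maps every
    input SNP to one category (kept/flipped/dropped_*).
    """

    data: pd.DataFrame
    exposures: list[str]
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id among kept instruments")
        for name in self.exposures:
            if (self.data[f"se_{name}"] <= 0).any():
                raise ValueError(f"non-positive se for exposure {name!r}")
        if (self.data["se_outcome"] <= 0).any():
            raise ValueError("non-positive outcome se")

    # -- convenience accessors (first exposure is "the" exposure) ----------
    @property
    def n_snp(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> list[str]:
        return self.data["snp_id"].tolist()

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.data[f"beta_{self.exposures[0]}"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.data[f"se_{self.exposures[0]}"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.data["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.data["se_outcome"].to_numpy(float)

    @property
    def eaf(self) -> np.ndarray:
        return self.data["eaf"].to_numpy(float)

    def exposure_matrix(self) -> np.ndarray:
        """(n_snp, K) matrix of exposure effects."""
        return np.column_stack(
            [self.data[f"beta_{n}"].to_numpy(float) for n in self.exposures])

    def exposure_se_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.data[f"se_{n}"].to_numpy(float) for n in self.exposures])

    def subset(self, index: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        """Positional subset (order follows ``index``)."""
        sub = self.data.iloc[list(index)].reset_index(drop=True)
        return HarmonizedSet(sub, list(self.exposures))

    def drop_indices(self, index: Iterable[int]) -> "HarmonizedSet":
        drop = set(int(i) for i in index)
        keep = [i for i in range(self.n_snp) if i not in drop]
        return self.subset(keep)

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        eaf=None,
        snp_id=None,
        extra_exposures: dict[str, tuple] | None = None,
        exposure_name: str = "exposure",
    ) -> "HarmonizedSet":
        """Build a set directly from effect arrays (mainly for simulation
        and testing).  ``extra_exposures`` maps name -> (beta, se)."""
        bx = np.asarray(beta_exposure, float)
        m = bx.size
        cols = {
            "snp_id": list(snp_id) if snp_id is not None
            else [f"snp{i+1}" for i in range(m)],
            f"beta_{exposure_name}": bx,
            f"se_{exposure_name}": np.asarray(se_exposure, float),
            "beta_outcome": np.asarray(beta_outcome, float),
            "se_outcome": np.asarray(se_outcome, float),
            "eaf": np.asarray(eaf, float) if eaf is not None
            else np.full(m, np.nan),
        }
        names = [exposure_name]
        for name, (b, s) in (extra_exposures or {}).items():
            cols[f"beta_{name}"] = np.asarray(b, float)
            cols[f"se_{name}"] = np.asarray(s, float)
            names.append(name)
        return cls(pd.DataFrame(cols), names)


@dataclass
class InstrumentStrength:
    """Per-instrument variance explained and F statistics, with set-level
    summaries.  Instruments with F < 10 are flagged, not dropped."""

    per_snp: pd.DataFrame  # snp_id, r_squared, f_statistic, weak
    total_r_squared: float
    mean_f: float
    min_f: float

    @property
    def n_weak(self) -> int:
        return int(self.per_snp["weak"].sum())


def select_significant(table: TraitTable, p_threshold: float = 5e-8) -> TraitTable:
    """Keep records with ``pvalue < p_threshold`` (strict), order preserved."""
    keep = table.data[table.data["pvalue"] < p_threshold].reset_index(drop=True)
    return TraitTable(table.trait_name, keep, table.trait_type)


def apply_exclusion_list(table: TraitTable, excluded: Iterable[str]) -> TraitTable:
    """Remove records whose snp_id is in ``excluded`` (confounder screen)."""
    excluded = set(excluded)
    before = len(table)
    keep = table.data[~table.data["snp_id"].isin(excluded)].reset_index(drop=True)
    removed = before - len(keep)
    if removed:
        logger.info("%s: excluded %d SNP(s) from confounder list",
                    table.trait_name, removed)
    return TraitTable(table.trait_name, keep, table.trait_type)


def clump(
    table: TraitTable,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    missing_ld: str = "error",
) -> TraitTable:
    """Greedy LD clumping: repeatedly keep the most significant remaining SNP
    and remove same-chromosome SNPs within ``window_kb`` whose r² with it
    exceeds ``r2_threshold`` (with no LD matrix, remove unconditionally
    within the window).  Ties in p are broken by ascending snp_id, so the
    result does not depend on input row order.

    ``missing_ld``: in LD mode, "error" (default) raises when a pair is
    absent from the matrix; "zero" treats it as r² = 0 with a warning.
    """
    df = table.data
    if df["chr"].isna().any() or df["pos"].isna().any():
        raise ValueError("clumping requires chromosome and position")
    if missing_ld not in ("error", "zero"):
        raise ValueError("missing_ld must be 'error' or 'zero'")

    order = df.assign(_row=np.arange(len(df))).sort_values(
        ["pvalue", "snp_id"], kind="mergesort")
    alive = dict.fromkeys(order["_row"].tolist(), True)
    chrom = df["chr"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(float)
    ids = df["snp_id"].to_numpy()

    kept_rows: list[int] = []
    for i in order["_row"]:
        if not alive[i]:
            continue
        kept_rows.append(i)
        alive[i] = False
        near = (
            (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_kb * 1000.0)
        )
        for j in np.flatnonzero(near):
            if j == i or not alive.get(int(j), False):
                continue
            if ld is None:
                prune = True
            else:
                try:
                    r2 = float(ld.loc[ids[i], ids[j]])
                except KeyError:
                    if missing_ld == "error":
                        raise KeyError(
                            f"SNP pair ({ids[i]}, {ids[j]}) absent from LD matrix")
                    logger.warning("LD missing for (%s, %s); assuming r²=0",
                                   ids[i], ids[j])
                    r2 = 0.0
                prune = r2 > r2_threshold
            if prune:
                alive[int(j)] = False
    kept_rows.sort()  # restore input order
    out = df.iloc[kept_rows].reset_index(drop=True)
    return TraitTable(table.trait_name, out, table.trait_type)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def _align_one(exp_ea, exp_oa, oth_ea, oth_oa, eaf_exp, eaf_oth,
               palindrome_eaf_limit):
    """Decide how a non-exposure table's record aligns with the exposure.

    Returns (status, flip) with status in {kept, flipped,
    dropped_palindromic, dropped_unmatched}; flip=True means negate the
    other table's beta and complement its eaf.
    """
    if _is_palindromic(exp_ea, exp_oa):
        if {oth_ea, oth_oa} != {exp_ea, exp_oa}:
            return DROPPED_UNMATCHED, False
        # strand is ambiguous: resolve by allele frequency, or drop
        if np.isnan(eaf_exp) or np.isnan(eaf_oth):
            return DROPPED_PALINDROMIC, False
        if (min(eaf_exp, 1 - eaf_exp) > palindrome_eaf_limit
                or min(eaf_oth, 1 - eaf_oth) > palindrome_eaf_limit):
            return DROPPED_PALINDROMIC, False
        freq_of_exp_ea = eaf_oth if oth_ea == exp_ea else 1 - eaf_oth
        if (eaf_exp < 0.5) == (freq_of_exp_ea < 0.5):
            # frequencies agree: same strand; flip only if alleles swapped
            return (KEPT, False) if oth_ea == exp_ea else (FLIPPED, True)
        # frequencies disagree: the labels refer to opposite strands
        return (FLIPPED, True) if oth_ea == exp_ea else (KEPT, False)

    if {oth_ea, oth_oa} == {exp_ea, exp_oa}:
        return (KEPT, False) if oth_ea == exp_ea else (FLIPPED, True)
    comp = {_COMPLEMENT[oth_ea], _COMPLEMENT[oth_oa]}
    if comp == {exp_ea, exp_oa}:
        # other table reported on the opposite strand
        if _COMPLEMENT[oth_ea] == exp_ea:
            return KEPT, False
        return FLIPPED, True
    return DROPPED_UNMATCHED, False


def harmonize(
    exposure: TraitTable,
    outcome: TraitTable,
    more: Sequence[TraitTable] | None = None,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonizedSet:
    """Align outcome (and any further trait) effects to the exposure's
    effect allele.

    Swapped alleles negate the other table's beta and complement its eaf;
    strand-complement reports are re-keyed; palindromic (A/T, C/G) SNPs are
    resolved by allele frequency when both frequencies are decisive
    (min(eaf, 1−eaf) ≤ ``palindrome_eaf_limit``) and dropped otherwise.
    Every input exposure SNP is assigned one provenance category.
    """
    more = list(more or [])
    # the outcome owns the "outcome" column pair; a trait literally named
    # "outcome" is re-keyed to avoid a column collision
    def _key(name: str) -> str:
        return name if name != "outcome" else "outcome_x"

    others = [outcome] + more
    prov_rows: list[tuple[str, str]] = []
    rows: list[dict] = []

    other_ix = []
    for t in others:
        if t.data["snp_id"].duplicated().any():
            raise ValueError(f"duplicate snp_id in table {t.trait_name!r}")
        other_ix.append(t.data.set_index("snp_id"))
    if exposure.data["snp_id"].duplicated().any():
        raise ValueError(f"duplicate snp_id in table {exposure.trait_name!r}")

    for rec in exposure.data.itertuples(index=False):
        status = KEPT
        flips: list[bool] = []
        payload: list[tuple[float, float]] = []
        for t_ix in other_ix:
            if rec.snp_id not in t_ix.index:
                status = DROPPED_UNMATCHED
                break
            o = t_ix.loc[rec.snp_id]
            st, flip = _align_one(
                rec.effect_allele, rec.other_allele,
                o["effect_allele"], o["other_allele"],
                float(rec.eaf) if pd.notna(rec.eaf) else np.nan,
                float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan,
                palindrome_eaf_limit,
            )
            if st in (DROPPED_PALINDROMIC, DROPPED_UNMATCHED):
                status = st
                break
            if st == FLIPPED:
                status = FLIPPED if status == KEPT else status
            flips.append(flip)
            payload.append((float(o["beta"]), float(o["se"])))
        prov_rows.append((rec.snp_id, status))
        if status in (KEPT, FLIPPED):
            row = {
                "snp_id": rec.snp_id,
                f"beta_{_key(exposure.trait_name)}": float(rec.beta),
                f"se_{_key(exposure.trait_name)}": float(rec.se),
                "eaf": float(rec.eaf) if pd.notna(rec.eaf) else np.nan,
            }
            for t, flip, (b, s) in zip(others, flips, payload):
                key = "outcome" if t is outcome else _key(t.trait_name)
                row[f"beta_{key}"] = -b if flip else b
                row[f"se_{key}"] = s
            rows.append(row)

    exposure_names = [_key(exposure.trait_name)] + [_key(t.trait_name) for t in more]
    columns = (["snp_id"]
               + [c for n in exposure_names for c in (f"beta_{n}", f"se_{n}")]
               + ["beta_outcome", "se_outcome", "eaf"])
    data = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(
        {c: pd.Series(dtype=float) for c in columns})
    provenance = pd.DataFrame(prov_rows, columns=["snp_id", "status"])
    return HarmonizedSet(data, exposure_names, provenance)


def instrument_strength(hset: HarmonizedSet, n_exposure: float) -> InstrumentStrength:
    """Variance explained and F per instrument.

    With the effect-allele frequency f available,
    R² = 2β²f(1−f) / [2β²f(1−f) + 2nσ²f(1−f)] = β²/(β² + nσ²) and
    F = R²(n−2)/(1−R²).  Without f, the fallback is F = (β/σ)² and
    R² = F/(F + n − 2).  Instruments with F < 10 are flagged as weak.
    """
    if n_exposure <= 2:
        raise ValueError("n_exposure must exceed 2")
    beta = hset.beta_exposure
    se = hset.se_exposure
    eaf = hset.eaf
    n = float(n_exposure)

    have_eaf = np.isfinite(eaf)
    fq = np.where(have_eaf, eaf, 0.5)
    num = 2.0 * beta**2 * fq * (1 - fq)
    den = num + 2.0 * n * se**2 * fq * (1 - fq)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2_eaf = np.where(den > 0, num / den, 0.0)
        f_eaf = r2_eaf * (n - 2) / (1 - r2_eaf)
        f_fb = (beta / se) ** 2
        r2_fb = f_fb / (f_fb + n - 2)
    r2 = np.where(have_eaf, r2_eaf, r2_fb)
    f = np.where(have_eaf, f_eaf, f_fb)

    per = pd.DataFrame({
        "snp_id": hset.snp_ids,
        "r_squared": r2,
        "f_statistic": f,
        "weak": f < 10,
    })
    return InstrumentStrength(
        per_snp=per,
        total_r_squared=float(np.sum(r2)),
        mean_f=float(np.mean(f)) if len(per) else float("nan"),
        min_f=float(np.min(f)) if len(per) else float("nan"),
    )
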