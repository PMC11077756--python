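"""Gene annotation via cis-eQTL lookups and hypergeometric
over-representation analysis against user-supplied gene sets."""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def annotate_genes(
    snps: set[str] | list[str],
    eqtl: pd.DataFrame,
    p_threshold: float = 5e-8,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """Map instrument SNPs to genes through cis-eQTL associations.

    Restricts the eQTL table to the given SNPs, computes Benjamini-
    Hochberg FDR across the restricted rows when no ``fdr`` column is
    present, and keeps genes with ``pvalue < p_threshold`` and
    ``fdr < fdr_threshold``.  Returns sorted unique gene symbols, so the
    output does not depend on eQTL row order.
    """
    if eqtl.empty:
        raise ValueError("empty eQTL table")
    snps = set(snps)
    sub = eqtl[eqtl["snp_id"].isin(snps)].copy()
    if sub.empty:
        return []
    if "fdr" not in sub.columns or sub["fdr"].isna().all():
        sub["fdr"] = multipletests(sub["pvalue"].to_numpy(), method="fdr_bh")[1]
    keep = sub[(sub["pvalue"] < p_threshold) & (sub["fdr"] < fdr_threshold)]
    return sorted(set(keep["gene"]))


def ora_test(
    selected: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    For a term with K background members, drawing n = |selected| genes
    from a universe of N = |background|, the p-value is P(X ≥ k) where k
    is the observed overlap.  Terms are intersected with the background
    before testing; BH FDR is computed across terms; rows are sorted by
    ascending p (ties by term name).
    """
    selected = set(selected)
    background = set(background)
    stray = selected - background
    if stray:
        raise ValueError(
            f"selected genes absent from background: {sorted(stray)}")
    n_total = len(background)
    n_sel = len(selected)
    rows = []
    for term, genes in gene_sets.items():
        in_bg = genes & background
        big_k = len(in_bg)
        k = len(in_bg & selected)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_sel))
        rows.append({"term": term, "k": k, "K": big_k, "n": n_sel,
                     "N": n_total, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(columns=["term", "k", "K", "n", "N", "pvalue", "fdr"])
    out["fdr"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return (out.sort_values(["pvalue", "term"], kind="mergesort")
            .reset_index(drop=True))
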