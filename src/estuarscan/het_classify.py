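"""Population-exclusive highly-heterozygous SNP classification and
per-individual non-synonymous gene-ratio statistics.

A SNP is "highly heterozygous" in a population when strictly more than half
of the genotyped individuals are heterozygous; a SNP exclusive to one
population is highly heterozygous there but not in the other. The fold
ratio of exclusive counts between two populations summarizes asymmetry in
retained heterozygosity (bottleneck/selection signal).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix

log = logging.getLogger("estuarscan")

LABELS = ("A_only", "B_only", "both", "neither")


def classify_exclusive_het(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-SNP heterozygote fractions in the two populations and the
    exclusivity label. SNPs with zero called genotypes in either population
    are skipped (with a warning)."""
    ia, ib = gm.pop_indices(pop_a), gm.pop_indices(pop_b)
    frac = {}
    called_ok = np.ones(gm.n_variants, dtype=bool)
    for key, idx in (("A", ia), ("B", ib)):
        codes = gm.codes[:, idx]
        called = (codes != MISSING).sum(axis=1)
        het = (codes == 1).sum(axis=1)
        called_ok &= called > 0
        frac[key] = np.divide(het, called, out=np.zeros(gm.n_variants),
                              where=called > 0)
    if not called_ok.all():
        log.warning("skipped %d SNPs with no called genotypes in a population",
                    int((~called_ok).sum()))
    high_a = frac["A"] > 0.5
    high_b = frac["B"] > 0.5
    label = np.where(high_a & high_b, "both",
                     np.where(high_a, "A_only",
                              np.where(high_b, "B_only", "neither")))
    df = pd.DataFrame({
        "chrom": gm.chrom, "pos": gm.pos,
        "het_frac_a": frac["A"], "het_frac_b": frac["B"], "label": label,
    })
    return df[called_ok].reset_index(drop=True)


def exclusive_counts_by_chrom(classification: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome counts of A_only and B_only SNPs."""
    tab = (classification.groupby(["chrom", "label"]).size()
           .unstack(fill_value=0).reindex(columns=list(LABELS), fill_value=0))
    return tab[["A_only", "B_only"]].reset_index()


def exclusive_fold_ratio(counts_a_only, counts_b_only) -> float:
    """Total A_only / total B_only, reported to 2 decimals; nan when the
    denominator is 0."""
    a = int(np.sum(counts_a_only))
    b = int(np.sum(counts_b_only))
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if b == 0:
        return math.nan
    return round(a / b, 2)


def nonsyn_gene_ratio(gm: GenotypeMatrix, effects: pd.DataFrame) -> pd.DataFrame:
    """Per-individual ratio (%) of variant-carrying genes that carry at least
    one non-synonymous variant in that individual.

    ``effects``: the io.read_effect_table frame (chrom, pos 0-based, effect,
    gene_id). Variants absent from the table count toward the denominator
    as effect "other".
    """
    key = pd.DataFrame({"chrom": gm.chrom.astype(str), "pos": gm.pos})
    eff = effects[["chrom", "pos", "effect", "gene_id"]].copy()
    eff["chrom"] = eff["chrom"].astype(str)
    merged = key.merge(eff, on=["chrom", "pos"], how="left")
    if merged["gene_id"].isna().any():
        log.info("%d variants missing from the effect table (treated as 'other', "
                 "no gene assignment)", int(merged["gene_id"].isna().sum()))
    gene_id = merged["gene_id"].to_numpy()
    is_nonsyn = (merged["effect"] == "nonsynonymous").to_numpy()
    in_gene = ~pd.isna(gene_id)

    rows = []
    carrier = (gm.codes == 1) | (gm.codes == 2)
    for j, sample in enumerate(gm.samples):
        has = carrier[:, j] & in_gene
        genes_any = set(gene_id[has])
        genes_nonsyn = set(gene_id[has & is_nonsyn])
        denom, numer = len(genes_any), len(genes_nonsyn)
        rows.append({
            "sample": sample,
            "population": gm.populations.get(sample),
            "genes_with_variant": denom,
            "genes_with_nonsyn": numer,
            "ratio_pct": 100.0 * numer / denom if denom else math.nan,
        })
    return pd.DataFrame(rows)


def population_ratio_summary(ratios: pd.DataFrame) -> pd.DataFrame:
    """Population mean +/- SEM of the per-individual non-synonymous ratio
    (individuals with no variant-carrying genes are excluded)."""
    ok = ratios.dropna(subset=["ratio_pct"])
    g = ok.groupby("population")["ratio_pct"]
    return pd.DataFrame({"mean_pct": g.mean(), "sem_pct": g.sem(),
                         "n": g.size()}).reset_index()


def rank_test(group_a, group_b=None, paired=False, exact=None):
    """Two-sided Wilcoxon test.

    Unpaired (default): rank-sum / Mann-Whitney with normal approximation and
    tie correction (``exact=True`` switches to the exact distribution).
    Paired: signed-rank on elementwise differences. Returns (statistic, p).
    """
    a = np.asarray(group_a, dtype=float)
    if paired:
        b = a * 0.0 if group_b is None else np.asarray(group_b, dtype=float)
        if len(a) != len(b) or len(a) < 3:
            raise ValueError("paired test needs >= 3 pairs of equal length")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        method = "exact" if exact else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
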