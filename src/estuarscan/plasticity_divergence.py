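"""Expression plasticity vs genomic divergence for the reciprocal-transplant design.

Samples come from a 2x2 layout: population of origin (N/S) crossed with
rearing habitat (n/s). Genes differentially expressed between habitats in
*both* populations are classified high-plasticity (HP); the rest are
low-plasticity (LP). Per-gene genomic regions (upstream flank / gene body /
downstream flank, strand-aware) are then compared between HP and LP genes on
mean per-site FST.

Differential expression is a negative-binomial Wald test with
median-of-ratios normalization and method-of-moments dispersion: light-weight
and self-contained; externally computed DE tables (gene, log2fc, p) can be
substituted anywhere a DE frame is accepted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .het_classify import rank_test
from .io import GeneModel

log = logging.getLogger("estuarscan")

REGION_CLASSES = ("upstream", "genic", "downstream")


def filter_expressed(counts: pd.DataFrame, min_count=10, min_fraction=0.9):
    """Genes with >= ``min_count`` reads in strictly more than ``min_fraction``
    of samples (genes x samples frame); returns the retained index."""
    frac = (counts >= min_count).mean(axis=1)
    return counts.index[frac > min_fraction]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq median-of-ratios size factors (genes with a zero anywhere are
    excluded from the reference)."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    usable = np.isfinite(logc).all(axis=1)
    if not usable.any():
        raise ValueError("no gene is nonzero in every sample; cannot normalize")
    ref = logc[usable].mean(axis=1)
    sf = np.exp(np.median(logc[usable] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def de_test(counts: pd.DataFrame, samples_a, samples_b, size_factors=None) -> pd.DataFrame:
    """Per-gene NB Wald test of group A vs group B (two-sided).

    Normalized group means are compared on the log scale; the variance of a
    log mean is (1/m + alpha)/n by the delta method with a pooled
    method-of-moments dispersion alpha (floored at 1e-8). The reference
    distribution is t with Welch-Satterthwaite degrees of freedom. Genes with
    zero counts in both groups get p = nan.

    Returns a frame indexed by gene: base_mean, log2fc (A over B), p, padj.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if size_factors is None:
        size_factors = estimate_size_factors(counts[samples_a + samples_b])
    norm = counts[samples_a + samples_b].div(size_factors, axis=1)
    A = norm[samples_a].to_numpy(float)
    B = norm[samples_b].to_numpy(float)
    na, nb = A.shape[1], B.shape[1]
    mA, mB = A.mean(1), B.mean(1)
    vA, vB = A.var(1, ddof=1), B.var(1, ddof=1)

    def mom_alpha(m, v):
        with np.errstate(invalid="ignore", divide="ignore"):
            a = (v - m) / np.where(m > 0, m**2, 1.0)
        return np.where(m > 0, a, 0.0)

    alpha = ((na - 1) * mom_alpha(mA, vA) + (nb - 1) * mom_alpha(mB, vB)) / (na + nb - 2)
    alpha = np.maximum(alpha, 1e-8)

    # pseudo-mean keeps logs finite when one group is all zero
    mA_ = np.maximum(mA, 0.5)
    mB_ = np.maximum(mB, 0.5)
    se2A = (1.0 / mA_ + alpha) / na
    se2B = (1.0 / mB_ + alpha) / nb
    z = (np.log(mA_) - np.log(mB_)) / np.sqrt(se2A + se2B)
    df = (se2A + se2B) ** 2 / (se2A**2 / (na - 1) + se2B**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(z), df)
    log2fc = (np.log(mA_) - np.log(mB_)) / math.log(2)

    untestable = (mA == 0) & (mB == 0)
    p[untestable] = np.nan
    log2fc[untestable] = np.nan
    if untestable.any():
        log.info("%d genes with zero counts in both groups excluded",
                 int(untestable.sum()))
    out = pd.DataFrame({"base_mean": (mA + mB) / 2, "log2fc": log2fc, "p": p},
                       index=counts.index)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving;
    NaN inputs are passed through and ignored in the adjustment)."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def classify_hp_lp(de_n: pd.DataFrame, de_s: pd.DataFrame, alpha=0.01) -> pd.DataFrame:
    """HP/LP classification from the two within-population habitat contrasts.

    A gene is HP iff its BH-adjusted p is < ``alpha`` in BOTH contrasts; all
    other tested genes are LP. Genes tested in only one contrast are LP with
    ``single_contrast=True``. The plasticity score is the mean |log2fc|
    across the available contrasts.
    """
    genes = de_n.index.union(de_s.index)
    n = de_n.reindex(genes)
    s = de_s.reindex(genes)
    tested_n = n["p"].notna()
    tested_s = s["p"].notna()
    hp = (tested_n & tested_s
          & (n["padj"] < alpha) & (s["padj"] < alpha))
    score = pd.concat([n["log2fc"].abs(), s["log2fc"].abs()], axis=1).mean(axis=1)
    out = pd.DataFrame({
        "label": np.where(hp, "HP", "LP"),
        "score": score,
        "single_contrast": ~(tested_n & tested_s),
    }, index=genes)
    return out[tested_n | tested_s]


@dataclass
class RegionPartition:
    """Strand-aware upstream / genic / downstream intervals of one gene
    (0-based half-open, truncated at chromosome bounds)."""

    gene_id: str
    chrom: str
    intervals: dict = field(default_factory=dict)  # region class -> (start, end)


def partition_regions(gene: GeneModel, flank=5000, chrom_length=None) -> RegionPartition:
    if flank <= 0:
        raise ValueError("flank must be positive")
    L = chrom_length if chrom_length is not None else gene.end + flank
    left = (max(gene.start - flank, 0), gene.start)
    right = (gene.end, min(gene.end + flank, L))
    genic = (gene.start, min(gene.end, L))
    if gene.strand == "+":
        up, down = left, right
    else:
        up, down = right, left
    return RegionPartition(gene.gene_id, gene.chrom,
                           {"upstream": up, "genic": genic, "downstream": down})


def region_fst(partitions, per_site_fst: pd.DataFrame) -> pd.DataFrame:
    """Mean per-site FST over the SNPs in each gene region.

    ``per_site_fst``: frame with chrom, pos, fst (popgen_stats.site_fst).
    Regions containing no SNP (or only undefined sites) get NaN.
    Returns a frame indexed by gene with one column per region class.
    """
    by_chrom = {}
    for c, sub in per_site_fst.groupby("chrom"):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        fst = sub["fst"].to_numpy(dtype=float)
        cum = np.concatenate([[0.0], np.nancumsum(fst)])
        cnt = np.concatenate([[0], np.cumsum(np.isfinite(fst).astype(int))])
        by_chrom[c] = (pos, cum, cnt)
    rows = {}
    for part in partitions:
        row = {}
        entry = by_chrom.get(part.chrom)
        for rc, (s, e) in part.intervals.items():
            if entry is None or e <= s:
                row[rc] = math.nan
                continue
            pos, cum, cnt = entry
            i, j = np.searchsorted(pos, (s, e), side="left")
            k = cnt[j] - cnt[i]
            row[rc] = (cum[j] - cum[i]) / k if k > 0 else math.nan
        rows[part.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(REGION_CLASSES))


def compare_hp_lp(region_fst_table: pd.DataFrame, classes) -> pd.DataFrame:
    """HP-vs-LP rank tests of mean region FST.

    One unpaired rank-sum test per region class (plus the three classes
    combined), and a paired signed-rank test of genic vs intergenic
    (mean of upstream/downstream) FST across all genes.
    """
    classes = pd.Series(classes).reindex(region_fst_table.index)
    results = []
    for rc in list(REGION_CLASSES) + ["combined"]:
        if rc == "combined":
            vals = region_fst_table[list(REGION_CLASSES)].mean(axis=1)
        else:
            vals = region_fst_table[rc]
        hp = vals[(classes == "HP") & vals.notna()]
        lp = vals[(classes == "LP") & vals.notna()]
        if len(hp) < 3 or len(lp) < 3:
            log.warning("region %s: too few genes per class, test skipped", rc)
            results.append({"region": rc, "n_hp": len(hp), "n_lp": len(lp),
                            "statistic": math.nan, "p": math.nan})
            continue
        stat, p = rank_test(hp.to_numpy(), lp.to_numpy())
        results.append({"region": rc, "n_hp": len(hp), "n_lp": len(lp),
                        "statistic": stat, "p": p})
    genic = region_fst_table["genic"]
    inter = region_fst_table[["upstream", "downstream"]].mean(axis=1)
    both = genic.notna() & inter.notna()
    if both.sum() >= 3:
        stat, p = rank_test(genic[both].to_numpy(), inter[both].to_numpy(),
                            paired=True)
    else:
        stat, p = math.nan, math.nan
    results.append({"region": "genic_vs_intergenic_paired",
                    "n_hp": int(both.sum()), "n_lp": int(both.sum()),
                    "statistic": stat, "p": p})
    return pd.DataFrame(results)
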