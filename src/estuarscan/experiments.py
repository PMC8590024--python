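"""Calibration and recovery experiments on synthetic data.

Each experiment builds data with the generators in :mod:`synthetic_data`,
runs the corresponding analysis stage, and returns the summary quantities a
reviewer would check: estimator calibration against closed-form expectations,
parameter recovery against the generating truth, and decision-rule
sensitivity/specificity against injected signals. The tests and the
reproduction script both call these, so the reported numbers always come from
a fresh run of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import plasticity_divergence as pdiv
from . import popgen_stats as ps
from . import sweep_scan as ss
from . import synthetic_data as sd
from .kmer_size import detect_peaks, genome_size


def bn_fst_recovery(seed, n_per_pop=50, n_snps=5000, F=0.15,
                    chrom_length=5_000_000):
    """Mean windowed Hudson FST between two Balding-Nichols populations with
    known differentiation F (E[FST] = F)."""
    gm, _ = sd.sim_genotypes({"A": n_per_pop, "B": n_per_pop},
                             {"chr1": chrom_length}, n_snps, fst=F, seed=seed)
    st = ps.windowed_stats(gm, {"chr1": chrom_length}, pairs=[("A", "B")])
    return float(st["fst_A_B"].dropna().mean())


def coalescent_calibration(seed, n=10, theta=5.0, n_reps=2000):
    """Mean S, pi-hat and Tajima's D over neutral coalescent replicates
    (expectations: theta*a1, theta, ~0)."""
    reps = sd.sim_coalescent(n, theta, n_reps, seed=seed)
    S, pi, D = [], [], []
    for H in reps:
        s, p, d = ps.haplotype_stats(H)
        S.append(s)
        pi.append(p)
        if np.isfinite(d):
            D.append(d)
    a1 = ps.tajima_constants(n)["a1"]
    return {"mean_S": float(np.mean(S)), "expected_S": theta * a1,
            "mean_pi": float(np.mean(pi)), "expected_pi": theta,
            "mean_D": float(np.mean(D))}


def sweep_recovery(seed, n_seeds=20, n_chroms=5, chrom_length=8_000_000,
                   snps_per_chrom=16_000, sweep_length=50_000, F=0.15,
                   n_per_pop=30):
    """Full composite-scan recovery of injected sweeps.

    Each replicate genome carries one sweep per chromosome (southern
    population target, centered) among ~4,000 windows; returns mean
    recovered (of n_chroms) and mean false regions over ``n_seeds``
    replicate genomes.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    chrom_lengths = {f"chr{i}": chrom_length for i in range(1, n_chroms + 1)}
    mid = chrom_length // 2
    sweeps = [sd.Sweep(c, mid, mid + sweep_length, target_pop="SC")
              for c in chrom_lengths]
    recovered, false = [], []
    for s in child_seeds:
        gm, _ = sd.sim_genotypes({"NC": n_per_pop, "MC": n_per_pop,
                                  "SC": n_per_pop},
                                 chrom_lengths, snps_per_chrom, fst=F,
                                 sweeps=sweeps, seed=int(s))
        st = ps.windowed_stats(gm, chrom_lengths)
        regions, _ = ss.scan(st, pairs=[("NC", "SC"), ("MC", "SC")],
                             pops=("NC", "MC", "SC"))
        hit = sum(1 for sw in sweeps
                  if any(r.chrom == sw.chrom and r.start < sw.end
                         and r.end > sw.start for r in regions))
        fp = sum(1 for r in regions
                 if not any(r.chrom == sw.chrom and r.start < sw.end
                            and r.end > sw.start for sw in sweeps))
        recovered.append(hit)
        false.append(fp)
    return {"n_sweeps": n_chroms,
            "mean_recovered": float(np.mean(recovered)),
            "mean_false_regions": float(np.mean(false))}


def _habitat_groups(meta):
    return {p: [list(meta[(meta["population"] == p)
                          & (meta["habitat"] == h)]["sample"])
                for h in ("n", "s")] for p in ("N", "S")}


def hp_lp_recovery(seed, n_genes=2000, reps_per_cell=5, effect_log2fc=2.0,
                   hp_fraction=0.3, alpha=0.01):
    """Balanced accuracy of HP/LP classification against generating truth."""
    counts, meta, truth = sd.sim_expression(
        n_genes=n_genes, reps_per_cell=reps_per_cell, hp_fraction=hp_fraction,
        effect_log2fc=effect_log2fc, seed=seed)
    sub = counts.loc[pdiv.filter_expressed(counts)]
    groups = _habitat_groups(meta)
    out = pdiv.classify_hp_lp(pdiv.de_test(sub, *groups["N"]),
                              pdiv.de_test(sub, *groups["S"]), alpha=alpha)
    t = truth.loc[out.index, "label"]
    sens = ((out["label"] == "HP") & (t == "HP")).sum() / max((t == "HP").sum(), 1)
    spec = ((out["label"] == "LP") & (t == "LP")).sum() / max((t == "LP").sum(), 1)
    return {"balanced_accuracy": float(0.5 * (sens + spec)),
            "n_genes_tested": int(len(out))}


def de_null_calibration(seed, n_genes=2000, reps_per_cell=5):
    """KS distance of null raw p-values from uniform (no-effect simulation)."""
    counts, meta, _ = sd.sim_expression(n_genes=n_genes,
                                        reps_per_cell=reps_per_cell,
                                        hp_fraction=0.0, effect_log2fc=0.0,
                                        seed=seed)
    sub = counts.loc[pdiv.filter_expressed(counts)]
    groups = _habitat_groups(meta)
    res = pdiv.de_test(sub, *groups["N"])
    p = res["p"].dropna().to_numpy()
    return {"ks_distance": float(sstats.kstest(p, "uniform").statistic),
            "n_genes": int(len(p))}


def _fig5_layout(n_genes=400, gene_length=2000, flank=2000):
    slot = gene_length + 5 * flank
    chrom_length = n_genes * slot
    genes = sd.sim_gene_models({"chr1": chrom_length},
                               n_genes_per_chrom=n_genes,
                               gene_length=gene_length,
                               min_gap=4 * flank, seed=0)
    parts = [pdiv.partition_regions(g, flank=flank, chrom_length=chrom_length)
             for g in genes]
    return genes, parts, chrom_length


def plasticity_divergence_pattern(seed, n_reps=40, n_genes=400,
                                  upstream_shift=0.05, snp_per_bp=1 / 200,
                                  alpha=0.05):
    """Power to detect upstream-elevated divergence of HP genes.

    Per replicate: half the genes are labelled HP and their upstream flanks
    get per-SNP FST raised by ``upstream_shift``; per-SNP baseline FST is
    Beta-distributed with mean 0.15. Returns the fraction of replicates where
    the HP-vs-LP upstream rank test rejects at ``alpha`` in the right
    direction, plus the genic-region rejection rate (a null by construction).
    """
    genes, parts, chrom_length = _fig5_layout(n_genes=n_genes)
    rng = np.random.default_rng(seed)
    n_snps = int(chrom_length * snp_per_bp)
    up_hits = 0
    genic_hits = 0
    labels = pd.Series(["HP"] * (n_genes // 2) + ["LP"] * (n_genes - n_genes // 2),
                       index=[g.gene_id for g in genes])
    hp_up = [parts[i].intervals["upstream"] for i in range(n_genes // 2)]
    for _ in range(n_reps):
        pos = np.sort(rng.choice(chrom_length, size=n_snps, replace=False))
        fst = rng.beta(1.5, 8.5, size=n_snps)
        if upstream_shift:
            in_up = np.zeros(n_snps, dtype=bool)
            for s, e in hp_up:
                i, j = np.searchsorted(pos, (s, e))
                in_up[i:j] = True
            fst[in_up] = np.minimum(fst[in_up] + upstream_shift, 1.0)
        table = pdiv.region_fst(parts, pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "fst": fst}))
        res = pdiv.compare_hp_lp(table, labels).set_index("region")
        up_mean_hp = table.loc[labels == "HP", "upstream"].mean()
        up_mean_lp = table.loc[labels == "LP", "upstream"].mean()
        if res.loc["upstream", "p"] < alpha and up_mean_hp > up_mean_lp:
            up_hits += 1
        if res.loc["genic", "p"] < alpha:
            genic_hits += 1
    return {"upstream_power": up_hits / n_reps,
            "genic_rejection_rate": genic_hits / n_reps,
            "n_reps": n_reps}


def kmer_recovery(seed, n_seeds=20, genome_size_true=5_000_000, depth=60):
    """Genome-size and peak recovery across replicate spectra."""
    rng = np.random.default_rng(seed)
    rel_err, het_err, hom_err = [], [], []
    for s in rng.integers(0, 2**31 - 1, size=n_seeds):
        spec, truth = sd.sim_kmer_spectrum(genome_size_true, depth, seed=int(s))
        cut, het, hom = detect_peaks(spec)
        est = genome_size(spec, error_cutoff=cut, hom_peak=hom)
        rel_err.append(abs(est - truth["genome_size"]) / truth["genome_size"])
        het_err.append(abs(het - depth / 2))
        hom_err.append(abs(hom - depth))
    return {"max_rel_error": float(np.max(rel_err)),
            "mean_rel_error": float(np.mean(rel_err)),
            "max_peak_error": float(max(np.max(het_err), np.max(hom_err)))}
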