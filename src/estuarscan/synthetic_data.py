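"""Synthetic-data generators with the statistical structure the analyses assume.

Everything is a pure function of its parameters and a seed (independent
RNG streams per component), so each pipeline stage is testable with known
ground truth and no external download:

* Balding-Nichols structured genotypes for an arbitrary set of populations
  (population allele frequencies Beta-distributed around a shared ancestral
  frequency with E[FST] = F), with phenomenological sweep injection:
  within a sweep interval the target population gets a block of sites driven
  to fixation (frequency differential + diversity reduction) plus a block of
  singleton sites (site-frequency-spectrum skew that forces Tajima's D down).
* A standard neutral coalescent (via msprime, n haploid lineages, infinite
  sites, E[S] = theta * a1) used as the calibration oracle for the windowed
  statistics.
* Negative-binomial expression counts for the 2x2 reciprocal-transplant
  design with known HP/LP labels.
* Diploid two-peak k-mer spectra with known genome size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .io import GeneModel, GenotypeMatrix
from .kmer_size import KmerSpectrum


@dataclass(frozen=True)
class Sweep:
    """A phenomenological sweep: within [start, end) on ``chrom`` the target
    population has ``fix_fraction`` of sites driven to alternate-allele
    fixation (high between-population differentiation, reduced diversity) and
    ``singleton_fraction`` of sites converted to singletons (negative
    Tajima's D)."""

    chrom: str
    start: int
    end: int
    target_pop: str
    fix_fraction: float = 0.7
    singleton_fraction: float = 0.3


def _spawn_rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sim_genotypes(pop_sizes: dict, chrom_lengths: dict, snps_per_chrom: int,
                  fst=0.15, sweeps=(), seed=0, p_range=(0.05, 0.95)):
    """Balding-Nichols diploid genotypes with optional sweep injection.

    Returns (GenotypeMatrix, truth) where truth carries the per-SNP ancestral
    and per-population allele frequencies plus the sweep list.
    """
    if not (0 <= fst < 1):
        raise ValueError("F must lie in [0, 1)")
    rng_pos, rng_freq, rng_geno, rng_sweep = _spawn_rngs(seed, 4)
    pops = list(pop_sizes)
    samples = [f"{p}_{i:03d}" for p in pops for i in range(pop_sizes[p])]
    populations = {s: s.rsplit("_", 1)[0] for s in samples}

    chroms, poss, codes_rows, freq_rows = [], [], [], []
    for chrom, length in chrom_lengths.items():
        pos = np.sort(rng_pos.choice(length, size=min(snps_per_chrom, length),
                                     replace=False))
        p_anc = rng_freq.uniform(*p_range, size=len(pos))
        block = np.empty((len(pos), len(samples)), dtype=np.int8)
        col = 0
        pop_freqs = {}
        for p in pops:
            npop = pop_sizes[p]
            if fst == 0:
                pf = p_anc.copy()
            else:
                a = p_anc * (1 - fst) / fst
                b = (1 - p_anc) * (1 - fst) / fst
                pf = rng_freq.beta(a, b)
            pop_freqs[p] = pf
            block[:, col:col + npop] = rng_geno.binomial(
                2, pf[:, None], size=(len(pos), npop)).astype(np.int8)
            col += npop
        # sweep injection overrides the target population inside the interval
        for sw in sweeps:
            if sw.chrom != chrom:
                continue
            in_sw = np.flatnonzero((pos >= sw.start) & (pos < sw.end))
            if in_sw.size == 0:
                continue
            off = 0
            for p in pops:
                if p == sw.target_pop:
                    break
                off += pop_sizes[p]
            npop = pop_sizes[sw.target_pop]
            roles = rng_sweep.choice(
                3, size=in_sw.size,
                p=[sw.fix_fraction, sw.singleton_fraction,
                   1 - sw.fix_fraction - sw.singleton_fraction])
            for v, role in zip(in_sw, roles):
                if role == 0:      # fixed for the alternate allele
                    block[v, off:off + npop] = 2
                    pop_freqs[sw.target_pop][v] = 1.0
                elif role == 1:    # singleton heterozygote
                    block[v, off:off + npop] = 0
                    carrier = rng_sweep.integers(npop)
                    block[v, off + carrier] = 1
                    pop_freqs[sw.target_pop][v] = 0.5 / npop
        chroms.append(np.repeat(chrom, len(pos)))
        poss.append(pos)
        codes_rows.append(block)
        fr = pd.DataFrame({"chrom": chrom, "pos": pos, "p_ancestral": p_anc})
        for p in pops:
            fr[f"p_{p}"] = pop_freqs[p]
        freq_rows.append(fr)

    gm = GenotypeMatrix(
        np.concatenate(chroms), np.concatenate(poss),
        np.repeat("A", sum(len(p) for p in poss)),
        np.repeat("T", sum(len(p) for p in poss)),
        np.vstack(codes_rows), samples, populations,
    )
    truth = {"snp_freqs": pd.concat(freq_rows, ignore_index=True),
             "sweeps": list(sweeps)}
    return gm, truth


def sim_coalescent(n: int, theta: float, n_reps: int, seed=0):
    """Neutral constant-size coalescent replicates with infinite-sites
    mutation; returns a list of 0/1 haplotype matrices (sites x n).

    Scaling: n haploid lineages, Ne = 1, per-lineage mutation rate theta/2 in
    coalescent time units, so E[S] = theta * a1 and E[pi_hat] = theta.
    """
    if n < 2 or theta <= 0:
        raise ValueError("need n >= 2 and theta > 0")
    rng = np.random.default_rng(seed)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seeds = rng.integers(1, 2**31 - 1, size=n_reps)
    reps = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1, sequence_length=1,
        num_replicates=n_reps, random_seed=anc_seed)
    out = []
    for ts, ms in zip(reps, mut_seeds):
        mts = msprime.sim_mutations(
            ts, rate=theta / 2.0, random_seed=int(ms),
            model=msprime.BinaryMutationModel(), discrete_genome=False)
        out.append(mts.genotype_matrix())
    return out


def sim_expression(n_genes=2000, reps_per_cell=5, hp_fraction=0.3,
                   effect_log2fc=2.0, dispersion=0.1,
                   baseline_log_mean=np.log(200.0), baseline_log_sd=1.0,
                   seed=0):
    """NB counts for the 2x2 (population of origin x habitat) design.

    HP genes respond to habitat in BOTH populations (same sign and magnitude
    ``effect_log2fc``); LP genes respond in one population (half of them) or
    neither. Returns (counts genes x samples, metadata, truth labels).
    """
    if reps_per_cell < 2:
        raise ValueError("need >= 2 replicates per design cell")
    rng_base, rng_fx, rng_counts, rng_sf = _spawn_rngs(seed, 4)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    meta_rows = []
    for popo in ("N", "S"):
        for hab in ("n", "s"):
            for r in range(1, reps_per_cell + 1):
                meta_rows.append({"sample": f"{popo}{hab}{r}",
                                  "population": popo, "habitat": hab,
                                  "replicate": r})
    meta = pd.DataFrame(meta_rows)
    base = rng_base.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)

    n_hp = int(round(hp_fraction * n_genes))
    labels = np.array(["HP"] * n_hp + ["LP"] * (n_genes - n_hp))
    sign = rng_fx.choice((-1.0, 1.0), size=n_genes)
    eff = {"N": np.zeros(n_genes), "S": np.zeros(n_genes)}
    eff["N"][:n_hp] = sign[:n_hp] * effect_log2fc
    eff["S"][:n_hp] = sign[:n_hp] * effect_log2fc
    lp_idx = np.arange(n_hp, n_genes)
    lp_single = lp_idx[rng_fx.random(len(lp_idx)) < 0.5]
    which = rng_fx.choice((0, 1), size=len(lp_single))
    for i, w in zip(lp_single, which):
        eff["N" if w == 0 else "S"][i] = sign[i] * effect_log2fc

    sf = rng_sf.uniform(0.7, 1.3, size=len(meta))
    counts = np.empty((n_genes, len(meta)), dtype=np.int64)
    r_nb = 1.0 / dispersion
    for j, row in meta.iterrows():
        mu = base * np.where(row["habitat"] == "s",
                             2.0 ** eff[row["population"]], 1.0) * sf[j]
        counts[:, j] = rng_counts.negative_binomial(r_nb, r_nb / (r_nb + mu))
    counts = pd.DataFrame(counts, index=genes, columns=meta["sample"])
    truth = pd.DataFrame({"label": labels, "effect_N": eff["N"],
                          "effect_S": eff["S"]}, index=genes)
    return counts, meta, truth


def sim_kmer_spectrum(genome_size=5_000_000, depth=60, error_rate=0.01,
                      het_fraction=0.02, het_depth=None, seed=0, noise=True):
    """Two-peak diploid k-mer spectrum with known genome size.

    Components (negative-binomial-shaped, mode pinned at the nominal depth):
    an error spike at depths 1-5, a heterozygous peak at ``het_depth``
    (default depth/2) and a homozygous peak at ``depth``. Total non-error
    k-mer mass equals genome_size x depth, so G = K_num/hom-peak recovers the
    truth. Returns (KmerSpectrum, truth dict).
    """
    from scipy.stats import nbinom

    if depth <= 5 or genome_size <= 0:
        raise ValueError("need depth > 5 and genome_size > 0")
    if het_depth is None:
        het_depth = depth / 2.0
    rng = np.random.default_rng(seed)
    grid = np.arange(1, int(2.5 * depth) + 1)

    def peak_pmf(mean):
        r = 4.0 * mean
        adj = mean * r / (r - 1.0)        # pins the NB mode at `mean`
        p = r / (r + adj)
        pmf = nbinom.pmf(grid, r, p)
        return pmf / pmf.sum()

    n_het = 2.0 * genome_size * het_fraction * (depth / 2.0) / het_depth
    n_hom = (genome_size * depth - n_het * het_depth) / depth
    expected = n_hom * peak_pmf(depth) + n_het * peak_pmf(het_depth)
    # pin total non-error mass to exactly G x depth
    expected *= genome_size * depth / np.sum(grid * expected)
    err_mass = error_rate * genome_size * depth
    if err_mass > 0:
        w = 0.3 ** np.arange(5, dtype=float)
        err_counts = err_mass * w / np.sum(w * grid[:5])
        expected[:5] += err_counts
    counts = rng.poisson(expected).astype(float) if noise else expected
    spectrum = KmerSpectrum(grid, counts)
    truth = {"genome_size": float(genome_size), "depth": float(depth),
             "het_depth": float(het_depth), "error_rate": float(error_rate)}
    return spectrum, truth


def sim_gene_models(chrom_lengths: dict, n_genes_per_chrom=20, gene_length=2000,
                    min_gap=6000, seed=0):
    """Toy non-overlapping gene models with random strands (for the gene
    annotation and region-partition stages)."""
    rng = np.random.default_rng(seed)
    genes = []
    i = 0
    for chrom, length in chrom_lengths.items():
        slot = length // n_genes_per_chrom
        if slot < gene_length + min_gap:
            raise ValueError("chromosome too short for the requested gene layout")
        for g in range(n_genes_per_chrom):
            start = g * slot + int(rng.integers(min_gap // 2,
                                                slot - gene_length - min_gap // 2))
            genes.append(GeneModel(f"gene{i:05d}", chrom, start,
                                   start + gene_length,
                                   "+" if rng.random() < 0.5 else "-"))
            i += 1
    return genes
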