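"""End-to-end pipeline: simulate -> filter -> windowed stats -> sweep scan ->
heterozygosity classification -> plasticity analysis -> k-mer sizing.

Plain files plus a JSON manifest (config hash, seed, output checksums) keep
runs reproducible and each stage re-entrant; no workflow engine.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from . import het_classify, kmer_size, plasticity_divergence as pdiv
from . import popgen_stats, sweep_scan, synthetic_data

REQUIRED_BLOCKS = ("seed", "genotypes", "window")


def demo_config():
    """A small configuration that runs end-to-end in well under a minute."""
    return {
        "seed": 1,
        "genotypes": {
            "pop_sizes": {"NC": 12, "MC": 12, "SC": 12},
            "chrom_lengths": {"chr1": 600_000, "chr2": 600_000},
            "snps_per_chrom": 1200,
            "fst": 0.15,
            "sweeps": [
                {"chrom": "chr1", "start": 250_000, "end": 300_000,
                 "target_pop": "SC"},
            ],
        },
        "window": {"size": 100_000, "step": 10_000},
        "scan": {"pairs": [["NC", "SC"], ["MC", "SC"]], "q": 0.99,
                 "valley_q": 0.05, "max_gap": 10_000},
        "het": {"pop_a": "NC", "pop_b": "SC"},
        "genes": {"n_genes_per_chrom": 12},
        "expression": {"n_genes": 400, "reps_per_cell": 5, "hp_fraction": 0.3,
                       "effect_log2fc": 2.0, "alpha": 0.01, "flank": 5000},
        "kmer": {"genome_size": 2_000_000, "depth": 60, "error_rate": 0.01},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> None:
    for block in REQUIRED_BLOCKS:
        if block not in config:
            raise ValueError(f"config missing required block: {block!r}")
    for key in ("pop_sizes", "chrom_lengths", "snps_per_chrom"):
        if key not in config["genotypes"]:
            raise ValueError(f"config missing required field: genotypes.{key!r}")


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31 - 1)
    outputs = {}

    # --- genotypes -----------------------------------------------------
    g = config["genotypes"]
    sweeps = [synthetic_data.Sweep(**sw) for sw in g.get("sweeps", [])]
    gm, truth = synthetic_data.sim_genotypes(
        g["pop_sizes"], g["chrom_lengths"], g["snps_per_chrom"],
        fst=g.get("fst", 0.15), sweeps=sweeps, seed=int(seeds[0]))
    vcf = outdir / "genotypes.vcf"
    eio.write_vcf(gm, vcf, contig_lengths=g["chrom_lengths"])
    truth["snp_freqs"].to_csv(outdir / "truth_snp_freqs.tsv", sep="\t", index=False)
    outputs["vcf"] = vcf
    outputs["truth_snp_freqs"] = outdir / "truth_snp_freqs.tsv"

    genes = []
    if "genes" in config:
        genes = synthetic_data.sim_gene_models(
            g["chrom_lengths"], seed=int(seeds[1]),
            **{k: v for k, v in config["genes"].items()})
        gff = outdir / "genes.gff3"
        eio.write_gff3_genes(genes, gff)
        outputs["gff3"] = gff

    # --- filtering + windowed statistics -------------------------------
    gm_f = eio.filter_snps(gm, maf_min=config.get("maf_min", 0.05),
                           call_rate_min=config.get("call_rate_min", 0.8))
    w = config["window"]
    stats = popgen_stats.windowed_stats(
        gm_f, g["chrom_lengths"], size=w.get("size", 100_000),
        step=w.get("step", 10_000))
    stats_path = outdir / "window_stats.tsv"
    stats.to_csv(stats_path, sep="\t", index=False)
    outputs["window_stats"] = stats_path

    # --- sweep scan -----------------------------------------------------
    if "scan" in config:
        sc = config["scan"]
        pairs = [tuple(p) for p in sc["pairs"]]
        regions, diag = sweep_scan.scan(
            stats, pairs=pairs, pops=list(g["pop_sizes"]), genes=genes,
            q=sc.get("q", 0.99), valley_q=sc.get("valley_q", 0.05),
            max_gap=sc.get("max_gap", w.get("step", 10_000)))
        bed = outdir / "sweep_regions.bed"
        eio.write_bed([(r.chrom, r.start, r.end) for r in regions], bed)
        reg = pd.DataFrame([
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "n_windows": len(r.windows),
             "valley_pops": ",".join(sorted(r.valley_pops)),
             "genes": ",".join(r.genes)} for r in regions])
        reg.to_csv(outdir / "sweep_regions.tsv", sep="\t", index=False)
        outputs["sweep_bed"] = bed
        outputs["sweep_regions"] = outdir / "sweep_regions.tsv"

    # --- exclusive heterozygosity ---------------------------------------
    if "het" in config:
        h = config["het"]
        cls = het_classify.classify_exclusive_het(gm_f, h["pop_a"], h["pop_b"])
        counts = het_classify.exclusive_counts_by_chrom(cls)
        fold = het_classify.exclusive_fold_ratio(counts["A_only"], counts["B_only"])
        counts.to_csv(outdir / "exclusive_het_counts.tsv", sep="\t", index=False)
        (outdir / "exclusive_het_fold.txt").write_text(f"{fold}\n")
        outputs["het_counts"] = outdir / "exclusive_het_counts.tsv"
        outputs["het_fold"] = outdir / "exclusive_het_fold.txt"

    # --- plasticity vs divergence ---------------------------------------
    if "expression" in config:
        e = config["expression"]
        counts, meta, truth_expr = synthetic_data.sim_expression(
            n_genes=e.get("n_genes", 400),
            reps_per_cell=e.get("reps_per_cell", 5),
            hp_fraction=e.get("hp_fraction", 0.3),
            effect_log2fc=e.get("effect_log2fc", 2.0),
            seed=int(seeds[2]))
        counts.to_csv(outdir / "expression_counts.tsv", sep="\t")
        meta.to_csv(outdir / "expression_meta.tsv", sep="\t", index=False)
        expressed = pdiv.filter_expressed(counts)
        sub = counts.loc[expressed]
        de = {}
        for popo in ("N", "S"):
            a = meta.query("population == @popo and habitat == 'n'")["sample"]
            b = meta.query("population == @popo and habitat == 's'")["sample"]
            de[popo] = pdiv.de_test(sub, list(a), list(b))
        labels = pdiv.classify_hp_lp(de["N"], de["S"], alpha=e.get("alpha", 0.01))
        labels.to_csv(outdir / "hp_lp_labels.tsv", sep="\t")
        outputs["hp_lp_labels"] = outdir / "hp_lp_labels.tsv"
        if genes and "het" in config:
            fst = popgen_stats.site_fst(gm_f, config["het"]["pop_a"],
                                        config["het"]["pop_b"])
            parts = [pdiv.partition_regions(
                gn, flank=e.get("flank", 5000),
                chrom_length=g["chrom_lengths"][gn.chrom]) for gn in genes]
            rf = pdiv.region_fst(parts, fst)
            rf.to_csv(outdir / "gene_region_fst.tsv", sep="\t")
            outputs["gene_region_fst"] = outdir / "gene_region_fst.tsv"

    # --- k-mer genome size -----------------------------------------------
    if "kmer" in config:
        k = config["kmer"]
        spectrum, ktruth = synthetic_data.sim_kmer_spectrum(
            genome_size=k.get("genome_size", 2_000_000),
            depth=k.get("depth", 60), error_rate=k.get("error_rate", 0.01),
            seed=int(seeds[3]))
        spectrum.to_tsv(outdir / "kmer_spectrum.tsv")
        cut, het, hom = kmer_size.detect_peaks(spectrum)
        est = kmer_size.genome_size(spectrum, error_cutoff=cut, hom_peak=hom)
        pd.DataFrame([{"error_cutoff": cut, "het_peak": het, "hom_peak": hom,
                       "genome_size_estimate": est,
                       "genome_size_true": ktruth["genome_size"]}]).to_csv(
            outdir / "kmer_size.tsv", sep="\t", index=False)
        outputs["kmer_size"] = outdir / "kmer_size.tsv"

    # --- manifest ---------------------------------------------------------
    cfg_json = json.dumps(config, sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "outputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                    for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
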