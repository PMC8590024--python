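"""Reading/writing the standard formats the pipeline touches and the variant filters.

Coordinate conventions: VCF is 1-based on disk; everything in memory is
0-based half-open; BED is emitted natively (0-based half-open). Conversions
happen only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger("estuarscan")

#: genotype code for a missing (uncalled) diploid genotype
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for a cohort of samples drawn from labelled populations.

    Genotype codes per variant per sample: 0 = hom-ref, 1 = het, 2 = hom-alt,
    ``MISSING`` (-1) = uncalled. Positions are 0-based.
    """

    chrom: np.ndarray          # (V,) chromosome id per variant
    pos: np.ndarray            # (V,) int64, 0-based
    ref: np.ndarray            # (V,) reference allele
    alt: np.ndarray            # (V,) alternate allele
    codes: np.ndarray          # (V, S) int8
    samples: list
    populations: dict = field(default_factory=dict)   # sample -> population label

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pop_labels(self) -> list:
        seen = []
        for s in self.samples:
            p = self.populations.get(s)
            if p is not None and p not in seen:
                seen.append(p)
        return seen

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.populations.get(s) == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"unknown or empty population: {population!r}")
        return idx

    def validate(self) -> None:
        if self.codes.shape != (self.n_variants, self.n_samples):
            raise ValueError("codes shape does not match variants x samples")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("invalid genotype codes present")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        pops = {self.populations.get(s) for s in self.samples}
        if None in pops:
            raise ValueError("population labels do not cover all samples")

    def take_variants(self, mask_or_index) -> "GenotypeMatrix":
        m = np.asarray(mask_or_index)
        if m.dtype == bool:
            m = np.flatnonzero(m)
        return GenotypeMatrix(
            self.chrom[m], self.pos[m], self.ref[m], self.alt[m],
            self.codes[m], list(self.samples), dict(self.populations),
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open) with a strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")


def _code_from_gt(gt, alt_index=1):
    if gt is None or any(a is None for a in gt):
        return MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    n_other = sum(1 for a in gt if a not in (0, alt_index))
    if n_other:
        return MISSING
    return n_alt


def read_vcf(path, population_map, multiallelic="skip", on_unmapped="drop"):
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    population_map : dict
        sample id -> population label. Samples absent from the map are
        dropped (``on_unmapped='drop'``) or raise (``'error'``).
    multiallelic : {'skip', 'split'}
        Multi-allelic records are skipped by default; ``'split'`` emits one
        biallelic row per alternate allele.
    """
    if multiallelic not in ("skip", "split"):
        raise ValueError("multiallelic must be 'skip' or 'split'")
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    unmapped = [s for s in vcf_samples if s not in population_map]
    if unmapped:
        if on_unmapped == "error":
            raise ValueError(f"samples missing from population map: {unmapped}")
        log.warning("dropping %d samples absent from population map", len(unmapped))
    samples = [s for s in vcf_samples if s in population_map]
    if not samples:
        raise ValueError("no VCF sample is covered by the population map")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped_multi = 0
    for rec in vf:
        rec_alts = rec.alts or ()
        if len(rec_alts) != 1:
            if multiallelic == "skip" or len(rec_alts) == 0:
                n_skipped_multi += 1
                continue
            alt_indices = range(1, len(rec_alts) + 1)
        else:
            alt_indices = (1,)
        for ai in alt_indices:
            try:
                row = [_code_from_gt(rec.samples[s].get("GT"), ai) for s in samples]
            except Exception as e:  # pragma: no cover - defensive
                raise ValueError(f"malformed VCF record at {rec.chrom}:{rec.pos}: {e}")
            chroms.append(rec.chrom)
            poss.append(rec.pos - 1)          # VCF 1-based -> internal 0-based
            refs.append(rec.ref)
            alts.append(rec_alts[ai - 1])
            rows.append(row)
    vf.close()
    if n_skipped_multi:
        log.info("skipped %d non-biallelic records (multiallelic=%s)",
                 n_skipped_multi, multiallelic)
    codes = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, len(samples)), dtype=np.int8))
    gm = GenotypeMatrix(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object),
        codes, samples, {s: population_map[s] for s in samples},
    )
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths=None) -> None:
    """Write a GT-only VCF 4.2 file (1-based positions on disk)."""
    chrom_order = list(pd.unique(gm.chrom))
    if contig_lengths is None:
        contig_lengths = {}
        for c in chrom_order:
            p = gm.pos[gm.chrom == c]
            contig_lengths[c] = int(p.max()) + 1 if p.size else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=estuarscan\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_variants):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.codes[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def apply_hard_filters(annotations: pd.DataFrame, mode="snp", on_missing="fail"):
    """GATK-style hard filtering: a variant *fails* iff any removal clause fires.

    SNP mode removes on QD < 2.0 or FS > 60.0 or MQ < 40.0; indel mode uses
    only the QD and FS clauses. Returns a boolean Series, True = pass.
    """
    if mode not in ("snp", "indel"):
        raise ValueError("mode must be 'snp' or 'indel'")
    if on_missing not in ("fail", "pass"):
        raise ValueError("on_missing must be 'fail' or 'pass'")
    needed = ["QD", "FS"] + (["MQ"] if mode == "snp" else [])
    for col in needed:
        if col not in annotations.columns:
            raise ValueError(f"annotation column {col!r} absent")
        vals = pd.to_numeric(annotations[col], errors="coerce")
        bad = vals.isna() & annotations[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric {col} annotation for variant(s) {list(annotations.index[bad])[:5]}")
    qd = pd.to_numeric(annotations["QD"], errors="coerce")
    fs = pd.to_numeric(annotations["FS"], errors="coerce")
    fails = (qd < 2.0) | (fs > 60.0)
    missing = qd.isna() | fs.isna()
    if mode == "snp":
        mq = pd.to_numeric(annotations["MQ"], errors="coerce")
        fails = fails | (mq < 40.0)
        missing = missing | mq.isna()
    passes = ~fails
    if on_missing == "fail":
        passes &= ~missing
    return passes


def allele_counts(gm: GenotypeMatrix, sample_idx=None):
    """Per-variant (alt allele count, called allele count) over the given samples."""
    codes = gm.codes if sample_idx is None else gm.codes[:, sample_idx]
    called = codes != MISSING
    alt = np.where(called, codes, 0).sum(axis=1)
    n = 2 * called.sum(axis=1)
    return alt.astype(np.int64), n.astype(np.int64)


def filter_snps(gm: GenotypeMatrix, maf_min=0.05, call_rate_min=0.8) -> GenotypeMatrix:
    """Retain variants with MAF strictly > ``maf_min`` (alleles pooled over all
    samples) and genotype call rate strictly > ``call_rate_min``."""
    if gm.n_variants == 0:
        return gm
    alt, n = allele_counts(gm)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    call_rate = (gm.codes != MISSING).mean(axis=1)
    keep = (maf > maf_min) & (call_rate > call_rate_min) & (n > 0)
    if not keep.any():
        log.warning("filter_snps removed every variant")
    return gm.take_variants(keep)


def write_bed(regions, path) -> None:
    """Write BED3(+name) lines, 0-based half-open, sorted by (chrom, start)."""
    rows = []
    for r in regions:
        if isinstance(r, (tuple, list)):
            rows.append(tuple(r))
        else:  # object with chrom/start/end
            name = getattr(r, "gene_id", None) or getattr(r, "name", None)
            rows.append((r.chrom, r.start, r.end) + ((name,) if name else ()))
    rows.sort(key=lambda t: (str(t[0]), int(t[1])))
    with open(path, "w") as fh:
        for t in rows:
            if int(t[1]) >= int(t[2]):
                raise ValueError(f"invalid BED interval: {t}")
            fh.write("\t".join(str(x) for x in t) + "\n")


def read_gff3_genes(path):
    """Read gene features from a GFF3 file into a list of :class:`GeneModel`.

    Only ``type == gene`` rows are consumed; GFF3 1-based inclusive
    coordinates are converted to 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str, "attributes": str},
    )
    df = df[df["type"] == "gene"]
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    if ids.isna().any():
        raise ValueError("gene feature without an ID attribute")
    if ids.duplicated().any():
        raise ValueError("duplicate gene IDs in GFF3")
    return [
        GeneModel(gene_id=i, chrom=c, start=int(s) - 1, end=int(e), strand=st)
        for i, c, s, e, st in zip(ids, df["chrom"], df["start"], df["end"], df["strand"])
    ]


def write_gff3_genes(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\testuarscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def read_effect_table(path) -> pd.DataFrame:
    """Read a SNP functional-effect TSV: chrom, pos (1-based), ref, alt,
    effect in {synonymous, nonsynonymous, other}, gene_id. Position is
    converted to the internal 0-based convention."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"chrom", "pos", "ref", "alt", "effect", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    bad = ~df["effect"].isin(["synonymous", "nonsynonymous", "other"])
    if bad.any():
        raise ValueError(f"invalid effect classes: {df.loc[bad, 'effect'].unique()}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    key = df[["chrom", "pos", "ref", "alt"]].astype(str).agg(":".join, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate variant keys in effect table")
    return df
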