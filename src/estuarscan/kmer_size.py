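"""k-mer-spectrum genome-size estimation and small comparative-genomics utilities.

A diploid k-mer depth histogram shows an error spike at very low depth, a
heterozygous single-copy peak near half the sequencing depth and a homozygous
single-copy peak at the sequencing depth. Genome size follows
G = K_num / homozygous-peak depth, where K_num is the total k-mer mass above
the error cutoff. Also provided: the k-selection rule (smallest odd k with
4^k / G > 200), C-value proportional scaling between species, and the
divergence-time formula T = Ks / (2 mu).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class KmerSpectrum:
    """Depth -> k-mer count histogram (depths ascending, >= 1)."""

    depth: np.ndarray
    count: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=float)
        if len(self.depth) != len(self.count):
            raise ValueError("depth and count lengths differ")
        if np.any(np.diff(self.depth) <= 0) or (len(self.depth) and self.depth[0] < 1):
            raise ValueError("depths must be ascending integers >= 1")
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["depth", "count"])
        return cls(df["depth"].to_numpy(), df["count"].to_numpy())

    def to_tsv(self, path):
        with open(path, "w") as fh:
            for d, c in zip(self.depth, self.count):
                fh.write(f"{int(d)}\t{int(round(c))}\n")


def choose_k(genome_size_prior: float) -> int:
    """Smallest odd k with 4^k / G strictly > 200."""
    if genome_size_prior <= 0:
        raise ValueError("genome size prior must be positive")
    k = 1
    while not 4**k > 200 * genome_size_prior:
        k += 2
    return k


def _smooth(counts, width=3):
    """Centered moving average; edges use the available part of the window."""
    kernel = np.ones(width)
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return num / den


def detect_peaks(spectrum: KmerSpectrum, smooth_width=3, single_peak=False):
    """(error_cutoff_depth, het_peak_depth, hom_peak_depth) from the smoothed
    spectrum.

    The error cutoff is the first local minimum; the peaks are the two
    largest local maxima above the cutoff (ties broken toward lower depth),
    ordered so the homozygous peak is the deeper. With ``single_peak`` a
    unimodal spectrum yields (cutoff, None, peak).
    """
    d, s = spectrum.depth, _smooth(spectrum.count, smooth_width)
    if len(d) < 5:
        raise ValueError("spectrum too short for peak detection")
    cutoff_i = None
    for i in range(1, len(s) - 1):
        if s[i] <= s[i - 1] and s[i] < s[i + 1]:
            cutoff_i = i
            break
    if cutoff_i is None:
        raise ValueError("no error-region local minimum found")
    maxima = []
    for i in range(cutoff_i + 1, len(s) - 1):
        if s[i] > s[i - 1] and s[i] >= s[i + 1]:
            maxima.append((s[i], int(d[i])))
    maxima.sort(key=lambda t: (-t[0], t[1]))
    if len(maxima) < 2:
        if single_peak and maxima:
            return int(d[cutoff_i]), None, maxima[0][1]
        raise ValueError(
            f"found {len(maxima)} peak(s) above the error cutoff; a diploid "
            "spectrum needs a heterozygous and a homozygous peak "
            "(pass single_peak=True for haploid-like spectra)")
    top = sorted(maxima[:2], key=lambda t: t[1])
    return int(d[cutoff_i]), top[0][1], top[1][1]


def genome_size(spectrum: KmerSpectrum, error_cutoff=None, hom_peak=None) -> float:
    """G = K_num / hom-peak depth with K_num the total k-mer mass
    (sum of depth x count) at depths strictly above the error cutoff."""
    if error_cutoff is None or hom_peak is None:
        cut, _het, hom = detect_peaks(spectrum)
        error_cutoff = cut if error_cutoff is None else error_cutoff
        hom_peak = hom if hom_peak is None else hom_peak
    if error_cutoff >= hom_peak:
        raise ValueError("error cutoff at or beyond the homozygous peak")
    above = spectrum.depth > error_cutoff
    k_num = float(np.sum(spectrum.depth[above] * spectrum.count[above]))
    return k_num / hom_peak


def c_value_scale(g_ref_mb: float, c_ref_pg: float, c_target_pg: float) -> float:
    """Scale a reference genome size (Mb) by the C-value ratio of the target
    to the reference species; reported to 1 decimal."""
    if min(g_ref_mb, c_ref_pg, c_target_pg) <= 0:
        raise ValueError("all inputs must be positive")
    return round(g_ref_mb * c_target_pg / c_ref_pg, 1)


def divergence_time(ks: float, mu: float) -> float:
    """T = Ks / (2 mu), in years when mu is per site per year."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * mu)
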