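"""Windowed and per-site population-genetic statistics.

Nucleotide diversity (pi), Watterson's theta, Tajima's D, the Hudson/Bhatia
ratio-of-sums FST estimator, and genotype-dosage LD (r^2) with a decay curve.

All window coordinates are 0-based half-open. Per-bp statistics divide window
sums by the window length L; Tajima's D uses window *sums* of per-site mean
pairwise differences, as the statistic is defined on counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LdDecayCurve:
    """Mean r^2 per distance bin; bins are left-closed and contiguous."""

    bin_left: np.ndarray
    bin_right: np.ndarray
    mean_r2: np.ndarray    # nan for empty bins
    n_pairs: np.ndarray


def sliding_windows(chrom_length, chrom="chr", size=100_000, step=10_000,
                    full_only=True):
    """Sliding windows starting at 0, ``step`` apart.

    With ``full_only`` (the default) only windows fully inside the chromosome
    are returned; otherwise trailing windows are truncated at the chromosome
    end.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    windows = []
    start = 0
    while start < chrom_length:
        end = start + size
        if end <= chrom_length:
            windows.append(Window(chrom, start, end))
        elif not full_only:
            windows.append(Window(chrom, start, int(chrom_length)))
        else:
            break
        start += step
    if full_only and chrom_length < size:
        warnings.warn(f"chromosome shorter than window size ({chrom_length} < {size})")
    return windows


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalizing constants for n sampled alleles."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


# ---------------------------------------------------------------------------
# per-site building blocks

def _window_mask(gm: GenotypeMatrix, window: Window) -> np.ndarray:
    return (gm.chrom == window.chrom) & (gm.pos >= window.start) & (gm.pos < window.end)


def _site_counts(codes: np.ndarray):
    """(alt allele count, called allele count) per site for a code block."""
    called = codes != MISSING
    alt = np.where(called, codes, 0).sum(axis=1).astype(np.int64)
    n = (2 * called.sum(axis=1)).astype(np.int64)
    return alt, n


def _pairwise_site_pi(alt, n):
    """Per-site mean pairwise difference 2x(n-x)/(n(n-1)); 0 where n < 2."""
    out = np.zeros(len(alt), dtype=float)
    ok = n >= 2
    x = alt[ok].astype(float)
    ns = n[ok].astype(float)
    out[ok] = 2.0 * x * (ns - x) / (ns * (ns - 1.0))
    return out


def _window_subset(gm, window, population, min_call_rate=0.9):
    """Window site codes restricted to population samples whose within-window
    call rate is >= ``min_call_rate`` (the sample set Tajima's D is computed
    on). Returns (codes, n_alleles) or (None, 0) when no usable samples."""
    idx = gm.pop_indices(population)
    mask = _window_mask(gm, window)
    codes = gm.codes[np.ix_(mask, idx)]
    if codes.shape[0] == 0:
        return codes, 2 * len(idx)
    call_rate = (codes != MISSING).mean(axis=0)
    keep = call_rate >= min_call_rate
    if not keep.any():
        return None, 0
    return codes[:, keep], 2 * int(keep.sum())


def window_pi(gm: GenotypeMatrix, window: Window, population: str) -> float:
    """Per-bp nucleotide diversity over the window (sites with <2 called
    alleles are skipped; a monomorphic window returns 0)."""
    idx = gm.pop_indices(population)
    codes = gm.codes[np.ix_(_window_mask(gm, window), idx)]
    alt, n = _site_counts(codes)
    return float(_pairwise_site_pi(alt, n).sum()) / window.length


def window_theta_w(gm: GenotypeMatrix, window: Window, population: str) -> float:
    """Per-bp Watterson estimator (S / a1) / L with n from the window-level
    call-rate rule."""
    codes, n = _window_subset(gm, window, population)
    if codes is None or n < 2:
        return math.nan
    alt, ns = _site_counts(codes)
    S = int(np.sum((alt > 0) & (alt < ns)))
    if S == 0:
        return 0.0
    a1 = tajima_constants(n)["a1"]
    return (S / a1) / window.length


def tajimas_d(gm: GenotypeMatrix, window: Window, population: str) -> float:
    """Tajima's D over the window; nan when S = 0 or fewer than 4 alleles."""
    codes, n = _window_subset(gm, window, population)
    if codes is None or n < 4:
        return math.nan
    alt, ns = _site_counts(codes)
    S = int(np.sum((alt > 0) & (alt < ns)))
    pi_hat = float(_pairwise_site_pi(alt, ns).sum())
    return _tajima_d_from_sums(S, pi_hat, n)


def _tajima_d_from_sums(S: int, pi_hat: float, n: int) -> float:
    if S == 0 or n < 4:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_hat - S / c["a1"]) / math.sqrt(var)


def _hudson_site_terms(alt1, n1, alt2, n2):
    """Per-site Hudson/Bhatia numerator and denominator with a validity mask.

    Sites need >= 2 called alleles in each population and must be polymorphic
    in at least one of the two populations.
    """
    ok = (n1 >= 2) & (n2 >= 2)
    p1 = np.divide(alt1, n1, out=np.zeros(len(alt1)), where=n1 > 0)
    p2 = np.divide(alt2, n2, out=np.zeros(len(alt2)), where=n2 > 0)
    mono_both = ((alt1 == 0) & (alt2 == 0)) | ((alt1 == n1) & (alt2 == n2))
    ok &= ~mono_both
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    return num, den, ok


def hudson_fst(gm: GenotypeMatrix, window: Window, pop_a: str, pop_b: str):
    """Window Hudson/Bhatia FST as a ratio of sums.

    Returns (fst, sum_numerator, sum_denominator); fst is nan when no site
    contributes. Negative values are reported as computed.
    """
    mask = _window_mask(gm, window)
    ia, ib = gm.pop_indices(pop_a), gm.pop_indices(pop_b)
    alt1, n1 = _site_counts(gm.codes[np.ix_(mask, ia)])
    alt2, n2 = _site_counts(gm.codes[np.ix_(mask, ib)])
    num, den, _ = _hudson_site_terms(alt1, n1, alt2, n2)
    sn, sd = float(num.sum()), float(den.sum())
    return (sn / sd if sd > 0 else math.nan), sn, sd


def site_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-site Hudson FST (single-site ratio N_i/D_i); nan where undefined."""
    ia, ib = gm.pop_indices(pop_a), gm.pop_indices(pop_b)
    alt1, n1 = _site_counts(gm.codes[:, ia])
    alt2, n2 = _site_counts(gm.codes[:, ib])
    num, den, ok = _hudson_site_terms(alt1, n1, alt2, n2)
    fst = np.full(gm.n_variants, np.nan)
    good = ok & (den > 0)
    fst[good] = num[good] / den[good]
    return pd.DataFrame({"chrom": gm.chrom, "pos": gm.pos, "fst": fst})


def haplotype_stats(H: np.ndarray):
    """(S, pi_hat, Tajima's D) from a 0/1 haplotype matrix (sites x samples)."""
    H = np.asarray(H)
    n = H.shape[1]
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    x = H.sum(axis=1)
    seg = (x > 0) & (x < n)
    S = int(seg.sum())
    pi_hat = float((2.0 * x * (n - x) / (n * (n - 1.0))).sum())
    return S, pi_hat, _tajima_d_from_sums(S, pi_hat, n)


# ---------------------------------------------------------------------------
# windowed scan (vectorized over the window grid via prefix sums)

def windowed_stats(gm: GenotypeMatrix, chrom_lengths: dict, pops=None, pairs=None,
                   size=100_000, step=10_000, full_only=True) -> pd.DataFrame:
    """Per-window statistics for every population and population pair.

    Returns a wide DataFrame with one row per window and columns
    ``S_<pop>, pi_<pop>, theta_<pop>, D_<pop>`` plus
    ``fst_<a>_<b>, fstnum_<a>_<b>, fstden_<a>_<b>`` per pair.

    The fast path assumes complete genotypes in a population; with missing
    data the per-window call-rate rule is applied through the slower
    per-window functions.
    """
    pops = list(pops) if pops is not None else gm.pop_labels
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    rows = []
    for chrom, length in chrom_lengths.items():
        windows = sliding_windows(length, chrom=chrom, size=size, step=step,
                                  full_only=full_only)
        if not windows:
            continue
        cmask = gm.chrom == chrom
        pos = gm.pos[cmask]
        starts = np.array([w.start for w in windows])
        ends = np.array([w.end for w in windows])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        L = ends - starts

        block = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "L": L})
        pop_counts = {}
        for p in pops:
            idx = gm.pop_indices(p)
            codes = gm.codes[np.ix_(cmask, idx)]
            alt, n = _site_counts(codes)
            pop_counts[p] = (alt, n)
            pi_site = _pairwise_site_pi(alt, n)
            seg = ((alt > 0) & (alt < n)).astype(np.int64)
            cpi = np.concatenate([[0.0], np.cumsum(pi_site)])
            cs = np.concatenate([[0], np.cumsum(seg)])
            S = cs[hi] - cs[lo]
            pi_sum = cpi[hi] - cpi[lo]
            if not (codes == MISSING).any():
                nal = 2 * len(idx)
                c = tajima_constants(nal) if nal >= 2 else None
                theta = np.where(S > 0, (S / c["a1"]) / L, 0.0)
                D = np.array([_tajima_d_from_sums(int(s), ph, nal)
                              for s, ph in zip(S, pi_sum)])
            else:
                theta = np.array([window_theta_w(gm, w, p) for w in windows])
                D = np.array([tajimas_d(gm, w, p) for w in windows])
            block[f"S_{p}"] = S
            block[f"pi_{p}"] = pi_sum / L
            block[f"theta_{p}"] = theta
            block[f"D_{p}"] = D
        for a, b in pairs:
            alt1, n1 = pop_counts[a]
            alt2, n2 = pop_counts[b]
            num, den, _ = _hudson_site_terms(alt1, n1, alt2, n2)
            cn = np.concatenate([[0.0], np.cumsum(num)])
            cd = np.concatenate([[0.0], np.cumsum(den)])
            sn = cn[hi] - cn[lo]
            sd = cd[hi] - cd[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                fst = np.where(sd > 0, sn / np.where(sd > 0, sd, 1.0), np.nan)
            block[f"fst_{a}_{b}"] = fst
            block[f"fstnum_{a}_{b}"] = sn
            block[f"fstden_{a}_{b}"] = sd
        rows.append(block)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "L"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# linkage disequilibrium

def ld_r2_pairs(gm: GenotypeMatrix, chromosome: str, max_dist=500_000,
                sample_idx=None):
    """All intra-chromosome locus pairs within ``max_dist``: (distance, r^2).

    r^2 is the squared Pearson correlation of genotype dosages across
    individuals (Rogers-Huff composite for unphased data), complete-case per
    pair; pairs monomorphic in the complete-case subset are skipped.
    """
    cmask = gm.chrom == chromosome
    pos = gm.pos[cmask]
    codes = gm.codes[cmask]
    if sample_idx is not None:
        codes = codes[:, sample_idx]
    dosage = codes.astype(float)
    dosage[codes == MISSING] = np.nan
    out = []
    V = len(pos)
    for i in range(V):
        for j in range(i + 1, V):
            d = int(pos[j] - pos[i])
            if d > max_dist:
                break
            both = ~np.isnan(dosage[i]) & ~np.isnan(dosage[j])
            if both.sum() < 2:
                continue
            x, y = dosage[i][both], dosage[j][both]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out.append((d, float(r * r)))
    return out


def ld_decay_curve(pairs, bin_width=100, max_dist=500_000) -> LdDecayCurve:
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for d, r2 in pairs:
        b = min(int(d // bin_width), n_bins - 1)
        if d <= max_dist:
            sums[b] += r2
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayCurve(edges[:-1], edges[1:], means, counts)


def ld_half_decay(curve: LdDecayCurve):
    """Midpoint of the first bin whose mean r^2 has dropped to half the
    maximum bin mean; None when the half level is never reached."""
    filled = ~np.isnan(curve.mean_r2)
    if filled.sum() < 2:
        raise ValueError("need at least two non-empty distance bins")
    half = np.nanmax(curve.mean_r2) / 2.0
    for left, right, m in zip(curve.bin_left, curve.bin_right, curve.mean_r2):
        if not np.isnan(m) and m <= half:
            return (int(left) + int(right)) / 2.0
    return None
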