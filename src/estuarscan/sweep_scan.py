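"""Composite selection-sweep detection.

The scan combines three signals computed on a shared sliding-window grid:
FST outliers (top quantile, default top 1%) in *both* population-pair
comparisons, intersected, then restricted to windows sitting in a Tajima's D
"valley" (a genome-wide lower quantile of the window D distribution) in at
least one population. Surviving windows are merged into regions and annotated
with overlapping genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen_stats import Window


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    windows: list = field(default_factory=list)          # member Windows
    valley_pops: set = field(default_factory=set)
    genes: list = field(default_factory=list)            # overlapping gene ids


def fst_outlier_threshold(window_fsts, q=0.99):
    """Empirical top-(1-q) threshold; windows with fst >= threshold are outliers.

    The threshold is the value ranked n - m in ascending order with
    m = max(floor(n*(1-q)), 1) so the "top 1%" is an exact count (ties at the
    threshold are all included).
    """
    vals = np.asarray(window_fsts, dtype=float)
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    if n == 0:
        raise ValueError("no finite FST values")
    if n < 100:
        warnings.warn(f"only {n} finite windows; a {1 - q:.0%} tail is noisy")
    m = max(int(np.floor(n * (1.0 - q))), 1)
    return float(np.sort(vals)[n - m])


def _wkey(w: Window):
    return (w.chrom, w.start, w.end)


def overlap_outliers(outliers_a, outliers_b):
    """Windows present in both outlier sets (same grid: identity intersection)."""
    sizes = {w.length for w in outliers_a} | {w.length for w in outliers_b}
    if len(sizes) > 1:
        raise ValueError("outlier sets come from mismatched window grids")
    keys_b = {_wkey(w) for w in outliers_b}
    return sorted((w for w in outliers_a if _wkey(w) in keys_b),
                  key=lambda w: (w.chrom, w.start))


def tajima_valley_filter(windows, window_stats: pd.DataFrame, pops,
                         valley_q=0.05):
    """Keep windows whose D is at or below the ``valley_q`` genome-wide
    quantile in at least one population; returns [(window, valley_pops)]."""
    if not (0 < valley_q < 1):
        raise ValueError("valley_q must lie in (0, 1)")
    thresholds = {}
    for p in pops:
        col = window_stats[f"D_{p}"].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"no finite Tajima's D values for population {p}")
        thresholds[p] = np.quantile(col, valley_q)
    lut = {(c, s, e): i for i, (c, s, e) in enumerate(
        zip(window_stats["chrom"], window_stats["start"], window_stats["end"]))}
    kept = []
    for w in windows:
        i = lut.get(_wkey(w))
        if i is None:
            raise KeyError(f"window {w} absent from the stats table")
        tags = {p for p in pops
                if np.isfinite(window_stats.at[i, f"D_{p}"])
                and window_stats.at[i, f"D_{p}"] <= thresholds[p]}
        if tags:
            kept.append((w, tags))
    return kept


def merge_and_annotate(tagged_windows, genes=(), max_gap=10_000):
    """Merge windows overlapping or within ``max_gap`` bp into maximal regions
    and attach genes overlapping each region by >= 1 bp.

    ``tagged_windows``: [(Window, valley_pop_set)] or plain Windows.
    """
    items = []
    for tw in tagged_windows:
        if isinstance(tw, Window):
            items.append((tw, set()))
        else:
            w, tags = tw
            items.append((w, set(tags)))
    items.sort(key=lambda wt: (wt[0].chrom, wt[0].start))
    regions = []
    for w, tags in items:
        if (regions and regions[-1].chrom == w.chrom
                and w.start - regions[-1].end <= max_gap):
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.windows.append(w)
            r.valley_pops |= tags
        else:
            regions.append(SweepRegion(w.chrom, w.start, w.end, [w], set(tags)))
    for r in regions:
        r.genes = sorted(g.gene_id for g in genes
                         if g.chrom == r.chrom and g.start < r.end and g.end > r.start)
    return regions


def scan(window_stats: pd.DataFrame, pairs, pops, genes=(), q=0.99,
         valley_q=0.05, max_gap=10_000):
    """Full composite scan on a window-stats table.

    ``pairs``: two (popA, popB) tuples, matching ``fst_<a>_<b>`` columns.
    Returns (regions, diagnostics dict with per-pair thresholds).
    """
    if len(pairs) != 2:
        raise ValueError("the scan is defined for exactly two population pairs")
    windows = [Window(c, int(s), int(e)) for c, s, e in
               zip(window_stats["chrom"], window_stats["start"], window_stats["end"])]
    outlier_sets, thresholds = [], {}
    for a, b in pairs:
        col = window_stats[f"fst_{a}_{b}"].to_numpy(dtype=float)
        thr = fst_outlier_threshold(col, q=q)
        thresholds[f"{a}_{b}"] = thr
        outlier_sets.append([w for w, v in zip(windows, col)
                             if np.isfinite(v) and v >= thr])
    shared = overlap_outliers(*outlier_sets)
    tagged = tajima_valley_filter(shared, window_stats, pops, valley_q=valley_q)
    regions = merge_and_annotate(tagged, genes=genes, max_gap=max_gap)
    return regions, {"fst_thresholds": thresholds,
                     "n_outliers_shared": len(shared),
                     "n_windows": len(windows)}
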