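"""Independent brute-force oracles used by the tests.

These deliberately re-derive every quantity from first principles (explicit
pair enumeration, literal constant formulas, plain loops) without touching
the library's implementations.
"""

import itertools
import math

import numpy as np

MISSING = -1


def alleles_at_site(codes_row):
    """Expand diploid codes into a list of 0/1 alleles, skipping missing."""
    out = []
    for c in codes_row:
        if c == MISSING:
            continue
        out.extend({0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(c)])
    return out


def brute_pi(codes, L):
    """Mean pairwise difference per bp by exhaustive pair enumeration."""
    total = 0.0
    for row in codes:
        al = alleles_at_site(row)
        if len(al) < 2:
            continue
        pairs = list(itertools.combinations(al, 2))
        total += sum(1 for a, b in pairs if a != b) / len(pairs)
    return total / L


def brute_tajima_d(codes):
    """Tajima's D from diploid codes (no missing data), literal 1989 formulas."""
    n = 2 * len(codes[0])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    S = 0
    pi_hat = 0.0
    for row in codes:
        al = alleles_at_site(row)
        x = sum(al)
        if 0 < x < len(al):
            S += 1
        pairs = list(itertools.combinations(al, 2))
        pi_hat += sum(1 for a, b in pairs if a != b) / len(pairs)
    if S == 0:
        return math.nan
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def brute_hudson_fst(codes_a, codes_b):
    """Hudson/Bhatia ratio-of-sums by plain per-site loops."""
    num_sum = 0.0
    den_sum = 0.0
    for ra, rb in zip(codes_a, codes_b):
        aa, ab = alleles_at_site(ra), alleles_at_site(rb)
        n1, n2 = len(aa), len(ab)
        if n1 < 2 or n2 < 2:
            continue
        x1, x2 = sum(aa), sum(ab)
        if (x1 == 0 and x2 == 0) or (x1 == n1 and x2 == n2):
            continue
        p1, p2 = x1 / n1, x2 / n2
        num_sum += ((p1 - p2) ** 2
                    - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    return num_sum / den_sum if den_sum > 0 else math.nan


def brute_region_means(intervals, snp_pos, snp_val):
    """Mean value of SNPs in each interval by an O(n*m) scan."""
    out = {}
    for name, (s, e) in intervals.items():
        vals = [v for p, v in zip(snp_pos, snp_val)
                if s <= p < e and not math.isnan(v)]
        out[name] = sum(vals) / len(vals) if vals else math.nan
    return out


def brute_bh(pvals):
    """Benjamini-Hochberg step-up by the textbook min-over-tail definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


def random_genotypes(rng, n_variants, n_samples, missing_rate=0.0):
    codes = rng.integers(0, 3, size=(n_variants, n_samples)).astype(np.int8)
    if missing_rate:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    return codes
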