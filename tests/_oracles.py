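"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exhaustive window
enumeration for ROH, exact rational arithmetic for the Hardy–Weinberg
conditional distribution, quadratic interval intersection, and plain sorting
for quantile thresholds.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# ROH: exhaustive O(n^2) window enumeration + containment filtering
# ---------------------------------------------------------------------------

def roh_windows_oracle(pos, g, rule):
    """All valid windows not contained in another valid window.

    A window [i, j] is valid iff: endpoints are called homozygous; het and
    missing counts within the class budgets; >= min_snps SNPs; span >=
    min_length_bp; no inter-SNP gap > max_gap_bp inside the window.
    """
    pos = np.asarray(pos)
    g = np.asarray(g)
    n = len(pos)
    het = g == 1
    miss = g == MISSING
    hom = ~het & ~miss
    seg_id = np.concatenate([[0], np.cumsum(np.diff(pos) > rule.max_gap_bp)])
    valid = []
    for i in range(n):
        if not hom[i]:
            continue
        n_het = n_miss = 0
        for j in range(i, n):
            if seg_id[j] != seg_id[i]:
                break
            n_het += het[j]
            n_miss += miss[j]
            if n_het > rule.allowed_het or n_miss > rule.allowed_missing:
                break
            if (hom[j] and j - i + 1 >= rule.min_snps
                    and pos[j] - pos[i] >= rule.min_length_bp):
                valid.append((i, j))
    # containment filter: drop (i,j) if some (i'<=i, j'>=j) exists
    best: dict[int, int] = {}
    for i, j in valid:
        best[i] = max(best.get(i, -1), j)
    out, max_j = [], -1
    for i in sorted(best):
        if best[i] > max_j:
            out.append((i, best[i]))
            max_j = best[i]
    return out


# ---------------------------------------------------------------------------
# Hardy–Weinberg: exact rational conditional distribution
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _exact_het_dist(n: int, n_a: int):
    """{het_count: exact probability} given n genotypes, n_a copies of a."""
    dist = {}
    denom = Fraction(math.comb(2 * n, n_a))
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - h) // 2
        hom_b = n - h - hom_a
        if hom_b < 0:
            continue
        ways = Fraction(math.factorial(n),
                        math.factorial(hom_a) * math.factorial(h)
                        * math.factorial(hom_b)) * 2 ** h
        dist[h] = ways / denom
    return dist


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value via rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    dist = _exact_het_dist(n, min(n_a, 2 * n - n_a))
    p_obs = dist[n_Aa]
    return float(sum(p for p in dist.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# Quantile threshold + flag/merge
# ---------------------------------------------------------------------------

def threshold_oracle(values, top_fraction):
    """k-th largest value with k = ceil(n * top_fraction), by full sort."""
    v = sorted(values, reverse=True)
    k = math.ceil(len(v) * top_fraction)
    return v[min(max(k, 1), len(v)) - 1]


def flag_merge_oracle(chrom, pos, values, top_fraction, merge_gap=0):
    """(threshold, list of (chrom, start_bp, end_bp, member indices))."""
    thr = threshold_oracle(values, top_fraction)
    flagged = [i for i, v in enumerate(values) if v >= thr]
    groups = []
    for i in flagged:
        if groups and chrom[i] == chrom[groups[-1][-1]] \
                and i - groups[-1][-1] - 1 <= merge_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return thr, [(chrom[g[0]], pos[g[0]], pos[g[-1]], g) for g in groups]


# ---------------------------------------------------------------------------
# Interval overlap: quadratic all-pairs
# ---------------------------------------------------------------------------

def overlap_oracle(regions, features, flank=0):
    """Set of (region index, feature index, overlap_bp) by brute force."""
    out = set()
    for ri, r in enumerate(regions):
        for fi, f in enumerate(features):
            if r[0] != f[0]:
                continue
            ov = min(r[2] + flank, f[2]) - max(r[1] - flank, f[1])
            if ov > 0:
                out.add((ri, fi, ov))
    return out


# ---------------------------------------------------------------------------
# Per-SNP ROH coverage: brute-force membership scan
# ---------------------------------------------------------------------------

def incidence_oracle(segments, chrom, pos):
    """Count, per SNP, of distinct samples with a covering segment.

    ``segments``: iterable of (sample_id, chrom, start_bp, end_bp).
    """
    counts = np.zeros(len(pos), dtype=int)
    for k in range(len(pos)):
        owners = set()
        for sid, c, s, e in segments:
            if c == chrom[k] and s <= pos[k] <= e:
                owners.add(sid)
        counts[k] = len(owners)
    return counts
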