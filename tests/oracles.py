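"""Independent brute-force oracles used to validate pipeline operations.

These deliberately re-derive each quantity with the most literal possible
algorithm (per-base loops, exhaustive enumeration) and stay independent of
the package implementations they check.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np


def rpkm_brute(fragments: Sequence[Tuple[str, int, int]], chrom_sizes: Dict[str, int],
               bin_size: int, total: int) -> Dict[str, np.ndarray]:
    """Per-bin RPKM via an O(fragments x bins) overlap scan."""
    out = {}
    for chrom, size in chrom_sizes.items():
        nb = math.ceil(size / bin_size)
        counts = np.zeros(nb)
        for b in range(nb):
            bs, be = b * bin_size, (b + 1) * bin_size
            for (fc, fs, fe) in fragments:
                if fc == chrom and min(fe, be) - max(fs, bs) >= 1:
                    counts[b] += 1
        out[chrom] = counts / ((bin_size / 1000.0) * (total / 1e6))
    return out


def rrach_scan(seq: str) -> int:
    """Sliding-window 5-mer scan for RRACH (overlaps allowed)."""
    seq = seq.upper()
    n = 0
    for i in range(len(seq) - 4):
        w = seq[i : i + 5]
        if w[0] in "GA" and w[1] in "GA" and w[2] == "A" and w[3] == "C" and w[4] in "ACT":
            n += 1
    return n


def max_per_base(values: np.ndarray, bin_size: int, start: int, end: int) -> float:
    """Max of the bin value at every base of [start, end)."""
    return max(values[pos // bin_size] for pos in range(start, end))


def gene_call_brute(gene_exons: Dict[str, List[Tuple[str, int, int]]],
                    peaks_by_rep: Dict[str, List[Tuple[str, int, int]]]) -> Dict[str, bool]:
    """All-pairs interval check: gene is positive if any exon overlaps any
    peak by >= 1 bp in any replicate."""
    out = {}
    for gid, exons in gene_exons.items():
        hit = False
        for peaks in peaks_by_rep.values():
            for (pc, ps, pe) in peaks:
                for (ec, es, ee) in exons:
                    if pc == ec and min(pe, ee) - max(ps, es) >= 1:
                        hit = True
        out[gid] = hit
    return out


def fisher_greater_enum(table) -> float:
    """One-sided (greater) Fisher p by exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if k >= a:
            p += math.comb(r1, k) * math.comb(r2, c1 - k) / denom
    return p


def wilcoxon_twosided_enum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p via full enumeration of rank assignments
    (assumes no ties). p = 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = np.array([sum(comb) - n * (n + 1) / 2
                   for comb in itertools.combinations(range(1, n + m + 1), n)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(min(p, 1.0))


def resample_bedgraph_brute(records: Sequence[Tuple[int, int, float]],
                            chrom_len: int, bin_size: int) -> np.ndarray:
    """Length-weighted bin means via a per-base expansion."""
    per_base = np.zeros(chrom_len)
    for s, e, v in records:
        per_base[s:e] = v
    nb = math.ceil(chrom_len / bin_size)
    out = np.zeros(nb)
    for b in range(nb):
        seg = per_base[b * bin_size : (b + 1) * bin_size]
        out[b] = seg.mean()
    return out


def pearson_direct(a: Sequence[float], b: Sequence[float]) -> float:
    """Textbook covariance / (sigma_a sigma_b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov / (a.std() * b.std()))
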