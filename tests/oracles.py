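"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a statistic by direct enumeration or accumulation,
without sharing code paths with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import hypergeom


def weighted_oracle(meth, context="ALL", region=None):
    """Two-pass explicit accumulation of the weighted methylation level."""
    mc = tot = 0
    for r in meth.itertuples(index=False):
        if r.total <= 0:
            continue
        if context != "ALL" and r.context_class != context:
            continue
        if region is not None:
            chrom, start, end = region
            if r.chrom != chrom or not (start <= r.pos - 1 < end):
                continue
        mc += r.mc
        tot += r.total
    return mc / tot if tot else float("nan")


def profile_oracle(meth, chrom_lengths, window_bp, context):
    """Per-window recomputation: filter sites window by window."""
    out = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            out.append(weighted_oracle(meth, context, (chrom, start, end)))
    return np.array(out)


def binom_tail_oracle(k, n, p):
    """P(X >= k | n, p) by direct summation of binomial pmf terms."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


def bh_oracle(pvalues):
    """Step-up Benjamini–Hochberg with an explicit running minimum."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins and
    summing the probabilities of tables no more likely than the observed."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, c1, r1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def ols_oracle(x, y):
    """Closed-form normal equations for slope, intercept, r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    sxx = ((x - mx) ** 2).sum()
    syy = ((y - my) ** 2).sum()
    sxy = ((x - mx) * (y - my)).sum()
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = sxy**2 / (sxx * syy) if syy > 0 else 0.0
    return slope, intercept, r2


def metagene_oracle(meth, features, flank_bp, body_bins, flank_bins, context):
    """Per-bin mean level by explicit per-feature interval membership.

    Bin intervals are constructed as explicit coordinate ranges per feature
    (upstream fixed-width, body proportional with float boundaries,
    downstream fixed-width), then sites are assigned by scanning.
    """
    nbins = 2 * flank_bins + body_bins
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    cov = meth[(meth["total"] > 0) & (meth["context_class"] == context)]
    for f in features.itertuples(index=False):
        length = f.end - f.start
        if length < body_bins:
            continue
        sites = cov[cov["chrom"] == f.chrom]
        pos0 = sites["pos"] - 1
        w = flank_bp / flank_bins if flank_bins else 0
        masks = []
        for j in range(flank_bins):
            lo = f.start - flank_bp + j * w
            masks.append((pos0 >= lo) & (pos0 < lo + w))
        off = pos0 - f.start  # body membership by exact integer comparison
        for j in range(body_bins):
            masks.append((off >= 0) & (off < length)
                         & (off * body_bins >= j * length)
                         & (off * body_bins < (j + 1) * length))
        for j in range(flank_bins):
            lo = f.end + j * w
            masks.append((pos0 >= lo) & (pos0 < lo + w))
        for b, mask in enumerate(masks):
            sub = sites[mask]
            if not len(sub):
                continue
            level = sub["mc"].sum() / sub["total"].sum()
            bin_idx = nbins - 1 - b if f.strand == "-" else b
            sums[bin_idx] += level
            counts[bin_idx] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, counts
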