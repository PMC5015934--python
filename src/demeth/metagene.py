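"""Metagene methylation profiles: scaled gene bodies with fixed flanks.

Each feature contributes a strand-corrected vector of weighted methylation
levels: a fixed number of fixed-width bins upstream of the 5' end, a fixed
number of proportional bins across the (length-scaled) body, and fixed-width
bins downstream of the 3' end.  The profile reported per bin is the
unweighted mean over features with a defined level, so long or deeply
covered features do not dominate.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CONTEXTS

logger = logging.getLogger(__name__)

SEGMENTS = ("upstream", "body", "downstream")


def metagene_profile(meth: pd.DataFrame, features: pd.DataFrame,
                     flank_bp: int = 1500, body_bins: int = 20,
                     flank_bins: int = 15,
                     contexts: Sequence[str] = CONTEXTS) -> pd.DataFrame:
    """Average methylation across scaled feature bodies and fixed flanks.

    Returns a tidy frame with one row per (bin, context): bin index, the
    segment it belongs to, mean weighted level over contributing features
    and the number of features contributing.  Bin 0 is always the 5'-most
    upstream bin (minus-strand features are reversed).  Features shorter
    than ``body_bins`` bp cannot fill their body bins and are skipped; the
    skipped count is logged and exposed via ``df.attrs['n_skipped']``.
    """
    if not len(features):
        raise ValueError("empty feature set")
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if flank_bins == 0:
        flank_bp = 0  # no flank bins to place flank sites into
    nbins = 2 * flank_bins + body_bins
    flank_width = flank_bp / flank_bins if flank_bins else 0.0

    cov = meth[meth["total"] > 0]
    by_chrom = {
        chrom: sub.sort_values("pos", kind="stable")
        for chrom, sub in cov.groupby("chrom", observed=True, sort=False)
    }

    level_sum = {ctx: np.zeros(nbins) for ctx in contexts}
    level_n = {ctx: np.zeros(nbins, dtype=np.int64) for ctx in contexts}
    n_skipped = 0

    for feat in features.itertuples(index=False):
        length = feat.end - feat.start
        if length < body_bins:
            n_skipped += 1
            continue
        sub = by_chrom.get(feat.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = feat.start - flank_bp, feat.end + flank_bp
        i0 = np.searchsorted(pos, lo + 1, side="left")
        i1 = np.searchsorted(pos, hi, side="right")
        if i0 == i1:
            continue
        window = sub.iloc[i0:i1]
        pos0 = window["pos"].to_numpy() - 1
        bins = np.empty(len(pos0), dtype=np.int64)
        up = pos0 < feat.start
        down = pos0 >= feat.end
        body = ~up & ~down
        if flank_bins:
            bins[up] = (pos0[up] - lo) // flank_width
            bins[down] = (flank_bins + body_bins
                          + (pos0[down] - feat.end) // flank_width)
        bins[body] = flank_bins + (pos0[body] - feat.start) * body_bins // length
        if feat.strand == "-":
            bins = nbins - 1 - bins
        for ctx in contexts:
            in_ctx = (window["context_class"] == ctx).to_numpy()
            if not in_ctx.any():
                continue
            mc = np.bincount(bins[in_ctx], weights=window["mc"].to_numpy()[in_ctx],
                             minlength=nbins)
            tot = np.bincount(bins[in_ctx], weights=window["total"].to_numpy()[in_ctx],
                              minlength=nbins)
            defined = tot > 0
            level_sum[ctx][defined] += mc[defined] / tot[defined]
            level_n[ctx][defined] += 1

    if n_skipped:
        logger.info("metagene_profile: skipped %d features shorter than "
                    "%d bp", n_skipped, body_bins)

    segment = np.array(
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    rows = []
    for ctx in contexts:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(level_n[ctx] > 0, level_sum[ctx] / level_n[ctx], np.nan)
        rows.append(pd.DataFrame({
            "bin": np.arange(nbins), "segment": segment, "context": ctx,
            "mean_level": mean, "n_features": level_n[ctx],
        }))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["n_skipped"] = n_skipped
    return out
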