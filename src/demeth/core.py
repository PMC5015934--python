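"""Methylation statistics: weighted levels, window profiles, distributions.

The central quantity everywhere is the *weighted methylation level* of a set
of cytosines: the sum of methylated read counts divided by the sum of total
read counts.  Unlike a per-site mean it weights each cytosine by its
coverage, which makes regional estimates robust to uneven sequencing depth.

Sites with zero covering reads carry no information and are excluded from
every statistic; an empty denominator yields an *undefined* value (NaN),
which is propagated as missing and never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import CONTEXTS

GRID_COLUMNS = ["chrom", "start", "end"]


class WeightedLevel(NamedTuple):
    """Weighted methylation of a site set with its supporting counts."""

    level: float  # NaN when no covered sites qualify
    mc: int
    total: int
    n_sites: int


def weighted_methylation(meth: pd.DataFrame, context: str = "ALL",
                         region: tuple[str, int, int] | None = None) -> WeightedLevel:
    """Weighted methylation over covered sites of one context (or pooled).

    ``context`` is CG, CHG, CHH or ``"ALL"`` to pool the three classes.
    ``region`` is an optional ``(chrom, start, end)`` half-open interval; a
    site belongs to it iff its 0-based position lies inside.  With no
    qualifying covered site the level is NaN (undefined), distinct from 0.
    """
    sel = meth["total"] > 0
    if context != "ALL":
        sel &= (meth["context_class"] == context).to_numpy()
    if region is not None:
        chrom, start, end = region
        pos0 = meth["pos"] - 1
        sel &= (meth["chrom"] == chrom).to_numpy() & (pos0 >= start).to_numpy() \
            & (pos0 < end).to_numpy()
    sub = meth.loc[sel]
    mc = int(sub["mc"].sum())
    total = int(sub["total"].sum())
    level = mc / total if total > 0 else float("nan")
    return WeightedLevel(level, mc, total, len(sub))


def make_windows(chrom_lengths: dict[str, int], window_bp: int) -> pd.DataFrame:
    """Tile each chromosome into half-open windows of ``window_bp``.

    Windows are non-overlapping and jointly cover the chromosome; the final
    partial window is retained.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        starts = np.arange(0, length, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def chromosome_profile(meth: pd.DataFrame, chrom_lengths: dict[str, int],
                       window_bp: int = 50_000,
                       contexts: Sequence[str] = CONTEXTS) -> pd.DataFrame:
    """Per-window per-context weighted methylation across the genome.

    Returns one row per tile from :func:`make_windows` with, for every
    context, methylated/total read sums, covered-site counts and the
    weighted level (NaN where the window has no covered site).
    """
    wins = make_windows(chrom_lengths, window_bp)
    cov = meth[meth["total"] > 0]
    widx = (cov["pos"] - 1) // window_bp
    agg = (
        cov.groupby([cov["chrom"].rename("chrom"), widx.rename("widx"),
                     cov["context_class"].rename("context_class")], observed=True)
        .agg(mc=("mc", "sum"), total=("total", "sum"), n=("pos", "size"))
        .reset_index()
    )
    wins = wins.assign(widx=wins["start"] // window_bp)
    for ctx in contexts:
        sub = agg[agg["context_class"] == ctx]
        merged = wins.merge(sub[["chrom", "widx", "mc", "total", "n"]],
                            on=["chrom", "widx"], how="left")
        mc = merged["mc"].fillna(0).astype(np.int64)
        total = merged["total"].fillna(0).astype(np.int64)
        wins[f"mc_{ctx}"] = mc.to_numpy()
        wins[f"total_{ctx}"] = total.to_numpy()
        wins[f"n_{ctx}"] = merged["n"].fillna(0).astype(np.int64).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            wins[f"level_{ctx}"] = np.where(total > 0, mc / total, np.nan)
    return wins.drop(columns="widx")


def _check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not (
        a[GRID_COLUMNS].reset_index(drop=True).equals(
            b[GRID_COLUMNS].reset_index(drop=True))
    ):
        raise ValueError("window grids of the two samples do not match")


def relative_profile(treated: pd.DataFrame, control: pd.DataFrame,
                     contexts: Sequence[str] = CONTEXTS) -> pd.DataFrame:
    """Per-window treated/control methylation ratio on a shared grid.

    The ratio is undefined (NaN) where either side is undefined or the
    control level is 0 — never infinity.
    """
    _check_same_grid(treated, control)
    out = treated[GRID_COLUMNS].reset_index(drop=True).copy()
    for ctx in contexts:
        t = treated[f"level_{ctx}"].to_numpy(dtype=float)
        c = control[f"level_{ctx}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where((c > 0) & ~np.isnan(t), t / c, np.nan)
        out[f"ratio_{ctx}"] = ratio
    return out


@dataclass
class SiteLevelDistribution:
    """Histogram of per-site methylation levels (mc/total) in one context."""

    context: str
    edges: np.ndarray          # bin edges over [0, 1]
    density: np.ndarray        # histogram mass per bin, sums to 1
    fraction_fully_methylated: float  # share of sites with level exactly 1.0
    n_sites: int


def site_level_distribution(meth: pd.DataFrame, context: str,
                            only_methylated_sites: bool = False,
                            bins: int = 20) -> SiteLevelDistribution:
    """Distribution of per-site methylation levels over covered sites.

    With ``only_methylated_sites`` the histogram is restricted to sites
    whose binary site call is 1 — the population plotted in per-site level
    frequency distributions.  A site counts as *completely methylated* iff
    every covering read supports methylation (level exactly 1.0).
    """
    sel = (meth["total"] > 0) & (meth["context_class"] == context)
    if only_methylated_sites:
        sel &= meth["call"] == 1
    sub = meth.loc[sel]
    if not len(sub):
        raise ValueError(f"no qualifying covered {context} sites")
    levels = (sub["mc"] / sub["total"]).to_numpy(dtype=float)
    counts, edges = np.histogram(levels, bins=bins, range=(0.0, 1.0))
    frac_full = float((sub["mc"] == sub["total"]).mean())
    return SiteLevelDistribution(
        context=context, edges=edges, density=counts / len(sub),
        fraction_fully_methylated=frac_full, n_sites=len(sub),
    )


def pairwise_high_meth_windows(treated: pd.DataFrame, control: pd.DataFrame,
                               context: str,
                               min_control_level: float) -> pd.DataFrame:
    """Paired (control, treated) levels for highly methylated windows.

    Retains windows whose control level is defined and at least
    ``min_control_level`` and whose treated level is defined.  The returned
    frame carries the paired levels and their ratio, from which summary
    demethylation slopes (quantiles of treated/control) can be read.
    """
    if not 0.0 <= min_control_level <= 1.0:
        raise ValueError("min_control_level must lie in [0, 1]")
    _check_same_grid(treated, control)
    c = control[f"level_{context}"].to_numpy(dtype=float)
    t = treated[f"level_{context}"].to_numpy(dtype=float)
    keep = ~np.isnan(c) & (c >= min_control_level) & ~np.isnan(t)
    out = control.loc[keep, GRID_COLUMNS].reset_index(drop=True).copy()
    out["control_level"] = c[keep]
    out["treated_level"] = t[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(c[keep] > 0, t[keep] / c[keep], np.nan)
    return out


def partition_pericentromere(
    windows: pd.DataFrame, pericentromere: dict[str, tuple[int, int]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split windows into (pericentromeric, arm) sets by window midpoint.

    A window is pericentromeric iff its midpoint falls in its chromosome's
    pericentromere interval (half-open); chromosomes absent from the map
    contribute only arm windows.  Every window lands in exactly one set.
    """
    mid = (windows["start"].to_numpy() + windows["end"].to_numpy()) / 2.0
    peri_mask = np.zeros(len(windows), dtype=bool)
    for chrom, (p0, p1) in pericentromere.items():
        on_chrom = (windows["chrom"] == chrom).to_numpy()
        peri_mask |= on_chrom & (mid >= p0) & (mid < p1)
    return (windows[peri_mask].reset_index(drop=True),
            windows[~peri_mask].reset_index(drop=True))


def feature_methylation(meth: pd.DataFrame, features: pd.DataFrame,
                        contexts: Sequence[str] = CONTEXTS) -> pd.DataFrame:
    """Per-feature per-context weighted methylation with site/call counts.

    Works for any interval set (genes, TE genes, promoter regions).  Several
    rows may share a ``feature_id`` (e.g. CDS pieces); counts are reported
    per row and can be pooled by id downstream.  Adds, per context, the
    read sums, covered-site count ``n``, called-methylated site count ``k``
    and the weighted level.
    """
    cov = meth[meth["total"] > 0]
    per_chrom: dict[str, dict] = {}
    for chrom, sub in cov.groupby("chrom", observed=True, sort=False):
        sub = sub.sort_values("pos", kind="stable")
        entry = {"pos": sub["pos"].to_numpy()}
        for ctx in contexts:
            in_ctx = (sub["context_class"] == ctx).to_numpy()
            # prefix sums give O(1) aggregation per feature interval
            entry[ctx] = {
                "mc": np.concatenate([[0], np.cumsum(sub["mc"].to_numpy() * in_ctx)]),
                "total": np.concatenate([[0], np.cumsum(sub["total"].to_numpy() * in_ctx)]),
                "n": np.concatenate([[0], np.cumsum(in_ctx.astype(np.int64))]),
                "k": np.concatenate([[0], np.cumsum((sub["call"].to_numpy() == 1) & in_ctx)]),
            }
        per_chrom[chrom] = entry

    out = features.reset_index(drop=True).copy()
    for ctx in contexts:
        for stat in ("mc", "total", "n", "k"):
            out[f"{stat}_{ctx}"] = 0
    for i, row in enumerate(out.itertuples(index=False)):
        entry = per_chrom.get(row.chrom)
        if entry is None:
            continue
        pos = entry["pos"]
        # site in [start, end) in 0-based coords <=> 1-based pos in [start+1, end]
        i0 = np.searchsorted(pos, row.start + 1, side="left")
        i1 = np.searchsorted(pos, row.end, side="right")
        for ctx in contexts:
            cs = entry[ctx]
            for stat in ("mc", "total", "n", "k"):
                out.iat[i, out.columns.get_loc(f"{stat}_{ctx}")] = \
                    cs[stat][i1] - cs[stat][i0]
    for ctx in contexts:
        total = out[f"total_{ctx}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"level_{ctx}"] = np.where(total > 0, out[f"mc_{ctx}"] / total, np.nan)
    return out
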