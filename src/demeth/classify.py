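"""Gene methylation classification by binomial enrichment tests.

Plant genes fall into distinct methylation classes with different
regulatory meaning: *gene-body methylated* (gbM) genes carry CG-only
methylation in their coding sequence and tend to be moderately-to-highly
expressed; *mCHG-enriched* genes additionally carry CHG methylation; and
*mCHH-enriched* genes carry methylated CHH sites — typically methylation in
all three contexts — and are usually transcriptionally silenced.

A gene is called *enriched* for a context when the number of
called-methylated cytosines among its covered cytosines exceeds what a
background methylation rate would produce, by a one-sided (upper-tail)
binomial test with Benjamini–Hochberg correction across genes.  Class
assignment then follows a fixed precedence: CHH enrichment wins regardless
of the other contexts, then CHG (such genes often carry mCG as well), then
CG alone gives gbM, else the gene is unmethylated.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import feature_methylation
from .io import CONTEXTS
from .stats import bh_adjust

logger = logging.getLogger(__name__)

#: default per-read methylation error rate (bisulfite non-conversion scale)
DEFAULT_ERROR_RATE = 0.005
#: default per-site binomial alpha for the binary site call
DEFAULT_SITE_ALPHA = 0.01

CLASS_LABELS = ("gbM", "mCHG", "mCHH", "unmethylated")


def site_call_pvalue(mc, total, error_rate: float = DEFAULT_ERROR_RATE) -> np.ndarray:
    """Upper-tail binomial p-value that a site's methylated reads arise from
    the error rate alone: P(X >= mc | n = total, p = error_rate)."""
    mc = np.asarray(mc)
    total = np.asarray(total)
    return sps.binom.sf(mc - 1, total, error_rate)


def site_call(mc, total, error_rate: float = DEFAULT_ERROR_RATE,
              alpha: float = DEFAULT_SITE_ALPHA) -> np.ndarray:
    """Binary methylation call per site; 0 where the site is uncovered."""
    mc = np.asarray(mc)
    total = np.asarray(total)
    call = (site_call_pvalue(mc, total, error_rate) <= alpha).astype(np.int64)
    return np.where(total > 0, call, 0)


def add_site_calls(meth: pd.DataFrame, error_rate: float = DEFAULT_ERROR_RATE,
                   alpha: float = DEFAULT_SITE_ALPHA) -> pd.DataFrame:
    """Return a copy of the cytosine table with the call column recomputed."""
    out = meth.copy()
    out["call"] = site_call(out["mc"].to_numpy(), out["total"].to_numpy(),
                            error_rate, alpha)
    return out


def background_rates(meth: pd.DataFrame, features: pd.DataFrame | None = None,
                     contexts: Sequence[str] = CONTEXTS) -> dict[str, float]:
    """Background methylation rate per context: called / covered sites.

    With ``features`` given, only sites inside the feature intervals
    (typically the coding sequences of all genes) are counted; otherwise
    the whole genome is used.  A context with no covered site in scope is a
    hard error, because no enrichment test is meaningful against it.
    """
    cov = meth[meth["total"] > 0]
    if features is not None:
        if not len(features):
            raise ValueError("empty feature scope for background rates")
        stats = feature_methylation(cov, features, contexts)
        rates = {}
        for ctx in contexts:
            n = int(stats[f"n_{ctx}"].sum())
            if n == 0:
                raise ValueError(f"no covered {ctx} sites in background scope")
            rates[ctx] = int(stats[f"k_{ctx}"].sum()) / n
        return rates
    rates = {}
    for ctx in contexts:
        sub = cov[cov["context_class"] == ctx]
        if not len(sub):
            raise ValueError(f"no covered {ctx} sites in background scope")
        rates[ctx] = float((sub["call"] == 1).mean())
    return rates


def classify_genes(meth: pd.DataFrame, genes: pd.DataFrame,
                   background: dict[str, float] | None = None,
                   alpha_q: float = 0.05,
                   contexts: Sequence[str] = CONTEXTS) -> pd.DataFrame:
    """Classify genes as gbM / mCHG / mCHH / unmethylated.

    ``genes`` is a feature table; rows sharing a ``feature_id`` (CDS
    pieces) are pooled.  ``background`` maps context to its background
    methylation rate; by default it is computed from the supplied gene
    intervals themselves.  Per gene and context a one-sided binomial test
    of the called-site count against the background rate is BH-corrected
    across genes within the context; enrichment means q <= ``alpha_q``.

    A gene with zero covered sites in a context is treated as not enriched
    in that context (p and q are NaN) and counted in the log.
    """
    if background is None:
        background = background_rates(meth, genes, contexts)
    for ctx in contexts:
        pi = background[ctx]
        if not 0.0 < pi < 1.0:
            raise ValueError(
                f"background rate for {ctx} is {pi}; enrichment test requires "
                "a rate strictly inside (0, 1)")

    per_row = feature_methylation(meth, genes, contexts)
    agg = {f"{stat}_{ctx}": "sum" for ctx in contexts for stat in ("n", "k")}
    agg["chrom"] = "first"
    tab = per_row.groupby("feature_id", sort=False).agg(agg).reset_index()

    n_uncovered = 0
    enriched = {}
    for ctx in contexts:
        n = tab[f"n_{ctx}"].to_numpy(dtype=np.int64)
        k = tab[f"k_{ctx}"].to_numpy(dtype=np.int64)
        p = np.full(len(tab), np.nan)
        has = n > 0
        n_uncovered += int((~has).sum())
        p[has] = sps.binom.sf(k[has] - 1, n[has], background[ctx])
        q = bh_adjust(p)
        tab[f"p_{ctx}"] = p
        tab[f"q_{ctx}"] = q
        enr = np.zeros(len(tab), dtype=bool)
        enr[has] = q[has] <= alpha_q
        tab[f"enriched_{ctx}"] = enr
        enriched[ctx] = enr
    if n_uncovered:
        logger.info("classify_genes: %d gene/context pairs had no covered "
                    "sites and were treated as not enriched", n_uncovered)

    label = np.full(len(tab), "unmethylated", dtype=object)
    label[enriched["CG"]] = "gbM"
    label[enriched["CHG"]] = "mCHG"
    label[enriched["CHH"]] = "mCHH"
    tab["meth_class"] = label
    tab = tab.drop(columns="chrom")
    return tab
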