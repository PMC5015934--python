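"""Dose–response fitting, differential-expression filtering and enrichment.

Three post-methylome analyses live here:

* an ordinary least-squares fit of weighted methylation level on inhibitor
  concentration (one point per concentration), summarised by slope, r² and
  the slope p-value — with only four concentrations the p-value is
  low-powered and is flagged as such;
* the differential-expression filter applied to Cuffdiff-style FPKM
  tables: a 0.1 pseudocount on both sides to avoid infinite fold changes,
  then *strictly* q < 0.05 and |log2 fold change| > 2;
* two-sided Fisher's exact tests for enrichment of gene categories
  (methylation classes against all genes, TE families against all TE
  genes) among upregulated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class DoseResponseFit:
    """OLS fit of methylation level against concentration (µM)."""

    concentrations: np.ndarray
    levels: np.ndarray
    slope: float        # level per µM
    intercept: float    # level at 0 µM
    r_squared: float
    p_value: float      # two-sided slope p-value; low-powered at n = 4
    agent: str = ""
    context: str = "ALL"
    low_powered: bool = field(default=False)


def fit_dose_response(points, agent: str = "", context: str = "ALL") -> DoseResponseFit:
    """Fit level ~ concentration by OLS over (concentration, level) pairs.

    Requires at least three distinct concentrations.  A flat response
    (constant level) yields slope 0 and r² = 0.
    """
    pts = [(float(c), float(y)) for c, y in points if not np.isnan(y)]
    if len({c for c, _ in pts}) < 3:
        raise ValueError("need >= 3 distinct concentrations with defined levels")
    x = np.array([c for c, _ in pts])
    y = np.array([y for _, y in pts])
    if np.ptp(y) == 0.0:
        fit = DoseResponseFit(x, y, 0.0, float(y[0]), 0.0, 1.0, agent, context)
    else:
        res = sps.linregress(x, y)
        fit = DoseResponseFit(x, y, float(res.slope), float(res.intercept),
                              float(res.rvalue) ** 2, float(res.pvalue),
                              agent, context)
    fit.low_powered = len(pts) <= 5
    return fit


def de_filter(expr: pd.DataFrame, pseudocount: float = 0.1,
              q_max: float = 0.05, lfc_min: float = 2.0) -> pd.DataFrame:
    """Classify genes as up / down / unchanged from FPKM and q-values.

    log2fc = log2((fpkm_treated + pseudocount) / (fpkm_control + pseudocount)).
    Thresholds are strict: a gene at log2fc exactly ``lfc_min`` or
    q exactly ``q_max`` is unchanged.
    """
    if (expr["fpkm_control"] < 0).any() or (expr["fpkm_treated"] < 0).any():
        raise ValueError("negative FPKM value")
    out = expr.copy()
    out["log2fc"] = np.log2((out["fpkm_treated"] + pseudocount)
                            / (out["fpkm_control"] + pseudocount))
    sig = out["q_value"] < q_max
    status = np.where(sig & (out["log2fc"] > lfc_min), "up",
                      np.where(sig & (out["log2fc"] < -lfc_min), "down",
                               "unchanged"))
    out["status"] = status
    return out


@dataclass
class EnrichmentResult:
    """Two-sided Fisher's exact test of a category among upregulated genes."""

    category: str
    table: np.ndarray       # [[up&cat, notup&cat], [up&rest, notup&rest]]
    odds_ratio: float       # sample odds ratio (a*d)/(b*c)
    p_value: float
    background: str


def fisher_enrichment(category_genes, background_genes, up_genes,
                      category: str = "", background: str = "") -> EnrichmentResult:
    """Fisher's exact test for over/under-representation of upregulated
    genes in a category relative to a stated background gene set.

    ``category_genes`` must be a subset of ``background_genes``; the 2×2
    table crosses category membership with upregulation status over the
    background.
    """
    cat = set(category_genes)
    bg = set(background_genes)
    if not cat or not bg:
        raise ValueError("empty category or background")
    if not cat <= bg:
        raise ValueError("category is not a subset of the background")
    up = set(up_genes) & bg
    a = len(cat & up)
    b = len(cat) - a
    c = len(up) - a
    d = len(bg) - len(cat) - c
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    _, p = sps.fisher_exact(table, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return EnrichmentResult(category, table, odds, float(p), background)


def upregulation_summary(de: pd.DataFrame, annotations: pd.DataFrame,
                         meth_classes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Composition of upregulated genes by kind, methylation class, TE family.

    Returns a tidy table with one row per (grouping, group): total genes in
    the group, upregulated genes, and the upregulated percentage
    (100 × up / total).  Groupings: gene kind (protein-coding vs TE gene),
    methylation class among protein-coding genes (with an
    ``other/uncategorized`` bucket for genes without a class label), and TE
    family among TE genes.  DE gene ids absent from the annotation are
    logged and excluded.
    """
    ann = annotations.drop_duplicates("feature_id")[
        ["feature_id", "kind", "te_family"]].set_index("feature_id")
    unknown = set(de["gene_id"]) - set(ann.index)
    if unknown:
        logger.info("upregulation_summary: %d DE gene ids not in the "
                    "annotation were excluded", len(unknown))
    de = de[de["gene_id"].isin(ann.index)]
    up_ids = set(de.loc[de["status"] == "up", "gene_id"])

    rows = []

    def add(grouping: str, group: str, ids) -> None:
        ids = set(ids)
        n_up = len(ids & up_ids)
        pct = 100.0 * n_up / len(ids) if ids else 0.0
        rows.append((grouping, group, len(ids), n_up, pct))

    pc = ann.index[ann["kind"] == "protein_coding_gene"]
    te = ann.index[ann["kind"] == "TE_gene"]
    add("kind", "protein_coding_gene", pc)
    add("kind", "TE_gene", te)

    if meth_classes is not None:
        cls = meth_classes.set_index("feature_id")["meth_class"]
        labelled = set(cls.index) & set(pc)
        for label in ("gbM", "mCHG", "mCHH", "unmethylated"):
            add("meth_class", label,
                [g for g in labelled if cls[g] == label])
        add("meth_class", "other/uncategorized", set(pc) - labelled)

    for family in sorted(ann.loc[te, "te_family"].unique()):
        add("te_family", family, te[ann.loc[te, "te_family"] == family])

    return pd.DataFrame(rows, columns=["grouping", "group", "n_total",
                                       "n_up", "pct_up"])
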