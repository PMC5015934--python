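"""Readers and writers for the file formats the pipeline touches.

Formats handled here:

* allc-style per-cytosine TSV (7 columns, no header): chromosome,
  1-based position, strand, trinucleotide context, methylated read count,
  total read count, binary site call.  This is the Methylpy output dialect;
  each CG position appears once per strand.
* GFF3 / BED feature annotation (genes, TE genes, arbitrary regions).
* chromosome-length TSV (name, length).
* per-window methylation statistics TSV (BED-compatible).
* Cuffdiff-style expression TSV (gene id, FPKM control, FPKM treated,
  q-value).

Internally every interval is 0-based half-open; conversion to and from
1-based inclusive coordinates happens only in this module.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column order of the allc dialect
ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "total", "call"]

#: recognised methylation sequence contexts, in canonical order
CONTEXTS = ("CG", "CHG", "CHH")

_H = frozenset("ACT")


class AllcFormatError(ValueError):
    """Raised when an allc file violates the format contract."""


def classify_context(context3: str) -> str | None:
    """Assign a CG/CHG/CHH class from a trinucleotide context string.

    The class depends on positions 2-3 of the trinucleotide: ``G`` at
    position 2 gives CG; ``H`` then ``G`` gives CHG; ``H`` then ``H`` gives
    CHH, where H is A, C or T.  Returns ``None`` for strings that cannot be
    classified (wrong length, N or other letters at the decisive positions).
    """
    if len(context3) != 3:
        return None
    c2, c3 = context3[1], context3[2]
    if c2 == "G":
        return "CG"
    if c2 in _H:
        if c3 == "G":
            return "CHG"
        if c3 in _H:
            return "CHH"
    return None


def _classify_context_series(context: pd.Series) -> pd.Series:
    c2 = context.str[1]
    c3 = context.str[2]
    ok_len = context.str.len() == 3
    out = pd.Series(pd.NA, index=context.index, dtype="object")
    out[ok_len & (c2 == "G")] = "CG"
    h2 = ok_len & c2.isin(_H)
    out[h2 & (c3 == "G")] = "CHG"
    out[h2 & c3.isin(_H)] = "CHH"
    return out


def read_allc(path: str | Path) -> pd.DataFrame:
    """Read an allc-style TSV into a cytosine table.

    Returns a DataFrame with the seven allc columns plus a derived
    ``context_class`` column.  Input order is preserved.  Records whose
    trinucleotide context cannot be classified (e.g. contains N at the
    decisive positions) are dropped with a logged count; a methylated read
    count exceeding the total read count is a hard error naming the
    offending line.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=ALLC_COLUMNS,
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "context": str,
            "mc": np.int64,
            "total": np.int64,
            "call": np.int64,
        },
    )
    bad = df.index[(df["mc"] > df["total"]) | (df["mc"] < 0) | (df["pos"] < 1)]
    if len(bad):
        i = int(bad[0])
        row = df.loc[i]
        raise AllcFormatError(
            f"{path}, line {i + 1}: invalid counts or position "
            f"(pos={row['pos']}, mc={row['mc']}, total={row['total']})"
        )
    df["context_class"] = _classify_context_series(df["context"])
    unknown = df["context_class"].isna()
    if unknown.any():
        logger.warning(
            "%s: skipped %d records with unclassifiable context", path, int(unknown.sum())
        )
        df = df[~unknown].reset_index(drop=True)
    df["context_class"] = pd.Categorical(df["context_class"], categories=list(CONTEXTS))
    return df


def write_allc(meth: pd.DataFrame, path: str | Path) -> None:
    """Write a cytosine table back to the 7-column allc dialect."""
    meth[ALLC_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length) TSV into an ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    if (df["length"] <= 0).any():
        raise ValueError(f"{path}: non-positive chromosome length")
    return dict(zip(df["chrom"], df["length"]))


def write_chrom_sizes(chrom_lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")


#: feature table columns used throughout the package
FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "feature_id", "kind", "te_family"]

_GFF_KIND = {
    "gene": "protein_coding_gene",
    "protein_coding_gene": "protein_coding_gene",
    "transposable_element_gene": "TE_gene",
}


def read_annotation(path: str | Path, dialect: str = "gff3",
                    use_cds: bool = False) -> pd.DataFrame:
    """Read gene/TE annotation from GFF3 or BED into a feature table.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is already half-open.  GFF3 features
    of type ``gene`` become ``protein_coding_gene`` and
    ``transposable_element_gene`` become ``TE_gene`` (family taken from the
    ``te_family`` attribute).  With ``use_cds=True`` the intervals of a gene
    are replaced by its CDS children where present (several rows may then
    share a ``feature_id``); genes without CDS keep their full body.
    """
    if dialect == "bed":
        return _read_bed(path)
    if dialect != "gff3":
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    rows = []
    for ftype, kind in _GFF_KIND.items():
        for f in db.features_of_type(ftype):
            if f.end < f.start:
                raise ValueError(f"{path}: feature {f.id} has end < start")
            family = f.attributes.get("te_family", [""])[0]
            if kind == "TE_gene" and not family:
                family = "other"
            if kind != "TE_gene":
                family = ""
            intervals = [(f.start - 1, f.end)]
            if use_cds:
                cds = [(c.start - 1, c.end) for c in db.children(f, featuretype="CDS")]
                if cds:
                    intervals = sorted(cds)
            for start, end in intervals:
                rows.append((f.seqid, start, end, f.strand, f.id, kind, family))
    feats = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if len(feats) and (feats["end"] <= feats["start"]).any():
        raise ValueError(f"{path}: feature with end <= start after normalization")
    return feats.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _read_bed(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = raw.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    feats = pd.DataFrame({
        "chrom": raw[0].astype(str),
        "start": raw[1].astype(np.int64),
        "end": raw[2].astype(np.int64),
        "strand": raw[5].astype(str) if ncol > 5 else "+",
        "feature_id": (raw[3].astype(str) if ncol > 3
                       else raw[0].astype(str) + ":" + raw[1].astype(str)
                       + "-" + raw[2].astype(str)),
        "kind": "region",
        "te_family": "",
    })
    if (feats["end"] <= feats["start"]).any():
        raise ValueError(f"{path}: BED interval with end <= start")
    return feats


def write_annotation(feats: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as GFF3 (genes and TE genes)."""
    type_of = {"protein_coding_gene": "gene", "TE_gene": "transposable_element_gene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in feats.itertuples(index=False):
            attrs = f"ID={row.feature_id}"
            if row.te_family:
                attrs += f";te_family={row.te_family}"
            fh.write(
                f"{row.chrom}\tdemeth\t{type_of.get(row.kind, row.kind)}\t"
                f"{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def write_windows(stats: pd.DataFrame, path: str | Path,
                  contexts: Iterable[str] = CONTEXTS) -> None:
    """Write per-window statistics as a BED-compatible TSV.

    Columns: chrom, start, end, then per context the weighted level, site
    count, methylated reads and total reads.  Undefined levels (zero
    covered sites) are written as ``NA``.
    """
    if not len(stats):
        raise ValueError("empty window statistics")
    cols = ["chrom", "start", "end"]
    for ctx in contexts:
        cols += [f"level_{ctx}", f"n_{ctx}", f"mc_{ctx}", f"total_{ctx}"]
    stats[cols].to_csv(path, sep="\t", header=True, index=False,
                       na_rep="NA", float_format="%.6g")


def read_windows(path: str | Path) -> pd.DataFrame:
    """Read a window-statistics TSV; weighted levels are recomputed from the
    stored read counts rather than trusted from the file."""
    df = pd.read_csv(path, sep="\t", na_values="NA")
    for col in df.columns:
        if col.startswith("level_"):
            ctx = col.removeprefix("level_")
            total = df[f"total_{ctx}"].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                df[col] = np.where(total > 0, df[f"mc_{ctx}"] / total, np.nan)
    return df


EXPRESSION_COLUMNS = ["gene_id", "fpkm_control", "fpkm_treated", "q_value"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a Cuffdiff-style expression table (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expression columns {sorted(missing)}")
    if (df["fpkm_control"] < 0).any() or (df["fpkm_treated"] < 0).any():
        raise ValueError(f"{path}: negative FPKM value")
    if df["q_value"].isna().any() or ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise ValueError(f"{path}: q_value missing or outside [0, 1]")
    return df[EXPRESSION_COLUMNS].copy()


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr[EXPRESSION_COLUMNS].to_csv(path, sep="\t", header=True, index=False,
                                    float_format="%.6g")
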