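"""Synthetic methylome, annotation and expression generator.

Emulates the data layout of a whole-genome bisulfite experiment on
inhibitor-treated seedlings with *planted, known* parameters, so that every
downstream statistic has a ground truth:

* a genome with chromosome arms and a TE-dense pericentromere: high
  all-context methylation in pericentromeric intergenic DNA and TE genes,
  low methylation on the arms;
* gene classes with distinct baseline per-context methylation
  probabilities (gbM: CG only; mCHG: CG+CHG; mCHH: all contexts;
  unmethylated: background);
* treatment as a per-context demethylation fraction d applied
  multiplicatively to every site's methylation probability, monotone
  non-decreasing in inhibitor concentration;
* per-site read coverage drawn from a Poisson distribution and methylated
  read counts from Binomial(coverage, p·(1−d));
* expression tables with upregulation planted at chosen per-class (or
  per-TE-family) fractions.

Two independent random streams are derived from the seed: one for genome
layout (site positions, strands, coverage) and one for methylated read
counts, so samples that differ only in treatment share site positions and
coverage, as resequencing the same genotype would.  Identical inputs and
seed give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import site_call
from .io import CONTEXTS, FEATURE_COLUMNS

#: cytosines per kb per context; CHH outnumbers the symmetric contexts
DEFAULT_SITE_DENSITY = {"CG": 22.0, "CHG": 18.0, "CHH": 80.0}

#: baseline per-context methylation probabilities per compartment/class
DEFAULT_BASELINES = {
    "gbM":             {"CG": 0.85, "CHG": 0.02, "CHH": 0.02},
    "mCHG":            {"CG": 0.75, "CHG": 0.45, "CHH": 0.02},
    "mCHH":            {"CG": 0.80, "CHG": 0.50, "CHH": 0.30},
    "unmethylated":    {"CG": 0.02, "CHG": 0.02, "CHH": 0.02},
    "TE":              {"CG": 0.90, "CHG": 0.70, "CHH": 0.25},
    "peri_intergenic": {"CG": 0.90, "CHG": 0.70, "CHH": 0.25},
    "arm_intergenic":  {"CG": 0.05, "CHG": 0.02, "CHH": 0.02},
}

#: planted demethylation fraction per concentration (µM); AZA near-linear,
#: ZEB saturating at the top dose
DOSE_CURVES = {
    "AZA": {0: 0.0, 25: 0.20, 50: 0.40, 100: 0.60},
    "ZEB": {0: 0.0, 25: 0.25, 50: 0.40, 100: 0.50},
    "control": {0: 0.0},
}

VALID_CONCENTRATIONS = (0, 25, 50, 100)
TE_FAMILIES = ("CACTA", "Copia", "Gypsy", "LINE", "other")

_H = np.array(list("ACT"))
_ACGT = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry and site-density parameters of the synthetic genome."""

    chrom_lengths: dict[str, int]
    pericentromere: dict[str, tuple[int, int]]
    site_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_DENSITY))
    seed: int = 0

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for chrom, (p0, p1) in self.pericentromere.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"pericentromere on unknown chromosome {chrom}")
            if not (0 <= p0 < p1 <= self.chrom_lengths[chrom]):
                raise ValueError(
                    f"pericentromere {chrom}:{p0}-{p1} outside chromosome")


@dataclass(frozen=True)
class TreatmentModel:
    """One sample's treatment: agent, dose and its demethylating effect."""

    agent: str = "control"
    concentration: int = 0          # µM
    demethylation: dict[str, float] = field(
        default_factory=lambda: {ctx: 0.0 for ctx in CONTEXTS})
    coverage_mean: float = 25.0     # mean reads per cytosine

    def __post_init__(self):
        if self.concentration not in VALID_CONCENTRATIONS:
            raise ValueError(
                f"concentration must be one of {VALID_CONCENTRATIONS}")
        for ctx, d in self.demethylation.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"demethylation fraction for {ctx} is {d}, "
                                 "outside [0, 1]")
        if self.concentration == 0 and any(
                d > 0 for d in self.demethylation.values()):
            raise ValueError("demethylation must be 0 at concentration 0")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.agent}_{self.concentration}uM"


def default_treatment(agent: str, concentration: int,
                      coverage_mean: float = 25.0) -> TreatmentModel:
    """Build a treatment from the default per-agent dose curves."""
    curve = DOSE_CURVES[agent]
    if concentration not in curve:
        raise ValueError(f"{agent} has no default effect at {concentration} µM")
    d = curve[concentration]
    return TreatmentModel(agent, concentration,
                          {ctx: d for ctx in CONTEXTS}, coverage_mean)


@dataclass(frozen=True)
class PlantedGeneClass:
    """One gene with its true methylation class and baselines."""

    gene_id: str
    gene_class: str                 # gbM | mCHG | mCHH | unmethylated | TE
    te_family: str = ""
    baselines: dict[str, float] | None = None  # default: class baseline

    def __post_init__(self):
        if self.gene_class not in ("gbM", "mCHG", "mCHH", "unmethylated", "TE"):
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if (self.gene_class == "TE") != bool(self.te_family):
            raise ValueError("te_family must be set iff gene_class is TE")

    def baseline(self) -> dict[str, float]:
        return self.baselines or DEFAULT_BASELINES[self.gene_class]


def make_gene_classes(class_counts: dict[str, int],
                      te_family_counts: dict[str, int] | None = None
                      ) -> list[PlantedGeneClass]:
    """Expand per-class (and per-TE-family) counts into a gene list."""
    genes = []
    for cls, n in class_counts.items():
        for i in range(n):
            genes.append(PlantedGeneClass(f"{cls}_{i + 1:04d}", cls))
    for family, n in (te_family_counts or {}).items():
        for i in range(n):
            genes.append(PlantedGeneClass(f"TE_{family}_{i + 1:04d}", "TE",
                                          te_family=family))
    return genes


def _validate_features(features: pd.DataFrame,
                       chrom_lengths: dict[str, int]) -> None:
    for chrom, sub in features.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            raise ValueError(f"feature on unknown chromosome {chrom}")
        if (sub["end"] > chrom_lengths[chrom]).any() or (sub["start"] < 0).any():
            raise ValueError(f"feature outside chromosome {chrom}")
        for strand, ss in sub.groupby("strand", sort=False):
            ss = ss.sort_values("start")
            if (ss["start"].to_numpy()[1:] < ss["end"].to_numpy()[:-1]).any():
                raise ValueError(
                    f"overlapping gene intervals on {chrom} strand {strand}")


def generate_annotation(spec: GenomeSpec, classes: list[PlantedGeneClass],
                        rng: np.random.Generator,
                        gene_length: int = 2500,
                        gap_range: tuple[int, int] = (500, 1500)) -> pd.DataFrame:
    """Place genes on the genome: TE genes inside the pericentromere,
    all other classes on the arms, without overlaps."""
    arm_regions, peri_regions = [], []
    for chrom, length in spec.chrom_lengths.items():
        if chrom in spec.pericentromere:
            p0, p1 = spec.pericentromere[chrom]
            if p0 > 0:
                arm_regions.append((chrom, 0, p0))
            peri_regions.append((chrom, p0, p1))
            if p1 < length:
                arm_regions.append((chrom, p1, length))
        else:
            arm_regions.append((chrom, 0, length))

    def place(genes, regions, label):
        rows = []
        it = iter(regions)
        try:
            chrom, cursor, end = next(it)
        except StopIteration:
            if genes:
                raise ValueError(f"no space to place {label} genes") from None
            return rows
        for g in genes:
            cursor += int(rng.integers(gap_range[0], gap_range[1] + 1))
            while cursor + gene_length > end:
                try:
                    chrom, cursor, end = next(it)
                except StopIteration:
                    raise ValueError(
                        f"genome too small to place all {label} genes") from None
                cursor += int(rng.integers(gap_range[0], gap_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            kind = "TE_gene" if g.gene_class == "TE" else "protein_coding_gene"
            rows.append((chrom, cursor, cursor + gene_length, strand,
                         g.gene_id, kind, g.te_family))
            cursor += gene_length
        return rows

    non_te = [g for g in classes if g.gene_class != "TE"]
    te = [g for g in classes if g.gene_class == "TE"]
    rows = place(non_te, arm_regions, "arm") + place(te, peri_regions, "TE")
    feats = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return feats.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _compartments(spec: GenomeSpec, features: pd.DataFrame,
                  baseline_of: dict[str, dict[str, float]]
                  ) -> list[tuple[str, int, int, dict[str, float]]]:
    """Partition every chromosome into (chrom, start, end, baselines) pieces:
    gene bodies keep their class baselines, the rest is intergenic."""
    out = []
    for chrom, length in spec.chrom_lengths.items():
        peri = spec.pericentromere.get(chrom)
        sub = features[features["chrom"] == chrom].sort_values("start")
        cursor = 0

        def intergenic(a, b):
            # split an intergenic stretch at the pericentromere boundaries
            cuts = [a, b]
            if peri:
                cuts += [p for p in peri if a < p < b]
            cuts = sorted(set(cuts))
            for x0, x1 in zip(cuts[:-1], cuts[1:]):
                mid = (x0 + x1) / 2
                key = ("peri_intergenic" if peri and peri[0] <= mid < peri[1]
                       else "arm_intergenic")
                out.append((chrom, x0, x1, DEFAULT_BASELINES[key]))

        for row in sub.itertuples(index=False):
            if row.start > cursor:
                intergenic(cursor, row.start)
            out.append((chrom, row.start, row.end, baseline_of[row.feature_id]))
            cursor = max(cursor, row.end)
        if cursor < length:
            intergenic(cursor, length)
    return out


def generate_methylome(spec: GenomeSpec, classes: list[PlantedGeneClass],
                       model: TreatmentModel,
                       features: pd.DataFrame | None = None,
                       seed: int | None = None,
                       gene_length: int = 2500
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one sample's allc-style cytosine table plus its annotation.

    Site positions, strands and coverage depend only on (spec, classes,
    seed); the treatment model enters through the methylated read counts
    alone, so a zero-effect treatment is byte-identical to the control.
    Returns ``(methylome, features)`` with the methylome sorted by
    chromosome then position.
    """
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    rng_layout, rng_counts = [np.random.default_rng(s) for s in ss.spawn(2)]

    if features is None:
        features = generate_annotation(spec, classes, rng_layout, gene_length)
    _validate_features(features, spec.chrom_lengths)
    baseline_of = {g.gene_id: g.baseline() for g in classes}
    missing = set(features["feature_id"]) - set(baseline_of)
    if missing:
        raise ValueError(f"features without a planted class: {sorted(missing)[:5]}")

    compartments = _compartments(spec, features, baseline_of)
    chrom_order = {c: i for i, c in enumerate(spec.chrom_lengths)}
    cols = {k: [] for k in ("chrom", "pos", "strand", "context",
                            "context_class", "p")}
    for chrom, start, end, baselines in compartments:
        span = end - start
        for ctx in CONTEXTS:
            n = int(rng_layout.poisson(spec.site_density[ctx] * span / 1000.0))
            n = min(n, span)
            if n == 0:
                continue
            pos0 = np.sort(rng_layout.choice(span, size=n, replace=False)) + start
            strand = np.where(rng_layout.random(n) < 0.5, "+", "-")
            if ctx == "CG":
                tri = np.char.add("CG", rng_layout.choice(_ACGT, n))
            elif ctx == "CHG":
                tri = np.char.add(np.char.add("C", rng_layout.choice(_H, n)), "G")
            else:
                tri = np.char.add(np.char.add("C", rng_layout.choice(_H, n)),
                                  rng_layout.choice(_H, n))
            cols["chrom"].append(np.full(n, chrom, dtype=object))
            cols["pos"].append(pos0 + 1)
            cols["strand"].append(strand)
            cols["context"].append(tri)
            cols["context_class"].append(np.full(n, ctx, dtype=object))
            cols["p"].append(np.full(n, baselines[ctx]))

    chrom_arr = np.concatenate(cols["chrom"])
    pos = np.concatenate(cols["pos"])
    ctx_class = np.concatenate(cols["context_class"])
    p = np.concatenate(cols["p"])
    order = np.lexsort((pos, np.vectorize(chrom_order.get)(chrom_arr)))

    total = rng_layout.poisson(model.coverage_mean, size=len(pos))
    d = np.array([model.demethylation.get(c, 0.0) for c in ctx_class])
    mc = rng_counts.binomial(total, p * (1.0 - d))

    meth = pd.DataFrame({
        "chrom": chrom_arr[order],
        "pos": pos[order].astype(np.int64),
        "strand": np.concatenate(cols["strand"])[order],
        "context": np.concatenate(cols["context"])[order],
        "mc": mc[order].astype(np.int64),
        "total": total[order].astype(np.int64),
    })
    meth["call"] = site_call(meth["mc"].to_numpy(), meth["total"].to_numpy())
    meth["context_class"] = pd.Categorical(ctx_class[order],
                                           categories=list(CONTEXTS))
    return meth[["chrom", "pos", "strand", "context", "mc", "total", "call",
                 "context_class"]], features


#: log-space FPKM baseline (mean, sd) per gene class: expressed gbM genes,
#: near-silent heterochromatic classes
EXPRESSION_BASELINES = {
    "gbM": (2.5, 1.0), "mCHG": (1.0, 1.0), "unmethylated": (2.0, 1.2),
    "mCHH": (-2.5, 1.0), "TE": (-3.0, 1.0),
}


def generate_expression(classes: list[PlantedGeneClass],
                        upregulated_fraction_by_class: dict[str, float],
                        seed: int) -> pd.DataFrame:
    """Simulate a Cuffdiff-style expression table with planted upregulation.

    Fractions are keyed by gene class, or by TE family for TE genes.  A
    gene drawn as upregulated gets its treated FPKM inflated by 2^U,
    U ~ Uniform(2.5, 6), on the pseudocounted scale (guaranteeing a log2
    fold change above 2 after the 0.1 pseudocount) and a q-value below
    0.05; all other genes get q >= 0.05.
    """
    if not classes:
        raise ValueError("empty gene class list")
    for key, f in upregulated_fraction_by_class.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"upregulated fraction for {key!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for g in classes:
        key = g.te_family if g.gene_class == "TE" else g.gene_class
        frac = upregulated_fraction_by_class.get(key, 0.0)
        mu, sd = EXPRESSION_BASELINES[g.gene_class]
        fc = float(np.exp(rng.normal(mu, sd)))
        if rng.random() < frac:
            uplift = rng.uniform(2.5, 6.0)
            ft = (fc + 0.1) * 2.0 ** uplift - 0.1
            q = rng.uniform(0.0, 0.049)
        else:
            ft = fc * 2.0 ** rng.normal(0.0, 0.3)
            q = rng.uniform(0.05, 1.0)
        rows.append((g.gene_id, fc, ft, q))
    return pd.DataFrame(rows, columns=["gene_id", "fpkm_control",
                                       "fpkm_treated", "q_value"])
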