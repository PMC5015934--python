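# Methods

## The measurement model

The atomic observation is one cytosine on one strand: a trinucleotide
context (classified CG / CHG / CHH from positions 2–3; H = A, C, T),
`mc` reads supporting methylation out of `total` covering reads, and a
binary site call. All regional statistics use the *weighted* methylation
level `Σ mc / Σ total` over covered sites (`total > 0`), so each site
contributes in proportion to its evidence. Sites with zero coverage are
excluded from every statistic; there is no additional minimum-coverage
threshold by default (it is configurable through pre-filtering the table).
An empty denominator yields an undefined value that propagates as missing
(NaN) — never 0 and never infinity. The treated/control ratio of a window
is likewise undefined when either side is undefined or the control level
is 0.

Coordinates are 0-based half-open internally; conversion from 1-based
GFF3/allc happens only at the I/O boundary. A site belongs to an interval
`[start, end)` iff its 0-based position lies inside; a window belongs to
the pericentromere iff its midpoint does. These membership rules make
window partitions exact: every site is counted in exactly one tile, every
tile in exactly one compartment.

"Completely methylated" is read literally: a site with `mc == total`.
The per-site level distribution can be restricted to called-methylated
sites, the population relevant when asking what fraction of methylated
CGs is fully methylated.

## Site calls and gene classification

The binary site call is an upper-tail binomial test of `mc` against a
per-read error rate (default 0.005, the typical magnitude of bisulfite
non-conversion) at per-site alpha 0.01. Both are parameters: real allc
files arrive with calls already made upstream, and the call column is
accepted as-is unless recomputation is requested.

Gene classification tests, per gene and context, whether the number of
called-methylated sites `k` among covered sites `n` in the coding
sequence exceeds a background rate π: one-sided p = P(X ≥ k | n, π),
BH-corrected *within each context across genes*, enriched iff q ≤ 0.05
(configurable). The background is the called/covered ratio over the coding
sequences of all genes by default (genome-wide optionally); the scope is a
parameter because it is a genuine modelling choice, not a data-determined
quantity. Class precedence is total and deterministic: CHH enrichment ⇒
mCHH regardless of the other contexts (such genes usually carry all three),
else CHG ⇒ mCHG (often with mCG alongside), else CG ⇒ gbM, else
unmethylated. A context with zero covered sites in a gene is treated as
not enriched and logged. Coding sequences default to union-of-CDS when the
GFF3 provides CDS features, else the full gene body.

## Metagene profiles

Each feature contributes fixed-width flank bins (default 15 bins × 100 bp
per 1500 bp flank) and proportional body bins (default 20), strand-corrected
so bin 0 is always 5′-most. Per bin the profile is the *unweighted mean over
features* of per-feature weighted levels, not a read pool across features:
this keeps long or deeply covered genes from dominating and matches common
metagene practice; pooling is the documented alternative. Features shorter
than the body-bin count are skipped and counted. Flank bins are not masked
for overlap with neighbouring genes — in gene-dense regions flank levels
therefore reflect neighbouring gene bodies as well as true intergenic
space.

## Dose–response, DE filter, enrichment

The dose–response model is ordinary least squares of weighted methylation
level on concentration, one point per concentration (the n = 4 design of a
0/25/50/100 µM series). r² is the squared Pearson correlation; a flat
response is defined to have slope 0 and r² = 0. The slope p-value at n = 4
is reported but flagged `low_powered`.

The DE filter adds a 0.1 pseudocount to both FPKM values before the log2
fold change, and applies *strict* inequalities: upregulated iff q < 0.05
and log2FC > 2.0 (a gene at exactly 2.0 is unchanged). Enrichment of a
category among upregulated genes is a two-sided Fisher's exact test on the
2×2 table of category membership × upregulation, methylation classes
tested against all annotated genes and TE families against all TE genes;
the sample odds ratio (ad/bc) is reported alongside. The composition table
includes an explicit other/uncategorized bucket for upregulated genes that
carry no class label.

## The synthetic-data generator

The generator emulates the data layout of a deeply sequenced inhibitor
dose series, not its molecular mechanism. A genome is specified by
chromosome lengths and a pericentromere interval per chromosome. Genes
(2500 bp by default, 0.5–1.5 kb gaps) are placed without overlap: protein-
coding classes on the arms, TE genes inside the pericentromere. Cytosines
are laid down per compartment at fixed densities (defaults 22 CG / 18 CHG /
80 CHH per kb — CHH sites outnumbering the symmetric contexts severalfold,
at an overall density compatible with a compact plant genome), with random
strands and consistent trinucleotide strings; no FASTA is needed.

Each compartment has baseline per-context methylation probabilities:

| compartment | CG | CHG | CHH |
|---|---|---|---|
| gbM gene | 0.85 | 0.02 | 0.02 |
| mCHG gene | 0.75 | 0.45 | 0.02 |
| mCHH gene | 0.80 | 0.50 | 0.30 |
| unmethylated gene | 0.02 | 0.02 | 0.02 |
| TE gene / pericentromeric intergenic | 0.90 | 0.70 | 0.25 |
| arm intergenic | 0.05 | 0.02 | 0.02 |

gbM genes carry arm-background CHG/CHH; the mCHG and unmethylated rows are
our choices on the same scale (high CG with substantial CHG but background
CHH; uniformly background). Coverage is Poisson with mean 25 (within the
20–30× range typical of deeply sequenced WGBS); zero-coverage sites are
written with zero counts and ignored by consumers. Treatment multiplies
every site's methylation probability by (1 − d_ctx), with default dose
curves d(0, 25, 50, 100 µM) = 0/.20/.40/.60 for AZA and 0/.25/.40/.50 for
ZEB — a near-linear response for one agent and a mildly saturating one for
the other, echoing the qualitative behaviour of such dose series without
claiming to reproduce any measured values. `mc ~ Binomial(coverage,
p·(1−d))`.

Two independent RNG streams derive from the seed: layout (positions,
strands, coverage) and methylated counts. Samples differing only in
treatment therefore share site positions and coverage, as resequencing the
same genotype would, and a zero-effect treatment is byte-identical to the
control. Identical inputs and seed give byte-identical files.

Expression tables plant upregulation per class (per TE family for TE
genes): upregulated genes get treated FPKM inflated by 2^U, U ~ U(2.5, 6),
on the pseudocounted scale, with q ~ U(0, 0.049); all others get
q ~ U(0.05, 1), so they can never pass the DE filter regardless of their
(mild, 2^N(0, 0.3)) expression noise. One treated replicate per condition
mirrors a deeply-sequenced single-replicate design; q-values are planted,
not computed from replicate variance.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequence-dependent site spacing and
methylation autocorrelation along the genome, partial-methylation
mosaicism across cells, bisulfite non-conversion and mapping artefacts,
RdDM boundary effects at TE edges, dose-dependent expression responses, or
replicate-based q-value estimation. Recovery results quantify the
correctness of the statistics under the stated sampling model, not
biological effect sizes.

## Validation scales and numerical choices

Tests validate each statistic against independent brute-force oracles
(explicit accumulation for weighted levels and window profiles, explicit
bin-interval membership for metagene bins, a step-up running-minimum BH
implementation, full hypergeometric enumeration for Fisher p-values,
normal equations for OLS) on ≥ 100 random instances each, and recover
planted parameters at moderate scale chosen for fast, well-powered checks:
a 1 Mb genome at 25× coverage for demethylation-ratio recovery (five seed
replicates; sampling error of a genome-wide ratio there is ≈ 0.1%, far
inside the ±0.03 assertion), a 3.4 Mb genome with 800 genes (≥ 50 CG sites
each) for class recovery, and 1000 TE genes for enrichment detection with
a 200-seed null calibration of the type-I error. Ties in BH are handled by
the running minimum; binomial tails use the survival function directly
(no normal approximation) so small-count sites are exact.

## Known limitations

* The pericentromere partition is a single interval per chromosome; real
  pericentromeres are ragged and must be supplied per chromosome.
* Window-grid comparisons require identical grids; there is no liftover or
  interpolation between samples.
* Classification assumes the background rate lies strictly inside (0, 1);
  a fully methylated scope makes enrichment undefined and is rejected.
* No DMR calling, no profile smoothing, and no expression estimation from
  reads — expression enters as an FPKM table with q-values.
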