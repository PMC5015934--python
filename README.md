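# demeth

Context-resolved analysis of chemically induced DNA demethylation from
whole-genome bisulfite sequencing (WGBS) data.

Cytosine analogs such as 5-azacytidine (AZA) and zebularine (ZEB) are
incorporated into DNA during replication and trap or inhibit DNA
methyltransferases, causing passive genome-wide demethylation. In plants,
where methylation occurs in three sequence contexts (mCG, mCHG, mCHH; H =
A, C or T) maintained by distinct pathways, a dose series of such
inhibitors asks several quantitative questions at once: how much
methylation is lost per context and per dose, whether loss is uniform along
chromosomes and across heterochromatin vs. euchromatin, which methylation
classes of genes are affected, and which silenced genes and transposable
elements (TEs) are transcriptionally reactivated. `demeth` implements that
whole desk-side analysis for allc-style per-cytosine methylation tables,
plus a synthetic methylome/expression generator with planted ground truth
used to validate every stage.

## What it computes

* **Weighted methylation level** of any site set (genome, window, feature):
  `m = Σᵢ mcᵢ / Σᵢ totᵢ` over covered cytosines — a coverage-weighted
  regional estimate robust to uneven depth. Undefined (not 0) when no
  covered site qualifies.
* **Window profiles and relative methylation**: non-overlapping tiles
  (e.g. 50 kb for chromosome views, 100 bp for pairwise comparisons),
  treated/control ratios per window, pericentromere/arm partition by
  window midpoint, and paired scatter data for highly methylated windows
  (control mCG ≥ 0.5, mCHH ≥ 0.3 by default).
* **Per-site level distributions** including the fraction of methylated
  sites that are *completely* methylated (every covering read methylated).
* **Gene methylation classes**: per gene and context, a one-sided binomial
  test of called-methylated site counts against a background rate π,
  BH-corrected across genes; precedence mCHH → mCHG → gbM → unmethylated.
* **Metagene profiles**: strand-corrected mean weighted methylation across
  scaled gene bodies with 1500 bp fixed flanks.
* **Dose–response**: OLS fit of weighted methylation on inhibitor
  concentration (`lm(level ~ concentration)`), reporting slope, r² and the
  (low-powered, n = 4) slope p-value.
* **Differential expression and enrichment**: the FPKM filter
  `log2((t+0.1)/(c+0.1))` with strict thresholds q < 0.05 and |log2FC| > 2,
  upregulation composition by gene kind / methylation class / TE family,
  and two-sided Fisher's exact tests (methylation classes vs. all genes,
  TE families vs. all TE genes).

## Worked example

Simulate a control and a 100 µM AZA-treated methylome (1 Mb genome, planted
demethylation fraction d = 0.6 for all contexts at 100 µM, mean coverage
25×) and recover the planted effect:

```python
from demeth import simulate as sim
from demeth import weighted_methylation, fit_dose_response

spec = sim.GenomeSpec({"chr1": 1_000_000}, {"chr1": (300_000, 700_000)}, seed=1)
ctrl, _ = sim.generate_methylome(spec, [], sim.TreatmentModel(coverage_mean=25))
points = []
for conc in (0, 25, 50, 100):
    model = (sim.TreatmentModel(coverage_mean=25) if conc == 0
             else sim.default_treatment("AZA", conc, 25))
    meth, _ = sim.generate_methylome(spec, [], model)
    points.append((conc, weighted_methylation(meth, "ALL").level))
    if conc == 100:
        for ctx in ("CG", "CHG", "CHH"):
            r = (weighted_methylation(meth, ctx).level
                 / weighted_methylation(ctrl, ctx).level)
            print(f"{ctx}: treated/control = {r:.4f}")
fit = fit_dose_response(points, agent="AZA")
print(f"dose-response r^2 = {fit.r_squared:.4f}, slope = {fit.slope:.6f}/uM")
```

Output:

```
CG: treated/control = 0.4026
CHG: treated/control = 0.3997
CHH: treated/control = 0.4002
dose-response r^2 = 0.9646, slope = -0.001131/uM
```

The per-context ratios recover 1 − d = 0.40 within sampling error, and the
near-linear planted dose curve gives r² ≈ 0.97: the genome-wide methylation
level falls monotonically with concentration.

The same pipeline is scriptable from a shell via the `demeth` command
(`simulate`, `global-stats`, `profile`, `relative`, `pairwise`, `region`,
`classify`, `metagene`, `dose-response`, `de-enrich`); see `demeth --help`.

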