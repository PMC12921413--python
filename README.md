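# chronometab

Analysis toolkit for **two-group circadian metabolomics**: studies that ask
how a treatment (here: continuous light, *LL*) reshapes the daily rhythms of
a metabolite panel relative to a normally entrained control (12:12
light/dark, *LD*), with tissue sampled at a few Zeitgeber times (ZT 0, 6,
12, 18) in independent animals.

It is written for the analyst who receives the wide metabolite-by-sample
intensity table from a targeted LC-MS experiment and needs the complete
downstream chain:

1. **Rhythmicity screening** (`chronometab.jtk`) — the JTK_CYCLE
   nonparametric test: the ranks of each series are correlated with the
   rank pattern of phase-lagged cosine reference waveforms via Kendall's
   tie-corrected score *S*; one-sided p-values come from the **exact**
   permutation null (computed with a q-multinomial generating function,
   not simulation) and are Bonferroni-adjusted over the lag grid.
2. **Differential rhythmicity** (`chronometab.rhythms`) — harmonic (cosinor)
   regression with group interactions,
   `y = β₀ + β_g·g + (a₀+a₁g)·cos(ωt) + (b₀+b₁g)·sin(ωt)`, ω = 2π/period.
   Per-group amplitude `A = √(a²+b²)` and acrophase
   `φ = (period/2π)·atan2(b, a)` follow by algebra; a joint 2-df F-test of
   `a₁ = b₁ = 0` calls a rhythm disruption, and phase differences are
   reported wrapped to (−12, 12] h with positive = phase delay.
3. **Differential abundance** (`chronometab.screening`) — Shapiro–Wilk-routed
   two-group tests (pooled-variance t with Cohen's *d*, or Mann–Whitney U
   with rank-biserial `r = Z/√N`), fold-change/volcano screening
   (FC > 1.2 & p < 0.05), PCA, PLS-DA with VIP scores
   (`VIP_j = √(p·Σ_a SSY_a w_{ja}² / Σ_a SSY_a)`) and label-permutation
   validation, per-timepoint screens (VIP > 1.5 & p < 0.05), Venn region
   counting and QC-replicate correlation.
4. **Pathway over-representation** (`chronometab.enrichment`) — one-sided
   hypergeometric tests against a user-supplied (or bundled toy) pathway
   map with Benjamini–Hochberg FDR control.
5. **Synthetic ground truth** (`chronometab.synthetic`) — a generator that
   emulates the full study design (398 metabolites, 2 × 4 ZT × 4 replicates,
   a rhythmic subset with nocturnally biased acrophases, planted phase
   delays, amplitude damping, rhythm loss and fold-change effects), so every
   stage of the pipeline can be validated against known truth.

A `chronometab` command-line interface wires these into a pipeline
(`simulate`, `screen-rhythm`, `compare-rhythm`, `diff`, `enrich`, `stats`,
`run-all`) that writes per-stage CSVs plus a JSON run manifest.

## Worked example

```python
from chronometab import (AnalysisConfig, GeneratorConfig, generate_dataset,
                         screen_rhythmic, compare_rhythms, reduction_pct)

cfg = AnalysisConfig(seed=1)
table, truth = generate_dataset(GeneratorConfig(seed=1))   # 398 x 32 panel

ld = screen_rhythmic(table, "LD", cfg)
ll = screen_rhythmic(table, "LL", cfg)
print(f"rhythmic: LD {ld.n_rhythmic}, LL {ll.n_rhythmic} "
      f"({reduction_pct(ld.n_rhythmic, ll.n_rhythmic):.1f}% reduction)")

disruption = compare_rhythms(table, ld.rhythmic_ids, cfg)
core = disruption.loc[truth.disrupted_ids]
print(f"planted +6.4 h / -21% effects: recovered "
      f"{int(core['disrupted'].sum())}/8, median delta-phase "
      f"{core['delta_phase'].median():+.1f} h, median amplitude change "
      f"{core['amp_change_pct'].median():+.1f}%")
```

prints

```
rhythmic: LD 74, LL 44 (40.5% reduction)
planted +6.4 h / -21% effects: recovered 8/8, median delta-phase +6.4 h, median amplitude change -24.0%
```

The generator planted 58 rhythmic metabolites; the screen recovers all of
them plus a handful of rank-test false positives (the screen's per-metabolite
α = 0.05 implies ≈ 15 expected false calls among 340 flat series, which is
why the detected LD count exceeds 58 — an `across_metabolite_fdr` switch in
`AnalysisConfig` removes them at the cost of the conventional JTK screening
behaviour). The eight metabolites planted with a +6.4 h phase delay and 21%
amplitude damping are all flagged by the interaction test, with the planted
effect sizes recovered by the harmonic fit.

The same machinery accepts real data as a CSV pair (wide abundance table +
long sample metadata):

```bash
chronometab --outdir out --seed 1 run-all --table abundance.csv --meta metadata.csv
```

## Data formats

* **Abundance CSV**: first column metabolite ID, header row of sample IDs,
  non-negative intensities; missing values as empty cells or `NA`.
* **Metadata CSV**: columns `sample_id, group, zt, replicate` with
  `group ∈ {LD, LL}` and `zt` in hours.
* **Pathway map TSV**: columns `pathway_id, name, metabolite` (one row per
  member) plus an optional one-ID-per-line background file.
* **Config YAML**: flat keys overriding `AnalysisConfig` defaults
  (thresholds, period, preprocessing switches, seed).
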