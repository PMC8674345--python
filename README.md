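# cistromekit

Toolkit for integrating transcription-factor cistromes (ChIP-seq peak sets)
with transcriptome responses, built for studies of two co-acting factors —
for example an androgen-receptor-like factor and a MYC-like factor in
prostate-cancer cells — where the questions are: which binding sites are
shared between the factors, which are lost or gained on treatment, which
genes fall into which occupancy class, and how binding relates to expression
change, enhancer acetylation, and super-enhancer architecture.

It is aimed at computational biologists who have peak calls (BED), signal
tracks (bedGraph), a gene/TSS table, and expression fold changes, and who
want the downstream integration steps as tested, scriptable primitives
rather than one-off notebook code.

## What it computes

* **Peak-set algebra** — partition of two peak sets into common and
  factor-specific sites by ≥1 bp overlap (peak-anchored counting), and
  lost / shared / gained dynamics between conditions.
* **Occupancy classes** — each gene is classed `A_only` / `B_only` /
  `common` / `none` by which factors have a peak within ±10 kb (default) of
  its TSS, with class-wise expression compared by two-sided Wilcoxon
  rank-sum tests (BH-adjusted).
* **Resampling enrichment** — for a query gene set, the percentage of genes
  with a peak within ±20 kb (default) of the TSS is compared with 1,000
  equal-size random gene sets drawn from the universe without replacement:

  `OR = observed% / mean(null%)`,

  with a +1-corrected empirical p-value and a one-sided t-test against the
  null draws.
* **Regulatory potential** — a distance-decayed binding score per gene,

  `RP(g) = Σ_peaks exp(−(0.5 + 4Δ))`, `Δ = |peak center − TSS| / 100 kb`,

  summed over peaks within 100 kb; up-/down-regulated gene classes are
  compared with a static class by a one-sided Kolmogorov–Smirnov test on
  the RP ranking.
* **Super-enhancers** — peaks stitched within 12.5 kb, ranked by total
  signal; on the unit-scaled curve (x = rank/m, y = signal/max) the cutoff
  is the slope-1 tangent point (the region maximizing x − y), and regions
  strictly above it are super-enhancers. Per-region condition fold change is
  `log2((signal_b + pc)/(signal_a + pc))`.
* **Signal pileups** — binned profile matrices (±2 kb, 50 bp bins by
  default) around peak centers, and per-region mean/sum quantification.
* **Signature scores** — per-sample sum over a gene list of
  `z = (x − μ)/σ` with study mean μ and sample SD σ per gene.
* **Synthetic data** — a seeded generator that plants all of the above
  (co-binding fraction, treatment loss/gain and intensity attenuation, an
  acetylation-like track, class-coupled expression effects) so every stage
  can be validated against known ground truth.

## Worked example

Generate the default synthetic study conditions and ask how the two
cistromes relate:

```bash
cistromekit simulate --seed 1 ds/
cistromekit overlap ds/peaks/a_vehicle.bed ds/peaks/b_vehicle.bed
```

```json
{
  "a_unique": 648,
  "a_common": 152,
  "b_unique": 450,
  "b_common": 150
}
```

150 of the 600 B peaks overlap an A peak — exactly the planted co-binding
fraction of 0.25. Treatment dynamics of the B cistrome:

```bash
cistromekit dynamics ds/peaks/b_vehicle.bed ds/peaks/b_treated.bed
```

```json
{
  "lost": 352,
  "shared": 248,
  "gained": 82
}
```

The generator removes the weakest 59% of B sites and gains 14% new weak
sites (the counts differ from the set-construction totals by a handful of
incidental overlaps, since dynamics is defined by interval overlap). The
full pipeline — partitioning, dynamics, occupancy classes, enrichment,
regulatory-potential association, super-enhancers, pileups, signature
scores — runs from one YAML config:

```bash
cistromekit run-all config.yaml
```

and reports, among other headline numbers, `common_b_fraction: 0.25`
(planted exactly), a B-only class median log2 fold change near the planted
−1, and an up-gene binding association p ≈ 1e−28 while the down-gene class
shows no association with A binding — the signature of a factor that
activates its direct targets.

Every function is also importable directly (`from cistromekit import
intersect_partition, resample_enrichment, ...`); the CLI is a thin layer.

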