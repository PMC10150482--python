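# trophostab

Resource-dependent belowground biodiversity, multi-trophic co-occurrence
networks, and functional trait stability — as a tested, reusable Python
pipeline.

Soil communities span several trophic levels: bacteria and fungi form the
basal (decomposer) level, protists and nematodes the high (consumer) level.
How resource availability (fertilisation, organic inputs) reshapes the
diversity of those groups, their within- and cross-trophic associations, and
ultimately the *stability* of soil functional traits is a central question
for sustainable agro-ecosystems. `trophostab` implements the full analysis
chain for such studies, and ships a synthetic-data module that generates
complete field and microcosm studies with planted ground truth, so every
stage is testable without any sequencing download.

It is aimed at microbial ecologists working with multi-amplicon OTU tables
(one per kingdom), soil chemistry tables, functional-gene frequency tables,
Biolog EcoPlate readings and plant biomass assays.

## What it computes

* **Composite resource availability (CRAI)** — each resource-relevant soil
  property (SOC, TN, TP, TK, (NH₄⁺-N+NO₃⁻-N):TN, AP:TP, AK:TK) is min–max
  standardized across all samples, `S = (x − x_min)/(x_max − x_min)`, and
  averaged per sample; samples are split low/high at each site's median.
  The soil fertility index is an Integrated Quality Index,
  `IQI = Σᵢ Wᵢ·Sᵢ`, with configurable piecewise-linear score functions.
* **Multi-kingdom diversity** — rarefaction without replacement, per-kingdom
  relative abundances merged into one integrated OTU table, Chao1, Shannon
  (`H = −Σ pᵢ ln pᵢ`), Pielou evenness, and the standardized four-kingdom
  reference diversity `Bio_ref` (mean of per-kingdom min–max standardized
  diversity).
* **Functional trait stability** — from a trait-redundancy table *R*
  (functional-gene frequencies per sample): the inverse coefficient of
  variation `1/CV = μ/σ` across traits (population σ), and
  `stability = ½·(s(R) + s(1/CV))` with both components min–max
  standardized across samples.
* **Trophic co-occurrence networks** — all-pairs Spearman ρ (average ranks,
  two-sided *t*-approximation p), Benjamini–Hochberg FDR across every tested
  pair, edges kept when |ρ| > 0.6 **and** adjusted p < 0.05 after an
  occurrence filter (≥ 20 of 30 samples). Edges are classified into 20
  (kingdom-pair, sign) types and 4 categories — positive/negative
  within-trophic (WTA) and cross-trophic (CTA) — and per-sample subnetworks
  (induced subgraphs on the OTUs present in a sample) give per-sample
  association proportions and network properties.
* **Microcosm statistics** — Biolog AWCD (mean blank-corrected OD over 31
  substrates), temporal functional stability `μ/σ` of AWCD across
  subculturings, and the bounded Orwin–Wardle resistance of plant biomass
  to temperature stress, `resistance = 1 − 2|D₀|/(C₀ + |D₀|)`.

## Worked example

```python
from trophostab import run_field_pipeline

bundle = run_field_pipeline(out_dir="out/field_demo", seed=1)
print(bundle.comparisons[["statistic_name", "mean_a", "mean_b", "p_value",
                          "stars"]])
```

which prints (mean_a = low-resource arm, mean_b = high-resource arm):

```
    statistic_name   mean_a   mean_b      p_value stars
              crai 0.268255 0.488735 2.371469e-10   ***
               sfi 0.672454 0.829086 3.474197e-10   ***
integrated_shannon 5.079899 5.306498 1.558075e-08   ***
         stability 0.303513 0.633863 3.019859e-11   ***
    cta_proportion 0.238647 0.662448 1.663716e-12   ***
    wta_proportion 0.761353 0.337552 1.663716e-12   ***
```

Read it as: the median CRAI split recovers the planted resource gradient
(confirmed independently by the fertility index), and the high-resource arm
shows higher integrated diversity, higher functional trait stability, and a
much larger share of cross-trophic associations in its per-sample
subnetworks — while within-trophic associations dominate the low-resource
arm. The `examples/` directory holds one short script per capability
(`resource_classification.py`, `trophic_network.py`, `field_pipeline.py`,
`microcosm_stability.py`); each prints the numbers it computes and a line on
what they mean.

A thin CLI wraps the same calls:

```sh
trophostab simulate --out out/study --seed 1
trophostab field-pipeline --out out/run --seed 1
trophostab microcosm-pipeline --out out/micro --seed 1
```

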