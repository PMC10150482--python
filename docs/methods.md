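# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Resource availability and fertility indices

CRAI is the per-sample mean of min–max standardized resource-relevant soil
properties: SOC, TN, TP, TK and the three availability ratios
(NH₄⁺-N+NO₃⁻-N):TN, AP:TP, AK:TK. Standardization pools **all** samples
across sites (so a site's absolute fertility matters), while the low/high
classification is a **per-site** median split — this is what produces a
within-site low/high contrast even between sites of very different absolute
fertility. Ties at the median are broken by treatment order
(C < NK < NPK < NPKM), so an even site always splits into equal halves; a
fixed treatment→level mapping can override the split when the experimental
design is the classification. Ratio indicators are computed before
standardization; samples with missing values or non-positive denominators
are excluded with a warning rather than erroring the run.

The soil fertility index is an Integrated Quality Index `IQI = Σ Wᵢ Sᵢ`.
The official score functions and weights are published in regional
grading tables rather than in journal text, so `IqiSpec` makes them fully
configurable; the default is four indicators (OM, AP, AK, pH) at equal
weight with monotone 3-breakpoint piecewise-linear curves over
agronomically plausible ranges (OM in g/kg, AP/AK in mg/kg). The default is
adequate for validating a low/high contrast, not for reproducing any
official land-quality grade.

Degenerate ranges (a constant indicator across samples) raise by default;
the `midpoint` policy emits 0.5 for every sample instead, which keeps batch
runs alive at the cost of that indicator carrying no information.

## Diversity

Rarefaction subsamples each sample **without replacement** (multivariate
hypergeometric draw) to a fixed depth, defaulting to the smallest
per-sample total of the kingdom; samples below depth are dropped with a
warning. Each kingdom is then transformed to within-kingdom relative
abundances and the four blocks are concatenated with kingdom-namespaced OTU
ids (`bacteria|OTU0001`) so independently picked OTU sets cannot collide.
By default the merged table is renormalized to a per-sample probability
vector; without renormalization a fully covered sample sums to 4, which
shifts the integrated Shannon by exactly ln 4 and changes nothing about
comparisons — both variants are exposed.

Shannon uses the natural log (configurable base; the choice only rescales
comparisons). Chao1 is `S_obs + F₁²/(2F₂)` with the bias-corrected
`S_obs + F₁(F₁−1)/2` fallback when no doubletons exist. Pielou evenness is
`H/ln S_obs` and requires ≥ 2 observed taxa. `Bio_ref` min–max standardizes
one chosen diversity index per kingdom across samples and averages the four
standardized values; it inherits the degenerate-range policy above.

## Functional trait stability

The trait table carries redundancy frequencies R of (by default ten)
functional genes per sample, taken directly as deposited — no probe-level
processing happens here. Per sample, `1/CV = μ/σ` is computed across traits
with the **population** σ (denominator *n*; `ddof=1` is available). `s(R)`
standardizes each trait across samples and averages over traits;
`stability = ½(s(R) + s(1/CV))` with 1/CV itself standardized across
samples, so stability lies in [0, 1] and reaches 1 only for a sample
maximal in both components. The alternative aggregation
(mean-then-standardize) is behind a flag; for comonotone traits it gives the
same rank order. Samples with zero trait variance are flagged and excluded
(the zero-σ check uses a relative 1e-12 tolerance so a constant vector is
caught despite floating-point residue).

## Co-occurrence networks

OTUs first pass an occurrence filter (nonzero abundance in ≥ 20 of the 30
samples of the arm being analysed, both thresholds configurable). All
remaining OTU pairs are tested: Spearman ρ with average ranks, two-sided p
from the *t*-approximation on n−2 df (an exact permutation p is available
for n ≤ 9). BH adjustment runs across **all tested pairs of one build**,
and an edge is retained only when |ρ| > 0.6 *and* adjusted p < 0.05 — the
conjunction is the conservative reading when both a correlation cutoff and
an FDR cutoff are stated without ordering. Constant OTUs are skipped with a
warning rather than failing the build; nodes are restricted to OTUs with at
least one retained edge.

Edge taxonomy: with self-pairs allowed there are 10 unordered kingdom pairs
× 2 signs = 20 types; a pair is *within-trophic* exactly when both
endpoints are basal (bacteria, fungi) or both high (protists, nematodes),
giving 12 within and 8 cross types collapsed into 4 sign×scope categories.
Per-sample subnetworks are induced subgraphs on the OTUs with nonzero
abundance in that sample; their category counts normalised by link count
give the per-sample WTA/CTA proportions (emitted as missing for link-free
samples). Network properties are the conventional set — node/link count,
mean degree, density, average clustering, and average path length on the
largest connected component, via networkx.

The builder is verified edge-for-edge against an independent brute-force
implementation (explicit average ranks, Pearson-on-ranks, hand-written
step-up BH) on small tables, and its null behaviour is checked on
independent-noise tables, where the retained-edge fraction sits far below
the nominal α.

## Microcosm statistics

AWCD is the mean over the 31 EcoPlate substrates of (substrate mean OD −
mean of the 3 blank wells), with negative corrected values truncated to 0
before averaging (standard EcoPlate practice). Temporal functional
stability is `μ/σ` of the per-subculture endpoint AWCD values of one
replicate trajectory (population σ; ≥ 2 subcultures required; flat
trajectories are flagged degenerate, not dropped). The reading time per
subculture is a data-preparation choice; the package consumes one plate per
(arm, replicate, subculture).

Biomass resistance uses the bounded Orwin–Wardle index
`1 − 2|D₀|/(C₀+|D₀|)` with C₀ the well-mean biomass at 20 °C and D₀ the
15 °C − 20 °C difference; stress and control wells are paired by replicate
order within each (system, resource) arm. The index is even in D₀, strictly
decreasing in |D₀|, equals 1 iff D₀ = 0 and approaches −1 as the
disturbance effect dominates. One-way ANOVA + Tukey HSD (and likewise
random-forest importance and PLS-SEM path modelling on the field side) are
deliberately left to external tools: they are off-the-shelf fits, so the
pipeline exposes its output tables to them through the
`POST_PIPELINE_HOOKS` registry rather than wrapping them.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions the tests run under.

* **Field design** — 5 sites × 4 treatments (C, NK, NPK, NPKM) × 3
  replicates = 60 samples. Soil pools get monotone treatment multipliers
  (totals ×1.00/1.12/1.28/1.55, available pools ×1.00/1.35/1.80/2.40) on
  site-specific baselines with 6 % lognormal replicate noise, so
  NPKM > NPK > NK > C holds in expectation within every site and C/NK vs
  NPK/NPKM is the true low/high split. The multipliers are in the range of
  long-term fertilisation contrasts; the noise level keeps the gradient
  recoverable by a median split, which is the point of the planted design.
* **Communities** — per-kingdom OTU counts 400/150/80/40 at fixed
  sequencing depths 20 000/10 000/6 000/3 000 (≥ 10 reads per OTU on
  average, enforced), realised as multinomial draws from a latent
  log-normal abundance model. Planted correlations use a latent Gaussian
  copula: members of a group share a factor with loading √0.9 (blocks) or
  are coupled directly at ρ = 0.9 (pairs), so their *rank* correlation —
  what the Spearman network stage sees — is controlled directly.
  Within-trophic blocks (10, size 3) are active in the low-resource arm
  and cross-trophic pairs (30) in the high-resource arm, with smaller
  opposite-arm counts (4 blocks, 10 pairs), and a quarter of couplings
  negative. High-resource samples get their base log-abundance spread
  shrunk ×0.75, making them more even and hence more diverse. Not
  emulated: realistic taxonomy, sequencing error/chimeras, compositional
  artefacts beyond the multinomial constraint, or spatial structure — so
  passing tests demonstrate that the *method* recovers planted structure,
  not that real soils behave this way.
* **Traits** — ten genes with means U(30, 70); low-resource samples get
  30 % multiplicative noise around those means, high-resource samples get
  means compressed halfway to the grand mean, gained ×1.35, with 10 %
  noise — larger s(R) and larger 1/CV in the high arm by construction.
* **Biolog** — four arms (C/M soil origin × Low/High medium) with mean
  AWCD 0.45/0.85/0.55/1.00 and temporal CV 0.22/0.10/0.20/0.07, six
  replicate trajectories over three subcultures; plates are reconstructed
  from a fixed substrate-utilisation profile so `compute_awcd` recovers
  the planted value up to small well noise. A CV of exactly 0 produces
  noise-free plates — the degenerate stability case.
* **Biomass** — 3 systems × 2 resources × 2 temperatures × 12 wells × 4
  seedlings (576 seedlings, 144 wells), seedling noise SD 1.5 mg. Planted
  means put system III/high on top at both temperatures (32 → 30 mg) and
  give system II its largest cooling loss under high resources
  (22 → 14 mg), so II-high resistance < II-low.

## Determinism and problem sizes

Every generator is a pure function of (spec, seed); the pipelines derive
all stage seeds from the single run seed, and a rerun is byte-identical
(tested). The default problem sizes — 60 samples, ~670 merged OTUs, 2×30
sample networks, 100-OTU null tables over 50 seeds, 100 brute-force
comparison seeds — keep the whole suite and the acceptance script in the
tens of seconds on one CPU while leaving the planted contrasts far from
marginal.

## Known limitations

* The IQI defaults are illustrative, not an official grading standard.
* The t-approximation p for Spearman is slightly anti-conservative at very
  small n; use the exact option below n = 10 if that matters.
* Edge retention near the |ρ| threshold is subject to floating-point ties
  in principle (strict `>` on both routes keeps the oracle comparison
  exact in practice).
* Per-sample subnetwork proportions are undefined (missing) for samples
  whose present OTUs induce no edges.
* The synthetic communities make no attempt at realistic taxonomy or
  compositional bias; direction-recovery results transfer to real data
  only as far as those simplifications allow.
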