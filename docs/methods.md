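# Methods

## Scope and model

`coldqtl` implements the desk side of a bulked-segregant QTL-seq study of
near-freezing (4 °C) growth tolerance in *S. cerevisiae*: growth-curve
phenotyping, extreme-pool construction, the SNP-index / Δ(SNP-index)
genome scan with candidate-region calling, candidate-gene triage, and a
synthetic-cross generator that reproduces the statistical structure the
scan assumes. Upstream wet-lab steps and read-level processing (alignment,
variant calling) are out of scope; the scan consumes per-site pooled
allele counts (VCF with AD fields, or TSV).

## Growth phenotyping

Raw OD600 series are blank-corrected (uninoculated-well background),
converted to y = ln(OD_t/OD_0) with OD_0 the first corrected reading (so
y(0) = 0 exactly), and fitted by bounded nonlinear least squares to the
reparameterized Gompertz model

y(t) = D·exp{−exp[μ_max·e/D·(λ−t)+1]},

D = ln(OD_∞/OD_0) (dimensionless), μ_max (h⁻¹), λ (h). Numerical choices:

- **Initialization** by the tangent-line heuristic: D₀ = max(y), μ_max,₀ =
  the steepest finite difference Δy/Δt, λ₀ = the time y first clears
  0.05·D₀ pulled back along the tangent. This keeps the optimizer off the
  flat pre-lag basin that dominates 4 °C series, where λ can exceed 100 h.
- **Bounds**: D ∈ (0, 10], μ_max ∈ (0, 1] h⁻¹, λ ∈ [0, t_max] — generous
  microplate-physical ranges.
- **Degenerate input**: a flat series (range of y below 1e-9, the
  "only grew slightly" case) returns μ_max = 0 with `converged=False`
  instead of an optimizer artefact; non-positive corrected OD readings are
  dropped with a warning, and a series losing all points is an error.
- Pool assignment uses strict inequalities (μ_max > 0.0135 → HIGH,
  < 0.0030 → LOW); a value exactly at a threshold is NEITHER, so a
  borderline segregant is never forced into a pool.

Recovery behaviour (asserted by the test suite and the acceptance script):
noiseless curves on the 8-h/18-day schedule are recovered to ~1e-9 in
μ_max at both parental anchors (0.0132, 0.0025 h⁻¹); with 3% multiplicative
OD noise the median relative μ_max error over 50 replicates is ≈1%.

## Genome scan

- SNP-index = alt/(alt+ref) per pool, alt being the superior-parent
  allele; zero-depth sites are dropped per pool and counted.
- Filters: the both-pool < 0.3 rule removes presumed artefact SNPs; sites
  below 0.3 in exactly one pool are *retained and flagged putative*.
  Whether such one-sided sites should enter the window means is a
  judgement call — they carry real but noisier signal — so retain-and-flag
  is the default and a config switch (`include_putative=False`) drops them
  instead. A `min_depth_per_pool` filter (default 10) is this package's
  addition; set 0 to apply only the index-based rule.
- Windows start at 1, 1+step, … per chromosome; a final right-anchored
  window ending at the chromosome end is added so no tail goes unscanned,
  and a chromosome shorter than the window yields a single clipped,
  flagged window. Window means are unweighted means of member-site deltas;
  empty windows carry no mean and never enter the quantile.
- The threshold is the k-th largest window mean with
  k = ⌈top_fraction·N⌉ over all non-empty windows **genome-wide** —
  a single genome-wide cutoff rather than per-chromosome quantiles, which
  would flag the top of every chromosome regardless of signal. Ties at the
  cut are all included (inclusive ≥ at region calling) so results do not
  depend on an arbitrary drop among equals.
- Region calling merges flagged windows that overlap or abut
  (next.start ≤ end+1); unflagged gaps split regions. Region mean =
  unweighted mean of member-window means; regions are ranked by mean
  descending. Coordinates are 1-based inclusive internally; BED output is
  0-based half-open.
- Polarity: a `polarity_flip` switch swaps parental roles for crosses
  called against the other parent's genome.

Genome-scale results from a real cross require the underlying sequencing
data and are not reproduced here; the scan machinery is instead verified
exactly (≤1e-12) against brute-force oracles on random small instances,
and end-to-end on simulation (below).

## Synthetic cross

The generator's defaults are the study conditions: 500 F2 haploid
segregants, pools of the top 21 / bottom 23 by phenotype, one additive QTL
raising μ_max from the inferior parent's 0.0025 h⁻¹ to the superior
parent's 0.0132 h⁻¹ (β = 0.0107), residual σ = 0.001 h⁻¹, mean pooled
depth 50×, base-error rate 0.005. The genome is scaled down to 16
chromosomes × 200 kb with 100 markers each so the full pipeline and its
20-replicate power check run in seconds; the marker density (1 per 2 kb)
matches the genome-wide density of the real cross's ~14.6k SNPs over
~12 Mb, so window occupancy is realistic even though chromosome-scale
linkage is compressed.

Modelling choices:

- **Recombination**: Haldane — Poisson crossover count per chromosome with
  mean equal to the genetic length in Morgans, uniform positions, no
  interference; default map density 0.35 cM/kb (a standard yeast-scale
  figure, configurable). Starting phase per chromosome is a fair coin.
- **Phenotype**: single additive major QTL plus Gaussian residual; the real
  trait shows continuous, roughly normal segregation, and a polygenic
  background can be emulated with extra small-β loci.
- **Sequencing**: per-site depth ~ Poisson(mean_depth); superior-allele
  reads ~ Binomial(depth, f(1−e) + (1−f)e) with f the pool allele
  frequency — error is symmetric substitution toward the other parental
  base only (a biallelic world; third alleles, indels and read-level
  artefacts are not modelled).
- **OD noise**: multiplicative Gaussian on OD, mimicking proportional
  plate-reader error.
- **Seeds**: one global seed per run; per-stage streams are derived
  deterministically via `numpy.random.SeedSequence`, so identical configs
  produce byte-identical artefacts.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: alignment and variant-calling artefacts,
depth heterogeneity beyond Poisson, segregation distortion, aneuploidy,
genotyping of the ~5% of real sites lost to quality filters, and
chromosome-scale linkage disequilibrium (chromosomes are scaled down).
Detection-power results on simulation are therefore upper bounds for a
real cross of the same design.

## Candidate-gene triage

Genes overlap a region if their CDS span (min/max over CDS intervals)
intersects it by ≥1 bp. Variant effects are classified by strand-aware
codon extraction and standard nuclear genetic-code translation (all
candidate genes are nuclear-encoded, including the mitochondrially
*acting* CBS1); only single-nucleotide substitutions are accepted —
MNVs/indels raise an error. Non-synonymous changes are labelled
`<ref-aa><residue><alt-aa>`, e.g. `F396S`.

The packaged strain panel (`data/strain_panel.tsv`) is a hand transcription
of a published allele matrix: 21 chromosome-IV genes, 30 non-synonymous SNP
positions, the two parents plus 28 sequenced strains. A focal allele is
**parent-unique** iff no non-parent strain with a *non-missing* call
carries it; missing cells are unknowns and never count as matches, so a
uniqueness claim can never rest on absent data. On this panel exactly the
CBS1 and NAT1 alleles of the superior parent are unique. Transcription
ambiguities (a duplicated W303 row kept as
`W303-2`; a 4-bp position discrepancy for the NAT1 SNP between table and
text) are documented in the fixture header; analyses key on gene identity,
not coordinates.

## Verification summary

The test suite checks, among others: segregation (Binomial(n, ½) allele
frequencies, Haldane-consistent recombination, monotone linkage decay),
variance decomposition of the phenotype model (β²/4 + σ²), binomial
concentration of the sequencing model, exact brute-force agreement of
window means / threshold order statistic / region merging on 100 random
instances, delta antisymmetry under pool swap, exhaustive 64-codon × 9-
neighbor synonymy agreement with the raw genetic-code table on both
strands, and 20-replicate end-to-end QTL detection under the default study
design (top-ranked region contains the planted QTL with mean Δ(SNP-index)
> 0.5). `scripts/acceptance.py` recomputes the headline quantities from
scratch at any seed.

## Known limitations

- No confidence bands on Δ(SNP-index) (simulation-based intervals and the
  G′ statistic are future work); the top-1% threshold is an empirical
  order statistic, not a significance level.
- The Gompertz fitter assumes a single growth phase; diauxic or declining
  series will fit poorly (inspect `rss`/`converged`).
- The uniqueness test is only as strong as the panel: alleles absent from
  28 strains may still segregate in wider populations.
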