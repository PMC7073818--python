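# Methods

## Turnover model

pulsekin assumes steady-state growth during the labeling pulse: protein
synthesis and loss are balanced, so the pre-existing (light) fraction of
each precursor decays as a single exponential,

    RIA(t) = L(t) / (L(t) + H(t)) = exp(−k_loss · t).

The intercept is fixed at 1 because no heavy label exists before the pulse;
consequently t = 0 observations are treated as an assumption rather than
data and never enter the fit. k_loss (per hour) lumps true degradation and
dilution by cell division (k_loss = k_deg + k_cd). `kdeg_from_kloss`
subtracts a supplied per-sample division rate (k_cd = ln 2 / doubling
time), but all cross-sample comparisons in the package use log2 k_loss as
the degradation proxy: division-rate measurements across related cell lines
are uncertain, and light amino-acid recycling biases absolute k_deg anyway.

Two estimation paths share the same optimizer and downstream handling:

* **RIA** — least squares on the isotope ratio, Σ_t (RIA_t − e^(−k t))²,
  k > 0, intercept fixed.
* **NLI** — every injection (sample × replicate × time point) is rescaled
  so its grand total H+L signal equals the median grand total across that
  sample's injections, then the light channel alone is fitted as
  L(t) = L0 · e^(−k t) with L0 free (t = 0 is a genuine observation here
  since the amplitude is estimated). The run-level (not per-precursor)
  normalization was chosen because the purpose of the step is to make
  injections comparable; on exact steady-state data the two paths coincide,
  which the tests verify to 1e-4.

### Optimization

The objective is one-dimensional in k, so the fit uses a log-spaced grid
(96 points over k ∈ [1e-6, 100] per hour) to bracket the minimum followed
by 70 golden-section iterations in log k. The NLI amplitude is profiled out
in closed form (L0*(k) = Σ L e^(−kt) / Σ e^(−2kt)). Bounding k prevents
divergence on degenerate profiles; the golden-section interval shrinks far
below any tolerance of interest (noiseless recovery error ~1e-13 relative).
All profiles are fitted simultaneously in padded arrays, which keeps a
~30,000-profile simulation under two seconds on one core.

### Filters

Mirroring standard practice for labeling time courses:

* profiles with fewer than two usable points are excluded
  (`single_time_point`);
* labeling must increase over time — the RIA (or normalized light signal)
  at the last observed time must be lower than at the first
  (`non_increasing_labeling`). Endpoint comparison rather than strict
  monotonicity keeps noisy-but-decaying profiles; a strict mode is
  available via `TurnoverConfig(strict_monotonic=True)`.
* Points where both channels are missing are skipped; a missing single
  channel counts as zero intensity.

### Aggregation

Precursor → peptide: weighted mean with weights equal to the summed L+H
signal over the profile (intensity proxies measurement precision; a uniform
scheme is available). Peptide → AS group: median (configurable mean) of
log2 peptide rates per sample, requiring at least two member peptides.
Cross-sample analyses only use peptides with a rate in every sample ("full
profiles"), so missingness cannot masquerade as regulation.

## Expression-filtered database and AS groups

Only protein-coding isoforms with per-sample mean FPKM strictly above 1 in
at least three samples enter the search database (both thresholds
configurable). "Expressed in a sample" is evaluated on the replicate-mean
because biological expression, not injection noise, is what the filter
targets. Protein sequences are taken from the annotation table directly;
translating nucleotide CDS is upstream annotation work outside this
package's scope.

Digestion is fully tryptic (cleave after K/R except before P, up to two
missed cleavages, peptide length 7–30 — a typical DIA detectability
window). Peptides mapping to several genes are excluded from all
quantification. Unique peptides form UQ groups keyed by their isoform;
shared peptides with an identical transcript-id footprint form one SM
group. Peptides of the same gene with different sharing footprints form
different groups — no merging heuristic is applied, preserving the
granularity at which the data actually distinguish isoforms. The SM
representative is the member transcript with the highest FPKM averaged over
all samples; ties break to the lexicographically smallest id so assembly is
deterministic. Isoleucine and leucine are treated as distinct residues.

## Matrix assembly

Protein abundance per peptide and sample is the median over replicate
injections in linear scale, requiring at least two quantified injections;
peptides must be full profiles; member peptides are summed in linear scale
before log2. Summing linear intensities is the physically meaningful
reading of "collapse by summing" (summing logs would multiply
intensities); a `collapse="sum_log"` switch preserves the alternative.
mRNA values use the per-sample replicate-mean FPKM of the group's single
(UQ) or representative (SM) transcript, log2 with no pseudocount — FPKM 0
maps to missing, which is safe because matrix rows passed the FPKM > 1
database filter.

## Correlation statistics

* **Absolute correlation**: Spearman across groups of sample-averaged layer
  values. **Relative correlation**: Spearman across groups of
  between-condition log2 fold changes. **Per-group correlation**: Spearman
  across the per-sample pairs of one group (12 points in the default
  design).
* Spearman p-values use the t-approximation
  t = ρ·√((n−2)/(1−ρ²)), df = n−2; the widely used significance cut
  |ρ| > 0.576 at n = 12, α = 0.05 follows from exactly this formula, which
  `critical_rho` reproduces. An exact permutation p is available for n ≤ 8.
* Protein CV for the quintile analysis is computed on linear-scale
  intensities (2^log2): CV is a ratio statistic and belongs on the natural
  scale. Quintiles are assigned by rank with a stable tie-break on group
  id, so segments are equal-sized ±1. The omnibus test is Kruskal–Wallis
  with BH-corrected pairwise Wilcoxon rank-sum tests.
* Differential expression/degradation uses a per-key two-sided two-sample
  t-test on log2 values with BH correction. Isoform-level differences
  within a gene use a t-test (two groups) or one-way ANOVA + Tukey HSD
  (more), and a gene is called only when significant *and* at least one
  pairwise |mean log2 difference| ≥ 0.32 (~1.25-fold) — an effect-size gate
  against large-n trivia.

## Enrichment

The 1D score s = 2·(r̄_in − r̄_out)/n is a bounded rank statistic in
(−1, 1), reaching ±1 exactly when members occupy an extreme block; it is
invariant under monotone transforms of the scores and antisymmetric under
negation. Significance is a two-sided Mann–Whitney U test, BH-corrected
across terms. 2D enrichment computes per-axis scores on the shared key set
and reports the larger of the two p-values — deliberately conservative and
simple; no bivariate rank test is attempted. Annotation terms need 10
scored members by default.

## Switch calling

A declared, simplified re-specification of dominance-based switch calling
(not a port of any external tool). Per transcript, a prefilter requires
non-zero FPKM in all replicate columns and FPKM > 1 in at least three.
Per gene and condition, the major isoform is the one with the highest mean
FPKM; the gene must exceed a summed-FPKM threshold of 1 in at least 50% of
samples, and the dominance ratio (major / second isoform) must reach the
configured minimum (default 1, i.e. no extra requirement) in both
conditions. An event is emitted iff the majors differ, classed by the
ordered biotype pair (retained-intron vs protein-coding). Consequence
testing compares each class's matched protein / k_loss fold changes to the
coding-to-coding control class with a rank-sum test.

## Synthetic data

The generator emulates: two conditions ("A"/"B") × 6 samples × 3 replicate
injections; labeling times 0/1/4.5/11 h; genes with 1–4 isoforms
(0.35/0.35/0.20/0.10), one dominant coding isoform carrying ~70% of gene
FPKM; non-dominant isoforms retained-intron with probability 0.2 (no
protein product); protein sequences built from concatenated tryptic
segments so constitutive segments yield shared peptides and
isoform-specific segments yield unique ones (K/R enriched so peptides land
in the 7–30 residue window); gene FPKM lognormal (median ≈ 20) with
per-sample log2 deviations (SD 0.7) and a gene-level condition shift
(SD 0.8); true k_loss log-uniform on [0.02, 0.6]/h; channel intensities
from the exact steady-state kinetics L = T·e^(−kt), H = T − L with
independent multiplicative lognormal noise (CV 0.1) per channel and point,
2% missingness. "Buffered" genes (a configurable fraction) get per-sample
log2 k_loss = log2 k_base + 0.8·(log2 mRNA deviation) + N(0, 0.2);
unbuffered genes get independent N(0, 0.15) jitter.

What it does **not** emulate — and what passing tests therefore do not
demonstrate about real data: light amino-acid recycling (which biases
k_loss downward in real pulses; deliberately omitted rather than guessing
a recycling model), arginine-to-proline conversion, retention-time or
charge-state chemistry, interference between co-eluting precursors,
intensity-dependent missingness (dropout here is uniform), and
isoform-specific turnover within a gene (all isoforms of a gene share one
true rate, so group-level truth is well-defined at every resolution).

## Problem sizes

The end-to-end analyses in the tests and the acceptance script use 300
genes (~600 quantifiable AS groups, ~700k precursor rows, ~30k profile
fits), 500 precursors for parameter recovery, 1,000 terms for the
enrichment null, and 100 genes / 20 planted events for switch calling —
sizes at which every statistic of interest is stable across seeds while a
full run stays around ten seconds.

## Known limitations

* The exponential model assumes steady state; perturbed or differentiating
  cultures violate it and the package offers no multi-compartment model.
* k bounded in [1e-6, 100]/h during optimization; rates outside are
  clamped and flagged only through their residuals.
* The NLI normalization equalizes whole injections; precursor-specific
  acquisition drift is not corrected.
* Group assembly is footprint-exact; peptides with overlapping but unequal
  isoform sets never merge, which can split evidence for one biological
  proteoform across groups.
* BH correction treats tests as independent or positively dependent; no
  Benjamini–Yekutieli option is exposed.
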