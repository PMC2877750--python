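# Methods

## The measurement model

A two-channel methylation BeadChip interrogates each CpG with two bead
types: one whose signal reports the methylated (M) allele, one the
unmethylated (U) allele, with roughly 15 beads per type and sample. The
methylation level of a probe in a sample is summarized as the beta value

    β = M / (M + U + α),    α = 100 by default,

where M and U are the mean bead intensities after normalization, negatives
floored at zero. The offset α regularizes β toward 0 when both signals are
near background; 100 is the platform convention for this array generation
(α = 0 is available via the `offset` argument — the source publication era
did not document the formula, so the choice is exposed rather than
hard-coded). β lives in [0, 1] and is monotone increasing in M, decreasing
in U.

Because the green and red channels have differently shaped raw intensity
distributions, each channel is quantile-normalized separately across
samples before aggregation: every sample's sorted vector is replaced by the
rank-wise mean of the sorted vectors. Ties receive the mean of the
reference values they span; samples of unequal bead counts are mapped
through linear interpolation of the averaged quantile function. A sample's
within-channel rank order is preserved exactly, which also makes the
detection test (rank-based) invariant to normalization.

## Detection P-values

Whether a probe is distinguishable from background is decided against the
negative-control beads of each channel: a one-sided Mann–Whitney U test of
the probe's beads exceeding the channel's negative-bead pool. One-sidedness
is a design choice — signal detection is inherently directional. Per sample
and channel, the P-values are Benjamini–Hochberg adjusted across all probes
(the only scope that yields a meaningful FDR for a genome-wide detection
call; the scope is configurable), and the per-probe detection P is the
minimum of the two adjusted channel values. Probes with detection P > 0.05
in any sample of the analyzed set are excluded; under the default generator
settings the excluded fraction is well below 0.1%, because every probe has
at least one channel (M or U) carrying most of the total intensity.

The scalar test uses the exact permutation distribution whenever the input
is tie-free and small enough to enumerate, and the tie-corrected normal
approximation with continuity correction otherwise; a fully tied input
returns P = 0.5 one-sided (the mid-rank convention's limit). One
calibration subtlety: uniformity of the null detection P holds across
independent replicates. If many probes are tested against one shared
finite negative pool, their P-values are correlated through that pool's
realization and the empirical distribution deviates from uniform by
roughly 1/√n_neg no matter how many probes are tested. The calibration
tests therefore draw a fresh pool per replicate.

## Differential methylation

The effect size between two sample groups is Δβ, the difference of
group-mean β. Markers change "by 0.2 or more": hypermethylated at
Δβ ≥ 0.2, hypomethylated at Δβ ≤ −0.2. Significance comes from a
two-sided two-sample Wilcoxon rank-sum test on the per-sample β values,
BH-adjusted across all retained probes of one comparison; comparisons
(age, sun, tissue, sex) are adjusted independently. `classify_markers`
supports both the Δ-only rule and the stricter rule that additionally
requires P(BH) < 0.01.

For the group sizes of this design (up to 10 per side) the exact
permutation null is used. For tie-free rows the rank-sum null distribution
over subsets of {1..N} is universal and computed once by dynamic
programming; rows with mid-rank ties get a per-row enumeration of all
group assignments. Two-sided P is twice the smaller tail (each tail
including the observed value), capped at 1; rows constant across both
groups return P = 1. Beyond 10 per side the tie-corrected normal
approximation applies.

**Granularity of the exact test.** With five samples per group there are
C(10,5) = 252 assignments, so the smallest attainable two-sided P is
2/252 ≈ 0.0079 and the attainable P-values below 0.05 are {2, 4, 8}/252.
Two consequences worth knowing:

- the null fraction of probes with p < 0.05 is exactly 8/252 ≈ 0.032, not
  0.05 — the test is conservative at conventional thresholds;
- a genome-wide BH-adjusted P below 0.01 is mathematically unattainable
  (BH at rank k requires p_raw ≤ 0.01·k/27578, i.e. more than ~21,800
  discoveries). Any filter stated as "P(BH) < 0.01" cannot bind in this
  regime. Where such a filter selects markers for the global shift test,
  the pipeline uses the raw-P < 0.01 rule instead: the same selection
  intent at the granularity five-per-group data supports. The shift-test
  function itself accepts any P-vector and thresholds, so the BH variant
  is available for larger designs.

Missing β values are excluded pairwise; probes with fewer than two values
in a group are dropped and reported.

## Global shift statistics

The RS ("ratio over sum") curve visualizes a genome-wide methylation
trend. Probes are sorted by |Δβ| in decreasing order (ties broken by probe
id) and the N-th point is

    x_N = N / M,    y_N = Σ_{i≤N} Δβ_i / Σ_{i≤N} (β_A,i + β_B,i).

The final point equals the global ratio of total Δβ to total β, a
conservation property the tests verify on arbitrary inputs. This
cumulative ratio-over-sum form is this package's documented reconstruction
of the plot — consistent with its name, the prescribed sorting rule and
the MA-plot analogy — and is isolated in one function so an alternative
formula can be swapped without touching callers.

The shift test asks whether the Δβ distribution of selected markers
(P filter as above, plus per-probe pooled within-group sd < 0.1 — which
sd the filter means is itself a choice; pooled within-group sd is used and
configurable) differs from chance: a Welch two-sample t-test against
`n_null` = 10,000 seeded draws from Normal(0.0, 0.1). A one-sample t-test
against mean 0 is available as a variant (`one_sample=True`); the
two-sample form is the default because the procedure is defined against a
random Gaussian sample. Under the null the test is calibrated: feeding
Δβ ~ N(0, 0.1) gives a 5% rejection rate at α = 0.05 over seeded
replicates.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
not the chemistry. A 27,578-probe universe (73% CpG-island associated, 4%
on chromosome X) receives a per-probe baseline β from a three-component
mixture: unmethylated ~ Beta(1, 20), methylated ~ Beta(20, 1),
intermediate ~ Uniform(0.2, 0.8), with weights 0.86/0.05/0.09 for island
probes and 0.51/0.29/0.20 otherwise — reproducing the bimodal profile
(86% of island markers at β ≤ 0.2, 5% at β ≥ 0.8, 29% methylated outside
islands). The study layout is 50 samples: 10 male suction-blister
epidermis samples (5 young, 5 old) and 40 female punch-biopsy samples
(10 donors × epidermis/dermis × sun-exposed/protected).

Planted effects, added to the shared baseline per sample group and
clamped to [0, 1]:

| effect | fraction of probes | magnitude | applies to |
|---|---|---|---|
| age hypermethylation | 110/27,578 (~0.4%), 87% island | +0.3 | old donors |
| sun hypomethylation | 14/27,578 (~0.05%) | −0.3 | sun-exposed sites |
| tissue differential | 1,776/27,578 (742 epidermis-hyper) | ±0.3 | dermis vs epidermis |
| X hypermethylation | all X probes | +0.3 | female donors |

Effect subsets are sampled disjointly and only from probes whose baseline
leaves room for the full shift (≤ 1−δ for hyper, ≥ δ for hypo), so the
ground-truth label "shifted by 0.3" is exact rather than censored by the
clamp — without this restriction roughly 8% of planted hyper effects would
be partially clamped and the recovery metrics would be measuring the
truth labels' own error.

Bead intensities: the methylated-allele beads (green channel) have mean
`total·β`, unmethylated (red) `total·(1−β)`, with `total` = 2000 a.u.,
15 beads per allele, and multiplicative lognormal noise at CV = 0.10 —
a standard fluorescence noise model; the emulated study reports no noise
magnitudes, so these are tuning parameters of the generator, chosen once
as realistic for this array class, not claims about the original data.
Negative-control beads (150 per channel and sample) are lognormal with
mean `total·0.02` and CV 0.5. All randomness derives from a single integer
seed split deterministically per sub-generator; identical seeds give
byte-identical outputs.

What the generator does **not** model: Infinium I/II chemistry
differences, dye bias, batch effects, bisulfite PCR strand bias,
sequencing error in reads, and biological interindividual variation beyond
bead noise. Passing recovery tests therefore show the pipeline correctly
inverts this generative model at realistic noise, not that it is robust to
artifacts real arrays can show.

## Bisulfite amplicon calling

Bisulfite reads are simulated full-length and error-free apart from
conversion: each CpG cytosine stays C with its site probability, every
non-CpG cytosine converts to T with probability 0.995 (the deamination
efficiency). Calling inverts this: at covered CpG positions C → methylated
and T → unmethylated, other bases are gaps; non-CpG cytosines tally the
conversion QC, flagged below 99%. Only the top strand is modeled. Reads
shorter than the amplicon are placed at the best ungapped offset under a
bisulfite-aware score (reference C matches read T), rejected below 90%
identity; gapped alignment (homopolymer indels) is out of scope. Reads
with partial conversion failure are retained with their per-read
efficiency reported, rather than filtered. Sequencing-vs-array concordance
pairs each linked CpG's percent methylation with 100× the array group-mean
β and flags differences above 20 points (the β = 0.2 convention in
percentage units).

## Numerical and degenerate-input choices

- Exact-test enumeration is capped at 500,000 assignments per row; beyond
  that (unreachable for ≤ 10 per side) the normal approximation applies.
- β with zero denominator returns 0; negative intensities floor at 0.
- Quantile normalization of a single sample is the identity, with a
  warning.
- Zero-variance profiles make r² undefined (NaN plus warning), not 0 or 1.
- Zero-coverage bisulfite sites are reported missing, never 0%.
- Fewer than 3 markers surviving the shift-test filters raises an error
  naming the failed filter.
- Writes are atomic (temp file + rename) and every output carries the
  package version and a config hash in `#` header comments; summaries are
  key-sorted JSON so identical runs are byte-identical.

## Problem sizes

The analysis drivers and the acceptance script run the full 50-sample,
27,578-probe study (≈ 41 million simulated beads, a few minutes on one
core). The test suite exercises the same code mostly on smaller universes,
with one session-scoped 20-sample full-probe fixture backing the
parameter-recovery checks; exact-test oracles enumerate group sizes up to
6, and calibration checks use 1,000–10,000 replicates.
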