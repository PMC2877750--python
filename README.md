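# methylskin

Bead-level analysis of two-channel CpG methylation arrays for skin
epigenetics studies — aging, chronic sun exposure, tissue identity and sex
— together with a synthetic bead-level data generator and a bisulfite
amplicon methylation caller for validation.

## The problem

Genome-scale DNA methylation in human skin is remarkably stable between
individuals (replicate profiles correlate at r² ≈ 0.97–0.98), which makes
small, directed shifts detectable with few samples: aging hypermethylates
a small set of mostly CpG-island markers, chronic sun exposure
hypomethylates an even smaller set, epidermis and dermis differ at
thousands of markers, and X-linked probes are hypermethylated in females.
Detecting these shifts from raw bead intensities requires a specific
statistical chain, which this package implements end to end:

1. **Quantile normalization** of the green and red channels separately
   (their raw distributions differ in shape).
2. **Detection P-values**: per channel, a one-sided Mann–Whitney test of
   each probe's beads against the negative-control beads, BH-adjusted
   across probes, minimum over the two channels; probes with P > 0.05
   anywhere are excluded.
3. **Beta values** β = M/(M + U + 100) per probe and sample, in [0, 1].
4. **Differential methylation**: Δβ (difference of group means) with a
   ≥ 0.2 call threshold, per-probe exact two-sample Wilcoxon P, and
   Benjamini–Hochberg adjustment; marker counts stratified by CpG-island
   association and chromosome.
5. **Global shift statistics**: the RS (ratio-over-sum) curve over probes
   sorted by |Δβ|, and a Welch t-test of the selected Δβ distribution
   against a Normal(0, 0.1) null.
6. **Bisulfite amplicon calling**: per-read, per-CpG methylation from
   converted reads, deamination-efficiency QC at non-CpG cytosines, and
   concordance with array β values.

A first-class synthetic-data module generates bead tables and bisulfite
reads with the full statistical structure above (bimodal β architecture,
planted age/sun/tissue/sex effects, lognormal bead noise), so every stage
is testable without array downloads — and with known ground truth.

## Worked example

```python
import methylskin as mk

design = mk.default_design()              # the 50-sample study layout
ann = mk.make_annotation(27578, seed=7)   # probe universe
betas, truth = mk.make_true_betas(ann, design, seed=7)
beads = mk.simulate_beads(betas, design, seed=7)

matrix = mk.preprocess_beads(beads)       # normalize -> detect -> beta
old = design.query("age_group == 'old' and sex == 'male'").sample_id.tolist()
young = design.query("age_group == 'young' and sex == 'male'").sample_id.tolist()
res = mk.differential_analysis(matrix.beta, old, young, annotation=ann)
print(res.counts["n_hyper"], res.counts["n_hypo"])
print(len(res.markers("hyper") & set(truth.age_hyper)))
```

prints

```
110 0
110
```

— all 110 planted age-hypermethylation markers (Δβ = +0.3) are recovered
as hypermethylated at the Δβ ≥ 0.2 cutoff, with no hypomethylated and no
false calls, from bead-level data at realistic noise.

The same chain is available from the shell:

```bash
methylskin simulate --n-probes 27578 --seed 7 --out study/
methylskin preprocess --beads study/beads.tsv --out study/
methylskin diff --beta study/beta.tsv --manifest study/manifest.tsv \
    --annotation study/annotation.tsv \
    --group-by age_group --a old --b young --out study/age/
methylskin shift-test --diff study/age/differential.tsv --seed 7
```

The `analysis/` directory holds the numbered drivers for the complete
study narrative (simulate → preprocess → differential → global shift →
bisulfite validation); each writes compact summaries to `results/` and
large intermediates to `scratch/`.

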