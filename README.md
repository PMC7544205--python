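# rnptools

Tested, reusable implementations of three computational analyses used to
characterise how an RNA-binding protein engages messenger RNP biogenesis:

1. **Stoichiometric IP-MS interaction profiling** — from MaxQuant-style
   `proteinGroups` label-free quantification (LFQ) tables to bait-relative
   interaction stoichiometries, hierarchical clustering of IP conditions and
   multi-bait overlap (Venn) counts.
2. **CLIP metagene / crosslink-conversion analysis** — strand-aware PAR-CLIP
   T>C conversion calling from `samtools mpileup` text, scaled TSS-to-TES and
   exon-anchored metagene profiles, and histograms of crosslink offsets
   upstream of exon–exon junctions (where the exon junction complex sits,
   ~20–27 nt upstream of the junction).
3. **Exon-number-bias analysis of differential expression** — given a
   DESeq2-format results table and a GTF, compare exon-count distributions of
   up- vs down-regulated transcripts (cumulative frequencies, Mann–Whitney U),
   with expression-matched subsets to control for expression level.

A fourth module, `synthetic_data`, generates ground-truthed inputs for all
three arms (LFQ matrices with planted interactors and missing-not-at-random
dropout; a toy genome annotation with crosslink events planted at known
junction offsets; DE tables whose down-regulation probability depends on exon
count), so every stage is testable end to end without downloading anything.

## The statistics at the core

**Enrichment.** After removing decoy/contaminant rows, log2-transforming LFQ
intensities, requiring ≥ 2 valid values per group, and imputing missing
values from a down-shifted normal N(μ<sub>col</sub> − 1.8 σ<sub>col</sub>,
(0.3 σ<sub>col</sub>)²) per sample column (the Perseus defaults), each bait
IP is tested against the control IP with a SAM-style moderated statistic

&nbsp;&nbsp;&nbsp;&nbsp;d = (x̄<sub>bait</sub> − x̄<sub>ctrl</sub>) / (s + s₀),

where s is the pooled two-sample standard error and s₀ (default 1 on the
log2 scale) damps significance at small fold changes. False discovery rates
come from sample-label permutations: q(p) = mean permuted count of
|d| ≥ |d<sub>p</sub>| divided by the observed count, clipped to [0, 1] and
made monotone. Proteins with q < 0.01 and positive log2 fold change are
significantly enriched.

**Stoichiometric abundance.** For each significant protein p in one IP
condition,

&nbsp;&nbsp;&nbsp;&nbsp;A<sub>p</sub> = mean LFQ(p, bait IP)/MW<sub>p</sub> − mean LFQ(p, control IP)/MW<sub>p</sub>,
&nbsp;&nbsp;&nbsp;&nbsp;S<sub>p</sub> = 100 · A<sub>p</sub> / A<sub>bait</sub>,

so the bait is pinned at 100 and S estimates copies per 100 bait copies.
Non-positive values are reported as ND. Heatmaps and clustering use
log2(S × 10³) with Euclidean distances and average linkage.

**Conversion calling.** At reference-T pileup positions, uppercase `C` read
bases are counted as plus-strand T>C crosslink conversions; at reference-A
positions, lowercase `g` bases (reverse reads) are minus-strand conversions.

**Exon bias.** At a DESeq2 FDR cutoff of 0.1, exon counts of up- vs
down-regulated transcripts are compared with a two-sided Mann–Whitney U test
(exact enumeration for small samples, tie-corrected normal approximation
otherwise), optionally on a greedily expression-matched 1:1 subset
(caliper 0.1 on log10 baseMean).

## Worked example

```python
import rnptools as rt

# --- IP-MS arm: 5 interactors planted at stoichiometries 0.5 ... 0.01 ---
matrix, truth = rt.simulate_ipms(rt.IpmsSimConfig(seed=11))
cfg = rt.TestConfig(seed=12)
logm = rt.impute_missing(
    rt.filter_valid_values(rt.log2_transform(matrix), cfg.min_valid), cfg)
result = rt.sam_test(logm, logm.samples_for("bait", "c1"),
                     logm.samples_for("control", "c1"), cfg)
called = rt.call_significant(result, cfg)
print(sorted(called))
# ['BAIT', 'INT001', 'INT002', 'INT003', 'INT004', 'INT005']

s = rt.stoichiometric_abundance(matrix, called, "BAIT", "c1")
print(s.dropna().sort_values(ascending=False).round(2))
# BAIT      100.00
# INT001     47.69
# INT002     23.86
# INT003      9.99
# INT004      4.90
# INT005      0.99
```

Exactly the bait and the five planted interactors are called significant out
of 206 proteins, and their recovered stoichiometric abundances (S/100 ≈ 0.48,
0.24, 0.10, 0.05, 0.01) track the configured truth (0.5, 0.2, 0.1, 0.05,
0.01) within replicate noise. The bait row is exactly 100 by construction of
the final normalization step.

```python
# --- CLIP arm: conversion events planted 10-20 and 25-35 nt upstream ---
ann = rt.simulate_annotation(rt.AnnotationSimConfig(n_transcripts=200, seed=11))
pileup, bed, _ = rt.simulate_clip(ann, rt.ClipSimConfig(seed=11))
open("sim.pileup", "w").write(pileup)
track = rt.call_conversions("sim.pileup")
hist = rt.junction_offset_histogram(track, ann, max_offset=50)
print(round(hist.loc[10:20].sum() / hist.sum(), 3),
      round(hist.loc[25:35].sum() / hist.sum(), 3))
# 0.516 0.484
```

All 25,541 recovered conversions land in the two planted offset windows, in
the configured 50/50 split up to sampling noise.

```python
# --- exon-bias arm: P(down-regulation) increases with exon count ---
big = rt.simulate_annotation(rt.AnnotationSimConfig(n_transcripts=4000, seed=11))
table, _ = rt.simulate_de_table(big, rt.DeSimConfig(seed=11))
table = rt.attach_exon_counts(rt.assign_directions(table, 0.1), big)
res = rt.exon_bias_test(table)
print(res.n_up, res.n_down, round(res.u_statistic), f"{res.p_value:.3g}")
# 591 425 94004 5.4e-12
matched = rt.expression_match(table, seed=11)
print(f"{rt.exon_bias_test(matched).p_value:.3g}")
# 3.09e-09
```

Down-regulated transcripts have more exons (median 5 vs 4), the Mann–Whitney
test rejects decisively, and the signal persists after expression matching
(410 pairs), showing it is exon- rather than expression-driven.

A `rnptools` console script exposes the same pipelines from the shell
(`rnptools simulate|ipms|stoich|clip|exonbias --help`).

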