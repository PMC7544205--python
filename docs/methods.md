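# Methods

This note documents the models, conventions and numerical choices behind the
three pipeline arms and the synthetic-data generators, including the points
where the design was genuinely open and what the synthetic tests do and do
not demonstrate about real data.

## IP-MS enrichment

**Workflow.** proteinGroups-style TSVs are filtered of rows flagged
"only identified by site", "reverse" or "potential contaminant"; LFQ
intensities of 0/blank are explicit missing values (MaxQuant encodes
non-detection as 0, never a measured zero). Intensities are log2-transformed,
proteins are required to have at least `min_valid` (default 2) observed
values, and remaining missing values are imputed.

**Valid-value scope.** The filter is applied per (role, condition) group by
default — a protein is kept when at least one group has `min_valid` observed
replicates. This keeps proteins that are cleanly detected in the bait IP but
absent from the control, which are exactly the candidates of interest under
left-censored missingness. A whole-row scope is available
(`scope="whole-row"`).

**Imputation.** Missing entries of each sample column are drawn from
Normal(μ − 1.8σ, (0.3σ)²), with μ and σ the observed mean and standard
deviation of that column (the Perseus "width 0.3, down shift 1.8" default).
This models non-detection as left-censoring: imputed values land in the
lower tail of the observed distribution. Columns with fewer than two
observed values are an error unless `impute_global_fallback` enables a
matrix-wide fallback distribution. Observed values are never altered, and
draws are deterministic under `TestConfig.seed`.

**Moderated test.** d = (x̄_a − x̄_b)/(s + s₀) with s the pooled
equal-variance two-sample standard error. With s₀ = 0, d is exactly the
classical Student t statistic (asserted against an independent
implementation in the tests). The default s₀ = 1 on the log2 scale treats the
threshold as the SAM/Perseus fudge factor rather than a separate
fold-change cutoff; the latter reading is available as
`fold_change_cutoff`. A zero denominator with zero numerator
yields d = 0 (a constant row is not evidence of enrichment).

**Permutation FDR.** Group labels are permuted over the pooled samples; for
each protein, q = (mean permuted count of |d| ≥ |d_p|) / (observed count of
|d| ≥ |d_p|), clipped to [0, 1] and made monotone non-increasing in |d| by a
step-up pass (each cutoff inherits the smallest estimate at any weaker
cutoff). The observed assignment and, for balanced designs, its mirror are
excluded from the null: they reproduce the observed statistics identically
and would otherwise floor every q-value at 2/C(n, n_a) (≈ 0.029 in a 4v4
design), making an FDR < 0.01 call structurally impossible at realistic
replicate numbers. `n_permutations` (default 250) is silently capped at the
exhaustive count; `"exhaustive"` forces full enumeration. Ties in |d| are
broken by protein input order; this only affects which of two identical
statistics is listed first and never the q-values themselves.

**Significance.** q < 0.01 (default) and log2 fold change > 0 — enrichment
is one-sided toward the bait IP by definition of a pull-down.

## Stoichiometric abundance

For each significant protein p (plus the bait), on raw un-logged
intensities:

    A_p = mean(bait replicates)/MW_p − mean(control replicates)/MW_p
    S_p = 100 · (A_p / A_bait)

Dividing by molecular weight converts intensity (proportional to total
peptide mass) into a molar quantity, background subtraction removes
non-specific binding, and normalization to the bait yields copies per 100
bait copies. Missing raw values enter the means as 0 by default (absent =
not detected); `missing_as_zero=False` averages observed replicates only.
Non-positive A_p is reported as ND (NaN), as is any S that would be ≤ 0.
A_bait ≤ 0 is a hard error: the condition failed. The ratio is computed as
`100 * (A_p / A_bait)` so the bait row is exactly 100 in IEEE arithmetic.
The bait MW cancels between the numerator of a prey's expected signal and
the bait normalizer, so recovered stoichiometries are insensitive to it.

**Heatmap / clustering.** Heat values are log2(S × 10³); ND propagates.
Conditions are clustered by average-linkage (UPGMA) agglomeration on
Euclidean distances. With ND present, distances are pairwise-complete and
scaled by √(n_total/n_shared) to stay comparable across pairs with different
overlap; column pairs sharing no defined entries receive the maximum
observed distance. Entirely-ND columns are dropped with a warning.

**Overlaps.** Per-bait unions of significant proteins over conditions, the
seven disjoint region counts of the 3-set Venn, and pairwise shared
fractions |A∩B|/|B|.

## CLIP metagene analysis

**Coordinates.** All internal coordinates are 0-based half-open; GTF input
(1-based closed) is converted on load. Exon rank 1 is the 5′-most exon in
transcript orientation — the genomically rightmost exon of a minus-strand
transcript. Categories: monoexonic, first, internal, last.

**Conversion calling.** The mpileup read-base string is parsed token by
token: `^` + mapping-quality char (read start) and `$` (read end) are
markers, `+N…`/`-N…` indel tokens are skipped in full, and `*`, `>`, `<`
consume depth like base symbols. A parsed-symbol count disagreeing with the
depth column is a hard error with the line number. At reference T, uppercase
`C` counts as a plus-strand conversion; at reference A, lowercase `g`
(reverse-strand reads) counts as a minus-strand conversion; everything else
is ignored. The asymmetry encodes that a T>C crosslink conversion on a
minus-strand gene appears as A>G on the reference strand.

**Profiles.** The TSS-to-TES profile maps exonic signal to mature-transcript
coordinates (introns excised), rescales each transcript's mature axis to
`n_bins` with fractional-overlap binning (mass-conserving, so the
un-normalized profile total equals the total assigned signal), and averages
bins across transcripts with equal weight per transcript rather than
weighting by expression. Transcripts shorter than the bin
count are handled by the same fractional binning. Exon-anchored profiles use
only exons strictly longer than 200 nt (> 200, not ≥) and concatenate three segments per exon: the first
`flank_bins` nt at single-nt resolution, the body rescaled to `body_bins`
bins, and the last `flank_bins` nt. Junction offsets are counted in mature
coordinates with offset 1 = the last exonic base before the junction; only
exons followed by a junction (first and internal) contribute, and offsets
beyond `max_offset` are dropped.

Signal within each transcript is sorted by mature coordinate before
accumulation, which makes every profile bit-identical under a global
coordinate reflection plus strand flip (asserted in the tests).

For genes with multiple annotated transcripts the longest mature transcript
represents the gene by default (`per_gene_representative=False` uses all), a
common convention when isoform-level signal cannot be resolved.

## Exon-number bias

Directions are assigned from the DESeq2 columns at `fdr_level` (default
0.1): up iff padj < 0.1 and log2FoldChange > 0, down symmetric, missing padj
(untested transcripts under independent filtering) unchanged. Exon counts
are per transcript id as it appears in the DE table; ids absent from the GTF
are dropped with a logged count. The Mann–Whitney U uses midranks for ties;
the null is enumerated exhaustively for n_x + n_y ≤ 12 (or on request up to
20 — beyond that the C(n, n_x) enumeration is refused), otherwise scipy's
tie-corrected normal approximation with continuity correction is used. The
exact two-sided p compares |U − n_x·n_y/2| across all arrangements, with a
1e-9 slack absorbing midrank float arithmetic.

Expression matching is greedy 1:1 nearest-neighbour on log10(baseMean)
without replacement: up-regulated transcripts are visited in seeded random
order and paired with the closest unused down-regulated transcript within
the caliper (default 0.1 log10 units); unmatched transcripts are discarded.
Greedy matching was chosen over optimal assignment for determinism and
auditability; the caliper is configurable and zero matchable pairs is an
error.

## Synthetic-data generators

The generators emulate the *formats and statistical structure* of the real
inputs, not their content. All are deterministic under their config seed.

**IP-MS** (`simulate_ipms`): one bait (raw intensity 10¹⁰), `n_interactors`
true interactors with mean intensity stoichiometry × bait × MW_i/MW_bait
(default stoichiometries 0.5, 0.2, 0.1, 0.05, 0.01 — spanning core subunits
to peripheral factors), and 200 background proteins with identical
log-uniform (10^6.5–10^9.5) means in both IPs. Bait and interactors are
absent from the control IP. Molecular weights are uniform on 10–300 kDa and
recorded, since the stoichiometry score divides by MW. Replicate noise is
multiplicative lognormal at a 20% CV, 4 + 4 replicates (matching a
triplicate/quadruplicate IP design). Dropout is logistic in log2 intensity
around a detection limit of 10⁷ (50% dropout at the limit), i.e.
missing-not-at-random left-censoring — the mechanism the downshifted-normal
imputation assumes. The TSV writer appends flagged decoy/contaminant rows to
exercise loader filtering. Replicate CV is a plausible default, not
calibrated to any deposited dataset.

**Annotation** (`simulate_annotation`): a single synthetic chromosome with
non-overlapping transcripts; 10% monoexonic, half minus-strand, multiexonic
exon counts from a long-tailed distribution over 2–20, exon lengths uniform
80–400 nt, introns 60–2000 nt. No sequence is emitted: the reference base is
implied by the pileup column, which is the only place it matters.

**CLIP** (`simulate_clip`): per junction, Poisson(3) events by default; each
event draws an offset from a two-peak distribution (uniform over 10–20 and
25–35 nt, equal mass — flanking the canonical EJC footprint), a read depth
Poisson(30), and Binomial(depth, 0.3) conversions. Events are projected to
genomic coordinates respecting strand and emitted as 6-column mpileup text
(uppercase = forward reads, lowercase = reverse; no indel tokens, though the
parser handles them) plus one BED6 interval per site with the conversion
count as score. Offsets exceeding the exon length are skipped and counted in
the truth object.

**DE tables** (`simulate_de_table`): log10 baseMean ~
N(1.5 + 0.5·log10(exon count), 0.8) — the positive coefficient reproduces
the known tendency of many-exon transcripts to be more highly expressed,
which is exactly the confounding expression matching must remove. A
transcript is DE with probability 0.25; given DE, it is down-regulated with
probability expit(−1.2 + 0.15·exon count) (the exon-dependent default; the
null preset sets slope and intercept to 0, giving 50/50). padj is drawn
below `fdr_level` for DE and above it otherwise, with very low-expression
non-DE transcripts left untested (NaN) to mimic independent filtering;
DESeq2's model itself is deliberately not re-implemented, since the analysis
under test begins at its output table.

**What passing tests show.** Generator/analyzer closure (every planted
quantity is recoverable in the noise-free limit), calibration (uniform null
p-values, FDR control within 2× nominal), and power under the planted
effects. They do not show robustness to real-data pathologies absent from
the generators: correlated replicates, batch effects, shared peptides,
overlapping genes, multi-isoform ambiguity, or alignment artefacts.

## Problem sizes

Test and benchmark runs use desk-scale instances chosen to make the
statistical assertions stable: 206-protein matrices (100 seeds for FDR and
recovery checks), 50–200-transcript annotations with ≥10⁴ crosslink events
for distribution-recovery checks (total-variation tolerance 0.05), and
4000-transcript DE tables (200 seeds for null calibration, 100 for power).
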