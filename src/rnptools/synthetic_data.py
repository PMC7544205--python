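"""Ground-truthed synthetic inputs for all three pipeline arms.

Three generators emulate the standard input formats the pipeline consumes,
with known ground truth attached so every downstream stage is testable
without external data:

* :func:`simulate_ipms` — MaxQuant-style LFQ matrices with a bait, true
  interactors at configured stoichiometries, non-specific background
  proteins, multiplicative replicate noise, and intensity-dependent
  (missing-not-at-random) dropout.
* :func:`simulate_annotation` / :func:`simulate_clip` — a toy single
  chromosome genome annotation with mono- and multi-exonic transcripts on
  both strands, plus PAR-CLIP crosslink-conversion events planted at
  configurable offsets upstream of exon-exon junctions, emitted as samtools
  mpileup text and BED intervals.
* :func:`simulate_de_table` — DESeq2-schema differential-expression tables
  in which the probability of down-regulation depends on exon count.

Every generator is deterministic under its config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .clip_metagene import GenomeAnnotation, Transcript
from .ipms_enrichment import (FILTER_COLUMNS, GENE_COLUMN, ID_COLUMN,
                              LFQ_PREFIX, MW_COLUMN, LfqMatrix)

logger = logging.getLogger(__name__)


def _sample_discrete(rng: np.random.Generator, spec, size: int) -> np.ndarray:
    """Sample from a discrete distribution spec: {value: weight} or a constant."""
    if isinstance(spec, (int, np.integer)):
        return np.full(size, int(spec), dtype=np.int64)
    items = sorted(spec.items())
    values = np.array([k for k, _ in items], dtype=np.int64)
    probs = np.array([w for _, w in items], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("distribution weights must be non-negative, sum > 0")
    return rng.choice(values, size=size, p=probs / probs.sum())


def discrete_probabilities(spec) -> pd.Series:
    """Normalized probabilities of a discrete distribution spec."""
    if isinstance(spec, (int, np.integer)):
        return pd.Series({int(spec): 1.0})
    s = pd.Series(spec, dtype=float).sort_index()
    return s / s.sum()


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class IpmsTruth:
    bait_id: str
    interactors: dict          # protein id -> true stoichiometry (bait fraction)
    background_ids: list


@dataclass
class ClipTruth:
    events: pd.DataFrame       # one row per planted crosslink event
    offset_distribution: object
    n_skipped: int = 0


@dataclass
class DeTruth:
    table: pd.DataFrame        # id, exon_count, true_direction


@dataclass
class SyntheticTruth:
    """Per-arm ground truth attached to every generator output."""

    ipms: IpmsTruth | None = None
    clip: ClipTruth | None = None
    de: DeTruth | None = None


# ---------------------------------------------------------------------------
# IP-MS LFQ matrices
# ---------------------------------------------------------------------------

@dataclass
class IpmsSimConfig:
    """Design of a synthetic bait-vs-control IP-MS experiment.

    Interactor mean raw intensity is
    ``stoichiometry * bait_intensity * MW_interactor / MW_bait`` before noise
    and dropout, so molecular-weight-normalized stoichiometry recovery is
    well-posed. Replicate noise is multiplicative lognormal with the given
    coefficient of variation; dropout probability rises as intensity falls
    below ``detection_limit`` (logistic in log2 intensity, 50% at the limit).
    """

    n_background_proteins: int = 200
    n_interactors: int = 5
    true_stoichiometries: tuple = (0.5, 0.2, 0.1, 0.05, 0.01)
    bait_intensity: float = 1e10
    replicate_cv: float = 0.2
    n_bait_replicates: int = 4
    n_control_replicates: int = 4
    detection_limit: float = 1e7
    dropout_curve_steepness: float = 1.5
    background_log10_range: tuple = (6.5, 9.5)
    condition: str = "c1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background_proteins", "n_interactors",
                     "n_bait_replicates", "n_control_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.true_stoichiometries) != self.n_interactors:
            raise ValueError("true_stoichiometries length must equal n_interactors")
        if any(s <= 0 for s in self.true_stoichiometries):
            raise ValueError("stoichiometries must be positive")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.bait_intensity <= 0:
            raise ValueError("bait_intensity must be positive")


def simulate_ipms(config: IpmsSimConfig) -> tuple[LfqMatrix, SyntheticTruth]:
    """Simulate a proteinGroups-style LFQ matrix with known interactors."""
    rng = np.random.default_rng(config.seed)
    bait_id = "BAIT"
    int_ids = [f"INT{i + 1:03d}" for i in range(config.n_interactors)]
    bg_ids = [f"BG{i + 1:04d}" for i in range(config.n_background_proteins)]
    ids = [bait_id] + int_ids + bg_ids
    n = len(ids)

    mw = rng.uniform(10.0, 300.0, size=n)  # kDa
    mw_bait = mw[0]

    lo, hi = config.background_log10_range
    bg_means = 10.0 ** rng.uniform(lo, hi, size=config.n_background_proteins)

    stoich = np.asarray(config.true_stoichiometries, float)
    mean_bait_group = np.concatenate([
        [config.bait_intensity],
        stoich * config.bait_intensity * mw[1:1 + config.n_interactors] / mw_bait,
        bg_means,
    ])
    # bait and specific interactors are absent from the control IP
    mean_ctrl_group = np.concatenate([
        np.zeros(1 + config.n_interactors), bg_means])

    bait_samples = [f"{config.condition}_bait_r{r + 1}"
                    for r in range(config.n_bait_replicates)]
    ctrl_samples = [f"{config.condition}_ctrl_r{r + 1}"
                    for r in range(config.n_control_replicates)]
    means = np.column_stack(
        [mean_bait_group] * len(bait_samples) +
        [mean_ctrl_group] * len(ctrl_samples))

    if config.replicate_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.replicate_cv ** 2))
        noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=means.shape)
        values = means * noise
    else:
        values = means.copy()
    values[means == 0] = np.nan

    if config.detection_limit > 0:
        with np.errstate(divide="ignore"):
            logratio = np.log2(values) - math.log2(config.detection_limit)
        p_drop = expit(-config.dropout_curve_steepness * logratio)
        drop = rng.random(size=values.shape) < p_drop
        values[drop & ~np.isnan(values)] = np.nan

    samples = pd.DataFrame(
        {
            "role": ["bait"] * len(bait_samples) + ["control"] * len(ctrl_samples),
            "condition": config.condition,
            "replicate": list(range(1, len(bait_samples) + 1))
                         + list(range(1, len(ctrl_samples) + 1)),
        },
        index=pd.Index(bait_samples + ctrl_samples, name="sample"),
    )
    matrix = LfqMatrix(
        values=pd.DataFrame(values, index=pd.Index(ids, name=ID_COLUMN),
                            columns=samples.index),
        samples=samples,
        mw_kda=pd.Series(mw, index=ids),
        gene_names=pd.Series(ids, index=ids),
    )
    truth = SyntheticTruth(ipms=IpmsTruth(
        bait_id=bait_id,
        interactors=dict(zip(int_ids, stoich.tolist())),
        background_ids=bg_ids,
    ))
    return matrix, truth


def protein_groups_tsv(matrix: LfqMatrix, n_decoys: int = 3,
                       decoy_seed: int = 1) -> str:
    """Render an :class:`LfqMatrix` as a MaxQuant proteinGroups-style TSV.

    Missing values are written as 0 (the MaxQuant non-detection encoding).
    ``n_decoys`` extra rows flagged in the site-only / reverse / contaminant
    columns are appended to exercise loader filtering.
    """
    df = pd.DataFrame({ID_COLUMN: matrix.values.index})
    df[GENE_COLUMN] = (matrix.gene_names.values if matrix.gene_names is not None
                       else matrix.values.index)
    df[MW_COLUMN] = matrix.mw_kda.values
    for col in FILTER_COLUMNS:
        df[col] = ""
    for sample in matrix.values.columns:
        df[LFQ_PREFIX + sample] = matrix.values[sample].fillna(0.0).values

    rng = np.random.default_rng(decoy_seed)
    decoy_rows = []
    for i in range(n_decoys):
        flag_col = FILTER_COLUMNS[i % len(FILTER_COLUMNS)]
        row = {ID_COLUMN: f"DECOY{i + 1:02d}", GENE_COLUMN: f"DECOY{i + 1:02d}",
               MW_COLUMN: float(rng.uniform(10, 300))}
        for col in FILTER_COLUMNS:
            row[col] = "+" if col == flag_col else ""
        for sample in matrix.values.columns:
            row[LFQ_PREFIX + sample] = float(10 ** rng.uniform(6, 9))
        decoy_rows.append(row)
    if decoy_rows:
        df = pd.concat([df, pd.DataFrame(decoy_rows)], ignore_index=True)
    return df.to_csv(sep="\t", index=False)


def sample_spec_for(matrix: LfqMatrix) -> dict:
    """Loader sample_spec mapping for a simulated matrix's LFQ columns."""
    return {
        LFQ_PREFIX + sample: (row["role"], row["condition"], row["replicate"])
        for sample, row in matrix.samples.iterrows()
    }


# ---------------------------------------------------------------------------
# Toy genome annotation
# ---------------------------------------------------------------------------

#: Default exon-count distribution of multiexonic transcripts.
DEFAULT_EXON_COUNT_DISTRIBUTION = {
    2: 0.18, 3: 0.16, 4: 0.14, 5: 0.12, 6: 0.10,
    8: 0.10, 10: 0.08, 12: 0.06, 15: 0.04, 20: 0.02,
}


@dataclass
class AnnotationSimConfig:
    """Layout of the toy single-chromosome genome annotation."""

    n_transcripts: int = 200
    exon_count_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_EXON_COUNT_DISTRIBUTION))
    exon_length_range: tuple = (80, 400)
    intron_length_range: tuple = (60, 2000)
    fraction_monoexonic: float = 0.1
    fraction_minus_strand: float = 0.5
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        for name in ("exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must satisfy 1 <= min <= max")
        for name in ("fraction_monoexonic", "fraction_minus_strand"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def exon_count_probabilities(config: AnnotationSimConfig) -> pd.Series:
    """Expected exon-count distribution (monoexonic mass + multiexonic spec)."""
    multi = discrete_probabilities(config.exon_count_distribution)
    mixture = multi * (1.0 - config.fraction_monoexonic)
    mixture.loc[1] = mixture.get(1, 0.0) + config.fraction_monoexonic
    return mixture.sort_index()


def simulate_annotation(config: AnnotationSimConfig) -> GenomeAnnotation:
    """Simulate a toy genome annotation on a single synthetic chromosome."""
    rng = np.random.default_rng(config.seed)
    transcripts = []
    cursor = 1000
    exon_lo, exon_hi = config.exon_length_range
    intron_lo, intron_hi = config.intron_length_range
    for i in range(config.n_transcripts):
        if rng.random() < config.fraction_monoexonic:
            n_exons = 1
        else:
            n_exons = int(_sample_discrete(
                rng, config.exon_count_distribution, 1)[0])
        strand = "-" if rng.random() < config.fraction_minus_strand else "+"
        exons = []
        pos = cursor
        for e in range(n_exons):
            length = int(rng.integers(exon_lo, exon_hi + 1))
            exons.append((pos, pos + length))
            pos += length
            if e < n_exons - 1:
                pos += int(rng.integers(intron_lo, intron_hi + 1))
        transcripts.append(Transcript(
            transcript_id=f"tx{i + 1:05d}", gene_id=f"gene{i + 1:05d}",
            chrom=config.chrom, strand=strand, exons=exons,
            biotype="protein_coding"))
        cursor = pos + int(rng.integers(500, 2000))
    return GenomeAnnotation(transcripts)


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write the annotation as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for tr in annotation.transcripts:
            attrs = (f'gene_id "{tr.gene_id}"; '
                     f'transcript_id "{tr.transcript_id}"; '
                     f'transcript_biotype "{tr.biotype}";')
            tx_start = tr.exons[0][0] + 1
            tx_end = tr.exons[-1][1]
            fh.write(f"{tr.chrom}\trnptools\ttranscript\t{tx_start}\t{tx_end}"
                     f"\t.\t{tr.strand}\t.\t{attrs}\n")
            for start, end in tr.exons:
                fh.write(f"{tr.chrom}\trnptools\texon\t{start + 1}\t{end}"
                         f"\t.\t{tr.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# PAR-CLIP conversion events
# ---------------------------------------------------------------------------

#: Two broad offset peaks, 10-20 nt and 25-35 nt upstream of the junction.
DEFAULT_OFFSET_DISTRIBUTION = {
    **{o: 0.5 / 11 for o in range(10, 21)},
    **{o: 0.5 / 11 for o in range(25, 36)},
}


@dataclass
class ClipSimConfig:
    """Crosslink-conversion events planted upstream of exon-exon junctions."""

    offset_distribution: object = field(
        default_factory=lambda: dict(DEFAULT_OFFSET_DISTRIBUTION))
    events_per_junction: float = 3.0
    conversion_rate: float = 0.3
    read_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.conversion_rate <= 1:
            raise ValueError("conversion_rate must lie in [0, 1]")
        if self.events_per_junction < 0 or self.read_depth <= 0:
            raise ValueError("events_per_junction >= 0 and read_depth > 0 required")
        probs = discrete_probabilities(self.offset_distribution)
        if (probs.index < 1).any():
            raise ValueError("offsets must be >= 1 nt upstream of the junction")


def simulate_clip(annotation: GenomeAnnotation, config: ClipSimConfig
                  ) -> tuple[str, str, SyntheticTruth]:
    """Plant conversion events upstream of junctions; emit mpileup + BED text.

    Offsets are drawn in mature-transcript coordinates (offset 1 = last
    exonic base before the junction) and projected to the genome respecting
    strand: plus-strand genes get reference-T lines with uppercase 'C'
    mismatches, minus-strand genes reference-A lines with lowercase 'g'
    mismatches on reverse reads. Events whose offset exceeds the exon length
    are skipped and logged.
    """
    multi = annotation.multiexonic()
    if not multi:
        raise ValueError("annotation needs at least one multiexonic transcript")
    rng = np.random.default_rng(config.seed)
    events = []
    n_skipped = 0
    for tr in multi:
        ranked = tr.exons_in_rank_order()
        for rank, (start, end) in enumerate(ranked, start=1):
            if rank == tr.n_exons:
                continue  # last exon has no downstream junction
            n_events = rng.poisson(config.events_per_junction)
            if n_events == 0:
                continue
            offsets = _sample_discrete(rng, config.offset_distribution, n_events)
            for offset in offsets:
                offset = int(offset)
                if offset > end - start:
                    logger.info("offset %d exceeds exon length %d in %s; "
                                "event skipped", offset, end - start,
                                tr.transcript_id)
                    n_skipped += 1
                    continue
                if tr.strand == "+":
                    pos = end - offset
                else:
                    pos = start + offset - 1
                depth = max(1, int(rng.poisson(config.read_depth)))
                conversions = int(rng.binomial(depth, config.conversion_rate))
                events.append((tr.transcript_id, rank, offset, tr.chrom,
                               pos, tr.strand, depth, conversions))
    events_df = pd.DataFrame(events, columns=[
        "transcript_id", "exon_rank", "offset", "chrom", "pos", "strand",
        "depth", "conversions"])

    # aggregate events sharing a genomic position into one pileup line
    pileup_lines = []
    bed_lines = []
    if len(events_df):
        agg = (events_df.groupby(["chrom", "pos", "strand"], as_index=False)
               [["depth", "conversions"]].sum()
               .sort_values(["chrom", "pos"], kind="stable"))
        for i, row in enumerate(agg.itertuples(index=False)):
            depth, conv = int(row.depth), int(row.conversions)
            if row.strand == "+":
                ref, match, mismatch = "T", ".", "C"
            else:
                ref, match, mismatch = "A", ",", "g"
            bases = match * (depth - conv) + mismatch * conv
            quals = "I" * depth
            pileup_lines.append(
                f"{row.chrom}\t{row.pos + 1}\t{ref}\t{depth}\t{bases}\t{quals}")
            bed_lines.append(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\txl{i + 1}\t{conv}\t"
                f"{row.strand}")
    pileup_text = "\n".join(pileup_lines) + ("\n" if pileup_lines else "")
    bed_text = "\n".join(bed_lines) + ("\n" if bed_lines else "")
    truth = SyntheticTruth(clip=ClipTruth(
        events=events_df, offset_distribution=config.offset_distribution,
        n_skipped=n_skipped))
    return pileup_text, bed_text, truth


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExonEffectModel:
    """How exon count shapes differential expression.

    A transcript is differentially expressed with probability ``p_de``; given
    DE, it is down-regulated with probability
    ``expit(down_intercept + down_slope * exon_count)``. ``down_slope = 0``
    with ``down_intercept = 0`` is the exon-independent null.
    """

    p_de: float = 0.25
    down_intercept: float = -1.2
    down_slope: float = 0.15
    lfc_magnitude: float = 1.5
    lfc_sd: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.p_de <= 1:
            raise ValueError("p_de must lie in [0, 1]")

    def p_down(self, exon_count) -> np.ndarray:
        return expit(self.down_intercept + self.down_slope
                     * np.asarray(exon_count, float))


NULL_EFFECT_MODEL = ExonEffectModel(down_intercept=0.0, down_slope=0.0)


@dataclass
class DeSimConfig:
    """Synthetic DESeq2-format results table over an annotation.

    baseMean is lognormal: log10(baseMean) ~ Normal(log10_mean +
    exon_count_coef * log10(exon_count), log10_sd); the positive default
    coefficient reflects that many-exon transcripts tend to be more highly
    expressed. ``dispersion`` is the log2 fold-change scatter of non-DE
    transcripts.
    """

    n_transcripts: int | None = None  # None = all annotation transcripts
    log10_mean: float = 1.5
    log10_sd: float = 0.8
    exon_count_coef: float = 0.5
    effect_model: ExonEffectModel = field(default_factory=ExonEffectModel)
    dispersion: float = 0.1
    fdr_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")


def simulate_de_table(annotation: GenomeAnnotation, config: DeSimConfig
                      ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit a DESeq2-schema table whose down-regulation bias follows exon count."""
    transcripts = annotation.transcripts
    if config.n_transcripts is not None:
        if config.n_transcripts > len(transcripts):
            raise ValueError("n_transcripts exceeds the annotation size")
        transcripts = transcripts[: config.n_transcripts]
    rng = np.random.default_rng(config.seed)
    model = config.effect_model

    ids = [t.transcript_id for t in transcripts]
    exon_counts = np.array([t.n_exons for t in transcripts])
    n = len(ids)

    log10_bm = rng.normal(
        config.log10_mean + config.exon_count_coef * np.log10(exon_counts),
        config.log10_sd)
    base_mean = 10.0 ** log10_bm

    is_de = rng.random(n) < model.p_de
    is_down = rng.random(n) < model.p_down(exon_counts)
    direction = np.where(is_de, np.where(is_down, "down", "up"), "unchanged")

    magnitude = np.abs(rng.normal(model.lfc_magnitude, model.lfc_sd, size=n))
    magnitude = np.maximum(magnitude, 0.05)
    null_lfc = rng.normal(0.0, config.dispersion, size=n)
    lfc = np.where(direction == "up", magnitude,
                   np.where(direction == "down", -magnitude, null_lfc))

    padj = np.where(is_de,
                    rng.uniform(0.0, config.fdr_level, size=n),
                    rng.uniform(config.fdr_level, 1.0, size=n))
    # emulate DESeq2 independent filtering: very low expression is untested
    padj = np.where(~is_de & (base_mean < 1.0), np.nan, padj)

    table = pd.DataFrame({
        "id": ids,
        "baseMean": base_mean,
        "log2FoldChange": lfc,
        "padj": padj,
    })
    truth = SyntheticTruth(de=DeTruth(table=pd.DataFrame({
        "id": ids, "exon_count": exon_counts, "true_direction": direction})))
    return table, truth
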