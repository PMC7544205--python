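"""CLIP metagene profiles and strand-aware crosslink-conversion calling.

Builds annotation-driven metagene profiles of CLIP signal (scaled
TSS-to-TES transcript profiles and exon-category anchored profiles), extracts
PAR-CLIP crosslink diagnostic conversions from samtools mpileup text (T>C
mismatches on plus-strand genes, A>G on reverse reads of minus-strand genes),
and summarises conversion positions as offsets upstream of exon-exon
junctions, where the exon junction complex is deposited ~20-27 nt upstream of
the junction.

All internal coordinates are 0-based half-open; GTF input (1-based closed) is
converted on load. Exon ranks and categories (monoexonic / first / internal /
last) follow transcript orientation, so the rank-1 exon of a minus-strand
transcript is its genomically rightmost exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXON_CATEGORIES = ("monoexonic", "first", "internal", "last")


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """One transcript with ordered exons (0-based half-open genomic intervals)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list  # [(start, end), ...] sorted by genomic start
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_in_rank_order(self) -> list:
        """Exons ordered 5'->3' in transcript orientation (rank 1 first)."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def exon_category(self, rank: int) -> str:
        """Category of the exon at 1-based ``rank`` in transcript orientation."""
        if self.n_exons == 1:
            return "monoexonic"
        if rank == 1:
            return "first"
        if rank == self.n_exons:
            return "last"
        return "internal"


@dataclass
class GenomeAnnotation:
    transcripts: list

    def __post_init__(self) -> None:
        self.by_id = {t.transcript_id: t for t in self.transcripts}
        if len(self.by_id) != len(self.transcripts):
            raise ValueError("duplicate transcript ids")

    def __len__(self) -> int:
        return len(self.transcripts)

    def multiexonic(self) -> list:
        return [t for t in self.transcripts if t.n_exons > 1]

    def representatives(self) -> list:
        """One transcript per gene: the longest mature sequence (ties by id)."""
        best = {}
        for t in self.transcripts:
            cur = best.get(t.gene_id)
            if cur is None or (t.mature_length, cur.transcript_id) > \
                    (cur.mature_length, t.transcript_id):
                best[t.gene_id] = t
        order = {t.transcript_id: i for i, t in enumerate(self.transcripts)}
        return sorted(best.values(), key=lambda t: order[t.transcript_id])


def load_annotation(gtf_path, biotype_filter: str | None = "protein_coding"
                    ) -> GenomeAnnotation:
    """Load a GTF into a :class:`GenomeAnnotation`.

    1-based closed GTF intervals become 0-based half-open. Transcripts whose
    biotype attribute does not match ``biotype_filter`` are dropped
    (transcripts without any biotype attribute are kept); transcript features
    with zero exon records are skipped with a warning.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )

    def _biotype(attrs) -> str | None:
        for key in ("transcript_biotype", "gene_biotype",
                    "transcript_type", "gene_type"):
            if key in attrs:
                return attrs[key][0]
        return None

    exons_by_tx: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        rec = exons_by_tx.setdefault(tid, {
            "gene_id": ex.attributes.get("gene_id", [tid])[0],
            "chrom": ex.seqid, "strand": ex.strand,
            "biotype": _biotype(ex.attributes), "exons": [],
        })
        rec["exons"].append((ex.start - 1, ex.end))

    try:
        tx_features = list(db.features_of_type("transcript"))
    except Exception:  # pragma: no cover - feature type absent
        tx_features = []
    for tx in tx_features:
        tid = tx.attributes["transcript_id"][0]
        if tid not in exons_by_tx:
            logger.warning("transcript %s has no exon records; skipped", tid)
        else:
            bt = _biotype(tx.attributes)
            if bt is not None:
                exons_by_tx[tid]["biotype"] = bt

    transcripts = []
    for tid, rec in exons_by_tx.items():
        biotype = rec["biotype"]
        if biotype_filter is not None and biotype is not None \
                and biotype != biotype_filter:
            continue
        transcripts.append(Transcript(
            transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], exons=rec["exons"],
            biotype=biotype or "protein_coding"))
    return GenomeAnnotation(transcripts)


# ---------------------------------------------------------------------------
# Crosslink tracks
# ---------------------------------------------------------------------------

@dataclass
class CrosslinkTrack:
    """Strand-aware per-position signal: (chrom, pos, strand) -> score >= 0."""

    records: pd.DataFrame  # columns chrom, pos, strand, score

    COLUMNS = ("chrom", "pos", "strand", "score")

    def __post_init__(self) -> None:
        df = self.records
        if df is None or len(df) == 0:
            df = pd.DataFrame(columns=list(self.COLUMNS))
        df = (df.groupby(["chrom", "pos", "strand"], as_index=False)["score"]
                .sum()
                .sort_values(["chrom", "strand", "pos"], kind="stable")
                .reset_index(drop=True))
        if len(df) and (df["score"] < 0).any():
            raise ValueError("track scores must be non-negative")
        self.records = df
        self._index: dict = {}
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=False):
            self._index[(chrom, strand)] = (
                grp["pos"].to_numpy(np.int64), grp["score"].to_numpy(float))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_score(self) -> float:
        return float(self.records["score"].sum()) if len(self.records) else 0.0

    def positions_in(self, chrom: str, strand: str, start: int, end: int):
        """Positions (ascending) and scores inside [start, end) on one strand."""
        pos, score = self._index.get((chrom, strand),
                                     (np.empty(0, np.int64), np.empty(0)))
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], score[lo:hi]

    def to_bed(self, path) -> None:
        """Write one BED6 row per position (name = site index, score column)."""
        with open(path, "w") as fh:
            for i, row in enumerate(self.records.itertuples(index=False)):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\tsite{i}\t"
                         f"{row.score:g}\t{row.strand}\n")


def load_track_bed(bed_path, mode: str = "per-base") -> CrosslinkTrack:
    """Load BED6 intervals as a per-base crosslink track.

    mode="per-base" assigns the full interval score to every covered base;
    mode="score-per-length" divides the score by the interval length first.
    Overlapping intervals sum per base.
    """
    if mode not in ("per-base", "score-per-length"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{bed_path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, _name, score, strand = parts[:6]
            if strand not in "+-":
                raise ValueError(
                    f"{bed_path}:{lineno}: malformed strand field {strand!r}")
            start, end, score = int(start), int(end), float(score)
            per_base = score if mode == "per-base" else score / max(end - start, 1)
            for pos in range(start, end):
                rows.append((chrom, pos, strand, per_base))
    return CrosslinkTrack(pd.DataFrame(rows, columns=list(CrosslinkTrack.COLUMNS)))


# ---------------------------------------------------------------------------
# Conversion calling from mpileup text
# ---------------------------------------------------------------------------

def _parse_pileup_bases(bases: str, lineno: int) -> list[str]:
    """Expand an mpileup read-base string into one symbol per read base.

    Handles read-start ('^' + mapping quality char), read-end ('$') and
    indel ('+N<seq>' / '-N<seq>') tokens, none of which consume depth; '*',
    '>' and '<' placeholders do.
    """
    symbols = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret plus mapping-quality char
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ValueError(f"line {lineno}: malformed indel token")
            length = int(bases[i + 1:j])
            i = j + length
        else:
            symbols.append(c)
            i += 1
    return symbols


def call_conversions(mpileup_path) -> CrosslinkTrack:
    """Extract PAR-CLIP diagnostic conversions from samtools mpileup text.

    At reference T positions, uppercase 'C' read bases are counted as
    plus-strand T>C conversions; at reference A positions, lowercase 'g' read
    bases (reverse reads) are counted as minus-strand conversions (A>G on the
    reference = T>C on the transcribed minus strand). All other mismatches
    are ignored. File positions are 1-based; the returned track is 0-based.
    """
    rows = []
    with open(mpileup_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: expected 6 mpileup columns")
            chrom, pos1, ref, depth, bases = parts[0], parts[1], parts[2], \
                parts[3], parts[4]
            symbols = _parse_pileup_bases(bases, lineno)
            if len(symbols) != int(depth):
                raise ValueError(
                    f"line {lineno}: depth {depth} inconsistent with "
                    f"{len(symbols)} parsed read bases")
            ref = ref.upper()
            pos0 = int(pos1) - 1
            if ref == "T":
                count = sum(1 for s in symbols if s == "C")
                if count:
                    rows.append((chrom, pos0, "+", float(count)))
            elif ref == "A":
                count = sum(1 for s in symbols if s == "g")
                if count:
                    rows.append((chrom, pos0, "-", float(count)))
    return CrosslinkTrack(pd.DataFrame(rows, columns=list(CrosslinkTrack.COLUMNS)))


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Averaged signal over features mapped to a common binned axis."""

    values: np.ndarray       # mean signal per bin
    n_features: int
    bin_labels: list
    total: float             # summed signal assigned across all features

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(len(self.values)),
            "label": self.bin_labels,
            "mean_signal": self.values,
            "n": self.n_features,
        })


def _transcript_mature_signal(track: CrosslinkTrack, tr: Transcript):
    """(mature positions, scores) of track entries on a transcript's exons.

    Positions are returned sorted by mature coordinate (5'->3' in transcript
    orientation), which keeps downstream accumulation order independent of
    genomic strand.
    """
    mats, scores = [], []
    cum = 0
    for start, end in tr.exons_in_rank_order():
        pos, sc = track.positions_in(tr.chrom, tr.strand, start, end)
        if len(pos):
            if tr.strand == "+":
                mats.append(cum + (pos - start))
            else:
                mats.append(cum + (end - 1 - pos))
            scores.append(sc)
        cum += end - start
    if not mats:
        return np.empty(0, np.int64), np.empty(0)
    mats = np.concatenate(mats)
    scores = np.concatenate(scores)
    order = np.argsort(mats, kind="stable")
    return mats[order], scores[order]


def _bin_fractional(mats: np.ndarray, scores: np.ndarray, length: int,
                    n_bins: int) -> np.ndarray:
    """Distribute per-nt scores onto ``n_bins`` scaled bins, mass-conserving.

    Each mature base i occupies [i, i+1) on the nt axis, i.e.
    [i*n/L, (i+1)*n/L) on the bin axis; its score is split over the bins it
    overlaps in proportion to overlap.
    """
    out = np.zeros(n_bins)
    scale = n_bins / length
    for m, s in zip(mats, scores):
        lo = m * scale
        hi = (m + 1) * scale
        b0 = int(np.floor(lo))
        b1 = min(int(np.ceil(hi)), n_bins)
        for b in range(b0, b1):
            overlap = min(hi, b + 1) - max(lo, b)
            if overlap > 0:
                out[b] += s * overlap / scale
    return out


def metagene_transcript_profile(track: CrosslinkTrack,
                                annotation: GenomeAnnotation,
                                n_bins: int,
                                per_gene_representative: bool = True
                                ) -> MetaProfile:
    """Scaled TSS-to-TES profile of exonic CLIP signal.

    Per transcript, exonic signal is mapped to mature-transcript coordinates
    (introns excised), the mature axis is rescaled to ``n_bins`` with
    fractional-overlap binning, and bins are averaged across transcripts
    (each transcript weighted equally). Bin 1 is always the TSS regardless of
    genomic strand.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    transcripts = (annotation.representatives() if per_gene_representative
                   else annotation.transcripts)
    sums = np.zeros(n_bins)
    total = 0.0
    for tr in transcripts:
        mats, scores = _transcript_mature_signal(track, tr)
        binned = _bin_fractional(mats, scores, tr.mature_length, n_bins)
        sums += binned
        total += float(scores.sum())
    n = len(transcripts)
    labels = [f"bin{i + 1}" for i in range(n_bins)]
    return MetaProfile(values=sums / n if n else sums, n_features=n,
                       bin_labels=labels, total=total)


def exon_anchored_profile(track: CrosslinkTrack, annotation: GenomeAnnotation,
                          category: str, min_exon_len: int = 200,
                          flank_bins: int = 50, body_bins: int = 100,
                          per_gene_representative: bool = True) -> MetaProfile:
    """Anchored profile over exons of one category (strictly > min_exon_len).

    Each qualifying exon contributes three segments in transcript
    orientation: its first ``flank_bins`` nt at single-nt resolution (5'
    anchor), its whole body rescaled to ``body_bins`` bins, and its last
    ``flank_bins`` nt (3' anchor). Segments are averaged across exons.
    """
    if category not in EXON_CATEGORIES:
        raise ValueError(f"category must be one of {EXON_CATEGORIES}")
    if flank_bins > min_exon_len:
        raise ValueError("flank_bins cannot exceed min_exon_len")
    transcripts = (annotation.representatives() if per_gene_representative
                   else annotation.transcripts)
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros(n_bins)
    total = 0.0
    n_exons = 0
    for tr in transcripts:
        cum = 0
        for rank, (start, end) in enumerate(tr.exons_in_rank_order(), start=1):
            length = end - start
            if tr.exon_category(rank) == category and length > min_exon_len:
                mats, scores = _transcript_mature_signal(track, tr)
                in_exon = (mats >= cum) & (mats < cum + length)
                em = mats[in_exon] - cum      # 0-based position within exon, 5'->3'
                es = scores[in_exon]
                # 5' anchor
                head = em < flank_bins
                np.add.at(sums, em[head], es[head])
                # scaled body
                sums[flank_bins:flank_bins + body_bins] += _bin_fractional(
                    em, es, length, body_bins)
                # 3' anchor
                tail = em >= length - flank_bins
                np.add.at(sums,
                          flank_bins + body_bins + (em[tail] - (length - flank_bins)),
                          es[tail])
                total += float(es.sum())
                n_exons += 1
            cum += length
    if n_exons == 0:
        logger.warning("no %s exons longer than %d nt", category, min_exon_len)
    labels = ([f"5p+{i}" for i in range(flank_bins)]
              + [f"body{i + 1}" for i in range(body_bins)]
              + [f"3p-{flank_bins - i}" for i in range(flank_bins)])
    values = sums / n_exons if n_exons else sums
    return MetaProfile(values=values, n_features=n_exons,
                       bin_labels=labels, total=total)


def junction_offset_histogram(track: CrosslinkTrack,
                              annotation: GenomeAnnotation,
                              max_offset: int = 50,
                              per_gene_representative: bool = True) -> pd.Series:
    """Summed conversion signal by offset upstream of exon-exon junctions.

    For every exon followed by a junction (first and internal exons of
    multiexonic transcripts), each track position inside the exon contributes
    its score at offset = mature-coordinate distance to the exon's 3' end
    (offset 1 = last exonic base). Offsets beyond ``max_offset`` are dropped.
    """
    transcripts = (annotation.representatives() if per_gene_representative
                   else annotation.transcripts)
    if not any(t.n_exons > 1 for t in transcripts):
        raise ValueError("annotation has no multiexonic transcripts")
    hist = np.zeros(max_offset)
    for tr in transcripts:
        ranked = tr.exons_in_rank_order()
        for rank, (start, end) in enumerate(ranked, start=1):
            if rank == tr.n_exons:  # no downstream junction
                continue
            pos, sc = track.positions_in(tr.chrom, tr.strand, start, end)
            if not len(pos):
                continue
            if tr.strand == "+":
                offsets = end - pos
            else:
                offsets = pos - start + 1
            keep = offsets <= max_offset
            np.add.at(hist, offsets[keep] - 1, sc[keep])
    return pd.Series(hist, index=pd.RangeIndex(1, max_offset + 1, name="offset"),
                     name="conversion_count")
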