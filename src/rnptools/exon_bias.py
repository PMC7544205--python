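"""Exon-number bias in differential expression results.

Consumes DESeq2-format results tables (id, baseMean, log2FoldChange, padj),
classifies transcripts as up-/down-regulated at an FDR cutoff, attaches exon
counts from a genome annotation, and compares the exon-count distributions of
the two groups with cumulative frequencies and a Mann-Whitney U test. An
expression-matched subset (greedy caliper matching on log10 baseMean) guards
against expression level confounding the exon-count comparison.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .clip_metagene import GenomeAnnotation

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "baseMean", "log2FoldChange", "padj")


# ---------------------------------------------------------------------------
# Loading and annotation
# ---------------------------------------------------------------------------

def assign_directions(df: pd.DataFrame, fdr_level: float = 0.1) -> pd.DataFrame:
    """Add the ``direction`` column: up / down / unchanged.

    up iff padj < fdr_level and log2FoldChange > 0; down symmetric; missing
    padj (transcripts DESeq2 did not test) means unchanged.
    """
    sig = df["padj"].notna() & (df["padj"] < fdr_level)
    df = df.copy()
    df["direction"] = "unchanged"
    df.loc[sig & (df["log2FoldChange"] > 0), "direction"] = "up"
    df.loc[sig & (df["log2FoldChange"] < 0), "direction"] = "down"
    return df


def load_de_table(path, fdr_level: float = 0.1) -> pd.DataFrame:
    """Read a DESeq2-format results TSV and assign regulation directions."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table is missing required columns: {missing}")
    return assign_directions(df, fdr_level=fdr_level)


def attach_exon_counts(table: pd.DataFrame,
                       annotation: GenomeAnnotation) -> pd.DataFrame:
    """Attach per-transcript exon counts from the annotation.

    Transcript ids absent from the annotation are dropped (count logged).
    """
    counts = {t.transcript_id: t.n_exons for t in annotation.transcripts}
    biotypes = {t.transcript_id: t.biotype for t in annotation.transcripts}
    resolvable = table["id"].isin(counts)
    n_dropped = int((~resolvable).sum())
    if n_dropped:
        logger.info("dropped %d DE rows with ids absent from the annotation",
                    n_dropped)
    out = table.loc[resolvable].copy()
    out["exon_count"] = out["id"].map(counts).astype(int)
    out["biotype"] = out["id"].map(biotypes)
    return out


# ---------------------------------------------------------------------------
# Exon-count comparison
# ---------------------------------------------------------------------------

def exon_count_ecdf(table: pd.DataFrame) -> dict:
    """Cumulative frequency of exon counts per regulation direction.

    Returns {"up": ECDF, "down": ECDF} (statsmodels step functions).
    """
    out = {}
    for direction in ("up", "down"):
        counts = table.loc[table["direction"] == direction, "exon_count"]
        if counts.empty:
            raise ValueError(f"no transcripts in direction {direction!r}")
        out[direction] = ECDF(counts.to_numpy(float))
    return out


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (midranks for ties)."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def _exact_mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumeration of all group assignments.

    Valid with ties: enumerates every C(n_x+n_y, n_x) split of the combined
    multiset and compares |U - n_x*n_y/2| with the observed value.
    """
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    center = nx * ny / 2
    obs_dev = abs(u_obs - center)
    n_total = nx + ny
    n_extreme = 0
    n_all = 0
    rank_offset = nx * (nx + 1) / 2
    for idx in itertools.combinations(range(n_total), nx):
        u = float(ranks[list(idx)].sum() - rank_offset)
        # tolerance guards midrank float arithmetic in the tie case
        if abs(u - center) >= obs_dev - 1e-9:
            n_extreme += 1
        n_all += 1
    return u_obs, n_extreme / n_all


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test (two-sided) of two count samples.

    Exact null by enumeration when n_x+n_y <= 12 or mode="exact" (refused
    above 20 samples total); otherwise the normal approximation with
    tie-corrected variance and continuity correction via scipy.

    Returns ``(U_x, p_two_sided)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n_total = len(x) + len(y)
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and n_total > 20:
        raise ValueError("exact enumeration refused for n_x+n_y > 20")
    if mode == "exact" or (mode == "auto" and n_total <= 12):
        return _exact_mann_whitney(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class BiasTestResult:
    """Exon-count comparison of up- vs down-regulated transcripts."""

    n_up: int
    n_down: int
    u_statistic: float
    p_value: float
    ecdfs: dict
    matched_ids: list | None = None


def exon_bias_test(table: pd.DataFrame, mode: str = "auto",
                   biotype: str | None = None) -> BiasTestResult:
    """Mann-Whitney comparison of exon counts in up vs down transcripts."""
    if biotype is not None:
        table = table[table["biotype"] == biotype]
    up = table.loc[table["direction"] == "up", "exon_count"].to_numpy(float)
    down = table.loc[table["direction"] == "down", "exon_count"].to_numpy(float)
    if len(up) == 0 or len(down) == 0:
        raise ValueError("need at least one transcript in each direction")
    u, p = mann_whitney(up, down, mode=mode)
    return BiasTestResult(n_up=len(up), n_down=len(down), u_statistic=u,
                          p_value=p, ecdfs=exon_count_ecdf(table))


# ---------------------------------------------------------------------------
# Expression matching
# ---------------------------------------------------------------------------

def expression_match(table: pd.DataFrame, caliper_log10: float = 0.1,
                     seed: int = 0) -> pd.DataFrame:
    """Expression-matched subset of up- and down-regulated transcripts.

    Greedy 1:1 nearest-neighbour matching on log10(baseMean) without
    replacement: up-regulated transcripts are visited in seeded random order
    and each is paired with the closest unused down-regulated transcript
    within the caliper; pairs outside the caliper are discarded. The result
    contains equal numbers of up and down transcripts and a ``pair`` column.
    """
    if caliper_log10 < 0:
        raise ValueError("caliper must be non-negative")
    up = table[table["direction"] == "up"]
    down = table[table["direction"] == "down"]
    if up.empty or down.empty:
        raise ValueError("both directions must be non-empty")
    rng = np.random.default_rng(seed)

    up_expr = np.log10(up["baseMean"].to_numpy(float))
    down_expr = np.log10(down["baseMean"].to_numpy(float))
    visit = rng.permutation(len(up))
    used = np.zeros(len(down), dtype=bool)
    pairs = []
    for i in visit:
        dist = np.abs(down_expr - up_expr[i])
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= caliper_log10:
            used[j] = True
            pairs.append((i, j))
    if not pairs:
        raise ValueError(
            "no up/down pairs within the caliper; consider increasing it")
    pairs.sort()
    rows = []
    for k, (i, j) in enumerate(pairs):
        for row in (up.iloc[i], down.iloc[j]):
            rec = row.to_dict()
            rec["pair"] = k
            rows.append(rec)
    return pd.DataFrame(rows).reset_index(drop=True)
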