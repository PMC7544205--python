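"""Stoichiometric interaction profiles from IP-MS enrichment results.

Converts raw LFQ intensities of significantly enriched proteins into
stoichiometric abundances relative to the bait (bait = 100), the
log2(S x 10^3) heatmap transform, average-linkage hierarchical clustering of
IP conditions on Euclidean distances, and multi-bait overlap (Venn) region
counts.

The stoichiometric abundance of protein p in one IP condition is

    A_p = mean_raw(p, bait replicates) / MW_p
        - mean_raw(p, control replicates) / MW_p
    S_p = 100 * A_p / A_bait

Missing raw intensities are treated as zero in the means by default (the
MaxQuant convention that absent = not detected); non-positive
background-subtracted values are reported as ND (NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ipms_enrichment import LfqMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stoichiometric abundance
# ---------------------------------------------------------------------------

def stoichiometric_abundance(raw: LfqMatrix, significant: set[str],
                             bait_id: str, condition,
                             missing_as_zero: bool = True) -> pd.Series:
    """Bait-relative stoichiometric abundance for one IP condition.

    Only proteins in ``significant`` (plus the bait) are scored. Returns a
    Series indexed by protein id with S on the bait = 100 scale; ND is NaN.
    """
    if raw.log_transformed:
        raise ValueError("stoichiometric abundance uses raw (un-logged) intensities")
    if bait_id not in raw.values.index:
        raise ValueError(f"bait {bait_id!r} not present in the matrix")
    bait_cols = raw.samples_for(role="bait", condition=condition)
    ctrl_cols = raw.samples_for(role="control", condition=condition)
    if not bait_cols or not ctrl_cols:
        raise ValueError(f"condition {condition!r} lacks bait or control samples")

    proteins = [p for p in raw.values.index if p in significant or p == bait_id]
    sub_bait = raw.values.loc[proteins, bait_cols]
    sub_ctrl = raw.values.loc[proteins, ctrl_cols]
    if missing_as_zero:
        mean_bait = sub_bait.fillna(0.0).mean(axis=1)
        mean_ctrl = sub_ctrl.fillna(0.0).mean(axis=1)
    else:
        mean_bait = sub_bait.mean(axis=1).fillna(0.0)
        mean_ctrl = sub_ctrl.mean(axis=1).fillna(0.0)

    mw = raw.mw_kda.loc[proteins]
    a = mean_bait / mw - mean_ctrl / mw
    a_bait = a.loc[bait_id]
    if a_bait <= 0:
        raise ValueError(
            f"bait {bait_id!r} is not enriched over control in condition "
            f"{condition!r} (A_bait = {a_bait:g}); condition unusable")
    # ratio first so the bait row is exactly 100 (x/x == 1 in IEEE arithmetic)
    s = 100.0 * (a / a_bait)
    s[s <= 0] = np.nan  # ND
    s.name = condition
    return s


def stoichiometry_table(raw: LfqMatrix, significant_by_condition: dict,
                        bait_id: str, missing_as_zero: bool = True) -> pd.DataFrame:
    """Stoichiometric abundances across conditions (proteins x conditions)."""
    cols = {
        cond: stoichiometric_abundance(raw, sig, bait_id, cond,
                                       missing_as_zero=missing_as_zero)
        for cond, sig in significant_by_condition.items()
    }
    table = pd.DataFrame(cols)
    return table.dropna(how="all")


def heat_transform(table: pd.DataFrame | pd.Series):
    """Heatmap values log2(S x 10^3); ND (NaN) propagates to ND."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(table * 1000.0)


# ---------------------------------------------------------------------------
# Hierarchical clustering of IP conditions
# ---------------------------------------------------------------------------

@dataclass
class ConditionClustering:
    """Average-linkage tree over IP-condition columns."""

    linkage: np.ndarray          # scipy linkage matrix
    labels: list                 # condition labels, input order (post ND-drop)
    leaf_order: list             # labels in dendrogram leaf order
    cophenetic: np.ndarray       # condensed cophenetic distances


def _pairwise_complete_euclidean(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed Euclidean distances over columns, ND-tolerant.

    Distances use pairwise-complete rows, scaled by sqrt(n_total / n_shared)
    to stay comparable across pairs with different numbers of shared defined
    entries; pairs sharing no defined entries get the maximum observed
    distance.
    """
    x = matrix.to_numpy(float)
    n_rows, n_cols = x.shape
    dist = np.zeros((n_cols, n_cols))
    no_overlap = []
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            shared = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            n_shared = int(shared.sum())
            if n_shared == 0:
                no_overlap.append((i, j))
                continue
            diff = x[shared, i] - x[shared, j]
            d = np.sqrt(np.sum(diff ** 2) * (n_rows / n_shared))
            dist[i, j] = dist[j, i] = d
    if no_overlap:
        dmax = dist.max()
        for i, j in no_overlap:
            dist[i, j] = dist[j, i] = dmax
    return squareform(dist, checks=False)


def cluster_conditions(matrix: pd.DataFrame, distance: str = "euclidean",
                       linkage: str = "average") -> ConditionClustering:
    """Agglomerative clustering of condition columns.

    Columns that are entirely ND are dropped with a warning. Only Euclidean
    distance is supported (pairwise-complete in the presence of ND).
    """
    if distance != "euclidean":
        raise ValueError("only euclidean distances are supported")
    all_nd = matrix.columns[matrix.isna().all(axis=0)]
    if len(all_nd):
        logger.warning("dropping entirely-ND condition columns: %s", list(all_nd))
        matrix = matrix.drop(columns=all_nd)
    if matrix.shape[1] < 2:
        raise ValueError("need at least two non-empty condition columns")
    condensed = _pairwise_complete_euclidean(matrix)
    z = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(z)
    labels = list(matrix.columns)
    return ConditionClustering(
        linkage=z,
        labels=labels,
        leaf_order=[labels[i] for i in leaves],
        cophenetic=hierarchy.cophenet(z),
    )


# ---------------------------------------------------------------------------
# Multi-bait overlaps (3-set Venn regions)
# ---------------------------------------------------------------------------

@dataclass
class OverlapSets:
    """Per-bait unions of significant proteins and 3-set Venn region counts.

    ``regions`` is keyed by membership pattern over the three baits in input
    order, e.g. "110" = in baits 1 and 2 only. ``shared_fraction[(a, b)]`` is
    |A ∩ B| / |B|.
    """

    baits: list
    unions: dict
    regions: dict
    shared_fraction: dict


def overlap_sets(per_bait_significant: dict) -> OverlapSets:
    """Region counts of the 3-set Venn over per-bait unions of significant hits.

    ``per_bait_significant`` maps each of exactly three baits to a list of
    per-condition significant-protein sets; a protein counts for a bait if it
    is significant in at least one of its conditions.
    """
    if len(per_bait_significant) != 3:
        raise ValueError("overlap_sets expects exactly three baits")
    baits = list(per_bait_significant)
    unions = {b: set().union(*sets) if sets else set()
              for b, sets in per_bait_significant.items()}
    u = [unions[b] for b in baits]
    regions = {}
    for pattern in ("100", "010", "001", "110", "101", "011", "111"):
        inc = [s for s, bit in zip(u, pattern) if bit == "1"]
        exc = [s for s, bit in zip(u, pattern) if bit == "0"]
        region = set.intersection(*inc) - set().union(*exc) if exc \
            else set.intersection(*inc)
        regions[pattern] = len(region)
    shared = {}
    for a in baits:
        for b in baits:
            if a != b:
                shared[(a, b)] = (len(unions[a] & unions[b]) / len(unions[b])
                                  if unions[b] else 0.0)
    return OverlapSets(baits=baits, unions=unions, regions=regions,
                       shared_fraction=shared)
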