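"""Perseus-style enrichment analysis of label-free IP-MS proteinGroups tables.

Implements the standard affinity-purification MS enrichment workflow: row
filtering of decoy/contaminant identifications, log2 transformation of LFQ
intensities, valid-value filtering, imputation of missing values from a
left-shifted normal distribution, and a SAM-style moderated two-sample test
with permutation-based FDR estimation.

LFQ intensities of zero (or blank) encode non-detection in MaxQuant output
and are carried as explicit missing values (NaN) throughout; they are never
treated as measured zeros on the log scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: proteinGroups columns whose "+" flag marks a row for removal.
FILTER_COLUMNS = ("Only identified by site", "Reverse", "Potential contaminant")

MW_COLUMN = "Mol. weight [kDa]"
ID_COLUMN = "Protein IDs"
GENE_COLUMN = "Gene names"
LFQ_PREFIX = "LFQ intensity "


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LfqMatrix:
    """Proteins x samples LFQ intensity matrix with sample design metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per sample. Missing
        (non-detected) entries are NaN.
    samples
        DataFrame indexed by sample label with columns ``role`` ("bait" or
        "control"), ``condition`` (IP/extraction condition id) and
        ``replicate`` (integer replicate index).
    mw_kda
        Molecular weight per protein in kDa (required, > 0).
    gene_names
        Optional gene symbols, aligned with ``values.index``.
    log_transformed
        Whether ``values`` hold log2 intensities.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    mw_kda: pd.Series
    gene_names: pd.Series | None = None
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample metadata index must match value columns")
        if self.samples.index.duplicated().any():
            raise ValueError("sample labels must be unique")
        self.mw_kda = self.mw_kda.reindex(self.values.index)
        if self.mw_kda.isna().any() or (self.mw_kda <= 0).any():
            raise ValueError("every protein needs a positive molecular weight")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    def samples_for(self, role: str | None = None,
                    condition: object | None = None) -> list[str]:
        """Sample labels matching a role and/or condition."""
        mask = pd.Series(True, index=self.samples.index)
        if role is not None:
            mask &= self.samples["role"] == role
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def copy(self) -> "LfqMatrix":
        return LfqMatrix(
            values=self.values.copy(),
            samples=self.samples.copy(),
            mw_kda=self.mw_kda.copy(),
            gene_names=None if self.gene_names is None else self.gene_names.copy(),
            log_transformed=self.log_transformed,
        )


@dataclass
class TestConfig:
    """Parameters of the imputation + moderated-test stage.

    ``s0`` is the SAM fudge factor added to the pooled standard error of the
    test statistic; ``impute_width`` and ``impute_downshift`` are the Perseus
    defaults for imputation from a down-shifted normal (width 0.3 and
    downshift 1.8, both in units of the per-column standard deviation).
    """

    s0: float = 1.0
    n_permutations: int | str = 250
    fdr_threshold: float = 0.01
    min_valid: int = 2
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    impute_global_fallback: bool = False
    fold_change_cutoff: float | None = None  # optional extra |log2FC| filter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.min_valid < 1:
            raise ValueError("min_valid must be >= 1")
        if self.n_permutations != "exhaustive" and int(self.n_permutations) < 1:
            raise ValueError("n_permutations must be >= 1 or 'exhaustive'")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_protein_groups(path, sample_spec: dict) -> LfqMatrix:
    """Read a MaxQuant-style proteinGroups TSV into an :class:`LfqMatrix`.

    Rows flagged "+" in any of the "Only identified by site", "Reverse" or
    "Potential contaminant" columns are removed. Zero or blank LFQ
    intensities become explicit missing values.

    ``sample_spec`` maps each ``LFQ intensity <sample>`` column name to a
    ``(role, condition, replicate)`` tuple.
    """
    df = pd.read_csv(path, sep="\t", dtype={ID_COLUMN: str})
    if MW_COLUMN not in df.columns:
        raise ValueError(f"required column {MW_COLUMN!r} is missing")
    if ID_COLUMN not in df.columns:
        raise ValueError(f"required column {ID_COLUMN!r} is missing")

    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    unmapped = [c for c in lfq_cols if c not in sample_spec]
    if unmapped:
        raise ValueError(f"unmapped LFQ intensity columns: {unmapped}")

    n_before = len(df)
    for col in FILTER_COLUMNS:
        if col in df.columns:
            flagged = df[col].astype(str).str.strip() == "+"
            df = df.loc[~flagged]
    n_dropped = n_before - len(df)
    logger.info("filtered %d flagged rows (site-only/reverse/contaminant)", n_dropped)
    if len(df) == 0:
        logger.warning("no proteins survive the decoy/contaminant filter")

    df = df.set_index(ID_COLUMN)
    values = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    values = values.where(values > 0)  # 0/blank encodes non-detection
    sample_labels = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    values.columns = sample_labels

    samples = pd.DataFrame(
        [sample_spec[c] for c in lfq_cols],
        index=pd.Index(sample_labels, name="sample"),
        columns=["role", "condition", "replicate"],
    )
    gene_names = df[GENE_COLUMN] if GENE_COLUMN in df.columns else None
    return LfqMatrix(
        values=values,
        samples=samples,
        mw_kda=df[MW_COLUMN].astype(float),
        gene_names=gene_names,
    )


# ---------------------------------------------------------------------------
# Transform / filter / impute
# ---------------------------------------------------------------------------

def log2_transform(m: LfqMatrix) -> LfqMatrix:
    """Return a copy with log2-transformed intensities (missing stays missing)."""
    if m.log_transformed:
        raise ValueError("matrix is already log2-transformed")
    if (m.values <= 0).any().any():
        raise ValueError("non-positive observed intensity: corrupt input")
    out = m.copy()
    out.values = np.log2(m.values)
    out.log_transformed = True
    return out


def filter_valid_values(m: LfqMatrix, min_valid: int = 2,
                        scope: str = "any-group") -> LfqMatrix:
    """Keep proteins with enough observed values.

    scope="any-group" (default): a protein is kept iff it has >= ``min_valid``
    observed values among the replicates of at least one (role, condition)
    group. scope="whole-row": >= ``min_valid`` observed values across all
    samples.
    """
    if not m.log_transformed:
        raise ValueError("valid-value filtering expects a log-transformed matrix")
    observed = m.values.notna()
    if scope == "any-group":
        groups = m.samples.groupby(["role", "condition"], sort=False).groups
        max_group = max(len(cols) for cols in groups.values())
        if min_valid > max_group:
            raise ValueError(
                f"min_valid={min_valid} exceeds the largest group size {max_group}")
        keep = pd.Series(False, index=m.values.index)
        for cols in groups.values():
            keep |= observed[list(cols)].sum(axis=1) >= min_valid
    elif scope == "whole-row":
        if min_valid > m.values.shape[1]:
            raise ValueError("min_valid exceeds the number of samples")
        keep = observed.sum(axis=1) >= min_valid
    else:
        raise ValueError(f"unknown scope {scope!r}")
    logger.info("valid-value filter (%s, >=%d): kept %d of %d proteins",
                scope, min_valid, int(keep.sum()), len(keep))
    out = m.copy()
    out.values = m.values.loc[keep]
    out.mw_kda = m.mw_kda.loc[keep]
    if m.gene_names is not None:
        out.gene_names = m.gene_names.loc[keep]
    return out


def impute_missing(m: LfqMatrix, cfg: TestConfig) -> LfqMatrix:
    """Impute missing log2 intensities from a down-shifted normal per column.

    Missing entries in each sample column are drawn from
    Normal(mean_col - downshift * sd_col, (width * sd_col)^2), emulating
    left-censored non-detection. Observed values are never altered.
    """
    if not m.log_transformed:
        raise ValueError("imputation expects a log-transformed matrix")
    rng = np.random.default_rng(cfg.seed)
    out = m.copy()
    all_observed = m.values.values[~np.isnan(m.values.values)]
    for col in m.values.columns:
        col_vals = out.values[col]
        missing = col_vals.isna()
        if not missing.any():
            continue
        observed = col_vals.dropna()
        if len(observed) >= 2:
            mu, sd = observed.mean(), observed.std(ddof=1)
        elif cfg.impute_global_fallback and len(all_observed) >= 2:
            mu, sd = all_observed.mean(), all_observed.std(ddof=1)
        else:
            raise ValueError(
                f"column {col!r} has <2 observed values and no global fallback")
        draws = rng.normal(mu - cfg.impute_downshift * sd,
                           cfg.impute_width * sd, size=int(missing.sum()))
        out.values.loc[missing, col] = draws
    return out


# ---------------------------------------------------------------------------
# SAM-style moderated test with permutation FDR
# ---------------------------------------------------------------------------

def _d_statistic(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """Moderated statistic d = (mean_a - mean_b) / (s_pooled + s0), rowwise.

    ``s_pooled`` is the pooled two-sample standard error; with s0 = 0 this is
    the classical equal-variance Student t statistic. A zero denominator with
    zero numerator yields d = 0.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    denom = se + s0
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
        d = np.where(denom == 0,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf), d)
    return d


def _label_assignments(n_total: int, n_a: int,
                       n_permutations: int | str, seed: int):
    """Yield index arrays for group A under sample-label permutation.

    The observed assignment (group A = the first ``n_a`` columns) and, for
    ``n_a == n_total - n_a``, its mirror are excluded: they reproduce the
    observed statistics exactly and are not draws from the null. Exhaustive
    mode enumerates every other C(n_total, n_a) assignment; otherwise
    ``n_permutations`` random non-observed assignments are drawn (silently
    capped at the exhaustive count).
    """
    observed = frozenset(range(n_a))
    mirror = frozenset(range(n_a, n_total)) if 2 * n_a == n_total else None
    exhaustive = math.comb(n_total, n_a) - 1 - (mirror is not None)
    if n_permutations == "exhaustive" or (
            isinstance(n_permutations, int) and n_permutations >= exhaustive):
        for combo in itertools.combinations(range(n_total), n_a):
            fs = frozenset(combo)
            if fs != observed and fs != mirror:
                yield np.asarray(combo)
        return
    rng = np.random.default_rng(seed)
    count = 0
    while count < int(n_permutations):
        idx = rng.permutation(n_total)[:n_a]
        fs = frozenset(int(i) for i in idx)
        if fs == observed or fs == mirror:
            continue
        count += 1
        yield idx


def _permutation_q(d_obs: np.ndarray, values: np.ndarray, n_a: int,
                   s0: float, n_permutations: int | str, seed: int) -> np.ndarray:
    """Perseus/SAM-convention permutation q-values for |d|.

    For each protein, q = (mean over permutations of the number of permuted
    |d| >= |d_obs|) / (number of observed |d| >= |d_obs|), clipped to [0, 1]
    and made monotone non-increasing in |d| by a step-up pass. Ties in |d|
    are broken by protein input order (non-semantic).
    """
    n_total = values.shape[1]
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")  # most significant first
    sorted_abs = abs_obs[order]
    # observed count of |d| >= threshold, ties included
    asc = np.sort(abs_obs)
    obs_count = len(abs_obs) - np.searchsorted(asc, sorted_abs, side="left")

    perm_count = np.zeros(len(abs_obs))
    n_perms = 0
    for a_idx in _label_assignments(n_total, n_a, n_permutations, seed):
        mask = np.zeros(n_total, dtype=bool)
        mask[a_idx] = True
        d_perm = _d_statistic(values[:, mask], values[:, ~mask], s0)
        perm_sorted = np.sort(np.abs(d_perm))
        perm_count += len(perm_sorted) - np.searchsorted(
            perm_sorted, sorted_abs, side="left")
        n_perms += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        q_raw = (perm_count / n_perms) / obs_count
    q_raw = np.clip(q_raw, 0.0, 1.0)
    # step-up: q at a cutoff is the best (smallest) estimate at any weaker cutoff
    q_mono = np.minimum.accumulate(q_raw[::-1])[::-1]
    q = np.empty_like(q_mono)
    q[order] = q_mono
    return q


def sam_test(m: LfqMatrix, group_a: list[str], group_b: list[str],
             cfg: TestConfig) -> pd.DataFrame:
    """SAM-style moderated two-sample test of group A (bait) vs B (control).

    Returns a DataFrame indexed by protein with columns ``mean_bait``,
    ``mean_control``, ``log2_fc``, ``d``, ``q`` and ``significant``
    (q < fdr_threshold and log2_fc > 0, i.e. enrichment toward the bait only).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    sub = m.values[list(group_a) + list(group_b)]
    if sub.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    values = sub.to_numpy(float)
    n_a = len(group_a)
    a, b = values[:, :n_a], values[:, n_a:]
    d = _d_statistic(a, b, cfg.s0)
    q = _permutation_q(d, values, n_a, cfg.s0, cfg.n_permutations, cfg.seed)
    result = pd.DataFrame(
        {
            "mean_bait": a.mean(axis=1),
            "mean_control": b.mean(axis=1),
            "log2_fc": a.mean(axis=1) - b.mean(axis=1),
            "d": d,
            "q": q,
        },
        index=m.values.index,
    )
    result["significant"] = (result["q"] < cfg.fdr_threshold) & (result["log2_fc"] > 0)
    if cfg.fold_change_cutoff is not None:
        result["significant"] &= result["log2_fc"].abs() > cfg.fold_change_cutoff
    return result


def call_significant(result: pd.DataFrame, cfg: TestConfig) -> set[str]:
    """Proteins significantly enriched on the bait side.

    q < fdr_threshold and log2 fold change > 0 (enrichment is one-sided
    toward the bait IP).
    """
    mask = (result["q"] < cfg.fdr_threshold) & (result["log2_fc"] > 0)
    if cfg.fold_change_cutoff is not None:
        mask &= result["log2_fc"].abs() > cfg.fold_change_cutoff
    return set(result.index[mask])
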