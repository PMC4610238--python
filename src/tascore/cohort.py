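"""Cohort-level addiction statistics: ranking, group tests, co-addiction.

Mirrors the primary-patient workflow: rank samples by their addiction to a
target of interest (e.g. a mutated kinase), test whether mutation-positive
and -negative samples separate in addiction with the Wilcoxon rank-sum
test, and search for co-addiction partners — other targets whose addiction
profile across the cohort tracks the anchor target's (Spearman, Bonferroni
corrected).  Shared-compound counts from the network are reported alongside
each partner so that correlation forced by shared inhibitors can be told
apart from genuinely distinct co-addiction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .errors import InvalidConfigError, LookupError_, UndefinedCorrelationError
from .network import TargetNetwork
from .tas import TASMatrix

logger = logging.getLogger(__name__)

EXACT_SIZE_THRESHOLD = 12
MIN_SHARED_SAMPLES = 5

__all__ = [
    "GroupComparison",
    "rank_samples_by_target",
    "compare_groups",
    "coaddiction",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group rank-sum comparison result."""

    statistic: float
    p_value: float
    method: str  # "exact" or "normal-approximation-with-tie-correction"
    n_positive: int
    n_negative: int
    alternative: str = "two-sided"


def _tas_frame(tas: TASMatrix | pd.DataFrame) -> pd.DataFrame:
    return tas.data if isinstance(tas, TASMatrix) else tas


def rank_samples_by_target(tas: TASMatrix | pd.DataFrame, target: str) -> pd.DataFrame:
    """Rank samples by their addiction to ``target``, descending.

    Ties keep input order (stable sort); samples with a missing score rank
    last and are flagged in the ``missing`` column.
    """
    data = _tas_frame(tas)
    if target not in data.columns:
        raise LookupError_(f"unknown target {target!r}")
    col = data[target]
    table = pd.DataFrame(
        {"sample_id": col.index, "tas": col.to_numpy(), "missing": col.isna().to_numpy()}
    )
    table = table.sort_values(
        ["missing", "tas"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return table


def compare_groups(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    *,
    alternative: str = "two-sided",
    exact_threshold: int = EXACT_SIZE_THRESHOLD,
) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney U) test between two labelled groups.

    ``labels`` must contain exactly two levels; the lexicographically larger
    level (e.g. "positive" > "negative") is treated as the first group so a
    one-sided "greater" alternative asks whether positives score higher.
    The exact null enumeration is used when both groups have at most
    ``exact_threshold`` observations and the data are tie-free; otherwise a
    normal approximation with continuity and tie correction.
    """
    vals = pd.Series(np.asarray(values, dtype=float))
    labs = pd.Series(np.asarray(labels))
    if len(vals) != len(labs):
        raise InvalidConfigError("values and labels must align")
    mask = vals.notna()
    vals, labs = vals[mask], labs[mask]
    levels = sorted(labs.unique())
    if len(levels) != 2:
        raise InvalidConfigError(f"need exactly two groups, got {levels}")
    hi, lo = levels[1], levels[0]
    x = vals[labs == hi].to_numpy()
    y = vals[labs == lo].to_numpy()
    if x.size == 0 or y.size == 0:
        raise InvalidConfigError("both groups must be nonempty")
    has_ties = pd.Series(np.concatenate([x, y])).duplicated().any()
    use_exact = (x.size <= exact_threshold and y.size <= exact_threshold) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if use_exact else "normal-approximation-with-tie-correction",
        n_positive=int(x.size),
        n_negative=int(y.size),
        alternative=alternative,
    )


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by full enumeration of group assignments.

    Independent brute-force reference for small groups: enumerates every
    way of assigning the pooled ranks to the first group and counts
    assignments with a U statistic at least as extreme as observed.
    Handles ties via midranks.  Exponential in the pooled size — intended
    for validation at n <= ~14, not production use.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n1 = x.size
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = pooled.size
    mid = n1 * (n - n1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if alternative == "greater":
            count += u >= obs_u - 1e-9
        elif alternative == "less":
            count += u <= obs_u + 1e-9
        else:
            count += abs(u - mid) >= abs(obs_u - mid) - 1e-9
    return count / total


def coaddiction(
    tas: TASMatrix | pd.DataFrame,
    anchor_target: str,
    rho_threshold: float = 0.94,
    alpha: float = 1e-5,
    network: TargetNetwork | None = None,
    min_samples: int = MIN_SHARED_SAMPLES,
) -> pd.DataFrame:
    """Spearman co-addiction of every other target with the anchor.

    Correlations use pairwise-complete samples; targets with fewer than
    ``min_samples`` shared samples are skipped with a warning.  Raw p-values
    are Bonferroni-adjusted over the number of targets actually tested, and
    partners are targets with rho > ``rho_threshold`` and adjusted p <
    ``alpha``.  When a network is supplied, the number of compounds each
    target shares with the anchor is annotated — identical compound sets
    force rho = 1 by construction of the addiction score.
    """
    data = _tas_frame(tas)
    if anchor_target not in data.columns:
        raise LookupError_(f"unknown anchor target {anchor_target!r}")
    anchor = data[anchor_target]
    if anchor.notna().sum() < min_samples:
        raise InvalidConfigError(
            f"anchor {anchor_target!r} has fewer than {min_samples} non-missing samples"
        )
    if anchor.dropna().nunique() == 1:
        raise UndefinedCorrelationError(f"anchor column {anchor_target!r} is constant")

    anchor_compounds = set(network.compounds_of(anchor_target)) if network else None
    rows = []
    for t in data.columns:
        if t == anchor_target:
            continue
        other = data[t]
        mask = anchor.notna() & other.notna()
        n_shared = int(mask.sum())
        if n_shared < min_samples:
            logger.warning("skipping target %s: only %d shared samples", t, n_shared)
            continue
        if other[mask].nunique() == 1:
            logger.warning("skipping target %s: constant addiction profile", t)
            continue
        rho, p = spearmanr(anchor[mask], other[mask])
        shared = (
            len(anchor_compounds & set(network.compounds_of(t))) if network else np.nan
        )
        rows.append((t, float(rho), float(p), n_shared, shared))
    if not rows:
        raise InvalidConfigError("no targets could be tested against the anchor")
    table = pd.DataFrame(
        rows, columns=["target_id", "rho", "p_raw", "n_samples", "shared_compounds"]
    )
    n_tested = len(table)
    table["p_bonferroni"] = np.minimum(table["p_raw"] * n_tested, 1.0)
    table["partner"] = (table["rho"] > rho_threshold) & (table["p_bonferroni"] < alpha)
    table.attrs["anchor_target"] = anchor_target
    table.attrs["n_tested"] = n_tested
    return table.sort_values("rho", ascending=False, ignore_index=True)
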