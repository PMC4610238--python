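"""Distances, Ward clustering, bootstrap cluster support and sample projection.

The clustering layer works on profile matrices (rows = objects such as cell
samples, columns = features such as targets or compounds).  The default
distance is the cosangle dissimilarity (uncentered correlation),

    d(x, y) = 1 - (x . y) / (||x|| ||y||),

which is invariant to positive rescaling of either profile and lies in
[0, 2].  Trees are built with Ward's minimum-variance linkage applied to the
distance matrix (ward.D2 semantics: squared distances in the Lance-Williams
update).

Cluster robustness is assessed by bootstrap: feature columns are resampled
with replacement, each replicate re-clustered, and a cluster's support is
the fraction of replicates whose tree contains the identical leaf set.  The
support is weighted by a linear height factor between 0.1 (leaf-level
merges) and 1 (the root), so that robustness of large, high sub-clusters
counts more than trivially tight pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .errors import InvalidConfigError, UndefinedDistanceError

logger = logging.getLogger(__name__)

MIN_SHARED_COORDS = 3

DISTANCE_LABELS = (
    "cosangle",
    "euclidean",
    "manhattan",
    "pearson",
    "spearman",
    "kendall",
    "binary",
)

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterSupport",
    "cosangle_distance",
    "profile_distance",
    "binary_label_distance",
    "ward_cluster",
    "cut_clusters",
    "bootstrap_support",
    "weighted_robustness",
    "project_and_correlate",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with object ids."""

    ids: list[str]
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        n = len(self.ids)
        if v.shape != (n, n):
            raise InvalidConfigError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidConfigError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InvalidConfigError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(v)):
            raise InvalidConfigError("distance matrix entries must be finite")
        # enforce exact symmetry/zero diagonal for downstream squareform
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return ~(np.isnan(x) | np.isnan(y))


def cosangle_distance(profiles: pd.DataFrame) -> DistanceMatrix:
    """Cosangle (uncentered-correlation) dissimilarity between rows.

    Missing entries are handled by pairwise-complete coordinates; fewer than
    three shared coordinates, or a zero-norm profile on the shared
    coordinates, is an error naming the offending row(s).
    """
    x = profiles.to_numpy(dtype=float)
    ids = [str(i) for i in profiles.index]
    if x.shape[0] < 2:
        raise InvalidConfigError("need >=2 rows for a distance matrix")
    if np.isnan(x).any():
        n = x.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mask = _pairwise_complete(x[i], x[j])
                if mask.sum() < MIN_SHARED_COORDS:
                    raise UndefinedDistanceError(
                        f"rows {ids[i]!r} and {ids[j]!r} share fewer than "
                        f"{MIN_SHARED_COORDS} coordinates"
                    )
                xi, xj = x[i, mask], x[j, mask]
                ni, nj = np.linalg.norm(xi), np.linalg.norm(xj)
                if ni == 0.0 or nj == 0.0:
                    bad = ids[i] if ni == 0.0 else ids[j]
                    raise UndefinedDistanceError(f"zero-norm profile for row {bad!r}")
                d[i, j] = d[j, i] = 1.0 - float(xi @ xj) / (ni * nj)
    else:
        norms = np.linalg.norm(x, axis=1)
        if np.any(norms == 0.0):
            bad = ids[int(np.argmax(norms == 0.0))]
            raise UndefinedDistanceError(f"zero-norm profile for row {bad!r}")
        xn = x / norms[:, None]
        d = 1.0 - xn @ xn.T
        np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return DistanceMatrix(ids=ids, values=d, label="cosangle")


def _correlation_distance(profiles: pd.DataFrame, method: str) -> np.ndarray:
    corr = profiles.T.corr(method=method, min_periods=MIN_SHARED_COORDS)
    if corr.isna().any().any():
        bad = corr.index[corr.isna().any(axis=1)][0]
        raise UndefinedDistanceError(f"undefined {method} correlation involving row {bad!r}")
    return 1.0 - corr.to_numpy()


def profile_distance(profiles: pd.DataFrame, label: str = "cosangle") -> DistanceMatrix:
    """Distance matrix between rows under any supported distance label.

    Supported: cosangle, euclidean, manhattan, pearson, spearman, kendall.
    Correlation distances are 1 - correlation (range [0, 2]).
    """
    if label == "cosangle":
        return cosangle_distance(profiles)
    ids = [str(i) for i in profiles.index]
    if profiles.shape[0] < 2:
        raise InvalidConfigError("need >=2 rows for a distance matrix")
    if label in ("euclidean", "manhattan"):
        x = profiles.to_numpy(dtype=float)
        if np.isnan(x).any():
            raise UndefinedDistanceError(
                f"{label} distance does not support missing entries"
            )
        metric = "cityblock" if label == "manhattan" else "euclidean"
        d = squareform(pdist(x, metric=metric))
    elif label in ("pearson", "spearman", "kendall"):
        d = _correlation_distance(profiles, label)
        d = np.clip(d, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
    else:
        raise InvalidConfigError(f"unknown distance label {label!r}")
    return DistanceMatrix(ids=ids, values=d, label=label)


def binary_label_distance(labels: Mapping[str, str] | pd.Series) -> DistanceMatrix:
    """0/1 distance: 0 for identical labels (e.g. same tissue origin), else 1."""
    ser = pd.Series(labels)
    if ser.isna().any():
        missing = list(ser.index[ser.isna()])
        raise InvalidConfigError(f"missing label(s) for {missing}")
    ids = [str(i) for i in ser.index]
    codes = pd.factorize(ser.to_numpy())[0]
    d = (codes[:, None] != codes[None, :]).astype(float)
    return DistanceMatrix(ids=ids, values=d, label="binary")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over named leaves.

    ``linkage`` is the (n-1) x 4 scipy linkage matrix; ``leaf_ids`` maps row
    indices 0..n-1 to object ids.
    """

    leaf_ids: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise InvalidConfigError("linkage matrix shape does not match leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        """Merge heights, one per internal node, in merge order."""
        return self.linkage[:, 2].copy()

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2])

    def clades(self) -> list[frozenset[str]]:
        """Leaf-id set of each internal node, in merge order."""
        n = self.n_leaves
        sets: list[frozenset[str]] = [frozenset([i]) for i in self.leaf_ids]
        out: list[frozenset[str]] = []
        for a, b, _, _ in self.linkage:
            merged = sets[int(a)] | sets[int(b)]
            sets.append(merged)
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        reprs = {i: _escape_newick(self.leaf_ids[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + k
            reprs[node] = f"({reprs[a]}:{la:.10g},{reprs[b]}:{lb:.10g})"
            heights[node] = h
        return reprs[2 * n - 2] + ";"


def _escape_newick(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def ward_cluster(distance: DistanceMatrix) -> Dendrogram:
    """Ward minimum-variance merge tree from a precomputed distance matrix.

    Uses the Lance-Williams update on squared distances (ward.D2).  scipy's
    implementation is deterministic; distance ties resolve to the smallest
    pair index.
    """
    if distance.n < 2:
        raise InvalidConfigError("need >=2 objects to cluster")
    z = hierarchy.linkage(distance.condensed(), method="ward")
    return Dendrogram(leaf_ids=list(distance.ids), linkage=z)


def cut_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the merge tree into ``k`` groups.

    Returns integer labels 1..k indexed by leaf id, renumbered in order of
    first appearance so labels are stable across runs.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise InvalidConfigError(f"k={k} out of range [1, {n}]")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return pd.Series(labels, index=dendrogram.leaf_ids, name="cluster")


@dataclass
class ClusterSupport:
    """Bootstrap support for every internal node of a dendrogram.

    ``table`` columns: node (merge index), height, probability (fraction of
    feature-bootstrap replicates containing the identical leaf set), weight
    (0.1 + 0.9 * height/root height) and weighted_robustness = probability *
    weight.  Members are the node's leaf ids.
    """

    dendrogram: Dendrogram
    table: pd.DataFrame
    n_boot: int
    seed: int
    extra: pd.DataFrame | None = None  # support of caller-supplied leaf sets


def bootstrap_support(
    profiles: pd.DataFrame,
    distance: str = "cosangle",
    n_boot: int = 1000,
    seed: int = 0,
    extra_leaf_sets: Sequence[frozenset] = (),
) -> ClusterSupport:
    """Feature-resampling bootstrap support for hierarchical clusters.

    Columns of ``profiles`` are resampled with replacement ``n_boot`` times;
    each replicate is re-clustered with the same distance and Ward linkage,
    and each original internal node's probability is the fraction of
    replicate trees containing its exact leaf set.  Resampling features
    (not objects) keeps the leaf set identical in every replicate, which is
    what makes per-cluster counting well defined.

    ``extra_leaf_sets`` may name additional leaf sets (frozensets of leaf
    ids) whose replicate support is counted alongside the tree's own nodes;
    their probabilities are returned in the ``extra`` table.
    """
    if n_boot < 1:
        raise InvalidConfigError("n_boot must be >= 1")
    if profiles.shape[1] < 2:
        raise InvalidConfigError("bootstrap degenerate with a single feature column")
    rng = np.random.default_rng(seed)
    base_tree = ward_cluster(profile_distance(profiles, distance))
    clades = base_tree.clades()
    extra_sets = [frozenset(str(x) for x in s) for s in extra_leaf_sets]
    counts = np.zeros(len(clades))
    extra_counts = np.zeros(len(extra_sets))
    p = profiles.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        boot = profiles.iloc[:, cols]
        boot_tree = ward_cluster(profile_distance(boot, distance))
        boot_clades = set(boot_tree.clades())
        for i, c in enumerate(clades):
            if c in boot_clades:
                counts[i] += 1
        for i, c in enumerate(extra_sets):
            if c in boot_clades:
                extra_counts[i] += 1
    prob = counts / n_boot
    extra_table = (
        pd.DataFrame(
            {
                "members": [";".join(sorted(c)) for c in extra_sets],
                "probability": extra_counts / n_boot,
            }
        )
        if extra_sets
        else None
    )
    h = base_tree.heights
    h_root = base_tree.root_height
    weight = 0.1 + 0.9 * (h / h_root) if h_root > 0 else np.ones_like(h)
    table = pd.DataFrame(
        {
            "node": np.arange(len(clades)),
            "height": h,
            "probability": prob,
            "weight": weight,
            "weighted_robustness": prob * weight,
            "members": [";".join(sorted(c)) for c in clades],
        }
    )
    return ClusterSupport(
        dendrogram=base_tree, table=table, n_boot=n_boot, seed=seed, extra=extra_table
    )


def weighted_robustness(probabilities: Sequence[float], dendrogram: Dendrogram) -> np.ndarray:
    """Height-weighted robustness: probability * (0.1 + 0.9 * h / h_root)."""
    prob = np.asarray(probabilities, dtype=float)
    h = dendrogram.heights
    if prob.shape != h.shape:
        raise InvalidConfigError("one probability per internal node required")
    h_root = dendrogram.root_height
    weight = 0.1 + 0.9 * (h / h_root) if h_root > 0 else np.ones_like(h)
    return prob * weight


def project_and_correlate(
    reference_tas: pd.DataFrame,
    new_tas: pd.DataFrame,
    aux_profiles: pd.DataFrame,
    k: int = 8,
    distance: str = "cosangle",
) -> pd.DataFrame:
    """Project new samples into the reference clustering and score similarity.

    The combined TAS matrix (reference + new rows, aligned target columns)
    is clustered with the same distance and Ward linkage and cut into ``k``
    groups.  For each new sample, the mean Spearman correlation of its
    auxiliary profile (e.g. gene expression) against the reference samples
    in its sub-cluster is compared with the background null of all pairwise
    Spearman correlations among reference samples:

        p = (1 + #{background pairs >= observed mean}) / (1 + #background pairs).

    New samples landing in a sub-cluster with no reference member are
    flagged with an undefined p.
    """
    shared_targets = reference_tas.columns.intersection(new_tas.columns)
    if shared_targets.empty:
        raise InvalidConfigError("reference and new TAS share no target columns")
    combined = pd.concat(
        [reference_tas[shared_targets], new_tas[shared_targets]], axis=0
    )
    if combined.index.has_duplicates:
        raise InvalidConfigError("sample ids overlap between reference and new TAS")
    missing_aux = combined.index.difference(aux_profiles.index)
    if len(missing_aux):
        raise InvalidConfigError(f"aux profiles missing for samples {list(missing_aux)}")
    labels = cut_clusters(ward_cluster(profile_distance(combined, distance)), k)

    ref_ids = list(reference_tas.index)
    new_ids = list(new_tas.index)
    aux = aux_profiles.loc[ref_ids + new_ids]
    rho = pd.DataFrame(
        spearmanr(aux.to_numpy(), axis=1)[0], index=aux.index, columns=aux.index
    )
    # background null: every reference-reference pair
    iu = np.triu_indices(len(ref_ids), k=1)
    background = rho.loc[ref_ids, ref_ids].to_numpy()[iu]

    rows = []
    for s in new_ids:
        members = [r for r in ref_ids if labels[r] == labels[s]]
        if not members:
            logger.warning("new sample %s has no reference co-members", s)
            rows.append((s, int(labels[s]), 0, np.nan, np.nan, True))
            continue
        mean_rho = float(rho.loc[s, members].mean())
        p = (1.0 + np.sum(background >= mean_rho)) / (1.0 + background.size)
        rows.append((s, int(labels[s]), len(members), mean_rho, float(p), False))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "cluster", "n_comembers", "mean_spearman", "p_value", "orphan"],
    ).set_index("sample_id")
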