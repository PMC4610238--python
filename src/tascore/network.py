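"""Assembly of the filtered compound -> target interaction network.

Edges arrive as long tables with one row per (compound, target) evidence
record.  Evidence comes from heterogeneous sources — text-mining/experimental
databases scored on a 0-1000 confidence scale (STITCH-style), quantitative
bioactivity databases and selectivity assays (IC50/Kd/Ki/potency in nM), and
curated primary-target annotations — each with its own retention rule:

* confidence-scored edges are kept when (experimental > 10 and combined >
  500) or (experimental < 10 and combined >= 900); compounds on a "relaxed"
  list additionally keep edges with experimental >= 300;
* bioactivity edges are kept when potency <= 35 nM (boundary inclusive),
  focusing the network on the most potent targets;
* promiscuous metabolism genes (cytochrome CYP*, ATP-binding cassette ABC*)
  are excluded regardless of evidence.

The surviving union is deduplicated per (compound, target) pair, provenance
is retained, and the per-target compound count ``n_t`` — the denominator of
the target addiction score — is computed.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyNetworkError, InvalidConfigError

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "compound_id",
    "target_id",
    "source",
    "bioactivity_nM",
    "experimental_score",
    "combined_score",
]

VALID_SOURCES = {"stitch", "chembl", "selectivity_assay", "curated"}

DEFAULT_EXCLUDE_PATTERNS = ("CYP*", "ABC*")
DEFAULT_MAX_BIOACTIVITY_NM = 35.0

__all__ = [
    "TargetNetwork",
    "make_edge_frame",
    "filter_stitch",
    "filter_bioactivity",
    "exclude_gene_families",
    "assemble_network",
    "validate_filters",
    "EDGE_COLUMNS",
    "DEFAULT_EXCLUDE_PATTERNS",
    "DEFAULT_MAX_BIOACTIVITY_NM",
]


def make_edge_frame(records: Iterable[Mapping] | pd.DataFrame) -> pd.DataFrame:
    """Normalise edge records to the canonical column layout.

    Target symbols are uppercased (one gene symbol per edge); missing
    numeric evidence becomes NaN.
    """
    df = pd.DataFrame(records).copy()
    if df.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[EDGE_COLUMNS]
    df["compound_id"] = df["compound_id"].astype(str)
    df["target_id"] = df["target_id"].astype(str).str.upper()
    df["source"] = df["source"].astype(str).str.lower()
    for col in ("bioactivity_nM", "experimental_score", "combined_score"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["source"][~df["source"].isin(VALID_SOURCES)].unique()
    if len(bad):
        raise InvalidConfigError(f"unknown edge source(s): {sorted(bad)}")
    if (df["bioactivity_nM"].dropna() <= 0).any():
        raise InvalidConfigError("bioactivity_nM must be > 0 where present")
    return df.reset_index(drop=True)


def filter_stitch(
    edges: pd.DataFrame, relaxed_compounds: Sequence[str] = ()
) -> pd.DataFrame:
    """Apply the confidence-score retention rule to STITCH-style edges.

    Keep an edge iff (experimental > 10 and combined > 500) or
    (experimental < 10 and combined >= 900), or — for compounds on the
    relaxed list — experimental >= 300.  Edges missing both score fields are
    rejected with a warning.
    """
    exp = edges["experimental_score"]
    comb = edges["combined_score"]
    both_missing = exp.isna() & comb.isna()
    if both_missing.any():
        logger.warning(
            "rejecting %d stitch edge(s) with no score fields", int(both_missing.sum())
        )
    relaxed = edges["compound_id"].isin(set(relaxed_compounds))
    keep = ((exp > 10) & (comb > 500)) | ((exp < 10) & (comb >= 900)) | (relaxed & (exp >= 300))
    return edges[keep.fillna(False)].reset_index(drop=True)


def filter_bioactivity(
    edges: pd.DataFrame, max_nM: float = DEFAULT_MAX_BIOACTIVITY_NM
) -> pd.DataFrame:
    """Keep edges whose bioactivity (IC50/Kd/Ki/potency) is <= ``max_nM``.

    The boundary is inclusive.  Where a (compound, target) pair carries
    several bioactivity records the most potent one decides; since any
    record <= the threshold keeps the pair and duplicates are merged at
    assembly, per-record filtering implements exactly that rule.
    """
    keep = edges["bioactivity_nM"] <= max_nM
    return edges[keep.fillna(False)].reset_index(drop=True)


def exclude_gene_families(
    edges: pd.DataFrame, patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS
) -> pd.DataFrame:
    """Drop edges whose target matches any glob pattern (default CYP*, ABC*)."""
    targets = edges["target_id"].astype(str)
    removed = pd.Series(False, index=edges.index)
    for pat in patterns:
        removed |= targets.map(lambda t: fnmatch.fnmatchcase(t, pat.upper()))
    dropped = sorted(targets[removed].unique())
    if dropped:
        logger.info("excluded %d metabolism-family target(s): %s", len(dropped), dropped)
    return edges[~removed].reset_index(drop=True)


@dataclass
class TargetNetwork:
    """Filtered bipartite compound -> target map.

    ``edges`` has one row per retained (compound, target) pair with a
    ``sources`` column listing the evidence sources that support it.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        if self.edges.duplicated(["compound_id", "target_id"]).any():
            raise InvalidConfigError("duplicate (compound, target) pairs in network edges")

    @property
    def compounds(self) -> list[str]:
        return sorted(self.edges["compound_id"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.edges["target_id"].unique())

    @property
    def n_t(self) -> pd.Series:
        """Per-target count of distinct compounds hitting it."""
        counts = self.edges.groupby("target_id")["compound_id"].nunique()
        return counts.rename("n_t").sort_index()

    def targets_of(self, compound_id: str) -> list[str]:
        sub = self.edges.loc[self.edges["compound_id"] == compound_id, "target_id"]
        return sorted(sub.unique())

    def compounds_of(self, target_id: str) -> list[str]:
        sub = self.edges.loc[self.edges["target_id"] == target_id, "compound_id"]
        return sorted(sub.unique())

    def membership(self) -> pd.DataFrame:
        """0/1 compounds x targets incidence matrix."""
        m = pd.crosstab(self.edges["compound_id"], self.edges["target_id"])
        return (m > 0).astype(float)

    def summary(self) -> pd.DataFrame:
        """Per-target summary table (target, n_t)."""
        return self.n_t.reset_index()

    def to_networkx(self):
        """Bipartite graph view (networkx), compounds on one side, targets on the other."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.compounds, bipartite="compound")
        g.add_nodes_from(self.targets, bipartite="target")
        g.add_edges_from(self.edges[["compound_id", "target_id"]].itertuples(index=False))
        return g


def assemble_network(
    edges: pd.DataFrame | Iterable[Mapping],
    *,
    relaxed_compounds: Sequence[str] = (),
    max_nM: float = DEFAULT_MAX_BIOACTIVITY_NM,
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS,
) -> TargetNetwork:
    """Filter per-source evidence and merge it into a TargetNetwork.

    STITCH-style edges pass the confidence-score rule, bioactivity-bearing
    sources (chembl, selectivity_assay) pass the potency cutoff, curated
    primary-target annotations pass as-is; metabolism gene families are then
    excluded and (compound, target) duplicates merged with provenance.
    """
    df = make_edge_frame(edges)
    parts = []
    for source, sub in df.groupby("source"):
        if source == "stitch":
            parts.append(filter_stitch(sub, relaxed_compounds))
        elif source in ("chembl", "selectivity_assay"):
            parts.append(filter_bioactivity(sub, max_nM))
        else:  # curated primary-target annotations
            parts.append(sub)
    kept = pd.concat(parts, ignore_index=True) if parts else df
    kept = exclude_gene_families(kept, exclude_patterns)
    if kept.empty:
        raise EmptyNetworkError("no edges survive the filters")
    merged = (
        kept.groupby(["compound_id", "target_id"], as_index=False)
        .agg(sources=("source", lambda s: ",".join(sorted(set(s)))))
        .sort_values(["compound_id", "target_id"], ignore_index=True)
    )
    return TargetNetwork(edges=merged)


def validate_filters(
    network: TargetNetwork,
    raw_edges: pd.DataFrame,
    *,
    relaxed_compounds: Sequence[str] = (),
    max_nM: float = DEFAULT_MAX_BIOACTIVITY_NM,
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS,
) -> bool:
    """Re-check every retained edge against its source's rule.

    Returns True iff the network equals a fresh assembly from ``raw_edges``
    under the same settings — the filters are order-independent, so this is
    a full validation pass.
    """
    rebuilt = assemble_network(
        raw_edges,
        relaxed_compounds=relaxed_compounds,
        max_nM=max_nM,
        exclude_patterns=exclude_patterns,
    )
    a = network.edges[["compound_id", "target_id"]].sort_values(
        ["compound_id", "target_id"], ignore_index=True
    )
    b = rebuilt.edges[["compound_id", "target_id"]].sort_values(
        ["compound_id", "target_id"], ignore_index=True
    )
    return a.equals(b)
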