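"""Target addiction scoring: deconvolute drug responses through the network.

For a sample *s* and protein target *t*, the target addiction score is the
mean observed drug response over the ``n_t`` compounds known to hit *t*:

    TAS[s, t] = (1 / n_t) * sum over compounds c targeting t of DR[s, c].

This is a linear map from compound space to target space that exploits
polypharmacology: each compound votes for every target it binds, so targets
repeatedly hit by effective compounds accumulate high scores.  TAS is in the
units of the input metric (DSS, AUC or pIC50).

Missing responses are excluded from the mean — a sample screened with a
subset of the panel is still scored, with the per-entry effective compound
count recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import ResponseMatrix
from .errors import IncompatibilityError, LookupError_
from .network import TargetNetwork

logger = logging.getLogger(__name__)

__all__ = ["TASMatrix", "compute_tas", "rank_targets"]


@dataclass
class TASMatrix:
    """Samples x targets addiction-score matrix.

    ``data``: scores, NaN where no targeting compound had a response.
    ``n_t``: per-target compound counts in the network (metadata).
    ``effective_counts``: per-entry number of non-missing responses averaged.
    ``metric``: the drug-response metric the scores are means of.
    """

    data: pd.DataFrame
    n_t: pd.Series
    effective_counts: pd.DataFrame
    metric: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.data.columns)


def compute_tas(response: ResponseMatrix, network: TargetNetwork) -> TASMatrix:
    """Average each sample's responses over the compounds hitting each target.

    Targets none of whose compounds appear in the response matrix are dropped
    with a warning; an entry is missing iff every targeting compound's
    response is missing in that sample.
    """
    dr = response.data
    membership = network.membership()  # compounds x targets, 0/1
    shared = membership.index.intersection(dr.columns)
    if shared.empty:
        raise IncompatibilityError(
            "response matrix and network share no compound ids"
        )
    dropped_compounds = membership.index.difference(dr.columns)
    if len(dropped_compounds):
        logger.info(
            "%d network compound(s) absent from response matrix", len(dropped_compounds)
        )
    m = membership.loc[shared]
    m = m.loc[:, m.sum(axis=0) > 0]
    lost_targets = membership.columns.difference(m.columns)
    if len(lost_targets):
        logger.warning(
            "dropping %d target(s) with no measured compound: %s",
            len(lost_targets),
            list(lost_targets),
        )
    sub = dr[shared]
    observed = sub.notna().astype(float)
    sums = sub.fillna(0.0).to_numpy() @ m.to_numpy()
    counts = observed.to_numpy() @ m.to_numpy()
    with np.errstate(invalid="ignore"):
        scores = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)
    data = pd.DataFrame(scores, index=dr.index, columns=m.columns)
    counts_df = pd.DataFrame(counts.astype(int), index=dr.index, columns=m.columns)
    data.index.name = "sample_id"
    data.columns.name = "target_id"
    return TASMatrix(
        data=data,
        n_t=network.n_t.loc[m.columns].sort_index(),
        effective_counts=counts_df,
        metric=response.metric,
    )


def rank_targets(tas: TASMatrix, sample_id: str) -> pd.DataFrame:
    """Rank one sample's targets by addiction score, descending.

    Ties break lexicographically on target id for determinism; targets with
    a missing score sort last and are flagged.
    """
    if sample_id not in tas.data.index:
        raise LookupError_(f"unknown sample {sample_id!r}")
    row = tas.data.loc[sample_id]
    table = pd.DataFrame(
        {"target_id": row.index, "tas": row.to_numpy(), "missing": row.isna().to_numpy()}
    )
    table = table.sort_values(
        ["missing", "tas", "target_id"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    return table
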