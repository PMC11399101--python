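"""Clustering-agreement evaluation: contingency tables and entropy metrics.

Two labelings of the same spots are compared through their contingency
table.  The entropy of cluster accuracy (ECA) is the average, over
predicted clusters, of the entropy of reference labels inside each cluster;
the entropy of cluster purity (ECP) is the mirror image, averaging over
reference classes the entropy of predicted labels within each class.  Both
are zero exactly for perfect agreement (up to label renaming) and grow as
clusters mix.  Natural logarithms are used throughout, so ECA is bounded by
ln(number of reference classes) and ECP by ln(number of predicted
clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy

__all__ = [
    "ContingencyTable",
    "contingency",
    "eca",
    "ecp",
    "downsample_concordance",
]

logger = logging.getLogger(__name__)


def _as_series(labels: Mapping[str, str] | pd.Series) -> pd.Series:
    s = pd.Series(labels)
    if s.index.has_duplicates:
        raise ValueError("duplicate spot ids in labeling")
    return s.astype(str)


@dataclass
class ContingencyTable:
    """Cross-tabulation of predicted clusters (rows) x reference classes (columns)."""

    table: pd.DataFrame

    @property
    def n_predicted(self) -> int:
        return self.table.shape[0]

    @property
    def n_reference(self) -> int:
        return self.table.shape[1]

    def display_log10(self) -> pd.DataFrame:
        """log10(n + 1) transform of the counts, for heatmap display."""
        return np.log10(self.table.astype(float) + 1.0)


def contingency(
    pred: Mapping[str, str] | pd.Series, ref: Mapping[str, str] | pd.Series
) -> ContingencyTable:
    """Contingency table over the spots shared by both labelings.

    Spots present in only one labeling are dropped; the drop counts are
    logged.  Disjoint spot universes are an error.
    """
    p = _as_series(pred)
    r = _as_series(ref)
    shared = p.index.intersection(r.index)
    if shared.empty:
        raise ValueError("labelings share no spots")
    n_drop = (len(p) - len(shared)) + (len(r) - len(shared))
    if n_drop:
        logger.info("contingency: dropped %d spots present in only one labeling", n_drop)
    tab = pd.crosstab(p.loc[shared], r.loc[shared])
    tab.index.name = "predicted"
    tab.columns.name = "reference"
    return ContingencyTable(tab)


def eca(pred, ref) -> float:
    """Entropy of cluster accuracy.

    ECA = -(1/M) * sum_i sum_j p_ij ln p_ij with p_ij the fraction of
    predicted cluster i's spots carrying reference label j (0 ln 0 := 0)
    and M the number of predicted clusters.  Zero iff every predicted
    cluster is pure.
    """
    tab = contingency(pred, ref).table.to_numpy(dtype=float)
    row_ent = _entropy(tab, axis=1)  # normalises rows internally, natural log
    return float(row_ent.mean())


def ecp(pred, ref) -> float:
    """Entropy of cluster purity.

    ECP = -(1/N) * sum_k sum_j q_jk ln q_jk with q_jk the fraction of
    reference class k's spots assigned to predicted cluster j and N the
    number of reference classes.  Zero iff every reference class is
    contained in a single predicted cluster.
    """
    tab = contingency(pred, ref).table.to_numpy(dtype=float)
    col_ent = _entropy(tab, axis=0)
    return float(col_ent.mean())


def downsample_concordance(
    full_labels: Mapping[str, str] | pd.Series,
    downsampled_labels_by_proportion: Mapping[float, Mapping[str, str] | pd.Series],
) -> pd.DataFrame:
    """ECA/ECP of downsampled-data clusterings against the full-data clustering.

    The full-data labels serve as the reference; each proportion's labels
    are evaluated against them.  Returns a frame with columns
    ``proportion, eca, ecp`` sorted by proportion.
    """
    rows = [
        {
            "proportion": float(p),
            "eca": eca(labels, full_labels),
            "ecp": ecp(labels, full_labels),
        }
        for p, labels in downsampled_labels_by_proportion.items()
    ]
    return pd.DataFrame(rows).sort_values("proportion").reset_index(drop=True)
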