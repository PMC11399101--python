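"""Marker-gene detection between two spot groups.

Differential expression uses the two-sided Wilcoxon rank-sum test on
median-normalised counts (exact null when the combined group size is small
and tie-free, normal approximation with tie and continuity corrections
otherwise), Benjamini-Hochberg adjustment across all tested genes, and a
three-threshold marker filter: detection in more than 5% of the
up-regulated group's spots, natural-log fold change above 0.25 and adjusted
P value below 0.01 (all strict inequalities).  Marker counts can be traced
as a function of sequencing depth by re-running the whole pipeline on
read-downsampled data, and marker sets from several platforms can be
partitioned by sharing pattern (upset-style).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core_io import (
    MoleculeTable,
    SpatialCountMatrix,
    filter_low_quality,
    normalize_median,
    quantify_molecules,
)
from .depth import _round_half_up, downsample_reads

__all__ = [
    "wilcoxon_markers",
    "filter_markers",
    "marker_depth_curve",
    "marker_intersection",
]

_EPS = 1e-9


def wilcoxon_markers(
    norm: pd.DataFrame, group1: Sequence[str], group2: Sequence[str]
) -> pd.DataFrame:
    """Per-gene rank-sum test between two disjoint spot groups.

    ``norm`` is a spots x genes frame of normalised expression (see
    :func:`sstbench.core_io.normalize_median`).  Returns a frame indexed by
    gene with columns ``log_fc`` (natural log of the ratio of group means,
    stabilised by a tiny epsilon), ``pct_group1``/``pct_group2`` (detection
    fractions, expression > 0), ``p_value`` (two-sided) and ``p_adj``
    (Benjamini-Hochberg across all genes).
    """
    g1, g2 = list(group1), list(group2)
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 spots")
    missing = [s for s in g1 + g2 if s not in norm.index]
    if missing:
        raise KeyError(f"spot {missing[0]!r} not in the normalised matrix")
    x = norm.loc[g1].to_numpy(dtype=float)
    y = norm.loc[g2].to_numpy(dtype=float)

    mean1 = x.mean(axis=0)
    mean2 = y.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_fc = np.log((mean1 + _EPS) / (mean2 + _EPS))
    pct1 = (x > 0).mean(axis=0)
    pct2 = (y > 0).mean(axis=0)

    n_small = (len(g1) + len(g2)) <= 25
    pvals = np.ones(norm.shape[1])
    for j in range(norm.shape[1]):
        xv, yv = x[:, j], y[:, j]
        pooled = np.concatenate([xv, yv])
        if np.all(pooled == pooled[0]):
            pvals[j] = 1.0
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (n_small and not has_ties) else "asymptotic"
        res = mannwhitneyu(xv, yv, alternative="two-sided", method=method)
        pvals[j] = res.pvalue
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "log_fc": log_fc,
            "pct_group1": pct1,
            "pct_group2": pct2,
            "p_value": pvals,
            "p_adj": p_adj,
        },
        index=norm.columns,
    )


def filter_markers(
    table: pd.DataFrame,
    min_pct: float = 0.05,
    min_log_fc: float = 0.25,
    max_padj: float = 0.01,
    direction: str = "up",
) -> set[str]:
    """Genes passing the three marker thresholds (all strict inequalities).

    ``direction="up"`` keeps genes up-regulated in group 1 (detection
    fraction in group 1 above ``min_pct``, log fold change above
    ``min_log_fc``, adjusted P below ``max_padj``); ``direction="down"``
    mirrors the rule for group 2.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if direction == "up":
        lfc = table["log_fc"]
        pct = table["pct_group1"]
    else:
        lfc = -table["log_fc"]
        pct = table["pct_group2"]
    keep = (pct > min_pct) & (lfc > min_log_fc) & (table["p_adj"] < max_padj)
    return set(table.index[keep])


def marker_depth_curve(
    mt: MoleculeTable,
    template: SpatialCountMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    proportions: Sequence[float],
    seed: int,
    min_pct: float = 0.05,
    min_log_fc: float = 0.25,
    max_padj: float = 0.01,
) -> pd.DataFrame:
    """Marker count as a function of read depth for one platform.

    For each proportion the reads are downsampled, re-quantified on the
    template spot frame, quality-filtered and renormalised, and the marker
    pipeline re-run; groups are intersected with the surviving spots.
    Returns columns ``proportion, reads, n_markers``.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(proportions))
    total = mt.total_reads
    rows = []
    for p, ss in zip(proportions, seeds):
        if not 0 <= p <= 1:
            raise ValueError("proportions must lie in [0, 1]")
        target = _round_half_up(p * total)
        sub = (
            mt
            if target == total
            else downsample_reads(mt, target, seed=int(ss.generate_state(1)[0] % 2**31))
        )
        ds = quantify_molecules(sub, template)
        # drop empty spots so normalisation is defined at low depth
        nonzero = np.flatnonzero(ds.spot_totals() > 0)
        ds = ds.subset_spots(nonzero)
        n_markers = 0
        if ds.n_spots >= 4:
            ds = filter_low_quality(ds)
            g1 = [s for s in group1 if s in ds.spot_ids]
            g2 = [s for s in group2 if s in ds.spot_ids]
            if len(g1) >= 2 and len(g2) >= 2:
                norm = normalize_median(ds)
                table = wilcoxon_markers(norm, g1, g2)
                n_markers = len(
                    filter_markers(
                        table, min_pct=min_pct, min_log_fc=min_log_fc, max_padj=max_padj
                    )
                )
        rows.append({"proportion": float(p), "reads": target, "n_markers": n_markers})
    return pd.DataFrame(rows)


def marker_intersection(named_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Partition the union of marker gene sets by exact membership signature.

    Returns one row per non-empty signature with columns ``signature``
    (tuple of platform names, sorted), ``n_platforms``, ``n_genes`` and
    ``genes`` (sorted list), ordered by decreasing sharing then signature.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two gene sets")
    names = sorted(named_sets)
    union = set().union(*named_sets.values())
    by_sig: dict[tuple[str, ...], list[str]] = {}
    for gene in union:
        sig = tuple(n for n in names if gene in named_sets[n])
        by_sig.setdefault(sig, []).append(gene)
    rows = [
        {
            "signature": sig,
            "n_platforms": len(sig),
            "n_genes": len(genes),
            "genes": sorted(genes),
        }
        for sig, genes in by_sig.items()
    ]
    return (
        pd.DataFrame(rows, columns=["signature", "n_platforms", "n_genes", "genes"])
        .sort_values(["n_platforms", "signature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
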