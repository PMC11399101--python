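"""Cross-platform gene-capture bias and contamination metrics.

Platforms differ in which genes they capture well.  Two rules are used to
surface this: a pairwise percentile rule (a gene very highly ranked in one
platform but in the bottom tail of another), and a multi-platform rule that
flags genes highly expressed everywhere except a focal platform.  Flagged
genes can then be related to gene attributes (GC fraction, length) by
one-way ANOVA and summarised by biotype.  A simple ambient-contamination
metric — the fraction of spots expressing a blood-like gene — completes the
set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .core_io import GeneAnnotation, SpatialCountMatrix

__all__ = [
    "HIGH_Q_STRICT",
    "HIGH_Q_RELAXED",
    "pairwise_gene_compare",
    "flag_bias_genes",
    "attribute_anova",
    "biotype_summary",
    "contamination_fraction",
]

# Two shipped presets for the upper percentile of the pairwise rule: the
# strict 99th-percentile variant and the relaxed 90th-percentile variant
# (both paired with a 10th-percentile lower cut).
HIGH_Q_STRICT = 0.99
HIGH_Q_RELAXED = 0.90


def pairwise_gene_compare(
    totals_a: pd.Series,
    totals_b: pd.Series,
    high_q: float = HIGH_Q_STRICT,
    low_q: float = 0.10,
) -> tuple[set[str], pd.DataFrame]:
    """Genes in the top tail of platform A but the bottom tail of platform B.

    Flags genes with total in A at or above A's ``high_q`` quantile and
    total in B at or below B's ``low_q`` quantile (type-7 quantiles over
    the shared gene set).  Swap the arguments for the symmetric call.
    Returns the flagged gene set and a per-gene table with both totals and
    the flag.
    """
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("need 0 <= low_q < high_q <= 1")
    shared = totals_a.index.intersection(totals_b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    a = totals_a.loc[shared].astype(float)
    b = totals_b.loc[shared].astype(float)
    thr_high = float(np.quantile(a.to_numpy(), high_q))
    thr_low = float(np.quantile(b.to_numpy(), low_q))
    flags = (a >= thr_high) & (b <= thr_low)
    table = pd.DataFrame(
        {"total_a": a, "total_b": b, "flagged": flags}, index=shared
    )
    return set(shared[flags]), table


def flag_bias_genes(
    totals: Mapping[str, pd.Series],
    focal_platform: str,
    expressed_q: float = 0.90,
    low_cut: float = 30.0,
) -> tuple[set[str], set[str]]:
    """Split widely-expressed genes into focal-platform bias vs comparison genes.

    Candidate genes must exceed the ``expressed_q`` quantile of totals in
    every non-focal platform (strictly).  Candidates whose total in the
    focal platform is below ``low_cut`` are bias genes; the remainder are
    the comparison set.  ``low_cut`` is an absolute count threshold and
    therefore depth-dependent; it is exposed as a parameter.
    """
    if focal_platform not in totals:
        raise ValueError(f"focal platform {focal_platform!r} absent from totals")
    others = [p for p in sorted(totals) if p != focal_platform]
    if not others:
        raise ValueError("need at least one non-focal platform")
    shared = totals[focal_platform].index
    for p in others:
        shared = shared.intersection(totals[p].index)
    candidates = pd.Series(True, index=shared)
    for p in others:
        vals = totals[p].loc[shared].astype(float)
        thr = float(np.quantile(vals.to_numpy(), expressed_q))
        candidates &= vals > thr
    cand = shared[candidates]
    focal = totals[focal_platform].loc[cand].astype(float)
    bias = set(cand[focal < low_cut])
    comparison = set(cand) - bias
    return bias, comparison


def attribute_anova(
    bias_genes: Sequence[str],
    comparison_genes: Sequence[str],
    annotation: GeneAnnotation,
    attribute: str,
) -> tuple[float, int, int, float]:
    """One-way ANOVA of a gene attribute between bias and comparison genes.

    ``attribute`` is ``"gc_fraction"`` or ``"length_bp"``.  Returns
    ``(F, df_between, df_within, p)``.
    """
    g1 = annotation.values_for(list(bias_genes), attribute)
    g2 = annotation.values_for(list(comparison_genes), attribute)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 annotated genes")
    res = f_oneway(g1, g2)
    df1 = 1
    df2 = len(g1) + len(g2) - 2
    return float(res.statistic), df1, df2, float(res.pvalue)


def biotype_summary(
    bias_genes: Sequence[str], annotation: GeneAnnotation
) -> pd.Series:
    """Biotype frequency table of the bias genes, sorted descending.

    Genes missing from the annotation count as ``"unannotated"``.
    """
    if not list(bias_genes):
        return pd.Series(dtype=int, name="n_genes")
    biotypes = [annotation.biotype_of(g) for g in bias_genes]
    return (
        pd.Series(biotypes, name="n_genes")
        .value_counts()
        .sort_values(ascending=False)
    )


def contamination_fraction(ds: SpatialCountMatrix, gene: str) -> float:
    """Fraction of spots expressing a gene (count > 0).

    Used with a blood hemoglobin gene this measures how widely ambient
    contamination has spread across the array.
    """
    counts = ds.gene_counts(gene)  # raises KeyError for unknown genes
    if ds.n_spots == 0:
        return 0.0
    return float((counts > 0).mean())
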