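"""Read-level downsampling to matched sequencing depth and saturation curves.

Platforms are sequenced to very different depths; comparing their UMI
(unique molecule) yield is only fair at an equal number of reads.  The
operations here subsample sequencing reads uniformly without replacement
over the global read pool — a molecule survives iff at least one of its
reads is drawn — and summarise the distinct-molecule yield as a function of
depth (the saturation curve).  A closed-form hypergeometric expectation is
provided as an independent oracle for the sampler.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import MoleculeTable

__all__ = [
    "downsample_reads",
    "downsample_to_common_depth",
    "saturation_curve",
    "expected_umis",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def downsample_reads(
    mt: MoleculeTable,
    target_reads: int,
    seed: int,
    method: str = "hypergeometric",
) -> MoleculeTable:
    """Retain exactly ``target_reads`` reads sampled uniformly without replacement.

    Equivalent to drawing ``target_reads`` distinct read IDs from the pooled
    reads of all molecules; a molecule survives iff at least one of its
    reads is retained, and its new read count is the number retained.

    ``method="binomial"`` instead keeps each read independently with
    probability ``target_reads / total_reads`` (binomial thinning); the
    realised total then varies around the target.
    """
    total = mt.total_reads
    if not 0 <= target_reads <= total:
        raise ValueError(f"target_reads={target_reads} outside [0, {total}]")
    rng = np.random.default_rng(seed)
    reads = mt.records["reads"].to_numpy()
    if method == "hypergeometric":
        if target_reads == total:
            kept = reads.copy()
        else:
            kept = rng.multivariate_hypergeometric(reads, target_reads)
    elif method == "binomial":
        p = target_reads / total if total else 0.0
        kept = rng.binomial(reads, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    surviving = kept > 0
    out = mt.records.loc[surviving].copy()
    out["reads"] = kept[surviving]
    return MoleculeTable(out)


def downsample_to_common_depth(
    tables: list[MoleculeTable], seed: int
) -> list[MoleculeTable]:
    """Downsample every table to the minimum total read count across inputs."""
    if len(tables) < 2:
        raise ValueError("need at least two molecule tables")
    target = min(t.total_reads for t in tables)
    seeds = np.random.SeedSequence(seed).spawn(len(tables))
    return [
        downsample_reads(t, target, seed=int(s.generate_state(1)[0] % 2**31))
        for t, s in zip(tables, seeds)
    ]


def saturation_curve(
    mt: MoleculeTable,
    proportions: list[float],
    n_rep: int,
    seed: int,
) -> pd.DataFrame:
    """Distinct-molecule yield at stepwise downsampled depths.

    For each proportion ``p`` (in ``(0, 1]``, strictly increasing), performs
    ``n_rep`` independent downsamples to ``round(p * total_reads)`` reads
    (round half up) and records the mean and sample s.d. of surviving
    distinct molecules.  Returns a frame with columns
    ``p, reads, mean_umis, sd_umis, n_rep``.
    """
    props = [float(p) for p in proportions]
    if any(not 0 < p <= 1 for p in props):
        raise ValueError("proportions must lie in (0, 1]")
    if any(b <= a for a, b in zip(props, props[1:])):
        raise ValueError("proportions must be strictly increasing")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    total = mt.total_reads
    seeds = np.random.SeedSequence(seed).spawn(len(props) * n_rep)
    rows = []
    k = 0
    for p in props:
        target = _round_half_up(p * total)
        umis = np.empty(n_rep)
        for r in range(n_rep):
            s = int(seeds[k].generate_state(1)[0] % 2**31)
            k += 1
            if target == total:
                umis[r] = mt.n_molecules
            else:
                umis[r] = downsample_reads(mt, target, seed=s).n_molecules
        sd = float(np.std(umis, ddof=1)) if n_rep > 1 else 0.0
        rows.append(
            {
                "p": p,
                "reads": target,
                "mean_umis": float(np.mean(umis)),
                "sd_umis": sd,
                "n_rep": n_rep,
            }
        )
    return pd.DataFrame(rows)


def expected_umis(mt: MoleculeTable, target_reads: int) -> float:
    """Exact expected number of surviving molecules under read downsampling.

    For a molecule with ``r`` of the ``R`` total reads, the probability that
    none of its reads is among ``T`` drawn without replacement is the
    hypergeometric point mass at zero, so

        E[UMIs] = sum_m 1 - C(R - r_m, T) / C(R, T).
    """
    total = mt.total_reads
    if not 0 <= target_reads <= total:
        raise ValueError(f"target_reads={target_reads} outside [0, {total}]")
    reads = mt.records["reads"].to_numpy()
    if not reads.size or target_reads == 0:
        return 0.0
    p_lost = hypergeom.pmf(0, total, reads, target_reads)
    return float(np.sum(1.0 - p_lost))
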