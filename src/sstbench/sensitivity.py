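"""Capture-sensitivity statistics.

A platform's sensitivity is summarised two ways: the total UMI yield over a
selected region (on all reads and at matched depth), and the summed counts
of region-specific marker genes inside small fixed-size windows (50 x 50 um
by default, the coarsest spot pitch among common platforms), reported with
mean and standard deviation across windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_io import MoleculeTable, RegionOfInterest, SpatialCountMatrix, quantify_molecules, select_roi
from .depth import downsample_to_common_depth

__all__ = [
    "Window",
    "WindowSums",
    "roi_total_umi",
    "window_marker_sum",
    "compare_platforms_sensitivity",
]


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangle [x0, x0+width) x [y0, y0+height) in micrometres."""

    x0: float
    y0: float
    width_um: float = 50.0
    height_um: float = 50.0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("window width and height must be positive")

    def contains(self, coords: np.ndarray) -> np.ndarray:
        x, y = coords[:, 0], coords[:, 1]
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width_um)
            & (y >= self.y0)
            & (y < self.y0 + self.height_um)
        )


class WindowSums(NamedTuple):
    values: np.ndarray  # per-window summed counts
    mean: float
    sd: float  # sample s.d. across windows (0 for a single window)


def roi_total_umi(ds: SpatialCountMatrix) -> int:
    """Total UMI count over all spots and genes of an (ROI-selected) dataset."""
    return ds.total_umis()


def window_marker_sum(
    ds: SpatialCountMatrix, genes: Sequence[str], windows: Sequence[Window]
) -> WindowSums:
    """Summed counts of ``genes`` per window, with mean and s.d. across windows.

    A spot contributes to a window iff its centre lies in the half-open
    rectangle.  Windows may overlap.
    """
    unknown = [g for g in genes if g not in ds.gene_ids]
    if unknown:
        raise KeyError(f"unknown gene: {unknown[0]!r}")
    cols = [ds.gene_ids.index(g) for g in genes]
    per_spot = np.asarray(ds.counts[:, cols].sum(axis=1)).ravel()
    values = np.array(
        [int(per_spot[w.contains(ds.coords)].sum()) for w in windows], dtype=np.int64
    )
    mean = float(values.mean()) if values.size else 0.0
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return WindowSums(values=values, mean=mean, sd=sd)


def compare_platforms_sensitivity(
    datasets: Mapping[str, SpatialCountMatrix],
    roi: RegionOfInterest | None,
    windows: Sequence[Window],
    genes: Sequence[str],
    common_depth: bool = False,
    molecule_tables: Mapping[str, MoleculeTable] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-platform sensitivity table with a rank order.

    When ``common_depth`` is set, molecule tables (one per platform) are
    first downsampled to the minimum total read count and re-quantified on
    each platform's spot frame.  Platforms are ranked by mean window marker
    sum (descending); ties break by ROI total UMI, then by name.
    """
    names = sorted(datasets)
    working: dict[str, SpatialCountMatrix] = {}
    if common_depth:
        if molecule_tables is None or any(n not in molecule_tables for n in names):
            raise ValueError("common_depth requires a molecule table per platform")
        if seed is None:
            raise ValueError("common_depth downsampling requires a seed")
        downsampled = downsample_to_common_depth(
            [molecule_tables[n] for n in names], seed=seed
        )
        for name, mt in zip(names, downsampled):
            working[name] = quantify_molecules(mt, datasets[name])
    else:
        working = {n: datasets[n] for n in names}

    rows = []
    for name in names:
        ds = working[name]
        if roi is not None:
            ds = select_roi(ds, roi)
        sums = window_marker_sum(ds, genes, windows)
        rows.append(
            {
                "platform": name,
                "roi_total_umi": roi_total_umi(ds),
                "window_mean": sums.mean,
                "window_sd": sums.sd,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["window_mean", "roi_total_umi", "platform"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
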