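"""Synthetic spot-array datasets with known ground truth.

The generator emulates the statistical structure of sequencing-based
spatial transcriptomics data from multiple platforms: a regular grid of
capture spots with configurable pitch and diameter, region-structured
expression programs with marker genes, isotropic Gaussian lateral diffusion
of molecules away from their emitting cell, per-molecule read duplication
(the source of saturation behaviour), and ambient contamination emitted
tissue-wide (e.g., a blood hemoglobin gene).

All randomness flows from a single seeded generator in a fixed draw order,
so the same seed reproduces the same dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .core_io import MoleculeTable, SpatialCountMatrix

__all__ = [
    "TissueLayout",
    "ExpressionProgram",
    "SyntheticTruth",
    "make_layout",
    "simulate_dataset",
]


@dataclass
class TissueLayout:
    """Deterministic geometric tissue layout.

    Two kinds are supported:

    ``eye_rings``
        Concentric annuli around ``center`` with strictly increasing
        ``radii``; label ``i`` applies between radius ``i-1`` and ``i``,
        and the last label covers everything beyond the outermost radius
        (e.g. lens / neural retina / melanocyte / outer).  Mirrors the
        concentric organisation of an embryonic eye.
    ``layers``
        Parallel bands along the y axis delimited by strictly increasing
        ``boundaries``; ``extent`` gives the x range.  Mirrors laminar
        structures such as cortical or olfactory-bulb layers.
    """

    kind: str
    region_labels: list[str]
    center: tuple[float, float] | None = None
    radii: list[float] | None = None
    boundaries: list[float] | None = None
    extent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if self.kind == "eye_rings":
            radii = list(self.radii or [])
            if not radii or any(b <= a for a, b in zip(radii, radii[1:])):
                raise ValueError("ring radii must be strictly increasing")
            if len(self.region_labels) != len(radii) + 1:
                raise ValueError("eye_rings needs len(radii)+1 region labels")
        elif self.kind == "layers":
            bounds = list(self.boundaries or [])
            if len(bounds) < 2 or any(b <= a for a, b in zip(bounds, bounds[1:])):
                raise ValueError("layer boundaries must be strictly increasing")
            if len(self.region_labels) != len(bounds) - 1:
                raise ValueError("layers needs len(boundaries)-1 region labels")
            if self.extent is None:
                raise ValueError("layers layout needs an x extent")
        else:
            raise ValueError(f"unknown layout kind {self.kind!r}")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """Bounding box (x0, y0, x1, y1) of the layout."""
        if self.kind == "eye_rings":
            cx, cy = self.center
            r = self.radii[-1]
            return (cx - r, cy - r, cx + r, cy + r)
        x0, x1 = self.extent
        return (x0, self.boundaries[0], x1, self.boundaries[-1])

    def region_of(self, x: float, y: float) -> str:
        """Region label at a point; every in-bounds point maps to exactly one."""
        if self.kind == "eye_rings":
            cx, cy = self.center
            r = math.hypot(x - cx, y - cy)
            for radius, label in zip(self.radii, self.region_labels):
                if r < radius:
                    return label
            return self.region_labels[-1]
        bounds = self.boundaries
        if not (bounds[0] <= y <= bounds[-1]):
            raise ValueError(f"point y={y} outside layer bounds")
        k = int(np.searchsorted(bounds, y, side="right")) - 1
        k = min(k, len(self.region_labels) - 1)  # y exactly at the top boundary
        return self.region_labels[k]

    def regions_of(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        if self.kind == "eye_rings":
            cx, cy = self.center
            r = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
            idx = np.searchsorted(np.asarray(self.radii), r, side="right")
            return np.asarray(self.region_labels, dtype=object)[idx]
        bounds = np.asarray(self.boundaries)
        k = np.searchsorted(bounds, coords[:, 1], side="right") - 1
        k = np.clip(k, 0, len(self.region_labels) - 1)
        return np.asarray(self.region_labels, dtype=object)[k]


def make_layout(kind: str, params: Mapping) -> TissueLayout:
    """Build a :class:`TissueLayout` from a parameter mapping (see class docs)."""
    params = dict(params)
    if kind == "eye_rings":
        return TissueLayout(
            kind=kind,
            region_labels=list(params["region_labels"]),
            center=tuple(params.get("center", (0.0, 0.0))),
            radii=[float(r) for r in params["radii"]],
        )
    if kind == "layers":
        return TissueLayout(
            kind=kind,
            region_labels=list(params["region_labels"]),
            boundaries=[float(b) for b in params["boundaries"]],
            extent=tuple(params.get("extent", (0.0, 100.0))),
        )
    raise ValueError(f"unknown layout kind {kind!r}")


@dataclass
class ExpressionProgram:
    """Region-structured expression rates plus an ambient component.

    ``region_rates`` maps region label -> {gene -> expected molecules per
    cell}.  ``ambient_rates`` maps gene -> baseline molecules per cell
    equivalent emitted tissue-wide irrespective of region (contamination);
    the effective ambient load is scaled by the simulation's
    ``contamination_fraction``.
    """

    region_rates: dict[str, dict[str, float]]
    ambient_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, rates in self.region_rates.items():
            for gene, rate in rates.items():
                if rate < 0:
                    raise ValueError(f"negative rate for {gene} in {region}")
        for gene, rate in self.ambient_rates.items():
            if rate < 0:
                raise ValueError(f"negative ambient rate for {gene}")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rates in self.region_rates.values():
            for g in rates:
                seen.setdefault(g)
        for g in self.ambient_rates:
            seen.setdefault(g)
        return list(seen)

    def markers(self) -> dict[str, str]:
        """Genes expressed in exactly one region, mapped to that region."""
        where: dict[str, list[str]] = {}
        for region, rates in self.region_rates.items():
            for gene, rate in rates.items():
                if rate > 0:
                    where.setdefault(gene, []).append(region)
        return {g: rs[0] for g, rs in where.items() if len(rs) == 1}


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset (enables parameter recovery)."""

    sigma_diff_um: float
    cells: pd.DataFrame  # columns x, y, region
    reads_per_molecule_mean: float
    contamination_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma_diff_um < 0:
            raise ValueError("sigma_diff_um must be >= 0")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction must lie in [0, 1]")


def _spot_grid(platform: Mapping) -> tuple[np.ndarray, list[str]]:
    x0, y0, x1, y1 = platform["capture_bbox"]
    pitch = float(platform["pitch_um"])
    if pitch <= 0:
        raise ValueError("pitch_um must be positive")
    nx = int(math.floor((x1 - x0) / pitch))
    ny = int(math.floor((y1 - y0) / pitch))
    if nx < 1 or ny < 1:
        raise ValueError("capture bbox too small for the spot pitch")
    xs = x0 + (np.arange(nx) + 0.5) * pitch
    ys = y0 + (np.arange(ny) + 0.5) * pitch
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    ids = [f"spot_{i}_{j}" for i in range(nx) for j in range(ny)]
    return centers, ids


def simulate_dataset(
    layout: TissueLayout,
    program: ExpressionProgram,
    platform: Mapping,
    n_cells: int,
    sigma_diff_um: float,
    reads_per_molecule_mean: float,
    contamination_fraction: float,
    seed: int,
) -> tuple[SpatialCountMatrix, MoleculeTable, SyntheticTruth]:
    """Simulate one platform's capture of a synthetic tissue.

    Generative model, in fixed draw order from one seeded generator:

    1. ``n_cells`` cell positions uniform over the layout bounding box,
       labelled by layout region.
    2. Per cell and gene, molecule counts ~ Poisson(region rate).
    3. Ambient molecules per gene ~ Poisson(rate * contamination_fraction *
       n_cells), positions uniform over the capture bbox.
    4. Each molecule's capture position = source position + isotropic
       Gaussian displacement with s.d. ``sigma_diff_um`` (lateral diffusion).
    5. A molecule is captured by the nearest spot centre iff within
       ``spot_diameter_um / 2`` (always captured when the diameter is
       absent); otherwise it is lost.
    6. Each captured molecule's read count = 1 + Poisson(mean - 1).

    Returns the UMI count matrix over the full spot grid, the molecule
    table, and the ground truth record.
    """
    if reads_per_molecule_mean < 1:
        raise ValueError("reads_per_molecule_mean must be >= 1")
    platform = dict(platform)
    platform.setdefault("capture_bbox", layout.bounds)
    x0, y0, x1, y1 = platform["capture_bbox"]
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty capture bbox")
    rng = np.random.default_rng(seed)
    genes = program.genes

    # 1. cells
    lx0, ly0, lx1, ly1 = layout.bounds
    if lx1 <= lx0 or ly1 <= ly0:
        raise ValueError("empty layout bounds")
    cell_xy = rng.uniform([lx0, ly0], [lx1, ly1], size=(n_cells, 2))
    cell_regions = layout.regions_of(cell_xy)
    cells = pd.DataFrame(
        {"x": cell_xy[:, 0], "y": cell_xy[:, 1], "region": cell_regions}
    )

    # 2. per-cell molecule counts, region by region in program order
    src_x: list[np.ndarray] = []
    src_y: list[np.ndarray] = []
    src_gene: list[np.ndarray] = []
    for region in program.region_rates:
        in_region = np.flatnonzero(cell_regions == region)
        if not in_region.size:
            continue
        for gene, rate in program.region_rates[region].items():
            if rate <= 0:
                continue
            counts = rng.poisson(rate, size=in_region.size)
            emitters = np.repeat(in_region, counts)
            if emitters.size:
                src_x.append(cell_xy[emitters, 0])
                src_y.append(cell_xy[emitters, 1])
                src_gene.append(np.full(emitters.size, gene, dtype=object))

    # 3. ambient molecules over the capture area
    for gene, rate in program.ambient_rates.items():
        lam = rate * contamination_fraction * n_cells
        n_amb = int(rng.poisson(lam)) if lam > 0 else 0
        if n_amb:
            pos = rng.uniform([x0, y0], [x1, y1], size=(n_amb, 2))
            src_x.append(pos[:, 0])
            src_y.append(pos[:, 1])
            src_gene.append(np.full(n_amb, gene, dtype=object))

    if src_x:
        mol_x = np.concatenate(src_x)
        mol_y = np.concatenate(src_y)
        mol_gene = np.concatenate(src_gene)
    else:
        mol_x = mol_y = np.zeros(0)
        mol_gene = np.zeros(0, dtype=object)
    n_emitted = mol_x.size

    # 4. lateral diffusion
    if sigma_diff_um > 0 and n_emitted:
        disp = rng.normal(0.0, sigma_diff_um, size=(n_emitted, 2))
        mol_x = mol_x + disp[:, 0]
        mol_y = mol_y + disp[:, 1]

    # 5. assignment to the nearest spot centre
    centers, spot_ids = _spot_grid(platform)
    tree = cKDTree(centers)
    if n_emitted:
        dist, nearest = tree.query(np.column_stack([mol_x, mol_y]))
    else:
        dist = np.zeros(0)
        nearest = np.zeros(0, dtype=int)
    diameter = platform.get("spot_diameter_um")
    captured = (
        dist <= float(diameter) / 2 if diameter is not None else np.ones(n_emitted, bool)
    )
    cap_idx = np.flatnonzero(captured)

    # 6. read multiplicity
    reads = 1 + rng.poisson(reads_per_molecule_mean - 1.0, size=cap_idx.size)

    records = pd.DataFrame(
        {
            "spot_id": [spot_ids[k] for k in nearest[cap_idx]],
            "gene_id": mol_gene[cap_idx],
            "molecule_id": [f"m{k:08d}" for k in cap_idx],
            "reads": reads,
        }
    )
    mt = MoleculeTable(records)

    gene_index = {g: j for j, g in enumerate(genes)}
    spot_index = {s: i for i, s in enumerate(spot_ids)}
    if len(records):
        rows = records["spot_id"].map(spot_index).to_numpy()
        cols = records["gene_id"].map(gene_index).to_numpy()
        counts = sp.csr_matrix(
            (np.ones(len(records), dtype=np.int64), (rows, cols)),
            shape=(len(spot_ids), len(genes)),
        )
    else:
        counts = sp.csr_matrix((len(spot_ids), len(genes)), dtype=np.int64)

    meta = {
        "name": platform.get("name", "synthetic"),
        "pitch_um": float(platform["pitch_um"]),
    }
    if diameter is not None:
        meta["spot_diameter_um"] = float(diameter)
    ds = SpatialCountMatrix(
        spot_ids=spot_ids, coords=centers, counts=counts, gene_ids=genes,
        platform_meta=meta,
    )
    truth = SyntheticTruth(
        sigma_diff_um=float(sigma_diff_um),
        cells=cells,
        reads_per_molecule_mean=float(reads_per_molecule_mean),
        contamination_fraction=float(contamination_fraction),
        seed=int(seed),
    )
    return ds, mt, truth
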