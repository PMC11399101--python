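"""Core data model and shared preprocessing for spot-array spatial data.

The central container is :class:`SpatialCountMatrix`: a sparse spots x genes
UMI count matrix with continuous spot coordinates in micrometres and a small
platform metadata record (array pitch, spot diameter).  Molecule-level data
(one row per captured molecule, carrying its sequencing-read multiplicity)
live in :class:`MoleculeTable`, the substrate for read-level downsampling.

This module also provides the preprocessing steps every analysis shares:
reading/writing the on-disk exchange formats (Matrix Market triplets plus
barcode/feature lists and a positions table), spatial binning, region-of-
interest selection, quality filtering of low-count spots, and median-total
normalisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Point, Polygon

__all__ = [
    "SpatialCountMatrix",
    "MoleculeTable",
    "RegionOfInterest",
    "GeneAnnotation",
    "read_spatial_dataset",
    "write_spatial_dataset",
    "read_molecule_table",
    "write_molecule_table",
    "read_roi",
    "write_roi",
    "read_gene_annotation",
    "bin_spots",
    "select_roi",
    "filter_low_quality",
    "normalize_median",
    "quantify_molecules",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpatialCountMatrix:
    """Sparse spots x genes UMI counts with micrometre spot coordinates.

    Parameters
    ----------
    spot_ids
        Unique spot (barcode) identifiers, one per matrix row.
    coords
        ``(n_spots, 2)`` float array of spot-centre ``(x, y)`` positions in
        micrometres.  The origin is arbitrary; coordinates must be finite.
    counts
        Sparse non-negative integer matrix, spots in rows, genes in columns.
    gene_ids
        Unique gene identifiers, one per column.
    platform_meta
        Free-form platform record; recognised keys are ``name``,
        ``pitch_um`` (centre-to-centre spot distance) and
        ``spot_diameter_um``.
    """

    spot_ids: list[str]
    coords: np.ndarray
    counts: sp.csr_matrix
    gene_ids: list[str]
    platform_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spot_ids = list(self.spot_ids)
        self.gene_ids = list(self.gene_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must be an (n_spots, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("spot coordinates must be finite")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        pitch = self.platform_meta.get("pitch_um")
        if pitch is not None and pitch <= 0:
            raise ValueError("pitch_um must be positive")

    # -- convenience ------------------------------------------------------

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def spot_totals(self) -> np.ndarray:
        """Total UMI count per spot."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_totals(self) -> pd.Series:
        """Total UMI count per gene, indexed by gene id."""
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        return pd.Series(totals, index=self.gene_ids, name="total")

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense per-spot counts for one gene."""
        j = self.gene_index(gene)
        return np.asarray(self.counts[:, j].todense()).ravel()

    def subset_spots(self, index: np.ndarray) -> "SpatialCountMatrix":
        """New dataset restricted to the given spot row indices (order kept)."""
        index = np.asarray(index)
        return SpatialCountMatrix(
            spot_ids=[self.spot_ids[i] for i in index],
            coords=self.coords[index],
            counts=self.counts[index],
            gene_ids=self.gene_ids,
            platform_meta=dict(self.platform_meta),
        )

    def total_umis(self) -> int:
        return int(self.counts.sum())


@dataclass
class MoleculeTable:
    """Long-form molecule records with per-molecule read multiplicity.

    ``records`` is a DataFrame with columns ``spot_id, gene_id, molecule_id,
    reads``; each row is one captured molecule (distinct UMI) and ``reads``
    is the number of sequencing reads supporting it (>= 1).  Collapsing the
    table (counting molecules per spot x gene) reproduces a UMI count
    matrix exactly.
    """

    records: pd.DataFrame

    COLUMNS = ("spot_id", "gene_id", "molecule_id", "reads")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        df = df.reset_index(drop=True)
        df["reads"] = df["reads"].astype(np.int64)
        if len(df) and (df["reads"] < 1).any():
            raise ValueError("every molecule must carry at least one read")
        if df.duplicated(["spot_id", "gene_id", "molecule_id"]).any():
            raise ValueError("(spot_id, gene_id, molecule_id) must be unique")
        self.records = df

    @property
    def total_reads(self) -> int:
        return int(self.records["reads"].sum())

    @property
    def n_molecules(self) -> int:
        return len(self.records)

    def collapse(self) -> pd.DataFrame:
        """Molecules per spot x gene as a tidy frame (spot_id, gene_id, umis)."""
        if not len(self.records):
            return pd.DataFrame(columns=["spot_id", "gene_id", "umis"])
        out = (
            self.records.groupby(["spot_id", "gene_id"], sort=True)
            .size()
            .rename("umis")
            .reset_index()
        )
        return out


@dataclass
class RegionOfInterest:
    """A named polygonal region in micrometre coordinates.

    The polygon is implicitly closed and must be simple (non-self-
    intersecting) with positive area.  Spot membership is decided by the
    spot centre; points on the boundary count as inside.
    """

    polygon: list[tuple[float, float]]
    name: str = "roi"

    def __post_init__(self) -> None:
        verts = [(float(x), float(y)) for x, y in self.polygon]
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"degenerate or self-intersecting polygon {self.name!r}")
        self.polygon = verts
        self._shape = poly

    @property
    def shape(self) -> Polygon:
        return self._shape

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (boundary inclusive)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return np.array([self._shape.covers(Point(x, y)) for x, y in coords])


@dataclass
class GeneAnnotation:
    """Per-gene attributes: biotype, length (bp) and GC fraction."""

    table: pd.DataFrame  # index: gene id; columns: biotype, length_bp, gc_fraction

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = {"biotype", "length_bp", "gc_fraction"} - set(df.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if (df["length_bp"] < 1).any():
            raise ValueError("length_bp must be >= 1")
        gc = df["gc_fraction"]
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("gc_fraction must lie in [0, 1]")
        self.table = df

    def biotype_of(self, gene: str) -> str:
        if gene in self.table.index:
            return str(self.table.loc[gene, "biotype"])
        return "unannotated"

    def values_for(self, genes: Sequence[str], attribute: str) -> np.ndarray:
        if attribute not in ("gc_fraction", "length_bp"):
            raise ValueError(f"unknown attribute {attribute!r}")
        present = [g for g in genes if g in self.table.index]
        return self.table.loc[present, attribute].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_spatial_dataset(
    matrix_path,
    barcodes_path,
    features_path,
    positions_path,
    platform_meta: Mapping | None = None,
) -> SpatialCountMatrix:
    """Read a dataset from Matrix Market triplets plus side tables.

    The matrix is coordinate-format integer with barcodes (spots) in rows
    and features (genes) in columns, 1-based indices on disk.  The positions
    table is a CSV with header ``barcode,x_um,y_um`` and must cover every
    barcode; a barcode without a position row is an error.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # malformed header / body
        raise ValueError(f"malformed Matrix Market file {matrix_path}: {exc}") from exc
    counts = sp.csr_matrix(mat)
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match {len(barcodes)} barcodes "
            f"x {len(features)} features"
        )
    pos = pd.read_csv(positions_path)
    required = {"barcode", "x_um", "y_um"}
    if not required.issubset(pos.columns):
        raise ValueError(f"positions table must have columns {sorted(required)}")
    pos = pos.set_index("barcode")
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise ValueError(f"barcode {missing[0]!r} has no position row")
    coords = pos.loc[barcodes, ["x_um", "y_um"]].to_numpy(dtype=float)
    return SpatialCountMatrix(
        spot_ids=barcodes,
        coords=coords,
        counts=counts,
        gene_ids=features,
        platform_meta=dict(platform_meta or {}),
    )


def _read_id_column(path) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def write_spatial_dataset(ds: SpatialCountMatrix, out_dir) -> None:
    """Write the Matrix Market triplet bundle read by :func:`read_spatial_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(ds.counts), field="integer")
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in ds.spot_ids))
    (out / "features.tsv").write_text("".join(f"{g}\n" for g in ds.gene_ids))
    pd.DataFrame(
        {"barcode": ds.spot_ids, "x_um": ds.coords[:, 0], "y_um": ds.coords[:, 1]}
    ).to_csv(out / "positions.csv", index=False)


def read_molecule_table(path) -> MoleculeTable:
    """Read a molecule table from TSV with header ``spot_id gene_id molecule_id reads``."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns)[:4] != list(MoleculeTable.COLUMNS):
        raise ValueError(
            f"molecule table must have columns {list(MoleculeTable.COLUMNS)}"
        )
    return MoleculeTable(df)


def write_molecule_table(mt: MoleculeTable, path) -> None:
    mt.records.to_csv(path, sep="\t", index=False)


def read_roi(path) -> RegionOfInterest:
    """Read a region of interest from JSON ``{"name": ..., "polygon": [[x, y], ...]}``."""
    with open(path) as fh:
        obj = json.load(fh)
    return RegionOfInterest(polygon=obj["polygon"], name=obj.get("name", "roi"))


def write_roi(roi: RegionOfInterest, path) -> None:
    with open(path, "w") as fh:
        json.dump({"name": roi.name, "polygon": [list(v) for v in roi.polygon]}, fh)


def read_gene_annotation(path) -> GeneAnnotation:
    """Read annotation CSV with header ``gene,biotype,length_bp,gc_fraction``."""
    df = pd.read_csv(path).set_index("gene")
    return GeneAnnotation(df)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def bin_spots(ds: SpatialCountMatrix, bin_um: float) -> SpatialCountMatrix:
    """Sum counts over a square grid of side ``bin_um``.

    Spots are assigned by centre to half-open cells ``[k*bin_um, (k+1)*bin_um)``
    on each axis; the binned spot coordinate is the cell centre.  Total UMI
    counts are conserved exactly.
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    cells = np.floor(ds.coords / bin_um).astype(np.int64)
    keys, inverse = np.unique(cells, axis=0, return_inverse=True)
    n_bins = len(keys)
    assign = sp.csr_matrix(
        (np.ones(ds.n_spots), (inverse, np.arange(ds.n_spots))),
        shape=(n_bins, ds.n_spots),
    )
    binned = sp.csr_matrix(assign @ ds.counts)
    centers = (keys + 0.5) * bin_um
    spot_ids = [f"bin_{kx}_{ky}" for kx, ky in keys]
    return SpatialCountMatrix(
        spot_ids=spot_ids,
        coords=centers,
        counts=binned,
        gene_ids=ds.gene_ids,
        platform_meta=dict(ds.platform_meta),
    )


def select_roi(ds: SpatialCountMatrix, roi: RegionOfInterest) -> SpatialCountMatrix:
    """Keep spots whose centres fall inside the region (boundary inclusive)."""
    mask = roi.contains(ds.coords) if ds.n_spots else np.zeros(0, dtype=bool)
    return ds.subset_spots(np.flatnonzero(mask))


def filter_low_quality(ds: SpatialCountMatrix, fraction: float = 0.3) -> SpatialCountMatrix:
    """Remove spots whose total count is below ``fraction`` of the first quartile.

    The first quartile is the 25th percentile of per-spot totals with
    type-7 linear interpolation (numpy default).  At least 4 spots are
    required for the quartile to be meaningful.
    """
    if ds.n_spots < 4:
        raise ValueError("need at least 4 spots to compute the first quartile")
    totals = ds.spot_totals()
    q1 = np.quantile(totals, 0.25)
    keep = totals >= fraction * q1
    return ds.subset_spots(np.flatnonzero(keep))


def normalize_median(ds: SpatialCountMatrix) -> pd.DataFrame:
    """Scale each spot so its total equals the median per-spot total.

    Returns a dense spots x genes DataFrame (index spot ids, columns gene
    ids).  Every spot must have a positive total; run
    :func:`filter_low_quality` first.
    """
    totals = ds.spot_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"spot {ds.spot_ids[zero[0]]!r} has zero total count")
    med = float(np.median(totals))
    dense = ds.counts.toarray().astype(float)
    dense *= (med / totals)[:, None]
    return pd.DataFrame(dense, index=ds.spot_ids, columns=ds.gene_ids)


def quantify_molecules(
    mt: MoleculeTable, template: SpatialCountMatrix
) -> SpatialCountMatrix:
    """Collapse a molecule table to UMI counts on a template's spot/gene frame.

    Spots or genes of the template absent from the table get zero counts;
    table records referring to spots/genes outside the template raise.
    """
    spot_index = {s: i for i, s in enumerate(template.spot_ids)}
    gene_index = {g: j for j, g in enumerate(template.gene_ids)}
    collapsed = mt.collapse()
    if len(collapsed):
        unknown_spots = set(collapsed["spot_id"]) - set(spot_index)
        if unknown_spots:
            raise ValueError(f"molecule spot {sorted(unknown_spots)[0]!r} not in template")
        unknown_genes = set(collapsed["gene_id"]) - set(gene_index)
        if unknown_genes:
            raise ValueError(f"molecule gene {sorted(unknown_genes)[0]!r} not in template")
        rows = collapsed["spot_id"].map(spot_index).to_numpy()
        cols = collapsed["gene_id"].map(gene_index).to_numpy()
        vals = collapsed["umis"].to_numpy()
    else:
        rows = cols = vals = np.zeros(0, dtype=np.int64)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(template.n_spots, template.n_genes)
    )
    return SpatialCountMatrix(
        spot_ids=list(template.spot_ids),
        coords=template.coords.copy(),
        counts=counts,
        gene_ids=list(template.gene_ids),
        platform_meta=dict(template.platform_meta),
    )
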