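"""Data model, file formats and shared preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstbench.core_io import (
    MoleculeTable,
    RegionOfInterest,
    bin_spots,
    filter_low_quality,
    normalize_median,
    quantify_molecules,
    read_spatial_dataset,
    select_roi,
    write_spatial_dataset,
)

from conftest import make_ds, make_molecules


def _write_bundle(tmp_path, entries, shape=(3, 2), barcodes=None, positions=None):
    barcodes = barcodes or [f"S{i+1}" for i in range(shape[0])]
    features = [f"G{j+1}" for j in range(shape[1])]
    mtx = tmp_path / "matrix.mtx"
    lines = [
        "%%MatrixMarket matrix coordinate integer general",
        f"{shape[0]} {shape[1]} {len(entries)}",
    ] + [f"{i} {j} {v}" for i, j, v in entries]
    mtx.write_text("\n".join(lines) + "\n")
    (tmp_path / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))
    (tmp_path / "features.tsv").write_text("".join(f + "\n" for f in features))
    if positions is None:
        positions = [(b, 10.0 * k, 0.0) for k, b in enumerate(barcodes)]
    pd.DataFrame(positions, columns=["barcode", "x_um", "y_um"]).to_csv(
        tmp_path / "positions.csv", index=False
    )
    return tmp_path


class TestReadSpatialDataset:
    def test_transcribes_triplets(self, tmp_path):
        d = _write_bundle(tmp_path, [(1, 1, 4), (2, 2, 1), (3, 1, 2)])
        ds = read_spatial_dataset(
            d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv", d / "positions.csv"
        )
        assert ds.gene_totals().tolist() == [6, 1]
        assert ds.spot_ids == ["S1", "S2", "S3"]

    def test_empty_entry_list_gives_zero_matrix(self, tmp_path):
        d = _write_bundle(tmp_path, [])
        ds = read_spatial_dataset(
            d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv", d / "positions.csv"
        )
        assert ds.counts.shape == (3, 2)
        assert ds.total_umis() == 0

    def test_missing_position_names_barcode(self, tmp_path):
        d = _write_bundle(
            tmp_path,
            [(1, 1, 4)],
            positions=[("S1", 0.0, 0.0), ("S2", 10.0, 0.0)],  # S3 absent
        )
        with pytest.raises(ValueError, match="S3"):
            read_spatial_dataset(
                d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv",
                d / "positions.csv",
            )

    def test_malformed_header_is_format_error(self, tmp_path):
        d = _write_bundle(tmp_path, [(1, 1, 4)])
        (d / "matrix.mtx").write_text("not a matrix market file\n1 2 3\n")
        with pytest.raises(ValueError):
            read_spatial_dataset(
                d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv",
                d / "positions.csv",
            )

    def test_roundtrip_is_exact(self, tmp_path, square_ds):
        write_spatial_dataset(square_ds, tmp_path)
        back = read_spatial_dataset(
            tmp_path / "matrix.mtx", tmp_path / "barcodes.tsv",
            tmp_path / "features.tsv", tmp_path / "positions.csv",
        )
        assert (back.counts != square_ds.counts).nnz == 0
        np.testing.assert_array_equal(back.coords, square_ds.coords)
        assert back.spot_ids == square_ds.spot_ids
        assert back.gene_ids == square_ds.gene_ids


class TestBinSpots:
    def test_hand_grid_assignment(self):
        ds = make_ds([[2], [5]], coords=[[1.0, 1.0], [3.0, 3.0]])
        binned = bin_spots(ds, 10.0)
        assert binned.n_spots == 1
        np.testing.assert_array_equal(binned.coords, [[5.0, 5.0]])
        assert binned.total_umis() == 7

    def test_fine_bins_preserve_totals(self, square_ds):
        binned = bin_spots(square_ds, 1.0)
        assert binned.n_spots == square_ds.n_spots
        assert sorted(np.asarray(binned.counts.sum(axis=1)).ravel()) == sorted(
            square_ds.spot_totals()
        )

    def test_boundary_spot_falls_in_upper_cell(self):
        ds = make_ds([[1]], coords=[[10.0, 0.0]])
        binned = bin_spots(ds, 10.0)
        # half-open cells: x=10 belongs to [10, 20) whose centre is 15
        assert binned.coords[0, 0] == 15.0

    def test_nonpositive_bin_rejected(self, square_ds):
        with pytest.raises(ValueError):
            bin_spots(square_ds, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(
        bin_um=st.floats(min_value=0.5, max_value=500, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_conserves_total_umis(self, bin_um, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(1.0, size=(30, 4))
        coords = rng.uniform(-200, 200, size=(30, 2))
        ds = make_ds(counts, coords)
        assert bin_spots(ds, bin_um).total_umis() == ds.total_umis()


class TestSelectRoi:
    square = RegionOfInterest([(0, 0), (10, 0), (10, 10), (0, 10)], "sq")

    def test_point_in_polygon(self):
        ds = make_ds([[1], [1]], coords=[[5.0, 5.0], [15.0, 5.0]])
        kept = select_roi(ds, self.square)
        assert kept.spot_ids == ["S1"]

    def test_edge_point_retained(self):
        ds = make_ds([[1]], coords=[[10.0, 5.0]])
        assert select_roi(ds, self.square).n_spots == 1

    def test_empty_selection_is_not_an_error(self):
        ds = make_ds([[1]], coords=[[50.0, 50.0]])
        assert select_roi(ds, self.square).n_spots == 0

    def test_idempotent(self, square_ds):
        once = select_roi(square_ds, self.square)
        twice = select_roi(once, self.square)
        assert twice.spot_ids == once.spot_ids
        assert (twice.counts != once.counts).nnz == 0

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest([(0, 0), (1, 1), (2, 2)], "line")
        with pytest.raises(ValueError):
            RegionOfInterest([(0, 0), (10, 10), (10, 0), (0, 10)], "bowtie")


class TestFilterLowQuality:
    def test_all_retained(self):
        ds = make_ds(np.diag([100, 200, 300, 400]))
        assert filter_low_quality(ds).n_spots == 4  # Q1=175, threshold 52.5

    def test_low_spot_removed(self):
        ds = make_ds(np.diag([10, 200, 300, 400]))
        kept = filter_low_quality(ds)
        # type-7 Q1 = 152.5, threshold 45.75, so the 10-count spot goes
        assert kept.n_spots == 3
        assert "S1" not in kept.spot_ids

    def test_equal_totals_all_retained(self):
        ds = make_ds(np.full((5, 2), 3))
        assert filter_low_quality(ds).n_spots == 5

    def test_too_few_spots_rejected(self):
        ds = make_ds([[1], [2], [3]])
        with pytest.raises(ValueError):
            filter_low_quality(ds)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_never_removes_max_total_spot(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=(8, 3)) + 1
        ds = make_ds(counts)
        kept = filter_low_quality(ds)
        top = ds.spot_ids[int(np.argmax(ds.spot_totals()))]
        assert top in kept.spot_ids


class TestNormalizeMedian:
    def test_equal_totals_identity(self):
        ds = make_ds([[2, 3], [3, 2], [1, 4]])
        norm = normalize_median(ds)
        np.testing.assert_allclose(norm.to_numpy(), ds.counts.toarray())

    def test_hand_value(self):
        ds = make_ds([[5, 5], [10, 10], [15, 15]])  # totals 10, 20, 30
        norm = normalize_median(ds)
        assert norm.loc["S1", "G1"] == pytest.approx(5 / 10 * 20)

    def test_row_sums_equal_median(self):
        rng = np.random.default_rng(0)
        ds = make_ds(rng.poisson(5.0, size=(7, 4)) + 1)
        norm = normalize_median(ds)
        med = np.median(ds.spot_totals())
        np.testing.assert_allclose(norm.sum(axis=1), med)

    def test_zero_total_spot_named(self):
        ds = make_ds([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="S1"):
            normalize_median(ds)


class TestMoleculeTable:
    def test_duplicate_molecule_rejected(self):
        df = pd.DataFrame(
            {
                "spot_id": ["S1", "S1"],
                "gene_id": ["G1", "G1"],
                "molecule_id": ["m0", "m0"],
                "reads": [1, 2],
            }
        )
        with pytest.raises(ValueError):
            MoleculeTable(df)

    def test_collapse_matches_counts(self, square_ds):
        mt = make_molecules([1, 2, 3])
        ds = quantify_molecules(mt, square_ds)
        assert ds.counts[0, 0] == 3  # three molecules at S1 x G1
        assert ds.total_umis() == 3
        assert ds.spot_ids == square_ds.spot_ids

    def test_unknown_spot_rejected(self, square_ds):
        mt = make_molecules([1], spot_id="nope")
        with pytest.raises(ValueError, match="nope"):
            quantify_molecules(mt, square_ds)
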