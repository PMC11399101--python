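"""Marker detection: rank-sum test, threshold filter, depth curves, intersections."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sstbench.core_io import MoleculeTable, normalize_median
from sstbench.markers import (
    filter_markers,
    marker_depth_curve,
    marker_intersection,
    wilcoxon_markers,
)

from conftest import make_ds


def norm_frame(values_by_gene, n1, n2):
    """Normalised-expression frame with groups g1*/g2* from per-gene arrays."""
    idx = [f"g1s{i}" for i in range(n1)] + [f"g2s{i}" for i in range(n2)]
    return pd.DataFrame(values_by_gene, index=idx)


def rank_sum_p_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    observed = ranks[:n1].sum()
    stats = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.array(stats)
    mean = stats.mean()
    extreme = np.abs(stats - mean) >= abs(observed - mean) - 1e-12
    return extreme.mean()


class TestWilcoxonMarkers:
    def test_exact_small_sample_p(self):
        frame = norm_frame({"gene": [5, 6, 7, 1, 2, 3]}, 3, 3)
        table = wilcoxon_markers(frame, ["g1s0", "g1s1", "g1s2"], ["g2s0", "g2s1", "g2s2"])
        assert table.loc["gene", "p_value"] == pytest.approx(0.1, abs=1e-12)
        assert table.loc["gene", "log_fc"] == pytest.approx(math.log(3), abs=1e-6)

    def test_identical_gene_is_null(self):
        frame = norm_frame({"flat": [2.0] * 6, "var": [1, 2, 3, 4, 5, 6]}, 3, 3)
        table = wilcoxon_markers(frame, ["g1s0", "g1s1", "g1s2"], ["g2s0", "g2s1", "g2s2"])
        assert table.loc["flat", "p_value"] == 1.0
        assert table.loc["flat", "log_fc"] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=3).round(2)
            y = rng.normal(size=3).round(2)
            if len(np.unique(np.concatenate([x, y]))) < 6:
                continue  # oracle below assumes no ties
            frame = norm_frame({"g": np.concatenate([x, y])}, 3, 3)
            table = wilcoxon_markers(
                frame, ["g1s0", "g1s1", "g1s2"], ["g2s0", "g2s1", "g2s2"]
            )
            assert table.loc["g", "p_value"] == pytest.approx(
                rank_sum_p_oracle(x, y), abs=1e-12
            )

    def test_pct_detected(self):
        frame = norm_frame({"g": [0, 1, 2, 0, 0, 3]}, 3, 3)
        table = wilcoxon_markers(frame, ["g1s0", "g1s1", "g1s2"], ["g2s0", "g2s1", "g2s2"])
        assert table.loc["g", "pct_group1"] == pytest.approx(2 / 3)
        assert table.loc["g", "pct_group2"] == pytest.approx(1 / 3)

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(1)
        frame = norm_frame(
            {f"g{j}": rng.poisson(2.0, 12) for j in range(20)}, 6, 6
        )
        g1 = [f"g1s{i}" for i in range(6)]
        g2 = [f"g2s{i}" for i in range(6)]
        table = wilcoxon_markers(frame, g1, g2)
        assert (table["p_adj"] >= table["p_value"] - 1e-15).all()

    def test_overlapping_groups_rejected(self):
        frame = norm_frame({"g": [1, 2, 3, 4]}, 2, 2)
        with pytest.raises(ValueError):
            wilcoxon_markers(frame, ["g1s0", "g1s1"], ["g1s1", "g2s0"])


TOY_TABLE = pd.DataFrame(
    {
        #                 passes?  reason
        "log_fc":    [1.0,   0.25,  1.0,   1.0,   -2.0,  0.9],
        "pct_group1": [0.50, 0.50,  0.04,  0.50,  0.50,  0.30],
        "pct_group2": [0.10, 0.10,  0.01,  0.10,  0.90,  0.05],
        "p_value":   [1e-5,  1e-5,  1e-5,  0.5,   1e-5,  1e-6],
        "p_adj":     [1e-4,  1e-4,  1e-4,  0.8,   1e-4,  1e-5],
    },
    index=["good1", "lfc_at_cut", "low_pct", "high_p", "down", "good2"],
)


class TestFilterMarkers:
    def test_toy_table_exact_selection(self):
        assert filter_markers(TOY_TABLE) == {"good1", "good2"}

    def test_log_fc_threshold_is_strict(self):
        assert "lfc_at_cut" not in filter_markers(TOY_TABLE)

    def test_low_pct_excluded_regardless_of_p(self):
        assert "low_pct" not in filter_markers(TOY_TABLE)

    def test_down_direction(self):
        assert filter_markers(TOY_TABLE, direction="down") == {"down"}

    def test_monotone_in_thresholds(self):
        strict = filter_markers(TOY_TABLE)
        loose = filter_markers(TOY_TABLE, min_pct=0.0, min_log_fc=0.0, max_padj=0.5)
        assert strict <= loose


class TestMarkerIntersection:
    def test_hand_partition(self):
        table = marker_intersection(
            {"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g2"}}
        )
        by_sig = dict(zip(table["signature"], table["genes"]))
        assert by_sig[("A", "B", "C")] == ["g2"]
        assert by_sig[("A",)] == ["g1"]
        assert by_sig[("B",)] == ["g3"]
        tiers = table.groupby("n_platforms")["n_genes"].sum()
        assert tiers.to_dict() == {3: 1, 1: 2}

    def test_identical_sets_all_shared(self):
        table = marker_intersection({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert table["n_platforms"].tolist() == [2]

    def test_disjoint_sets_all_unique(self):
        table = marker_intersection({"A": {"g1"}, "B": {"g2"}})
        assert set(table["n_platforms"]) == {1}

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            marker_intersection({"A": {"g1"}})


class TestMarkerDepthCurve:
    def _planted(self, seed=0):
        """Two spot groups on a grid; 3 genes doubled in group 1."""
        rng = np.random.default_rng(seed)
        n_spots, n_genes = 40, 15
        base = rng.poisson(8.0, size=(n_spots, n_genes))
        base[:20, :3] *= 2  # planted markers in the first 20 spots
        coords = np.column_stack(
            [np.repeat(np.arange(8), 5) * 10.0, np.tile(np.arange(5), 8) * 10.0]
        )
        ds = make_ds(base, coords)
        rows = []
        k = 0
        for i, s in enumerate(ds.spot_ids):
            for j, g in enumerate(ds.gene_ids):
                for _ in range(base[i, j]):
                    rows.append((s, g, f"m{k}", int(1 + rng.poisson(1.0))))
                    k += 1
        mt = MoleculeTable(
            pd.DataFrame(rows, columns=["spot_id", "gene_id", "molecule_id", "reads"])
        )
        g1 = ds.spot_ids[:20]
        g2 = ds.spot_ids[20:]
        return ds, mt, g1, g2

    def test_full_depth_reproduces_direct_count(self):
        ds, mt, g1, g2 = self._planted()
        from sstbench.core_io import filter_low_quality, quantify_molecules

        curve = marker_depth_curve(mt, ds, g1, g2, proportions=[1.0], seed=5)
        ds_full = quantify_molecules(mt, ds)
        ds_full = filter_low_quality(ds_full)
        table = wilcoxon_markers(
            normalize_median(ds_full),
            [s for s in g1 if s in ds_full.spot_ids],
            [s for s in g2 if s in ds_full.spot_ids],
        )
        assert curve.iloc[0].n_markers == len(filter_markers(table))

    def test_zero_depth_has_no_markers(self):
        ds, mt, g1, g2 = self._planted()
        curve = marker_depth_curve(mt, ds, g1, g2, proportions=[0.0], seed=5)
        assert curve.iloc[0].n_markers == 0

    def test_more_depth_finds_more_markers_on_average(self):
        counts = {0.05: [], 1.0: []}
        for seed in range(5):
            ds, mt, g1, g2 = self._planted(seed)
            curve = marker_depth_curve(
                mt, ds, g1, g2, proportions=[0.05, 1.0], seed=100 + seed
            )
            counts[0.05].append(curve.iloc[0].n_markers)
            counts[1.0].append(curve.iloc[1].n_markers)
        assert np.mean(counts[1.0]) >= np.mean(counts[0.05])
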