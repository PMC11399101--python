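"""Gene-capture bias rules, attribute ANOVA and contamination."""

import numpy as np
import pandas as pd
import pytest

from sstbench.bias import (
    HIGH_Q_RELAXED,
    attribute_anova,
    biotype_summary,
    contamination_fraction,
    flag_bias_genes,
    pairwise_gene_compare,
)
from sstbench.core_io import GeneAnnotation

from conftest import make_ds


def totals(values, genes=None):
    genes = genes or [f"g{i+1}" for i in range(len(values))]
    return pd.Series(list(values), index=genes, dtype=float)


class TestPairwiseGeneCompare:
    def test_hand_quantiles(self):
        a = totals([100, 90, 0, 1, 2, 3, 4, 5, 6, 7])
        b = totals([0, 80, 50, 40, 30, 60, 70, 55, 45, 35])
        flags, table = pairwise_gene_compare(a, b)
        # type-7 q99(a) between the two largest values; q10(b) near the bottom
        assert flags == {"g1"}
        assert table.loc["g1", "flagged"]

    def test_identical_platforms_flag_nothing(self):
        a = totals(np.arange(1, 21))
        assert pairwise_gene_compare(a, a.copy())[0] == set()

    def test_planted_gene_recovered_exactly(self):
        rng = np.random.default_rng(0)
        background = rng.integers(1, 100, size=499).astype(float)
        a = totals(np.concatenate([background, [10_000.0]]))
        b = a.copy()
        b.iloc[-1] = 0.0
        flags, _ = pairwise_gene_compare(a, b)
        assert flags == {a.index[-1]}

    def test_relaxed_preset_flags_more(self):
        rng = np.random.default_rng(1)
        a = totals(rng.integers(0, 200, size=100).astype(float))
        b = totals(rng.integers(0, 200, size=100).astype(float))
        strict, _ = pairwise_gene_compare(a, b)
        relaxed, _ = pairwise_gene_compare(a, b, high_q=HIGH_Q_RELAXED)
        assert strict <= relaxed

    def test_too_few_shared_genes_rejected(self):
        with pytest.raises(ValueError):
            pairwise_gene_compare(totals([1, 2, 3]), totals([1, 2, 3]))


class TestFlagBiasGenes:
    PLATFORMS = {
        "A": totals([500, 400, 300, 5, 4, 3], list("abcdef")),
        "B": totals([450, 350, 320, 6, 5, 2], list("abcdef")),
        "focal": totals([5, 450, 2, 3, 4, 1], list("abcdef")),
    }

    def test_rule_application(self):
        bias, comparison = flag_bias_genes(self.PLATFORMS, "focal", expressed_q=0.5)
        # a, b, c exceed the median in both non-focal platforms;
        # focal totals: a=5 (<30, bias), b=450 (comparison), c=2 (bias)
        assert bias == {"a", "c"}
        assert comparison == {"b"}

    def test_partition_property(self):
        bias, comparison = flag_bias_genes(self.PLATFORMS, "focal", expressed_q=0.5)
        assert bias & comparison == set()

    def test_gene_low_in_one_platform_excluded(self):
        platforms = dict(self.PLATFORMS)
        platforms["B"] = platforms["B"].copy()
        platforms["B"]["a"] = 0.0  # no longer high everywhere
        bias, comparison = flag_bias_genes(platforms, "focal", expressed_q=0.5)
        assert "a" not in bias | comparison

    def test_missing_focal_platform(self):
        with pytest.raises(ValueError):
            flag_bias_genes(self.PLATFORMS, "nope")


ANNOTATION = GeneAnnotation(
    pd.DataFrame(
        {
            "biotype": ["protein_coding"] * 4 + ["lncRNA", "protein_coding"],
            "length_bp": [1, 2, 3, 4, 5, 6],
            "gc_fraction": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
        },
        index=list("abcdef"),
    )
)


class TestAttributeAnova:
    def test_hand_decomposition(self):
        f, df1, df2, p = attribute_anova(
            ["a", "b", "c"], ["d", "e", "f"], ANNOTATION, "length_bp"
        )
        assert f == pytest.approx(13.5)
        assert (df1, df2) == (1, 4)

    def test_identical_groups_give_zero_f(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "biotype": ["x"] * 4,
                    "length_bp": [10, 20, 10, 20],
                    "gc_fraction": [0.5] * 4,
                },
                index=list("wxyz"),
            )
        )
        f, _, _, p = attribute_anova(["w", "x"], ["y", "z"], ann, "length_bp")
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_manual_decomposition(self):
        rng = np.random.default_rng(2)
        lengths = rng.integers(100, 10_000, size=30)
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "biotype": ["x"] * 30,
                    "length_bp": lengths,
                    "gc_fraction": rng.uniform(0.3, 0.7, 30),
                },
                index=[f"g{i}" for i in range(30)],
            )
        )
        g1 = [f"g{i}" for i in range(12)]
        g2 = [f"g{i}" for i in range(12, 30)]
        f, _, _, _ = attribute_anova(g1, g2, ann, "length_bp")
        x1 = lengths[:12].astype(float)
        x2 = lengths[12:].astype(float)
        grand = np.concatenate([x1, x2]).mean()
        ssb = 12 * (x1.mean() - grand) ** 2 + 18 * (x2.mean() - grand) ** 2
        ssw = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
        assert f == pytest.approx(ssb / (ssw / 28), rel=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            attribute_anova(["a"], ["d", "e"], ANNOTATION, "length_bp")


class TestBiotypeSummary:
    def test_counts_sorted(self):
        out = biotype_summary(["a", "b", "c", "e"], ANNOTATION)
        assert out.to_dict() == {"protein_coding": 3, "lncRNA": 1}

    def test_empty_set(self):
        assert biotype_summary([], ANNOTATION).empty

    def test_unannotated_gene(self):
        out = biotype_summary(["a", "mystery"], ANNOTATION)
        assert out["unannotated"] == 1


class TestContaminationFraction:
    def test_definition(self):
        counts = np.zeros((10, 1), dtype=int)
        counts[:7, 0] = 1
        ds = make_ds(counts)
        assert contamination_fraction(ds, "G1") == pytest.approx(0.7)

    def test_absent_everywhere(self):
        ds = make_ds(np.zeros((5, 1), dtype=int))
        assert contamination_fraction(ds, "G1") == 0.0

    def test_unknown_gene(self, square_ds):
        with pytest.raises(KeyError):
            contamination_fraction(square_ds, "Gx")

    def test_synthetic_ambient_positivity(self):
        from sstbench.synthetic import ExpressionProgram, make_layout, simulate_dataset

        layout = make_layout(
            "layers",
            {"boundaries": [0.0, 100.0], "region_labels": ["only"], "extent": (0.0, 100.0)},
        )
        program = ExpressionProgram(
            region_rates={"only": {}}, ambient_rates={"Amb": 2.0}
        )
        frac = 0.5
        n_cells = 1000
        ds, _, _ = simulate_dataset(
            layout, program,
            {"pitch_um": 10.0, "capture_bbox": (0.0, 0.0, 100.0, 100.0)},
            n_cells=n_cells, sigma_diff_um=0.0, reads_per_molecule_mean=1.0,
            contamination_fraction=frac, seed=9,
        )
        # expected molecules per spot ~ Poisson(rate*frac*n_cells / n_spots)
        lam = 2.0 * frac * n_cells / ds.n_spots
        expected = 1 - np.exp(-lam)
        measured = contamination_fraction(ds, "Amb")
        se = np.sqrt(expected * (1 - expected) / ds.n_spots)
        assert abs(measured - expected) < 4 * se
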