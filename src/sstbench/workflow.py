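"""Configuration-driven end-to-end benchmark on generated data.

:func:`run_full_benchmark` takes one configuration (a mapping, usually
loaded from YAML), simulates the configured platforms, and runs every
analysis stage — saturation curves, depth-matched sensitivity, diffusion
LWHM summaries, clustering-entropy concordance, marker detection and depth
curves, gene-capture bias, contamination — writing CSV tables per stage and
a machine-readable ``summary.json``.  All randomness flows from the
configured seeds, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans

from . import bias as bias_mod
from . import cluster_eval, markers, sensitivity
from .core_io import (
    filter_low_quality,
    normalize_median,
    quantify_molecules,
    write_molecule_table,
    write_spatial_dataset,
)
from .depth import _round_half_up, downsample_reads, saturation_curve
from .diffusion import Strip, diffusion_summary
from .synthetic import ExpressionProgram, make_layout, simulate_dataset

__all__ = ["default_demo_config", "load_config", "run_full_benchmark", "StageError"]

logger = logging.getLogger(__name__)


def _jsonable(obj):
    """Recursively convert numpy scalars so the summary serialises."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_demo_config(seed: int = 7, scale: float = 1.0) -> dict:
    """A self-contained two-platform demo scenario on an eye-ring layout.

    ``scale`` shrinks cell numbers for quick smoke runs.  The two platforms
    differ in pitch, spot diameter (hence capture efficiency), diffusion
    and read depth, mimicking a high-resolution bead array versus a
    coarser grid array.
    """
    n = max(1, int(round(400 * scale)))
    return {
        "seed": int(seed),
        "layout": {
            "kind": "eye_rings",
            "params": {
                "center": [150.0, 150.0],
                "radii": [50.0, 100.0, 120.0],
                "region_labels": ["lens", "neural_retina", "melanocyte", "outer"],
            },
        },
        "program": {
            "region_rates": {
                "lens": {"Vit": 6.0, "Crybb3": 5.0, "Aldh1a1": 0.2, "Pmel": 0.0,
                         "Actb": 3.0},
                "neural_retina": {"Aldh1a1": 5.0, "Vit": 0.2, "Actb": 3.0},
                "melanocyte": {"Pmel": 6.0, "Actb": 3.0},
                "outer": {"Actb": 2.0},
            },
            "ambient_rates": {"Hba-a1": 1.0},
        },
        "platforms": [
            {
                "name": "beadarray",
                "pitch_um": 5.0,
                "spot_diameter_um": 5.0,
                "sigma_diff_um": 2.0,
                "reads_per_molecule_mean": 3.0,
                "n_cells": 10 * n,
                "contamination_fraction": 0.05,
            },
            {
                "name": "gridarray",
                "pitch_um": 20.0,
                "spot_diameter_um": 14.0,
                "sigma_diff_um": 10.0,
                "reads_per_molecule_mean": 2.0,
                "n_cells": 10 * n,
                "contamination_fraction": 0.3,
            },
        ],
        "windows": [
            [125.0, 125.0, 50.0, 50.0],
            [100.0, 125.0, 50.0, 50.0],
            [125.0, 100.0, 50.0, 50.0],
            [140.0, 140.0, 50.0, 50.0],
        ],
        "marker_genes": ["Vit", "Crybb3"],
        "strips": [
            {"anchor": [150.0, 150.0], "axis": [1.0, 0.0], "length_um": 140.0,
             "width_um": 50.0, "bin_um": 20.0},
            {"anchor": [150.0, 150.0], "axis": [0.0, 1.0], "length_um": 140.0,
             "width_um": 50.0, "bin_um": 20.0},
            {"anchor": [150.0, 150.0], "axis": [-1.0, 0.0], "length_um": 140.0,
             "width_um": 50.0, "bin_um": 20.0},
            {"anchor": [150.0, 150.0], "axis": [0.0, -1.0], "length_um": 140.0,
             "width_um": 50.0, "bin_um": 20.0},
        ],
        "diffusion_gene": "Pmel",
        "saturation_proportions": [0.1, 0.25, 0.5, 0.75, 1.0],
        "saturation_reps": 3,
        "concordance_proportions": [0.25, 0.5, 1.0],
        "marker_groups": {"group1_region": "lens", "group2_region": "melanocyte"},
        "marker_depth_proportions": [0.25, 0.5, 1.0],
        "bias_focal_platform": "gridarray",
        "contamination_gene": "Hba-a1",
    }


def load_config(path) -> dict:
    """Load a YAML benchmark configuration."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    with open(p) as fh:
        return yaml.safe_load(fh)


def _spot_region_labels(ds, layout) -> pd.Series:
    return pd.Series(layout.regions_of(ds.coords), index=ds.spot_ids, dtype=object)


def _kmeans_labels(norm: pd.DataFrame, k: int, seed: int) -> pd.Series:
    values = np.log1p(norm.to_numpy())
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(values)
    return pd.Series([f"c{v}" for v in labels], index=norm.index)


def run_full_benchmark(config: Mapping, out_dir) -> dict:
    """Run every benchmark stage on the configured synthetic scenario.

    Writes per-stage CSVs and ``summary.json`` under ``out_dir`` and
    returns the summary dict.  A failing stage raises :class:`StageError`
    naming the stage; outputs of earlier stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"seed": seed, "platforms": {}}

    # --- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        layout = make_layout(config["layout"]["kind"], config["layout"]["params"])
        program = ExpressionProgram(
            region_rates={
                r: dict(g) for r, g in config["program"]["region_rates"].items()
            },
            ambient_rates=dict(config["program"].get("ambient_rates", {})),
        )
        datasets, mols, truths = {}, {}, {}
        for i, plat in enumerate(config["platforms"]):
            name = plat["name"]
            ds, mt, truth = simulate_dataset(
                layout=layout,
                program=program,
                platform={
                    "name": name,
                    "pitch_um": plat["pitch_um"],
                    "spot_diameter_um": plat.get("spot_diameter_um"),
                    "capture_bbox": layout.bounds,
                },
                n_cells=int(plat["n_cells"]),
                sigma_diff_um=float(plat["sigma_diff_um"]),
                reads_per_molecule_mean=float(plat["reads_per_molecule_mean"]),
                contamination_fraction=float(plat["contamination_fraction"]),
                seed=seed + 1000 * (i + 1),
            )
            datasets[name], mols[name], truths[name] = ds, mt, truth
            pdir = out / name
            write_spatial_dataset(ds, pdir)
            write_molecule_table(mt, pdir / "molecules.tsv")
            (pdir / "truth.json").write_text(
                json.dumps(
                    {
                        "sigma_diff_um": truth.sigma_diff_um,
                        "reads_per_molecule_mean": truth.reads_per_molecule_mean,
                        "contamination_fraction": truth.contamination_fraction,
                        "seed": truth.seed,
                        "n_cells": len(truth.cells),
                    },
                    sort_keys=True,
                )
            )
            summary["platforms"][name] = {
                "total_reads": mt.total_reads,
                "total_umis": ds.total_umis(),
                "n_spots": ds.n_spots,
            }
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, exc) from exc

    # --- saturation -----------------------------------------------------
    stage = "saturation"
    try:
        curves = []
        for name, mt in mols.items():
            curve = saturation_curve(
                mt,
                proportions=list(config["saturation_proportions"]),
                n_rep=int(config["saturation_reps"]),
                seed=seed + 11,
            )
            curve.insert(0, "platform", name)
            curves.append(curve)
        sat = pd.concat(curves, ignore_index=True)
        sat.to_csv(out / "saturation.csv", index=False)
        summary["saturation"] = {
            name: {
                str(row.p): row.mean_umis
                for row in sat[sat.platform == name].itertuples()
            }
            for name in mols
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- sensitivity ----------------------------------------------------
    stage = "sensitivity"
    try:
        windows = [sensitivity.Window(*w) for w in config["windows"]]
        table = sensitivity.compare_platforms_sensitivity(
            datasets,
            roi=None,
            windows=windows,
            genes=list(config["marker_genes"]),
            common_depth=True,
            molecule_tables=mols,
            seed=seed + 21,
        )
        table.to_csv(out / "sensitivity.csv", index=False)
        summary["sensitivity_rank"] = list(table["platform"])
        summary["sensitivity_window_mean"] = {
            row.platform: row.window_mean for row in table.itertuples()
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- diffusion ------------------------------------------------------
    stage = "diffusion"
    try:
        strips = [
            Strip(
                anchor=tuple(s["anchor"]),
                axis=tuple(s["axis"]),
                length_um=float(s["length_um"]),
                width_um=float(s.get("width_um", 50.0)),
                bin_um=float(s.get("bin_um", 10.0)),
            )
            for s in config["strips"]
        ]
        diff = diffusion_summary(
            {name: strips for name in datasets}, datasets, config["diffusion_gene"]
        )
        diff.drop(columns=["lwhm_values"]).to_csv(out / "diffusion.csv", index=False)
        summary["diffusion_median_lwhm"] = {
            row.platform: row.median_lwhm for row in diff.itertuples()
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- clustering concordance ----------------------------------------
    stage = "cluster_eval"
    try:
        conc_rows = []
        for name in datasets:
            ds_full = filter_low_quality(datasets[name])
            nonzero = np.flatnonzero(ds_full.spot_totals() > 0)
            ds_full = ds_full.subset_spots(nonzero)
            regions = _spot_region_labels(ds_full, layout)
            k = regions.nunique()
            full_labels = _kmeans_labels(normalize_median(ds_full), k, seed + 31)
            by_prop = {}
            total = mols[name].total_reads
            for j, p in enumerate(config["concordance_proportions"]):
                target = _round_half_up(float(p) * total)
                sub = (
                    mols[name]
                    if target == total
                    else downsample_reads(mols[name], target, seed=seed + 41 + j)
                )
                ds_p = quantify_molecules(sub, datasets[name])
                ds_p = ds_p.subset_spots(np.flatnonzero(ds_p.spot_totals() > 0))
                ds_p = filter_low_quality(ds_p)
                by_prop[float(p)] = _kmeans_labels(
                    normalize_median(ds_p), k, seed + 51 + j
                )
            conc = cluster_eval.downsample_concordance(full_labels, by_prop)
            conc.insert(0, "platform", name)
            conc_rows.append(conc)
        concordance = pd.concat(conc_rows, ignore_index=True)
        concordance.to_csv(out / "cluster_concordance.csv", index=False)
        summary["cluster_concordance"] = {
            name: {
                str(row.proportion): {"eca": row.eca, "ecp": row.ecp}
                for row in concordance[concordance.platform == name].itertuples()
            }
            for name in datasets
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- markers --------------------------------------------------------
    stage = "markers"
    try:
        g1_region = config["marker_groups"]["group1_region"]
        g2_region = config["marker_groups"]["group2_region"]
        marker_sets = {}
        depth_curves = []
        for name in datasets:
            ds = filter_low_quality(datasets[name])
            ds = ds.subset_spots(np.flatnonzero(ds.spot_totals() > 0))
            regions = _spot_region_labels(ds, layout)
            g1 = list(regions.index[regions == g1_region])
            g2 = list(regions.index[regions == g2_region])
            norm = normalize_median(ds)
            table = markers.wilcoxon_markers(norm, g1, g2)
            table.to_csv(out / f"markers_{name}.csv")
            marker_sets[name] = markers.filter_markers(table)
            curve = markers.marker_depth_curve(
                mols[name],
                datasets[name],
                g1,
                g2,
                proportions=list(config["marker_depth_proportions"]),
                seed=seed + 61,
            )
            curve.insert(0, "platform", name)
            depth_curves.append(curve)
        pd.concat(depth_curves, ignore_index=True).to_csv(
            out / "marker_depth.csv", index=False
        )
        inter = markers.marker_intersection(marker_sets)
        inter.assign(signature=inter["signature"].map(lambda s: "|".join(s))).to_csv(
            out / "marker_intersection.csv", index=False
        )
        summary["n_markers"] = {n: len(s) for n, s in marker_sets.items()}
        summary["markers_shared_by_all"] = int(
            inter.loc[inter.n_platforms == len(datasets), "n_genes"].sum()
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- bias and contamination ----------------------------------------
    stage = "bias"
    try:
        totals = {n: ds.gene_totals() for n, ds in datasets.items()}
        names = sorted(datasets)
        if len(names) >= 2 and len(totals[names[0]]) >= 10:
            flags, pair_table = bias_mod.pairwise_gene_compare(
                totals[names[0]], totals[names[1]]
            )
            pair_table.to_csv(out / "pairwise_bias.csv")
            summary["pairwise_bias_genes"] = sorted(flags)
        focal = config.get("bias_focal_platform", names[-1])
        bias_genes, comparison = bias_mod.flag_bias_genes(totals, focal)
        summary["bias_genes"] = sorted(bias_genes)
        summary["contamination_fraction"] = {
            n: bias_mod.contamination_fraction(ds, config["contamination_gene"])
            for n, ds in datasets.items()
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    summary = _jsonable(summary)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    logger.info("benchmark complete; summary at %s", summary_path)
    return summary
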