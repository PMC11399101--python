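"""Generate a synthetic spot-array dataset with known ground truth.

Builds a concentric "embryonic eye" layout (lens, neural retina,
melanocyte ring), attaches region-specific expression programs plus a
blood-like ambient gene, and simulates capture on a 5 um bead array with
2 um of lateral diffusion and 3x read duplication.
"""

from sstbench import ExpressionProgram, make_layout, simulate_dataset

layout = make_layout(
    "eye_rings",
    {
        "center": (150.0, 150.0),
        "radii": [50.0, 100.0, 120.0],
        "region_labels": ["lens", "neural_retina", "melanocyte", "outer"],
    },
)
program = ExpressionProgram(
    region_rates={
        "lens": {"Vit": 6.0, "Crybb3": 5.0, "Actb": 3.0},
        "neural_retina": {"Aldh1a1": 5.0, "Actb": 3.0},
        "melanocyte": {"Pmel": 6.0, "Actb": 3.0},
        "outer": {"Actb": 2.0},
    },
    ambient_rates={"Hba-a1": 1.0},
)

ds, molecules, truth = simulate_dataset(
    layout,
    program,
    platform={"name": "beadarray", "pitch_um": 5.0, "spot_diameter_um": 5.0},
    n_cells=4000,
    sigma_diff_um=2.0,
    reads_per_molecule_mean=3.0,
    contamination_fraction=0.05,
    seed=7,
)

print(f"spots: {ds.n_spots}, genes: {ds.n_genes}")
print(f"captured molecules (UMIs): {ds.total_umis()}")
print(f"sequencing reads: {molecules.total_reads}")
print(f"reads per molecule: {molecules.total_reads / molecules.n_molecules:.2f}")
# The UMI count is what a spatial experiment observes; the ratio of reads
# to UMIs sets how much the saturation analysis can recover by downsampling.
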