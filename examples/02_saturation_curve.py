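"""Saturation: distinct molecules recovered as a function of read depth.

Downsamples reads without replacement at stepwise proportions and compares
the Monte-Carlo mean with the exact hypergeometric expectation.
"""

import numpy as np
import pandas as pd

from sstbench import MoleculeTable, expected_umis, saturation_curve

rng = np.random.default_rng(0)
reads = 1 + rng.poisson(2.0, size=2000)  # ~3 reads per molecule
mt = MoleculeTable(
    pd.DataFrame(
        {
            "spot_id": "S1",
            "gene_id": "G1",
            "molecule_id": [f"m{i}" for i in range(len(reads))],
            "reads": reads,
        }
    )
)

curve = saturation_curve(mt, proportions=[0.1, 0.25, 0.5, 0.75, 1.0], n_rep=20, seed=1)
print(curve.to_string(index=False))
for _, row in curve.iterrows():
    closed_form = expected_umis(mt, int(row.reads))
    print(f"p={row.p:.2f}: simulated {row.mean_umis:8.1f}  closed form {closed_form:8.1f}")
# The curve flattens as most molecules have been seen at least once; the
# closed form is the exact expectation the sampler is checked against.
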