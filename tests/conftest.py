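import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from sstbench.core_io import MoleculeTable, SpatialCountMatrix


def make_ds(counts, coords=None, spot_ids=None, gene_ids=None, **meta):
    """Build a SpatialCountMatrix from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    if spot_ids is None:
        spot_ids = [f"S{i+1}" for i in range(n)]
    if gene_ids is None:
        gene_ids = [f"G{j+1}" for j in range(g)]
    return SpatialCountMatrix(
        spot_ids=spot_ids,
        coords=np.asarray(coords, dtype=float),
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        platform_meta=dict(meta),
    )


def make_molecules(reads, spot_id="S1", gene_id="G1"):
    """Molecule table with the given per-molecule read counts, one spot/gene."""
    return MoleculeTable(
        pd.DataFrame(
            {
                "spot_id": spot_id,
                "gene_id": gene_id,
                "molecule_id": [f"m{i}" for i in range(len(reads))],
                "reads": list(reads),
            }
        )
    )


@pytest.fixture
def square_ds():
    """4 spots on a 10 um square with simple counts, 2 genes."""
    counts = np.array([[3, 0], [5, 1], [0, 2], [1, 1]])
    coords = np.array([[5.0, 5.0], [15.0, 5.0], [5.0, 15.0], [15.0, 15.0]])
    return make_ds(counts, coords, pitch_um=10.0)
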