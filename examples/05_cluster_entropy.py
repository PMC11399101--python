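"""Clustering agreement: entropy of cluster accuracy (ECA) and purity (ECP).

Compares a degraded labeling against a reference and shows the exact
values for easy hand-checkable cases.
"""

import math

import pandas as pd

from sstbench import contingency, eca, ecp

spots = [f"s{i}" for i in range(8)]
reference = pd.Series(["a", "a", "a", "a", "b", "b", "b", "b"], index=spots)

perfect = pd.Series(["x", "x", "x", "x", "y", "y", "y", "y"], index=spots)
merged = pd.Series(["z"] * 8, index=spots)  # everything in one cluster
half_mixed = pd.Series(["x", "x", "x", "y", "y", "y", "y", "x"], index=spots)

for name, pred in [("perfect", perfect), ("merged", merged), ("mixed", half_mixed)]:
    print(f"{name:8s} ECA={eca(pred, reference):.4f} ECP={ecp(pred, reference):.4f}")
print(f"ln 2 = {math.log(2):.4f} (entropy of a 50/50 split)")
print(contingency(half_mixed, reference).table)
# ECA = 0 means every predicted cluster is pure; the merged labeling pays
# exactly ln 2 because each cluster mixes the two classes evenly.
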