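"""Intersect transcription-factor regulators of two gene groups.

Given a gene-to-TF annotation, finds the regulators shared between a drug's
DEGs and a knockdown's DEGs, then keeps only the shared TFs that are
themselves repressed in the drug profile.
"""

import numpy as np
import pandas as pd

from revscreen import filter_tfs_by_expression, shared_tfs

tf_map = {
    "MMP1": {"JUN", "FOS"},
    "PTGS2": {"JUN", "NFKB1"},
    "ANGPTL4": {"PPARG"},
    "TNC": {"JUN"},
}

drug_degs = ["MMP1", "PTGS2"]
kd_degs = ["PTGS2", "TNC"]

shared, regions = shared_tfs(tf_map, drug_degs)
shared_kd, _ = shared_tfs(tf_map, kd_degs)
common = shared & shared_kd
print(f"TFs shared across both DEG groups: {sorted(common)}")

deg_table = pd.DataFrame(
    {"fold_change": [0.3, 1.1], "log2fc": np.log2([0.3, 1.1]), "p_value": [0.004, 0.6]},
    index=["JUN", "FOS"],
)
repressed = filter_tfs_by_expression(common, deg_table, direction="down")
print(f"of those, repressed by the drug: {sorted(repressed)}")
# JUN regulates genes in both groups and is itself knocked down more than
# two-fold, so it survives the expression filter.
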