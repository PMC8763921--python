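"""False-discovery behaviour under random relabelling.

Takes a dataset with no real group structure, repeatedly splits its samples
into random case/control halves, and records the percentage of features each
workflow calls significant (BH q <= 0.05). A well-behaved workflow should
call nothing on the vast majority of replicates.
"""

import numpy as np

from microda import MethodConfig, fdr_simulation
from microda.simulate import SyntheticSpec, generate_null_dataset

table, labels, _ = generate_null_dataset(SyntheticSpec(seed=7))
sims = fdr_simulation(
    table,
    labels,
    ["ttest_rare", "wilcoxon_rare", "maaslin2", "lefse"],
    n_replicates=30,
    cfg=MethodConfig(seed=7),
    seed=7,
)

print(f"{'method':<15} {'median %sig':>12} {'mean %sig':>10} {'max %sig':>9}")
for s in sims:
    v = s.replicate_pct_significant[~np.isnan(s.replicate_pct_significant)]
    print(f"{s.method:<15} {np.median(v):>12.2f} {v.mean():>10.2f} {v.max():>9.2f}")
# BH-corrected tests stay at (or very near) 0% on relabelled data; the
# LEfSe-style rule, which applies no correction, is the usual outlier.
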