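"""Simulate a small variant MPRA and estimate allelic effects.

Generates 500 variants in five effect groups (true log2 fold changes
-2, -0.5, 0, 0.5, 2), fits the barcode-level weighted GLS model, and
compares the estimated logFC per group with the simulated truth.
"""

import numpy as np
import pandas as pd
from scipy import stats

from mprakit import SimulationSpec, create_variant_frame, fit_variants, simulate_dataset

counts, truth, vmap = simulate_dataset(SimulationSpec(n_variants=500, seed=1))
frame = create_variant_frame(counts, vmap)

fit_bc = fit_variants(frame, mode="barcode")
fit_ag = fit_variants(frame, mode="aggregate")

groups = truth.set_index("variant_id")["group"]
summary = pd.DataFrame({
    "true_logFC": truth.set_index("variant_id")["true_logfc"],
    "estimated_logFC": pd.Series(fit_bc.coef, index=fit_bc.row_ids),
    "significant": pd.Series(fit_bc.adj_p_value < 0.05, index=fit_bc.row_ids),
}).groupby(groups).agg({"true_logFC": "first", "estimated_logFC": "mean",
                        "significant": "sum"})
print(summary.round(3))
print(f"\nconsensus within-replicate correlation: {fit_bc.consensus_rho:.3f}")
r = stats.pearsonr(fit_bc.coef, fit_ag.coef).statistic
print(f"barcode-mode vs aggregate-mode logFC Pearson r: {r:.4f}")
print("\nThe mean estimated logFC per group should match the simulated truth;")
print("strong effects (|logFC|=2) should all be significant at BH 0.05, and")
print("the neutral group should stay near the 5% false-positive rate.")
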