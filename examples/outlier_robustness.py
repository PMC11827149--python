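"""Why model barcodes individually: robustness to RNA outliers.

Simulates a small variant dataset, injects multiplicative x25 RNA
outliers into 10% of barcodes, and compares how well barcode-level and
aggregated logFC estimates survive the contamination.
"""

from scipy import stats

from mprakit import (
    OutlierConfig,
    SimulationSpec,
    create_variant_frame,
    fit_variants,
    inject_outliers,
    simulate_dataset,
)

counts, truth, vmap = simulate_dataset(SimulationSpec(n_variants=400, seed=2))
frame = create_variant_frame(counts, vmap)
clean = {m: fit_variants(frame, m) for m in ("barcode", "aggregate")}

noisy, registry = inject_outliers(counts, OutlierConfig(fraction=0.1, seed=2))
print(f"injected outliers: {registry['barcode'].nunique()} barcodes, "
      f"{len(registry)} RNA cells multiplied by 25")
nframe = create_variant_frame(noisy, vmap)
for mode in ("barcode", "aggregate"):
    fit = fit_variants(nframe, mode)
    r = stats.pearsonr(fit.coef, clean[mode].coef).statistic
    print(f"{mode:>9}-mode logFC correlation with clean data: {r:.4f}")
print("\nA single x25 barcode corrupts an entire replicate sum in aggregate")
print("mode, but is one sample among hundreds in barcode mode, so the")
print("barcode-level correlation with the uncontaminated fit stays higher.")
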