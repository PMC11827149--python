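"""Standard count-table preprocessing before modeling.

Builds a small simulated table, spikes in one extreme RNA outlier, and
runs the filtering chain: minimum counts per replicate, minimum barcodes
per sequence, 3-SD RNA outlier removal, and 95th-percentile barcode
downsampling.
"""

from mprakit import (
    BarcodeCountTable,
    SimulationSpec,
    downsample_barcodes,
    filter_min_barcodes,
    filter_min_counts,
    remove_outlier_barcodes,
    simulate_dataset,
)

counts, _, _ = simulate_dataset(SimulationSpec(n_variants=50, seed=4))
df = counts.df.copy()
df.loc[df.index[0], "rna_count"] *= 200  # one wild RNA count
counts = BarcodeCountTable.from_frame(df)
spiked_barcode = df.loc[df.index[0], "barcode"]

print(f"input: {counts.n_barcodes} barcodes, {len(counts)} records")
step = filter_min_counts(counts, min_count=1)
print(f"after min-count filter (DNA & RNA >= 1 in every replicate): "
      f"{step.n_barcodes} barcodes")
step = filter_min_barcodes(step, min_barcodes=10)
print(f"after min-barcode filter (>= 10 barcodes per sequence): "
      f"{step.barcode_multiplicity().size} sequences")
step = remove_outlier_barcodes(step, n_sd=3)
removed = spiked_barcode not in set(step.df["barcode"])
print(f"after 3-SD RNA outlier removal: {step.n_barcodes} barcodes "
      f"(spiked outlier removed: {removed})")
step = downsample_barcodes(step, percentile=95, seed=0)
print(f"after 95th-percentile downsampling: max multiplicity "
      f"{step.barcode_multiplicity().max()}")
print("\nEach step only drops records; counts are never altered or imputed.")
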