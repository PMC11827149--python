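"""Count-table filtering, outlier removal, and barcode downsampling.

The recommended order before modeling is::

    filter_min_counts -> filter_min_barcodes -> remove_outlier_barcodes
        -> filter_min_barcodes (re-check) -> downsample_barcodes

Each step only removes records; counts are never modified or imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import BarcodeCountTable

log = logging.getLogger(__name__)

__all__ = [
    "filter_min_counts",
    "filter_min_barcodes",
    "remove_outlier_barcodes",
    "downsample_barcodes",
    "preprocess_pipeline",
]


def filter_min_counts(counts: BarcodeCountTable, min_count: int = 1) -> BarcodeCountTable:
    """Keep barcodes with DNA and RNA counts >= ``min_count`` in every replicate.

    A barcode absent from some replicate fails the requirement as well.
    """
    df = counts.df
    n_reps = df["replicate"].nunique()
    good = (df["dna_count"] >= min_count) & (df["rna_count"] >= min_count)
    ok_reps = good.groupby(df["barcode"]).sum()
    seen_reps = df.groupby("barcode")["replicate"].nunique()
    keep = ok_reps.index[(ok_reps == n_reps) & (seen_reps == n_reps)]
    out = df[df["barcode"].isin(set(keep))]
    log.info("filter_min_counts removed %d of %d barcodes",
             df["barcode"].nunique() - len(keep), df["barcode"].nunique())
    return BarcodeCountTable.from_frame(out, validate=False)


def filter_min_barcodes(counts: BarcodeCountTable, min_barcodes: int = 10) -> BarcodeCountTable:
    """Drop oligos with fewer than ``min_barcodes`` surviving barcodes."""
    mult = counts.barcode_multiplicity()
    keep = set(mult.index[mult >= min_barcodes])
    out = counts.df[counts.df["oligo"].isin(keep)]
    log.info("filter_min_barcodes dropped %d of %d oligos",
             len(mult) - len(keep), len(mult))
    return BarcodeCountTable.from_frame(out, validate=False)


def remove_outlier_barcodes(counts: BarcodeCountTable, n_sd: float = 3.0) -> BarcodeCountTable:
    """Remove barcodes with an extreme RNA count for their sequence.

    Per (oligo, replicate) group the mean and sample (n-1) standard
    deviation of the RNA counts are computed; a barcode deviating by more
    than ``n_sd`` standard deviations in *any* replicate is removed from
    *all* replicates.  Groups with zero or undefined SD remove nothing.
    """
    df = counts.df
    grp = df.groupby(["oligo", "replicate"])["rna_count"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton groups
    with np.errstate(invalid="ignore"):
        flag = (df["rna_count"] - mean).abs() > n_sd * sd
    flag &= sd.fillna(0.0) > 0
    bad = set(df.loc[flag, "barcode"])
    out = df[~df["barcode"].isin(bad)]
    log.info("remove_outlier_barcodes removed %d barcodes", len(bad))
    return BarcodeCountTable.from_frame(out, validate=False)


def downsample_barcodes(counts: BarcodeCountTable, percentile: float = 95,
                        seed: int | None = 0) -> BarcodeCountTable:
    """Cap barcode multiplicity at a percentile of the per-oligo distribution.

    The cap is the given percentile (linear interpolation, floored to an
    integer) of distinct-barcode counts across oligos; oligos above the cap
    keep a uniformly random cap-sized subset of their barcodes.
    Deterministic given ``seed``.
    """
    mult = counts.barcode_multiplicity()
    cap = int(np.floor(np.percentile(mult.to_numpy(), percentile)))
    over = mult.index[mult > cap]
    if len(over) == 0:
        return counts
    rng = np.random.default_rng(seed)
    df = counts.df
    drop: set[str] = set()
    bc_by_oligo = df[df["oligo"].isin(set(over))].groupby("oligo")["barcode"].unique()
    for oligo in over:
        bcs = np.sort(bc_by_oligo[oligo])
        keep = rng.choice(len(bcs), size=cap, replace=False)
        drop.update(np.delete(bcs, keep))
    out = df[~df["barcode"].isin(drop)]
    log.info("downsample_barcodes: cap %d, reduced %d oligos", cap, len(over))
    return BarcodeCountTable.from_frame(out, validate=False)


def preprocess_pipeline(counts: BarcodeCountTable, min_count: int = 1,
                        min_barcodes: int = 10, outlier_sd: float | None = 3.0,
                        downsample_percentile: float | None = 95,
                        seed: int | None = 0) -> BarcodeCountTable:
    """Standard filtering chain; pass ``outlier_sd=None`` or
    ``downsample_percentile=None`` to skip those steps."""
    out = filter_min_counts(counts, min_count)
    out = filter_min_barcodes(out, min_barcodes)
    if outlier_sd is not None:
        out = remove_outlier_barcodes(out, outlier_sd)
        out = filter_min_barcodes(out, min_barcodes)
    if downsample_percentile is not None:
        out = downsample_barcodes(out, downsample_percentile, seed)
    return out
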