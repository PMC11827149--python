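"""Desk-scale simulation benchmark: barcode-level vs aggregated fitting.

Reproduces the simulation study internally: a clean dataset with five
known effect groups, plus repeated random outlier injections on a grid of
fractions.  For each dataset and mode it records per-group significant
counts, logFC/adjusted-p correlations against the clean fit of the same
mode, mode-vs-mode logFC correlations, and the Kolmogorov-Smirnov
statistic of the neutral group's raw p-values against U(0,1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import create_variant_frame
from .fit import fit_variants
from .simulate import OutlierConfig, SimulationSpec, inject_outliers, simulate_dataset

__all__ = ["run_benchmark", "significant_counts"]

DEFAULT_FRACTIONS = (0.1, 0.05, 0.01, 0.005, 0.001)


def significant_counts(fit, truth: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Significant variants (BH-adjusted p < alpha) per effect group."""
    sig = pd.Series(fit.adj_p_value < alpha, index=fit.row_ids)
    return sig.groupby(truth.set_index("variant_id")["group"]).sum()


def _correlate(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return np.nan
    return float(stats.pearsonr(a[mask], b[mask])[0])


def run_benchmark(n_variants: int = 5000,
                  fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
                  n_repetitions: int = 5, seed: int = 0, alpha: float = 0.05,
                  fast: bool = False) -> pd.DataFrame:
    """Run the full simulation benchmark; returns a tidy metrics table.

    ``fast=True`` scales to 1000 variants and 2 repetitions.
    """
    if fast:
        n_variants, n_repetitions = 1000, 2
    spec = SimulationSpec(n_variants=n_variants, seed=seed)
    counts, truth, vmap = simulate_dataset(spec)
    frame = create_variant_frame(counts, vmap)
    clean = {m: fit_variants(frame, m) for m in ("barcode", "aggregate")}

    rows: list[dict] = []

    def record(dataset, fraction, repetition, mode, metric, group, value):
        rows.append(dict(dataset=dataset, fraction=fraction,
                         repetition=repetition, mode=mode, metric=metric,
                         group=group, value=value))

    neutral = (truth["group"] == "neutral").to_numpy()
    for mode, fit in clean.items():
        for group, n in significant_counts(fit, truth, alpha).items():
            record("clean", 0.0, 0, mode, "n_significant", group, int(n))
        p_null = fit.p_value[neutral]
        p_null = p_null[np.isfinite(p_null)]
        ks = stats.kstest(p_null, "uniform").statistic
        record("clean", 0.0, 0, mode, "null_p_ks", "neutral", float(ks))
    record("clean", 0.0, 0, "barcode_vs_aggregate", "logfc_pearson", "all",
           _correlate(clean["barcode"].coef, clean["aggregate"].coef))

    for fraction in fractions:
        for rep in range(n_repetitions):
            cfg = OutlierConfig(fraction=fraction,
                                seed=seed + 1000 * rep + int(1e6 * fraction))
            noisy, _ = inject_outliers(counts, cfg)
            nframe = create_variant_frame(noisy, vmap)
            for mode in ("barcode", "aggregate"):
                fit = fit_variants(nframe, mode)
                for group, n in significant_counts(fit, truth, alpha).items():
                    record("outlier", fraction, rep, mode,
                           "n_significant", group, int(n))
                record("outlier", fraction, rep, mode, "logfc_pearson_vs_clean",
                       "all", _correlate(fit.coef, clean[mode].coef))
                record("outlier", fraction, rep, mode, "adjp_pearson_vs_clean",
                       "all", _correlate(fit.adj_p_value,
                                         clean[mode].adj_p_value))
    return pd.DataFrame(rows)
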