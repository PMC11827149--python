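"""Per-replicate normalization, log-ratios, and mean-variance precision weights.

Activity of a barcode is the log2 ratio of its library-normalized RNA and
DNA counts.  Counts are scaled counts-per-million-style by per-replicate
library sizes (totals over every column of the replicate block), so depth
differences between replicates cancel.

Weights follow the voom recipe adapted to DNA-count abundance: a LOWESS
trend of the quarter-root residual variance (sqrt of the residual SD) of
each row's ordinary least-squares fit against the row's mean log2 DNA
abundance; each cell's weight is the trend value interpolated at that
cell's *own* DNA abundance, raised to the power -4 — so high-count
barcodes of a sequence carry more precision, which is the point of
modeling barcodes individually.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from ._gls import BlockedGLS
from .data_model import WideCountFrame

__all__ = ["NormalizationError", "WeightingError", "normalize_and_logratio",
           "voom_weights", "WeightedLogratioFrame", "plot_mean_variance_trend"]


class NormalizationError(ValueError):
    """A replicate block has zero total counts."""


class WeightingError(ValueError):
    """The mean-variance trend cannot be estimated."""


def normalize_and_logratio(frame: WideCountFrame, pseudocount: float = 1.0,
                           target_library: float = 1e6):
    """Return (logratio, log_dna_abundance), NaN at missing cells.

    Library sizes are per replicate block: the total DNA (resp. RNA) count
    over all non-missing cells in the block's columns and all rows.
    """
    nm = ~frame.missing_mask
    R, B, W = frame.n_rows, frame.n_blocks, frame.block_width
    l_dna = (frame.dna * nm).reshape(R, B, W).sum(axis=(0, 2))
    l_rna = (frame.rna * nm).reshape(R, B, W).sum(axis=(0, 2))
    if np.any(l_dna <= 0) or np.any(l_rna <= 0):
        bad = [frame.blocks[i] for i in range(B)
               if l_dna[i] <= 0 or l_rna[i] <= 0]
        raise NormalizationError(f"zero total counts in replicate block(s) {bad}")
    col_l_dna = np.repeat(l_dna, W)
    col_l_rna = np.repeat(l_rna, W)
    with np.errstate(divide="ignore"):
        log_dna = np.log2((frame.dna + pseudocount) / col_l_dna * target_library)
        log_rna = np.log2((frame.rna + pseudocount) / col_l_rna * target_library)
    logratio = np.where(nm, log_rna - log_dna, np.nan)
    log_dna = np.where(nm, log_dna, np.nan)
    return logratio, log_dna


def _interpolate_trend(trend_x: np.ndarray, trend_y: np.ndarray,
                       at: np.ndarray) -> np.ndarray:
    """Evaluate the fitted trend at arbitrary abundances, clamped to the
    fitted range; collapses duplicate x positions first."""
    x, idx = np.unique(trend_x, return_index=True)
    y = trend_y[idx]
    floor = max(1e-8, 1e-4 * float(np.median(np.abs(y))) if len(y) else 1e-8)
    return np.clip(np.interp(at, x, y), floor, None)


def _predicted_abundance(log_dna: np.ndarray, missing_mask: np.ndarray,
                         n_blocks: int) -> np.ndarray:
    """Leave-own-replicate-out DNA abundance per cell.

    The weight for a cell must not depend on that cell's own observed
    count: a high DNA draw simultaneously raises the naive weight and
    pushes the log-ratio down, correlating weights with residuals (which
    corrupts downstream correlation and variance estimation — the reason
    the voom recipe evaluates its trend at fitted rather than observed
    log-counts).  Each barcode slot occupies the same position in every
    replicate block, so the slot's mean abundance over the *other*
    replicates predicts the cell's abundance independently of its own
    noise.  Slots observed in fewer than two replicates fall back to the
    row mean.
    """
    R, C = log_dna.shape
    width = C // n_blocks
    d3 = np.where(~missing_mask, log_dna, np.nan).reshape(R, n_blocks, width)
    obs = ~np.isnan(d3)
    total = np.nansum(d3, axis=1)            # (R, width)
    count = obs.sum(axis=1)                  # (R, width)
    denom = count[:, None, :] - obs.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (total[:, None, :] - np.nan_to_num(d3)) / denom
    row_mean = np.nanmean(np.where(~missing_mask, log_dna, np.nan),
                          axis=1)[:, None, None]
    loo = np.where(denom > 0, loo, row_mean)
    return loo.reshape(R, C)


def voom_weights(logratio: np.ndarray, log_dna_abundance: np.ndarray,
                 design: np.ndarray, missing_mask: np.ndarray,
                 span: float = 0.5, n_blocks: int = 1) -> np.ndarray:
    """Mean-variance trend precision weights; zero at missing cells.

    The LOWESS trend is fitted at row level (residual quarter-root
    variance vs mean log2 DNA abundance) and evaluated per cell at the
    cell's leave-own-replicate-out predicted abundance, so barcodes with
    high DNA representation get higher precision without tying a cell's
    weight to its own sampling noise.
    """
    nm = ~missing_mask
    ols = BlockedGLS(np.nan_to_num(logratio), nm.astype(float), design, n_blocks=1)
    _, _, sigma, df, ok = ols.fit(rho=0.0)
    use = ok & (df > 0) & np.isfinite(sigma) & (sigma > 0)
    if not use.any():
        raise WeightingError("no rows with positive residual degrees of freedom")
    d_row = np.nanmean(np.where(nm, log_dna_abundance, np.nan), axis=1)
    lo = sm.nonparametric.lowess(np.sqrt(sigma[use]), d_row[use], frac=span,
                                 delta=0.01 * np.ptp(d_row[use]))
    cell_d = _predicted_abundance(log_dna_abundance, missing_mask, n_blocks)
    trend = _interpolate_trend(lo[:, 0], lo[:, 1], np.nan_to_num(cell_d))
    weights = np.where(nm, trend**-4.0, 0.0)
    return weights


class WeightedLogratioFrame:
    """Log-ratios plus precision weights ready for GLS fitting.

    Weights are strictly positive on non-missing cells and exactly zero on
    missing cells; log-ratios are finite wherever non-missing.
    """

    def __init__(self, frame: WideCountFrame, pseudocount: float = 1.0,
                 target_library: float = 1e6, span: float = 0.5):
        self.frame = frame
        self.logratio, self.log_dna_abundance = normalize_and_logratio(
            frame, pseudocount, target_library)
        self.design = frame.design()
        self.weight = voom_weights(self.logratio, self.log_dna_abundance,
                                   self.design, frame.missing_mask, span,
                                   n_blocks=frame.n_blocks)

    @property
    def row_ids(self):
        return self.frame.row_ids

    @property
    def block(self):
        return self.frame.block

    @property
    def allele(self):
        return self.frame.allele

    @property
    def missing_mask(self):
        return self.frame.missing_mask


def plot_mean_variance_trend(wframe: WeightedLogratioFrame, path=None,
                             span: float = 0.5):
    """QC plot: per-row residual spread against mean log2 DNA abundance,
    with the fitted LOWESS trend that drives the precision weights."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nm = ~wframe.missing_mask
    ols = BlockedGLS(np.nan_to_num(wframe.logratio), nm.astype(float),
                     wframe.design, n_blocks=1)
    _, _, sigma, df, ok = ols.fit(rho=0.0)
    use = ok & (df > 0) & np.isfinite(sigma) & (sigma > 0)
    d_row = np.nanmean(np.where(nm, wframe.log_dna_abundance, np.nan), axis=1)
    lo = sm.nonparametric.lowess(np.sqrt(sigma[use]), d_row[use], frac=span,
                                 delta=0.01 * np.ptp(d_row[use]))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(d_row[use], np.sqrt(sigma[use]), s=4, alpha=0.3,
               color="grey", label="rows")
    ax.plot(lo[:, 0], lo[:, 1], color="firebrick", lw=2, label="LOWESS trend")
    ax.set_xlabel("mean log2 DNA abundance")
    ax.set_ylabel(r"residual SD$^{1/2}$")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
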