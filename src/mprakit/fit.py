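"""Weighted GLS fitting of barcode log-ratios with empirical Bayes moderation.

The model per row (variant or element) is

    Y = beta0 + beta X + eps,   eps ~ N(0, sigma^2 W^{-1} Sigma)

with X the 0/1 reference/alternative allele indicator (absent in element
mode), W the voom-style precision weights and Sigma block-diagonal
compound-symmetric over technical replicates with a single *consensus*
correlation shared by all rows.  Per-row residual variances are then
shrunk toward a common prior estimated from all rows (empirical Bayes),
and moderated t-statistics are tested on df_residual + df_prior degrees of
freedom with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from ._gls import BlockedGLS
from .data_model import WideCountFrame, aggregate_frame
from .weights import WeightedLogratioFrame

__all__ = [
    "FitResult",
    "ConsensusCorrelationError",
    "estimate_consensus_correlation",
    "gls_fit_rows",
    "squeeze_variances",
    "moderated_test",
    "benjamini_hochberg",
    "fit_variants",
    "fit_elements",
]


class ConsensusCorrelationError(ValueError):
    """Within-replicate correlation is unidentifiable (single column per block)."""


# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Per-row coefficients, moderated statistics, and shrinkage parameters."""

    row_ids: np.ndarray
    coef: np.ndarray
    stdev_unscaled: np.ndarray
    sigma: np.ndarray
    df_residual: np.ndarray
    df_prior: float
    s2_prior: float
    s2_post: np.ndarray
    t: np.ndarray
    p_value: np.ndarray
    adj_p_value: np.ndarray
    consensus_rho: float
    coef_label: str = "logFC"
    n_barcodes: np.ndarray | None = None
    labels: np.ndarray | None = None
    ok: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "id": self.row_ids,
            self.coef_label: self.coef,
            "t": self.t,
            "p_value": self.p_value,
            "adj_p_value": self.adj_p_value,
            "n_barcodes": (self.n_barcodes if self.n_barcodes is not None
                           else np.full(len(self.row_ids), np.nan)),
        })
        if self.labels is not None:
            out["label"] = self.labels
        return out


# ----------------------------------------------------------------------
def estimate_consensus_correlation(wframe: WeightedLogratioFrame,
                                   grid_points: int = 81,
                                   trim: float = 0.15) -> float:
    """Consensus within-replicate correlation of the weighted residuals.

    Per row, the equicorrelated-within-block correlation is estimated by
    REML on a grid (with a parabolic refinement around the per-row
    optimum); per-row estimates are pooled on the atanh scale by a
    two-sided trimmed mean and transformed back.
    """
    frame = wframe.frame
    gls = BlockedGLS(np.nan_to_num(wframe.logratio), wframe.weight,
                     wframe.design, frame.n_blocks)
    if gls.max_block_size < 2:
        raise ConsensusCorrelationError(
            "every replicate block has a single usable column; within-block "
            "correlation is unidentifiable — use aggregated mode")
    lo = max(gls.rho_lower_bound() + 1e-3, -0.99)
    grid = np.linspace(lo, 0.99, grid_points)
    ll, usable = gls.reml_profile(grid)
    if not usable.any():
        raise ConsensusCorrelationError("no rows usable for correlation estimation")
    ll = ll[usable]
    best = np.argmax(ll, axis=1)
    rho_hat = grid[best]
    # parabolic refinement where the optimum is interior
    interior = (best > 0) & (best < grid_points - 1)
    if interior.any():
        i = best[interior]
        y0, y1, y2 = (ll[interior, i - 1], ll[interior, i], ll[interior, i + 1])
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        h = grid[1] - grid[0]
        rho_hat[interior] = np.clip(grid[i] + np.clip(shift, -1, 1) * h,
                                    lo, 0.99)
    z = np.arctanh(np.clip(rho_hat, -0.999, 0.999))
    return float(np.tanh(stats.trim_mean(z, proportiontocut=trim)))


def gls_fit_rows(wframe: WeightedLogratioFrame, rho: float):
    """Row-wise weighted GLS at the given consensus correlation.

    Returns ``(beta, stdev_unscaled, sigma, df_residual, ok)``; rows whose
    non-missing columns leave the design rank-deficient, or with no
    residual degrees of freedom, have ``ok=False`` and NaN statistics.
    """
    gls = BlockedGLS(np.nan_to_num(wframe.logratio), wframe.weight,
                     wframe.design, wframe.frame.n_blocks)
    return gls.fit(rho)


# ----------------------------------------------------------------------
def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_variances(sigma2: np.ndarray, df: np.ndarray):
    """Empirical Bayes shrinkage of residual variances toward a common prior.

    Assuming s_g^2 | sigma_g^2 scaled chi-square on df_g and a scaled
    inverse-chi-square prior (d0, s0^2) on sigma_g^2, the prior is
    estimated by moment matching on e_g = log s_g^2 - digamma(df_g/2) +
    log(df_g/2).  Returns ``(df_prior, s2_prior, s2_post)``; an infinite
    df_prior (observed spread consistent with pure chi-square noise) gives
    s2_post identically s2_prior.  With fewer than two usable rows,
    moderation is skipped (df_prior 0, s2_post = s^2).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.asarray(df, dtype=float)
    use = np.isfinite(sigma2) & (sigma2 > 0) & (df > 0)
    if use.sum() < 2:
        import warnings
        warnings.warn("fewer than 2 rows with positive variance; "
                      "variance moderation skipped", stacklevel=2)
        return 0.0, np.nan, sigma2.copy()
    z = np.log(sigma2[use])
    e = z - special.digamma(df[use] / 2.0) + np.log(df[use] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df[use] / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s20 = float(np.exp(emean))
    if np.isinf(d0):
        s2_post = np.where(np.isfinite(sigma2), s20, np.nan)
    else:
        s2_post = (d0 * s20 + df * sigma2) / (d0 + df)
        s2_post = np.where(df > 0, s2_post,
                           np.where(np.isfinite(sigma2), s20, np.nan))
    return float(d0), s20, s2_post


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs are passed through untested."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def moderated_test(coef: np.ndarray, stdev_unscaled: np.ndarray,
                   s2_post: np.ndarray, df_residual: np.ndarray,
                   df_prior: float):
    """Moderated t-statistics, two-sided p-values, and BH adjustment."""
    se = np.sqrt(s2_post) * stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    df_total = df_residual + df_prior
    if np.isinf(df_prior):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(t) & (df_residual > 0), p, np.nan)
    return t, p, benjamini_hochberg(p)


# ----------------------------------------------------------------------
def _fit_chain(frame: WideCountFrame, coef_index: int, coef_label: str,
               pseudocount: float, span: float,
               estimate_correlation: bool) -> FitResult:
    wframe = WeightedLogratioFrame(frame, pseudocount=pseudocount, span=span)
    if estimate_correlation:
        rho = estimate_consensus_correlation(wframe)
    else:
        rho = 0.0
    beta, su, sigma, df, ok = gls_fit_rows(wframe, rho)
    sigma2 = sigma**2
    d0, s20, s2_post = squeeze_variances(np.where(ok, sigma2, np.nan),
                                         np.where(ok, df, 0))
    coef = beta[:, coef_index]
    su_c = su[:, coef_index]
    t, p, adj = moderated_test(coef, su_c, s2_post, df, d0)
    t, p, adj = (np.where(ok, arr, np.nan) for arr in (t, p, adj))
    meta = frame.row_meta
    return FitResult(
        row_ids=frame.row_ids, coef=np.where(ok, coef, np.nan),
        stdev_unscaled=np.where(ok, su_c, np.nan),
        sigma=sigma, df_residual=df.astype(float), df_prior=d0, s2_prior=s20,
        s2_post=s2_post, t=t, p_value=p, adj_p_value=adj, consensus_rho=rho,
        coef_label=coef_label,
        n_barcodes=(meta["n_barcodes"].to_numpy() if "n_barcodes" in meta else None),
        labels=(meta["label"].to_numpy() if "label" in meta else None),
        ok=ok,
    )


def fit_variants(frame: WideCountFrame, mode: str = "barcode",
                 pseudocount: float = 1.0, span: float = 0.5) -> FitResult:
    """Estimate allelic log2 fold changes (alt vs ref) for every variant.

    ``mode='barcode'`` models every barcode slot as a sample;
    ``mode='aggregate'`` first sums counts per (replicate, allele) and runs
    the identical chain on the collapsed frame.
    """
    if frame.allele is None:
        raise ValueError("fit_variants requires a variant-mode frame")
    if mode == "aggregate":
        frame = aggregate_frame(frame)
    elif mode != "barcode":
        raise ValueError(f"unknown mode {mode!r}")
    return _fit_chain(frame, coef_index=1, coef_label="logFC",
                      pseudocount=pseudocount, span=span,
                      estimate_correlation=True)


def fit_elements(frame: WideCountFrame, mode: str = "barcode",
                 pseudocount: float = 1.0, span: float = 0.5) -> FitResult:
    """Estimate the log2 activity (intercept-only fit) of every sequence.

    In aggregated element mode each replicate collapses to one column, so
    the within-replicate correlation is unidentifiable and the fit falls
    back to independent columns.
    """
    if frame.allele is not None:
        raise ValueError("fit_elements requires an element-mode frame")
    if mode == "aggregate":
        frame = aggregate_frame(frame)
        estimate_corr = False
    elif mode == "barcode":
        estimate_corr = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _fit_chain(frame, coef_index=0, coef_label="activity",
                      pseudocount=pseudocount, span=span,
                      estimate_correlation=estimate_corr)
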