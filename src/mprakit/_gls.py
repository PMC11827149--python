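"""Row-wise weighted generalized least squares under block-equicorrelation.

The model for one row (sequence or variant) is

    y = X beta + eps,   eps ~ N(0, sigma^2 W^{-1} Sigma)

where ``W`` is a diagonal matrix of per-observation precision weights and
``Sigma`` is block-diagonal over technical replicates, compound-symmetric
(equicorrelated with correlation ``rho``) within a block and independent
across blocks.  Observations with zero weight (missing barcode slots) are
excluded from the row's problem entirely: they contribute nothing to the
normal equations and do not enter the block size used for ``Sigma``.

Everything is vectorised over rows.  The key identity is the closed-form
inverse of an m x m compound-symmetric correlation matrix,

    Sigma_b^{-1} = a I + b J,
    a = 1 / (1 - rho),
    b = -rho / ((1 - rho) (1 + (m - 1) rho)),

so any bilinear form u' V^{-1} v with V = W^{-1/2} Sigma W^{-1/2} reduces to
weighted elementwise sums plus per-block sums of sqrt(w)-scaled vectors.
This avoids factorising a dense covariance per row and makes a REML profile
over rho cheap: the data-dependent cross-products are rho-free and are
precomputed once.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BlockedGLS"]


class BlockedGLS:
    """Precomputed cross-products for row-wise GLS on a padded wide frame.

    Parameters
    ----------
    y : (R, C) array
        Observations (log-ratios).  Values at zero-weight cells are ignored.
    w : (R, C) array
        Non-negative precision weights; exactly zero marks a missing cell.
    X : (C, p) array
        Column-level design matrix, shared by all rows.
    n_blocks : int
        Number of replicate blocks; columns must be grouped contiguously in
        equal-sized blocks (the frame constructors guarantee this layout).
    """

    def __init__(self, y: np.ndarray, w: np.ndarray, X: np.ndarray, n_blocks: int):
        y = np.asarray(y, dtype=float)
        w = np.asarray(w, dtype=float)
        X = np.asarray(X, dtype=float)
        R, C = y.shape
        if X.shape[0] != C:
            raise ValueError("design rows must equal frame columns")
        if C % n_blocks != 0:
            raise ValueError("columns must divide evenly into blocks")
        self.n_rows, self.n_cols = R, C
        self.n_blocks = n_blocks
        self.block_width = C // n_blocks
        self.p = X.shape[1]

        sw = np.sqrt(w)
        y0 = np.where(w > 0, y, 0.0)
        # G = sqrt(W) [X | y], shape (R, C, p+1)
        G = sw[:, :, None] * np.concatenate(
            [np.broadcast_to(X[None, :, :], (R, C, self.p)), y0[:, :, None]], axis=2
        )
        # rho-independent pieces of the normal equations
        self._A1 = np.einsum("rci,rcj->rij", G, G)  # elementwise (a-) term
        self._S = G.reshape(R, n_blocks, self.block_width, self.p + 1).sum(axis=2)
        # effective block sizes: non-missing cells per (row, block)
        self.m = (w > 0).reshape(R, n_blocks, self.block_width).sum(axis=2)
        self.nnz = self.m.sum(axis=1)

    # ------------------------------------------------------------------
    @property
    def max_block_size(self) -> int:
        return int(self.m.max()) if self.m.size else 0

    def rho_lower_bound(self) -> float:
        """Smallest rho keeping every row's Sigma positive definite."""
        m = self.max_block_size
        if m <= 1:
            return -0.99
        return -1.0 / (m - 1)

    # ------------------------------------------------------------------
    def _normal_equations(self, rho: float):
        """Return stacked [X|y]' V^{-1} [X|y] per row, shape (R, p+1, p+1)."""
        a = 1.0 / (1.0 - rho)
        denom = (1.0 - rho) * (1.0 + (self.m - 1.0) * rho)
        bcoef = np.where(self.m > 0, -rho / denom, 0.0)
        return a * self._A1 + np.einsum("rb,rbi,rbj->rij", bcoef, self._S, self._S)

    def fit(self, rho: float):
        """Solve the weighted GLS problem for every row at correlation rho.

        Returns
        -------
        beta : (R, p); stdev_unscaled : (R, p); sigma : (R,); df : (R,);
        ok : (R,) bool — rows with positive residual df and full-rank design.
        """
        M = self._normal_equations(rho)
        p = self.p
        XtX = M[:, :p, :p]
        Xty = M[:, :p, p]
        yty = M[:, p, p]
        df = self.nnz - p

        diag = np.diagonal(XtX, axis1=1, axis2=2)
        det = np.linalg.det(XtX)
        diag_prod = np.clip(np.prod(diag, axis=1), 1e-300, None)
        ok = (df > 0) & (det > 1e-10 * diag_prod)

        beta = np.full((self.n_rows, p), np.nan)
        su = np.full((self.n_rows, p), np.nan)
        sigma = np.full(self.n_rows, np.nan)
        if ok.any():
            XtX_ok = XtX[ok]
            beta[ok] = np.linalg.solve(XtX_ok, Xty[ok][..., None])[..., 0]
            inv = np.linalg.inv(XtX_ok)
            su[ok] = np.sqrt(np.clip(np.diagonal(inv, axis1=1, axis2=2), 0.0, None))
            rss = np.clip(yty[ok] - np.einsum("ri,ri->r", beta[ok], Xty[ok]), 0.0, None)
            sigma[ok] = np.sqrt(rss / df[ok])
        return beta, su, sigma, df, ok

    # ------------------------------------------------------------------
    def _logdet_sigma(self, rho: float) -> np.ndarray:
        """Per-row log|Sigma(rho)| for the effective (non-missing) blocks."""
        m = self.m
        with np.errstate(invalid="ignore"):
            term = (m - 1.0) * np.log(1.0 - rho) + np.log1p((m - 1.0) * rho)
        return np.where(m > 0, term, 0.0).sum(axis=1)

    def reml_profile(self, rho_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Restricted log-likelihood per row on a grid of rho values.

        Returns ``(ll, usable)`` where ``ll`` has shape (R, len(grid)) and
        ``usable`` marks rows whose likelihood actually depends on rho
        (some block with >= 2 non-missing cells) and that have residual df.
        """
        p = self.p
        df = self.nnz - p
        R = self.n_rows
        ll = np.full((R, len(rho_grid)), -np.inf)
        informative = (self.m >= 2).any(axis=1)
        for j, rho in enumerate(rho_grid):
            M = self._normal_equations(rho)
            XtX = M[:, :p, :p]
            Xty = M[:, :p, p]
            yty = M[:, p, p]
            sign, logdet_xtx = np.linalg.slogdet(XtX)
            valid = (sign > 0) & (df > 0)
            if not valid.any():
                continue
            beta = np.full((R, p), 0.0)
            beta[valid] = np.linalg.solve(XtX[valid], Xty[valid][..., None])[..., 0]
            rss = np.clip(yty - np.einsum("ri,ri->r", beta, Xty), 1e-300, None)
            s2 = rss / np.clip(df, 1, None)
            val = -0.5 * (self._logdet_sigma(rho) + logdet_xtx + df * np.log(s2))
            ll[:, j] = np.where(valid, val, -np.inf)
        usable = informative & (df > 0) & np.isfinite(ll).all(axis=1)
        return ll, usable
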