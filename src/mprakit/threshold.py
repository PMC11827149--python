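"""Threshold t-tests of element activity against negative-control percentiles.

Instead of testing activity against zero, each element is tested against a
threshold derived from a labeled negative-control group: the upper
threshold is a high percentile (default 97.5th) of the controls' fitted
activities, the lower threshold the mirrored percentile.  Before testing,
activities are shifted to be centered at the mean of the controls, which
keeps the test correct when the control distribution (and hence the upper
threshold) is negative; reported activities remain unshifted.

The test itself is a threshold t-test (TREAT): for the activating
direction, p = P(T >= (beta' - tau)/se) on the moderated degrees of
freedom, where beta' is the shifted activity and tau the shifted
threshold.  The two-sided form uses
p = P(T >= (|beta'| - tau)/se) + P(T >= (|beta'| + tau)/se).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FitResult, benjamini_hochberg

__all__ = ["ThresholdTestConfig", "Thresholds", "derive_thresholds",
           "treat_test", "plot_group_activities"]


@dataclass
class ThresholdTestConfig:
    negative_label: str = "negative_control"
    percentile: float = 0.975
    direction: str = "activating"  # activating | repressing | both
    min_controls: int = 20

    def __post_init__(self):
        if not (0.5 < self.percentile < 1.0):
            raise ValueError("percentile must be strictly between 0.5 and 1")
        if self.direction not in ("activating", "repressing", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class Thresholds:
    upper: float
    lower: float
    shift: float


def _labels_for(fit: FitResult, labels) -> np.ndarray:
    if labels is None:
        if fit.labels is None:
            raise ValueError("no labels available on the fit result")
        return np.asarray(fit.labels, dtype=object)
    series = labels.series if hasattr(labels, "series") else pd.Series(labels)
    return series.reindex(np.asarray(fit.row_ids)).to_numpy(dtype=object)


def derive_thresholds(fit: FitResult, labels=None,
                      cfg: ThresholdTestConfig | None = None) -> Thresholds:
    """Percentile thresholds and mean shift from the negative-control group.

    ``upper`` is the ``percentile`` quantile (linear interpolation) of the
    controls' fitted activities, ``lower`` the (1 - percentile) quantile,
    ``shift`` their mean.
    """
    cfg = cfg or ThresholdTestConfig()
    lab = _labels_for(fit, labels)
    mask = (lab == cfg.negative_label) & np.isfinite(fit.coef)
    if not mask.any():
        available = sorted({str(x) for x in lab if isinstance(x, str)})
        raise ValueError(f"label {cfg.negative_label!r} not found; "
                         f"available labels: {available}")
    neg = fit.coef[mask]
    if len(neg) < cfg.min_controls:
        raise ValueError(f"only {len(neg)} negative controls; "
                         f"need at least {cfg.min_controls}")
    return Thresholds(upper=float(np.quantile(neg, cfg.percentile)),
                      lower=float(np.quantile(neg, 1.0 - cfg.percentile)),
                      shift=float(np.mean(neg)))


def treat_test(fit: FitResult, thresholds: Thresholds,
               cfg: ThresholdTestConfig | None = None) -> FitResult:
    """Threshold t-test of fitted activities against the control percentile.

    Returns a new :class:`FitResult` with threshold p-values and BH
    adjustment; coefficients stay unshifted.
    """
    cfg = cfg or ThresholdTestConfig()
    beta_shifted = fit.coef - thresholds.shift
    se = np.sqrt(fit.s2_post) * fit.stdev_unscaled
    df = fit.df_residual + fit.df_prior

    def _sf(x):
        if np.isinf(fit.df_prior):
            return stats.norm.sf(x)
        return stats.t.sf(x, df)

    if cfg.direction == "activating":
        tau = thresholds.upper - thresholds.shift
        tstat = (beta_shifted - tau) / se
        p = _sf(tstat)
    elif cfg.direction == "repressing":
        tau = thresholds.shift - thresholds.lower
        tstat = (-beta_shifted - tau) / se
        p = _sf(tstat)
    else:  # both
        tau = thresholds.upper - thresholds.shift
        tstat = (np.abs(beta_shifted) - tau) / se
        p = _sf(tstat) + _sf((np.abs(beta_shifted) + tau) / se)
    if tau < 0:
        raise ValueError("threshold is negative after mean-shifting; "
                         "the percentile is too low for the control spread")
    tested = np.isfinite(fit.p_value) if fit.ok is None else fit.ok
    p = np.where(tested, p, np.nan)
    tstat = np.where(tested, tstat, np.nan)
    return replace(fit, t=tstat, p_value=p, adj_p_value=benjamini_hochberg(p))


def plot_group_activities(fit: FitResult, labels=None,
                          cfg: ThresholdTestConfig | None = None,
                          path=None, thresholds: Thresholds | None = None):
    """Violin plot of fitted activities per label group.

    When a config is given (or thresholds passed directly), horizontal
    lines mark the upper and lower thresholds.  Returns the figure; saves
    to ``path`` when provided.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lab = _labels_for(fit, labels)
    finite = np.isfinite(fit.coef)
    groups = sorted({str(x) for x in lab[finite] if isinstance(x, str)})
    if not groups:
        groups = ["all"]
        data = [fit.coef[finite]]
    else:
        data = [fit.coef[finite & (lab == g)] for g in groups]

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(groups), 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(np.arange(1, len(groups) + 1), groups, rotation=30, ha="right")
    ax.set_ylabel("fitted log2 activity")
    if cfg is not None and thresholds is None:
        thresholds = derive_thresholds(fit, labels, cfg)
    if thresholds is not None:
        ax.axhline(thresholds.upper, color="firebrick", ls="--", lw=1,
                   label="upper threshold")
        ax.axhline(thresholds.lower, color="steelblue", ls="--", lw=1,
                   label="lower threshold")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
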