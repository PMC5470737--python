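"""Fit statistics and four-way model comparison.

AIC = 2k + n ln(RSS/n) and BIC = k ln(n) + n ln(RSS/n) on the n series
points; R^2 = 1 - RSS/TSS (negative when a nonlinear model fits worse than
the mean); Curvature Mismatch (CM) is the summed squared difference between
the second-order central finite differences of data and prediction, a
discrete proxy for the integrated squared difference of second derivatives.
CM uses unit spacing per grid step (one 3-month bin); absolute CM values
scale with that convention but orderings do not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def goodness_stats(y, yhat, k: int) -> tuple[float, float, float, float]:
    """Return (rss, r2, aic, bic); aic/bic are NaN (undefined) when rss = 0."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-d arrays of equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if k < 1:
        raise ValueError("k must be >= 1")
    resid = y - yhat
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant y: R^2 undefined (zero total sum of squares)")
    r2 = 1.0 - rss / tss
    if rss == 0.0:
        return rss, r2, float("nan"), float("nan")
    aic = 2.0 * k + n * np.log(rss / n)
    bic = k * np.log(n) + n * np.log(rss / n)
    return rss, r2, float(aic), float(bic)


def curvature_mismatch(y, yhat) -> float:
    """Sum of squared differences of interior second-order central differences."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-d arrays of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 points for second differences")
    d2 = np.diff(y, 2) - np.diff(yhat, 2)
    return float(d2 @ d2)


def compare_models(fits: list) -> pd.DataFrame:
    """Model-comparison table sorted by AIC, with pairwise AIC/BIC differences.

    All fits must come from the same series (equal n and, when predictions
    are on the same grid, identical data implied by the caller). Columns
    mirror the fitted-parameter/statistic summary: model, alpha, lambda, mu,
    sigma, k, r2, aic, bic, cm plus delta_aic/delta_bic relative to the best
    model. When two fits share k, delta BIC equals delta AIC exactly.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits were computed on different series lengths")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model,
                "alpha": f.theta.get("alpha", np.nan),
                "lambda": f.theta.get("lambda", np.nan),
                "mu": f.theta.get("mu", np.nan),
                "sigma": f.theta.get("sigma", np.nan),
                "k": f.k,
                "r2": f.r2,
                "aic": f.aic,
                "bic": f.bic,
                "cm": f.cm,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["delta_bic"] = table["bic"] - table["bic"].min()
    return table


def pairwise_differences(table: pd.DataFrame, stat: str = "aic") -> pd.DataFrame:
    """Antisymmetric matrix of ``stat`` differences (row minus column)."""
    vals = table[stat].to_numpy()
    diff = vals[:, None] - vals[None, :]
    return pd.DataFrame(diff, index=table["model"], columns=table["model"])
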