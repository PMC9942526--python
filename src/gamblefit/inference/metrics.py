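"""Model-comparison and goodness-of-fit metrics.

WAIC is computed on the deviance scale (lower is better):

    WAIC = -2 * sum_i [ log mean_s exp(ll_is) - var_s(ll_is) ]

where ``ll`` is the pointwise log-likelihood matrix (posterior draws x
observations). Stacking weights maximize the combined log pointwise
predictive density over the weight simplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

__all__ = ["WaicResult", "waic", "stacking_weights", "efron_r2", "calibration"]


@dataclass(frozen=True)
class WaicResult:
    """Deviance-scale WAIC with its effective-parameter penalty."""

    waic: float
    p_waic: float
    lppd: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray
    se: float

    @property
    def elpd(self) -> float:
        return self.lppd - self.p_waic


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a (draws x observations) pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood matrix must be 2-D (draws x points)")
    n_draws, n_points = ll.shape
    if n_draws < 2:
        raise ValueError("WAIC requires at least 2 posterior draws")
    if n_points == 0 or not np.all(np.isfinite(ll)):
        raise ValueError("degenerate pointwise log-likelihood matrix")
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = np.var(ll, axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    se = float(2.0 * np.sqrt(n_points * np.var(elpd_i, ddof=1))) if n_points > 1 else 0.0
    return WaicResult(
        waic=float(-2.0 * np.sum(elpd_i)),
        p_waic=float(np.sum(p_i)),
        lppd=float(np.sum(lppd_i)),
        pointwise_lppd=lppd_i,
        pointwise_p=p_i,
        se=se,
    )


def stacking_weights(
    pointwise_logliks: Sequence[np.ndarray],
    penalized: bool = True,
    tol: float = 1e-12,
) -> np.ndarray:
    """Stacking weights over candidate models from their pointwise matrices.

    Each element of ``pointwise_logliks`` is a (draws x observations)
    matrix on identical data. The returned weights are nonnegative, sum
    to one, and maximize ``sum_i log sum_k w_k p_ik`` where ``log p_ik``
    is model k's WAIC-style pointwise log predictive density of
    observation i: the log posterior-mean density minus, when
    ``penalized`` (the default), the pointwise effective-parameter
    penalty. The penalty is what makes the weights WAIC-based rather
    than a raw in-sample likelihood comparison.
    """
    if len(pointwise_logliks) < 1:
        raise ValueError("at least one model required")
    lpd = []
    n_points = None
    for ll in pointwise_logliks:
        ll = np.asarray(ll, dtype=float)
        if ll.ndim != 2:
            raise ValueError("each pointwise matrix must be 2-D")
        if n_points is None:
            n_points = ll.shape[1]
        elif ll.shape[1] != n_points:
            raise ValueError("models were evaluated on different numbers of observations")
        lpd_k = logsumexp(ll, axis=0) - np.log(ll.shape[0])
        if penalized and ll.shape[0] > 1:
            lpd_k = lpd_k - np.var(ll, axis=0, ddof=1)
        lpd.append(lpd_k)
    lpd = np.column_stack(lpd)  # (points, K)
    K = lpd.shape[1]
    if K == 1:
        return np.array([1.0])

    # Optimize over softmax-parameterized weights (smooth, unconstrained).
    def objective(z: np.ndarray) -> float:
        w = softmax(np.append(z, 0.0))
        return -float(np.sum(logsumexp(lpd + np.log(w + tol), axis=1)))

    best = None
    for z0 in (np.zeros(K - 1), np.full(K - 1, -1.0)):
        res = minimize(objective, z0, method="Nelder-Mead" if K <= 3 else "BFGS",
                       options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12}
                       if K <= 3 else {"maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    w = softmax(np.append(best.x, 0.0))
    w = np.clip(w, 0.0, 1.0)
    return w / w.sum()


def efron_r2(observed, predicted) -> float:
    """Efron's pseudo-R^2: 1 - sum (y-p)^2 / sum (y-ybar)^2."""
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    ybar = y.mean()
    denom = np.sum((y - ybar) ** 2)
    if denom == 0:
        raise ValueError("observed outcomes are constant; pseudo-R^2 undefined")
    return float(1.0 - np.sum((y - p) ** 2) / denom)


def calibration(observed, predicted, bins: int = 10) -> pd.DataFrame:
    """Binned predicted probability vs observed gamble frequency.

    Empty bins are reported with NaN observed/predicted means rather
    than dropped.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = idx == b
        count = int(mask.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": count,
                "mean_predicted": float(p[mask].mean()) if count else np.nan,
                "observed_rate": float(y[mask].mean()) if count else np.nan,
            }
        )
    return pd.DataFrame(rows)
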