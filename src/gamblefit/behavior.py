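"""Model-agnostic behavioral measures, exclusion filters, and group tests.

Six per-subject measures are derived from gamble proportions (or
ambiguous-choice proportions in conditions 7-8), all coded so that
higher scores indicate more aversion:

- ``risk_aversion``: 1 - P(gamble | condition 4)
- ``loss_aversion``: P(gamble | 4) - P(gamble | 1)
- ``amb_sure_gain``: 1 - P(ambiguous | 7)
- ``amb_sure_loss``: 1 - P(ambiguous | 8)
- ``amb_risky_gain``: P(gamble | 1) - P(gamble | 3)
- ``amb_risky_loss``: P(gamble | 1) - P(gamble | 2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_measures",
    "ambiguous_choice_counts",
    "exclusion_filters",
    "group_bias_tests",
    "TTestOutcome",
    "MEASURE_COLUMNS",
]

MEASURE_COLUMNS = (
    "risk_aversion",
    "loss_aversion",
    "amb_sure_gain",
    "amb_sure_loss",
    "amb_risky_gain",
    "amb_risky_loss",
)


def _gamble_props(data: pd.DataFrame) -> pd.DataFrame:
    """Per-subject gamble proportion by condition (NaN if condition absent)."""
    props = (
        data.groupby(["subject", "condition"])["chose_gamble"].mean().unstack("condition")
    )
    return props.reindex(columns=range(1, 9))


def compute_measures(data: pd.DataFrame) -> pd.DataFrame:
    """Six aversion-coded behavioral measures per subject.

    Measures whose conditions are missing for a subject come back NaN
    rather than raising.
    """
    p = _gamble_props(data)
    out = pd.DataFrame(index=p.index)
    out["risk_aversion"] = 1.0 - p[4]
    out["loss_aversion"] = p[4] - p[1]
    out["amb_sure_gain"] = 1.0 - p[7]
    out["amb_sure_loss"] = 1.0 - p[8]
    out["amb_risky_gain"] = p[1] - p[3]
    out["amb_risky_loss"] = p[1] - p[2]
    return out.reset_index()


def ambiguous_choice_counts(data: pd.DataFrame) -> pd.Series:
    """Number of trials on which each subject chose an option containing
    an ambiguous slot.

    The ambiguous option is the gamble in conditions 2, 3, 5, 7, 8 and
    the sure option in condition 6.
    """
    chose_amb = np.where(
        data["condition"].isin([2, 3, 5, 7, 8]),
        data["chose_gamble"],
        np.where(data["condition"] == 6, 1 - data["chose_gamble"], 0),
    )
    return pd.Series(chose_amb, index=data.index).groupby(data["subject"]).sum()


def exclusion_filters(
    data: pd.DataFrame,
    questionnaire: pd.DataFrame | None = None,
    chi2_p: float = 0.001,
) -> pd.DataFrame:
    """Apply the two subject-exclusion rules.

    Flag A marks subjects who never chose any ambiguous option. Flag B
    marks multivariate questionnaire outliers: squared Mahalanobis
    distance from the sample mean/covariance exceeding the chi-square
    quantile at ``1 - chi2_p`` with df = number of items.

    ``questionnaire`` must be numeric with a ``subject`` column; when
    omitted, flag B is False throughout.
    """
    counts = ambiguous_choice_counts(data)
    flags = pd.DataFrame({"subject": counts.index, "n_ambiguous_choices": counts.values})
    flags["flag_no_ambiguous"] = flags["n_ambiguous_choices"] == 0

    flags["mahalanobis_sq"] = np.nan
    flags["flag_outlier"] = False
    if questionnaire is not None:
        q = questionnaire.set_index("subject")
        if q.isna().any().any():
            raise ValueError("questionnaire matrix contains missing values")
        X = q.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(logdet):
            raise ValueError(
                "questionnaire covariance is singular; remove collinear items "
                "(regularization is off by default)"
            )
        prec = np.linalg.inv(cov)
        centered = X - mu
        d2 = np.einsum("ij,jk,ik->i", centered, prec, centered)
        threshold = stats.chi2.ppf(1.0 - chi2_p, df=X.shape[1])
        d2_series = pd.Series(d2, index=q.index)
        flags["mahalanobis_sq"] = flags["subject"].map(d2_series)
        flags["flag_outlier"] = flags["mahalanobis_sq"] > threshold
        flags["flag_outlier"] = flags["flag_outlier"].fillna(False)
    flags["keep"] = ~(flags["flag_no_ambiguous"] | flags["flag_outlier"])
    return flags


@dataclass(frozen=True)
class TTestOutcome:
    name: str
    t: float
    p: float
    df: int
    cohen_d: float


def _one_sample(name: str, x: np.ndarray, popmean: float) -> TTestOutcome:
    if len(x) < 2:
        raise ValueError("group tests require at least 2 subjects")
    if np.std(x, ddof=1) == 0:
        if np.allclose(x, popmean):
            return TTestOutcome(name, 0.0, 1.0, len(x) - 1, 0.0)
        raise ValueError(f"{name}: zero variance away from the null value")
    res = stats.ttest_1samp(x, popmean)
    d = float((np.mean(x) - popmean) / np.std(x, ddof=1))
    return TTestOutcome(name, float(res.statistic), float(res.pvalue), len(x) - 1, d)


def group_bias_tests(data: pd.DataFrame) -> dict[str, TTestOutcome]:
    """Group-level bias tests on gamble proportions.

    - ``risk``: one-sample t of aversion-coded overall gamble proportion
      (1 - proportion) against 0.5; positive t = risk aversion.
    - ``loss``: paired t of condition 4 minus condition 1 proportions
      (loss-averse subjects gamble less when a loss is at stake).
    - ``ambiguity``: paired t of condition 6 minus condition 4
      (ambiguity-averse subjects gamble more when the sure option is
      ambiguous), so positive t = aversion for all three tests.
    """
    overall = data.groupby("subject")["chose_gamble"].mean()
    p = _gamble_props(data)
    results = {
        "risk": _one_sample("risk", (1.0 - overall).to_numpy(), 0.5),
        "loss": _one_sample("loss", (p[4] - p[1]).dropna().to_numpy(), 0.0),
        "ambiguity": _one_sample("ambiguity", (p[6] - p[4]).dropna().to_numpy(), 0.0),
    }
    return results
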