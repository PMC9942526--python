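"""Derived per-subject measures from a fitted model.

Mean learning rates for the mean-tracker family are obtained by
forward-simulating the task from posterior parameter draws and
averaging the per-trial learning rate over trials and draws. The
learning bias for asymmetric models is the positive minus the negative
learning rate. Aversion scores reverse parameters whose raw direction
encodes preference (``rho`` and the gain-side ambiguity weights) by
subtracting each subject's value from the cohort maximum, so that
higher processed scores always mean more aversion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..modelspace import build_params, parse_model_id
from ..simulate import simulate_subject
from ..task import TaskSchedule
from .fitting import FitResult

__all__ = ["mean_learning_rate", "learning_bias", "aversion_scores", "derived_measures"]

#: Parameters reversed (max minus value) so higher = more averse.
REVERSED_PARAMS = ("rho", "alpha_rg", "alpha_sg", "alpha_gain")


def _g_mean(reveals: list[tuple[int, str, float]], theta: float, v0: float, n: int) -> float:
    """Mean over trials of the would-be learning rate G (both valences)."""
    vg = vl = v0
    total = 0.0
    pos = 0
    for t, valence, _ in sorted(reveals, key=lambda r: r[0]):
        g_gain = vg / (vg + theta)
        g_loss = vl / (vl + theta)
        total += 0.5 * (g_gain + g_loss) * (t + 1 - pos)
        if valence == "gain":
            vg = (1.0 - g_gain) * vg
        else:
            vl = (1.0 - g_loss) * vl
        pos = t + 1
    total += 0.5 * (vg / (vg + theta) + vl / (vl + theta)) * (n - pos)
    return total / n


def mean_learning_rate(
    result: FitResult,
    schedules: list[TaskSchedule],
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.Series:
    """Posterior-mean of the trial-averaged mean-tracker learning rate.

    For each posterior draw, data are regenerated from the model on the
    subject's schedule and the per-trial learning rate trajectory is
    averaged over trials; the returned value is the mean across draws.
    """
    spec = parse_model_id(result.model_id)
    if not spec.learning_name.startswith("BMT"):
        raise ValueError("mean learning rate is defined for the mean-tracker family only")
    sched_by_subject = {s.subject: s for s in schedules}
    out = {}
    for s, const in result.draws.items():
        schedule = sched_by_subject[s]
        n_use = min(n_draws, const.shape[0])
        rng = np.random.default_rng([seed, 211, s])
        means = np.empty(n_use)
        for i in range(n_use):
            values = dict(zip(result.param_names, const[i]))
            decision, learning = build_params(spec, values)
            records = simulate_subject(schedule, decision, learning, rng)
            reveals = [
                (t, r.reveal_valence, float(r.outcome))
                for t, r in enumerate(records)
                if r.reveal_valence is not None
            ]
            means[i] = _g_mean(reveals, learning.theta_eps_sq, learning.v0, len(schedule))
        out[s] = float(means.mean())
    return pd.Series(out, name="mean_learning_rate")


def learning_bias(result: FitResult) -> pd.Series:
    """Positive minus negative learning rate, per subject."""
    spec = parse_model_id(result.model_id)
    if "lr_pos" not in spec.free_params:
        raise ValueError("learning bias requires an asymmetric learning model")
    est = result.estimates.set_index("subject")
    return (est["lr_pos"] - est["lr_neg"]).rename("learning_bias")


def aversion_scores(estimates: pd.DataFrame, model_id: str) -> pd.DataFrame:
    """Aversion-coded parameter scores (higher = more averse).

    Parameters in ``REVERSED_PARAMS`` are replaced by (cohort max minus
    value); all others are passed through unchanged. The most-averse
    subject on a reversed parameter therefore scores its cohort range,
    and the least-averse scores 0.
    """
    spec = parse_model_id(model_id)
    out = estimates.copy().set_index("subject")
    for name in spec.free_params:
        if name in REVERSED_PARAMS and name in out.columns:
            out[name] = out[name].max() - out[name]
    return out.reset_index()


def derived_measures(
    result: FitResult,
    schedules: list[TaskSchedule] | None = None,
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bundle of derived measures appropriate to the fitted model."""
    spec = parse_model_id(result.model_id)
    frames = [aversion_scores(result.estimates, result.model_id).set_index("subject")]
    if spec.learning_name.startswith("BMT") and schedules is not None:
        frames.append(mean_learning_rate(result, schedules, n_draws=n_draws, seed=seed))
    if "lr_pos" in spec.free_params:
        frames.append(learning_bias(result))
    return pd.concat(frames, axis=1).reset_index()
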