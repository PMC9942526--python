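"""Vectorized per-subject likelihood for any decision x learning model.

This is the fast path used by the fitting routines. It mirrors, in
array form, the scalar reference implementations in
:mod:`gamblefit.decision` and :mod:`gamblefit.learning`; the test suite
asserts exact agreement between the two routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..decision import SOFTMAX_CLIP
from ..modelspace import ModelSpec
from ..task import LOSS_CONTEXT_CONDITIONS

__all__ = ["SubjectData", "subject_data_from_frame", "pointwise_loglik", "trajectory_arrays"]


@dataclass
class SubjectData:
    """Arrays for one subject's trials, precomputed for likelihood evaluation."""

    subject: int
    n: int
    cond: np.ndarray  # int, 1-8
    y: np.ndarray  # chose_gamble in {0, 1}
    gain_mag: np.ndarray  # unambiguous gain magnitude in the gamble (0 where absent)
    loss_abs: np.ndarray  # |unambiguous loss| in the gamble (0 where absent)
    sure_mag: np.ndarray  # sure-option magnitude (0 for conds 1-3 and 6)
    reveals: list  # (position, valence, outcome)
    baseline_gain: float
    baseline_loss: float
    masks: dict  # condition -> bool array
    loss_context: np.ndarray  # bool array


def subject_data_from_frame(frame: pd.DataFrame) -> SubjectData:
    """Build :class:`SubjectData` from one subject's choice-data rows."""
    frame = frame.sort_values("trial").reset_index(drop=True)
    subject = int(frame["subject"].iloc[0])
    cond = frame["condition"].to_numpy(dtype=int)
    y = frame["chose_gamble"].to_numpy(dtype=float)
    n = len(frame)

    slot1 = frame["gamble_slot1_value"].to_numpy(dtype=float)
    slot2 = frame["gamble_slot2_value"].to_numpy(dtype=float)
    sure = frame["sure_value"].to_numpy(dtype=float)

    gain_mag = np.where(np.isin(cond, (1, 2, 4, 6)), slot1, 0.0)
    loss_abs = np.where(np.isin(cond, (1, 3)), np.abs(slot2), 0.0)
    sure_mag = np.where(np.isin(cond, (4, 5, 7, 8)), sure, 0.0)
    if np.isnan(gain_mag).any() or np.isnan(loss_abs).any() or np.isnan(sure_mag).any():
        raise ValueError("unambiguous magnitude missing from choice data")

    reveals = []
    rv = frame["reveal_valence"]
    outcomes = frame["outcome"].to_numpy(dtype=float)
    for t in range(n):
        valence = rv.iloc[t]
        if isinstance(valence, str) and valence in ("gain", "loss"):
            reveals.append((t, valence, outcomes[t]))

    gains = list(slot1[np.isin(cond, (1, 2, 4, 6))]) + list(sure[np.isin(cond, (4, 5, 7))])
    losses = list(slot2[np.isin(cond, (1, 3))]) + list(sure[cond == 8])
    if not gains or not losses:
        raise ValueError("subject data lacks unambiguous slots of a needed valence")

    masks = {c: cond == c for c in range(1, 9)}
    loss_context = np.isin(cond, sorted(LOSS_CONTEXT_CONDITIONS))
    return SubjectData(
        subject=subject,
        n=n,
        cond=cond,
        y=y,
        gain_mag=gain_mag,
        loss_abs=loss_abs,
        sure_mag=np.abs(sure_mag) * np.where(cond == 8, -1.0, 1.0),
        reveals=reveals,
        baseline_gain=float(np.mean(gains)),
        baseline_loss=float(np.mean(losses)),
        masks=masks,
        loss_context=loss_context,
    )


def trajectory_arrays(
    data: SubjectData, spec: ModelSpec, values: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-decision implied values (V_gain, V_loss) and per-trial G.

    G is the mean tracker's would-be learning rate given the current
    variance (defined on every trial, whether or not a reveal occurs);
    it is NaN for non-BMT families.
    """
    n = data.n
    name = spec.learning_name
    G = np.full(n, np.nan)
    if name == "none":
        return (
            np.full(n, data.baseline_gain),
            np.full(n, data.baseline_loss),
            G,
        )

    if name in ("RW1", "BMT1", "RW4"):
        v0g, v0l = 5.0, -5.0
    elif "V0_gain" in spec.learning_param_names:
        v0g, v0l = values["V0_gain"], values["V0_loss"]
    else:
        v0g, v0l = values["V0"], -values["V0"]

    Vg = np.empty(n)
    Vl = np.empty(n)
    if name.startswith("BMT"):
        theta = values["theta"]
        var0 = values.get("v0", 100.0)
        mg, ml = v0g, v0l
        vg, vl = var0, var0
        pos = 0
        for t, valence, outcome in data.reveals:
            Vg[pos : t + 1] = mg
            Vl[pos : t + 1] = ml
            if valence == "gain":
                g = vg / (vg + theta)
                mg = mg + g * (outcome - mg)
                vg = (1.0 - g) * vg
            else:
                g = vl / (vl + theta)
                ml = ml + g * (outcome - ml)
                vl = (1.0 - g) * vl
            pos = t + 1
        Vg[pos:] = mg
        Vl[pos:] = ml
        # per-trial would-be G (average of the two valences' rates)
        vg, vl = var0, var0
        g_gain = np.empty(n)
        g_loss = np.empty(n)
        pos = 0
        for t, valence, outcome in data.reveals:
            g_gain[pos : t + 1] = vg / (vg + theta)
            g_loss[pos : t + 1] = vl / (vl + theta)
            if valence == "gain":
                vg = (1.0 - vg / (vg + theta)) * vg
            else:
                vl = (1.0 - vl / (vl + theta)) * vl
            pos = t + 1
        g_gain[pos:] = vg / (vg + theta)
        g_loss[pos:] = vl / (vl + theta)
        G = 0.5 * (g_gain + g_loss)
        return Vg, Vl, G

    # Rescorla-Wagner families
    asym = name in ("RW4", "RW5", "RW6")
    mg, ml = v0g, v0l
    pos = 0
    for t, valence, outcome in data.reveals:
        Vg[pos : t + 1] = mg
        Vl[pos : t + 1] = ml
        if valence == "gain":
            delta = outcome - mg
        else:
            delta = outcome - ml
        if asym:
            rate = values["lr_pos"] if delta > 0 else values["lr_neg"]
        else:
            rate = values["lr"]
        if valence == "gain":
            mg = mg + rate * delta
        else:
            ml = ml + rate * delta
        pos = t + 1
    Vg[pos:] = mg
    Vl[pos:] = ml
    return Vg, Vl, G


def _spow(x: np.ndarray, rho: float) -> np.ndarray:
    return np.sign(x) * np.abs(x) ** rho


def utilities(data: SubjectData, spec: ModelSpec, values: dict) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (u_gamble, u_sure) arrays."""
    rho = values["rho"]
    lam = values["lam"]
    if rho <= 0 or lam <= 0:
        raise ValueError("rho and lam must be strictly positive")

    Vg, Vl, _ = trajectory_arrays(data, spec, values)

    d = spec.decision_variant
    ones = np.ones(data.n)
    if d == 1:
        a_rg = a_sg = a_rl = a_sl = ones
    elif d == 2:
        a_rg = a_sg = a_rl = a_sl = values["alpha"] * ones
    elif d == 3:
        a_rg = a_sg = values["alpha_gain"] * ones
        a_rl = a_sl = values["alpha_loss"] * ones
    elif d == 4:
        ctx = np.where(data.loss_context, values["alpha_loss"], values["alpha_gain"])
        a_rg = a_sg = a_rl = a_sl = ctx
    else:
        a_rg = values["alpha_rg"] * ones
        a_sg = values["alpha_sg"] * ones
        a_rl = values["alpha_rl"] * ones
        a_sl = values["alpha_sl"] * ones

    g = data.gain_mag**rho  # 0**rho = 0 where absent
    l = -lam * data.loss_abs**rho
    vg_r = _spow(Vg, rho)
    vl_r = _spow(Vl, rho)
    sure_pow = _spow(data.sure_mag, rho)

    m = data.masks
    u_g = np.zeros(data.n)
    u_s = np.zeros(data.n)

    u_g[m[1]] = 0.5 * g[m[1]] + 0.5 * l[m[1]]
    u_g[m[2]] = 0.5 * g[m[2]] + 0.5 * lam * (a_rl * vl_r)[m[2]]
    u_g[m[3]] = 0.5 * (a_rg * vg_r)[m[3]] + 0.5 * l[m[3]]
    u_g[m[4]] = 0.5 * g[m[4]]
    u_g[m[5]] = 0.5 * (a_rg * vg_r)[m[5]]
    u_g[m[6]] = 0.5 * g[m[6]]
    u_g[m[7]] = (a_sg * vg_r)[m[7]]
    u_g[m[8]] = lam * (a_sl * vl_r)[m[8]]

    for c in (4, 5, 7):
        u_s[m[c]] = sure_pow[m[c]]
    u_s[m[6]] = (a_sg * vg_r)[m[6]]
    u_s[m[8]] = lam * sure_pow[m[8]]  # sure_mag is negative for condition 8

    return u_g, u_s


def pointwise_loglik(data: SubjectData, spec: ModelSpec, values: dict) -> np.ndarray:
    """Per-trial Bernoulli log-likelihood of the observed choices."""
    u_g, u_s = utilities(data, spec, values)
    z = np.clip(values["gamma"] * (u_g - u_s), -SOFTMAX_CLIP, SOFTMAX_CLIP)
    # log sigmoid computed stably for both outcomes
    ll = np.where(data.y == 1.0, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
    return ll


def choice_probs(data: SubjectData, spec: ModelSpec, values: dict) -> np.ndarray:
    u_g, u_s = utilities(data, spec, values)
    z = np.clip(values["gamma"] * (u_g - u_s), -SOFTMAX_CLIP, SOFTMAX_CLIP)
    return 1.0 / (1.0 + np.exp(-z))
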