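"""Value-learning rules supplying implied values of ambiguous options.

Ten variants are supported: a no-learning baseline (implied value = mean
of unambiguous magnitudes of the same valence), Rescorla-Wagner with a
single learning rate, Rescorla-Wagner with asymmetric rates for positive
and negative prediction errors, and a Bayesian mean tracker whose
effective learning rate shrinks as its variance estimate shrinks. Each
learning family comes in three starting-value schemes: fixed (+5/-5),
a single estimated magnitude shared between valences (mirrored in sign),
and separately estimated gain and loss starts.

Implied values are tracked per valence and updated only when an
ambiguous outcome of that valence is actually received.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task import TaskSchedule

__all__ = [
    "LearningParams",
    "LearningState",
    "ImpliedValues",
    "LEARNING_VARIANTS",
    "implied_baseline",
    "rw_update",
    "rw_asym_update",
    "bmt_update",
    "run_learning",
    "trajectory_from_reveals",
]

#: variant id -> (name, family, start scheme)
LEARNING_VARIANTS: dict[int, tuple[str, str, str]] = {
    1: ("none", "none", "none"),
    2: ("RW1", "rw", "fixed"),
    3: ("RW2", "rw", "estimated_shared"),
    4: ("RW3", "rw", "estimated_separate"),
    5: ("RW4", "rw_asym", "fixed"),
    6: ("RW5", "rw_asym", "estimated_shared"),
    7: ("RW6", "rw_asym", "estimated_separate"),
    8: ("BMT1", "bmt", "fixed"),
    9: ("BMT2", "bmt", "estimated_shared"),
    10: ("BMT3", "bmt", "estimated_separate"),
}

_NAME_TO_VARIANT = {name: vid for vid, (name, _, _) in LEARNING_VARIANTS.items()}

_FIXED_START_GAIN = 5.0
_FIXED_START_LOSS = -5.0

#: Default Bayesian mean tracker prior variance (points^2) when not estimated.
DEFAULT_BMT_V0 = 100.0


@dataclass(frozen=True)
class ImpliedValues:
    """Implied values of the four ambiguous slot types (points).

    The learning rules track one value per valence, so the risky and
    sure entries of a valence coincide for learned values; they are kept
    as four fields because the decision model weights them differently.
    """

    V_ARG: float
    V_ASG: float
    V_ARL: float
    V_ASL: float

    @classmethod
    def from_valence(cls, v_gain: float, v_loss: float) -> "ImpliedValues":
        return cls(V_ARG=v_gain, V_ASG=v_gain, V_ARL=v_loss, V_ASL=v_loss)


@dataclass(frozen=True)
class LearningParams:
    """Parameters of one learning variant (Table of ten variants).

    Only the fields relevant to ``family`` are consulted:

    - ``rw``: ``alpha``
    - ``rw_asym``: ``alpha_pos``, ``alpha_neg``
    - ``bmt``: ``theta_eps_sq`` (error variance) and ``v0`` (prior variance)
    """

    family: str  # "none" | "rw" | "rw_asym" | "bmt"
    start_scheme: str = "fixed"
    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None
    theta_eps_sq: float | None = None
    v0: float = DEFAULT_BMT_V0
    V0_gain: float = _FIXED_START_GAIN
    V0_loss: float = _FIXED_START_LOSS

    def __post_init__(self) -> None:
        if self.family not in ("none", "rw", "rw_asym", "bmt"):
            raise ValueError(f"unknown learning family {self.family!r}")
        if self.family == "none":
            return
        if self.start_scheme not in ("fixed", "estimated_shared", "estimated_separate"):
            raise ValueError(f"unknown start scheme {self.start_scheme!r}")
        if self.start_scheme == "fixed":
            if self.V0_gain != _FIXED_START_GAIN or self.V0_loss != _FIXED_START_LOSS:
                raise ValueError("fixed start scheme forces V0_gain=5, V0_loss=-5")
        elif self.start_scheme == "estimated_shared":
            if self.V0_loss != -self.V0_gain:
                raise ValueError("shared start scheme forces V0_loss = -V0_gain")
        if self.family == "rw":
            if self.alpha is None or not (0.0 <= self.alpha <= 1.0):
                raise ValueError("rw requires a learning rate alpha in [0, 1]")
        elif self.family == "rw_asym":
            for name, rate in (("alpha_pos", self.alpha_pos), ("alpha_neg", self.alpha_neg)):
                if rate is None or not (0.0 <= rate <= 1.0):
                    raise ValueError(f"rw_asym requires {name} in [0, 1]")
        elif self.family == "bmt":
            if self.theta_eps_sq is None or self.theta_eps_sq <= 0:
                raise ValueError("bmt requires error variance theta_eps_sq > 0")
            if self.v0 <= 0:
                raise ValueError("bmt requires prior variance v0 > 0")

    @property
    def variant_id(self) -> int:
        if self.family == "none":
            return 1
        offset = {"fixed": 0, "estimated_shared": 1, "estimated_separate": 2}[self.start_scheme]
        base = {"rw": 2, "rw_asym": 5, "bmt": 8}[self.family]
        return base + offset

    @property
    def variant_name(self) -> str:
        return LEARNING_VARIANTS[self.variant_id][0]

    @classmethod
    def from_variant(cls, variant: int | str, **kwargs) -> "LearningParams":
        """Build parameters for a Table-3 variant id (1-10) or name ("RW4")."""
        vid = _NAME_TO_VARIANT[variant] if isinstance(variant, str) else int(variant)
        if vid not in LEARNING_VARIANTS:
            raise ValueError(f"unknown learning variant {variant!r}")
        _, family, scheme = LEARNING_VARIANTS[vid]
        if family == "none":
            return cls(family="none")
        if scheme == "fixed":
            kwargs.setdefault("V0_gain", _FIXED_START_GAIN)
            kwargs.setdefault("V0_loss", _FIXED_START_LOSS)
        elif scheme == "estimated_shared":
            if "V0_gain" in kwargs:
                kwargs["V0_loss"] = -kwargs["V0_gain"]
        return cls(family=family, start_scheme=scheme, **kwargs)


@dataclass(frozen=True)
class LearningState:
    """Per-valence learning state, immutable; updates return new states."""

    V_gain: float
    V_loss: float
    v_gain: float = DEFAULT_BMT_V0
    v_loss: float = DEFAULT_BMT_V0
    G_last: float | None = None

    def implied(self) -> ImpliedValues:
        return ImpliedValues.from_valence(self.V_gain, self.V_loss)

    @classmethod
    def initial(cls, params: LearningParams) -> "LearningState":
        return cls(
            V_gain=params.V0_gain,
            V_loss=params.V0_loss,
            v_gain=params.v0,
            v_loss=params.v0,
        )


def _valence_of(outcome: float, valence: str | None) -> str:
    if valence is not None:
        if valence not in ("gain", "loss"):
            raise ValueError(f"invalid valence {valence!r}")
        return valence
    return "gain" if outcome >= 0 else "loss"


def rw_update(
    state: LearningState,
    outcome: float,
    params: LearningParams,
    valence: str | None = None,
) -> LearningState:
    """Rescorla-Wagner: V <- V + alpha * (outcome - V), one valence only."""
    if params.alpha is None or not (0.0 <= params.alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    val = _valence_of(outcome, valence)
    if val == "gain":
        delta = outcome - state.V_gain
        return replace(state, V_gain=state.V_gain + params.alpha * delta)
    delta = outcome - state.V_loss
    return replace(state, V_loss=state.V_loss + params.alpha * delta)


def rw_asym_update(
    state: LearningState,
    outcome: float,
    params: LearningParams,
    valence: str | None = None,
) -> LearningState:
    """Asymmetric Rescorla-Wagner: rate alpha_pos for positive prediction
    errors, alpha_neg for negative ones; a zero error leaves V unchanged."""
    for name, rate in (("alpha_pos", params.alpha_pos), ("alpha_neg", params.alpha_neg)):
        if rate is None or not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    val = _valence_of(outcome, valence)
    current = state.V_gain if val == "gain" else state.V_loss
    delta = outcome - current
    if delta > 0:
        new = current + params.alpha_pos * delta
    elif delta < 0:
        new = current + params.alpha_neg * delta
    else:
        new = current
    if val == "gain":
        return replace(state, V_gain=new)
    return replace(state, V_loss=new)


def bmt_update(
    state: LearningState,
    outcome: float,
    params: LearningParams,
    valence: str | None = None,
) -> LearningState:
    """Bayesian mean tracker: Kalman-style mean/variance update.

    G = v / (v + theta_eps_sq) is computed from the prior variance, the
    mean moves by G times the prediction error, and the variance shrinks
    by (1 - G). Gain and loss valences carry independent state.
    """
    if params.theta_eps_sq is None or params.theta_eps_sq <= 0:
        raise ValueError("theta_eps_sq must be positive")
    val = _valence_of(outcome, valence)
    if val == "gain":
        v = state.v_gain
        m = state.V_gain
    else:
        v = state.v_loss
        m = state.V_loss
    if v <= 0:
        raise ValueError("variance must be positive")
    G = v / (v + params.theta_eps_sq)
    m_new = m + G * (outcome - m)
    v_new = (1.0 - G) * v
    if val == "gain":
        return replace(state, V_gain=m_new, v_gain=v_new, G_last=G)
    return replace(state, V_loss=m_new, v_loss=v_new, G_last=G)


_UPDATERS = {"rw": rw_update, "rw_asym": rw_asym_update, "bmt": bmt_update}


def implied_baseline(schedule: TaskSchedule) -> ImpliedValues:
    """No-learning implied values: mean unambiguous magnitude per valence."""
    gains: list[int] = []
    losses: list[int] = []
    for trial in schedule:
        for opt in (trial.gamble, trial.sure):
            for slot in opt.slots:
                if slot.ambiguous:
                    continue
                if slot.valence == "gain":
                    gains.append(slot.magnitude)
                elif slot.valence == "loss":
                    losses.append(slot.magnitude)
    if not gains:
        raise ValueError("schedule contains no unambiguous gain slots")
    if not losses:
        raise ValueError("schedule contains no unambiguous loss slots")
    return ImpliedValues.from_valence(float(np.mean(gains)), float(np.mean(losses)))


def trajectory_from_reveals(
    n_trials: int,
    reveals: Sequence[tuple[int, str, float]],
    params: LearningParams,
) -> pd.DataFrame:
    """Run a learning rule over a sequence of reveal events.

    Parameters
    ----------
    n_trials:
        Length of the trial sequence.
    reveals:
        ``(trial_position, valence, outcome)`` triples, 0-based positions
        in increasing order; one per trial at most.
    params:
        Learning parameters; family ``"none"`` is not accepted here (the
        baseline has no trajectory dynamics).

    Returns
    -------
    DataFrame with one row per trial holding the *pre-decision* values
    ``V_gain``/``V_loss`` (and ``v_gain``/``v_loss``/``G`` for the mean
    tracker; ``G`` is the learning rate applied on that trial's reveal,
    NaN on trials without one).
    """
    if params.family == "none":
        raise ValueError("the no-learning baseline has no trajectory; use implied_baseline")
    update = _UPDATERS[params.family]
    state = LearningState.initial(params)
    V_gain = np.empty(n_trials)
    V_loss = np.empty(n_trials)
    v_gain = np.empty(n_trials)
    v_loss = np.empty(n_trials)
    G = np.full(n_trials, np.nan)
    reveal_iter = iter(sorted(reveals, key=lambda r: r[0]))
    next_reveal = next(reveal_iter, None)
    for t in range(n_trials):
        V_gain[t] = state.V_gain
        V_loss[t] = state.V_loss
        v_gain[t] = state.v_gain
        v_loss[t] = state.v_loss
        if next_reveal is not None and next_reveal[0] == t:
            _, valence, outcome = next_reveal
            state = update(state, outcome, params, valence=valence)
            if params.family == "bmt":
                G[t] = state.G_last
            next_reveal = next(reveal_iter, None)
    out = pd.DataFrame(
        {"V_gain": V_gain, "V_loss": V_loss, "v_gain": v_gain, "v_loss": v_loss, "G": G}
    )
    return out


def run_learning(
    schedule: TaskSchedule,
    choices: Iterable,
    params: LearningParams,
) -> pd.DataFrame:
    """Trial-indexed implied-value trajectory for a subject's choice record.

    ``choices`` is an iterable aligned with the schedule whose elements
    expose ``outcome`` and ``reveal_valence`` attributes (or are
    ``(outcome, reveal_valence)`` pairs). Values before each trial's
    decision reflect only reveals on strictly earlier trials.
    """
    records = list(choices)
    if len(records) != len(schedule):
        raise ValueError(
            f"choices ({len(records)}) misaligned with schedule ({len(schedule)})"
        )
    reveals = []
    for t, rec in enumerate(records):
        outcome = getattr(rec, "outcome", None)
        valence = getattr(rec, "reveal_valence", None)
        if outcome is None and isinstance(rec, tuple):
            outcome, valence = rec
        if valence is not None and not (isinstance(valence, float) and np.isnan(valence)):
            reveals.append((t, valence, float(outcome)))
    if params.family == "none":
        base = implied_baseline(schedule)
        n = len(schedule)
        return pd.DataFrame(
            {
                "V_gain": np.full(n, base.V_ARG),
                "V_loss": np.full(n, base.V_ARL),
                "v_gain": np.nan,
                "v_loss": np.nan,
                "G": np.nan,
            }
        )
    return trajectory_from_reveals(len(schedule), reveals, params)
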