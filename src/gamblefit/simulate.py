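"""Synthetic choice-data generator for any decision x learning combination.

Simulates whole cohorts: per-subject parameters are drawn from
configurable population distributions matched to each parameter's
support (log-normal for positive parameters, logit-normal for learning
rates, normal for starting values), choices are sampled trial by trial
from the softmax rule, outcomes are resolved, and learning state is
updated on ambiguous reveals. All randomness flows through one master
seed with per-subject substreams, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import learning as _learning
from .decision import DecisionParams, choice_probability, utility
from .learning import LearningParams, LearningState, implied_baseline
from .modelspace import ModelSpec, build_params, parse_model_id
from .task import TaskSchedule, build_schedule, resolve_outcome, schedules_to_frame

__all__ = [
    "ChoiceRecord",
    "ParamDist",
    "PopulationSpec",
    "default_population",
    "simulate_subject",
    "simulate_cohort",
    "records_to_frame",
    "write_choices",
    "read_choices",
]

_UPDATERS = {
    "rw": _learning.rw_update,
    "rw_asym": _learning.rw_asym_update,
    "bmt": _learning.bmt_update,
}


@dataclass(frozen=True)
class ChoiceRecord:
    """One trial's behavioral record.

    ``chose_gamble`` is 1 when the gamble (conditions 1-6) or the
    ambiguous option (conditions 7-8) was chosen, else 0.
    """

    subject: int
    block: int
    trial: int
    condition: int
    chose_gamble: int
    outcome: int
    running_score: int
    reveal_valence: str | None = None


@dataclass(frozen=True)
class ParamDist:
    """A population distribution for one parameter.

    ``dist`` is one of ``"lognormal"`` (loc/scale on the log scale),
    ``"logitnormal"`` (loc/scale on the logit scale, support (0, 1)) or
    ``"normal"``.
    """

    dist: str
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "logitnormal", "normal"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        z = self.loc + self.scale * rng.standard_normal(n)
        if self.dist == "lognormal":
            return np.exp(z)
        if self.dist == "logitnormal":
            return 1.0 / (1.0 + np.exp(-z))
        return z


def _lognorm(median: float, sigma: float) -> ParamDist:
    return ParamDist("lognormal", float(np.log(median)), sigma)


#: Default population distributions keyed by free-parameter name.
_DEFAULT_DISTS: dict[str, ParamDist] = {
    "rho": _lognorm(0.85, 0.25),
    "lam": _lognorm(1.5, 0.35),
    "gamma": _lognorm(0.3, 0.8),
    "alpha": _lognorm(1.0, 0.5),
    "alpha_gain": _lognorm(1.0, 0.5),
    "alpha_loss": _lognorm(1.0, 0.5),
    "alpha_rg": _lognorm(1.0, 0.5),
    "alpha_sg": _lognorm(1.0, 0.5),
    "alpha_rl": _lognorm(1.0, 0.5),
    "alpha_sl": _lognorm(1.0, 0.5),
    "lr": ParamDist("logitnormal", -0.85, 1.0),
    "lr_pos": ParamDist("logitnormal", -0.85, 1.0),
    "lr_neg": ParamDist("logitnormal", -0.85, 1.0),
    "theta": _lognorm(100.0, 0.7),
    "V0": ParamDist("normal", 5.0, 10.0),
    "V0_gain": ParamDist("normal", 5.0, 15.0),
    "V0_loss": ParamDist("normal", -5.0, 15.0),
}


@dataclass
class PopulationSpec:
    """A generating population: model id, size, seed, and distributions."""

    model_id: str
    n_subjects: int
    seed: int
    dists: dict[str, ParamDist] = field(default_factory=dict)
    latent_mode: str = "constant"

    def __post_init__(self) -> None:
        spec = parse_model_id(self.model_id)
        merged = {}
        for name in spec.free_params:
            merged[name] = self.dists.get(name, _DEFAULT_DISTS[name])
        self.dists = merged
        self.spec = spec


def default_population(model_id: str, n_subjects: int, seed: int) -> PopulationSpec:
    return PopulationSpec(model_id=model_id, n_subjects=n_subjects, seed=seed)


def draw_parameters(pop: PopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one row of free-parameter values per subject."""
    cols = {"subject": np.arange(1, pop.n_subjects + 1)}
    for name, dist in pop.dists.items():
        cols[name] = dist.sample(rng, pop.n_subjects)
    return pd.DataFrame(cols)


def simulate_subject(
    schedule: TaskSchedule,
    decision_params: DecisionParams,
    learning_params: LearningParams,
    seed: int | np.random.Generator,
) -> list[ChoiceRecord]:
    """Simulate one subject's choices over a schedule.

    Per trial: implied values come from the current learning state (or
    the schedule-wide baseline for the no-learning family), utilities
    and the softmax probability are computed, a choice is sampled, the
    outcome is resolved, and the learning state is updated if the paying
    slot was ambiguous. The running score accumulates outcomes and
    resets at each block boundary.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = None
    state = None
    updater = None
    if learning_params.family == "none":
        baseline = implied_baseline(schedule)
    else:
        state = LearningState.initial(learning_params)
        updater = _UPDATERS[learning_params.family]

    records: list[ChoiceRecord] = []
    score = 0
    current_block = None
    for trial in schedule:
        if trial.block != current_block:
            current_block = trial.block
            score = 0
        implied = baseline if baseline is not None else state.implied()
        u = utility(trial, decision_params, implied)
        p = choice_probability(u, decision_params.gamma)
        chose_gamble = bool(rng.random() < p)
        outcome, reveal = resolve_outcome(trial, chose_gamble, rng)
        score += outcome
        if reveal is not None and state is not None:
            state = updater(state, outcome, learning_params, valence=reveal)
        records.append(
            ChoiceRecord(
                subject=schedule.subject,
                block=trial.block,
                trial=trial.trial_index,
                condition=trial.condition,
                chose_gamble=int(chose_gamble),
                outcome=outcome,
                running_score=score,
                reveal_valence=reveal,
            )
        )
    return records


def records_to_frame(records: Iterable[ChoiceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def simulate_cohort(
    pop: PopulationSpec,
    schedules: list[TaskSchedule] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (choice data, true-parameter table).

    The choice table merges schedule columns (magnitudes, ambiguity
    flags, latent values) with behavioral columns so it can be fed
    directly to the inference module. The truth table is keyed by
    subject id for recovery scoring.
    """
    if schedules is None:
        schedules = build_schedule(
            pop.seed, subjects=pop.n_subjects, latent_mode=pop.latent_mode
        )
    if len(schedules) != pop.n_subjects:
        raise ValueError("schedule count does not match population size")
    rng = np.random.default_rng([pop.seed, 17])
    truth = draw_parameters(pop, rng)
    sched_frame = schedules_to_frame(schedules)
    all_records: list[ChoiceRecord] = []
    for schedule, (_, row) in zip(schedules, truth.iterrows()):
        values: Mapping[str, float] = row.drop("subject").to_dict()
        decision, learn = build_params(pop.spec, values)
        sub_rng = np.random.default_rng([pop.seed, 29, schedule.subject])
        all_records.extend(simulate_subject(schedule, decision, learn, sub_rng))
    behav = records_to_frame(all_records)
    data = sched_frame.merge(behav, on=["subject", "block", "trial", "condition"])
    if len(data) != len(sched_frame):
        raise AssertionError("schedule/choice merge lost rows")
    truth.insert(1, "model_id", pop.model_id)
    return data, truth


def write_choices(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", index=False)


def read_choices(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
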