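"""Eight-condition risky/ambiguous gambling task: trial structure and schedules.

The task presents, on every trial, a choice between two options. In
conditions 1-6 one option is a 50/50 "risky" gamble over two outcome
slots and the other is a sure outcome; in conditions 7-8 both options
are sure and the choice is between an ambiguous and an unambiguous
outcome. Gains lie on a 10..90 point grid, losses on -90..-10, and
ambiguous slots hide their magnitude behind a latent true value that is
only revealed (through the running score) when that slot pays out.

Condition layout (gamble option vs sure option):

1. unambiguous gain / unambiguous loss   vs sure 0
2. unambiguous gain / ambiguous loss     vs sure 0
3. ambiguous gain / unambiguous loss     vs sure 0
4. unambiguous gain / zero               vs sure gain
5. ambiguous gain / zero                 vs sure gain
6. unambiguous gain / zero               vs ambiguous sure gain
7. ambiguous sure gain                   vs sure gain
8. ambiguous sure loss                   vs sure loss

The "gamble" label refers to the risky option in conditions 1-6 and to
the ambiguous option in conditions 7-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Slot",
    "OptionSpec",
    "TrialSpec",
    "TaskSchedule",
    "build_schedule",
    "resolve_outcome",
    "schedules_to_frame",
    "frame_to_schedules",
    "write_schedules",
    "read_schedules",
    "GAIN_GRID",
    "LOSS_GRID",
    "N_TRIALS",
    "N_BLOCKS",
    "CONDITIONS",
    "DEFAULT_CONDITION_COUNTS",
    "LOSS_CONTEXT_CONDITIONS",
    "AMBIGUOUS_CONDITIONS",
]

#: Magnitude grids (points). Gains and losses move in steps of 5.
GAIN_GRID: tuple[int, ...] = tuple(range(10, 95, 5))
LOSS_GRID: tuple[int, ...] = tuple(range(-90, -5, 5))

N_TRIALS = 138
N_BLOCKS = 7
CONDITIONS = (1, 2, 3, 4, 5, 6, 7, 8)

#: Near-balanced default allocation of the 138 trials over conditions 1-8.
DEFAULT_CONDITION_COUNTS: dict[int, int] = {
    1: 18, 2: 18, 3: 18, 4: 17, 5: 17, 6: 17, 7: 17, 8: 16,
}

#: Conditions in which at least one loss outcome is present.
LOSS_CONTEXT_CONDITIONS = frozenset({1, 2, 3, 8})
#: Conditions containing an ambiguous slot somewhere.
AMBIGUOUS_CONDITIONS = frozenset({2, 3, 5, 6, 7, 8})

_BLOCK_SIZES = (20, 20, 20, 20, 20, 19, 19)

#: Sure-option fractions of the gamble gain used in condition 4.
_SURE_FRACTIONS = (0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass(frozen=True)
class Slot:
    """A single outcome slot inside an option.

    ``magnitude`` is ``None`` exactly when the slot is ambiguous: the
    true value is then carried by the trial's latent fields.
    """

    magnitude: int | None
    valence: str  # "gain" | "loss" | "zero"
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.valence not in ("gain", "loss", "zero"):
            raise ValueError(f"invalid valence {self.valence!r}")
        if self.ambiguous:
            if self.magnitude is not None:
                raise ValueError("ambiguous slot must not carry a visible magnitude")
            if self.valence == "zero":
                raise ValueError("zero slots cannot be ambiguous")
        else:
            if self.magnitude is None:
                raise ValueError("unambiguous slot requires a magnitude")
            if self.valence == "gain" and not (10 <= self.magnitude <= 90):
                raise ValueError(f"gain magnitude {self.magnitude} outside [10, 90]")
            if self.valence == "loss" and not (-90 <= self.magnitude <= -10):
                raise ValueError(f"loss magnitude {self.magnitude} outside [-90, -10]")
            if self.valence == "zero" and self.magnitude != 0:
                raise ValueError("zero slot must have magnitude 0")


@dataclass(frozen=True)
class OptionSpec:
    """One choosable option: either one sure slot or two 50/50 slots."""

    slots: tuple[Slot, ...]

    def __post_init__(self) -> None:
        if len(self.slots) not in (1, 2):
            raise ValueError("an option has one or two slots")

    @property
    def probabilities(self) -> tuple[float, ...]:
        return (1.0,) if len(self.slots) == 1 else (0.5, 0.5)

    @property
    def risky(self) -> bool:
        return len(self.slots) == 2

    @property
    def has_ambiguous(self) -> bool:
        return any(s.ambiguous for s in self.slots)


@dataclass(frozen=True)
class TrialSpec:
    """One trial: condition, both options, and latent ambiguous values."""

    condition: int
    gamble: OptionSpec
    sure: OptionSpec
    block: int = 0
    trial_index: int = 0
    latent_gain: int | None = None
    latent_loss: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition {self.condition} outside 1-8")
        for opt, label in ((self.gamble, "gamble"), (self.sure, "sure")):
            for slot in opt.slots:
                if slot.ambiguous:
                    latent = (
                        self.latent_gain if slot.valence == "gain" else self.latent_loss
                    )
                    if latent is None:
                        raise ValueError(
                            f"{label} option has an ambiguous {slot.valence} slot "
                            "but no latent value"
                        )

    @property
    def loss_context(self) -> bool:
        return self.condition in LOSS_CONTEXT_CONDITIONS

    def latent_for(self, slot: Slot) -> int:
        value = self.latent_gain if slot.valence == "gain" else self.latent_loss
        assert value is not None
        return value


@dataclass
class TaskSchedule:
    """An ordered sequence of trials for one subject."""

    subject: int
    trials: list[TrialSpec]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def validate(self) -> None:
        """Raise if the schedule violates the task design invariants."""
        if len(self.trials) != N_TRIALS:
            raise ValueError(f"schedule has {len(self.trials)} trials, expected {N_TRIALS}")
        blocks = {t.block for t in self.trials}
        if blocks != set(range(1, N_BLOCKS + 1)):
            raise ValueError(f"expected blocks 1-{N_BLOCKS}, found {sorted(blocks)}")
        conditions = {t.condition for t in self.trials}
        if conditions != set(CONDITIONS):
            raise ValueError(f"conditions missing: {set(CONDITIONS) - conditions}")
        for i, trial in enumerate(self.trials, start=1):
            if trial.trial_index != i:
                raise ValueError(f"trial_index mismatch at position {i}")


def _round5(x: float) -> int:
    return int(5 * round(x / 5))


def _stratified(grid: Sequence[int], n: int, rng: np.random.Generator) -> list[int]:
    """Sample n magnitudes spanning the grid: shuffled full passes, truncated."""
    reps = math.ceil(n / len(grid))
    out: list[int] = []
    for _ in range(reps):
        out.extend(int(v) for v in rng.permutation(np.asarray(grid)))
    return out[:n]


def _condition_trials(
    condition: int,
    count: int,
    rng: np.random.Generator,
    latent_gain: int,
    latent_loss: int,
) -> list[TrialSpec]:
    zero = Slot(0, "zero")
    amb_gain = Slot(None, "gain", ambiguous=True)
    amb_loss = Slot(None, "loss", ambiguous=True)
    trials: list[TrialSpec] = []

    def trial(gamble: OptionSpec, sure: OptionSpec) -> TrialSpec:
        lg = latent_gain if (gamble.has_ambiguous or sure.has_ambiguous) else None
        ll = latent_loss
        needs_gain = any(
            s.ambiguous and s.valence == "gain" for s in gamble.slots + sure.slots
        )
        needs_loss = any(
            s.ambiguous and s.valence == "loss" for s in gamble.slots + sure.slots
        )
        return TrialSpec(
            condition=condition,
            gamble=gamble,
            sure=sure,
            latent_gain=lg if needs_gain else None,
            latent_loss=ll if needs_loss else None,
        )

    if condition == 1:
        gains = _stratified(GAIN_GRID, count, rng)
        losses = _stratified(LOSS_GRID, count, rng)
        for g, l in zip(gains, losses):
            trials.append(
                trial(OptionSpec((Slot(g, "gain"), Slot(l, "loss"))), OptionSpec((zero,)))
            )
    elif condition == 2:
        gains = _stratified(GAIN_GRID, count, rng)
        for g in gains:
            trials.append(
                trial(OptionSpec((Slot(g, "gain"), amb_loss)), OptionSpec((zero,)))
            )
    elif condition == 3:
        losses = _stratified(LOSS_GRID, count, rng)
        for l in losses:
            trials.append(
                trial(OptionSpec((amb_gain, Slot(l, "loss"))), OptionSpec((zero,)))
            )
    elif condition == 4:
        gains = _stratified(GAIN_GRID, count, rng)
        fracs = _stratified(
            [int(f * 100) for f in _SURE_FRACTIONS], count, rng
        )
        for g, f in zip(gains, fracs):
            sure_val = min(90, max(10, _round5(g * f / 100)))
            trials.append(
                trial(
                    OptionSpec((Slot(g, "gain"), zero)),
                    OptionSpec((Slot(sure_val, "gain"),)),
                )
            )
    elif condition == 5:
        sures = _stratified(GAIN_GRID[:9], count, rng)  # 10..50
        for s in sures:
            trials.append(
                trial(OptionSpec((amb_gain, zero)), OptionSpec((Slot(s, "gain"),)))
            )
    elif condition == 6:
        gains = _stratified(GAIN_GRID, count, rng)
        for g in gains:
            trials.append(
                trial(OptionSpec((Slot(g, "gain"), zero)), OptionSpec((amb_gain,)))
            )
    elif condition == 7:
        sures = _stratified(GAIN_GRID, count, rng)
        for s in sures:
            trials.append(trial(OptionSpec((amb_gain,)), OptionSpec((Slot(s, "gain"),))))
    elif condition == 8:
        sures = _stratified(LOSS_GRID, count, rng)
        for s in sures:
            trials.append(trial(OptionSpec((amb_loss,)), OptionSpec((Slot(s, "loss"),))))
    else:  # pragma: no cover
        raise ValueError(condition)
    return trials


def build_schedule(
    seed: int,
    subjects: int = 1,
    condition_counts: dict[int, int] | None = None,
    latent_mode: str = "constant",
) -> list[TaskSchedule]:
    """Generate one reproducible 138-trial schedule per subject.

    Trial values (magnitudes, latent ambiguous values, block membership)
    are shared across subjects; only the within-block trial order differs
    between subjects, each drawn from a per-subject substream of ``seed``.

    Parameters
    ----------
    seed:
        Master seed for all randomness.
    subjects:
        Number of per-subject schedules to produce.
    condition_counts:
        Trials per condition; must sum to 138. Defaults to the
        near-balanced allocation ``DEFAULT_CONDITION_COUNTS``.
    latent_mode:
        ``"constant"`` draws one latent true value per valence, shared by
        every ambiguous slot of that valence; ``"per_trial"`` redraws the
        latent value on every ambiguous trial.
    """
    counts = dict(condition_counts or DEFAULT_CONDITION_COUNTS)
    if set(counts) != set(CONDITIONS):
        raise ValueError("condition_counts must cover conditions 1-8")
    total = sum(counts.values())
    if total != N_TRIALS:
        raise ValueError(f"condition counts sum to {total}, must be {N_TRIALS}")
    if latent_mode not in ("constant", "per_trial"):
        raise ValueError(f"unknown latent_mode {latent_mode!r}")

    master = np.random.default_rng(seed)
    latent_gain = int(master.choice(np.asarray(GAIN_GRID)))
    latent_loss = int(master.choice(np.asarray(LOSS_GRID)))

    pool: list[TrialSpec] = []
    for condition in CONDITIONS:
        pool.extend(
            _condition_trials(condition, counts[condition], master, latent_gain, latent_loss)
        )
    if latent_mode == "per_trial":
        redrawn = []
        for t in pool:
            lg = int(master.choice(np.asarray(GAIN_GRID))) if t.latent_gain is not None else None
            ll = int(master.choice(np.asarray(LOSS_GRID))) if t.latent_loss is not None else None
            redrawn.append(
                TrialSpec(t.condition, t.gamble, t.sure, latent_gain=lg, latent_loss=ll)
            )
        pool = redrawn

    # Fixed block composition shared across subjects.
    order = master.permutation(len(pool))
    blocks: list[list[TrialSpec]] = []
    start = 0
    for size in _BLOCK_SIZES:
        blocks.append([pool[i] for i in order[start : start + size]])
        start += size

    schedules = []
    for subj in range(1, subjects + 1):
        sub_rng = np.random.default_rng([seed, subj])
        trials: list[TrialSpec] = []
        idx = 0
        for block_no, block in enumerate(blocks, start=1):
            for j in sub_rng.permutation(len(block)):
                t = block[j]
                idx += 1
                trials.append(
                    TrialSpec(
                        condition=t.condition,
                        gamble=t.gamble,
                        sure=t.sure,
                        block=block_no,
                        trial_index=idx,
                        latent_gain=t.latent_gain,
                        latent_loss=t.latent_loss,
                    )
                )
        schedule = TaskSchedule(subject=subj, trials=trials, seed=seed)
        schedule.validate()
        schedules.append(schedule)
    return schedules


def resolve_outcome(
    trial: TrialSpec, chose_gamble: bool, rng: np.random.Generator
) -> tuple[int, str | None]:
    """Resolve a choice into a point outcome and an optional reveal.

    For a two-slot option one slot is drawn with probability 0.5; a sure
    option pays its single slot. If the paying slot is ambiguous, its
    latent true value is paid out and the reveal valence is returned so
    learning models know which implied value to update.

    Returns
    -------
    (outcome, reveal)
        ``outcome`` in points; ``reveal`` is ``"gain"``/``"loss"`` when
        the paying slot was ambiguous, otherwise ``None``.
    """
    option = trial.gamble if chose_gamble else trial.sure
    if option.risky:
        slot = option.slots[0] if rng.random() < 0.5 else option.slots[1]
    else:
        slot = option.slots[0]
    if slot.ambiguous:
        return trial.latent_for(slot), slot.valence
    return int(slot.magnitude), None


# ---------------------------------------------------------------------------
# Delimited-text serialization. Ambiguous magnitudes are written as empty
# fields (never 0) alongside explicit flags.

_SCHEDULE_COLUMNS = [
    "subject",
    "block",
    "trial",
    "condition",
    "gamble_slot1_value",
    "gamble_slot2_value",
    "sure_value",
    "gamble_slot1_ambiguous",
    "gamble_slot2_ambiguous",
    "sure_ambiguous",
    "latent_gain",
    "latent_loss",
]


def schedules_to_frame(schedules: Iterable[TaskSchedule]) -> pd.DataFrame:
    rows = []
    for sched in schedules:
        for t in sched.trials:
            g1 = t.gamble.slots[0]
            g2 = t.gamble.slots[1] if t.gamble.risky else None
            s = t.sure.slots[0]
            rows.append(
                {
                    "subject": sched.subject,
                    "block": t.block,
                    "trial": t.trial_index,
                    "condition": t.condition,
                    "gamble_slot1_value": g1.magnitude,
                    "gamble_slot2_value": g2.magnitude if g2 is not None else None,
                    "sure_value": s.magnitude,
                    "gamble_slot1_ambiguous": int(g1.ambiguous),
                    "gamble_slot2_ambiguous": int(g2.ambiguous) if g2 is not None else None,
                    "sure_ambiguous": int(s.ambiguous),
                    "latent_gain": t.latent_gain,
                    "latent_loss": t.latent_loss,
                }
            )
    return pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS)


def _rebuild_trial(row: pd.Series) -> TrialSpec:
    cond = int(row["condition"])

    def slot(value, ambiguous, valence) -> Slot:
        if ambiguous:
            return Slot(None, valence, ambiguous=True)
        return Slot(int(value), valence)

    # Slot 1 of the gamble is the gain-valence slot in conditions 1-7 and
    # the (single) loss slot in condition 8; slot 2 is loss or zero.
    g1_amb = bool(row["gamble_slot1_ambiguous"])
    s_amb = bool(row["sure_ambiguous"])
    if cond in (1, 2, 3):
        g2_val = "loss"
    elif cond in (4, 5, 6):
        g2_val = "zero"
    else:
        g2_val = None
    g1_valence = "loss" if cond == 8 else "gain"
    slots = [slot(row["gamble_slot1_value"], g1_amb, g1_valence)]
    if g2_val is not None:
        slots.append(slot(row["gamble_slot2_value"], bool(row["gamble_slot2_ambiguous"]), g2_val))
    sure_valence = "zero" if cond in (1, 2, 3) else ("loss" if cond == 8 else "gain")
    sure = OptionSpec((slot(row["sure_value"], s_amb, sure_valence),))
    lg = row["latent_gain"]
    ll = row["latent_loss"]
    return TrialSpec(
        condition=cond,
        gamble=OptionSpec(tuple(slots)),
        sure=sure,
        block=int(row["block"]),
        trial_index=int(row["trial"]),
        latent_gain=None if pd.isna(lg) else int(lg),
        latent_loss=None if pd.isna(ll) else int(ll),
    )


def frame_to_schedules(frame: pd.DataFrame) -> list[TaskSchedule]:
    schedules = []
    for subject, group in frame.groupby("subject", sort=True):
        trials = [_rebuild_trial(row) for _, row in group.sort_values("trial").iterrows()]
        schedules.append(TaskSchedule(subject=int(subject), trials=trials))
    return schedules


def write_schedules(schedules: Iterable[TaskSchedule], path) -> None:
    schedules_to_frame(schedules).to_csv(path, sep="\t", index=False)


def read_schedules(path) -> list[TaskSchedule]:
    return frame_to_schedules(pd.read_csv(path, sep="\t"))
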