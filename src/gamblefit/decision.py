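"""Prospect-theory utilities, ambiguity-parameter tying, and softmax choice.

The subjective utility of an option sums probability-weighted slot
terms: an unambiguous gain of magnitude ``x`` contributes ``x**rho``, an
unambiguous loss of magnitude ``x`` contributes ``-lam * |x|**rho``, and
an ambiguous slot contributes its implied value ``V`` weighted by the
slot-specific ambiguity parameter (``alpha * spow(V, rho)`` for gains,
``lam * alpha * spow(V, rho)`` for losses, where ``spow`` is the
sign-preserving power). Losses therefore reduce utility, which is
the only reading under which loss aversion (``lam > 1``) penalizes
gambles containing losses.

Choice follows a logistic (softmax) rule in the utility difference with
inverse temperature ``gamma``; "gamble" denotes the risky option in
conditions 1-6 and the ambiguous option in conditions 7-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .learning import ImpliedValues
from .task import LOSS_CONTEXT_CONDITIONS, TrialSpec

__all__ = [
    "DecisionParams",
    "UtilityPair",
    "DECISION_VARIANT_ALPHAS",
    "apply_variant",
    "utility",
    "choice_probability",
    "spow",
    "SOFTMAX_CLIP",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

#: Exponent clip applied inside the softmax for overflow safety.
SOFTMAX_CLIP = 500.0

#: Free ambiguity-parameter names per decision variant.
DECISION_VARIANT_ALPHAS: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("alpha",),
    3: ("alpha_gain", "alpha_loss"),
    4: ("alpha_gain", "alpha_loss"),
    5: ("alpha_rg", "alpha_sg", "alpha_rl", "alpha_sl"),
}


def spow(x: float, rho: float) -> float:
    """Sign-preserving power: sign(x) * |x|**rho (0 maps to 0)."""
    if x == 0:
        return 0.0
    return math.copysign(abs(x) ** rho, x)


@dataclass(frozen=True)
class UtilityPair:
    u_gamble: float
    u_sure: float

    @property
    def difference(self) -> float:
        return self.u_gamble - self.u_sure


@dataclass(frozen=True)
class DecisionParams:
    """Decision-rule parameters with variant-encoded ambiguity tying.

    ``variant`` 1-5 selects how the four ambiguity slots are tied:

    1. all fixed at 1 (classic three-parameter prospect theory);
    2. one shared parameter;
    3. tied by valence (gain vs loss);
    4. routed by trial context (any loss present -> loss alpha);
    5. all four free.

    For variants 1-3 and 5 the four ``alpha_*`` fields hold the resolved
    slot values. Variant 4 routes per trial, so its slot fields are NaN
    and ``alpha_gain_context``/``alpha_loss_context`` carry the two free
    parameters; use :meth:`ambiguity_weights` to resolve per condition.
    """

    rho: float
    lam: float
    gamma: float
    variant: int = 1
    alpha_rg: float = 1.0
    alpha_sg: float = 1.0
    alpha_rl: float = 1.0
    alpha_sl: float = 1.0
    alpha_gain_context: float | None = None
    alpha_loss_context: float | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be strictly positive")
        if self.lam <= 0:
            raise ValueError("lam must be strictly positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.variant not in DECISION_VARIANT_ALPHAS:
            raise ValueError(f"decision variant {self.variant} outside 1-5")
        if self.variant == 4:
            if self.alpha_gain_context is None or self.alpha_loss_context is None:
                raise ValueError("variant 4 requires both context alphas")
            if self.alpha_gain_context <= 0 or self.alpha_loss_context <= 0:
                raise ValueError("ambiguity parameters must be strictly positive")
        else:
            for a in (self.alpha_rg, self.alpha_sg, self.alpha_rl, self.alpha_sl):
                if not a > 0:
                    raise ValueError("ambiguity parameters must be strictly positive")

    def ambiguity_weights(self, condition: int) -> tuple[float, float, float, float]:
        """Effective (alpha_rg, alpha_sg, alpha_rl, alpha_sl) on a trial."""
        if self.variant == 4:
            a = (
                self.alpha_loss_context
                if condition in LOSS_CONTEXT_CONDITIONS
                else self.alpha_gain_context
            )
            return (a, a, a, a)
        return (self.alpha_rg, self.alpha_sg, self.alpha_rl, self.alpha_sl)


def apply_variant(
    variant: int,
    rho: float,
    lam: float,
    gamma: float,
    free_alphas: Sequence[float] = (),
) -> DecisionParams:
    """Construct :class:`DecisionParams` from a variant's free parameters.

    ``free_alphas`` must contain exactly (0, 1, 2, 2, 4) values for
    variants 1-5 respectively, in the order listed in
    ``DECISION_VARIANT_ALPHAS``.
    """
    names = DECISION_VARIANT_ALPHAS.get(variant)
    if names is None:
        raise ValueError(f"decision variant {variant} outside 1-5")
    if len(free_alphas) != len(names):
        raise ValueError(
            f"variant {variant} expects {len(names)} free ambiguity parameters, "
            f"got {len(free_alphas)}"
        )
    base = dict(rho=rho, lam=lam, gamma=gamma, variant=variant)
    if variant == 1:
        return DecisionParams(**base)
    if variant == 2:
        (a,) = free_alphas
        return DecisionParams(**base, alpha_rg=a, alpha_sg=a, alpha_rl=a, alpha_sl=a)
    if variant == 3:
        a_g, a_l = free_alphas
        return DecisionParams(**base, alpha_rg=a_g, alpha_sg=a_g, alpha_rl=a_l, alpha_sl=a_l)
    if variant == 4:
        a_g, a_l = free_alphas
        return DecisionParams(
            **base,
            alpha_rg=float("nan"),
            alpha_sg=float("nan"),
            alpha_rl=float("nan"),
            alpha_sl=float("nan"),
            alpha_gain_context=a_g,
            alpha_loss_context=a_l,
        )
    a_rg, a_sg, a_rl, a_sl = free_alphas
    return DecisionParams(**base, alpha_rg=a_rg, alpha_sg=a_sg, alpha_rl=a_rl, alpha_sl=a_sl)


def params_to_dict(params: DecisionParams) -> dict:
    """Flat key-value form of a parameter set (JSON/YAML friendly)."""
    out = {"variant": params.variant, "rho": params.rho, "lam": params.lam,
           "gamma": params.gamma}
    if params.variant == 4:
        out["alpha_gain_context"] = params.alpha_gain_context
        out["alpha_loss_context"] = params.alpha_loss_context
    elif params.variant != 1:
        out.update(alpha_rg=params.alpha_rg, alpha_sg=params.alpha_sg,
                   alpha_rl=params.alpha_rl, alpha_sl=params.alpha_sl)
    return out


def params_from_dict(d: dict) -> DecisionParams:
    variant = int(d["variant"])
    core = (d["rho"], d["lam"], d["gamma"])
    if variant == 1:
        return apply_variant(1, *core)
    if variant == 2:
        return apply_variant(2, *core, (d["alpha_rg"],))
    if variant == 3:
        return apply_variant(3, *core, (d["alpha_rg"], d["alpha_rl"]))
    if variant == 4:
        return apply_variant(4, *core, (d["alpha_gain_context"], d["alpha_loss_context"]))
    return apply_variant(
        5, *core, (d["alpha_rg"], d["alpha_sg"], d["alpha_rl"], d["alpha_sl"])
    )


def save_params(params: DecisionParams, path) -> None:
    """Write a parameter set as YAML (or JSON if the path ends in .json)."""
    d = params_to_dict(params)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            import json

            json.dump(d, fh, indent=2)
        else:
            import yaml

            yaml.safe_dump(d, fh)


def load_params(path) -> DecisionParams:
    path = str(path)
    with open(path) as fh:
        if path.endswith(".json"):
            import json

            d = json.load(fh)
        else:
            import yaml

            d = yaml.safe_load(fh)
    return params_from_dict(d)


def _option_utility(
    option, trial: TrialSpec, params: DecisionParams, implied: ImpliedValues | None
) -> float:
    a_rg, a_sg, a_rl, a_sl = params.ambiguity_weights(trial.condition)
    risky = option.risky
    total = 0.0
    for slot, prob in zip(option.slots, option.probabilities):
        if slot.valence == "zero":
            continue
        if slot.ambiguous:
            if implied is None:
                raise ValueError("ambiguous slot requires implied values")
            if slot.valence == "gain":
                V = implied.V_ARG if risky else implied.V_ASG
                alpha = a_rg if risky else a_sg
                term = alpha * spow(V, params.rho)
            else:
                V = implied.V_ARL if risky else implied.V_ASL
                alpha = a_rl if risky else a_sl
                term = params.lam * alpha * spow(V, params.rho)
        else:
            mag = slot.magnitude
            if slot.valence == "gain":
                term = mag ** params.rho
            else:
                term = -params.lam * abs(mag) ** params.rho
        total += prob * term
    return total


def utility(
    trial: TrialSpec, params: DecisionParams, implied: ImpliedValues | None = None
) -> UtilityPair:
    """Subjective utilities of both options on one trial.

    ``implied`` must be given whenever the trial contains an ambiguous
    slot; the learning module (or the no-learning baseline) supplies it.
    """
    return UtilityPair(
        u_gamble=_option_utility(trial.gamble, trial, params, implied),
        u_sure=_option_utility(trial.sure, trial, params, implied),
    )


def choice_probability(u: UtilityPair | tuple[float, float], gamma: float) -> float:
    """Softmax probability of choosing the gamble/ambiguous option.

    ``P = 1 / (1 + exp(-gamma * (u_gamble - u_sure)))``, with the
    exponent clipped to +-SOFTMAX_CLIP for overflow safety.
    """
    if isinstance(u, UtilityPair):
        diff = u.difference
    else:
        diff = u[0] - u[1]
    if not (np.isfinite(diff) and np.isfinite(gamma)):
        raise ValueError("utilities and gamma must be finite")
    z = float(np.clip(gamma * diff, -SOFTMAX_CLIP, SOFTMAX_CLIP))
    return 1.0 / (1.0 + math.exp(-z))
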