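"""Registry of candidate models: 5 decision variants x 10 learning variants.

Model ids are strings like ``"D5-BMT3"`` (decision variant 5 with the
separately-started Bayesian mean tracker) or ``"D1-none"`` (classic
prospect theory, no learning). Every model shares the core decision
parameters ``rho``, ``lam``, ``gamma``; the decision variant adds its
free ambiguity parameters and the learning variant its learning
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decision import DECISION_VARIANT_ALPHAS
from .learning import LEARNING_VARIANTS

__all__ = ["ModelSpec", "enumerate_models", "parse_model_id", "model_free_params"]

#: Free learning-parameter names per learning-variant name.
_LEARNING_FREE: dict[str, tuple[str, ...]] = {
    "none": (),
    "RW1": ("lr",),
    "RW2": ("lr", "V0"),
    "RW3": ("lr", "V0_gain", "V0_loss"),
    "RW4": ("lr_pos", "lr_neg"),
    "RW5": ("lr_pos", "lr_neg", "V0"),
    "RW6": ("lr_pos", "lr_neg", "V0_gain", "V0_loss"),
    "BMT1": ("theta",),
    "BMT2": ("theta", "V0"),
    "BMT3": ("theta", "V0_gain", "V0_loss"),
}

_CORE = ("rho", "lam", "gamma")


@dataclass(frozen=True)
class ModelSpec:
    """One decision x learning combination."""

    decision_variant: int
    learning_name: str

    def __post_init__(self) -> None:
        if self.decision_variant not in DECISION_VARIANT_ALPHAS:
            raise ValueError(f"decision variant {self.decision_variant} outside 1-5")
        if self.learning_name not in _LEARNING_FREE:
            raise ValueError(f"unknown learning variant {self.learning_name!r}")

    @property
    def id(self) -> str:
        return f"D{self.decision_variant}-{self.learning_name}"

    @property
    def learning_variant_id(self) -> int:
        for vid, (name, _, _) in LEARNING_VARIANTS.items():
            if name == self.learning_name:
                return vid
        raise AssertionError  # pragma: no cover

    @property
    def free_params(self) -> tuple[str, ...]:
        return (
            _CORE
            + DECISION_VARIANT_ALPHAS[self.decision_variant]
            + _LEARNING_FREE[self.learning_name]
        )

    @property
    def decision_alpha_names(self) -> tuple[str, ...]:
        return DECISION_VARIANT_ALPHAS[self.decision_variant]

    @property
    def learning_param_names(self) -> tuple[str, ...]:
        return _LEARNING_FREE[self.learning_name]


def enumerate_models() -> list[ModelSpec]:
    """All decision x learning combinations, in registry order."""
    return [
        ModelSpec(d, name)
        for d in sorted(DECISION_VARIANT_ALPHAS)
        for _, (name, _, _) in sorted(LEARNING_VARIANTS.items())
    ]


def parse_model_id(model_id: str) -> ModelSpec:
    """Parse an id like ``"D5-BMT3"`` into a :class:`ModelSpec`."""
    try:
        dec, learn = model_id.split("-", 1)
        variant = int(dec.removeprefix("D"))
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed model id {model_id!r}") from exc
    return ModelSpec(decision_variant=variant, learning_name=learn)


def model_free_params(model_id: str) -> tuple[str, ...]:
    return parse_model_id(model_id).free_params


def build_params(spec: ModelSpec | str, values: dict):
    """Materialize (DecisionParams, LearningParams) from free-parameter values.

    ``values`` maps each name in ``spec.free_params`` to a float. Raises
    ``KeyError`` on missing parameters and ``ValueError`` on support
    violations (delegated to the parameter classes).
    """
    from .decision import apply_variant
    from .learning import LearningParams

    if isinstance(spec, str):
        spec = parse_model_id(spec)
    free_alphas = [values[name] for name in spec.decision_alpha_names]
    decision = apply_variant(
        spec.decision_variant, values["rho"], values["lam"], values["gamma"], free_alphas
    )
    name = spec.learning_name
    if name == "none":
        learning = LearningParams(family="none")
    elif name.startswith("RW"):
        kwargs = {}
        if "lr" in spec.learning_param_names:
            kwargs["alpha"] = values["lr"]
        else:
            kwargs["alpha_pos"] = values["lr_pos"]
            kwargs["alpha_neg"] = values["lr_neg"]
        if "V0" in spec.learning_param_names:
            kwargs["V0_gain"] = values["V0"]
        elif "V0_gain" in spec.learning_param_names:
            kwargs["V0_gain"] = values["V0_gain"]
            kwargs["V0_loss"] = values["V0_loss"]
        learning = LearningParams.from_variant(name, **kwargs)
    else:  # BMT
        kwargs = {"theta_eps_sq": values["theta"]}
        if "V0" in spec.learning_param_names:
            kwargs["V0_gain"] = values["V0"]
        elif "V0_gain" in spec.learning_param_names:
            kwargs["V0_gain"] = values["V0_gain"]
            kwargs["V0_loss"] = values["V0_loss"]
        if "v0" in values:
            kwargs["v0"] = values["v0"]
        learning = LearningParams.from_variant(name, **kwargs)
    return decision, learning
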