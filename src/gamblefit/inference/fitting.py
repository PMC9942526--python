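"""Model fitting: per-subject MAP with Laplace posterior draws, and an
empirical-Bayes hierarchical mode that shares group-level priors.

Parameters are optimized on unconstrained scales (log for positive
parameters, logit for learning rates, a points/10 linear scale for
starting values) under Gaussian priors. ``mode="map"`` fits subjects
independently under fixed weakly-informative priors; ``mode=
"hierarchical"`` iteratively re-estimates the group-level prior
location and scale from the subject-level estimates, shrinking
individual fits toward the group. Posterior uncertainty is approximated
by a Gaussian (Laplace) expansion at each subject's MAP, from which the
pointwise log-likelihood draws used for WAIC and stacking are sampled.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ..modelspace import ModelSpec, parse_model_id
from . import metrics
from .likelihood import SubjectData, choice_probs, pointwise_loglik, subject_data_from_frame

__all__ = ["FitResult", "FitConfig", "fit", "dataset_loglik"]

#: Unconstrained-scale transform per parameter name.
_TRANSFORM: dict[str, str] = {
    "rho": "log",
    "lam": "log",
    "gamma": "log",
    "alpha": "log",
    "alpha_gain": "log",
    "alpha_loss": "log",
    "alpha_rg": "log",
    "alpha_sg": "log",
    "alpha_rl": "log",
    "alpha_sl": "log",
    "theta": "log",
    "lr": "logit",
    "lr_pos": "logit",
    "lr_neg": "logit",
    "V0": "lin10",
    "V0_gain": "lin10",
    "V0_loss": "lin10",
}

#: Default Gaussian priors on the unconstrained scale: name -> (center, sd).
_DEFAULT_PRIOR: dict[str, tuple[float, float]] = {
    "rho": (math.log(0.9), 0.7),
    "lam": (math.log(1.5), 0.8),
    "gamma": (math.log(0.25), 1.0),
    "alpha": (0.0, 0.7),
    "alpha_gain": (0.0, 0.7),
    "alpha_loss": (0.0, 0.7),
    "alpha_rg": (0.0, 0.7),
    "alpha_sg": (0.0, 0.7),
    "alpha_rl": (0.0, 0.7),
    "alpha_sl": (0.0, 0.7),
    "theta": (math.log(100.0), 1.5),
    "lr": (-0.85, 1.5),
    "lr_pos": (-0.85, 1.5),
    "lr_neg": (-0.85, 1.5),
    "V0": (0.5, 1.5),
    "V0_gain": (0.5, 1.5),
    "V0_loss": (-0.5, 1.5),
}

#: Unconstrained-scale box bounds per parameter, wide enough to be
#: non-binding in practice while keeping power terms finite.
_Z_BOUNDS: dict[str, tuple[float, float]] = {
    "rho": (math.log(0.05), math.log(20.0)),
    "lam": (math.log(0.01), math.log(100.0)),
    "gamma": (math.log(1e-4), math.log(100.0)),
    "theta": (math.log(1e-2), math.log(1e6)),
    "V0": (-15.0, 15.0),
    "V0_gain": (-15.0, 15.0),
    "V0_loss": (-15.0, 15.0),
}
_DEFAULT_LOG_BOUND = (math.log(0.01), math.log(100.0))  # ambiguity weights
_LOGIT_BOUND = (-8.0, 8.0)


def _z_bounds(names: tuple[str, ...]) -> list[tuple[float, float]]:
    out = []
    for name in names:
        if name in _Z_BOUNDS:
            out.append(_Z_BOUNDS[name])
        elif _TRANSFORM[name] == "logit":
            out.append(_LOGIT_BOUND)
        else:
            out.append(_DEFAULT_LOG_BOUND)
    return out


def _constrain(z: np.ndarray, names: tuple[str, ...]) -> dict:
    values = {}
    for zi, name in zip(z, names):
        kind = _TRANSFORM[name]
        if kind == "log":
            values[name] = math.exp(zi)
        elif kind == "logit":
            values[name] = 1.0 / (1.0 + math.exp(-zi))
        else:
            values[name] = 10.0 * zi
    return values


def _unconstrain(values: dict, names: tuple[str, ...]) -> np.ndarray:
    z = np.empty(len(names))
    for i, name in enumerate(names):
        x = values[name]
        kind = _TRANSFORM[name]
        if kind == "log":
            z[i] = math.log(x)
        elif kind == "logit":
            x = min(max(x, 1e-9), 1 - 1e-9)
            z[i] = math.log(x / (1 - x))
        else:
            z[i] = x / 10.0
    return z


@dataclass
class FitConfig:
    """Tunable fitting knobs; defaults suit recovery-scale problems."""

    n_draws: int = 200
    em_iters: int = 2
    n_starts: int = 2
    maxiter: int = 300
    prior_sd_floor: float = 0.15
    priors: dict | None = None  # name -> (center, sd) overrides


@dataclass
class FitResult:
    """Result of fitting one model to a choice dataset."""

    model_id: str
    mode: str
    seed: int
    param_names: tuple[str, ...]
    estimates: pd.DataFrame  # posterior-mean point estimates, one row per subject
    map_estimates: pd.DataFrame
    draws: dict  # subject -> (n_draws x n_params) constrained-scale array
    pointwise_loglik: np.ndarray  # (n_draws, total trials)
    trial_info: pd.DataFrame  # subject, trial, condition, chose_gamble
    predicted_prob: np.ndarray  # posterior-mean P(gamble) per trial
    waic: metrics.WaicResult
    efron_r2: float
    converged: dict  # subject -> bool
    prior: dict  # final prior used, name -> (center, sd)

    @property
    def n_subjects(self) -> int:
        return len(self.estimates)

    def calibration(self, bins: int = 10) -> pd.DataFrame:
        return metrics.calibration(
            self.trial_info["chose_gamble"].to_numpy(), self.predicted_prob, bins=bins
        )

    def manifest(self) -> dict:
        cfg = {
            "model_id": self.model_id,
            "mode": self.mode,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_draws": int(self.pointwise_loglik.shape[0]),
            "waic": self.waic.waic,
            "waic_scale": "deviance",
            "p_waic": self.waic.p_waic,
            "efron_r2": self.efron_r2,
            "converged_fraction": float(np.mean(list(self.converged.values()))),
            "prior": {k: list(v) for k, v in self.prior.items()},
        }
        cfg["config_hash"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:12]
        return cfg


def _neg_log_posterior(
    z: np.ndarray,
    data: SubjectData,
    spec: ModelSpec,
    names: tuple[str, ...],
    centers: np.ndarray,
    sds: np.ndarray,
) -> float:
    values = _constrain(z, names)
    ll = float(np.sum(pointwise_loglik(data, spec, values)))
    penalty = 0.5 * float(np.sum(((z - centers) / sds) ** 2))
    return -ll + penalty


def _fit_subject(
    data: SubjectData,
    spec: ModelSpec,
    names: tuple[str, ...],
    centers: np.ndarray,
    sds: np.ndarray,
    rng: np.random.Generator,
    config: FitConfig,
) -> tuple[np.ndarray, float, bool]:
    best = None
    bounds = _z_bounds(names)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.clip(centers, lo, hi)]
    for _ in range(config.n_starts - 1):
        starts.append(np.clip(centers + 0.5 * rng.standard_normal(len(names)), lo, hi))
    for x0 in starts:
        res = minimize(
            _neg_log_posterior,
            x0,
            args=(data, spec, names, centers, sds),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, float(best.fun), bool(best.success)


def _num_hessian(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def _laplace_cov(f, z_map: np.ndarray) -> np.ndarray:
    H = _num_hessian(f, z_map)
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    vals = np.clip(vals, 1e-3, None)
    return (vecs / vals) @ vecs.T


def fit(
    data: pd.DataFrame,
    model_id: str,
    mode: str = "map",
    seed: int = 0,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one decision x learning model to a choice dataset.

    Parameters
    ----------
    data:
        Tidy choice data (one row per trial) in the format produced by
        :func:`gamblefit.simulate.simulate_cohort`.
    model_id:
        Registry id such as ``"D5-BMT3"``.
    mode:
        ``"map"`` for independent per-subject fits under fixed priors,
        ``"hierarchical"`` for empirical-Bayes shrinkage in which the
        group-level prior is re-estimated from the subject fits.
    seed:
        Controls optimizer restarts and posterior draws; refitting with
        the same seed reproduces estimates exactly.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    if mode not in ("map", "hierarchical"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or FitConfig()
    spec = parse_model_id(model_id)
    names = spec.free_params

    prior = dict(_DEFAULT_PRIOR)
    if config.priors:
        prior.update(config.priors)
    centers = np.array([prior[n][0] for n in names])
    sds = np.array([prior[n][1] for n in names])

    subject_frames = {int(s): g for s, g in data.groupby("subject", sort=True)}
    subjects = sorted(subject_frames)
    sdata = {s: subject_data_from_frame(subject_frames[s]) for s in subjects}

    passes = 1 + (config.em_iters if mode == "hierarchical" else 0)
    z_maps: dict[int, np.ndarray] = {}
    fun_vals: dict[int, float] = {}
    ok: dict[int, bool] = {}
    for it in range(passes):
        for s in subjects:
            rng = np.random.default_rng([seed, 7, it, s])
            z_maps[s], fun_vals[s], ok[s] = _fit_subject(
                sdata[s], spec, names, centers, sds, rng, config
            )
        if mode == "hierarchical" and it < passes - 1:
            Z = np.vstack([z_maps[s] for s in subjects])
            centers = Z.mean(axis=0)
            if len(subjects) > 1:
                sds = np.maximum(Z.std(axis=0, ddof=1), config.prior_sd_floor)

    draws: dict[int, np.ndarray] = {}
    ll_blocks = []
    prob_blocks = []
    est_rows = []
    map_rows = []
    info_rows = []
    for s in subjects:
        d = sdata[s]
        z_map = z_maps[s]

        def f(z, d=d):
            return _neg_log_posterior(z, d, spec, names, centers, sds)

        cov = _laplace_cov(f, z_map)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(names)))
        rng = np.random.default_rng([seed, 101, s])
        Z = z_map + rng.standard_normal((config.n_draws, len(names))) @ chol.T
        bounds = _z_bounds(names)
        Z = np.clip(Z, [b[0] for b in bounds], [b[1] for b in bounds])
        const = np.empty((config.n_draws, len(names)))
        ll = np.empty((config.n_draws, d.n))
        probs = np.empty((config.n_draws, d.n))
        for i in range(config.n_draws):
            values = _constrain(Z[i], names)
            const[i] = [values[n] for n in names]
            ll[i] = pointwise_loglik(d, spec, values)
            probs[i] = choice_probs(d, spec, values)
        draws[s] = const
        ll_blocks.append(ll)
        prob_blocks.append(probs.mean(axis=0))
        est_rows.append({"subject": s, **dict(zip(names, const.mean(axis=0)))})
        map_rows.append({"subject": s, **_constrain(z_map, names)})
        frame = subject_frames[s].sort_values("trial")
        info_rows.append(frame[["subject", "trial", "condition", "chose_gamble"]])

    pointwise = np.hstack(ll_blocks)
    predicted = np.concatenate(prob_blocks)
    trial_info = pd.concat(info_rows, ignore_index=True)
    waic_res = metrics.waic(pointwise)
    y = trial_info["chose_gamble"].to_numpy()
    # constant choices leave the pseudo-R^2 undefined; report NaN rather
    # than failing the whole fit
    r2 = metrics.efron_r2(y, predicted) if y.min() != y.max() else float("nan")
    return FitResult(
        model_id=model_id,
        mode=mode,
        seed=seed,
        param_names=names,
        estimates=pd.DataFrame(est_rows),
        map_estimates=pd.DataFrame(map_rows),
        draws=draws,
        pointwise_loglik=pointwise,
        trial_info=trial_info,
        predicted_prob=predicted,
        waic=waic_res,
        efron_r2=r2,
        converged=ok,
        prior={n: (float(c), float(sd)) for n, c, sd in zip(names, centers, sds)},
    )


def dataset_loglik(data: pd.DataFrame, model_id: str, values: dict) -> float:
    """Total log-likelihood of a dataset under fixed parameter values.

    ``values`` maps free-parameter names to floats applied to every
    subject (useful for nesting checks and oracle comparisons).
    """
    spec = parse_model_id(model_id)
    total = 0.0
    for _, g in data.groupby("subject"):
        d = subject_data_from_frame(g)
        total += float(np.sum(pointwise_loglik(d, spec, values)))
    return total
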