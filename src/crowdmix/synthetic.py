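"""Synthetic stimulus designs and simulated continuous-report responses.

Emulates a radial orientation-crowding experiment: a peripheral Gabor
target on the horizontal meridian, shown alone or flanked radially by
two or four Gabors at 1.5° centre-to-centre spacing, with the observer
reproducing the target orientation on a continuous wheel. Two geometries
are available:

* ``exp1`` — target at 7° eccentricity in the middle of the string
  (flankers at 5.5°/8.5°, or 4°/5.5°/8.5°/10°).
* ``exp2`` — target shifted one position outward to 8.5° (two-flanker
  condition has both flankers inward at 5.5°/7°; four-flanker at
  4°/5.5°/7°/10°).

Orientations are drawn uniformly from the 180 discrete values 1°–180°;
every flanker is constrained by rejection sampling to differ from the
target by at least 15° on the orientation circle. Responses are sampled
from any of the six mixture models: a latent source (target / guess /
flanker i) is drawn with probabilities (P_T, gamma, beta_i), then the
response is the source orientation plus von Mises noise of width sigma
(guesses are uniform). The latent source is recorded so that recovery
tests can condition on the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circ_diff, sample_vm_noise, wrap_orientation
from .models import ModelSpec, ParamVector, get_model

__all__ = [
    "DesignConfig",
    "StimulusTrial",
    "ResponseTrial",
    "GenerativeScenario",
    "GEOMETRY",
    "TRIAL_COLUMNS",
    "generate_design",
    "simulate_responses",
    "generate_dataset",
    "default_scenario",
]

#: Minimum target–flanker orientation difference enforced at generation, degrees.
MIN_TARGET_FLANKER_SEP = 15.0

#: Number of discrete orientation values in the stimulus space.
N_ORIENTATIONS = 180

#: (roles fovea→periphery, eccentricities) per experiment and condition,
#: plus the target eccentricity. Adjacent items are 1.5° apart.
GEOMETRY = {
    "exp1": {
        "target_ecc": 7.0,
        "uncrowded": ((), ()),
        "two_flanker": (("1I", "1O"), (5.5, 8.5)),
        "four_flanker": (("2I", "1I", "1O", "2O"), (4.0, 5.5, 8.5, 10.0)),
    },
    "exp2": {
        "target_ecc": 8.5,
        "uncrowded": ((), ()),
        "two_flanker": (("2I", "1I"), (5.5, 7.0)),
        "four_flanker": (("3I", "2I", "1I", "1O"), (4.0, 5.5, 7.0, 10.0)),
    },
}

CONDITIONS = ("uncrowded", "two_flanker", "four_flanker")

#: Canonical trial-table schema (CSV, one row per trial).
TRIAL_COLUMNS = [
    "observer_id",
    "experiment",
    "condition",
    "hemifield",
    "target_ori",
    "ori_3I",
    "ori_2I",
    "ori_1I",
    "ori_1O",
    "ori_2O",
    "response_ori",
    "latent_source",
]


@dataclass(frozen=True)
class DesignConfig:
    """Stimulus-design settings; the defaults reproduce one observer's
    session: 3 conditions × 200 trials = 600 trials."""

    experiment: str = "exp1"
    n_observers: int = 1
    trials_per_condition: int = 200
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in GEOMETRY:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")


@dataclass(frozen=True)
class StimulusTrial:
    """One generated stimulus: geometry plus orientations."""

    observer_id: int
    experiment: str
    condition: str
    hemifield: str
    target_ecc: float
    roles: tuple[str, ...]
    eccentricities: tuple[float, ...]
    target_ori: float
    flanker_oris: tuple[float, ...]


@dataclass(frozen=True)
class ResponseTrial(StimulusTrial):
    """A stimulus trial plus the simulated report and its latent source."""

    response_ori: float = float("nan")
    latent_source: str = ""


@dataclass(frozen=True)
class GenerativeScenario:
    """Generating truth per condition: a model name and its parameters.

    The uncrowded condition must use the standard model (there are no
    flankers to misreport).
    """

    params: dict = field(default_factory=dict)  # condition -> (model name, ParamVector)
    seed: int = 0

    def model_for(self, condition: str) -> tuple[ModelSpec, ParamVector]:
        try:
            name, pv = self.params[condition]
        except KeyError:
            raise KeyError(f"scenario has no entry for condition {condition!r}") from None
        model = get_model(name)
        if condition == "uncrowded" and (model.n_flankers > 0 or model.pooled):
            raise ValueError("uncrowded condition must use the standard model")
        return model, pv


def default_scenario(seed: int = 0) -> GenerativeScenario:
    """A realistic crowding regime for the exp1 geometry.

    Guess rates and sigma sit in the typical fitted range for peripheral
    orientation reports (~12–16°); misreport mass loads on the first
    outer flanker, with the remaining flankers at a low common rate —
    the characteristic inner–outer asymmetry.
    """
    return GenerativeScenario(
        params={
            "uncrowded": ("standard", ParamVector(gamma=0.03, sigma=12.0)),
            "two_flanker": (
                "two_misreport",
                ParamVector(gamma=0.05, sigma=15.0, betas=(0.05, 0.25)),
            ),
            "four_flanker": (
                "four_misreport",
                ParamVector(gamma=0.05, sigma=15.0, betas=(0.07, 0.07, 0.24, 0.07)),
            ),
        },
        seed=seed,
    )


def _draw_orientation(rng: np.random.Generator) -> float:
    return float(rng.integers(1, N_ORIENTATIONS + 1))


def _draw_flanker(rng: np.random.Generator, target: float) -> float:
    # rejection sampling; acceptance 150/179 per draw
    while True:
        ori = _draw_orientation(rng)
        if abs(circ_diff(ori, target)) >= MIN_TARGET_FLANKER_SEP:
            return ori


def generate_design(config: DesignConfig) -> list[StimulusTrial]:
    """Generate the full randomized trial list for every observer.

    Per observer: ``trials_per_condition`` trials per requested
    condition, hemifields balanced within condition, trial order
    shuffled across conditions. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    geom = GEOMETRY[config.experiment]
    all_trials: list[StimulusTrial] = []
    for obs in range(1, config.n_observers + 1):
        observer_trials: list[StimulusTrial] = []
        for condition in config.conditions:
            roles, eccs = geom[condition]
            n = config.trials_per_condition
            hemis = np.array(["left", "right"]).repeat((n + 1) // 2)[:n]
            rng.shuffle(hemis)
            for i in range(n):
                target = _draw_orientation(rng)
                flankers = tuple(_draw_flanker(rng, target) for _ in roles)
                observer_trials.append(
                    StimulusTrial(
                        observer_id=obs,
                        experiment=config.experiment,
                        condition=condition,
                        hemifield=str(hemis[i]),
                        target_ecc=geom["target_ecc"],
                        roles=roles,
                        eccentricities=eccs,
                        target_ori=target,
                        flanker_oris=flankers,
                    )
                )
        order = rng.permutation(len(observer_trials))
        all_trials.extend(observer_trials[i] for i in order)
    return all_trials


def _simulate_one(
    trial: StimulusTrial,
    model: ModelSpec,
    pv: ParamVector,
    rng: np.random.Generator,
) -> ResponseTrial:
    m = len(trial.flanker_oris)
    if not model.compatible_with(m):
        raise ValueError(
            f"scenario model {model.name!r} incompatible with condition "
            f"{trial.condition!r} ({m} flankers)"
        )
    if model.pooled:
        (beta,) = pv.betas
        flanker_probs = [beta / m] * m
    elif model.n_flankers > 0:
        if len(pv.betas) != m:
            raise ValueError("scenario betas must match the trial's flanker count")
        flanker_probs = list(pv.betas)
    else:
        flanker_probs = []
    probs = np.array([pv.p_target, pv.gamma, *flanker_probs])
    probs = probs / probs.sum()
    idx = rng.choice(len(probs), p=probs)
    if idx == 1:
        response = float(rng.uniform(0.0, 180.0))
        response = 180.0 if response == 0.0 else response
        source = "guess"
    else:
        if idx == 0:
            centre = trial.target_ori
            source = "target"
            if model.has_bias:
                # mu is defined on outward-realigned errors: positive mu
                # pushes the report toward the 1O flanker when present
                shift = pv.mu
                if "1O" in trial.roles:
                    off = circ_diff(trial.flanker_oris[trial.roles.index("1O")], trial.target_ori)
                    shift = pv.mu * (1.0 if off > 0 else -1.0)
                centre = centre + shift
        else:
            j = idx - 2
            centre = trial.flanker_oris[j]
            source = trial.roles[j]
        response = wrap_orientation(centre + sample_vm_noise(rng, pv.sigma))
    return ResponseTrial(
        **{k: getattr(trial, k) for k in StimulusTrial.__dataclass_fields__},
        response_ori=response,
        latent_source=source,
    )


def simulate_responses(
    trials: list[StimulusTrial], scenario: GenerativeScenario
) -> list[ResponseTrial]:
    """Sample one response per trial from the scenario's generating model."""
    rng = np.random.default_rng(scenario.seed)
    out = []
    for trial in trials:
        model, pv = scenario.model_for(trial.condition)
        out.append(_simulate_one(trial, model, pv, rng))
    return out


def trials_to_frame(trials: list[ResponseTrial]) -> pd.DataFrame:
    """Canonical trial table: one row per trial, one column per flanker role."""
    rows = []
    for t in trials:
        row = {
            "observer_id": t.observer_id,
            "experiment": t.experiment,
            "condition": t.condition,
            "hemifield": t.hemifield,
            "target_ori": t.target_ori,
            "response_ori": t.response_ori,
            "latent_source": t.latent_source,
        }
        for role in ("3I", "2I", "1I", "1O", "2O"):
            row[f"ori_{role}"] = np.nan
        for role, ori in zip(t.roles, t.flanker_oris):
            row[f"ori_{role}"] = ori
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_dataset(
    config: DesignConfig, scenario: GenerativeScenario | None = None
) -> pd.DataFrame:
    """Design + simulated responses as the canonical trial table."""
    scenario = scenario or default_scenario(seed=config.seed + 1)
    design = generate_design(config)
    responses = simulate_responses(design, scenario)
    return trials_to_frame(responses)
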