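"""The six crowding-error mixture models.

Each model describes the density of a trial's signed estimation error
(response − target, wrapped to (−90, +90]) as a mixture of

* a von Mises component centred on the target (mean 0, or ``mu`` in the
  bias variants),
* a uniform guessing component with mass ``gamma`` spread over the 180
  possible orientations, and
* optionally one von Mises "misreport" component per flanker, centred on
  that flanker's offset from the target, with mass ``beta_i``.

All von Mises components share a single width ``sigma``. The target
component's mass is whatever is left: ``P_T = 1 − gamma − Σ beta_i``.

Catalog (short labels as used in figures and comparison tables):

====  =====================  ==========================================
S     standard               gamma, sigma
M     misreport              gamma, sigma, one pooled beta split 1/m
2M    two_misreport          gamma, sigma, independent beta per flanker (2)
2B    two_misreport_bias     2M plus a target-mean bias mu
4M    four_misreport         gamma, sigma, independent beta per flanker (4)
4B    four_misreport_bias    4M plus a target-mean bias mu
====  =====================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import PERIOD, sigma_to_kappa, vm_density_kappa, wrap_error

__all__ = [
    "ModelSpec",
    "ParamVector",
    "TrialErrors",
    "model_catalog",
    "get_model",
    "trial_density",
    "log_likelihood",
    "target_report_rate",
    "MODEL_LABELS",
]

#: Flanker roles ordered from fovea to periphery; targets sit between 1I and 1O.
ROLE_ORDER = ("3I", "2I", "1I", "1O", "2O")

MODEL_LABELS = {
    "standard": "S",
    "misreport": "M",
    "two_misreport": "2M",
    "two_misreport_bias": "2B",
    "four_misreport": "4M",
    "four_misreport_bias": "4B",
}


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one mixture model: which components exist and their names.

    ``n_flankers`` is the number of independent misreport components
    (0 for the standard model, 2 or 4 for the independent-beta models);
    ``pooled`` marks the single-beta model whose mass is split equally
    over however many flankers the trial shows.
    """

    name: str
    label: str
    n_flankers: int
    pooled: bool
    has_bias: bool
    parameter_names: tuple[str, ...]

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.parameter_names)

    def compatible_with(self, n_trial_flankers: int) -> bool:
        if self.pooled:
            return n_trial_flankers >= 1
        if self.n_flankers == 0:
            return True  # standard model ignores flankers
        return n_trial_flankers == self.n_flankers


def _beta_names(n: int) -> tuple[str, ...]:
    if n == 2:
        return ("beta_1I", "beta_1O")
    if n == 4:
        return ("beta_2I", "beta_1I", "beta_1O", "beta_2O")
    raise ValueError(n)


_CATALOG: tuple[ModelSpec, ...] = (
    ModelSpec("standard", "S", 0, False, False, ("gamma", "sigma")),
    ModelSpec("misreport", "M", 0, True, False, ("gamma", "sigma", "beta")),
    ModelSpec("two_misreport", "2M", 2, False, False, ("gamma", "sigma") + _beta_names(2)),
    ModelSpec(
        "two_misreport_bias", "2B", 2, False, True, ("gamma", "sigma") + _beta_names(2) + ("mu",)
    ),
    ModelSpec("four_misreport", "4M", 4, False, False, ("gamma", "sigma") + _beta_names(4)),
    ModelSpec(
        "four_misreport_bias", "4B", 4, False, True, ("gamma", "sigma") + _beta_names(4) + ("mu",)
    ),
)

_BY_NAME = {m.name: m for m in _CATALOG}
_BY_NAME.update({m.label: m for m in _CATALOG})


def model_catalog() -> list[ModelSpec]:
    """The six models in canonical order S, M, 2M, 2B, 4M, 4B."""
    return list(_CATALOG)


def catalog_index(name: str) -> int:
    return _CATALOG.index(get_model(name))


def get_model(name: str) -> ModelSpec:
    """Look a model up by full name or short label (e.g. ``"2M"``)."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; expected one of "
            f"{sorted(m.name for m in _CATALOG)} or labels {sorted(MODEL_LABELS.values())}"
        ) from None


@dataclass(frozen=True)
class ParamVector:
    """Constrained parameters of a mixture model.

    ``betas`` is ordered to match the trial's flanker offsets
    (fovea → periphery); for the pooled misreport model it holds the
    single pooled beta. ``mu`` is the target-component mean shift in
    degrees, used only by the bias models and interpreted on
    outward-realigned errors (positive = toward the outer flanker).
    """

    gamma: float
    sigma: float
    betas: tuple[float, ...] = field(default_factory=tuple)
    mu: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))

    def validate(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma={self.gamma} outside [0, 1]")
        if any(b < 0 or b > 1 for b in self.betas):
            raise ValueError(f"betas={self.betas} outside [0, 1]")
        if self.gamma + sum(self.betas) > 1.0 + 1e-9:
            raise ValueError("gamma + sum(betas) exceeds 1")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma={self.sigma} must be positive")
        if not -90.0 < self.mu <= 90.0:
            raise ValueError(f"mu={self.mu} outside (-90, 90]")

    @property
    def p_target(self) -> float:
        return max(0.0, 1.0 - self.gamma - sum(self.betas))

    def as_dict(self, model: ModelSpec) -> dict[str, float]:
        d = {"gamma": self.gamma, "sigma": self.sigma}
        beta_names = [n for n in model.parameter_names if n.startswith("beta")]
        d.update(dict(zip(beta_names, self.betas)))
        if model.has_bias:
            d["mu"] = self.mu
        return d


@dataclass(frozen=True)
class TrialErrors:
    """One trial reduced to target-relative quantities.

    ``theta`` is the signed estimation error; ``flanker_offsets`` are the
    flankers' signed offsets from the target, ordered fovea → periphery,
    with ``roles`` naming each position.
    """

    theta: float
    flanker_offsets: tuple[float, ...] = field(default_factory=tuple)
    roles: tuple[str, ...] = field(default_factory=tuple)
    condition: str = ""

    def __post_init__(self):
        object.__setattr__(self, "flanker_offsets", tuple(float(x) for x in self.flanker_offsets))
        object.__setattr__(self, "roles", tuple(self.roles))
        if self.roles and len(self.roles) != len(self.flanker_offsets):
            raise ValueError("roles and flanker_offsets must have equal length")


def _check_compat(model: ModelSpec, n_flankers: int) -> None:
    if not model.compatible_with(n_flankers):
        raise ValueError(
            f"model {model.name!r} is incompatible with a trial carrying "
            f"{n_flankers} flanker(s)"
        )


def trial_density(params: ParamVector, trial: TrialErrors, model: ModelSpec) -> float:
    """Mixture density (per degree) of the trial's error under the model."""
    params.validate()
    m = len(trial.flanker_offsets)
    _check_compat(model, m)
    kappa = sigma_to_kappa(params.sigma)
    mu = params.mu if model.has_bias else 0.0
    dens = params.p_target * vm_density_kappa(wrap_error(trial.theta - mu), kappa)
    dens += params.gamma / PERIOD
    if model.pooled:
        (beta,) = params.betas
        for off in trial.flanker_offsets:
            dens += (beta / m) * vm_density_kappa(wrap_error(trial.theta - off), kappa)
    elif model.n_flankers > 0:
        if len(params.betas) != m:
            raise ValueError("number of betas must match number of flankers")
        for beta, off in zip(params.betas, trial.flanker_offsets):
            dens += beta * vm_density_kappa(wrap_error(trial.theta - off), kappa)
    return float(dens)


class DensityWorkspace:
    """Vectorized likelihood evaluation for a fixed (trials, model) pair.

    Pre-stages the error vector and the flanker-offset matrix so that one
    likelihood evaluation costs a single exp over an (n_trials, n_components)
    array — the optimizer calls this thousands of times.
    """

    def __init__(self, trials: list[TrialErrors], model: ModelSpec):
        if len(trials) == 0:
            raise ValueError("empty trial list")
        counts = {len(t.flanker_offsets) for t in trials}
        if len(counts) > 1:
            raise ValueError(f"trials have inconsistent flanker counts {sorted(counts)}")
        self.m = counts.pop()
        _check_compat(model, self.m)
        self.model = model
        self.n = len(trials)
        self.theta = np.array([t.theta for t in trials], dtype=float)
        if self.m:
            offsets = np.array([t.flanker_offsets for t in trials], dtype=float)
            # (n, m) differences response-error minus flanker offset
            self.flanker_delta = wrap_error(self.theta[:, None] - offsets)
        else:
            self.flanker_delta = np.empty((self.n, 0))

    def densities(self, params: ParamVector) -> np.ndarray:
        kappa = sigma_to_kappa(params.sigma)
        mu = params.mu if self.model.has_bias else 0.0
        target_term = vm_density_kappa(wrap_error(self.theta - mu), kappa)
        dens = params.p_target * target_term + params.gamma / PERIOD
        if self.model.pooled and self.m:
            (beta,) = params.betas
            dens = dens + (beta / self.m) * vm_density_kappa(self.flanker_delta, kappa).sum(axis=1)
        elif self.model.n_flankers > 0:
            if len(params.betas) != self.m:
                raise ValueError("number of betas must match number of flankers")
            w = np.asarray(params.betas)
            dens = dens + vm_density_kappa(self.flanker_delta, kappa) @ w
        return dens

    def log_likelihood(self, params: ParamVector) -> float:
        dens = self.densities(params)
        if np.any(dens <= 0):
            return -np.inf
        return float(np.log(dens).sum())


def log_likelihood(params: ParamVector, trials: list[TrialErrors], model: ModelSpec) -> float:
    """Sum of log trial densities over the trial list."""
    params.validate()
    return DensityWorkspace(trials, model).log_likelihood(params)


def target_report_rate(params: ParamVector) -> float:
    """P_T = 1 − gamma − Σ beta: the probability mass centred on the target."""
    params.validate()
    return params.p_target
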