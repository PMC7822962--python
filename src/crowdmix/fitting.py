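"""Maximum-likelihood fitting and AICc model comparison.

Each observer × condition is fitted independently. The mixture weights
(target, guess, per-flanker misreports) live on a probability simplex;
the optimizer works in an unconstrained space via a softmax transform
with the target weight as the reference category, so the simplex and
bound constraints hold exactly at every iterate. Sigma (and mu for the
bias models) are mapped to their bounds through a scaled logistic.

Fitting is multi-start: starting points are drawn once per fit from a
seeded generator (weights from a flat Dirichlet over the simplex, sigma
and mu from a Latin hypercube over their bounds) and each start is
refined with L-BFGS-B. The best converged start wins; ties in the
likelihood are irrelevant because only the maximum is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .models import (
    DensityWorkspace,
    ModelSpec,
    ParamVector,
    TrialErrors,
    catalog_index,
    get_model,
)

__all__ = ["FitConfig", "FitResult", "ComparisonRow", "fit_mle", "aicc", "compare_models"]

_EPS_W = 1e-7  # weight floor used when mapping simplex points to logits


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_mle`.

    ``n_starts`` random restarts; ``seed`` makes the whole fit
    deterministic; ``tol`` is the relative convergence tolerance on the
    negative log-likelihood; ``min_trials`` is a floor below which a fit
    is refused rather than silently overfit.
    """

    n_starts: int = 20
    seed: int = 0
    tol: float = 1e-8
    sigma_bounds: tuple[float, float] = (0.5, 80.0)
    mu_bounds: tuple[float, float] = (-45.0, 45.0)
    min_trials: int = 20


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: str
    params: ParamVector
    log_likelihood: float
    n_trials: int
    converged: bool
    n_starts_used: int
    seed: int

    @property
    def k(self) -> int:
        return get_model(self.model).k

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n_trials)


@dataclass(frozen=True)
class ComparisonRow:
    """One row of an AICc comparison table."""

    model: str
    aicc: float
    delta_aicc: float
    k: int
    is_best: bool


class _Transform:
    """Bijection between the model's constrained parameters and R^k."""

    def __init__(self, model: ModelSpec, n_trial_flankers: int, config: FitConfig):
        self.model = model
        self.config = config
        if model.pooled:
            self.n_betas = 1
        elif model.n_flankers > 0:
            self.n_betas = n_trial_flankers
        else:
            self.n_betas = 0
        # logits for (gamma, beta_1..n) relative to the target weight,
        # then the sigma logistic, then mu for bias models
        self.size = 1 + self.n_betas + 1 + (1 if model.has_bias else 0)

    def to_params(self, z: np.ndarray) -> ParamVector:
        nw = 1 + self.n_betas
        logits = np.concatenate([[0.0], z[:nw]])  # target is the reference
        logits = logits - logits.max()
        w = np.exp(logits)
        w /= w.sum()
        lo, hi = self.config.sigma_bounds
        sigma = lo + (hi - lo) * expit(z[nw])
        mu = 0.0
        if self.model.has_bias:
            mlo, mhi = self.config.mu_bounds
            mu = mlo + (mhi - mlo) * expit(z[nw + 1])
        return ParamVector(gamma=float(w[1]), sigma=float(sigma), betas=tuple(w[2:]), mu=float(mu))

    def from_params(self, params: ParamVector) -> np.ndarray:
        w = np.array([params.p_target, params.gamma, *params.betas], dtype=float)
        w = np.clip(w, _EPS_W, None)
        w /= w.sum()
        z = list(np.log(w[1:]) - np.log(w[0]))
        lo, hi = self.config.sigma_bounds
        s = np.clip((params.sigma - lo) / (hi - lo), _EPS_W, 1 - _EPS_W)
        z.append(logit(s))
        if self.model.has_bias:
            mlo, mhi = self.config.mu_bounds
            u = np.clip((params.mu - mlo) / (mhi - mlo), _EPS_W, 1 - _EPS_W)
            z.append(logit(u))
        return np.array(z, dtype=float)


def _draw_starts(transform: _Transform, config: FitConfig, rng: np.random.Generator):
    """Starting points in natural space: simplex-uniform weights, LHS scales."""
    n = config.n_starts
    n_betas = transform.n_betas
    weights = rng.dirichlet(np.ones(2 + n_betas), size=n)
    n_scales = 1 + (1 if transform.model.has_bias else 0)
    sampler = qmc.LatinHypercube(d=n_scales, seed=rng.integers(0, 2**31 - 1))
    unit = sampler.random(n)
    lo, hi = config.sigma_bounds
    sigmas = lo + (hi - lo) * unit[:, 0]
    starts = []
    for i in range(n):
        mu = 0.0
        if transform.model.has_bias:
            mlo, mhi = config.mu_bounds
            mu = mlo + (mhi - mlo) * unit[i, 1]
        p = ParamVector(
            gamma=float(weights[i, 1]),
            sigma=float(sigmas[i]),
            betas=tuple(weights[i, 2:]),
            mu=float(mu),
        )
        starts.append(transform.from_params(p))
    return starts


def fit_mle(
    trials: list[TrialErrors],
    model: ModelSpec | str,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one mixture model to one observer-condition's trials by MLE.

    Returns the best of ``config.n_starts`` bounded optimizations;
    deterministic given (trials, config.seed). A fit where no start
    converges is returned flagged ``converged=False`` with the best
    point found, never raised.
    """
    if isinstance(model, str):
        model = get_model(model)
    config = config or FitConfig()
    if len(trials) < config.min_trials:
        raise ValueError(f"need at least {config.min_trials} trials, got {len(trials)}")
    ws = DensityWorkspace(trials, model)
    transform = _Transform(model, ws.m, config)
    rng = np.random.default_rng(config.seed)
    starts = _draw_starts(transform, config, rng)

    def neg_ll(z):
        ll = ws.log_likelihood(transform.to_params(z))
        # large finite penalty keeps L-BFGS finite-difference gradients clean
        return 1e12 if not np.isfinite(ll) else -ll

    best_z, best_val, any_ok = None, np.inf, False
    for z0 in starts:
        res = minimize(
            neg_ll,
            z0,
            method="L-BFGS-B",
            options={"ftol": config.tol, "gtol": 1e-8, "maxiter": 500},
        )
        if res.fun < best_val:
            best_val, best_z = res.fun, res.x
        any_ok = any_ok or bool(res.success)
    params = transform.to_params(best_z)
    return FitResult(
        model=model.name,
        params=params,
        log_likelihood=ws.log_likelihood(params),
        n_trials=ws.n,
        converged=any_ok and np.isfinite(best_val),
        n_starts_used=config.n_starts,
        seed=config.seed,
    )


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    ``AICc = −2·logL + 2k + 2k(k+1)/(n − k − 1)``; requires ``n > k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def compare_models(fits: list[FitResult]) -> list[ComparisonRow]:
    """Rank fits of the same data by AICc (ascending).

    Ties are broken toward fewer parameters, then catalog order. All
    fits must share the same trial count (same data).
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n_trials for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits have mixed trial counts {sorted(ns)}; not comparable")
    scored = sorted(fits, key=lambda f: (f.aicc, f.k, catalog_index(f.model)))
    best = scored[0].aicc
    return [
        ComparisonRow(
            model=f.model,
            aicc=f.aicc,
            delta_aicc=f.aicc - best,
            k=f.k,
            is_best=(i == 0),
        )
        for i, f in enumerate(scored)
    ]
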