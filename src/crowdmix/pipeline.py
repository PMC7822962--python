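"""End-to-end analysis of a trial table.

Stages: signed errors and flanker offsets → per-condition precision →
per-observer maximum-likelihood fits of the condition's candidate models
→ AICc comparison → per-flanker report rates → outward-realigned bias
check. Operates on the canonical trial table produced by
:mod:`crowdmix.synthetic` (or loaded from CSV with the same columns).

Candidate models follow the condition: the uncrowded condition is fitted
with the standard mixture only; a two-flanker condition with the
standard, pooled-misreport, two-misreport and two-misreport-with-bias
models; a four-flanker condition with the standard, pooled-misreport,
four-misreport and four-misreport-with-bias models. Bias models are
fitted on outward-realigned errors, which requires a first-outer (1O)
flanker; in geometries without one (the outward-target two-flanker
arrangement) the bias variant is dropped from the candidate set.
Realignment leaves the likelihood of the non-bias models unchanged
because all their components are symmetric, so AICc values remain
comparable across the two framings.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circular import circ_diff, circ_moments
from .fitting import ComparisonRow, FitConfig, FitResult, aicc, compare_models, fit_mle
from .models import MODEL_LABELS, ParamVector, TrialErrors, get_model

__all__ = [
    "PipelineConfig",
    "ObserverFit",
    "PipelineResult",
    "compute_errors",
    "trial_errors",
    "realign_outward",
    "precision_summary",
    "fit_condition_set",
    "flanker_report_rates",
    "flanker_relative_histogram",
    "run_pipeline",
]

ROLE_ORDER = ("3I", "2I", "1I", "1O", "2O")

#: Candidate model names per condition (short labels accepted too).
DEFAULT_CANDIDATES = {
    "uncrowded": ("standard",),
    "two_flanker": ("standard", "misreport", "two_misreport", "two_misreport_bias"),
    "four_flanker": ("standard", "misreport", "four_misreport", "four_misreport_bias"),
}

_REQUIRED_COLUMNS = ("observer_id", "condition", "target_ori", "response_ori")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings.

    ``precision_mode`` selects 1/variance (default) or 1/SD of the
    errors in radians; ``bin_width`` is the flanker-relative histogram
    bin width in degrees.
    """

    fit: FitConfig = field(default_factory=FitConfig)
    precision_mode: str = "variance"
    bin_width: float = 10.0
    candidates: dict = field(default_factory=lambda: dict(DEFAULT_CANDIDATES))


@dataclass(frozen=True)
class ObserverFit:
    """One model fitted to one observer × condition."""

    observer_id: object
    condition: str
    roles: tuple[str, ...]
    fit: FitResult
    realigned: bool = False


@dataclass(frozen=True)
class PipelineResult:
    summary: pd.DataFrame
    comparison: pd.DataFrame
    rates: pd.DataFrame
    fits: list[ObserverFit]
    log: dict


def _roles_present(df: pd.DataFrame) -> tuple[str, ...]:
    roles = []
    for role in ROLE_ORDER:
        col = f"ori_{role}"
        if col in df.columns and df[col].notna().any():
            roles.append(role)
    return tuple(roles)


def compute_errors(df: pd.DataFrame) -> pd.DataFrame:
    """Add signed errors to a trial table.

    ``theta`` is the estimation error (response − target) and
    ``off_<role>`` the flanker offsets (flanker − target), all wrapped
    to (−90, +90] so that zero indicates the target value.
    """
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"trial table is missing required column {col!r}")
    out = df.copy()
    out["theta"] = circ_diff(df["response_ori"].to_numpy(float), df["target_ori"].to_numpy(float))
    for role in ROLE_ORDER:
        col = f"ori_{role}"
        if col in df.columns:
            vals = df[col].to_numpy(float)
            off = np.full(len(df), np.nan)
            mask = np.isfinite(vals)
            if mask.any():
                off[mask] = circ_diff(vals[mask], df["target_ori"].to_numpy(float)[mask])
            out[f"off_{role}"] = off
    return out


def trial_errors(df: pd.DataFrame, condition: str | None = None) -> list[TrialErrors]:
    """Convert (a slice of) an error table into :class:`TrialErrors` objects."""
    if condition is not None:
        df = df[df["condition"] == condition]
    if "theta" not in df.columns:
        df = compute_errors(df)
    roles = _roles_present(df)
    cols = [f"off_{r}" for r in roles]
    thetas = df["theta"].to_numpy(float)
    offsets = df[cols].to_numpy(float) if cols else np.empty((len(df), 0))
    conds = df["condition"].to_numpy() if "condition" in df.columns else [""] * len(df)
    return [
        TrialErrors(
            theta=float(thetas[i]),
            flanker_offsets=tuple(offsets[i]),
            roles=roles,
            condition=str(conds[i]),
        )
        for i in range(len(df))
    ]


def realign_outward(trials: list[TrialErrors]) -> list[TrialErrors]:
    """Flip each trial's error signs so the first-outer flanker is positive.

    For trials whose 1O offset is negative, the sign of theta and of all
    flanker offsets is flipped; the operation is idempotent. Requires
    every trial to carry a 1O flanker (uncrowded trials are rejected).
    """
    out = []
    for t in trials:
        if "1O" not in t.roles:
            raise ValueError("realign_outward requires trials with a 1O flanker")
        off_1o = t.flanker_offsets[t.roles.index("1O")]
        if off_1o < 0:
            out.append(
                replace(
                    t,
                    theta=-t.theta,
                    flanker_offsets=tuple(-x for x in t.flanker_offsets),
                )
            )
        else:
            out.append(t)
    return out


def precision_summary(errors, mode: str = "variance") -> float:
    """Precision of a set of signed errors, in inverse radians.

    Errors are converted to radians; ``mode="variance"`` returns
    1/variance (rad⁻²), ``mode="sd"`` returns 1/SD (rad⁻¹). Zero
    variance yields an infinite-precision sentinel with a warning.
    """
    x = np.asarray(errors, dtype=float) * np.pi / 180.0
    if x.size < 2:
        raise ValueError("need at least 2 errors")
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        warnings.warn("zero error variance; returning infinite precision", RuntimeWarning)
        return float("inf")
    if mode == "variance":
        return 1.0 / var
    if mode == "sd":
        return 1.0 / float(np.sqrt(var))
    raise ValueError(f"unknown precision mode {mode!r}")


def _fit_candidates(
    trials: list[TrialErrors],
    roles: tuple[str, ...],
    candidates,
    fit_config: FitConfig,
    observer_id,
    condition: str,
) -> list[ObserverFit]:
    fits = []
    realigned_cache = None
    for name in candidates:
        model = get_model(name)
        if model.has_bias:
            if "1O" not in roles:
                continue  # no outward realignment possible in this geometry
            if realigned_cache is None:
                realigned_cache = realign_outward(trials)
            data = realigned_cache
        else:
            data = trials
        fit = fit_mle(data, model, fit_config)
        fits.append(
            ObserverFit(
                observer_id=observer_id,
                condition=condition,
                roles=roles,
                fit=fit,
                realigned=model.has_bias,
            )
        )
    return fits


def fit_condition_set(
    df: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[list[ObserverFit], pd.DataFrame]:
    """Fit every candidate model per observer × condition.

    Returns the individual fits plus a comparison table with one row per
    (observer, condition, model): AICc, per-observer delta AICc, and the
    across-observer mean AICc delta that a group-level comparison plots.
    Failed fits are carried as flagged rows, never raised.
    """
    config = config or PipelineConfig()
    err = compute_errors(df)
    all_fits: list[ObserverFit] = []
    rows = []
    for (obs, condition), sub in err.groupby(["observer_id", "condition"], sort=True):
        candidates = config.candidates.get(condition, ("standard",))
        roles = _roles_present(sub)
        trials = trial_errors(sub)
        seed_offset = zlib.crc32(f"{obs}|{condition}".encode()) % 10_000
        fit_config = replace(config.fit, seed=config.fit.seed + seed_offset)
        fits = _fit_candidates(trials, roles, candidates, fit_config, obs, condition)
        all_fits.extend(fits)
        comparison = compare_models([f.fit for f in fits])
        for row in comparison:
            rows.append(
                {
                    "observer_id": obs,
                    "condition": condition,
                    "model": row.model,
                    "label": MODEL_LABELS[row.model],
                    "k": row.k,
                    "aicc": row.aicc,
                    "delta_aicc": row.delta_aicc,
                    "is_best": row.is_best,
                    "converged": next(
                        f.fit.converged for f in fits if f.fit.model == row.model
                    ),
                }
            )
    comparison_df = pd.DataFrame(rows)
    if not comparison_df.empty:
        group = (
            comparison_df.groupby(["condition", "model"])["aicc"].mean().rename("mean_aicc")
        )
        comparison_df = comparison_df.merge(group, on=["condition", "model"])
        best_mean = comparison_df.groupby("condition")["mean_aicc"].transform("min")
        comparison_df["mean_delta_aicc"] = comparison_df["mean_aicc"] - best_mean
    return all_fits, comparison_df


def flanker_report_rates(fits: list[ObserverFit]) -> pd.DataFrame:
    """Per-item report rates from independent-misreport fits.

    One row per (observer, condition, role): the fitted beta for each
    flanker role, plus a ``T`` row carrying the target-report rate P_T.
    Only fits of models with independent flanker components are used.
    """
    rows = []
    for of in fits:
        model = get_model(of.fit.model)
        if model.n_flankers == 0:
            continue
        pv = of.fit.params
        rows.append(
            {
                "observer_id": of.observer_id,
                "condition": of.condition,
                "model": of.fit.model,
                "role": "T",
                "rate": pv.p_target,
            }
        )
        for role, beta in zip(of.roles, pv.betas):
            rows.append(
                {
                    "observer_id": of.observer_id,
                    "condition": of.condition,
                    "model": of.fit.model,
                    "role": role,
                    "rate": beta,
                }
            )
    return pd.DataFrame(rows, columns=["observer_id", "condition", "model", "role", "rate"])


def flanker_relative_histogram(df: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    """Histogram of reports around each flanker's value.

    For each flanker role present, bins ``circ_diff(response, flanker)``
    over (−90, 90] with the given bin width. Long-format output:
    (role, bin_left, bin_right, count). Diagnostic / plotting aid only.
    """
    if 180.0 % bin_width:
        raise ValueError("bin_width must divide 180")
    edges = np.arange(-90.0, 90.0 + bin_width, bin_width)
    rows = []
    for role in ROLE_ORDER:
        col = f"ori_{role}"
        if col not in df.columns or not df[col].notna().any():
            continue
        sub = df[df[col].notna()]
        rel = circ_diff(sub["response_ori"].to_numpy(float), sub[col].to_numpy(float))
        # shift the +90 boundary into the last bin (half-open bins from np.histogram)
        rel = np.where(rel == 90.0, np.nextafter(90.0, 0.0), rel)
        counts, _ = np.histogram(rel, bins=edges)
        for i, c in enumerate(counts):
            rows.append(
                {"role": role, "bin_left": edges[i], "bin_right": edges[i + 1], "count": int(c)}
            )
    return pd.DataFrame(rows, columns=["role", "bin_left", "bin_right", "count"])


def _best_fit_rows(fits: list[ObserverFit], err: pd.DataFrame, config: PipelineConfig):
    by_key: dict = {}
    for of in fits:
        by_key.setdefault((of.observer_id, of.condition), []).append(of)
    rows = []
    for (obs, condition), group_fits in sorted(by_key.items(), key=lambda kv: str(kv[0])):
        comparison = compare_models([f.fit for f in group_fits])
        best_name = next(r.model for r in comparison if r.is_best)
        best = next(f for f in group_fits if f.fit.model == best_name)
        sub = err[(err["observer_id"] == obs) & (err["condition"] == condition)]
        moments = circ_moments(sub["theta"].to_numpy(float))
        pv = best.fit.params
        model = get_model(best.fit.model)
        row = {
            "observer_id": obs,
            "condition": condition,
            "n_trials": len(sub),
            "mean_error": moments.linear_mean,
            "precision": precision_summary(sub["theta"].to_numpy(float), config.precision_mode),
            "best_model": best.fit.model,
            "P_T": pv.p_target,
            "gamma": pv.gamma,
            "sigma": pv.sigma,
            "mu": pv.mu if model.has_bias else np.nan,
        }
        for role in ROLE_ORDER:
            row[f"beta_{role}"] = np.nan
        if model.n_flankers > 0:
            for role, beta in zip(best.roles, pv.betas):
                row[f"beta_{role}"] = beta
        elif model.pooled:
            row["beta_pooled"] = pv.betas[0]
        for r in comparison:
            row[f"delta_aicc_{MODEL_LABELS[r.model]}"] = r.delta_aicc
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    df: pd.DataFrame, config: PipelineConfig | None = None, out_dir=None
) -> PipelineResult:
    """Run the full analysis on a canonical trial table.

    Returns per-observer summaries (errors, precision, best model and
    its parameters), the full AICc comparison table, and the per-item
    report-rate table. If ``out_dir`` is given, the three tables are
    written there as CSV along with a small JSON run log.
    """
    config = config or PipelineConfig()
    err = compute_errors(df)
    fits, comparison = fit_condition_set(df, config)
    summary = _best_fit_rows(fits, err, config)
    rates = flanker_report_rates(fits)
    log = {
        "n_trials": int(len(df)),
        "n_observers": int(df["observer_id"].nunique()),
        "conditions": sorted(df["condition"].unique().tolist()),
        "precision_mode": config.precision_mode,
        "fit_seed": config.fit.seed,
        "n_starts": config.fit.n_starts,
    }
    if out_dir is not None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "observer_summary.csv", index=False)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        rates.to_csv(out / "report_rates.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return PipelineResult(summary=summary, comparison=comparison, rates=rates, fits=fits, log=log)
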