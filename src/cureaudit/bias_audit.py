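"""Simulation audit: do models give different groups different diagnosis
probabilities when only diagnostic *timing* differs?

The harness sweeps scenarios (between-group timing gap x administrative
cutoff), fits all four models to each replicate, and tabulates per-group
predicted diagnosis probabilities against the known truth (the configured
event rate, identical in both groups by construction).  Any between-group
gap in the estimates is therefore algorithmic bias induced by the model's
handling of timing and censoring, not a real difference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import comparators, curemodel
from .simcohort import ScenarioConfig, apply_admin_censoring, generate_cohort, group_indicator

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_KINDS",
    "AuditReport",
    "make_lambda2_grid",
    "fast_profile",
    "fit_model",
    "run_simulation_grid",
    "bootstrap_cis",
    "bootstrap_ci",
    "render_report",
]

MODEL_KINDS = ("logistic", "cox", "lognormal", "cure")

_GROUP_ROWS = {1: {"group2": 0.0}, 2: {"group2": 1.0}}


@dataclass
class AuditReport:
    """Long-format estimates plus per-cell summaries.

    ``estimates`` has one row per (scenario, replicate, cutoff, model,
    group) with columns ``estimate`` (the predicted diagnosis probability
    for that group), ``truth`` and optional CI bounds; failed fits keep
    their row with a NaN estimate and a ``reason``.  ``summary``
    aggregates each (scenario, model, cutoff, group) cell: mean estimate,
    bias = mean - truth, replicate SD; ``gaps`` holds the group-1 minus
    group-2 mean gap per (scenario, model, cutoff).
    """

    estimates: pd.DataFrame
    summary: pd.DataFrame
    gaps: pd.DataFrame
    configs: dict

    @property
    def n_failed(self) -> int:
        return int(self.estimates["estimate"].isna().sum())


def make_lambda2_grid(base: ScenarioConfig, lambda2_values=(4.0, 7.0, 10.0)) -> dict:
    """Scenario family varying the delayed group's median time."""
    return {
        f"lambda2={v:g}": replace(base, median_time_g2=float(v))
        for v in lambda2_values
    }


def fast_profile(base: ScenarioConfig | None = None) -> ScenarioConfig:
    """Desk-scale profile: 20 replicates of n=2000 instead of 100 x 10 000."""
    base = base or ScenarioConfig()
    return replace(base, n_subjects=2_000, n_replicates=20)


def fit_model(model_kind: str, cohort: pd.DataFrame, covariates=("group2",),
              cure_options: curemodel.FitOptions | None = None):
    """Fit one of the four audited models to an analytic cohort table."""
    if model_kind == "logistic":
        return comparators.fit_logistic_ever_never(cohort, covariates)
    if model_kind == "cox":
        return comparators.fit_cox_ph(cohort, covariates)
    if model_kind == "lognormal":
        return comparators.fit_lognormal_aft(cohort, covariates)
    if model_kind == "cure":
        design = curemodel.CureDesign(
            incidence_covariates=covariates, latency_covariates=covariates
        )
        return curemodel.fit_mixture_cure(cohort, design,
                                          cure_options or curemodel.FitOptions())
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def run_simulation_grid(scenarios: dict, models=MODEL_KINDS,
                        cutoffs=None, truth=None) -> AuditReport:
    """Run the full audit: generate -> censor -> fit -> predict per group.

    Parameters
    ----------
    scenarios
        Mapping of scenario id -> :class:`ScenarioConfig` (see
        :func:`make_lambda2_grid`).
    models
        Subset of ``("logistic", "cox", "lognormal", "cure")``.
    cutoffs
        Administrative cutoffs; defaults to each config's own grid.
    truth
        True per-group diagnosis probability; defaults to each scenario's
        ``event_rate`` (the simulation ground truth).

    Fully seeded via each config's seed; failed fits are recorded with a
    reason, never silently dropped.
    """
    unknown = set(models) - set(MODEL_KINDS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}")
    rows = []
    for scen_id, config in scenarios.items():
        scen_truth = config.event_rate if truth is None else truth
        scen_cutoffs = tuple(cutoffs) if cutoffs is not None else config.admin_censor_times
        for rep in range(config.n_replicates):
            cohort = group_indicator(generate_cohort(config, rep))
            for cutoff in scen_cutoffs:
                analytic = apply_admin_censoring(cohort, cutoff)
                if analytic["event"].sum() == 0:
                    for model_kind in models:
                        for g in (1, 2):
                            rows.append(_row(scen_id, rep, model_kind, g, cutoff,
                                             np.nan, scen_truth, "no events after cutoff"))
                    continue
                for model_kind in models:
                    try:
                        fit = fit_model(model_kind, analytic)
                        for g in (1, 2):
                            est = comparators.predict_diag_prob(fit, _GROUP_ROWS[g], cutoff)
                            rows.append(_row(scen_id, rep, model_kind, g, cutoff,
                                             est, scen_truth, ""))
                    except Exception as exc:
                        logger.warning("fit failed: %s %s rep=%d cutoff=%g: %s",
                                       scen_id, model_kind, rep, cutoff, exc)
                        for g in (1, 2):
                            rows.append(_row(scen_id, rep, model_kind, g, cutoff,
                                             np.nan, scen_truth, str(exc)))
    columns = ["scenario", "replicate", "model", "group", "admin_cutoff",
               "estimate", "truth", "ci_lower", "ci_upper", "reason"]
    estimates = pd.DataFrame(rows, columns=columns)
    return _build_report(estimates, {k: v.to_dict() for k, v in scenarios.items()})


def _row(scen_id, rep, model_kind, group, cutoff, est, truth, reason):
    return {
        "scenario": scen_id, "replicate": rep, "model": model_kind,
        "group": group, "admin_cutoff": float(cutoff),
        "estimate": est, "truth": float(truth),
        "ci_lower": np.nan, "ci_upper": np.nan, "reason": reason,
    }


def _build_report(estimates: pd.DataFrame, configs: dict) -> AuditReport:
    keys = ["scenario", "model", "admin_cutoff", "group"]
    grp = estimates.groupby(keys, sort=True)["estimate"]
    summary = grp.agg(mean_estimate="mean", sd="std", n_ok="count").reset_index()
    truth = estimates.groupby(keys, sort=True)["truth"].first().reset_index(drop=True)
    summary["truth"] = truth
    summary["bias"] = summary["mean_estimate"] - summary["truth"]
    summary["n_failed"] = (
        estimates.assign(failed=estimates["estimate"].isna())
        .groupby(keys, sort=True)["failed"].sum().to_numpy()
    )
    wide = summary.pivot_table(index=["scenario", "model", "admin_cutoff"],
                               columns="group", values="mean_estimate",
                               dropna=False)
    for g in (1, 2):
        if g not in wide.columns:
            wide[g] = np.nan
    gaps = wide.rename(columns={1: "group1_mean", 2: "group2_mean"}).reset_index()
    gaps["gap"] = gaps["group1_mean"] - gaps["group2_mean"]
    return AuditReport(estimates=estimates, summary=summary, gaps=gaps, configs=configs)


def bootstrap_cis(cohort: pd.DataFrame, model_kind: str, cutoff: float,
                  n_boot: int = 1000, seed: int = 0, alpha: float = 0.05,
                  covariates=("group2",)) -> dict:
    """Percentile bootstrap CIs of the per-group diagnosis probability.

    Subjects are resampled with replacement at full cohort size
    (unstratified); the model is refit on each resample after the same
    administrative cutoff, and the 2.5/97.5 percentiles taken per group.
    Returns ``{group: (lo, hi)}`` plus ``"n_failed"`` and ``"unreliable"``
    (True when more than 20% of resample fits failed).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    analytic = apply_admin_censoring(cohort, cutoff)
    warm = None
    cure_opts = None
    if model_kind == "cure":
        # warm-start resample fits from the full-data optimum
        base_fit = fit_model("cure", analytic, covariates)
        warm = base_fit.params
        cure_opts = curemodel.FitOptions(init_params=warm, compute_covariance=False,
                                         gtol=1e-5)
    n = len(analytic)
    draws = {1: [], 2: []}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = analytic.iloc[idx].reset_index(drop=True)
        try:
            fit = fit_model(model_kind, sample, covariates, cure_options=cure_opts)
            for g in (1, 2):
                draws[g].append(comparators.predict_diag_prob(fit, _GROUP_ROWS[g], cutoff))
        except Exception:
            n_failed += 1
    out = {"n_failed": n_failed, "unreliable": n_failed > 0.2 * n_boot}
    for g in (1, 2):
        if draws[g]:
            lo, hi = np.percentile(draws[g], [100 * alpha / 2, 100 * (1 - alpha / 2)])
            out[g] = (float(lo), float(hi))
        else:
            out[g] = (np.nan, np.nan)
    if out["unreliable"]:
        logger.warning("bootstrap: %d/%d resample fits failed; CI unreliable",
                       n_failed, n_boot)
    return out


def bootstrap_ci(cohort: pd.DataFrame, model_kind: str, group: int, cutoff: float,
                 n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Single-group convenience wrapper around :func:`bootstrap_cis`."""
    return bootstrap_cis(cohort, model_kind, cutoff, n_boot=n_boot, seed=seed)[group]


def render_report(report: AuditReport, out_dir) -> list:
    """Write tidy estimates, summaries, KM curves and bias panels.

    Deterministic file naming; returns the list of paths written.
    KM curves are computed on replicate 0 of each scenario before any
    administrative cutoff, mirroring how the audit's survival-curve
    figures are drawn.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "estimates.csv"
    report.estimates.to_csv(p, index=False)
    written.append(p)
    p = out / "summary.csv"
    report.summary.to_csv(p, index=False)
    written.append(p)

    km_rows = []
    for scen_id, cfg_dict in report.configs.items():
        config = ScenarioConfig(**{**cfg_dict, "admin_censor_times":
                                   tuple(cfg_dict["admin_censor_times"])})
        cohort = generate_cohort(config, 0)
        for curve in comparators.kaplan_meier(cohort, by_group=True):
            frame = curve.to_frame()
            frame.insert(0, "scenario", scen_id)
            km_rows.append(frame)
    if km_rows:
        p = out / "km_curves.csv"
        pd.concat(km_rows, ignore_index=True).to_csv(p, index=False)
        written.append(p)

    models = sorted(report.summary["model"].unique())
    if models:
        for scen_id, sub in report.summary.groupby("scenario"):
            cutoffs = sorted(sub["admin_cutoff"].unique())
            fig, axes = plt.subplots(len(models), len(cutoffs),
                                     figsize=(3 * len(cutoffs), 2.2 * len(models)),
                                     squeeze=False, sharey=True)
            for i, model in enumerate(models):
                for j, cutoff in enumerate(cutoffs):
                    ax = axes[i][j]
                    cell = report.estimates.query(
                        "scenario == @scen_id and model == @model "
                        "and admin_cutoff == @cutoff"
                    )
                    data = [cell.loc[cell["group"] == g, "estimate"].dropna()
                            for g in (1, 2)]
                    ax.boxplot(data, tick_labels=["g1", "g2"])
                    ax.axhline(cell["truth"].iloc[0] if len(cell) else np.nan,
                               ls="--", color="grey")
                    if j == 0:
                        ax.set_ylabel(model)
                    if i == 0:
                        ax.set_title(f"cutoff={cutoff:g}")
            fig.suptitle(f"Predicted diagnosis probability by group — {scen_id}")
            fig.tight_layout()
            p = out / f"bias_panel_{scen_id.replace('=', '_')}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    p = out / "run_metadata.json"
    with open(p, "w") as fh:
        json.dump({"configs": report.configs, "n_failed": report.n_failed},
                  fh, indent=2)
    written.append(p)
    return written
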