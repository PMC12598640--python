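"""Synthetic two-group cohort generator with a cured/susceptible mixture.

The data-generating process mirrors the simulation design used to study
diagnosis-timing bias: a fixed fraction of subjects ("susceptible") will
eventually experience the event, the rest ("cured") never do.  Susceptible
event times are log-normal with a group-specific median, so a delayed-timing
group can be induced without changing the ultimate event rate.  Loss to
follow-up is uniform on (0, censor_upper); administrative study cutoffs are
applied afterwards with :func:`apply_admin_censoring`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "generate_cohort",
    "apply_admin_censoring",
    "summarize_cohort",
    "group_indicator",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "susceptible",
    "true_event_time",
    "censor_time",
    "observed_time",
    "event",
]


class ConfigError(ValueError):
    """Raised when a scenario configuration field is invalid."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario.

    Parameters
    ----------
    n_subjects
        Cohort size per replicate.
    group_fraction
        Proportion of subjects assigned to group 1 (default 0.5).
    event_rate
        Proportion susceptible to the event, identical in both groups.
        The cured fraction is ``1 - event_rate``.
    median_time_g1, median_time_g2
        Median event time (time units, e.g. years) among susceptible
        subjects in group 1 / group 2.  Equal medians give the null
        (no timing difference) scenario.
    log_scale_sigma
        Standard deviation of log event time (log-normal shape).
    censor_upper
        Upper bound of the Uniform(0, b) loss-to-follow-up distribution.
    admin_censor_times
        Strictly increasing grid of administrative study cutoffs.
    n_replicates
        Number of independent replicate datasets the scenario comprises.
    seed
        Root seed; replicate ``r`` uses the substream ``(seed, r)``.
    bernoulli_groups
        If True, group membership is Bernoulli(1 - group_fraction) per
        subject; by default groups are assigned by deterministic
        interleaving so group sizes are exact.
    """

    n_subjects: int = 10_000
    group_fraction: float = 0.5
    event_rate: float = 0.25
    median_time_g1: float = 4.0
    median_time_g2: float = 4.0
    log_scale_sigma: float = 0.5
    censor_upper: float = 12.0
    admin_censor_times: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0)
    n_replicates: int = 100
    seed: int = 0
    bernoulli_groups: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects > 0):
            raise ConfigError(f"n_subjects must be a positive integer, got {self.n_subjects!r}")
        if not 0.0 < self.group_fraction < 1.0:
            raise ConfigError(f"group_fraction must be in (0, 1), got {self.group_fraction!r}")
        if not 0.0 < self.event_rate < 1.0:
            raise ConfigError(f"event_rate must be in (0, 1), got {self.event_rate!r}")
        for name in ("median_time_g1", "median_time_g2", "log_scale_sigma", "censor_upper"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ConfigError(f"{name} must be a positive real, got {val!r}")
        times = tuple(float(t) for t in self.admin_censor_times)
        if len(times) == 0 or any(t <= 0 for t in times):
            raise ConfigError(f"admin_censor_times must be positive, got {times!r}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError(f"admin_censor_times must be strictly increasing, got {times!r}")
        object.__setattr__(self, "admin_censor_times", times)
        if not (isinstance(self.n_replicates, (int, np.integer)) and self.n_replicates > 0):
            raise ConfigError(f"n_replicates must be a positive integer, got {self.n_replicates!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "admin_censor_times" in raw:
            raw["admin_censor_times"] = tuple(raw["admin_censor_times"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["admin_censor_times"] = list(d["admin_censor_times"])
        return d


def _interleaved_groups(n: int, fraction_g1: float) -> np.ndarray:
    """Exact-count group labels: subject i is group 1 when the running
    quota floor(fraction*(i+1)) increments, giving an interleaved pattern
    with exactly round-off-free counts."""
    i = np.arange(n)
    quota = np.floor(fraction_g1 * (i + 1)) - np.floor(fraction_g1 * i)
    return np.where(quota > 0, 1, 2).astype(np.int64)


def generate_cohort(config: ScenarioConfig, replicate_index: int = 0) -> pd.DataFrame:
    """Draw one replicate cohort under ``config``.

    Reproducible: the RNG stream is derived from ``(config.seed,
    replicate_index)`` only.  Cured subjects carry ``true_event_time =
    +inf``.  The ``event`` flag and ``observed_time`` reflect loss to
    follow-up only; administrative cutoffs are applied separately.
    """
    if not 0 <= replicate_index < config.n_replicates:
        raise ConfigError(
            f"replicate_index must be in [0, {config.n_replicates}), got {replicate_index}"
        )
    rng = np.random.default_rng([int(config.seed), int(replicate_index)])
    n = config.n_subjects

    if config.bernoulli_groups:
        group = np.where(rng.random(n) < config.group_fraction, 1, 2).astype(np.int64)
    else:
        group = _interleaved_groups(n, config.group_fraction)

    susceptible = rng.random(n) < config.event_rate
    medians = np.where(group == 1, config.median_time_g1, config.median_time_g2)
    log_t = rng.normal(np.log(medians), config.log_scale_sigma)
    true_event_time = np.where(susceptible, np.exp(log_t), np.inf)
    censor_time = rng.uniform(0.0, config.censor_upper, n)

    observed_time = np.minimum(true_event_time, censor_time)
    event = (true_event_time <= censor_time).astype(np.int8)

    return pd.DataFrame(
        {
            "subject_id": np.arange(n, dtype=np.int64),
            "group": group,
            "susceptible": susceptible,
            "true_event_time": true_event_time,
            "censor_time": censor_time,
            "observed_time": observed_time,
            "event": event,
        }
    )


def apply_admin_censoring(cohort: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Truncate follow-up at an administrative study cutoff.

    Observed times are capped at ``cutoff`` and events occurring after the
    cutoff are recoded as censored.  Idempotent, and composing two cutoffs
    equals applying the smaller one.
    """
    if not (np.isfinite(cutoff) and cutoff > 0):
        raise ValueError(f"cutoff must be a positive real, got {cutoff!r}")
    out = cohort.copy()
    late = out["observed_time"] > cutoff
    out.loc[late, "event"] = 0
    out["event"] = out["event"].astype(np.int8)
    out["observed_time"] = np.minimum(out["observed_time"], cutoff)
    return out


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Event / censoring rates and per-group breakdown for one cohort."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ev = cohort["event"].astype(float)
    per_group = cohort.groupby("group")["event"].agg(["mean", "size"])
    return {
        "n": int(len(cohort)),
        "event_rate": float(ev.mean()),
        "censoring_rate": float(1.0 - ev.mean()),
        "median_observed_time": float(cohort["observed_time"].median()),
        "group_sizes": {int(g): int(r["size"]) for g, r in per_group.iterrows()},
        "group_event_rates": {int(g): float(r["mean"]) for g, r in per_group.iterrows()},
    }


def group_indicator(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a 0/1 ``group2`` indicator column (1 = group 2),
    the covariate coding used by all model fits."""
    out = cohort.copy()
    out["group2"] = (out["group"] == 2).astype(float)
    return out


def write_cohort_csv(cohort: pd.DataFrame, path, config: ScenarioConfig | None = None,
                     replicate_index: int | None = None) -> None:
    """Write a cohort CSV (cured subjects' true_event_time serialized as
    empty) plus a JSON metadata sidecar when a config is supplied."""
    out = cohort.copy()
    out["true_event_time"] = out["true_event_time"].replace(np.inf, np.nan)
    out.to_csv(path, index=False, columns=COHORT_COLUMNS)
    if config is not None:
        from . import __version__

        meta = {
            "config": config.to_dict(),
            "replicate_index": replicate_index,
            "package_version": __version__,
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV; empty true_event_time means cured (+inf)."""
    df = pd.read_csv(path)
    df["true_event_time"] = df["true_event_time"].fillna(np.inf)
    df["susceptible"] = df["susceptible"].astype(bool)
    df["event"] = df["event"].astype(np.int8)
    return df
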