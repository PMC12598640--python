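"""Synthetic administrative-claims emulator and computable-phenotype pipeline.

Real claims data behind studies of diagnosis timing are not shareable, so
this module emulates their *structure*: a long-format stream of
(person_id, service_date, dx_code) claim lines plus enrollment spans, from
which a case/non-case cohort is built with a computable phenotype — at
least ``min_code_count`` qualifying diagnosis codes, event time at the
first code, censoring at disenrollment or the database end.

The latent event process reuses the cured/susceptible mixture from
:mod:`cureaudit.simcohort`, so timing differences between groups and the
true (latent) case status are known and retained for validation.
Group labels are abstract (1/2): the methodological point concerns any
grouping with timing differences, so no demographic attributes are
synthesized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simcohort import ScenarioConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeSpec",
    "ClaimsGenConfig",
    "generate_synthetic_claims",
    "build_cohort",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class PhenotypeSpec:
    """A computable phenotype over coded claims.

    A person is a case when at least ``min_code_count`` claims carry a
    code in ``code_set``; the event time is the date of the first
    qualifying code.  The shipped default code set is a synthetic
    placeholder list, not any published phenotype.
    """

    code_set: frozenset = frozenset({"F84.0", "F84.5", "F84.9"})
    min_code_count: int = 2
    event_time_rule: str = "first_code"

    def __post_init__(self):
        object.__setattr__(self, "code_set", frozenset(self.code_set))
        if len(self.code_set) == 0:
            raise ValueError("code_set must be non-empty")
        if self.min_code_count < 1:
            raise ValueError("min_code_count must be >= 1")
        if self.event_time_rule != "first_code":
            raise ValueError("only the first_code event-time rule is supported")

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "code_set" in raw:
            raw["code_set"] = frozenset(raw["code_set"])
        return cls(**raw)


@dataclass(frozen=True)
class ClaimsGenConfig:
    """Settings of the synthetic claims stream around the latent cohort.

    Births are uniform over ``birth_year``.  Enrollment must begin within
    ``enroll_within_days`` of birth and run continuously through
    ``continuous_through_days`` for a person to satisfy the cohort
    filters; small fractions of rule-violators are injected so the
    filters have work to do.  ``noise_code_rate`` is the probability that
    a non-case accrues a single (sub-threshold) qualifying code.
    """

    birth_year: int = 2014
    database_end: str = "2023-12-31"
    enroll_within_days: int = 31
    continuous_through_days: int = 548      # 18 months
    late_enroll_fraction: float = 0.03
    early_disenroll_fraction: float = 0.03
    noise_code_rate: float = 0.05
    second_code_gap_days: tuple[int, int] = (7, 90)


def _dates(birth: pd.Series, age_years) -> pd.Series:
    return birth + pd.to_timedelta(np.asarray(age_years) * DAYS_PER_YEAR, unit="D")


def generate_synthetic_claims(
    cohort_config: ScenarioConfig,
    phenotype_spec: PhenotypeSpec | None = None,
    seed: int = 0,
    gen_config: ClaimsGenConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit (claims, spans, truth) tables for a synthetic claims database.

    True cases — susceptible subjects whose latent diagnosis falls inside
    their coverage — receive ``min_code_count`` qualifying claims with
    the first at the simulated diagnosis date; non-cases receive at most
    one noise code.  The truth table records, per person, the latent
    state and the cohort row (group, observed age, event flag) the
    phenotype pipeline is expected to reconstruct.
    """
    spec = phenotype_spec or PhenotypeSpec()
    gcfg = gen_config or ClaimsGenConfig()
    rng = np.random.default_rng([int(seed), 7])
    latent = generate_cohort(cohort_config, 0)
    n = len(latent)
    codes = sorted(spec.code_set)

    birth = (pd.Timestamp(f"{gcfg.birth_year}-01-01")
             + pd.to_timedelta(rng.integers(0, 365, n), unit="D"))
    database_end = pd.Timestamp(gcfg.database_end)

    # enrollment: start within the required window except for injected
    # late enrollees; disenrollment at the latent censor age, floored at
    # the continuous-coverage requirement except for early dropouts
    start_offset = rng.integers(0, gcfg.enroll_within_days + 1, n)
    late = rng.random(n) < gcfg.late_enroll_fraction
    start_offset = np.where(late, gcfg.enroll_within_days + 1
                            + rng.integers(0, 120, n), start_offset)
    min_cov_years = gcfg.continuous_through_days / DAYS_PER_YEAR
    disenroll_age = np.maximum(latent["censor_time"].to_numpy(), min_cov_years + 1e-9)
    early = rng.random(n) < gcfg.early_disenroll_fraction
    disenroll_age = np.where(early, rng.uniform(0.2, min_cov_years * 0.95, n),
                             disenroll_age)
    span_start = birth + pd.to_timedelta(start_offset, unit="D")
    span_end = _dates(pd.Series(birth), disenroll_age).clip(upper=database_end)

    spans = pd.DataFrame({
        "person_id": latent["subject_id"],
        "birth_date": birth,
        "span_start": span_start,
        "span_end": span_end,
        "group": latent["group"],
    })

    db_end_age = (database_end - birth).days / DAYS_PER_YEAR
    censor_age = np.minimum(disenroll_age, db_end_age)
    diag_age = latent["true_event_time"].to_numpy()
    gap_years = rng.integers(gcfg.second_code_gap_days[0],
                             gcfg.second_code_gap_days[1] + 1, n) / DAYS_PER_YEAR

    passes_filters = (~late) & (disenroll_age >= min_cov_years)
    first_in = diag_age <= censor_age
    # the phenotype needs all min_code_count codes inside coverage
    last_code_age = diag_age + gap_years * (spec.min_code_count - 1)
    fully_coded = first_in & (last_code_age <= censor_age)

    claim_rows = []
    for i in np.flatnonzero(first_in):
        ages = diag_age[i] + gap_years[i] * np.arange(spec.min_code_count)
        ages = ages[ages <= censor_age[i]]
        for k, age in enumerate(ages):
            claim_rows.append((int(latent["subject_id"].iloc[i]),
                               birth[i] + pd.to_timedelta(age * DAYS_PER_YEAR, unit="D"),
                               codes[k % len(codes)]))
    noise = (~first_in) & (rng.random(n) < gcfg.noise_code_rate)
    for i in np.flatnonzero(noise):
        age = rng.uniform(0.1, max(censor_age[i], 0.2))
        claim_rows.append((int(latent["subject_id"].iloc[i]),
                           birth[i] + pd.to_timedelta(age * DAYS_PER_YEAR, unit="D"),
                           codes[int(rng.integers(0, len(codes)))]))
    claims = pd.DataFrame(claim_rows,
                          columns=["person_id", "service_date", "dx_code"])
    claims = claims.sort_values(["person_id", "service_date"]).reset_index(drop=True)

    truth = pd.DataFrame({
        "person_id": latent["subject_id"],
        "group": latent["group"],
        "susceptible": latent["susceptible"],
        "true_event_time": diag_age,
        "passes_filters": passes_filters,
        "event": (fully_coded).astype(np.int8),
        "observed_time": np.where(fully_coded, diag_age, censor_age),
    })
    return claims, spans, truth


def build_cohort(
    claims: pd.DataFrame,
    spans: pd.DataFrame,
    phenotype_spec: PhenotypeSpec | None = None,
    database_end: str | pd.Timestamp = "2023-12-31",
    attrition: dict | None = None,
) -> pd.DataFrame:
    """Apply enrollment filters and the computable phenotype.

    Filters: enrolled within 31 days of birth and a single span covering
    through 18 months (zero gap tolerance).  Cases have at least
    ``min_code_count`` qualifying codes within coverage; event time is
    the age (in years, using 365.25-day years) at the first qualifying
    code, censoring age at min(span end, database end).  Emits the same
    cohort schema the model modules consume; exclusion counts go to the
    ``attrition`` dict (and the log) rather than being silent.
    """
    spec = phenotype_spec or PhenotypeSpec()
    database_end = pd.Timestamp(database_end)
    attr = attrition if attrition is not None else {}

    orphans = set(claims["person_id"]) - set(spans["person_id"])
    attr["claims_without_span"] = len(orphans)
    if orphans:
        logger.warning("%d persons have claims but no enrollment span; excluded",
                       len(orphans))

    s = spans.copy()
    attr["total"] = len(s)
    enroll_ok = (s["span_start"] - s["birth_date"]).dt.days <= 31
    attr["excluded_late_enrollment"] = int((~enroll_ok).sum())
    s = s[enroll_ok]
    cont_ok = (s["span_end"] - s["birth_date"]).dt.days >= 548
    attr["excluded_short_enrollment"] = int((~cont_ok).sum())
    s = s[cont_ok]
    attr["analytic"] = len(s)

    coverage_end = s.set_index("person_id")[["birth_date", "span_end"]]
    coverage_end["cov_end"] = coverage_end["span_end"].clip(upper=database_end)

    qual = claims[claims["dx_code"].isin(spec.code_set)].merge(
        coverage_end.reset_index()[["person_id", "birth_date", "cov_end"]],
        on="person_id", how="inner",
    )
    qual = qual[qual["service_date"] <= qual["cov_end"]]
    counts = qual.groupby("person_id").agg(
        n_codes=("dx_code", "size"), first_code=("service_date", "min")
    )

    out = s[["person_id", "group", "birth_date", "span_end"]].merge(
        counts, on="person_id", how="left"
    )
    out["n_codes"] = out["n_codes"].fillna(0).astype(int)
    is_case = out["n_codes"] >= spec.min_code_count
    censor_age = ((out["span_end"].clip(upper=database_end) - out["birth_date"])
                  .dt.days / DAYS_PER_YEAR)
    event_age = (out["first_code"] - out["birth_date"]).dt.days / DAYS_PER_YEAR

    cohort = pd.DataFrame({
        "subject_id": out["person_id"].to_numpy(),
        "group": out["group"].to_numpy(),
        "censor_time": censor_age.to_numpy(),
        "observed_time": np.where(is_case, event_age, censor_age),
        "event": is_case.astype(np.int8).to_numpy(),
    })
    cohort["observed_time"] = cohort["observed_time"].clip(lower=1e-6)
    return cohort.reset_index(drop=True)
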