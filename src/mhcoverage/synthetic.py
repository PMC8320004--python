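"""Synthetic Atlas-style cohorts with known ground truth.

No country microdata underlying service-coverage reporting are public, so
every stage of the pipeline is exercised against generated data whose
truth is known.  The generator emulates the *structure* of country
reports, not the 2017 country distribution:

* a country's treated population is drawn patient-by-patient from its
  true coverage of the expected prevalent pool;
* treated persons split into inpatient and outpatient users, and each
  inpatient independently receives an outpatient follow-up with the
  country's true follow-up fraction — those individuals appear in *both*
  facility tallies, exactly the double-counting the pipeline corrects;
* per-case visit rates are at least one for clean reporters, so the
  visits-per-case screen can only fire on corrupted strata;
* corrupted strata: ``incomplete`` reporters omit a required field
  (caught by the completeness screen); ``visits_mistaken_as_cases``
  reporters put visit counts in the case columns, inflating coverage past
  any admissible upper threshold (caught by the threshold filter).  The
  latter corruption is only assigned to bipolar and depression by
  default: psychosis carries no upper threshold, so the failure mode is
  structurally undetectable there.

Ground truth is emitted alongside the data and never leaks into the
pipeline inputs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_ingest import (AtlasRecord, CountryContext, Disorder, IncomeGroup,
                           WHO_REGIONS)
from .coverage import inverse_logit
from .expected_cases import (AdjustmentConstants, PrevalenceEstimate,
                             TimeFrame)

#: GBD super-regions with two representative world regions each.
GBD_GEOGRAPHY: dict[str, tuple[str, str]] = {
    "Central Europe, Eastern Europe, and Central Asia":
        ("Central Asia", "Eastern Europe"),
    "High-income": ("Western Europe", "High-income North America"),
    "Latin America and Caribbean": ("Andean Latin America", "Caribbean"),
    "North Africa and Middle East":
        ("North Africa and Middle East", "North Africa and Middle East B"),
    "South Asia": ("South Asia", "South Asia B"),
    "Southeast Asia, East Asia, and Oceania": ("East Asia", "Southeast Asia"),
    "Sub-Saharan Africa":
        ("Eastern Sub-Saharan Africa", "Western Sub-Saharan Africa"),
}

#: Mean contact coverage per (disorder, income group) used as the centre of
#: the between-country distribution on the logit scale.  Values follow the
#: income-group means reported for specialist-service contact coverage of
#: the three disorders.
DEFAULT_COVERAGE_MEANS: dict[tuple[Disorder, IncomeGroup], float] = {
    (Disorder.PSYCHOSIS, IncomeGroup.LOW): 0.109,
    (Disorder.PSYCHOSIS, IncomeGroup.LOWER_MIDDLE): 0.215,
    (Disorder.PSYCHOSIS, IncomeGroup.UPPER_MIDDLE): 0.292,
    (Disorder.PSYCHOSIS, IncomeGroup.HIGH): 0.595,
    (Disorder.BIPOLAR, IncomeGroup.LOW): 0.031,
    (Disorder.BIPOLAR, IncomeGroup.LOWER_MIDDLE): 0.035,
    (Disorder.BIPOLAR, IncomeGroup.UPPER_MIDDLE): 0.031,
    (Disorder.BIPOLAR, IncomeGroup.HIGH): 0.104,
    (Disorder.DEPRESSION, IncomeGroup.LOW): 0.029,
    (Disorder.DEPRESSION, IncomeGroup.LOWER_MIDDLE): 0.043,
    (Disorder.DEPRESSION, IncomeGroup.UPPER_MIDDLE): 0.130,
    (Disorder.DEPRESSION, IncomeGroup.HIGH): 0.311,
}

#: Mean prevalence in the convention the burden-of-disease inputs use:
#: point prevalence of schizophrenia, 12-month prevalence of bipolar
#: disorder, point prevalence of all-severity depression.
DEFAULT_PREVALENCE_MEANS: dict[Disorder, float] = {
    Disorder.PSYCHOSIS: 0.003,
    Disorder.BIPOLAR: 0.006,
    Disorder.DEPRESSION: 0.035,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic cohorts.

    Defaults describe a world of mixed-income countries whose service
    systems are mostly outpatient-prioritised, with modest reporting
    corruption; see the package methods note for the rationale of each
    value.
    """

    disorders: tuple[Disorder, ...] = (
        Disorder.PSYCHOSIS, Disorder.BIPOLAR, Disorder.DEPRESSION)
    coverage_means: dict[tuple[Disorder, IncomeGroup], float] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_MEANS))
    coverage_logit_sd: float = 1.0
    prevalence_means: dict[Disorder, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_MEANS))
    prevalence_log_sd: float = 0.3
    prevalence_rel_halfwidth: float = 0.10
    prevalence_error_realized: bool = True
    inpatient_share_range: tuple[float, float] = (0.05, 0.40)
    followup_range: tuple[float, float] = (0.02, 0.98)
    followup_missing_rate: float = 0.15
    representativeness_range: tuple[float, float] = (0.6, 1.0)
    population_range: tuple[float, float] = (1e6, 1e8)
    population_missing_rate: float = 0.10
    population_divergent_rate: float = 0.05
    incomplete_rate: float = 0.08
    visits_as_cases_rate: float = 0.08
    visits_as_cases_disorders: tuple[Disorder, ...] = (
        Disorder.BIPOLAR, Disorder.DEPRESSION)
    corrupted_visit_rate_range: tuple[float, float] = (12.0, 52.0)
    constants: AdjustmentConstants = field(default_factory=AdjustmentConstants)

    def __post_init__(self) -> None:
        for lo, hi, name in (
                (*self.inpatient_share_range, "inpatient_share_range"),
                (*self.followup_range, "followup_range"),
                (*self.representativeness_range, "representativeness_range")):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered pair in [0, 1]")
        for rate in (self.followup_missing_rate, self.population_missing_rate,
                     self.population_divergent_rate, self.incomplete_rate,
                     self.visits_as_cases_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("corruption/missingness rates must be "
                                 "probabilities")
        if self.incomplete_rate + self.visits_as_cases_rate > 1.0:
            raise ValueError("corruption rates sum above 1")


def _country_code(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return (letters[i // 676 % 26] + letters[i // 26 % 26] + letters[i % 26])


def followup_category_of(fraction: float) -> int:
    """The reporting bin containing a true follow-up fraction."""
    if fraction <= 0.25:
        return 1
    if fraction <= 0.50:
        return 2
    if fraction <= 0.75:
        return 3
    return 4


@dataclass
class SyntheticCohort:
    """Generated inputs plus their ground truth."""

    records: list[AtlasRecord]
    contexts: dict[str, CountryContext]
    prevalences: dict[tuple[str, Disorder], PrevalenceEstimate]
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialise the four tables as CSV; missing cells become empty."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "atlas": out / "atlas_records.csv",
            "context": out / "country_context.csv",
            "prevalence": out / "prevalence.csv",
            "truth": out / "truth.csv",
        }

        def cell(v) -> str:
            if v is None:
                return ""
            if isinstance(v, float) and v.is_integer() and abs(v) < 1e15:
                return str(int(v))
            return str(v.value) if hasattr(v, "value") else str(v)

        with paths["atlas"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("country_code", "disorder", "inpatient_cases",
                        "outpatient_cases", "inpatient_visits",
                        "outpatient_visits", "representativeness",
                        "followup_category", "reported_population"))
            for r in self.records:
                w.writerow(map(cell, (
                    r.country_code, r.disorder, r.inpatient_cases,
                    r.outpatient_cases, r.inpatient_visits,
                    r.outpatient_visits, r.representativeness,
                    r.followup_category, r.reported_population)))
        with paths["context"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("country_code", "income_group", "who_region",
                        "gbd_region", "gbd_super_region", "un_population"))
            for ctx in self.contexts.values():
                w.writerow(map(cell, (
                    ctx.country_code, ctx.income_group, ctx.who_region,
                    ctx.gbd_region, ctx.gbd_super_region,
                    ctx.un_population)))
        with paths["prevalence"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("country_code", "disorder", "rate", "lower95",
                        "upper95", "time_frame"))
            for prev in self.prevalences.values():
                w.writerow(map(cell, (
                    prev.country_code, prev.disorder, prev.rate,
                    prev.lower95, prev.upper95, prev.time_frame)))
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def simulate_patient_level(n_expected: int, coverage: float,
                           inpatient_share: float, followup_fraction: float,
                           rng: np.random.Generator,
                           ) -> tuple[int, int, int]:
    """Agent-level registry simulation for one country × disorder.

    Each prevalent person independently contacts services with probability
    ``coverage``; each treated person is an inpatient with probability
    ``inpatient_share``; each inpatient receives an outpatient follow-up
    with probability ``followup_fraction`` and then appears in *both*
    facility tallies.  Returns ``(unique_persons, inpatient_tally,
    outpatient_tally)`` exactly as a registry without a unique patient
    identifier would report them.
    """
    treated = int(np.count_nonzero(rng.random(n_expected) < coverage))
    inpatient = int(np.count_nonzero(rng.random(treated) < inpatient_share))
    followed_up = int(np.count_nonzero(
        rng.random(inpatient) < followup_fraction))
    outpatient = (treated - inpatient) + followed_up
    return treated, inpatient, outpatient


def generate_cohort(n_countries: int,
                    config: GeneratorConfig | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Generate a deterministic synthetic world of country reports."""
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    income_groups = list(IncomeGroup)
    super_regions = list(GBD_GEOGRAPHY)
    constants = config.constants
    dep_split = (constants.depression_moderate_prop.value
                 + constants.depression_severe_prop.value)

    records: list[AtlasRecord] = []
    contexts: dict[str, CountryContext] = {}
    prevalences: dict[tuple[str, Disorder], PrevalenceEstimate] = {}
    truth_rows: list[dict] = []

    for i in range(n_countries):
        code = _country_code(i)
        income = income_groups[i % len(income_groups)]
        who_region = WHO_REGIONS[i % len(WHO_REGIONS)]
        super_region = super_regions[i % len(super_regions)]
        gbd_region = GBD_GEOGRAPHY[super_region][(i // len(super_regions)) % 2]
        lo, hi = config.population_range
        un_pop = float(round(10 ** rng.uniform(math.log10(lo),
                                               math.log10(hi))))
        if rng.random() < config.population_missing_rate:
            reported_pop = None
        elif rng.random() < config.population_divergent_rate:
            reported_pop = float(round(un_pop * rng.uniform(1.5, 4.0)))
        else:
            reported_pop = float(round(un_pop * rng.uniform(0.98, 1.02)))
        contexts[code] = CountryContext(
            country_code=code, income_group=income, who_region=who_region,
            gbd_region=gbd_region, gbd_super_region=super_region,
            un_population=un_pop)

        for disorder in config.disorders:
            base_rate = (config.prevalence_means[disorder]
                         * float(rng.lognormal(0.0, config.prevalence_log_sd)))
            hw = config.prevalence_rel_halfwidth
            time_frame = (TimeFrame.TWELVE_MONTH
                          if disorder is Disorder.BIPOLAR else TimeFrame.POINT)
            prevalences[(code, disorder)] = PrevalenceEstimate(
                country_code=code, disorder=disorder, rate=base_rate,
                lower95=base_rate * (1 - hw), upper95=base_rate * (1 + hw),
                time_frame=time_frame)
            # The reported estimate is a noisy measurement of the true
            # prevalence: the country's true rate deviates from it by a
            # log-normal error matching the stated 95% interval, so stated
            # standard errors describe realised error.
            if config.prevalence_error_realized:
                true_rate = base_rate * float(
                    rng.lognormal(0.0, hw / 1.959964))
            else:
                true_rate = base_rate
            # Treatable 12-month prevalence after case-definition adjustment.
            if disorder is Disorder.PSYCHOSIS:
                p_adj = true_rate / constants.schiz_to_psychosis_ratio
            elif disorder is Disorder.DEPRESSION:
                p_adj = (true_rate * constants.depression_point_to_12m_factor
                         * dep_split)
            else:
                p_adj = true_rate

            mean_cov = config.coverage_means[(disorder, income)]
            true_cov = inverse_logit(
                math.log(mean_cov / (1 - mean_cov))
                + config.coverage_logit_sd * float(rng.standard_normal()))
            repr_frac = float(rng.uniform(*config.representativeness_range))
            followup = float(rng.uniform(*config.followup_range))
            category: int | None = followup_category_of(followup)
            if rng.random() < config.followup_missing_rate:
                category = None

            n_expected = max(1, int(round(p_adj * un_pop * repr_frac)))
            treated = int(rng.binomial(n_expected, true_cov))
            inpatient = int(rng.binomial(
                treated, rng.uniform(*config.inpatient_share_range)))
            followed_up = int(rng.binomial(inpatient, followup))
            outpatient = (treated - inpatient) + followed_up

            u = rng.random()
            if u < config.incomplete_rate:
                quality = "incomplete"
            elif (u < config.incomplete_rate + config.visits_as_cases_rate
                  and disorder in config.visits_as_cases_disorders):
                quality = "visits_mistaken_as_cases"
            else:
                quality = "cases"

            in_cases: int | None = inpatient
            out_cases: int | None = outpatient
            representativeness: float | None = repr_frac
            if quality == "cases":
                in_visits = (0 if inpatient == 0 else
                             math.ceil(inpatient * (1 + rng.gamma(2.0, 2.0))))
                out_visits = (0 if outpatient == 0 else
                              math.ceil(outpatient * (1 + rng.gamma(2.0, 2.0))))
                if treated == 0:
                    in_visits = out_visits = None  # nothing used, none logged
            elif quality == "visits_mistaken_as_cases":
                # Visit volumes exceed the prevalent pool by construction, so
                # the inflated "coverage" always trips an upper threshold.
                rate = max(float(rng.uniform(
                    *config.corrupted_visit_rate_range)), 1.2 / true_cov)
                in_cases = math.ceil(inpatient * rate)
                out_cases = max(math.ceil(outpatient * rate),
                                math.ceil(1.2 * n_expected))
                in_visits, out_visits = in_cases, out_cases
            else:  # incomplete
                drop = ("inpatient_cases", "outpatient_cases",
                        "representativeness")[int(rng.integers(3))]
                if drop == "inpatient_cases":
                    in_cases = None
                elif drop == "outpatient_cases":
                    out_cases = None
                else:
                    representativeness = None
                in_visits = (0 if inpatient == 0 else
                             math.ceil(inpatient * (1 + rng.gamma(2.0, 2.0))))
                out_visits = (0 if outpatient == 0 else
                              math.ceil(outpatient * (1 + rng.gamma(2.0, 2.0))))

            records.append(AtlasRecord(
                country_code=code, disorder=disorder,
                inpatient_cases=in_cases, outpatient_cases=out_cases,
                inpatient_visits=in_visits, outpatient_visits=out_visits,
                representativeness=representativeness,
                followup_category=category,
                reported_population=reported_pop))
            truth_rows.append({
                "country_code": code,
                "disorder": disorder.value,
                "true_coverage": true_cov,
                "true_prevalence": p_adj,
                "true_followup_fraction": followup,
                "population": un_pop,
                "income_group": income.value,
                "who_region": who_region,
                "gbd_region": gbd_region,
                "gbd_super_region": super_region,
                "reporting_quality": quality,
                "unique_treated": treated,
                "inpatient_tally": inpatient,
                "outpatient_tally": outpatient,
            })

    return SyntheticCohort(
        records=records, contexts=contexts, prevalences=prevalences,
        truth=pd.DataFrame(truth_rows))


def clean_config(**overrides) -> GeneratorConfig:
    """A generator configuration with every corruption channel off."""
    defaults = dict(incomplete_rate=0.0, visits_as_cases_rate=0.0,
                    population_missing_rate=0.0,
                    population_divergent_rate=0.0,
                    followup_missing_rate=0.0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
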