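"""Per-country contact-coverage estimates with delta-method uncertainty.

Contact coverage is the ratio of treated prevalence (unique treated persons
over the covered population) to expected prevalence.  Standard errors are
chained through four steps: binomial SE for the treated prevalence, normal
interval reconstruction for the expected prevalence, the independent-ratio
delta method for the coverage proportion, and the logit delta method for
the scale on which estimates are pooled.  A final validity screen drops
estimates falling outside disorder × income-group plausibility thresholds,
the mechanism that catches registries reporting visits as cases.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .atlas_ingest import (Disorder, ExclusionReason, IncomeGroup,
                           ValidationError)
from .expected_cases import Z95

logger = logging.getLogger(__name__)

#: Coverage cap applied when treated cases exceed expected cases.
COVERAGE_CAP = 0.999


@dataclass(frozen=True)
class CoverageEstimate:
    """One country × disorder coverage proportion and its uncertainty."""

    country_code: str
    disorder: Disorder
    income_group: IncomeGroup
    who_region: str
    gbd_region: str
    gbd_super_region: str
    proportion: float
    se: float
    logit: float
    se_logit: float
    ci_lower: float
    ci_upper: float
    included: bool = True
    exclusion_reason: ExclusionReason = ExclusionReason.OK

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.proportion <= self.ci_upper):
            raise ValidationError(
                f"{self.country_code}: CI ({self.ci_lower}, {self.ci_upper}) "
                f"does not bracket the estimate {self.proportion}")
        if self.included != (self.exclusion_reason is ExclusionReason.OK):
            raise ValidationError(
                "exclusion_reason must be 'ok' exactly when included")

    def group_value(self, grouping: str) -> str:
        if grouping == "all":
            return "all"
        value = getattr(self, grouping)
        return value.value if hasattr(value, "value") else value


@dataclass(frozen=True)
class Threshold:
    lower: float | None
    upper: float | None

    def __post_init__(self) -> None:
        if (self.lower is not None and self.upper is not None
                and not self.lower < self.upper):
            raise ValidationError("threshold lower bound must be < upper")


class ThresholdTable:
    """Admissible coverage bounds per (disorder, income group).

    An absent bound never excludes.  Shipped defaults are reconstructed,
    editable placeholders: psychosis carries only lower bounds (specialist
    coverage can legitimately be high), bipolar and depression only upper
    bounds (their true coverage is expected to be low).
    """

    def __init__(self, table: dict[Disorder, dict[IncomeGroup, Threshold]]):
        self._table = table

    def get(self, disorder: Disorder, income_group: IncomeGroup) -> Threshold:
        return self._table.get(disorder, {}).get(
            income_group, Threshold(None, None))

    @classmethod
    def from_mapping(cls, data: dict) -> "ThresholdTable":
        table: dict[Disorder, dict[IncomeGroup, Threshold]] = {}
        for disorder_key, groups in data.items():
            disorder = Disorder(disorder_key)
            table[disorder] = {}
            for group_key, bounds in (groups or {}).items():
                bounds = bounds or {}
                table[disorder][IncomeGroup(group_key)] = Threshold(
                    lower=bounds.get("lower"), upper=bounds.get("upper"))
        return cls(table)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdTable":
        with Path(path).open() as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ThresholdTable":
        ref = importlib.resources.files("mhcoverage.data") / "thresholds.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


def treated_prevalence(unique_cases: float,
                       effective_population: float) -> tuple[float, float]:
    """Treated prevalence and its binomial standard error."""
    if effective_population <= 0:
        raise ValidationError("effective_population must be positive")
    if unique_cases > effective_population:
        raise ValidationError(
            f"unique treated cases ({unique_cases:.0f}) exceed the covered "
            f"population ({effective_population:.0f})")
    p = unique_cases / effective_population
    se = math.sqrt(p * (1.0 - p) / effective_population)
    return p, se


def coverage_ratio(p_t: float, se_t: float, p_g: float,
                   se_g: float) -> tuple[float, float]:
    """Coverage c = p_t / p_g with independent-ratio delta-method SE.

    se_c = c * sqrt((se_t/p_t)^2 + (se_g/p_g)^2).  A zero numerator keeps
    only the numerator variance term; a ratio above one is capped at
    0.999 with a warning — exclusion is the threshold filter's job, not
    the ratio's.
    """
    if p_g <= 0:
        raise ValidationError(
            "expected prevalence must be positive for coverage to be defined")
    if p_t == 0:
        return 0.0, se_t / p_g
    c = p_t / p_g
    se_c = c * math.sqrt((se_t / p_t) ** 2 + (se_g / p_g) ** 2)
    if c > 1.0:
        logger.warning(
            "coverage ratio %.3f exceeds 1; capped at %.3f", c, COVERAGE_CAP)
        c = COVERAGE_CAP
    return c, se_c


def logit_with_delta(c: float, se_c: float,
                     effective_population: float | None = None,
                     ) -> tuple[float, float]:
    """Logit transform with delta-method SE: se_logit = se_c / (c (1−c)).

    Boundary estimates (c = 0 or 1) take a continuity-correction path,
    replacing c with 1/(4n) or 1 − 1/(4n), n the covered population; a
    zero SE at the boundary is floored at the binomial SE of the corrected
    proportion so pooling weights stay finite.
    """
    if c <= 0.0 or c >= 1.0:
        if effective_population is None or effective_population <= 0:
            raise ValidationError(
                "boundary coverage needs the covered population for a "
                "continuity correction")
        corr = 1.0 / (4.0 * effective_population)
        c = corr if c <= 0.0 else 1.0 - corr
        if se_c == 0.0:
            se_c = math.sqrt(c * (1.0 - c) / effective_population)
    return math.log(c / (1.0 - c)), se_c / (c * (1.0 - c))


def inverse_logit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def logit_ci(logit: float, se_logit: float) -> tuple[float, float]:
    """95% CI on the natural scale via the logit scale (respects (0,1))."""
    return (inverse_logit(logit - Z95 * se_logit),
            inverse_logit(logit + Z95 * se_logit))


def apply_thresholds(est: CoverageEstimate,
                     table: ThresholdTable) -> CoverageEstimate:
    """Exclude estimates outside the admissible coverage band."""
    if not est.included:
        return est
    bounds = table.get(est.disorder, est.income_group)
    outside = ((bounds.lower is not None and est.proportion < bounds.lower)
               or (bounds.upper is not None and est.proportion > bounds.upper))
    if outside:
        return replace(est, included=False,
                       exclusion_reason=ExclusionReason.OUTSIDE_THRESHOLD)
    return est
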