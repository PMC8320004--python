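"""Unique treated cases with inpatient/outpatient double-counting correction.

Registries tally inpatient and outpatient cases separately, so a person
seen in both settings is counted twice.  Countries are classified by which
setting treats the majority of reported cases.  In outpatient-prioritised
countries every inpatient who receives an outpatient follow-up also appears
in the outpatient tally, so the outpatient count is deflated by the
follow-up fraction times the inpatient count before summing; if that
deflation goes negative the raw sum is kept (the report is internally
inconsistent and the adjustment would fabricate a lower bound).  In
inpatient-prioritised countries no adjustment is applied.

The follow-up fraction is reported only as a four-level category; the
category's range midpoint stands in for the fraction, and countries not
reporting a category receive the median midpoint of their world region.
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .atlas_ingest import AtlasRecord, CountryContext, ValidationError

logger = logging.getLogger(__name__)

#: Range midpoints of the four follow-up categories
#: (<=25%, 26-50%, 51-75%, >75% of discharged inpatients followed up).
FOLLOWUP_MIDPOINTS: dict[int, float] = {1: 0.125, 2: 0.38, 3: 0.63, 4: 0.875}


class Prioritisation(str, enum.Enum):
    INPATIENT = "inpatient_prioritised"
    OUTPATIENT = "outpatient_prioritised"


class ConfigError(ValueError):
    """A required configuration value cannot be derived from the data."""


@dataclass(frozen=True)
class TreatedCases:
    unique_cases: float
    prioritisation: Prioritisation
    followup_midpoint_used: float
    midpoint_imputed: bool
    negative_fallback_used: bool


def classify_prioritisation(record: AtlasRecord) -> Prioritisation:
    """Which setting treats the majority of reported cases.

    Ties go to outpatient-prioritised, the conservative choice because it
    applies the de-duplication adjustment.
    """
    if record.inpatient_cases is None or record.outpatient_cases is None:
        raise ValidationError(
            "prioritisation requires both case counts; screen first")
    if record.inpatient_cases > record.outpatient_cases:
        return Prioritisation.INPATIENT
    return Prioritisation.OUTPATIENT


def followup_midpoint(category: int) -> float:
    """Midpoint of a follow-up category's percentage range, as a fraction."""
    try:
        return FOLLOWUP_MIDPOINTS[category]
    except KeyError:
        raise ValidationError(
            f"followup_category must be in {{1,2,3,4}}, got {category}"
        ) from None


def impute_followup(region_midpoints: Sequence[float],
                    global_midpoints: Sequence[float] | None = None,
                    region: str = "?") -> float:
    """Median follow-up midpoint of a world region.

    Falls back to the global median (with a warning) when no country in
    the region reported a category; raises when nobody anywhere did.
    """
    if region_midpoints:
        return statistics.median(region_midpoints)
    if global_midpoints:
        logger.warning(
            "no follow-up reporter in region %s; global median used", region)
        return statistics.median(global_midpoints)
    raise ConfigError(
        "no country reported a follow-up category anywhere; an explicit "
        "default follow-up fraction is required")


def followup_midpoint_table(records: Iterable[AtlasRecord],
                            contexts: Mapping[str, CountryContext],
                            ) -> dict[str, float]:
    """Per-GBD-region median follow-up midpoint for imputation.

    Every region present in ``contexts`` gets an entry; regions without a
    reporter receive the global median.
    """
    by_region: dict[str, list[float]] = {}
    all_midpoints: list[float] = []
    for record in records:
        if record.followup_category is None:
            continue
        ctx = contexts.get(record.country_code)
        if ctx is None:
            continue
        m = followup_midpoint(record.followup_category)
        by_region.setdefault(ctx.gbd_region, []).append(m)
        all_midpoints.append(m)
    regions = {ctx.gbd_region for ctx in contexts.values()}
    return {
        region: impute_followup(by_region.get(region, ()), all_midpoints,
                                region=region)
        for region in sorted(regions)
    }


def unique_treated_cases(record: AtlasRecord, midpoint: float,
                         midpoint_imputed: bool = False,
                         prioritisation: Prioritisation | None = None,
                         ) -> TreatedCases:
    """Unique persons treated across both settings in 12 months.

    Outpatient-prioritised: ``inpatient + (outpatient − midpoint ×
    inpatient)``, falling back to the unadjusted sum when the deflated
    outpatient count is negative.  Inpatient-prioritised: the unadjusted
    sum.  Fractional results are kept; downstream quantities are
    proportions.  ``prioritisation`` defaults to the majority-rule
    classification of the record itself.
    """
    if not (0.0 <= midpoint <= 1.0):
        raise ValidationError(f"midpoint must lie in [0, 1], got {midpoint}")
    if prioritisation is None:
        prioritisation = classify_prioritisation(record)
    inpatient = record.inpatient_cases
    outpatient = record.outpatient_cases
    assert inpatient is not None and outpatient is not None
    if prioritisation is Prioritisation.INPATIENT:
        return TreatedCases(
            unique_cases=float(inpatient + outpatient),
            prioritisation=prioritisation,
            followup_midpoint_used=midpoint,
            midpoint_imputed=midpoint_imputed,
            negative_fallback_used=False,
        )
    adjusted_out = outpatient - midpoint * inpatient
    if adjusted_out < 0:
        logger.warning(
            "%s/%s: adjusted outpatient count negative (%.1f); raw sum kept",
            record.country_code, record.disorder.value, adjusted_out)
        return TreatedCases(
            unique_cases=float(inpatient + outpatient),
            prioritisation=prioritisation,
            followup_midpoint_used=midpoint,
            midpoint_imputed=midpoint_imputed,
            negative_fallback_used=True,
        )
    return TreatedCases(
        unique_cases=inpatient + adjusted_out,
        prioritisation=prioritisation,
        followup_midpoint_used=midpoint,
        midpoint_imputed=midpoint_imputed,
        negative_fallback_used=False,
    )
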