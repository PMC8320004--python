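"""Ingest and validity screening of Atlas-style service-utilisation tables.

Country-reported service-utilisation data arrive as one row per
(country, disorder) with inpatient/outpatient case counts, visit counts,
the representativeness of the reporting system, a categorical inpatient
follow-up rate and the country's self-reported population.  Before any
estimation the rows pass two screens:

* completeness — a row must report case counts for *both* inpatient and
  outpatient facilities, and the representativeness of the population the
  data were drawn from;
* visits-per-case — total visits divided by total cases must be at least 1;
  a ratio below one signals an internally inconsistent report.

Population denominators are taken from the country report when it agrees
with the UN estimate, and substituted by the UN estimate otherwise.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

DEFAULT_DIVERGENCE_LIMIT = 0.30


class Disorder(str, enum.Enum):
    PSYCHOSIS = "psychosis"
    BIPOLAR = "bipolar"
    DEPRESSION = "depression"


class IncomeGroup(str, enum.Enum):
    LOW = "low"
    LOWER_MIDDLE = "lower_middle"
    UPPER_MIDDLE = "upper_middle"
    HIGH = "high"


#: The six WHO regions.
WHO_REGIONS = ("AFR", "AMR", "SEAR", "EUR", "EMR", "WPR")


class ExclusionReason(str, enum.Enum):
    OK = "ok"
    MISSING_INPATIENT_OR_OUTPATIENT = "missing_inpatient_or_outpatient"
    MISSING_REPRESENTATIVENESS = "missing_representativeness"
    VISITS_PER_CASE_BELOW_ONE = "visits_per_case_below_one"
    OUTSIDE_THRESHOLD = "outside_threshold"


class SchemaError(ValueError):
    """A CSV header does not match the documented schema."""


class ValidationError(ValueError):
    """A field value violates its invariant."""


class ContextLookupError(KeyError):
    """No country-context row exists for a country code."""


@dataclass(frozen=True)
class AtlasRecord:
    """One country × disorder service-utilisation report.

    Counts are per 12 months.  ``None`` means the cell was not reported —
    never coerced to zero, since zero is itself a legitimate report.
    """

    country_code: str
    disorder: Disorder
    inpatient_cases: int | None = None
    outpatient_cases: int | None = None
    inpatient_visits: int | None = None
    outpatient_visits: int | None = None
    representativeness: float | None = None
    followup_category: int | None = None
    reported_population: float | None = None

    def __post_init__(self) -> None:
        for name in ("inpatient_cases", "outpatient_cases",
                     "inpatient_visits", "outpatient_visits"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.representativeness is not None and not (
                0.0 <= self.representativeness <= 1.0):
            raise ValidationError(
                f"representativeness must lie in [0, 1], got "
                f"{self.representativeness}")
        if self.followup_category is not None and self.followup_category not in (
                1, 2, 3, 4):
            raise ValidationError(
                f"followup_category must be in {{1,2,3,4}}, got "
                f"{self.followup_category}")
        if self.reported_population is not None and self.reported_population <= 0:
            raise ValidationError("reported_population must be positive")


@dataclass(frozen=True)
class CountryContext:
    """Static country attributes used for denominators and aggregation."""

    country_code: str
    income_group: IncomeGroup
    who_region: str
    gbd_region: str
    gbd_super_region: str
    un_population: float

    def __post_init__(self) -> None:
        if self.un_population <= 0:
            raise ValidationError("un_population must be positive")
        if self.who_region not in WHO_REGIONS:
            raise ValidationError(f"unknown WHO region {self.who_region!r}")


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    reason: ExclusionReason

    def __post_init__(self) -> None:
        if self.included != (self.reason is ExclusionReason.OK):
            raise ValidationError(
                "reason must be 'ok' exactly when the record is included")


ATLAS_COLUMNS = (
    "country_code", "disorder", "inpatient_cases", "outpatient_cases",
    "inpatient_visits", "outpatient_visits", "representativeness",
    "followup_category", "reported_population",
)

CONTEXT_COLUMNS = (
    "country_code", "income_group", "who_region", "gbd_region",
    "gbd_super_region", "un_population",
)


def _parse_count(cell: str, column: str, row: int) -> int | None:
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError as exc:
        raise ValidationError(
            f"row {row}: {column} is not numeric: {cell!r}") from exc
    if value < 0:
        raise ValidationError(f"row {row}: {column} is negative ({cell})")
    if value != int(value):
        raise ValidationError(
            f"row {row}: {column} must be an integer count, got {cell}")
    return int(value)


def _parse_float(cell: str, column: str, row: int) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(
            f"row {row}: {column} is not numeric: {cell!r}") from exc


def _check_header(header: list[str] | None, expected: tuple[str, ...],
                  path: Path) -> None:
    missing = [c for c in expected if header is None or c not in header]
    if missing:
        raise SchemaError(
            f"{path}: header is missing column(s) {', '.join(missing)}")


def read_atlas_table(path: str | Path) -> list[AtlasRecord]:
    """Read ``atlas_records.csv`` into validated :class:`AtlasRecord` rows.

    Empty cells become absent fields.  Errors carry the offending 1-based
    data row number.
    """
    path = Path(path)
    records: list[AtlasRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ATLAS_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                disorder = Disorder(row["disorder"].strip())
            except ValueError as exc:
                raise ValidationError(
                    f"row {i}: unknown disorder {row['disorder']!r}") from exc
            try:
                records.append(AtlasRecord(
                    country_code=row["country_code"].strip(),
                    disorder=disorder,
                    inpatient_cases=_parse_count(
                        row["inpatient_cases"], "inpatient_cases", i),
                    outpatient_cases=_parse_count(
                        row["outpatient_cases"], "outpatient_cases", i),
                    inpatient_visits=_parse_count(
                        row["inpatient_visits"], "inpatient_visits", i),
                    outpatient_visits=_parse_count(
                        row["outpatient_visits"], "outpatient_visits", i),
                    representativeness=_parse_float(
                        row["representativeness"], "representativeness", i),
                    followup_category=_parse_count(
                        row["followup_category"], "followup_category", i),
                    reported_population=_parse_float(
                        row["reported_population"], "reported_population", i),
                ))
            except ValidationError as exc:
                if str(exc).startswith("row "):
                    raise
                raise ValidationError(f"row {i}: {exc}") from exc
    return records


def read_country_context(path: str | Path) -> dict[str, CountryContext]:
    """Read ``country_context.csv`` into a mapping keyed by country code."""
    path = Path(path)
    contexts: dict[str, CountryContext] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, CONTEXT_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            code = row["country_code"].strip()
            if code in contexts:
                raise ValidationError(
                    f"row {i}: duplicate country context for {code}")
            try:
                income = IncomeGroup(row["income_group"].strip())
            except ValueError as exc:
                raise ValidationError(
                    f"row {i}: unknown income group "
                    f"{row['income_group']!r}") from exc
            contexts[code] = CountryContext(
                country_code=code,
                income_group=income,
                who_region=row["who_region"].strip(),
                gbd_region=row["gbd_region"].strip(),
                gbd_super_region=row["gbd_super_region"].strip(),
                un_population=float(row["un_population"]),
            )
    return contexts


def screen_completeness(record: AtlasRecord) -> InclusionDecision:
    """Exclude records lacking either facility's cases or representativeness."""
    if record.inpatient_cases is None or record.outpatient_cases is None:
        return InclusionDecision(
            False, ExclusionReason.MISSING_INPATIENT_OR_OUTPATIENT)
    if record.representativeness is None:
        return InclusionDecision(
            False, ExclusionReason.MISSING_REPRESENTATIVENESS)
    return InclusionDecision(True, ExclusionReason.OK)


def visits_per_case_check(record: AtlasRecord) -> InclusionDecision:
    """Exclude records whose pooled visits-per-case ratio is below one.

    The ratio pools inpatient and outpatient totals.  If neither visits
    field was reported the check cannot fire and the record passes with a
    logged warning.  Visits reported against zero total cases signal an
    inconsistent report and exclude the record.
    """
    if record.inpatient_visits is None and record.outpatient_visits is None:
        logger.warning(
            "%s/%s: no visit data reported; visits-per-case check skipped",
            record.country_code, record.disorder.value)
        return InclusionDecision(True, ExclusionReason.OK)
    visits = (record.inpatient_visits or 0) + (record.outpatient_visits or 0)
    cases = (record.inpatient_cases or 0) + (record.outpatient_cases or 0)
    if cases == 0:
        return InclusionDecision(
            False, ExclusionReason.VISITS_PER_CASE_BELOW_ONE)
    if visits / cases < 1.0:
        return InclusionDecision(
            False, ExclusionReason.VISITS_PER_CASE_BELOW_ONE)
    return InclusionDecision(True, ExclusionReason.OK)


def resolve_population(record: AtlasRecord,
                       context: Mapping[str, CountryContext] | CountryContext,
                       divergence_limit: float = DEFAULT_DIVERGENCE_LIMIT,
                       ) -> float:
    """Return the population denominator for a record.

    The self-reported population is used when present and within
    ``divergence_limit`` relative difference of the UN estimate; otherwise
    the UN estimate is substituted (and the substitution logged).
    """
    if isinstance(context, CountryContext):
        ctx = context
    else:
        try:
            ctx = context[record.country_code]
        except KeyError:
            raise ContextLookupError(
                f"no country context for {record.country_code!r}") from None
    reported = record.reported_population
    if reported is None:
        logger.info("%s: no reported population, using UN estimate",
                    record.country_code)
        return ctx.un_population
    if abs(reported - ctx.un_population) / ctx.un_population > divergence_limit:
        logger.warning(
            "%s: reported population %.0f diverges from UN estimate %.0f "
            "by more than %.0f%%; UN estimate used",
            record.country_code, reported, ctx.un_population,
            100 * divergence_limit)
        return ctx.un_population
    return reported


def screen_records(records: Iterable[AtlasRecord],
                   ) -> tuple[list[AtlasRecord],
                              list[tuple[AtlasRecord, str, ExclusionReason]]]:
    """Apply both pre-estimation screens, returning (passed, ledger).

    The ledger holds one ``(record, stage, reason)`` entry per excluded
    record; ``len(passed) + len(ledger)`` always equals the input count.
    """
    passed: list[AtlasRecord] = []
    ledger: list[tuple[AtlasRecord, str, ExclusionReason]] = []
    for record in records:
        decision = screen_completeness(record)
        if not decision.included:
            ledger.append((record, "completeness", decision.reason))
            continue
        decision = visits_per_case_check(record)
        if not decision.included:
            ledger.append((record, "visits_per_case", decision.reason))
            continue
        passed.append(record)
    return passed, ledger
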