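"""Expected 12-month prevalent cases from prevalence inputs.

Prevalence estimates enter in the form the burden-of-disease literature
publishes them: point prevalence of schizophrenia, point prevalence of
all-severity depression, and 12-month prevalence of bipolar disorder,
each with a 95% uncertainty interval.  Two case-definition adjustments
align them with what specialist mental-health services actually see:

* schizophrenia → non-affective psychosis, dividing by the 0.49
  schizophrenia share of non-affective psychosis prevalence;
* depression → 12-month moderate-severe depression, multiplying by a
  point-to-12-month factor and by the combined moderate (0.17) plus
  severe (0.10) severity split.

The adjusted rate times the covered population (population ×
representativeness) gives the expected prevalent cases — the coverage
denominator — with a standard error reconstructed from the interval.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .atlas_ingest import Disorder, SchemaError, ValidationError

#: Two-sided 95% normal quantile used throughout for interval ↔ SE moves.
Z95 = 1.959964


class TimeFrame(str, enum.Enum):
    POINT = "point"
    TWELVE_MONTH = "twelve_month"


@dataclass(frozen=True)
class ProportionWithCI:
    value: float
    lower95: float
    upper95: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower95 <= self.value <= self.upper95 < 1.0):
            raise ValidationError(
                f"proportion interval must satisfy 0 <= lower <= value <= "
                f"upper < 1, got ({self.lower95}, {self.value}, "
                f"{self.upper95})")

    @property
    def se(self) -> float:
        return se_from_interval(self.lower95, self.upper95)


@dataclass(frozen=True)
class AdjustmentConstants:
    """Case-definition adjustment constants.

    ``schiz_to_psychosis_ratio`` is the share of non-affective psychosis
    prevalence attributable to schizophrenia.  The severity splits are the
    moderate and severe fractions of all depression cases.  The
    point→12-month factor for depression is the inverse of a
    12-month→point study covariate; its published value is not recoverable,
    so it is exposed as configuration with a documented default.
    """

    schiz_to_psychosis_ratio: float = 0.49
    depression_moderate_prop: ProportionWithCI = field(
        default_factory=lambda: ProportionWithCI(0.17, 0.13, 0.22))
    depression_severe_prop: ProportionWithCI = field(
        default_factory=lambda: ProportionWithCI(0.10, 0.03, 0.20))
    depression_point_to_12m_factor: float = 1.30

    def __post_init__(self) -> None:
        if not (0.0 < self.schiz_to_psychosis_ratio <= 1.0):
            raise ValidationError(
                "schiz_to_psychosis_ratio must lie in (0, 1]")
        if self.depression_point_to_12m_factor < 1.0:
            raise ValidationError(
                "depression_point_to_12m_factor must be >= 1")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Prevalence rate with a 95% interval for one disorder in one country."""

    country_code: str
    disorder: Disorder
    rate: float
    lower95: float
    upper95: float
    time_frame: TimeFrame

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower95 <= self.rate <= self.upper95 < 1.0):
            raise ValidationError(
                f"{self.country_code}/{self.disorder.value}: prevalence "
                f"interval must satisfy 0 <= lower <= rate <= upper < 1, "
                f"got ({self.lower95}, {self.rate}, {self.upper95})")

    @property
    def se(self) -> float:
        return se_from_interval(self.lower95, self.upper95)


@dataclass(frozen=True)
class ExpectedCases:
    """Expected prevalent persons in the covered population."""

    count: float
    se: float
    effective_population: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("se must be >= 0")
        if self.count > self.effective_population:
            raise ValidationError(
                "expected cases cannot exceed the covered population")


def se_from_interval(lower95: float, upper95: float) -> float:
    """SE reconstructed from a symmetric 95% normal interval."""
    if lower95 > upper95:
        raise ValidationError(
            f"interval lower bound {lower95} exceeds upper bound {upper95}")
    return (upper95 - lower95) / (2.0 * Z95)


def _rescale_interval(rate: float, se: float) -> tuple[float, float]:
    # Symmetric normal interval around the adjusted rate; clipped into
    # [0, 1) so the container invariant holds for extreme inputs.
    lower = max(rate - Z95 * se, 0.0)
    upper = min(rate + Z95 * se, math.nextafter(1.0, 0.0))
    return lower, max(upper, rate)


def adjust_depression(prev: PrevalenceEstimate,
                      consts: AdjustmentConstants) -> PrevalenceEstimate:
    """Point all-severity depression → 12-month moderate-severe depression.

    The rate is multiplied by the point→12-month factor and by the combined
    moderate+severe split.  The split is applied at its central value; its
    uncertainty enters by adding, in quadrature on the relative scale, the
    SE of the combined split to the relative SE of the prevalence.
    """
    if prev.disorder is not Disorder.DEPRESSION:
        raise ValidationError("adjust_depression requires a depression row")
    factor = consts.depression_point_to_12m_factor
    if prev.time_frame is TimeFrame.TWELVE_MONTH and factor != 1.0:
        raise ValidationError(
            f"{prev.country_code}: depression prevalence is already "
            "12-month; refusing a second point->12-month conversion")
    split = (consts.depression_moderate_prop.value
             + consts.depression_severe_prop.value)
    split_se = math.hypot(consts.depression_moderate_prop.se,
                          consts.depression_severe_prop.se)
    rate = prev.rate * factor * split
    if rate == 0.0:
        return replace(prev, rate=0.0, lower95=0.0, upper95=0.0,
                       time_frame=TimeFrame.TWELVE_MONTH)
    rel_var = (prev.se / prev.rate) ** 2 if prev.rate > 0 else 0.0
    if split > 0:
        rel_var += (split_se / split) ** 2
    se = rate * math.sqrt(rel_var)
    lower, upper = _rescale_interval(rate, se)
    return replace(prev, rate=rate, lower95=lower, upper95=upper,
                   time_frame=TimeFrame.TWELVE_MONTH)


def adjust_psychosis(prev: PrevalenceEstimate,
                     consts: AdjustmentConstants) -> PrevalenceEstimate:
    """Schizophrenia prevalence → non-affective psychosis prevalence.

    Divides rate and interval bounds by the schizophrenia share (0.49) of
    non-affective psychosis.  The time frame is left unchanged: point
    prevalence of psychosis is accepted as a 12-month proxy because the
    two were not statistically distinguishable in burden-of-disease
    covariate modelling.
    """
    if prev.disorder is not Disorder.PSYCHOSIS:
        raise ValidationError("adjust_psychosis requires a psychosis row")
    ratio = consts.schiz_to_psychosis_ratio
    if ratio <= 0:
        raise ValidationError("schiz_to_psychosis_ratio must be positive")
    rate = prev.rate / ratio
    upper = prev.upper95 / ratio
    if rate >= 1.0 or upper >= 1.0:
        raise ValidationError(
            f"{prev.country_code}: adjusted psychosis prevalence "
            f"{rate:.3f} is not a valid proportion")
    return replace(prev, rate=rate, lower95=prev.lower95 / ratio,
                   upper95=upper)


def expected_case_count(prev: PrevalenceEstimate, population: float,
                        representativeness: float | None) -> ExpectedCases:
    """Expected prevalent cases among the covered population.

    The denominator is shrunk by representativeness: coverage is computed
    among the population the reporting system actually covers.
    """
    if representativeness is None:
        raise ValidationError(
            "representativeness is required to size the covered population; "
            "the record should have been screened out earlier")
    if population <= 0:
        raise ValidationError("population must be positive")
    effective = population * representativeness
    return ExpectedCases(
        count=prev.rate * effective,
        se=prev.se * effective,
        effective_population=effective,
    )


PREVALENCE_COLUMNS = ("country_code", "disorder", "rate", "lower95",
                      "upper95", "time_frame")


def read_prevalence_table(path: str | Path,
                          ) -> dict[tuple[str, Disorder], PrevalenceEstimate]:
    """Read ``prevalence.csv`` keyed by (country_code, disorder)."""
    path = Path(path)
    out: dict[tuple[str, Disorder], PrevalenceEstimate] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in PREVALENCE_COLUMNS
                   if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise SchemaError(
                f"{path}: header is missing column(s) {', '.join(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                prev = PrevalenceEstimate(
                    country_code=row["country_code"].strip(),
                    disorder=Disorder(row["disorder"].strip()),
                    rate=float(row["rate"]),
                    lower95=float(row["lower95"]),
                    upper95=float(row["upper95"]),
                    time_frame=TimeFrame(row["time_frame"].strip()),
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            key = (prev.country_code, prev.disorder)
            if key in out:
                raise ValidationError(
                    f"row {i}: duplicate prevalence for {key}")
            out[key] = prev
    return out


def adjust_prevalence(prev: PrevalenceEstimate,
                      consts: AdjustmentConstants) -> PrevalenceEstimate:
    """Dispatch the disorder-appropriate case-definition adjustment."""
    if prev.disorder is Disorder.DEPRESSION:
        return adjust_depression(prev, consts)
    if prev.disorder is Disorder.PSYCHOSIS:
        return adjust_psychosis(prev, consts)
    if prev.time_frame is not TimeFrame.TWELVE_MONTH:
        raise ValidationError(
            f"{prev.country_code}: bipolar prevalence must be 12-month")
    return prev
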