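"""End-to-end estimation: screens → adjustments → coverage → pooling.

`estimate_countries` is the in-memory core: validated records go through
the completeness and visits-per-case screens, population resolution,
prevalence adjustment, the double-counting correction, the delta-method
uncertainty chain and the threshold filter, producing one coverage
estimate or one exclusion-ledger entry per input row.  `run_pipeline`
wraps it with file I/O, per-grouping pooling, Baujat diagnostics and a
run manifest; identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .atlas_ingest import (AtlasRecord, CountryContext, Disorder,
                           ExclusionReason, ValidationError,
                           read_atlas_table, read_country_context,
                           resolve_population, screen_records,
                           DEFAULT_DIVERGENCE_LIMIT)
from .coverage import (CoverageEstimate, ThresholdTable, apply_thresholds,
                       coverage_ratio, inverse_logit, logit_ci,
                       logit_with_delta, treated_prevalence)
from .expected_cases import (AdjustmentConstants, PrevalenceEstimate,
                             ProportionWithCI, adjust_prevalence,
                             expected_case_count, read_prevalence_table)
from .pooling import PooledEstimate, aggregate_groups, baujat_coordinates
from .treated_cases import (followup_midpoint, followup_midpoint_table,
                            unique_treated_cases)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExclusionEntry:
    country_code: str
    disorder: Disorder
    stage: str
    reason: ExclusionReason


@dataclass
class EstimationResult:
    """Per-country estimates plus the exclusion and adjustment ledgers.

    Every input row lands exactly once in either the included estimates
    or the exclusion ledger; threshold-excluded rows keep their estimate
    (flagged) and also appear in the ledger.
    """

    estimates: list[CoverageEstimate]
    exclusions: list[ExclusionEntry]
    adjustment_log: list[dict]

    @property
    def included(self) -> list[CoverageEstimate]:
        return [e for e in self.estimates if e.included]


def estimate_countries(records: Sequence[AtlasRecord],
                       contexts: Mapping[str, CountryContext],
                       prevalences: Mapping[tuple[str, Disorder],
                                            PrevalenceEstimate],
                       constants: AdjustmentConstants | None = None,
                       thresholds: ThresholdTable | None = None,
                       divergence_limit: float = DEFAULT_DIVERGENCE_LIMIT,
                       ) -> EstimationResult:
    """Run every per-country stage of the coverage pipeline."""
    constants = constants or AdjustmentConstants()
    thresholds = thresholds if thresholds is not None else ThresholdTable.default()

    passed, screen_ledger = screen_records(records)
    exclusions = [ExclusionEntry(r.country_code, r.disorder, stage, reason)
                  for r, stage, reason in screen_ledger]
    midpoints_by_region = followup_midpoint_table(passed, contexts) \
        if passed else {}

    estimates: list[CoverageEstimate] = []
    adjustment_log: list[dict] = []
    for record in passed:
        ctx = contexts.get(record.country_code)
        if ctx is None:
            raise ValidationError(
                f"no country context for {record.country_code!r}")
        population = resolve_population(record, ctx, divergence_limit)
        key = (record.country_code, record.disorder)
        if key not in prevalences:
            raise ValidationError(
                f"no prevalence input for {record.country_code}/"
                f"{record.disorder.value}")
        prev = adjust_prevalence(prevalences[key], constants)
        expected = expected_case_count(prev, population,
                                       record.representativeness)
        if record.followup_category is not None:
            midpoint = followup_midpoint(record.followup_category)
            imputed = False
        else:
            midpoint = midpoints_by_region[ctx.gbd_region]
            imputed = True
        treated = unique_treated_cases(record, midpoint,
                                       midpoint_imputed=imputed)
        p_t, se_t = treated_prevalence(treated.unique_cases,
                                       expected.effective_population)
        p_g, se_g = prev.rate, prev.se
        c, se_c = coverage_ratio(p_t, se_t, p_g, se_g)
        logit, se_logit = logit_with_delta(
            c, se_c, expected.effective_population)
        # store the continuity-corrected proportion so CI brackets it
        c_stored = inverse_logit(logit)
        ci_lower, ci_upper = logit_ci(logit, se_logit)
        est = CoverageEstimate(
            country_code=record.country_code,
            disorder=record.disorder,
            income_group=ctx.income_group,
            who_region=ctx.who_region,
            gbd_region=ctx.gbd_region,
            gbd_super_region=ctx.gbd_super_region,
            proportion=c_stored,
            se=se_c,
            logit=logit,
            se_logit=se_logit,
            ci_lower=ci_lower,
            ci_upper=ci_upper,
        )
        est = apply_thresholds(est, thresholds)
        if not est.included:
            exclusions.append(ExclusionEntry(
                record.country_code, record.disorder, "threshold",
                est.exclusion_reason))
        estimates.append(est)
        adjustment_log.append({
            "country_code": record.country_code,
            "disorder": record.disorder.value,
            "prioritisation": treated.prioritisation.value,
            "midpoint": treated.followup_midpoint_used,
            "midpoint_imputed": treated.midpoint_imputed,
            "negative_fallback_used": treated.negative_fallback_used,
            "unique_cases": treated.unique_cases,
            "expected_cases": expected.count,
            "effective_population": expected.effective_population,
        })
    return EstimationResult(estimates, exclusions, adjustment_log)


# ---------------------------------------------------------------------------
# File-driven pipeline


@dataclass
class PipelineConfig:
    """Single source of every constant and path the pipeline uses."""

    atlas_path: Path
    context_path: Path
    prevalence_path: Path
    out_dir: Path
    thresholds_path: Path | None = None
    constants: AdjustmentConstants = field(default_factory=AdjustmentConstants)
    divergence_limit: float = DEFAULT_DIVERGENCE_LIMIT
    groupings: tuple[str, ...] = ("income_group", "who_region",
                                  "gbd_super_region")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        inputs = raw.get("inputs", {})
        for k in ("atlas", "context", "prevalence"):
            if k not in inputs:
                raise ValidationError(f"config is missing inputs.{k}")
        consts = raw.get("constants", {})

        def prop(key: str, default: ProportionWithCI) -> ProportionWithCI:
            if key not in consts:
                return default
            d = consts[key]
            return ProportionWithCI(d["value"], d["lower95"], d["upper95"])

        defaults = AdjustmentConstants()
        constants = AdjustmentConstants(
            schiz_to_psychosis_ratio=consts.get(
                "schiz_to_psychosis_ratio",
                defaults.schiz_to_psychosis_ratio),
            depression_moderate_prop=prop("depression_moderate_prop",
                                          defaults.depression_moderate_prop),
            depression_severe_prop=prop("depression_severe_prop",
                                        defaults.depression_severe_prop),
            depression_point_to_12m_factor=consts.get(
                "depression_point_to_12m_factor",
                defaults.depression_point_to_12m_factor),
        )
        return cls(
            atlas_path=resolve(inputs["atlas"]),
            context_path=resolve(inputs["context"]),
            prevalence_path=resolve(inputs["prevalence"]),
            out_dir=resolve(raw.get("out_dir", "results")),
            thresholds_path=(resolve(raw["thresholds"])
                             if raw.get("thresholds") else None),
            constants=constants,
            divergence_limit=raw.get("divergence_limit",
                                     DEFAULT_DIVERGENCE_LIMIT),
            groupings=tuple(raw.get("groupings", ("income_group",
                                                  "who_region",
                                                  "gbd_super_region"))),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


@dataclass
class PipelineResult:
    estimation: EstimationResult
    pooled: list[tuple[Disorder, str, PooledEstimate]]
    output_paths: dict[str, Path]


def _config_fingerprint(config: PipelineConfig) -> str:
    payload = {
        "atlas": str(config.atlas_path),
        "context": str(config.context_path),
        "prevalence": str(config.prevalence_path),
        "thresholds": str(config.thresholds_path),
        "divergence_limit": config.divergence_limit,
        "groupings": list(config.groupings),
        "seed": config.seed,
        "constants": {
            "schiz_to_psychosis_ratio":
                config.constants.schiz_to_psychosis_ratio,
            "depression_moderate_prop":
                config.constants.depression_moderate_prop.value,
            "depression_severe_prop":
                config.constants.depression_severe_prop.value,
            "depression_point_to_12m_factor":
                config.constants.depression_point_to_12m_factor,
        },
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all output files."""
    logging.basicConfig(level=config.log_level)
    for path in (config.atlas_path, config.context_path,
                 config.prevalence_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    records = read_atlas_table(config.atlas_path)
    contexts = read_country_context(config.context_path)
    prevalences = read_prevalence_table(config.prevalence_path)
    thresholds = (ThresholdTable.from_yaml(config.thresholds_path)
                  if config.thresholds_path else ThresholdTable.default())

    result = estimate_countries(
        records, contexts, prevalences, config.constants, thresholds,
        config.divergence_limit)

    pooled: list[tuple[Disorder, str, PooledEstimate]] = []
    baujat_rows: list[dict] = []
    for disorder in Disorder:
        ests = [e for e in result.included if e.disorder is disorder]
        if not ests:
            continue
        seen_all = False
        for grouping in list(config.groupings) + ["all"]:
            for pe in aggregate_groups(ests, grouping):
                tag = "all" if pe.group_label == "all" else grouping
                if pe.group_label == "all":
                    if seen_all:
                        continue
                    seen_all = True
                pooled.append((disorder, tag, pe))
                members = [e for e in ests
                           if pe.group_label == "all"
                           or e.group_value(grouping) == pe.group_label]
                if len(members) >= 2:
                    for pt in baujat_coordinates(members):
                        baujat_rows.append({
                            "disorder": disorder.value, "grouping": tag,
                            "group_label": pe.group_label,
                            "country_code": pt.country_code,
                            "x": pt.x, "y": pt.y})

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "country_estimates": out / "country_estimates.csv",
        "pooled_estimates": out / "pooled_estimates.csv",
        "baujat": out / "baujat.csv",
        "exclusions": out / "exclusions.csv",
        "adjustments": out / "adjustments.csv",
        "manifest": out / "manifest.json",
    }
    with paths["country_estimates"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("country_code", "disorder", "income_group", "coverage",
                    "se", "ci_lower", "ci_upper", "included",
                    "exclusion_reason"))
        for e in result.estimates:
            w.writerow((e.country_code, e.disorder.value,
                        e.income_group.value, repr(e.proportion), repr(e.se),
                        repr(e.ci_lower), repr(e.ci_upper), e.included,
                        e.exclusion_reason.value))
    with paths["pooled_estimates"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("disorder", "grouping", "group_label", "k",
                    "pooled_coverage", "ci_lower", "ci_upper", "tau2", "Q",
                    "I2"))
        for disorder, grouping, pe in pooled:
            w.writerow((disorder.value, grouping, pe.group_label, pe.k,
                        repr(pe.pooled_proportion), repr(pe.ci_lower),
                        repr(pe.ci_upper), repr(pe.tau2), repr(pe.Q),
                        repr(pe.I2)))
    with paths["baujat"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("disorder", "grouping", "group_label", "country_code",
                    "x", "y"))
        for row in baujat_rows:
            w.writerow((row["disorder"], row["grouping"], row["group_label"],
                        row["country_code"], repr(row["x"]), repr(row["y"])))
    with paths["exclusions"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("country_code", "disorder", "stage", "reason"))
        for entry in result.exclusions:
            w.writerow((entry.country_code, entry.disorder.value, entry.stage,
                        entry.reason.value))
    with paths["adjustments"].open("w", newline="") as fh:
        w = csv.writer(fh)
        header = ("country_code", "disorder", "prioritisation", "midpoint",
                  "midpoint_imputed", "negative_fallback_used",
                  "unique_cases", "expected_cases", "effective_population")
        w.writerow(header)
        for row in result.adjustment_log:
            w.writerow(tuple(row[k] for k in header))
    manifest = {
        "package_version": __version__,
        "config_sha256": _config_fingerprint(config),
        "seed": config.seed,
        "n_input_rows": len(records),
        "n_included": len(result.included),
        "n_excluded": len(result.exclusions),
    }
    with paths["manifest"].open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d/%d rows included",
                len(result.included), len(records))
    return PipelineResult(estimation=result, pooled=pooled,
                          output_paths=paths)
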