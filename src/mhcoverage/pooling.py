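"""Random-effects pooling of country coverage estimates on the logit scale.

Country estimates y_i = logit(c_i) with delta-method standard errors se_i
are combined per aggregation group (World Bank income group, WHO region,
GBD region / super-region, and all countries) by DerSimonian–Laird
random-effects meta-analysis:

    w_i   = 1 / se_i^2                     (fixed weights)
    Q     = sum w_i (y_i - ybar_w)^2       (Cochran heterogeneity)
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1 / (se_i^2 + tau^2)           (random weights)

with pooled logit sum(w* y)/sum(w*), SE sqrt(1/sum w*), and
I^2 = max(0, (Q - (k-1))/Q) x 100.  The pooled proportion and its CI are
the inverse logit of the pooled logit and its normal interval.

Baujat coordinates (per-study contribution to Q versus leave-one-out
influence on the pooled estimate) support outlier inspection; influential
studies are reported, never auto-excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .atlas_ingest import ValidationError
from .coverage import CoverageEstimate, inverse_logit, logit_ci

GROUPINGS = ("income_group", "who_region", "gbd_region",
             "gbd_super_region", "all")


@dataclass(frozen=True)
class PooledEstimate:
    """Group-level random-effects summary of contact coverage."""

    group_label: str
    k: int
    pooled_proportion: float
    ci_lower: float
    ci_upper: float
    tau2: float
    Q: float
    I2: float
    pooled_logit: float
    se_pooled_logit: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("a pooled estimate needs k >= 1 studies")
        if not (self.ci_lower <= self.pooled_proportion <= self.ci_upper):
            raise ValidationError("pooled CI must bracket the estimate")


@dataclass(frozen=True)
class BaujatPoint:
    country_code: str
    x: float  # contribution to overall heterogeneity Q
    y: float  # squared standardised change in the pooled estimate when deleted


def dl_random_effects(estimates: Sequence[tuple[float, float]],
                      group_label: str = "all") -> PooledEstimate:
    """DerSimonian–Laird random-effects pool of (logit, se) pairs.

    A single study passes through unchanged with tau2 = Q = I2 = 0.
    """
    if len(estimates) == 0:
        raise ValidationError(f"group {group_label!r} has no estimates")
    y = np.asarray([e[0] for e in estimates], dtype=float)
    se = np.asarray([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValidationError(
            f"group {group_label!r}: every estimate needs a positive SE")
    k = len(y)
    if k == 1:
        pooled_logit = float(y[0])
        se_pooled = float(se[0])
        tau2 = q = i2 = 0.0
    else:
        w = 1.0 / se**2
        ybar = float(np.sum(w * y) / np.sum(w))
        q = float(np.sum(w * (y - ybar) ** 2))
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        pooled_logit = float(np.sum(w_star * y) / np.sum(w_star))
        se_pooled = float(np.sqrt(1.0 / np.sum(w_star)))
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    ci_lower, ci_upper = logit_ci(pooled_logit, se_pooled)
    return PooledEstimate(
        group_label=group_label,
        k=k,
        pooled_proportion=inverse_logit(pooled_logit),
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        tau2=tau2,
        Q=q,
        I2=i2,
        pooled_logit=pooled_logit,
        se_pooled_logit=se_pooled,
    )


def aggregate_groups(estimates: Iterable[CoverageEstimate],
                     grouping: str) -> list[PooledEstimate]:
    """Pool included estimates per group, plus an all-countries row.

    ``grouping`` is one of income_group, who_region, gbd_region,
    gbd_super_region or all.  Excluded estimates never enter.
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}")
    included = [e for e in estimates if e.included]
    groups: dict[str, list[tuple[float, float]]] = {}
    for est in included:
        groups.setdefault(est.group_value(grouping), []).append(
            (est.logit, est.se_logit))
    pooled = [dl_random_effects(pairs, label)
              for label, pairs in sorted(groups.items())]
    if grouping != "all" and included:
        pooled.append(dl_random_effects(
            [(e.logit, e.se_logit) for e in included], "all"))
    return pooled


def baujat_coordinates(estimates: Sequence[CoverageEstimate],
                       ) -> list[BaujatPoint]:
    """Baujat diagnostic coordinates for a group of k >= 2 estimates.

    x_i is study i's contribution to Q under fixed-effect weights;
    y_i is the squared change in the fixed-effect pooled estimate when
    study i is deleted, standardised by the variance of the
    leave-one-out pool.
    """
    if len(estimates) < 2:
        raise ValidationError("Baujat diagnostics need at least 2 estimates")
    y = np.asarray([e.logit for e in estimates], dtype=float)
    se = np.asarray([e.se_logit for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValidationError("every estimate needs a positive SE")
    w = 1.0 / se**2
    pooled = float(np.sum(w * y) / np.sum(w))
    points = []
    for i, est in enumerate(estimates):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        w_i, y_i = w[mask], y[mask]
        pooled_without = float(np.sum(w_i * y_i) / np.sum(w_i))
        var_without = 1.0 / float(np.sum(w_i))
        points.append(BaujatPoint(
            country_code=est.country_code,
            x=float(w[i] * (y[i] - pooled) ** 2),
            y=(pooled - pooled_without) ** 2 / var_without,
        ))
    return points
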