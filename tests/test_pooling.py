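"""Random-effects pooling against an independent step-by-step oracle."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from mhcoverage.atlas_ingest import Disorder, ExclusionReason, IncomeGroup
from mhcoverage.coverage import CoverageEstimate, logit_ci
from mhcoverage.pooling import (ValidationError, aggregate_groups,
                                baujat_coordinates, dl_random_effects)

# Fixed heterogeneous 5-study fixture (logit, se) used throughout.
FIVE_STUDIES = [(-1.2, 0.30), (-0.4, 0.15), (0.1, 0.22), (0.9, 0.45),
                (-0.8, 0.18)]


def dl_by_hand(studies):
    """Step-by-step textbook DerSimonian–Laird, written independently.

    Plain-loop arithmetic only; serves as the oracle for the vectorised
    implementation.
    """
    k = len(studies)
    w = [1.0 / se**2 for _, se in studies]
    sw = sum(w)
    ybar = sum(wi * y for wi, (y, _) in zip(w, studies)) / sw
    q = sum(wi * (y - ybar) ** 2 for wi, (y, _) in zip(w, studies))
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = [1.0 / (se**2 + tau2) for _, se in studies]
    pooled = sum(wi * y for wi, (y, _) in zip(w_star, studies)) / sum(w_star)
    se_pooled = math.sqrt(1.0 / sum(w_star))
    return pooled, se_pooled, tau2, q


class TestDLRandomEffects:
    def test_matches_hand_oracle_on_heterogeneous_fixture(self):
        pooled, se_pooled, tau2, q = dl_by_hand(FIVE_STUDIES)
        out = dl_random_effects(FIVE_STUDIES)
        assert out.pooled_logit == pytest.approx(pooled, abs=1e-10)
        assert out.se_pooled_logit == pytest.approx(se_pooled, abs=1e-10)
        assert out.tau2 == pytest.approx(tau2, abs=1e-10)
        assert out.Q == pytest.approx(q, abs=1e-10)

    def test_homogeneous_studies_have_no_heterogeneity(self):
        out = dl_random_effects([(0.0, 0.1)] * 3)
        assert out.pooled_logit == 0.0
        assert out.tau2 == 0.0 and out.Q == 0.0 and out.I2 == 0.0
        assert out.pooled_proportion == pytest.approx(0.5)

    def test_singleton_passes_through(self):
        out = dl_random_effects([(1.0, 0.2)])
        assert out.pooled_logit == 1.0 and out.tau2 == 0.0 and out.k == 1
        lo, hi = logit_ci(1.0, 0.2)
        assert (out.ci_lower, out.ci_upper) == pytest.approx((lo, hi))
        # CI half-width on the logit scale is 1.96 × 0.2 ≈ 0.392
        assert math.log(hi / (1 - hi)) - 1.0 == pytest.approx(
            1.959964 * 0.2, abs=1e-9)

    def test_zero_tau2_equals_fixed_effect_pooling(self):
        # homogeneous-enough studies so Q < k-1 forces tau2 to 0
        studies = [(0.10, 0.30), (0.12, 0.25), (0.11, 0.40)]
        out = dl_random_effects(studies)
        assert out.tau2 == 0.0
        w = [1 / se**2 for _, se in studies]
        fixed = sum(wi * y for wi, (y, _) in zip(w, studies)) / sum(w)
        assert out.pooled_logit == pytest.approx(fixed, abs=1e-12)

    def test_pooled_estimate_within_input_range(self):
        out = dl_random_effects(FIVE_STUDIES)
        ys = [y for y, _ in FIVE_STUDIES]
        assert min(ys) <= out.pooled_logit <= max(ys)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            perm = [FIVE_STUDIES[i]
                    for i in rng.permutation(len(FIVE_STUDIES))]
            a, b = dl_random_effects(FIVE_STUDIES), dl_random_effects(perm)
            assert a.pooled_logit == pytest.approx(b.pooled_logit, abs=1e-14)
            assert a.tau2 == pytest.approx(b.tau2, abs=1e-14)

    def test_degenerate_weight_rejected(self):
        with pytest.raises(ValidationError):
            dl_random_effects([(0.0, 0.0), (0.1, 0.2)])

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            dl_random_effects([])


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not on PATH")
class TestAgainstMetafor:
    def test_matches_metafor_dl(self, tmp_path):
        """Cross-check against the reference meta-analysis implementation."""
        script = tmp_path / "dl.R"
        rows = ";".join(f"{y},{se}" for y, se in FIVE_STUDIES)
        script.write_text(f"""
            suppressMessages(library(metafor))
            d <- do.call(rbind, lapply(strsplit(strsplit("{rows}", ";")[[1]],
                         ","), as.numeric))
            fit <- rma(yi = d[,1], sei = d[,2], method = "DL")
            cat(sprintf("%.12f %.12f %.12f %.12f", coef(fit), fit$se,
                        fit$tau2, fit$QE))
        """)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        pooled, se_pooled, tau2, q = map(float, out.stdout.split())
        ours = dl_random_effects(FIVE_STUDIES)
        assert ours.pooled_logit == pytest.approx(pooled, abs=1e-8)
        assert ours.se_pooled_logit == pytest.approx(se_pooled, abs=1e-8)
        assert ours.tau2 == pytest.approx(tau2, abs=1e-8)
        assert ours.Q == pytest.approx(q, abs=1e-8)


def make_estimate(code, c, se_logit, income=IncomeGroup.LOW, who="AFR",
                  included=True):
    logit = math.log(c / (1 - c))
    lo, hi = logit_ci(logit, se_logit)
    reason = ExclusionReason.OK if included else ExclusionReason.OUTSIDE_THRESHOLD
    return CoverageEstimate(
        country_code=code, disorder=Disorder.PSYCHOSIS, income_group=income,
        who_region=who, gbd_region="r", gbd_super_region="sr",
        proportion=c, se=0.01, logit=logit, se_logit=se_logit,
        ci_lower=lo, ci_upper=hi, included=included, exclusion_reason=reason)


class TestAggregateGroups:
    def test_partition_plus_all_row(self):
        ests = [make_estimate(f"A{i}{g.value[0]}", 0.1 + 0.01 * i, 0.2,
                              income=g)
                for g in IncomeGroup for i in range(3)]
        pooled = aggregate_groups(ests, "income_group")
        labels = [p.group_label for p in pooled]
        assert len(pooled) == 5 and "all" in labels

    def test_singleton_group_reports_raw_estimate(self):
        ests = [make_estimate("AAA", 0.217, 0.3)]
        pooled = aggregate_groups(ests, "who_region")
        by_label = {p.group_label: p for p in pooled}
        assert by_label["AFR"].k == 1
        assert by_label["AFR"].pooled_proportion == pytest.approx(0.217)
        assert by_label["AFR"].tau2 == 0.0

    def test_excluded_estimates_enter_no_group(self):
        ests = [make_estimate("AAA", 0.2, 0.2),
                make_estimate("BBB", 0.3, 0.2),
                make_estimate("CCC", 0.9, 0.2, included=False)]
        pooled = aggregate_groups(ests, "all")
        assert pooled[0].k == 2

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_groups([], "continent")


class TestBaujat:
    def test_planted_outlier_attains_both_maxima(self):
        rng = np.random.default_rng(3)
        ests = [make_estimate(f"C{i:02d}", 0.20 + 0.002 * float(rng.random()),
                              0.15) for i in range(9)]
        ests.append(make_estimate("OUT", 0.85, 0.15))
        points = baujat_coordinates(ests)
        top = max(points, key=lambda p: p.x)
        assert top.country_code == "OUT"
        assert max(points, key=lambda p: p.y).country_code == "OUT"

    def test_leave_one_out_brute_force(self):
        ests = [make_estimate(f"C{i}", c, se) for i, (c, se) in
                enumerate([(0.1, 0.2), (0.2, 0.3), (0.4, 0.25), (0.15, 0.4)])]
        points = baujat_coordinates(ests)
        y = [e.logit for e in ests]
        w = [1 / e.se_logit**2 for e in ests]
        pooled = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
        for i, pt in enumerate(points):
            rest = [j for j in range(len(y)) if j != i]
            pooled_wo = (sum(w[j] * y[j] for j in rest)
                         / sum(w[j] for j in rest))
            var_wo = 1.0 / sum(w[j] for j in rest)
            assert pt.x == pytest.approx(w[i] * (y[i] - pooled) ** 2,
                                         abs=1e-12)
            assert pt.y == pytest.approx((pooled - pooled_wo) ** 2 / var_wo,
                                         abs=1e-12)

    def test_homogeneous_studies_sit_near_origin(self):
        ests = [make_estimate(f"C{i}", 0.2, 0.2) for i in range(4)]
        points = baujat_coordinates(ests)
        assert all(p.x < 1e-20 and p.y < 1e-20 for p in points)

    def test_two_studies_symmetric_influence(self):
        ests = [make_estimate("AAA", 0.2, 0.2), make_estimate("BBB", 0.4, 0.2)]
        a, b = baujat_coordinates(ests)
        assert a.x == pytest.approx(b.x)
        assert a.y == pytest.approx(b.y)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            baujat_coordinates([make_estimate("AAA", 0.2, 0.2)])
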