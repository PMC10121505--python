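import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spinemorph.stats import (
    AgreementReport,
    BlandAltman,
    ContingencyCounts,
    bland_altman,
    ci_overlap_significant,
    cohens_kappa,
    diagnostic_metrics,
    icc,
    kappa_from_table,
    koo_band,
    landis_koch_band,
)
from oracles import clopper_pearson, icc2_variance_components


class TestICC:
    def test_identical_ratings_give_one(self):
        x = np.column_stack([np.arange(1.0, 11.0)] * 2)
        rep = icc(x, form="ICC2")
        assert rep.estimate == pytest.approx(1.0)

    def test_constant_offset_consistency_vs_agreement(self):
        a = np.arange(1.0, 6.0)
        x = np.column_stack([a, a + 1.0])
        assert icc(x, form="ICC2").estimate < 1.0
        assert icc(x, form="ICC3").estimate == pytest.approx(1.0)

    def test_koo_bands(self):
        assert koo_band(0.85) == "good"
        assert koo_band(0.846) == "good"
        assert koo_band(0.95) == "excellent"
        assert koo_band(0.6) == "moderate"
        assert koo_band(0.3) == "poor"

    def test_band_attached(self):
        rng = np.random.default_rng(0)
        subj = rng.normal(0, 5, 20)
        x = np.column_stack([subj + rng.normal(0, 1, 20),
                             subj + rng.normal(0, 1, 20)])
        rep = icc(x)
        assert rep.band == koo_band(rep.estimate)

    def test_zero_between_subject_variance_error(self):
        x = np.array([[1.0, 2.0]] * 6)
        with pytest.raises(ValueError, match="between-subject"):
            icc(x)

    def test_too_few_subjects_or_raters(self):
        with pytest.raises(ValueError):
            icc(np.ones((3, 2)))
        with pytest.raises(ValueError):
            icc(np.ones((10, 1)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_variance_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        subj = rng.normal(0, 3, 10)
        x = np.column_stack([subj + rng.normal(0.5, 1, 10),
                             subj + rng.normal(0, 1, 10)])
        rep = icc(x, form="ICC2")
        assert rep.estimate == pytest.approx(icc2_variance_components(x),
                                             abs=1e-8)

    @pytest.mark.parametrize("form,pg_type", [("ICC1", "ICC(1,1)"),
                                              ("ICC2", "ICC(A,1)"),
                                              ("ICC3", "ICC(C,1)"),
                                              ("ICC2k", "ICC(A,k)")])
    def test_matches_pingouin(self, form, pg_type):
        rng = np.random.default_rng(42)
        subj = rng.normal(0, 3, 12)
        data = []
        for i, s in enumerate(subj):
            for j in range(3):
                data.append({"subject": i, "rater": f"r{j}",
                             "score": s + rng.normal(0.2 * j, 1)})
        df = pd.DataFrame(data)
        wide = df.pivot(index="subject", columns="rater",
                        values="score").to_numpy()
        ours = icc(wide, form=form)
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        assert ours.estimate == pytest.approx(ref.loc[pg_type, "ICC"],
                                              abs=1e-9)
        lo, hi = ref.loc[pg_type, "CI95"]  # pingouin rounds to 2 decimals
        assert ours.ci_low == pytest.approx(lo, abs=6e-3)
        assert ours.ci_high == pytest.approx(hi, abs=6e-3)


class TestKappa:
    def test_identical_vectors(self):
        a = np.array([1, 1, 0, 0, 1])
        assert cohens_kappa(a, a).estimate == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        a = np.array(["+", "+", "-", "-"])
        b = np.array(["-", "-", "+", "+"])
        assert cohens_kappa(a, b).estimate == pytest.approx(-1.0)

    def test_agreement_table_45_5_5_45(self):
        rep = kappa_from_table(np.array([[45, 5], [5, 45]]))
        assert rep.estimate == pytest.approx(0.8)
        assert rep.extra["po"] == pytest.approx(0.9)
        assert rep.extra["pe"] == pytest.approx(0.5)

    def test_constant_raters_undefined(self):
        a = np.zeros(10)
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa(a, a)

    def test_landis_koch_bands(self):
        assert landis_koch_band(0.907) == "almost perfect"
        assert landis_koch_band(0.7) == "substantial"
        assert landis_koch_band(-0.2) == "poor"

    @settings(max_examples=60, deadline=None)
    @given(labels=st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                           min_size=4, max_size=40))
    def test_kappa_bounded_and_one_iff_perfect(self, labels):
        a = np.array([p[0] for p in labels])
        b = np.array([p[1] for p in labels])
        try:
            rep = cohens_kappa(a, b)
        except ValueError:
            return  # degenerate: expected agreement 1
        assert -1.0 - 1e-12 <= rep.estimate <= 1.0 + 1e-12
        assert (rep.estimate == pytest.approx(1.0)) == bool((a == b).all())


class TestBlandAltman:
    def test_identical_measurements(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(a, a)
        assert ba.mean_diff == 0.0 and ba.loa_halfwidth == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(a, a + 0.5)
        assert ba.mean_diff == pytest.approx(-0.5)
        assert ba.loa_halfwidth == pytest.approx(0.0)

    def test_alternating_differences(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.zeros(4)
        ba = bland_altman(a, b)
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(np.std(a, ddof=1))
        assert ba.loa_halfwidth == pytest.approx(1.96 * 1.1547, abs=1e-3)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])

    def test_limits_bracket_mean(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(size=50)
        ba = bland_altman(a, b)
        assert ba.loa_low <= ba.mean_diff <= ba.loa_high


class TestDiagnosticMetrics:
    def test_entire_cohort_counts(self):
        counts = ContingencyCounts(tp=224, fp=24, tn=738, fn=14)
        m = diagnostic_metrics(counts)
        assert round(m["sensitivity"].estimate, 3) == 0.941
        assert round(m["specificity"].estimate, 3) == 0.969
        assert round(m["accuracy"].estimate, 3) == 0.962

    def test_inhouse_accuracy(self):
        m = diagnostic_metrics(ContingencyCounts(tp=112, fp=13, tn=365, fn=5))
        assert round(m["accuracy"].estimate, 3) == 0.964

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ContingencyCounts(tp=10, fp=0, tn=20, fn=0))
        for rep in m.values():
            assert rep.estimate == 1.0

    def test_zero_denominator_flagged_not_fatal(self):
        m = diagnostic_metrics(ContingencyCounts(tp=0, fp=0, tn=20, fn=0))
        assert np.isnan(m["sensitivity"].estimate)
        assert "undefined" in m["sensitivity"].extra["note"]
        assert m["specificity"].estimate == 1.0

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            ContingencyCounts(tp=-1, fp=0, tn=1, fn=0)
        with pytest.raises(ValueError):
            ContingencyCounts(tp=0, fp=0, tn=0, fn=0)

    def test_clopper_pearson_matches_beta_quantiles(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 500))
            x = int(rng.integers(0, n + 1))
            counts = ContingencyCounts(tp=x, fp=0, tn=1, fn=n - x)
            rep = diagnostic_metrics(counts)["sensitivity"]
            lo, hi = clopper_pearson(x, n)
            assert rep.ci_low == pytest.approx(lo, abs=1e-9)
            assert rep.ci_high == pytest.approx(hi, abs=1e-9)
            assert rep.ci_low <= rep.estimate <= rep.ci_high

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (10, 100, 1000, 10000):
            x = int(0.7 * n)
            rep = diagnostic_metrics(
                ContingencyCounts(tp=x, fp=0, tn=1, fn=n - x))["sensitivity"]
            widths.append(rep.ci_high - rep.ci_low)
        assert widths == sorted(widths, reverse=True)

    def test_wilson_alternative(self):
        counts = ContingencyCounts(tp=224, fp=24, tn=738, fn=14)
        cp = diagnostic_metrics(counts, method="clopper-pearson")
        wi = diagnostic_metrics(counts, method="wilson")
        assert cp["sensitivity"].ci_low != wi["sensitivity"].ci_low
        with pytest.raises(ValueError):
            diagnostic_metrics(counts, method="bayes")


class TestCIOverlap:
    def test_published_overlapping_intervals(self):
        a = AgreementReport("sens-a", 0.941, 0.903, 0.968, 238)
        b = AgreementReport("sens-b", 0.969, 0.954, 0.980, 762)
        assert not ci_overlap_significant(a, b)

    def test_disjoint_significant(self):
        a = AgreementReport("x", 0.15, 0.10, 0.20, 50)
        b = AgreementReport("y", 0.35, 0.30, 0.40, 50)
        assert ci_overlap_significant(a, b)
        assert ci_overlap_significant(b, a)

    def test_touching_endpoints_not_significant(self):
        a = AgreementReport("x", 0.2, 0.10, 0.30, 50)
        b = AgreementReport("y", 0.35, 0.30, 0.40, 50)
        assert not ci_overlap_significant(a, b)

    def test_undefined_ci_error(self):
        a = AgreementReport("x", float("nan"), float("nan"), float("nan"), 0)
        b = AgreementReport("y", 0.3, 0.2, 0.4, 10)
        with pytest.raises(ValueError):
            ci_overlap_significant(a, b)

    def test_report_invariant(self):
        with pytest.raises(ValueError):
            AgreementReport("bad", 0.5, 0.6, 0.7, 10)
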