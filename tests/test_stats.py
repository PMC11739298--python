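"""Statistics battery: frozen printed-value checks, closed-form and
simulation oracles, and cross-checks against an independent implementation
(pingouin) for the ANOVA path."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from swaquant import stats as qstats
from swaquant.stats import GroupSummary

# printed baseline T-maze group summaries (percent correct)
EARLY_TG = GroupSummary(17, 42.65, 14.99)
EARLY_WT = GroupSummary(18, 79.63, 28.18)
LATE_TG = GroupSummary(20, 53.75, 29.43)
LATE_WT = GroupSummary(18, 75.93, 18.28)
# insoluble Abeta-40 (pg/mg)
ELISA_SO = GroupSummary(5, 4.982, 0.379)
ELISA_PL = GroupSummary(5, 4.459, 0.158)


def _raw_with_exact_summary(s: GroupSummary, rng) -> np.ndarray:
    """Raw values whose sample mean/SD equal the summary exactly."""
    x = rng.standard_normal(s.n)
    x = (x - x.mean()) / x.std(ddof=1)
    return s.mean + s.sd * x


class TestIndependentT:
    def test_welch_reproduces_printed_early_cohort(self):
        res = qstats.independent_t(EARLY_WT, EARLY_TG, variant="welch")
        assert res.t == pytest.approx(4.884, abs=0.01)
        assert res.df == pytest.approx(26.21, abs=0.1)
        assert res.p < 0.001

    def test_student_reproduces_printed_late_cohort(self):
        res = qstats.independent_t(LATE_WT, LATE_TG, variant="student")
        assert res.t == pytest.approx(2.753, abs=0.01)
        assert res.df == 36

    def test_identical_groups_null(self, rng):
        x = rng.standard_normal(20)
        res = qstats.independent_t(x, x.copy(), variant="student")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_summary_equals_raw(self, rng):
        """Student t from summaries equals Student t from raw data generated
        to those exact summaries."""
        g1 = _raw_with_exact_summary(EARLY_TG, rng)
        g2 = _raw_with_exact_summary(EARLY_WT, rng)
        from_raw = qstats.independent_t(g1, g2, variant="student")
        from_sum = qstats.independent_t(EARLY_TG, EARLY_WT, variant="student")
        assert from_raw.t == pytest.approx(from_sum.t, abs=1e-9)
        assert from_raw.df == from_sum.df

    def test_auto_variant_uses_levene(self, rng):
        equal = rng.standard_normal(30)
        unequal = rng.standard_normal(30) * 6.0
        assert qstats.independent_t(equal, rng.standard_normal(30),
                                    variant="auto").variant == "student"
        assert qstats.independent_t(equal, unequal,
                                    variant="auto").variant == "welch"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            qstats.independent_t(np.ones(5), np.full(5, 2.0), variant="student")

    def test_ci_covers_difference_sign(self):
        res = qstats.independent_t(EARLY_WT, EARLY_TG, variant="welch")
        lo, hi = res.ci95
        assert lo > 0 and hi > lo  # WT clearly above Tg


class TestCohensD:
    @pytest.mark.parametrize("g1,g2,expected", [
        (EARLY_WT, EARLY_TG, 1.64),
        (LATE_WT, LATE_TG, 0.91),
        (ELISA_SO, ELISA_PL, 1.80),
    ])
    def test_reproduces_printed_values(self, g1, g2, expected):
        assert qstats.cohens_d_independent(g1, g2) == pytest.approx(expected,
                                                                    abs=0.01)

    def test_equal_means_zero(self):
        assert qstats.cohens_d_independent(GroupSummary(5, 3.0, 1.0),
                                           GroupSummary(5, 3.0, 2.0)) == 0.0

    def test_both_sds_zero_rejected(self):
        with pytest.raises(ValueError):
            qstats.cohens_d_independent(GroupSummary(5, 1.0, 0.0),
                                        GroupSummary(5, 2.0, 0.0))


class TestPairedT:
    def test_no_change_gives_zero(self, rng):
        x = rng.standard_normal(10)
        res = qstats.paired_t(x, x.copy())
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_shift_degenerate(self):
        with pytest.raises(ValueError):
            qstats.paired_t(np.arange(5.0), np.arange(5.0) + 1.0)

    def test_sign_convention_improvement_positive(self, rng):
        before = rng.standard_normal(12)
        res = qstats.paired_t(before, before + 2.0 + 0.1 * rng.standard_normal(12))
        assert res.t > 0 and res.d > 0

    def test_power_matches_noncentral_t_closed_form(self):
        """Simulated power for a 1-sigma paired shift at n=10 vs the
        noncentral-t closed form."""
        n, delta, sd = 10, 1.0, 1.0
        nc = delta / (sd / np.sqrt(n))
        tcrit = sps.t.ppf(0.975, n - 1)
        power_exact = sps.nct.sf(tcrit, n - 1, nc) + sps.nct.cdf(-tcrit, n - 1, nc)
        rng = np.random.default_rng(77)
        hits = 0
        reps = 1000
        for _ in range(reps):
            before = rng.standard_normal(n)
            after = before + rng.normal(delta, sd, n)
            hits += qstats.paired_t(before, after).p < 0.05
        assert hits / reps == pytest.approx(power_exact, abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qstats.paired_t(np.zeros(4), np.zeros(5))


def _bh_oracle(p):
    """Hand implementation of Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestHourlyFdr:
    def _gains(self, rng, n_sub, shift_by_hour):
        data = {h: rng.standard_normal(n_sub) + mu
                for h, mu in enumerate(shift_by_hour)}
        return pd.DataFrame(data)

    def test_uniform_p_unchanged_by_bh(self, rng):
        """Identical data in every hour -> identical raw p, and BH leaves a
        constant p-vector unchanged."""
        a_col = rng.standard_normal(8)
        b_col = rng.standard_normal(8) + 1.0
        a = pd.DataFrame({h: a_col for h in range(24)})
        b = pd.DataFrame({h: b_col for h in range(24)})
        out = qstats.hourly_gain_tests_fdr(a, b)
        assert np.allclose(out["p_adj"], out["p_raw"])

    def test_adjustment_matches_hand_bh(self, rng):
        a = self._gains(rng, 8, [3.0] + [0.0] * 23)
        b = self._gains(rng, 8, [0.0] * 24)
        out = qstats.hourly_gain_tests_fdr(a, b)
        assert np.allclose(out["p_adj"], _bh_oracle(out["p_raw"]))
        assert bool(out.loc[out["zt_hour"] == 0, "significant"].iloc[0])

    def test_bh_monotone_and_never_decreases(self, rng):
        a = self._gains(rng, 6, rng.uniform(0, 1.5, 24))
        b = self._gains(rng, 6, np.zeros(24))
        out = qstats.hourly_gain_tests_fdr(a, b).sort_values("p_raw")
        assert np.all(out["p_adj"].to_numpy() >= out["p_raw"].to_numpy())
        assert np.all(np.diff(out["p_adj"].to_numpy()) >= -1e-12)

    def test_insufficient_subjects_rejected(self):
        a = pd.DataFrame({0: [1.0]})
        b = pd.DataFrame({0: [1.0, 2.0]})
        with pytest.raises(ValueError):
            qstats.hourly_gain_tests_fdr(a, b)


def _anova_frame(rng, means, ns):
    rows = []
    for (gen, trt), mu in means.items():
        for _ in range(ns[(gen, trt)]):
            rows.append({"genotype": gen, "treatment": trt,
                         "value": rng.normal(mu, 1.0)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    MEANS = {("WT", "placebo"): 0.0, ("WT", "SO"): 1.0,
             ("Tg", "placebo"): 2.0, ("Tg", "SO"): 3.0}

    def test_additive_effects_no_interaction(self, rng):
        ns = {k: 40 for k in self.MEANS}
        res = qstats.two_way_anova(_anova_frame(rng, self.MEANS, ns))
        inter = res.effects["genotype:treatment"]
        assert inter.p > 0.01
        assert res.effects["genotype"].p < 1e-4
        assert res.effects["treatment"].p < 1e-4

    def test_eta_identity_holds(self, rng):
        ns = {("WT", "placebo"): 7, ("WT", "SO"): 7,
              ("Tg", "placebo"): 9, ("Tg", "SO"): 9}
        res = qstats.two_way_anova(_anova_frame(rng, self.MEANS, ns))
        for e in res.effects.values():
            assert e.eta_p_sq == pytest.approx(
                e.F * e.df1 / (e.F * e.df1 + e.df2), abs=1e-12)

    def test_matches_pingouin_on_unbalanced_data(self, rng):
        pg = pytest.importorskip("pingouin")
        ns = {("WT", "placebo"): 7, ("WT", "SO"): 9,
              ("Tg", "placebo"): 5, ("Tg", "SO"): 11}
        df = _anova_frame(rng, self.MEANS, ns)
        res = qstats.two_way_anova(df)
        ref = pg.anova(data=df, dv="value", between=["genotype", "treatment"],
                       ss_type=3).set_index("Source")
        for ours, theirs in [("genotype", "genotype"),
                             ("treatment", "treatment"),
                             ("genotype:treatment", "genotype * treatment")]:
            assert res.effects[ours].F == pytest.approx(ref.loc[theirs, "F"],
                                                        rel=1e-6)
            assert res.effects[ours].eta_p_sq == pytest.approx(
                ref.loc[theirs, "np2"], rel=1e-6)

    def test_pairwise_comparisons_reported(self, rng):
        ns = {k: 8 for k in self.MEANS}
        res = qstats.two_way_anova(_anova_frame(rng, self.MEANS, ns))
        assert len(res.pairwise) == 4
        for pw in res.pairwise:
            lo, hi = pw.ci95
            assert lo < pw.difference < hi

    def test_empty_cell_rejected(self, rng):
        ns = {k: 8 for k in self.MEANS}
        df = _anova_frame(rng, self.MEANS, ns)
        df = df[~((df.genotype == "WT") & (df.treatment == "SO"))]
        with pytest.raises(ValueError):
            qstats.two_way_anova(df)

    def test_genotype_shift_detected_with_power(self):
        """Detection rate of a 1-SD genotype shift at the study's cell sizes
        matches the noncentral-F closed form (and is substantial)."""
        rng = np.random.default_rng(42)
        means = {("WT", "placebo"): 0.0, ("WT", "SO"): 0.0,
                 ("Tg", "placebo"): 1.0, ("Tg", "SO"): 1.0}
        ns = {("WT", "placebo"): 7, ("WT", "SO"): 7,
              ("Tg", "placebo"): 9, ("Tg", "SO"): 9}
        hits = sum(qstats.two_way_anova(_anova_frame(rng, means, ns))
                   .effects["genotype"].p < 0.05 for _ in range(200))
        # genotype contrast c = (-1/2,-1/2,1/2,1/2) over cell means:
        # lambda = d^2 / (sigma^2 * sum c_i^2/n_i) = 4 / sum(1/n_i)
        lam = 4.0 / (1 / 7 + 1 / 7 + 1 / 9 + 1 / 9)
        fcrit = sps.f.ppf(0.95, 1, 28)
        power = sps.ncf.sf(fcrit, 1, 28, lam)
        assert hits / 200 == pytest.approx(power, abs=0.06)
        assert hits / 200 > 0.6


class TestPartialEtaSq:
    @pytest.mark.parametrize("F,eta", [
        (3.807, 0.120), (10.820, 0.279), (3.634, 0.115),
        (4.054, 0.126), (13.965, 0.333), (2.951, 0.095),
    ])
    def test_reproduces_printed_values(self, F, eta):
        assert qstats.partial_eta_sq_from_f(F, 1, 28) == pytest.approx(eta,
                                                                       abs=0.001)

    def test_zero_f(self):
        assert qstats.partial_eta_sq_from_f(0.0, 1, 28) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            qstats.partial_eta_sq_from_f(-1.0, 1, 28)


def _split_search(r_pb, n, target_rb, tol=1e-3):
    """Brute-force oracle: which success counts reproduce the printed r_b."""
    return [k for k in range(1, n)
            if abs(qstats.biserial_from_point_biserial(r_pb, n, k).r - target_rb)
            < tol]


class TestBiserial:
    def test_early_cohort_printed_value(self):
        splits = _split_search(0.653, 8, 0.819)
        assert splits == [4]  # only the balanced split reproduces the print
        res = qstats.biserial_from_point_biserial(0.653, 8, 4)
        assert res.r == pytest.approx(0.819, abs=0.001)

    def test_late_cohort_printed_value(self):
        splits = _split_search(0.563, 9, 0.786)
        assert splits == [2, 7]  # 7/2 split (either labelling) matches
        res = qstats.biserial_from_point_biserial(0.563, 9, 7)
        assert res.r == pytest.approx(0.786, abs=0.001)

    def test_null_r_stays_null(self):
        for k in range(1, 8):
            assert qstats.biserial_from_point_biserial(0.0, 8, k).r == 0.0

    @given(r_pb=st.floats(-0.95, 0.95), n=st.integers(5, 40),
           frac=st.floats(0.1, 0.9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_magnitude_amplified_and_label_symmetric(self, r_pb, n, frac):
        k = min(max(int(frac * n), 1), n - 1)
        res = qstats.biserial_from_point_biserial(r_pb, n, k)
        if abs(r_pb) > 1e-12:
            assert abs(res.r) > abs(r_pb)
        flipped = qstats.biserial_from_point_biserial(-r_pb, n, n - k)
        assert res.r == pytest.approx(-flipped.r, abs=1e-9)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            qstats.biserial_from_point_biserial(0.5, 8, 0)
        with pytest.raises(ValueError):
            qstats.biserial_from_point_biserial(0.5, 8, 8)

    def test_from_raw_data_agrees_with_pointbiserialr(self, rng):
        x = rng.standard_normal(20)
        succ = x + rng.standard_normal(20) > 0
        res = qstats.biserial_corr(x, succ)
        ref = sps.pointbiserialr(succ.astype(float), x)
        assert res.r_pb == pytest.approx(ref.correlation, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert qstats.pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_inverse(self):
        assert qstats.pearson_corr([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        hits = sum(qstats.pearson_corr(rng.standard_normal(6),
                                       rng.standard_normal(6)).p < 0.05
                   for _ in range(1000))
        # binomial 99% envelope around 0.05 at 1000 reps
        assert abs(hits / 1000 - 0.05) < 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            qstats.pearson_corr(np.ones(5), np.arange(5.0))


class TestAssumptionScreen:
    def test_fence_flags_extreme_value(self):
        screen = qstats.screen_assumptions({"g": [1.0, 2.0, 3.0, 100.0]})
        assert list(screen.outliers["g"]) == [100.0]

    def test_identical_groups_levene_null(self):
        screen = qstats.screen_assumptions({"a": [1.0, 2.0, 3.0],
                                            "b": [1.0, 2.0, 3.0]})
        assert screen.levene_stat == 0.0
        assert screen.levene_p == 1.0

    def test_levene_type_i_error_calibrated(self):
        rng = np.random.default_rng(8)
        hits = sum(qstats.screen_assumptions(
            {"a": rng.standard_normal(20), "b": rng.standard_normal(20)}
        ).levene_p < 0.05 for _ in range(1000))
        assert abs(hits / 1000 - 0.05) < 0.02

    def test_moments_reported_per_group(self, rng):
        x = rng.standard_normal(50)
        screen = qstats.screen_assumptions({"a": x, "b": x ** 2})
        assert abs(screen.skewness["a"]) < 1.0
        assert screen.skewness["b"] > 1.0
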