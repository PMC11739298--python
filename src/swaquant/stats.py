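"""The preclinical statistics battery.

Implements the analysis conventions used throughout the study: independent
t-tests (Student or Welch, selectable or Levene-driven), Cohen's d on the
unweighted average of the two group variances, paired t-tests, per-hour
t-test series with Benjamini-Hochberg FDR correction, two-way
genotype x treatment ANOVA with Type-III sums of squares, partial eta
squared and unadjusted pairwise comparisons, the point-biserial to biserial
correlation transformation, Pearson correlation, and the assumption screen
(boxplot outlier fences, skewness/kurtosis, Levene's test).

All tests are two-sided at alpha = 0.05 unless stated otherwise. Group
inputs may be raw value arrays or printed summary statistics
(``GroupSummary(n, mean, sd)``); t-tests and effect sizes are computable
from summaries alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary", "TTestResult", "AnovaResult", "EffectResult",
    "PairwiseComparison", "CorrelationResult", "AssumptionScreen",
    "independent_t", "cohens_d_independent", "paired_t",
    "hourly_gain_tests_fdr", "two_way_anova", "partial_eta_sq_from_f",
    "biserial_from_point_biserial", "biserial_corr", "pearson_corr",
    "screen_assumptions",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed-style group summary: sample size, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, x) -> "GroupSummary":
        x = np.asarray(x, float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    d: float                  # Cohen's d, sign matching t
    ci95: tuple               # 95% CI for the mean difference
    variant: str              # "student" | "welch" | "paired"

    def summary(self) -> str:
        lo, hi = self.ci95
        return (f"t({self.df:.2f}) = {self.t:.3f}, p = {self.p:.3g}, "
                f"d = {self.d:.2f}, 95% CI [{lo:.3f}, {hi:.3f}] ({self.variant})")


@dataclass
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float


@dataclass
class PairwiseComparison:
    label: str
    difference: float
    ci95: tuple
    p: float


@dataclass
class AnovaResult:
    effects: dict                      # name -> EffectResult
    pairwise: list = field(default_factory=list)
    cell_means: pd.DataFrame | None = None
    residual_ms: float = float("nan")

    def summary(self) -> str:
        lines = []
        for name, e in self.effects.items():
            lines.append(f"{name}: F({e.df1}, {e.df2}) = {e.F:.3f}, "
                         f"p = {e.p:.3g}, eta_p^2 = {e.eta_p_sq:.3f}")
        for pw in self.pairwise:
            lo, hi = pw.ci95
            lines.append(f"  {pw.label}: diff = {pw.difference:.3f} "
                         f"[{lo:.3f}, {hi:.3f}], p = {pw.p:.3g}")
        return "\n".join(lines)


@dataclass
class CorrelationResult:
    kind: str                 # "pearson" | "point_biserial" | "biserial"
    r: float
    n: int
    p: float
    r_pb: float | None = None        # for biserial: the underlying point-biserial r
    p_success: float | None = None   # success proportion of the dichotomy
    ordinate: float | None = None    # normal density at the p_success quantile

    def summary(self) -> str:
        base = f"{self.kind}: r = {self.r:.3f} (n = {self.n}), p = {self.p:.3g}"
        if self.kind == "biserial":
            base += f" [r_pb = {self.r_pb:.3f}, p_success = {self.p_success:.3f}]"
        return base


@dataclass
class AssumptionScreen:
    outliers: dict            # group label -> array of flagged values
    skewness: dict            # group label -> sample skewness
    kurtosis: dict            # group label -> sample excess kurtosis
    levene_stat: float
    levene_p: float


def _as_summary(g) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return GroupSummary.from_values(g)


def cohens_d_independent(g1, g2) -> float:
    """Cohen's d on the unweighted average of the two group variances.

    d = |m1 − m2| / sqrt((sd1² + sd2²) / 2). This variant (rather than the
    n-weighted pooled SD) matches the study's printed effect sizes.
    """
    s1, s2 = _as_summary(g1), _as_summary(g2)
    denom = np.sqrt((s1.sd ** 2 + s2.sd ** 2) / 2.0)
    if denom == 0:
        raise ValueError("both group SDs are zero; d undefined")
    return float(abs(s1.mean - s2.mean) / denom)


def independent_t(g1, g2, variant: str = "auto") -> TTestResult:
    """Two-sample t-test from raw values or printed summaries.

    ``variant``: "student" (pooled), "welch", or "auto" (Welch when Levene's
    test on the raw values rejects homogeneity at alpha = 0.05, Student
    otherwise; raw values required for "auto").
    """
    raw = not isinstance(g1, GroupSummary) and not isinstance(g2, GroupSummary)
    s1, s2 = _as_summary(g1), _as_summary(g2)
    if s1.sd == 0 and s2.sd == 0:
        raise ValueError("zero variance in both groups")
    if variant == "auto":
        if not raw:
            raise ValueError("variant='auto' needs raw values (Levene); "
                             "choose 'student' or 'welch' for summary input")
        _, lev_p = sps.levene(np.asarray(g1, float), np.asarray(g2, float),
                              center="mean")
        variant = "welch" if lev_p < 0.05 else "student"
    diff = s1.mean - s2.mean
    if variant == "student":
        sp2 = (((s1.n - 1) * s1.sd ** 2 + (s2.n - 1) * s2.sd ** 2)
               / (s1.n + s2.n - 2))
        se = np.sqrt(sp2 * (1.0 / s1.n + 1.0 / s2.n))
        df = s1.n + s2.n - 2
    elif variant == "welch":
        v1, v2 = s1.sd ** 2 / s1.n, s2.sd ** 2 / s2.n
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (s1.n - 1) + v2 ** 2 / (s2.n - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    d = cohens_d_independent(s1, s2) * (1 if t >= 0 else -1)
    return TTestResult(float(t), float(df), float(p), float(d),
                       (float(diff - tcrit * se), float(diff + tcrit * se)), variant)


def paired_t(before, after) -> TTestResult:
    """Paired t-test on after − before; d = mean(diff) / sd(diff)."""
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.size != after.size:
        raise ValueError("paired samples must have equal length")
    if before.size < 2:
        raise ValueError("need n >= 2 pairs")
    diff = after - before
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):  # no change at all: t = 0 by convention
            return TTestResult(0.0, float(diff.size - 1), 1.0, 0.0,
                               (0.0, 0.0), "paired")
        raise ValueError("zero variance of the paired differences")
    n = diff.size
    se = sd / np.sqrt(n)
    t = diff.mean() / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    m = diff.mean()
    return TTestResult(float(t), float(df), float(p), float(m / sd),
                       (float(m - tcrit * se), float(m + tcrit * se)), "paired")


def hourly_gain_tests_fdr(gains_a: pd.DataFrame, gains_b: pd.DataFrame,
                          q: float = 0.05, variant: str = "student",
                          ) -> pd.DataFrame:
    """Per-ZT-hour independent t-tests with Benjamini-Hochberg correction.

    Inputs are wide tables (one row per subject, one column per ZT hour,
    values = hourly delta gain in p.p.). Hours with fewer than two subjects
    in either group are dropped. Adjustment spans all tested hours; the
    significance flag applies the BH criterion at rate ``q``.
    """
    hours = [h for h in gains_a.columns if h in set(gains_b.columns)]
    rows = []
    for h in hours:
        a = gains_a[h].dropna().to_numpy(float)
        b = gains_b[h].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            continue
        res = independent_t(a, b, variant=variant)
        rows.append({"zt_hour": h, "t": res.t, "df": res.df, "p_raw": res.p})
    if not rows:
        raise ValueError("no common hours with >= 2 subjects per group")
    out = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(out["p_raw"], alpha=q, method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = rej
    return out


def partial_eta_sq_from_f(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F·df1 / (F·df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("require F >= 0 and dfs >= 1")
    return float(F * df1 / (F * df1 + df2))


def two_way_anova(df: pd.DataFrame, value: str = "value",
                  factor_a: str = "genotype", factor_b: str = "treatment",
                  ) -> AnovaResult:
    """Two-way ANOVA (Type-III sums of squares) with interaction.

    Unbalanced designs are allowed; every factor cell must be non-empty.
    Reports F, p and partial eta squared per effect, plus unadjusted
    (LSD-style) pairwise cell comparisons within each level of the other
    factor, with 95% CIs from the residual mean square.
    """
    df = df.dropna(subset=[value, factor_a, factor_b]).copy()
    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    if len(levels_a) < 2 or len(levels_b) < 2 or len(counts) < len(levels_a) * len(levels_b):
        raise ValueError("empty design cell in the two-way layout")
    model = smf.ols(f"Q('{value}') ~ C(Q('{factor_a}'), Sum) * C(Q('{factor_b}'), Sum)",
                    data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    df2 = int(table.loc["Residual", "df"])
    mse = table.loc["Residual", "sum_sq"] / df2
    name_map = {}
    for idx in table.index:
        if factor_a in idx and factor_b in idx:
            name_map[idx] = f"{factor_a}:{factor_b}"
        elif factor_a in idx:
            name_map[idx] = factor_a
        elif factor_b in idx:
            name_map[idx] = factor_b
    effects = {}
    for idx, name in name_map.items():
        F = float(table.loc[idx, "F"])
        d1 = int(table.loc[idx, "df"])
        effects[name] = EffectResult(F, d1, df2, float(table.loc[idx, "PR(>F)"]),
                                     partial_eta_sq_from_f(F, d1, df2))
    cell = df.groupby([factor_a, factor_b], observed=True)[value].agg(["mean", "count"])
    tcrit = sps.t.ppf(0.975, df2)
    pairwise = []

    def _compare(label, m1, n1, m2, n2):
        se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        diff = m1 - m2
        if se == 0:
            pairwise.append(PairwiseComparison(label, float(diff),
                                               (float(diff), float(diff)),
                                               float("nan")))
            return
        t = diff / se
        pairwise.append(PairwiseComparison(
            label, float(diff), (float(diff - tcrit * se), float(diff + tcrit * se)),
            float(2.0 * sps.t.sf(abs(t), df2))))

    for a in levels_a:  # treatment effect within each genotype
        (m1, n1), (m2, n2) = (cell.loc[(a, b)] for b in levels_b[:2])
        _compare(f"{a}: {levels_b[0]} - {levels_b[1]}", m1, n1, m2, n2)
    for b in levels_b:  # genotype effect within each treatment
        (m1, n1), (m2, n2) = (cell.loc[(a, b)] for a in levels_a[:2])
        _compare(f"{b}: {levels_a[0]} - {levels_a[1]}", m1, n1, m2, n2)
    return AnovaResult(effects, pairwise, cell.reset_index(), float(mse))


def biserial_from_point_biserial(r_pb: float, n: int, n_success: int,
                                 ) -> CorrelationResult:
    """Transform a point-biserial r into the biserial r.

    r_b = r_pb · sqrt(p·(1−p)) / y, where p is the success proportion and y
    the standard-normal ordinate at the p-quantile (latent-continuum
    assumption behind the fail/success dichotomy). The p-value is carried
    through from the point-biserial t-test on n − 2 df.
    """
    if not 0 < n_success < n:
        raise ValueError("dichotomy must have both categories present")
    if abs(r_pb) > 1:
        raise ValueError("|r_pb| must be <= 1")
    p_s = n_success / n
    z = sps.norm.ppf(p_s)
    y = sps.norm.pdf(z)
    r_b = r_pb * np.sqrt(p_s * (1.0 - p_s)) / y
    if abs(r_pb) < 1:
        t = r_pb * np.sqrt((n - 2) / (1.0 - r_pb ** 2))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    else:
        p = 0.0
    return CorrelationResult("biserial", float(r_b), n, float(p),
                             r_pb=float(r_pb), p_success=float(p_s),
                             ordinate=float(y))


def biserial_corr(values, successes) -> CorrelationResult:
    """Biserial correlation from a continuous variable and a boolean dichotomy.

    Computes the point-biserial r (Pearson r against the 0/1 indicator),
    then applies the biserial transformation.
    """
    values = np.asarray(values, float)
    ind = np.asarray(successes).astype(float)
    n = values.size
    r_pb = float(np.corrcoef(values, ind)[0, 1])
    return biserial_from_point_biserial(r_pb, n, int(ind.sum()))


def pearson_corr(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult("pearson", float(res.statistic), x.size,
                             float(res.pvalue))


def screen_assumptions(groups: dict) -> AssumptionScreen:
    """Boxplot outlier fences, skewness/kurtosis and Levene's test per group.

    ``groups`` maps labels to value arrays. Outliers lie outside the
    1.5 x IQR fences of their own group; skewness and excess kurtosis are
    bias-corrected sample statistics; Levene uses the mean as center.
    """
    outliers, skews, kurts = {}, {}, {}
    arrays = []
    for label, vals in groups.items():
        v = np.asarray(vals, float)
        arrays.append(v)
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        outliers[label] = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
        skews[label] = float(sps.skew(v, bias=False)) if v.size > 2 else float("nan")
        kurts[label] = float(sps.kurtosis(v, bias=False)) if v.size > 3 else float("nan")
    if len(arrays) >= 2 and all(a.size >= 3 for a in arrays):
        if all(np.allclose(a, arrays[0]) for a in arrays[1:]) and \
           all(a.size == arrays[0].size for a in arrays[1:]):
            stat, p = 0.0, 1.0  # identical groups: no variance heterogeneity
        else:
            stat, p = sps.levene(*arrays, center="mean")
    else:
        stat, p = float("nan"), float("nan")
    return AssumptionScreen(outliers, skews, kurts, float(stat), float(p))
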