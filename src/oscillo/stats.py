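"""Group-comparison harness for cohort-level derived measures.

Two-group comparisons follow a normality-gated selection: each group is
screened with the Shapiro-Wilk test (alpha 0.05); if both pass, an F-ratio
test of variance equality chooses between Student's and Welch's t test,
otherwise the Mann-Whitney U test is used — all two-tailed.  Factorial
designs go through an ordinary two-way ANOVA with Sidak-adjusted pairwise
contrasts (adjusted p = 1 - (1-p)^m).  Animals, not trials, are the
experimental unit: trial-level values are averaged per animal before any
group test.  Linear mixed models for repeated measures are delegated to
statsmodels' MixedLM behind a thin contract (random intercept per animal,
likelihood-ratio test against the null) and are not re-implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

MEASURES = (
    "theta_power",
    "gamma_power",
    "low_gamma_power",
    "high_gamma_power",
    "mi",
    "coupling_ratio",
    "freezing_pct",
)


@dataclass(frozen=True)
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    normality_gate: dict = field(default_factory=dict)
    adjustment: str = "none"
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m."""
    if not 0 <= p <= 1:
        raise ValidationError("p must lie in [0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def _variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed F-ratio test of variance equality."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p_one = sps.f.sf(f, dfa, dfb) if f >= 1 else sps.f.cdf(f, dfa, dfb)
    return float(min(1.0, 2.0 * p_one))


def compare_two_groups(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool = False,
    alpha_gate: float = 0.05,
) -> TestReport:
    """Normality-gated two-group comparison (two-tailed throughout).

    Both groups normal by Shapiro-Wilk -> t test (Welch's variant when the
    F-ratio test rejects variance equality; paired t test when ``paired``);
    otherwise Mann-Whitney U (Wilcoxon signed-rank when ``paired``).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 values")
    if paired and len(a) != len(b):
        raise ValidationError("paired comparison needs equal-length groups")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # constant sample: treat as non-normal
        return float(sps.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    gate = {"shapiro_p_a": pa, "shapiro_p_b": pb, "alpha": alpha_gate}
    normal = pa > alpha_gate and pb > alpha_gate

    if normal:
        if paired:
            res = sps.ttest_rel(a, b)
            name = "paired t test"
            gate["variance_f_p"] = None
        else:
            p_var = _variance_f_test(a, b)
            gate["variance_f_p"] = p_var
            equal_var = p_var > alpha_gate
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            name = "Student's t test" if equal_var else "Welch's t test"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            res = sps.wilcoxon(a, b, alternative="two-sided")
            name = "Wilcoxon signed-rank test"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U test"
        stat, p = float(res.statistic), float(res.pvalue)

    return TestReport(name, stat, min(p, 1.0), (len(a), len(b)), gate)


def factorial_compare(
    table: pd.DataFrame,
    factors: tuple[str, str] = ("group", "condition"),
    value_col: str = "value",
    posthoc: str = "sidak",
) -> dict:
    """Two-way ANOVA plus Sidak-adjusted pairwise group contrasts per level.

    ``table`` is tidy: one row per observation with the two factor columns
    and ``value_col``.  Returns the ANOVA table and a contrast frame with
    raw and adjusted p-values (m = number of contrasts in the family).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    fa, fb = factors
    for f in factors:
        if table[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 levels")
    df = table.rename(columns={fa: "_A", fb: "_B", value_col: "_y"})
    model = ols("_y ~ C(_A) * C(_B)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    groups = sorted(df["_A"].unique())
    rows = []
    for level in sorted(df["_B"].unique()):
        sub = df[df["_B"] == level]
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1 :]:
                x = sub.loc[sub["_A"] == g1, "_y"].to_numpy()
                y = sub.loc[sub["_A"] == g2, "_y"].to_numpy()
                rep = compare_two_groups(x, y)
                rows.append((level, g1, g2, rep.test_name, rep.p_value))
    contrasts = pd.DataFrame(
        rows, columns=[fb, f"{fa}_1", f"{fa}_2", "test", "p_raw"]
    )
    m = len(contrasts)
    if posthoc == "sidak":
        contrasts["p_adj"] = [sidak_adjust(p, m) for p in contrasts["p_raw"]]
    elif posthoc == "none":
        contrasts["p_adj"] = contrasts["p_raw"]
    else:
        raise ValidationError(f"unknown posthoc {posthoc!r}")
    return {"anova": anova, "contrasts": contrasts, "m": m}


def mixed_model_lrt(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    animal_col: str = "animal_id",
) -> TestReport:
    """Linear mixed model with random intercept per animal; LRT for group.

    Thin contract over statsmodels MixedLM: fixed effect of group, random
    intercept per animal, likelihood-ratio test (ML fits) against the
    no-group null.
    """
    import statsmodels.formula.api as smf

    df = table.rename(
        columns={value_col: "_y", group_col: "_g", animal_col: "_animal"}
    )
    full = smf.mixedlm("_y ~ C(_g)", df, groups=df["_animal"]).fit(reml=False)
    null = smf.mixedlm("_y ~ 1", df, groups=df["_animal"]).fit(reml=False)
    lr = 2.0 * (full.llf - null.llf)
    dof = df["_g"].nunique() - 1
    p = float(sps.chi2.sf(max(lr, 0.0), dof))
    return TestReport(
        "mixed model LRT", float(lr), p,
        tuple(df.groupby("_g")["_animal"].nunique()),
        detail={"df": dof},
    )


def power_recovery_report(
    make_cohort_measures,
    n_reps: int = 100,
    alpha: float = 0.05,
    master_seed: int = 0,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Detection/sign-recovery rates of the pipeline over replicate cohorts.

    ``make_cohort_measures(seed)`` must return a tidy frame with columns
    ``group``, ``measure``, ``value`` (one row per animal x measure) with
    exactly two groups.  ``reference_group`` names the group expected to be
    unaffected/higher (default: first group alphabetically).  For each
    measure the report gives the fraction of replicates where the
    non-reference group mean is lower (sign recovery) and where the gated
    two-group test is significant at ``alpha``.
    """
    if n_reps < 50:
        raise ValidationError("need at least 50 replicates for stable rates")
    counters: dict[str, dict[str, int]] = {}
    for rep in range(n_reps):
        df = make_cohort_measures(master_seed + rep)
        groups = sorted(df["group"].unique())
        if len(groups) != 2:
            raise ValidationError("power report expects exactly two groups")
        if reference_group is None:
            ref, other = groups
        else:
            if reference_group not in groups:
                raise ValidationError(f"reference group {reference_group!r} not in {groups}")
            ref = reference_group
            other = groups[1 - groups.index(ref)]
        for measure, sub in df.groupby("measure"):
            x = sub.loc[sub["group"] == ref, "value"].to_numpy()
            y = sub.loc[sub["group"] == other, "value"].to_numpy()
            c = counters.setdefault(measure, {"sign": 0, "detect": 0})
            if y.mean() < x.mean():
                c["sign"] += 1
            if compare_two_groups(x, y).p_value < alpha:
                c["detect"] += 1
    rows = [
        (measure, c["sign"] / n_reps, c["detect"] / n_reps, n_reps)
        for measure, c in sorted(counters.items())
    ]
    return pd.DataFrame(
        rows, columns=["measure", "sign_recovery_rate", "detection_rate", "n_reps"]
    )
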