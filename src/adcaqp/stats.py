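"""The statistical battery applied to the cohort feature table.

Reliability (two-way random-effects absolute-agreement single-measures
ICC, with ICC >= 0.75 read as good reliability), Kolmogorov-Smirnov
normality, one-way ANOVA with Fisher's LSD post hoc under a Bonferroni
family threshold (alpha / number of pairwise comparisons, 0.05/3 = 0.017
for three differentiation groups), Pearson correlation of matched
histogram features, and independent t-tests for the two-level stage
contrasts. All p-values are two-sided; the omnibus alpha is 0.05.

scipy.stats provides the classical distributions and tests; ICC and the
LSD pairwise machinery are computed here from the subjects x raters /
groups mean-squares decompositions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "ICCResult",
    "icc_two_observers",
    "ks_normality",
    "one_way_anova",
    "lsd_posthoc",
    "pearson",
    "independent_t_test",
    "analyze_cohort",
]

GOOD_RELIABILITY_ICC = 0.75


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model_label: str
    reliability_label: str
    defined: bool = True


def icc_two_observers(ratings) -> ICCResult:
    """Inter-observer agreement of an n-subjects x k-raters rating matrix.

    Two-way random-effects, absolute-agreement, single-measures ICC —
    ICC(2,1) in the Shrout-Fleiss taxonomy — computed from the mean squares
    of the subjects x raters decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Labelled "good" when ICC >= 0.75, else "poor"; with zero
    between-subject variance the coefficient is undefined and flagged.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n_subjects, >=2 raters) matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - gm) ** 2).sum()
    ssc = n * ((col_means - gm) ** 2).sum()
    sst = ((x - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    model = "two-way random effects, absolute agreement, single measures (ICC2,1)"
    if msr <= 0:
        return ICCResult(icc=float("nan"), model_label=model,
                         reliability_label="undefined", defined=False)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    label = "good" if icc >= GOOD_RELIABILITY_ICC else "poor"
    return ICCResult(icc=float(icc), model_label=model, reliability_label=label)


def ks_normality(values):
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD).

    Returns ``(statistic, p)`` where the statistic is the sup-distance
    between the empirical CDF and the fitted normal CDF.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError(f"KS normality test needs n >= 5, got {values.size}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("KS normality test is undefined for a constant sample")
    res = sps.kstest(values, "norm", args=(values.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups):
    """Classic one-way ANOVA; returns ``(F, p)``.

    F is the between/within mean-square ratio with p from the F
    distribution. Identical constant groups give F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has n = {g.size} < 2")
    allv = np.concatenate(groups)
    gm = allv.mean()
    ssb = sum(g.size * (g.mean() - gm) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (float("inf"), 0.0)
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def lsd_posthoc(groups, family_alpha: float = 0.05, n_comparisons: int = None,
                labels=None):
    """Fisher's LSD pairwise comparisons after an omnibus ANOVA.

    Each pair is tested with a t statistic using the pooled within-group
    mean square (df = N - k); the significance flag compares the pairwise p
    against the Bonferroni threshold family_alpha / n_comparisons, reported
    rounded to 3 decimals.

    Returns ``(pairs, threshold)`` where pairs is a list of dicts with
    keys pair, t, p, significant.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("post hoc comparison needs at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has n = {g.size} < 2")
    all_pairs = list(combinations(range(k), 2))
    if n_comparisons is None:
        n_comparisons = len(all_pairs)
    if n_comparisons <= 0:
        raise ValueError("n_comparisons must be positive")
    threshold = round(family_alpha / n_comparisons, 3)
    ntot = sum(g.size for g in groups)
    df = ntot - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    if labels is None:
        labels = [str(i) for i in range(k)]
    out = []
    for i, j in all_pairs:
        diff = groups[i].mean() - groups[j].mean()
        se = np.sqrt(msw * (1.0 / groups[i].size + 1.0 / groups[j].size))
        if se == 0.0:
            t = 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
        else:
            t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        out.append({"pair": (labels[i], labels[j]), "t": float(t), "p": p,
                    "significant": bool(p < threshold)})
    return out, threshold


def pearson(x, y):
    """Pearson product-moment correlation; two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation is undefined for a constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def independent_t_test(a, b, variant: str = "student"):
    """Two-sided independent-samples t-test; pooled-variance by default.

    ``variant="welch"`` switches to the unequal-variance form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean())) * float("inf"), 0.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

_LABEL_COLS = ("differentiation", "t_stage", "n_status")
_DIFF_ORDER = ("good", "moderate", "poor")


def analyze_cohort(table: pd.DataFrame, family_alpha: float = 0.05,
                   alpha: float = 0.05, t_variant: str = "student") -> dict:
    """Run the full statistical battery on a cohort feature table.

    Expects columns ``adc_<feature>`` and ``ihc_<feature>`` for the eight
    histogram features, ``manual_score``, and the label columns
    ``differentiation`` (good/moderate/poor), ``t_stage`` (T1-2/T3-4) and
    ``n_status`` (N-/N+).

    Returns a dict of tidy DataFrames:

    * ``correlations`` — Pearson r/p of each ADC feature against its
      like-named IHC feature, plus mean ADC vs manual score;
    * ``differentiation_anova`` — per-feature group mean ± SD, omnibus
      F/p, and LSD pairwise p-values flagged at the Bonferroni threshold;
    * ``stage_tests`` — per-feature t-tests for T stage and nodal status;
    * ``thresholds`` — every alpha/threshold applied.
    """
    if len(table) < 2:
        raise ValueError("cohort table needs at least two subjects")
    for col in _LABEL_COLS:
        if col not in table.columns:
            raise ValueError(f"missing label column: {col!r}")
    for f in FEATURE_NAMES:
        for pre in ("adc_", "ihc_"):
            if f"{pre}{f}" not in table.columns:
                raise ValueError(f"missing feature column: {pre}{f!r}")

    corr_rows = []
    for f in FEATURE_NAMES:
        r, p = pearson(table[f"adc_{f}"], table[f"ihc_{f}"])
        corr_rows.append({"feature": f, "pair": f"adc_{f} vs ihc_{f}",
                          "r": r, "p": p, "significant": p < alpha})
    if "manual_score" in table.columns:
        r, p = pearson(table["adc_mean"], table["manual_score"])
        corr_rows.append({"feature": "manual_score",
                          "pair": "adc_mean vs manual_score",
                          "r": r, "p": p, "significant": p < alpha})
    correlations = pd.DataFrame(corr_rows)

    groups_by_label = {g: table[table["differentiation"] == g] for g in _DIFF_ORDER}
    present = [g for g in _DIFF_ORDER if len(groups_by_label[g]) >= 2]
    if len(present) < 2:
        raise ValueError("need at least two differentiation groups with n >= 2")
    anova_rows = []
    bonf_threshold = None
    for f in FEATURE_NAMES:
        groups = [groups_by_label[g][f"adc_{f}"].to_numpy() for g in present]
        fstat, pval = one_way_anova(groups)
        pairs, bonf_threshold = lsd_posthoc(groups, family_alpha=family_alpha,
                                            labels=present)
        row = {"feature": f}
        for g, vals in zip(present, groups):
            row[f"mean_{g}"] = float(np.mean(vals))
            row[f"sd_{g}"] = float(np.std(vals, ddof=1))
        row.update({"F": fstat, "p": pval, "significant": pval < alpha})
        for pr in pairs:
            tag = f"{pr['pair'][0]}_vs_{pr['pair'][1]}"
            row[f"p_{tag}"] = pr["p"]
            row[f"sig_{tag}"] = pr["significant"]
        anova_rows.append(row)
    anova = pd.DataFrame(anova_rows)

    stage_rows = []
    for col, lv in (("t_stage", ("T1-2", "T3-4")), ("n_status", ("N-", "N+"))):
        a_tab = table[table[col] == lv[0]]
        b_tab = table[table[col] == lv[1]]
        for f in FEATURE_NAMES:
            a = a_tab[f"adc_{f}"].to_numpy()
            b = b_tab[f"adc_{f}"].to_numpy()
            t, p = independent_t_test(a, b, variant=t_variant)
            stage_rows.append({
                "contrast": col, "feature": f,
                f"mean_{lv[0]}": float(np.mean(a)), f"sd_{lv[0]}": float(np.std(a, ddof=1)),
                f"mean_{lv[1]}": float(np.mean(b)), f"sd_{lv[1]}": float(np.std(b, ddof=1)),
                "t": t, "p": p, "significant": p < alpha,
            })
    stage = pd.DataFrame(stage_rows)

    thresholds = {"alpha": alpha, "family_alpha": family_alpha,
                  "bonferroni_pairwise_threshold": bonf_threshold,
                  "icc_good_reliability": GOOD_RELIABILITY_ICC,
                  "t_test_variant": t_variant}
    return {"correlations": correlations, "differentiation_anova": anova,
            "stage_tests": stage, "thresholds": thresholds}
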