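"""Nonparametric statistics, correlation, power planning and the NPI.

The analysis layer mirrors a three-contrast design per measure: a paired
Wilcoxon signed-rank test within participants (peri-tumoural rim vs whole
breast), and Mann-Whitney U tests of each of those against the control
whole breast, with Bonferroni correction over the three comparisons
(alpha/3, displayed as 0.017).  Spearman rank correlations against tumour
covariates carry Fisher-z confidence intervals.  Sample-size planning uses
Cohen's d with the noncentral-t power function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "spearman_ci",
    "bonferroni_threshold",
    "cohens_d",
    "sample_size_two_sample_t",
    "npi",
    "fishers_exact",
    "CorrelationResult",
    "run_study_comparisons",
]


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y):
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    Exact null distribution when both samples have at most 12 observations
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    exact = x.size <= 12 and y.size <= 12 and not _has_ties(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(paired_x, paired_y):
    """Two-sided Wilcoxon signed-rank test for paired samples; ``(W, p)``.

    Zero differences are dropped; the exact distribution is used for up to
    25 nonzero untied differences, the tie-corrected normal approximation
    (with continuity correction) otherwise.  If every difference is zero the
    test is vacuous and ``(0, 1.0)`` is returned.
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method="exact" if exact else "asymptotic",
                       correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    r_s: float
    ci_low: float
    ci_high: float
    n: int
    covariate: str = ""


def spearman_ci(x, y, level: float = 0.95,
                covariate: str = "") -> CorrelationResult:
    """Spearman rank correlation with a Fisher-z confidence interval.

    r_s is the Pearson correlation of mid-ranks; the CI transforms
    z = atanh(r_s) with standard error 1/sqrt(n-3) and back-transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("at least 4 observations are required")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    r = float(sps.spearmanr(x, y).statistic)
    if abs(r) >= 1.0:
        lo, hi = (r, r)
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(x.size - 3)
        zc = sps.norm.ppf(0.5 + level / 2.0)
        lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    return CorrelationResult(r, lo, hi, int(x.size), covariate)


def bonferroni_threshold(alpha: float = 0.05, k: int = 3) -> float:
    """Per-comparison significance threshold alpha/k (unrounded).

    Displayed rounded to three decimals (0.05/3 -> ``0.017``) but comparisons
    must use the exact value.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / k


def cohens_d(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Absolute standardised mean difference with (n-1)-weighted pooled SD."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                       / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return abs(mean1 - mean2) / pooled


def _t_power(n: int, d: float, alpha: float, two_sided: bool) -> float:
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    if two_sided:
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        upper = sps.nct.sf(tc, df, nc)
        lower = sps.nct.cdf(-tc, df, nc)
        if math.isnan(lower):  # far-tail underflow at large noncentrality
            lower = 0.0
        return float(upper + lower)
    tc = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(tc, df, nc))


def sample_size_two_sample_t(d: float, power: float = 0.80,
                             alpha: float = 0.05,
                             two_sided: bool = True,
                             n_max: int = 10_000) -> int:
    """Smallest per-group n whose two-sample t-test power reaches ``power``.

    Power is evaluated from the noncentral-t distribution with
    noncentrality d*sqrt(n/2) and 2n-2 degrees of freedom.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not alpha < power < 1:
        raise ValueError("power must lie in (alpha, 1)")
    for n in range(2, n_max + 1):
        if _t_power(n, d, alpha, two_sided) >= power:
            return n
    raise ValueError(f"requested power not reachable with n <= {n_max}")


def npi(grade: int, node_category: int, size_cm: float) -> float:
    """Nottingham Prognostic Index: grade + nodal category + 0.2 * size (cm).

    Grade and nodal category are 1-3 (nodal: 1 negative, 2 for 1-3 positive
    nodes, 3 for more); size must be positive.
    """
    if grade not in (1, 2, 3):
        raise ValueError("grade must be 1, 2 or 3")
    if node_category not in (1, 2, 3):
        raise ValueError("node category must be 1, 2 or 3")
    if size_cm <= 0:
        raise ValueError("tumour size must be positive (cm)")
    return grade + node_category + 0.2 * size_cm


def fishers_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table (utility for demographics)."""
    res = sps.fisher_exact(np.asarray(table))
    return float(res[0]), float(res[1])


CONTRASTS = ("Peri-P vs WB-P", "Peri-P vs WB-C", "WB-P vs WB-C")


def run_study_comparisons(profile_table: pd.DataFrame,
                          alpha: float = 0.05,
                          k: int = 3,
                          covariates: pd.DataFrame | None = None):
    """The study's three contrasts per lipid and measure, plus correlations.

    ``profile_table`` is tidy with columns ``subject``, ``region`` (Peri-P /
    WB-P / WB-C), ``lipid`` and the five measures.  The paired Wilcoxon test
    handles Peri-P vs WB-P (matched within participant); Mann-Whitney U
    handles the two contrasts against the control whole breast.  Significance
    is flagged at the Bonferroni threshold alpha/k.

    ``covariates`` (optional) is indexed by participant ``subject`` with one
    column per covariate (e.g. tumour size, Ki-67, CD163); Peri-P measures
    are Spearman-correlated against each.

    Returns ``(comparisons, correlations)`` DataFrames (the latter empty
    without covariates).
    """
    thr = bonferroni_threshold(alpha, k)
    profile_table = profile_table.copy()
    if "flags" in profile_table.columns:
        # under-sized regions: higher-order measures excluded from testing
        small = profile_table["flags"].fillna("").str.contains(
            "below-min-voxels")
        for m in ("skewness", "entropy", "kurtosis"):
            if m in profile_table.columns:
                profile_table.loc[small, m] = np.nan
    measures = [m for m in ("mean", "median", "skewness", "entropy", "kurtosis")
                if m in profile_table.columns]
    rows = []
    for lipid, sub in profile_table.groupby("lipid", sort=False):
        regions = {r: g.set_index("subject") for r, g in sub.groupby("region")}
        for measure in measures:
            def vals(region):
                if region not in regions:
                    return None
                v = regions[region][measure].dropna()
                return v if len(v) else None

            peri, wbp, wbc = vals("Peri-P"), vals("WB-P"), vals("WB-C")
            for contrast in CONTRASTS:
                a_name, b_name = contrast.split(" vs ")
                a = {"Peri-P": peri, "WB-P": wbp, "WB-C": wbc}[a_name]
                b = {"Peri-P": peri, "WB-P": wbp, "WB-C": wbc}[b_name]
                if a is None or b is None:
                    continue
                if contrast == "Peri-P vs WB-P":
                    common = a.index.intersection(b.index)
                    if len(common) == 0:
                        raise ValueError(
                            "paired contrast requires matched participants")
                    stat, p = wilcoxon_signed_rank(a.loc[common].to_numpy(),
                                                   b.loc[common].to_numpy())
                    test = "wilcoxon"
                    n = len(common)
                else:
                    stat, p = mann_whitney_u(a.to_numpy(), b.to_numpy())
                    test = "mann-whitney"
                    n = len(a) + len(b)
                rows.append({
                    "lipid": lipid, "measure": measure, "contrast": contrast,
                    "test": test, "n": n, "statistic": stat, "p_value": p,
                    "significant": p < thr,
                })
    comparisons = pd.DataFrame(rows)

    corr_rows = []
    if covariates is not None:
        peri_tab = profile_table[profile_table["region"] == "Peri-P"]
        for lipid, sub in peri_tab.groupby("lipid", sort=False):
            sub = sub.set_index("subject")
            for measure in measures:
                for cov in covariates.columns:
                    joined = pd.concat([sub[measure], covariates[cov]],
                                       axis=1, join="inner").dropna()
                    if len(joined) < 4:
                        continue
                    r = spearman_ci(joined.iloc[:, 0], joined.iloc[:, 1],
                                    covariate=cov)
                    corr_rows.append({
                        "lipid": lipid, "measure": measure, "covariate": cov,
                        "r_s": r.r_s, "ci_low": r.ci_low, "ci_high": r.ci_high,
                        "n": r.n,
                    })
    correlations = pd.DataFrame(corr_rows)
    return comparisons, correlations
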