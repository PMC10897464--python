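"""Statistical layer against enumeration and definitional oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from perilipid.stats import (bonferroni_threshold, cohens_d, fishers_exact,
                             mann_whitney_u, npi, run_study_comparisons,
                             sample_size_two_sample_t, spearman_ci,
                             wilcoxon_signed_rank)


# ---------------------------------------------------------------- oracles

def mwu_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all labelings."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    u_lo = min(u_obs, n1 * n2 - u_obs)
    total = hits = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = u_of(combo)
        total += 1
        if u <= u_lo or u >= n1 * n2 - u_lo:
            hits += 1
    return hits / total


def wilcoxon_enumeration_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d < 0].sum()
    w_max = ranks.sum()
    w_lo = min(w_obs, w_max - w_obs)
    total = hits = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if w <= w_lo + 1e-9 or w >= w_max - w_lo - 1e-9:
            hits += 1
    return hits / total


# ----------------------------------------------------------- Mann-Whitney

def test_mwu_separated_samples_enumerated():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    u, p = mann_whitney_u(x, y)
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)
    assert p == pytest.approx(mwu_enumeration_p(np.array(x), np.array(y)))


def test_mwu_identical_samples_give_p_one():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    _, p = mann_whitney_u(x, x + 10 - 10)
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(6))
def test_mwu_matches_enumeration_for_small_samples(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(3, 8, size=2)
    x = rng.normal(0, 1, n1)
    y = rng.normal(0.5, 1, n2)
    _, p = mann_whitney_u(x, y)
    assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)


def test_mwu_empty_sample_is_an_error():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# --------------------------------------------------------------- Wilcoxon

def test_wilcoxon_all_positive_differences_enumerated():
    x = np.array([2.0, 3.0, 4.0, 5.0])
    y = np.array([1.0, 1.0, 1.0, 1.0])
    w, p = wilcoxon_signed_rank(x, y)
    assert w == 0.0  # negative-rank sum
    assert p == pytest.approx(0.125, abs=1e-12)
    assert p == pytest.approx(wilcoxon_enumeration_p(x - y))


def test_wilcoxon_antisymmetric_differences_give_p_one():
    _, p = wilcoxon_signed_rank([1.0, -1.0], [0.0, 0.0])
    assert p == pytest.approx(1.0)


def test_wilcoxon_all_zero_differences_flagged_p_one():
    w, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    assert p == 1.0


@pytest.mark.parametrize("seed", range(6))
def test_wilcoxon_matches_enumeration_for_small_samples(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(4, 9))
    d = rng.normal(0.3, 1, n)
    _, p = wilcoxon_signed_rank(d, np.zeros(n))
    assert p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)


# --------------------------------------------------------------- Spearman

def test_spearman_monotone_pairs():
    x = np.arange(12.0)
    r = spearman_ci(x, np.exp(x))
    assert r.r_s == pytest.approx(1.0)
    r2 = spearman_ci(x, -x ** 3)
    assert r2.r_s == pytest.approx(-1.0)


def test_spearman_equals_rank_then_pearson():
    rng = np.random.default_rng(17)
    x, y = rng.normal(size=12), rng.normal(size=12)
    r = spearman_ci(x, y)
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert r.r_s == pytest.approx(oracle, abs=1e-12)
    assert r.ci_low <= r.r_s <= r.ci_high
    # Fisher-z endpoints
    z, se = math.atanh(oracle), 1 / math.sqrt(12 - 3)
    assert r.ci_low == pytest.approx(math.tanh(z - 1.959963984540054 * se))


def test_spearman_constant_vector_is_an_error():
    with pytest.raises(ValueError):
        spearman_ci(np.ones(6), np.arange(6.0))


# ----------------------------------------------- planning arithmetic, NPI

def test_bonferroni_threshold_values():
    t = bonferroni_threshold(0.05, 3)
    assert f"{t:.3f}" == "0.017"
    assert t == pytest.approx(0.05 / 3)
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.01, 5) == pytest.approx(0.002)


def test_cohens_d_examples():
    assert cohens_d(0.40, 0.01, 12, 0.38, 0.02, 12) == pytest.approx(
        0.02 / math.sqrt((0.01 ** 2 + 0.02 ** 2) / 2))
    assert cohens_d(0.5, 0.1, 10, 0.5, 0.1, 10) == 0.0
    assert cohens_d(1.0, 0.2, 8, 0.8, 0.2, 8) == pytest.approx(1.0)


def test_sample_size_matches_brute_force_power_scan():
    def power(n, d, alpha=0.05):
        from scipy import stats as sps
        df, nc = 2 * n - 2, d * math.sqrt(n / 2)
        tc = sps.t.ppf(1 - alpha / 2, df)
        return 1 - sps.nct.cdf(tc, df, nc) + sps.nct.cdf(-tc, df, nc)

    for d in (0.5, 0.8, 1.2, 2.0):
        n = sample_size_two_sample_t(d)
        assert power(n, d) >= 0.80
        assert n == 2 or power(n - 1, d) < 0.80


def test_sample_size_monotonicity_and_limits():
    # d large enough that even df=2 has full power -> minimum feasible n
    assert sample_size_two_sample_t(50.0) == 2
    assert (sample_size_two_sample_t(0.5)
            >= sample_size_two_sample_t(0.8)
            >= sample_size_two_sample_t(1.2))
    assert (sample_size_two_sample_t(0.8, power=0.9)
            >= sample_size_two_sample_t(0.8, power=0.8))


def test_npi_formula_and_validation():
    assert npi(3, 2, 2.4) == pytest.approx(5.48)
    assert npi(2, 1, 1.2) == pytest.approx(3.24)
    with pytest.raises(ValueError):
        npi(1, 1, 0.0)
    with pytest.raises(ValueError):
        npi(4, 1, 1.0)


def test_fishers_exact_utility():
    _, p = fishers_exact([[8, 2], [1, 5]])
    assert 0 <= p <= 1


# -------------------------------------------------------- study plumbing

def _profile_frame(rng, n_part=5, n_ctrl=5, shift=0.0):
    rows = []
    for i in range(n_part):
        base = rng.normal(0.42, 0.01)
        rows.append({"subject": f"P{i}", "region": "Peri-P", "lipid": "MUFA",
                     "mean": base - shift + rng.normal(0, 0.005)})
        rows.append({"subject": f"P{i}", "region": "WB-P", "lipid": "MUFA",
                     "mean": base + rng.normal(0, 0.005)})
    for i in range(n_ctrl):
        rows.append({"subject": f"C{i}", "region": "WB-C", "lipid": "MUFA",
                     "mean": rng.normal(0.42, 0.01)})
    return pd.DataFrame(rows)


def test_single_measure_input_yields_three_contrast_rows():
    comp, corr = run_study_comparisons(_profile_frame(np.random.default_rng(0)))
    assert len(comp) == 3
    assert set(comp["contrast"]) == {"Peri-P vs WB-P", "Peri-P vs WB-C",
                                     "WB-P vs WB-C"}
    assert corr.empty


def test_bonferroni_flag_is_subset_of_uncorrected():
    comp, _ = run_study_comparisons(
        _profile_frame(np.random.default_rng(1), shift=0.05))
    assert ((~comp["significant"]) | (comp["p_value"] < 0.05)).all()


def test_correlations_against_covariates():
    rng = np.random.default_rng(2)
    table = _profile_frame(rng, n_part=8)
    cov = pd.DataFrame({"tumour_size_cm":
                        table[table.region == "Peri-P"]["mean"].to_numpy() * 10},
                       index=[f"P{i}" for i in range(8)])
    _, corr = run_study_comparisons(table, covariates=cov)
    assert len(corr) == 1
    assert corr.iloc[0]["r_s"] == pytest.approx(1.0)


def test_mann_whitney_power_near_planning_target():
    """Two-sample shift of d = 1.2 at n = 12/group: the Mann-Whitney
    rejection rate sits near the 80% planning power (Pitman efficiency
    vs the t-test ~0.95)."""
    rng = np.random.default_rng(123)
    rejections = 0
    reps = 4000
    for _ in range(reps):
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(1.2, 1.0, 12)
        _, p = mann_whitney_u(x, y)
        rejections += p < 0.05
    assert rejections / reps == pytest.approx(0.80, abs=0.05)
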